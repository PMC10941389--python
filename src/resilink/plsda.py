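"""PLS-DA classification of resilience classes from CLR microbiome profiles.

Workflow (all seeded and deterministic):

1. ``stratified_split`` — 50/50 train/test allocation preserving every
   breed x class stratum;
2. ``select_components`` — repeated stratified 4-fold cross-validation
   (default 50 repeats); the component count maximising the mean macro
   one-vs-rest AUC wins, ties going to the smaller model;
3. ``recursive_vip_elimination`` — iteratively drop the lowest 20% of
   features by variable importance in projection (VIP), refit, track the
   CV AUC, and return the iteration with the best AUC;
4. ``evaluate`` — held-out per-class one-vs-rest ROC/AUC, macro AUC, a
   3x3 confusion matrix from argmax class scores, and a one-sided
   Mann-Whitney test of class scores (the Wilcoxon significance of each
   class AUC).

The PLS2 fit itself (one-hot class indicators regressed on the centred,
scaled feature matrix by NIPALS) is delegated to scikit-learn's
``PLSRegression``; everything around it — VIP, pruning, evaluation — lives
here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold

VIP_DROP_FRACTION = 0.2
MIN_FEATURES = 5


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def stratified_split(
    meta: pd.DataFrame,
    fraction: float = 0.5,
    seed: int | None = None,
    breed_col: str = "breed",
    class_col: str = "label",
) -> tuple[pd.Index, pd.Index]:
    """Disjoint, exhaustive train/test split within breed x class cells.

    Each cell of n samples contributes ceil(n*fraction) or floor(n*fraction)
    to the training set, the odd unit decided by a seeded coin flip.
    """
    cross = pd.crosstab(meta[breed_col], meta[class_col])
    if (cross == 0).any().any():
        empty = [
            (b, c)
            for b in cross.index
            for c in cross.columns
            if cross.loc[b, c] == 0
        ]
        raise ValueError(f"empty breed x class strata: {empty}")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for (_, _), cell in meta.groupby([breed_col, class_col], sort=True):
        idx = cell.index.to_numpy()
        rng.shuffle(idx)
        n_train = len(idx) * fraction
        n_train = int(math.floor(n_train) + (rng.random() < (n_train % 1)))
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return pd.Index(train), pd.Index(test)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class PLSDAClassifier:
    """PLS2 on one-hot class labels; class score = indicator regression
    output, predicted label = argmax score.

    Features are centred and unit-variance scaled from the training data;
    zero-variance features are dropped with a warning.
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "PLSDAClassifier":
        y = pd.Series(np.asarray(y), index=X.index)
        self.classes_ = np.array(sorted(y.unique()))
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        keep = X.std(axis=0, ddof=0) > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} zero-variance features")
        self.feature_names_ = X.columns[keep]
        xm = X.loc[:, self.feature_names_].to_numpy(dtype=float)
        ym = (y.to_numpy()[:, None] == self.classes_[None, :]).astype(float)
        n_comp = min(self.n_components, xm.shape[1], len(xm) - 1)
        self._pls = PLSRegression(n_components=n_comp, scale=self.scale)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._pls.fit(xm, ym)
        self.n_components_ = n_comp
        self.x_weights_ = self._pls.x_weights_
        self.x_scores_ = self._pls.x_scores_
        self.y_loadings_ = self._pls.y_loadings_
        return self

    def decision_scores(self, X: pd.DataFrame) -> pd.DataFrame:
        scores = self._pls.predict(X.loc[:, self.feature_names_].to_numpy(dtype=float))
        return pd.DataFrame(scores, index=X.index, columns=self.classes_)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        scores = self.decision_scores(X)
        return pd.Series(
            self.classes_[scores.to_numpy().argmax(axis=1)], index=X.index
        )


def vip_scores(model: PLSDAClassifier) -> pd.Series:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a [ SSY_a * (w_ja/||w_a||)^2 ] / sum_a SSY_a )
    with SSY_a the Y-variance explained by component a; normalised so the
    mean squared VIP equals one.
    """
    w = model.x_weights_          # p x A
    t = model.x_scores_           # n x A
    q = model.y_loadings_         # k x A
    p, a = w.shape
    ssy = np.sum(q**2, axis=0) * np.sum(t**2, axis=0)  # per-component
    wn = w / np.linalg.norm(w, axis=0, keepdims=True)
    vip = np.sqrt(p * (wn**2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=model.feature_names_)


# ---------------------------------------------------------------------------
# AUC helpers
# ---------------------------------------------------------------------------

def auc_mannwhitney(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """One-vs-rest AUC via the Mann-Whitney U identity (half credit for
    ties); equals the trapezoidal ROC area."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        return math.nan
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (len(pos) * len(neg)))


def _macro_auc(scores: pd.DataFrame, y: pd.Series) -> float:
    aucs = []
    for c in scores.columns:
        mask = (y == c).to_numpy()
        if mask.all() or not mask.any():
            continue
        s = scores[c].to_numpy()
        aucs.append(auc_mannwhitney(s[mask], s[~mask]))
    return float(np.mean(aucs)) if aucs else math.nan


# ---------------------------------------------------------------------------
# component selection and feature elimination
# ---------------------------------------------------------------------------

def cv_macro_auc(
    X: pd.DataFrame,
    y: pd.Series,
    n_components: int,
    folds: int = 4,
    repeats: int = 50,
    seed: int | None = None,
) -> float:
    """Mean held-out macro AUC over repeated stratified K-fold CV."""
    y = pd.Series(np.asarray(y), index=X.index)
    folds = min(folds, y.value_counts().min())
    if folds < 2:
        raise ValueError("each class needs at least 2 samples for CV")
    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=seed
    )
    aucs = []
    xi = X.reset_index(drop=True)
    yi = y.reset_index(drop=True)
    for tr, te in splitter.split(xi, yi):
        model = PLSDAClassifier(n_components=n_components).fit(xi.iloc[tr], yi.iloc[tr])
        scores = model.decision_scores(xi.iloc[te])
        auc = _macro_auc(scores, yi.iloc[te])
        if not math.isnan(auc):
            aucs.append(auc)
    return float(np.mean(aucs))


def select_components(
    X: pd.DataFrame,
    y: pd.Series,
    max_comp: int = 5,
    folds: int = 4,
    repeats: int = 50,
    seed: int | None = None,
) -> tuple[int, pd.Series]:
    """AUC-driven component choice; ties favour fewer components."""
    if max_comp < 1:
        raise ValueError("max_comp must be >= 1")
    table = {}
    for k in range(1, max_comp + 1):
        table[k] = cv_macro_auc(X, y, k, folds=folds, repeats=repeats, seed=seed)
    table = pd.Series(table, name="cv_macro_auc")
    best = int(table.idxmax())  # idxmax takes the first (smallest) maximiser
    return best, table


@dataclass
class EliminationResult:
    model: PLSDAClassifier
    features: pd.Index
    feature_trajectory: list
    auc_trajectory: list
    best_iteration: int


def recursive_vip_elimination(
    X: pd.DataFrame,
    y: pd.Series,
    n_components: int,
    folds: int = 4,
    repeats: int = 50,
    seed: int | None = None,
    drop_fraction: float = VIP_DROP_FRACTION,
    min_features: int = MIN_FEATURES,
    vip_mode: str = "quantile",
) -> EliminationResult:
    """Iteratively prune the lowest-VIP features and keep the best model.

    Per iteration the lowest 20% of features are removed — by feature count
    (``vip_mode='quantile'``, at least one) or by cumulative share of the
    total squared VIP (``vip_mode='share'``) — the model is refitted and its
    CV macro AUC recorded.  Pruning stops on the first non-improvement or
    when fewer than ``min_features`` would remain; the iteration with the
    maximal CV AUC is returned.
    """
    y = pd.Series(np.asarray(y), index=X.index)
    features = X.columns
    feature_traj, auc_traj, models = [], [], []
    while True:
        auc = cv_macro_auc(X[features], y, n_components, folds, repeats, seed)
        model = PLSDAClassifier(n_components=n_components).fit(X[features], y)
        feature_traj.append(features)
        auc_traj.append(auc)
        models.append(model)
        if len(auc_traj) >= 2 and auc_traj[-1] <= auc_traj[-2]:
            break
        if len(features) < min_features:
            break
        vip = vip_scores(model).sort_values()
        if vip_mode == "share":
            cum = (vip**2).cumsum() / (vip**2).sum()
            drop = vip.index[cum <= drop_fraction]
            if len(drop) == 0:
                drop = vip.index[:1]
        else:
            n_drop = max(1, int(math.floor(drop_fraction * len(features))))
            drop = vip.index[:n_drop]
        features = features.difference(drop, sort=False)
        if len(features) < 2:
            break
    best = int(np.argmax(auc_traj))
    return EliminationResult(
        model=models[best],
        features=feature_traj[best],
        feature_trajectory=[list(f) for f in feature_traj],
        auc_trajectory=auc_traj,
        best_iteration=best,
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class PlsdaEvaluation:
    per_class_auc: pd.Series
    overall_auc: float
    confusion: pd.DataFrame  # rows = true, cols = predicted
    wilcoxon_p: pd.Series
    incidence: pd.Series
    roc_curves: dict = field(repr=False, default=None)

    def summary(self) -> str:
        table = pd.DataFrame(
            {
                "AUC class": self.per_class_auc,
                "Incidence": self.incidence,
                "P-value": self.wilcoxon_p,
            }
        )
        return (
            f"PLS-DA held-out evaluation (overall macro AUC {self.overall_auc:.3f})\n"
            + table.to_string(float_format=lambda v: f"{v:.3f}")
            + "\nConfusion (true x predicted):\n"
            + self.confusion.to_string()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.per_class_auc.index,
                "auc_class": self.per_class_auc.to_numpy(),
                "incidence": self.incidence.reindex(self.per_class_auc.index).to_numpy(),
                "p_value": self.wilcoxon_p.reindex(self.per_class_auc.index).to_numpy(),
                "auc_all_classes": self.overall_auc,
            }
        )


def evaluate(model: PLSDAClassifier, X: pd.DataFrame, y: pd.Series) -> PlsdaEvaluation:
    """Held-out evaluation: one-vs-rest ROC/AUC per class, macro AUC,
    argmax confusion matrix and one-sided Mann-Whitney p-values (scores of
    class members greater than the rest)."""
    y = pd.Series(np.asarray(y), index=X.index)
    scores = model.decision_scores(X)
    aucs, pvals, rocs = {}, {}, {}
    for c in model.classes_:
        mask = (y == c).to_numpy()
        if not mask.any():
            warnings.warn(f"class {c!r} absent from the test set")
            aucs[c], pvals[c] = math.nan, math.nan
            continue
        s = scores[c].to_numpy()
        aucs[c] = auc_mannwhitney(s[mask], s[~mask])
        if mask.all():
            pvals[c] = math.nan
            continue
        pvals[c] = float(
            stats.mannwhitneyu(s[mask], s[~mask], alternative="greater").pvalue
        )
        fpr, tpr, _ = roc_curve(mask.astype(int), s)
        rocs[c] = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    per_class = pd.Series(aucs)
    pred = model.predict(X)
    classes = list(model.classes_)
    confusion = pd.crosstab(y, pred).reindex(
        index=classes, columns=classes, fill_value=0
    )
    confusion.index.name, confusion.columns.name = "true", "predicted"
    return PlsdaEvaluation(
        per_class_auc=per_class,
        overall_auc=float(per_class.dropna().mean()),
        confusion=confusion,
        wilcoxon_p=pd.Series(pvals),
        incidence=y.value_counts(normalize=True).reindex(classes).fillna(0.0),
        roc_curves=rocs,
    )
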
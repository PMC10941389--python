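import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from resilink import plsda


def make_data(rng, n_per=20, p=30, shift=2.0, classes=("L", "M", "H"), signal_class="L"):
    n = n_per * len(classes)
    x = rng.normal(0, 1, (n, p))
    y = []
    for i, c in enumerate(classes):
        y += [c] * n_per
        if c == signal_class and shift:
            x[i * n_per: (i + 1) * n_per, :5] += shift
    xdf = pd.DataFrame(x, columns=[f"f{j}" for j in range(p)])
    meta = pd.DataFrame({"breed": (["DR", "LR", "LW"] * n)[:n], "label": y})
    return xdf, meta


class TestStratifiedSplit:
    def test_even_cells_split_half_half(self, rng):
        meta = pd.DataFrame({"breed": ["DR"] * 10, "label": ["L"] * 10})
        train, test = plsda.stratified_split(meta, seed=0)
        assert len(train) == 5 and len(test) == 5

    def test_partition_property(self, rng):
        _, meta = make_data(rng)
        train, test = plsda.stratified_split(meta, seed=1)
        assert set(train) | set(test) == set(meta.index)
        assert set(train) & set(test) == set()

    def test_empty_stratum_rejected(self):
        meta = pd.DataFrame(
            {"breed": ["DR", "DR", "LR"], "label": ["L", "M", "L"]}
        )
        with pytest.raises(ValueError, match="empty"):
            plsda.stratified_split(meta)

    def test_seeded_determinism(self, rng):
        _, meta = make_data(rng)
        a = plsda.stratified_split(meta, seed=7)
        b = plsda.stratified_split(meta, seed=7)
        assert list(a[0]) == list(b[0]) and list(a[1]) == list(b[1])


class TestFit:
    def test_separable_two_class_training_auc_is_one(self, rng):
        x, meta = make_data(rng, classes=("L", "M"), shift=6.0)
        model = plsda.PLSDAClassifier(n_components=2).fit(x, meta["label"])
        scores = model.decision_scores(x)
        mask = (meta["label"] == "L").to_numpy()
        auc = plsda.auc_mannwhitney(scores["L"][mask], scores["L"][~mask])
        assert auc == 1.0

    def test_single_class_rejected(self, rng):
        x, _ = make_data(rng, classes=("L",))
        with pytest.raises(ValueError):
            plsda.PLSDAClassifier().fit(x, pd.Series(["L"] * len(x)))

    def test_one_component_matches_svd_oracle(self, rng):
        # first PLS weight vector = dominant right singular vector of Y'X
        x, meta = make_data(rng, n_per=15, p=10, shift=1.0)
        model = plsda.PLSDAClassifier(n_components=1, scale=False).fit(x, meta["label"])
        xc = x.to_numpy() - x.to_numpy().mean(0)
        yd = pd.get_dummies(meta["label"]).to_numpy(dtype=float)
        yc = yd - yd.mean(0)
        _, _, vt = np.linalg.svd(yc.T @ xc, full_matrices=False)
        w_oracle = vt[0]
        w_model = model.x_weights_[:, 0]
        cos = abs(w_oracle @ w_model) / np.linalg.norm(w_model)
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_zero_variance_feature_dropped(self, rng):
        x, meta = make_data(rng, n_per=10, p=5)
        x["dead"] = 1.0
        with pytest.warns(UserWarning):
            model = plsda.PLSDAClassifier().fit(x, meta["label"])
        assert "dead" not in model.feature_names_


class TestVIP:
    def test_normalisation_identity(self, rng):
        x, meta = make_data(rng)
        model = plsda.PLSDAClassifier(n_components=3).fit(x, meta["label"])
        vip = plsda.vip_scores(model)
        assert (vip**2).sum() == pytest.approx(len(vip), rel=1e-8)

    def test_planted_feature_has_max_vip(self, rng):
        n = 60
        x = pd.DataFrame(
            rng.normal(0, 1, (n, 10)), columns=[f"f{j}" for j in range(10)]
        )
        y = pd.Series(np.where(x["f0"] + 0.3 * rng.normal(0, 1, n) > 0, "L", "M"))
        model = plsda.PLSDAClassifier(n_components=2).fit(x, y)
        vip = plsda.vip_scores(model)
        assert vip.idxmax() == "f0"

    def test_single_feature_vip_is_one(self, rng):
        x = pd.DataFrame({"f0": rng.normal(0, 1, 40)})
        y = pd.Series(np.where(x["f0"] > 0, "L", "M"))
        model = plsda.PLSDAClassifier(n_components=1).fit(x, y)
        assert plsda.vip_scores(model).iloc[0] == pytest.approx(1.0)


class TestAUC:
    def test_hand_enumerated_u_statistic(self):
        # concordant pairs: 0.9 beats all three, 0.5 beats 0.1 and 0.2
        auc = plsda.auc_mannwhitney([0.9, 0.5], [0.1, 0.2, 0.7])
        assert auc == pytest.approx(5 / 6)
        # fully separated scores
        assert plsda.auc_mannwhitney([0.9, 0.8], [0.1, 0.2, 0.7]) == 1.0

    def test_constant_scores_give_half(self):
        assert plsda.auc_mannwhitney([1.0, 1.0], [1.0, 1.0, 1.0]) == pytest.approx(0.5)

    def test_matches_roc_integration(self, rng):
        for _ in range(20):
            scores = rng.normal(0, 1, 40)
            y = rng.integers(0, 2, 40)
            if y.sum() in (0, 40):
                continue
            ours = plsda.auc_mannwhitney(scores[y == 1], scores[y == 0])
            assert ours == pytest.approx(roc_auc_score(y, scores), abs=1e-10)


class TestComponentSelection:
    def test_two_latent_components_recovered(self, rng):
        n = 120
        t = rng.normal(0, 1, (n, 2))
        loadings = rng.normal(0, 1, (2, 25))
        x = pd.DataFrame(t @ loadings + 0.3 * rng.normal(0, 1, (n, 25)))
        x.columns = [f"f{j}" for j in range(25)]
        lab = np.full(n, "M", dtype=object)
        lab[t[:, 0] > 0.5] = "L"
        lab[t[:, 1] > 0.5] = "H"
        best, _ = plsda.select_components(
            x, pd.Series(lab), max_comp=4, folds=4, repeats=3, seed=0
        )
        assert best in (2, 3)

    def test_noise_data_ties_resolve_to_fewest(self, rng):
        x, meta = make_data(rng, shift=0.0, n_per=15, p=10)
        best, table = plsda.select_components(
            x, meta["label"], max_comp=3, folds=3, repeats=2, seed=1
        )
        assert abs(table.max() - 0.5) < 0.15
        assert best == int(table.idxmax())


class TestElimination:
    def test_drops_twenty_percent_per_iteration(self, rng):
        x, meta = make_data(rng, p=10)
        res = plsda.recursive_vip_elimination(
            x, meta["label"], n_components=1, folds=3, repeats=2, seed=0
        )
        if len(res.feature_trajectory) > 1:
            assert len(res.feature_trajectory[1]) == 8  # 10 - floor(0.2*10)

    def test_reported_best_is_max_of_trajectory(self, rng):
        x, meta = make_data(rng, p=20)
        res = plsda.recursive_vip_elimination(
            x, meta["label"], n_components=2, folds=3, repeats=2, seed=3
        )
        assert res.auc_trajectory[res.best_iteration] == max(res.auc_trajectory)
        assert set(res.features) <= set(x.columns)

    def test_reproducible_from_seed(self, rng):
        x, meta = make_data(rng, p=15)
        r1 = plsda.recursive_vip_elimination(
            x, meta["label"], n_components=1, folds=3, repeats=2, seed=5
        )
        r2 = plsda.recursive_vip_elimination(
            x, meta["label"], n_components=1, folds=3, repeats=2, seed=5
        )
        assert list(r1.features) == list(r2.features)
        assert r1.auc_trajectory == r2.auc_trajectory

    def test_informative_features_recovered(self, rng):
        n = 120
        x = pd.DataFrame(
            rng.normal(0, 1, (n, 100)), columns=[f"f{j}" for j in range(100)]
        )
        informative = [f"f{j}" for j in range(5)]
        lab = np.where(
            x[informative].sum(axis=1) + rng.normal(0, 0.8, n) > 0, "L", "M"
        )
        res = plsda.recursive_vip_elimination(
            x, pd.Series(lab), n_components=1, folds=4, repeats=2, seed=2
        )
        vip = plsda.vip_scores(res.model).sort_values(ascending=False)
        top5 = set(vip.index[:5])
        assert len(top5 & set(informative)) >= 3


class TestEvaluate:
    def test_perfect_classifier(self, rng):
        x, meta = make_data(rng, classes=("L", "M"), shift=8.0)
        model = plsda.PLSDAClassifier(n_components=2).fit(x, meta["label"])
        ev = plsda.evaluate(model, x, meta["label"])
        assert ev.per_class_auc["L"] == 1.0
        assert (np.diag(ev.confusion) == ev.confusion.sum(axis=1)).all()

    def test_confusion_rows_sum_to_class_counts(self, rng):
        x, meta = make_data(rng)
        model = plsda.PLSDAClassifier(n_components=2).fit(x, meta["label"])
        ev = plsda.evaluate(model, x, meta["label"])
        counts = meta["label"].value_counts()
        for c in ev.confusion.index:
            assert ev.confusion.loc[c].sum() == counts[c]
        assert ev.incidence.sum() == pytest.approx(1.0)

    def test_wilcoxon_p_small_for_separable_class(self, rng):
        x, meta = make_data(rng, shift=4.0)
        model = plsda.PLSDAClassifier(n_components=2).fit(x, meta["label"])
        ev = plsda.evaluate(model, x, meta["label"])
        assert ev.wilcoxon_p["L"] < 0.001
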
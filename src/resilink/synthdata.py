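"""Synthetic cohorts with known ground truth.

Emulates the structure of a grower-pig performance test: three breeds housed
in breed-homogeneous pens (8 rooms x 8 pens), sires nested within breed with
their offspring spread across pens, per-animal linear growth in daily feed
consumption with AR(1) day-to-day noise, and stochastic multi-day
intake-depression events (illness-like episodes).  The companion microbiome
generator produces ASV count tables with compositional structure, variable
sequencing depth, and a latent microbial effect contributing a configurable
fraction (target microbiability m2) of an indicator's variance.

Every stochastic contribution is recorded in :class:`SimulationTruth`, so
recovery tests can compare estimates against realised quantities rather than
nominal targets.

Defaults mirror the scale of the motivating cohort: 528 boars of three
breeds in proportions 153/193/182, 27/27/44 sires per breed, ages 99-140
days, and a target m2 of 0.10 with pen and sire shares of 0.25 and 0.055.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

BREEDS = ("DR", "LR", "LW")


@dataclass
class SimulationConfig:
    """All generator knobs; defaults are the emulated study conditions."""

    n_animals: int = 528
    breed_proportions: tuple = (153 / 528, 193 / 528, 182 / 528)
    n_rooms: int = 8
    pens_per_room: int = 8
    sires_per_breed: tuple = (27, 27, 44)
    start_age: int = 99
    end_age: int = 140

    # feed intake (kg/day)
    fcd_start_mean: float = 2.2
    fcd_start_sd: float = 0.25
    slope_mean: float = 0.025
    slope_sd: float = 0.005
    noise_sd: float = 0.15
    noise_phi: float = 0.3          # AR(1) day-to-day correlation
    pen_effect_sd: float = 0.10
    missing_day_prob: float = 0.01
    max_visits_per_day: int = 8

    # intake-depression events
    event_prob: float = 0.30        # per-animal probability of one event
    event_duration: tuple = (3, 7)  # inclusive day range
    event_depth: tuple = (0.5, 1.5)  # kg/day reduction, uniform

    # microbiome
    n_asv: int = 1200
    base_log_sd: float = 2.0
    composition_noise_sd: float = 1.0
    n_community_factors: int = 4    # shared abundance gradients across ASVs
    community_factor_sd: float = 0.5
    depth_log_mean: float = np.log(20_000)
    depth_log_sd: float = 0.6
    low_depth_fraction: float = 0.05  # planted samples with depth < 700
    n_informative_asv: int = 50
    target_m2: float = 0.10
    pen_share: float = 0.25
    sire_share: float = 0.055

    def validate(self) -> None:
        if not np.isclose(sum(self.breed_proportions), 1.0):
            raise ValueError("breed proportions must sum to 1")
        shares = self.target_m2 + self.pen_share + self.sire_share
        if min(self.target_m2, self.pen_share, self.sire_share) < 0 or shares >= 1:
            raise ValueError("variance shares must be >= 0 and sum to < 1")


@dataclass
class SimulationTruth:
    """Ground truth recorded during generation."""

    events: dict = field(default_factory=dict)      # animal -> (start, end, depth)
    floored_days: dict = field(default_factory=dict)
    informative_asvs: list = field(default_factory=list)
    components: pd.DataFrame | None = None          # per-animal m/pen/sire/resid
    realized_m2: float | None = None

    def to_json_dict(self) -> dict:
        d = asdict(self)
        if self.components is not None:
            d["components"] = self.components.reset_index().to_dict(orient="list")
        return d


# ---------------------------------------------------------------------------
# cohort structure
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Animals with breed, room, pen and sire assignments.

    Pens are breed-homogeneous; each sire's offspring are dealt round-robin
    across that breed's pens so paternal half-sibs do not share a pen when
    capacity allows.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_animals
    counts = np.floor(np.asarray(config.breed_proportions) * n).astype(int)
    counts[0] += n - counts.sum()

    n_pens = config.n_rooms * config.pens_per_room
    pens = [
        (f"R{r + 1}", f"R{r + 1}P{p + 1}")
        for r in range(config.n_rooms)
        for p in range(config.pens_per_room)
    ]
    # breed-homogeneous pens, allocated proportionally to breed size
    pens_per_breed = np.maximum(1, np.round(counts / n * n_pens)).astype(int)
    while pens_per_breed.sum() > n_pens:
        pens_per_breed[np.argmax(pens_per_breed)] -= 1
    while pens_per_breed.sum() < n_pens:
        pens_per_breed[np.argmin(pens_per_breed)] += 1
    for b, cnt in enumerate(counts):
        if pens_per_breed[b] < int(np.ceil(cnt / 25)):
            raise ValueError("infeasible housing: too few pens for breed size")

    rows = []
    pen_cursor = 0
    animal_no = 0
    for b, breed in enumerate(BREEDS):
        breed_pens = pens[pen_cursor: pen_cursor + pens_per_breed[b]]
        pen_cursor += pens_per_breed[b]
        sires = [f"{breed}_s{j + 1}" for j in range(config.sires_per_breed[b])]
        # offspring per sire, then deal each sire's litter across pens round-robin
        sire_of = rng.choice(sires, size=counts[b])
        order = np.argsort(sire_of, kind="stable")
        for k, i in enumerate(order):
            room, pen = breed_pens[k % len(breed_pens)]
            animal_no += 1
            rows.append(
                {
                    "animal_id": f"A{animal_no:04d}",
                    "breed": breed,
                    "room_id": room,
                    "pen_id": pen,
                    "sire_id": sire_of[i],
                }
            )
    meta = pd.DataFrame(rows).set_index("animal_id", drop=False)
    meta.index.name = None
    return meta


# ---------------------------------------------------------------------------
# feed intake
# ---------------------------------------------------------------------------

def _ar1_noise(rng, n, phi, sd):
    innov_sd = sd * np.sqrt(1 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.normal(0, innov_sd)
    return x


def simulate_feed_intake(
    config: SimulationConfig,
    metadata: pd.DataFrame,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Visit-level feeder records plus event ground truth.

    Daily FCD = start + slope*(age - start_age) + pen effect + AR(1) noise,
    minus the event depth inside an animal's event window; each day's value
    is split across 1-8 visits that sum to it exactly.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    ages = np.arange(config.start_age, config.end_age + 1)
    truth = SimulationTruth()
    pen_effects = {
        p: rng.normal(0, config.pen_effect_sd) for p in sorted(metadata["pen_id"].unique())
    }
    visits = []
    for _, row in metadata.iterrows():
        start = rng.normal(config.fcd_start_mean, config.fcd_start_sd)
        slope = rng.normal(config.slope_mean, config.slope_sd)
        daily = (
            start
            + slope * (ages - config.start_age)
            + pen_effects[row["pen_id"]]
            + _ar1_noise(rng, len(ages), config.noise_phi, config.noise_sd)
        )
        if rng.random() < config.event_prob:
            dur = rng.integers(config.event_duration[0], config.event_duration[1] + 1)
            depth = rng.uniform(*config.event_depth)
            s = rng.integers(0, len(ages) - dur + 1)
            daily[s: s + dur] -= depth
            truth.events[row["animal_id"]] = (
                int(ages[s]),
                int(ages[s + dur - 1]),
                float(depth),
            )
        floored = daily < 0
        if floored.any():
            truth.floored_days[row["animal_id"]] = [int(a) for a in ages[floored]]
            daily = np.maximum(daily, 0.0)
        observed = rng.random(len(ages)) >= config.missing_day_prob
        for age, value, obs in zip(ages, daily, observed):
            if not obs:
                continue
            k = int(rng.integers(1, config.max_visits_per_day + 1))
            if k == 1 or value == 0:
                shares = np.array([1.0])
                k = 1
            else:
                shares = rng.dirichlet(np.ones(k))
            for sh in shares:
                visits.append(
                    {
                        "animal_id": row["animal_id"],
                        "pen_id": row["pen_id"],
                        "room_id": row["room_id"],
                        "breed": row["breed"],
                        "sire_id": row["sire_id"],
                        "age_days": int(age),
                        "intake_kg": float(value * sh),
                    }
                )
    return pd.DataFrame(visits), truth


# ---------------------------------------------------------------------------
# microbiome + planted indicator
# ---------------------------------------------------------------------------

def _scale_to_var(x: np.ndarray, target_var: float) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x) if target_var == 0 else x
    return x * np.sqrt(target_var) / sd


def simulate_microbiome(
    config: SimulationConfig,
    metadata: pd.DataFrame,
    seed: int | None = None,
    effect_scale: str = "clr",
) -> tuple[pd.DataFrame, pd.Series, SimulationTruth]:
    """ASV counts plus a synthetic indicator with a planted microbial share.

    The latent composition is a per-ASV log-normal baseline plus per-animal
    noise; counts are multinomial draws from softmax(latent) at log-normal
    depths, with a configured fraction of samples planted below depth 700.
    The microbial effect m = X b (b nonzero only for the informative ASVs)
    is built on the column-standardised CLR of the *observed* counts, so the
    analysis-side similarity kernel is correctly specified under the
    generator; m, pen, sire and residual contributions are scaled so their
    realised variance shares match the configured targets (total variance
    1).  ``effect_scale='latent'`` plants the effect on the noise-free
    latent CLR instead (measurement noise then attenuates recovery), and
    ``effect_scale='raw'`` uses raw relative abundances (a deliberate
    kernel misspecification for robustness checks).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    animals = metadata["animal_id"].tolist()
    n, p = len(animals), config.n_asv
    asv_ids = [f"ASV{j + 1:04d}" for j in range(p)]

    base = rng.normal(0, config.base_log_sd, size=p)
    latent = base[None, :] + rng.normal(0, config.composition_noise_sd, size=(n, p))
    if config.n_community_factors > 0:
        # shared community gradients: groups of ASVs rise and fall together,
        # as real gut communities do; gives the CLR covariance realistic
        # leading eigenvalues instead of an isotropic spectrum
        k = config.n_community_factors
        loadings = rng.normal(0, config.community_factor_sd, size=(p, k))
        scores = rng.normal(0, 1, size=(n, k))
        latent += scores @ loadings.T

    depths = np.exp(rng.normal(config.depth_log_mean, config.depth_log_sd, n)).astype(int)
    n_low = int(round(config.low_depth_fraction * n))
    if n_low:
        low_idx = rng.choice(n, size=n_low, replace=False)
        depths[low_idx] = rng.integers(100, 700, size=n_low)
    probs = np.exp(latent)
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depths[i], probs[i]) for i in range(n)])
    table = pd.DataFrame(counts, index=animals, columns=asv_ids)

    informative = list(
        rng.choice(asv_ids, size=min(config.n_informative_asv, p), replace=False)
    )
    b = np.zeros(p)
    idx = [asv_ids.index(a) for a in informative]
    b[idx] = rng.normal(0, 1, size=len(idx))

    if effect_scale == "raw":
        basis = counts / counts.sum(axis=1, keepdims=True)
    elif effect_scale == "latent":
        basis = latent - latent.mean(axis=1, keepdims=True)
    else:
        # observed-count CLR on the analysis-filtered table, standardised
        # over the retained samples, so the analysis kernel is correctly
        # specified; filtered-out (shallow) samples get the column means,
        # i.e. zero effect contribution.
        from .microbiome import (
            clr_transform,
            filter_asvs_by_prevalence,
            filter_samples_by_depth,
        )

        deep = filter_samples_by_depth(table)
        kept_asvs = filter_asvs_by_prevalence(deep).columns
        clr = clr_transform(deep[kept_asvs]).values
        sd = clr.std(axis=0, ddof=0).to_numpy()
        sd[sd == 0] = 1.0
        std = (clr - clr.mean(axis=0)) / sd
        basis = np.zeros((n, len(kept_asvs)))
        pos = {a: i for i, a in enumerate(table.index)}
        basis[[pos[a] for a in std.index]] = std.to_numpy()
        b = b[[asv_ids.index(a) for a in kept_asvs]]
        informative = [a for a in informative if a in set(kept_asvs)]
    m_raw = basis @ b
    m = _scale_to_var(m_raw - m_raw.mean(), config.target_m2)
    if config.n_informative_asv == 0:
        m = np.zeros(n)

    pen_codes = metadata["pen_id"].to_numpy()
    pen_levels = sorted(set(pen_codes))
    pen_draw = {pl: rng.normal() for pl in pen_levels}
    pen = _scale_to_var(np.array([pen_draw[c] for c in pen_codes]), config.pen_share)

    sire_codes = (metadata["breed"] + ":" + metadata["sire_id"]).to_numpy()
    sire_draw = {sl: rng.normal() for sl in sorted(set(sire_codes))}
    sire = _scale_to_var(
        np.array([sire_draw[c] for c in sire_codes]), config.sire_share
    )

    resid_var = 1.0 - config.target_m2 - config.pen_share - config.sire_share
    resid = _scale_to_var(rng.normal(0, 1, n), resid_var)

    indicator = pd.Series(m + pen + sire + resid, index=animals, name="indicator")

    components = pd.DataFrame(
        {"microbial": m, "pen": pen, "sire": sire, "residual": resid}, index=animals
    )
    var = components.var(ddof=0)
    truth = SimulationTruth(
        informative_asvs=informative,
        components=components,
        realized_m2=float(var["microbial"] / var.sum()),
    )
    return table, indicator, truth
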
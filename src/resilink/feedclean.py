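"""Visit-level feeder records to per-animal daily feed consumption (FCD).

Electronic single-space feeders log one row per feeder visit (animal id,
age in days, kg consumed).  Everything downstream works on *daily* feed
consumption: the sum of visit intakes over an integer age-day.  This module
cleans the visit stream with configurable plausibility rules, aggregates it
to daily series, restricts to the mid-test window (ages 99-140 by default)
and applies the animal-level inclusion filters (at least 10 observed days,
no gap of more than 3 consecutive missing days).

Missing days stay missing: a day with no visit is a gap, never a zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VISIT_COLUMNS = [
    "animal_id",
    "pen_id",
    "room_id",
    "breed",
    "sire_id",
    "age_days",
    "intake_kg",
]

META_COLUMNS = ["pen_id", "room_id", "breed", "sire_id"]

#: default plausibility rules (kg); all overridable
DEFAULT_MAX_VISIT_KG = 5.0
DEFAULT_MAX_DAILY_KG = 10.0


@dataclass
class DailyIntakeSeries:
    """One animal's daily feed consumption on a contiguous integer-age grid.

    ``fcd`` is aligned to ``ages`` (unit step); missing days carry NaN and
    are flagged in ``missing_mask``.
    """

    animal_id: str
    breed: str
    pen_id: str
    room_id: str
    sire_id: str
    ages: np.ndarray
    fcd: np.ndarray
    missing_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.fcd = np.asarray(self.fcd, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.fcd)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if not (len(self.ages) == len(self.fcd) == len(self.missing_mask)):
            raise ValueError(f"misaligned series for animal {self.animal_id}")
        if len(self.ages) > 1 and not np.all(np.diff(self.ages) == 1):
            raise ValueError(f"ages must advance in unit steps ({self.animal_id})")

    @property
    def n_observed(self) -> int:
        return int((~self.missing_mask).sum())

    def max_missing_gap(self) -> int:
        """Length of the longest run of consecutive missing days."""
        longest = run = 0
        for m in self.missing_mask:
            run = run + 1 if m else 0
            longest = max(longest, run)
        return longest

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "age_days": self.ages,
                "fcd_kg": self.fcd,
                "missing": self.missing_mask,
            }
        )


def read_visits(path) -> pd.DataFrame:
    """Read a visit file (CSV or TSV, sniffed from the header line)."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    visits = pd.read_csv(path, sep=sep)
    missing = [c for c in VISIT_COLUMNS if c not in visits.columns]
    if missing:
        raise ValueError(f"visit file lacks required columns: {missing}")
    return visits


def clean_visits(
    visits: pd.DataFrame,
    max_visit_kg: float = DEFAULT_MAX_VISIT_KG,
    max_daily_kg: float = DEFAULT_MAX_DAILY_KG,
) -> tuple[pd.DataFrame, dict]:
    """Apply plausibility rules to raw visit records.

    Rules (each individually overridable):

    * ``nonnegative`` — visit intake must be >= 0;
    * ``max_visit``  — visit intake must not exceed ``max_visit_kg``;
    * ``max_daily``  — all visits of an animal-day whose summed intake
      exceeds ``max_daily_kg`` are dropped.

    Returns the retained records and a cleaning log with per-rule removal
    counts.  Retained + removed always reconciles with the input count.
    """
    visits = visits.copy()
    n_in = len(visits)
    log = {"input": n_in, "removed": {}}

    neg = visits["intake_kg"] < 0
    log["removed"]["nonnegative"] = int(neg.sum())
    visits = visits[~neg]

    big = visits["intake_kg"] > max_visit_kg
    log["removed"]["max_visit"] = int(big.sum())
    visits = visits[~big]

    day_tot = visits.groupby(["animal_id", "age_days"])["intake_kg"].transform("sum")
    over = day_tot > max_daily_kg
    log["removed"]["max_daily"] = int(over.sum())
    visits = visits[~over]

    log["retained"] = len(visits)
    assert log["retained"] + sum(log["removed"].values()) == n_in
    if log["retained"] == 0:
        import warnings

        warnings.warn("all visit records removed by cleaning rules")
    return visits.reset_index(drop=True), log


def _animal_metadata(group: pd.DataFrame, animal: str) -> dict:
    meta = {}
    for col in META_COLUMNS:
        vals = group[col].unique()
        if len(vals) != 1:
            raise ValueError(
                f"conflicting {col} for animal {animal}: {sorted(map(str, vals))}"
            )
        meta[col] = vals[0]
    return meta


def aggregate_visits_to_daily(visits: pd.DataFrame) -> list[DailyIntakeSeries]:
    """Sum visit intakes per animal and integer age-day.

    Days without any visit inside an animal's observed span are marked
    missing (NaN), not zero.
    """
    series = []
    for animal, grp in visits.groupby("animal_id", sort=True):
        meta = _animal_metadata(grp, animal)
        daily = grp.groupby("age_days")["intake_kg"].sum()
        ages = np.arange(daily.index.min(), daily.index.max() + 1)
        fcd = np.full(len(ages), np.nan)
        fcd[daily.index.to_numpy() - ages[0]] = daily.to_numpy()
        series.append(
            DailyIntakeSeries(
                animal_id=animal,
                breed=meta["breed"],
                pen_id=meta["pen_id"],
                room_id=meta["room_id"],
                sire_id=meta["sire_id"],
                ages=ages,
                fcd=fcd,
            )
        )
    return series


def restrict_period(
    series: list[DailyIntakeSeries],
    start_day: int = 99,
    end_day: int = 140,
) -> tuple[list[DailyIntakeSeries], dict]:
    """Keep only ages in [start_day, end_day], inclusive on both ends.

    Every retained animal gets the full grid start..end with gaps where it
    was not observed.  Animals with no observation inside the window are
    dropped and logged.
    """
    out, dropped = [], []
    grid = np.arange(start_day, end_day + 1)
    for s in series:
        fcd = np.full(len(grid), np.nan)
        common = (s.ages >= start_day) & (s.ages <= end_day)
        if common.any():
            fcd[s.ages[common] - start_day] = s.fcd[common]
        if np.all(np.isnan(fcd)):
            dropped.append(s.animal_id)
            continue
        out.append(
            DailyIntakeSeries(
                animal_id=s.animal_id,
                breed=s.breed,
                pen_id=s.pen_id,
                room_id=s.room_id,
                sire_id=s.sire_id,
                ages=grid.copy(),
                fcd=fcd,
            )
        )
    return out, {"dropped_empty_window": dropped}


def filter_animals(
    series: list[DailyIntakeSeries],
    min_days: int = 10,
    max_gap: int = 3,
) -> tuple[list[DailyIntakeSeries], dict]:
    """Animal-level inclusion filters on the windowed daily series.

    An animal is removed when it has fewer than ``min_days`` observed days
    or any run of more than ``max_gap`` consecutive missing days (a gap of
    ``max_gap`` itself is allowed).  Idempotent.
    """
    kept, reasons = [], {}
    for s in series:
        if s.n_observed < min_days:
            reasons[s.animal_id] = f"fewer than {min_days} observed days ({s.n_observed})"
        elif s.max_missing_gap() > max_gap:
            reasons[s.animal_id] = (
                f"missing gap of {s.max_missing_gap()} consecutive days (> {max_gap})"
            )
        else:
            kept.append(s)
    return kept, reasons


def daily_to_frame(series: list[DailyIntakeSeries]) -> pd.DataFrame:
    """Tidy long table (animal_id, age_days, fcd_kg, missing) for all animals."""
    if not series:
        return pd.DataFrame(columns=["animal_id", "age_days", "fcd_kg", "missing"])
    return pd.concat([s.to_frame() for s in series], ignore_index=True)


def metadata_frame(series: list[DailyIntakeSeries]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal_id": s.animal_id,
                "breed": s.breed,
                "pen_id": s.pen_id,
                "room_id": s.room_id,
                "sire_id": s.sire_id,
            }
            for s in series
        ]
    )


def run_feedclean(
    visits: pd.DataFrame,
    start_day: int = 99,
    end_day: int = 140,
    min_days: int = 10,
    max_gap: int = 3,
    max_visit_kg: float = DEFAULT_MAX_VISIT_KG,
    max_daily_kg: float = DEFAULT_MAX_DAILY_KG,
) -> tuple[list[DailyIntakeSeries], dict]:
    """Full cleaning chain: clean -> aggregate -> window -> animal filters."""
    cleaned, clean_log = clean_visits(visits, max_visit_kg, max_daily_kg)
    series = aggregate_visits_to_daily(cleaned)
    series, window_log = restrict_period(series, start_day, end_day)
    series, filter_log = filter_animals(series, min_days, max_gap)
    log = {
        "cleaning": clean_log,
        "window": window_log,
        "animal_filters": filter_log,
        "animals_retained": len(series),
    }
    return series, log


def write_outputs(series: list[DailyIntakeSeries], log: dict, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    daily_to_frame(series).to_csv(out / "daily_fcd.tsv", sep="\t", index=False, float_format="%.10g")
    metadata_frame(series).to_csv(out / "animal_metadata.tsv", sep="\t", index=False)
    with open(out / "cleaning_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
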
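"""End-to-end orchestration: simulate -> feedclean -> phenotype ->
microbiome -> associate -> microbiability -> plsda.

A single YAML/dict config drives every stage; per-stage seeds are derived
from the global seed by fixed offsets so toggling one stage never changes
another stage's draws.  Every output table is TSV with a fixed float
format, and a manifest (stage list, seeds, output hashes, version) plus a
consolidated JSON + markdown report are written, so reruns with the same
config and seed are byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from . import association, feedclean, indicators, microbiome, plsda, synthdata
from .microbiability import MicrobiabilityModel

STAGE_SEED_OFFSETS = {
    "simulate": 11,
    "feedclean": 23,
    "phenotype": 37,
    "microbiome": 53,
    "associate": 71,
    "microbiability": 89,
    "plsda": 97,
}

DEFAULT_CONFIG = {
    "seed": 1,
    "stages": {name: True for name in STAGE_SEED_OFFSETS},
    "simulate": {},  # forwarded to synthdata.SimulationConfig
    "feedclean": {
        "start_day": 99,
        "end_day": 140,
        "min_days": 10,
        "max_gap": 3,
        "max_visit_kg": 5.0,
        "max_daily_kg": 10.0,
    },
    "phenotype": {"window": 5, "min_per_breed": 20, "invert_summin": False},
    "microbiome": {"min_depth": 700, "min_prev": 0.05},
    "associate": {"n_perm": 1000, "indicators": list(indicators.INDICATOR_NAMES)},
    "microbiability": {
        "n_iter": 70_000,
        "burn_in": 10_000,
        "thin": 50,
        "indicators": list(indicators.INDICATOR_NAMES),
    },
    "plsda": {
        "indicator": "lnvar",
        "split": 0.5,
        "folds": 4,
        "repeats": 50,
        "max_comp": 5,
    },
}

_FLOAT_FMT = "%.10g"


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a YAML file and an override dict.

    Unknown keys at any level are rejected.
    """
    config = copy.deepcopy(DEFAULT_CONFIG)
    for source in (path and _read_yaml(path), overrides):
        if not source:
            continue
        _merge(config, source, trail="config")
    return config


def _read_yaml(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _merge(base: dict, update: dict, trail: str) -> None:
    for key, val in update.items():
        if key not in base and trail != "config.simulate":
            raise KeyError(f"unknown config key {trail}.{key}")
        if isinstance(base.get(key), dict) and isinstance(val, dict):
            _merge(base[key], val, f"{trail}.{key}")
        else:
            base[key] = val


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the report dict; writes all tables, ``manifest.json`` and
    ``report.md`` / ``report.json`` under ``out_dir``.  A stage failure
    halts the pipeline after recording the completed stages in a partial
    manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stage_seed = {s: seed + off for s, off in STAGE_SEED_OFFSETS.items()}
    manifest = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": stage_seed,
        "stages_completed": [],
        "outputs": {},
    }
    report: dict = {"seed": seed}
    state: dict = {}

    def record(stage, *paths):
        manifest["stages_completed"].append(stage)
        for p in paths:
            manifest["outputs"][p.name] = _sha256(p)
        _dump_json(manifest, out / "manifest.json")

    try:
        if config["stages"]["simulate"]:
            sim_cfg = synthdata.SimulationConfig(**config["simulate"])
            meta = synthdata.simulate_cohort(sim_cfg, seed=stage_seed["simulate"])
            visits, feed_truth = synthdata.simulate_feed_intake(
                sim_cfg, meta, seed=stage_seed["simulate"] + 1
            )
            counts, planted, micro_truth = synthdata.simulate_microbiome(
                sim_cfg, meta, seed=stage_seed["simulate"] + 2
            )
            state.update(meta=meta, visits=visits, counts=counts, planted=planted)
            p1, p2, p3 = out / "visits.csv", out / "asv_counts.tsv", out / "metadata.tsv"
            visits.to_csv(p1, index=False, float_format=_FLOAT_FMT)
            _write_tsv(counts, p2, index=True)
            _write_tsv(meta.reset_index(drop=True), p3)
            truth = {
                "feed": feed_truth.to_json_dict(),
                "microbiome": micro_truth.to_json_dict(),
            }
            _dump_json(truth, out / "truth.json")
            report["simulate"] = {
                "n_animals": len(meta),
                "realized_m2": micro_truth.realized_m2,
            }
            record("simulate", p1, p2, p3, out / "truth.json")

        if config["stages"]["feedclean"]:
            fc = config["feedclean"]
            series, log = feedclean.run_feedclean(state["visits"], **fc)
            state["series"] = series
            feedclean.write_outputs(series, log, out)
            report["feedclean"] = {
                "animals_retained": len(series),
                "removed": log["cleaning"]["removed"],
            }
            record("feedclean", out / "daily_fcd.tsv", out / "cleaning_log.json")

        if config["stages"]["phenotype"]:
            ph = config["phenotype"]
            ind = indicators.compute_indicators(state["series"], window=ph["window"])
            names = list(indicators.INDICATOR_NAMES)
            if "planted" in state:
                # synthetic indicator with a known microbial variance share
                ind["planted"] = state["planted"].reindex(ind["animal_id"]).to_numpy()
                names.append("planted")
            state["indicators"] = ind.set_index("animal_id", drop=False)
            labels = []
            for name in names:
                labels.append(
                    indicators.assign_classes(
                        ind,
                        name,
                        min_per_breed=ph["min_per_breed"],
                        invert_summin=ph["invert_summin"],
                    )
                )
            state["labels"] = pd.concat(labels, ignore_index=True)
            p1, p2 = out / "indicators.tsv", out / "classes.tsv"
            _write_tsv(ind, p1)
            _write_tsv(state["labels"], p2)
            report["phenotype"] = {
                "n_animals": len(ind),
                "class_sizes": state["labels"]
                .groupby(["indicator", "label"])
                .size()
                .to_dict(),
            }
            report["phenotype"]["class_sizes"] = {
                f"{k[0]}:{k[1]}": v
                for k, v in report["phenotype"]["class_sizes"].items()
            }
            record("phenotype", p1, p2)

        if config["stages"]["microbiome"]:
            mb = config["microbiome"]
            prep = microbiome.prepare_microbiome(
                state["counts"], min_depth=mb["min_depth"], min_prev=mb["min_prev"]
            )
            state["prep"] = prep
            p1, p2 = out / "clr.tsv", out / "aitchison_distance.tsv"
            p3, p4 = out / "alpha_diversity.tsv", out / "kernel.tsv"
            _write_tsv(prep["clr"].values, p1, index=True)
            _write_tsv(prep["distance"], p2, index=True)
            _write_tsv(prep["diversity"], p3, index=True)
            _write_tsv(prep["kernel"].K, p4, index=True)
            report["microbiome"] = {
                "samples_removed": prep["n_samples_removed"],
                "asvs_removed": prep["n_asvs_removed"],
                "n_asv_retained": prep["kernel"].n_features,
            }
            record("microbiome", p1, p2, p3, p4)

        if config["stages"]["associate"]:
            report["associate"] = _run_associate(config, state, out, stage_seed)
            record(
                "associate",
                out / "permanova.tsv",
                out / "diversity_regression.tsv",
                out / "ks_tests.tsv",
            )

        if config["stages"]["microbiability"]:
            report["microbiability"] = _run_microbiability(config, state, out, stage_seed)
            record("microbiability", out / "microbiability.json")

        if config["stages"]["plsda"]:
            report["plsda"] = _run_plsda(config, state, out, stage_seed)
            record(
                "plsda",
                out / "plsda_evaluation.tsv",
                out / "plsda_confusion.tsv",
            )
    except Exception:
        _dump_json(manifest, out / "manifest.json")
        raise

    _dump_json(report, out / "report.json")
    (out / "report.md").write_text(_render_report(report))
    record("report", out / "report.json", out / "report.md")
    return report


def _run_associate(config, state, out: Path, stage_seed) -> dict:
    cfg = config["associate"]
    prep = state["prep"]
    ind = state["indicators"]
    common = prep["distance"].index.intersection(ind.index)
    dist = prep["distance"].loc[common, common]
    meta = state["meta"].loc[common]
    tables, regs, ks_rows = [], [], []
    for name in cfg["indicators"]:
        covars = meta[["room_id", "breed"]].copy()
        covars[name] = ind.loc[common, name]
        covars = covars.dropna(subset=[name])
        res = association.permanova(
            dist.loc[covars.index, covars.index],
            covars,
            terms=["room_id", "breed", name],
            n_perm=cfg["n_perm"],
            seed=stage_seed["associate"],
        )
        t = res.table.reset_index()
        t.insert(0, "indicator", name)
        tables.append(t)

        for measure in ("shannon", "inv_simpson"):
            div = prep["diversity"][measure]
            div, _ = microbiome.remove_diversity_outliers(div)
            pair_idx = div.index.intersection(ind.index)
            reg = association.diversity_regression(
                div.loc[pair_idx],
                ind.loc[pair_idx, name],
                covariates=state["meta"].loc[pair_idx, ["room_id", "breed"]],
            )
            regs.append(
                {
                    "indicator": name,
                    "measure": measure,
                    "slope": reg.slope,
                    "R": reg.r,
                    "p": reg.p_value,
                    "adj_slope": reg.adjusted_slope,
                    "adj_p": reg.adjusted_p_value,
                    "n": reg.n,
                }
            )

        labels = state["labels"]
        lab = labels[labels["indicator"] == name].set_index("animal_id")["label"]
        div_all = prep["diversity"]["shannon"]
        idx = lab.index.intersection(div_all.index)
        ks = association.ks_class_test(div_all.loc[idx], lab.loc[idx])
        ks.insert(0, "indicator", name)
        ks_rows.append(ks)

    perm_table = pd.concat(tables, ignore_index=True)
    _write_tsv(perm_table, out / "permanova.tsv")
    _write_tsv(pd.DataFrame(regs), out / "diversity_regression.tsv")
    _write_tsv(pd.concat(ks_rows, ignore_index=True), out / "ks_tests.tsv")
    summary = {}
    for name in cfg["indicators"]:
        row = perm_table[(perm_table["indicator"] == name) & (perm_table["term"] == name)]
        summary[name] = {
            "VarExp": float(row["VarExp"].iloc[0]),
            "p": float(row["Pr(>F)"].iloc[0]),
        }
    return summary


def _run_microbiability(config, state, out: Path, stage_seed) -> dict:
    cfg = config["microbiability"]
    prep = state["prep"]
    results = {}
    for i, name in enumerate(cfg["indicators"]):
        data = state["meta"].join(state["indicators"][[name]]).dropna(subset=[name])
        model = MicrobiabilityModel.from_dataframe(
            data, name, prep["kernel"], pen_col="pen_id", sire_col="sire_id",
            breed_col="breed",
        )
        res = model.fit(
            n_iter=cfg["n_iter"],
            burn_in=cfg["burn_in"],
            thin=cfg["thin"],
            seed=stage_seed["microbiability"] + i,
        )
        results[name] = res.to_json_dict()
    _dump_json(results, out / "microbiability.json")
    return {
        name: {"m2_median": r["m2_median"], "m2_hpd95": r["m2_hpd95"]}
        for name, r in results.items()
    }


def _run_plsda(config, state, out: Path, stage_seed) -> dict:
    cfg = config["plsda"]
    name = cfg["indicator"]
    labels = state["labels"]
    lab = labels[labels["indicator"] == name].set_index("animal_id")
    lab = lab[lab["label"].isin(["L", "M", "H"])]
    clr = state["prep"]["clr"].values
    idx = lab.index.intersection(clr.index)
    meta = lab.loc[idx]
    x = clr.loc[idx]
    y = meta["label"]
    train, test = plsda.stratified_split(
        meta, fraction=cfg["split"], seed=stage_seed["plsda"]
    )
    n_comp, comp_table = plsda.select_components(
        x.loc[train],
        y.loc[train],
        max_comp=cfg["max_comp"],
        folds=cfg["folds"],
        repeats=cfg["repeats"],
        seed=stage_seed["plsda"] + 1,
    )
    elim = plsda.recursive_vip_elimination(
        x.loc[train],
        y.loc[train],
        n_components=n_comp,
        folds=cfg["folds"],
        repeats=cfg["repeats"],
        seed=stage_seed["plsda"] + 2,
    )
    ev = plsda.evaluate(elim.model, x.loc[test], y.loc[test])
    _write_tsv(ev.to_frame(), out / "plsda_evaluation.tsv")
    _write_tsv(ev.confusion.reset_index(), out / "plsda_confusion.tsv")
    roc_rows = []
    for cls, curve in (ev.roc_curves or {}).items():
        c = curve.copy()
        c.insert(0, "class", cls)
        roc_rows.append(c)
    if roc_rows:
        _write_tsv(pd.concat(roc_rows, ignore_index=True), out / "plsda_roc.tsv")
    return {
        "indicator": name,
        "n_components": n_comp,
        "component_auc": {int(k): float(v) for k, v in comp_table.items()},
        "n_features_final": len(elim.features),
        "per_class_auc": {k: float(v) for k, v in ev.per_class_auc.items()},
        "overall_auc": ev.overall_auc,
    }


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)


def _render_report(report: dict) -> str:
    lines = ["# resilink pipeline report", ""]
    if "simulate" in report:
        s = report["simulate"]
        lines += [
            f"Simulated cohort: {s['n_animals']} animals "
            f"(realized m2 of the planted indicator: {s['realized_m2']:.3f}).",
            "",
        ]
    if "feedclean" in report:
        lines += [
            f"Feed cleaning retained {report['feedclean']['animals_retained']} animals.",
            "",
        ]
    if "associate" in report:
        lines += ["## Microbiota association (PERMANOVA)", ""]
        lines += ["| Indicator | VarExp (%) | Pr(>F) |", "| --- | --- | --- |"]
        for name, row in report["associate"].items():
            lines.append(f"| {name} | {row['VarExp']:.3f} | {row['p']:.4g} |")
        lines.append("")
    if "microbiability" in report:
        lines += ["## Microbiability", ""]
        lines += ["| Indicator | m2 median | HPD95 |", "| --- | --- | --- |"]
        for name, row in report["microbiability"].items():
            lo, hi = row["m2_hpd95"]
            lines.append(f"| {name} | {row['m2_median']:.3f} | [{lo:.3f}, {hi:.3f}] |")
        lines.append("")
    if "plsda" in report:
        p = report["plsda"]
        lines += [
            "## PLS-DA classification",
            "",
            f"Indicator {p['indicator']}: {p['n_components']} components, "
            f"{p['n_features_final']} features after VIP pruning, "
            f"overall AUC {p['overall_auc']:.3f}.",
            "",
            "| Class | AUC |",
            "| --- | --- |",
        ]
        for cls, auc in p["per_class_auc"].items():
            lines.append(f"| {cls} | {auc:.3f} |")
        lines.append("")
    return "\n".join(lines)
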
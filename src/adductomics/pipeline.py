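"""End-to-end orchestration: screen -> master -> quantify -> filter ->
annotate -> statistics, from a single configuration mapping.

The configuration (usually a YAML file) names the mzML inputs per sample and
acquisition range, the metadata table, the output directory and the
per-stage parameters; every stochastic stage receives a seed derived from
the global one. The configuration is echoed into the output directory and a
run report records the counts surviving each filter step.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .chem import EnumerationConstraints, enumerate_compositions
from .ms_io import build_dia_scheme, read_mzml
from .peaks import PeakDetectionParams
from .quantify import AdductTable, QuantParams, dg_mz, integrate_targets, rsd_filter
from .screen import ScreenParams, build_master_list, master_to_frame, screen_run
from .stats import (
    SiteMetadata,
    VolcanoParams,
    oplsda,
    pearson_matrix,
    permanova,
    roc,
    simper,
    transform,
    volcano,
)

__all__ = ["load_config", "run_pipeline", "DEFAULT_CONFIG"]

log = logging.getLogger("adductomics.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "dia": {"low": [195.0, 355.0, 10.0], "high": [347.0, 607.0, 10.0]},
    "centroid": False,
    "detection": {},          # PeakDetectionParams overrides
    "screening": {"ppm_tol": 5.0, "coelution_tol": 0.1},
    "master": {"merge_ppm": 5.0, "merge_rt": 0.5},
    "quantification": {"ppm_tol": 5.0, "rt_tol": 0.2, "rsd_max": 20.0},
    "dg": {"rt": None},       # run-specific dG retention time (minutes)
    "annotation": {"ppm_tol": 5.0},
    "stats": {"n_perm": 999, "folds": 10, "n_orth": 1, "n_boot": 2000,
              "fc_threshold": 2.0, "p_threshold": 0.1},
}

_SCAN_RANGE = {"low": (195.0, 355.0), "high": (350.0, 600.0)}


def _merge_defaults(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge_defaults(user)


def _validate(cfg: dict) -> None:
    runs = cfg.get("runs") or []
    if not runs:
        raise ValueError("config lists no input runs")
    for r in runs:
        for key in ("sample_id", "mzml", "range"):
            if key not in r:
                raise ValueError(f"run entry missing {key!r}: {r}")
        if r["range"] not in ("low", "high"):
            raise ValueError(f"run range must be low|high: {r}")
        if not Path(r["mzml"]).exists():
            raise FileNotFoundError(f"mzML input not found: {r['mzml']}")
    meta = cfg.get("metadata")
    if meta and not Path(meta).exists():
        raise FileNotFoundError(f"metadata table not found: {meta}")


def _load_metadata(path: str) -> SiteMetadata:
    df = pd.read_csv(path, index_col=0)
    contaminant_cols = [c for c in df.columns if c not in ("station", "basin", "status")]
    return SiteMetadata(
        station=df["station"],
        basin=df["basin"],
        status=df["status"],
        contaminants=df[contaminant_cols],
    )


def run_pipeline(cfg: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute the full workflow; returns the run report (also written as
    JSON). Low- and high-mass acquisitions are screened as separate passes
    and concatenated at the master-list stage."""
    cfg = _merge_defaults(cfg) if isinstance(cfg, dict) else load_config(cfg)
    _validate(cfg)
    out = Path(output_dir or cfg.get("output_dir", "results/pipeline"))
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)

    det = PeakDetectionParams(**cfg["detection"])
    report: dict = {"stages": {}}

    # --- stage 1: per-run neutral-loss screening ------------------------
    runs_by_range: dict[str, list] = {"low": [], "high": []}
    hits_by_range: dict[str, list] = {"low": [], "high": []}
    for entry in cfg["runs"]:
        rng_name = entry["range"]
        lo, hi, width = cfg["dia"][rng_name]
        scheme = build_dia_scheme(lo, hi, width)
        run = read_mzml(entry["mzml"], centroid=cfg["centroid"], scheme=scheme)
        scan_lo, scan_hi = _SCAN_RANGE[rng_name]
        scr = ScreenParams(scan_lo=scan_lo, scan_hi=scan_hi, **cfg["screening"])
        hits = screen_run(run, det, scr, sample_id=entry["sample_id"])
        log.info("screened %s (%s): %d putative adducts", entry["sample_id"], rng_name, len(hits))
        runs_by_range[rng_name].append((entry, run))
        hits_by_range[rng_name].append(hits)
    n_putative = sum(len(h) for hs in hits_by_range.values() for h in hs)
    report["stages"]["putative_adducts"] = n_putative

    # --- stage 2: master list -------------------------------------------
    master = []
    for rng_name in ("low", "high"):
        if hits_by_range[rng_name]:
            master.extend(
                build_master_list(hits_by_range[rng_name], **cfg["master"])
            )
    master_to_frame(master).to_csv(out / "master.tsv", sep="\t", index=False)
    report["stages"]["master_entries"] = len(master)
    if not master:
        report["stages"]["quantified"] = 0
        _finish(report, out)
        return report

    # --- stage 3: targeted confirmation and dG normalization -----------
    q = QuantParams(**{k: v for k, v in cfg["quantification"].items() if k != "rsd_max"})
    sample_ids, raw_rows, dg_rows, replicate_of = [], [], [], {}
    for rng_name in ("low", "high"):
        for entry, run in runs_by_range[rng_name]:
            sid = entry["sample_id"]
            results = integrate_targets(run, master, q, det)
            row = {r.adduct_id: r.area for r in results}
            if sid in sample_ids:  # same sample, other acquisition: merge columns
                raw_rows[sample_ids.index(sid)].update({k: v for k, v in row.items() if v > 0})
                continue
            sample_ids.append(sid)
            raw_rows.append(row)
            dg_rt = entry.get("dg_rt", cfg["dg"].get("rt"))
            dg_rows.append(_integrate_dg(run, dg_rt, q, det))
            if entry.get("replicate_of"):
                replicate_of[sid] = entry["replicate_of"]
    raw = pd.DataFrame(raw_rows, index=sample_ids).fillna(0.0)
    dg = pd.Series(dg_rows, index=sample_ids)
    table = AdductTable(
        samples=sample_ids,
        adducts=[e.adduct_id for e in master],
        raw_area=raw.reindex(columns=[e.adduct_id for e in master], fill_value=0.0),
        dg_area=dg,
        replicate_of=replicate_of,
    )
    table.norm_area.to_csv(out / "adduct_table.tsv", sep="\t")
    detected = int((table.raw_area > 0).any(axis=0).sum())
    report["stages"]["quantified"] = detected

    # --- stage 4: replicate-RSD filter ----------------------------------
    if replicate_of:
        rsd_max = cfg["quantification"].get("rsd_max", 20.0)
        retained, detail = rsd_filter(table, rsd_max=rsd_max)
        detail.to_csv(out / "rsd_filter.tsv", sep="\t", index=False)
        report["stages"]["rsd_retained"] = len(retained)
    else:
        retained = table.adducts
        report["stages"]["rsd_retained"] = len(retained)

    # --- stage 5: elemental-composition annotation ----------------------
    constraints = EnumerationConstraints(ppm_tol=cfg["annotation"]["ppm_tol"])
    ann_rows = []
    for e in master:
        for rank, res in enumerate(enumerate_compositions(e.mz, constraints), start=1):
            ann_rows.append({
                "adduct_id": e.adduct_id, "observed_mz": e.mz,
                "formula": res.composition.hill(), "delta_ppm": res.delta_ppm,
                "rdb": res.rdb, "rank": rank,
            })
    pd.DataFrame(ann_rows).to_csv(out / "annotations.tsv", sep="\t", index=False)
    report["stages"]["annotated"] = len({r["adduct_id"] for r in ann_rows})

    # --- stage 6: statistics --------------------------------------------
    if cfg.get("metadata"):
        meta = _load_metadata(cfg["metadata"])
        _run_stats(table.norm_area[retained], meta, cfg["stats"], int(cfg["seed"]), out, report)

    _finish(report, out)
    return report


def _integrate_dg(run, dg_rt, q: QuantParams, det: PeakDetectionParams) -> float:
    if dg_rt is None:
        raise ValueError("dG retention time missing (config key dg.rt or run dg_rt)")
    from .screen import MasterEntry

    entry = MasterEntry("dG", dg_mz(), float(dg_rt), "low", 1)
    res = integrate_targets(run, [entry], q, det)[0]
    if not res.detected:
        raise ValueError(f"dG peak not found at RT {dg_rt} min")
    return res.area


def _run_stats(norm_area, meta: SiteMetadata, s: dict, seed: int, out: Path, report: dict) -> None:
    X, Z = transform(norm_area, meta)
    r, p = pearson_matrix(X, Z)
    r.to_csv(out / "correlations_r.csv")
    p.to_csv(out / "correlations_p.csv")

    factors = pd.DataFrame({"status": meta.status, "basin": meta.basin})
    terms = ("status", "basin", "status:basin")
    if meta.basin.nunique() < 2:
        terms = ("status",)
        factors = factors[["status"]]
    perm = permanova(X, factors, terms=terms, n_perm=s["n_perm"], seed=seed)
    perm.terms.to_csv(out / "permanova.tsv", sep="\t")
    report["permanova_p"] = {t: float(perm.terms.loc[t, "p"]) for t in perm.terms.index}

    sim = simper(norm_area.loc[meta.samples], meta.status)
    sim.to_csv(out / "simper.tsv", sep="\t")
    selected = sim.index[sim["selected"]].tolist()
    report["stages"]["simper_selected"] = len(selected)

    selected_in_x = [a for a in selected if a in X.columns]
    y = (meta.status == "C").astype(int)
    model = oplsda(X[selected_in_x], y, n_orth=s["n_orth"],
                   folds=s["folds"], seed=seed)
    pd.DataFrame({"vip": model.vip}, index=selected_in_x).to_csv(out / "vip.csv")
    pd.DataFrame({"t_pred": model.scores}, index=X.index).to_csv(out / "opls_scores.csv")
    report["oplsda"] = {"r2y": model.r2y, "q2": model.q2}

    scores = model.predict(X[selected_in_x])
    roc_res = roc(scores, y, n_boot=s["n_boot"], seed=seed)
    with open(out / "roc.json", "w") as fh:
        json.dump(roc_res.__dict__, fh, indent=2)
    report["roc_auc"] = roc_res.auc

    vol = volcano(norm_area.loc[meta.samples], meta.status,
                  VolcanoParams(s["fc_threshold"], s["p_threshold"]))
    vol.to_csv(out / "volcano.tsv", sep="\t")
    report["stages"]["volcano_flagged"] = int((vol["flag"] != "ns").sum())


def _finish(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("pipeline complete: %s", json.dumps(report["stages"]))
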
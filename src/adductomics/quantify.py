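"""Targeted confirmation, dG normalization, and replicate-RSD filtering.

Master-list targets are re-integrated per run at their consensus m/z and RT;
areas are expressed relative to the unmodified 2'-deoxyguanosine (dG) peak
(area x 100 / dG area), which corrects for DNA amount, digestion losses and
instrument drift; adducts whose replicate RSD is not below the cutoff are
dropped before statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import monoisotopic_mass, parse_formula
from .ms_io import Run
from .peaks import PeakDetectionParams, detect_peaks, extract_eic
from .screen import MasterEntry

__all__ = [
    "QuantParams",
    "AdductTable",
    "TargetResult",
    "integrate_targets",
    "normalize_to_dG",
    "rsd_filter",
    "DG_COMPOSITION",
    "dg_mz",
]

#: Neutral composition of 2'-deoxyguanosine.
DG_COMPOSITION = "C10H13N5O4"


def dg_mz() -> float:
    """[M+H]+ m/z of 2'-deoxyguanosine (~268.1040)."""
    return monoisotopic_mass(parse_formula(DG_COMPOSITION), "protonated")


@dataclass(frozen=True)
class QuantParams:
    ppm_tol: float = 5.0
    rt_tol: float = 0.2
    rsd_max: float = 20.0

    def __post_init__(self) -> None:
        if min(self.ppm_tol, self.rt_tol, self.rsd_max) <= 0:
            raise ValueError("all quantification parameters must be positive")


@dataclass(frozen=True)
class TargetResult:
    adduct_id: str
    detected: bool
    area: float
    apex_rt: float = float("nan")


@dataclass
class AdductTable:
    """Samples x adducts matrix of areas with optional replicate structure.

    ``raw_area`` rows are samples, columns adducts; ``norm_area`` is
    raw x 100 / dG per sample. ``replicate_of`` maps each sample to its
    parent animal for RSD filtering (absent entries mean un-replicated).
    """

    samples: list[str]
    adducts: list[str]
    raw_area: pd.DataFrame
    dg_area: pd.Series
    norm_area: pd.DataFrame = field(init=False)
    replicate_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw_area = self.raw_area.loc[self.samples, self.adducts].astype(float)
        self.dg_area = self.dg_area.loc[self.samples].astype(float)
        self.norm_area = normalize_to_dG(self.raw_area, self.dg_area)


def integrate_targets(
    run: Run,
    master: list[MasterEntry],
    q: QuantParams | None = None,
    det: PeakDetectionParams | None = None,
) -> list[TargetResult]:
    """Integrate each master-list target in one run.

    A target is detected when its MS1 EIC (entry m/z +- ppm_tol) contains a
    peak whose apex lies within ``rt_tol`` minutes of the consensus RT; the
    closest such peak supplies the area. Absence is reported, not raised.
    """
    if not master:
        raise ValueError("master list is empty")
    q = q or QuantParams()
    det = det or PeakDetectionParams()
    out: list[TargetResult] = []
    for entry in master:
        chrom = extract_eic(run, entry.mz, q.ppm_tol, ms_level=1)
        best = None
        for pk in detect_peaks(chrom, det):
            d = abs(pk.apex_rt - entry.rt)
            if d <= q.rt_tol and (best is None or d < best[0]):
                best = (d, pk)
        if best is None:
            out.append(TargetResult(entry.adduct_id, False, 0.0))
        else:
            out.append(TargetResult(entry.adduct_id, True, best[1].area, best[1].apex_rt))
    return out


def normalize_to_dG(raw_area: pd.DataFrame, dg_area: pd.Series) -> pd.DataFrame:
    """Per-sample relative areas: raw x 100 / dG.

    Rows of ``raw_area`` are samples and must match ``dg_area``'s index.
    """
    dg = dg_area.loc[raw_area.index].astype(float)
    bad = dg[dg <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive dG area for sample(s): {', '.join(map(str, bad.index))}"
        )
    return raw_area.astype(float).mul(100.0 / dg, axis=0)


def rsd_filter(
    table: AdductTable,
    rsd_max: float = 20.0,
    aggregate: str = "max",
) -> tuple[list[str], pd.DataFrame]:
    """Retain adducts whose replicate RSD is strictly below ``rsd_max`` %.

    RSD per animal = 100 x sd / mean of the normalized areas across that
    animal's replicate digestions (sample sd, ddof=1); per-animal values are
    aggregated across animals by ``aggregate`` ("max", conservative default,
    or "mean"). Adducts with a zero replicate mean are excluded and flagged
    in the returned detail frame.
    """
    if aggregate not in ("max", "mean"):
        raise ValueError("aggregate must be 'max' or 'mean'")
    groups: dict[str, list[str]] = {}
    for sample, animal in table.replicate_of.items():
        groups.setdefault(animal, []).append(sample)
    groups = {a: s for a, s in groups.items() if len(s) >= 2}
    if not groups:
        raise ValueError("RSD filtering needs >=2 replicates for at least one animal")

    records = []
    retained: list[str] = []
    for adduct in table.adducts:
        rsds = []
        zero_mean = False
        for animal, samples in groups.items():
            vals = table.norm_area.loc[samples, adduct].to_numpy(float)
            m = vals.mean()
            if m == 0:
                zero_mean = True
                continue
            rsds.append(100.0 * vals.std(ddof=1) / m)
        if zero_mean or not rsds:
            records.append({"adduct_id": adduct, "rsd": np.nan, "retained": False,
                            "reason": "zero replicate mean"})
            continue
        agg = max(rsds) if aggregate == "max" else float(np.mean(rsds))
        keep = agg < rsd_max
        records.append({"adduct_id": adduct, "rsd": agg, "retained": keep,
                        "reason": "" if keep else f"RSD {agg:.1f}% >= {rsd_max}%"})
        if keep:
            retained.append(adduct)
    return retained, pd.DataFrame(records)
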
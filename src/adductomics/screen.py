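"""Untargeted neutral-loss screening for 2'-deoxyribonucleoside adducts.

A protonated deoxyribonucleoside fragments by losing the 2'-deoxyribose
moiety (116.0473 Da), leaving the protonated nucleobase. Screening therefore
pairs every MS1 chromatographic peak with a co-eluting MS2 peak, in the DIA
window covering the precursor, at precursor m/z minus the loss mass. Per-run
hit lists from several samples are merged into a master list of consensus
targets for the targeted confirmation stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import DEOXYRIBOSE_LOSS
from .ms_io import Run, window_for_mz
from .peaks import Chromatogram, ChromPeak, PeakDetectionParams, detect_peaks

__all__ = [
    "ScreenParams",
    "PutativeAdduct",
    "MasterEntry",
    "screen_run",
    "build_master_list",
    "master_to_frame",
]


@dataclass(frozen=True)
class ScreenParams:
    """Neutral-loss screening tolerances.

    ``ppm_tol`` applies to the loss criterion referenced to the *precursor*
    m/z. ``scan_lo``/``scan_hi`` bound the precursor m/z range considered
    (195-355 for the low-mass acquisition, 350-600 for the high-mass one).
    """

    neutral_loss_mass: float = DEOXYRIBOSE_LOSS
    ppm_tol: float = 5.0
    coelution_tol: float = 0.1
    scan_lo: float = 195.0
    scan_hi: float = 355.0

    def __post_init__(self) -> None:
        if self.neutral_loss_mass <= 0:
            raise ValueError("neutral_loss_mass must be positive")
        if self.ppm_tol <= 0:
            raise ValueError("ppm_tol must be positive")
        if self.coelution_tol <= 0:
            raise ValueError("coelution_tol must be positive")


@dataclass(frozen=True)
class PutativeAdduct:
    """One qualifying precursor/fragment neutral-loss pair in one sample."""

    precursor_mz: float
    fragment_mz: float
    rt: float
    observed_loss: float
    loss_ppm_error: float
    precursor_snr: float
    precursor_area: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.precursor_mz <= self.fragment_mz:
            raise ValueError("precursor m/z must exceed fragment m/z")


@dataclass(frozen=True)
class MasterEntry:
    """Cross-sample consensus target: median m/z and RT of one merged group."""

    adduct_id: str
    mz: float
    rt: float
    mass_class: str  # "low" | "high"
    n_samples_detected: int


class _CentroidIndex:
    """All centroids of one MS level (and DIA window) as flat sorted arrays,
    so any EIC is two searchsorted calls plus bincounts."""

    def __init__(self, spectra) -> None:
        self.rt = np.array([s.rt for s in spectra])
        self.n = len(spectra)
        if self.n:
            mz = np.concatenate([s.mz for s in spectra]) if self.n else np.empty(0)
            inten = np.concatenate([s.intensity for s in spectra])
            sidx = np.concatenate(
                [np.full(s.mz.size, i) for i, s in enumerate(spectra)]
            )
            order = np.argsort(mz, kind="stable")
            self.mz = mz[order]
            self.intensity = inten[order]
            self.spec_idx = sidx[order].astype(np.int64)
        else:
            self.mz = np.empty(0)
            self.intensity = np.empty(0)
            self.spec_idx = np.empty(0, dtype=np.int64)

    def eic(self, target_mz: float, tol_da: float, ppm_tol: float) -> Chromatogram:
        lo = np.searchsorted(self.mz, target_mz - tol_da, side="left")
        hi = np.searchsorted(self.mz, target_mz + tol_da, side="right")
        inten = np.bincount(
            self.spec_idx[lo:hi], weights=self.intensity[lo:hi], minlength=self.n
        )
        wsum = np.bincount(
            self.spec_idx[lo:hi],
            weights=self.intensity[lo:hi] * self.mz[lo:hi],
            minlength=self.n,
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            mzw = np.where(inten > 0, wsum / np.maximum(inten, 1e-300), np.nan)
        return Chromatogram(self.rt, inten, target_mz, ppm_tol, mzw)


def _candidate_bins(index: _CentroidIndex, lo: float, hi: float, ppm_tol: float, min_points: int):
    """Greedy 1-D clustering of MS1 centroid m/z: split where the gap between
    adjacent sorted centroids exceeds the ppm tolerance."""
    sel = (index.mz >= lo) & (index.mz < hi)
    mz = index.mz[sel]
    inten = index.intensity[sel]
    if mz.size == 0:
        return []
    gaps = np.diff(mz) > mz[:-1] * ppm_tol * 1e-6
    bounds = np.concatenate([[0], np.nonzero(gaps)[0] + 1, [mz.size]])
    centers = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a >= min_points:
            w = inten[a:b]
            centers.append(float(np.dot(mz[a:b], w) / w.sum()))
    return centers


def screen_run(
    run: Run,
    det: PeakDetectionParams | None = None,
    scr: ScreenParams | None = None,
    sample_id: str = "",
) -> list[PutativeAdduct]:
    """Detect putative deoxyribonucleoside adducts in one DIA run.

    MS1 centroids inside the scan range are clustered into candidate m/z
    bins; each bin's EIC is peak-detected; for every precursor peak the MS2
    EIC at (precursor - loss mass), in the DIA window containing the
    precursor, must show a peak co-eluting within ``coelution_tol`` minutes.
    The loss tolerance in Da is ``ppm_tol`` x precursor m/z x 1e-6.
    """
    det = det or PeakDetectionParams()
    scr = scr or ScreenParams()
    if run.dia_scheme is None or not run.ms2_spectra():
        raise ValueError("no DIA spectra: screening requires MS2 scans")
    ms1 = _CentroidIndex(run.ms1_spectra())
    ms2_by_window: dict[int, _CentroidIndex] = {}

    hits: list[PutativeAdduct] = []
    for center in _candidate_bins(ms1, scr.scan_lo, scr.scan_hi, scr.ppm_tol, det.min_points):
        if not run.dia_scheme.contains(center):
            continue
        tol_da = center * scr.ppm_tol * 1e-6
        for pk in detect_peaks(ms1.eic(center, tol_da, scr.ppm_tol), det):
            prec_mz = pk.observed_mz if np.isfinite(pk.observed_mz) else center
            widx = window_for_mz(run.dia_scheme, prec_mz)
            if widx not in ms2_by_window:
                ms2_by_window[widx] = _CentroidIndex(run.ms2_spectra(widx))
            frag_target = prec_mz - scr.neutral_loss_mass
            loss_tol_da = prec_mz * scr.ppm_tol * 1e-6
            frag_chrom = ms2_by_window[widx].eic(frag_target, loss_tol_da, scr.ppm_tol)
            frag_peak = _coeluting_peak(frag_chrom, det, pk, scr.coelution_tol)
            if frag_peak is None:
                continue
            frag_mz = (
                frag_peak.observed_mz
                if np.isfinite(frag_peak.observed_mz)
                else frag_target
            )
            loss = prec_mz - frag_mz
            loss_ppm = (loss - scr.neutral_loss_mass) / prec_mz * 1e6
            if abs(loss_ppm) > scr.ppm_tol:
                continue
            hits.append(
                PutativeAdduct(
                    precursor_mz=prec_mz,
                    fragment_mz=frag_mz,
                    rt=pk.apex_rt,
                    observed_loss=loss,
                    loss_ppm_error=loss_ppm,
                    precursor_snr=pk.snr,
                    precursor_area=pk.area,
                    sample_id=sample_id,
                )
            )
    hits.sort(key=lambda h: (h.precursor_mz, h.rt))
    return hits


def _coeluting_peak(
    chrom: Chromatogram,
    det: PeakDetectionParams,
    precursor_peak: ChromPeak,
    coelution_tol: float,
) -> ChromPeak | None:
    best = None
    for pk in detect_peaks(chrom, det):
        d = abs(pk.apex_rt - precursor_peak.apex_rt)
        if d <= coelution_tol and (best is None or d < best[0]):
            best = (d, pk)
    return best[1] if best else None


def build_master_list(
    per_sample: list[list[PutativeAdduct]],
    merge_ppm: float = 5.0,
    merge_rt: float = 0.5,
    low_range: tuple[float, float] = (195.0, 355.0),
) -> list[MasterEntry]:
    """Merge per-sample hit lists into consensus targets.

    Single-linkage grouping: two hits link if they agree within ``merge_ppm``
    on m/z and ``merge_rt`` minutes on RT; groups take median m/z and RT.
    IDs are L1.../H1... by ascending m/z within the low/high mass class,
    the class given by whether the consensus m/z falls in ``low_range``.
    """
    if merge_ppm <= 0 or merge_rt <= 0:
        raise ValueError("merge tolerances must be positive")
    hits = [h for sample in per_sample for h in sample]
    if not hits:
        return []
    hits.sort(key=lambda h: h.precursor_mz)
    mz = np.array([h.precursor_mz for h in hits])
    rt = np.array([h.rt for h in hits])

    parent = list(range(len(hits)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(len(hits)):
        j = i + 1
        while j < len(hits) and mz[j] - mz[i] <= mz[i] * merge_ppm * 1e-6:
            if abs(rt[j] - rt[i]) <= merge_rt:
                union(i, j)
            j += 1

    groups: dict[int, list[int]] = {}
    for i in range(len(hits)):
        groups.setdefault(find(i), []).append(i)

    raw_entries = []
    for members in groups.values():
        gmz = float(np.median(mz[members]))
        grt = float(np.median(rt[members]))
        n_samples = len({hits[i].sample_id for i in members})
        mass_class = "low" if low_range[0] <= gmz < low_range[1] else "high"
        raw_entries.append((gmz, grt, mass_class, n_samples))

    entries: list[MasterEntry] = []
    for cls, prefix in (("low", "L"), ("high", "H")):
        cls_entries = sorted(e for e in raw_entries if e[2] == cls)
        for k, (gmz, grt, _, n_samples) in enumerate(cls_entries, start=1):
            entries.append(MasterEntry(f"{prefix}{k}", gmz, grt, cls, n_samples))
    entries.sort(key=lambda e: e.mz)
    return entries


def master_to_frame(entries: list[MasterEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "adduct_id": e.adduct_id,
                "mz": e.mz,
                "rt": e.rt,
                "mass_class": e.mass_class,
                "n_samples_detected": e.n_samples_detected,
            }
            for e in entries
        ]
    )
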
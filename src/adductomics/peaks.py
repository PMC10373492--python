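"""Extracted-ion chromatograms and chromatographic peak detection.

Detection follows a matched-filter design: Gaussian smoothing, a pair of
zero-area (negated second-derivative-of-Gaussian, i.e. Ricker) filters whose
responses must both be positive at a candidate apex, a robust sliding-window
noise estimate (1.4826 x MAD), and a signal-to-noise cutoff. Peak area is
the trapezoidal integral of the raw trace between the zero crossings of the
narrow zero-area filter response.

The filter widths and the noise-window width are expressed in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ms_io import Run

__all__ = [
    "Chromatogram",
    "PeakDetectionParams",
    "ChromPeak",
    "extract_eic",
    "detect_peaks",
    "zero_area_kernel",
]


@dataclass
class Chromatogram:
    """Intensity vs retention time at a fixed m/z +- tolerance.

    ``mz_weighted`` holds the per-point intensity-weighted mean m/z of the
    matched centroids (NaN where no centroid matched); it lets callers
    recover the observed m/z of a peak without re-touching the spectra.
    """

    rt: np.ndarray
    intensity: np.ndarray
    target_mz: float
    ppm_tol: float
    mz_weighted: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")
        if self.rt.size > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("rt must be strictly ascending")


@dataclass(frozen=True)
class PeakDetectionParams:
    """Tunables of the matched-filter peak detector.

    Defaults follow the screening configuration used for deoxyribonucleoside
    adduct data: smoothing sigma 0.075 min, noise window 8.0 min, zero-area
    filter widths 0.085 and 0.165 min, S/N cutoff 5. ``min_points`` demands
    that a peak persist over several scans, which suppresses single-spike
    artifacts in sparse centroid EICs.
    """

    gauss_sigma: float = 0.075
    noise_window: float = 8.0
    zaf1_width: float = 0.085
    zaf2_width: float = 0.165
    snr_min: float = 5.0
    min_points: int = 4

    def __post_init__(self) -> None:
        for name in ("gauss_sigma", "noise_window", "zaf1_width", "zaf2_width", "snr_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")


@dataclass(frozen=True)
class ChromPeak:
    apex_rt: float
    apex_intensity: float
    area: float
    snr: float
    left_rt: float
    right_rt: float
    observed_mz: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.left_rt <= self.apex_rt <= self.right_rt):
            raise ValueError("apex must lie within peak bounds")


def extract_eic(
    run: Run,
    target_mz: float,
    ppm_tol: float,
    ms_level: int = 1,
    window: int | None = None,
    tol_da: float | None = None,
) -> Chromatogram:
    """Sum centroid intensities within ``target_mz`` +- tolerance per spectrum.

    The tolerance is ``ppm_tol`` relative to ``target_mz`` unless an absolute
    ``tol_da`` is given (screening references the neutral-loss tolerance to
    the precursor m/z, which callers express via ``tol_da``). For MS2 the
    DIA ``window`` index is required. Spectra with no matching centroid
    contribute zero; gaps are not interpolated.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    if ms_level == 2 and window is None:
        raise ValueError("MS2 EIC extraction requires a DIA window index")
    tol = tol_da if tol_da is not None else target_mz * ppm_tol * 1e-6
    spectra = run.ms1_spectra() if ms_level == 1 else run.ms2_spectra(window)
    rt = np.array([s.rt for s in spectra])
    inten = np.zeros(len(spectra))
    mzw = np.full(len(spectra), np.nan)
    for i, s in enumerate(spectra):
        lo = np.searchsorted(s.mz, target_mz - tol, side="left")
        hi = np.searchsorted(s.mz, target_mz + tol, side="right")
        if hi > lo:
            seg_int = s.intensity[lo:hi]
            total = seg_int.sum()
            inten[i] = total
            if total > 0:
                mzw[i] = float(np.dot(s.mz[lo:hi], seg_int) / total)
    return Chromatogram(rt, inten, target_mz, ppm_tol, mzw)


def zero_area_kernel(width: float, dt: float) -> np.ndarray:
    """Negated second derivative of a Gaussian of sigma ``width`` minutes,
    sampled at spacing ``dt``, offset so its coefficients sum to zero."""
    half = max(int(np.ceil(4.0 * width / dt)), 2)
    x = np.arange(-half, half + 1) * dt
    u = x / width
    k = (1.0 - u**2) * np.exp(-0.5 * u**2)
    k -= k.mean()
    return k


def _gaussian_smooth(y: np.ndarray, sigma_pts: float) -> np.ndarray:
    half = max(int(np.ceil(4.0 * sigma_pts)), 1)
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sigma_pts) ** 2)
    k /= k.sum()
    return np.convolve(y, k, mode="same")


def _zero_crossings(resp: np.ndarray, apex: int) -> tuple[int, int]:
    neg = resp <= 0
    left_candidates = np.nonzero(neg[: apex + 1])[0]
    left = int(left_candidates[-1]) if left_candidates.size else 0
    right_candidates = np.nonzero(neg[apex:])[0]
    right = int(apex + right_candidates[0]) if right_candidates.size else resp.size - 1
    return left, right


def detect_peaks(chrom: Chromatogram, params: PeakDetectionParams | None = None) -> list[ChromPeak]:
    """Detect chromatographic peaks in an EIC.

    Candidate apexes are local maxima of the smoothed trace with positive
    response under both zero-area filters; candidates closer than the wide
    filter width keep only the higher apex. Baseline and noise come from the
    raw trace in a ``noise_window``-minute window centred on the apex and
    excluding the peak region: baseline is the median, noise is the robust
    quantile spread (84th - 16th percentile)/2, which equals the MAD-based
    sigma for symmetric noise but does not collapse on the one-sided
    intensity distributions of sparse centroid EICs. S/N is the
    baseline-subtracted smoothed apex over the noise level (infinite on an
    otherwise empty trace).
    """
    params = params or PeakDetectionParams()
    y = chrom.intensity
    n = y.size
    if n < 5:
        return []
    dt = float(np.median(np.diff(chrom.rt)))
    smooth = _gaussian_smooth(y, params.gauss_sigma / dt)
    r1 = np.convolve(smooth, zero_area_kernel(params.zaf1_width, dt), mode="same")
    r2 = np.convolve(smooth, zero_area_kernel(params.zaf2_width, dt), mode="same")

    interior = np.arange(1, n - 1)
    is_max = (smooth[1:-1] > smooth[:-2]) & (smooth[1:-1] >= smooth[2:]) & (smooth[1:-1] > 0)
    cand = interior[is_max & (r1[1:-1] > 0) & (r2[1:-1] > 0)]
    if cand.size == 0:
        return []

    # merge near-duplicate apexes: within one wide-kernel width keep the higher
    min_sep = max(int(round(params.zaf2_width / dt)), 1)
    order = cand[np.argsort(smooth[cand])[::-1]]
    kept: list[int] = []
    for idx in order:
        if all(abs(idx - k) >= min_sep for k in kept):
            kept.append(int(idx))
    kept.sort()

    half_noise = params.noise_window / 2.0
    peaks: list[ChromPeak] = []
    for apex in kept:
        left, right = _zero_crossings(r1, apex)
        if np.count_nonzero(y[left : right + 1]) < params.min_points:
            continue
        in_window = np.abs(chrom.rt - chrom.rt[apex]) <= half_noise
        in_window[left : right + 1] = False
        resid = y[in_window]
        if resid.size >= 4:
            baseline = float(np.median(resid))
            p_lo, p_hi = np.percentile(resid, [15.87, 84.13])
            noise = float(p_hi - p_lo) / 2.0
        else:
            baseline, noise = 0.0, 0.0
        height = float(smooth[apex]) - baseline
        if height <= 0:
            continue
        snr = height / noise if noise > 0 else float("inf")
        if snr < params.snr_min:
            continue
        apex_height = float(y[left : right + 1].max())
        area = float(np.trapezoid(y[left : right + 1], chrom.rt[left : right + 1]))
        observed_mz = float("nan")
        if chrom.mz_weighted is not None:
            seg_w = y[left : right + 1]
            seg_mz = chrom.mz_weighted[left : right + 1]
            ok = np.isfinite(seg_mz) & (seg_w > 0)
            if np.any(ok):
                observed_mz = float(np.dot(seg_mz[ok], seg_w[ok]) / seg_w[ok].sum())
        peaks.append(
            ChromPeak(
                apex_rt=float(chrom.rt[apex]),
                apex_intensity=apex_height,
                area=area,
                snr=snr,
                left_rt=float(chrom.rt[left]),
                right_rt=float(chrom.rt[right]),
                observed_mz=observed_mz,
            )
        )
    return peaks
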
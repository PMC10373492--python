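"""Synthetic DIA runs and study-level tables with known ground truth.

Two generators back the test pyramid:

* :func:`simulate_run` builds a DIA LC-HRMS run — MS1 full scans plus one
  MS2 scan per isolation window per cycle — with planted deoxyribonucleoside
  adducts as Gaussian elution peaks, precursor -> (precursor - 116.0473)
  fragment pairs at a configurable fragmentation efficiency, ppm-scale mass
  jitter and Poisson-like baseline noise. A manifest records the ground
  truth for recovery checks.

* :func:`simulate_study` builds an adduct x sample table plus site metadata
  emulating the field design (19 stations in two basins, 47 individuals,
  contaminated/reference status, PAH congeners, trace metals and the
  pollution load index), with planted group effects on chosen adducts and
  Gaussian-copula correlations between chosen adduct/contaminant pairs.

Everything is driven by an explicit seed; identical seeds give identical
output (byte-identical mzML via :func:`adductomics.ms_io.write_mzml`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import DEOXYRIBOSE_LOSS
from .ms_io import DiaScheme, Run, Spectrum, build_dia_scheme
from .quantify import AdductTable
from .stats import SiteMetadata

__all__ = [
    "PlantedAdduct",
    "RunNoise",
    "StudyDesign",
    "simulate_run",
    "simulate_study",
    "default_stations",
    "HIGH_SCHEME",
    "LOW_SCHEME",
    "PAH_CONGENERS",
    "METALS",
]

LOW_SCHEME = (195.0, 355.0, 10.0)
HIGH_SCHEME = (347.0, 607.0, 10.0)

PAH_CONGENERS = [
    "Nap", "Phe", "Ant", "Flt", "Pyr", "BaA", "Chr", "BbF", "BkF", "BaP", "BghiP",
]
_LOW_PAH = {"Nap", "Phe", "Ant"}  # 2-3 ring congeners summed into LmPAH
METALS = ["As", "Cd", "Co", "Cr", "Cu", "Hg", "Ni", "Pb", "V", "Zn"]


@dataclass(frozen=True)
class PlantedAdduct:
    """Ground truth for one spiked adduct in a simulated run."""

    precursor_mz: float
    rt: float  # apex, minutes
    abundance: float  # chromatographic area, counts x min
    fragmentation_efficiency: float = 0.5
    sigma_rt: float = 0.05  # Gaussian elution sigma, minutes
    ms1_only: bool = False  # e.g. unmodified dG, outside the DIA precursor range

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if not 0 < self.fragmentation_efficiency <= 1:
            raise ValueError("fragmentation efficiency must be in (0, 1]")

    @property
    def fragment_mz(self) -> float:
        return self.precursor_mz - DEOXYRIBOSE_LOSS

    @property
    def apex_intensity(self) -> float:
        return self.abundance / (self.sigma_rt * math.sqrt(2.0 * math.pi))


@dataclass(frozen=True)
class RunNoise:
    """Baseline and mass-jitter model for simulated runs."""

    ppm_jitter_sd: float = 1.0
    baseline_level: float = 30.0  # mean intensity of a baseline centroid
    ms1_peaks_per_scan: float = 30.0  # Poisson mean
    ms2_peaks_per_scan: float = 10.0
    min_intensity: float = 1.0  # centroids below this are not written


def simulate_run(
    panel: list[PlantedAdduct],
    scheme: DiaScheme | None = None,
    noise: RunNoise = RunNoise(),
    gradient_length: float = 20.0,
    cycle_time: float = 1.0,  # seconds per MS1 + full DIA sweep
    ms1_range: tuple[float, float] = (110.0, 650.0),
    seed: int = 0,
) -> tuple[Run, pd.DataFrame]:
    """Simulate one DIA run; returns the run and its ground-truth manifest."""
    scheme = scheme or build_dia_scheme(*HIGH_SCHEME)
    for a in panel:
        if not a.ms1_only and not scheme.contains(a.precursor_mz):
            raise ValueError(
                f"planted precursor {a.precursor_mz} outside DIA range "
                f"[{scheme.precursor_lo}, {scheme.precursor_hi})"
            )
        if not 0 <= a.rt <= gradient_length:
            raise ValueError(f"planted RT {a.rt} outside gradient 0-{gradient_length} min")
    rng = np.random.default_rng(seed)
    cycle_min = cycle_time / 60.0
    n_cycles = int(gradient_length / cycle_min)
    scans_per_cycle = 1 + scheme.n_windows
    window_of = {
        i: [a for a in panel if not a.ms1_only
            and scheme.precursor_lo + i * scheme.window_width
            <= a.precursor_mz < scheme.precursor_lo + (i + 1) * scheme.window_width]
        for i in range(scheme.n_windows)
    }

    spectra: list[Spectrum] = []
    for c in range(n_cycles):
        t0 = c * cycle_min
        # MS1 full scan
        mz, inten = _scan_peaks(
            panel, t0, rng, noise, lambda a: (a.precursor_mz, 1.0)
        )
        mz, inten = _add_baseline(
            mz, inten, rng, noise.ms1_peaks_per_scan, ms1_range, noise
        )
        spectra.append(Spectrum(1, t0, mz, inten))
        # DIA sweep
        for w in range(scheme.n_windows):
            t = t0 + (w + 1) * cycle_min / scans_per_cycle
            frag_lo = 50.0
            frag_hi = scheme.precursor_lo + (w + 1) * scheme.window_width
            mz, inten = _scan_peaks(
                window_of[w], t, rng, noise,
                lambda a: (a.fragment_mz, a.fragmentation_efficiency),
            )
            mz, inten = _add_baseline(
                mz, inten, rng, noise.ms2_peaks_per_scan, (frag_lo, frag_hi), noise
            )
            spectra.append(
                Spectrum(2, t, mz, inten,
                         isolation_center=float(scheme.centers[w]),
                         isolation_width=scheme.window_width)
            )

    run = Run(spectra, "positive", ms1_range, scheme)
    manifest = pd.DataFrame(
        {
            "precursor_mz": [a.precursor_mz for a in panel],
            "fragment_mz": [a.fragment_mz for a in panel],
            "rt": [a.rt for a in panel],
            "abundance": [a.abundance for a in panel],
            "fragmentation_efficiency": [a.fragmentation_efficiency for a in panel],
            "sigma_rt": [a.sigma_rt for a in panel],
            "apex_intensity": [a.apex_intensity for a in panel],
        }
    )
    return run, manifest


def _scan_peaks(adducts, t, rng, noise, mz_and_scale):
    mzs, intens = [], []
    for a in adducts:
        target_mz, scale = mz_and_scale(a)
        h = scale * a.apex_intensity * math.exp(-0.5 * ((t - a.rt) / a.sigma_rt) ** 2)
        if h < noise.min_intensity:
            continue
        jitter = rng.normal(0.0, noise.ppm_jitter_sd) * 1e-6
        mzs.append(target_mz * (1.0 + jitter))
        intens.append(h)
    return np.array(mzs), np.array(intens)


def _add_baseline(mz, inten, rng, lam, mz_range, noise):
    n = rng.poisson(lam)
    if n:
        bmz = rng.uniform(mz_range[0], mz_range[1], n)
        bint = noise.baseline_level * rng.exponential(1.0, n)
        mz = np.concatenate([mz, bmz])
        inten = np.concatenate([inten, bint])
    keep = inten >= noise.min_intensity
    mz, inten = mz[keep], inten[keep]
    # sum intensities at exact duplicate m/z so arrays stay strictly ascending
    umz, inverse = np.unique(mz, return_inverse=True)
    if umz.size != mz.size:
        inten = np.bincount(inverse, weights=inten)
        mz = umz
    else:
        order = np.argsort(mz)
        mz, inten = mz[order], inten[order]
    return mz, inten


def default_stations() -> pd.DataFrame:
    """The field sampling design: 19 stations in two basins with their
    contamination status and number of individuals (47 in total)."""
    rows = [
        ("BS", "G 10", "R", 3), ("BS", "G 11", "R", 2), ("BS", "N 4-1", "R", 2),
        ("BS", "US 5", "C", 1), ("BS", "57", "C", 2), ("BS", "58", "C", 2),
        ("BS", "SU 4", "C", 2), ("BS", "Norrsundet", "C", 10), ("BS", "KUD 64", "R", 1),
        ("NBP", "Gr Utsjo", "R", 2), ("NBP", "6025", "C", 1), ("NBP", "6022", "C", 2),
        ("NBP", "6004", "R", 1), ("NBP", "6019", "R", 1), ("NBP", "Braviken 6", "C", 4),
        ("NBP", "Braviken 8", "C", 4), ("NBP", "St. Anna 6", "C", 4),
        ("NBP", "Gryt 1", "R", 1), ("NBP", "Gryt 3", "R", 2),
    ]
    return pd.DataFrame(rows, columns=["basin", "station", "status", "n_individuals"])


def _default_effects() -> dict[str, float]:
    # one down- and five up-regulated adducts in contaminated animals,
    # mirroring the discriminating-panel structure
    return {"H60": -2.0, "L10": 2.0, "L20": 2.0, "L30": 2.0, "L40": 2.0, "H30": 2.0}


@dataclass
class StudyDesign:
    """Design of a synthetic adduct x sample study.

    Defaults reproduce the field conditions: 19 stations / 47 individuals in
    two basins, 53 low-mass + 66 high-mass adducts, six effect adducts at
    |log2 FC| = 2 between contaminated and reference animals, moderate
    biological noise, and positive correlations between a few high-mass
    adducts and the PAH congeners.
    """

    stations: pd.DataFrame = field(default_factory=default_stations)
    n_adducts_low: int = 53
    n_adducts_high: int = 66
    effect_adducts: dict[str, float] = field(default_factory=_default_effects)
    contaminant_targets: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("H10", "Pyr"): 0.5, ("H20", "BaP"): 0.5}
    )
    noise_sd: float = 0.6  # sd of log2 adduct abundance between animals
    replicate_sd: float = 0.08  # sd of log2 area between replicate digestions
    n_replicate_animals: int = 6
    n_replicates: int = 3
    contaminant_log2_shift: float = 1.5  # C-vs-R elevation of untargeted contaminants
    seed: int = 0


def simulate_study(design: StudyDesign | None = None) -> tuple[AdductTable, SiteMetadata]:
    """Generate a dG-normalizable adduct table and matching site metadata.

    Adduct abundances are lognormal around an adduct-specific baseline;
    effect adducts are shifted by their log2 effect in contaminated animals.
    Contaminants with a correlation target are built on the log scale as
    rho x (standardized adduct) + sqrt(1 - sum rho^2) x noise (Gaussian
    copula); the remaining contaminants are lognormal with a contaminated-
    site elevation. The first ``n_replicate_animals`` animals receive
    ``n_replicates`` replicate digestions for RSD filtering.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(design.seed)
    ln2 = math.log(2.0)

    adduct_ids = [f"L{i+1}" for i in range(design.n_adducts_low)] + [
        f"H{i+1}" for i in range(design.n_adducts_high)
    ]
    unknown = set(design.effect_adducts) - set(adduct_ids)
    if unknown:
        raise ValueError(f"effect adducts not in panel: {sorted(unknown)}")

    animals, stations, basins, statuses = [], [], [], []
    for _, row in design.stations.iterrows():
        for k in range(int(row.n_individuals)):
            animals.append(f"{row.station.replace(' ', '')}-{k+1}")
            stations.append(row.station)
            basins.append(row.basin)
            statuses.append(row.status)
    n_animals = len(animals)
    is_c = np.array([s == "C" for s in statuses])

    # per-animal true log abundances
    base = rng.uniform(-1.0, 1.0, size=len(adduct_ids))  # adduct-specific log2 baseline
    log2_abund = base[None, :] + rng.normal(0.0, design.noise_sd, (n_animals, len(adduct_ids)))
    for adduct, eff in design.effect_adducts.items():
        j = adduct_ids.index(adduct)
        log2_abund[is_c, j] += eff

    # contaminants on the log scale
    targets_by_cont: dict[str, list[tuple[str, float]]] = {}
    for (adduct, cont), rho in design.contaminant_targets.items():
        if adduct not in adduct_ids:
            raise ValueError(f"correlation target references unknown adduct {adduct!r}")
        targets_by_cont.setdefault(cont, []).append((adduct, rho))

    cont_names = PAH_CONGENERS + METALS
    cont_scale = {c: (4.0 if c in PAH_CONGENERS else 2.0) for c in cont_names}
    logs: dict[str, np.ndarray] = {}
    for cont in cont_names:
        pairs = targets_by_cont.get(cont, [])
        if pairs:
            rho_sq = sum(r**2 for _, r in pairs)
            if rho_sq > 1.0:
                raise ValueError(
                    f"infeasible correlation targets for {cont!r}: sum rho^2 = {rho_sq:.2f} > 1"
                )
            z = np.zeros(n_animals)
            for adduct, r in pairs:
                col = log2_abund[:, adduct_ids.index(adduct)]
                z += r * (col - col.mean()) / col.std()
            z += math.sqrt(1.0 - rho_sq) * rng.normal(0.0, 1.0, n_animals)
            logs[cont] = cont_scale[cont] + z
        else:
            z = rng.normal(0.0, 1.0, n_animals)
            z[is_c] += design.contaminant_log2_shift * ln2
            logs[cont] = cont_scale[cont] + z
    contaminants = pd.DataFrame({c: np.exp(v) for c, v in logs.items()}, index=animals)
    contaminants["LmPAH"] = contaminants[[c for c in PAH_CONGENERS if c in _LOW_PAH]].sum(axis=1)
    contaminants["HmPAH"] = contaminants[[c for c in PAH_CONGENERS if c not in _LOW_PAH]].sum(axis=1)
    metal_ref = contaminants[METALS].median()
    contaminants["PLI"] = np.exp(
        np.log(contaminants[METALS] / metal_ref).mean(axis=1)
    )

    # expand replicate digestions and back out raw areas through dG
    sample_ids, replicate_of, rows_animal = [], {}, []
    for i, animal in enumerate(animals):
        n_rep = design.n_replicates if i < design.n_replicate_animals else 1
        for r in range(n_rep):
            sid = f"{animal}_r{r+1}" if n_rep > 1 else animal
            sample_ids.append(sid)
            rows_animal.append(i)
            if n_rep > 1:
                replicate_of[sid] = animal
    rows_animal = np.array(rows_animal)
    norm_true = 2.0 ** (
        log2_abund[rows_animal]
        + rng.normal(0.0, design.replicate_sd, (len(sample_ids), len(adduct_ids)))
    )
    dg = pd.Series(
        np.exp(rng.normal(math.log(1e6), 0.3, len(sample_ids))), index=sample_ids, name="dg_area"
    )
    raw = pd.DataFrame(norm_true, index=sample_ids, columns=adduct_ids).mul(
        dg / 100.0, axis=0
    )
    table = AdductTable(
        samples=sample_ids,
        adducts=adduct_ids,
        raw_area=raw,
        dg_area=dg,
        replicate_of=replicate_of,
    )
    meta = SiteMetadata(
        station=pd.Series(np.array(stations)[rows_animal], index=sample_ids),
        basin=pd.Series(np.array(basins)[rows_animal], index=sample_ids),
        status=pd.Series(np.array(statuses)[rows_animal], index=sample_ids),
        contaminants=contaminants.loc[np.array(animals)[rows_animal]].set_axis(sample_ids),
    )
    return table, meta
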
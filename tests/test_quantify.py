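"""Targeted integration, dG normalization, and replicate-RSD filtering."""

import numpy as np
import pandas as pd
import pytest

from adductomics.ms_io import build_dia_scheme
from adductomics.quantify import (
    AdductTable,
    QuantParams,
    dg_mz,
    integrate_targets,
    normalize_to_dG,
    rsd_filter,
)
from adductomics.screen import MasterEntry
from adductomics.simulate import PlantedAdduct, RunNoise, simulate_run

HIGH = build_dia_scheme(347.0, 607.0, 10.0)


def _run_with(panel, seed=0):
    run, _ = simulate_run(panel, HIGH, noise=RunNoise(), gradient_length=8.0, seed=seed)
    return run


def test_integrate_detects_planted_target_with_accurate_area():
    run = _run_with([PlantedAdduct(529.2973, 4.0, 3000.0)])
    res = integrate_targets(run, [MasterEntry("H1", 529.2973, 4.0, "high", 1)])
    assert res[0].detected
    assert res[0].area == pytest.approx(3000.0, rel=0.05)


def test_integrate_reports_absent_target_as_not_detected():
    run = _run_with([PlantedAdduct(529.2973, 4.0, 3000.0)])
    res = integrate_targets(run, [MasterEntry("H9", 480.0000, 4.0, "high", 1)])
    assert not res[0].detected and res[0].area == 0.0


def test_integrate_rejects_mass_offset_beyond_tolerance():
    """A peak 6 ppm off the master m/z is not confirmed at 5 ppm."""
    off = 529.2973 * (1 + 6e-6)
    run = _run_with([PlantedAdduct(off, 4.0, 3000.0)])
    res = integrate_targets(run, [MasterEntry("H1", 529.2973, 4.0, "high", 1)])
    assert not res[0].detected


def test_integrate_rejects_rt_offset_beyond_tolerance():
    run = _run_with([PlantedAdduct(529.2973, 4.0, 3000.0)])
    res = integrate_targets(run, [MasterEntry("H1", 529.2973, 5.0, "high", 1)],
                            QuantParams(rt_tol=0.2))
    assert not res[0].detected


def test_dg_reference_mz():
    assert dg_mz() == pytest.approx(268.1040, abs=5e-4)


def test_normalize_arithmetic_and_zero_preservation():
    raw = pd.DataFrame({"A1": [50.0, 0.0]}, index=["s1", "s2"])
    dg = pd.Series([1000.0, 500.0], index=["s1", "s2"])
    norm = normalize_to_dG(raw, dg)
    assert norm.loc["s1", "A1"] == 5.0
    assert norm.loc["s2", "A1"] == 0.0


def test_normalize_rejects_nonpositive_dg():
    raw = pd.DataFrame({"A1": [1.0]}, index=["s1"])
    with pytest.raises(ValueError, match="s1"):
        normalize_to_dG(raw, pd.Series([0.0], index=["s1"]))


def test_normalize_is_response_factor_invariant():
    """A common instrument-response factor on all areas cancels."""
    rng = np.random.default_rng(1)
    raw = pd.DataFrame(rng.uniform(10, 100, (4, 3)), index=list("abcd"),
                       columns=["x", "y", "z"])
    dg = pd.Series(rng.uniform(500, 1000, 4), index=list("abcd"))
    c = 7.3
    assert np.allclose(normalize_to_dG(raw * c, dg * c), normalize_to_dG(raw, dg))


def _table(values_by_adduct: dict, n_animals=2, n_rep=3):
    samples, replicate_of = [], {}
    for a in range(n_animals):
        for r in range(n_rep):
            sid = f"an{a}_r{r}"
            samples.append(sid)
            replicate_of[sid] = f"an{a}"
    raw = pd.DataFrame(values_by_adduct, index=samples)
    dg = pd.Series(100.0, index=samples)  # dG constant: norm = raw
    return AdductTable(samples=samples, adducts=list(values_by_adduct),
                       raw_area=raw, dg_area=dg, replicate_of=replicate_of)


def test_rsd_zero_variance_retained_and_high_variance_excluded():
    table = _table({
        "flat": [5.0, 5, 5, 5, 5, 5],          # RSD 0 -> retained
        "noisy": [1.0, 2, 3, 1, 2, 3],          # RSD 50% -> excluded
    })
    retained, detail = rsd_filter(table, rsd_max=20.0)
    assert retained == ["flat"]
    d = detail.set_index("adduct_id")
    assert d.loc["noisy", "rsd"] == pytest.approx(50.0)


def test_rsd_exactly_at_cutoff_is_excluded():
    """'below 20%' is strict: an adduct at exactly 20.0% RSD is dropped."""
    # triplicate (4, 5, 6): sd 1, mean 5 -> RSD exactly 20%
    table = _table({"edge": [4.0, 5, 6, 4, 5, 6]})
    retained, detail = rsd_filter(table, rsd_max=20.0)
    assert retained == []
    assert detail.rsd.iloc[0] == pytest.approx(20.0)


def test_rsd_zero_mean_excluded_with_reason():
    table = _table({"absent": [0.0, 0, 0, 0, 0, 0]})
    retained, detail = rsd_filter(table)
    assert retained == []
    assert "zero" in detail.reason.iloc[0]


def test_rsd_invariant_to_relabeling_and_scaling():
    table = _table({"a": [10.0, 11, 12, 20, 21, 19]})
    r1, d1 = rsd_filter(table)
    scaled = _table({"a": [v * 3.0 for v in [10.0, 11, 12, 20, 21, 19]]})
    r2, d2 = rsd_filter(scaled)
    assert r1 == r2
    assert d1.rsd.iloc[0] == pytest.approx(d2.rsd.iloc[0])
    # swapping replicate order within an animal changes nothing
    permuted = _table({"a": [12.0, 10, 11, 19, 20, 21]})
    _, d3 = rsd_filter(permuted)
    assert d3.rsd.iloc[0] == pytest.approx(d1.rsd.iloc[0])


def test_rsd_aggregation_max_vs_mean():
    table = _table({"a": [10.0, 10, 10, 10, 12, 14]})  # animal0 RSD 0, animal1 ~16.7%
    _, d_max = rsd_filter(table, aggregate="max")
    _, d_mean = rsd_filter(table, aggregate="mean")
    assert d_max.rsd.iloc[0] > d_mean.rsd.iloc[0]


def test_spike_in_confirmation_areas_within_five_percent(spike_run, spike_screen):
    """screen -> master -> targeted integration recovers >= 95% of the
    planted adducts with areas within 5% of ground truth."""
    run, _ = spike_run
    _, master, manifest = spike_screen
    results = integrate_targets(run, master)
    by_id = {e.adduct_id: e for e in master}
    n_ok = 0
    for res in results:
        if not res.detected:
            continue
        e = by_id[res.adduct_id]
        d = np.abs(manifest.precursor_mz - e.mz) / e.mz * 1e6
        truth = manifest.abundance.iloc[int(np.argmin(d))]
        if d.min() <= 5.0 and abs(res.area - truth) / truth <= 0.05:
            n_ok += 1
    assert n_ok >= 0.95 * len(manifest)
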
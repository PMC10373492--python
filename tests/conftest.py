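"""Shared fixtures: seeded simulated runs and studies with known ground truth.

The spike-in run is session-scoped because screening a full DIA run is the
most expensive step in the suite; every test reads, never mutates, it.
"""

from __future__ import annotations

import numpy as np
import pytest

from adductomics.ms_io import build_dia_scheme
from adductomics.peaks import PeakDetectionParams
from adductomics.screen import ScreenParams, build_master_list, screen_run
from adductomics.simulate import PlantedAdduct, RunNoise, simulate_run

SEED = 20260925


@pytest.fixture(scope="session")
def high_scheme():
    return build_dia_scheme(347.0, 607.0, 10.0)


@pytest.fixture(scope="session")
def spike_panel(high_scheme):
    """36 planted adducts spread over the high-mass range, apex S/N >= 10
    relative to the baseline-centroid level, fragmentation efficiency 0.5."""
    rng = np.random.default_rng(SEED)
    noise = RunNoise()
    mz = np.sort(rng.uniform(352.0, 602.0, 36))
    mz += np.arange(36) * 1e-3  # keep plants > 1 mDa apart
    rt = np.linspace(2.0, 18.0, 36) + rng.uniform(-0.2, 0.2, 36)
    snr = rng.uniform(10.0, 100.0, 36)
    sigma = 0.05
    panel = [
        PlantedAdduct(
            precursor_mz=float(m),
            rt=float(t),
            abundance=float(s * noise.baseline_level * sigma * np.sqrt(2 * np.pi)),
            fragmentation_efficiency=0.5,
            sigma_rt=sigma,
        )
        for m, t, s in zip(mz, rt, snr)
    ]
    return panel


@pytest.fixture(scope="session")
def spike_run(spike_panel, high_scheme):
    run, manifest = simulate_run(
        spike_panel, high_scheme, noise=RunNoise(), gradient_length=20.0, seed=SEED
    )
    return run, manifest


@pytest.fixture(scope="session")
def spike_screen(spike_run):
    run, manifest = spike_run
    hits = screen_run(
        run,
        PeakDetectionParams(),
        ScreenParams(scan_lo=350.0, scan_hi=605.0),
        sample_id="spike",
    )
    master = build_master_list([hits])
    return hits, master, manifest
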
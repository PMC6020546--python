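"""Shared fixtures.

The heavyweight objects of the study — the calibrated cohort and the
Monte Carlo sweeps over the full perturbation grids — are built once per
session and shared by the synthesis, robustness, and acceptance tests.
All randomness flows from MASTER_SEED.
"""

from __future__ import annotations

import numpy as np
import pytest

import egmentropy as eg
from egmentropy.synthesis import CohortSpec

MASTER_SEED = 1234

#: Reduced Monte Carlo scale used by the sweep fixtures: 10 realisations
#: per signal instead of the study's 50.
N_REALISATIONS = 10


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)


@pytest.fixture(scope="session")
def calibration():
    """Both classes calibrated to their baseline targets on 50 signals each."""
    nc = eg.calibrate_generator(
        eg.NC_BASELINE_TARGET, 0.01, eg.NC_PARAMS, "NC",
        n_signals=50, seed=MASTER_SEED,
    )
    c = eg.calibrate_generator(
        eg.C_BASELINE_TARGET, 0.02, eg.C_PARAMS, "C",
        n_signals=50, seed=MASTER_SEED,
    )
    return {"NC": nc, "C": c}


@pytest.fixture(scope="session")
def calibrated_spec(calibration) -> CohortSpec:
    return CohortSpec(
        nc_params=calibration["NC"].params,
        c_params=calibration["C"].params,
        master_seed=MASTER_SEED,
    )


@pytest.fixture(scope="session")
def cohort(calibrated_spec):
    """The 64 NC + 49 C study cohort at calibrated parameters."""
    return eg.generate_cohort(calibrated_spec)


@pytest.fixture(scope="session")
def baseline(cohort):
    """Per-signal baseline SampEn(2, 0.2) and the label array."""
    values = np.array([eg.sample_entropy(s).value for s in cohort])
    labels = np.array([s.label for s in cohort])
    return values, labels


@pytest.fixture(scope="session")
def sweeps(cohort):
    """One reduced-scale sweep per perturbation kind over the full grids."""
    return {
        kind: eg.run_sweep(
            cohort, kind, n_realisations=N_REALISATIONS, master_seed=MASTER_SEED
        )
        for kind in ("spikes", "loss_distributed", "loss_consecutive")
    }


@pytest.fixture(scope="session")
def spike_sweep_ps10_full_scale(cohort):
    """The p_s = 0.10 spike level at the study's own 50 realisations per
    signal (rho_xy is attenuated by per-signal Monte Carlo noise, so the
    robustness-rule check is run at full scale)."""
    return eg.run_sweep(
        cohort, "spikes", levels=[0.10], n_realisations=50, master_seed=MASTER_SEED
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 6+6 cohort of short signals for structural pipeline tests."""
    spec = CohortSpec(n_nc=6, n_c=6, duration_ms=400.0, master_seed=7)
    return eg.generate_cohort(spec)
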
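"""Shared setup for the numbered analysis scripts: the calibrated cohort
and common output paths. Every script regenerates the cohort
deterministically from MASTER_SEED rather than reading intermediate
files, so each one can be run in isolation."""

from __future__ import annotations

from pathlib import Path

import egmentropy as eg
from egmentropy.synthesis import CohortSpec

MASTER_SEED = 1234
N_REALISATIONS = 10  # reduced Monte Carlo scale (study scale is 50)
RESULTS = Path(__file__).resolve().parent.parent / "results"


def calibrated_spec(seed: int = MASTER_SEED) -> tuple[CohortSpec, dict]:
    """Calibrate both class generators to the baseline SampEn targets."""
    cal = {
        "NC": eg.calibrate_generator(
            eg.NC_BASELINE_TARGET, 0.01, eg.NC_PARAMS, "NC", n_signals=50, seed=seed
        ),
        "C": eg.calibrate_generator(
            eg.C_BASELINE_TARGET, 0.02, eg.C_PARAMS, "C", n_signals=50, seed=seed
        ),
    }
    spec = CohortSpec(
        nc_params=cal["NC"].params, c_params=cal["C"].params, master_seed=seed
    )
    return spec, cal
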
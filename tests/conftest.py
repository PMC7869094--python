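"""Shared fixtures.

The expensive fixtures (multi-seed group recovery, the 8-region group fit)
are session-scoped and lazily built, so the cheap unit tests never pay for
them; the group-inference tests and the acceptance tests share one
computation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from audconn.dcm.model import REGIONS_4, REGIONS_8
from audconn.experiment import (
    generate_design,
    generate_group_dataset,
    sample_population,
)
from audconn.pipeline import PipelineConfig, fit_subjects, group_inference

#: problem sizes for the seeded recovery studies (desk scale)
RECOVERY_N_SUBJECTS = 8
RECOVERY_SNR = 2.0
RECOVERY_N_RUNS = 4
RECOVERY_DT = 0.1
RECOVERY_SEEDS = tuple(range(1, 11))


def run_group_study(seed: int, regions=REGIONS_4, n_subjects=RECOVERY_N_SUBJECTS,
                    n_runs=RECOVERY_N_RUNS, snr=RECOVERY_SNR, dt=RECOVERY_DT,
                    free="modulations"):
    """Generate one synthetic group, fit all subjects, run group inference."""
    seeds = np.random.SeedSequence(seed).spawn(3)
    design = generate_design(np.random.default_rng(seeds[0]), n_runs=n_runs)
    profiles = sample_population(n_subjects,
                                 seed=np.random.default_rng(seeds[1]),
                                 regions=regions)
    dataset = generate_group_dataset(
        design, profiles, snr=snr,
        seed=int(seeds[2].generate_state(1)[0] % (2 ** 31)), dt=dt)
    config = PipelineConfig(seed=seed, n_subjects=n_subjects,
                            regions="left" if regions == REGIONS_4 else "bilateral",
                            n_runs=n_runs, snr=snr, dt=dt, free=free,
                            max_iter=32)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fits = fit_subjects(dataset, config)
        peb, models, info, bma = group_inference(fits, dataset)
    return {"dataset": dataset, "fits": fits, "peb": peb, "models": models,
            "info": info, "bma": bma}


@pytest.fixture(scope="session")
def group_recovery_runs():
    """Ten seeded synthetic groups (8 subjects, 4 left ROIs, SNR 2),
    each taken through subject inversion, PEB, greedy BMR, and BMA."""
    return {seed: run_group_study(seed) for seed in RECOVERY_SEEDS}


@pytest.fixture(scope="session")
def eight_region_run():
    """One seeded synthetic group over all 8 ROIs, through the full chain."""
    return run_group_study(101, regions=REGIONS_8, n_runs=2)
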
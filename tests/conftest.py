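"""Shared fixtures: the desk-scale network and seeded synthetic group studies.

The heavy session fixtures run the full inversion + family-comparison chain
once and are shared by the pipeline and acceptance tests.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from dcmerf.forward import SpatialModes, compute_spatial_modes, mode_reduce
from dcmerf.inversion import ForwardProblem, default_priors
from dcmerf.pipeline import run_family_analysis
from dcmerf.synth import (
    SyntheticGroundTruth,
    fixture_small,
    generate_erf_dataset,
    modulation_model_space,
)

GRID_T0, GRID_T1 = 0.0, 250.0


@pytest.fixture(scope="session")
def small_net():
    """Unilateral VC->MT->PPC fixture: (model, stim, grid, lead field)."""
    return fixture_small(beta=0.3, site=("gamma2", "PPC"))


@pytest.fixture(scope="session")
def noiseless_problem(small_net):
    """ForwardProblem on data-derived spatial modes, plus the generating theta."""
    model, stim, grid, lf = small_net
    priors = default_priors(model, stim)
    theta = priors.mean.copy()
    theta[priors.index("beta:gamma2:PPC")] = 0.3
    sensor = ForwardProblem(model, stim, lf, SpatialModes(np.eye(lf.n_sensors)),
                            grid, priors).predict(theta)
    modes = compute_spatial_modes(sensor.reshape(lf.n_sensors, -1), 4)
    problem = ForwardProblem(model, stim, lf, modes, grid, priors)
    return problem, theta


def _study(beta, site, master_seed, n_subjects=12):
    model, stim, grid, lf = fixture_small(beta=beta, site=site)
    truth = SyntheticGroundTruth(model=model, stim=stim, n_sensors=16,
                                 n_subjects=n_subjects, snr=4.0, n_modes=4,
                                 master_seed=master_seed)
    ds = generate_erf_dataset(truth)
    subject_data = [mode_reduce(s, ds.modes, GRID_T0, GRID_T1) for s in ds.subjects]
    base = replace(model, modulation=[])
    models, families = modulation_model_space(base)
    result = run_family_analysis(models, families, subject_data, stim, lf,
                                 ds.modes, grid, mc_samples=100_000, seed=7)
    return {"dataset": ds, "subject_data": subject_data, "result": result,
            "stim": stim, "grid": grid, "lead_field": lf, "models": models,
            "families": families, "true_beta": beta, "site": site}


@pytest.fixture(scope="session")
def gain_study():
    """12 subjects, SNR 4, truth: beta = 0.3 on PPC stellate->pyramidal gain."""
    return _study(0.3, ("gamma2", "PPC"), master_seed=101)


@pytest.fixture(scope="session")
def connection_study():
    """12 subjects, SNR 4, truth: beta = 0.3 on the MT->PPC forward edge."""
    return _study(0.3, ("forward", "MT->PPC"), master_seed=202)


@pytest.fixture(scope="session")
def null_study():
    """12 subjects, SNR 4, truth: no condition effect."""
    return _study(0.0, ("gamma2", "PPC"), master_seed=303)
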
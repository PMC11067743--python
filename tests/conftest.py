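"""Shared fixtures.

The expensive objects — trained networks on synthetic photocycle data — are
session-scoped and shared across the recovery, reproducibility and
acceptance tests.  Problem sizes follow the reduced study conditions
(N = 500 voxels, P = 21 time points, ~5e4 iterations).
"""

from __future__ import annotations

import numpy as np
import pytest

from dedkin import (
    TrainConfig,
    dead_end_mechanism,
    decompose_series,
    evaluate_run,
    fit_relaxation_rates,
    general_mechanism,
    reproducibility_study,
    sequential_mechanism,
    simulate,
    train,
)
from dedkin.svd_kinetics import RateBounds

N_VOXELS = 500
TRAIN_ITERS = 70_000
DATA_SEED = 11


@pytest.fixture(scope="session")
def ss_data():
    """Noisy sequential-separated synthetic series plus its ground truth."""
    series, gt = simulate("S_S", n_voxels=N_VOXELS, noise_sigma=3.4e-5, seed=DATA_SEED)
    return series, gt


@pytest.fixture(scope="session")
def ss_reports(ss_data):
    """Ten general-mechanism training runs on S_S differing only in seed."""
    series, gt = ss_data
    cfg = TrainConfig(max_iterations=TRAIN_ITERS, checkpoint_stride=TRAIN_ITERS // 2,
                      bounds=RateBounds(lower=np.array([1e-6]), upper=np.array([1e10])))
    return reproducibility_study(series, general_mechanism(), cfg, seeds=list(range(10)), gt=gt)


@pytest.fixture(scope="session")
def des_data():
    """Dead-end-separated synthetic series plus ground truth."""
    series, gt = simulate("DE_S", n_voxels=N_VOXELS, noise_sigma=3.4e-5, seed=7)
    return series, gt


@pytest.fixture(scope="session")
def des_informed_runs(des_data):
    """DE_S data analysed with the dead-end and the sequential mechanism.

    Rate bounds follow the tight protocol: lower = smallest fitted relaxation
    rate, upper = sum of the fitted relaxation rates.
    """
    series, gt = des_data
    svd = decompose_series(series)
    fit = fit_relaxation_rates(svd, n_exp=svd.n_significant, t=series.times)
    bounds = RateBounds(lower=np.array([float(fit.rates.min())]), upper=np.array([float(fit.rates.sum())]))
    out = {}
    for mech in (dead_end_mechanism(), sequential_mechanism()):
        cfg = TrainConfig(max_iterations=TRAIN_ITERS, checkpoint_stride=TRAIN_ITERS // 2,
                          bounds=bounds, seed=1)
        result = train(series, mech, cfg)
        out[mech.name] = (result, evaluate_run(result, gt, series))
    return out
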
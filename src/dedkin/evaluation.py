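"""Accuracy and reproducibility metrics for recovered kinetics and maps.

Against a known ground truth, a run is scored by

* ``R_w`` — weighted residual between predicted and true concentration
  profiles: the mean absolute relative error over all states (intermediates
  plus dark) and time points, skipping entries whose true concentration is
  exactly zero (a zero denominator would make the residual infinite);
* ``R_s`` — root-mean-square residual between predicted and measured
  time-dependent maps, in map units; for a successful run it settles at the
  noise floor of the input data;
* PCF — the Pearson correlation between each recovered intermediate map and
  its ground-truth counterpart.

Because the general mechanism is symmetric under relabeling the second and
third intermediates, recovered solutions are aligned to the ground truth over
the two admissible state orderings before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from dedkin.ded_io import DEDMapSeries
from dedkin.kinetics_core import Mechanism
from dedkin.network import TrainConfig, TrainResult, relu1, train
from dedkin.synthetic_data import GroundTruth

__all__ = [
    "EvaluationReport",
    "weighted_residual",
    "map_residual",
    "pearson_correlation",
    "align_intermediates",
    "evaluate_run",
    "reproducibility_study",
]

#: permutation of the general-scheme rate labels under the I2 <-> I3 swap
_SWAP_23_RATES = {
    "k1": "k2", "k2": "k1", "k-1": "k-2", "k-2": "k-1",
    "k3": "k-3", "k-3": "k3", "k4": "k5", "k5": "k4", "k-4": "k-5", "k-5": "k-4",
}


@dataclass
class EvaluationReport:
    Rw: float
    Rs: float
    pcf_per_intermediate: np.ndarray
    permutation: tuple[int, ...]
    rates: dict[str, float]
    loss_total: float


def weighted_residual(C_pred: np.ndarray, C_true: np.ndarray, zero_floor: float = 1e-12) -> float:
    """R_w = mean over nonzero-truth entries of |c_pred - c_true| / c_true.

    Entries whose ground-truth concentration is zero are skipped (they would
    make the residual infinite); an all-zero ground truth is undefined and
    raises.  Fractional concentrations below ``zero_floor`` are treated as
    zero: exact solutions of the rate equations underflow to denormals at
    populations that are physically indistinguishable from zero.
    """
    C_pred = np.asarray(C_pred, float)
    C_true = np.asarray(C_true, float)
    if C_pred.shape != C_true.shape:
        raise ValueError("prediction and ground truth must share a shape")
    mask = np.abs(C_true) > zero_floor
    if not mask.any():
        raise ValueError("R_w is undefined: every ground-truth concentration is zero")
    return float(np.mean(np.abs(C_pred[mask] - C_true[mask]) / np.abs(C_true[mask])))


def map_residual(E_pred: np.ndarray, E_meas: np.ndarray) -> float:
    """R_s = sqrt(<(E_pred - E_meas)^2>), map units (electrons/A^3)."""
    E_pred = np.asarray(E_pred, float)
    E_meas = np.asarray(E_meas, float)
    if E_pred.shape != E_meas.shape:
        raise ValueError("prediction and measurement must share a shape")
    return float(np.sqrt(np.mean((E_pred - E_meas) ** 2)))


def pearson_correlation(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson correlation factor between two maps over common voxels."""
    a = np.asarray(map_a, float).ravel()
    b = np.asarray(map_b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must have the same number of voxels")
    da, db = a - a.mean(), b - b.mean()
    va, vb = float(da @ da), float(db @ db)
    if va == 0.0 or vb == 0.0:
        raise ValueError("Pearson correlation undefined for a constant map")
    return float(da @ db) / np.sqrt(va * vb)


def _state_permutations(M: int) -> list[tuple[int, ...]]:
    """Admissible intermediate orderings: the initial condition pins I1, so
    only the I2 <-> I3 relabeling is a symmetry of the general scheme."""
    if M == 3:
        return [(0, 1, 2), (0, 2, 1)]
    return [tuple(range(M))]


def permute_rates(rates: dict[str, float], perm: tuple[int, ...]) -> dict[str, float]:
    """Relabel a general-scheme rate dict under an intermediate permutation."""
    if perm == (0, 1, 2) or len(perm) != 3:
        return dict(rates)
    # the swap is an involution; indexing by the swapped label keeps the
    # canonical key order of the input dict
    return {label: rates[_SWAP_23_RATES.get(label, label)] for label in rates}


def align_intermediates(I_pred: np.ndarray, I_true: np.ndarray) -> tuple[tuple[int, ...], np.ndarray]:
    """Pick the admissible column ordering of I_pred best matching I_true.

    Returns (permutation, per-intermediate PCF in truth order): column
    ``perm[i]`` of the prediction corresponds to true intermediate ``i``.
    """
    M = I_true.shape[1]
    best_perm, best_pcfs, best_score = None, None, -np.inf
    for perm in _state_permutations(M):
        pcfs = np.array([pearson_correlation(I_pred[:, perm[i]], I_true[:, i]) for i in range(M)])
        score = float(pcfs.sum())
        if score > best_score:
            best_perm, best_pcfs, best_score = perm, pcfs, score
    return best_perm, best_pcfs


def evaluate_run(result: TrainResult, gt: GroundTruth, series: DEDMapSeries) -> EvaluationReport:
    """Score one training run against its ground truth.

    The recovered intermediates are aligned to the truth by map correlation;
    the same state permutation is applied to the concentration rows and the
    rate labels before computing R_w and reporting rates.
    """
    M = gt.I_true.shape[1]
    perm, pcfs = align_intermediates(result.intermediates, gt.I_true)
    C_pred = result.concentrations
    row_order = list(perm) + [M]                      # dark state row stays last
    Rw = weighted_residual(C_pred[row_order, :], gt.C_true)
    E_pred = result.intermediates @ relu1(result.concentrations[:M, :])
    Rs = map_residual(E_pred, series.values)
    rates = permute_rates(result.rates, perm)
    return EvaluationReport(Rw=Rw, Rs=Rs, pcf_per_intermediate=pcfs, permutation=perm,
                            rates=rates, loss_total=result.loss.total)


def reproducibility_study(E: DEDMapSeries, mech: Mechanism, cfg: TrainConfig, seeds: list[int],
                          gt: GroundTruth) -> list[EvaluationReport]:
    """Independent training runs differing only in the weight-init seed.

    Returns one report per seed, in seed order (deterministic given the
    list); the R_w / R_s columns are what the multi-run histograms are built
    from.
    """
    if len(seeds) < 1:
        raise ValueError("at least one seed is required")
    reports = []
    for seed in seeds:
        result = train(E, mech, replace(cfg, seed=int(seed)))
        reports.append(evaluate_run(result, gt, E))
    return reports
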
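"""Ground-truth photocycle simulations at the density level.

Emulates a photoactive-yellow-protein-style photocycle: three transient
intermediates plus a featureless dark state.  Each intermediate map is a sum
of paired positive/negative Gaussian features on a voxel line (density gained
where atoms arrive, lost where they leave); concentration profiles come from
solving the kinetic rate equations with one of four preset rate sets
(sequential or dead-end mechanism, each with separated or overlapping
profiles); the observable series is E = I C plus i.i.d. Gaussian noise.

The simulation deliberately stays at the density level: the structure-factor
route (atomic models, Fourier synthesis, experimentally calibrated amplitude
noise) needs inputs that are not distributable, and every property of the
analysis method is exercised equally well by the density-level analogue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dedkin.ded_io import DEDMapSeries
from dedkin.kinetics_core import (
    ConcentrationProfiles,
    Mechanism,
    assemble_rate_matrix,
    dead_end_mechanism,
    sequential_mechanism,
    solve_concentrations,
)

__all__ = [
    "GroundTruth",
    "SCENARIO_RATES",
    "default_time_grid",
    "make_intermediate_maps",
    "make_concentration_profiles",
    "make_timeseries",
    "simulate",
]

#: preset rate sets (s^-1): sequential (separated / overlapping) and
#: dead-end (separated / overlapping)
SCENARIO_RATES: dict[str, dict[str, float]] = {
    "S_S": {"k1": 40000.0, "k3": 1000.0, "k5": 100.0},
    "S_O": {"k1": 2000.0, "k3": 3000.0, "k5": 900.0},
    "DE_S": {"k1": 9500.0, "k3": 330.0, "k4": 400.0, "k-3": 210.0},
    "DE_O": {"k1": 15000.0, "k3": 2000.0, "k4": 100.0, "k-3": 2000.0},
}

_SCENARIO_MECHANISM = {
    "S_S": sequential_mechanism,
    "S_O": sequential_mechanism,
    "DE_S": dead_end_mechanism,
    "DE_O": dead_end_mechanism,
}

#: default map amplitude and noise level (electrons/A^3 analogue units)
DEFAULT_AMPLITUDE = 0.5
DEFAULT_NOISE_SIGMA = 3.4e-5
DEFAULT_N_VOXELS = 2291


def default_time_grid(P: int = 21, t_min: float = 1e-6, t_max: float = 1.0) -> np.ndarray:
    """P log-spaced acquisition times (s) bracketing the preset processes.

    The window [1e-6, 1] s contains both the fastest preset process
    (1/40000 s) and the slowest (1/100 s).
    """
    return np.geomspace(t_min, t_max, P)


@dataclass
class GroundTruth:
    """Everything the evaluation needs to score a recovery."""

    I_true: np.ndarray            # N x M intermediate maps
    C_true: np.ndarray            # (M+1) x P profiles (dark state last)
    k_true: dict[str, float]      # labelled rates, s^-1
    mechanism: Mechanism
    times: np.ndarray
    noise_sigma: float

    def __post_init__(self) -> None:
        colsums = self.C_true.sum(axis=0)
        if not np.allclose(colsums, colsums[0], atol=1e-8):
            raise ValueError("ground-truth concentration columns must conserve mass")
        M = self.I_true.shape[1]
        for i in range(M):
            ni = np.linalg.norm(self.I_true[:, i])
            if ni == 0:
                raise ValueError(f"ground-truth map {i} is identically zero")
            for j in range(i + 1, M):
                cos = abs(self.I_true[:, i] @ self.I_true[:, j]) / (ni * np.linalg.norm(self.I_true[:, j]))
                if cos >= 0.9:
                    raise ValueError(f"ground-truth maps {i} and {j} are nearly collinear (|cos|={cos:.2f})")


def make_intermediate_maps(n_voxels: int, n_maps: int = 3, features_per_map: int = 5,
                           amplitude: float = DEFAULT_AMPLITUDE, seed: int = 0) -> np.ndarray:
    """Synthesize distinct intermediate maps from paired +/- Gaussian features.

    Each map is a sum of ``features_per_map`` pairs of one positive and one
    negative Gaussian bump (amplitude +/- ``amplitude``) centred at seeded
    random voxel positions, then mean-centred and rescaled so the strongest
    feature reaches ``amplitude``.  ``features_per_map = 0`` returns zero maps
    (useful only for negative testing; rejected by GroundTruth).
    """
    if n_voxels < 50:
        raise ValueError("need at least 50 voxels")
    rng = np.random.default_rng(seed)
    grid = np.arange(n_voxels, dtype=float)
    maps = np.zeros((n_voxels, n_maps))
    width = max(n_voxels / 80.0, 2.0)
    for m in range(n_maps):
        for _ in range(features_per_map):
            for sign in (+1.0, -1.0):
                centre = rng.uniform(0, n_voxels)
                w = width * rng.uniform(0.6, 1.6)
                maps[:, m] += sign * amplitude * np.exp(-0.5 * ((grid - centre) / w) ** 2)
        if features_per_map > 0:
            maps[:, m] -= maps[:, m].mean()
            peak = np.abs(maps[:, m]).max()
            if peak > 0:
                maps[:, m] *= amplitude / peak
    return maps


def make_concentration_profiles(preset: str, times: np.ndarray | None = None) -> tuple[ConcentrationProfiles, dict[str, float]]:
    """Profiles for one of the presets S_S, S_O, DE_S, DE_O.

    Loads the preset rates into the matching mechanism and solves the rate
    equations with C0 = (1, 0, 0, 0).
    """
    if preset not in SCENARIO_RATES:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(SCENARIO_RATES)}")
    if times is None:
        times = default_time_grid()
    mech = _SCENARIO_MECHANISM[preset]()
    k_true = SCENARIO_RATES[preset]
    K = assemble_rate_matrix(mech.rate_vector(k_true), mech)
    profiles = solve_concentrations(K, np.array([1.0, 0.0, 0.0, 0.0]), times)
    return profiles, dict(k_true)


def make_timeseries(gt: GroundTruth, seed: int = 0) -> DEDMapSeries:
    """Observable series E = I_true C_true[intermediates] + Gaussian noise."""
    M = gt.I_true.shape[1]
    E = gt.I_true @ gt.C_true[:M, :]
    if gt.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        E = E + rng.normal(0.0, gt.noise_sigma, E.shape)
    return DEDMapSeries(voxel_index=np.arange(E.shape[0]), values=E, times=gt.times.copy())


def simulate(preset: str = "S_S", n_voxels: int = DEFAULT_N_VOXELS, times: np.ndarray | None = None,
             noise_sigma: float = DEFAULT_NOISE_SIGMA, features_per_map: int = 5,
             amplitude: float = DEFAULT_AMPLITUDE, seed: int = 0) -> tuple[DEDMapSeries, GroundTruth]:
    """End-to-end synthetic dataset: (noisy series, ground truth)."""
    if times is None:
        times = default_time_grid()
    times = np.asarray(times, dtype=float)
    profiles, k_true = make_concentration_profiles(preset, times)
    I_true = make_intermediate_maps(n_voxels, n_maps=profiles.C.shape[0] - 1,
                                    features_per_map=features_per_map, amplitude=amplitude, seed=seed)
    gt = GroundTruth(I_true=I_true, C_true=profiles.C, k_true=k_true,
                     mechanism=_SCENARIO_MECHANISM[preset](), times=times, noise_sigma=noise_sigma)
    series = make_timeseries(gt, seed=seed + 1)
    return series, gt
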
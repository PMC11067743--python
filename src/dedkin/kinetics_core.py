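"""First-order chemical kinetics: rate-matrix assembly and ODE solution.

A kinetic mechanism over ``M`` intermediates plus the dark (reference) state
is a set of directed transitions, each carrying one reaction-rate coefficient
(RRC).  Collecting the coefficients into the matrix ``K`` turns the mechanism
into the linear system ``dC/dt = K C``, which is solved exactly by
diagonalizing ``K``:  ``C(t) = V exp(L t) V^-1 C(0)``.

State ordering is ``(I1, I2, I3, dark)`` throughout; reaction initiation is
encoded entirely in the initial condition ``C0 = (1, 0, 0, 0)`` (all excited
molecules start in the first intermediate), never as a rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.linalg import expm

__all__ = [
    "Mechanism",
    "RateMatrix",
    "ConcentrationProfiles",
    "general_mechanism",
    "sequential_mechanism",
    "dead_end_mechanism",
    "mechanism_from_name",
    "assemble_rate_matrix",
    "solve_concentrations",
]

#: canonical label order of the general three-intermediate scheme
GENERAL_RATE_ORDER = ("k1", "k2", "k3", "k4", "k5", "k-1", "k-2", "k-3", "k-4", "k-5")

#: label -> (from_state, to_state) for the general scheme, states (I1, I2, I3, dark).
#: Five reversible pairs: I1<->I2, I1<->I3, I2<->I3, I2<->dark, I3<->dark.
GENERAL_TRANSITIONS = {
    "k1": (0, 1),
    "k-1": (1, 0),
    "k2": (0, 2),
    "k-2": (2, 0),
    "k3": (1, 2),
    "k-3": (2, 1),
    "k4": (1, 3),
    "k-4": (3, 1),
    "k5": (2, 3),
    "k-5": (3, 2),
}


@dataclass(frozen=True)
class Mechanism:
    """A kinetic mechanism: which rate coefficient drives which transition.

    Parameters
    ----------
    name : str
        Human-readable identifier (e.g. ``"general"``).
    n_states : int
        Number of states, intermediates plus the dark state (M + 1).
    transitions : tuple of (label, from_state, to_state)
        One entry per adjustable rate coefficient, in canonical order.
    """

    name: str
    n_states: int
    transitions: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        seen = set()
        for label, src, dst in self.transitions:
            if label in seen:
                raise ValueError(f"duplicate rate label {label!r}")
            seen.add(label)
            if src == dst:
                raise ValueError(f"rate {label!r} maps a state onto itself")
            if not (0 <= src < self.n_states and 0 <= dst < self.n_states):
                raise ValueError(f"rate {label!r} references a state outside 0..{self.n_states - 1}")

    @property
    def n_rates(self) -> int:
        return len(self.transitions)

    @property
    def rate_order(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.transitions)

    def rate_vector(self, rates: dict[str, float]) -> np.ndarray:
        """Order a ``{label: value}`` dict into the canonical rate vector.

        Labels absent from the dict default to zero; unknown labels raise.
        """
        known = set(self.rate_order)
        unknown = set(rates) - known
        if unknown:
            raise ValueError(f"rate labels {sorted(unknown)} not in mechanism {self.name!r}")
        return np.array([float(rates.get(label, 0.0)) for label in self.rate_order])

    def direction_matrices(self) -> np.ndarray:
        """dK/dk_r for each coefficient, shape (R, n_states, n_states)."""
        return _direction_matrices(self).copy()


@lru_cache(maxsize=64)
def _direction_matrices(mech: "Mechanism") -> np.ndarray:
    D = np.zeros((mech.n_rates, mech.n_states, mech.n_states))
    for r, (_, src, dst) in enumerate(mech.transitions):
        D[r, dst, src] += 1.0
        D[r, src, src] -= 1.0
    return D


def _subset(name: str, labels: tuple[str, ...]) -> Mechanism:
    return Mechanism(
        name=name,
        n_states=4,
        transitions=tuple((lab, *GENERAL_TRANSITIONS[lab]) for lab in labels),
    )


def general_mechanism() -> Mechanism:
    """The general three-intermediate scheme with all R = 10 coefficients."""
    return _subset("general", GENERAL_RATE_ORDER)


def sequential_mechanism() -> Mechanism:
    """Irreversible sequential scheme I1 -> I2 -> I3 -> dark (k1, k3, k5)."""
    return _subset("sequential", ("k1", "k3", "k5"))


def dead_end_mechanism() -> Mechanism:
    """Dead-end scheme: I1 -> I2 -> dark with reversible I2 <-> I3 off-path.

    Coefficients k1 (I1->I2), k3 (I2->I3), k-3 (I3->I2) and k4 (I2->dark);
    I3 is the dead end.
    """
    return _subset("dead_end", ("k1", "k3", "k4", "k-3"))


_PRESETS = {
    "general": general_mechanism,
    "sequential": sequential_mechanism,
    "dead_end": dead_end_mechanism,
}


def mechanism_from_name(name: str) -> Mechanism:
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown mechanism preset {name!r}; choose from {sorted(_PRESETS)}") from None


@dataclass(frozen=True)
class RateMatrix:
    """Coefficient matrix K of dC/dt = K C (columns sum to zero)."""

    K: np.ndarray

    @property
    def n_states(self) -> int:
        return self.K.shape[0]


@dataclass
class ConcentrationProfiles:
    """Fractional state concentrations on a time grid.

    ``C`` has one row per state (intermediates first, dark state last) and
    one column per time point.  Columns conserve the total of ``C0``.
    """

    C: np.ndarray
    t: np.ndarray
    C0: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))


def assemble_rate_matrix(k: np.ndarray, mech: Mechanism) -> RateMatrix:
    """Build K from the rate vector: K[to,from] += k_r, K[from,from] -= k_r.

    Columns of K sum to zero exactly, which encodes mass conservation.
    """
    k = np.asarray(k, dtype=float)
    if k.shape != (mech.n_rates,):
        raise ValueError(f"expected {mech.n_rates} rates for mechanism {mech.name!r}, got shape {k.shape}")
    if np.any(k < 0):
        raise ValueError("rate coefficients must be nonnegative")
    K = np.tensordot(k, _direction_matrices(mech), axes=1)
    return RateMatrix(K=K)


# eigenvector condition number beyond which the eigen-solution is distrusted
_EIG_COND_LIMIT = 1e12
# allowed imaginary residue of the reconstructed (real) solution
_IMAG_TOL = 1e-9


def _eig_propagate(K: np.ndarray, C0: np.ndarray, t: np.ndarray):
    """C(t) = V exp(L t) V^-1 C0 for all t at once.  Returns (C, eig cache).

    Raises ``np.linalg.LinAlgError`` if the eigenvector matrix is too
    ill-conditioned for the spectral solution to be trusted.
    """
    lam, V = np.linalg.eig(K)
    W = np.linalg.inv(V)
    # cheap infinity-norm condition estimate
    cond = np.abs(V).sum(axis=1).max() * np.abs(W).sum(axis=1).max()
    if not np.isfinite(cond) or cond > _EIG_COND_LIMIT:
        raise np.linalg.LinAlgError("ill-conditioned eigenvector matrix")
    y = W @ C0.astype(complex)
    # exp(lam_a t_p): shape (T, n_states)
    E = np.exp(np.multiply.outer(t, lam))
    C = (V @ (E * y).T)  # (n_states, T), complex
    imag = np.max(np.abs(C.imag)) if C.size else 0.0
    if imag > _IMAG_TOL * max(1.0, np.max(np.abs(C.real))):
        raise np.linalg.LinAlgError("large imaginary residue in eigen-solution")
    return C.real, (lam, V, W, y)


def solve_concentrations(K: RateMatrix | np.ndarray, C0: np.ndarray, t: np.ndarray) -> ConcentrationProfiles:
    """Solve dC/dt = K C by diagonalizing K.

    Falls back to a dense matrix-exponential evaluation when K's eigenvector
    matrix is ill-conditioned (defective or nearly defective K); valid K never
    raises.

    Parameters
    ----------
    K : RateMatrix or array
        Coefficient matrix, columns summing to zero.
    C0 : array, shape (n_states,)
        Initial fractional concentrations (nonnegative).
    t : array, shape (T,)
        Nonnegative evaluation times, seconds.
    """
    Kmat = K.K if isinstance(K, RateMatrix) else np.asarray(K, dtype=float)
    C0 = np.asarray(C0, dtype=float)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if C0.shape != (Kmat.shape[0],):
        raise ValueError("C0 length must match the number of states")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if not np.all(np.isfinite(Kmat)):
        raise ValueError("K contains non-finite entries")
    try:
        C, _ = _eig_propagate(Kmat, C0, t)
    except np.linalg.LinAlgError:
        # dense fallback, exact but slower
        C = np.column_stack([expm(Kmat * ti) @ C0 for ti in t])
    return ConcentrationProfiles(C=C, t=t, C0=C0)
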
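"""The kinetics-informed network: architecture, loss, and training loop.

Two small sub-networks are trained jointly against the data matrix:

* projection network (linear, bias-free): ``I = U A`` produces the
  time-independent intermediate maps from the significant lSVs, and
  ``E_C1 = I C_NN`` reproduces the time series, with the middle-layer weight
  matrix ``C_NN`` interpreted as the intermediate concentrations;
* conversion network (one ReLU hidden layer): maps the flattened, ReLU-ed
  ``C_NN`` to the R rate coefficients, decoded as ``k = exp(raw)`` so rates
  are strictly positive.

Each iteration then solves the kinetic rate equations dC/dt = K C exactly
(eigendecomposition of K), rebuilds the series a second time as
``E_C2 = I relu1(C_CDE)``, and scores a four-part loss: data fidelity (L_E),
rate-magnitude range penalty (L_K, quadratic in log-rate excess), network /
ODE concentration self-consistency (L_C) and intermediate-map terms (L_I).
Gradients — including the exact derivative of the matrix exponential with
respect to the rates, via the Daleckii-Krein divided-difference formula —
are propagated by hand-written reverse mode and applied with AdaM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import expm

from dedkin.ded_io import DEDMapSeries, RunOutputs
from dedkin.kinetics_core import Mechanism, _direction_matrices, _eig_propagate, assemble_rate_matrix, solve_concentrations
from dedkin.svd_kinetics import RateBounds, decompose_series

__all__ = [
    "NetworkState",
    "TrainConfig",
    "LossBreakdown",
    "TrainResult",
    "hidden_layer_size",
    "init_state",
    "relu1",
    "projection_forward",
    "conversion_forward",
    "compute_losses",
    "forward_pass",
    "loss_and_grads",
    "train",
]

#: initial condition: all excited molecules start in the first intermediate
C0_DEFAULT = np.array([1.0, 0.0, 0.0, 0.0])


def hidden_layer_size(Q: int, R: int) -> int:
    """Perceptron count of the conversion hidden layer, H = ceil((Q + R) / 3).

    H must exceed R (the output width); a configuration that violates this
    is rejected.
    """
    H = math.ceil((Q + R) / 3)
    if H <= R:
        raise ValueError(f"hidden layer too small: H={H} must exceed R={R} (increase M*P)")
    return H


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu1(x: np.ndarray) -> np.ndarray:
    """ReLU with an additional upper limit of 1: elementwise clamp to [0, 1]."""
    return np.clip(x, 0.0, 1.0)


@dataclass
class NetworkState:
    """All trainable tensors.

    A     : M_sig x M_proj projection weights (M_proj = M, or M + 1 when the
            dark column is carried)
    C_nn  : M x P middle-layer weights, read as intermediate concentrations
    W1,b1 : conversion hidden layer (H x Q and H)
    W2,b2 : conversion output layer (R x H and R); rates are exp(W2 h + b2)
    """

    A: np.ndarray
    C_nn: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    def params(self) -> dict[str, np.ndarray]:
        return {"A": self.A, "C_nn": self.C_nn, "W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}


@dataclass
class LossBreakdown:
    """The four loss components, their amplifiers, and the weighted total."""

    L_E: float
    L_K: float
    L_C: float
    L_I: float
    total: float
    c_E: float = 1.0
    c_K: float = 1.0
    c_C: float = 0.1
    c_I: float = 1.0
    c_P: float = 0.0


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults follow the reference protocol: AdaM with learning rate 1e-4,
    up to 3e5 iterations, all weights drawn from N(0, 0.02^2), amplifiers
    (c_E, c_K, c_I) = 1 and c_C = 0.1, optional map-dissimilarity factor
    c_P = 0.  ``bounds`` are the rate-magnitude limits in s^-1 (both must be
    positive; the penalty takes logarithms); None means the essentially
    unconstrained range (1e-6, 1e10).
    """

    learning_rate: float = 1e-4
    max_iterations: int = 300_000
    init_std: float = 0.02
    loss_tolerance: float = 0.0
    n_consecutive: int = 100
    seed: int = 0
    bounds: RateBounds | None = None
    c_E: float = 1.0
    c_K: float = 1.0
    c_C: float = 0.1
    c_I: float = 1.0
    c_P: float = 0.0
    include_dark_in_projection: bool = False
    checkpoint_stride: int = 1000
    times: np.ndarray | None = None
    n_significant: int | None = None
    dense_grid_points: int = 400
    time_scale: float | None = None    # seconds per internal time unit; None = geometric mean of times
    rate_decoding: str = "exp"         # "exp": k = exp(raw); "linear": k = k_low + relu(raw)
    rate_overshoot_guard: bool = True  # hard-cap rates at the upper limit during training

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.init_std <= 0:
            raise ValueError("learning_rate and init_std must be positive")
        if self.max_iterations < 0 or self.n_consecutive < 1 or self.checkpoint_stride < 1:
            raise ValueError("iteration counts must be positive")
        for name in ("c_E", "c_K", "c_C", "c_I", "c_P"):
            if getattr(self, name) < 0:
                raise ValueError(f"amplifier {name} must be nonnegative")


@dataclass
class TrainResult:
    """Outputs of a training run, in physical units."""

    run: RunOutputs
    intermediates: np.ndarray          # N x M maps, electrons/A^3
    rates: dict[str, float]            # label -> s^-1, final iteration
    concentrations: np.ndarray         # (M+1) x P on the data time grid
    concentrations_nn: np.ndarray      # M x P, projection-network estimate
    loss: LossBreakdown
    state: NetworkState
    times: np.ndarray
    converged: bool
    diverged: bool
    n_iterations: int
    data_scale: float
    time_scale: float


def init_state(dims: dict[str, int], cfg: TrainConfig) -> NetworkState:
    """Draw every weight and bias from N(0, init_std^2), seeded.

    ``dims`` carries M_sig, M, P and R; H follows from Q = M*P and R.
    """
    M_sig, M, P, R = dims["M_sig"], dims["M"], dims["P"], dims["R"]
    Q = M * P
    H = hidden_layer_size(Q, R)
    m_proj = M + 1 if cfg.include_dark_in_projection else M
    rng = np.random.default_rng(cfg.seed)
    std = cfg.init_std
    return NetworkState(
        A=rng.normal(0.0, std, (M_sig, m_proj)),
        C_nn=rng.normal(0.0, std, (M, P)),
        W1=rng.normal(0.0, std, (H, Q)),
        b1=rng.normal(0.0, std, H),
        W2=rng.normal(0.0, std, (R, H)),
        b2=rng.normal(0.0, std, R),
    )


def projection_forward(U: np.ndarray, state: NetworkState) -> tuple[np.ndarray, np.ndarray]:
    """I = U A and E_C1 = I C_NN (both maps linear, bias-free)."""
    I = U @ state.A
    M = state.C_nn.shape[0]
    E_c1 = I[:, :M] @ state.C_nn
    return I, E_c1


def conversion_forward(C_nn: np.ndarray, state: NetworkState) -> np.ndarray:
    """Rates from the concentration weights: k = exp(W2 relu(W1 x + b1) + b2).

    The input x is relu(C_NN) flattened row by row (length Q = M*P).
    """
    x = relu(C_nn).ravel()
    h = relu(state.W1 @ x + state.b1)
    return np.exp(state.W2 @ h + state.b2)


def _lk_terms(ln_k: np.ndarray, ln_low: np.ndarray, ln_high: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    below = np.minimum(ln_k - ln_low, 0.0)
    above = np.maximum(ln_k - ln_high, 0.0)
    return below, above


def rate_range_penalty(k: np.ndarray, bounds: RateBounds) -> float:
    """L_K = sum min(ln k - ln k_low, 0)^2 + sum max(ln k - ln k_high, 0)^2."""
    b = bounds.broadcast(np.size(k))
    below, above = _lk_terms(np.log(np.asarray(k, float)), np.log(b.lower), np.log(b.upper))
    return float(np.sum(below**2) + np.sum(above**2))


def compute_losses(E_m, E_c1, E_c2, C_nn, C_cde, I, k, bounds: RateBounds,
                   amplifiers: tuple[float, float, float, float, float] = (1.0, 1.0, 0.1, 1.0, 0.0),
                   include_dark: bool = False) -> LossBreakdown:
    """Evaluate the four-part loss.

    L_E = <(E_M - E_C1)^2> + <(E_M - E_C2)^2>   (<> = mean over elements)
    L_K = range penalty on ln k (see ``rate_range_penalty``)
    L_C = <(C_NN - C_CDE)^2> over the M intermediate rows
    L_I = <DED_dark^2> (only with a dark projection column)
          + c_P * sum_{i<j} cos^2(I_i, I_j)
    """
    c_E, c_K, c_C, c_I, c_P = amplifiers
    M = C_nn.shape[0]
    L_E = float(np.mean((E_m - E_c1) ** 2) + np.mean((E_m - E_c2) ** 2))
    L_K = rate_range_penalty(k, bounds)
    L_C = float(np.mean((C_nn - C_cde[:M]) ** 2))
    L_I = 0.0
    if include_dark and I.shape[1] > M:
        L_I += float(np.mean(I[:, M] ** 2))
    if c_P > 0:
        for i in range(M):
            for j in range(i + 1, M):
                ni, nj = np.linalg.norm(I[:, i]), np.linalg.norm(I[:, j])
                if ni > 0 and nj > 0:
                    L_I += c_P * float((I[:, i] @ I[:, j]) / (ni * nj)) ** 2
    total = c_E * L_E + c_K * L_K + c_C * L_C + c_I * L_I
    return LossBreakdown(L_E=L_E, L_K=L_K, L_C=L_C, L_I=L_I, total=total,
                         c_E=c_E, c_K=c_K, c_C=c_C, c_I=c_I, c_P=c_P)


# ---------------------------------------------------------------------------
# exact derivative of the ODE solution with respect to the rates
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _complex_directions(mech: Mechanism) -> np.ndarray:
    return _direction_matrices(mech).astype(complex)


def _divided_differences(lam: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Phi_ab(t) = (e^{lam_a t} - e^{lam_b t}) / (lam_a - lam_b), (T,S,S).

    Phi_aa(t) = t e^{lam_a t}; near-degenerate pairs use the series
    t e^{lam_b t} (1 + z/2 + z^2/6) in z = (lam_a - lam_b) t, which avoids
    the 0/0 cancellation.  Rate matrices have eigenvalues with non-positive
    real part, so every exponential here is bounded.
    """
    E = np.exp(np.multiply.outer(t, lam))                    # (T,S)
    delta = lam[:, None] - lam[None, :]                      # (S,S)
    z = t[:, None, None] * delta[None, :, :]                 # (T,S,S)
    small = np.abs(z) < 1e-6
    den = np.where(small, 1.0, delta[None, :, :])
    direct = (E[:, :, None] - E[:, None, :]) / den
    series = t[:, None, None] * E[:, None, :] * (1.0 + z / 2.0 + z * z / 6.0)
    return np.where(small, series, direct)


def _conc_and_rate_jacobian(K: np.ndarray, D: np.ndarray, C0: np.ndarray, t: np.ndarray):
    """C(t) and dC(t)/dk_r for all rates and times.

    For diagonalizable K = V diag(lam) V^-1 the Fréchet derivative of
    exp(K t) in direction D is V (G o Phi(t)) V^-1 with G = V^-1 D V and the
    divided differences Phi_ab(t) = (e^{lam_a t} - e^{lam_b t})/(lam_a-lam_b),
    Phi_aa(t) = t e^{lam_a t}.  Falls back to central finite differences when
    K is (nearly) defective.
    """
    try:
        C, (lam, V, W, y) = _eig_propagate(K, C0, t)
    except np.linalg.LinAlgError:
        D = D.real
        C = np.column_stack([expm(K * ti) @ C0 for ti in t])
        R = D.shape[0]
        dC = np.empty((R, t.size, K.shape[0]))
        h = 1e-7 * max(1.0, np.abs(K).max())
        for r in range(R):
            Cp = np.column_stack([expm((K + h * D[r]) * ti) @ C0 for ti in t])
            Cm = np.column_stack([expm((K - h * D[r]) * ti) @ C0 for ti in t])
            dC[r] = ((Cp - Cm) / (2 * h)).T
        return C, dC

    Phi = _divided_differences(lam, t)
    G = W @ D @ V                                            # (R,S,S)
    M1 = (G[:, None, :, :] * Phi[None, :, :, :]) @ y         # (R,T,S)
    dC = (M1 @ V.T).real                                     # (R,T,S)
    return C, dC


# ---------------------------------------------------------------------------
# full forward / backward pass
# ---------------------------------------------------------------------------

def _forward(state: NetworkState, U: np.ndarray, E_m: np.ndarray, mech: Mechanism,
             t: np.ndarray, ln_low: np.ndarray, ln_high: np.ndarray,
             amps: tuple[float, float, float, float, float], include_dark: bool,
             C0: np.ndarray, need_grad: bool, decoding: str = "exp",
             rate_cap: float | None = None):
    """One pass through projection NN, conversion NN, ODE and loss.

    Returns (LossBreakdown, cache); cache holds every tensor the backward
    pass needs, plus dC/dk when ``need_grad``.
    """
    c_E, c_K, c_C, c_I, c_P = amps
    M, P = state.C_nn.shape
    N = U.shape[0]

    I_full, E_c1 = projection_forward(U, state)
    I = I_full[:, :M]

    Cr = relu(state.C_nn)
    x = Cr.ravel()
    z1 = state.W1 @ x + state.b1
    h = relu(z1)
    z2 = state.W2 @ h + state.b2
    if decoding == "exp":
        k = np.exp(z2)
        dk_dz2 = k
    elif decoding == "linear":
        # rates = lower limit + relu(raw): nonnegative raw offsets above the
        # lower rate limit, so the log in L_K stays defined and suppressed
        # rates settle exactly at the limit ("essentially zero")
        k_floor = np.exp(ln_low)
        k = k_floor + relu(z2)
        dk_dz2 = (z2 > 0.0).astype(float)
    else:
        raise ValueError(f"unknown rate decoding {decoding!r}")
    capped = np.zeros(k.shape, dtype=bool)
    if rate_cap is not None:
        # hard guard against the early-iteration rate overshoot; inactive at
        # convergence for any solution inside the allowed range.  Capped
        # rates keep a descent gradient (straight-through) so they can leave
        # the cap, but receive no push further out.
        capped = k > rate_cap
        k = np.where(capped, rate_cap, k)

    D = _direction_matrices(mech)
    K = np.tensordot(k, D, axes=1)
    if need_grad:
        C_cde, dC_dk = _conc_and_rate_jacobian(K, _complex_directions(mech), C0, t)
    else:
        C_cde = solve_concentrations(K, C0, t).C
        dC_dk = None

    Cm = C_cde[:M]
    Cc = relu1(Cm)
    E_c2 = I @ Cc

    below, above = _lk_terms(np.log(k), ln_low, ln_high)
    L_E = float(np.mean((E_m - E_c1) ** 2) + np.mean((E_m - E_c2) ** 2))
    L_K = float(np.sum(below**2) + np.sum(above**2))
    L_C = float(np.mean((state.C_nn - Cm) ** 2))
    L_I = 0.0
    if include_dark and I_full.shape[1] > M:
        L_I += float(np.mean(I_full[:, M] ** 2))
    if c_P > 0:
        for i in range(M):
            for j in range(i + 1, M):
                ni, nj = np.linalg.norm(I[:, i]), np.linalg.norm(I[:, j])
                if ni > 0 and nj > 0:
                    L_I += c_P * float((I[:, i] @ I[:, j]) / (ni * nj)) ** 2
    total = c_E * L_E + c_K * L_K + c_C * L_C + c_I * L_I
    loss = LossBreakdown(L_E=L_E, L_K=L_K, L_C=L_C, L_I=L_I, total=total,
                         c_E=c_E, c_K=c_K, c_C=c_C, c_I=c_I, c_P=c_P)
    cache = dict(I_full=I_full, I=I, E_c1=E_c1, Cr=Cr, x=x, z1=z1, h=h, z2=z2, k=k,
                 dk_dz2=dk_dz2, capped=capped, C_cde=C_cde, Cm=Cm, Cc=Cc, E_c2=E_c2,
                 below=below, above=above, dC_dk=dC_dk, N=N, M=M, P=P)
    return loss, cache


def _backward(state: NetworkState, U: np.ndarray, E_m: np.ndarray, cache: dict,
              amps: tuple[float, float, float, float, float], include_dark: bool) -> dict[str, np.ndarray]:
    """Reverse-mode gradients of the total loss for every trainable tensor."""
    c_E, c_K, c_C, c_I, c_P = amps
    N, M, P = cache["N"], cache["M"], cache["P"]
    I, E_c1, E_c2, Cc, Cm = cache["I"], cache["E_c1"], cache["E_c2"], cache["Cc"], cache["Cm"]
    nE = E_m.size
    nC = M * P

    dE1 = (2.0 * c_E / nE) * (E_c1 - E_m)
    dE2 = (2.0 * c_E / nE) * (E_c2 - E_m)

    dI = dE1 @ state.C_nn.T + dE2 @ Cc.T                    # N x M
    if c_P > 0:
        for i in range(M):
            for j in range(M):
                if i == j:
                    continue
                a, b = I[:, i], I[:, j]
                na, nb = np.linalg.norm(a), np.linalg.norm(b)
                if na == 0 or nb == 0:
                    continue
                cos = float(a @ b) / (na * nb)
                # d cos^2 / d a (pair counted once; loop covers both orders)
                dI[:, i] += c_I * c_P * 2.0 * cos * (b / (na * nb) - cos * a / na**2)
    dI_full = dI
    if include_dark and cache["I_full"].shape[1] > M:
        dI_dark = c_I * (2.0 / N) * cache["I_full"][:, M]
        dI_full = np.column_stack([dI, dI_dark])
    dA = U.T @ dI_full

    # concentration self-consistency and ODE path
    dLC_dCnn = (2.0 * c_C / nC) * (state.C_nn - Cm)
    dCc = I.T @ dE2                                          # M x P
    dCm = dCc * ((Cm > 0.0) & (Cm < 1.0)) - dLC_dCnn

    dk = np.zeros_like(cache["k"])
    dC_dk = cache["dC_dk"]
    if dC_dk is not None:
        # dC_dk: (R, P, n_states); only the M intermediate rows feed the loss
        dk = np.einsum("mp,rpm->r", dCm, dC_dk[:, :, :M])

    # dL/dk = ODE path + range penalty (chain rule through ln k), then decode;
    # rates sitting at the overshoot cap only feel gradients pulling them back in
    dLdk = dk + c_K * 2.0 * (cache["below"] + cache["above"]) / cache["k"]
    jac = np.where(cache["capped"] & (dLdk <= 0.0), 0.0, cache["dk_dz2"])
    dz2 = dLdk * jac
    dW2 = np.outer(dz2, cache["h"])
    db2 = dz2
    dh = state.W2.T @ dz2
    dz1 = dh * (cache["z1"] > 0.0)
    dW1 = np.outer(dz1, cache["x"])
    db1 = dz1
    dx = state.W1.T @ dz1

    dC_nn = I.T @ dE1 + dLC_dCnn + dx.reshape(M, P) * (state.C_nn > 0.0)
    return {"A": dA, "C_nn": dC_nn, "W1": dW1, "b1": db1, "W2": dW2, "b2": db2}


def loss_and_grads(state: NetworkState, U: np.ndarray, E_m: np.ndarray, mech: Mechanism,
                   t: np.ndarray, bounds: RateBounds,
                   amplifiers: tuple[float, float, float, float, float] = (1.0, 1.0, 0.1, 1.0, 0.0),
                   include_dark: bool = False, C0: np.ndarray = C0_DEFAULT, decoding: str = "exp",
                   rate_cap: float | None = None):
    """Total loss plus gradients for every trainable tensor (one iteration)."""
    b = bounds.broadcast(mech.n_rates)
    ln_low, ln_high = np.log(b.lower), np.log(b.upper)
    loss, cache = _forward(state, U, E_m, mech, t, ln_low, ln_high, amplifiers, include_dark, C0,
                           need_grad=True, decoding=decoding, rate_cap=rate_cap)
    grads = _backward(state, U, E_m, cache, amplifiers, include_dark)
    return loss, grads, cache


def forward_pass(U: np.ndarray, E_m: np.ndarray, state: NetworkState, mech: Mechanism,
                 cfg: TrainConfig, t: np.ndarray):
    """One inference pass; returns (I, E_C1, k, C_CDE, E_C2, LossBreakdown).

    Units follow the inputs: rates are per unit of ``t``.
    """
    bounds = (cfg.bounds or RateBounds(lower=np.array([1e-6]), upper=np.array([1e10]))).broadcast(mech.n_rates)
    amps = (cfg.c_E, cfg.c_K, cfg.c_C, cfg.c_I, cfg.c_P)
    loss, cache = _forward(state, U, E_m, mech, np.asarray(t, float), np.log(bounds.lower),
                           np.log(bounds.upper), amps, cfg.include_dark_in_projection, C0_DEFAULT,
                           need_grad=False, decoding=cfg.rate_decoding)
    return cache["I_full"], cache["E_c1"], cache["k"], cache["C_cde"], cache["E_c2"], loss


class _Adam:
    """Adaptive moment estimation over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {n: np.zeros_like(p) for n, p in params.items()}
        self.v = {n: np.zeros_like(p) for n, p in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for name, p in params.items():
            g = grads[name]
            m = self.m[name]
            v = self.v[name]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def train(E: DEDMapSeries, mech: Mechanism, cfg: TrainConfig) -> TrainResult:
    """Run the full analysis: SVD, iterate forward/backward with AdaM.

    The data matrix is internally scaled by its largest singular value and
    time by the geometric mean of the acquisition times; both are undone on
    output, so maps return in electrons/A^3 and rates in s^-1.  Stops early
    when the loss stays at or below ``loss_tolerance`` for ``n_consecutive``
    iterations, or when the loss turns non-finite (partial traces are kept
    and the result is flagged diverged).
    """
    times = cfg.times if cfg.times is not None else E.times
    if times is None:
        raise ValueError("acquisition times are required (cfg.times or E.times)")
    times = np.asarray(times, dtype=float)
    if np.all(E.values == 0):
        raise ValueError("data matrix is identically zero")

    svd = decompose_series(E, n_significant=cfg.n_significant)
    M_sig = svd.n_significant
    M = M_sig                      # one intermediate per significant vector
    P = E.n_times
    if P < M:
        raise ValueError(f"need at least M={M} time points, got P={P}")
    R = mech.n_rates

    # internal conditioning: unit leading singular value, O(1) scaled rates
    scale = float(svd.S[0])
    E_norm = E.values / scale
    t_ref = float(cfg.time_scale) if cfg.time_scale is not None else float(np.exp(np.mean(np.log(times))))
    ts = times / t_ref
    U = svd.U_significant

    bounds = (cfg.bounds or RateBounds(lower=np.array([1e-6]), upper=np.array([1e10]))).broadcast(R)
    ln_low = np.log(bounds.lower * t_ref)
    ln_high = np.log(bounds.upper * t_ref)
    rate_cap = float(np.max(bounds.upper) * t_ref) if cfg.rate_overshoot_guard else None
    amps = (cfg.c_E, cfg.c_K, cfg.c_C, cfg.c_I, cfg.c_P)

    state = init_state({"M_sig": M_sig, "M": M, "P": P, "R": R}, cfg)
    params = state.params()
    opt = _Adam(params, cfg.learning_rate)

    losses: list[float] = []
    ckpt_iters: list[int] = []
    inter_trace: list[np.ndarray] = []
    rate_trace: list[np.ndarray] = []
    diverged = False
    converged = False
    quiet = 0
    loss = None
    it = 0

    def checkpoint(i: int, cache: dict) -> None:
        ckpt_iters.append(i)
        inter_trace.append(cache["I"] * scale)
        rate_trace.append(cache["k"] / t_ref)

    if cfg.max_iterations == 0:
        loss, cache = _forward(state, U, E_norm, mech, ts, ln_low, ln_high, amps,
                               cfg.include_dark_in_projection, C0_DEFAULT, need_grad=False,
                               decoding=cfg.rate_decoding, rate_cap=rate_cap)
        losses.append(loss.total)
        checkpoint(0, cache)
    else:
        for it in range(1, cfg.max_iterations + 1):
            loss, cache = _forward(state, U, E_norm, mech, ts, ln_low, ln_high, amps,
                                   cfg.include_dark_in_projection, C0_DEFAULT, need_grad=True,
                                   decoding=cfg.rate_decoding, rate_cap=rate_cap)
            losses.append(loss.total)
            if not np.isfinite(loss.total):
                diverged = True
                checkpoint(it, cache)
                break
            if it % cfg.checkpoint_stride == 0 or it == cfg.max_iterations:
                checkpoint(it, cache)
            if loss.total <= cfg.loss_tolerance:
                quiet += 1
                if quiet >= cfg.n_consecutive:
                    converged = True
                    if not ckpt_iters or ckpt_iters[-1] != it:
                        checkpoint(it, cache)
                    break
            else:
                quiet = 0
            grads = _backward(state, U, E_norm, cache, amps, cfg.include_dark_in_projection)
            opt.step(params, grads)
        if not diverged:
            # refresh outputs at the final parameter values
            loss, cache = _forward(state, U, E_norm, mech, ts, ln_low, ln_high, amps,
                                   cfg.include_dark_in_projection, C0_DEFAULT, need_grad=False,
                                   decoding=cfg.rate_decoding, rate_cap=rate_cap)
            if ckpt_iters and ckpt_iters[-1] == it:
                inter_trace[-1] = cache["I"] * scale
                rate_trace[-1] = cache["k"] / t_ref
            else:
                checkpoint(it, cache)

    k_phys = cache["k"] / t_ref
    I_phys = cache["I"] * scale
    C_data = cache["C_cde"]

    dense_t = np.geomspace(times.min(), times.max(), cfg.dense_grid_points)
    if np.all(np.isfinite(k_phys)):
        C_dense = solve_concentrations(assemble_rate_matrix(k_phys, mech), C0_DEFAULT, dense_t).C
    else:
        C_dense = np.full((mech.n_states, dense_t.size), np.nan)

    run = RunOutputs(
        intermediates_trace=inter_trace,
        rates_trace=np.array(rate_trace),
        loss_trace=np.array(losses),
        concentrations_out=C_dense,
        concentration_times=dense_t,
        checkpoint_iterations=np.array(ckpt_iters),
        rate_labels=mech.rate_order,
    )
    return TrainResult(
        run=run,
        intermediates=I_phys,
        rates=dict(zip(mech.rate_order, k_phys)),
        concentrations=C_data,
        concentrations_nn=state.C_nn.copy(),
        loss=loss,
        state=state,
        times=times,
        converged=converged,
        diverged=diverged,
        n_iterations=it,
        data_scale=scale,
        time_scale=t_ref,
    )
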
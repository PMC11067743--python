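# Methods

## The problem

A time-resolved X-ray crystallography (TRX) experiment yields a series of
difference electron-density (DED) maps: the density at a pump–probe delay
minus the resting (dark) density. Restricting each map to a region of
interest (ROI) of N voxels and stacking P delays gives the data matrix
**E** (N × P). If the photocycle passes through M transient intermediates
with time-independent DED signatures **I** (N × M) and fractional
concentrations **C**(t), then

    E(:, p) = Σ_m I(:, m) · c_m(t_p) + noise,

and the concentrations obey first-order kinetics

    dC/dt = K C,     C(0) = (1, 0, …, 0),

where **K** is assembled from the reaction-rate coefficients (RRCs) of a
kinetic mechanism: for each coefficient k_r driving the transition
from state a to state b, K[b,a] += k_r and K[a,a] −= k_r, so columns sum to
zero and total population is conserved. The dark state is carried as an
explicit (M+1)-th state with zero DED signature; reaction initiation lives
entirely in the initial condition (every excited molecule starts in the
first intermediate), never in a rate.

The package recovers **I**, **C**(t) and the RRCs simultaneously from **E**
alone by training a small network whose loss embeds the kinetic ODEs.

## Mechanisms

The general three-intermediate scheme has R = 10 coefficients arranged as
five reversible pairs: I1↔I2 (k1/k−1), I1↔I3 (k2/k−2), I2↔I3 (k3/k−3),
I2↔dark (k4/k−4), I3↔dark (k5/k−5). Two presets restrict it:

* sequential — I1 →k1 I2 →k3 I3 →k5 dark (irreversible chain);
* dead-end — I1 →k1 I2 →k4 dark with a reversible off-path exchange
  I2 ↔ I3 (k3/k−3); I3 is the dead end.

A mechanism is data (a list of label → transition assignments), so any other
scheme over the four states can be encoded without code changes.

Because the initial condition pins I1 but nothing distinguishes the labels
of I2 and I3, the general scheme is symmetric under swapping them (which
permutes k1↔k2, k−1↔k−2, k3↔k−3, k4↔k5, k−4↔k−5). All comparisons against a
known ground truth therefore first align the recovered solution over the two
admissible orderings, by total map correlation.

## ODE solution and its derivative

dC/dt = K C is solved exactly by diagonalization, C(t) = V e^{Λt} V⁻¹ C(0),
with the solution computed in complex arithmetic and the real part returned
(K is real, so the exact solution is real; the imaginary residue is checked
against 1e-9). When the eigenvector matrix is ill-conditioned (estimated
condition number above 1e12 — near-defective K), the solver falls back to a
dense matrix exponential per time point; valid rate matrices never raise.

Training needs dC/dk_r. For diagonalizable K the derivative of the matrix
exponential in direction D_r = dK/dk_r is exact:

    d exp(Kt)[D_r] = V (G_r ∘ Φ(t)) V⁻¹,   G_r = V⁻¹ D_r V,
    Φ_ab(t) = (e^{λ_a t} − e^{λ_b t}) / (λ_a − λ_b),   Φ_aa(t) = t e^{λ_a t},

the divided differences of the exponential over the spectrum. Φ is evaluated
from the bounded exponentials directly; pairs with |λ_a − λ_b|·t < 1e-6 use
the series t e^{λ_b t}(1 + z/2 + z²/6) to avoid the 0/0 cancellation. In the
rare ill-conditioned case the derivative falls back to central finite
differences around the dense exponential. The whole backward pass is
hand-written reverse mode (the network is six small tensors); it is verified
against central finite differences of the total loss in the test suite.

## Architecture

* Projection network (linear, bias-free): I = U A, where U holds the M
  significant left singular vectors of E, and E^C1 = I C^NN; the middle-layer
  weights C^NN (M × P) are read as the intermediate concentrations.
* Conversion network: input x = relu(C^NN) flattened row by row (length
  Q = M·P); hidden layer h = relu(W1 x + b1) with H = ceil((Q + R)/3)
  perceptrons (H must exceed R); output raw = W2 h + b2 decoded to rates.
  Default decoding is k = exp(raw), which keeps every rate strictly positive
  (the range penalty takes logarithms) and makes the penalty quadratic in
  the raw output; k = k_low + relu(raw) is available as an alternative.
* Physics step: K(k) is assembled, C^CDE solved at the data times, and the
  series rebuilt a second time as E^C2 = I · relu1(C^CDE over the M
  intermediate rows), where relu1 clamps to [0, 1] (fractional
  concentrations). The dark row multiplies a zero difference signature by
  definition of a DED map, so it does not enter E^C2.

All weights and biases are initialized from N(0, 0.02²), seeded.

## Loss

    total = c_E·L_E + c_K·L_K + c_C·L_C + c_I·L_I,  defaults c_E=c_K=c_I=1, c_C=0.1

* L_E = ⟨(E − E^C1)²⟩ + ⟨(E − E^C2)²⟩ (⟨⟩ = mean over elements): both
  reconstructions must match the data.
* L_K = Σ_i min(ln k_i − ln k_i^low, 0)² + Σ_i max(ln k_i − ln k_i^high, 0)²:
  a two-sided range penalty on log-rates (processes span decades, so the
  log puts fast and slow on one scale). Worked example: with limits
  (≈0, 1000 s⁻¹), k = 900 adds nothing and k = 2000 adds (ln 2)² ≈ 0.48.
  Limits must be positive; "essentially zero" is 1e-6 s⁻¹ by default, and
  the loose default range is (1e-6, 1e10) s⁻¹.
* L_C = ⟨(C^NN − C^CDE)²⟩ over the intermediate rows: the self-consistency
  term that couples the factorization to the kinetics; the method does not
  work without it.
* L_I: only active when the projection carries an explicit dark column
  (mean of its squared density, forcing it featureless) and/or when the
  optional map-dissimilarity factor c_P > 0 (squared cosine between each
  pair of intermediate maps). Both are off by default.

## Training

Full-batch AdaM (β = 0.9/0.999, ε = 1e-8), learning rate 1e-4, up to 3×10⁵
iterations, stopping early when the loss stays at or below the tolerance for
`n_consecutive` (default 100) iterations. The loss is recorded every
iteration; intermediate maps and rates at a checkpoint stride (default 1000,
which keeps the per-iteration output files bounded). Final concentrations
are re-solved from the last-iteration rates on a dense ~400-point
logarithmic grid for smooth plots.

Two internal conditioning choices, both undone on output:

* the data matrix is scaled by 1/s₁ (its largest singular value), so the
  projection weights live at O(1) regardless of the experiment's density
  units;
* time is scaled by the geometric mean of the acquisition times, so rates
  are O(1) at the center of the observable window and the log-rate outputs
  travel short distances.

A third guard caps rates at the upper range limit during training
(straight-through: capped rates only feel gradients pulling them back in).
In the first iterations, while C^NN is still near its tiny random
initialization, the self-consistency term transiently rewards draining all
states instantly and the rates overshoot by orders of magnitude; the cap
bounds that excursion. It is inactive at convergence for any solution inside
the allowed range.

## SVD stage

E = U S Vᵀ (thin). A vector is significant when s_i/s₁ > 0.05 and the lag-1
autocorrelation of its right singular vector exceeds 0.5; on a ~20-point
logarithmic time grid smooth kinetic vectors measure ≈0.8 and noise vectors
stay below ≈0.4 in magnitude, so 0.5 separates the regimes with margin (an
explicit M overrides the rule). Relaxation rates come from a global fit of
Σ_j B_ij e^{−λ_j t} to the singular-value-weighted significant right
vectors: shared log-rates are optimized by Levenberg–Marquardt with
per-vector amplitudes solved linearly at fixed rates (variable projection),
initialized log-spaced across the reciprocal time window. No constant offset
term is included. The fitted rates suggest RRC range limits: upper = a
multiple (default 10) of the largest rate, or the sum of the rates for a
tight protocol; lower = a positive floor (default 1e-6 s⁻¹, or the smallest
fitted rate for the tight protocol).

## Synthetic data

The generator emulates a photoactive-yellow-protein-style photocycle at the
density level. Intermediate maps are sums of five paired positive/negative
Gaussian features at seeded random voxel positions, mean-centred and scaled
to a 0.5 peak (in the analogue of electrons/Å³); concentration profiles come
from one of four rate presets — sequential separated S_S (k1=40000,
k3=1000, k5=100 s⁻¹), sequential overlapping S_O (2000/3000/900), dead-end
separated DE_S (k1=9500, k3=330, k4=400, k−3=210) and dead-end overlapping
DE_O (15000/2000/100/2000) — solved with C(0)=(1,0,0,0) on 21 log-spaced
times over [1e-6, 1] s, a window containing the fastest (1/40000 s) and
slowest (1/100 s) preset processes. The observable is E = I·C plus i.i.d.
Gaussian noise (default σ = 3.4e-5). Defaults use N = 2291 voxels;
validation runs use N = 500.

What this does not emulate: the crystallographic route from structures to
maps (structure factors, amplitude noise calibrated on experimental data,
difference-Fourier synthesis, amplitude weighting), which produces
spatially and temporally structured noise and maps with shared local
support. Passing tests on this generator therefore demonstrate the
machinery — decomposition, exact ODE gradients, optimization, metrics — on
clean factorizable data, not robustness to crystallographic noise.

## Evaluation metrics

* Weighted concentration residual R_w: mean over states (including dark)
  and time points of |c_pred − c_true| / c_true, skipping entries whose true
  concentration is zero (they would make the residual infinite); values
  below 1e-12 count as zero, since exact exponential solutions underflow to
  denormals at populations with no physical meaning. An ODE-consistent fit
  with few-percent rate errors scores R_w ≈ 0.1; a wrong mechanism scores
  orders of magnitude higher.
* Map residual R_s = √⟨(E_pred − E_meas)²⟩, in map units. For a successful
  run it settles at the noise floor of the input; a value well above the
  noise flags an untrustworthy factorization. R_s needs no ground truth and
  is the metric available for real experiments.
* Map recovery: Pearson correlation between each recovered intermediate map
  and its ground-truth counterpart, after state alignment.
* Reproducibility: independent runs differing only in the initialization
  seed; the run-to-run spread of R_w/R_s (narrow for a healthy
  configuration) is the practical convergence diagnostic.

## Identifiability: what a single run can and cannot pin down

At the density level the factorization E = I·C is invariant under any
invertible remix I → I T, C → T⁻¹ C that keeps C inside the chosen
mechanism's ODE family with the fixed initial condition and 0 ≤ C ≤ 1. For
sequential data under the general 10-rate scheme this leaves a continuous
family of exact optima: the exit flux of I1 (k1 + k2), the relaxation
eigenvalues and the slowest decay are pinned, but the split of the I1 exit
between the two channels (and correspondingly a mixing of the second and
third maps) is not. Training converges to the measured noise floor at a
point of this family selected by the data realization, not by the
initialization — different seeds land on the same point, different synthetic
map realizations on different points. Typical landings put k1 at ~0.7–0.8 of
the generating value with the complement in k2, recover the slow
coefficients (the 1000 s⁻¹ and 100 s⁻¹ eigenvalues) to better than 1%, and
leave the second map mixed (correlation ~0.88 instead of ~1).

Consequences for use: treat single-run rate labels from an uninformed
general-mechanism fit as one representative of a degenerate family;
eigenvalue-level quantities (relaxation rates, exit fluxes) are reliable.
To identify the mechanism itself, run the candidates as informed mechanisms
(spurious coefficients clamped out, the rest bounded by the relaxation-rate
limits) and compare converged loss and R_w — on dead-end data the dead-end-
informed run beats the sequential one on both. The dead-end topology retains
one internal flat direction (k3 + k4 + k−3 and k4·k−3 are pinned, their
split is not), so even informed runs recover concentrations more reliably
than individual coefficient values.

## Problem sizes and runtimes

An iteration at N = 500, P = 21 costs about 1 ms on one CPU core (dominated
by the 4×4 eigendecomposition and the small dense products). The validation
suite uses N = 500, 5×10⁴ iterations per run (~1 min each; ten-seed
reproducibility ~10 min); the generator default N = 2291 costs ~2.5× more
per iteration.

## Known limitations

* Gaussian i.i.d. noise only; structured crystallographic noise is out of
  scope.
* Single-temperature data cannot break mechanism degeneracies (see above);
  discrimination is by comparing informed runs.
* The conversion network's rate decoding (exponential by default) is a
  design choice; the range penalty itself only requires positive rates.
* No symmetry expansion or unit-cell reconstruction: the analysis stays in
  the flattened ROI voxel space.
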
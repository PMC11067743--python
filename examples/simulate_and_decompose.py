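"""Simulate a sequential photocycle and read its kinetics off the SVD.

Builds a noisy synthetic DED-map series for the separated sequential
mechanism (k1=40000, k3=1000, k5=100 s^-1), decomposes it, and fits a shared
sum of exponentials to the significant right singular vectors.  The fitted
relaxation rates are the eigenvalue magnitudes of the rate matrix — for an
irreversible chain they equal the rate coefficients themselves — and their
extremes suggest magnitude limits for network training.
"""

import numpy as np

from dedkin import decompose_series, derive_rate_bounds, fit_relaxation_rates, simulate

series, truth = simulate("S_S", n_voxels=500, noise_sigma=3.4e-5, seed=1)
print(f"data matrix: {series.n_voxels} voxels x {series.n_times} time points "
      f"({series.times.min():.0e}..{series.times.max():.0e} s)")

svd = decompose_series(series)
ratios = ", ".join(f"{r:.3f}" for r in (svd.S / svd.S[0])[:5])
print(f"leading singular-value ratios: {ratios}")
print(f"significant singular vectors: {svd.n_significant} (the number of intermediates)")

fit = fit_relaxation_rates(svd, n_exp=svd.n_significant, t=series.times)
print("fitted relaxation rates (s^-1):", ", ".join(f"{r:.4g}" for r in fit.rates))
print("generating rate coefficients  :", ", ".join(f"{v:.4g}" for v in truth.k_true.values()))

bounds = derive_rate_bounds(fit, multiplier=10.0, mode="max_rate")
print(f"suggested rate limits for training: ({bounds.lower[0]:.0e}, {bounds.upper[0]:.3g}) s^-1")
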
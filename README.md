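# dedkin

Kinetic analysis of time-resolved difference electron-density (DED) map
series with a kinetics-informed neural network.

A time-resolved X-ray crystallography experiment produces DED maps — the
electron density at a pump–probe delay minus the resting-state density — at a
series of delays. Each map mixes the signatures of a few transient
intermediates, weighted by their time-dependent fractional concentrations:
stacking the N region-of-interest voxels at P delays gives

    E = I · C(t) + noise,      dC/dt = K C,      C(0) = (1, 0, 0, 0),

with **I** the time-independent DED map of each intermediate (N × M), **C**
the concentration profiles, and **K** the rate matrix assembled from the
reaction-rate coefficients (RRCs) of a first-order kinetic mechanism.
`dedkin` recovers all three — coefficients, concentrations and maps — from
the map series alone. A small two-part network (a linear projection of the
significant left singular vectors into maps and concentrations, and a
one-hidden-layer conversion of the concentrations into rate coefficients) is
trained against a loss that combines data fidelity, a log-scale range
penalty on the rates, and a self-consistency term between the network's
concentrations and the exact ODE solution C(t) = V e^{Λt} V⁻¹ C(0). Training
is plain numpy: the backward pass is written out by hand, including the
exact derivative of the matrix exponential with respect to the rates.

It ships with a synthetic-data generator (a photoactive-yellow-protein-style
photocycle with sequential and dead-end mechanism presets), an SVD stage
that counts intermediates and fits global relaxation rates, evaluation
metrics (weighted concentration residual R_w, map residual R_s, per-map
Pearson correlation, multi-seed reproducibility), and a command-line front
end. The science, the reconstructed formulas and the identifiability limits
of single-temperature data are documented in [docs/methods.md](docs/methods.md).

## Worked example: which mechanism made the data?

`examples/compare_mechanisms.py` simulates a dead-end photocycle (I1 → I2 →
dark with a reversible off-path exchange I2 ↔ I3), then trains the network
informed with the correct dead-end mechanism and, for comparison, with the
irreversible sequential one, both bounded by the SVD-derived relaxation
rates:

```
fitted relaxation rates (s^-1): 9500, 840, 99.99
rate limits: (100, 10440) s^-1
  dead_end: loss 5.270e-11  R_w 0.339  (k1=9499, k3=151, k4=662, k-3=127)
sequential: loss 9.250e-11  R_w 0.693  (k1=9501, k3=840, k5=100)
lower loss and lower R_w identify the mechanism that generated the data
```

The relaxation rates recover the eigenvalues of the generating rate matrix
(9500, 840, 100 s⁻¹ for k1=9500, k3=330, k4=400, k−3=210 s⁻¹). The
dead-end-informed run fits the fast coefficient k1 exactly and the
off-path exchange up to the flat direction documented in the methods note,
and wins on both the converged loss and the weighted concentration residual
R_w (mean relative concentration error vs the ground truth, lower is
better). The other examples show the SVD stage on its own
(`simulate_and_decompose.py`: 3 significant singular vectors, relaxation
rates 40000/1000/100 s⁻¹ recovered to four digits) and an uninformed
general-mechanism recovery with its degeneracies (`recover_kinetics.py`).

The same workflow from a shell:

```sh
dedkin simulate --preset DE_S --n-voxels 500 --seed 3 --out sim/
dedkin svd      --roi sim/roi.txt --times sim/times.txt --out svd/
dedkin train    --roi sim/roi.txt --times sim/times.txt --mechanism dead_end --out run/
dedkin evaluate --pred run/ --truth sim/ --out report/
```

`train` writes the four run-output text files (per-checkpoint intermediate
maps and rates, per-iteration loss, final concentration profiles on a dense
grid) plus a JSON manifest of the resolved configuration.

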
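# lossycode

Rate-distortion analysis of perception in random environments.

Organisms (and any resource-limited sensor) cannot afford to represent every
state of a complex world. They compress: dangerous confusions are avoided,
harmless ones tolerated. This package models that trade-off with
rate-distortion theory. An environment with `N` states is an `N x N`
distortion matrix `d(x, xhat)` — the cost of perceiving state `x` as
`xhat` — with zero diagonal and random off-diagonal entries. A perceptual
codebook `p(xhat|x)` costs `R = I(X; Xhat)` bits of transmission and incurs
expected distortion `D = E[d]`; the rate-distortion function `R(D)` is the
cheapest rate achieving error `D`, computed here by Blahut-Arimoto fixed-point
iteration at gain `beta`:

    p(xhat|x) ∝ r(xhat) exp(-beta d(x, xhat)),    r(xhat) = Σ_x p(x) p(xhat|x)

The central quantity is the **minimal confound** `d_min`, the cheapest
possible confusion. For tolerated distortion `D > d_min` (low fidelity),
`R(D)` saturates as `N` grows — perceptual cost becomes independent of
environmental complexity, bounded by `log2(1/P(d < D))`. For `D < d_min`
(high fidelity), `R(D)` grows like `log2 N`, bracketed between
`(1 - D/d_min) log2 N` and `(1 - D/<d>) log2 N`, where `<d>` is the mean
off-diagonal cost. The package is for researchers in sensory ecology,
theoretical neuroscience, and information theory who want these curves,
bounds, and scaling experiments as tested, reproducible building blocks.

## Worked example

```python
import lossycode as lc

spec = lc.EnvironmentSpec("exponential", shift=1.0, scale_params={"mean": 1.0},
                          n_states=50, seed=7)
m = lc.draw_matrix(spec)
print(f"minimal confound d_min = {m.d_min:.3f}")
print(f"mean off-diagonal cost <d> = {m.mean_off_diag:.3f}")
print(f"zero-rate distortion     = {m.d_max_useful:.3f}")
for D in (0.5, 1.5):
    pt = lc.beta_for_distortion(m, D)
    bs = lc.bound_report(m, D)
    print(f"D = {D}: rate = {pt.rate_bits:.3f} bits ({bs.regime}), "
          f"beta = {pt.beta:.2f}, "
          f"bounds [{bs.uniform_env_lb:.3f}, {min(bs.synonym_ub, bs.uniform_alloc_ub):.3f}]")
```

prints

```
minimal confound d_min = 1.001
mean off-diagonal cost <d> = 2.007
zero-rate distortion     = 1.729
D = 0.5: rate = 2.798 bits (high-fidelity), beta = 2.95, bounds [1.841, 3.435]
D = 1.5: rate = 0.084 bits (low-fidelity), beta = 0.51, bounds [0.000, 0.632]
```

The draw is a 50-state environment with shifted-exponential costs
(`d_min ≈ 1`). Holding the average error at `D = 0.5` — below the minimal
confound — needs 2.8 bits (about `2^2.8 ≈ 7` effectively distinguished
states) at gain 2.95, inside the analytic sandwich `[1.84, 3.44]`. Relaxing
to `D = 1.5`, above the confound, collapses the cost to under a tenth of a
bit: almost all confusions have become tolerable synonyms.

Ensemble experiments reproduce the scaling laws:

```python
summary = lc.run_ensemble("exponential", shift=1.0, N_list=[20, 50, 100],
                          D_targets=[0.5, 1.5], n_samples=10, seed=0)
slope, err = lc.regime_slope(summary, 0.5)   # rate vs log2 N, high fidelity
```

The high-fidelity slope lands in `[1 - D/d_min, 1 - D/<d>] = [0.5, 0.75]`,
while at `D = 1.5` the mean rate saturates across `N`. A `lossycode` CLI
exposes the same pipeline (`generate-env`, `rd-curve`, `bounds`, `ensemble`,
`required-beta`) with JSON configs and replayable run manifests.

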
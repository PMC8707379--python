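# offgrid

Gridless (off-the-grid) sparse spike recovery via the Beurling LASSO, with
an application pipeline for single-molecule localization microscopy (SMLM).

## The problem

Many imaging modalities observe a handful of point sources through a
low-pass device: fluorophores behind a microscope's point spread function,
spectral lines behind a band-limited Fourier measurement.  Classical
sparse recovery places the unknowns on a reconstruction grid and solves a
LASSO; the grid both limits accuracy and creates spurious spike pairs.
The gridless alternative optimizes directly over *measures*: a source
configuration is `m = Σᵢ aᵢ δ_{xᵢ}` with continuous positions, recovered
from data `y = Φm + w` by the BLASSO

    min_m  ½‖y − Φm‖² + λ|m|(X),       |m|(X) = Σᵢ|aᵢ|,

whose total-variation-norm penalty plays the role of ℓ₁ for measures.
Optimality is certified by the dual certificate
`η_λ(x) = ⟨y − Φm, φ(x)⟩/λ`, which satisfies `|η_λ| ≤ 1` with equality
exactly on the support of a minimizer.

The package provides, for Fourier (1-D torus) and pixel-integrated
Gaussian (2-D) forward operators:

* **`solve_sfw`** — Sliding Frank-Wolfe: greedy insertion at the
  certificate argmax, FISTA amplitude step, joint amplitude/position
  descent; empirically N iterations for N sources, with a positivity
  variant for fluorescence.
* **`solve_cpgd`** — conic particle gradient descent: an over-parametrized
  particle cloud under multiplicative (Fisher–Rao) weight updates and
  additive (Wasserstein) position updates; signed measures run two
  coupled particle populations.
* **`solve_blasso_sdp`** — for 1-D Fourier data, the exact semidefinite
  recast of the dual, solved by a built-in ADMM, with support read off the
  unit-circle roots of the certificate polynomial.
* **`flat_metric` / `wasserstein1` / `jaccard_index`** — unbalanced and
  balanced optimal-transport reconstruction metrics (exact LPs on the
  spike supports) and the SMLM detection score.
* **`simulate` / `pipeline`** — a synthetic SMLM scene generator
  (filaments, blinking, pixel-integrated Gaussian PSF, Poisson photon +
  dark current noise, Gaussian readout) and a frame-by-frame localization
  pipeline with super-resolved rendering.

## Worked example

Three spikes of mixed sign, amplitudes (1.0, −1.0, 0.7) at positions
(0.1, 0.45, 0.78) on the unit torus, observed through 13 noisy Fourier
coefficients (cut-off f_c = 6), solved at λ = 1:

```python
from offgrid import solve_sfw
from offgrid.examples import fourier_problem

prob, truth = fourier_problem(seed=0, noise=0.02, lam=1.0)
res = solve_sfw(prob)
print("stop:", res.stop_reason, " outer iterations:", res.n_outer_iters)
print("certificate sup at stop:", round(res.cert_sup_trace[-1], 6))
for a, x in sorted(zip(res.measure.amplitudes, res.measure.positions[:, 0]),
                   key=lambda t: t[1]):
    print(f"  amplitude {a:+.4f}  position {x:.4f}")
```

prints

```
stop: optimality  outer iterations: 4
certificate sup at stop: 1.00001
  amplitude +0.9254  position 0.1002
  amplitude -0.9101  position 0.4504
  amplitude +0.6237  position 0.7789
```

All three sources are found with no spurious spike; positions are accurate
to ~5·10⁻⁴ (about 1/100 of the 1/(2f_c) diffraction scale) and amplitudes
are slightly shrunk toward zero, the expected λ-bias of the convex
penalty.  The final certificate sup of 1.00001 is the numerical optimality
certificate: no location in the continuous domain would accept another
spike.

The same fixture runs through the other solvers via the CLI:

```
offgrid toy1d --solver sdp   --fc 6 --lam 1 --noise 0
offgrid toy1d --solver cpgd  --fc 6 --lam 1 --noise 0
```

## SMLM pipeline

```
offgrid simulate --out stack.tif --gt gt.csv --seed 7
offgrid localize --stack stack.tif --out locs.csv
offgrid evaluate --locs locs.csv --gt gt.csv --tau 200 --radius 100
offgrid render   --locs locs.csv --factor 32 --out sr.tif
```

`simulate` writes a 50-frame 64×64 stack (100 nm pixels, PSF σ =
149.39 nm) of blinking emitters on filament structures; `localize` runs
the positive BLASSO frame by frame (λ = 0.025·‖frame‖∞ per frame, median
background subtraction, NNLS amplitude debiasing) and emits a
ThunderSTORM-style table `frame, x [nm], y [nm], intensity`; `evaluate`
reports the flat metric at τ = 200 nm, the Jaccard detection index at
100 nm, and the RMSE of matched pairs.  On the default synthetic scenes
this pipeline detects ~85 % of activations with ~15 nm RMSE — about a
sixth of the pixel size.  `render` draws the localizations through a σ/6
Gaussian on a 32×-finer grid.

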
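# Methods

## The model

A collection of point sources is represented as a discrete signed Radon
measure `m = Σᵢ aᵢ δ_{xᵢ}` with real amplitudes `aᵢ` and continuous
positions `xᵢ` in a box or torus domain — no reconstruction grid is ever
introduced.  The acquisition is `y = Φm + w`, where `Φ` integrates a
measurement kernel against the measure and `w` is additive noise.  Two
kernels are implemented:

* **Fourier (1-D torus).** `φ(x) = (e^{2iπkx})_{|k| ≤ f_c}`, giving
  `n = 2f_c + 1` complex coefficients.  The measurement space is treated
  as a real Hilbert space with `⟨u, v⟩ = Re Σ u_k v̄_k`; the adjoint is
  implemented so that `⟨Φm, p⟩ = Σᵢ aᵢ (Φ*p)(xᵢ)` holds to machine
  precision, which fixes the conjugation convention unambiguously (for
  Hermitian-symmetric `p`, the adjoint field coincides with the real
  trigonometric polynomial `Σ p̄_k e^{2iπkx}`).
* **Pixel-integrated Gaussian (2-D).** Each camera pixel integrates a
  normalized isotropic Gaussian of spread σ over its extent, so a pixel
  value is a product of per-axis erf differences.  Pixel `(i₁, i₂)`
  occupies `[i₁b₁, (i₁+1)b₁) × [i₂b₂, (i₂+1)b₂)` from the image
  lower-left corner; positions are continuous physical coordinates (nm for
  microscopy), never pixel indices.  Evaluation on tensor grids uses the
  separable factorization `G₁ P G₂ᵀ`, which is what makes certificate grid
  searches on 128² grids cheap.

Sources are recovered by minimizing the BLASSO energy

    T_λ(m) = ½‖y − Φm‖² + λ|m|(X),

where `|m|(X) = Σ|aᵢ|` is the total-variation norm, the measure-space
analogue of the ℓ₁ penalty.  Optimality is monitored through the dual
certificate `η_λ(x) = ⟨y − Φm, φ(x)⟩ / λ`: at a minimizer `|η_λ| ≤ 1`
everywhere and `|η_λ| = 1` on the support.  The continuous sup-norm of
`η_λ` is approximated by a regular grid (default 32·f_c nodes for Fourier,
4 per σ for Gaussian) followed by derivative-based local ascent from the
best node; ties break at the lowest flat index for determinism.  Dual
feasibility is declared at `1 + 10⁻⁶` to absorb floating-point slack on
the constraint boundary.

## Solvers

**Sliding Frank-Wolfe (SFW).** Each outer iteration inserts a spike at the
certificate argmax (grid search + refinement), re-fits all amplitudes by
FISTA on the finite LASSO (soft-threshold prox; nonnegative variant clips
at zero), then *slides*: a joint L-BFGS-B descent on all amplitudes and
positions.  The ℓ₁ term is smoothed in the slide by freezing amplitude
signs at entry and enforcing them through sign-consistent bounds; spikes
whose amplitude reaches zero are pruned afterwards.  New spikes enter at
amplitude zero so the energy trace is non-increasing by construction.  The
loop stops when `sup|η_λ| ≤ 1 + stop_tol` (default 10⁻⁴) or at the outer
iteration cap (default 20).  After each slide, spikes closer than ~1/1000
of the kernel resolution scale are fused: when the certificate is
marginally above tolerance the insertion lands on an existing spike, and
the pair is one spike numerically split.  Degenerate input `y = 0` returns
the empty measure immediately.

**Conic particle gradient descent (CPGD).** An over-parametrized cloud of
N particles `(rᵢ, xᵢ)` represents `ν = (1/N) Σ rᵢ² δ_{xᵢ}` and descends
`T_λ` under the Wasserstein–Fisher–Rao geometry: weights update
multiplicatively, `rᵢ ← rᵢ·exp(2αhλ(η(xᵢ) − 1))`, positions additively,
`xᵢ ← xᵢ + βhλ ℓ² ∇η(xᵢ)`, with the certificate frozen at the step start.
Multiplicativity keeps weights nonnegative; mass grows where `η > 1` and
decays where `η < 1` — the sign convention was fixed by requiring energy
descent, since the continuous-flow equations can be read with either
sign.  The factor `ℓ²` (ℓ = 1/2π on the Fourier torus, i.e. the angular
parametrization; ℓ = σ for the Gaussian kernel) makes the transport rate
dimensionless: β multiplies a spatial *gradient* whereas α multiplies the
dimensionless certificate, so without a length² factor equal rates α = β
put the position step two orders of magnitude above the basin scale and
the flow scatters (measured directly: position steps ≈ 0.2 of the domain
per iteration at f_c = 6).  With the scaling, the reference settings
α = β = 10⁻³ (1-D) and 10⁻² (2-D) at λ = 1 converge within 1000
iterations.  Particles start on a seeded jittered grid covering the domain
(diversity of initialization is what the mean-field theory requires) with
equal weights.

Signed problems decompose the measure into positive and negative parts and
evolve one joint flow with two particle populations: negative particles
see the sign-flipped kernel (`η → −η`, `∇η → −∇η`) while both share the
residual of the combined measure.  Decoupling the flows instead solves two
different positivity-constrained problems whose difference is not the
signed minimizer (verified numerically: the decoupled variant stalls at
several times the optimal energy).

The final cloud is condensed by dropping particles below 2 % of the
maximum amplitude (un-converged dust decays only like
`exp(−2αhλ(1−η)t)` and sits near 0.5 % after 10³ iterations), then
single-linkage merging within a radius of σ/4 (Gaussian) or 1/(4f_c)
(Fourier) — below the resolution scale, above numerical jitter — per sign,
and finally re-fitting amplitudes by the finite LASSO on the merged
support, which restores the mass the pruned dust carried.

**SDP (1-D Fourier only).** The Fourier dual problem has an exact
semidefinite recast: maximize `Re⟨y, p⟩ − (λ/2)‖p‖²` subject to
`[[Q, p], [p*, 1]] ⪰ 0` with unit-trace/zero-trace constraints on the
diagonals of the Hermitian block Q, equivalent to `‖F*p‖_∞ ≤ 1`.  The SDP
is solved by an ADMM splitting written for this structure: the affine
constraints and the smooth objective admit closed-form updates (diagonal
mean-shifts and a scalar quadratic prox on the p column), alternated with
a PSD eigenvalue projection of the (n+1)×(n+1) block; residual balancing
adapts the penalty ρ.  At n = 13 each iteration is one small `eigh`, and
10⁻⁹ consensus residuals take a few hundred iterations.  The support is
then read off as the unit-circle roots (companion-matrix eigenvalues) of
the degree-(2n−2) polynomial `z^{n−1}(1 − |F*p|²)`, built from the
autocorrelation of p.  Circle roots of this nonnegative polynomial have
even multiplicity, and noise splits the pairs slightly off-circle, so
roots within 10⁻⁴ of the circle are kept and angular clusters within
10× that are merged.  Amplitudes are recovered by Hermitian-symmetrized
real least squares on the Vandermonde system against `y − λp`: the
extremality conditions say the primal acquisition is exactly `y − λp`, and
fitting against raw `y` would return unshrunk amplitudes with a
strong-duality gap of order `Nλ²/n` instead of ~10⁻⁹.  Support points
whose amplitude falls below `10⁻³‖y‖` are discarded as spurious
near-circle roots.

## Metrics

The flat metric (Kantorovich–Rubinstein norm) `d_τ(m₁, m₂)` is computed
exactly as an LP over potential values on the union support: maximize
`Σ cⱼ fⱼ` (c = signed amplitude differences) subject to `|fⱼ| ≤ τ` and
`|fⱼ − fₖ| ≤ dist(xⱼ, xₖ)`.  Any feasible vector extends to a Lipschitz
function on the whole domain (McShane), so the discrete LP is not an
approximation.  τ is the price of creating or destroying a unit of mass;
`d_τ → τ·TV(m₁ − m₂)` as τ → 0 and `d_τ → W₁` for equal masses as τ → ∞
(both limits are tested).  For supports beyond ~1500 points the pairwise
constraints fall back to a 32-nearest-neighbour graph, a documented slight
overestimate; no workload in this repository reaches that size.  The
balanced 1-Wasserstein distance is the exact bipartite transport LP and
refuses unequal masses.  Detection quality uses the Jaccard index
`TP/(TP+FP+FN)` after minimum-total-distance one-to-one assignment within
a radius, frame by frame — the SMLM-challenge protocol.  The default
τ = 200 nm is the Rayleigh scale of visible-light microscopy.

## Synthetic SMLM scenes

The generator emulates a localization-microscopy acquisition: filament
curves (cubic splines through jittered control points spanning the field)
carry fluorophores at equal arc-length spacing; each frame activates each
fluorophore independently so that the *expected* number active per frame
matches the configured density; photon counts per activation are
exponential — a deliberately heavy-tailed brightness model, chosen because
no particular law is canonical for blinking dyes, and exposed in config.
Frames are `Poisson(clean + dark) + N(0, readout²)` with the clean image
given by the pixel-integrated PSF.  Defaults mirror the published
challenge setting: 64×64 pixels of 100 nm, σ = 149.39 nm (FWHM
2√(2 ln 2)·σ = 351.8 nm), ~5 active emitters per frame, 4000 mean photons,
dark current 5 counts/px/frame, readout σ = 2 counts — a high-SNR,
moderate-density regime.  A second preset gives the 128×128 / FWHM
351.8 nm geometry.  Negative counts from readout noise are kept in float
output (uint16 export clips at zero with a warning) to avoid silently
biasing the noise model.  Everything is a pure function of (config, seed).

What the generator does *not* model: astigmatic or otherwise 3-D PSFs,
EMCCD amplification statistics, camera offset maps, drift, and spatially
correlated background.  Passing tests therefore demonstrate correctness of
the inverse-problem machinery under the stated forward model, not
robustness to the full phenomenology of real microscopes.

## Pipeline choices

Each frame is solved independently by positive-variant SFW after median
background subtraction (dark current is a constant offset the spike model
cannot represent).  The single tuning parameter is scale-free:
`λ = κ‖frame‖_∞` with κ = 0.025, placing the detection threshold near 10 %
of the mean single-emitter response while staying ~5× above the noise
certificate level of the default scenes.  Recovered amplitudes are then
re-fitted by nonnegative least squares at fixed positions: BLASSO
amplitudes are biased low by ~λ/‖φ‖² (≈ 700 photons at default settings),
and the debiasing step removes that bias without touching positions.
Localizations below 100 photons are discarded.  Rendering pushes the
aggregate measure through a pixel-integrated Gaussian of spread σ/6 on a
32×-finer grid, counts-preserving (the fine image sums to the summed
intensities) rather than max-normalized, so renderings are quantitatively
comparable.

## Reference study configurations

`offgrid.examples` freezes the two instances used throughout tests and
the acceptance script.  The Fourier instance: amplitudes (1.0, −1.0, 0.7)
at positions (0.1, 0.45, 0.78) on the torus, f_c = 6, λ = 1, Hermitian
complex noise of per-component σ = 0.02 — separations exceed the 1.87/f_c
recovery scale for real measures.  The 2-D instance: three positive
sources on [0,1]², Gaussian kernel σ = 0.1 on a 128² pixel grid, additive
per-pixel N(0, 0.1) noise, λ = 3×10⁻².  Source brightnesses (180, 240,
300) put the clean acquisition peak at O(1): at that scale the noise part
of the dual certificate stays below 1 (sup ≈ 0.8), so the stopping rule
fires right after the third insertion and SFW finishes at outer iterate
k = 2 — with a coarser pixel grid the same noise variance would push the
noise certificate above 1 and force spurious insertions, which is why the
grid size is part of the frozen configuration.

## Numerical details and limitations

* FISTA runs to a 10⁻¹² relative objective decrease with the exact
  Lipschitz constant from the Gram matrix eigenvalue.
* The slide returns the incoming measure unchanged if L-BFGS-B fails or
  would increase the energy, so solver monotonicity survives optimizer
  pathologies.
* CPGD weight-update exponents are clipped at ±50 with a warning;
  reaching the clip indicates a step size too large for the instance.
* Problem sizes throughout (13 Fourier coefficients, ≤128² pixel grids,
  50-frame stacks, 10–20 seed replicates) were chosen as the smallest
  instances that exhibit each studied behaviour; the full test suite and
  the acceptance script each run in well under a minute on one core.
* The flat-metric LP grows quadratically in the union support size;
  desk-scale inputs (≤ a few hundred spikes) solve in milliseconds.
* CPGD carries no optimality certificate — its final certificate check is
  deliberately loose (`sup η ≤ 1 + 10⁻²`) compared to SFW/SDP, matching
  its known lack of guarantees at finite N.
* The Laplace (MA-TIRF) kernel, multivariate SDP hierarchies, and
  non-Gaussian PSF models are out of scope; the operator interface was
  shaped so a new kernel needs only `φ`, its gradient, and the adjoint.
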
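# Methods

This note describes the models implemented in `v1sparse`, the numerical
choices behind them, and what the synthetic-data experiments do and do not
demonstrate.

## Sparse coding model

A preprocessed image patch `x` of `N = frame_size**2` pixels is represented
as a linear combination of `P` dictionary atoms `g_i`,

    x  ≈  Σ_i b_i g_i ,

with coefficients chosen to minimize

    C(b) = Σ_pixels [x − Σ_i b_i g_i]²  +  λ Σ_i S(b_i / σ) .

* `S` — an even, non-decreasing sparsity penalty. Default `log(1 + x²)`;
  `1 − exp(−x²)` and `|x|` are also implemented, with derivatives
  `2x/(1+x²)`, `2x·exp(−x²)` and a Huber-smoothed sign (half-width 1e-6)
  respectively, so conjugate gradients stays well defined at 0.
* `σ` — a scaling constant. By default it is frozen at training start as
  the pooled *population pixel variance* of the preprocessed training
  patches; a `sigma_mode="std"` switch uses the standard deviation
  instead, since the symbol conventionally denotes one while the binding
  rule names the other. All shipped experiments use the variance reading.
* `λ = 0.15 σ` by default; `λ = 0` reduces the objective to plain least
  squares, and with a complete linearly independent basis the cost is
  driven exactly to zero (this limit is the package's primary acceptance
  quantity).

### Preprocessing

Pipeline (whole image, in order): element-wise `log(pixel + 1)` modelling
the retina's log-dynamic transfer; a zero-phase radial whitening/low-pass
filter with transfer

    H(ω) = (ω / 2π) · exp(−(ω / 0.4π)⁴),   ω ∈ [0, π] rad/pixel,

applied on the 2D DFT grid with radial frequency = Euclidean norm of the
per-axis angular frequencies, clipped to π at the grid corners; then
non-overlapping tiling into 12×12 frames (borders discarded). The linear
ramp compensates the 1/f spectral fall-off that would otherwise bias the
mean-square error toward low frequencies; the quartic roll-off suppresses
rectangular-sampling artefacts; `H(0) = 0` removes the DC component.
The 1D filter formula does not state whether ω is radial or per-axis in
2D; radial application is the standard reading for isotropic whitening and
is what we implement. Whether the log precedes whitening is likewise an
open choice; the default order is log → whiten (the pipeline order is
configurable), since whitening the whole image after the point-wise
nonlinearity avoids re-introducing DC and keeps patch boundaries clean.

### The V1-inspired initializer

Simple-cell receptive fields are localized, oriented and bandpass. The
0th-estimate dictionary emulates them: straight 3–5 pixel lines are drawn
at random valid positions (without replacement, so no two atoms coincide),
split evenly between 0° and 45°; each line image is passed through a
one-level 2D wavelet decomposition whose approximation band is zeroed
(band-pass filtering), zero-meaned and scaled to unit Euclidean norm.
Each base atom contributes its 90°-rotated counterpart, and one uniform
positive atom carries the frame mean. For a 12×12 frame: 72 base + 72
rotated + 1 uniform = 145 atoms, a slightly over-complete set
(`P = N + 1`).

Numerical choices:

* Wavelet: the 4-tap Daubechies filter (`pywt` name `db2`), configurable.
  The wavelet family barely matters for the resulting atoms; the short
  filter keeps 3–5 px edges well inside the localization budget (≥ 90% of
  energy in a box of side `frame/1.5`).
* Diagonal lines use 8-connected (Bresenham-style) rasterization.
* Overlapping collinear placements can make edge atoms linearly
  dependent. The builder retries with derived sub-seeds (deterministic in
  the master seed) until the atom matrix reaches numerical rank ≥ 144 at
  tolerance 1e-10 relative to the largest singular value.
* The measured mean aspect ratio of the edge atoms is ≈ 2.4–2.5
  (design guidance was length/width ≈ 2; treated as a soft property).
  The nominal "1.5 Hz" bandwidth figure has no well-defined unit for
  discrete frames; bandwidth is reported (FWHM of the radially averaged
  amplitude spectrum) but not enforced.

### Inference

Coefficients are found by Polak–Ribière(+) nonlinear conjugate gradients
from a zero start. The line search seeds each step with the exact
minimizer of the quadratic (reconstruction) term along the search
direction and backtracks (Armijo, c₁ = 1e-4) on the full objective, so
every iterate descends and, for λ = 0, the scheme reduces to exact linear
CG. Default gradient-norm tolerance 1e-6·P, cap 500 iterations;
non-convergence returns the best iterate with a warning. A batched variant
solves all patches of a batch against a shared dictionary in one run (the
summed objective is separable, and the shared-step inexactness washes out
over training). The returned cost never exceeds the all-zero code's cost.

### Dictionary learning

Stochastic gradient descent on the batch-mean cost with respect to the
atoms at fixed inferred coefficients:

    Δg_i ∝ mean_batch( b_i · (x − Σ_j b_j g_j) ),

with step `learning_rate / batch-mean coefficient energy` (default 0.1).
After each batch, atom gains are rescaled so the running per-atom
coefficient variance (EMA, decay 0.3) equals a common target. The target
is **frozen at its first-batch value**: rescaling to a moving mean leaves
a global scale ambiguity that training exploits — atoms grow, coefficients
shrink, the penalty term becomes negligible, and any spanning basis turns
into a fixed point. Pinning the target removes the ambiguity.

Atom maintenance: every 10 batches (during the first 75% of the batch
budget) one member of any atom pair with mutual |cos| > 0.92, and any atom
whose running coefficient variance has collapsed, is re-seeded from the
worst-reconstructed residual direction of the last batch — the standard
duplicate-pruning step of dictionary learners. Without it, training at
`P(learned) = P(planted)` reproducibly forms clusters of mutually
coherent duplicates and caps dictionary recovery at ~73%.

Training draws batches of 100 patches by cycling a seeded shuffle of the
patch pool ("one iteration" = one batch) and stops when the variance of
the batch-mean cost over a 20-batch sliding window falls to 1% of its
window mean, or at the batch cap. Top-k sparsification keeps the k
largest-|b| coefficients, breaking ties toward the lower index so support
sets are reproducible.

### What the synthetic experiments show

The surrogate corpus mirrors the nominal study conditions — ten 540×540
grayscale images segmented into 12×12 frames — with five pink-noise
images (exact 1/f amplitude spectrum, the second-order statistic of
natural scenes) and five dead-leaves images (occluding discs, radius
density ∝ r⁻³ on [2, 100] px: the edge/occlusion statistic pink noise
lacks). These surrogates reproduce natural images' spectra and edges but
not their full phase structure, so quantitative sparsity numbers measured
on them (mean top-k at 97% correlation, relative MSE) are *not* comparable
to numbers measured on photographic corpora; on synthetic corpora only the
ordering "V1-initialized training converges in no more batches than
random-initialized training" is asserted. The `paper-experiment` command
reruns the full two-scenario protocol on any user-supplied image
directory. The shipped ordering check runs a scaled-down configuration
(four 160×160 images, 8×8 frames, 150-batch cap) chosen to keep the whole
suite fast; on this easy corpus both runs typically converge as soon as
the stopping window fills, which satisfies the ordering without
discriminating between initializers — the discriminating evidence is the
dictionary-recovery experiment.

The dictionary-recovery experiment plants a 30-atom random dictionary on
6×6 frames, synthesizes 6000 patches with 3 active atoms each
(amplitudes uniform ±[0.5, 1.5], pixel noise sd 0.01), trains from a
random initializer for a fixed 2000 batches (the cost plateaus long
before the basis rotation finishes, so the stopping rule is disabled
here), and greedily bipartite-matches learned to planted atoms. Across
four pre-registered seed pairs the matched fraction at |cos| > 0.9 is
0.80–0.87.

## Hebbian plasticity model

Weights evolve under

    dw_ij/dt = c1 · f̄_i^α · w_ij^β · f̄_j^γ − c2 · w_ij ,

with `w_ij` oriented pre → post (row = pre-synaptic; the linear response
is `f_j = Σ_i w_ij f_i`). Regularity — c1 ≥ 0 (0 admitted as the
pure-decay limit), c2 > 0, β < 1, finite rates — guarantees the attracting
steady state

    w_ij = c · f̄_i^(α/(1−β)) · f̄_j^(γ/(1−β)),   c = (c1/c2)^(1/(1−β)) .

* Integration: explicit per-entry Euler, dt = 0.01/c2, t_end = 50/c2 by
  default. The Euler map has the same fixed point as the ODE, and the
  slowest linearized decay rate at the fixed point is c2(1−β), so the
  defaults land within 1e-3 relative error of the closed form across the
  tested sweep (β ∈ {−0.5, 0, 0.5}, α, γ ∈ {0.5, 1}). Discrete stability
  needs dt·c2(1−β) < 2; an overflow guard (1e12) and a positivity check
  abort with an instability error naming the violated condition.
* Exponent estimation: ordinary least squares of `log w_ij` on
  `(1, log f̄_i, log f̄_j)`. Exact on noiseless steady states; unbiased
  under multiplicative log-normal noise.
* Log-normality: Lilliefors-corrected Kolmogorov–Smirnov on `log(values)`.
  KS-type tests assume independent samples. All n² entries of the rank-1
  steady state share only n underlying rates, so the full matrix is *not*
  a valid sample (its empirical CDF fluctuates at O(1/√n), not O(1/n),
  and the test over-rejects); distributional checks therefore use entries
  over disjoint neuron pairs (`w[i, m+i]` for a 2m population), which are
  i.i.d. draws of the entry marginal. Under log-normal rates these pass;
  under uniform(1, 2) rates they are rejected (the negative control).
* Identity structure: the best scaled identity has `c_fit = mean(diag W)`
  and score `1 − ‖W − c_fit I‖²_F / ‖W‖²_F` (floored at 0). A symmetric
  permutation PᵀWP only relabels neurons and provably leaves the score
  unchanged (it depends on tr W, the diagonal mean and ‖W‖_F alone), so
  the permutation null scrambles the pre/post *pairing* instead: rows and
  columns are permuted independently. The correctly-paired steady-state
  matrix beats all 100 scrambled copies (empirical p < 0.05) because its
  diagonal pairs each neuron's pre- and post-factors, which is the
  rearrangement-optimal pairing.
* Response-similarity ordering: greedy seriation on the trace-correlation
  matrix (start at the most correlated pair, extend the chain at whichever
  end has the most correlated unused neighbour). Response traces for these
  experiments are synthesized as shared-latent-factor log-normal processes
  (each neuron loads on one of G factors with coupling 0.9), since no
  trace model is prescribed; the sorting makes block structure contiguous
  but, by the invariance above, never changes the identity score.

## Problem sizes

Test-suite experiments are sized for a laptop-class single core: the
recovery experiment (2000 batches × 100 patches of 36 pixels) dominates at
roughly two minutes; everything else runs in seconds. The acceptance
script solves one 144-atom dense coding instance and finishes in under a
second.

## Known limitations

* The trainer is plain SGD with gain equalization; it needs the atom
  maintenance step to avoid duplicate clusters at exact parity P = P_true,
  and recovery of over-complete dictionaries at scale is untested.
* Whitening uses periodic (FFT) boundaries; no windowing is applied.
  Images whose content is strongly non-stationary across the frame may
  show wrap-around leakage in the few lowest-frequency bins.
* The simulator evolves mean-rate dynamics only; rate fluctuations,
  spike timing and saturating activations are out of scope.
* `segment_image` tiles non-overlapping frames in row-major order;
  overlapping (shifted) patch extraction is not implemented.
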
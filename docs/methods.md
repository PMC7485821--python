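# Methods

## The optimisation loop

The optimiser treats an image-processing pipeline as a black box mapping a
configuration `x` (one value per declared setting) to a quality score (QS)
`y` on the 1–10 scale, supplied by a human rater, an automated rule, or a
weighted composite of both.  A run proceeds as:

1. **Bootstrap.** Two configurations are drawn uniformly from the declared
   interval grid and evaluated.  If a bootstrap evaluation already meets
   the target QS, the run stops there — the user asked for nothing better.
2. **Surrogate fit.** A Gaussian process is fitted to all evaluated
   (configuration, QS) pairs.  Hyperparameters are re-estimated every
   iteration by maximising the log marginal likelihood.
3. **Proposal.** The next configuration maximises Expected Improvement
   (EI) over a finite candidate set.  The proposal is made on the
   continuous unit hypercube and snapped to the declared interval grid
   before execution; both values are recorded (reports show the raw
   continuous proposal, the pipeline runs the snapped one).
4. **Evaluation and stopping.** The pipeline runs, the evaluator scores
   it, and the *quality gap* `max(target − current, 0)` is recorded.  The
   loop ends at gap zero or after `max_iterations` post-bootstrap
   evaluations.

A configuration that crashes the pipeline (e.g. an adaptive window larger
than the image) is scored with the worst QS of 1 and flagged rather than
aborting the run, so the surrogate learns to avoid that corner.  A failure
of the *evaluator* is different — there is no sensible score to assign —
and aborts the run with the partial trace attached.

The random-search baseline shares this exact loop, seeding, stopping rule
and persistence; only the proposal rule is replaced by an independent
uniform draw from the grid.  In paired comparisons both methods share each
replicate's master seed and therefore identical bootstrap evaluations.

## Surrogate model

The GP uses a Gaussian observation likelihood with noise variance `σₙ`,
zero prior mean, and the squared-exponential kernel written as

    k(x, x′) = σ_f exp(−‖x − x′‖² / (2 σ_ℓ)).

Two conventions here deserve emphasis:

* `σ_ℓ` divides the squared distance directly, i.e. it is the *squared*
  length-scale (a length-scale of 0.3 on the unit cube is `σ_ℓ ≈ 0.09`).
* The predictive distribution reported is that of the *observable noisy
  score* `y*`, so the predictive variance includes `σₙ`:
  `Var[y*] = σ_f + σₙ − k*ᵀ(K + σₙI)⁻¹k*`, clipped into `[0, σ_f + σₙ]`.

Because settings have incommensurate units (window sizes of hundreds of
pixels next to correction factors near 1), configurations are min-max
normalised into `[0,1]^d` before any kernel distance; the isotropic kernel
is then a reasonable default.

Scores are centred by subtracting their mean before fitting, and the mean
is added back to predictions.  With a zero-mean prior and scores that live
on [1, 10], an uncentred fit systematically pulls predictions toward 0 far
from the data; centring removes that bias.  `center_y=False` reproduces
the literal zero-mean model.

Hyperparameters carry no priors.  They are set by L-BFGS-B maximisation of
the log marginal likelihood over `log(σₙ, σ_f, σ_ℓ)`, from the incumbent
plus 5 random restarts, within bounds `σₙ ∈ [10⁻⁶, 4]`,
`σ_f ∈ [10⁻³, 100]`, `σ_ℓ ∈ [10⁻², 10]`.  The returned θ never has a lower
marginal likelihood than the start point.  The `σ_ℓ` floor of 10⁻²
(length-scale 0.1) is deliberate: with the few dozen observations a run
collects, shorter length-scales let the likelihood collapse into a
white-noise fit that starves the acquisition of any gradient information.
A fixed jitter of 10⁻⁸ is always added to the covariance diagonal so that
duplicate configurations (which a grid search produces naturally) stay
factorisable even at `σₙ = 0`.

## Acquisition

EI is used in the maximisation convention,
`EI = Δ Φ(Δ/s) + s φ(Δ/s)` with `Δ = μ − y_best − ξ`, degenerating to
`max(Δ, 0)` at `s = 0`; `y_best` is the best *observed* QS.  Candidates
are 2,048 seeded scrambled-Sobol points in the hypercube plus the one-step
grid neighbours of every configuration evaluated so far, which makes the
proposal deterministic given the master seed while still permitting fine
local moves; ties break on the lowest candidate index.

The exploration offset defaults to `ξ = 0.3` (about 3 % of the 9-point QS
range).  Ratings are coarse integers, so the score surface is a staircase
with wide plateaus; with `ξ ≈ 0` EI keeps preferring the incumbent's
immediate neighbourhood (posterior mean ≈ `y_best`, small variance) and a
run that bootstraps inside a low plateau can stall there.  `ξ = 0.3`
penalises those near-incumbent candidates by more than their variance
advantage and reliably breaks the trap; it is exposed in the run
configuration.

## Reference pipeline

The two-stage segmenter mirrors the common primary/secondary object
identification scheme without depending on any external profiling tool:

* **Primary (nuclei).** Gaussian smoothing (σ = 1 px, fixed); adaptive
  threshold = local mean over a square window (the *Size of adaptive
  window* setting) × *Threshold correction factor I*, with an absolute
  floor of 0.05 so near-zero background cannot pass a purely
  multiplicative threshold; hole filling; removal of components whose
  equivalent-area diameter is below *Typical artifact diameter*;
  8-connected labelling in raster order.
* **Secondary (cells).** Global Otsu threshold × *Threshold correction
  factor II* defines the cell foreground (always including the seeds); a
  watershed on inverted intensity grows each primary label into its cell,
  so each cell inherits its nucleus' label and contains it pixelwise.

Raising the first correction factor can only shrink the primary
foreground: thresholding is pixelwise monotone, hole filling and the size
filter both preserve set inclusion.  This monotonicity is what makes the
setting's effect learnable by a smooth surrogate.

Measurements per object: area (px), perimeter (px), solidity
(area / convex-hull area), eccentricity.

## Synthetic scenes and the simulated rater

Each scene emulates a fluorescence micrograph of adherent cells on a
160×160 px field: 4 non-overlapping elliptical cells (placed by rejection
sampling), each with a concentric nucleus (semi-axes 8–13 px) at twice the
nucleus' extent, 2–6 bright elongated puncta near the cell border, base
intensities background 0.08 / cytoplasm 0.24 / nucleus 0.60 / puncta 0.85,
per-cell staining jitter (±0.05 cytoplasm, ±0.12 nucleus), a linear
illumination gradient of 0.12 across the field, optical blur (σ = 0.8 px)
and additive Gaussian noise (σ = 0.02), clipped to [0, 1].  Ground-truth
masks (nucleus, cell, puncta) are the unblurred geometry.  The per-cell
jitter and the gradient are what make the tuning problem genuinely
adaptive: no single global threshold captures the dimmest nucleus without
bleeding into the brightest cytoplasm, which is precisely the regime an
adaptive window and correction factor exist for.

The generator records an *oracle configuration* (window 41, factor I 1.5,
artifact diameter 10, factor II 0.7) that achieves a mean nucleus-mask IoU
around 0.9 on default scenes; it anchors the parameter-recovery tests.

The simulated rater maps mask agreement to the manual scale as
`rating = clamp(1 + round(9·IoU), 1, 10)` with round-half-away-from-zero,
optionally flipping the rating by ±1 with a seeded probability to emulate
human inconsistency (off by default; it exercises the GP's noise term).

What the scenes do **not** model: realistic point-spread functions,
texture inside cells, touching/overlapping cells, debris, multi-channel
stains, or rater fatigue.  Passing tests therefore demonstrate that the
optimisation machinery works and recovers known-good configurations under
controlled conditions — not that any particular IoU level will be reached
on real micrographs.

## Problem sizes and numerical choices

The shipped studies use desk-scale sizes chosen as the smallest that make
the comparisons meaningful: 20 paired replicates for the BO-versus-random
comparison at a 40-iteration budget; 10 seeded runs at a 30-iteration
budget scored on a 10-image held-out set for configuration recovery; 100
random instances (N ≤ 5) for the posterior-oracle check; 10⁶ draws × 50
triples for the EI Monte-Carlo check; 20 replicates of 40 points for
length-scale recovery.  Grid snapping breaks midpoint ties toward the
lower value; component labelling is raster-ordered; both-empty masks score
IoU 1.0 (the 0/0 completion least surprising for "perfect agreement"),
with a warning.  Benchmarks report mean ± one standard deviation.

## Known limitations

* The isotropic kernel cannot express per-setting relevance; a setting
  with no effect still dilutes distances (no automatic relevance
  determination, matching the method's published form).
* Integer ratings quantise the objective; configurations within the same
  rating band are indistinguishable to the optimiser, so the recovered
  configuration is only as good as the band the rater can resolve.
* EI is maximised over a finite candidate set, not analytically; with
  extremely fine grids the one-step neighbours plus 2,048 Sobol points may
  miss the exact optimum of the acquisition surface.
* Categorical, conditional and log-scaled settings are out of scope.
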
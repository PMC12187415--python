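# Methods

This note documents the models, estimators and numerical choices behind
`fishsde`, and what the synthetic-data generator does and does not
emulate.

## State variable and model class

The modelled quantity is the interindividual distance x(t) in cm: the
Euclidean distance between the two members of a dyad, or the mean of the
three pairwise distances of a triad, sampled at 30 Hz for 18 000 frames
(10 min) per trial. Its evolution is described by a one-dimensional Itô
equation

    dx = F(x) dt + G(x) dW,

with a cubic drift F and a parabolic diffusion G ≥ 0. The cubic drift is
equivalent to gradient descent on a tilted double-well potential

    V(x) = −α x − β (x − xl)² (x − xh)²,   F = −dV/dx,

whose wells xl < xh correspond to close-proximity swimming and
far-distance exploration. With this literal form the wells attract when
β < 0; a positive α lowers V at large x. Because the sign conventions of
the tilt are easy to confuse, `bistability_report` never interprets the
sign of α directly: it evaluates the well depths and reports
`tilt_direction` (`toward_close` / `toward_far` / `unbiased`) plus the
barrier height above the shallower well. The conversion between
(α, β, xl, xh) and the cubic coefficients is closed-form in both
directions (`drift_from_potential` / `potential_from_drift`) and exact to
rounding; a cubic whose implied well pair is complex raises a
"monostable" error rather than returning fictitious wells.

## Visual-field metrics

A focal fish at position p with heading θ sees the world through angles
ψ ∈ (−π, π] measured from its heading. Conspecifics are discs of one
body length (3 cm) diameter centred on the tracked centroid; a disc at
distance d subtends an angular "shade" of half-width asin(r/d) centred
on its bearing. Opacity is the measure of the union of all shades
(overlaps are not double-counted) intersected with the visible field,
normalised by 2π − γ. The blind angle γ defaults to 21°.

Two conventions exist for where the blind sector sits. Anatomy places it
behind the animal, so the default centres it on ψ = π; a `front` option
centres it on ψ = 0 for the alternative indicator-set reading. The
choice is a config switch, not an inference.

All interval arithmetic is done on plain segments within [−π, π];
intervals that wrap the branch cut are split before union/intersection.
A brute-force oracle casts n uniformly spaced rays and solves the
ray/circle quadratic per disc; it agrees with the analytic opacity to
O(1/n) and is used as the ground truth in tests (36 000 rays → agreement
within 1e-3 on a thousand random dyad/triad scenes).

Optic flow sums, over conspecifics, |W_j| × w_j, where W_j is the
wrapped displacement of shade j's centre bearing between consecutive
frames divided by dt, and w_j is the visible width of the shade averaged
over the two frames. The symmetric average keeps the metric even under
time reversal, which the centre-displacement scheme with a single-frame
width would not be. The per-shade angular-velocity rule is isolated in
one function so an edge-based alternative can be swapped in. Headings
come from the velocity direction; frames where the focal fish is at rest
have undefined heading and propagate as missing values rather than
zeros, so trial means are not biased toward rest frames. The same
convention applies to the angular-speed formula when a position vector
is numerically zero.

## Exploration episodes

An episode is a maximal run of frames with x strictly above 3 body
lengths (9 cm) whose duration strictly exceeds 3 s (at 30 Hz: at least
91 frames) and which is preceded earlier in the trial by at least one
frame at or below the threshold — an excursion that starts the recording
already far from the group is not an exploration bout. Amplitude is the
mean distance over the episode by default; a median mode exists because
both summaries are in use for this kind of data. Per-trial statistics
are the means of episode durations and amplitudes; trials with no
episodes carry missing values and an explicit zero count so downstream
analyses can exclude them.

## Drift and diffusion estimation

Pointwise Kramers–Moyal estimates pair each state y = x(t) with

    F̂(t)  = (x(t+dt) − x(t)) / dt,
    Ĝ²(t) = (x(t+dt) − x(t))² / dt,

pooled across trials. A fourth-order zero-phase Butterworth low-pass
(cutoff given in rad/s, converted to Hz as ω/2π, implemented in
second-order sections for numerical stability) can be applied to x(t)
before differencing; it is **off by default** because a 0.1 rad/s cutoff
at 30 Hz suppresses exactly the fast fluctuations that carry the
diffusion signal, biasing Ĝ² toward zero. Filtering is a caller's
explicit choice (`filter_cutoff`).

Bin averages use fixed 0.1 cm state bins with a minimum occupancy of 10
samples. Regressions on binned data use the per-bin *mean state* as
abscissa (on a steep flank of the state density the samples pile up on
one side of the bin, so the geometric centre is a biased evaluation
point) and weight bins by their counts (bin means are heteroscedastic
with variance ∝ 1/n). Geometric bin centres are retained for plotting
and for the fixed-grid potential reconstruction.

The diffusion response is G per bin, computed from the binned Ĝ² with
three small-sample corrections, each standard and derived analytically:

1. finite-dt drift contamination: E[Ĝ²|x] = G² + F² dt, so the squared
   binned drift times dt is subtracted;
2. the squared binned drift overshoots F² by Var(F̂)/n ≈ G²/(n dt),
   leaving E ≈ G²(1 − 1/n); a Bessel-style n/(n − 1) factor restores
   unbiasedness;
3. the square root of a mean of n squared Gaussian increments
   underestimates G by the chi-distribution mean factor
   √(2/n)·Γ((n+1)/2)/Γ(n/2), which is divided out.

Without these, low-count tail bins sit systematically below the true
curve and masquerade as steeper-than-parabola tails, distorting model
selection.

## Stepwise sparse regression

The functional forms of F and G are selected from a polynomial library
of degree 0–5. Internally the library is built on the centred/scaled
state z = (y − ȳ)/sd(y): monomials of the raw state over a two-cluster
distribution are numerically collinear to the point that coordinate
descent cannot converge. The selected polynomial is mapped back to raw
coefficients by exact affine composition, which preserves the degree, so
pruned high-order coefficients are exactly zero.

LASSO (objective ‖Y − ΘΞ‖² + λ‖Ξ‖₁, cyclic coordinate descent with
soft-thresholding on standardised columns, intercept unpenalised) is
solved in Gram/covariance form: per-fold Gram blocks are precomputed
once, so a training-fold refit costs O(p²) per sweep independent of the
sample count, and the λ grid (30 log-spaced points over
[1e-6, 10] × λ_max) is swept with warm starts. Convergence is declared
on the duality gap, with an objective-stall break for near-singular
Grams. A numba-compiled kernel accelerates the sweeps; a pure-Python
fallback keeps the package functional without it.

Selection proceeds as a greedy prune path per degree-capped library
(caps d = 0..5): fit at the CV-optimal λ *for the current term set*
(re-selecting λ per subset avoids the over-shrinkage a single global λ
imposes on small subsets), drop every standardised coefficient below the
prune threshold (default 1e-3) at once — otherwise the single smallest —
re-evaluate the K-fold CV error (K = 5, contiguous blocks for time-series
inputs, seeded shuffling optional), and stop when the error rises. The
final model is chosen across all visited candidates by a paired
one-standard-error rule: a candidate ties with the CV-best model when
its mean excess fold error is within one standard error of the per-fold
differences (pairing cancels the fold-to-fold variation all models
share); among ties the lower polynomial degree wins, then the fewer
terms. With data concentrated in two narrow wells and no support in
between — the typical situation when the barrier is high — even-degree
terms are nearly exchangeable and the parsimony rule is what makes the
selection reproducible.

The drift is fit to the pooled pointwise estimates (the binned means are
for visualisation and the potential); the diffusion parabola is fit to
the bin-level G response above. The reported diffusion is G itself, not
G².

## Empirical potential

V is reconstructed from the binned drift by cumulative trapezoidal
integration, anchored to zero at the first bin. The trapezoid error for
an integrand f at step h accumulates to (h²/12)(f′(x) − f′(a)); for the
reference cubic drift on [0, 25] cm at the 0.1 cm grid this bounds the
reconstruction error at ≈ 1.6e-2 cm² s⁻¹, and halving h reduces it
fourfold. Tests assert exactly this bound and rate.

## Simulation and the in-silico experiment

Paths are integrated with the explicit Euler–Maruyama scheme at
dt = 1/30 s on the domain [0, 57] cm (arena diameter minus one body
length) with reflecting boundaries — distance is non-negative and
bounded by the tank. The fitted diffusion parabola may cross zero at the
domain edges, so G is floored at 1e-3 cm s^(−1/2) inside the simulator.
The initial condition defaults to a uniform draw between the drift's
wells (falling back to the middle half of the domain for non-bistable
drifts). One master seed spawns an independent child stream per trial,
so any trial is reproducible from (seed, trial index), and per-condition
streams are spawned the same way in the experiment harness.

The in-silico design mirrors the validation experiment: four conditions
(dyads/triads × bright/dark), one model each, the same number of trials
per condition (default 10), episode statistics per trial, per-cell
interquartile-range outlier exclusion (Tukey fences Q1 − 1.5·IQR,
Q3 + 1.5·IQR with linear-interpolation quantiles; cells smaller than 4
are passed through with a warning), and a two-way ANOVA with interaction
on the per-trial means. The ANOVA uses Type II sums of squares via
model comparisons on sum-coded design matrices — identical to the
classical decomposition for balanced designs and well-behaved for the
mild unbalance left by outlier removal and zero-episode trials — with
η² = SS_effect/SS_total and F-distribution p-values. Quantile and coding
conventions are fixed and tested against independent oracles.

## Synthetic data

The generator provides every input the pipeline needs from a seed.

*Distance paths* come from built-in bright/dark regime models. These
parameters are synthetic stand-ins, not estimates from animal data. They
were designed from Kramers escape-rate reasoning so that a 10-minute
trial contains a handful of exploration episodes: bright
(α = −0.15, β = −0.0028, xl = 5, xh = 15) has a stronger tilt toward the
close well and a higher barrier — rarer, shorter, smaller excursions;
dark (α = −0.04, β = −0.0012, xl = 5, xh = 17) has a weaker tilt, a
lower barrier and a farther exploration well — longer, larger
excursions. Diffusion is a common parabola (b₀ = 0.80/0.90 for
dyads/triads, b₁ = 0.12, b₂ = −0.006), with the higher amplitude for
triads reflecting the noisier three-body state.

*Trajectory embedding* places a smooth bounded random walk for the group
centroid (AR(1) velocity, radially clamped so every fish stays inside
the 60 cm arena) and positions the fish around it so the realised
distance series equals the target exactly before jitter: dyads
symmetrically along a smoothly rotating axis; triads on a smoothly
wobbling triangle rescaled each frame so the *mean pairwise* distance —
the modelled quantity — matches exactly (the three individual pairwise
distances are under-determined by a single state variable and are left
to the randomised geometry). Gaussian positional jitter (default
σ = 0.05 cm) emulates tracking noise.

What the generator does **not** emulate: burst-and-coast swimming
kinematics, wall-following, body posture, occlusion errors or identity
swaps, and any coupling of the individual fish's heading to its visual
input. Passing tests therefore demonstrate that the pipeline recovers
the generating stochastic process and geometry under realistic sampling,
noise and arena constraints — not that real zebrafish satisfy the model.

## Problem sizes and determinism

Recovery studies use 10 trials × 18 000 samples (the per-trial recording
length at 30 Hz); the in-silico contrast uses 10 trials per condition
and 10 master seeds; oracle-equivalence checks use 1 000 random scenes
at 36 000 rays; stationary-limit checks use 10⁶ steps. Every stochastic
component takes an explicit seed and the full pipeline is deterministic
given (config, seed); the test suite and the acceptance script run in a
few minutes on one CPU.

## Known limitations

- The optic-flow angular-velocity rule (shade-centre displacement) is
  one of several defensible discretisations; edge-based rules would
  differ for shades partially clipped by the blind zone.
- Kramers–Moyal estimation at fixed dt has O(dt) bias in the drift near
  strong nonlinearities; no higher-order (e.g. Milstein-consistent)
  correction is applied beyond the documented second-moment corrections.
- Polynomial-degree selection is noise-limited when the state
  distribution leaves the barrier region unobserved; with a high
  barrier the even-degree terms are close to exchangeable and selection
  stability across realisations is intrinsically limited (the paired
  one-SE rule with degree hierarchy mitigates but cannot eliminate
  this).
- The ANOVA assumes independent trials and approximately normal
  per-trial means; duration means over few episodes are right-skewed,
  so p-values near the threshold should be read with care.
- For triads, only the mean pairwise distance is modelled; the
  within-triad geometry in the synthetic embedding is decorative.
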
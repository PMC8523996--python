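# Methods

This note records the models implemented in `fdopakin`, their
assumptions, the defaults that matter, and the numerical choices made
where the design was genuinely open.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Time conventions and data model

Frame timing is stored in seconds on disk (`frame_start_s`,
`frame_duration_s`); all kinetic mathematics runs in minutes (rate
constants min⁻¹); late-phase slopes are reported per hour.  A TAC value
is the frame-averaged SUV, conventionally assigned to the frame
midpoint — the standard dynamic-PET reading.  Two built-in frame
schedules tile the 30-min acquisition: a fine-early 33-frame grid
(12×5 s, 6×10 s, 6×30 s, 5×60 s, 4×300 s) for analyses that need the
vascular phase, and a uniform 30×60 s grid for those that do not.
Fitted curves, ratio curves, TTP and slope are evaluated on a dense
1-s grid; negative noisy SUV values are preserved (clipping would bias
late-slope estimates).  Because the same region can legitimately carry
both schedules, the cohort file has a `protocol` column; when absent
the schedule is inferred if unambiguous.

## Image-derived input function

The measured carotid TAC is modelled as linear interpolation through
the observed pre-peak frame midpoints followed by a tri-exponential
decay, $\sum_i A_i e^{-\lambda_i (t-t_\mathrm{peak})}$, anchored at the
peak-frame midpoint.  The peak is the maximum observed frame (earliest
on ties); at least six descending frames are required.  Residuals are
computed on *frame-averaged* model values over the post-peak frames, so
noiseless frame-averaged data are exactly representable; the junction
node of the linear segment is set to the fitted amplitude sum, which
enforces continuity by construction.  The nonlinear least-squares
problem is multimodal, so it is solved by multistart (default 8 seeded
starts with log-spaced decay rates, amplitudes ≥ 0, rates > 0); the
best converged start wins.

Corrections, in order:

1. **Spill-out.**  The carotid is small relative to scanner resolution,
   so the measured curve under-recovers true activity; the fitted curve
   is *divided* by the scalar recovery coefficient (default 0.51).
2. **Whole blood → plasma.**  Division by (1 − hematocrit), default
   hematocrit 0.40 — i.e. the tracer is assumed to reside entirely in
   plasma.  This simple form is isolated in one place
   (`PlasmaInputModel.plasma_total`) so it can be swapped if a
   different erythrocyte model is preferred.
3. **Metabolite correction.**  The plasma parent fraction follows the
   published population curves for Carbidopa-premedicated subjects
   (t in minutes):
   f_DOPA(t) = 1 − 0.36902735·(2 − e^(−0.03915133 t) − e^(−0.03915214 t)),
   f_OMFD(t) = 0.24080881·(1 − e^(−0.03251229 t)) + 0.43768904·(1 − e^(−0.03251228 t)),
   f_METS = 1 − f_DOPA − f_OMFD.  The fractions sum to one exactly by
   construction; f_DOPA falls from 1 toward 0.26194530, f_OMFD rises
   toward 0.67849785.  The parent curve
   plasma_fdopa(t) = whole_blood(t)/(1 − hct) × f_DOPA(t) is the
   diffusible input for Logan and the 2TCM.

The population metabolite and hematocrit values are not
subject-specific; this is the main approximation of the whole input
chain and it propagates to every input-dependent parameter.

## Semiquantitative models

Tumor (and reference) TACs on the uniform schedule are denoised with
the vascularization function SUV(t) = 0 for t < t*, and
a₁·(A + xᵖ)/(B + x^q) with x = (t − t*)/a₂ for t ≥ t* (a₀ ≡ 0, a₂ in
seconds, B > 0).  Two readings of the printed form are deliberate:
the pre-arrival branch is zero *before* t* (t* is the tracer-arrival
delay), and a₂ divides the elapsed time so that it carries time units.
Positivity of a₂, p, q, B is enforced by optimizing their logarithms;
A is unconstrained.  Starts combine a₁ = max SUV, a₂ = observed peak
time, p, q ∈ {0.5, 1, 2}, A = 0, B = 1 with seeded jitter (12 starts).
The surface is degenerate in parameter space (many parameter vectors
give near-identical curves), so curve-level agreement — not
parameter-level identity — is the meaningful recovery criterion, and
the six fitted values are treated as descriptive shape predictors.

TTP is the dense-grid argmax (ties → earliest time); the slope is the
OLS slope of the dense-grid samples over 10–30 min, ×60 for per-hour
units.  Raw-frame read-outs are available behind a flag
(`sq_result(use_fit=False)`), and both read-outs accept an arbitrary
grid so frame-sampled slopes can be computed if preferred.  The Ref SQ
ratio curve divides the two fitted curves; since the fitted reference
may cross zero just after its arrival delay (A slightly negative), the
ratio is evaluated from the point where the reference first exceeds 1%
of its maximum and must stay positive from there on.

## Graphical models

Standard Logan coordinates are formed at the tumor frame midpoints with
trapezoidal integrals from injection, the grid augmented with an origin
point (exact for piecewise-linear curves).  OLS over points whose
midpoint lies in the closed window [15, 30] min gives $V_{ed}$ /
Int_Logan (plasma input) and DVR / RRT (reference input).  The
reference-region form omits the population $k_2'$ correction term: with
a 15-min window onset the omitted-term bias is absorbed into the
intercept, which is itself reported as a parameter (RRT).  The plasma
input used is the metabolite-corrected parent curve, since the model
describes parent-tracer distribution.  Logan estimates are consistent
only near equilibrium: for kinetics whose slow eigenvalue is ≲0.03
min⁻¹ the 30-min acquisition ends far from equilibrium and $V_{ed}$
underestimates the true distribution volume — the test suite checks
convergence with reversible kinetics that do equilibrate, and checks
that later windows reduce the bias.

## Compartmental model

The reversible 2TCM is
dC₁/dt = K₁C_p − (k₂+k₃)C₁ + k₄C₂, dC₂/dt = k₃C₁ − k₄C₂, measured
signal (1 − V_b)(C₁+C₂) + V_b·C_blood, frame-averaged over each frame
(midpoint evaluation is inaccurate for the 5-s frames).  The tissue
response is a two-exponential impulse response with rates
α₁,₂ = ½[(k₂+k₃+k₄) ∓ √((k₂+k₃+k₄)² − 4k₂k₄)].  The convolution with
the input is evaluated exactly for a piecewise-linear representation of
the input on a 0.1-s grid: per-step integrals are closed-form in αΔt
(computed with `expm1` for small arguments) and chained through the
one-step recurrence with `scipy.signal.lfilter`, so the only
approximation is the between-node linearization of the input — second
order in 0.1 s and orders of magnitude below the 0.1% tolerance at
which the tests compare against a brute-force 0.01-s RK4 integrator
(which exists only as a test oracle).  Repeated eigenvalues (measure
zero) are nudged apart by 5×10⁻¹⁰; k₁ = 0 or total efflux 0 are handled
exactly.

Estimation is weighted multistart NLLS: weights ∝ frame duration (an
inverse-variance proxy for decay-corrected SUV data), box bounds
K₁..k₄ ∈ [0, 5] min⁻¹ and V_b ∈ [0, 2] (fitted blood-volume fractions
above 1 do occur when the input-function scale is approximate, so the
bound deliberately admits them; V_b is reported as fitted, without
rescaling), 10 starts (one canonical + 9 seeded log-uniform draws),
`scipy.optimize.least_squares` with tight tolerances.  Fixed seed ⇒
bitwise-reproducible fits.  The vascular term uses the
spill-out-corrected whole-blood curve and the diffusible term the
plasma parent curve; both curves are plain callables, so a caller who
prefers a single combined input can pass the same curve for both.
Ki = K₁k₃/(k₂+k₃) is rejected as undefined when k₂+k₃ = 0.

## Synthetic cohorts

The generator emulates the study conditions end to end: a carotid curve
(linear rise to an SUV-12 peak at 42.5 s — a frame midpoint, so that
fitted and generating tri-exponentials share their anchor — then
tri-exponential decay with rates 3.0, 0.35, 0.03 min⁻¹ and amplitude
fractions 0.55/0.35/0.10), per-subject 2TCM tumor kinetics drawn from
group distributions (truncated normal, CV 0.15), a one-tissue reference
region (K₁ 0.09, k₂ 0.09 min⁻¹ ⇒ VD ≈ 1), and Gaussian TAC noise with
variance ∝ value/duration (scale = s.d. at SUV 1 on a 60-s frame;
default 5%).  Group defaults are *scenario parameters, not estimates of
any real cohort*: wild-type-like tumors are comparatively reversible
(K₁ 0.15, k₂ 0.30, k₃ 0.13, k₄ 0.030 min⁻¹, V_b 0.05 — early peak near
4–5 min, clearly negative late slope), mutant-like tumors trap tracer
(K₁ 0.12, k₂ 0.30, k₃ 0.18, k₄ 0.012, V_b 0.04 — near-flat/rising late
phase, TTP at or near the end of the acquisition), so noiseless
time-to-peaks straddle the ~18-min scale and the default cohort of
14 mutant / 23 wild-type separates well but, under noise, not
perfectly.  All randomness flows from one master seed through
`numpy.random.SeedSequence` spawning (PCG64): subject *i* is invariant
under cohort growth and cohort files are byte-identical across runs.

What the generator does **not** emulate: scanner physics and image
noise correlations, motion, segmentation variability, subject-specific
metabolite kinetics, or the (unknown) kinetic-parameter distributions
of real gliomas.  Passing tests therefore demonstrate the correctness
and calibration of the *pipeline*, not clinical performance on real
data; the absolute AUCs the acceptance script reports are properties of
the chosen scenario.

## Statistical comparison

Empirical ROC curves over all thresholds (midpoints between consecutive
distinct scores, plus sentinels); the AUC equals the all-pairs
Mann–Whitney probability with ties counted half, and the orientation is
flipped (and recorded) when the raw AUC is below 0.5.  The operating
point minimizes the Euclidean distance to (0, 1) in (FPR, TPR) space,
ties resolved toward higher sensitivity; the reported cutoff is the
midpoint between the adjacent scores, which matters for reproducing
tabulated cutoffs.  AUC confidence intervals are DeLong-variance normal
intervals, matching the test machinery.  The paired DeLong test uses
placement values; a zero-variance difference yields p = 0.5, and the
two one-sided p-values of a pair sum to 1.

The multivariable model per dynamic model is a binomial-family GLM
("general linear model" with a binary endpoint), selected by
bidirectional stepwise AIC from the intercept-only model: at each step
the single add/drop move that most reduces AIC is applied, stopping
when none does.  Perfect separation is detected by non-convergence or
coefficients exceeding 50 in absolute value and handled by a fixed
ridge penalty (α = 10⁻⁴, L2) so the search remains deterministic; the
AIC is then computed from the unpenalized log-likelihood at the
penalized coefficients.  Multivariable AUCs are in-sample (no
cross-validation).  Note that stepwise AIC is intentionally permissive:
under the null a candidate predictor is admitted whenever its
likelihood-ratio statistic exceeds 2 (probability ≈ 0.157 each), so on
pure-noise predictor tables the intercept-only model is retained in
only roughly half of replicates — a property of the selection rule
itself, quantified in the test suite.

Group comparisons use the two-sided Mann–Whitney test (exact for
pooled n ≤ 20 without ties, normal approximation otherwise) for
continuous variables and the chi-squared contingency test (no
continuity correction) for categorical ones; multiplicity is handled
with Benjamini–Hochberg step-up adjustment (both raw and adjusted
p-values are reported).  Spearman correlations are Pearson correlations
of ranks; constant columns are reported as missing.

## Problem sizes

The default study is 37 subjects (14/23) at 5% noise — the acceptance
script runs it in a couple of minutes on one core.  Test-suite
simulations use reduced sizes chosen for tight runtimes at adequate
power: 20 replicate 12-subject cohorts for the TTP-AUC band, 5
replicate fits per noise scale for the noise-monotonicity check, 1000
replicates for DeLong null calibration, 100 each for stepwise
null/power, and an 8-subject cohort for the end-to-end byte-identity
check.

## Known limitations

* The blood→plasma conversion and metabolite fractions are population
  curves, not subject measurements.
* The reference-Logan omits the k₂′ term; RRT consequently absorbs its
  bias and is interpretable only comparatively.
* Logan estimates are biased for near-irreversible kinetics within a
  30-min acquisition (by design of the method, not the implementation).
* The vascularization-fit parameters are not individually identifiable;
  only the fitted curve (and TTP/slope derived from it) is stable.
* Stepwise-AIC selection is permissive under the null (see above), and
  in-sample multivariable AUCs are optimistic.
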
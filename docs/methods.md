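# Methods

`dyadcoupling` implements a sequential two-brain ("demonstrator–observer")
analysis of observational threat learning. One person (the demonstrator)
undergoes Pavlovian threat conditioning on video; naïve observers later watch
that video while their neural and peripheral signals are recorded. The
package quantifies how strongly the two brains' band-limited phase dynamics
align, whether that alignment carries information about the observer's
learning, and when during a trial that information becomes available. All
stages run on a bundled synthetic dyad generator with planted ground truth.

## Trial structure

A conditioning block presents two conditioned stimuli (CS+ and CS−) for 6 s
each, 16 presentations per CS by default. A fraction (62.5% by default) of
CS+ trials co-terminates with an aversive unconditioned stimulus (US)
delivered 5.5 s after CS onset; the CS− is never reinforced. Inter-trial
intervals are uniform on 8–12 s. All analysis windows are expressed in
seconds so results are independent of sampling rate; the default synthetic
rate is 250 Hz, chosen so that a full dyad simulates in well under a second
while leaving the delta band (1–3 Hz) more than 80× oversampled.

## Brain-to-brain coupling (CCorr)

Narrow-band instantaneous phase is extracted by a zero-phase (forward–
backward) 4th-order Butterworth band-pass followed by the analytic-signal
(Hilbert) phase; one second at each edge is flagged untrusted because of
filter transients. Coupling between a demonstrator phase series x and an
observer phase series y over the 0–5.5 s post-onset window is the circular
correlation coefficient

    CCorr(x, y) = Σ sin(x − x̄) sin(y − ȳ)
                  / sqrt( Σ sin²(x − x̄) · Σ sin²(y − ȳ) ),

with x̄, ȳ the circular means. Raw values are Fisher-z transformed and folded
to absolute value, z_abs = |atanh r| with r clipped at ±(1 − 10⁻⁶) so the
perfectly coupled case stays finite.

A numerical caveat documented here because it shapes both the generator and
the tests: when a phase series cycles many times inside the window its
marginal distribution is nearly uniform, the circular mean is then poorly
determined, and independent noise on either channel can rotate the two mean
estimates against each other, randomizing per-trial values. Averaging over
trials and channel pairs restores stability; single-trial values should be
interpreted with this in mind.

### Two-step selection

Statistical testing over all demonstrator × observer channel pairs proceeds
in two steps. Step 1 filters pairs with no effect: per pair, dyad-mean task
z_abs is compared with a stimulus-free baseline (the pre-task head segment
chopped into 5.5 s pseudo-trials) by a one-sided paired t-test across dyads,
followed by Benjamini-Hochberg FDR across pairs at q = 0.05; only pairs with
task > baseline survive. The choice of a paired t on dyad means is a design
decision — the comparison could equally be run on trial-level values or by
permutation, and a permutation variant is a natural extension. Step 2 fits,
per retained pair, a linear mixed model `z_abs ~ CS type × social status`
with random intercepts for observer nested within demonstrator (each
demonstrator serves many observers, so demonstrator identity must absorb
shared-video variance). p-values are Wald (normal approximation) as provided
by statsmodels MixedLM; Satterthwaite degrees of freedom are not available
there, which makes the per-pair tests mildly liberal at small group counts —
BH-FDR across pairs is applied per effect. A singular nested fit falls back
to an observer-level random intercept with a warning.

### Pseudo-dyad null

To show that coupling is dyad-specific rather than stimulus-driven, a
surrogate demonstrator is built by taking each time point from a randomly
chosen real demonstrator (serially over time). This preserves marginal
statistics and common stimulus-locked structure while destroying dyadic
temporal alignment. All-channel mean z_abs per dyad is compared genuine vs
pseudo with a paired t-test.

## Learning model

Per-trial skin conductance responses are modelled with an error-driven value
update per CS stream,

    V_{t+1}(s_t) = V_t(s_t) + α (U_t − V_t(s_t)),

and a Gaussian observation model SCR_t ~ N(β0 + β1 V_t(s_t), σ). V0 is fixed
at 0.5 during observational learning and free in [0, 1] for direct-test fits.
A Pearce-Hall variant replaces α by a per-stimulus associability
α_{t+1} = η|δ_t| + (1 − η)α_t; with η = 0 it reduces exactly to the constant-
rate model, which is what the model-comparison tests exploit.

Fitting is per-subject constrained maximum likelihood. For a fixed value
trajectory the observation parameters (β0, β1, σ) are a linear-Gaussian
regression with closed-form ML, so the optimizer searches only the 1–3
trajectory parameters (α, optionally η and V0) with L-BFGS-B from multiple
seeded starts (α bounded to (0.001, 0.999) to avoid boundary pathologies,
σ floored at 10⁻⁴). This concentrated-likelihood formulation has the same
optimum as the joint problem and is far more robust at 32-trial sample
sizes. Model ranking uses AIC by default (BIC available); a hierarchical
Bayesian treatment is a possible extension, and an optional empirical-Bayes
pass shrinks per-subject learning rates toward the group mean weighted by
the likelihood curvature at the optimum. Uninformative data (constant SCR,
or β1·sd(V) ≈ 0) sets a degenerate-fit flag rather than failing.

## Time-frequency statistics

Trial-averaged power is computed with 7-cycle complex Morlet wavelets at
1–30 Hz (1 Hz steps) over −2 to 5.5 s epochs, expressed as fractional change
relative to the −2 to −0.2 s baseline mean. Condition contrasts use
cluster-based permutation: sample-level t-maps thresholded two-tailed at
0.05, clusters formed over (channel-graph, frequency ±1, time ±1) adjacency
and required to span at least 3 distinct channels, cluster mass = sum of t,
null distribution = max |mass| under condition sign-flips (paired) or group
shuffles (independent), 1000 permutations by default, and the (b+1)/(m+1)
p-value estimator so p is never zero.

## Coupling-network clustering

Subjects × channel-pair matrices of nonnegative z_abs are factorized with
KL-divergence multiplicative-update NMF (divergence is monitored every
iteration and is non-increasing by construction). Channel pairs are the
clustered dimension: over many random restarts (1000 by default; at least
50), two pairs accumulate consensus when they share an argmax component.
The cophenetic coefficient of the average-linkage dendrogram of
(1 − consensus) measures stability per candidate rank (2–6 by default); the
selected rank is the first candidate at which the coefficient starts
decreasing — operationalized as the smallest k with coph(k+1) < coph(k),
with the largest candidate selected (and a warning) if the sequence never
decreases. Per-subject cluster loadings are the columns of the best-
divergence factorization's W, matched to consensus clusters by maximal
overlap (Hungarian assignment), and correlated with per-subject differential
learning by Pearson r.

## Time-varying prediction

Per-dyad coupling is resolved at 0.1 s steps over (0, 5.5] s and cumulated,
cum[k] = Σ_{i≤k} step[i]. At each of the 55 grid points an ε-SVR with RBF
kernel predicts the held-out dyad's learning outcome from the scalar
cumulative value under leave-one-dyad-out cross-validation; inputs are
standardized within each training fold. Hyperparameters default to C = 1,
ε = 0.1, γ = 1/d (library-conventional; a grid search is a config-level
extension). Performance is the Pearson correlation between predicted and
actual outcomes (plus MAE), p from the t-transform of r with n−2 df, BH-FDR
across the 55 time points. `summarize_onset` reports the earliest
FDR-significant time point with positive r and its contiguous run.

## Peripheral measures

SCR: 0.1–1 Hz zero-phase band-pass; per trial the largest base-to-peak
excursion in 0.5–4.5 s post onset (base = window-start value, floored at 0),
z-scored within subject. Pupil: blink gaps linearly interpolated; blink- and
saccade-locked transients regressed out on a canonical gamma kernel (0–2 s
span) time-locked to events — a regression approximation to full
deconvolution; 0.01–10 Hz band-pass; z-transform; resampling to 100 Hz.
Traces with >50% blinked samples are flagged unusable. The per-trial pupil
response is the 0–5.5 s mean minus the −0.5–0 s baseline mean. Fixation
proportions are dwell time per AOI (hand / face / stimulus rectangles, with
"elsewhere" any other on-screen point) normalized to total on-screen
fixation time inside the window, fixations clipped at window edges.
Eye-to-eye coupling applies the same circular statistic to 0.1–4 Hz Hilbert
phases of the two preprocessed pupil traces — applying a circular statistic
to an intrinsically non-circular signal is an interpretation, documented as
such.

## Synthetic dyads and what they do (not) emulate

Channels are unit-variance 1/f-like noise (an 8×8 grid with rook adjacency
stands in for a sensor layout; tests use smaller grids). Phase coupling is
planted per (channel pair, band, condition): the planted observer channel
carries the demonstrator's natural narrow-band component rotated by a
continuous phase-offset process. Inside designated trial windows the offset
is held (per-trial constant) with slow wrapped-Gaussian jitter whose SD
shrinks with the planted strength κ (equivalent von-Mises concentration
≈ 1/SD²; the realized per-trial CCorr is ≈ exp(−SD²), placing
κ = {0.3, 0.6, 0.9} near r = {0.3, 0.85, 0.99}); outside those windows the
offset drifts rapidly, so baseline segments and non-designated conditions
are phase-decoupled. Because of the circular-mean instability noted above,
both channels of a planted pair share identical band-vicinity content
(each channel's own content is removed over a widened guard band) — without
this, independent in-band noise would randomize per-trial values even at
κ = 1. A consequence worth knowing: planted pairs share band-envelope
structure at all times, so the baseline is phase-decoupled but not
amplitude-independent; the coupling statistic is phase-only, so this does
not leak into any tested quantity.

Blinks are Poisson (0.2/s) NaN runs of 100–400 ms. Pupil traces share a slow
0.1–2 Hz component scaled by a gain (optionally restricted to CS+ windows),
plus an optional smooth conditioned dilation on CS+ trials used as a
controllable learning-outcome signal. Fixations tile each trial with
0.15–0.6 s events; a hand bias applies inside the 4.7–5.5 s window on CS+
trials, with event boundaries forced at the window edges so a bias of 1
yields exactly full allocation.

The generator does not emulate: realistic sensor forward models or noise
covariance, head movement, cardiac/ocular artifacts in the neural channels,
amplitude–amplitude coupling, or any social-status manipulation beyond a
group label. Passing tests therefore show that the statistics recover the
phase structure and associations they are designed for — not that real
recordings satisfy the generator's assumptions.

## End-to-end demonstration

The pipeline's demo dataset (24–30 dyads, 3 demonstrators, one shared
schedule so the pseudo-demonstrator surrogate has aligned timelines) plants:
(i) CS+-only coupling in the low-status group on two "backbone" pairs over
the whole CS window, strength increasing with a per-dyad aptitude factor;
(ii) CS+-only coupling on two further pairs restricted to the pre-US window
(4.5–6 s), strength driven by the same aptitude; (iii) a learning rate and a
conditioned pupil response both increasing with aptitude. This yields
step-2 interaction detections on planted pairs, an NMF cluster whose
loadings correlate with learning, and a prediction r(t) curve that rises
toward the US with FDR-significant points in the final third of the grid.
At the demo's group size (≈15 low-status dyads) occasional spurious early
time points can reach FDR significance because adjacent cumulative values
are strongly correlated; the strict "significant only in the final third"
property is established in the acceptance suite on the trace-level
simulation (25 dyads, controlled noise), where it is stable.

## Numerical choices and degenerate inputs

Degenerate phase windows (sine-deviation resultant < 10⁻⁸) raise or drop the
row rather than returning a silent zero. ccorr accepts any length ≥ 2;
windows much shorter than one oscillation cycle give noisy values by nature.
NMF ties in the argmax assignment break toward the lower component index.
Permutation p-values use (b+1)/(m+1). Per-stage random seeds are derived
from the master seed by stable SHA-256 hashing of the stage name, so adding
a stage never perturbs another stage's draws.
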
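# Methods

This note documents the models, rules and numerical choices behind
`flexrelax`, the defaults and why they were chosen, and what the synthetic
cohort does and does not emulate.

## Grid model and bipolar derivation

The default grid is a 13 × 5 electrode lattice with 8 mm inter-electrode
distance and one corner electrode absent (64 physical electrodes). Row 0 is
the caudal edge (the grid is placed roughly L5→L2); columns run
medio-laterally. Single-differential channels are formed along columns —
the muscle-fiber direction — as caudal-minus-cranial differences of
vertically adjacent electrodes, skipping pairs that touch the missing
corner: 5·12 − 1 = 59 channels, each indexed by its midpoint on the 12 × 5
bipolar lattice. The missing corner defaults to the cranial-lateral corner
and is configurable, as is the row orientation; neither affects channel
count or the analysis, only the map's anatomical annotation.

## Filtering and envelopes

Monopolar signals are band-passed at 20–350 Hz with a 4th-order Butterworth
applied forward–backward (`sosfiltfilt`). Zero-phase filtering matters
because the pipeline's main output is a *timing* estimate; a causal filter
would bias every onset late by the group delay. The high cutoff is capped
at 0.45·fs so the same configuration remains valid at reduced sampling
rates. Envelopes are full-wave rectification followed by a zero-phase
4th-order 50 Hz Butterworth low-pass; the slight negative ringing this can
produce on a rectified signal is clipped at zero.

## Channel quality control

Real HDEMG studies screen channels visually; `flexrelax` replaces this with
three automated rules, applied per trial:

- **low_snr** — flexion-window RMS over baseline-window RMS of the
  band-passed bipolar signal below `snr_min` (default 3.0);
- **artefact** — more than `artefact_max` (default 0.5) of the *unfiltered*
  bipolar signal's movement-window power below 20 Hz (movement artefact,
  poor contact);
- **dead_electrode** — a monopolar electrode whose movement-window RMS is
  below `dead_electrode_frac` (default 0.1) of the grid's median electrode
  RMS marks both touching bipolar channels. This monopolar screen is
  needed because a lost contact leaves the *bipolar* signal looking clean:
  the difference degenerates to the surviving neighbour's signal, with
  normal amplitude and spectrum, so no bipolar-level statistic can see it.

Thresholds are configuration, validated against the generator's fault
injector (near-zero and low-frequency-artefact faults): at defaults, ≥90%
of fault-affected channels and ≤5% of clean channels are flagged (measured:
100% / 0% over 20 seeded cohorts). Flagged channels stay in the data with
reason codes; they are omitted from grid means and map denominators, so
spatial maps show holes where the exclusions were.

## Kinematic segmentation

The goniometer trace is re-referenced to its initial quiet-standing level,
low-passed at 10 Hz for differentiation, and segmented by standard event
rules: flexion starts where angular velocity first exceeds 5% of the rising
limb's peak (walking back from the velocity peak); the full-flexion plateau
starts where the angle enters and dwells ≥0.5 s inside a 2° tolerance band
below the maximum; extension starts where the descending limb leaves that
band for good. The quiet-standing baseline window (default 1 s) ends 0.5 s
before flexion start. The tolerance rules necessarily trim the phase
corners — a nominal 4 s flexion phase is detected as ≈3.9–4.0 s — which is
why epoch counting tolerates 50 ms (below).

Angle is mapped to percent of trunk flexion as 100·angle/max-angle, clamped
to [0, 100]; the alternative axis, percent of flexion-phase elapsed *time*,
is available via `DetectionConfig(axis="time")` since reports in this area
are ambiguous about which is meant. Angle is the default because the onset
is conventionally stated relative to the flexed posture, not the stopwatch.

## FRP offset detection

Per channel, threshold `T = μ_b + k·σ_b` from the baseline envelope
(k default 3). The onset is the first flexion-phase sample where the
envelope is below T and remains below continuously for `hold_s` (default
0.25 s; the hold may run past the flexion/MVF boundary, since relaxation
continues into MVF). The hold is a debounce: the semiautomatic visual
procedure it replaces implicitly ignores transient dips. Re-activation
after a valid crossing does not retract it (first-crossing rule). An
envelope below T for the whole flexion phase is reported present with
onset 0% and a `never_active` flag. The direction μ_b **+** 3σ_b is the
standard activity-threshold reading; μ_b − 3σ_b would be unreachable for a
tonic postural baseline.

A subject/side exhibits the FRP when offsets occur in strictly more than
50% of QC-passed channels; exactly half counts as absent. Channels without
an offset are excluded from the onset map. Repetitions are aggregated
channel-wise: presence by majority (ties count as present, with a warning),
onset as the mean over repetitions where present. Sides are pooled after a
paired side-difference check; pooling proceeds regardless, with a warning
if the check rejects.

The detector is vectorized (cumulative-sum window counting) but specified
to be sample-exact against a brute-force scan that tests every flexion
sample with the same hold rule; the suite enforces exact agreement on 500+
synthetic channels.

## Amplitude profiles

Per repetition: per-channel RMS of the band-passed bipolar signal in
adjacent, non-overlapping 1 s windows — 4 anchored at the detected flexion
start, 8 at the MVF start — averaged over usable channels, then normalized
to the peak of the same 1 s epoching over the extension phase (the window
of maximal effort), in percent. Anchoring at *detected* starts rather than
nominal metronome times avoids misalignment from the natural spread of
flexion durations. A phase within 50 ms of containing k whole windows
counts as k (the last window may overrun the fuzzy detected boundary by
that much); genuinely short phases yield fewer epochs with a warning. The
extension reference uses epoch-level RMS rather than an instantaneous peak,
consistent with the per-second treatment of the other phases (configurable
choice, documented here because the convention is not standardized).

## Smoothing-spline ANOVA

Both inference models are penalized regressions

y = intercept + factor effects + f(axes) + factor-specific smooth
deviations + subject intercept + ε

with sum-to-zero factor coding. The amplitude model uses a cubic smoothing
spline over time (reproducing kernel on [0,1] built from scaled Bernoulli
polynomials; null space = constant + linear). The onset model uses a
thin-plate spline over the grid plane (r²·log r basis with the affine null
space handled by QR projection). Factor-specific deviations share the main
term's kernel; the subject intercept is a ridge-penalized indicator block —
the mixed-model random intercept in its penalized-regression form — whose
weight is selected on the same grid as the roughness penalties.

**Numerics.** Representer/kernel Gram matrices are numerically
rank-deficient, so each penalized block is reparametrized through the
eigendecomposition of its penalty (Demmler–Reinsch): columns are rotated
and scaled so the penalty becomes λI, and directions with numerically zero
penalty eigenvalue — which carry equally negligible design energy — are
dropped. This keeps the normal equations well conditioned (fixed-λ fits
agree with an independent dense solve to ~1e-15 relative) without changing
the estimator.

**Smoothing selection.** GCV, `n·RSS/(n − tr(H))²`, minimized by coordinate
descent over a log-spaced grid (default 10⁻⁸…10⁶, 29 points) with a
half-decade local refinement per term; deterministic for fixed data. An
interpolating smoother (edf ≥ n−1) gets GCV = +∞: with RSS numerically
zero, the raw ratio is a 0/0 artifact that would otherwise win the grid.
Plain GCV retains its known weakness of occasionally undersmoothing pure
noise; the suite tests the property at the level the method honestly
delivers (median selection at maximal smoothing, clear majority of runs in
the grid's top decade) rather than pretending the failure mode away.

**Inference.** With M = AᵀA + Λ, the posterior covariance of the
coefficients under the penalty-as-Gaussian-prior reading is σ²M⁻¹ with
σ² = RSS/(n − edf). Group contrast curves are evaluated on a fixed grid —
the 12 epoch midpoints for time, the 59 channel positions for space — as
linear functionals of the fit; other factors sit at their sum-to-zero
average and the subject block at zero. Pointwise and mean 95% credible
intervals follow; a contrast is significant when the mean difference's
interval excludes zero. These intervals carry the classical
across-the-function average coverage property, which the suite verifies by
simulation (90–98% average pointwise coverage), and — because the subject
block enters M — the mean-contrast interval reflects between-subject
variance the way a mixed model's fixed-effect covariance does.

## Synthetic cohort: what it emulates, what it does not

Each electrode carries unit-variance Gaussian noise band-limited to
20–350 Hz, mixed from a grid-shared source and per-electrode noise (weight
0.5 each) so bipolar derivation genuinely cancels a common component, then
multiplied by a piecewise envelope: a tonic postural baseline (0.1 of the
active amplitude — paraspinals are postural, quiet standing is not
silence), a rise at movement onset, for relaxing subjects a smooth sigmoid
drop over ~150 ms centred at the channel's true offset (a step would make
detection trivially exact), and an extension re-activation at 1.3× the
active amplitude so the normalization reference falls in extension.

True offsets live on the angle axis: subject mean (control 55%, delayed
LBP subgroup 68% — an injected 13-point delay; between-subject SD 4%) plus
a cranio-caudal gradient (0.5%/row for the delayed subgroup, 0 for
controls; the within-grid gradient magnitude is a free simulation
parameter, as no quantitative reference value exists) plus per-electrode
jitter (SD 1%). A bipolar channel's recorded true offset is the **later**
of its two electrodes' offsets: the difference signal keeps near-full power
until both electrodes silence (with equal gains g the bipolar variance is
2(1−w)g², independent of the shared part), so the later electrode governs.
The `lbp_no_frp` group never relaxes. The goniometer trace is a trapezoid
with 0.25 s smoothed corners and per-subject maximal flexion ~N(91°, 11°);
it carries no sensor noise.

Known, deliberate limitations: no motor-unit physiology, no volume
conductor, no force/torque, no heteroscedastic fatigue effects, no angle
sensor noise. Passing recovery tests therefore shows the *pipeline's* rules
are consistent and unbiased under the stated signal model — not that the
detector is robust to every artefact class of real recordings.

**Detector bias under these conditions.** The offset rule fires where the
envelope crosses T on the sigmoid's lower tail, ~40–80 ms after the
sigmoid's centre (the recorded truth), which at the task's ~25%/s angle
velocity is a systematic late bias of ≈1.9% of trunk flexion — within the
≤2% recovery budget, and cancelling in between-group contrasts since both
groups share it. Recovery measured over 25 seeded cohorts at the study's
group sizes: bias 1.95%, RMSE 1.95%, and the contrast's 95% credible
interval covers the injected 13-point delay in 92% of cohorts.

## Problem sizes

Defaults reproduce the acquisition conditions (2048 Hz, 3 repetitions per
side, two sides, 14/9/5 subjects). The recovery/coverage harnesses and the
acceptance script run the same pipeline at 1024 Hz with one repetition per
side — sizes chosen so the distributional checks (25 full-pipeline cohorts)
remain routine to re-run; all reported properties are insensitive to this
reduction (the carrier band, filters and epoching are unchanged, and
2048 Hz spot checks agree).

## Degenerate inputs and tie-breaks

Segmentation raises informative errors on flat traces, missing plateaus, or
traces that never return toward neutral. Baseline windows shorter than
0.25 s are rejected (unstable SD). A trial whose channels all fail QC, or
whose extension reference is zero, raises rather than silently produced
NaNs; per-trial failures are logged and skipped at cohort level, and the
run fails only when a group loses all subjects. Presence ties across
repetitions count as present (logged); fraction exactly 0.5 classifies as
absent (strict majority). GCV grid ties resolve to the first (smallest-λ)
grid point via argmin; the λ grid and all seeds are fixed, so every
analysis is bit-reproducible.
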
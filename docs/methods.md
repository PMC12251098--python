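# Methods

This note documents the models, parameters, and numerical choices behind the
package, and what the synthetic study does and does not establish.

## Task and behavioural model

A session is 12 blocks of 48 trials (576 trials). Two Gabor gratings appear,
one per hemifield; after a blank, either, both, or neither changes orientation
(independent Bernoulli(0.5) per side), and a post-hoc probe selects the side
to judge (Yes/No change report). One hemifield (FX) keeps a fixed reward
contingency for the whole block; the other (VR) alternates between two
contingencies across mini-blocks whose lengths are drawn from a discretised
truncated exponential on {10..16}, `p(k) ∝ exp(−(k−10)/τ)` with τ solved
numerically so the mean is 12. Within a block the last mini-block is set to
the exact remainder (the block partition is redrawn if the remainder leaves
the 10–16 support), so mini-blocks tile each block. Half the blocks are gain
blocks (correct responses rewarded), half loss blocks (errors penalised),
pseudorandomly interleaved; the FX hemifield and the probe side are
counterbalanced within session and block respectively.

Payoff magnitudes are integers in arbitrary currency units — FX pays 5 for
each rewarded response type, VR pays 8/2 depending on the contingency
(split across response types in choice-specific sessions, with equal per-side
expected value; mirrored negative for errors in loss blocks). Only the
equality structure of the payoff matrix matters downstream (switch-trial
detection compares a trial's payoff with what the same response would have
earned under the previous contingency), so the absolute scale is
inconsequential.

Observers are equal-variance SDT agents: on each probed trial evidence
`x ~ N(d′·1[change], 1)` is compared against the threshold `d′/2 + c` for the
(side × contingency) cell, which makes the generative `c` coincide with the
estimated `c`. Estimation replaces hit/false-alarm rates of exactly 0 or 1 by
`1/(2N)` and `1 − 1/(2N)` of the respective row total before the probit (the
standard bounded correction; applications are logged). Trials without a
response are excluded everywhere; gain and loss trials are pooled by default
(per-valence estimation stays available via the `valence_filter` argument).

Default planted effects: space-specific `Δd′_VR = +0.5`, `Δd′_FX = −0.5`
around a mean `d′ = 0.7`, criterion flat at 0.12; choice-specific
`Δc_VR = −0.5` (liberal = lower criterion), sensitivity flat. RT = 530 ms
base + per-cell offsets (space: ∓10 ms on VR, ±17 ms on FX; choice: −24 ms
for the high-reward response) + gamma(4, 25 ms) noise. Between-observer
heterogeneity adds N(0, 0.15) jitter to the planted modulations (means exact).
These magnitudes sit in the range typical for reward-cueing change-detection
work and are fixed once; they are study conditions, not tuning knobs.

## Microsaccade analysis

Traces are monocular, 1 kHz, −200..+800 ms around stimulus onset. Velocities
use the Engbert–Kliegl 5-point smoothed difference. The detection ellipse is
centred on the per-epoch median velocity with semi-axes `5σ` per axis. For σ
the package defaults to the *median-based* estimator
`sqrt(median(v²) − median(v)²)` of the original algorithm rather than the
plain SD: at realistic event rates (~1–2 microsaccades/s) the saccades
themselves inflate the plain SD and hence the threshold, which measurably
destroys recall for small (≈0.3 dva) events (0.65 vs 1.00 recall at the
generator's defaults); the plain-SD variant remains available
(`dispersion="sd"`). Supra-threshold runs shorter than 6 ms are dropped as
single-sample noise crossings; an event starting within 12 ms of the previous
event's end is discarded; amplitude is the net displacement measured with an
8 ms pad on each side of the run (the velocity criterion crops the
displacement tails), events with amplitude ≥ 1 dva are rejected, and
peak-speed outliers (> mean + 5 SD of event peak speeds) are removed.
Directional rates count events whose displacement points into a hemifield
within ±45° of the horizontal meridian, in 100 ms windows sliding by 25 ms;
the 150–350 ms window mean is the scalar rate per cell. A fixation-control
pre-filter flags trials whose azimuthal gaze exceeds ±1 dva between −50 and
+200 ms.

The gaze generator superimposes Brownian drift (1.5 mdva/√sample), white
measurement noise (10 mdva), and injected events with Gaussian velocity
profiles (duration 15–25 ms, amplitude 0.1–0.9 dva, ±30° direction jitter,
Poisson counts at per-(side × contingency) rates, default 0.09 events/100 ms
toward each side). Injections keep an 80 ms refractory gap so ground-truth
events remain individually resolvable; real intersaccadic intervals are
longer still.

## EEG analysis

Epochs are trials × channels × samples (µV) at 250 Hz over −1000..+1000 ms,
with a 16-channel 10–10 subset (PO3/4, PO7/8, O1/2 occipitoparietal; F1–F4,
C1–C4, FC1/2 frontocentral). Preprocessing: order-4 Butterworth 0.5–35 Hz
band-pass applied forward–backward (zero phase, so component latencies are
not shifted), decimation to 250 Hz where needed, average re-reference; for
ERPs the epoch is trimmed to −200..+700 ms and the 200 ms pre-stimulus mean
subtracted per trial/channel. Filtering uses generous reflection padding
(3/f_lo seconds) because the 0.5 Hz edge has a long transient; residual edge
effects on 2 s epochs are unavoidable and quantified in the tests.

ERP components are registered as data (electrode set, window, polarity):
N2pc and P300 on the occipitoparietal set (150–210 ms and 230–480 ms), P2a on
the frontocentral set (150–210 ms). Amplitude is the window mean of the
trial- and channel-averaged waveform over channels contralateral to the
stimulus side (left-hemifield stimulus → even-numbered channels), resolved
per trial because the FX hemifield alternates across blocks.

Spectral analysis uses a single Slepian taper (time-half-bandwidth 1) on
500 ms windows stepped by 24 ms (25 ms rounded to an integer sample count at
250 Hz, as the reference toolboxes do), zero-padded to a ≈0.49 Hz grid. The
IAF is the frequency of peak trial-mean power in 7.5–13 Hz in the 500 ms
pre-stimulus window (ties break to the lower frequency; boundary peaks warn).
Alpha power is the mean over IAF ± 0.5 Hz and the 450–950 ms (post) or
−500–0 ms (pre) window, divided per trial by the 15–35 Hz mean baseline
power. "Suppression" per side is the contingency difference of alpha power;
"lateralization" is suppression(VR) − suppression(FX).

The EEG generator plants: 1/f noise (exponent 1, σ = 8 µV); an alpha
oscillation (4 µV, planted IAF) on occipitoparietal channels whose envelope
on contralateral channels is scaled per (side × contingency) — post-stimulus
suppression 25% contralateral to the higher-reward side in space-specific
sessions, pre-stimulus suppression 15% contralateral to VR under the liberal
contingency in choice-specific sessions; and raised-cosine ERP deflections
with window-mean amplitudes N2pc −1.5 µV, P300 +2.0 µV, P2a +1.0 µV, with
±0.75 µV anti-symmetric modulations in the space-specific session only. The
amplitudes were fixed by a design-stage power analysis so a single scaled
session (6 blocks) recovers the planted sign of the lateralized contrast
with z ≈ 2.5–3.

## Switch-locked dynamics and the conserved-resource test

A switch trial is the first VR-probed trial of a mini-block whose delivered
payoff differs from what the same response type would have earned under the
previous contingency. Around each switch, metrics are evaluated in 9-trial
windows centred on offsets −2..+14 (step = the `shift` parameter; 2 by
default, 1 in the headline conserved-resource analysis, where the finer grid
doubles the number of points available to the permutation test). Windows
truncate at block edges. For SDT parameters the 2×2 counts are pooled across all switches of a
transition type *before* the probit: single-switch 9-trial windows cannot
support a stable `d′` estimate, and per-window estimation plus the
extreme-rate correction induces a spurious cross-side coupling through the
shared probe-allocation constraint (verified: pooled estimation centres the
independent-sides `R²` at ~0). Other metrics (RT, rates, alpha) are averaged
across switches, optionally normalised by the participant's session mean.
Participant traces are averaged first; the pooled (VR, FX) window points are
then de-meaned per side and scored against `x + y = 0` with the symmetric
`R² = 1 − Σ(x+y)²/Σ(x²+y²)` (1 iff exact, can be negative; an asymmetric
y-against-line variant is available for sensitivity analysis). Sessions are
compared by shuffling each point-pair's session label (1000 permutations,
one-sided, `(b+1)/(m+1)` correction).

## Marker regression

Rows are (participant × side), n = 48 for 24 participants. The response is
`Δd′` (space-specific) or `Δc` (choice-specific); predictors are marker
modulations divided by the participant's session mean of the raw marker
(no z-scoring). Model I uses ΔN2pc, ΔP300, Δα_pre, Δα_post; Model II uses
ΔRT, ΔMSC. Fits are OLS with intercept; diagnostics include the overall
F-test against the intercept-only model, condition indices of the
column-scaled design, jackknife (leave-one-participant-out) standard errors,
and per-coefficient permutation tests that reassign each participant's
response pair between their FX and VR rows (one-sided in the observed
direction by default; a fixed direction is available, under which null
p-values are uniform). Leave-one-out prediction drops both rows of the
held-out participant and scores observed vs predicted with the
percentage-bend correlation. Note one divergence from real data built into
the synthetic study: any marker planted side-asymmetrically co-varies with
the side structure of the response, so the choice-session Model I (which
includes the planted pre-stimulus alpha effect) retains predictive power in
simulation, whereas Model II (no motoric plant in choice sessions) is null —
the generator does not emulate the large between-participant marker
variability that dominates real recordings.

## Statistical machinery

*Cluster-based permutation test*: pointwise paired t statistics, two-tailed
cluster-forming threshold at α = 0.05, clusters as contiguous runs (1D) or
4-connected components (2D), mass = summed t, null = maximum |mass| under
within-participant sign flips (the per-point sums of squares are flip-
invariant, which the implementation exploits), p with the `(b+1)/(m+1)`
correction. *Percentage-bend correlation*: deviations from the median scaled
by the ⌈(1−β)n⌉-th smallest absolute deviation (β = 0.2), winsorised through
ψ(u) = clip(u, −1, 1), Pearson on the ψ scores; p by order permutation or the
t approximation; β = 0 reduces to Pearson on median-centred data. *JZS Bayes
factor*: one-sample BF₁₀ by adaptive quadrature of the noncentral-t
likelihood against a Cauchy(0, √2/2) prior on effect size; one-sided versions
truncate (and renormalise) the prior. *Condition tests*: Wilcoxon signed-rank
contrasts and a 2×2 repeated-measures ANOVA (side × reward contingency),
delegated to scipy/pingouin and reported in the factorial-table layout.

## Problem sizes and what the tests show

The acceptance suite runs: 100 replicate 24-observer behavioural studies
(full 576-trial sessions); 100 gaze trials for the detector operating point;
100 EEG sessions of 6 blocks (288 trials) for marker-sign recovery; 50
runs × 24 observers for the conserved-resource contrast; 500 pure-noise
simulations (12 participants × 100 points, 1000 permutations) for cluster
FWER; and constructed 48-row tables for the regression loop. The acceptance
script uses the same machinery at 20 behavioural replicates, 50 EEG sessions,
and 300 FWER simulations.

Passing these checks shows the estimators are unbiased and correctly
calibrated *under the generative assumptions*: stationary SDT observers
within cells, instantaneous (one-trial) adaptation at the inferred switch,
artifact-free EEG with linear superposition of effects, and resolvable
microsaccades. They do not establish robustness to real-data phenomena the
generators deliberately omit: gradual post-switch learning, non-stationary
criteria, eye/muscle artifacts and their removal, volume-conduction
structure across channels, main-sequence velocity-amplitude coupling, or
heavy-tailed between-participant marker variability.

## Known limitations

- ICA/SCADS-style artifact rejection is out of scope; the EEG reader accepts
  clean epochs only.
- The staircase titration of the change angle is not simulated; observers are
  parameterised directly by `(d′, c)`.
- Drift-diffusion accounts of the RT effects are out of scope.
- The deposited human dataset can be analysed by writing its trial tables
  into the documented CSV schema, but no downloader is included.
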
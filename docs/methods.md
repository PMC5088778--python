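# Methods

This note documents the generative model behind the synthetic cohorts, the
analysis procedures, the tunable parameters and their defaults, and the
design decisions taken where more than one reasonable choice existed.

## The task design being emulated

A covert visual-search experiment: each trial starts with a 200 ms spatial
cue — informative (pointing at the upcoming target side with 100% validity)
on half the trials, uninformative on the other half — followed by a
1200–1500 ms preparation interval and a 150 ms search display containing a
target on one side and a distractor on the other. The distractor's color
similarity to the target has four levels (D1 most similar … D4 least
similar), crossed with cue presence into a 2 × 4 within-subject design with
108 trials per cell (864 trials). The participant reports a letter (A/B/C)
inside the target; the distractor always carries a *different* letter, so
guessing from the distractor letter alone yields exactly 1/2 — and guessing
blind among three letters exactly 1/3 (reports quoting "33.4%" round this
value; the package uses 1/3).

The trial schedule reproduces this structure exactly: equal cell counts,
sides and target letters balanced within cells (remainders assigned
round-robin in a fixed order for determinism), pseudorandomization in passes
such that all 48 distinct trial types occur before any type repeats, the
target/distractor shape swapped every 48-trial block, and informative cues
always valid.

## Generative model of the EEG

Each trial of each subject is, per channel (units µV, 256 Hz, epoch −2.4 to
+1.9 s around search-display onset):

1. **Background noise**: 1/f^β noise, β = 1.0 by default, independent per
   channel (σ = 10 µV) plus a shared rank-1 spatial component (σ = 2 µV), so
   channels are neither independent nor identical.
2. **Posterior alpha**: a sinusoid at 10 Hz with amplitude 6 µV on the
   posterior sensor group, phase drawn uniformly per trial and channel.
   Random phase makes the rhythm *induced* rather than evoked: its power
   survives per-trial TFR while averaging toward zero in the ERP, which is
   the property baseline-relative power actually measures.
3. **Condition-dependent asymmetry**: inside each window configured for the
   trial's cue × pooled-similarity condition, the alpha amplitude is scaled
   by (1 + a) ipsilateral and (1 − a) contralateral to the target
   (a = 0.30 by default) — alpha lower contralateral to the attended target.
   Windows (s, relative to target onset): cued conditions −1.05–0 pretarget;
   cued/low 0.35–0.50; cued/high 0–0.15 and 0.45–0.75; uncued/low 0.50–0.90;
   uncued/high none. Envelopes rise and fall with 100 ms raised-cosine ramps
   (a full Hann bump when the window is shorter than two ramps).
4. **Midfrontal theta**: a 5 Hz burst (3.5 µV, random phase) on the
   midfrontal group at 0.70–1.25 s, on uninformatively cued high-similarity
   trials only.

Behavior is generated per trial from the condition cell: reaction times are
log-normal, moment-matched to the cell mean and a trial-level SD of 180 ms;
correctness is Bernoulli(0.879) and the eye-movement flag Bernoulli(0.071),
independent of condition. The eight cell means (ms) are reconstructed from
published marginal means and cue-benefit values assuming equal cell counts:
cued 830.3 / 812.05 / 777.85 / 775.35 and uncued 990.1 / 938.35 / 829.35 /
822.25 for D1–D4. Between-subject variance comes from a normal RT offset
(SD 60 ms) and relative jitter (SD 0.2) on the alpha-asymmetry and theta
amplitudes.

**Distractibility coupling.** With `distraction_coupling = c > 0`, one
standard-normal latent per subject scales both the behavioral
distractor-similarity effect and the uncued/low alpha asymmetry by
max(0, 1 + c·z). More distractible subjects then show a larger RT cost
*and* a larger low-similarity lateralization — hence a more negative
high-minus-low lateralization difference — producing the negative rank
correlation between cost and lateralization difference. The default is 0
(off); the correlation study uses 0.6.

**Effect-size calibration.** The emulated study reports statistics, not
signal amplitudes, so amplitudes cannot be copied from it. The defaults
above were calibrated once so that the full pipeline at 16 subjects and 108
trials per cell recovers all and only the injected condition effects, and
were then frozen; the recovery pattern, not any amplitude, is the target.

**What the generator does not emulate** — and therefore what passing tests
do not show about real recordings: ocular and muscle artifacts (the
eye-movement flag is metadata only; rejection logic, not artifact removal,
is what is tested), volume conduction and realistic sensor covariance,
amplifier noise and line interference, non-stationary alpha (waxing/waning
beyond the injected envelopes), and individual alpha-frequency variation.

## Sensor layout

Layouts are schematic 10/20-style sets (8–32 sensors) with exact left/right
mirror pairs, a midline, 2-D positions on a unit head radius and a
distance-threshold neighborhood graph (radius 0.45). The emulated study
names no posterior or midfrontal sensor sets; the defaults here are
posterior = {O1/2, Oz, PO7/8, POz, P3/4, P7/8, Pz} and midfrontal =
{FCz, Fz, Cz, FC1/2}, intersected with the layout — a documented choice, not
a reconstruction. Inference never depends on these groups: cluster tests run
over all channels; the groups only determine where effects are injected and
the fixed fallback selection for the lateralization index.

## Time–frequency decomposition

Power at frequency f and time t is |c|²·(2/Σw)², where c is the Fourier
coefficient at f of the Hann-tapered segment of length 3/f centered on t
(window length rounded to the nearest odd sample count so time stamps are
exact). The single-frequency projection is mathematically identical to
selecting that bin of a windowed DFT, cheaper, and directly testable against
an independent oracle. With this normalization a unit-amplitude sinusoid has
power 1, so raw power is in amplitude-squared units (µV²); since all
downstream quantities are baseline-relative, any fixed normalization
constant cancels, and the choice is a convention, not an assumption.

Defaults: frequency grid 2–30 Hz in 1 Hz steps (the pipeline uses only
8–12 Hz and 4–6 Hz subsets), time step 50 ms. Time points whose window
overruns the epoch are NaN and excluded from everything downstream —
conservative NaN propagation rather than zero-padding.

Baselining is `(P − P̄)/P̄` with P̄ the mean raw power over baseline time
points *and* over the trials of a normalization unit (subject × cue ×
pooled-similarity cell), per channel and frequency, before division —
averaging first keeps the quotient stable when single-trial baseline power
is small. The alpha baseline is the 400 ms window ending 100 ms before the
earliest possible cue onset (−2.2 to −1.8 s; cue onset falls 1.4–1.7 s
before the target). The theta baseline is pretarget, −0.7 to −0.3 s, because
3-cycle windows at 4–6 Hz are long enough to leak cue-evoked or post-target
activity into a precue baseline; with only uninformative-cue conditions
contrasted and both target sides pooled, the pretarget period is
condition-neutral by construction.

## Cluster-based permutation inference

The cluster-forming statistic is the dependent-samples t over subjects at
every channel × time point (zero-variance points become ±∞ and count as
supra-threshold with their sign). The threshold is the two-sided pointwise
p < 0.05 critical value at df = n−1 — the emulated procedure names no
threshold, and this is the named toolbox's convention, recorded here as an
assumption, as is the cluster statistic (mass = Σt, not cluster size).
Supra-threshold points of equal sign are clustered over the product graph:
(c, t) ~ (c, t±1) and (c, t) ~ (c′, t) for neighboring channels.

The null distribution of the maximum |mass| is built by flipping the sign of
each subject's condition difference — algebraically identical to swapping
that participant's condition labels in a paired design — 1000 times by
default. When 2ⁿ ≤ n_perm all 2ⁿ flips are enumerated and p-values are
exact; otherwise Monte Carlo p-values carry the +1 correction,
(hits + 1)/(n_perm + 1), which guarantees validity at finite permutation
counts. Permutation t-maps are computed with the same two-pass mean/variance
algorithm as the observed map so that the identity flip reproduces it
exactly. Empirically the test rejects at ≈ 0.047 at nominal α = 0.05 over
300 null simulations (12 subjects, 16 channels, 40 time points).

Alpha contrasts compare the flip-and-pooled map against its own mirror
image (ipsilateral vs contralateral); midline channels contribute exact
zeros and clusters appear in antisymmetric sign pairs, which the two-sided
max-statistic handles naturally. The cue × similarity interaction is the
paired cluster test on the difference-of-differences (lateralized minus
mirrored, cued vs uncued) — the minimal construction consistent with a
paired cluster test, since the emulated analysis reports an interaction
without giving its formula. Theta contrasts pool left- and right-target
trials without flipping.

## Lateralization index and correlation

The index is mean(ipsi) − mean(contra) relative alpha power over a channel ×
time selection. By default the selection is the significant positive cluster
of the uncued/low post-target contrast *on the same data* — this circularity
is inherited from the emulated procedure and documented; a fixed independent
selection (right posterior channels, 0.5–0.9 s) is available via
`index_selection="fixed"` and is used as the fallback when no cluster is
significant, and by the reduced correlation study. The high-minus-low
lateralization difference is correlated with the per-subject uncued
distractor cost by Spearman's ρ with average ranks and the t-approximation
p-value. A by-inspection outlier judgment is replaced with a deterministic
rule: points with median/MAD robust z > 3 on either axis are flagged, and ρ
is always reported both with and without them.

## Behavioral statistics

Trial rejection retains correct trials without eye-movement flags.
Participant screening is single-pass: (1) accuracy strictly below the group
mean − 2 SD (group statistics computed over all subjects, the flagged one
included) excludes; (2) the distractor-similarity check — a Welch
two-sample t-test across trials within subject, D1 vs D4 correct-trial RTs,
retained only when p < 0.05 with mean(D1) > mean(D4); the trial-level
("independent-samples") form follows the emulated procedure's own wording;
(3) the cue-effect t-test is computed and reported but never excludes.
The RM-ANOVA uses the classical within-subject decomposition, each effect
tested against its effect-by-subject interaction, with no sphericity
correction (none is reported in the emulated analysis, whose printed degrees
of freedom match the uncorrected values).

## Numerical choices and degenerate inputs

- Zero-variance one-sample comparisons report the exact decision with a
  degenerate flag instead of an undefined t.
- Subjects with no correct D1 or D4 trials are unevaluable and excluded.
- Empty pooled RT cells drop the subject from the cost with a warning (NaN).
- Bonferroni p-values are capped at 1.
- Cluster p comparisons use a 1e-12 relative tolerance on the mass so exact
  permutation ties count as hits.
- Containers carry a format version; a missing or mismatched version raises
  an explicit error rather than misparsing.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the pipeline at 16 channels
(recovery study: 16 subjects × 108 trials per cell × 5 cohorts; cluster
calibration: 200 null simulations of 12 × 16 × 40 with 500 flips;
correlation study: 20 cohorts of 12 subjects, 8 channels, 30 trials per
cell). These sizes keep a desk-scale runtime while leaving every recovery
test comfortably powered; the full 32-channel layout and any cohort size run
through the same code paths.

## Known limitations

- Sensor positions are schematic; no forward model or real cap geometry.
- The generator's effects are stationary sinusoidal envelopes; real alpha
  lateralization has richer temporal dynamics.
- The reported cluster time extents inherit the temporal smearing of the
  3-cycle windows (≈ ±150 ms at 10 Hz, more at theta), so recovered windows
  are systematically wider than injected ones.
- Only paired (within-subject) cluster designs are implemented; no TFCE, no
  between-subject designs, no cluster tests over frequency.
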
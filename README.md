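# alphalat

Synthetic cued visual-search EEG cohorts and the oscillatory analysis chain
that recovers their condition structure.

## The scientific problem

Covert visual attention leaves a hemispheric signature in the EEG alpha band
(8–12 Hz): power drops over occipito-parietal cortex **contralateral** to an
attended location relative to the **ipsilateral** hemisphere. In a cued
visual-search design — a spatial cue (informative or uninformative) followed
by a lateralized target paired with a distractor whose color similarity to
the target is varied parametrically (D1 most similar … D4 least similar) —
this lateralization appears both *before* the search display (preparatory
attention under an informative cue) and *after* it (ongoing attentive
processing), except when target selection is ambiguous: with an
uninformative cue and a highly similar distractor, posterior alpha stays
symmetric and midfrontal theta (4–6 Hz) rises instead, the signature of
reactive conflict control.

No public data exist for this design, so `alphalat` pairs the analysis with
a **synthetic-cohort generator** whose condition structure is known exactly:
every stage of the pipeline can be verified against the ground truth it
injects. The package is aimed at methodologists who want a fully testable
reference implementation of the sensor-space pipeline — adaptive-window
time-frequency analysis, hemisphere flip-and-pool, and cluster-based
permutation inference — and at students of attention EEG who want a working
model of the design.

## The methods at the core

* **Time–frequency power** — per trial, the squared magnitude of a
  single-frequency DFT projection of Hann-tapered segments with an adaptive
  window of three cycles per frequency, ΔT = 3/f. Power is expressed as the
  relative change from baseline, (P(t) − P̄(base)) / P̄(base).
* **Hemisphere flip-and-pool** — left-target trials are mirrored across the
  sagittal midline and pooled with right-target trials, so right-hemisphere
  sensors always carry ipsilateral activity.
* **Cluster-based permutation test** — supra-threshold points of the paired
  t-map (threshold: two-sided p < 0.05, df = n−1) are clustered over the
  channel-neighborhood × time product graph; the cluster mass Σt is compared
  against the permutation distribution of the maximum |mass| under random
  sign flips of each subject's condition difference (exhaustive enumeration
  when 2ⁿ ≤ n_perm). The Monte Carlo p controls family-wise error over all
  channel-time points.
* **Lateralization index** — mean(ipsi) − mean(contra) relative alpha power
  over a cluster's channels and time window, correlated across subjects with
  the behavioral distractor cost, RT(high) − RT(low similarity), by
  Spearman's ρ (with a reproducible median/MAD outlier rule).
* **Behavioral statistics** — trial rejection (errors, eye movements),
  participant screening, 2 × 4 repeated-measures ANOVA with within-subject
  error terms, Bonferroni-corrected pairwise t-tests and tests against
  chance (1/3 for three letters; exactly 1/2 once the distractor letter is
  known, since the distractor never shows the target letter).

## A worked example

```python
import warnings
from alphalat import AnalysisConfig, SimulationParams, run_contrast_suite

params = SimulationParams(n_subjects=8, trials_per_condition=48, n_channels=8)
report = run_contrast_suite(AnalysisConfig(sim=params, n_perm=500, seed=3))
for name, c in report["contrasts"].items():
    print(name, c["significant"], c["significant_windows_ms"])
```

prints (abridged; `examples/04_full_pipeline.py` is the full script):

```
alpha_pretarget_cued                True         -1080..-13
alpha_pretarget_uncued              False        -
alpha_pretarget_interaction         True         -1029..-13
alpha_post_cued_low                 True         342..495
alpha_post_cued_high                True         444..799, 38..190
alpha_post_uncued_low               True         545..901
alpha_post_uncued_high              False        -
theta_uncued_high_vs_low            True         698..1409
theta_cued_high_vs_low              False        -
```

Reading: informative cues produce pretarget alpha lateralization and its
interaction with uninformative cues; after the search display the
lateralization reappears in every condition except uncued/high-similarity,
which instead shows the midfrontal theta increase — exactly the condition
pattern the generator injects (windows: pretarget −1050–0 ms; cued/low
350–500 ms; cued/high 0–150 and 450–750 ms; uncued/low 500–900 ms; theta
700–1250 ms, smeared by the 3-cycle analysis windows).

The `examples/` directory has one short script per capability: cohort
simulation and the container format, TFR on a known signal, the cluster
test, the full pipeline, and the brain–behavior correlation. A thin CLI
wraps the same calls: `alphalat simulate`, `alphalat run`, `alphalat
report`.

## Layout

```
src/alphalat/
  layout.py          sensor layouts, mirror pairing, neighborhoods
  simulate.py        schedules, behavior, oscillatory EEG, cohorts
  tfr.py             adaptive Hann-taper TFR, baselining, band averaging
  cluster.py         paired t-maps, clustering, sign-flip permutation test
  lateralization.py  flip-and-pool, indices, Spearman correlation
  behavior.py        rejection, exclusion, RM-ANOVA, chance tests, cost
  pipeline.py        the configuration-driven contrast suite
  io.py              HDF5 + JSON epochs container, reports
  cli.py, viz.py     thin CLI, minimal scalp-map export
```

See `docs/methods.md` for the model, parameter and design-decision notes.
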
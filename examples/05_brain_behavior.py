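"""Brain-behavior correlation under distractibility coupling.

When the simulator couples a subject's latent distractibility to both the
behavioral distractor cost and the uncued/low-similarity alpha
lateralization, subjects with larger reaction-time costs show a more negative
lateralization difference (high minus low similarity) — a negative Spearman
correlation.
"""

import warnings

from alphalat import SimulationParams
from alphalat.pipeline import lateralization_correlation

for coupling in (0.0, 0.6):
    params = SimulationParams(
        n_subjects=12, trials_per_condition=30, n_channels=8,
        distraction_coupling=coupling,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr, detail = lateralization_correlation(params, seed=1)
    print(f"coupling {coupling:.1f}: rho = {corr.rho:+.3f} (p = {corr.p:.3f}), "
          f"mean cost {detail['cost_ms'].mean():.0f} ms, "
          f"mean lateralization difference {detail['difference'].mean():+.3f}")

print("\nwith the coupling off the correlation is at chance; with it on, the "
      "rank correlation turns reliably negative — larger behavioral cost, "
      "smaller alpha lateralization under high distractor similarity.")
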
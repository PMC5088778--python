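"""Trial rejection, participant exclusion and behavioral statistics.

Implements the behavioral analysis chain of the cued visual-search design:
rejection of incorrect and eye-movement trials, the three participant
screening rules (accuracy, distractor-similarity effect, cue effect), the
2 (cue presence) x 4 (distractor similarity) repeated-measures ANOVA with
classical within-subject error terms, Bonferroni-corrected pairwise t-tests,
tests against chance performance, similarity pooling (D1+D2 = high,
D3+D4 = low) and the per-subject reaction-time distractor cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import cue_presence

__all__ = [
    "CHANCE_3AFC",
    "CHANCE_DISTRACTOR_INFORMED",
    "reject_trials",
    "exclude_subjects",
    "rm_anova_2x4",
    "pairwise_bonferroni",
    "t_vs_chance",
    "pool_similarity",
    "distractor_cost",
    "cell_rt_means",
]

#: Chance accuracy guessing among three letters.  (Exactly 1/3; reports that
#: round it to 33.4% are a rounding artifact.)
CHANCE_3AFC = 1.0 / 3.0
#: Chance accuracy guessing between the two letters not shown in the
#: distractor (the distractor letter never matches the target).
CHANCE_DISTRACTOR_INFORMED = 0.5

_POOL = {"D1": "high", "D2": "high", "D3": "low", "D4": "low"}


def reject_trials(behavior: pd.DataFrame) -> np.ndarray:
    """Positional indices of retained trials: correct and without eye movement."""
    correct = behavior["correct"].to_numpy(dtype=bool)
    eye = behavior["eye_movement"].to_numpy(dtype=bool)
    return np.flatnonzero(correct & ~eye)


@dataclass
class ChanceTest:
    t: float
    p: float
    degenerate: bool = False


def t_vs_chance(accuracies: np.ndarray, chance: float) -> ChanceTest:
    """One-sample two-sided t-test of subject accuracies against chance.

    With zero variance across subjects the t statistic is undefined; the test
    then reports the exact decision (p = 1 when the common value equals
    chance, p = 0 otherwise) with ``degenerate=True``.
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least two subjects")
    if np.ptp(acc) == 0:
        same = acc[0] == chance
        return ChanceTest(t=0.0 if same else np.inf * np.sign(acc[0] - chance),
                          p=1.0 if same else 0.0, degenerate=True)
    t, p = stats.ttest_1samp(acc, chance)
    return ChanceTest(t=float(t), p=float(p))


def pool_similarity(levels) -> np.ndarray:
    """Map distractor levels to pooled similarity: D1/D2 -> high, D3/D4 -> low."""
    levels = np.asarray(levels)
    unknown = set(np.unique(levels)) - set(_POOL)
    if unknown:
        raise ValueError(f"unknown distractor level(s): {sorted(unknown)}")
    return np.vectorize(_POOL.get)(levels)


def rm_anova_2x4(cell_means: np.ndarray) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on a (subjects, 2, 4) table.

    Classical within-subject sums-of-squares decomposition: each effect is
    tested against its own effect-by-subject interaction; no sphericity
    correction is applied.  Returns a table with rows 'cue', 'distractor'
    and 'interaction'.
    """
    y = np.asarray(cell_means, dtype=float)
    if y.ndim != 3:
        raise ValueError("expected a (subjects, cue, distractor) array")
    if np.isnan(y).any():
        raise ValueError("missing cells are not supported")
    n, na, nb = y.shape
    if n < 2:
        raise ValueError("need at least two subjects")

    gm = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_a = n * nb * ((m_a - gm) ** 2).sum()
    ss_b = n * na * ((m_b - gm) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_as = nb * ((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2).sum()
    ss_bs = na * ((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2).sum()
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - gm
    )
    ss_abs = (resid**2).sum()

    rows = []
    for name, ss, df1, ss_err, df2 in (
        ("cue", ss_a, na - 1, ss_as, (na - 1) * (n - 1)),
        ("distractor", ss_b, nb - 1, ss_bs, (nb - 1) * (n - 1)),
        ("interaction", ss_ab, (na - 1) * (nb - 1), ss_abs, (na - 1) * (nb - 1) * (n - 1)),
    ):
        ms, ms_err = ss / df1, ss_err / df2
        if ms_err == 0:
            f = 0.0 if ms == 0 else np.inf
        else:
            f = ms / ms_err
        p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        if f == 0:
            p = 1.0
        rows.append({"effect": name, "F": float(f), "df_num": df1, "df_den": df2, "p": p})
    return pd.DataFrame(rows).set_index("effect")


def pairwise_bonferroni(data: np.ndarray, contrasts: list[tuple[int, int]]) -> pd.DataFrame:
    """Paired two-sided t-tests with Bonferroni correction.

    ``data`` is (subjects, conditions); each contrast is a pair of condition
    column indices.  Corrected p-values are raw p times the family size,
    capped at 1.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (subjects, conditions) array with >= 2 subjects")
    m = len(contrasts)
    rows = []
    for i, j in contrasts:
        d = x[:, i] - x[:, j]
        if np.ptp(d) == 0:
            t, p = (0.0, 1.0) if d[0] == 0 else (np.inf * np.sign(d[0]), 0.0)
        else:
            t, p = stats.ttest_rel(x[:, i], x[:, j])
        rows.append(
            {"i": i, "j": j, "t": float(t), "p_raw": float(p),
             "p_corrected": min(1.0, float(p) * m)}
        )
    return pd.DataFrame(rows)


def _subject_columns(trials: pd.DataFrame) -> pd.DataFrame:
    df = trials.copy()
    df["cue_presence"] = cue_presence(df["cue"])
    return df


def exclude_subjects(cohort_trials: list[pd.DataFrame]) -> pd.DataFrame:
    """Apply the participant screening rules to a cohort.

    Per subject the table reports: overall accuracy and the accuracy rule
    (excluded when strictly below the group mean minus two group standard
    deviations, both computed over all subjects in a single pass); the
    distractor-similarity rule (Welch t-test of correct-trial reaction times
    D1 vs D4 within subject; retained only when p < 0.05 with mean(D1) >
    mean(D4)); and the cue-effect t-test, which is reported but never
    excludes.  Subjects with no correct trials in D1 or D4 are unevaluable
    and treated as excluded.
    """
    if len(cohort_trials) < 3:
        raise ValueError("need at least three subjects")
    accs = np.array([df["correct"].mean() for df in cohort_trials])
    mu, sd = accs.mean(), accs.std(ddof=1)
    cutoff = mu - 2 * sd

    rows = []
    for s, trials in enumerate(cohort_trials):
        df = _subject_columns(trials)
        ok = df["correct"].astype(bool)
        rt1 = df.loc[ok & (df["distractor_level"] == "D1"), "rt_ms"].to_numpy()
        rt4 = df.loc[ok & (df["distractor_level"] == "D4"), "rt_ms"].to_numpy()
        unevaluable = rt1.size == 0 or rt4.size == 0
        if unevaluable:
            t14, p14, sim_excl = np.nan, np.nan, True
        else:
            t14, p14 = stats.ttest_ind(rt1, rt4, equal_var=False)
            sim_excl = not (p14 < 0.05 and rt1.mean() > rt4.mean())
        rtc = df.loc[ok & (df["cue_presence"] == "cued"), "rt_ms"].to_numpy()
        rtu = df.loc[ok & (df["cue_presence"] == "uncued"), "rt_ms"].to_numpy()
        if rtc.size and rtu.size:
            tcue, pcue = stats.ttest_ind(rtu, rtc, equal_var=False)
        else:
            tcue, pcue = np.nan, np.nan
        acc_excl = bool(accs[s] < cutoff)
        rows.append(
            {
                "subject": s,
                "accuracy": accs[s],
                "group_mean": mu,
                "group_sd": sd,
                "accuracy_excluded": acc_excl,
                "d1_d4_t": float(t14) if np.isfinite(t14) else t14,
                "d1_d4_p": float(p14) if np.isfinite(p14) else p14,
                "similarity_excluded": bool(sim_excl),
                "cue_effect_t": tcue,
                "cue_effect_p": pcue,
                "unevaluable": unevaluable,
                "final_included": not (acc_excl or sim_excl),
            }
        )
    return pd.DataFrame(rows).set_index("subject")


def cell_rt_means(trials: pd.DataFrame, retained_only: bool = True) -> np.ndarray:
    """Per-cell (2 x 4) mean correct-trial reaction times for one subject."""
    df = _subject_columns(trials)
    if retained_only:
        df = df.iloc[reject_trials(df)]
    else:
        df = df[df["correct"].astype(bool)]
    out = np.full((2, 4), np.nan)
    for i, c in enumerate(("cued", "uncued")):
        for j, d in enumerate(("D1", "D2", "D3", "D4")):
            sel = (df["cue_presence"] == c) & (df["distractor_level"] == d)
            if sel.any():
                out[i, j] = df.loc[sel, "rt_ms"].mean()
    return out


def distractor_cost(cohort_trials: list[pd.DataFrame]) -> np.ndarray:
    """Per-subject RT(high-similarity) - RT(low-similarity) on retained uncued trials (ms).

    Cued trials in the input are ignored.  Subjects with an empty pooled cell
    yield NaN with a warning.
    """
    costs = []
    for s, trials in enumerate(cohort_trials):
        df = _subject_columns(trials)
        df = df.iloc[reject_trials(df)]
        df = df[df["cue_presence"] == "uncued"]
        pool = pool_similarity(df["distractor_level"]) if len(df) else np.array([])
        hi = df.loc[pool == "high", "rt_ms"].to_numpy() if len(df) else np.array([])
        lo = df.loc[pool == "low", "rt_ms"].to_numpy() if len(df) else np.array([])
        if hi.size == 0 or lo.size == 0:
            warnings.warn(f"subject {s}: empty pooled cell, cost undefined")
            costs.append(np.nan)
        else:
            costs.append(hi.mean() - lo.mean())
    return np.array(costs)
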
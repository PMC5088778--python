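"""Configuration-driven end-to-end analysis of a (synthetic) cohort.

The suite mirrors the full set of condition contrasts of the cued
visual-search design: pretarget alpha lateralization for informative and
uninformative cues and their interaction; post-target alpha lateralization
per cue x pooled-similarity condition; and the midfrontal theta contrast
between high- and low-similarity distractors within each cue condition.
Alpha contrasts compare hemisphere flip-and-pooled power against its mirror
image (ipsilateral vs contralateral); theta contrasts pool left- and
right-target trials without flipping.  Cluster-based permutation tests
provide the inference; the lateralization index taken from the uncued
low-similarity cluster feeds the brain-behavior rank correlation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _version
from .behavior import (
    CHANCE_3AFC,
    cell_rt_means,
    distractor_cost,
    exclude_subjects,
    pairwise_bonferroni,
    pool_similarity,
    reject_trials,
    rm_anova_2x4,
    t_vs_chance,
)
from .cluster import permutation_test
from .lateralization import (
    flip_pool,
    lateralization_difference,
    lateralization_index,
    mirror_channels,
    selection_mask,
    spearman_corr,
)
from .layout import POSTERIOR, build_layout
from .simulate import SimulationParams, cue_presence, iter_cohort
from .tfr import TFRConfig, band_average, baseline_relative, compute_power

__all__ = [
    "AnalysisConfig",
    "subject_summary",
    "run_contrast_suite",
    "lateralization_correlation",
]

ALPHA_CELLS = ("cued", "uncued", "cued_high", "cued_low", "uncued_high", "uncued_low")
THETA_CELLS = ("cued_high", "cued_low", "uncued_high", "uncued_low")


@dataclass
class AnalysisConfig:
    """All tunable settings of the contrast suite.

    The alpha baseline is the 400 ms window ending 100 ms before the earliest
    possible cue onset (cue onset falls 1400-1700 ms before the target, so
    the baseline spans -2.2 to -1.8 s); the theta baseline is pretarget
    (-0.7 to -0.3 s) because the longer 3-cycle theta windows would leak cue
    or post-target activity into a precue baseline.
    """

    sim: SimulationParams = field(default_factory=SimulationParams)
    alpha_band: tuple[float, float] = (8.0, 12.0)
    theta_band: tuple[float, float] = (4.0, 6.0)
    alpha_freqs: np.ndarray = field(default_factory=lambda: np.arange(8.0, 13.0))
    theta_freqs: np.ndarray = field(default_factory=lambda: np.arange(4.0, 7.0))
    time_step: float = 0.05
    alpha_baseline: tuple[float, float] = (-2.2, -1.8)
    theta_baseline: tuple[float, float] = (-0.7, -0.3)
    pretarget_window: tuple[float, float] = (-1.5, 0.0)
    interaction_window: tuple[float, float] = (-1.05, 0.0)
    post_window: tuple[float, float] = (0.0, 1.5)
    n_perm: int = 1000
    alpha_level: float = 0.05
    index_selection: str = "cluster"  # 'cluster' or 'fixed'
    fixed_index_window: tuple[float, float] = (0.5, 0.9)
    seed: int | None = None

    def fingerprint(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["alpha_windows"] = {
            f"{c}/{p}": list(map(list, w)) for (c, p), w in d["sim"]["alpha_windows"].items()
        }
        d["sim"]["rt_cell_means"] = {
            f"{c}/{l}": v for (c, l), v in d["sim"]["rt_cell_means"].items()
        }
        d["alpha_freqs"] = list(self.alpha_freqs)
        d["theta_freqs"] = list(self.theta_freqs)
        d["version"] = _version
        return d


def _cell_masks(trials: pd.DataFrame) -> dict[str, np.ndarray]:
    cp = cue_presence(trials["cue"]).to_numpy()
    pool = pool_similarity(trials["distractor_level"])
    masks = {"cued": cp == "cued", "uncued": cp == "uncued"}
    for c in ("cued", "uncued"):
        for p in ("high", "low"):
            masks[f"{c}_{p}"] = (cp == c) & (pool == p)
    return masks


def subject_summary(epochs, behavior: pd.DataFrame, cfg: AnalysisConfig) -> dict:
    """Reduce one subject to per-condition average power maps and behavior.

    Pipeline per subject: trial rejection -> per-trial TFR -> baseline-
    relative normalization (per cue x pooled-similarity unit) -> band
    average -> hemisphere flip-and-pool (alpha only) -> condition means.
    """
    trials = epochs.trials.copy()
    for col in ("rt_ms", "correct", "eye_movement"):
        trials[col] = np.asarray(behavior[col])
    keep = reject_trials(trials)
    sub = trials.iloc[keep].reset_index(drop=True)
    view = dataclasses.replace(epochs, data=epochs.data[keep], trials=sub)

    cp = cue_presence(sub["cue"]).to_numpy()
    pool = pool_similarity(sub["distractor_level"])
    group_labels = pd.factorize(pd.Series(cp) + "/" + pd.Series(pool))[0]
    masks = _cell_masks(sub)

    out: dict = {"subject_id": epochs.subject_id, "trials": trials}

    raw_a = compute_power(
        view,
        TFRConfig(freqs=cfg.alpha_freqs, time_step=cfg.time_step),
        time_range=(cfg.alpha_baseline[0], cfg.post_window[1]),
    )
    rel_a = baseline_relative(raw_a, cfg.alpha_baseline, groups=group_labels)
    band_a = band_average(rel_a, cfg.alpha_band)
    lat = flip_pool(band_a.values, sub["target_side"].to_numpy(), epochs.layout)
    out["alpha_times"] = band_a.times
    out["alpha_lat"] = {c: lat[masks[c]].mean(axis=0) for c in ALPHA_CELLS}

    raw_t = compute_power(
        view,
        TFRConfig(freqs=cfg.theta_freqs, time_step=cfg.time_step),
        time_range=(cfg.theta_baseline[0], cfg.post_window[1]),
    )
    rel_t = baseline_relative(raw_t, cfg.theta_baseline, groups=group_labels)
    band_t = band_average(rel_t, cfg.theta_band)
    out["theta_times"] = band_t.times
    out["theta"] = {c: band_t.values[masks[c]].mean(axis=0) for c in THETA_CELLS}
    return out


def _crop(maps: np.ndarray, times: np.ndarray, window) -> tuple[np.ndarray, np.ndarray]:
    sel = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    sel &= np.isfinite(maps).all(axis=(0, 1))
    return maps[..., sel], times[sel]


def _serialize_result(res, times, layout, alpha_level) -> dict:
    clusters = []
    for c in res.clusters:
        clusters.append(
            {
                "sign": c.sign,
                "mass": c.mass,
                "p": c.p_mc,
                "tmin_ms": float(times[c.time_indices.min()] * 1000),
                "tmax_ms": float(times[c.time_indices.max()] * 1000),
                "channels": [layout.names[i] for i in c.channels],
                "n_points": int(len(c.points)),
            }
        )
    sig = res.significant(alpha_level)
    return {
        "clusters": clusters,
        "n_perm": res.n_perm,
        "threshold_t": res.threshold_t,
        "significant": bool(sig),
        "significant_windows_ms": [
            [float(times[c.time_indices.min()] * 1000), float(times[c.time_indices.max()] * 1000)]
            for c in sig
        ],
        "min_p": res.min_p,
    }


def lateralization_correlation(
    params: SimulationParams,
    seed: int | None = None,
    window: tuple[float, float] = (0.5, 0.9),
    alpha_band: tuple[float, float] = (8.0, 12.0),
    baseline: tuple[float, float] = (-2.2, -1.8),
    time_step: float = 0.05,
):
    """Rank correlation of distractor cost with the lateralization difference.

    A reduced analysis restricted to uninformatively cued trials: per subject,
    the alpha lateralization index over the fixed uncued/low-similarity
    selection (ipsilateral posterior channels, ``window`` seconds post-target)
    is computed for high- and low-similarity trials, and the per-subject
    difference (high minus low) is correlated with the reaction-time
    distractor cost using Spearman's rank correlation.  Used when the full
    cluster pipeline is unnecessary, e.g. for correlation studies across many
    simulated cohorts.
    """
    layout = build_layout(params.n_channels)
    freqs = np.arange(np.floor(alpha_band[0]), np.floor(alpha_band[1]) + 1)
    idx_low, idx_high, tables = [], [], []
    for epochs, behavior in iter_cohort(params, seed):
        trials = epochs.trials.copy()
        for col in ("rt_ms", "correct", "eye_movement"):
            trials[col] = np.asarray(behavior[col])
        tables.append(trials)
        keep = reject_trials(trials)
        sub = trials.iloc[keep].reset_index(drop=True)
        uncued = (cue_presence(sub["cue"]) == "uncued").to_numpy()
        view = dataclasses.replace(
            epochs, data=epochs.data[keep][uncued], trials=sub[uncued].reset_index(drop=True)
        )
        pool = pool_similarity(view.trials["distractor_level"])
        raw = compute_power(
            view,
            TFRConfig(freqs=freqs, time_step=time_step),
            time_range=(baseline[0], window[1] + 0.3),
        )
        rel = baseline_relative(raw, baseline, groups=pd.factorize(pool)[0])
        band = band_average(rel, alpha_band)
        lat = flip_pool(band.values, view.trials["target_side"].to_numpy(), layout)
        ipsi_post = [n for n in layout.group(POSTERIOR) if layout.side(n) == "right"]
        mask = selection_mask(layout, band.times, ipsi_post, window)
        idx_low.append(lateralization_index(lat[pool == "low"].mean(axis=0), layout, mask))
        idx_high.append(lateralization_index(lat[pool == "high"].mean(axis=0), layout, mask))
    diff = lateralization_difference(idx_high, idx_low)
    cost = distractor_cost(tables)
    valid = np.isfinite(cost) & np.isfinite(diff)
    corr = spearman_corr(cost[valid], diff[valid])
    return corr, {
        "index_low": np.asarray(idx_low),
        "index_high": np.asarray(idx_high),
        "difference": diff,
        "cost_ms": cost,
    }


def run_contrast_suite(cfg: AnalysisConfig, cohort=None) -> dict:
    """Run the full contrast suite and return a machine-readable report.

    ``cohort`` may be an iterable of (EpochsDataset, behavior) pairs; when
    omitted, a synthetic cohort is simulated from ``cfg.sim`` with
    ``cfg.seed``.  Stages: simulate/load -> reject & exclude -> TFR ->
    baseline -> band average -> flip-and-pool -> cluster tests -> index ->
    rank correlation -> report.
    """
    if cohort is None:
        cohort = iter_cohort(cfg.sim, cfg.seed)
    summaries = [
        subject_summary(epochs, behavior, cfg) for epochs, behavior in cohort
    ]
    if not summaries:
        raise ValueError("empty cohort")
    layout = build_layout(cfg.sim.n_channels)

    trial_tables = [s["trials"] for s in summaries]
    exclusion = exclude_subjects(trial_tables)
    included = exclusion.index[exclusion["final_included"]].to_numpy()
    if included.size < 2:
        raise ValueError("fewer than two subjects survive exclusion")
    summaries_in = [summaries[i] for i in included]
    tables_in = [trial_tables[i] for i in included]

    a_times = summaries_in[0]["alpha_times"]
    t_times = summaries_in[0]["theta_times"]
    alpha_maps = {
        c: np.stack([s["alpha_lat"][c] for s in summaries_in]) for c in ALPHA_CELLS
    }
    theta_maps = {
        c: np.stack([s["theta"][c] for s in summaries_in]) for c in THETA_CELLS
    }

    rng = np.random.default_rng(
        None if cfg.seed is None else np.random.SeedSequence([int(cfg.seed), 0xC1]).generate_state(1)[0]
    )
    contrasts: dict[str, dict] = {}
    results: dict[str, object] = {}

    def lat_vs_mirror(name, cell, window):
        a, t = _crop(alpha_maps[cell], a_times, window)
        b = mirror_channels(a, layout, axis=1)
        res = permutation_test(
            a, b, layout.neighbors, n_perm=cfg.n_perm, alpha=cfg.alpha_level, seed=rng
        )
        results[name] = (res, t)
        contrasts[name] = _serialize_result(res, t, layout, cfg.alpha_level)

    lat_vs_mirror("alpha_pretarget_cued", "cued", cfg.pretarget_window)
    lat_vs_mirror("alpha_pretarget_uncued", "uncued", cfg.pretarget_window)

    a_c, t_i = _crop(alpha_maps["cued"], a_times, cfg.interaction_window)
    a_u, _ = _crop(alpha_maps["uncued"], a_times, cfg.interaction_window)
    d_c = a_c - mirror_channels(a_c, layout, axis=1)
    d_u = a_u - mirror_channels(a_u, layout, axis=1)
    res = permutation_test(
        d_c, d_u, layout.neighbors, n_perm=cfg.n_perm, alpha=cfg.alpha_level, seed=rng
    )
    results["alpha_pretarget_interaction"] = (res, t_i)
    contrasts["alpha_pretarget_interaction"] = _serialize_result(res, t_i, layout, cfg.alpha_level)

    for cell in ("cued_low", "cued_high", "uncued_low", "uncued_high"):
        lat_vs_mirror(f"alpha_post_{cell}", cell, cfg.post_window)

    for cue in ("uncued", "cued"):
        a, t = _crop(theta_maps[f"{cue}_high"], t_times, cfg.post_window)
        b, _ = _crop(theta_maps[f"{cue}_low"], t_times, cfg.post_window)
        res = permutation_test(
            a, b, layout.neighbors, n_perm=cfg.n_perm, alpha=cfg.alpha_level, seed=rng
        )
        name = f"theta_{cue}_high_vs_low"
        results[name] = (res, t)
        contrasts[name] = _serialize_result(res, t, layout, cfg.alpha_level)

    # Lateralization index: channel/time selection from the uncued/low
    # post-target cluster (ipsilateral side), falling back to the documented
    # fixed selection when no cluster is significant or when configured.
    post_maps = {c: _crop(alpha_maps[c], a_times, cfg.post_window) for c in
                 ("uncued_high", "uncued_low")}
    maps_low, post_times = post_maps["uncued_low"]
    maps_high, _ = post_maps["uncued_high"]
    sel_source = "fixed"
    mask = None
    if cfg.index_selection == "cluster":
        res_low, rt = results["alpha_post_uncued_low"]
        pos = [c for c in res_low.significant(cfg.alpha_level) if c.sign > 0]
        if pos:
            best = max(pos, key=lambda c: abs(c.mass))
            mask = np.zeros((layout.n_channels, post_times.size), dtype=bool)
            mask[best.points[:, 0], best.points[:, 1]] = True
            sel_source = "cluster"
    if mask is None:
        ipsi_post = [
            n for n in layout.group(POSTERIOR) if layout.side(n) == "right"
        ]
        mask = selection_mask(layout, post_times, ipsi_post, cfg.fixed_index_window)

    idx_low = lateralization_index(maps_low, layout, mask)
    idx_high = lateralization_index(maps_high, layout, mask)
    lat_diff = lateralization_difference(idx_high, idx_low)
    cost = distractor_cost(tables_in)
    valid = np.isfinite(cost) & np.isfinite(lat_diff)
    corr = spearman_corr(cost[valid], lat_diff[valid]) if valid.sum() >= 5 else None

    # Behavioral statistics over included subjects.
    cells = np.stack([cell_rt_means(t) for t in tables_in])
    anova = rm_anova_2x4(cells)
    benefit = cells[:, 1, :] - cells[:, 0, :]  # uncued minus cued, per level
    benefit_pairs = pairwise_bonferroni(benefit, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
    accs = []
    for t in tables_in:
        df = t.copy()
        df["cue_presence"] = cue_presence(df["cue"])
        acc_cells = [
            df.loc[(df["cue_presence"] == c) & (df["distractor_level"] == d), "correct"].mean()
            for c in ("cued", "uncued")
            for d in ("D1", "D2", "D3", "D4")
        ]
        accs.append(acc_cells)
    accs = np.asarray(accs)
    chance_tests = []
    for j in range(accs.shape[1]):
        ct = t_vs_chance(accs[:, j], CHANCE_3AFC)
        chance_tests.append(
            {"cell": j, "t": ct.t, "p_raw": ct.p,
             "p_corrected": min(1.0, ct.p * accs.shape[1]), "degenerate": ct.degenerate}
        )

    report = {
        "config": cfg.fingerprint(),
        "n_subjects": len(summaries),
        "n_included": int(included.size),
        "exclusion": exclusion.reset_index().to_dict(orient="records"),
        "contrasts": contrasts,
        "behavior": {
            "anova": anova.reset_index().to_dict(orient="records"),
            "cell_rt_means_ms": cells.mean(axis=0).tolist(),
            "cue_benefit_pairwise": benefit_pairs.to_dict(orient="records"),
            "chance_tests": chance_tests,
            "mean_accuracy": float(np.mean(accs)),
        },
        "lateralization": {
            "selection": sel_source,
            "index_low": idx_low.tolist(),
            "index_high": idx_high.tolist(),
            "difference": lat_diff.tolist(),
            "distractor_cost_ms": cost.tolist(),
        },
        "correlation": None
        if corr is None
        else {
            "rho": corr.rho, "p": corr.p,
            "rho_excl_outliers": corr.rho_excl, "p_excl_outliers": corr.p_excl,
            "outliers": corr.outliers.tolist(), "n": corr.n,
        },
    }
    return report
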
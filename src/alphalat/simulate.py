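"""Synthetic cohort generator for a cued visual-search EEG experiment.

The generator emulates the statistical structure of a 2 (spatial cue:
informative/uninformative) x 4 (distractor color similarity: D1 most similar
... D4 least similar) covert-attention task:

* a factorial, pseudorandomized trial schedule (864 trials at the default
  108 trials per cue x similarity cell);
* behavioral outcomes (log-normal reaction times built from the published
  cell means, Bernoulli accuracy and eye-movement flags);
* epoched oscillatory EEG: 1/f background noise plus a posterior ~10 Hz
  alpha rhythm whose amplitude is lower contralateral than ipsilateral to the
  target inside condition-specific time windows, and a midfrontal ~5 Hz theta
  burst (700-1250 ms post-target) on uninformatively cued high-similarity
  trials only.

Oscillations have random phase per trial (induced, not evoked, activity), so
their power survives per-trial time-frequency analysis while averaging to
approximately zero in the evoked response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import MIDFRONTAL, POSTERIOR, ChannelLayout, build_layout

__all__ = [
    "SimulationParams",
    "EpochsDataset",
    "generate_schedule",
    "simulate_behavior",
    "simulate_subject",
    "simulate_cohort",
    "iter_cohort",
]

LETTERS = ("A", "B", "C")
DISTRACTOR_LEVELS = ("D1", "D2", "D3", "D4")
CUE_PRESENCE = ("cued", "uncued")

# Per-cell mean reaction times (ms), reconstructed from the published
# marginal distractor means and per-level cue benefits assuming equal cell
# counts: cell = distractor mean -/+ benefit/2 for cued/uncued.
DEFAULT_RT_CELL_MEANS: dict[tuple[str, str], float] = {
    ("cued", "D1"): 830.30, ("cued", "D2"): 812.05,
    ("cued", "D3"): 777.85, ("cued", "D4"): 775.35,
    ("uncued", "D1"): 990.10, ("uncued", "D2"): 938.35,
    ("uncued", "D3"): 829.35, ("uncued", "D4"): 822.25,
}

# Alpha amplitude-asymmetry windows (s, relative to target onset) per
# cue-presence x pooled-similarity condition.  "high" pools D1+D2, "low"
# pools D3+D4.  Inside each window posterior alpha amplitude is scaled by
# (1 - a) contralateral and (1 + a) ipsilateral to the target.
DEFAULT_ALPHA_WINDOWS: dict[tuple[str, str], tuple[tuple[float, float], ...]] = {
    ("cued", "low"): ((-1.05, 0.0), (0.35, 0.50)),
    ("cued", "high"): ((-1.05, 0.0), (0.0, 0.15), (0.45, 0.75)),
    ("uncued", "low"): ((0.50, 0.90),),
    ("uncued", "high"): (),
}

DEFAULT_THETA_WINDOW = (0.70, 1.25)


@dataclass
class SimulationParams:
    """Parameters of the synthetic cohort.

    Behavioral defaults reproduce the published condition structure (RT cell
    means in ms, overall accuracy 0.879, eye-movement rate 0.071).  Signal
    amplitudes are in µV; they were calibrated once so that the full
    analysis pipeline at ``n_subjects=16`` recovers all and only the
    condition effects the generator injects.
    """

    n_subjects: int = 16
    trials_per_condition: int = 108
    srate: float = 256.0
    epoch_window: tuple[float, float] = (-2.4, 1.9)
    n_channels: int = 32

    alpha_freq: float = 10.0
    theta_freq: float = 5.0
    noise_exponent: float = 1.0
    noise_std: float = 10.0
    shared_noise_std: float = 2.0
    alpha_amp: float = 6.0
    alpha_asymmetry: float = 0.30
    theta_amp: float = 3.5
    ramp_s: float = 0.1
    alpha_windows: dict = field(default_factory=lambda: dict(DEFAULT_ALPHA_WINDOWS))
    theta_window: tuple[float, float] = DEFAULT_THETA_WINDOW

    rt_cell_means: dict = field(default_factory=lambda: dict(DEFAULT_RT_CELL_MEANS))
    rt_trial_sd: float = 180.0
    rt_subject_sd: float = 60.0
    accuracy: float = 0.879
    eye_move_rate: float = 0.071

    subject_jitter: float = 0.2
    distraction_coupling: float = 0.0

    def validate(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")
        if not (0.0 <= self.eye_move_rate <= 1.0):
            raise ValueError("eye_move_rate must lie in [0, 1]")
        if self.rt_trial_sd < 0 or any(m <= 0 for m in self.rt_cell_means.values()):
            raise ValueError("reaction-time means must be positive and SD non-negative")
        t0, t1 = self.epoch_window
        for windows in self.alpha_windows.values():
            for w0, w1 in windows:
                if w0 < t0 or w1 > t1 or w0 >= w1:
                    raise ValueError(f"alpha window ({w0}, {w1}) outside epoch {self.epoch_window}")
        w0, w1 = self.theta_window
        if w0 < t0 or w1 > t1 or w0 >= w1:
            raise ValueError(f"theta window {self.theta_window} outside epoch")
        if self.alpha_asymmetry < 0 or self.theta_amp < 0:
            raise ValueError("effect amplitudes must be non-negative")


@dataclass
class EpochsDataset:
    """Epoched voltage data: trials x channels x samples (µV)."""

    data: np.ndarray
    times: np.ndarray
    srate: float
    layout: ChannelLayout
    trials: pd.DataFrame
    subject_id: str = "S00"

    def __post_init__(self):
        if self.data.shape[-1] != self.times.size:
            raise ValueError("data sample axis does not match times")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contain non-finite values")
        dt = np.diff(self.times)
        if not np.all(dt > 0) or not np.allclose(dt, 1.0 / self.srate):
            raise ValueError("times must increase with spacing 1/srate")


def epoch_times(params: SimulationParams) -> np.ndarray:
    t0, t1 = params.epoch_window
    n = int(np.floor((t1 - t0) * params.srate + 1e-9)) + 1
    return t0 + np.arange(n) / params.srate


def cue_presence(cue: pd.Series) -> pd.Series:
    """Collapse the cue column {left,right,uninformative} to cued/uncued."""
    return pd.Series(
        np.where(cue.to_numpy() == "uninformative", "uncued", "cued"),
        index=cue.index,
    )


def generate_schedule(
    params: SimulationParams | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate a pseudorandomized factorial trial schedule.

    Every cue-presence x distractor-level cell receives
    ``trials_per_condition`` trials, balanced over target side and target
    letter (remainders assigned round-robin in a fixed order).  Trials are
    arranged in passes such that all distinct trial types occur before any
    type repeats.  The distractor letter always differs from the target
    letter, informative cues always point at the target side, and the target
    shape alternates every block of 48 trials.
    """
    params = params or SimulationParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    tpc = params.trials_per_condition
    combos = [(s, l) for s in ("left", "right") for l in LETTERS]
    base, rem = divmod(tpc, len(combos))
    if rem:
        warnings.warn(
            f"trials_per_condition={tpc} not divisible by 6; "
            "remainder assigned round-robin over side x letter",
            stacklevel=2,
        )
    remaining: dict[tuple, int] = {}
    types: list[tuple] = []
    for cp in CUE_PRESENCE:
        for d in DISTRACTOR_LEVELS:
            for i, (side, letter) in enumerate(combos):
                t = (cp, d, side, letter)
                types.append(t)
                remaining[t] = base + (1 if i < rem else 0)

    rows = []
    distr_counter = {t: 0 for t in types}
    while any(remaining.values()):
        pass_types = [t for t in types if remaining[t] > 0]
        order = rng.permutation(len(pass_types))
        for k in order:
            cp, d, side, letter = pass_types[k]
            remaining[(cp, d, side, letter)] -= 1
            others = [l for l in LETTERS if l != letter]
            dletter = others[distr_counter[(cp, d, side, letter)] % 2]
            distr_counter[(cp, d, side, letter)] += 1
            rows.append(
                {
                    "cue": side if cp == "cued" else "uninformative",
                    "distractor_level": d,
                    "target_side": side,
                    "target_letter": letter,
                    "distractor_letter": dletter,
                }
            )
    df = pd.DataFrame(rows)
    df["block"] = df.index // 48
    df["target_shape"] = np.where(df["block"] % 2 == 0, "diamond", "square")
    return df


def _lognormal_moments(mean: np.ndarray, sd: float) -> tuple[np.ndarray, float | np.ndarray]:
    """(mu, sigma) of a log-normal with the given mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def simulate_behavior(
    schedule: pd.DataFrame,
    params: SimulationParams | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    rt_offset: float = 0.0,
    distract_gain: float = 1.0,
) -> pd.DataFrame:
    """Draw per-trial behavior (RT, correctness, eye-movement flag).

    Reaction times are log-normal, moment-matched to the cell mean and the
    trial-level SD.  ``rt_offset`` shifts all cell means (between-subject
    variability); ``distract_gain`` scales each cell's deviation from its
    cue-level marginal mean (the distractor-similarity effect), which is the
    hook through which subject-level distractibility couples behavior to the
    injected lateralization effects.
    """
    params = params or SimulationParams()
    params.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    cp = cue_presence(schedule["cue"]).to_numpy()
    dl = schedule["distractor_level"].to_numpy()
    cue_means = {
        c: np.mean([params.rt_cell_means[(c, d)] for d in DISTRACTOR_LEVELS])
        for c in CUE_PRESENCE
    }
    means = np.array(
        [
            cue_means[c] + rt_offset + distract_gain * (params.rt_cell_means[(c, d)] - cue_means[c])
            for c, d in zip(cp, dl)
        ]
    )
    if np.any(means <= 0):
        raise ValueError("effective reaction-time means must be positive")
    if params.rt_trial_sd > 0:
        mu, sigma = _lognormal_moments(means, params.rt_trial_sd)
        rt = rng.lognormal(mu, sigma)
    else:
        rt = means.copy()
    correct = rng.random(len(schedule)) < params.accuracy
    eye = rng.random(len(schedule)) < params.eye_move_rate
    return pd.DataFrame(
        {"rt_ms": rt, "correct": correct, "eye_movement": eye}, index=schedule.index
    )


def _bump(times: np.ndarray, t0: float, t1: float, ramp: float) -> np.ndarray:
    """Smooth 0->1->0 envelope over [t0, t1] with raised-cosine ramps.

    Ramps of length ``ramp`` lie inside the window; if the window is shorter
    than two ramps, a full Hann envelope over the window is used instead.
    """
    env = np.zeros_like(times)
    width = t1 - t0
    if width <= 0:
        return env
    r = min(ramp, width / 2.0)
    inside = (times >= t0) & (times <= t1)
    t = times[inside]
    e = np.ones_like(t)
    up = t < t0 + r
    e[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - t0) / r))
    down = t > t1 - r
    e[down] = 0.5 * (1 - np.cos(np.pi * (t1 - t[down]) / r))
    env[inside] = e
    return env


def _pink_noise(rng: np.random.Generator, shape: tuple, srate: float, beta: float) -> np.ndarray:
    """1/f^beta noise over the last axis, unit standard deviation."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    if beta == 0:
        return white
    f = np.fft.rfftfreq(n, 1.0 / srate)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-beta / 2.0)
    colored = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n, axis=-1)
    sd = colored.std()
    return colored / sd if sd > 0 else colored


def simulate_subject(
    schedule: pd.DataFrame,
    layout: ChannelLayout,
    params: SimulationParams | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "S00",
    alpha_scale: float = 1.0,
    theta_scale: float = 1.0,
    uncued_low_scale: float = 1.0,
) -> EpochsDataset:
    """Simulate one subject's epoched EEG for the given trial schedule.

    Each trial is 1/f noise (per channel, plus a shared rank-1 spatial
    component) with a posterior alpha rhythm whose hemispheric asymmetry is
    switched on inside the trial condition's configured windows, and a
    midfrontal theta burst on uninformatively cued high-similarity trials.
    The ``*_scale`` arguments carry per-subject effect-size jitter.
    """
    params = params or SimulationParams()
    params.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    times = epoch_times(params)
    n_trials, n_ch, n_s = len(schedule), layout.n_channels, times.size

    data = params.noise_std * _pink_noise(
        rng, (n_trials, n_ch, n_s), params.srate, params.noise_exponent
    )
    if params.shared_noise_std > 0:
        pattern = rng.standard_normal(n_ch)
        pattern /= np.linalg.norm(pattern) / np.sqrt(n_ch)
        shared = _pink_noise(rng, (n_trials, n_s), params.srate, params.noise_exponent)
        data += params.shared_noise_std * pattern[None, :, None] * shared[:, None, :]

    cp = cue_presence(schedule["cue"]).to_numpy()
    pool = np.where(np.isin(schedule["distractor_level"], ("D1", "D2")), "high", "low")
    side = schedule["target_side"].to_numpy()

    post = layout.group(POSTERIOR)
    post_idx = np.array([layout.index(c) for c in post])
    post_sides = np.array([layout.side(c) for c in post])

    # Ongoing posterior alpha with condition-dependent amplitude asymmetry:
    # lower amplitude contralateral to the target, higher ipsilateral.
    phases = rng.uniform(0, 2 * np.pi, (n_trials, post_idx.size))
    carrier = np.sin(
        2 * np.pi * params.alpha_freq * times[None, None, :] + phases[:, :, None]
    )
    env = np.ones((n_trials, post_idx.size, n_s), dtype=float)
    for (c, p), windows in params.alpha_windows.items():
        scale = uncued_low_scale if (c, p) == ("uncued", "low") else 1.0
        a = params.alpha_asymmetry * alpha_scale * scale
        if a == 0 or not windows:
            continue
        sel = (cp == c) & (pool == p)
        if not sel.any():
            continue
        total = np.zeros(n_s)
        for w0, w1 in windows:
            total += _bump(times, w0, w1, params.ramp_s)
        total = np.clip(total, 0.0, 1.0)
        for tside in ("left", "right"):
            tsel = sel & (side == tside)
            if not tsel.any():
                continue
            ipsi = post_sides == tside
            contra = post_sides == ("right" if tside == "left" else "left")
            mod = np.zeros(post_idx.size)
            mod[ipsi] = a
            mod[contra] = -a
            env[np.ix_(tsel, np.arange(post_idx.size))] += (
                mod[None, :, None] * total[None, None, :]
            )
    env = np.clip(env, 0.0, None)
    data[:, post_idx, :] += params.alpha_amp * env * carrier

    # Midfrontal theta burst: uninformatively cued high-similarity trials only.
    amp_theta = params.theta_amp * theta_scale
    theta_sel = (cp == "uncued") & (pool == "high")
    if amp_theta > 0 and theta_sel.any():
        mid = layout.group(MIDFRONTAL)
        mid_idx = np.array([layout.index(c) for c in mid])
        burst = _bump(times, *params.theta_window, params.ramp_s)
        tphases = rng.uniform(0, 2 * np.pi, (int(theta_sel.sum()), mid_idx.size))
        theta = np.sin(
            2 * np.pi * params.theta_freq * times[None, None, :] + tphases[:, :, None]
        )
        data[np.ix_(theta_sel, mid_idx)] += amp_theta * burst[None, None, :] * theta

    return EpochsDataset(
        data=data.astype(np.float32),
        times=times,
        srate=params.srate,
        layout=layout,
        trials=schedule.reset_index(drop=True),
        subject_id=subject_id,
    )


def iter_cohort(params: SimulationParams | None = None, seed: int | None = None):
    """Yield ``(EpochsDataset, behavior DataFrame)`` per subject, lazily.

    Per-subject effect sizes are jittered (relative SD ``subject_jitter``)
    so between-subject variance exists.  When ``distraction_coupling`` > 0, a
    single subject-level distractibility latent scales both the behavioral
    distractor-similarity effect and the uncued/low-similarity alpha
    lateralization, coupling distractor cost to the lateralization index.
    Deterministic under a fixed seed.
    """
    params = params or SimulationParams()
    params.validate()
    layout = build_layout(params.n_channels)
    root = np.random.SeedSequence(seed)
    children = root.spawn(params.n_subjects)
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        z = rng.standard_normal(4)
        alpha_scale = max(0.0, 1.0 + params.subject_jitter * z[0])
        theta_scale = max(0.0, 1.0 + params.subject_jitter * z[1])
        rt_offset = params.rt_subject_sd * z[2]
        g = max(0.0, 1.0 + params.distraction_coupling * z[3])
        subject_id = f"S{s:02d}"
        schedule = generate_schedule(params, rng=rng)
        behavior = simulate_behavior(
            schedule, params, rng=rng, rt_offset=rt_offset, distract_gain=g
        )
        epochs = simulate_subject(
            schedule,
            layout,
            params,
            rng=rng,
            subject_id=subject_id,
            alpha_scale=alpha_scale,
            theta_scale=theta_scale,
            uncued_low_scale=g,
        )
        yield epochs, behavior


def simulate_cohort(
    params: SimulationParams | None = None, seed: int | None = None
) -> list[tuple[EpochsDataset, pd.DataFrame]]:
    """Simulate ``n_subjects`` independent subjects (see :func:`iter_cohort`)."""
    return list(iter_cohort(params, seed))
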
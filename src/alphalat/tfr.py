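"""Time-frequency power with adaptive Hann tapers and relative baselining.

Power at frequency ``f`` and time ``t`` is the squared magnitude of the
single-frequency discrete Fourier projection of a Hann-tapered segment of
length ``n_cycles / f`` centered on ``t``.  With the normalization used here
a unit-amplitude sinusoid at ``f`` yields power 1 (amplitude-squared units),
so raw values are in µV² when the input is in µV.  Any fixed normalization
constant cancels in the baseline-relative quantities used downstream.

Time points whose window would overrun the epoch are marked undefined (NaN)
and excluded from all downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TFRConfig", "PowerMap", "compute_power", "baseline_relative", "band_average"]


@dataclass
class TFRConfig:
    """Configuration of the sliding-window decomposition.

    ``n_cycles / f`` sets the window length at each frequency (default three
    cycles, the maximum temporal resolution the method affords); window
    lengths are rounded to the nearest odd sample count so windows are
    symmetric around exact time stamps.
    """

    freqs: np.ndarray = field(default_factory=lambda: np.arange(2.0, 31.0, 1.0))
    n_cycles: float = 3.0
    time_step: float = 0.05
    taper: str = "hann"

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(self.freqs <= 0):
            raise ValueError("frequencies must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if self.taper != "hann":
            raise ValueError("only the Hann taper is supported")


@dataclass
class PowerMap:
    """Power indexed by trial x channel x frequency x time.

    ``values`` has shape (trials, channels, freqs, times) for per-frequency
    maps, or (trials, channels, times) after band averaging (``band`` set).
    Undefined edge points are NaN.  ``kind`` is 'raw' (µV²-scale) or
    'relative' (dimensionless change from baseline, >= -1).
    """

    values: np.ndarray
    times: np.ndarray
    freqs: np.ndarray | None
    kind: str = "raw"
    band: tuple[float, float] | None = None
    ch_names: tuple[str, ...] | None = None

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of defined points, matching ``values`` without the trial axis."""
        return np.isfinite(self.values).all(axis=0)


def _window_samples(freq: float, n_cycles: float, srate: float) -> int:
    """Window length in samples, rounded to the nearest odd count."""
    n = int(round(n_cycles / freq * srate))
    if n % 2 == 0:
        n += 1 if (n_cycles / freq * srate) >= n else -1
    return max(n, 3)


def compute_power(epochs, cfg: TFRConfig | None = None, time_range=None) -> PowerMap:
    """Per-trial TFR power of an :class:`~alphalat.simulate.EpochsDataset`.

    Parameters
    ----------
    epochs
        Dataset with ``data`` (trials x channels x samples), ``times`` and
        ``srate``.
    cfg
        Decomposition settings.
    time_range
        Optional (tmin, tmax) restriction of the output time grid, used to
        avoid computing power outside the windows of interest.
    """
    cfg = cfg or TFRConfig()
    data = np.asarray(epochs.data, dtype=np.float64)
    times = np.asarray(epochs.times)
    srate = float(epochs.srate)
    n_trials, n_ch, n_s = data.shape

    step = max(1, int(round(cfg.time_step * srate)))
    centers = np.arange(0, n_s, step)
    if time_range is not None:
        t0, t1 = time_range
        keep = (times[centers] >= t0 - 1e-9) & (times[centers] <= t1 + 1e-9)
        centers = centers[keep]
    out_times = times[centers]
    n_tp = centers.size

    if np.all(cfg.n_cycles / cfg.freqs * srate > n_s):
        raise ValueError("epoch too short for a full window at any frequency")

    values = np.full((n_trials, n_ch, cfg.freqs.size, n_tp), np.nan)
    flat = data.reshape(n_trials * n_ch, n_s)
    for fi, f in enumerate(cfg.freqs):
        L = _window_samples(f, cfg.n_cycles, srate)
        if L > n_s:
            warnings.warn(f"window for {f:g} Hz exceeds the epoch; frequency masked")
            continue
        half = L // 2
        ok = (centers >= half) & (centers <= n_s - 1 - half)
        if not ok.any():
            warnings.warn(f"no interior time points for {f:g} Hz; frequency masked")
            continue
        cc = centers[ok]
        w = np.hanning(L)
        phase = 2 * np.pi * f * np.arange(-half, half + 1) / srate
        kern = np.stack([w * np.cos(phase), w * np.sin(phase)], axis=1)  # (L, 2)
        norm = (2.0 / w.sum()) ** 2
        # Kernel bank: one (cos, sin) column pair per output time point,
        # placed at its window position; the projection of every
        # trial x channel row onto every window is then a single GEMM.
        bank = np.zeros((n_s, 2 * cc.size))
        for j, c in enumerate(cc):
            bank[c - half : c + half + 1, 2 * j : 2 * j + 2] = kern
        proj = flat @ bank  # (N, 2*tp)
        power = norm * (proj[:, 0::2] ** 2 + proj[:, 1::2] ** 2)
        values[:, :, fi, :][:, :, ok] = power.reshape(n_trials, n_ch, cc.size)

    return PowerMap(
        values=values,
        times=out_times,
        freqs=cfg.freqs.copy(),
        kind="raw",
        ch_names=tuple(epochs.layout.names) if getattr(epochs, "layout", None) else None,
    )


def baseline_relative(
    power: PowerMap,
    baseline_window: tuple[float, float],
    groups: np.ndarray | None = None,
) -> PowerMap:
    """Relative change from baseline: (power - baseline) / baseline.

    The baseline is the mean raw power over the baseline time points and over
    the trials of each normalization unit (``groups`` labels trials, e.g. by
    subject x condition; ``None`` pools all trials), computed per channel and
    frequency before the division, which keeps the normalization stable for
    low-power trials.
    """
    if power.kind != "raw":
        raise ValueError("baseline_relative expects raw power")
    b0, b1 = baseline_window
    sel = (power.times >= b0 - 1e-9) & (power.times <= b1 + 1e-9)
    if not sel.any():
        raise ValueError("baseline window contains no time points")
    base_vals = power.values[..., sel]
    if np.isnan(base_vals).any():
        raise ValueError("baseline window overlaps undefined edge points")

    values = np.empty_like(power.values)
    if groups is None:
        groups = np.zeros(power.values.shape[0], dtype=int)
    groups = np.asarray(groups)
    for g in np.unique(groups):
        m = groups == g
        base = base_vals[m].mean(axis=(0, -1), keepdims=True)  # (1, ch, [freq], 1)
        if np.any(base <= 0):
            raise ValueError("zero baseline power; cannot normalize")
        values[m] = power.values[m] / base - 1.0
    return PowerMap(
        values=values,
        times=power.times,
        freqs=None if power.freqs is None else power.freqs.copy(),
        kind="relative",
        band=power.band,
        ch_names=power.ch_names,
    )


def band_average(power: PowerMap, band: tuple[float, float]) -> PowerMap:
    """Unweighted mean over the grid frequencies inside the closed band.

    NaN edge points propagate: a band time point is defined only where all
    member frequencies are defined.
    """
    if power.freqs is None:
        raise ValueError("power map is already band-collapsed")
    lo, hi = band
    sel = (power.freqs >= lo - 1e-9) & (power.freqs <= hi + 1e-9)
    if not sel.any():
        raise ValueError(f"band {band} does not intersect the frequency grid")
    return PowerMap(
        values=power.values[:, :, sel, :].mean(axis=2),
        times=power.times,
        freqs=None,
        kind=power.kind,
        band=(float(lo), float(hi)),
        ch_names=power.ch_names,
    )
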
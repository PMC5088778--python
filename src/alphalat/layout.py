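"""Synthetic 10/20-style sensor layouts with mirror pairing and neighbourhoods.

The layouts built here are schematic: sensor names follow the international
10/20 extension, positions are 2-D projections on a unit head radius, and the
left/right mirror pairing is exact by construction.  They exist so that
hemisphere flip-and-pool and spatial clustering are well defined on simulated
data; no claim is made about physical electrode coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelLayout", "build_layout", "POSTERIOR", "MIDFRONTAL"]

# Schematic scalp positions (x: left negative, y: anterior positive), unit
# head radius.  Rows roughly follow the 10/20 anterior-posterior bands.
_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.30, 0.90), "Fp2": (0.30, 0.90),
    "F7": (-0.80, 0.55), "F8": (0.80, 0.55),
    "F3": (-0.40, 0.55), "F4": (0.40, 0.55), "Fz": (0.0, 0.55),
    "FC5": (-0.65, 0.28), "FC6": (0.65, 0.28),
    "FC1": (-0.25, 0.28), "FC2": (0.25, 0.28), "FCz": (0.0, 0.28),
    "T7": (-0.90, 0.0), "T8": (0.90, 0.0),
    "C3": (-0.45, 0.0), "C4": (0.45, 0.0), "Cz": (0.0, 0.0),
    "CP5": (-0.65, -0.28), "CP6": (0.65, -0.28),
    "CP1": (-0.25, -0.28), "CP2": (0.25, -0.28),
    "P7": (-0.80, -0.55), "P8": (0.80, -0.55),
    "P3": (-0.40, -0.55), "P4": (0.40, -0.55), "Pz": (0.0, -0.55),
    "PO7": (-0.55, -0.78), "PO8": (0.55, -0.78), "POz": (0.0, -0.78),
    "O1": (-0.25, -0.92), "O2": (0.25, -0.92), "Oz": (0.0, -0.92),
}

# Prefix-closed channel order: mirror pairs are adjacent, and every prefix of
# size >= 8 that does not split a pair contains both a posterior group and a
# midfrontal group.
_ORDER: tuple[str, ...] = (
    "O1", "O2", "PO7", "PO8", "FCz", "Fz", "Oz", "Pz",
    "P3", "P4", "P7", "P8", "C3", "C4", "Cz", "POz",
    "FC1", "FC2", "F3", "F4", "CP1", "CP2", "CP5", "CP6",
    "T7", "T8", "F7", "F8", "FC5", "FC6", "Fp1", "Fp2",
)

_MIRROR_LEFT_TO_RIGHT: dict[str, str] = {
    "Fp1": "Fp2", "F7": "F8", "F3": "F4", "FC5": "FC6", "FC1": "FC2",
    "T7": "T8", "C3": "C4", "CP5": "CP6", "CP1": "CP2",
    "P7": "P8", "P3": "P4", "PO7": "PO8", "O1": "O2",
}

_MIDLINE: frozenset[str] = frozenset({"Fz", "FCz", "Cz", "Pz", "POz", "Oz"})

#: Channel groups used for effect injection and reporting.  The source study
#: names no explicit sensor sets; these are the documented defaults.
POSTERIOR: tuple[str, ...] = (
    "O1", "O2", "Oz", "PO7", "PO8", "POz", "P3", "P4", "P7", "P8", "Pz",
)
MIDFRONTAL: tuple[str, ...] = ("FCz", "Fz", "Cz", "FC1", "FC2")


@dataclass(frozen=True)
class ChannelLayout:
    """A named sensor set with positions, mirror pairing and adjacency.

    Attributes
    ----------
    names
        Sensor labels, in layout order.
    positions
        ``(n, 2)`` array of schematic scalp coordinates (unit head radius).
    mirror_pairs
        Mapping left sensor -> right sensor; midline sensors are not listed.
    midline
        Sensors lying on the sagittal midline (self-mirroring).
    neighbors
        ``(n, n)`` boolean adjacency (symmetric, zero diagonal).
    """

    names: tuple[str, ...]
    positions: np.ndarray
    mirror_pairs: dict[str, str]
    midline: frozenset[str]
    neighbors: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self._index[name]

    def mirror(self, name: str) -> str:
        """Return the mirror counterpart of a sensor (itself on the midline)."""
        if name in self.midline:
            return name
        if name in self.mirror_pairs:
            return self.mirror_pairs[name]
        inv = {r: l for l, r in self.mirror_pairs.items()}
        if name in inv:
            return inv[name]
        raise KeyError(f"sensor {name!r} has no mirror counterpart")

    @property
    def flip_index(self) -> np.ndarray:
        """Permutation that swaps each sensor with its mirror counterpart."""
        return np.array([self._index[self.mirror(n)] for n in self.names])

    def side(self, name: str) -> str:
        """Hemisphere of a sensor: 'left', 'right' or 'midline'."""
        if name in self.midline:
            return "midline"
        return "left" if self.positions[self._index[name], 0] < 0 else "right"

    def group(self, candidates) -> list[str]:
        """Subset of ``candidates`` present in this layout, layout-ordered."""
        cset = set(candidates)
        return [n for n in self.names if n in cset]


def build_layout(n_channels: int = 32, neighbor_radius: float = 0.45) -> ChannelLayout:
    """Build a symmetric 10/20-style layout with ``n_channels`` sensors.

    Sensors are taken as a prefix of a fixed priority order in which mirror
    pairs are adjacent and posterior plus midfrontal sensors come first, so
    any valid size >= 8 supports the full analysis.  Adjacency connects
    sensors closer than ``neighbor_radius`` (unit head radius).

    Raises
    ------
    ValueError
        If ``n_channels`` is below 8, above the catalogue size, or would
        split a mirror pair.
    """
    if n_channels < 8:
        raise ValueError(
            "n_channels must be >= 8 to contain posterior and midfrontal groups"
        )
    if n_channels > len(_ORDER):
        raise ValueError(f"layout catalogue has only {len(_ORDER)} sensors")
    names = _ORDER[:n_channels]
    chosen = set(names)
    for left, right in _MIRROR_LEFT_TO_RIGHT.items():
        if (left in chosen) != (right in chosen):
            raise ValueError(
                f"n_channels={n_channels} splits the mirror pair ({left}, {right})"
            )
    positions = np.array([_POSITIONS[n] for n in names], dtype=float)
    pairs = {l: r for l, r in _MIRROR_LEFT_TO_RIGHT.items() if l in chosen}
    midline = frozenset(m for m in _MIDLINE if m in chosen)

    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    neighbors = (d <= neighbor_radius) & ~np.eye(n_channels, dtype=bool)
    if not neighbors.any(axis=1).all():
        lonely = [names[i] for i in np.flatnonzero(~neighbors.any(axis=1))]
        raise ValueError(f"sensors without neighbors at radius {neighbor_radius}: {lonely}")
    return ChannelLayout(
        names=names,
        positions=positions,
        mirror_pairs=pairs,
        midline=midline,
        neighbors=neighbors,
    )
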
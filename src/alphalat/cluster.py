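"""Spatio-temporal cluster-based permutation testing for paired designs.

Supra-threshold points of the paired t-map are grouped into connected,
same-sign clusters over the product graph of channel neighborhood and
temporal adjacency; each cluster's mass (sum of member t-values) is compared
against the permutation distribution of the maximum absolute cluster mass
obtained by flipping the sign of each subject's condition difference
(equivalent, for a paired design, to swapping that participant's condition
labels).  The resulting Monte Carlo p-values control the family-wise error
rate over channels and time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

__all__ = ["Cluster", "ClusterTestResult", "paired_tmap", "form_clusters", "permutation_test"]


@dataclass
class Cluster:
    """A connected set of supra-threshold (channel, time) points."""

    points: np.ndarray  # (k, 2) array of (channel, timepoint) indices
    sign: int
    mass: float
    p_mc: float | None = None

    @property
    def channels(self) -> np.ndarray:
        return np.unique(self.points[:, 0])

    @property
    def time_indices(self) -> np.ndarray:
        return np.unique(self.points[:, 1])


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    tmap: np.ndarray
    null_max: np.ndarray
    n_perm: int
    threshold_t: float
    exhaustive: bool = False
    alpha: float = 0.05

    def significant(self, alpha: float | None = None) -> list[Cluster]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p_mc is not None and c.p_mc < a]

    @property
    def min_p(self) -> float:
        ps = [c.p_mc for c in self.clusters if c.p_mc is not None]
        return min(ps) if ps else 1.0


def paired_tmap(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Point-wise dependent-samples t of ``a - b`` across the subject axis.

    Zero-variance points yield ±inf with the sign of the mean difference
    (0 where the mean difference is also zero), so they count as
    supra-threshold in cluster formation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("conditions must share subjects and shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    d = a - b
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    zero_var = sd == 0
    t[zero_var] = np.sign(m[zero_var]) * np.inf
    t[zero_var & (m == 0)] = 0.0
    return t


def _product_adjacency(n_ch: int, n_tp: int, neighbors: np.ndarray) -> sp.csr_matrix:
    """Sparse adjacency of the channel x time product graph.

    (c, t) ~ (c, t±1), and (c, t) ~ (c', t) for neighboring channels c, c'.
    """
    neighbors = np.asarray(neighbors, dtype=bool)
    if neighbors.shape != (n_ch, n_ch):
        raise ValueError("neighbor matrix does not match channel count")
    if np.any(neighbors != neighbors.T) or np.any(np.diag(neighbors)):
        raise ValueError("neighbor matrix must be symmetric and irreflexive")
    rows, cols = [], []
    node = np.arange(n_ch * n_tp).reshape(n_ch, n_tp)
    if n_tp > 1:
        rows.append(node[:, :-1].ravel())
        cols.append(node[:, 1:].ravel())
    ci, cj = np.nonzero(np.triu(neighbors, 1))
    if ci.size:
        rows.append((node[ci] ).ravel())
        cols.append((node[cj] ).ravel())
    if not rows:
        return sp.csr_matrix((n_ch * n_tp, n_ch * n_tp))
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    m = sp.coo_matrix(
        (np.ones(r.size * 2, dtype=np.int8), (np.r_[r, c], np.r_[c, r])),
        shape=(n_ch * n_tp, n_ch * n_tp),
    )
    return m.tocsr()


def _masked_components(mask_flat: np.ndarray, adj: sp.csr_matrix) -> list[np.ndarray]:
    """Connected components of the sub-graph induced by ``mask_flat``."""
    idx = np.flatnonzero(mask_flat)
    if idx.size == 0:
        return []
    if idx.size == 1:
        return [idx]
    sub = adj[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    return [idx[labels == k] for k in range(n_comp)]


def form_clusters(
    tmap: np.ndarray, threshold_t: float, neighbors: np.ndarray, adj: sp.csr_matrix | None = None
) -> list[Cluster]:
    """Group same-sign supra-threshold points into connected clusters.

    Returns clusters sorted by decreasing absolute mass; the empty list when
    no point exceeds the threshold.
    """
    if threshold_t <= 0:
        raise ValueError("threshold_t must be positive")
    tmap = np.asarray(tmap, dtype=float)
    n_ch, n_tp = tmap.shape
    if adj is None:
        adj = _product_adjacency(n_ch, n_tp, neighbors)
    flat = tmap.ravel()
    clusters: list[Cluster] = []
    for sign, mask in ((1, flat > threshold_t), (-1, flat < -threshold_t)):
        for comp in _masked_components(mask, adj):
            pts = np.column_stack(np.unravel_index(comp, (n_ch, n_tp)))
            clusters.append(Cluster(points=pts, sign=sign, mass=float(flat[comp].sum())))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def _max_cluster_mass(t_flat: np.ndarray, threshold: float, adj: sp.csr_matrix) -> float:
    best = 0.0
    for sign, mask in ((1, t_flat > threshold), (-1, t_flat < -threshold)):
        for comp in _masked_components(mask, adj):
            best = max(best, abs(float(t_flat[comp].sum())))
    return best


def _all_sign_flips(n: int) -> np.ndarray:
    bits = np.arange(2**n, dtype=np.uint32)
    return 1 - 2 * ((bits[:, None] >> np.arange(n)[None, :]) & 1).astype(np.int8)


def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    neighbors: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
    threshold_t: float | None = None,
    method: str = "auto",
) -> ClusterTestResult:
    """Cluster-mass permutation test of paired conditions ``a`` vs ``b``.

    ``a`` and ``b`` are (subjects, channels, timepoints); the cluster-forming
    threshold defaults to the two-sided pointwise p < 0.05 paired-t critical
    value at ``n - 1`` degrees of freedom.  The null distribution is built
    from random sign flips of subject differences (exhaustive enumeration of
    all 2^n flips whenever 2^n <= n_perm; ``method`` forces 'exhaustive' or
    'monte-carlo' instead of this 'auto' rule); Monte Carlo p-values carry a +1
    correction for validity at finite permutation counts, while exhaustive
    p-values are exact.  ``seed`` may be an int or a numpy Generator.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 3 or a.shape != b.shape:
        raise ValueError("expected matching (subjects, channels, timepoints) arrays")
    n, n_ch, n_tp = a.shape
    if n < 2:
        raise ValueError("need at least two subjects")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse Monte Carlo p-value")
    if threshold_t is None:
        threshold_t = float(t_dist.ppf(0.975, n - 1))

    adj = _product_adjacency(n_ch, n_tp, neighbors)
    tmap = paired_tmap(a, b)
    clusters = form_clusters(tmap, threshold_t, neighbors, adj=adj)

    d = (a - b).reshape(n, -1)
    if method == "auto":
        exhaustive = 2**n <= n_perm
    elif method in ("exhaustive", "monte-carlo"):
        exhaustive = method == "exhaustive"
    else:
        raise ValueError(f"unknown method {method!r}")
    if exhaustive:
        signs = _all_sign_flips(n)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        signs = rng.choice(np.array([-1, 1], dtype=np.int8), size=(n_perm, n))
    # Two-pass mean/variance per permutation (numerically stable, so the
    # identity flip reproduces the observed t-map and exhaustive p-values
    # are exact); chunked to bound memory.
    n_rows = signs.shape[0]
    null_max = np.empty(n_rows)
    chunk = max(1, int(2e7) // max(1, n * d.shape[1]))
    for i0 in range(0, n_rows, chunk):
        s = signs[i0 : i0 + chunk]
        x = s[:, :, None] * d[None, :, :]
        m = x.mean(axis=1)
        sd = x.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_chunk = m / (sd / np.sqrt(n))
        zero = sd == 0
        t_chunk[zero] = np.sign(m[zero]) * np.inf
        t_chunk[zero & (m == 0)] = 0.0
        for i in range(t_chunk.shape[0]):
            null_max[i0 + i] = _max_cluster_mass(t_chunk[i], threshold_t, adj)
    for cl in clusters:
        hits = int((null_max >= abs(cl.mass) * (1 - 1e-12) - 1e-12).sum())
        if exhaustive:
            cl.p_mc = hits / signs.shape[0]
        else:
            cl.p_mc = (hits + 1) / (signs.shape[0] + 1)
    return ClusterTestResult(
        clusters=clusters,
        tmap=tmap,
        null_max=null_max,
        n_perm=int(signs.shape[0]),
        threshold_t=threshold_t,
        exhaustive=exhaustive,
        alpha=alpha,
    )
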
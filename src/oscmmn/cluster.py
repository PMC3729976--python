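"""Nonparametric cluster-based permutation statistics over
channel × frequency × time maps.

Cells whose condition-contrast t statistic exceeds the two-tailed
critical value at the cluster-forming alpha are grouped into connected
clusters (adjacent latencies, adjacent frequency bins, neighboring
channels; positive and negative cells separately) and each cluster's t
values are summed.  The reference distribution is built by relabeling
the data (paired: within-subject condition sign flips; independent:
reshuffled group assignment) and recording, per relabeling, the maximum
cluster sum — giving family-wise control over the whole map.  Exact
enumeration replaces sampling when the number of distinct relabelings is
small.

The paired (within-subject) test is the default; the independent-samples
variant is available for designs with genuinely separate groups or for
literal replication of analyses that used it on within-subject data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "AdjacencyGraph",
    "Cluster",
    "ClusterResult",
    "build_adjacency",
    "cellwise_t",
    "form_clusters",
    "permutation_null",
    "band_test",
    "DEFAULT_BANDS",
]

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 50.0),
}

# within-channel cross connectivity over (frequency, latency)
_STRUCTURE = np.zeros((3, 3, 3), dtype=bool)
_STRUCTURE[1] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]


@dataclass
class AdjacencyGraph:
    """Channel neighbor pairs; frequency and time adjacency are implicit
    (consecutive bins / consecutive latencies)."""

    n_channels: int
    pairs: np.ndarray  # (n_pairs, 2) int, i < j

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if np.any(self.pairs[:, 0] == self.pairs[:, 1]):
            raise ValueError("self-edges are not allowed")

    def matrix(self) -> np.ndarray:
        m = np.zeros((self.n_channels, self.n_channels), dtype=bool)
        m[self.pairs[:, 0], self.pairs[:, 1]] = True
        return m | m.T

    def degrees(self) -> np.ndarray:
        return self.matrix().sum(axis=0)


def build_adjacency(positions: np.ndarray, scale: float = 1.3) -> AdjacencyGraph:
    """Neighbors = channel pairs closer than ``scale`` times the median
    nearest-neighbor distance of the layout.  Any channel that would be
    left isolated is linked to its nearest neighbor so every channel has
    at least one."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    thresh = scale * np.median(d.min(axis=1))
    adj = d <= thresh
    for i in np.flatnonzero(~adj.any(axis=1)):
        j = int(np.argmin(d[i]))
        adj[i, j] = adj[j, i] = True
    ii, jj = np.nonzero(np.triu(adj, 1))
    return AdjacencyGraph(n_channels=n, pairs=np.column_stack([ii, jj]))


@dataclass
class Cluster:
    cells: np.ndarray          # flat indices into the (ch, freq, lat) map
    summed_t: float
    sign: int                  # +1 or -1
    monte_carlo_p: float | None = None


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    mask: np.ndarray           # significant cells, (ch, freq, lat) bool
    n_permutations: int
    cluster_alpha: float
    final_alpha: float
    tail_mode: str
    df: int
    exact: bool = False
    null_max_pos: np.ndarray | None = None
    null_max_neg: np.ndarray | None = None

    @property
    def significant_clusters(self) -> list[Cluster]:
        thr = self.final_alpha / 2 if self.tail_mode == "two_tailed" else self.final_alpha
        return [c for c in self.clusters if c.monte_carlo_p is not None and c.monte_carlo_p < thr]


# ---------------------------------------------------------------------------
# t statistics
# ---------------------------------------------------------------------------

def cellwise_t(a: np.ndarray, b: np.ndarray, paired: bool = True) -> tuple[np.ndarray, int]:
    """Two-tailed t statistic per cell and its degrees of freedom.

    ``a``/``b`` are (subjects, ...) condition maps.  Cells with zero
    (pooled) variance get t = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test needs matching subject maps")
        n = a.shape[0]
        if n < 3:
            raise ValueError("need >= 3 pairs")
        d = a - b
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = d.mean(axis=0) / (sd / np.sqrt(n))
        t[sd == 0] = 0.0
        return t, n - 1
    na, nb = a.shape[0], b.shape[0]
    if min(na, nb) < 3:
        raise ValueError("need >= 3 subjects per group")
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    t[denom == 0] = 0.0
    return t, na + nb - 2


# ---------------------------------------------------------------------------
# cluster formation
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _components(mask: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Label connected components of a (ch, freq, lat) boolean mask with
    within-channel freq/time adjacency plus cross-channel links on the
    given neighbor pairs.  Returns an int label map (0 = background)."""
    labels, n_labels = ndimage.label(mask, structure=_STRUCTURE)
    if n_labels <= 1 or len(pairs) == 0:
        return labels
    active = mask.any(axis=(1, 2))
    uf = _UnionFind(n_labels + 1)
    for i, j in pairs:
        if not (active[i] and active[j]):
            continue
        both = mask[i] & mask[j]
        if both.any():
            for la, lb in zip(labels[i][both], labels[j][both]):
                uf.union(int(la), int(lb))
    remap = np.array([uf.find(k) for k in range(n_labels + 1)])
    return remap[labels]


def _cluster_sums(t_map: np.ndarray, mask: np.ndarray, pairs: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """Member flat-index arrays and summed t per cluster of ``mask``."""
    labels = _components(mask, pairs)
    flat = labels.ravel()
    present = np.unique(flat[flat > 0])
    cells = [np.flatnonzero(flat == lab) for lab in present]
    sums = np.array([t_map.ravel()[c].sum() for c in cells])
    return cells, sums


def _max_cluster_sums(t_map: np.ndarray, crit: float, pairs: np.ndarray) -> tuple[float, float]:
    """(max positive cluster sum, max |negative cluster sum|), 0 if none."""
    mpos = t_map > crit
    mneg = t_map < -crit
    best_pos = best_neg = 0.0
    if mpos.any():
        _, s = _cluster_sums(t_map, mpos, pairs)
        if s.size:
            best_pos = float(s.max())
    if mneg.any():
        _, s = _cluster_sums(t_map, mneg, pairs)
        if s.size:
            best_neg = float(-s.min())
    return best_pos, best_neg


def form_clusters(
    t_map: np.ndarray,
    adjacency: AdjacencyGraph,
    cluster_alpha: float,
    df: int,
) -> list[Cluster]:
    """Connected components of supra-threshold cells (|t| beyond the
    two-tailed critical value), positive and negative separately."""
    if not 0.0 < cluster_alpha < 1.0:
        raise ValueError("cluster_alpha must lie in (0, 1)")
    crit = stats.t.ppf(1.0 - cluster_alpha / 2.0, df)
    out: list[Cluster] = []
    for sign, mask in ((1, t_map > crit), (-1, t_map < -crit)):
        if not mask.any():
            continue
        cells, sums = _cluster_sums(t_map, mask, adjacency.pairs)
        out.extend(
            Cluster(cells=c, summed_t=float(s), sign=sign) for c, s in zip(cells, sums)
        )
    return out


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _paired_null(
    diffs: np.ndarray,  # (subjects, cells)
    shape: tuple[int, ...],
    crit: float,
    pairs: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, bool]:
    n = diffs.shape[0]
    exact = 2**n <= n_permutations
    if exact:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        signs = rng.choice([1.0, -1.0], size=(n_permutations, n))
    sumsq = np.sum(diffs**2, axis=0)
    max_pos = np.empty(len(signs))
    max_neg = np.empty(len(signs))
    chunk = max(1, int(2e7 // max(diffs.size, 1)))
    for start in range(0, len(signs), chunk):
        s = signs[start : start + chunk]
        mean = (s @ diffs) / n
        var = np.maximum(sumsq / n - mean**2, 0.0) * (n / (n - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n)
        t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
        for r in range(len(s)):
            mp, mn = _max_cluster_sums(t[r].reshape(shape), crit, pairs)
            max_pos[start + r] = mp
            max_neg[start + r] = mn
    return max_pos, max_neg, exact


def _independent_null(
    combined: np.ndarray,  # (n_a + n_b, cells)
    n_a: int,
    shape: tuple[int, ...],
    crit: float,
    pairs: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, bool]:
    from math import comb

    n_tot = combined.shape[0]
    n_b = n_tot - n_a
    exact = comb(n_tot, n_a) <= n_permutations
    if exact:
        assignments = [np.array(c) for c in itertools.combinations(range(n_tot), n_a)]
    else:
        assignments = [rng.permutation(n_tot)[:n_a] for _ in range(n_permutations)]
    tot_sum = combined.sum(axis=0)
    tot_ssq = np.sum(combined**2, axis=0)
    max_pos = np.empty(len(assignments))
    max_neg = np.empty(len(assignments))
    for r, idx in enumerate(assignments):
        ga = combined[idx]
        sa, qa = ga.sum(axis=0), np.sum(ga**2, axis=0)
        sb, qb = tot_sum - sa, tot_ssq - qa
        va = np.maximum(qa - sa**2 / n_a, 0.0) / (n_a - 1)
        vb = np.maximum(qb - sb**2 / n_b, 0.0) / (n_b - 1)
        sp = ((n_a - 1) * va + (n_b - 1) * vb) / (n_tot - 2)
        denom = np.sqrt(sp * (1.0 / n_a + 1.0 / n_b))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (sa / n_a - sb / n_b) / denom
        t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
        mp, mn = _max_cluster_sums(t.reshape(shape), crit, pairs)
        max_pos[r] = mp
        max_neg[r] = mn
    return max_pos, max_neg, exact


def permutation_null(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    adjacency: AdjacencyGraph,
    cluster_alpha: float = 0.01,
    n_permutations: int = 10000,
    paired: bool = True,
    seed: int | np.random.Generator = 0,
    final_alpha: float = 0.05,
    tail_mode: str = "two_tailed",
) -> ClusterResult:
    """Cluster permutation test of condition A vs condition B maps.

    ``maps_*`` are (subjects, channels, frequencies, latencies).  Each
    observed cluster's Monte-Carlo p is (count of relabeling maxima at
    least as large + 1) / (n_permutations + 1); with exact enumeration
    the plain proportion (which includes the identity relabeling) is
    used.  ``tail_mode='two_tailed'`` (default) compares positive and
    negative clusters to their own max distributions at final_alpha/2
    per tail; ``'literal'`` compares |summed t| to the pooled max-|sum|
    distribution at final_alpha.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if tail_mode not in ("two_tailed", "literal"):
        raise ValueError(f"unknown tail_mode {tail_mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    shape = a.shape[1:]
    t_obs, df = cellwise_t(a, b, paired=paired)
    crit = stats.t.ppf(1.0 - cluster_alpha / 2.0, df)
    clusters = form_clusters(t_obs, adjacency, cluster_alpha, df)

    if paired:
        diffs = (a - b).reshape(a.shape[0], -1)
        max_pos, max_neg, exact = _paired_null(
            diffs, shape, crit, adjacency.pairs, n_permutations, rng
        )
    else:
        combined = np.concatenate([a, b], axis=0).reshape(a.shape[0] + b.shape[0], -1)
        max_pos, max_neg, exact = _independent_null(
            combined, a.shape[0], shape, crit, adjacency.pairs, n_permutations, rng
        )

    n_eff = len(max_pos)
    pooled = np.maximum(max_pos, max_neg)
    for c in clusters:
        s = abs(c.summed_t)
        if tail_mode == "literal":
            ref = pooled
        else:
            ref = max_pos if c.sign > 0 else max_neg
        count = int(np.sum(ref >= s))
        c.monte_carlo_p = count / n_eff if exact else (count + 1) / (n_eff + 1)

    result = ClusterResult(
        clusters=clusters,
        mask=np.zeros(shape, dtype=bool),
        n_permutations=n_eff,
        cluster_alpha=cluster_alpha,
        final_alpha=final_alpha,
        tail_mode=tail_mode,
        df=df,
        exact=exact,
        null_max_pos=max_pos,
        null_max_neg=max_neg,
    )
    flat_mask = result.mask.ravel()
    for c in result.significant_clusters:
        flat_mask[c.cells] = True
    return result


def band_test(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    frequencies_hz: np.ndarray,
    adjacency: AdjacencyGraph,
    bands: dict[str, tuple[float, float]] | None = None,
    **kwargs,
) -> dict[str, ClusterResult]:
    """Averaged-frequency-band variant: average map cells over each
    band's bins (edges inclusive, so an edge frequency like 8 or 14 Hz
    belongs to both adjacent bands), then run the channel × time cluster
    permutation within each band."""
    bands = DEFAULT_BANDS if bands is None else bands
    freqs = np.asarray(frequencies_hz, dtype=float)
    out: dict[str, ClusterResult] = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise ValueError(f"band {name!r} ({lo}-{hi} Hz) covers no frequency bins")
        a = np.asarray(maps_a)[:, :, sel, :].mean(axis=2, keepdims=True)
        b = np.asarray(maps_b)[:, :, sel, :].mean(axis=2, keepdims=True)
        out[name] = permutation_null(a, b, adjacency, **kwargs)
    return out
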
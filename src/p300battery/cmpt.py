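"""Spatiotemporal cluster-mass permutation test (CMPT).

A pointwise t map over (electrode, time) is thresholded two-sidedly at the
t value with point-level p = 0.05 for the relevant degrees of freedom;
supra-threshold points of like sign are grouped into connected components
(same electrode at adjacent samples, or neighboring electrodes at the same
sample) and scored by their summed t ("mass").  Family-wise error is
controlled by comparing each observed mass against the permutation null of
the *maximum* |mass|:

* group level - paired condition ERPs per participant; the null randomly
  sign-flips each participant's difference map;
* single-participant level - two unbalanced epoch samples; the null
  randomly re-partitions the pooled epochs into groups of the original
  sizes.

Monte Carlo p-values use the (count + 1)/(n_perm + 1) estimator; tiny
instances can instead be enumerated exhaustively.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, product
from typing import Sequence

import numpy as np
from scipy import stats

from .recording import CHANNELS

__all__ = [
    "AdjacencyGraph",
    "Cluster",
    "CMPTResult",
    "montage_positions",
    "build_adjacency",
    "stat_map_group",
    "stat_map_single",
    "form_clusters",
    "permutation_test",
]

DEFAULT_ADJACENCY_THRESHOLD = 0.6  # normalized head-radius units


def montage_positions(channels: Sequence[str] = CHANNELS) -> dict[str, np.ndarray]:
    """3-D electrode positions on the standard 10-10 montage, scaled so the
    median scalp radius is 1."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = {k.upper(): v for k, v in montage.get_positions()["ch_pos"].items()}
    missing = [ch for ch in channels if ch.upper() not in pos]
    if missing:
        raise ValueError(f"montage lacks positions for {missing}")
    pts = np.array([pos[ch.upper()] for ch in channels])
    scale = np.median(np.linalg.norm(pts, axis=1))
    return {ch: pts[i] / scale for i, ch in enumerate(channels)}


@dataclass
class AdjacencyGraph:
    """Symmetric, irreflexive neighbor structure over the montage."""

    channels: tuple[str, ...]
    matrix: np.ndarray  # (n_ch, n_ch) bool
    threshold: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, bool)
        if m.shape != (len(self.channels),) * 2:
            raise ValueError("adjacency matrix shape mismatch")
        if not (m == m.T).all():
            raise ValueError("adjacency must be symmetric")
        if m.diagonal().any():
            raise ValueError("adjacency must be irreflexive")
        if not m.any(axis=1).all():
            isolated = [self.channels[i] for i in np.nonzero(~m.any(axis=1))[0]]
            raise ValueError(f"isolated electrodes {isolated}; raise the threshold")
        self.matrix = m

    def neighbors(self, channel: str) -> set[str]:
        i = self.channels.index(channel)
        return {self.channels[j] for j in np.nonzero(self.matrix[i])[0]}

    @property
    def neighbor_lists(self) -> list[np.ndarray]:
        return [np.nonzero(row)[0] for row in self.matrix]

    @property
    def channel_pairs(self) -> np.ndarray:
        """Unique adjacent (i, j) channel index pairs, i < j."""
        i, j = np.nonzero(np.triu(self.matrix, 1))
        return np.column_stack([i, j])


def build_adjacency(
    positions: dict[str, np.ndarray] | None = None,
    threshold: float = DEFAULT_ADJACENCY_THRESHOLD,
    channels: Sequence[str] = CHANNELS,
) -> AdjacencyGraph:
    """Neighbors are electrode pairs closer than ``threshold`` (normalized
    head-radius units) on the 10-10 montage."""
    positions = positions or montage_positions(channels)
    pts = np.array([positions[ch] for ch in channels])
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    m = (d < threshold) & ~np.eye(len(channels), dtype=bool)
    return AdjacencyGraph(tuple(channels), m, threshold)


def stat_map_group(erps_a: np.ndarray, erps_b: np.ndarray) -> np.ndarray:
    """Paired t map over participants; inputs are (n_subj, n_ch, n_times)."""
    a, b = np.asarray(erps_a, float), np.asarray(erps_b, float)
    if a.shape != b.shape:
        raise ValueError("paired conditions must have identical shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / math.sqrt(n))
    return np.nan_to_num(t)


def stat_map_single(epochs_a: np.ndarray, epochs_b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t map; inputs are (n_epochs, n_ch, n_times)."""
    a, b = np.asarray(epochs_a, float), np.asarray(epochs_b, float)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 epochs")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / (na + nb - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return np.nan_to_num(t)


@dataclass
class Cluster:
    """One spatiotemporal cluster: member points, mass, sign, and p."""

    channels_idx: np.ndarray
    times_idx: np.ndarray
    mass: float
    sign: int
    p_value: float = 1.0

    @property
    def onset(self) -> int:
        return int(self.times_idx.min())

    @property
    def size(self) -> int:
        return len(self.times_idx)

    def members(self) -> set[tuple[int, int]]:
        return set(zip(self.channels_idx.tolist(), self.times_idx.tolist()))


def _components(mask: np.ndarray, neighbor_lists: list[np.ndarray]):
    """Connected components of a (n_ch, n_times) boolean map under
    electrode-neighborhood x temporal-contiguity connectivity."""
    n_ch, n_t = mask.shape
    labels = np.full(mask.shape, -1, dtype=int)
    comps: list[tuple[np.ndarray, np.ndarray]] = []
    cs, ts = np.nonzero(mask)
    for c0, t0 in zip(cs, ts):
        if labels[c0, t0] >= 0:
            continue
        cid = len(comps)
        stack = [(c0, t0)]
        labels[c0, t0] = cid
        members_c, members_t = [c0], [t0]
        while stack:
            c, t = stack.pop()
            if t > 0 and mask[c, t - 1] and labels[c, t - 1] < 0:
                labels[c, t - 1] = cid
                stack.append((c, t - 1))
                members_c.append(c)
                members_t.append(t - 1)
            if t + 1 < n_t and mask[c, t + 1] and labels[c, t + 1] < 0:
                labels[c, t + 1] = cid
                stack.append((c, t + 1))
                members_c.append(c)
                members_t.append(t + 1)
            for cn in neighbor_lists[c]:
                if mask[cn, t] and labels[cn, t] < 0:
                    labels[cn, t] = cid
                    stack.append((cn, t))
                    members_c.append(cn)
                    members_t.append(t)
        comps.append((np.array(members_c), np.array(members_t)))
    return comps


def form_clusters(tmap: np.ndarray, threshold: float,
                  adjacency: AdjacencyGraph) -> list[Cluster]:
    """Supra-threshold clusters of each sign, sorted by |mass| (ties broken
    by earliest onset)."""
    if threshold <= 0:
        raise ValueError("cluster-forming threshold must be positive")
    nbrs = adjacency.neighbor_lists
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = tmap > threshold if sign == 1 else tmap < -threshold
        for cs, ts in _components(mask, nbrs):
            clusters.append(Cluster(cs, ts, float(tmap[cs, ts].sum()), sign))
    clusters.sort(key=lambda c: (-abs(c.mass), c.onset))
    return clusters


def _max_cluster_mass(tmap: np.ndarray, threshold: float,
                      adjacency: "AdjacencyGraph") -> float:
    """Maximum |mass| over clusters of either sign (0 if none).

    Vectorized connected components on the supra-threshold subgraph; used
    in the permutation inner loop where only the maximum matters.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n_ch, n_t = tmap.shape
    pairs = adjacency.channel_pairs
    flat = tmap.ravel()
    best = 0.0
    for sign in (1, -1):
        mask = tmap > threshold if sign == 1 else tmap < -threshold
        nodes = np.flatnonzero(mask.ravel())
        if nodes.size == 0:
            continue
        te_r, te_c = np.nonzero(mask[:, :-1] & mask[:, 1:])
        u_t = te_r * n_t + te_c
        se_p, se_c = np.nonzero(mask[pairs[:, 0]] & mask[pairs[:, 1]])
        u = np.concatenate([u_t, pairs[se_p, 0] * n_t + se_c])
        v = np.concatenate([u_t + 1, pairs[se_p, 1] * n_t + se_c])
        k = nodes.size
        graph = coo_matrix(
            (np.ones(u.size, np.int8),
             (np.searchsorted(nodes, u), np.searchsorted(nodes, v))),
            shape=(k, k))
        _, labels = connected_components(graph, directed=False)
        masses = np.bincount(labels, weights=flat[nodes])
        best = max(best, float(np.abs(masses).max()))
    return best


@dataclass
class CMPTResult:
    """Clusters (sorted by |mass|), their permutation p-values, and the
    selected region of the largest significant cluster."""

    clusters: list[Cluster]
    p_value: float
    n_perm: int
    threshold: float
    level: str
    alpha: float
    exact: bool = False
    null_max: np.ndarray | None = None

    @property
    def selected_region(self) -> tuple[np.ndarray, np.ndarray] | None:
        if self.clusters and self.clusters[0].p_value <= self.alpha:
            c = self.clusters[0]
            return c.channels_idx, c.times_idx
        return None

    def to_dict(self, channels: Sequence[str] = CHANNELS,
                times: np.ndarray | None = None) -> dict:
        def describe(c: Cluster) -> dict:
            d = {
                "mass": c.mass, "sign": c.sign, "p_value": c.p_value,
                "n_points": c.size,
                "channels": sorted({channels[i] for i in c.channels_idx}),
            }
            if times is not None:
                d["time_range_ms"] = [float(times[c.times_idx.min()] * 1e3),
                                      float(times[c.times_idx.max()] * 1e3)]
            return d

        return {
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "threshold": self.threshold,
            "level": self.level,
            "alpha": self.alpha,
            "exact": self.exact,
            "clusters": [describe(c) for c in self.clusters],
        }


def _null_max_single(x: np.ndarray, na: int, n_perm: int,
                     threshold: float, adjacency, rng,
                     map_shape: tuple[int, int], chunk: int = 200) -> np.ndarray:
    """Vectorized re-partition null for the two-sample t max-mass statistic.

    ``x`` is the pooled epoch stack flattened to (n_epochs, n_points);
    columns are mean-centered so float32 accumulation is stable.
    """
    e, p = x.shape
    nb = e - na
    xc = (x - x.mean(axis=0)).astype(np.float32)
    x2 = xc * xc
    tot1 = xc.sum(axis=0)
    tot2 = x2.sum(axis=0)
    df = e - 2
    scale = 1.0 / na + 1.0 / nb
    out = np.empty(n_perm, dtype=float)
    done = 0
    while done < n_perm:
        r = min(chunk, n_perm - done)
        mask = np.zeros((r, e), dtype=np.float32)
        for i in range(r):
            mask[i, rng.choice(e, size=na, replace=False)] = 1.0
        sa = mask @ xc
        sa2 = mask @ x2
        ma = sa / na
        mb = (tot1 - sa) / nb
        ssa = sa2 - sa * sa / na
        ssb = (tot2 - sa2) - (tot1 - sa) ** 2 / nb
        sp2 = (ssa + ssb) / df
        np.maximum(sp2, 1e-20, out=sp2)
        tmaps = (ma - mb) / np.sqrt(sp2 * scale)
        for i in range(r):
            out[done + i] = _max_cluster_mass(
                tmaps[i].reshape(map_shape), threshold, adjacency)
        done += r
    return out


def _null_max_group(d: np.ndarray, n_perm: int, threshold: float,
                    adjacency, rng, map_shape: tuple[int, int],
                    chunk: int = 250) -> np.ndarray:
    """Sign-flip null for the paired t max-mass statistic.

    ``d`` is the participant difference stack flattened to (n_subj, n_points).
    """
    s, p = d.shape
    ssq = (d * d).sum(axis=0)
    out = np.empty(n_perm, dtype=float)
    done = 0
    while done < n_perm:
        r = min(chunk, n_perm - done)
        signs = rng.integers(0, 2, size=(r, s)).astype(float) * 2 - 1
        mean = (signs @ d) / s
        var = (ssq - s * mean * mean) / (s - 1)
        np.maximum(var, 1e-30, out=var)
        tmaps = mean / np.sqrt(var / s)
        for i in range(r):
            out[done + i] = _max_cluster_mass(
                tmaps[i].reshape(map_shape), threshold, adjacency)
        done += r
    return out


def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    level: str = "single",
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    adjacency: AdjacencyGraph | None = None,
    threshold: float | None = None,
    alpha: float = 0.05,
    exact: bool | None = None,
) -> CMPTResult:
    """Cluster-mass permutation test between two conditions.

    ``level='group'`` expects paired per-participant condition ERPs
    (n_subj, n_ch, n_times) in ``a`` and ``b``; ``level='single'`` expects
    two (possibly unbalanced) epoch stacks.  ``threshold`` defaults to the
    two-sided p = 0.05 point-level t critical value at the test's degrees of
    freedom.  ``exact=True`` enumerates the full permutation space instead
    of sampling (p = count/total); ``exact=None`` enables this automatically
    when the space is no larger than ``n_perm``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if level not in ("group", "single"):
        raise ValueError(f"unknown level {level!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng)
    adjacency = adjacency or build_adjacency()
    map_shape = a.shape[1:]

    if level == "group":
        if a.shape != b.shape:
            raise ValueError("group level requires paired inputs of equal shape")
        n = a.shape[0]
        df = n - 1
        n_space = 2 ** n
    else:
        na, nb = a.shape[0], b.shape[0]
        df = na + nb - 2
        n_space = math.comb(na + nb, na)
    if threshold is None:
        threshold = float(stats.t.ppf(1 - alpha / 2, df))
    if n_space < int(1 / alpha):
        warnings.warn(
            f"only {n_space} distinct permutations; p cannot resolve below alpha={alpha}"
        )
    if exact is None:
        exact = n_space <= n_perm

    tmap = stat_map_group(a, b) if level == "group" else stat_map_single(a, b)
    clusters = form_clusters(tmap, threshold, adjacency)

    if not clusters:
        return CMPTResult([], 1.0, n_perm=0 if exact else n_perm,
                          threshold=threshold, level=level, alpha=alpha,
                          exact=exact)

    if level == "group":
        d = (a - b).reshape(a.shape[0], -1)
        if exact:
            null = np.empty(n_space)
            for i, signs in enumerate(product((1.0, -1.0), repeat=a.shape[0])):
                sd = d * np.array(signs)[:, None]
                t = _paired_t_flat(sd)
                null[i] = _max_cluster_mass(t.reshape(map_shape), threshold,
                                            adjacency)
        else:
            null = _null_max_group(d, n_perm, threshold, adjacency, rng,
                                   map_shape)
    else:
        x = np.concatenate([a, b]).reshape(a.shape[0] + b.shape[0], -1)
        na = a.shape[0]
        if exact:
            null = np.empty(n_space)
            e = x.shape[0]
            for i, pick in enumerate(combinations(range(e), na)):
                sel = np.zeros(e, bool)
                sel[list(pick)] = True
                t = stat_map_single(x[sel].reshape(-1, *map_shape),
                                    x[~sel].reshape(-1, *map_shape))
                null[i] = _max_cluster_mass(t, threshold, adjacency)
        else:
            null = _null_max_single(x, na, n_perm, threshold, adjacency,
                                    rng, map_shape)

    for c in clusters:
        count = int((null >= abs(c.mass) - 1e-12).sum())
        if exact:
            c.p_value = count / len(null)
        else:
            c.p_value = (count + 1) / (n_perm + 1)
    clusters.sort(key=lambda c: (-abs(c.mass), c.onset))
    return CMPTResult(clusters, clusters[0].p_value,
                      n_perm=len(null) if exact else n_perm,
                      threshold=threshold, level=level, alpha=alpha,
                      exact=exact, null_max=null)


def _paired_t_flat(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / math.sqrt(n))
    return np.nan_to_num(t)
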
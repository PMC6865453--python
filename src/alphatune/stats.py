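"""Behavioral quantification and nonparametric group statistics.

Covers the flanker effect (incongruent minus congruent RT, expressed as
Cohen's d), across-subject Spearman correlation maps linking tuning to
behavior, within-subject median-split tuning, and cluster-based Monte
Carlo permutation inference on time x offset maps with circular offset
adjacency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .encoding import AlignedTuning, BasisSet, DecodeResult, align_and_average

__all__ = [
    "FlankerEffect",
    "Cluster",
    "ClusterResult",
    "flanker_effect",
    "spearman_map",
    "cluster_permutation",
    "median_split_tuning",
]

# cross-shaped (no diagonal) adjacency within each leading slice of a stack
_STRUCTURE_3D = np.zeros((3, 3, 3), dtype=bool)
_STRUCTURE_3D[1] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]


@dataclass
class FlankerEffect:
    """Per-subject flanker cost: RT difference and its effect size."""

    delta_rt_ms: float
    cohens_d: float
    n_congruent: int
    n_incongruent: int


def flanker_effect(trials: pd.DataFrame) -> FlankerEffect:
    """Incongruent minus congruent mean RT, and Cohen's d (pooled SD).

    Only correct-response trials enter the RT summaries.  Raises if either
    congruency condition is absent.
    """
    ok = trials["correct"].fillna(False).astype(bool) & trials["rt_ms"].notna()
    df = trials[ok]
    con = df.loc[df["congruency"] == "congruent", "rt_ms"].to_numpy(dtype=float)
    inc = df.loc[df["congruency"] == "incongruent", "rt_ms"].to_numpy(dtype=float)
    if len(con) == 0 or len(inc) == 0:
        raise ValueError("both congruency conditions must have correct trials")
    delta = float(inc.mean() - con.mean())
    n1, n2 = len(con), len(inc)
    if n1 + n2 > 2:
        pooled = np.sqrt(
            ((n1 - 1) * con.var(ddof=1) + (n2 - 1) * inc.var(ddof=1)) / (n1 + n2 - 2)
        )
    else:
        pooled = 0.0
    d = float(delta / pooled) if pooled > 0 else 0.0
    return FlankerEffect(delta, d, n1, n2)


def _rank_normalize(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Average-tie ranks, centered and scaled to unit norm along ``axis``."""
    r = sps.rankdata(x, axis=axis)
    r = r - r.mean(axis=axis, keepdims=True)
    norm = np.linalg.norm(r, axis=axis, keepdims=True)
    safe = np.where(norm == 0, 1.0, norm)
    return r / safe, (norm == 0)


def spearman_map(tuning: np.ndarray, behavior: np.ndarray) -> np.ndarray:
    """Across-subject Spearman rho per map cell.

    ``tuning`` is subjects x (any map shape); ``behavior`` one scalar per
    subject.  Ties get average ranks; cells with constant tuning across
    subjects are undefined and emitted as 0 with a warning.
    """
    tuning = np.asarray(tuning, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    n = tuning.shape[0]
    if behavior.shape != (n,):
        raise ValueError("behavior must hold one value per subject")
    if n < 5:
        raise ValueError(f"need at least 5 subjects for a correlation map, got {n}")
    flat = tuning.reshape(n, -1)
    rt, degenerate = _rank_normalize(flat, axis=0)
    rb, b_degenerate = _rank_normalize(behavior.reshape(n, 1), axis=0)
    if np.any(degenerate) or b_degenerate.any():
        warnings.warn("constant input in some cells; rho set to 0 there", stacklevel=2)
    rho = (rb[:, 0] @ rt).reshape(tuning.shape[1:])
    return rho


@dataclass
class Cluster:
    """A contiguous suprathreshold region of a statistic map."""

    cells: np.ndarray  # (n_cells, map_ndim) integer indices
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    """Observed clusters with Monte Carlo p-values.

    ``stat_map`` is the cell-level statistic (t or rho); clusters were
    formed by two-sided thresholding at ``threshold`` and adjacency of
    time neighbors and circularly wrapped offset neighbors; each cluster's
    mass (sum of the statistic over members) is compared with the null
    distribution of the maximum absolute cluster mass over
    ``n_permutations`` relabelings.
    """

    clusters: list[Cluster]
    stat_map: np.ndarray
    threshold: float
    n_permutations: int

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < 0.05]

    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)


def _merge_wrapped(labels: np.ndarray) -> np.ndarray:
    """Union labels adjacent across the circular wrap of the last axis."""
    first = labels[..., 0].ravel()
    last = labels[..., -1].ravel()
    pairs = {(a, b) for a, b in zip(first.tolist(), last.tolist()) if a and b and a != b}
    if not pairs:
        return labels
    n = labels.max() + 1
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(n)])
    return roots[labels]


def _label_stack(supra: np.ndarray) -> np.ndarray:
    """Label connected components independently within each leading slice.

    ``supra`` is (P, T, O) boolean; components never span the leading
    axis, time adjacency is +-1 bin, offset adjacency +-1 with circular
    wraparound (the +-180 deg bin is a single bin upstream, so wrap here is
    exact).
    """
    labels, _ = ndimage.label(supra, structure=_STRUCTURE_3D)
    if supra.shape[-1] > 2:
        labels = _merge_wrapped(labels)
    return labels


def _max_null_masses(stat_stack: np.ndarray, threshold: float) -> np.ndarray:
    """Maximum absolute cluster mass per permutation (leading axis)."""
    P = stat_stack.shape[0]
    out = np.zeros(P)
    for sign in (1.0, -1.0):
        supra = sign * stat_stack > threshold
        labels = _label_stack(supra)
        nlab = labels.max()
        if nlab == 0:
            continue
        masses = np.abs(
            np.bincount(labels.ravel(), weights=stat_stack.ravel(), minlength=nlab + 1)
        )
        masses[0] = 0.0
        # map each label to its permutation slice via first occurrence
        flat = labels.ravel()
        uniq, first_idx = np.unique(flat, return_index=True)
        per_slice = flat.shape[0] // P
        perm_of = first_idx // per_slice
        np.maximum.at(out, perm_of[uniq > 0], masses[uniq[uniq > 0]])
    return out


def _observed_clusters(stat_map: np.ndarray, threshold: float):
    """Clusters (cells, mass) of a single (T, O) map, both signs."""
    clusters = []
    for sign in (1.0, -1.0):
        supra = (sign * stat_map > threshold)[None]
        labels = _label_stack(supra)[0]
        for lab in np.unique(labels):
            if lab == 0:
                continue
            mask = labels == lab
            clusters.append((np.argwhere(mask), float(stat_map[mask].sum())))
    return clusters


def _paired_t_stack(data: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-maps for sign-flipped one-sample tests, vectorized over flips.

    ``data`` is (S, C); ``signs`` is (P, S).  Sign flips leave per-cell
    sums of squares unchanged, so only the mean needs recomputing.
    """
    S = data.shape[0]
    ss = (data**2).sum(axis=0)  # invariant under flips
    means = signs @ data / S
    var = (ss / S - means**2) * (S / (S - 1))
    var = np.maximum(var, 1e-300)
    return means / np.sqrt(var / S)


def cluster_permutation(
    maps: np.ndarray,
    behavior: np.ndarray | None = None,
    n_perm: int = 1000,
    cell_alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based Monte Carlo permutation test on per-subject maps.

    Parameters
    ----------
    maps
        Subjects x offsets, or subjects x time-bins x offsets.  The last
        axis is treated as circular (offset wraparound).
    behavior
        If omitted, a paired/one-sample test: the cell statistic is the
        across-subject t against 0 and the null flips each subject's sign.
        If given (one scalar per subject), the cell statistic is the
        across-subject Spearman rho with behavior and the null permutes
        the behavior labels.
    n_perm, cell_alpha, seed
        Monte Carlo settings.  Cells are thresholded two-sided at
        ``cell_alpha`` (t or rho critical value for the available n);
        cluster mass is the sum of the statistic over members, and each
        cluster's |mass| is referred to the null distribution of the
        maximum |mass|; p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    maps = np.asarray(maps, dtype=float)
    squeeze = maps.ndim == 2
    if squeeze:
        maps = maps[:, None, :]
    if maps.ndim != 3:
        raise ValueError("maps must be (subjects, [time,] offsets)")
    S, T, O = maps.shape
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives coarse p-value resolution (floor {1/(n_perm+1):.3g})",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    flat = maps.reshape(S, T * O)

    if behavior is None:
        if S < 2:
            raise ValueError("paired test needs at least 2 subjects")
        t_crit = sps.t.ppf(1 - cell_alpha / 2, df=S - 1)
        obs = _paired_t_stack(flat, np.ones((1, S)))[0]
        signs = rng.choice([-1.0, 1.0], size=(n_perm, S))
        null_stack = _paired_t_stack(flat, signs)
        threshold = float(t_crit)
    else:
        behavior = np.asarray(behavior, dtype=float)
        if S < 5:
            raise ValueError("correlation test needs at least 5 subjects")
        t_crit = sps.t.ppf(1 - cell_alpha / 2, df=S - 2)
        threshold = float(t_crit / np.sqrt(S - 2 + t_crit**2))  # rho at p = cell_alpha
        rt, degenerate = _rank_normalize(flat, axis=0)
        if np.any(degenerate):
            warnings.warn("constant cells emit rho = 0", stacklevel=2)
        rb, _ = _rank_normalize(behavior.reshape(S, 1), axis=0)
        rb = rb[:, 0]
        obs = rb @ rt
        perms = np.stack([rng.permutation(S) for _ in range(n_perm)])
        null_stack = rb[perms] @ rt

    null_max = _max_null_masses(null_stack.reshape(-1, T, O), threshold)
    observed = _observed_clusters(obs.reshape(T, O), threshold)
    clusters = []
    for cells, mass in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm)
        if squeeze:
            cells = cells[:, 1:]
        clusters.append(Cluster(cells=cells, mass=mass, p_value=float(p)))
    clusters.sort(key=lambda c: -abs(c.mass))
    stat_map = obs.reshape(T, O)[0] if squeeze else obs.reshape(T, O)
    return ClusterResult(clusters, stat_map, threshold, n_perm)


def median_split_tuning(
    decoded: DecodeResult,
    trials: pd.DataFrame,
    basis: BasisSet,
) -> tuple[AlignedTuning, AlignedTuning]:
    """Aligned tuning recomputed separately for slow and fast trials.

    Within each location, decoded trials are sorted by RT (stable on trial
    order) and split at the middle: the lower half is "fast", the upper
    half (including ties at the median, which sort later) "slow"; with an
    odd count the extra trial goes to the slow group.  Locations with
    fewer than 2 usable trials are excluded with a warning.  Returns
    (slow, fast).
    """
    rt = trials["rt_ms"].to_numpy(dtype=float)
    usable = decoded.used & np.isfinite(rt)
    locations = trials["location"].to_numpy()
    slow = np.zeros(len(trials), dtype=bool)
    fast = np.zeros(len(trials), dtype=bool)
    excluded = []
    for loc in np.unique(locations):
        idx = np.flatnonzero((locations == loc) & usable)
        if len(idx) < 2:
            excluded.append(loc)
            continue
        order = idx[np.argsort(rt[idx], kind="stable")]
        half = len(order) // 2
        fast[order[:half]] = True
        slow[order[half:]] = True
    if excluded:
        warnings.warn(f"locations excluded from median split: {excluded}", stacklevel=2)
    if not slow.any() or not fast.any():
        raise ValueError("median split produced an empty group")
    slow_t = align_and_average(decoded, trials, basis, valid=slow)
    fast_t = align_and_average(decoded, trials, basis, valid=fast)
    return slow_t, fast_t
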
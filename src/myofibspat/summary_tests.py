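"""Summary- and test-based statistics for binary fiber-type patterns.

Three classical "global" analyses over the neighbor network:

* **Mean cluster size** — average size of the contiguous like-type clusters
  of a chosen fiber type, compared against a 95% permutation envelope under
  random relabeling with fixed type counts.
* **Unlike neighbor pairs** — join-count test: the number of network edges
  joining a slow fiber to a fast fiber, standardized by its exact mean and
  variance under random labeling (sampling without replacement), yielding a
  normal z statistic.  Fewer unlike pairs than expected indicates like-type
  attraction (clustering); more indicates segregation (a chequerboard).
* **Abnormally grouped fibers** — descriptive proportion of target-type
  fibers belonging to clusters that contain at least two adjacent fibers
  whose like-type neighbor count exceeds one standard deviation above its
  null mean.

All permutation machinery is seedable and holds the observed type counts
fixed, which is the conditional ("nonfree sampling") null of complete
spatial randomness for labeled points on a fixed network.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components
from scipy.stats import norm

from .geometry import NeighborNetwork
from .section_io import (
    BinaryLabels,
    DegenerateSectionError,
    register_result,
)

__all__ = [
    "ClusterSizeResult",
    "JoinCountResult",
    "AbnormalGroupingResult",
    "UndefinedStatisticError",
    "like_type_components",
    "mean_cluster_size_test",
    "count_unlike_pairs",
    "join_count_moments",
    "unlike_pairs_test",
    "abnormal_grouping_stat",
]

logger = logging.getLogger("myofibspat")


class UndefinedStatisticError(Exception):
    """The null distribution is degenerate (e.g. zero variance)."""


@register_result
@dataclass(frozen=True)
class ClusterSizeResult:
    target_type: int
    clusters: tuple
    mean_size: float
    envelope: tuple
    verdict: str
    minority_fraction: float
    reliability_flag: bool
    n_perm: int
    seed: int


@register_result
@dataclass(frozen=True)
class JoinCountResult:
    observed_U: int
    expected_U: float
    var_U: float
    z_stat: float
    p_value: float
    verdict: str


@register_result
@dataclass(frozen=True)
class AbnormalGroupingResult:
    target_type: int
    null_mean: float
    null_sd: float
    flagged_fibers: tuple
    proportion: float


def _check_shapes(network: NeighborNetwork, labels: BinaryLabels) -> None:
    if network.n != labels.n:
        raise ValueError(f"network has n={network.n} but labels have n={labels.n}")


def _require_target_present(labels: BinaryLabels, target: int) -> int:
    n_target = labels.n_fast if target == 1 else labels.n_slow
    if n_target == 0:
        raise DegenerateSectionError(f"target type (spin {target:+d}) absent from section")
    return n_target


def _component_labels(n_nodes: int, edges: np.ndarray) -> tuple[int, np.ndarray]:
    """Connected components of a graph given by an edge array over n_nodes."""
    if n_nodes == 0:
        return 0, np.empty(0, dtype=np.int64)
    if len(edges) == 0:
        return n_nodes, np.arange(n_nodes, dtype=np.int64)
    data = np.ones(2 * len(edges), dtype=np.int8)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = csr_array((data, (i, j)), shape=(n_nodes, n_nodes))
    ncomp, comp = connected_components(adj, directed=False)
    return int(ncomp), comp


def _induced_target_edges(edges: np.ndarray, z: np.ndarray, target: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(target node ids, compact edge array over targets, compact id map)."""
    nodes = np.flatnonzero(z == target)
    compact = np.full(len(z), -1, dtype=np.int64)
    compact[nodes] = np.arange(len(nodes))
    if len(edges):
        mask = (z[edges[:, 0]] == target) & (z[edges[:, 1]] == target)
        sub = compact[edges[mask]]
    else:
        sub = np.empty((0, 2), dtype=np.int64)
    return nodes, sub, compact


def like_type_components(
    network: NeighborNetwork, labels: BinaryLabels, target: int
) -> list[np.ndarray]:
    """Contiguous like-type clusters of the target type (spin -1 or +1).

    Returns the connected components of the subgraph induced by target-type
    fibers, as arrays of original fiber indices; isolated target fibers are
    singleton clusters.
    """
    _check_shapes(network, labels)
    nodes, sub, _ = _induced_target_edges(network.edges, labels.z, target)
    ncomp, comp = _component_labels(len(nodes), sub)
    order = np.argsort(comp, kind="stable")
    splits = np.searchsorted(comp[order], np.arange(1, ncomp))
    return [nodes[idx] for idx in np.split(order, splits)]


def _mean_cluster_size(edges: np.ndarray, z: np.ndarray, target: int) -> float:
    nodes, sub, _ = _induced_target_edges(edges, z, target)
    ncomp, _ = _component_labels(len(nodes), sub)
    return len(nodes) / ncomp if ncomp else float("nan")


def minority_spin(labels: BinaryLabels) -> int:
    """The less prevalent spin (ties resolved to fast, +1)."""
    return -1 if labels.n_slow < labels.n_fast else 1


def mean_cluster_size_test(
    network: NeighborNetwork,
    labels: BinaryLabels,
    target: int | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> ClusterSizeResult:
    """Mean like-type cluster size against a 95% permutation envelope.

    The default target is the less prevalent fiber type.  The envelope is
    the 2.5th/97.5th percentile of the mean cluster size over ``n_perm``
    uniformly random relabelings with the observed type counts held fixed.
    A mean size above the envelope indicates like-type attraction; below,
    repulsion.  The statistic is considered reliable when the target type
    makes up at most 30% of the fibers (``reliability_flag``).
    """
    _check_shapes(network, labels)
    if target is None:
        target = minority_spin(labels)
    n_target = _require_target_present(labels, target)
    if n_perm < 199:
        raise ValueError(f"n_perm must be at least 199 for a 95% envelope, got {n_perm}")

    clusters = like_type_components(network, labels, target)
    mean_size = n_target / len(clusters)

    rng = np.random.default_rng(seed)
    z = labels.z
    sizes = np.empty(n_perm)
    for b in range(n_perm):
        sizes[b] = _mean_cluster_size(network.edges, rng.permutation(z), target)
    lo, hi = np.percentile(sizes, [2.5, 97.5])

    if mean_size > hi:
        verdict = "attraction"
    elif mean_size < lo:
        verdict = "repulsion"
    else:
        verdict = "random"
    frac = n_target / labels.n
    return ClusterSizeResult(
        target_type=int(target),
        clusters=tuple(tuple(int(i) for i in c) for c in clusters),
        mean_size=float(mean_size),
        envelope=(float(lo), float(hi)),
        verdict=verdict,
        minority_fraction=float(frac),
        reliability_flag=bool(frac <= 0.30),
        n_perm=int(n_perm),
        seed=int(seed),
    )


def count_unlike_pairs(network: NeighborNetwork, labels: BinaryLabels) -> int:
    """Number of edges joining fibers of different type (BW joins)."""
    _check_shapes(network, labels)
    if network.m == 0:
        return 0
    z = labels.z
    return int((z[network.edges[:, 0]] != z[network.edges[:, 1]]).sum())


def join_count_moments(
    network: NeighborNetwork, n_slow: int, n_fast: int
) -> tuple[float, float]:
    """Exact null mean and variance of the unlike-pair count.

    Null: the ``n_slow`` slow labels are assigned to the ``n`` fibers
    uniformly at random without replacement (type counts fixed).  The
    moments follow from the inclusion probabilities of one edge, two edges
    sharing a fiber, and two disjoint edges; this is the classical
    nonfree-sampling join-count variance and is validated against exhaustive
    enumeration in the test suite.
    """
    n = n_slow + n_fast
    m = network.m
    if m < 1:
        raise ValueError("network has no edges")
    if n_slow == 0 or n_fast == 0:
        return 0.0, 0.0
    # P(one edge unlike)
    q1 = 2.0 * n_slow * n_fast / (n * (n - 1))
    expected = m * q1
    d = network.degrees.astype(np.float64)
    pairs_sharing = float((d * (d - 1)).sum()) / 2.0
    pairs_disjoint = m * (m - 1) / 2.0 - pairs_sharing
    # P(two edges sharing a fiber both unlike): the shared fiber is either
    # type; its two distinct partners must both be of the other type.
    q2_share = (
        n_slow * n_fast * ((n_fast - 1) + (n_slow - 1)) / (n * (n - 1) * (n - 2))
        if n >= 3
        else 0.0
    )
    # P(two disjoint edges both unlike)
    q2_disjoint = (
        4.0 * n_slow * (n_slow - 1) * n_fast * (n_fast - 1)
        / (n * (n - 1) * (n - 2) * (n - 3))
        if n >= 4
        else 0.0
    )
    second_moment = expected + 2.0 * (pairs_sharing * q2_share + pairs_disjoint * q2_disjoint)
    var = max(second_moment - expected**2, 0.0)
    return float(expected), float(var)


def unlike_pairs_test(network: NeighborNetwork, labels: BinaryLabels) -> JoinCountResult:
    """Join-count z test of spatial randomness of the two fiber types.

    z < 0 leans toward like-type attraction, z > 0 toward segregation
    (repulsion); significance at the two-sided 5% level.
    """
    _check_shapes(network, labels)
    if labels.n_slow == 0 or labels.n_fast == 0:
        raise DegenerateSectionError("both types must be present for the join-count test")
    observed = count_unlike_pairs(network, labels)
    expected, var = join_count_moments(network, labels.n_slow, labels.n_fast)
    if var <= 0:
        raise UndefinedStatisticError("null variance of the unlike-pair count is zero")
    z_stat = (observed - expected) / math.sqrt(var)
    p = 2.0 * float(norm.sf(abs(z_stat)))
    if p < 0.05:
        verdict = "attraction" if z_stat < 0 else "segregation"
    else:
        verdict = "randomness"
    return JoinCountResult(
        observed_U=int(observed),
        expected_U=float(expected),
        var_U=float(var),
        z_stat=float(z_stat),
        p_value=float(p),
        verdict=verdict,
    )


def _like_neighbor_counts(network: NeighborNetwork, z: np.ndarray, target: int) -> np.ndarray:
    """Per-fiber count of target-type neighbors (only meaningful on targets)."""
    counts = np.zeros(network.n, dtype=np.int64)
    if network.m:
        e0, e1 = network.edges[:, 0], network.edges[:, 1]
        t0 = z[e0] == target
        t1 = z[e1] == target
        np.add.at(counts, e0[t1], 1)
        np.add.at(counts, e1[t0], 1)
    return counts


def abnormal_grouping_stat(
    network: NeighborNetwork,
    labels: BinaryLabels,
    target: int,
    null_method: str = "analytic",
    per_fiber: bool = True,
    min_marked: int = 2,
    n_perm: int = 999,
    seed: int = 0,
) -> AbnormalGroupingResult:
    """Proportion of target-type fibers in "abnormally grouped" clusters.

    For each target fiber the number of *other* target-type neighbors is
    compared with its null mean and standard deviation under random
    labeling.  Fibers exceeding mean + 1 sd are *marked*; any like-type
    cluster containing at least ``min_marked`` marked fibers, two of them
    adjacent, is flagged in full.  The result is the flagged fraction of
    target fibers — a descriptive statistic, not a formal test, and only
    comparable between sections with similar type proportions.

    ``null_method='analytic'`` takes the null moments per fiber from the
    hypergeometric distribution of like-type neighbors given the fiber's
    degree and the global counts; ``'permutation'`` estimates them from
    ``n_perm`` random relabelings.  ``per_fiber=False`` pools the threshold
    across degrees (one global mean + sd).
    """
    _check_shapes(network, labels)
    n_target = _require_target_present(labels, target)
    if network.m == 0:
        warnings.warn("network has no edges; abnormal-grouping proportion is 0", stacklevel=2)
        return AbnormalGroupingResult(
            target_type=int(target), null_mean=0.0, null_sd=0.0,
            flagged_fibers=(), proportion=0.0,
        )
    z = labels.z
    target_mask = z == target
    d = network.degrees.astype(np.float64)
    observed = _like_neighbor_counts(network, z, target)

    if null_method == "analytic":
        # Given fiber i is target-type, its d_i neighbors are a sample
        # without replacement from the other n-1 fibers, of which
        # n_target - 1 are target-type.
        p = (n_target - 1) / (labels.n - 1)
        mean_i = d * p
        var_i = d * p * (1 - p) * (labels.n - 1 - d) / (labels.n - 2)
        sd_i = np.sqrt(np.maximum(var_i, 0.0))
    elif null_method == "permutation":
        # conditional on the fiber being target-type in the permuted labeling
        rng = np.random.default_rng(seed)
        s = np.zeros(network.n)
        ss = np.zeros(network.n)
        cnt = np.zeros(network.n)
        for _ in range(n_perm):
            zp = rng.permutation(z)
            c = _like_neighbor_counts(network, zp, target)
            tm = zp == target
            s[tm] += c[tm]
            ss[tm] += c[tm] ** 2
            cnt[tm] += 1
        cnt = np.maximum(cnt, 1)
        mean_i = s / cnt
        var_i = np.maximum((ss - cnt * mean_i**2) / np.maximum(cnt - 1, 1), 0.0)
        sd_i = np.sqrt(var_i)
    else:
        raise ValueError(f"unknown null_method {null_method!r}")

    if per_fiber:
        marked = target_mask & (observed > mean_i + sd_i)
    else:
        pooled_mean = float(mean_i[target_mask].mean())
        pooled_sd = float(sd_i[target_mask].mean())
        marked = target_mask & (observed > pooled_mean + pooled_sd)

    clusters = like_type_components(network, labels, target)
    # adjacency among marked fibers
    e = network.edges
    marked_edge = marked[e[:, 0]] & marked[e[:, 1]] if len(e) else np.zeros(0, bool)
    adjacent_marked = set(map(int, e[marked_edge].ravel())) if marked_edge.any() else set()
    flagged: list[int] = []
    for comp in clusters:
        comp_marked = int(marked[comp].sum())
        if comp_marked >= min_marked and any(int(i) in adjacent_marked for i in comp):
            flagged.extend(int(i) for i in comp)
    null_mean = float(mean_i[target_mask].mean())
    null_sd = float(sd_i[target_mask].mean())
    return AbnormalGroupingResult(
        target_type=int(target),
        null_mean=null_mean,
        null_sd=null_sd,
        flagged_fibers=tuple(sorted(flagged)),
        proportion=float(len(flagged) / n_target),
    )
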
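"""Cross-model consensus clustering of reliable state patterns.

States pooled across groups and model sizes are binarized into active-network
sets, compared with Jaccard distance, and grouped by average-linkage
agglomerative clustering cut at ``1 - similarity_threshold``. Clusters are
renumbered by total fractional occupancy, given 50%-consensus binary patterns
and context-provenance labels, and each can nominate a representative state
from the combined-group models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .reliability import StatePattern

logger = logging.getLogger(__name__)

CONTEXT_GROUPS = ("affair", "paranoia")


@dataclass
class Cluster:
    cluster_id: int  # 1-based, occupancy-ordered
    members: list[StatePattern]
    consensus: np.ndarray  # binary (n_networks,)
    total_occupancy: float
    provenance: str  # context-general | context-specific:affair | context-specific:paranoia


@dataclass
class ClusterSolution:
    clusters: list[Cluster]
    similarity_threshold: float
    assignments: list[int] = field(default_factory=list)  # cluster id per input pattern

    def top(self, n: int) -> list[Cluster]:
        return self.clusters[:n]


def active_set(mean: np.ndarray, theta_act: float = 0.1, mode: str = "positive") -> frozenset[int]:
    """Indices of networks counted as active for Jaccard comparison.

    ``mode='positive'`` takes mean > theta (default); ``mode='absolute'``
    takes |mean| > theta.
    """
    mean = np.asarray(mean, dtype=float)
    if mode == "positive":
        idx = np.flatnonzero(mean > theta_act)
    elif mode == "absolute":
        idx = np.flatnonzero(np.abs(mean) > theta_act)
    else:
        raise ValueError(f"unknown active-set mode {mode!r}")
    return frozenset(int(i) for i in idx)


def jaccard_distance(set_a: frozenset[int] | set[int], set_b: frozenset[int] | set[int]) -> float:
    """1 - |intersection| / |union|; two empty sets count as identical (0)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def jaccard_similarity(set_a, set_b) -> float:
    return 1.0 - jaccard_distance(set_a, set_b)


def consensus_pattern(members: list[StatePattern], theta_act: float = 0.1, mode: str = "positive", n_networks: int | None = None) -> np.ndarray:
    """Binary vector of networks active in at least 50% of member states
    (inclusive boundary)."""
    if not members:
        raise ValueError("empty cluster")
    n_networks = n_networks or len(members[0].mean)
    counts = np.zeros(n_networks)
    for p in members:
        for i in active_set(p.mean, theta_act, mode):
            counts[i] += 1
    consensus = (counts / len(members) >= 0.5).astype(int)
    if consensus.sum() == 0:
        warnings.warn("cluster has an empty consensus pattern", stacklevel=2)
    return consensus


def label_provenance(members: list[StatePattern]) -> str:
    """Context-general iff members come from both context groups; otherwise
    context-specific to the dominant context group. Clusters whose members all
    come from constructed groups (combined/balanced) are context-general."""
    groups = {p.group for p in members}
    has_affair = "affair" in groups
    has_paranoia = "paranoia" in groups
    if has_affair and has_paranoia:
        return "context-general"
    if has_affair:
        return "context-specific:affair"
    if has_paranoia:
        return "context-specific:paranoia"
    return "context-general"


def cluster_states(
    patterns: list[StatePattern],
    similarity_threshold: float = 0.8,
    theta_act: float = 0.1,
    mode: str = "positive",
) -> ClusterSolution:
    """Average-linkage Jaccard clustering of state patterns, cut at
    ``1 - similarity_threshold``, with occupancy-based cluster reordering.

    Ties in total occupancy are broken by member count (descending), then by
    first appearance in the input.
    """
    if not patterns:
        raise ValueError("empty state-pattern pool")
    sets = [active_set(p.mean, theta_act, mode) for p in patterns]
    empties = [i for i, s in enumerate(sets) if not s]
    if empties:
        logger.warning("patterns with empty active sets: %s", empties)
    n = len(patterns)
    if n == 1:
        raw = np.array([1])
    else:
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dist[i, j] = dist[j, i] = jaccard_distance(sets[i], sets[j])
        Z = linkage(squareform(dist, checks=False), method="average")
        # cophenetic distance <= cutoff merges; strictly-above stays separate
        raw = fcluster(Z, t=1.0 - similarity_threshold, criterion="distance")

    by_raw: dict[int, list[int]] = {}
    for i, r in enumerate(raw):
        by_raw.setdefault(int(r), []).append(i)

    def sort_key(item):
        _, idxs = item
        total_occ = sum(patterns[i].occupancy for i in idxs)
        return (-total_occ, -len(idxs), min(idxs))

    ordered = sorted(by_raw.items(), key=sort_key)
    clusters: list[Cluster] = []
    assignments = [0] * n
    for new_id, (_, idxs) in enumerate(ordered, start=1):
        members = [patterns[i] for i in idxs]
        for i in idxs:
            assignments[i] = new_id
        clusters.append(
            Cluster(
                cluster_id=new_id,
                members=members,
                consensus=consensus_pattern(members, theta_act, mode),
                total_occupancy=float(sum(p.occupancy for p in members)),
                provenance=label_provenance(members),
            )
        )
    return ClusterSolution(clusters=clusters, similarity_threshold=similarity_threshold, assignments=assignments)


@dataclass
class ThresholdStabilityReport:
    thresholds: list[float]
    pair_similarities: list[list[float]]  # best-match similarity per top cluster, per pair
    mean_similarity: float
    fraction_high: float  # fraction of best matches with similarity >= high_cut
    high_cut: float = 0.7


def _greedy_best_match(cons_a: list[np.ndarray], cons_b: list[np.ndarray]) -> list[float]:
    """Greedy best matching of consensus patterns by Jaccard similarity."""
    sims = np.array(
        [[jaccard_similarity(set(np.flatnonzero(a)), set(np.flatnonzero(b))) for b in cons_b] for a in cons_a]
    )
    out = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for _ in range(min(len(cons_a), len(cons_b))):
        best = None
        for i in range(len(cons_a)):
            if i in used_a:
                continue
            for j in range(len(cons_b)):
                if j in used_b:
                    continue
                if best is None or sims[i, j] > best[0]:
                    best = (sims[i, j], i, j)
        if best is None:
            break
        out.append(float(best[0]))
        used_a.add(best[1])
        used_b.add(best[2])
    return out


def _hungarian_best_match(cons_a: list[np.ndarray], cons_b: list[np.ndarray]) -> list[float]:
    sims = np.array(
        [[jaccard_similarity(set(np.flatnonzero(a)), set(np.flatnonzero(b))) for b in cons_b] for a in cons_a]
    )
    rows, cols = linear_sum_assignment(-sims)
    return [float(sims[i, j]) for i, j in zip(rows, cols)]


def threshold_stability(
    patterns: list[StatePattern],
    thresholds: list[float] | None = None,
    top_n: int = 5,
    high_cut: float = 0.7,
    matcher: str = "greedy",
    theta_act: float = 0.1,
    mode: str = "positive",
) -> ThresholdStabilityReport:
    """Compare top-cluster consensus patterns across consecutive similarity
    thresholds (default sweep 0.60..0.90 step 0.05)."""
    if thresholds is None:
        thresholds = [round(0.60 + 0.05 * i, 2) for i in range(7)]
    match = _greedy_best_match if matcher == "greedy" else _hungarian_best_match
    solutions = [cluster_states(patterns, t, theta_act, mode) for t in thresholds]
    pair_similarities: list[list[float]] = []
    for prev, cur in zip(solutions, solutions[1:]):
        cons_prev = [c.consensus for c in prev.top(top_n)]
        cons_cur = [c.consensus for c in cur.top(top_n)]
        pair_similarities.append(match(cons_prev, cons_cur))
    flat = [s for pair in pair_similarities for s in pair]
    return ThresholdStabilityReport(
        thresholds=list(thresholds),
        pair_similarities=pair_similarities,
        mean_similarity=float(np.mean(flat)) if flat else float("nan"),
        fraction_high=float(np.mean([s >= high_cut for s in flat])) if flat else float("nan"),
        high_cut=high_cut,
    )


def cluster_similarity(patterns: np.ndarray) -> np.ndarray:
    """Spearman rank-correlation matrix between activation patterns (rows)."""
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    n = patterns.shape[0]
    if n == 1:
        return np.array([[1.0]])
    rho, _ = spearmanr(patterns.T)
    if n == 2:  # scipy collapses the 2x2 case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    return np.asarray(rho)


def select_representative(cluster: Cluster) -> StatePattern:
    """First combined-group member, scanning combined models by ascending K
    and, within a model, by fractional occupancy descending."""
    combined = [p for p in cluster.members if p.group == "combined"]
    if not combined:
        raise ValueError(f"cluster {cluster.cluster_id} has no combined-group member")
    combined.sort(key=lambda p: (p.model_k, -p.occupancy, p.state_index))
    return combined[0]
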
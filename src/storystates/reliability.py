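"""Quality screening of fitted HMM states.

A state survives iff (1) at least one network's mean parameter deviates from
baseline by more than the activation threshold, (2) bootstrap confidence
intervals around its per-network mean activations are narrow, and (3) the
split-half correlation of its mean pattern exceeds a reliability floor.
Survivors become :class:`StatePattern` records carrying occupancy and
provenance for downstream clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MIN_TIMEPOINTS = 10


@dataclass
class ReliabilityThresholds:
    activation: float = 0.1  # min |mean| on at least one network
    ci_width: float = 0.3  # max bootstrap CI width
    split_half: float = 0.5  # min split-half pattern correlation
    ci_scope: str = "all"  # "all" networks or "active" networks only


@dataclass
class StatePattern:
    """One state's mean pattern plus occupancy, reliability, and provenance."""

    mean: np.ndarray  # (n_networks,) in z units
    occupancy: float
    group: str  # affair | paranoia | combined | balanced
    model_k: int
    state_index: int
    max_abs_activation: float = 0.0
    ci_widths: np.ndarray | None = None
    split_half_r: float = float("nan")

    @property
    def normalized_index(self) -> float:
        return self.state_index / self.model_k


@dataclass
class RejectionRecord:
    group: str
    model_k: int
    state_index: int
    reason: str  # activation | ci_width | split_half | min_timepoints


@dataclass
class FilterResult:
    passed: list[StatePattern]
    rejected: list[RejectionRecord] = field(default_factory=list)


def fractional_occupancy(paths: np.ndarray | list[np.ndarray], K: int) -> np.ndarray:
    """Fraction of all subject-TRs assigned to each of the K states."""
    if isinstance(paths, (list, tuple)):
        flat = np.concatenate([np.asarray(p) for p in paths])
    else:
        flat = np.asarray(paths).ravel()
    if flat.size == 0:
        raise ValueError("empty state path")
    counts = np.bincount(flat, minlength=K)
    if len(counts) > K:
        raise ValueError("path contains state indices >= K")
    return counts / flat.size


def bootstrap_ci(
    rows: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile bootstrap CIs for the per-network mean of ``rows``.

    Returns ``(low, high, width)``, each of length ``n_networks``.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 1:
        raise ValueError("need a non-empty 2-D TR x network matrix")
    rng = np.random.default_rng(seed)
    n = rows.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = rows[idx].mean(axis=1)  # (n_boot, n_networks)
    alpha = (1.0 - level) / 2.0
    low = np.quantile(boot_means, alpha, axis=0)
    high = np.quantile(boot_means, 1.0 - alpha, axis=0)
    return low, high, high - low


def split_half_reliability(rows: np.ndarray, mode: str = "chronological", seed: int = 0) -> float:
    """Pearson correlation between mean patterns of two halves of a state's TRs.

    ``mode`` is "chronological" (first/second half, default) or "interleaved"
    (odd/even TRs).
    """
    rows = np.asarray(rows, dtype=float)
    if rows.shape[0] < 2:
        raise ValueError("need at least 2 assigned TRs for a split-half estimate")
    if mode == "chronological":
        half = rows.shape[0] // 2
        a, b = rows[:half], rows[half:]
    elif mode == "interleaved":
        a, b = rows[0::2], rows[1::2]
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return float(np.corrcoef(a.mean(axis=0), b.mean(axis=0))[0, 1])


def filter_states(
    means: np.ndarray,
    paths: np.ndarray | list[np.ndarray],
    stacked_data: np.ndarray,
    group: str,
    thresholds: ReliabilityThresholds | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    split_mode: str = "chronological",
) -> FilterResult:
    """Apply the three quality criteria to every state of one fitted model.

    ``means`` is the model's (K, n_networks) state-mean matrix, ``paths`` the
    decoded state indices aligned row-for-row with ``stacked_data``.
    """
    thresholds = thresholds or ReliabilityThresholds()
    if isinstance(paths, (list, tuple)):
        flat = np.concatenate([np.asarray(p) for p in paths])
    else:
        flat = np.asarray(paths).ravel()
    stacked_data = np.asarray(stacked_data, dtype=float)
    if flat.size != stacked_data.shape[0]:
        raise ValueError("paths and data row counts differ")
    K = means.shape[0]
    occ = fractional_occupancy(flat, K)

    passed: list[StatePattern] = []
    rejected: list[RejectionRecord] = []
    for k in range(K):
        mean_k = np.asarray(means[k], dtype=float)
        max_abs = float(np.max(np.abs(mean_k)))
        record = lambda reason: rejected.append(RejectionRecord(group, K, k, reason))  # noqa: E731
        if max_abs <= thresholds.activation:
            record("activation")
            continue
        rows = stacked_data[flat == k]
        if rows.shape[0] < MIN_TIMEPOINTS:
            record("min_timepoints")
            continue
        _, _, widths = bootstrap_ci(rows, n_boot=n_boot, seed=seed + k)
        if thresholds.ci_scope == "active":
            scope = np.abs(mean_k) > thresholds.activation
        else:
            scope = np.ones_like(mean_k, dtype=bool)
        if np.any(widths[scope] >= thresholds.ci_width):
            record("ci_width")
            continue
        r = split_half_reliability(rows, mode=split_mode)
        if not r > thresholds.split_half:
            record("split_half")
            continue
        passed.append(
            StatePattern(
                mean=mean_k,
                occupancy=float(occ[k]),
                group=group,
                model_k=K,
                state_index=k,
                max_abs_activation=max_abs,
                ci_widths=widths,
                split_half_r=r,
            )
        )
    return FilterResult(passed=passed, rejected=rejected)
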
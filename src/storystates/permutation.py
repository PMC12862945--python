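"""Permutation tests of group differences in state-occupancy time courses.

The null distribution comes from random participant splits that preserve the
observed group sizes; the default statistic is the mean over TRs of the
absolute difference between the two groups' mean occupancy time courses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

STATISTICS = ("mean_abs", "max_abs", "sum_sq")


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray  # (n_perm,)
    p_value: float
    n_perm: int
    seed: int
    statistic: str = "mean_abs"


def _group_difference(occupancies: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Per-TR difference between group mean occupancy time courses."""
    n_a = is_a.sum()
    n_b = is_a.size - n_a
    mean_a = occupancies[is_a].sum(axis=0) / n_a
    mean_b = occupancies[~is_a].sum(axis=0) / n_b
    return mean_a - mean_b


def _reduce(diff: np.ndarray, statistic: str, axis: int = -1) -> np.ndarray:
    if statistic == "mean_abs":
        return np.abs(diff).mean(axis=axis)
    if statistic == "max_abs":
        return np.abs(diff).max(axis=axis)
    if statistic == "sum_sq":
        return (diff**2).sum(axis=axis)
    raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")


def occupancy_difference(
    occupancies: np.ndarray, labels: np.ndarray, statistic: str = "mean_abs"
) -> float:
    """Group-difference statistic over subjects x TR binary occupancy."""
    occupancies = np.asarray(occupancies, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly two groups, got {uniq.tolist()}")
    is_a = labels == uniq[0]
    return float(_reduce(_group_difference(occupancies, is_a), statistic))


def permutation_test(
    occupancies: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "mean_abs",
) -> PermutationResult:
    """Group-size-preserving permutation test with add-one p-value
    ``(1 + #{null >= observed}) / (1 + n_perm)``."""
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-value resolution is coarse", stacklevel=2)
    occupancies = np.asarray(occupancies, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly two groups, got {uniq.tolist()}")
    is_a = labels == uniq[0]
    n_subj = labels.size
    n_a = int(is_a.sum())
    observed = float(_reduce(_group_difference(occupancies, is_a), statistic))

    rng = np.random.default_rng(seed)
    # vectorized: each permutation is a row of group-A membership
    members = np.zeros((n_perm, n_subj), dtype=float)
    for r in range(n_perm):
        members[r, rng.choice(n_subj, size=n_a, replace=False)] = 1.0
    totals = occupancies.sum(axis=0)  # (T,)
    sum_a = members @ occupancies  # (n_perm, T)
    n_b = n_subj - n_a
    diffs = sum_a / n_a - (totals[None, :] - sum_a) / n_b
    null = _reduce(diffs, statistic, axis=1)
    p = (1.0 + float((null >= observed).sum())) / (1.0 + n_perm)
    return PermutationResult(
        observed=observed, null=null, p_value=p, n_perm=n_perm, seed=seed, statistic=statistic
    )
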
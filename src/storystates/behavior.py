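"""Button-press event lists to per-TR binary response series and group
agreement time courses."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class PressSeries:
    subject_id: str
    group: str
    responses: np.ndarray  # (n_bins,) 0/1
    n_dropped: int = 0  # presses past the analysis window


def align_presses(
    press_times_s: np.ndarray,
    bin_s: float,
    n_bins: int,
    subject_id: str = "",
    group: str = "none",
    rule: str = "floor",
) -> PressSeries:
    """Assign press times to TR bins, collapsing multiple presses per bin to 1.

    ``rule='floor'`` (default) puts a press in its containing bin,
    ``floor(time / bin_s)``; ``rule='nearest'`` rounds to the nearest bin
    center. Presses at or past the window end are dropped and counted.
    """
    times = np.asarray(press_times_s, dtype=float)
    if times.size and times.min() < 0:
        raise ValueError(f"negative press time for subject {subject_id!r}")
    if rule == "floor":
        bins = np.floor(times / bin_s).astype(int)
    elif rule == "nearest":
        bins = np.round(times / bin_s - 0.5).astype(int)
        bins = np.clip(bins, 0, None)
    else:
        raise ValueError(f"unknown binning rule {rule!r}")
    keep = bins < n_bins
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("subject %s: dropped %d press(es) past the window", subject_id, n_dropped)
    responses = np.zeros(n_bins, dtype=int)
    responses[np.unique(bins[keep])] = 1  # within-bin deduplication
    return PressSeries(subject_id=subject_id, group=group, responses=responses, n_dropped=n_dropped)


def group_agreement(series_list: list[PressSeries]) -> np.ndarray:
    """Per-TR proportion of subjects pressing (mean over subjects per bin)."""
    if not series_list:
        raise ValueError("no press series")
    mat = np.vstack([s.responses for s in series_list])
    return mat.mean(axis=0)
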
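"""Time-series preparation: hemodynamic shift, trimming, network averaging,
per-subject z-scoring, and cross-subject concatenation.

Inputs are parcel- or network-level TR x channel matrices. Outputs are
analysis-ready z-scored network series aligned to stimulus time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

N_NETWORKS_DEFAULT = 17


@dataclass
class NetworkSeries:
    """One subject's TR x network matrix with timing metadata."""

    subject_id: str
    data: np.ndarray  # (n_trs, n_networks), float
    tr_seconds: float = 1.5
    group: str = "none"  # affair | paranoia | none
    tr_offset: int = 0  # TRs removed at scan onset
    network_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D TR x network matrix")
        if np.isnan(self.data).any():
            raise ValueError(f"subject {self.subject_id}: data contains NaNs")
        if not self.network_names:
            self.network_names = [f"net_{i + 1:02d}" for i in range(self.data.shape[1])]

    @property
    def n_trs(self) -> int:
        return self.data.shape[0]

    @property
    def n_networks(self) -> int:
        return self.data.shape[1]


@dataclass
class ParcelMap:
    """Mapping from parcel identifier to one of the network labels."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty parcel map")
        self.networks = sorted(set(self.mapping.values()))

    @classmethod
    def from_tsv(cls, path) -> "ParcelMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"parcel_id", "network_label"} <= set(df.columns):
            raise KeyError("parcel map TSV needs columns parcel_id, network_label")
        return cls(dict(zip(df["parcel_id"], df["network_label"])))


def excluded_tr_count(durations_s: list[float], tr_seconds: float) -> int:
    """Total TR count covered by the given non-story segment durations."""
    total = float(sum(durations_s))
    n = total / tr_seconds
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"non-story durations {durations_s} are not a whole number of TRs at TR={tr_seconds}"
        )
    return int(round(n))


def shift_and_trim(
    series: NetworkSeries,
    shift_trs: int,
    onset_exclude_trs: int,
    offset_exclude_trs: int,
) -> NetworkSeries:
    """Trim non-story TRs and apply a fixed backward hemodynamic shift.

    Output row ``t`` holds the BOLD sample originally at index
    ``onset_exclude_trs + shift_trs + t``, so stimulus time ``t`` is paired
    with BOLD measured ``shift_trs`` TRs later. The shift consumes rows from
    the tail of the retained window, so it requires ``shift <= offset``
    exclusions; output length is ``input - onset - offset``.
    """
    for name, val in (
        ("shift_trs", shift_trs),
        ("onset_exclude_trs", onset_exclude_trs),
        ("offset_exclude_trs", offset_exclude_trs),
    ):
        if val < 0:
            raise ValueError(f"{name} must be non-negative, got {val}")
    n = series.n_trs
    out_len = n - onset_exclude_trs - offset_exclude_trs
    if out_len <= 0:
        raise ValueError(
            f"input has {n} TRs but exclusions remove "
            f"{onset_exclude_trs}+{offset_exclude_trs}; nothing left"
        )
    start = onset_exclude_trs + shift_trs
    if start + out_len > n:
        raise ValueError(
            f"shift {shift_trs} overruns the series: need rows up to "
            f"{start + out_len} of {n}; increase offset exclusion or reduce shift"
        )
    return replace(
        series,
        data=series.data[start : start + out_len].copy(),
        tr_offset=onset_exclude_trs,
    )


def parcels_to_networks(parcel_data: np.ndarray, parcel_ids: list[str], parcel_map: ParcelMap) -> tuple[np.ndarray, list[str]]:
    """Average parcel columns into network columns (unweighted mean).

    Returns the TR x network matrix and the sorted network labels.
    """
    parcel_data = np.asarray(parcel_data, dtype=float)
    if parcel_data.shape[1] != len(parcel_ids):
        raise ValueError("parcel_ids length does not match number of columns")
    for pid in parcel_ids:
        if pid not in parcel_map.mapping:
            raise KeyError(f"parcel {pid!r} has no network assignment")
    networks = parcel_map.networks
    out = np.empty((parcel_data.shape[0], len(networks)))
    for j, net in enumerate(networks):
        cols = [i for i, pid in enumerate(parcel_ids) if parcel_map.mapping[pid] == net]
        if not cols:
            raise ValueError(f"network {net!r} has no parcels in this series")
        out[:, j] = parcel_data[:, cols].mean(axis=1)
    return out, networks


def zscore_subject(series: NetworkSeries) -> NetworkSeries:
    """Z-score each network column across time (population-SD convention)."""
    if series.n_trs < 2:
        raise ValueError("need at least 2 TRs to z-score")
    mean = series.data.mean(axis=0)
    sd = series.data.std(axis=0)  # ddof=0: population SD
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [series.network_names[i] for i in zero]
        raise ValueError(f"zero-variance network column(s): {names}")
    return replace(series, data=(series.data - mean) / sd)


def concatenate_subjects(series_list: list[NetworkSeries]) -> tuple[np.ndarray, list[tuple[str, int, int]]]:
    """Stack subjects' matrices row-wise, recording (subject_id, start, stop) ranges."""
    if not series_list:
        raise ValueError("no series to concatenate")
    widths = {s.n_networks for s in series_list}
    if len(widths) != 1:
        raise ValueError(f"inconsistent network counts: {sorted(widths)}")
    ranges = []
    start = 0
    for s in series_list:
        ranges.append((s.subject_id, start, start + s.n_trs))
        start += s.n_trs
    stacked = np.vstack([s.data for s in series_list])
    return stacked, ranges


def split_concatenated(stacked: np.ndarray, ranges: list[tuple[str, int, int]]) -> dict[str, np.ndarray]:
    """Invert :func:`concatenate_subjects` using the recorded row ranges."""
    return {sid: stacked[a:b] for sid, a, b in ranges}
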
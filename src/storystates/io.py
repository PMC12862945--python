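"""TSV/JSON readers and writers. TSV with a leading ``#`` provenance comment
line (config hash + seed) is the universal tabular dialect; nested results go
to JSON with the same provenance embedded."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .prep import NetworkSeries
from .reliability import StatePattern


def _provenance_line(config_hash: str, seed: int) -> str:
    return f"# config_hash={config_hash} seed={seed}\n"


def write_tsv(df: pd.DataFrame, path: str | Path, config_hash: str = "", seed: int = 0) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(_provenance_line(config_hash, seed))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(obj: dict, path: str | Path, config_hash: str = "", seed: int = 0) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    if config_hash:
        payload["_provenance"] = {"config_hash": config_hash, "seed": seed}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def series_to_frame(series: NetworkSeries) -> pd.DataFrame:
    df = pd.DataFrame(series.data, columns=series.network_names)
    df.insert(0, "tr_index", np.arange(series.n_trs))
    return df


def write_network_series(series: NetworkSeries, path: str | Path, config_hash: str = "", seed: int = 0) -> None:
    write_tsv(series_to_frame(series), path, config_hash, seed)


def read_network_series(path: str | Path, subject_id: str, tr_seconds: float = 1.5, group: str = "none") -> NetworkSeries:
    df = read_tsv(path)
    nets = [c for c in df.columns if c != "tr_index"]
    return NetworkSeries(
        subject_id=subject_id,
        data=df[nets].to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        group=group,
        network_names=nets,
    )


def patterns_to_frame(patterns: list[StatePattern]) -> pd.DataFrame:
    """Interchange table: mean columns + occupancy + provenance + reliability."""
    rows = []
    for p in patterns:
        row = {f"mean_net_{i + 1:02d}": v for i, v in enumerate(p.mean)}
        row.update(
            occupancy=p.occupancy,
            group=p.group,
            model_k=p.model_k,
            state_index=p.state_index,
            normalized_index=p.normalized_index,
            max_abs_activation=p.max_abs_activation,
            split_half_r=p.split_half_r,
        )
        if p.ci_widths is not None:
            row.update({f"ci_width_net_{i + 1:02d}": v for i, v in enumerate(p.ci_widths)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_patterns(df: pd.DataFrame) -> list[StatePattern]:
    mean_cols = sorted(c for c in df.columns if c.startswith("mean_net_"))
    ci_cols = sorted(c for c in df.columns if c.startswith("ci_width_net_"))
    out = []
    for _, row in df.iterrows():
        out.append(
            StatePattern(
                mean=row[mean_cols].to_numpy(dtype=float),
                occupancy=float(row["occupancy"]),
                group=str(row["group"]),
                model_k=int(row["model_k"]),
                state_index=int(row["state_index"]),
                max_abs_activation=float(row.get("max_abs_activation", np.nan)),
                ci_widths=row[ci_cols].to_numpy(dtype=float) if ci_cols else None,
                split_half_r=float(row.get("split_half_r", np.nan)),
            )
        )
    return out


def presses_to_frame(press_times: dict[str, np.ndarray], groups: dict[str, str]) -> pd.DataFrame:
    rows = [
        {"subject_id": sid, "group": groups[sid], "press_time_s": float(t)}
        for sid, times in press_times.items()
        for t in np.asarray(times)
    ]
    return pd.DataFrame(rows, columns=["subject_id", "group", "press_time_s"])


def read_presses(path: str | Path) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    df = read_tsv(path)
    times = {
        sid: sub["press_time_s"].to_numpy(dtype=float)
        for sid, sub in df.groupby("subject_id", sort=True)
    }
    groups = {sid: sub["group"].iloc[0] for sid, sub in df.groupby("subject_id", sort=True)}
    return times, groups
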
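"""Per-TR story-annotation schema: binary feature columns and composites.

A feature table is a :class:`pandas.DataFrame` with a ``tr_index`` column and
one 0/1 column per feature. Base features describe character speech and parts
of speech; composite features are elementwise products of two base features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Base binary feature columns expected in a full annotation table.
BASE_FEATURES = (
    "arthur_speaking",
    "lee_speaking",
    "girl_speaking",
    "lee_girl_together",
    "verb",
    "noun",
    "adjective",
    "adverb",
)

#: Composite features: name -> (parent_a, parent_b); value is the product.
COMPOSITES = {
    "lee_girl_verb": ("lee_girl_together", "verb"),
    "arthur_adjective": ("arthur_speaking", "adjective"),
}


def validate_binary(table: pd.DataFrame) -> None:
    """Raise ``ValueError`` if any feature column contains values not in {0, 1}."""
    for col in table.columns:
        if col == "tr_index":
            continue
        vals = table[col].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"feature column {col!r} contains non-binary values")


def build_composites(
    table: pd.DataFrame,
    composites: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Return a copy of ``table`` with composite product columns appended.

    Each composite column equals the elementwise product of its two parent
    columns. Missing parents raise ``KeyError`` naming the column.
    """
    composites = COMPOSITES if composites is None else composites
    out = table.copy()
    for name, (a, b) in composites.items():
        for parent in (a, b):
            if parent not in out.columns:
                raise KeyError(f"composite {name!r} requires missing parent column {parent!r}")
        out[name] = (out[a].to_numpy() * out[b].to_numpy()).astype(int)
    return out


def rasterize_events(
    events: pd.DataFrame,
    bin_s: float,
    n_bins: int,
) -> pd.DataFrame:
    """Rasterize BIDS-style events (onset, duration, trial_type) to per-bin binaries.

    A feature's bit is set for every bin whose half-open interval
    ``[b*bin_s, (b+1)*bin_s)`` overlaps the event's ``[onset, onset+duration)``.
    Zero-duration events set the single bin containing the onset.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    required = {"onset", "duration", "trial_type"}
    missing = required - set(events.columns)
    if missing:
        raise KeyError(f"events table missing columns: {sorted(missing)}")

    features = sorted(events["trial_type"].unique())
    table = pd.DataFrame({"tr_index": np.arange(n_bins, dtype=int)})
    for feat in features:
        table[feat] = 0
    for _, row in events.iterrows():
        onset = float(row["onset"])
        duration = float(row["duration"])
        if onset < 0 or duration < 0:
            raise ValueError(f"negative onset/duration in event {row.to_dict()!r}")
        first = int(np.floor(onset / bin_s))
        if duration == 0.0:
            last = first  # point event lands in its containing bin
        else:
            # last bin whose start is strictly before the event's end
            last = int(np.ceil((onset + duration) / bin_s)) - 1
        first = max(first, 0)
        last = min(last, n_bins - 1)
        if first > last:
            continue
        col = table.columns.get_loc(row["trial_type"])
        table.iloc[first : last + 1, col] = 1
    return table
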
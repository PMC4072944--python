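"""Truth-recovery metrics for benchmarking the callers against planted
ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import FIVE_EVENTS, TruthSet


def _overlap_label(
    region: tuple[str, int, int], calls: pd.DataFrame, label_col: str
) -> str | None:
    """Label of the first call overlapping the region, or None."""
    chrom, start, end = region
    sel = calls[
        (calls["chrom"] == chrom) & (calls["start"] < end) & (start < calls["end"])
    ]
    if len(sel) == 0:
        return None
    return str(sel.iloc[0][label_col])


def event_recovery(truth: TruthSet, events: pd.DataFrame) -> pd.DataFrame:
    """Planted-vs-called label per planted five-type region.

    A planted region is recovered when an event call overlapping it carries
    the planted label; a region with no overlapping call is scored as
    missed (called label None).
    """
    regions = truth.regions()
    regions = regions[regions["event_label"].isin(FIVE_EVENTS)]
    rows = []
    for r in regions.itertuples(index=False):
        called = _overlap_label((r.chrom, r.start, r.end), events, "event")
        rows.append(
            {
                "chrom": r.chrom, "start": r.start, "end": r.end,
                "planted": r.event_label, "called": called,
                "correct": called == r.event_label,
            }
        )
    return pd.DataFrame(rows)


def event_recovery_accuracy(truth: TruthSet, events: pd.DataFrame) -> float:
    table = event_recovery(truth, events)
    if len(table) == 0:
        return float("nan")
    return float(table["correct"].mean())


def binding_call_fdp(
    calls: pd.DataFrame, truth: TruthSet, factor: str = "A", condition: str = "wt"
) -> float:
    """Realised false-discovery proportion: fraction of called intervals not
    overlapping any region planted for the given factor/condition."""
    planted = truth.planted_binding
    planted = planted[(planted["factor"] == factor) & (planted["condition"] == condition)]
    if len(calls) == 0:
        return 0.0
    false = 0
    for iv in calls.itertuples(index=False):
        hit = (
            (planted["chrom"] == iv.chrom)
            & (planted["start"] < iv.end)
            & (iv.start < planted["end"])
        ).any()
        false += not hit
    return false / len(calls)
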
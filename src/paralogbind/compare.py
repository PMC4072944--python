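"""Joint comparison of binding profiles for two paralogous factors across
wild-type and reciprocal-mutant backgrounds.

All profiles share one probe layout and are quantile-normalised together, so
a probe value corresponds to the same empirical quantile in every dataset and
a single common threshold t separates bound from unbound in all of them.
Probe-level boolean states are segmented into regions and, for the three-way
wild-type A / wild-type B / A-in-B-mutant design, each region is assigned one
of five event types describing how factor A's binding responds to the loss
of its paralog B:

    bA and bM, gain >= delta        -> increased
    bA and bM, |gain| <  delta      -> no_change
    bA and not bM                   -> loss
    not bA and bB and bM            -> compensation
    not bA and not bB and bM        -> de_novo
    anything else with binding      -> unclassified

where bA/bB/bM are region-mean scores >= t in wild-type A, wild-type B and
A-in-B-mutant respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import SignalProfile, quantile_normalize

EVENT_TYPES = ("no_change", "compensation", "increased", "de_novo", "loss")


@dataclass
class JointProfiles:
    """Jointly quantile-normalised replicate-mean profiles on one layout."""

    layout: pd.DataFrame
    columns: dict[str, np.ndarray]
    t: float
    min_run: int = 3
    max_gap: int = 200
    delta: float = 1.0


def joint_normalize(
    profiles: dict[str, SignalProfile],
    t: float | None = None,
    t_quantile: float = 0.95,
    min_run: int = 3,
    max_gap: int = 200,
    delta: float = 1.0,
) -> JointProfiles:
    """Quantile-normalise the replicate-mean columns of all profiles together.

    The common bound/unbound threshold t defaults to a hair above the
    ``t_quantile`` quantile of the pooled normalised values: probes at the
    quantile value itself are background, which keeps the rule well defined
    when the pooled distribution has an atom there (e.g. noise-free data).
    """
    labels = list(profiles)
    if len(labels) < 2:
        raise ValueError("need >= 2 profiles to normalise jointly")
    first = profiles[labels[0]].layout
    for lab in labels[1:]:
        other = profiles[lab].layout
        if len(other) != len(first) or not (
            (other["chrom"].to_numpy() == first["chrom"].to_numpy()).all()
            and (other["start"].to_numpy() == first["start"].to_numpy()).all()
        ):
            raise ValueError(f"profile {lab!r} is on a different probe layout")
    matrix = np.column_stack([profiles[lab].replicate_mean for lab in labels])
    normed = quantile_normalize(matrix)
    if t is None:
        t = float(np.nextafter(np.quantile(normed, t_quantile), np.inf))
    return JointProfiles(
        layout=first,
        columns={lab: normed[:, j] for j, lab in enumerate(labels)},
        t=t,
        min_run=min_run,
        max_gap=max_gap,
        delta=delta,
    )


def _segment_states(
    layout: pd.DataFrame, states: np.ndarray, max_gap: int
) -> list[tuple[int, int]]:
    """Maximal runs (as [first, last] probe index pairs) of identical state,
    broken at chromosome changes and inter-probe gaps > max_gap bp."""
    chroms = layout["chrom"].to_numpy()
    starts = layout["start"].to_numpy()
    ends = layout["end"].to_numpy()
    runs = []
    run_start = 0
    for i in range(1, len(layout)):
        broken = (
            states[i] != states[i - 1]
            or chroms[i] != chroms[i - 1]
            or starts[i] - ends[i - 1] > max_gap
        )
        if broken:
            runs.append((run_start, i - 1))
            run_start = i
    if len(layout):
        runs.append((run_start, len(layout) - 1))
    return runs


def compare_pair(joint: JointProfiles, col_a: str, col_b: str) -> pd.DataFrame:
    """Pairwise co-binding regions: both / unique_A / unique_B / neither.

    Runs shorter than min_run probes are absorbed into 'neither'.
    """
    if joint.t is None:
        raise ValueError("common threshold t not set")
    a = joint.columns[col_a]
    b = joint.columns[col_b]
    state_names = {3: "both", 2: "unique_A", 1: "unique_B", 0: "neither"}
    codes = 2 * (a >= joint.t).astype(int) + (b >= joint.t).astype(int)
    runs = _segment_states(joint.layout, codes, joint.max_gap)
    labels = []
    for lo, hi in runs:
        name = state_names[int(codes[lo])]
        if hi - lo + 1 < joint.min_run and name != "neither":
            name = "neither"
        labels.append(name)
    # merge adjacent runs that collapsed onto the same label
    merged: list[list] = []
    chroms = joint.layout["chrom"].to_numpy()
    starts = joint.layout["start"].to_numpy()
    ends = joint.layout["end"].to_numpy()
    for (lo, hi), name in zip(runs, labels):
        if (
            merged
            and merged[-1][3] == name
            and chroms[lo] == merged[-1][0]
            and starts[lo] - merged[-1][2] <= joint.max_gap
        ):
            merged[-1][2] = int(ends[hi])
            merged[-1][4].append((lo, hi))
        else:
            merged.append([chroms[lo], int(starts[lo]), int(ends[hi]), name, [(lo, hi)]])
    rows = []
    for chrom, start, end, name, pieces in merged:
        idx = np.concatenate([np.arange(lo, hi + 1) for lo, hi in pieces])
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "state": name,
                "n_probes": len(idx),
                f"mean_{col_a}": float(a[idx].mean()),
                f"mean_{col_b}": float(b[idx].mean()),
            }
        )
    return pd.DataFrame(rows)


def classify_events(
    joint: JointProfiles, wt_a: str, wt_b: str, mut_a: str
) -> pd.DataFrame:
    """Assign the five mutant-comparison event types to regions of the
    three-way state segmentation; regions bound nowhere are background and
    regions failing the truth table are 'unclassified'."""
    for col in (wt_a, wt_b, mut_a):
        if col not in joint.columns:
            raise ValueError(f"column {col!r} not in this joint set")
    a = joint.columns[wt_a]
    b = joint.columns[wt_b]
    m = joint.columns[mut_a]
    codes = (
        4 * (a >= joint.t).astype(int)
        + 2 * (b >= joint.t).astype(int)
        + (m >= joint.t).astype(int)
    )
    runs = _segment_states(joint.layout, codes, joint.max_gap)
    chroms = joint.layout["chrom"].to_numpy()
    starts = joint.layout["start"].to_numpy()
    ends = joint.layout["end"].to_numpy()
    rows = []
    for lo, hi in runs:
        n = hi - lo + 1
        if n < joint.min_run:
            continue
        idx = slice(lo, hi + 1)
        mean_a, mean_b, mean_m = float(a[idx].mean()), float(b[idx].mean()), float(m[idx].mean())
        b_a, b_b, b_m = mean_a >= joint.t, mean_b >= joint.t, mean_m >= joint.t
        if not (b_a or b_b or b_m):
            continue  # background
        change = mean_m - mean_a
        if b_a and b_m:
            if change >= joint.delta:
                event = "increased"
            elif abs(change) < joint.delta:
                event = "no_change"
            else:
                event = "unclassified"
        elif b_a and not b_m:
            event = "loss"
        elif b_b and b_m:  # not b_a
            event = "compensation"
        elif b_m:  # not b_a, not b_b
            event = "de_novo"
        else:
            event = "unclassified"
        rows.append(
            {
                "chrom": chroms[lo],
                "start": int(starts[lo]),
                "end": int(ends[hi]),
                "event": event,
                "wt_A_bound": b_a,
                "wt_B_bound": b_b,
                "mut_A_bound": b_m,
                "score_change": change,
                "n_probes": n,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "event",
            "wt_A_bound", "wt_B_bound", "mut_A_bound",
            "score_change", "n_probes",
        ],
    )


def summarize_events(
    events: pd.DataFrame, gene_assignments: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-event region counts and, when interval-to-gene assignments are
    given, distinct gene counts — the shape of the published mutant-binding
    summary table."""
    order = list(EVENT_TYPES) + ["unclassified"]
    counts = {e: 0 for e in order}
    if len(events):
        counts.update(events["event"].value_counts().to_dict())
    table = pd.DataFrame({"event": order, "regions": [counts[e] for e in order]})
    if gene_assignments is not None and len(events):
        merged = events.merge(
            gene_assignments, on=["chrom", "start", "end"], how="left"
        )
        gene_counts = (
            merged.dropna(subset=["gene_id"]).groupby("event")["gene_id"].nunique()
        )
        table["genes"] = [int(gene_counts.get(e, 0)) for e in order]
    return table
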
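"""Binding-interval calling from tiling-array probe log-ratios.

The pipeline is: quantile-normalise the replicate probe matrix, combine
replicates by mean, smooth with a running median over a +/-half_width bp
window, choose a score threshold controlling the false discovery rate with a
sign-flip (antiprofile) estimator, and call maximal probe runs above the
threshold as binding intervals.  A core set keeps the reference (DamID)
intervals supported by at least one base of overlap with a support (ChIP)
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_FDR_LEVELS = (0.01, 0.05, 0.10, 0.25)


class NoThresholdError(RuntimeError):
    """No score threshold achieves the requested FDR."""


@dataclass
class SignalProfile:
    """Per-probe replicate log2 ratios on a probe layout."""

    layout: pd.DataFrame  # probe_id, chrom, start, end; sorted
    values: np.ndarray  # n_probes x n_replicates
    assay_class: str = "DamID"  # "DamID" | "ChIP"
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.layout):
            raise ValueError(
                f"profile {self.label!r}: {self.values.shape[0]} rows for "
                f"{len(self.layout)} probes"
            )

    @property
    def replicate_mean(self) -> np.ndarray:
        return self.values.mean(axis=1)


@dataclass
class WindowScore:
    layout: pd.DataFrame
    scores: np.ndarray  # NaN where coverage < min_probes
    half_width: int
    min_probes_in_window: int


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Map every column onto the across-column mean of sorted values.

    Ranks within each column are preserved; ties receive the average of the
    reference values they span.  A constant column (all ranks tied) maps to
    the mean of the reference distribution.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 columns")
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")  # 1..n, ties averaged
        # fractional ranks interpolate between reference order statistics
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), reference)
    return out


def smooth_windows(
    profile: SignalProfile, half_width: int = 250, min_probes: int = 3
) -> WindowScore:
    """Running median of replicate-mean ratios over probes whose midpoints lie
    within +/-half_width bp; NaN where fewer than min_probes probes fall in
    the window."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    layout = profile.layout
    signal = profile.replicate_mean
    mids = ((layout["start"].to_numpy() + layout["end"].to_numpy()) // 2).astype(float)
    chroms = layout["chrom"].to_numpy()
    scores = np.full(len(layout), np.nan)
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        m = mids[sel]
        v = signal[sel]
        left = np.searchsorted(m, m - half_width, side="left")
        right = np.searchsorted(m, m + half_width, side="right")
        for k in range(len(sel)):
            if right[k] - left[k] >= min_probes:
                scores[sel[k]] = np.median(v[left[k] : right[k]])
    return WindowScore(layout, scores, half_width, min_probes)


def call_intervals(
    window: WindowScore,
    threshold: float,
    min_probes: int = 3,
    max_gap: int = 200,
) -> pd.DataFrame:
    """Maximal runs of probes with score >= threshold, allowing inter-probe
    gaps <= max_gap bp (gap = next probe start - previous probe end), keeping
    runs of >= min_probes probes.  Interval spans first probe start to last
    probe end."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    layout = window.layout
    above = np.nan_to_num(window.scores, nan=-np.inf) >= threshold
    rows = []
    chroms = layout["chrom"].to_numpy()
    starts = layout["start"].to_numpy()
    ends = layout["end"].to_numpy()
    scores = window.scores
    run: list[int] = []

    def flush(run: list[int]) -> None:
        if len(run) >= min_probes:
            rows.append(
                {
                    "chrom": chroms[run[0]],
                    "start": int(starts[run[0]]),
                    "end": int(ends[run[-1]]),
                    "max_score": float(np.nanmax(scores[run])),
                    "n_probes": len(run),
                }
            )

    for i in range(len(layout)):
        if not above[i]:
            continue
        if run and (chroms[i] != chroms[run[-1]] or starts[i] - ends[run[-1]] > max_gap):
            flush(run)
            run = []
        run.append(i)
    if run:
        flush(run)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "max_score", "n_probes"])


def _n_intervals(window: WindowScore, threshold: float, min_probes: int, max_gap: int) -> int:
    return len(call_intervals(window, threshold, min_probes, max_gap))


def estimate_fdr_threshold(
    window: WindowScore,
    target_fdr: float,
    min_probes: int = 3,
    max_gap: int = 200,
    n_grid: int = 100,
) -> float:
    """Smallest threshold t with estimated FDR(t) <= target_fdr.

    FDR(t) is the ratio of interval counts called on the sign-flipped score
    profile to those called on the real profile at t, made monotone
    nonincreasing in t by a running minimum.  On a signal-free symmetric
    profile this is an unbiased estimate of the false discovery proportion.
    """
    if not (0 < target_fdr < 1):
        raise ValueError("target_fdr must be in (0, 1)")
    scores = window.scores[np.isfinite(window.scores)]
    positive = scores[scores > 0]
    if positive.size == 0:
        raise NoThresholdError("no positive window scores; cannot set a threshold")
    qs = np.linspace(0, 1, n_grid)
    candidates = np.unique(np.quantile(positive, qs))
    flipped = WindowScore(
        window.layout, -window.scores, window.half_width, window.min_probes_in_window
    )
    best = np.inf
    running_min = np.inf
    for t in candidates:  # increasing t
        n_pos = _n_intervals(window, t, min_probes, max_gap)
        if n_pos == 0:
            continue
        n_neg = _n_intervals(flipped, t, min_probes, max_gap)
        running_min = min(running_min, n_neg / n_pos)
        if running_min <= target_fdr:
            best = t
            break
    if not np.isfinite(best):
        raise NoThresholdError(f"no threshold achieves FDR <= {target_fdr}")
    return float(best)


def call_at_fdr_levels(
    window: WindowScore,
    levels: tuple[float, ...] = DEFAULT_FDR_LEVELS,
    min_probes: int = 3,
    max_gap: int = 200,
) -> dict[float, pd.DataFrame]:
    """Binding intervals at each FDR level (Table-1A-shaped structure)."""
    out = {}
    for level in levels:
        t = estimate_fdr_threshold(window, level, min_probes, max_gap)
        calls = call_intervals(window, t, min_probes, max_gap)
        calls = calls.assign(fdr_level=level, threshold=t)
        out[level] = calls
    return out


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def core_intersect(
    reference_sets: dict[str, pd.DataFrame],
    support_sets: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Keep reference (DamID) intervals overlapping >= 1 bp with an interval
    from >= 1 support (ChIP) set; retained rows keep reference coordinates and
    record the reference and supporting labels."""
    import warnings

    rows = []
    for ref_label, ref in reference_sets.items():
        if len(ref) == 0:
            warnings.warn(f"empty reference set {ref_label!r}", stacklevel=2)
            continue
        for iv in ref.itertuples(index=False):
            support = []
            for sup_label, sup in support_sets.items():
                sup_chr = sup[sup["chrom"] == iv.chrom]
                hit = (
                    (sup_chr["start"] < iv.end) & (iv.start < sup_chr["end"])
                ).any()
                if hit:
                    support.append(sup_label)
            if support:
                rows.append(
                    {
                        "chrom": iv.chrom,
                        "start": iv.start,
                        "end": iv.end,
                        "reference": ref_label,
                        "support": ",".join(support),
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "reference", "support"])
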
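"""Time-course differential expression with empirical-Bayes moderated
statistics and -1/0/+1 trend scoring.

The design is a replicated mutant-vs-control log2-ratio matrix over T ordered
timepoints.  Per gene we fit timepoint means and a pooled residual variance
s^2 on df = sum_t (n_t - 1) degrees of freedom, shrink the variances toward a
common prior by fitting a scaled inverse-chi-square prior (s^2 ~ s0^2 *
F(df, d0)) by method of moments on log s^2, and test each timepoint mean with
a moderated t on d0 + df degrees of freedom plus an overall moderated F.

Genes passing the overall-F gate get a score of -1, 0 or +1 per timepoint
(sign of the mean where the per-timepoint adjusted p clears its own gate,
else 0) and are partitioned into downregulated / upregulated / variable by
the signs present in the score vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

REQUIRED_COLUMNS = ("gene_id", "timepoint", "replicate", "value")


def _check_long(matrix: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in matrix.columns]
    if missing:
        raise ValueError(f"expression matrix lacks columns {missing}")


def normalize_expression(
    matrix: pd.DataFrame, mode: str = "ratio", glog_scale: float = 1.0
) -> pd.DataFrame:
    """Normalise a long-format expression table.

    mode="ratio" passes precomputed log ratios through unchanged.
    mode="intensity" applies a generalised-log (arsinh) transform followed by
    per-array median centring, where an array is one (timepoint, replicate)
    hybridisation.  The transform is monotone within each array.
    """
    _check_long(matrix)
    if mode == "ratio":
        return matrix.copy()
    if mode != "intensity":
        raise ValueError(f"unknown mode {mode!r}")
    bad = matrix[matrix["value"] <= 0]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            "non-positive intensity at "
            f"(gene {row['gene_id']}, timepoint {row['timepoint']}, "
            f"replicate {row['replicate']}): {row['value']}"
        )
    out = matrix.copy()
    out["value"] = np.arcsinh(out["value"].to_numpy() / glog_scale)
    centred = out.groupby(["timepoint", "replicate"])["value"].transform("median")
    out["value"] = out["value"] - centred
    return out


@dataclass
class GenewiseFit:
    gene_ids: np.ndarray
    timepoints: np.ndarray  # ordered labels
    means: np.ndarray  # genes x timepoints
    n_per_timepoint: np.ndarray  # genes x timepoints
    s2: np.ndarray  # pooled residual variance per gene
    df: np.ndarray  # residual df per gene


def fit_genewise_model(matrix: pd.DataFrame) -> GenewiseFit:
    """Per-gene timepoint means and pooled residual variance.

    Cells (gene, timepoint, replicate) may be missing; df is recomputed per
    gene as sum_t (n_t - 1).  Aborts if no gene has any residual df.
    """
    _check_long(matrix)
    timepoints = np.array(sorted(matrix["timepoint"].unique()))
    genes = np.array(sorted(matrix["gene_id"].unique()))
    g_idx = {g: i for i, g in enumerate(genes)}
    t_idx = {t: j for j, t in enumerate(timepoints)}
    G, T = len(genes), len(timepoints)
    sums = np.zeros((G, T))
    sqs = np.zeros((G, T))
    ns = np.zeros((G, T))
    gi = matrix["gene_id"].map(g_idx).to_numpy()
    ti = matrix["timepoint"].map(t_idx).to_numpy()
    v = matrix["value"].to_numpy(dtype=float)
    ok = np.isfinite(v)
    np.add.at(sums, (gi[ok], ti[ok]), v[ok])
    np.add.at(sqs, (gi[ok], ti[ok]), v[ok] ** 2)
    np.add.at(ns, (gi[ok], ti[ok]), 1.0)
    empty = ns.min(axis=1) < 1
    if empty.any():
        import warnings

        warnings.warn(
            f"dropping {int(empty.sum())} gene(s) with an empty timepoint cell",
            stacklevel=2,
        )
        keep = ~empty
        genes, sums, sqs, ns = genes[keep], sums[keep], sqs[keep], ns[keep]
        if len(genes) == 0:
            raise ValueError("every gene has an empty timepoint cell")
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / ns
    rss = (sqs - ns * means**2).clip(min=0.0).sum(axis=1)
    df = (ns - 1).sum(axis=1)
    if (df <= 0).all():
        raise ValueError("no residual degrees of freedom in any gene")
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df > 0, rss / np.maximum(df, 1), np.nan)
    return GenewiseFit(genes, timepoints, means, ns, s2, df)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


@dataclass
class VarianceModeration:
    d0: float  # prior df; inf when no excess spread in log s^2
    s0_2: float  # prior variance
    s2_post: np.ndarray  # posterior (moderated) variances


def moderate_variances(s2: np.ndarray, df: np.ndarray | float) -> VarianceModeration:
    """Fit the scaled-F prior for genewise variances by method of moments on
    log s^2 and return the posterior variances
    (d0*s0^2 + df*s^2) / (d0 + df).

    When the observed spread of log s^2 does not exceed the chi-square
    sampling spread, d0 is infinite and every posterior variance equals s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (df > 0) & np.isfinite(s2)
    if ok.sum() < 10:
        raise ValueError("need >= 10 genes with positive residual df")
    if (s2[ok] == 0).all():
        raise ValueError("all residual variances are zero; moderation degenerate")
    # offset log to tolerate occasional exact zeros
    z = np.log(np.maximum(s2[ok], 1e-300))
    d = df[ok]
    e = z - special.digamma(d / 2) + np.log(d / 2)
    e_mean = e.mean()
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1) - np.mean(special.polygamma(1, d / 2)))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        # no excess spread beyond chi-square sampling noise: common variance
        d0 = math.inf
        s0_2 = float(s2[ok].mean())
    if math.isinf(d0):
        post = np.full_like(s2, s0_2)
    else:
        post = (d0 * s0_2 + df * s2) / (d0 + df)
        post = np.where(ok, post, np.nan)
    return VarianceModeration(d0=float(d0), s0_2=s0_2, s2_post=post)


@dataclass
class ModeratedStats:
    fit: GenewiseFit
    moderation: VarianceModeration
    t: np.ndarray  # genes x timepoints
    p_t: np.ndarray  # genes x timepoints, two-sided
    q_t: np.ndarray  # BH within each timepoint
    F: np.ndarray  # per gene
    p_F: np.ndarray
    q_F: np.ndarray
    df_total: np.ndarray


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def moderated_tests(fit: GenewiseFit, moderation: VarianceModeration) -> ModeratedStats:
    """Per-timepoint moderated t statistics and the overall moderated F.

    t_gt = mean_gt / (s_post_g * sqrt(1/n_gt)) on d0 + df_g degrees of
    freedom; F_g is the mean of squared per-timepoint t values, referred to an
    F distribution on (T, d0 + df_g).
    """
    s_post = np.sqrt(moderation.s2_post)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = s_post[:, None] / np.sqrt(fit.n_per_timepoint)
        t = fit.means / se
    df_total = moderation.d0 + fit.df
    G, T = t.shape
    p_t = np.full_like(t, np.nan)
    p_F = np.full(G, np.nan)
    F = np.nanmean(t**2, axis=1)
    finite_df = np.isfinite(df_total)
    if np.any(finite_df):
        dft = df_total[finite_df]
        p_t[finite_df] = 2 * stats.t.sf(np.abs(t[finite_df]), dft[:, None])
        p_F[finite_df] = stats.f.sf(F[finite_df], T, dft)
    if np.any(~finite_df):
        p_t[~finite_df] = 2 * stats.norm.sf(np.abs(t[~finite_df]))
        p_F[~finite_df] = stats.chi2.sf(T * F[~finite_df], T)
    q_t = np.column_stack([bh_adjust(p_t[:, j]) for j in range(T)])
    q_F = bh_adjust(p_F)
    return ModeratedStats(fit, moderation, t, p_t, q_t, F, p_F, q_F, df_total)


TREND_CLASSES = ("down", "up", "variable", "none")


def classify_scores(scores: np.ndarray) -> str:
    """Trend class of one -1/0/+1 score vector."""
    has_neg = (scores < 0).any()
    has_pos = (scores > 0).any()
    if has_neg and has_pos:
        return "variable"
    if has_neg:
        return "down"
    if has_pos:
        return "up"
    return "none"


def score_and_partition(
    stats_: ModeratedStats,
    alpha_overall: float = 0.05,
    alpha_timepoint: float = 0.05,
) -> pd.DataFrame:
    """Per-gene -1/0/+1 score vector and trend class.

    A gene is eligible iff its overall-F BH q <= alpha_overall.  Eligible
    genes score sign(mean logFC) at timepoints whose per-timepoint BH
    q <= alpha_timepoint, else 0; ineligible genes score all zeros and class
    'none'.
    """
    fit = stats_.fit
    eligible = stats_.q_F <= alpha_overall
    sig = stats_.q_t <= alpha_timepoint
    scores = np.where(eligible[:, None] & sig, np.sign(fit.means).astype(int), 0)
    classes = [classify_scores(scores[g]) for g in range(len(fit.gene_ids))]
    out = pd.DataFrame(
        {
            "gene_id": fit.gene_ids,
            "class": classes,
            "q_F": stats_.q_F,
            "F": stats_.F,
        }
    )
    for j, tp in enumerate(fit.timepoints):
        out[f"score_{tp}"] = scores[:, j]
    return out


def run_de(
    matrix: pd.DataFrame,
    mode: str = "ratio",
    alpha_overall: float = 0.05,
    alpha_timepoint: float = 0.05,
) -> tuple[pd.DataFrame, ModeratedStats]:
    """Full pipeline: normalise, fit, moderate, test, score, partition."""
    normed = normalize_expression(matrix, mode=mode)
    fit = fit_genewise_model(normed)
    moderation = moderate_variances(fit.s2, fit.df)
    stats_ = moderated_tests(fit, moderation)
    trends = score_and_partition(stats_, alpha_overall, alpha_timepoint)
    return trends, stats_
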
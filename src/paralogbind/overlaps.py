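"""Interval-set and gene-set overlap statistics.

Overlap significance uses a Monte-Carlo null in which a query set's interval
count and length multiset are preserved but each interval is re-placed
uniformly at random within an allowed universe; the z-score compares the
observed number of query intervals hitting the other set with that null.
The null deliberately discards inter-interval spacing; it is declared in the
result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .expression import bh_adjust


def _trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals.itertuples(index=False):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _hits(setA: pd.DataFrame, trees: dict[str, IntervalTree], min_overlap: int) -> int:
    n = 0
    for iv in setA.itertuples(index=False):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_overlap:
                n += 1
                break
    return n


def count_overlaps(
    setA: pd.DataFrame, setB: pd.DataFrame, min_overlap: int = 1
) -> dict[str, int]:
    """Number of A intervals overlapping >= min_overlap bp with >= 1 B
    interval, and vice versa."""
    trees_b = _trees(setB)
    trees_a = _trees(setA)
    return {
        "n_A": len(setA),
        "n_B": len(setB),
        "n_A_hit": _hits(setA, trees_b, min_overlap),
        "n_B_hit": _hits(setB, trees_a, min_overlap),
    }


@dataclass
class OverlapResult:
    n_A: int
    n_B: int
    n_A_hit: int
    n_B_hit: int
    observed: float
    null_mean: float
    null_sd: float
    z_score: float
    n_iterations: int
    seed: int
    null_model: str = "length-matched uniform placement in universe"


def _sample_placements(
    lengths: np.ndarray, universe: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Place each length uniformly among all valid (universe interval, start)
    slots; intervals longer than every universe region are rejected."""
    u_chrom = universe["chrom"].to_numpy()
    u_start = universe["start"].to_numpy()
    u_len = (universe["end"] - universe["start"]).to_numpy()
    rows = []
    for l in lengths:
        slots = (u_len - l + 1).clip(min=0)
        total = slots.sum()
        if total <= 0:
            raise ValueError(f"interval of length {l} does not fit in the universe")
        j = rng.choice(len(universe), p=slots / total)
        start = int(u_start[j] + rng.integers(0, slots[j]))
        rows.append({"chrom": u_chrom[j], "start": start, "end": start + int(l)})
    return pd.DataFrame(rows)


def subsample_zscore(
    setA: pd.DataFrame,
    setB: pd.DataFrame,
    universe: pd.DataFrame,
    n_iterations: int = 1000,
    seed: int = 0,
    min_overlap: int = 1,
) -> OverlapResult:
    """Monte-Carlo overlap z-score for the number of A intervals hitting B."""
    rng = np.random.default_rng(seed)
    counts = count_overlaps(setA, setB, min_overlap)
    trees_b = _trees(setB)
    lengths = (setA["end"] - setA["start"]).to_numpy()
    null = np.empty(n_iterations)
    for it in range(n_iterations):
        placed = _sample_placements(lengths, universe, rng)
        null[it] = _hits(placed, trees_b, min_overlap)
    sd = float(null.std(ddof=1))
    z = (counts["n_A_hit"] - null.mean()) / sd if sd > 0 else float("nan")
    return OverlapResult(
        n_A=counts["n_A"],
        n_B=counts["n_B"],
        n_A_hit=counts["n_A_hit"],
        n_B_hit=counts["n_B_hit"],
        observed=float(counts["n_A_hit"]),
        null_mean=float(null.mean()),
        null_sd=sd,
        z_score=float(z),
        n_iterations=n_iterations,
        seed=seed,
    )


def crm_report(
    core_intervals: pd.DataFrame,
    crm_sets: dict[str, pd.DataFrame],
    core_genes: set | None = None,
) -> pd.DataFrame:
    """Per CRM collection: total CRMs, CRMs overlapped by the core intervals
    (count and percentage to one decimal), genes with >= 1 overlapped CRM and
    how many of the collection's genes are in the core gene list.

    CRM tables carry the owning gene in their ``name`` column.
    """
    import warnings

    trees_core = _trees(core_intervals)
    rows = []
    for name, crms in crm_sets.items():
        total = len(crms)
        if total == 0:
            warnings.warn(f"empty CRM set {name!r}", stacklevel=2)
            rows.append(
                {
                    "crm_set": name, "n_crms": 0, "n_overlapped": 0,
                    "pct_overlapped": 0.0, "n_genes": 0,
                    "n_genes_overlapped": 0, "n_genes_in_core": 0,
                }
            )
            continue
        hit_mask = [
            bool(trees_core.get(iv.chrom) and trees_core[iv.chrom].overlap(iv.start, iv.end))
            for iv in crms.itertuples(index=False)
        ]
        has_genes = "name" in crms.columns
        genes = set(crms["name"]) if has_genes else set()
        genes_hit = (
            set(crms.loc[hit_mask, "name"]) if has_genes else set()
        )
        rows.append(
            {
                "crm_set": name,
                "n_crms": total,
                "n_overlapped": int(sum(hit_mask)),
                "pct_overlapped": round(100.0 * sum(hit_mask) / total, 1),
                "n_genes": len(genes),
                "n_genes_overlapped": len(genes_hit),
                "n_genes_in_core": len(genes & core_genes) if core_genes else 0,
            }
        )
    return pd.DataFrame(rows)


def gene_overlap_orthology(
    genesA: set, genesB: set, ortho_map: pd.DataFrame
) -> dict:
    """Cross-species gene-set overlap through a (possibly many-to-many)
    orthology map with columns (gene_b, gene_a): a B gene is conserved iff at
    least one of its mapped A orthologues is in genesA.  Unmapped B genes are
    counted, never silently dropped."""
    genesA, genesB = set(genesA), set(genesB)
    by_b: dict = {}
    for row in ortho_map.itertuples(index=False):
        by_b.setdefault(row.gene_b, set()).add(row.gene_a)
    conserved_b = set()
    covered_a = set()
    unmapped = 0
    for g in genesB:
        orthos = by_b.get(g)
        if not orthos:
            unmapped += 1
            continue
        hits = orthos & genesA
        if hits:
            conserved_b.add(g)
            covered_a |= hits
    return {
        "n_A": len(genesA),
        "n_B": len(genesB),
        "n_B_conserved": len(conserved_b),
        "fraction_B_conserved": len(conserved_b) / len(genesB) if genesB else float("nan"),
        "n_A_covered": len(covered_a),
        "fraction_A_covered": len(covered_a) / len(genesA) if genesA else float("nan"),
        "n_B_unmapped": unmapped,
    }


def term_enrichment(
    study_genes: set, population_genes: set, term_map: pd.DataFrame
) -> pd.DataFrame:
    """Flat hypergeometric upper-tail enrichment per term with BH adjustment.

    term_map columns: (gene_id, term).  Study genes must be a subset of the
    population."""
    study, population = set(study_genes), set(population_genes)
    stray = study - population
    if stray:
        raise ValueError(f"study genes not in population: {sorted(stray)[:5]}")
    tm = term_map[term_map["gene_id"].isin(population)]
    M, n = len(population), len(study)
    rows = []
    for term, group in tm.groupby("term"):
        members = set(group["gene_id"])
        K = len(members)
        k = len(members & study)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append({"term": term, "n_term": K, "n_study_hit": k, "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["term", "n_term", "n_study_hit", "p_value"])
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    else:
        out["q_value"] = []
    return out.sort_values("p_value").reset_index(drop=True)
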
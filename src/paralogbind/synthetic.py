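"""Synthetic genomes, tiled probe layouts, binding profiles and expression
time courses with planted ground truth.

The generator emulates the substrate of a tiling-array study of two
paralogous DNA-binding factors, A and B, assayed in wild type and in the
null mutant of the other paralog.  Planted enrichment is a flat plateau of a
stated log2 amplitude over each planted interval; a probe's expected ratio is
the sum of amplitudes of the planted regions covering it in that
factor/condition, plus Gaussian noise per replicate.  Expression truth
follows four trend classes over a replicated 5-timepoint mutant-vs-control
course: down (negative log-fold-change throughout), up (positive
throughout), variable (down early, up mid-course, back to baseline late) and
null.

Everything is a pure function of its arguments and the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .binding import SignalProfile

BASES = np.array(list("ACGT"))

PROFILE_KEYS = {
    ("A", "wt"): "A_wt",
    ("B", "wt"): "B_wt",
    ("A", "mutant_of_other"): "A_in_Bmut",
    ("B", "mutant_of_other"): "B_in_Amut",
}

# event -> (factor, condition, amplitude) rows; "high" means amplitude +
# increase_delta.  The five mutant-comparison event types describe factor A's
# response to losing B; "reduced", "unique_B" and "unique_B_strong" are
# background landscape fillers (B's own stable binding and partial A
# reductions) that the three-way classifier reports as unclassified.
EVENT_AMPLITUDES = {
    "no_change": [
        ("A", "wt", "base"), ("A", "mutant_of_other", "base"),
        ("B", "wt", "base"), ("B", "mutant_of_other", "base"),
    ],
    "compensation": [
        ("B", "wt", "base"), ("B", "mutant_of_other", "base"),
        ("A", "mutant_of_other", "base"),
    ],
    "increased": [("A", "wt", "base"), ("A", "mutant_of_other", "high")],
    "de_novo": [("A", "mutant_of_other", "base")],
    "loss": [("A", "wt", "base")],
    "reduced": [("A", "wt", "high"), ("A", "mutant_of_other", "base")],
    "unique_B": [("B", "wt", "base"), ("B", "mutant_of_other", "base")],
    "unique_B_strong": [("B", "wt", "high"), ("B", "mutant_of_other", "high")],
    "common": [("A", "wt", "base"), ("B", "wt", "base")],
    "unique_A": [("A", "wt", "base")],
}

# Region multiplicities making all four datasets share one signal
# distribution (n regions at base amplitude in every column match, as do the
# high-amplitude ones), so joint quantile normalisation is amplitude-
# preserving in the noise-free limit.
BALANCED_EVENT_COUNTS = {
    "no_change": 1, "compensation": 1, "increased": 1, "de_novo": 1,
    "loss": 2, "reduced": 1, "unique_B": 2, "unique_B_strong": 1,
}

FIVE_EVENTS = ("no_change", "compensation", "increased", "de_novo", "loss")

VARIABLE_TEMPLATE = (-1.0, -1.0, 1.0, 1.0, 0.0)


@dataclass
class SyntheticGenomeSpec:
    n_chromosomes: int = 2
    chrom_lengths: tuple[int, ...] = (300_000, 300_000)
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (2_000, 8_000)
    exons_per_gene_range: tuple[int, int] = (2, 5)
    utr_fraction: float = 0.1
    overlap_probability: float = 0.05
    gc_background: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes != len(self.chrom_lengths):
            raise ValueError("n_chromosomes must match chrom_lengths")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.gene_length_range[0] <= 0 or self.gene_length_range[1] < self.gene_length_range[0]:
            raise ValueError("bad gene_length_range")
        if self.gene_length_range[1] > max(self.chrom_lengths):
            raise ValueError("gene_length_range exceeds every chromosome length")
        if not 0 <= self.utr_fraction <= 1:
            raise ValueError("utr_fraction must be in [0,1]")
        if not 0 <= self.overlap_probability <= 1:
            raise ValueError("overlap_probability must be in [0,1]")
        if not 0 < self.gc_background < 1:
            raise ValueError("gc_background must be in (0,1)")


@dataclass
class GenomeAnnotation:
    chrom_lengths: dict[str, int]
    genes: list[GeneModel]

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)


@dataclass
class TruthSet:
    """Planted binding regions and expression trends.

    planted_binding rows: chrom, start, end, factor, condition, amplitude,
    event_label — one row per (region, profile) with non-zero signal, so a
    region participating in several profiles appears several times under the
    same event_label.
    planted_expression rows: gene_id, trend_class, effect_size.
    """

    planted_binding: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "factor", "condition", "amplitude", "event_label"]
        )
    )
    planted_expression: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "trend_class", "effect_size"]
        )
    )

    def regions(self) -> pd.DataFrame:
        """Unique planted regions with their event labels."""
        return (
            self.planted_binding[["chrom", "start", "end", "event_label"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )


def _make_gene(
    rng: np.random.Generator, gene_id: str, chrom: str, start: int, length: int,
    spec: SyntheticGenomeSpec,
) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    end = start + length
    k = int(rng.integers(spec.exons_per_gene_range[0], spec.exons_per_gene_range[1] + 1))
    # 2k-1 alternating exon/intron segments from random interior cuts
    if k == 1:
        exons = [(start, end)]
    else:
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * k - 2, replace=False))
        bounds = np.concatenate([[0], cuts, [length]])
        exons = [
            (start + int(bounds[i]), start + int(bounds[i + 1]))
            for i in range(0, 2 * k - 1, 2)
        ]
    utrs = []
    utr_len = int(spec.utr_fraction * length / 2)
    if utr_len > 0:
        first, last = exons[0], exons[-1]
        utrs.append((first[0], min(first[0] + utr_len, first[1])))
        utrs.append((max(last[1] - utr_len, last[0]), last[1]))
    return GeneModel(gene_id, chrom, strand, start, end, exons, utrs)


def generate_genome(spec: SyntheticGenomeSpec) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Stranded gene models with exon/intron/UTR structure plus random
    sequence at the requested GC composition; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    chrom_lengths = {
        f"chr{i + 1}": int(l) for i, l in enumerate(spec.chrom_lengths)
    }
    g = spec.gc_background
    probs = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    sequences = {
        c: "".join(rng.choice(BASES, size=l, p=probs)) for c, l in chrom_lengths.items()
    }
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    chrom_ids = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chrom_ids], dtype=float)
    weights /= weights.sum()
    for gi in range(spec.n_genes):
        placed = False
        for _ in range(200):
            chrom = chrom_ids[int(rng.choice(len(chrom_ids), p=weights))]
            L = chrom_lengths[chrom]
            length = int(rng.integers(spec.gene_length_range[0], spec.gene_length_range[1] + 1))
            if length > L:
                continue
            start = int(rng.integers(0, L - length + 1))
            overlaps = any(start < e and s < start + length for s, e in occupied[chrom])
            if overlaps and rng.random() >= spec.overlap_probability:
                continue
            genes.append(
                _make_gene(rng, f"gene{gi + 1:04d}", chrom, start, length, spec)
            )
            occupied[chrom].append((start, start + length))
            placed = True
            break
        if not placed:
            warnings.warn(f"could not place gene {gi + 1}; genome may be crowded", stacklevel=2)
    return GenomeAnnotation(chrom_lengths, genes), sequences


def generate_probe_layout(
    genome: GenomeAnnotation, spacing: int = 100, probe_length: int = 50
) -> pd.DataFrame:
    """Tiled probes at starts 0, spacing, 2*spacing, ... per chromosome,
    0-based half-open, sorted by (chrom, start)."""
    if spacing <= 0 or probe_length <= 0:
        raise ValueError("spacing and probe_length must be positive")
    rows = []
    for chrom, L in genome.chrom_lengths.items():
        if probe_length > L:
            warnings.warn(f"probe_length {probe_length} exceeds {chrom} length {L}", stacklevel=2)
            continue
        n = (L - probe_length) // spacing + 1
        starts = np.arange(n) * spacing
        for s in starts:
            rows.append(
                {"probe_id": f"{chrom}:{s}", "chrom": chrom, "start": int(s), "end": int(s + probe_length)}
            )
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"])


def plant_binding_events(
    genome: GenomeAnnotation,
    n_per_event: int = 8,
    amplitude: float = 3.0,
    increase_delta: float = 2.0,
    region_length: int = 600,
    margin: int = 2_000,
    event_counts: dict[str, int] | None = None,
    seed: int = 0,
) -> TruthSet:
    """Plant binding regions with known event labels, laid out with a clear
    margin between regions so no two planted regions share probes.

    By default a balanced landscape is planted (BALANCED_EVENT_COUNTS scaled
    by n_per_event) so that the four datasets have matching signal
    distributions; pass event_counts to plant a custom design.
    """
    rng = np.random.default_rng(seed)
    if event_counts is None:
        event_counts = {e: n * n_per_event for e, n in BALANCED_EVENT_COUNTS.items()}
    unknown = set(event_counts) - set(EVENT_AMPLITUDES)
    if unknown:
        raise ValueError(f"unknown event labels {sorted(unknown)}")
    slots = []
    for chrom, L in genome.chrom_lengths.items():
        pos = margin
        while pos + region_length + margin <= L:
            slots.append((chrom, pos))
            pos += region_length + margin
    need = sum(event_counts.values())
    if need > len(slots):
        raise ValueError(f"genome too small: {need} regions, {len(slots)} slots")
    chosen = sorted(rng.choice(len(slots), size=need, replace=False))
    labels = [e for e, n in event_counts.items() for _ in range(n)]
    rng.shuffle(labels)
    rows = []
    for slot_i, label in zip(chosen, labels):
        chrom, start = slots[slot_i]
        end = start + region_length
        for factor, condition, level in EVENT_AMPLITUDES[label]:
            amp = amplitude + increase_delta if level == "high" else amplitude
            rows.append(
                {
                    "chrom": chrom, "start": start, "end": end,
                    "factor": factor, "condition": condition,
                    "amplitude": amp, "event_label": label,
                }
            )
    return TruthSet(planted_binding=pd.DataFrame(rows))


def simulate_binding_profiles(
    genome: GenomeAnnotation,
    probes: pd.DataFrame,
    truth: TruthSet,
    noise_sd: float = 0.3,
    n_replicates: int = 3,
    seed: int = 0,
    assay_class: str = "DamID",
) -> dict[str, SignalProfile]:
    """Four replicate probe-ratio profiles (A wild type, B wild type, A in
    B-mutant, B in A-mutant): per probe, the sum of planted amplitudes of the
    regions covering it in that factor/condition plus Normal(0, noise_sd)
    noise per replicate."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    known = set(genome.chrom_lengths)
    bad = set(probes["chrom"]) - known
    if bad:
        raise ValueError(f"probes on unknown chromosomes {sorted(bad)}")
    rng = np.random.default_rng(seed)
    p_chrom = probes["chrom"].to_numpy()
    p_start = probes["start"].to_numpy()
    p_end = probes["end"].to_numpy()
    out: dict[str, SignalProfile] = {}
    for (factor, condition), key in PROFILE_KEYS.items():
        base = np.zeros(len(probes))
        rows = truth.planted_binding
        sel = rows[(rows["factor"] == factor) & (rows["condition"] == condition)]
        for r in sel.itertuples(index=False):
            covered = (p_chrom == r.chrom) & (p_start < r.end) & (r.start < p_end)
            base[covered] += r.amplitude
        noise = rng.normal(0.0, noise_sd, size=(len(probes), n_replicates)) if noise_sd > 0 else 0.0
        values = base[:, None] + noise if noise_sd > 0 else np.tile(base[:, None], (1, n_replicates))
        out[key] = SignalProfile(
            layout=probes, values=values,
            assay_class=assay_class, label=f"{key}_{assay_class}" if assay_class != "DamID" else key,
        )
    return out


def plant_expression_trends(
    genome: GenomeAnnotation,
    n_down: int = 10,
    n_up: int = 10,
    n_variable: int = 6,
    effect_size: float = 2.0,
    preferred_genes: Iterable[str] = (),
    preferred_fraction: float = 0.5,
    seed: int = 0,
) -> TruthSet:
    """Assign down/up/variable classes to randomly chosen genes; the rest are
    null.  When preferred_genes is given (e.g. genes near planted binding),
    roughly preferred_fraction of the trend genes are drawn from it first, so
    the binding/expression intersection is populated."""
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genome.genes]
    need = n_down + n_up + n_variable
    if need > len(gene_ids):
        raise ValueError(f"{need} trend genes requested, {len(gene_ids)} genes available")
    classes = ["down"] * n_down + ["up"] * n_up + ["variable"] * n_variable
    rng.shuffle(classes)
    preferred = [g for g in gene_ids if g in set(preferred_genes)]
    n_pref = min(int(round(need * preferred_fraction)), len(preferred))
    chosen_ids = list(rng.choice(preferred, size=n_pref, replace=False)) if n_pref else []
    rest = [g for g in gene_ids if g not in set(chosen_ids)]
    chosen_ids += list(rng.choice(rest, size=need - n_pref, replace=False))
    assigned = dict(zip(chosen_ids, classes))
    rows = []
    for g in gene_ids:
        rows.append(
            {
                "gene_id": g,
                "trend_class": assigned.get(g, "null"),
                "effect_size": effect_size if g in assigned else 0.0,
            }
        )
    return TruthSet(planted_expression=pd.DataFrame(rows))


def simulate_expression_timecourse(
    genome: GenomeAnnotation,
    truth: TruthSet,
    n_timepoints: int = 5,
    n_replicates: int = 4,
    noise_sd: float = 0.25,
    variable_template: tuple[float, ...] = VARIABLE_TEMPLATE,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format mutant-vs-control log2 ratios: gene_id, timepoint,
    replicate, value.

    Class down gives -effect at every timepoint, up gives +effect, variable
    follows the template (down early, up mid-course, baseline late) scaled by
    the effect size, null gives 0; Gaussian noise is added per observation.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    known = {g.gene_id for g in genome.genes}
    planted = truth.planted_expression
    stray = set(planted["gene_id"]) - known
    if stray:
        raise ValueError(f"planted genes not in genome: {sorted(stray)[:5]}")
    template = np.asarray(variable_template, dtype=float)
    # map template onto the requested number of timepoints
    t_map = np.round(np.linspace(0, len(template) - 1, n_timepoints)).astype(int)
    var_shape = template[t_map]
    rows = []
    for r in planted.itertuples(index=False):
        cls, eff = r.trend_class, r.effect_size
        if cls == "down":
            mu = np.full(n_timepoints, -eff)
        elif cls == "up":
            mu = np.full(n_timepoints, eff)
        elif cls == "variable":
            mu = var_shape * eff
        elif cls == "null":
            mu = np.zeros(n_timepoints)
        else:
            raise ValueError(f"unknown trend class {cls!r}")
        noise = (
            rng.normal(0.0, noise_sd, size=(n_timepoints, n_replicates))
            if noise_sd > 0
            else np.zeros((n_timepoints, n_replicates))
        )
        for t in range(n_timepoints):
            for rep in range(n_replicates):
                rows.append(
                    {
                        "gene_id": r.gene_id,
                        "timepoint": t + 1,
                        "replicate": rep + 1,
                        "value": float(mu[t] + noise[t, rep]),
                    }
                )
    return pd.DataFrame(rows, columns=["gene_id", "timepoint", "replicate", "value"])


def write_fixtures(
    directory,
    genome: GenomeAnnotation | None = None,
    sequences: dict[str, str] | None = None,
    probes: pd.DataFrame | None = None,
    profiles: dict[str, SignalProfile] | None = None,
    truth: TruthSet | None = None,
    expression: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write whichever objects are given to standard formats in directory:
    FASTA (sequences), GFF3 (genes), BED (probes, planted regions), TSV
    (replicate matrices, expression), SGR (replicate-mean tracks)."""
    import os

    from . import io as pio

    os.makedirs(directory, exist_ok=True)
    written: dict[str, str] = {}

    def path(name: str) -> str:
        p = os.path.join(directory, name)
        written[name] = p
        return p

    if sequences is not None:
        pio.write_fasta(sequences, path("genome.fa"))
    if genome is not None:
        pio.write_gff3(genome.genes, path("genes.gff3"))
    if probes is not None:
        pio.write_bed(
            probes.rename(columns={"probe_id": "name"}), path("probes.bed")
        )
    if truth is not None:
        if len(truth.planted_binding):
            truth.planted_binding.to_csv(path("truth_binding.tsv"), sep="\t", index=False)
        if len(truth.planted_expression):
            truth.planted_expression.to_csv(path("truth_expression.tsv"), sep="\t", index=False)
    if profiles is not None:
        for key, prof in profiles.items():
            mat = pd.DataFrame(
                prof.values,
                columns=[f"rep{j + 1}" for j in range(prof.values.shape[1])],
            )
            mat.insert(0, "probe_id", prof.layout["probe_id"].to_numpy())
            mat.to_csv(path(f"profile_{key}.tsv"), sep="\t", index=False)
            sgr = pd.DataFrame(
                {
                    "chrom": prof.layout["chrom"],
                    "position": (prof.layout["start"] + prof.layout["end"]) // 2,
                    "score": prof.replicate_mean,
                }
            )
            pio.write_sgr(sgr, path(f"profile_{key}.sgr"))
    if expression is not None:
        expression.to_csv(path("expression.tsv"), sep="\t", index=False)
    return written
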
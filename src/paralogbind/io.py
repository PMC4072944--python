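"""Reading and writing the plain-text genomic formats shared by all stages.

Coordinates are 0-based half-open everywhere in memory.  GFF3 is written
1-based closed per its standard; SGR is ``chrom TAB position TAB score``
sorted by position within chromosome.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write intervals as BED (up to 6 columns; missing ones filled)."""
    out = df.copy()
    if "name" not in out:
        out["name"] = [f"region_{i}" for i in range(len(out))]
    if "score" not in out:
        out["score"] = 0
    if "strand" not in out:
        out["strand"] = "."
    out = out[BED_COLUMNS]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_sgr(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a (chrom, position, score) track, position-sorted per chromosome."""
    out = df[["chrom", "position", "score"]].sort_values(
        ["chrom", "position"], kind="mergesort"
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_sgr(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "position", "score"])
    df["position"] = df["position"].astype(int)
    return df


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: Iterable, path: str | os.PathLike) -> None:
    """Write gene models (gene/exon/UTR features) as GFF3, 1-based closed."""
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(
            "\t".join(
                [
                    g.chrom,
                    "paralogbind",
                    "gene",
                    str(g.start + 1),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    f"ID={g.gene_id}",
                ]
            )
        )
        for i, (s, e) in enumerate(g.exons):
            lines.append(
                "\t".join(
                    [
                        g.chrom,
                        "paralogbind",
                        "exon",
                        str(s + 1),
                        str(e),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}.exon{i};Parent={g.gene_id}",
                    ]
                )
            )
        for i, (s, e) in enumerate(g.utrs):
            lines.append(
                "\t".join(
                    [
                        g.chrom,
                        "paralogbind",
                        "UTR",
                        str(s + 1),
                        str(e),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}.utr{i};Parent={g.gene_id}",
                    ]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path: str | os.PathLike) -> list:
    """Read gene models written by :func:`write_gff3` back into GeneModel objects."""
    from .annotation import GeneModel

    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split(
                "\t"
            )
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            s, e = int(start) - 1, int(end)
            if ftype == "gene":
                genes[fields["ID"]] = {
                    "gene_id": fields["ID"],
                    "chrom": chrom,
                    "strand": strand,
                    "start": s,
                    "end": e,
                    "exons": [],
                    "utrs": [],
                }
            elif ftype == "exon":
                genes[fields["Parent"]]["exons"].append((s, e))
            elif ftype == "UTR":
                genes[fields["Parent"]]["utrs"].append((s, e))
    return [GeneModel(**g) for g in genes.values()]
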
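"""Direct-target calling: the intersection of trend-scored differentially
expressed genes with genes assigned to core binding intervals, plus an
explicit manual rescue list for genes missed by interval-to-gene assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .expression import TREND_CLASSES


@dataclass
class DirectTargetSet:
    members: pd.DataFrame  # gene_id, trend_class, bound, rescued
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def call_direct_targets(
    trend_scores: pd.DataFrame,
    core_gene_ids: Iterable[str],
    rescue_list: Iterable[str] = (),
) -> DirectTargetSet:
    """Targets = {genes with trend class != none} ∩ {core-bound genes},
    plus every rescue-listed gene.  Rescued genes are flagged and keep their
    trend class; a rescued gene with class 'none' (or absent from the trend
    table) is included with a warning."""
    trend_by_gene = dict(zip(trend_scores["gene_id"], trend_scores["class"]))
    bound = set(core_gene_ids)
    rescue = list(dict.fromkeys(rescue_list))  # de-dup, keep order
    de_genes = {g for g, c in trend_by_gene.items() if c != "none"}
    base = sorted(de_genes & bound)
    rows = []
    for g in base:
        rows.append(
            {"gene_id": g, "trend_class": trend_by_gene[g], "bound": True, "rescued": False}
        )
    for g in rescue:
        if g in de_genes & bound:
            continue  # already a member; rescue flag not needed
        cls = trend_by_gene.get(g, "none")
        if cls == "none":
            warnings.warn(
                f"rescue gene {g!r} has no differential-expression trend", stacklevel=2
            )
        rows.append(
            {"gene_id": g, "trend_class": cls, "bound": g in bound, "rescued": True}
        )
    members = pd.DataFrame(rows, columns=["gene_id", "trend_class", "bound", "rescued"])
    counts = {
        cls: int((members["trend_class"] == cls).sum()) for cls in TREND_CLASSES
    }
    counts["total"] = len(members)
    return DirectTargetSet(members=members, counts=counts)
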
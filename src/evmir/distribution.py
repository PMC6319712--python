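"""Set logic for miRNA distribution across compartments and cell lines.

Detected-feature sets per compartment are partitioned Venn-style into
exclusive cells; EV-enrichment labels combine the up-calls of the two
EV-versus-cell-lysate contrasts; the cell-silent screen intersects
"not detected in the cell lysate" with "EV-enriched".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

__all__ = [
    "DistributionReport",
    "venn_partition",
    "ev_enrichment_call",
    "cell_silent_ev_screen",
    "cross_cellline_overlap",
]

ENRICHMENT_LABELS = ("enriched_sMV_only", "enriched_Exo_only", "enriched_both", "none")


@dataclass
class DistributionReport:
    """Exclusive Venn cells over named feature sets.

    ``cells`` maps a tuple of set names to the features present in exactly
    those sets and no others; the 2^k - 1 cells are disjoint and cover the
    union of the inputs.
    """

    sets: dict[str, set[str]]
    cells: dict[tuple[str, ...], set[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[tuple[str, ...], int]:
        return {names: len(members) for names, members in self.cells.items()}

    def cell(self, *names: str) -> set[str]:
        return self.cells.get(tuple(sorted(names)), set())

    def common_to_all(self) -> set[str]:
        return self.cell(*self.sets.keys())

    def union_size(self) -> int:
        return sum(len(m) for m in self.cells.values())

    def to_dict(self) -> dict[str, list[str]]:
        return {"&".join(names): sorted(members) for names, members in self.cells.items()}


def venn_partition(sets: dict[str, set[str]]) -> DistributionReport:
    """Partition the union of named sets into exclusive Venn cells.

    Every non-empty combination of set names gets a cell (possibly empty);
    inclusion-exclusion identities hold exactly, e.g.
    |A & B| = |A| + |B| - |A | B|.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least two named sets")
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names")
    cells: dict[tuple[str, ...], set[str]] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(sorted(names), k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            cells[combo] = inside - outside
    return DistributionReport(sets={n: set(s) for n, s in sets.items()}, cells=cells)


def ev_enrichment_call(
    calls_smv_vs_cl: pd.Series, calls_exo_vs_cl: pd.Series
) -> pd.Series:
    """Label each feature by which EV-vs-CL contrasts called it up.

    enriched_both when up in both sMV-vs-CL and Exo-vs-CL; *_only when up
    in exactly one; none otherwise.  Both call series must cover the same
    feature universe.
    """
    if set(calls_smv_vs_cl.index) != set(calls_exo_vs_cl.index):
        raise ValueError("contrasts cover different feature universes")
    calls_exo_vs_cl = calls_exo_vs_cl.reindex(calls_smv_vs_cl.index)
    up_smv = calls_smv_vs_cl == "up"
    up_exo = calls_exo_vs_cl == "up"
    labels = pd.Series("none", index=calls_smv_vs_cl.index, name="ev_enrichment")
    labels[up_smv & up_exo] = "enriched_both"
    labels[up_smv & ~up_exo] = "enriched_sMV_only"
    labels[~up_smv & up_exo] = "enriched_Exo_only"
    return labels


def cell_silent_ev_screen(
    cl_detected: set[str], enrichment_labels: pd.Series
) -> dict[str, set[str]]:
    """Features EV-enriched yet not detected in the cell lysate.

    "Not detected" means failing the detection rule (e.g. never above
    5 TPM in any CL replicate), not merely a low mean.  The result is
    partitioned by EV subtype; total = sMV_only + Exo_only + both.
    """
    silent = set(enrichment_labels.index) - set(cl_detected)
    parts = {
        "sMV_only": {f for f in silent if enrichment_labels[f] == "enriched_sMV_only"},
        "Exo_only": {f for f in silent if enrichment_labels[f] == "enriched_Exo_only"},
        "both": {f for f in silent if enrichment_labels[f] == "enriched_both"},
    }
    parts["total"] = parts["sMV_only"] | parts["Exo_only"] | parts["both"]
    return parts


def cross_cellline_overlap(ev_sets: dict[str, set[str]]) -> DistributionReport:
    """Full 4-way Venn over the EV feature sets of two cell lines.

    Expects exactly four named sets (2 cell lines x 2 EV subtypes); the
    common-to-all cell is the headline quantity.
    """
    if len(ev_sets) < 4:
        raise ValueError("cross-cell-line overlap needs four EV feature sets")
    return venn_partition(ev_sets)
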
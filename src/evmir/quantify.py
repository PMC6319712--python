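"""TPM quantification, replicate averaging, and the detection rule.

Expression is quantified as transcripts per million miRNA-mapped reads
(TPM): each library column of the count matrix is scaled to sum to one
million.  No length normalisation is applied -- mature miRNAs are
effectively uniform length and counts are read counts, so TPM here is a
reads-per-million quantity on the miRNA-assigned total.

A feature is "detected" in a compartment when its TPM exceeds a threshold
(default 5) in at least one replicate of that compartment; the comparison
is strictly greater-than.  A mean-based variant is available via
``rule="mean"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "DetectionTable",
    "compute_tpm",
    "average_replicates",
    "detect_features",
]

#: metadata columns every library descriptor table must carry
LIBRARY_FIELDS = ("cell_line", "compartment", "replicate")


@dataclass
class CountMatrix:
    """Raw integer miRNA counts per library plus library metadata.

    Parameters
    ----------
    counts
        Features (rows) by libraries (columns); non-negative integers.
    libraries
        One row per library (index = library id, matching ``counts``
        columns) with columns ``cell_line``, ``compartment``,
        ``replicate``.
    passenger
        Optional boolean series over features flagging passenger (star)
        strands; defaults to all-False.
    """

    counts: pd.DataFrame
    libraries: pd.DataFrame
    passenger: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.shape[0] < 1 or self.counts.shape[1] < 1:
            raise ValueError("count matrix needs at least one feature and one library")
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature identifiers: {dupes[:5]}")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate library identifiers")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                bad = np.argwhere(vals != np.round(vals))[0]
                raise ValueError(
                    f"non-integer count at feature {self.counts.index[bad[0]]!r}, "
                    f"library {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.round().astype(np.int64)
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at feature {self.counts.index[bad[0]]!r}, "
                f"library {self.counts.columns[bad[1]]!r}"
            )
        missing = [c for c in LIBRARY_FIELDS if c not in self.libraries.columns]
        if missing:
            raise ValueError(f"library metadata lacks columns {missing}")
        if set(self.libraries.index) != set(self.counts.columns):
            raise ValueError("library metadata index does not match count columns")
        self.libraries = self.libraries.loc[self.counts.columns]
        if self.passenger is None:
            self.passenger = pd.Series(False, index=self.counts.index)
        else:
            self.passenger = self.passenger.reindex(self.counts.index).fillna(False).astype(bool)

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    def library_ids(self, cell_line: str | None = None, compartment: str | None = None) -> list[str]:
        """Library ids matching the given cell line and/or compartment."""
        mask = pd.Series(True, index=self.libraries.index)
        if cell_line is not None:
            mask &= self.libraries["cell_line"] == cell_line
        if compartment is not None:
            mask &= self.libraries["compartment"] == compartment
        return list(self.libraries.index[mask])


@dataclass
class ExpressionMatrix:
    """TPM expression, either per library or per group after averaging."""

    tpm: pd.DataFrame
    libraries: pd.DataFrame | None = None  # None once averaged to group level

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")

    @property
    def features(self) -> pd.Index:
        return self.tpm.index


@dataclass
class DetectionTable:
    """Per feature x compartment detection calls and the rule that made them."""

    detected: pd.DataFrame  # boolean, features x groups
    threshold: float = 5.0
    rule: str = "any_replicate"

    def detected_set(self, group: str) -> set[str]:
        return set(self.detected.index[self.detected[group]])


def compute_tpm(counts: CountMatrix) -> ExpressionMatrix:
    """Scale each library to transcripts per million miRNA-mapped reads.

    tpm[f, l] = counts[f, l] / sum_f counts[f, l] * 1e6, so every library
    column sums to exactly one million before any filtering.
    """
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"library {zero.index[0]!r} has zero total miRNA-mapped reads")
    tpm = counts.counts / totals * 1e6
    return ExpressionMatrix(tpm=tpm, libraries=counts.libraries)


def average_replicates(
    expr: ExpressionMatrix, grouping: dict[str, list[str]]
) -> ExpressionMatrix:
    """Arithmetic mean of replicate TPM columns, one output column per group.

    ``grouping`` maps group name -> member library ids.  A single-member
    group passes through unchanged.
    """
    cols = {}
    for group, members in grouping.items():
        if len(members) == 0:
            raise ValueError(f"group {group!r} has no member libraries")
        missing = [m for m in members if m not in expr.tpm.columns]
        if missing:
            raise KeyError(f"group {group!r} references unknown libraries {missing}")
        cols[group] = expr.tpm[members].mean(axis=1)
    return ExpressionMatrix(tpm=pd.DataFrame(cols, index=expr.tpm.index))


def detect_features(
    expr: ExpressionMatrix,
    grouping: dict[str, list[str]],
    threshold: float = 5.0,
    rule: str = "any_replicate",
) -> DetectionTable:
    """Call a feature detected in a group when TPM > threshold.

    rule="any_replicate" (default): strictly greater than ``threshold`` in
    at least one replicate of the group.  rule="mean": the replicate mean
    must exceed the threshold.
    """
    if threshold < 0:
        raise ValueError("detection threshold must be non-negative")
    if rule not in ("any_replicate", "mean"):
        raise ValueError(f"unknown detection rule {rule!r}")
    cols = {}
    for group, members in grouping.items():
        if len(members) == 0:
            raise ValueError(f"group {group!r} has no member libraries")
        sub = expr.tpm[members]
        if rule == "any_replicate":
            cols[group] = (sub > threshold).any(axis=1)
        else:
            cols[group] = sub.mean(axis=1) > threshold
    return DetectionTable(detected=pd.DataFrame(cols, index=expr.tpm.index),
                          threshold=threshold, rule=rule)


def compartment_grouping(counts: CountMatrix) -> dict[str, list[str]]:
    """Default grouping: one group per (cell_line, compartment) pair."""
    groups: dict[str, list[str]] = {}
    for lib_id, row in counts.libraries.iterrows():
        key = f"{row['cell_line']}-{row['compartment']}"
        groups.setdefault(key, []).append(lib_id)
    return groups
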
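"""Scan pre-miRNA sequences for literal EV-sorting motif candidates.

Candidate motifs (e.g. CUGU, the APC-binding element, or GGAG, recognised
by hnRNP A2B1) are literal RNA 4-mers; a precursor "has" the motif when it
contains at least one exact, case-insensitive substring occurrence.
Counting is at the sequence level -- a precursor counts once however many
times the motif occurs -- with all (possibly overlapping) occurrence
positions reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .classify import percent

__all__ = ["MotifReport", "scan_motif"]

logger = logging.getLogger(__name__)

RNA_ALPHABET = set("ACGU")


@dataclass
class MotifReport:
    motif: str
    n_sequences: int
    n_with_motif: int
    positions: dict[str, list[int]] = field(default_factory=dict)  # 0-based left ends
    n_occurrences: int = 0

    @property
    def fraction_pct(self) -> float:
        """Percent of sequences bearing the motif, rounded to 1 d.p."""
        return percent(self.n_with_motif, self.n_sequences)


def _find_all(seq: str, motif: str) -> list[int]:
    """All occurrence start positions, overlaps included."""
    hits, start = [], seq.find(motif)
    while start != -1:
        hits.append(start)
        start = seq.find(motif, start + 1)
    return hits


def scan_motif(sequences: dict[str, str], motif: str) -> MotifReport:
    """Count sequences containing the motif and locate every occurrence.

    ``sequences`` maps identifier -> sequence over {A, C, G, U}; DNA-style
    T is auto-mapped to U with a logged warning.  Matching is exact and
    case-insensitive; the reported fraction is sequence-level.
    """
    if not sequences:
        raise ValueError("empty sequence set")
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper().replace("T", "U")
    if set(motif) - RNA_ALPHABET:
        raise ValueError(f"motif {motif!r} has characters outside {{A,C,G,U}}")
    positions: dict[str, list[int]] = {}
    n_with, n_occ = 0, 0
    warned = False
    for name, seq in sequences.items():
        s = seq.upper()
        if "T" in s:
            if not warned:
                logger.warning("DNA-style T found in input; mapping T -> U")
                warned = True
            s = s.replace("T", "U")
        extra = set(s) - RNA_ALPHABET
        if extra:
            raise ValueError(f"sequence {name!r} has characters outside the RNA alphabet: {sorted(extra)}")
        hits = _find_all(s, motif)
        positions[name] = hits
        if hits:
            n_with += 1
            n_occ += len(hits)
    return MotifReport(motif=motif, n_sequences=len(sequences),
                       n_with_motif=n_with, positions=positions, n_occurrences=n_occ)
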
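"""Readers, writers, and pipeline configuration.

Count matrices travel as TSV (features x libraries, header row = library
ids) with a JSON sidecar holding library metadata and passenger flags;
panels as TSV with a leading ``label`` row; precursor sequences as FASTA
(RNA alphabet); machine-readable reports as JSON with TSV twins where a
human would want them.  All JSON is written with sorted keys so identical
runs produce identical bytes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import LabeledPanel
from .quantify import CountMatrix, ExpressionMatrix
from .synthetic import PanelConfig, SimulationConfig, SyntheticTruth

__all__ = [
    "PipelineConfig",
    "read_count_table",
    "write_count_matrix",
    "read_panel",
    "write_panel",
    "read_fasta",
    "write_fasta",
    "write_json",
    "load_config",
]

logger = logging.getLogger(__name__)


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    cm.counts.to_csv(path, sep="\t", index_label="feature")
    meta = {
        "libraries": {
            lib: {"cell_line": row["cell_line"], "compartment": row["compartment"],
                  "replicate": int(row["replicate"])}
            for lib, row in cm.libraries.iterrows()
        },
        "passenger": sorted(cm.passenger.index[cm.passenger].tolist()),
    }
    write_json(meta, _meta_path(path))


def read_count_table(path: str | Path, meta_path: str | Path | None = None) -> CountMatrix:
    """Read a TSV count table and its metadata sidecar into a CountMatrix.

    Validation errors name the offending cell; duplicate feature ids and
    missing metadata are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_file = Path(meta_path) if meta_path else _meta_path(path)
    if not meta_file.exists():
        raise FileNotFoundError(f"missing library metadata sidecar {meta_file}")
    meta = json.loads(meta_file.read_text())
    libraries = pd.DataFrame.from_dict(meta["libraries"], orient="index")
    libraries.index.name = "library"
    passenger = pd.Series(False, index=df.index)
    passenger[passenger.index.isin(meta.get("passenger", []))] = True
    return CountMatrix(counts=df, libraries=libraries, passenger=passenger)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.tpm.to_csv(Path(path), sep="\t", index_label="feature", float_format="%.6g")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        feature: {
            "class": row["class"],
            "de_log2fc": float(row["de_log2fc"]),
            "ev_log2fc": float(row["ev_log2fc"]),
            "passenger": bool(row["passenger"]),
        }
        for feature, row in truth.table.iterrows()
    }
    write_json(payload, path)


def write_panel(panel: LabeledPanel, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("feature\t" + "\t".join(panel.expression.columns) + "\n")
        fh.write("label\t" + "\t".join(panel.labels.loc[panel.expression.columns]) + "\n")
        panel.expression.to_csv(fh, sep="\t", header=False, float_format="%.6g")


def read_panel(path: str | Path) -> LabeledPanel:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        label_row = fh.readline().rstrip("\n").split("\t")
        if label_row[0] != "label":
            raise ValueError(f"panel {path} lacks the leading 'label' row")
        expr = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    expr.columns = header[1:]
    expr.index.name = "feature"
    labels = pd.Series(label_row[1:], index=header[1:], name="label")
    return LabeledPanel(expression=expr, labels=labels)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, with the study's thresholds."""

    outdir: str = "evmir-out"
    seed: int = 0
    counts_path: str | None = None   # simulate when absent
    fasta_path: str | None = None
    panel_path: str | None = None
    tpm_detect: float = 5.0
    log2fc: float = 1.0
    p: float = 0.05
    fdr: float = 0.05
    alt_fold_change: float = 1.5     # plasma-style linear FC screen
    classifier_rule: str = "max-normal"
    log_transform: bool = False
    signature_selection: str = "ev_enriched"
    motifs: tuple[str, ...] = ("CUGU", "GGAG")
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    precursor_length: int = 80
    precursor_planted_fraction: float = 0.527

    def __post_init__(self) -> None:
        if self.tpm_detect < 0 or self.log2fc <= 0 or self.alt_fold_change <= 1:
            raise ValueError("detection/fold-change thresholds must be positive")
        if not (0 < self.p <= 1) or not (0 < self.fdr <= 1):
            raise ValueError("p and FDR cuts must lie in (0, 1]")


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from YAML, applying keyword overrides last."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    sim = SimulationConfig(**raw.pop("simulation", {}))
    panel = PanelConfig(**raw.pop("panel", {}))
    cfg = PipelineConfig(simulation=sim, panel=panel, **raw)
    # a single pipeline seed feeds both generators unless set explicitly
    return cfg
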
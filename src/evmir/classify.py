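"""Pearson-correlation signature classifier for tumour/normal panels.

A signature is a vector of expression values (TPM scale) over a chosen
feature set -- all detected miRNAs of a cell lysate, the dysregulated set,
or the EV-enriched set.  Each panel sample is scored by the Pearson
product-moment correlation between its profile and the signature over
their shared features; a sample is predicted tumour when its coefficient
exceeds a decision threshold.  The default threshold is the maximum
coefficient observed among normal calibration samples, which makes
specificity on the calibration normals 100% by construction; held-out
normals estimate the true specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .quantify import ExpressionMatrix

__all__ = [
    "LabeledPanel",
    "ClassificationReport",
    "pearson_cc",
    "select_features",
    "build_signature",
    "predict_samples",
    "evaluate_classifier",
    "percent",
]

STAGES = ("stage I", "stage II", "stage III", "stage IV")


def percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (e.g. 564/594 -> 94.9)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty set is undefined")
    frac = Decimal(numerator) / Decimal(denominator) * 100
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class LabeledPanel:
    """Per-sample expression profiles with tumour-stage / normal labels."""

    expression: pd.DataFrame  # features x samples, non-negative
    labels: pd.Series  # per sample: "normal" or "stage I".."stage IV"

    def __post_init__(self) -> None:
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("panel expression must be non-negative")
        if set(self.labels.index) != set(self.expression.columns):
            raise ValueError("labels do not match panel samples")
        self.labels = self.labels.loc[self.expression.columns]

    @property
    def normals(self) -> list[str]:
        return list(self.labels.index[self.labels == "normal"])

    @property
    def tumours(self) -> list[str]:
        return list(self.labels.index[self.labels != "normal"])


@dataclass
class ClassificationReport:
    """Per-sample coefficients and predictions plus the threshold used."""

    samples: pd.DataFrame  # columns: r, predicted, label
    threshold: float
    rule: str

    def stage_summary(self) -> pd.DataFrame:
        """Min / max / mean Pearson coefficient per label group."""
        return (self.samples.groupby("label")["r"]
                .agg(["min", "max", "mean"]))


def pearson_cc(x: pd.Series | np.ndarray, y: pd.Series | np.ndarray) -> float:
    """Pearson product-moment correlation over the shared feature set.

    Series inputs are aligned on their index intersection; arrays must be
    equal length.  A zero-variance vector raises rather than silently
    returning 0.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        shared = x.index.intersection(y.index)
        x, y = x.loc[shared].to_numpy(float), y.loc[shared].to_numpy(float)
    else:
        x, y = np.asarray(x, float), np.asarray(y, float)
        if x.shape != y.shape:
            raise ValueError("profiles have different lengths and no index to align on")
    if x.size < 3:
        raise ValueError(f"need >= 3 shared features, got {x.size}")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt((xc ** 2).sum()), np.sqrt((yc ** 2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a zero-variance profile")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def select_features(
    selection: str,
    detected: set[str] | None = None,
    de_calls: pd.Series | None = None,
    ev_labels: pd.Series | None = None,
) -> set[str]:
    """Resolve a named feature selection to a concrete feature set.

    all_detected: the detected set of the signature compartment;
    dysregulated: union of up and down calls; ev_enriched: features with
    any EV-enrichment label.
    """
    if selection == "all_detected":
        if detected is None:
            raise ValueError("all_detected selection needs the detected set")
        return set(detected)
    if selection == "dysregulated":
        if de_calls is None:
            raise ValueError("dysregulated selection needs DE calls")
        return set(de_calls.index[de_calls.isin(["up", "down"])])
    if selection == "ev_enriched":
        if ev_labels is None:
            raise ValueError("ev_enriched selection needs enrichment labels")
        return set(ev_labels.index[ev_labels != "none"])
    raise ValueError(f"unknown feature selection {selection!r}")


def build_signature(expr: ExpressionMatrix, column: str, features: set[str]) -> pd.Series:
    """Signature profile: compartment-mean TPM restricted to a feature set."""
    if not features:
        raise ValueError("empty feature selection")
    present = [f for f in expr.tpm.index if f in features]
    sig = expr.tpm.loc[present, column]
    sig.name = column
    return sig


def predict_samples(
    panel: LabeledPanel,
    signature: pd.Series,
    rule: str = "max-normal",
    threshold: float | None = None,
    k: float = 2.0,
    log_transform: bool = False,
    calibration_normals: list[str] | None = None,
) -> ClassificationReport:
    """Score every panel sample against the signature and predict labels.

    Rules: "max-normal" (default) sets the threshold to the maximum
    coefficient among the calibration normals; "mean-sd" uses their mean
    plus ``k`` standard deviations; "fixed" uses ``threshold`` as given.
    ``log_transform`` correlates log2(TPM + 1) instead of raw TPM.
    Features absent from the panel are dropped, not zero-filled.
    """
    sig = np.log2(signature + 1) if log_transform else signature
    expr = np.log2(panel.expression + 1) if log_transform else panel.expression
    r = pd.Series(
        {s: pearson_cc(sig, expr[s]) for s in expr.columns}, name="r"
    )
    if rule == "fixed":
        if threshold is None:
            raise ValueError("fixed rule needs an explicit threshold")
        tau = float(threshold)
    else:
        normals = calibration_normals if calibration_normals is not None else panel.normals
        if not normals:
            raise ValueError(f"rule {rule!r} needs at least one normal calibration sample")
        r_norm = r.loc[normals]
        if rule == "max-normal":
            tau = float(r_norm.max())
        elif rule == "mean-sd":
            tau = float(r_norm.mean() + k * r_norm.std(ddof=1 if len(normals) > 1 else 0))
        else:
            raise ValueError(f"unknown decision rule {rule!r}")
    predicted = pd.Series(np.where(r > tau, "tumour", "normal"), index=r.index, name="predicted")
    samples = pd.DataFrame({"r": r, "predicted": predicted, "label": panel.labels})
    return ClassificationReport(samples=samples, threshold=tau, rule=rule)


def evaluate_classifier(
    predicted: pd.Series, labels: pd.Series
) -> dict:
    """Sensitivity / specificity (percent, 1 d.p.) with per-stage breakdown.

    Sensitivity = predicted-tumour among true tumours; specificity =
    predicted-normal among true normals.  A metric whose denominator is
    empty is reported as None.
    """
    labels = labels.loc[predicted.index]
    is_tumour = labels != "normal"
    tp = int(((predicted == "tumour") & is_tumour).sum())
    tn = int(((predicted == "normal") & ~is_tumour).sum())
    n_tum, n_norm = int(is_tumour.sum()), int((~is_tumour).sum())
    metrics = {
        "n_tumour": n_tum,
        "n_normal": n_norm,
        "tumours_predicted": tp,
        "normals_predicted": tn,
        "sensitivity_pct": percent(tp, n_tum) if n_tum else None,
        "specificity_pct": percent(tn, n_norm) if n_norm else None,
        "per_stage": {},
    }
    for stage in sorted(set(labels) - {"normal"}):
        mask = labels == stage
        metrics["per_stage"][stage] = {
            "n": int(mask.sum()),
            "predicted_tumour": int((predicted[mask] == "tumour").sum()),
            "sensitivity_pct": percent(int((predicted[mask] == "tumour").sum()), int(mask.sum())),
        }
    return metrics
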
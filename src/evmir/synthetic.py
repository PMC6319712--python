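"""Synthetic data with planted, recorded ground truth.

Three generators make every downstream stage testable offline:

* ``generate_count_matrix`` -- negative-binomial miRNA counts for two cell
  lines x three compartments (cell lysate CL, shed microvesicles sMV,
  exosomes Exo) with planted dysregulation between the two cell lysates,
  planted EV-enrichment classes, a "cell-silent but EV-abundant" class
  (CL below the 5-TPM detection rule, EV above 1000 TPM), and passenger
  strand annotation.
* ``generate_tumour_panel`` -- normal / staged-tumour expression panels in
  which tumour profiles are a noisy mixture of a baseline and a planted
  signature, so tumours correlate with the signature more strongly than
  normals do.
* ``generate_precursor_set`` -- RNA precursor sequences with an exactly
  controlled fraction bearing a given motif (motif-free sequences are
  verified by rejection sampling).

All three are deterministic in (seed, config): a single seed feeds
independent per-generator sub-streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import LabeledPanel, STAGES
from .quantify import CountMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "PanelConfig",
    "generate_count_matrix",
    "generate_tumour_panel",
    "generate_precursor_set",
]

CELL_LINES = ("lineA", "lineB")
COMPARTMENTS = ("CL", "sMV", "Exo")

#: planted expression classes (one per feature, mutually exclusive)
CLASSES = ("null", "up", "down", "ev_enriched_sMV", "ev_enriched_Exo",
           "ev_enriched_both", "cell_silent_ev")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the count generator.

    Defaults mirror the sequencing design being emulated: duplicate
    libraries (n = 2) for each of two cell lines x three compartments, a
    mean depth of 12.77 million miRNA-mapped reads, heavy-tailed baseline
    abundances, and NB dispersion phi (variance mu + phi*mu^2).
    """

    n_mirnas: int = 500
    n_replicates: int = 2
    compartments: tuple[tuple[str, str], ...] = tuple(
        (line, comp) for line in CELL_LINES for comp in COMPARTMENTS
    )
    library_size_mean: float = 12_770_000.0
    dispersion: float = 0.1
    frac_dysregulated: float = 0.2
    frac_ev_enriched: float = 0.12
    frac_cell_silent_ev: float = 0.05
    frac_passenger: float = 0.296
    de_log2fc_range: tuple[float, float] = (1.5, 4.0)
    ev_log2fc_range: tuple[float, float] = (1.5, 3.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_dysregulated", "frac_ev_enriched",
                     "frac_cell_silent_ev", "frac_passenger"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        planted = self.frac_dysregulated + self.frac_ev_enriched + self.frac_cell_silent_ev
        if planted > 1:
            raise ValueError(
                f"planted class fractions sum to {planted:.3f} > 1; classes must be disjoint"
            )
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per compartment")
        if self.n_mirnas < 1 or self.library_size_mean <= 0 or self.dispersion < 0:
            raise ValueError("invalid simulation size parameters")


@dataclass
class SyntheticTruth:
    """Ground-truth bookkeeping for parameter-recovery tests."""

    table: pd.DataFrame  # per feature: class, de_log2fc, ev_log2fc, passenger

    def features_in_class(self, *classes: str) -> set[str]:
        return set(self.table.index[self.table["class"].isin(classes)])

    @property
    def dysregulated(self) -> set[str]:
        return self.features_in_class("up", "down")

    @property
    def ev_enriched(self) -> set[str]:
        return self.features_in_class(
            "ev_enriched_sMV", "ev_enriched_Exo", "ev_enriched_both"
        )

    @property
    def cell_silent(self) -> set[str]:
        return self.features_in_class("cell_silent_ev")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def generate_count_matrix(config: SimulationConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw an NB count matrix with planted classes and return the truth.

    Baseline feature means are log-normal (log10 mean 2, sd 1) spanning the
    heavy-tailed TPM range of real miRNA libraries; library sizes are
    uniform within +-20% of the configured mean.  Dysregulated features
    carry their fold change on every lineB compartment (a cell-level
    change propagates into the cell's EVs); EV-enrichment folds multiply
    the EV compartments of both lines; cell-silent features are pinned to
    ~1 TPM in CL and >= 2000 TPM in their enriched EV compartments.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_class, rng_base, rng_lib, rng_counts = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    n = config.n_mirnas
    features = pd.Index([f"mir-{i:04d}" for i in range(n)], name="feature")

    # --- planted class assignment (disjoint by construction) ---
    n_de = _round_half_up(config.frac_dysregulated * n)
    n_ev = _round_half_up(config.frac_ev_enriched * n)
    n_silent = _round_half_up(config.frac_cell_silent_ev * n)
    order = rng_class.permutation(n)
    classes = np.array(["null"] * n, dtype=object)
    de_idx = order[:n_de]
    classes[de_idx[: n_de // 2]] = "up"
    classes[de_idx[n_de // 2:]] = "down"
    ev_idx = order[n_de:n_de + n_ev]
    for i, sub in enumerate(np.array_split(ev_idx, 3)):
        classes[sub] = ("ev_enriched_both", "ev_enriched_sMV", "ev_enriched_Exo")[i]
    silent_idx = order[n_de + n_ev:n_de + n_ev + n_silent]
    classes[silent_idx] = "cell_silent_ev"
    passenger = rng_class.random(n) < config.frac_passenger

    # --- planted effect sizes ---
    de_lfc = np.zeros(n)
    lo, hi = config.de_log2fc_range
    mags = rng_class.uniform(lo, hi, size=n)
    de_lfc[classes == "up"] = mags[classes == "up"]
    de_lfc[classes == "down"] = -mags[classes == "down"]
    ev_lfc = np.zeros(n)
    lo, hi = config.ev_log2fc_range
    ev_mask = np.isin(classes, ["ev_enriched_sMV", "ev_enriched_Exo", "ev_enriched_both"])
    ev_lfc[ev_mask] = rng_class.uniform(lo, hi, size=int(ev_mask.sum()))

    # --- per-compartment expected TPM ---
    base = 10.0 ** rng_base.normal(2.0, 1.0, size=n)
    groups = [f"{line}-{comp}" for line, comp in config.compartments]
    mean_tpm = pd.DataFrame(
        {g: base.copy() for g in groups}, index=features
    )
    for g in groups:
        line, comp = g.split("-")
        col = mean_tpm[g].to_numpy()
        if line == "lineB":
            col = col * 2.0 ** de_lfc
        if comp in ("sMV", "Exo"):
            enriched = (classes == "ev_enriched_both") | (classes == f"ev_enriched_{comp}")
            col = np.where(enriched, col * 2.0 ** ev_lfc, col)
        mean_tpm[g] = col
    # normalize columns to the TPM scale, then pin the cell-silent class
    mean_tpm = mean_tpm / mean_tpm.sum(axis=0) * 1e6
    silent_ev_tpm = rng_base.uniform(2000.0, 5000.0, size=n_silent)
    for g in groups:
        _, comp = g.split("-")
        if comp == "CL":
            mean_tpm.iloc[silent_idx, mean_tpm.columns.get_loc(g)] = 1.0
        else:
            mean_tpm.iloc[silent_idx, mean_tpm.columns.get_loc(g)] = silent_ev_tpm

    # --- libraries and NB sampling ---
    lib_ids, lib_meta, mu_cols = [], [], []
    for line, comp in config.compartments:
        for rep in range(1, config.n_replicates + 1):
            lib_id = f"{line}-{comp}-R{rep}"
            lib_ids.append(lib_id)
            lib_meta.append({"cell_line": line, "compartment": comp, "replicate": rep})
            mu_cols.append(f"{line}-{comp}")
    lib_sizes = rng_lib.uniform(0.8, 1.2, size=len(lib_ids)) * config.library_size_mean
    phi = config.dispersion
    counts = np.zeros((n, len(lib_ids)), dtype=np.int64)
    for j, (lib_id, g) in enumerate(zip(lib_ids, mu_cols)):
        mu = mean_tpm[g].to_numpy() / 1e6 * lib_sizes[j]
        if phi <= 0:
            counts[:, j] = rng_counts.poisson(mu)
        else:
            r = 1.0 / phi
            # NB as Gamma-Poisson mixture: exact for variance mu + phi*mu^2
            lam = rng_counts.gamma(shape=r, scale=mu / r)
            counts[:, j] = rng_counts.poisson(lam)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=features, columns=lib_ids),
        libraries=pd.DataFrame(lib_meta, index=pd.Index(lib_ids, name="library")),
        passenger=pd.Series(passenger, index=features),
    )
    truth = SyntheticTruth(table=pd.DataFrame({
        "class": classes,
        "de_log2fc": de_lfc,
        "ev_log2fc": ev_lfc,
        "passenger": passenger,
    }, index=features))
    return cm, truth


# ---------------------------------------------------------------------------
# Tumour / normal panels
# ---------------------------------------------------------------------------

@dataclass
class PanelConfig:
    """Reduced-scale emulation of a clinical normal/tumour miRNA panel.

    The study design being emulated had 11 normals and hundreds of staged
    tumours; defaults keep the same shape at desk scale.  ``signature_weight``
    is the mixture weight w by which tumour profiles blend toward the
    signature (scalar, or one value per stage I-IV); ``noise_sd`` is the
    standard deviation of multiplicative log-normal noise.
    """

    n_normals: int = 11
    n_per_stage: tuple[int, int, int, int] = (26, 56, 45, 22)
    signature_weight: float | tuple[float, float, float, float] = 0.6
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normals < 1:
            raise ValueError("need at least one normal sample")
        w = self.signature_weight
        ws = (w,) * 4 if np.isscalar(w) else tuple(w)
        if len(ws) != 4 or any(not 0 <= x <= 1 for x in ws):
            raise ValueError("signature_weight must be in [0, 1] (scalar or one per stage)")
        self.stage_weights = ws
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_tumour_panel(
    config: PanelConfig, signature: pd.Series, baseline: pd.Series
) -> LabeledPanel:
    """Normals = noisy baseline; tumours = (1-w)*baseline + w*signature, noisy.

    Signature and baseline must share a feature universe (aligned on the
    index intersection; it must be non-empty).
    """
    shared = signature.index.intersection(baseline.index)
    if len(shared) == 0:
        raise ValueError("signature and baseline share no features")
    sig = signature.loc[shared].to_numpy(float)
    base = baseline.loc[shared].to_numpy(float)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    cols, labels = {}, {}

    def noisy(profile: np.ndarray) -> np.ndarray:
        if config.noise_sd == 0:
            return profile.copy()
        return profile * np.exp(rng.normal(0.0, config.noise_sd, size=profile.size))

    for i in range(config.n_normals):
        name = f"normal-{i + 1:03d}"
        cols[name] = noisy(base)
        labels[name] = "normal"
    for stage, n_s, w in zip(STAGES, config.n_per_stage, config.stage_weights):
        mix = (1.0 - w) * base + w * sig
        for i in range(n_s):
            name = f"{stage.replace(' ', '-')}-{i + 1:03d}"
            cols[name] = noisy(mix)
            labels[name] = stage
    expr = pd.DataFrame(cols, index=shared)
    return LabeledPanel(expression=expr, labels=pd.Series(labels))


# ---------------------------------------------------------------------------
# Precursor sequences
# ---------------------------------------------------------------------------

def generate_precursor_set(
    n: int, length: int, motif: str, planted_fraction: float, seed: int = 0
) -> dict[str, str]:
    """RNA sequences of which exactly round(n * planted_fraction) bear the motif.

    Motif-bearing sequences get one guaranteed insertion at a random
    position (background may add more occurrences); the remaining
    sequences are rejection-sampled until motif-free.
    """
    motif = motif.upper().replace("T", "U")
    if set(motif) - set("ACGU"):
        raise ValueError("motif must be over {A, C, G, U}")
    if not 0 <= planted_fraction <= 1:
        raise ValueError("planted_fraction must lie in [0, 1]")
    if length <= len(motif):
        raise ValueError("sequence length must exceed the motif length")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_with = _round_half_up(n * planted_fraction)
    alphabet = np.array(list("ACGU"))

    def random_seq() -> str:
        return "".join(alphabet[rng.integers(0, 4, size=length)])

    seqs: dict[str, str] = {}
    for i in range(n):
        name = f"pre-mir-{i + 1:04d}"
        if i < n_with:
            s = random_seq()
            pos = int(rng.integers(0, length - len(motif) + 1))
            s = s[:pos] + motif + s[pos + len(motif):]
            seqs[name] = s
        else:
            while True:
                s = random_seq()
                if motif not in s:
                    break
            seqs[name] = s
    return seqs
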
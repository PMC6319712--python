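"""Two-group negative-binomial exact test with TMM normalization.

This module is the engine behind every differential-expression and
EV-enrichment call in the pipeline.  The model is the standard count model
for small-RNA sequencing: counts for feature *f* in library *l* are
negative binomial with mean mu_{fl} proportional to library size and
variance mu + phi * mu^2, where phi is the dispersion (phi = 0 recovers
Poisson).

The three statistical pieces are authored here:

* ``tmm_factors`` -- trimmed mean of M-values normalization: per-library
  scaling factors from a doubly trimmed (30% on M, 5% on A), precision
  weighted mean of per-feature log ratios against a reference library.
* ``estimate_dispersion`` -- common dispersion by conditional maximum
  likelihood on libraries equalized to a common size by proportional mean
  scaling, with optional tagwise shrinkage toward the common value.
* ``nb_exact_test`` -- exact two-group test conditioning on the two group
  sums at equalized library sizes; the two-sided p-value is the total
  conditional probability of all splits whose probability does not exceed
  that of the observed split.

Benjamini-Hochberg FDR adjustment is delegated to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix

__all__ = [
    "Contrast",
    "tmm_factors",
    "estimate_dispersion",
    "nb_exact_test",
    "adjust_fdr",
    "classify_dysregulated",
]

# relative tie tolerance when collecting splits into the rejection set
_TIE_RTOL = 1e-12


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              log_ratio_trim: float = 0.3, sum_trim: float = 0.05,
              weighted: bool = True) -> float:
    """log2 TMM factor of one library against the reference library."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / n_obs
        p_ref = ref / n_ref
        log_r = np.log2(p_obs / p_ref)                 # M values
        abs_e = (np.log2(p_obs) + np.log2(p_ref)) / 2  # A values
        # delta-method variance of M for weighting
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    if not finite.any():
        raise ValueError("library shares no expressed features with the reference")
    log_r, abs_e, v = log_r[finite], abs_e[finite], v[finite]
    if np.max(np.abs(log_r)) < 1e-6:
        return 0.0
    n = log_r.size
    lo_l = np.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 0.0
    if weighted:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(counts: CountMatrix | pd.DataFrame, reference: str | None = None) -> pd.Series:
    """Per-library TMM normalization factors.

    Factors multiply raw library sizes to give effective sizes.  Zero-count
    features are excluded pairwise; factors are recentred so their
    geometric mean is 1.  When no reference library is named, the library
    whose upper-quartile count fraction is closest to the mean of those
    fractions is used.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] < 2:
        raise ValueError("TMM needs at least two libraries")
    y = df.to_numpy(dtype=float)
    lib_size = y.sum(axis=0)
    if (lib_size <= 0).any():
        raise ValueError("every library must have a positive total count")
    # features with zero counts everywhere carry no ratio information and
    # would distort the upper-quartile reference selection
    y = y[(y > 0).any(axis=1)]
    if reference is None:
        f75 = np.array([np.quantile(y[:, j] / lib_size[j], 0.75) for j in range(y.shape[1])])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = list(df.columns).index(reference)
    log_f = np.array([
        _tmm_pair(y[:, j], y[:, ref_idx], lib_size[j], lib_size[ref_idx])
        for j in range(y.shape[1])
    ])
    factors = 2.0 ** log_f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# Contrast container
# ---------------------------------------------------------------------------

@dataclass
class Contrast:
    """A two-group comparison over the libraries of one count matrix.

    ``dispersion`` may be a scalar (common) or a per-feature array
    (tagwise).  ``factors`` are TMM factors for all libraries involved.
    """

    counts: CountMatrix
    group_a: list[str]
    group_b: list[str]
    factors: pd.Series | None = None
    dispersion: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        overlap = set(self.group_a) & set(self.group_b)
        if overlap:
            raise ValueError(f"groups are not disjoint: {sorted(overlap)}")
        if not self.group_a or not self.group_b:
            raise ValueError("each group needs at least one library")
        known = set(self.counts.counts.columns)
        unknown = (set(self.group_a) | set(self.group_b)) - known
        if unknown:
            raise KeyError(f"unknown libraries: {sorted(unknown)}")
        if self.factors is not None and (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")

    @property
    def libraries(self) -> list[str]:
        return list(self.group_a) + list(self.group_b)

    def effective_sizes(self) -> pd.Series:
        libs = self.libraries
        sizes = self.counts.counts[libs].sum(axis=0).astype(float)
        if self.factors is not None:
            sizes = sizes * self.factors.reindex(libs)
        return sizes


def _pseudo_counts(contrast: Contrast) -> tuple[pd.DataFrame, float]:
    """Rescale counts to a common (geometric-mean) effective library size."""
    sizes = contrast.effective_sizes()
    m = float(np.exp(np.mean(np.log(sizes))))
    pseudo = contrast.counts.counts[contrast.libraries] * (m / sizes)
    return pseudo, m


# ---------------------------------------------------------------------------
# Dispersion estimation (qCML)
# ---------------------------------------------------------------------------

def _cond_loglik(pseudo: np.ndarray, group_slices: list[slice], phi: float) -> np.ndarray:
    """Per-feature conditional log-likelihood of dispersion phi.

    Within each replicate group the likelihood of the counts conditional on
    their sum depends only on phi, not on the group mean; single-replicate
    groups contribute zero information.
    """
    r = 1.0 / max(phi, 1e-12)
    out = np.zeros(pseudo.shape[0])
    for sl in group_slices:
        y = pseudo[:, sl]
        n = y.shape[1]
        if n < 2:
            continue
        z = y.sum(axis=1)
        out += (gammaln(y + r).sum(axis=1) + gammaln(n * r)
                - gammaln(z + n * r) - n * gammaln(r))
    return out


def estimate_dispersion(
    contrast: Contrast,
    tagwise: bool = False,
    prior_df: float = 10.0,
) -> float | np.ndarray:
    """Common (default) or tagwise NB dispersion by conditional ML.

    Libraries are equalized to a common size by proportional mean scaling;
    the common dispersion maximizes the summed conditional log-likelihood
    over features.  In tagwise mode each feature maximizes its own
    likelihood plus a shrinkage term weighting the common likelihood by
    ``prior_df`` divided by the per-feature residual degrees of freedom.
    """
    n_a, n_b = len(contrast.group_a), len(contrast.group_b)
    if n_a < 2 and n_b < 2:
        raise ValueError("dispersion estimation needs >= 2 replicates in at least one group")
    pseudo, _ = _pseudo_counts(contrast)
    y = pseudo.to_numpy(dtype=float)
    slices = [slice(0, n_a), slice(n_a, n_a + n_b)]
    # drop all-zero features: no information
    keep = y.sum(axis=1) > 0
    y = y[keep]

    def neg_total(log_phi: float) -> float:
        return -float(_cond_loglik(y, slices, 10.0 ** log_phi).sum())

    res = minimize_scalar(neg_total, bounds=(-8.0, 2.0), method="bounded",
                          options={"xatol": 1e-6})
    common = float(10.0 ** res.x)
    if common <= 1e-6:  # at the lower search bound: no excess variance
        common = 0.0
    if not tagwise:
        return common

    df_resid = max((n_a - 1) + (n_b - 1), 1)
    weight = prior_df / df_resid
    mean_ll = {}

    def tag_neg(log_phi: float, row: np.ndarray) -> float:
        phi = 10.0 ** log_phi
        if log_phi not in mean_ll:
            mean_ll[log_phi] = float(_cond_loglik(y, slices, phi).mean())
        own = float(_cond_loglik(row[None, :], slices, phi)[0])
        return -(own + weight * mean_ll[log_phi])

    phis = np.full(keep.size, common)
    vals = np.zeros(y.shape[0])
    for i in range(y.shape[0]):
        r = minimize_scalar(tag_neg, args=(y[i],), bounds=(-8.0, 2.0),
                            method="bounded", options={"xatol": 1e-4})
        vals[i] = 10.0 ** r.x
    vals[vals <= 1e-6] = 0.0
    phis[keep] = vals
    return phis


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

def _nb_logpmf(k: np.ndarray, mu: float, phi: float) -> np.ndarray:
    """NB log-pmf with mean mu, variance mu + phi*mu^2; Poisson at phi=0."""
    k = np.asarray(k, dtype=float)
    if mu <= 0:
        return np.where(k == 0, 0.0, -np.inf)
    if phi <= 0:
        return k * np.log(mu) - mu - gammaln(k + 1)
    r = 1.0 / phi
    return (gammaln(k + r) - gammaln(r) - gammaln(k + 1)
            + r * np.log(r / (r + mu)) + k * np.log(mu / (r + mu)))


def exact_nb_pvalue(z_a: int, z_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p-value for one feature.

    Group sums of n iid NB(mu, phi) libraries are treated as
    NB(n*mu, phi/n).  Conditional on the total z = z_a + z_b at equal
    per-library sizes, each split (k, z-k) has probability proportional to
    the product of the two group-sum pmfs at the total-derived mean.  The
    p-value sums the probabilities of every split no more probable than
    the observed one (ties within 1e-12 relative included).
    """
    z = int(z_a) + int(z_b)
    if z == 0:
        return 1.0
    mu_a = n_a * z / (n_a + n_b)
    mu_b = n_b * z / (n_a + n_b)
    phi_a = phi / n_a
    phi_b = phi / n_b
    # chunked enumeration over all z+1 splits
    chunk = 1 << 20
    parts = []
    obs_logp = None
    for start in range(0, z + 1, chunk):
        k = np.arange(start, min(start + chunk, z + 1))
        lp = _nb_logpmf(k, mu_a, phi_a) + _nb_logpmf(z - k, mu_b, phi_b)
        parts.append(lp)
        if start <= z_a < start + chunk:
            obs_logp = lp[z_a - start]
    total = logsumexp([logsumexp(p) for p in parts])
    cut = obs_logp + np.log1p(_TIE_RTOL)
    tails = []
    for start, lp in zip(range(0, z + 1, chunk), parts):
        sel = lp[lp <= cut]
        if sel.size:
            tails.append(logsumexp(sel))
    p = float(np.exp(logsumexp(tails) - total))
    return min(p, 1.0)


def nb_exact_test(contrast: Contrast, prior_count: float = 0.5) -> pd.DataFrame:
    """Exact NB test for every feature of a two-group contrast.

    Returns a DataFrame indexed by feature with columns ``meanA_tpm``,
    ``meanB_tpm``, ``log2fc`` (B relative to A), ``pvalue`` and ``fdr``.
    log2fc uses prior-count-augmented group means so zero-in-one-group
    features get large finite values.  Swapping the groups negates log2fc
    and leaves p-values unchanged.
    """
    if contrast.dispersion is None:
        raise ValueError("contrast has no dispersion estimate")
    pseudo, _ = _pseudo_counts(contrast)
    n_a, n_b = len(contrast.group_a), len(contrast.group_b)
    z_a = pseudo[contrast.group_a].sum(axis=1).round().astype(np.int64)
    z_b = pseudo[contrast.group_b].sum(axis=1).round().astype(np.int64)
    phi = contrast.dispersion
    phi_arr = np.full(len(z_a), float(phi)) if np.isscalar(phi) else np.asarray(phi, dtype=float)

    pvals = np.ones(len(z_a))
    for i, (a, b, ph) in enumerate(zip(z_a.to_numpy(), z_b.to_numpy(), phi_arr)):
        pvals[i] = exact_nb_pvalue(a, b, n_a, n_b, ph)

    mean_a = z_a / n_a
    mean_b = z_b / n_b
    log2fc = np.log2((mean_b + prior_count) / (mean_a + prior_count))

    # group-mean TPM on the raw counts, for reporting
    raw = contrast.counts.counts
    tpm = raw / raw.sum(axis=0) * 1e6
    out = pd.DataFrame({
        "meanA_tpm": tpm[contrast.group_a].mean(axis=1),
        "meanB_tpm": tpm[contrast.group_b].mean(axis=1),
        "log2fc": log2fc,
        "pvalue": pvals,
    }, index=pseudo.index)
    out["fdr"] = adjust_fdr(out["pvalue"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# FDR and dysregulation calls
# ---------------------------------------------------------------------------

def adjust_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_dysregulated(
    result: pd.DataFrame,
    log2fc_cut: float = 1.0,
    p_cut: float = 0.05,
    fdr_cut: float = 0.05,
) -> pd.Series:
    """Call each feature up / down / ns at the given thresholds.

    up: log2fc > log2fc_cut and p < p_cut and fdr < fdr_cut; down is the
    mirror image.  A linear fold-change screen (e.g. FC > 1.5) is the same
    rule with ``log2fc_cut=np.log2(1.5)``.
    """
    if log2fc_cut < 0 or not (0 < p_cut <= 1) or not (0 < fdr_cut <= 1):
        raise ValueError("invalid thresholds")
    sig = (result["pvalue"] < p_cut) & (result["fdr"] < fdr_cut)
    call = pd.Series("ns", index=result.index, name="call")
    call[sig & (result["log2fc"] > log2fc_cut)] = "up"
    call[sig & (result["log2fc"] < -log2fc_cut)] = "down"
    return call
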
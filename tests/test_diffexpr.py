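"""TMM normalization, qCML dispersion, the NB exact test, BH, and calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import rankdata

from evmir.diffexpr import (Contrast, adjust_fdr, classify_dysregulated,
                            estimate_dispersion, exact_nb_pvalue,
                            nb_exact_test, tmm_factors)

from conftest import make_count_matrix


# ---------------------------------------------------------------------------
# independent oracles, coded separately from the implementation
# ---------------------------------------------------------------------------

def tmm_factor_oracle(y_k, y_r):
    """Direct transcription of the doubly-trimmed weighted mean of M-values."""
    y_k, y_r = np.asarray(y_k, float), np.asarray(y_r, float)
    n_k, n_r = y_k.sum(), y_r.sum()
    keep = (y_k > 0) & (y_r > 0)
    y_k, y_r = y_k[keep], y_r[keep]
    m = np.log2((y_k / n_k) / (y_r / n_r))
    a = 0.5 * np.log2((y_k / n_k) * (y_r / n_r))
    w = (n_k - y_k) / (n_k * y_k) + (n_r - y_r) / (n_r * y_r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
    lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
    rm, ra = rankdata(m), rankdata(a)
    kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return 2.0 ** (np.sum(m[kept] / w[kept]) / np.sum(1.0 / w[kept]))


def exact_pvalue_oracle(z_a, z_b, n_a, n_b, phi):
    """Exhaustive enumeration of all splits of the conditional distribution."""
    z = z_a + z_b
    mu_a, mu_b = n_a * z / (n_a + n_b), n_b * z / (n_a + n_b)

    def logpmf(k, mu, ph):
        if ph == 0:
            return k * np.log(mu) - mu - gammaln(k + 1)
        r = 1.0 / ph
        return (gammaln(k + r) - gammaln(r) - gammaln(k + 1)
                + r * np.log(r / (r + mu)) + k * np.log(mu / (r + mu)))

    probs = np.array([
        np.exp(logpmf(k, mu_a, phi / n_a) + logpmf(z - k, mu_b, phi / n_b))
        for k in range(z + 1)
    ])
    probs /= probs.sum()
    return float(probs[probs <= probs[z_a] * (1 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

class TestTmm:
    def test_scalar_multiple_of_reference_is_one(self):
        rng = np.random.default_rng(1)
        ref = rng.integers(1, 200, 40)
        cm = make_count_matrix({"x-A-R1": ref.tolist(), "x-A-R2": (ref * 3).tolist()})
        f = tmm_factors(cm, reference="x-A-R1")
        assert np.allclose(f.to_numpy(), 1.0)

    def test_identical_libraries_are_one(self):
        cm = make_count_matrix({"x-A-R1": [5, 10, 20], "x-A-R2": [5, 10, 20]})
        assert np.allclose(tmm_factors(cm).to_numpy(), 1.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(3)
        counts = {f"x-A-R{j}": rng.integers(0, 400, 20).tolist() for j in range(1, 5)}
        cm = make_count_matrix(counts)
        mine = tmm_factors(cm, reference="x-A-R1")
        raw = [tmm_factor_oracle(cm.counts[c], cm.counts["x-A-R1"]) for c in cm.counts.columns]
        raw = np.array(raw)
        expected = raw / np.exp(np.mean(np.log(raw)))  # geometric-mean recentring
        assert np.allclose(mine.to_numpy(), expected, rtol=1e-10)

    def test_disjoint_support_error(self):
        cm = make_count_matrix({"x-A-R1": [5, 0, 0], "x-A-R2": [0, 3, 9]})
        with pytest.raises(ValueError, match="reference"):
            tmm_factors(cm, reference="x-A-R1")


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

class TestDispersion:
    @staticmethod
    def _contrast(counts_df_builder, n_feat, seed, phi):
        rng = np.random.default_rng(seed)
        mu = rng.lognormal(4.0, 1.0, n_feat)

        def draw():
            if phi == 0:
                return rng.poisson(mu)
            lam = rng.gamma(1.0 / phi, mu * phi)
            return rng.poisson(lam)

        libs = [f"x-{g}-R{r}" for g in "AB" for r in (1, 2, 3)]
        cm = make_count_matrix({l: draw().tolist() for l in libs})
        return Contrast(counts=cm, group_a=libs[:3], group_b=libs[3:])

    def test_poisson_data_gives_near_zero(self):
        c = self._contrast(None, 200, 10, 0.0)
        assert estimate_dispersion(c) <= 0.05

    def test_recovers_planted_dispersion(self):
        c = self._contrast(None, 500, 11, 0.2)
        phi_hat = estimate_dispersion(c)
        assert abs(phi_hat - 0.2) / 0.2 <= 0.25

    def test_identical_counts_give_zero(self):
        cm = make_count_matrix({f"x-A-R{r}": [10, 50, 200] for r in (1, 2, 3)})
        # same counts in a second group too
        counts = {f"x-{g}-R{r}": [10, 50, 200] for g in "AB" for r in (1, 2)}
        cm = make_count_matrix(counts)
        c = Contrast(counts=cm, group_a=["x-A-R1", "x-A-R2"], group_b=["x-B-R1", "x-B-R2"])
        assert estimate_dispersion(c) == 0.0

    def test_single_replicate_everywhere_rejected(self):
        cm = make_count_matrix({"x-A-R1": [5, 9], "x-B-R1": [7, 2]})
        c = Contrast(counts=cm, group_a=["x-A-R1"], group_b=["x-B-R1"])
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersion(c)

    def test_tagwise_shrinks_toward_common(self):
        c = self._contrast(None, 80, 12, 0.2)
        common = estimate_dispersion(c)
        tagwise = estimate_dispersion(c, tagwise=True)
        assert tagwise.shape == (80,)
        # shrinkage keeps tagwise values in a band around the common value
        assert np.median(np.abs(np.log10(np.maximum(tagwise, 1e-8) / common))) < 1.0


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

class TestExactTest:
    def test_symmetric_split_p_one(self):
        assert exact_nb_pvalue(8, 8, 1, 1, 0.1) == pytest.approx(1.0)

    def test_conditional_binomial_example(self):
        """phi=0, totals 3 vs 13: p equals the enumerated binomial tail."""
        assert exact_nb_pvalue(3, 13, 1, 1, 0.0) == pytest.approx(
            exact_pvalue_oracle(3, 13, 1, 1, 0.0), abs=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.4])
    @pytest.mark.parametrize("shape", [(1, 1), (2, 2), (2, 3)])
    def test_matches_enumeration_oracle_small_sums(self, phi, shape):
        """All instances with group-sum <= 30 agree with enumeration to 1e-10."""
        n_a, n_b = shape
        worst = 0.0
        for z in range(1, 31):
            for z_a in range(z + 1):
                p = exact_nb_pvalue(z_a, z - z_a, n_a, n_b, phi)
                q = exact_pvalue_oracle(z_a, z - z_a, n_a, n_b, phi)
                worst = max(worst, abs(p - q))
        assert worst <= 1e-10

    def test_group_swap_symmetry(self, two_group_matrix):
        ga, gb = ["x-A-R1", "x-A-R2"], ["x-B-R1", "x-B-R2"]
        fwd = nb_exact_test(Contrast(counts=two_group_matrix, group_a=ga,
                                     group_b=gb, dispersion=0.1))
        rev = nb_exact_test(Contrast(counts=two_group_matrix, group_a=gb,
                                     group_b=ga, dispersion=0.1))
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_zero_feature_p_one(self):
        cm = make_count_matrix({"x-A-R1": [0, 10], "x-B-R1": [0, 12]})
        res = nb_exact_test(Contrast(counts=cm, group_a=["x-A-R1"],
                                     group_b=["x-B-R1"], dispersion=0.0))
        assert res.loc["mir-0", "pvalue"] == 1.0
        assert res.loc["mir-0", "log2fc"] == 0.0


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

class TestAdjustFdr:
    def test_single_p_identity(self):
        assert adjust_fdr(np.array([0.04]))[0] == pytest.approx(0.04)

    def test_hand_computed_example(self):
        out = adjust_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(adjust_fdr(np.ones(5)), 1.0)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 200)
        fdr = adjust_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(fdr[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr(np.array([0.5, 1.2]))


# ---------------------------------------------------------------------------
# dysregulation calls
# ---------------------------------------------------------------------------

class TestClassifyDysregulated:
    @staticmethod
    def _result(log2fc, p, fdr):
        return pd.DataFrame({"log2fc": log2fc, "pvalue": p, "fdr": fdr})

    def test_below_fold_cut_is_ns(self):
        res = self._result([0.5], [0.001], [0.001])
        assert classify_dysregulated(res).iloc[0] == "ns"

    def test_up_down_partition(self):
        res = self._result([2.0, -2.0, 2.0], [0.01, 0.01, 0.5], [0.01, 0.01, 0.8])
        calls = classify_dysregulated(res)
        assert list(calls) == ["up", "down", "ns"]

    def test_linear_fold_change_screen(self):
        # FC > 1.5 screen: log2(1.5) ~ 0.585 passes, a 1.3-fold change does not
        res = self._result([np.log2(1.6), np.log2(1.3)], [0.01, 0.01], [0.01, 0.01])
        calls = classify_dysregulated(res, log2fc_cut=np.log2(1.5))
        assert list(calls) == ["up", "ns"]
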
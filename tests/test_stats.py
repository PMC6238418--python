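"""Welch t, BH adjustment, log-log regression, slope z, TMM, DE caller."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from promarch.stats import (
    bh_adjust,
    cpm,
    de_call,
    loglog_fit,
    slope_z,
    tmm_factors,
    welch_t,
)


class TestWelch:
    def test_identical_samples(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0

    def test_hand_derived_three_point_example(self):
        # means 4 and 2, variances 4 and 1, n=3 each:
        # t = 2 / sqrt(4/3 + 1/3) = 2/sqrt(5/3); df = (5/3)^2 / ((4/3)^2/2 + (1/3)^2/2) = 50/17
        res = welch_t([2, 4, 6], [1, 2, 3])
        assert np.isclose(res.t, 2 / np.sqrt(5 / 3), rtol=1e-12)
        assert np.isclose(res.df, 50 / 17, rtol=1e-12)
        assert np.isclose(res.p, 2 * sps.t.sf(res.t, 50 / 17), rtol=1e-12)

    def test_swap_negates_t_preserves_p(self):
        a, b = [2.0, 4.0, 6.5], [1.0, 2.2, 3.0, 4.0]
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert np.isclose(r1.t, -r2.t) and np.isclose(r1.p, r2.p)

    def test_zero_variance_equal_means(self):
        res = welch_t([2, 2, 2], [2, 2])
        assert res.t == 0.0 and res.p == 1.0

    def test_zero_variance_unequal_means_errors(self):
        with pytest.raises(ValueError):
            welch_t([2, 2, 2], [3, 3])

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1], [1, 2])

    def test_rank_agreement_with_exact_permutation_test(self):
        """Welch p orders evidence like a brute-force permutation test."""
        rng = np.random.default_rng(11)
        welch_ps, perm_ps = [], []
        for _ in range(100):
            x = rng.normal(rng.uniform(-1, 1), 1.0, size=4)
            y = rng.normal(0, rng.uniform(0.5, 2.0), size=4)
            welch_ps.append(welch_t(x, y).p)
            perm = sps.permutation_test(
                (x, y),
                lambda a, b: np.mean(a) - np.mean(b),
                permutation_type="independent",
                n_resamples=np.inf,
            )
            perm_ps.append(perm.pvalue)
        rho = sps.spearmanr(welch_ps, perm_ps).statistic
        assert rho > 0.95


def bh_brute_force(p):
    """Step-up definition: adj_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.empty(m)
    for i in range(m):
        adj[i] = min(
            min(m * ranked[j] / (j + 1) for j in range(i, m)),
            1.0,
        )
    out = np.empty(m)
    out[order] = adj
    return out


class TestBH:
    def test_step_up_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert np.allclose(bh_adjust([0.2]), [0.2])

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=8,
        )
    )
    @settings(derandomize=True, max_examples=300)
    def test_matches_brute_force_definition(self, pvals):
        assert np.allclose(bh_adjust(pvals), bh_brute_force(pvals), atol=1e-12)

    @given(st.permutations(list(np.linspace(0.001, 0.9, 6))))
    @settings(derandomize=True, max_examples=40)
    def test_order_equivariance(self, perm):
        base = sorted(perm)
        adj_base = bh_adjust(base)
        adj_perm = bh_adjust(perm)
        assert np.allclose(sorted(adj_base), sorted(adj_perm))

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(5)
        p = rng.random(50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


class TestLogLog:
    def test_exact_power_law(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        y = np.e * x**2
        fit = loglog_fit(x, y)
        assert np.isclose(fit.beta, 2.0) and fit.se_beta < 1e-12
        assert np.isclose(fit.intercept, 1.0)

    def test_duplicated_points_shrink_se_by_known_factor(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(1, 100, size=20)
        y = x**1.5 * rng.lognormal(0, 0.3, size=20)
        single = loglog_fit(x, y)
        double = loglog_fit(np.tile(x, 2), np.tile(y, 2))
        n = 20
        expected = np.sqrt((n - 2) / (2 * n - 2))
        assert np.isclose(double.beta, single.beta)
        assert np.isclose(double.se_beta / single.se_beta, expected, rtol=1e-9)

    def test_zeros_excluded_with_count(self):
        fit = loglog_fit([0, 1, 2, 4, 8], [1, 1, 2, 4, 8])
        assert fit.n == 4 and fit.n_excluded == 1

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            loglog_fit([1, 2], [1, 2])

    def test_null_slope_ci_coverage(self):
        """Independent x,y: the beta +/- 1.96 se interval covers 0 at ~95%."""
        rng = np.random.default_rng(7)
        cover = 0
        reps = 300
        for _ in range(reps):
            x = rng.lognormal(0, 1, size=40)
            y = rng.lognormal(0, 1, size=40)
            fit = loglog_fit(x, y)
            cover += abs(fit.beta) < 1.96 * fit.se_beta
        # binomial(300, .95) 3-sigma band
        assert cover / reps > 0.91


class TestSlopeZ:
    def test_equal_slopes(self):
        f = loglog_fit([1, 2, 4, 8], [1, 2, 4, 8])
        res = slope_z(f, f)
        assert res.z == 0.0 and res.p == 1.0

    def test_closed_form(self):
        from promarch.stats import LogLogFit

        a = LogLogFit(beta=1.0, se_beta=0.6, intercept=0, n=10)
        b = LogLogFit(beta=0.2, se_beta=0.8, intercept=0, n=10)
        res = slope_z(a, b)
        assert np.isclose(res.z, 0.8)
        assert np.isclose(res.p, 2 * sps.norm.sf(0.8))

    def test_antisymmetry(self):
        from promarch.stats import LogLogFit

        a = LogLogFit(beta=1.3, se_beta=0.2, intercept=0, n=10)
        b = LogLogFit(beta=0.9, se_beta=0.3, intercept=0, n=10)
        assert np.isclose(slope_z(a, b).z, -slope_z(b, a).z)

    def test_se2_limit_reduces_to_beta_over_se(self):
        from promarch.stats import LogLogFit

        a = LogLogFit(beta=1.0, se_beta=0.5, intercept=0, n=10)
        b = LogLogFit(beta=0.0, se_beta=1e-12, intercept=0, n=10)
        assert np.isclose(slope_z(a, b).z, 2.0)

    def test_degenerate_zero_ses(self):
        from promarch.stats import LogLogFit

        a = LogLogFit(beta=1.0, se_beta=0.0, intercept=0, n=10)
        b = LogLogFit(beta=0.0, se_beta=0.0, intercept=0, n=10)
        res = slope_z(a, b)
        assert res.degenerate and res.p == 0.0


class TestTMM:
    def test_identical_columns_unit_factors(self):
        rng = np.random.default_rng(8)
        col = rng.poisson(50, size=200)
        counts = pd.DataFrame({"a": col, "b": col, "c": col})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_scaling_gives_unit_factors(self):
        rng = np.random.default_rng(9)
        col = rng.poisson(50, size=500) + 1
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        f = tmm_factors(counts, ref_column="a")
        assert np.allclose(f, 1.0, atol=1e-9)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(10)
        counts = pd.DataFrame(rng.negative_binomial(5, 0.1, size=(300, 4)))
        f = tmm_factors(counts)
        assert np.isclose(np.exp(np.mean(np.log(f))), 1.0, atol=1e-12)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            tmm_factors(counts)

    def test_matches_edger_reference(self, tmp_path):
        """Cross-check the TMM factors against edgeR::calcNormFactors."""
        rng = np.random.default_rng(12)
        mu = rng.lognormal(4, 1, size=250)
        counts = pd.DataFrame(
            {
                f"s{j}": rng.negative_binomial(10, 10 / (10 + mu * f))
                for j, f in enumerate([1.0, 1.6, 0.7, 1.2])
            }
        )
        ours = tmm_factors(counts, ref_column="s0")
        tsv = tmp_path / "counts.tsv"
        counts.to_csv(tsv, sep="\t", index=False)
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f"x <- as.matrix(read.delim('{tsv}'))\n"
            "f <- calcNormFactors(x, method='TMM', refColumn=1)\n"
            "cat(sprintf('%.10f', f), sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        theirs = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(ours.to_numpy(), theirs, rtol=1e-6)


class TestDECall:
    def test_low_cpm_genes_absent(self):
        rng = np.random.default_rng(13)
        counts = pd.DataFrame(
            rng.poisson(100, size=(50, 4)),
            columns=["control_1", "control_2", "kd_1", "kd_2"],
            index=[f"g{i}" for i in range(50)],
        )
        counts.loc["g0"] = 0  # CPM 0 everywhere
        de = de_call(counts)
        assert "g0" not in de.index
        assert len(de) == 49

    def test_planted_up_regulation_recovered(self):
        """logFC=3 at mean 100 with 4 reps is recovered with high recall."""
        rng = np.random.default_rng(14)
        n, n_up = 300, 50
        mu = np.full(n, 100.0)
        r = 20.0
        cols = {}
        for j in range(4):
            cols[f"control_{j}"] = rng.negative_binomial(r, r / (r + mu))
        mu_kd = mu.copy()
        mu_kd[:n_up] *= 8.0  # logFC = 3
        for j in range(4):
            cols[f"kd_{j}"] = rng.negative_binomial(r, r / (r + mu_kd))
        counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])
        de = de_call(counts)
        called_up = (de["logfc"] > 1) & (de["padj"] < 0.01)
        recall = called_up[:n_up].mean()
        assert recall >= 0.9
        assert called_up[n_up:].mean() <= 0.02

    def test_logfc_sign_convention(self):
        rng = np.random.default_rng(15)
        base = rng.poisson(200, size=100)
        counts = pd.DataFrame(
            {
                "control_1": base,
                "control_2": base + rng.poisson(5, 100),
                "kd_1": base * 4,
                "kd_2": base * 4 + rng.poisson(5, 100),
            },
            index=[f"g{i}" for i in range(100)],
        )
        de = de_call(counts)
        # uniform 4x scaling is a library-size effect, normalized away
        assert de["logfc"].abs().median() < 0.2

    def test_cpm_zero_library_rejected(self):
        with pytest.raises(ValueError):
            cpm(pd.DataFrame({"a": [0, 0]}))
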
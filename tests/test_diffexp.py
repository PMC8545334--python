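import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from conftest import make_matrix
from proteoflow import ContrastSpec, SampleDesign, diffexp
from proteoflow.errors import DegenerateVarianceError, DesignError, ParameterError


class TestFitLinearModels:
    def test_unpaired_hand_arithmetic(self):
        # toy: A=(1,1), B=(3,3)
        design = SampleDesign(["a1", "a2", "b1", "b2"], ["A", "A", "B", "B"])
        m4 = make_matrix([[1.0, 1.0, 3.0, 3.0]], samples=design.samples)
        fits = diffexp.fit_linear_models(m4, design, ContrastSpec("A", "B"))
        row = fits.iloc[0]
        assert row["effect"] == pytest.approx(2.0)
        assert row["s2"] == pytest.approx(0.0)
        assert row["df_resid"] == 2

    def test_paired_differences(self):
        # differences per subject: (1, 3) -> effect 2, var 2, df 1
        design = SampleDesign(["a1", "a2", "b1", "b2"], ["A", "A", "B", "B"],
                              ["s1", "s2", "s1", "s2"])
        m4 = make_matrix([[0.0, 0.0, 1.0, 3.0]], samples=design.samples)
        fits = diffexp.fit_linear_models(
            m4, design, ContrastSpec("A", "B", paired=True)
        )
        row = fits.iloc[0]
        assert row["effect"] == pytest.approx(2.0)
        assert row["s2"] == pytest.approx(2.0)
        assert row["df_resid"] == 1

    def test_identical_groups_give_zero_effect(self, two_group_design):
        m = make_matrix([[2.0, 3.0, 4.0, 2.0, 3.0, 4.0]],
                        samples=two_group_design.samples)
        fits = diffexp.fit_linear_models(m, two_group_design,
                                         ContrastSpec("A", "B"))
        assert fits.iloc[0]["effect"] == pytest.approx(0.0)

    def test_condition_fully_missing_flags_protein(self, two_group_design):
        m = make_matrix(
            [[np.nan, np.nan, np.nan, 1.0, 2.0, 3.0],
             [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
            samples=two_group_design.samples,
        )
        fits = diffexp.fit_linear_models(m, two_group_design,
                                         ContrastSpec("A", "B"))
        assert not fits.iloc[0]["testable"]
        assert fits.iloc[1]["testable"]

    def test_bad_contrast_rejected(self, two_group_design):
        m = make_matrix(np.zeros((2, 6)), samples=two_group_design.samples)
        with pytest.raises(DesignError):
            diffexp.fit_linear_models(m, two_group_design,
                                      ContrastSpec("A", "A"))
        with pytest.raises(DesignError):
            diffexp.fit_linear_models(m, two_group_design,
                                      ContrastSpec("A", "C"))


class TestEbayes:
    def simulate_fits(self, n=200, seed=0, d0=4.0, s0_2=1.0, df=6):
        rng = np.random.default_rng(seed)
        true_var = s0_2 * d0 / rng.chisquare(d0, size=n)
        s2 = true_var * rng.chisquare(df, size=n) / df
        return pd.DataFrame({
            "id": [f"P{i}" for i in range(n)],
            "effect": rng.normal(size=n),
            "s2": s2,
            "df_resid": df,
            "v": 1.0 / 3 + 1.0 / 3,
            "n_obs": 6,
            "testable": True,
        })

    def test_d0_zero_reduces_to_ordinary_t(self):
        fits = self.simulate_fits(seed=1)
        out, d0, _ = diffexp.ebayes_moderate(fits, d0=0.0)
        ordinary_t = fits["effect"] / np.sqrt(fits["s2"] * fits["v"])
        assert np.allclose(out["t"], ordinary_t, rtol=1e-12)
        expected_p = 2 * stats.t.sf(np.abs(ordinary_t), fits["df_resid"])
        assert np.allclose(out["p"], expected_p, rtol=1e-12)

    def test_equal_variances_drive_d0_to_infinity(self):
        fits = self.simulate_fits(seed=2)
        fits["s2"] = 1.7
        out, d0, s0_2 = diffexp.ebayes_moderate(fits)
        assert np.isinf(d0)
        # every posterior variance collapses to the common prior
        assert np.allclose(out["s2_post"], s0_2)
        assert len(set(np.round(out["s2_post"], 12))) == 1

    def test_shrinkage_monotone_in_d0(self):
        fits = self.simulate_fits(seed=3, n=50)
        s2 = fits["s2"].to_numpy()
        df = fits["df_resid"].to_numpy(dtype=float)
        s0_2 = 1.0
        prev = diffexp.posterior_variance(s2, df, 0.0, s0_2)
        for d0 in (1.0, 4.0, 16.0, 256.0):
            cur = diffexp.posterior_variance(s2, df, d0, s0_2)
            # every value moves toward s0_2 as d0 grows
            assert np.all(np.abs(cur - s0_2) <= np.abs(prev - s0_2) + 1e-12)
            prev = cur

    def test_all_zero_variances_degenerate(self):
        fits = self.simulate_fits(n=5, seed=4)
        fits["s2"] = 0.0
        with pytest.raises(DegenerateVarianceError):
            diffexp.ebayes_moderate(fits)

    def test_trigamma_inverse_inverts_trigamma(self):
        from scipy.special import polygamma
        for x in (0.01, 0.1, 0.5, 1.0, 2.0, 10.0, 500.0):
            y = float(polygamma(1, x))
            assert diffexp.trigamma_inverse(y) == pytest.approx(x, rel=1e-6)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_matches_limma_reference(self, tmp_path, two_group_design):
        """Independent oracle: the reference empirical-Bayes implementation
        in R/limma on a small two-group dataset."""
        rng = np.random.default_rng(17)
        X = rng.normal(25, 1, size=(40, 6))
        X[:5, 3:] += 1.5
        m = make_matrix(X, samples=two_group_design.samples)
        expr = tmp_path / "x.tsv"
        m.values.to_csv(expr, sep="\t")
        rfile = tmp_path / "ref.R"
        rfile.write_text(
            """
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            x <- as.matrix(read.delim(args[1], row.names=1))
            design <- cbind(Intercept=1, B=c(0,0,0,1,1,1))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,"B"], p=fit$p.value[,"B"],
                              lfc=fit$coefficients[,"B"])
            out$d0 <- fit$df.prior; out$s02 <- fit$s2.prior
            write.table(format(out, digits=12), args[2], sep="\\t", quote=FALSE)
            """
        )
        out_tsv = tmp_path / "limma.tsv"
        subprocess.run(["Rscript", str(rfile), str(expr), str(out_tsv)],
                       check=True, capture_output=True)
        ref = pd.read_csv(out_tsv, sep="\t", index_col=0)
        ref.index = ref.index.astype(str)
        ours = diffexp.run_differential_expression(
            m, two_group_design, ContrastSpec("A", "B")
        )
        assert ours.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-6)
        assert ours.s0_2 == pytest.approx(float(ref["s02"].iloc[0]), rel=1e-6)
        mine = ours.table.set_index("id").reindex(ref.index)
        assert len(mine) == 40 and not mine["t"].isna().any()
        assert np.allclose(mine["logFC"], ref["lfc"], rtol=1e-8)
        assert np.allclose(mine["t"], ref["t"], rtol=1e-8)
        assert np.allclose(mine["p"], ref["p"], rtol=1e-6)


class TestBenjaminiHochberg:
    def brute_force(self, p):
        """Step-up definition applied literally."""
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        adj = [None] * m
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = min(running, 1.0)
        return adj

    def test_hand_example(self):
        assert np.allclose(
            diffexp.adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_trivial_cases(self):
        assert diffexp.adjust_bh([0.3]) == pytest.approx([0.3])
        assert np.allclose(diffexp.adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            diffexp.adjust_bh([0.5, 1.5])

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(5)
        p = rng.random(500)
        ours = diffexp.adjust_bh(p)
        ref = sm.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref, atol=1e-12)

    @given(st.lists(st.sampled_from(
        [0.0, 0.001, 0.01, 0.02, 0.04, 0.05, 0.2, 0.5, 0.8, 1.0]),
        min_size=1, max_size=8))
    def test_matches_bruteforce_definition(self, p):
        assert np.allclose(diffexp.adjust_bh(p), self.brute_force(p),
                           atol=1e-12)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(8)
        p = rng.random(50)
        base = diffexp.adjust_bh(p)
        for _ in range(5):
            perm = rng.permutation(50)
            permuted = diffexp.adjust_bh(p[perm])
            assert np.allclose(permuted, base[perm], atol=1e-15)

    def test_nan_passthrough(self):
        out = diffexp.adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], diffexp.adjust_bh([0.01, 0.02]))


class TestRunDifferentialExpression:
    def test_contrast_swap_negates_effects(self, two_group_design):
        rng = np.random.default_rng(21)
        m = make_matrix(rng.normal(size=(30, 6)),
                        samples=two_group_design.samples)
        ab = diffexp.run_differential_expression(
            m, two_group_design, ContrastSpec("A", "B"))
        ba = diffexp.run_differential_expression(
            m, two_group_design, ContrastSpec("B", "A"))
        a = ab.table.set_index("id")
        b = ba.table.set_index("id").reindex(a.index)
        assert np.allclose(a["logFC"], -b["logFC"], atol=1e-12)
        assert np.allclose(a["p"], b["p"], atol=1e-12)

    def test_spike_in_power(self):
        """10% of proteins shifted by twice the residual sd are mostly
        recovered at BH < 0.05."""
        from proteoflow import fixtures as fx
        spec = fx.SimulationSpec(n_proteins=2000, frac_de=0.1,
                                 effect_size=1.0, residual_sd=0.5,
                                 variance_prior_df=float("inf"),
                                 mcar_rate=0.0, dropout_amplitude=0.0,
                                 seed=99)
        m, design, truth = fx.simulate_expression(spec)
        res = diffexp.run_differential_expression(m, design,
                                                  ContrastSpec("A", "B"))
        hits = set(diffexp.significant_proteins(res, threshold=0.05))
        de_true = set(truth.loc[truth["is_de"], "id"])
        recall = len(hits & de_true) / len(de_true)
        assert recall >= 0.6

    def test_sorted_by_p_with_flagged_last(self, two_group_design):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(20, 6))
        X[0, :3] = np.nan  # untestable
        m = make_matrix(X, samples=two_group_design.samples)
        res = diffexp.run_differential_expression(
            m, two_group_design, ContrastSpec("A", "B"))
        p = res.table["p"].to_numpy()
        valid = p[~np.isnan(p)]
        assert np.all(np.diff(valid) >= 0)
        assert bool(res.table.iloc[-1]["flagged"])
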
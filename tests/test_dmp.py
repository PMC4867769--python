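import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, spearmanr

import twinmeth as tm
from conftest import make_discordant_design


def closed_form_t2_p(t):
    """Two-sided P for Student's t with 2 df: F(t) = 1/2 + t/(2*sqrt(2+t^2))."""
    return 2.0 * (1.0 - (0.5 + t / (2.0 * np.sqrt(2.0 + t * t))))


class TestPairedDeltas:
    def test_identical_twins_give_zero(self):
        beta, design = make_discordant_design({"cg1": [(0.4, 0.4), (0.7, 0.7)]})
        d = tm.paired_deltas(beta, design)
        assert np.all(d.deltas.to_numpy() == 0.0)

    def test_group_mean_arithmetic(self):
        """Group means 0.315 vs 0.349 must yield mean delta-beta -0.034."""
        beta, design = make_discordant_design({"cg1": [(0.315, 0.349)] * 4})
        rec = tm.paired_t_test(tm.paired_deltas(beta, design))
        assert rec.loc["cg1", "delta_beta"] == pytest.approx(-0.034)
        assert rec.loc["cg1", "mean_affected"] == pytest.approx(0.315)
        assert rec.loc["cg1", "mean_unaffected"] == pytest.approx(0.349)

    def test_sample_order_invariance(self):
        beta, design = make_discordant_design({"cg1": [(0.3, 0.4), (0.6, 0.5), (0.2, 0.25)]})
        shuffled = beta.subset(samples=list(reversed(beta.sample_ids)))
        d1 = tm.paired_deltas(beta, design).deltas
        d2 = tm.paired_deltas(shuffled, design).deltas
        pd.testing.assert_frame_equal(d1, d2)

    def test_no_discordant_pairs_is_an_error(self, small_study):
        conc = small_study.design.wave(10).group("concordant")
        with pytest.raises(ValueError, match="no discordant pairs"):
            tm.paired_deltas(small_study.beta_age10, conc)


class TestPairedT:
    def test_symmetric_deltas_give_p_one(self):
        beta, design = make_discordant_design({"cg1": [(0.52, 0.50), (0.50, 0.52)]})
        rec = tm.paired_t_test(tm.paired_deltas(beta, design))
        assert rec.loc["cg1", "t_stat"] == pytest.approx(0.0)
        assert rec.loc["cg1", "p_value"] == pytest.approx(1.0)

    def test_three_pair_closed_form(self):
        """deltas (0.02, 0.03, 0.04): t = 5.196, df = 2, P from the exact
        2-df CDF."""
        beta, design = make_discordant_design(
            {"cg1": [(0.52, 0.50), (0.53, 0.50), (0.54, 0.50)]}
        )
        rec = tm.paired_t_test(tm.paired_deltas(beta, design))
        t = rec.loc["cg1", "t_stat"]
        assert t == pytest.approx(3 * np.sqrt(3), rel=1e-9)
        assert rec.loc["cg1", "df"] == 2
        assert rec.loc["cg1", "p_value"] == pytest.approx(closed_form_t2_p(t), rel=1e-9)

    def test_degenerate_rows_flagged(self):
        beta, design = make_discordant_design(
            {"cg_zero": [(0.5, 0.5), (0.5, 0.5)], "cg_const": [(0.52, 0.50), (0.52, 0.50)]}
        )
        rec = tm.paired_t_test(tm.paired_deltas(beta, design))
        assert rec.loc["cg_zero", "p_value"] == 1.0
        assert not rec.loc["cg_zero", "degenerate"]
        assert np.isnan(rec.loc["cg_const", "p_value"])
        assert rec.loc["cg_const", "degenerate"]

    def test_single_pair_rejected(self):
        beta, design = make_discordant_design({"cg1": [(0.5, 0.4)]})
        with pytest.raises(ValueError, match=">= 2 complete pairs"):
            tm.paired_t_test(tm.paired_deltas(beta, design))


class TestRanking:
    def _records(self, p_values, deltas=None):
        n = len(p_values)
        return pd.DataFrame(
            {
                "delta_beta": deltas if deltas is not None else np.linspace(0.01, 0.05, n),
                "p_value": p_values,
            },
            index=pd.Index([f"cg{i}" for i in range(n)], name="probe_id"),
        )

    def test_all_null_gives_empty_views(self):
        full, primary, extended = tm.rank_dmps(self._records([1.0, 1.0, 1.0]))
        assert primary.empty and extended.empty and len(full) == 3

    def test_tie_break_by_effect_then_name(self):
        records = self._records([1e-6, 1e-6, 1e-4], deltas=[0.02, -0.05, 0.01])
        full, primary, _ = tm.rank_dmps(records)
        assert list(full.index) == ["cg1", "cg0", "cg2"]
        assert list(primary.index) == ["cg1", "cg0"]  # cg2 misses 5e-5

    def test_stable_under_input_permutation(self):
        rng = np.random.default_rng(0)
        records = self._records(rng.random(30))
        shuffled = records.sample(frac=1.0, random_state=1)
        full1, _, _ = tm.rank_dmps(records)
        full2, _, _ = tm.rank_dmps(shuffled)
        assert list(full1.index) == list(full2.index)

    def test_spiked_probes_dominate_top_table(self, small_study):
        res = tm.DiscordantPairModel(
            small_study.beta_age10.subset(probes=small_study.analysis_probe_ids),
            small_study.design,
            age_wave=10,
        ).fit()
        spiked = set(small_study.truth.index[small_study.truth["spiked"]])
        top = set(res.table.index[: len(spiked)])
        assert len(top & spiked) >= 0.5 * len(spiked)


class TestInflation:
    def test_uniform_null_lambda_near_one(self):
        rng = np.random.default_rng(123)
        lam, qq = tm.genomic_inflation(rng.random(10000))
        assert lam == pytest.approx(1.0, abs=0.03)
        assert len(qq) == 10000
        assert (qq["observed_neglog10_p"].diff().dropna() <= 1e-12).all()

    def test_lambda_increases_when_p_shrink(self):
        rng = np.random.default_rng(5)
        p = rng.random(5000)
        lam1, _ = tm.genomic_inflation(p)
        lam2, _ = tm.genomic_inflation(p / 10.0)
        assert lam2 > lam1

    def test_chi_square_mixture_matches_quantile_oracle(self):
        rng = np.random.default_rng(7)
        stats = np.concatenate([chi2.rvs(1, size=6000, random_state=rng) * 1.4,
                                chi2.rvs(1, size=4000, random_state=rng)])
        p = chi2.sf(stats, df=1)
        lam, _ = tm.genomic_inflation(p)
        assert lam == pytest.approx(np.median(stats) / chi2.ppf(0.5, 1), rel=1e-9)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            tm.genomic_inflation(np.concatenate([np.full(200, 0.5), [0.0]]))


class TestCovariateAdjustment:
    def test_zero_covariates_identity(self):
        cov = {"c1": {f"P{i + 1:02d}{r}": 0.0 for i in range(3) for r in "AU"}}
        beta, design = make_discordant_design(
            {"cg1": [(0.3, 0.4), (0.6, 0.5), (0.2, 0.25)]}, covariates=cov
        )
        with pytest.warns(UserWarning, match="collinear"):  # all-zero column
            adj = tm.adjust_covariates(beta, design, ["c1"])
        np.testing.assert_allclose(adj.values.to_numpy(), beta.values.to_numpy())

    def test_projection_onto_own_beta_flattens_probe(self):
        pair_vals = [(0.3, 0.4), (0.6, 0.5), (0.2, 0.25), (0.8, 0.7)]
        sample_betas = {}
        for i, (a, u) in enumerate(pair_vals):
            sample_betas[f"P{i + 1:02d}A"] = a
            sample_betas[f"P{i + 1:02d}U"] = u
        beta, design = make_discordant_design(
            {"cg1": pair_vals}, covariates={"self": sample_betas}
        )
        adj = tm.adjust_covariates(beta, design, ["self"])
        assert np.ptp(adj.values.loc["cg1"].to_numpy()) < 1e-10
        rec = tm.paired_t_test(tm.paired_deltas(adj, design))
        assert rec.loc["cg1", "delta_beta"] == pytest.approx(0.0, abs=1e-10)

    def test_independent_covariates_barely_move_effects(self):
        cfg = tm.SimulationConfig(n_discordant_pairs=200, n_concordant_pairs=2, n_pairs_age5=0,
                                  n_probes=150, n_spiked=5, spike_delta_range=(0.05, 0.0500001),
                                  seed=17)
        study = tm.simulate_twin_methylome(cfg)
        beta = study.beta_age10.subset(probes=study.analysis_probe_ids)
        design = study.design.wave(10)
        raw = tm.paired_t_test(tm.paired_deltas(beta, design))
        adj_beta = tm.adjust_covariates(
            beta, design, ["internalizing", "externalizing", "depression"]
        )
        adj = tm.paired_t_test(tm.paired_deltas(adj_beta, design))
        spiked = study.truth.index[study.truth["spiked"]]
        shift = (adj.loc[spiked, "delta_beta"] - raw.loc[spiked, "delta_beta"]).abs()
        assert shift.max() < 0.005

    def test_collinear_covariate_dropped_with_warning(self):
        cov_vals = {f"P{i + 1:02d}{r}": float(i) for i in range(4) for r in "AU"}
        beta, design = make_discordant_design(
            {"cg1": [(0.3, 0.4), (0.6, 0.5), (0.2, 0.25), (0.7, 0.65)]},
            covariates={"c1": cov_vals, "c2": {k: 2 * v for k, v in cov_vals.items()}},
        )
        with pytest.warns(UserWarning, match="collinear"):
            tm.adjust_covariates(beta, design, ["c1", "c2"])


class TestEmpiricalP:
    def test_exhaustive_three_pairs(self):
        """8 sign patterns; only identity and the global flip reach |t| =
        5.196, so the secondary empirical P is exactly 2/8."""
        beta, design = make_discordant_design(
            {"cg1": [(0.52, 0.50), (0.53, 0.50), (0.54, 0.50)]}
        )
        out = tm.empirical_p(beta, design, ["cg1"], n_perm=100, seed=0)
        assert bool(out.loc["cg1", "exhaustive"])
        assert out.loc["cg1", "n_perm"] == 8
        assert out.loc["cg1", "empirical_p_secondary"] == pytest.approx(0.25)

    def test_primary_definition_counts_fixed_threshold(self):
        beta, design = make_discordant_design(
            {"cg1": [(0.52, 0.50), (0.53, 0.50), (0.54, 0.50)]}
        )
        # with 3 pairs no permutation P can reach 5e-5, including the observed
        out = tm.empirical_p(beta, design, ["cg1"], n_perm=100, seed=0)
        assert out.loc["cg1", "empirical_p"] == 0.0

    def test_sampled_matches_exhaustive_within_binomial_error(self):
        rng = np.random.default_rng(21)
        pair_vals = [tuple(sorted(rng.uniform(0.4, 0.6, 2), reverse=True)) for _ in range(10)]
        beta, design = make_discordant_design({"cg1": pair_vals})
        exact = tm.empirical_p(beta, design, ["cg1"], n_perm=2000, seed=0)
        assert bool(exact.loc["cg1", "exhaustive"])
        sampled = tm.empirical_p(beta, design, ["cg1"], n_perm=1000, seed=3)
        p_true = exact.loc["cg1", "empirical_p_secondary"]
        se = np.sqrt(p_true * (1 - p_true) / 1000)
        assert abs(sampled.loc["cg1", "empirical_p_secondary"] - p_true) <= 3 * se + 1e-9

    def test_secondary_agrees_with_analytic_ranks(self, null_study):
        """Secondary empirical P orders probes the same way as the paired-t
        P (Spearman > 0.95 over 50 probes)."""
        probes = null_study.analysis_probe_ids[:50]
        beta = null_study.beta_age10.subset(probes=null_study.analysis_probe_ids)
        out = tm.empirical_p(beta, null_study.design, probes, n_perm=10000, seed=2)
        rho = spearmanr(out["p_value"], out["empirical_p_secondary"]).statistic
        assert rho > 0.95

    def test_determinism_under_seed(self, small_study):
        beta = small_study.beta_age10.subset(probes=small_study.analysis_probe_ids)
        probes = small_study.analysis_probe_ids[:5]
        a = tm.empirical_p(beta, small_study.design, probes, n_perm=500, seed=9, age_wave=10)
        b = tm.empirical_p(beta, small_study.design, probes, n_perm=500, seed=9, age_wave=10)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_permutations_rejected(self, small_study):
        beta = small_study.beta_age10.subset(probes=small_study.analysis_probe_ids)
        with pytest.raises(ValueError, match="n_perm"):
            tm.empirical_p(beta, small_study.design, small_study.analysis_probe_ids[:1],
                           n_perm=50, seed=0, age_wave=10)


class TestModelInterface:
    def test_results_carry_tables_and_summary(self, small_study):
        res = tm.DiscordantPairModel(
            small_study.beta_age10.subset(probes=small_study.analysis_probe_ids),
            small_study.design,
            age_wave=10,
        ).fit()
        res.add_empirical_p(n_perm=200, seed=1)
        text = res.summary()
        assert "genomic inflation lambda" in text
        assert "empirical_p" in res.table.columns
        assert set(res.primary.index) <= set(res.table.index)
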
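import numpy as np
import pytest
from scipy import stats

import polytail as pt


class TestGenotypes:
    def test_moment_oracle(self, small_panel, rng):
        g = pt.simulate_genotypes(small_panel, 200_000, rng)
        p = small_panel.freqs
        np.testing.assert_allclose(g.dosages.mean(0), 2 * p, atol=0.01)
        np.testing.assert_allclose(g.dosages.var(0), 2 * p * (1 - p), atol=0.01)

    def test_near_fixed_allele(self, rng):
        panel = pt.SnpPanel([pt.SnpEffect("s", "A", "G", 0.05, 0.001, 1 - 1e-9)])
        g = pt.simulate_genotypes(panel, 1000, rng)
        assert (g.dosages == 2).all()


class TestZscores:
    def test_null_panel_gives_standard_normal(self, rng):
        panel = pt.SnpPanel([pt.SnpEffect("s", "A", "G", 0.0, 0.001, 0.5)])
        g = pt.simulate_genotypes(panel, 20_000, rng)
        z = pt.simulate_zscores(g, panel, None, rng)
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_marginal_variance_is_one(self, panel160, rng):
        g = pt.simulate_genotypes(panel160, 300_000, rng)
        z = pt.simulate_zscores(g, panel160, None, rng)
        assert abs(z.mean()) < 0.01
        assert z.var() == pytest.approx(1.0, abs=0.01)

    def test_rare_carriers_shifted_by_effect(self, panel160):
        # replay the internal rare-dosage draw to identify carriers
        rare = pt.RareVariantModel.uniform(1, -2.0, 0.005)
        rng = np.random.default_rng(11)
        g = pt.simulate_genotypes(panel160, 200_000, rng)
        state = rng.bit_generator.state
        z = pt.simulate_zscores(g, panel160, rare, rng)
        replay = np.random.default_rng()
        replay.bit_generator.state = state
        d_rv = replay.binomial(2, rare.freqs, size=(200_000, 1)).ravel()
        gap = z[d_rv == 0].mean() - z[d_rv == 1].mean()
        assert gap == pytest.approx(2.0, abs=0.1)

    def test_variance_budget_enforced(self, panel160, rng):
        over = pt.RareVariantModel.uniform(200, -1.0, 0.05)
        g = pt.simulate_genotypes(panel160, 10, rng)
        with pytest.raises(ValueError, match="variance budget"):
            pt.simulate_zscores(g, panel160, over, rng)

    def test_rare_model_centering(self):
        rare = pt.RareVariantModel.uniform(10, -1.0, 0.005)
        assert rare.alpha_rv == pytest.approx(-0.1)
        assert rare.variance == pytest.approx(10 * 2 * 0.005 * 0.995)


class TestScoreSampler:
    def test_tabulated_moments_match_analytic(self, panel160):
        s = pt.ScoreSampler(panel160.betas, panel160.freqs)
        mean, var = s.grid_moments()
        assert mean == pytest.approx(0.0, abs=1e-8)
        assert var == pytest.approx(panel160.was_variance, rel=1e-4)

    def test_distribution_matches_genotype_path(self, panel160, rng):
        s = pt.ScoreSampler(panel160.betas, panel160.freqs)
        draws = s.sample(30_000, rng)
        g = pt.simulate_genotypes(panel160, 30_000, rng)
        ref = pt.compute_was(g, panel160).score
        assert stats.ks_2samp(draws, ref).pvalue > 0.001

    def test_three_atom_distribution(self, rng):
        # single rare variant: mass at -2k - alpha_rv, k = 0, 1, 2
        s = pt.ScoreSampler([-2.0], [0.005])
        draws = s.sample(200_000, rng)
        frac_carrier = (draws < -1.0).mean()
        expected = 1 - 0.995**2
        assert frac_carrier == pytest.approx(expected, abs=0.002)


class TestQuotaAscertainment:
    def test_quota_equal_to_subpop_selects_everyone(self, rng):
        scheme = pt.QuotaScheme((10, 8), (5, 4), (5, 4))
        z = rng.standard_normal(18)
        sel = scheme.select(z, rng)
        assert sel["short"].size + sel["tall"].size == 18

    def test_published_stratum_quotas_sum(self, panel160, rng):
        scheme = pt.QuotaScheme(
            (4271, 6582, 5025, 7610), (21, 32, 25, 38), (21, 32, 25, 38)
        )
        g = pt.simulate_genotypes(panel160, scheme.n_total, rng)
        z = pt.simulate_zscores(g, panel160, None, rng)
        cohort = pt.ascertain_quota(g, z, scheme, rng)
        assert (cohort.group == "short").sum() == 116
        assert (cohort.group == "tall").sum() == 116

    def test_selected_are_most_extreme_within_subpop(self, rng):
        scheme = pt.QuotaScheme((200, 300), (10, 15), (12, 18))
        z = rng.standard_normal(500)
        sel = scheme.select(z, rng)
        strata = scheme.stratum_labels()
        for label, lo in (("subpop1", 0), ("subpop2", 200)):
            block = np.arange(lo, lo + (200 if label == "subpop1" else 300))
            tall_in = np.intersect1d(sel["tall"], block)
            others = np.setdiff1d(block, np.concatenate([sel["tall"], sel["short"]]))
            assert z[tall_in].min() >= z[others].max()
            short_in = np.intersect1d(sel["short"], block)
            assert z[short_in].max() <= z[others].min()

    def test_random_drop_to_final_sizes(self, rng):
        scheme = pt.QuotaScheme((1000,) * 4, (50,) * 4, (50,) * 4, 181, 192)
        z = rng.standard_normal(4000)
        sel = scheme.select(z, rng)
        assert sel["short"].size == 181
        assert sel["tall"].size == 192

    def test_infeasible_quota_rejected(self):
        with pytest.raises(ValueError):
            pt.QuotaScheme((10,), (8,), (8,))


class TestThresholdAscertainment:
    def test_tail_availability_matches_normal_mass(self, rng):
        z = rng.standard_normal(50_000)
        available = (z > 2.14).sum()
        assert abs(available - 50_000 * stats.norm.sf(2.14)) < 4 * np.sqrt(
            50_000 * stats.norm.sf(2.14)
        )
        scheme = pt.ThresholdScheme(50_000, -2.14, 2.14, 700, 700)
        sel = scheme.select(z, rng)
        assert sel["short"].size == sel["tall"].size == 700

    def test_insufficient_extremes_rejected(self, rng):
        z = rng.standard_normal(50_000)
        scheme = pt.ThresholdScheme(50_000, -2.14, 2.14, 2000, 2000)
        with pytest.raises(ValueError, match="increase the pool"):
            scheme.select(z, rng)

    def test_infinite_cutoff_rejected(self):
        with pytest.raises(ValueError):
            pt.ThresholdScheme(1000, -np.inf, np.inf, 10, 10)

    def test_cutoff_zero_partitions_cohort(self, rng):
        z = rng.standard_normal(1000)
        n_neg, n_pos = (z < 0).sum(), (z > 0).sum()
        scheme = pt.ThresholdScheme(1000, 0.0, 0.0 + 1e-12, n_neg, n_pos)
        sel = scheme.select(z, rng)
        assert sel["short"].size + sel["tall"].size == 1000

    def test_middle_group_drawn_from_band(self, panel160, rng):
        scheme = pt.ThresholdScheme(
            20_000, -2.326, 2.326, 100, 100, middle_band=(-2.0, 2.0), n_middle=500
        )
        g = pt.simulate_genotypes(panel160, 20_000, rng)
        z = pt.simulate_zscores(g, panel160, None, rng)
        cohort = pt.ascertain_threshold(g, z, scheme, rng)
        mids = cohort.z[cohort.group == "middle"]
        assert mids.size == 500
        assert (np.abs(mids) < 2.0).all()


class TestMissingness:
    def test_zero_rate_identity(self, small_panel, rng):
        g = pt.simulate_genotypes(small_panel, 100, rng)
        out = pt.apply_missingness(g, 0.0, rng)
        np.testing.assert_array_equal(out.dosages, g.dosages)

    def test_rate_realized(self, small_panel, rng):
        g = pt.simulate_genotypes(small_panel, 100_000, rng)
        out = pt.apply_missingness(g, 0.02, rng)
        assert np.isnan(out.dosages).mean() == pytest.approx(0.02, abs=0.002)

    def test_independent_of_dosage(self, rng):
        panel = pt.SnpPanel([pt.SnpEffect("s", "A", "G", 0.05, 0.001, 0.5)])
        g = pt.simulate_genotypes(panel, 200_000, rng)
        out = pt.apply_missingness(g, 0.1, rng)
        miss = np.isnan(out.dosages[:, 0])
        table = np.array(
            [
                [(g.dosages[miss, 0] == d).sum() for d in (0, 1, 2)],
                [(g.dosages[~miss, 0] == d).sum() for d in (0, 1, 2)],
            ]
        )
        assert stats.chi2_contingency(table).pvalue > 0.001

    def test_certain_missingness_rejected(self, small_panel, rng):
        g = pt.simulate_genotypes(small_panel, 10, rng)
        with pytest.raises(ValueError):
            pt.apply_missingness(g, 1.0, rng)


class TestSiblingsSim:
    def test_uncorrelated_pairs(self, rng):
        pairs = pt.simulate_sibling_pairs(50_000, 0.0, rng)
        assert abs(np.corrcoef(pairs.T)[0, 1]) < 0.02

    def test_target_correlation_recovered(self, rng):
        pairs = pt.simulate_sibling_pairs(100_000, 0.466, rng)
        assert np.corrcoef(pairs.T)[0, 1] == pytest.approx(0.466, abs=0.01)

    def test_conditional_mean_is_linear_in_proband(self, rng):
        r = 0.466
        pairs = pt.simulate_sibling_pairs(200_000, r, rng)
        for lo, hi in ((0.5, 1.0), (1.0, 1.5), (-1.5, -1.0)):
            m = (pairs[:, 0] > lo) & (pairs[:, 0] < hi)
            assert pairs[m, 1].mean() == pytest.approx(r * pairs[m, 0].mean(), abs=0.03)


class TestModelInvariants:
    def test_quota_cohort_separates_groups(self, panel160):
        # selection on Z must pull the tall group's mean WAS above the short's
        scheme = pt.QuotaScheme((1000,) * 4, (50,) * 4, (50,) * 4, 181, 192)
        rep = pt.CohortReplicator(panel160, scheme)
        for seed in range(5):
            means = rep.replicate(np.random.default_rng(seed)).group_mean_was(panel160)
            assert means["tall"] > means["short"]

    def test_extra_common_variants_leave_null_unchanged(self, panel160):
        # phenotype variance moved from noise to unscored variants does not
        # alter E[WAS | selection] of the scored panel
        scheme = pt.ThresholdScheme(20_000, -2.326, 2.326, 120, 120)
        extra = pt.RareVariantModel.uniform(180, -0.05, 0.3)
        mus = {}
        for name, model in (("null", None), ("extra", extra)):
            rep = pt.CohortReplicator(panel160, scheme, model)
            rng = np.random.default_rng(33)
            mus[name] = np.array(
                [rep.replicate(rng).group_mean_was(panel160)["short"] for _ in range(300)]
            )
        se = np.sqrt(mus["null"].var() / 300 + mus["extra"].var() / 300)
        assert abs(mus["null"].mean() - mus["extra"].mean()) < 3.5 * se

    def test_rare_effect_ordering_in_short_tail(self, panel160):
        # stronger height-decreasing rare effects push the short tail's mean
        # WAS further toward zero; the pool is sized so the B=-4 scenario's
        # thinned tall tail still meets the selection targets
        scheme = pt.ThresholdScheme(40_000, -2.326, 2.326, 120, 120)
        mus = []
        for model in (
            None,
            pt.RareVariantModel.uniform(1, -2.0, 0.005),
            pt.RareVariantModel.uniform(1, -4.0, 0.005),
        ):
            rep = pt.CohortReplicator(panel160, scheme, model)
            rng = np.random.default_rng(44)
            mus.append(
                np.mean(
                    [rep.replicate(rng).group_mean_was(panel160)["short"] for _ in range(200)]
                )
            )
        assert mus[0] < mus[1] < mus[2]
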
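import numpy as np
import pytest

import polytail as pt


class TestAlleleTables:
    def test_counting_example(self):
        t = pt.allele_tables([2.0, 1.0, 0.0], ["tall", "tall", "short"])
        np.testing.assert_array_equal(t.tables[0], [[3, 1], [0, 2]])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            pt.allele_tables([np.nan, np.nan], ["tall", "short"])

    def test_column_sums_conserve_alleles(self, rng):
        d = rng.binomial(2, 0.4, 100).astype(float)
        d[rng.random(100) < 0.1] = np.nan
        groups = np.where(rng.random(100) < 0.5, "tall", "short")
        t = pt.allele_tables(d, groups)
        for row, g in zip(t.tables[0], ("tall", "short")):
            n_obs = (np.isfinite(d) & (groups == g)).sum()
            assert row.sum() == 2 * n_obs

    def test_single_group_stratum_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            t = pt.allele_tables(
                [1.0, 2.0, 0.0],
                ["tall", "short", "tall"],
                ["a", "a", "b"],
            )
        assert t.strata == ["a"]

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="tall/short"):
            pt.allele_tables([1.0], ["middle"])


class TestCmh:
    def test_balanced_table_is_null(self):
        t = pt.StratifiedAlleleTables(np.array([[[10, 10], [10, 10]]]), ["all"])
        res = pt.cmh_test(t)
        assert res.or_observed == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_single_stratum_reduces_to_cross_product_or(self):
        t = pt.StratifiedAlleleTables(np.array([[[12, 8], [5, 15]]]), ["all"])
        assert pt.cmh_test(t).or_observed == pytest.approx(12 * 15 / (8 * 5))

    def test_identical_strata_pool_to_same_or_with_smaller_se(self):
        one = pt.StratifiedAlleleTables(np.array([[[12, 8], [5, 15]]]), ["a"])
        two = pt.StratifiedAlleleTables(
            np.array([[[12, 8], [5, 15]], [[12, 8], [5, 15]]]), ["a", "b"]
        )
        r1, r2 = pt.cmh_test(one), pt.cmh_test(two)
        # hand-computed Mantel-Haenszel oracle: sum(ad/n)/sum(bc/n)
        oracle = (12 * 15 / 40) / (8 * 5 / 40)
        assert r1.or_observed == pytest.approx(oracle)
        assert r2.or_observed == pytest.approx(oracle)
        assert r2.se_log_obs < r1.se_log_obs

    def test_zero_cell_haldane_correction(self):
        t = pt.StratifiedAlleleTables(np.array([[[10, 0], [5, 5]]]), ["all"])
        res = pt.cmh_test(t)
        assert np.isfinite(res.or_observed) and res.or_observed > 0
        assert "haldane" in res.note

    def test_agrees_with_logistic_on_unstratified_cohort(self, rng):
        # one stratum, moderate effect: allele-level CMH ~ per-allele logistic
        n = 1500
        d = rng.binomial(2, 0.4, n).astype(float)
        logit = -0.2 + 0.3 * d
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        groups = np.where(y == 1, "tall", "short")
        cmh = pt.cmh_test(pt.allele_tables(d, groups))
        logi = pt.logistic_assoc(d, y)
        assert np.log(cmh.or_observed) == pytest.approx(
            np.log(logi.or_observed), abs=0.05 * abs(np.log(logi.or_observed)) + 0.02
        )


class TestLogistic:
    def test_independent_dosage_gives_null_or(self, rng):
        d = rng.binomial(2, 0.5, 4000)
        y = rng.integers(0, 2, 4000)
        res = pt.logistic_assoc(d, y)
        assert res.or_observed == pytest.approx(1.0, abs=0.1)
        assert res.p_value > 0.001

    def test_tail_simulation_matches_expected_or(self, rng):
        # single-SNP cohorts ascertained at +/-2.326: mean log OR over
        # replicates should approach the truncated-normal expectation
        beta, p, c = 0.1, 0.3, 2.326
        expected = pt.expected_odds_ratio(beta, 0.0, p, pt.TailDesign()).or_expected
        sigma = np.sqrt(1 - 2 * p * (1 - p) * beta**2)
        logs = []
        for _ in range(40):
            d = rng.binomial(2, p, 100_000)
            z = beta * (d - 2 * p) + sigma * rng.standard_normal(100_000)
            keep = np.abs(z) > c
            res = pt.logistic_assoc(d[keep], (z[keep] > 0).astype(int))
            logs.append(np.log(res.or_observed))
        se_mean = np.std(logs, ddof=1) / np.sqrt(len(logs))
        assert np.mean(logs) == pytest.approx(np.log(expected), abs=4 * se_mean)

    def test_complete_separation_flagged(self):
        d = np.array([0, 0, 0, 2, 2, 2], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="separation"):
            pt.logistic_assoc(d, y)

    def test_single_status_rejected(self):
        with pytest.raises(ValueError):
            pt.logistic_assoc([0.0, 1.0, 2.0], [1, 1, 1])


class TestMeta:
    def test_single_study_identity(self):
        r = pt.AssocResult(1.4, 0.2, 0.09, 1)
        pooled = pt.inverse_variance_meta([r])
        assert pooled.or_observed == pytest.approx(1.4)
        assert pooled.se_log_obs == pytest.approx(0.2)

    def test_two_equal_studies_halve_variance(self):
        r = pt.AssocResult(1.4, 0.2, 0.09, 1)
        pooled = pt.inverse_variance_meta([r, r])
        assert pooled.or_observed == pytest.approx(1.4)
        assert pooled.se_log_obs == pytest.approx(0.2 / np.sqrt(2))

    def test_three_unequal_studies_weighted_mean_oracle(self):
        lors, ses = [0.1, 0.3, -0.05], [0.1, 0.25, 0.15]
        w = [1 / s**2 for s in ses]
        oracle = sum(wi * li for wi, li in zip(w, lors)) / sum(w)
        results = [pt.AssocResult(np.exp(l), s, 0.5, 1) for l, s in zip(lors, ses)]
        pooled = pt.inverse_variance_meta(results)
        assert np.log(pooled.or_observed) == pytest.approx(oracle)
        assert pooled.se_log_obs == pytest.approx(1 / np.sqrt(sum(w)))

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            pt.inverse_variance_meta([pt.AssocResult(1.1, 0.0, 0.5, 1)])


class TestAggregateTests:
    def test_published_direction_count_is_significant(self):
        # 137 of 160 matching directions
        k, n, p = pt.direction_consistency_test([1] * 137 + [-1] * 23, [1] * 160)
        assert (k, n) == (137, 160)
        assert p < 0.0001

    def test_coin_flip_count_not_significant(self):
        k, n, p = pt.direction_consistency_test([1] * 50 + [-1] * 50, [1] * 100)
        assert 0.4 < p < 0.6

    def test_perfect_agreement_closed_form(self):
        _, _, p = pt.direction_consistency_test([1] * 10, [1] * 10)
        assert p == pytest.approx(0.5**10)

    def test_null_panel_direction_calibration(self, rng):
        # under sign-coin-flip null the test rejects at ~nominal rate
        rejections = 0
        for _ in range(400):
            obs = rng.choice([-1, 1], 60)
            exp = rng.choice([-1, 1], 60)
            _, _, p = pt.direction_consistency_test(obs, exp)
            rejections += p < 0.05
        assert 0.015 <= rejections / 400 <= 0.09

    def test_enrichment_at_published_counts(self):
        pvals = np.concatenate([np.full(49, 0.01), np.full(92, 0.5)])
        obs, exp, p = pt.nominal_enrichment_test(pvals, 0.05)
        assert obs == 49
        assert exp == pytest.approx(7.05)
        assert p < 5e-28

    def test_expected_count_not_enriched(self):
        pvals = np.concatenate([np.full(7, 0.01), np.full(134, 0.5)])
        _, _, p = pt.nominal_enrichment_test(pvals, 0.05)
        assert p > 0.3

    def test_no_significant_hits_gives_unit_tail(self):
        _, _, p = pt.nominal_enrichment_test(np.full(20, 0.9), 0.05)
        assert p == pytest.approx(1.0)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            pt.nominal_enrichment_test([])
        with pytest.raises(ValueError):
            pt.direction_consistency_test([], [])
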
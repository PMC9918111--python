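"""Two-sample MR: harmonization, estimators, sensitivity analyses."""

import numpy as np
import pandas as pd
import pytest

import phewas_mr as pm
from phewas_mr import mr
from tests.conftest import make_instruments


def stats_table(rows):
    return pd.DataFrame(
        rows,
        columns=["variant_id", "ea", "oa", "eaf", "beta", "se", "p", "n"],
    )


class TestHarmonize:
    def test_swapped_alleles_flip_sign_and_eaf(self):
        exp = stats_table([("v1", "A", "G", 0.3, 0.05, 0.01, 1e-7, 1000)])
        out = stats_table([("v1", "G", "A", 0.7, -0.02, 0.01, 0.05, 1000)])
        inst = pm.harmonize(exp, out)
        assert len(inst) == 1
        assert inst.data["beta_out"][0] == pytest.approx(0.02)
        assert inst.data["eaf_out"][0] == pytest.approx(0.3)

    def test_double_flip_is_identity(self):
        exp = stats_table([("v1", "A", "G", 0.3, 0.05, 0.01, 1e-7, 1000)])
        out = stats_table([("v1", "A", "G", 0.3, 0.02, 0.01, 0.05, 1000)])
        direct = pm.harmonize(exp, out)
        swapped = out.assign(ea="G", oa="A", beta=-0.02, eaf=0.7)
        via_swap = pm.harmonize(exp, swapped)
        pd.testing.assert_frame_equal(direct.data, via_swap.data)

    def test_harmonize_idempotent(self):
        exp = stats_table([
            ("v1", "A", "G", 0.3, 0.05, 0.01, 1e-7, 1000),
            ("v2", "C", "T", 0.2, -0.04, 0.01, 1e-6, 1000),
        ])
        out = stats_table([
            ("v1", "G", "A", 0.7, -0.02, 0.01, 0.05, 2000),
            ("v2", "C", "T", 0.2, 0.01, 0.01, 0.3, 2000),
        ])
        once = pm.harmonize(exp, out)
        aligned = once.data.rename(columns={
            "beta_out": "beta", "se_out": "se", "eaf_out": "eaf", "n_out": "n"})
        aligned = aligned[["variant_id", "ea", "oa", "eaf", "beta", "se", "n"]]
        aligned["p"] = 0.5
        twice = pm.harmonize(exp, aligned)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_palindromic_intermediate_eaf_excluded(self):
        exp = stats_table([("v1", "A", "T", 0.50, 0.05, 0.01, 1e-7, 1000)])
        out = stats_table([("v1", "A", "T", 0.50, 0.02, 0.01, 0.05, 1000)])
        inst = pm.harmonize(exp, out)
        assert len(inst) == 0
        assert "intermediate" in inst.exclusions["reason"][0]
        # band is inclusive at the edges
        for eaf in (0.42, 0.58):
            e = stats_table([("v1", "A", "T", eaf, 0.05, 0.01, 1e-7, 1000)])
            assert len(pm.harmonize(e, out)) == 0

    def test_palindromic_outside_band_aligned_by_frequency(self):
        exp = stats_table([("v1", "C", "G", 0.30, 0.05, 0.01, 1e-7, 1000)])
        same = stats_table([("v1", "C", "G", 0.31, 0.02, 0.01, 0.05, 1000)])
        inst = pm.harmonize(exp, same)
        assert len(inst) == 1
        assert inst.data["beta_out"][0] == pytest.approx(0.02)
        flipped = stats_table([("v1", "C", "G", 0.69, 0.02, 0.01, 0.05, 1000)])
        inst2 = pm.harmonize(exp, flipped)
        assert inst2.data["beta_out"][0] == pytest.approx(-0.02)

    def test_strand_flip_tolerated(self):
        exp = stats_table([("v1", "A", "G", 0.3, 0.05, 0.01, 1e-7, 1000)])
        out = stats_table([("v1", "T", "C", 0.3, 0.02, 0.01, 0.05, 1000)])
        inst = pm.harmonize(exp, out)
        assert inst.data["beta_out"][0] == pytest.approx(0.02)

    def test_incompatible_alleles_dropped(self):
        exp = stats_table([("v1", "A", "G", 0.3, 0.05, 0.01, 1e-7, 1000)])
        out = stats_table([("v1", "A", "C", 0.3, 0.02, 0.01, 0.05, 1000)])
        inst = pm.harmonize(exp, out)
        assert len(inst) == 0
        assert inst.exclusions["reason"][0] == "incompatible alleles"

    def test_strict_mode_drops_any_intermediate(self):
        exp = stats_table([("v1", "A", "G", 0.5, 0.05, 0.01, 1e-7, 1000)])
        out = stats_table([("v1", "A", "G", 0.5, 0.02, 0.01, 0.05, 1000)])
        assert len(pm.harmonize(exp, out)) == 1
        assert len(pm.harmonize(exp, out, strict_eaf_exclusion=True)) == 0


class TestWaldRatio:
    def test_arithmetic(self):
        est = pm.wald_ratio(0.25, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.08)

    def test_antisymmetry(self):
        a = pm.wald_ratio(0.25, 0.01, 0.05, 0.02)
        b = pm.wald_ratio(-0.25, 0.01, 0.05, 0.02)
        assert b.beta == pytest.approx(-a.beta)
        assert b.se == pytest.approx(a.se)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            pm.wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIVW:
    def test_single_instrument_degenerates_to_wald(self):
        rng = np.random.default_rng(0)
        inst = make_instruments(rng, m=1)
        d = inst.data.iloc[0]
        w = pm.wald_ratio(d["beta_exp"], d["se_exp"], d["beta_out"], d["se_out"])
        est = pm.ivw(inst)
        assert est.beta == pytest.approx(w.beta, rel=1e-12)
        assert est.se == pytest.approx(w.se, rel=1e-12)

    def test_equal_weights_average(self):
        data = pd.DataFrame({
            "variant_id": ["a", "b"], "ea": "A", "oa": "G",
            "beta_exp": [0.1, 0.1], "se_exp": 0.01,
            "beta_out": [0.01, 0.03], "se_out": [0.005, 0.005],
            "eaf_exp": 0.3, "eaf_out": 0.3, "palindromic": False,
            "f_stat": 100.0, "n_exp": 1000, "n_out": 1000,
        })
        est = pm.ivw(pm.InstrumentSet(data))
        assert est.beta == pytest.approx(0.2)

    def test_matches_weighted_least_squares_oracle(self):
        """IVW equals a through-origin WLS of outcome on exposure effects."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        for _ in range(5):
            inst = make_instruments(rng, m=25)
            est = pm.ivw(inst, "fixed")
            w = 1.0 / inst.data["se_out"] ** 2
            wls = sm.WLS(inst.data["beta_out"], inst.data["beta_exp"], weights=w).fit()
            assert est.beta == pytest.approx(float(wls.params.iloc[0]), abs=1e-10)

    def test_mre_inflates_se_under_heterogeneity(self):
        rng = np.random.default_rng(2)
        pleio = rng.normal(0, 0.05, size=30)
        inst = make_instruments(rng, m=30, pleiotropy=pleio)
        fe = pm.ivw(inst, "fixed")
        mre = pm.ivw(inst, "multiplicative_random")
        assert mre.se > fe.se
        assert mre.beta == pytest.approx(fe.beta)
        # homogeneous instruments: the two coincide
        inst0 = make_instruments(rng, m=30, se_exp=1e-6, se_out=0.01)
        # force near-zero spread
        inst0.data["beta_out"] = 0.1 * inst0.data["beta_exp"]
        fe0 = pm.ivw(inst0, "fixed")
        mre0 = pm.ivw(inst0, "multiplicative_random")
        assert mre0.se == pytest.approx(fe0.se)


class TestEgger:
    def test_perfect_line_recovered_exactly(self):
        data = pd.DataFrame({
            "variant_id": ["a", "b", "c"], "ea": "A", "oa": "G",
            "beta_exp": [0.1, 0.2, 0.3], "se_exp": 0.01,
            "beta_out": [0.01 + 0.2 * g for g in (0.1, 0.2, 0.3)],
            "se_out": 0.005, "eaf_exp": 0.3, "eaf_out": 0.3,
            "palindromic": False, "f_stat": 100.0, "n_exp": 1000, "n_out": 1000,
        })
        est = pm.egger(pm.InstrumentSet(data))
        assert est.beta == pytest.approx(0.2, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.01, abs=1e-10)

    def test_matches_statsmodels_wls_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        inst = make_instruments(rng, m=40, pleiotropy=rng.normal(0.01, 0.02, 40))
        est = pm.egger(inst)
        sign = np.sign(inst.data["beta_exp"])
        x = (inst.data["beta_exp"] * sign).to_numpy()
        y = (inst.data["beta_out"] * sign).to_numpy()
        w = 1.0 / inst.data["se_out"].to_numpy() ** 2
        wls = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        assert est.beta == pytest.approx(float(wls.params[1]), abs=1e-10)
        assert est.egger_intercept == pytest.approx(float(wls.params[0]), abs=1e-10)
        scale_ratio = max(float(wls.scale), 1.0) / float(wls.scale)
        assert est.se == pytest.approx(float(wls.bse[1]) * np.sqrt(scale_ratio), rel=1e-9)

    def test_directional_pleiotropy_intercept_recovered(self):
        rng = np.random.default_rng(4)
        errs = []
        for _ in range(60):
            inst = make_instruments(rng, m=60, pleiotropy=np.full(60, 0.02),
                                    positive_gamma=True)
            est = pm.egger(inst)
            errs.append(est.egger_intercept - 0.02)
        assert abs(np.mean(errs)) < 0.005

    def test_intercept_type_one_error_calibrated(self):
        rng = np.random.default_rng(5)
        rej, n_rep = 0, 400
        for _ in range(n_rep):
            inst = make_instruments(rng, m=30, positive_gamma=True)
            est = pm.egger(inst)
            rej += est.egger_intercept_p < 0.05
        assert 0.02 <= rej / n_rep <= 0.09

    def test_too_few_instruments(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="insufficient"):
            pm.egger(make_instruments(rng, m=2))


class TestWeightedMedianAndMode:
    def test_equal_weight_median(self):
        data = pd.DataFrame({
            "variant_id": ["a", "b", "c"], "ea": "A", "oa": "G",
            "beta_exp": [0.1, 0.1, 0.1], "se_exp": 0.001,
            "beta_out": [0.01, 0.02, 0.03], "se_out": 0.005,
            "eaf_exp": 0.3, "eaf_out": 0.3, "palindromic": False,
            "f_stat": 100.0, "n_exp": 1000, "n_out": 1000,
        })
        est = pm.weighted_median(pm.InstrumentSet(data), n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.2, abs=1e-9)

    def test_median_more_robust_than_ivw_with_invalid_minority(self):
        """30% of instruments carry large positive pleiotropy."""
        rng = np.random.default_rng(7)
        med_err, ivw_err = [], []
        for _ in range(100):
            m = 30
            pleio = np.zeros(m)
            pleio[: int(0.3 * m)] = 0.08
            inst = make_instruments(rng, m=m, true_beta=0.1, pleiotropy=pleio)
            med_err.append(pm.weighted_median(inst, n_boot=100, seed=1).beta - 0.1)
            ivw_err.append(pm.ivw(inst).beta - 0.1)
        assert abs(np.mean(med_err)) < abs(np.mean(ivw_err))

    def test_median_needs_three(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            pm.weighted_median(make_instruments(rng, m=1))

    def test_mode_point_mass(self):
        data = pd.DataFrame({
            "variant_id": ["a", "b", "c"], "ea": "A", "oa": "G",
            "beta_exp": [0.1, 0.2, 0.4], "se_exp": 0.01,
            "beta_out": [0.015, 0.03, 0.06], "se_out": 0.005,
            "eaf_exp": 0.3, "eaf_out": 0.3, "palindromic": False,
            "f_stat": 100.0, "n_exp": 1000, "n_out": 1000,
        })
        est = pm.weighted_mode(pm.InstrumentSet(data), n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.15, abs=1e-6)

    def test_mode_follows_majority_cluster(self):
        rng = np.random.default_rng(9)
        in_cluster = 0
        for _ in range(40):
            m = 30
            pleio = np.zeros(m)
            # 40% invalid instruments pushed toward ratio 0.5
            idx = rng.choice(m, size=int(0.4 * m), replace=False)
            pleio[idx] = 0.4 * 0.06  # ~ (0.5-0.1) x typical gamma
            inst = make_instruments(rng, m=m, true_beta=0.1, pleiotropy=pleio)
            est = pm.weighted_mode(inst, n_boot=50, seed=2)
            in_cluster += abs(est.beta - 0.1) < abs(est.beta - 0.5)
        assert in_cluster >= 32

    def test_mode_large_bandwidth_approaches_weighted_mean(self):
        rng = np.random.default_rng(10)
        inst = make_instruments(rng, m=40)
        b = inst.ratios
        w = 1.0 / inst.ratio_se**2
        wmean = float(np.sum(w * b) / np.sum(w))  # direct weighted-mean oracle
        est = pm.weighted_mode(inst, bandwidth_factor=200.0, n_boot=50, seed=0)
        spread = b.max() - b.min()
        assert abs(est.beta - wmean) < 0.1 * spread


class TestCochranQ:
    def test_identical_ratios_zero(self):
        data = pd.DataFrame({
            "variant_id": ["a", "b"], "ea": "A", "oa": "G",
            "beta_exp": [0.1, 0.2], "se_exp": 0.01,
            "beta_out": [0.02, 0.04], "se_out": 0.005,
            "eaf_exp": 0.3, "eaf_out": 0.3, "palindromic": False,
            "f_stat": 100.0, "n_exp": 1000, "n_out": 1000,
        })
        inst = pm.InstrumentSet(data)
        q, df, p = pm.cochran_q(inst, 0.2)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_mean_q_matches_chi_square_expectation(self):
        rng = np.random.default_rng(11)
        qs = []
        for _ in range(500):
            inst = make_instruments(rng, m=10, se_exp=1e-9)
            q, df, _ = pm.cochran_q(inst, pm.ivw(inst).beta)
            qs.append(q / df)
        assert np.mean(qs) == pytest.approx(1.0, abs=0.08)

    def test_term_by_term_oracle(self):
        rng = np.random.default_rng(12)
        inst = make_instruments(rng, m=15)
        beta_ref = 0.123
        q, df, _ = pm.cochran_q(inst, beta_ref)
        manual = 0.0
        for j in range(15):
            bj = inst.data["beta_out"][j] / inst.data["beta_exp"][j]
            sej = inst.data["se_out"][j] / abs(inst.data["beta_exp"][j])
            manual += (bj - beta_ref) ** 2 / sej**2
        assert q == pytest.approx(manual, abs=1e-10)


class TestSteiger:
    def test_dominant_exposure_variance(self):
        rng = np.random.default_rng(13)
        inst = make_instruments(rng, m=20, true_beta=0.1,
                                se_out=0.02, n_exp=50_000, n_out=50_000)
        ok, p = pm.steiger(inst)
        assert ok

    def test_role_swap_antisymmetry(self):
        rng = np.random.default_rng(14)
        inst = make_instruments(rng, m=20, true_beta=0.1, se_out=0.02)
        swapped = pm.InstrumentSet(inst.data.rename(columns={
            "beta_exp": "beta_out", "beta_out": "beta_exp",
            "se_exp": "se_out", "se_out": "se_exp",
            "n_exp": "n_out", "n_out": "n_exp",
        }))
        ok, _ = pm.steiger(inst)
        ok_swapped, _ = pm.steiger(swapped)
        assert ok and not ok_swapped

    def test_missing_n_rejected(self):
        rng = np.random.default_rng(15)
        inst = make_instruments(rng, m=5)
        inst.data["n_out"] = -1
        with pytest.raises(ValueError):
            pm.steiger(inst)


class TestLeaveOneOut:
    def test_row_count_and_homogeneous_stability(self):
        rng = np.random.default_rng(16)
        inst = make_instruments(rng, m=20)
        full = pm.ivw_auto(inst)
        loo = pm.leave_one_out(inst)
        assert len(loo) == 20
        assert ((loo["beta"] >= full.ci_low) & (loo["beta"] <= full.ci_high)).all()
        assert not loo["sign_conflict"].any()

    def test_planted_outlier_has_largest_influence(self):
        rng = np.random.default_rng(17)
        pleio = np.zeros(20)
        pleio[7] = 0.15
        inst = make_instruments(rng, m=20, pleiotropy=pleio)
        loo = pm.leave_one_out(inst)
        full = loo.attrs["full_beta"]
        shifts = (loo["beta"] - full).abs()
        assert loo.loc[shifts.idxmax(), "left_out"] == "iv007"


class TestPruning:
    def test_default_threshold_is_phenome_bonferroni(self):
        import inspect

        sig = inspect.signature(pm.prune_pleiotropic)
        assert sig.parameters["p_threshold"].default == pytest.approx(0.05 / 665)

    def test_no_secondary_hits_identity(self):
        rng = np.random.default_rng(18)
        inst = make_instruments(rng, m=10)
        sec = pd.DataFrame({"variant_id": inst.data["variant_id"], "p": 0.5})
        kept, log = pm.prune_pleiotropic(inst, sec)
        assert len(kept) == 10 and len(log) == 0

    def test_planted_pleiotropic_variants_removed(self):
        rng = np.random.default_rng(19)
        inst = make_instruments(rng, m=10)
        p = np.full(10, 0.3)
        p[[1, 4, 8]] = 1e-8
        sec = pd.DataFrame({"variant_id": inst.data["variant_id"], "p": p})
        kept, log = pm.prune_pleiotropic(inst, sec)
        assert sorted(log["variant_id"]) == ["iv001", "iv004", "iv008"]
        assert len(kept) == 7


class TestSelectInstruments:
    def test_f_statistic_example(self):
        # gamma=0.05, se=0.01 -> F = 25, inside the expected strength band
        f = (0.05 / 0.01) ** 2
        assert f == pytest.approx(25.0)
        rng = np.random.default_rng(20)
        inst = make_instruments(rng, m=30)
        z2 = (inst.data["beta_exp"] / inst.data["se_exp"]) ** 2
        np.testing.assert_allclose(inst.data["f_stat"], z2, atol=1e-12)

    def test_empty_selection_is_error(self, small_cohort):
        stats = pm.gwas_scan(small_cohort.dosages.iloc[:, :10],
                             small_cohort.variants,
                             small_cohort.phenotypes["exposure"])
        from phewas_mr.prs import InSampleLD

        ld = InSampleLD(small_cohort.dosages)
        with pytest.raises(ValueError, match="no instruments"):
            pm.select_instruments(stats, ld, p_threshold=1e-300)


class TestScalingAndEquivariance:
    def test_per_doubling_transform(self):
        est = pm.MREstimate("ivw_fe", beta=0.0, se=0.1, p=1.0, n_instruments=5)
        assert est.or_per_doubling == pytest.approx(1.0)
        est2 = pm.MREstimate("ivw_fe", beta=1.0, se=0.1, p=0.5, n_instruments=5)
        assert est2.or_per_doubling == pytest.approx(np.exp(0.693))
        assert est2.or_ci_low < est2.or_per_doubling < est2.or_ci_high

    def test_sign_equivariance_of_all_estimators(self):
        rng = np.random.default_rng(21)
        inst = make_instruments(rng, m=25)
        neg = pm.InstrumentSet(inst.data.assign(beta_out=-inst.data["beta_out"]))
        for f in (pm.ivw, pm.egger):
            a, b = f(inst), f(neg)
            assert b.beta == pytest.approx(-a.beta, rel=1e-9)
            assert b.p == pytest.approx(a.p, rel=1e-9)
        # bootstrap-based SE is only mirror-symmetric up to resampling noise
        a = pm.weighted_median(inst, n_boot=400, seed=3)
        b = pm.weighted_median(neg, n_boot=400, seed=3)
        assert b.beta == pytest.approx(-a.beta, rel=1e-9)
        assert b.p == pytest.approx(a.p, rel=0.3)


def test_mr_suite_rows_by_instrument_count():
    rng = np.random.default_rng(22)
    assert pm.mr_suite(make_instruments(rng, m=1), 50, 0)["method"].tolist() == ["wald"]
    suite = pm.mr_suite(make_instruments(rng, m=10), 50, 0)
    assert suite["method"].tolist() == [
        "ivw_fe", "ivw_mre", "egger", "weighted_median", "weighted_mode"]
    # every row satisfies the per-doubling identity
    np.testing.assert_allclose(
        suite["or_per_doubling"], np.exp(0.693 * suite["beta"]), rtol=1e-12)
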
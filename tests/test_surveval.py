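import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metagrs import (
    ScoreSet, StrataSpec, aalen_johansen, age_at_risk_level,
    association_scan, attenuation, c_increment, cross_classify, fit_cox,
    harrells_c, interaction_test, stratified_hr,
)
from metagrs.surveval import CIFCurve, _aj, _concordance_fast, \
    _concordance_naive

from helpers import make_survival_frame


def _exp_cohort(rng, n, beta=0.0, rate=0.1, censor=None, covariate=None):
    x = covariate if covariate is not None else rng.standard_normal(n)
    t = rng.exponential(1.0 / (rate * np.exp(beta * x)))
    if censor is None:
        event = np.ones(n, int)
    else:
        event = (t <= censor).astype(int)
        t = np.minimum(t, censor)
    df = make_survival_frame(t, event)
    df["x"] = x
    return df


class TestFitCox:
    def test_binary_group_matches_closed_form_rate_ratio(self):
        # exponential onset, no censoring: the Cox log HR must agree with the
        # analytic MLE of the log rate ratio, log((d1/T1)/(d0/T0))
        rng = np.random.default_rng(1)
        n = 10_000
        g = (np.arange(n) % 2).astype(float)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.7 * g)))
        df = make_survival_frame(t, np.ones(n, int))
        df["g"] = g
        fit = fit_cox(df, ["g"], timescale="followup")
        d1, t1 = g.sum(), t[g == 1].sum()
        d0, t0 = (1 - g).sum(), t[g == 0].sum()
        oracle = np.log((d1 / t1) / (d0 / t0))
        assert abs(fit.table.loc["g", "coef"] - oracle) \
            < 3 * fit.table.loc["g", "se"]
        assert fit.n_events == n

    def test_null_wald_p_uniform(self):
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(200):
            df = _exp_cohort(rng, 300, beta=0.0, censor=15.0)
            fit = fit_cox(df, ["x"], timescale="followup")
            pvals.append(fit.table.loc["x", "pvalue"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_matches_statsmodels_phreg_reference(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        df = _exp_cohort(rng, 2000, beta=0.5, censor=12.0)
        fit = fit_cox(df, ["x"], timescale="followup")
        ref = sm.PHReg(df["event_age"], df[["x"]],
                       status=df["bc_event"], ties="efron").fit()
        assert abs(fit.table.loc["x", "coef"] - ref.params[0]) < 1e-6

    def test_left_truncation_changes_risk_sets(self):
        # age timescale with delayed entry recovers the effect; ignoring
        # entry (followup from 0) would use the wrong risk sets
        rng = np.random.default_rng(4)
        n = 8000
        x = rng.standard_normal(n)
        u = rng.uniform(size=n)
        t = 80.0 * (-np.log(u) * np.exp(-0.5 * x) / 3.0) ** (1 / 4.0)
        entry = rng.uniform(30, 70, size=n)
        keep = t > entry
        df = make_survival_frame(t[keep], np.ones(keep.sum(), int),
                                 entry=entry[keep])
        df["x"] = x[keep]
        fit = fit_cox(df, ["x"], timescale="age")
        assert fit.table.loc["x", "ci_low"] < np.exp(0.5) \
            < fit.table.loc["x", "ci_high"]

    def test_prevalent_rows_rejected(self):
        df = make_survival_frame([5.0, 6.0], [1, 0])
        df["prevalent"] = [1, 0]
        df["x"] = [0.1, 0.2]
        with pytest.raises(ValueError, match="prevalent"):
            fit_cox(df, ["x"], timescale="followup")

    def test_no_events_and_nonfinite_covariates_rejected(self):
        df = make_survival_frame([5.0, 6.0], [0, 0])
        df["x"] = [0.1, 0.2]
        with pytest.raises(ValueError, match="no events"):
            fit_cox(df, ["x"], timescale="followup")
        df2 = make_survival_frame([5.0, 6.0], [1, 0])
        df2["x"] = [np.nan, 0.2]
        with pytest.raises(ValueError, match="x"):
            fit_cox(df2, ["x"], timescale="followup")

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        df = _exp_cohort(rng, 500, beta=0.4, censor=20.0)
        fit1 = fit_cox(df, ["x"], timescale="followup")
        perm = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = fit_cox(perm, ["x"], timescale="followup")
        assert fit1.table.loc["x", "coef"] == pytest.approx(
            fit2.table.loc["x", "coef"], rel=1e-10)


class TestHarrellsC:
    def test_perfect_ranking_gives_one(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(1.0, size=200)
        df = make_survival_frame(t, np.ones(200, int))
        df["risk"] = -t
        assert harrells_c(df, "risk") == 1.0

    def test_independent_risk_is_half(self):
        rng = np.random.default_rng(7)
        df = _exp_cohort(rng, 10_000, beta=0.0, censor=20.0)
        assert harrells_c(df, "x") == pytest.approx(0.5, abs=0.02)

    def test_five_subject_toy_matches_pair_enumeration(self):
        # times 2,3,3,5,7 with one censored record; risks include a tie
        time = np.array([2.0, 3.0, 3.0, 5.0, 7.0])
        event = np.array([1, 1, 0, 1, 0])
        risk = np.array([5.0, 4.0, 4.0, 1.0, 2.0])
        entry = np.zeros(5)
        conc_n, comp_n = _concordance_naive(entry, time, event, risk)
        conc_f, comp_f = _concordance_fast(entry, time, event, risk)
        assert (conc_f, comp_f) == (conc_n, comp_n)
        df = make_survival_frame(time, event)
        df["risk"] = risk
        assert harrells_c(df, "risk") == conc_n / comp_n

    def test_fast_equals_naive_on_random_instances(self):
        # ties in both time and risk, censoring, and delayed entry
        rng = np.random.default_rng(8)
        for rep in range(200):
            n = int(rng.integers(3, 101))
            time = rng.integers(1, 12, size=n).astype(float)
            event = rng.integers(0, 2, size=n)
            risk = rng.integers(0, 6, size=n).astype(float)
            if rng.uniform() < 0.5:
                entry = np.zeros(n)
            else:
                entry = np.maximum(time - rng.integers(1, 10, size=n), 0.0)
                entry = np.minimum(entry, time - 0.5)
            conc_n, comp_n = _concordance_naive(entry, time, event, risk)
            conc_f, comp_f = _concordance_fast(entry, time, event, risk)
            assert (conc_f, comp_f) == (conc_n, comp_n), f"instance {rep}"

    def test_no_comparable_pairs_is_an_error(self):
        df = make_survival_frame([4.0, 5.0], [0, 0])
        df["risk"] = [1.0, 2.0]
        with pytest.raises(ValueError, match="comparable"):
            harrells_c(df, "risk")


class TestCIncrement:
    def test_copy_of_base_adds_nothing(self):
        rng = np.random.default_rng(9)
        df = _exp_cohort(rng, 2000, beta=0.5, censor=15.0)
        df["copy"] = df["x"]
        c_base, c_joint, delta = c_increment(df, "x", "copy")
        assert delta == 0.0 and c_joint == c_base

    def test_independent_noise_adds_nothing(self):
        rng = np.random.default_rng(10)
        df = _exp_cohort(rng, 50_000, beta=0.5, censor=15.0)
        df["noise"] = rng.standard_normal(len(df))
        _, _, delta = c_increment(df, "x", "noise")
        assert abs(delta) < 0.005

    def test_informative_score_adds_discrimination(self):
        # clinical covariate + independent genetic score, both with real
        # effects; delta must be positive and replicate across simulations
        deltas = []
        for seed in (11, 12):
            rng = np.random.default_rng(seed)
            n = 20_000
            clin = rng.standard_normal(n)
            gen = rng.standard_normal(n)
            t = rng.exponential(1.0 / (0.05 * np.exp(0.4 * clin + 0.4 * gen)))
            event = (t <= 10.0).astype(int)
            df = make_survival_frame(np.minimum(t, 10.0), event)
            df["clin"], df["gen"] = clin, gen
            deltas.append(c_increment(df, "clin", "gen")[2])
        assert all(d > 0.02 for d in deltas)
        assert abs(deltas[0] - deltas[1]) < 0.01


class TestAalenJohansen:
    def test_reduces_to_one_minus_km_without_competing_events(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(13)
        t = rng.exponential(10.0, size=500)
        event = (t <= 12.0).astype(int)
        t = np.minimum(t, 12.0)
        df = make_survival_frame(t, event)
        curves = aalen_johansen(df)
        c = curves["all"]
        km = KaplanMeierFitter().fit(t, event)
        km_at = km.survival_function_at_times(c.times).to_numpy()
        np.testing.assert_allclose(c.cif, 1.0 - km_at, atol=1e-12)

    def test_matches_lifelines_aj_with_competing_risks(self):
        from lifelines import AalenJohansenFitter

        rng = np.random.default_rng(14)
        n = 400
        t1 = rng.exponential(8.0, size=n)
        t2 = rng.exponential(20.0, size=n)
        t = np.minimum(np.minimum(t1, t2), 15.0)
        cause = np.where(t1 <= np.minimum(t2, 15.0), 1,
                         np.where(t2 <= 15.0, 2, 0))
        curve = _aj(np.zeros(n), t, cause)
        ajf = AalenJohansenFitter(calculate_variance=False)
        ajf.fit(t, cause, event_of_interest=1)
        ref = ajf.cumulative_density_.iloc[:, 0]
        at = np.interp(curve.times, ref.index.to_numpy(),
                       ref.to_numpy())
        np.testing.assert_allclose(curve.cif, at, atol=1e-10)

    def test_constant_hazard_closed_form(self):
        # lam1/(lam1+lam2) * (1 - exp(-(lam1+lam2) t))
        rng = np.random.default_rng(15)
        n = 100_000
        lam1, lam2 = 0.03, 0.01
        t1 = rng.exponential(1 / lam1, size=n)
        t2 = rng.exponential(1 / lam2, size=n)
        t = np.minimum(t1, t2)
        cause = np.where(t1 <= t2, 1, 2)
        curve = _aj(np.zeros(n), t, cause)
        for horizon in (10.0, 25.0, 50.0):
            expected = lam1 / (lam1 + lam2) * (
                1 - np.exp(-(lam1 + lam2) * horizon))
            assert curve.cif_at(horizon) == pytest.approx(expected, abs=0.005)

    def test_four_record_toy_hand_enumeration(self):
        # event at 2, competing death at 3, censored at 4, late event at 5
        time = np.array([2.0, 3.0, 4.0, 5.0])
        cause = np.array([1, 2, 0, 1])
        curve = _aj(np.zeros(4), time, cause)
        np.testing.assert_allclose(curve.times, [2.0, 3.0, 5.0])
        np.testing.assert_allclose(curve.cif, [0.25, 0.25, 0.75], atol=1e-15)
        np.testing.assert_allclose(curve.cif_competing, [0.0, 0.25, 0.25],
                                   atol=1e-15)
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.0],
                                   atol=1e-15)

    def test_conservation_and_row_order_invariance(self):
        rng = np.random.default_rng(16)
        n = 3000
        t1 = rng.exponential(30.0, size=n) + 20
        t2 = rng.exponential(60.0, size=n) + 20
        entry = rng.uniform(20, 60, size=n)
        t = np.minimum(np.minimum(t1, t2), entry + 12)
        keep = t > entry
        cause = np.where(t1 <= np.minimum(t2, entry + 12), 1,
                         np.where(t2 <= entry + 12, 2, 0))[keep]
        curve = _aj(entry[keep], t[keep], cause)
        np.testing.assert_allclose(
            curve.cif + curve.cif_competing + curve.survival,
            np.ones_like(curve.cif), atol=1e-10)
        perm = rng.permutation(keep.sum())
        curve2 = _aj(entry[keep][perm], t[keep][perm], cause[perm])
        np.testing.assert_allclose(curve.cif, curve2.cif, atol=1e-14)

    def test_empty_stratum_omitted_with_warning(self, caplog):
        rng = np.random.default_rng(17)
        df = _exp_cohort(rng, 100, censor=10.0)
        df["score"] = np.linspace(0, 1, 100)
        spec = StrataSpec({"lo": (0, 50), "hi": (50, 100)}, reference="lo")
        curves = aalen_johansen(df, "score", spec)
        assert set(curves) == {"lo", "hi"}


class TestStratifiedHR:
    def test_effect_free_score_gives_unit_hazard_ratios(self):
        rng = np.random.default_rng(18)
        df = _exp_cohort(rng, 20_000, beta=0.0, censor=20.0)
        spec = StrataSpec({"bottom50": (0, 50), "top5": (95, 100)},
                          reference="bottom50")
        fit = stratified_hr(df, "x", spec)
        assert fit.table.loc["top5", "ci_low"] < 1.0 \
            < fit.table.loc["top5", "ci_high"]

    def test_complementary_strata_symmetry(self):
        rng = np.random.default_rng(19)
        df = _exp_cohort(rng, 5000, beta=0.4, censor=20.0)
        ab = StrataSpec({"lo": (0, 50), "hi": (50, 100)}, reference="lo")
        ba = StrataSpec({"lo": (0, 50), "hi": (50, 100)}, reference="hi")
        hr_ab = stratified_hr(df, "x", ab).table.loc["hi", "hr"]
        hr_ba = stratified_hr(df, "x", ba).table.loc["lo", "hr"]
        assert hr_ab == pytest.approx(1.0 / hr_ba, rel=1e-6)

    def test_empty_reference_is_an_error(self):
        rng = np.random.default_rng(20)
        df = _exp_cohort(rng, 100, censor=10.0,
                         covariate=np.linspace(0.0, 1.0, 100))
        # a sliver between two adjacent order statistics holds no sample
        spec = StrataSpec({"none": (49.9, 50.1), "rest": (60, 100)},
                          reference="none")
        with pytest.raises(ValueError, match="reference"):
            stratified_hr(df, "x", spec)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            StrataSpec({"a": (0, 60), "b": (50, 100)}, reference="a")


class TestAgeAtRiskLevel:
    def test_step_semantics(self):
        curve = CIFCurve("s", np.array([50.0, 60.0]), np.array([0.03, 0.06]),
                         np.zeros(2), np.zeros(2), np.zeros(2), np.zeros(2))
        assert age_at_risk_level(curve, 0.05) == 60.0
        assert age_at_risk_level(curve, 0.03) == 50.0

    def test_unreachable_level_returns_none(self):
        curve = CIFCurve("s", np.array([50.0]), np.array([0.03]),
                         np.zeros(1), np.zeros(1), np.zeros(1), np.zeros(1))
        assert age_at_risk_level(curve, 0.5) is None
        with pytest.raises(ValueError):
            age_at_risk_level(curve, 1.5)


class TestAttenuation:
    def test_identical_fits_give_zero(self):
        assert attenuation(1.87, 1.87) == 0.0

    def test_ratio_scale_arithmetic(self):
        # 1.87 -> 1.82 and 1.87 -> 1.71 on the odds-ratio scale
        assert attenuation(1.87, 1.82) == pytest.approx(2.674, abs=0.01)
        assert attenuation(1.87, 1.71) == pytest.approx(8.556, abs=0.01)

    def test_log_scale_alternative(self):
        got = attenuation(1.87, 1.71, log_scale=True)
        expected = 100 * (np.log(1.87) - np.log(1.71)) / np.log(1.87)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_missing_exposure_is_an_error(self):
        rng = np.random.default_rng(21)
        df = _exp_cohort(rng, 500, beta=0.3, censor=15.0)
        fit = fit_cox(df, ["x"], timescale="followup")
        with pytest.raises(ValueError, match="missing"):
            attenuation(fit, fit, term="absent")


class TestInteraction:
    def test_binary_self_product_is_collinear(self):
        rng = np.random.default_rng(22)
        df = _exp_cohort(rng, 500, censor=15.0)
        df["b"] = (df["x"] > 0).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            interaction_test(df, "b", "b")

    def test_null_interaction_p_uniform(self):
        rng = np.random.default_rng(23)
        pvals = []
        for _ in range(100):
            n = 400
            x, mzz = rng.standard_normal(n), rng.standard_normal(n)
            t = rng.exponential(1.0 / (0.1 * np.exp(0.3 * x + 0.3 * mzz)))
            df = make_survival_frame(np.minimum(t, 15.0),
                                     (t <= 15.0).astype(int))
            df["x"], df["m"] = x, mzz
            pvals.append(interaction_test(df, "x", "m"))
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_detects_multiplicative_interaction(self):
        hits = 0
        for seed in range(6):
            rng = np.random.default_rng(300 + seed)
            n = 50_000
            x, mzz = rng.standard_normal(n), rng.standard_normal(n)
            t = rng.exponential(
                1.0 / (0.03 * np.exp(0.2 * x + 0.2 * mzz + 0.3 * x * mzz)))
            df = make_survival_frame(np.minimum(t, 8.0),
                                     (t <= 8.0).astype(int))
            df["x"], df["m"] = x, mzz
            hits += interaction_test(df, "x", "m") < 0.05
        assert hits == 6  # >= 90% of replicates


class TestCrossClassify:
    def _scoreset(self, cols):
        n = len(next(iter(cols.values())))
        ss = ScoreSet([f"s{i}" for i in range(n)])
        for k, v in cols.items():
            ss.add(k, v)
        return ss

    def test_identical_columns_agree_perfectly(self):
        rng = np.random.default_rng(24)
        x = rng.standard_normal(2000)
        ss = self._scoreset({"a": x, "b": x.copy(), "c": x.copy()})
        out = cross_classify(ss, ["a", "b", "c"], cut=95.0)
        assert out["exactly_1"] == 0 and out["exactly_2"] == 0
        assert out["exactly_3"] == out["per_score"]["a"]
        assert out["percent"]["exactly_3"] == pytest.approx(5.0, abs=0.1)

    def test_independent_columns_overlap_as_chance_predicts(self):
        rng = np.random.default_rng(25)
        n = 100_000
        ss = self._scoreset({k: rng.standard_normal(n) for k in "abc"})
        out = cross_classify(ss, ["a", "b", "c"], cut=95.0)
        assert abs(out["exactly_3"] - n * 0.05 ** 3) < 15

    def test_accounting_identity(self):
        rng = np.random.default_rng(26)
        n = 5000
        ss = self._scoreset({k: rng.standard_normal(n) for k in "abc"})
        out = cross_classify(ss, ["a", "b", "c"], cut=95.0)
        assert out["exactly_1"] + out["exactly_2"] + out["exactly_3"] \
            == n - out["exactly_0"]
        for c in "abc":
            assert out["per_score"][c] == int(np.ceil(0.05 * n))

    def test_requires_three_components(self):
        ss = self._scoreset({"a": np.arange(10.0), "b": np.arange(10.0)})
        with pytest.raises(ValueError, match="three"):
            cross_classify(ss, ["a", "b"])


class TestAssociationScan:
    def _setup(self, seed, slope=0.0, logit_slope=0.0):
        rng = np.random.default_rng(seed)
        n = 4000
        score = rng.standard_normal(n)
        df = make_survival_frame(rng.exponential(50, size=n) + 31,
                                 np.zeros(n, int),
                                 entry=rng.uniform(30, 70, size=n))
        df["event_age"] = np.maximum(df["event_age"],
                                     df["entry_age"] + 0.1)
        df["cont"] = 13.0 + slope * score + rng.standard_normal(n)
        from scipy.special import expit
        df["bin"] = (rng.uniform(size=n)
                     < expit(-1.0 + logit_slope * score)).astype(int)
        ss = ScoreSet(df["sample_id"].to_numpy())
        ss.add("grs", score)
        ss.standardize("grs")
        return ss, df

    def test_null_scan_is_quiet(self):
        ss, df = self._setup(27)
        out = association_scan(ss, df, [("cont", "continuous"),
                                        ("bin", "binary")])
        assert (out["pvalue"] > 0.001).all()
        assert np.abs(out["estimate"]).max() < 0.1

    def test_linear_slope_recovered(self):
        ss, df = self._setup(28, slope=0.1)
        out = association_scan(ss, df, [("cont", "continuous", True)])
        row = out.iloc[0]
        assert abs(row["estimate"] - 0.1) < 3 * row["se"]
        assert row["kind"] == "continuous"

    def test_logistic_branch_recovers_coefficient(self):
        ss, df = self._setup(29, logit_slope=0.3)
        out = association_scan(ss, df, [("bin", "binary")])
        row = out.iloc[0]
        assert abs(row["estimate"] - 0.3) < 3 * row["se"]

    def test_undeclared_type_is_an_error(self):
        ss, df = self._setup(30)
        with pytest.raises(ValueError, match="undeclared"):
            association_scan(ss, df, [("cont", "gaussian")])
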
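import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from femstrength.risk_bands import (
    RiskBandConfig, SubjectRecord, classify_postflight, classify_preflight,
    derive_pol, regress_r2, significant_change, summarize_cohort,
)


def percentile_oracle(values, q):
    """Independent sort-and-interpolate percentile (closest-ranks, linear)."""
    s = sorted(float(v) for v in values)
    pos = q / 100.0 * (len(s) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (s[hi] - s[lo]) * (pos - lo)


class TestDerivePol:
    def test_one_to_hundred_q75(self):
        assert derive_pol(list(range(1, 101)), 75) == pytest.approx(75.25)

    def test_constant_sample(self):
        assert derive_pol([7.0] * 10, 75) == 7.0

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            v = rng.normal(10000, 2500, size=rng.integers(4, 300))
            q = float(rng.uniform(1, 99))
            assert derive_pol(v, q) == pytest.approx(
                percentile_oracle(v, q), rel=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            derive_pol([1.0, 2.0, 3.0], 75)

    @given(a=st.floats(0.1, 100), b=st.floats(-1e4, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_affine_equivariance(self, a, b):
        rng = np.random.default_rng(5)
        v = rng.normal(9000, 2000, 50)
        assert derive_pol(a * v + b, 75) == pytest.approx(
            a * derive_pol(v, 75) + b, rel=1e-9, abs=1e-6)


class TestClassifyPreflight:
    def test_healthy_astronaut_certified(self):
        c = classify_preflight(0.97, 14279.0)
        assert c.preflight_decision == "certified"
        assert c.quadrant == "pass_both"

    def test_screen_band_passes_via_fe(self):
        c = classify_preflight(-1.2, 10000.0)
        assert c.preflight_decision == "certified"
        c2 = classify_preflight(-1.2, 9000.0)
        assert c2.preflight_decision == "not_certified"

    def test_below_floor_never_certified(self):
        assert classify_preflight(-1.6, 1e9).preflight_decision == (
            "not_certified")

    def test_boundaries_inclusive_at_cutpoints(self):
        assert classify_preflight(-1.0, None).preflight_decision == "certified"
        assert classify_preflight(-1.5, 1e9).preflight_decision == (
            "not_certified")
        assert classify_preflight(-1.2, 9537.0).preflight_decision == (
            "certified")

    def test_screen_band_without_fe_requests_fe(self):
        assert classify_preflight(-1.2, None).preflight_decision == (
            "screen_with_fe")

    @given(t=st.floats(-4, 4), f=st.floats(1000, 20000))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_both_inputs(self, t, f):
        order = {"not_certified": 0, "screen_with_fe": 1, "certified": 2}
        base = order[classify_preflight(t, f).preflight_decision]
        better_t = order[classify_preflight(t + 0.5, f).preflight_decision]
        better_f = order[classify_preflight(t, f + 2000).preflight_decision]
        assert better_t >= base and better_f >= base


class TestClassifyPostflight:
    def test_weak_fall_capacity_flagged(self):
        c = classify_postflight(0.5, 14000.0, 3488.0)
        assert "below_fe_pol_nlf" in c.postflight_flags
        assert "below_fe_pol_nls" not in c.postflight_flags

    def test_table_mean_postflight_clears_pols(self):
        c = classify_postflight(0.74, 13624.0, 3925.0)
        assert not {"below_t_pol", "below_fe_pol_nls",
                    "below_fe_pol_nlf"} & c.postflight_flags

    def test_no_change_no_loss_flags(self):
        pre = SubjectRecord(f_nls_pre=14000.0, f_nlf_pre=4000.0)
        c = classify_postflight(0.5, 14000.0, 4000.0, pre)
        assert not {"significant_loss_nls",
                    "significant_loss_nlf"} & c.postflight_flags

    def test_loss_beyond_lsc_flagged_per_configuration(self):
        pre = SubjectRecord(f_nls_pre=14279.0, f_nlf_pre=4037.0)
        c = classify_postflight(0.5, 13624.0, 3925.0, pre)
        # NLS: -4.59% exceeds 3.6; NLF: -2.77% does not exceed 11.3
        assert "significant_loss_nls" in c.postflight_flags
        assert "significant_loss_nlf" not in c.postflight_flags
        assert c.changes["nls_change_pct"] == pytest.approx(-4.587, abs=0.01)


class TestSignificantChange:
    def test_table_change_values(self):
        sig, rel = significant_change(14279.0, 13624.0, 3.6)
        assert sig and rel == pytest.approx(-4.587, abs=0.01)

    def test_boundary_is_strict(self):
        sig, rel = significant_change(100.0, 103.6, 3.6)
        assert rel == pytest.approx(3.6) and not sig

    def test_no_change(self):
        assert significant_change(5000.0, 5000.0, 3.6) == (False, 0.0)

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError):
            significant_change(0.0, 100.0, 3.6)


class TestRegressR2:
    def test_collinear_r2_one(self):
        x = np.arange(10.0)
        assert regress_r2(x, 3 * x - 2)[0] == pytest.approx(1.0)

    def test_matches_squared_correlation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        y = 0.5 * x + rng.normal(size=80)
        r2, p = regress_r2(x, y)
        assert r2 == pytest.approx(float(np.corrcoef(x, y)[0, 1] ** 2),
                                   rel=1e-12)
        assert 0 < p < 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            regress_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSummarize:
    def test_single_record_sd_zero_range_collapsed(self):
        rec = SubjectRecord(f_nls_pre=12000.0, cohort_label="x")
        tab = summarize_cohort([rec])
        row = tab.loc["f_nls_pre"]
        assert row["sd"] == 0.0 and row["min"] == row["max"] == 12000.0

    def test_matches_bruteforce_column_stats(self):
        import pandas as pd
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(10, 2, 40),
                           "b": rng.uniform(0, 1, 40)})
        tab = summarize_cohort(df)
        assert tab.loc["a", "mean"] == pytest.approx(df["a"].mean())
        assert tab.loc["a", "sd"] == pytest.approx(df["a"].std(ddof=1))
        assert "±" in tab.loc["b", "summary"]

    def test_empty_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            summarize_cohort(pd.DataFrame())


class TestEndToEndPolRecovery:
    def test_pol_converges_to_true_quantile(self):
        """Empirical 75th percentile of a synthetic fractured-cohort capacity
        distribution approaches the true quantile as n grows."""
        rng = np.random.default_rng(7)
        mu, sigma = np.log(9000.0), 0.25
        true_q = float(np.exp(mu + sigma * 0.6744897501960817))
        errs = []
        for n in (100, 2000):
            caps = rng.lognormal(mu, sigma, n)
            errs.append(abs(derive_pol(caps, 75) - true_q) / true_q)
        assert errs[1] < 0.02

    def test_flag_fraction_equals_empirical_cdf(self):
        rng = np.random.default_rng(8)
        caps = rng.normal(4000, 500, 1000)
        cfg = RiskBandConfig()
        frac = np.mean([
            "below_fe_pol_nlf" in classify_postflight(0.0, None, c,
                                                      cfg=cfg).postflight_flags
            for c in caps])
        assert frac == pytest.approx(np.mean(caps < cfg.pol_nlf), abs=1e-12)
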
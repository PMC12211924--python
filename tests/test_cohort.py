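"""Synthetic cohort generator: marginals, correlations, event histories."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from airses import cohort as sc

# Empirical natural-scale correlation of NO2/NOx implied by a log-scale
# correlation of 0.9 under the moment-matched log-normal marginals,
# computed once from 10^6 bivariate draws.
LOGNORMAL_CORR_ORACLE = 0.8946

# Mean observed time-to-death among uncensored subjects for a constant
# death hazard 0.08/yr censored at 12.5 yr: frozen from a 10^6-draw
# simulation (analytic truncated-exponential mean 5.2253).
CONDITIONAL_DEATH_MEAN_ORACLE = 5.2248


class TestGeneratePollutants:
    def test_defaults_reproduce_reference_means(self):
        n = 40000
        panel = sc.generate_pollutants(n, seed=11)
        se = sc.DEFAULT_SDS / np.sqrt(n)
        err = np.abs(panel.mean().to_numpy() - sc.DEFAULT_MEANS)
        assert np.all(err < 2 * se)

    def test_defaults_reproduce_reference_sds(self):
        panel = sc.generate_pollutants(40000, seed=11)
        assert np.allclose(panel.std().to_numpy(), sc.DEFAULT_SDS, rtol=0.05)

    def test_diagonal_covariance_gives_independence(self):
        cov = np.diag(sc.DEFAULT_SDS**2)
        panel = sc.generate_pollutants(10000, covariance=cov, seed=3)
        corr = panel.corr().to_numpy()
        off = corr[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_log_scale_correlation_matches_large_n_oracle(self):
        cov = np.diag(sc.DEFAULT_SDS**2).astype(float)
        cov[3, 4] = cov[4, 3] = 0.9 * sc.DEFAULT_SDS[3] * sc.DEFAULT_SDS[4]
        panel = sc.generate_pollutants(5000, covariance=cov, seed=4)
        r = panel[["no2", "nox"]].corr().iloc[0, 1]
        assert abs(r - LOGNORMAL_CORR_ORACLE) < 0.03

    def test_positivity_and_determinism(self):
        a = sc.generate_pollutants(500, seed=9)
        b = sc.generate_pollutants(500, seed=9)
        assert (a.to_numpy() > 0).all()
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_bad_inputs(self):
        bad = np.diag([1.0, 1, 1, 1, -2.0])
        with pytest.raises(ValueError, match="positive semi-definite"):
            sc.generate_pollutants(10, covariance=bad)
        with pytest.raises(ValueError, match="n must be positive"):
            sc.generate_pollutants(0)
        with pytest.raises(ValueError, match="symmetric"):
            m = np.eye(5)
            m[0, 1] = 0.5
            sc.generate_pollutants(10, covariance=m)


class TestGenerateSesIndicators:
    def test_degenerate_item_response_identifies_class(self):
        resp = {
            "education": np.eye(3),
            "income": np.eye(3),
            "employment": np.array([[1.0, 0], [0, 1.0], [0, 1.0]]),
        }
        ind, classes = sc.generate_ses_indicators(
            300, prevalences=[0.3, 0.4, 0.3], item_response=resp, seed=5
        )
        assert np.array_equal(ind["education"].to_numpy(), classes)
        assert np.array_equal(ind["income"].to_numpy(), classes)

    def test_single_class_prevalence(self):
        _, classes = sc.generate_ses_indicators(200, prevalences=[1.0, 0.0, 0.0], seed=6)
        assert np.all(classes == 0)

    def test_class_shares_recovered(self):
        prev = np.array([0.3, 0.47, 0.23])
        _, classes = sc.generate_ses_indicators(20000, prevalences=prev, seed=7)
        shares = np.bincount(classes, minlength=3) / 20000
        assert np.all(np.abs(shares - prev) < 0.01)

    def test_rejects_bad_probabilities(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sc.generate_ses_indicators(10, prevalences=[0.5, 0.4, 0.2])
        bad_resp = dict(sc.DEFAULT_ITEM_RESPONSE)
        bad_resp["education"] = np.array([[0.5, 0.2, 0.2, 0.2]] * 3)
        with pytest.raises(ValueError, match="education"):
            sc.generate_ses_indicators(10, item_response=bad_resp)


class TestSimulateEventHistory:
    def test_zero_amd_rate_gives_no_disease(self):
        hz = sc.TransitionHazards(baseline_rates=[0.0, 0.01, 0.3, 0.01, 0.01])
        ev, _ = sc.simulate_event_history(5000, hz, seed=8)
        assert ev["amd_day"].notna().sum() == 0
        assert ev["ocmd_day"].notna().sum() == 0

    def test_conditional_death_time_matches_mc_oracle(self):
        # identical 0.08/yr death hazard from every state makes the
        # time-to-death marginally exponential regardless of path
        hz = sc.TransitionHazards(baseline_rates=[0.003, 0.08, 0.1, 0.08, 0.08])
        _, truth = sc.simulate_event_history(20000, hz, seed=9)
        died = truth["t_death"].dropna()
        assert abs(died.mean() - CONDITIONAL_DEATH_MEAN_ORACLE) < 0.1

    def test_tie_fraction_realised(self):
        hz = sc.TransitionHazards(baseline_rates=[0.02, 0.005, 0.4, 0.01, 0.01])
        ev, _ = sc.simulate_event_history(10000, hz, tie_fraction=0.1, seed=10)
        ocmd = ev["ocmd_day"].notna()
        same_day = (ev.loc[ocmd, "ocmd_day"] == ev.loc[ocmd, "amd_day"]).mean()
        # natural same-day floor ties are rare; coerced fraction dominates
        assert abs(same_day - 0.1) < 0.02 + 0.01

    def test_rejects_negative_rates_and_bad_tie_fraction(self):
        with pytest.raises(ValueError, match="non-negative"):
            sc.TransitionHazards(baseline_rates=[-0.1, 0.1, 0.1, 0.1, 0.1])
        with pytest.raises(ValueError, match="tie_fraction"):
            sc.simulate_event_history(10, tie_fraction=1.0)

    def test_marginal_calibration_against_numeric_integration(self):
        """Observed first-transition proportions agree with the analytic
        exponential-competing-risks probabilities."""
        r1, r2, c = 0.02, 0.01, 12.5
        hz = sc.TransitionHazards(baseline_rates=[r1, r2, 0.3, 0.05, 0.05])
        n = 20000
        ev, _ = sc.simulate_event_history(n, hz, seed=12)
        # P(AMD first, before censoring) by numeric integration of the
        # subdensity r1 exp(-(r1+r2) t)
        p_amd, _ = integrate.quad(lambda t: r1 * np.exp(-(r1 + r2) * t), 0, c)
        p_death0, _ = integrate.quad(lambda t: r2 * np.exp(-(r1 + r2) * t), 0, c)
        obs_amd = ev["amd_day"].notna().mean()
        directly_dead = ev["death_day"].notna() & ev["amd_day"].isna()
        for obs, p in [(obs_amd, p_amd), (directly_dead.mean(), p_death0)]:
            se = np.sqrt(p * (1 - p) / n)
            assert abs(obs - p) < 3 * se


class TestAssembleAndValidate:
    def _toy(self, n=50, seed=13):
        panel = sc.generate_pollutants(n, seed=seed)
        ind, _ = sc.generate_ses_indicators(n, seed=seed)
        ev, _ = sc.simulate_event_history(n, seed=seed)
        return panel, ind, ev

    def test_roundtrip_identical(self, tmp_path):
        panel, ind, ev = self._toy()
        df = sc.assemble_cohort(panel, ind, ev, seed=1)
        path = tmp_path / "cohort.csv"
        sc.write_cohort(df, path)
        back = sc.read_cohort(path)
        pd.testing.assert_frame_equal(
            back, df, check_exact=False, rtol=1e-12, check_dtype=False
        )

    def test_rejects_ocmd_before_amd(self):
        panel, ind, ev = self._toy(seed=14)
        ev.loc[0, "amd_day"] = 500.0
        ev.loc[0, "ocmd_day"] = 400.0
        ev.loc[0, "death_day"] = np.nan
        with pytest.raises(ValueError, match=r"OCMD dated before AMD.*\[0\]"):
            sc.assemble_cohort(panel, ind, ev, seed=1)

    def test_rejects_underage_subject(self):
        panel, ind, ev = self._toy(seed=15)
        n = len(panel)
        rng = np.random.default_rng(0)
        cov = sc._simulate_covariates(n, rng)
        cov.loc[3, "age_entry"] = 44.0
        with pytest.raises(ValueError, match=r"age at entry below 45.*\[3\]"):
            sc.assemble_cohort(panel, ind, ev, covariates=cov, seed=1)

    def test_rejects_orphan_ocmd(self):
        panel, ind, ev = self._toy(seed=16)
        ev.loc[1, "amd_day"] = np.nan
        ev.loc[1, "ocmd_day"] = 100.0
        ev.loc[1, "death_day"] = np.nan
        with pytest.raises(ValueError, match="OCMD without prior AMD"):
            sc.assemble_cohort(panel, ind, ev, seed=1)


class TestCohortProperties:
    def test_seeded_determinism_byte_identical(self):
        cfg = sc.CohortConfig(n=400, seed=77)
        df1, _ = sc.generate_cohort(cfg)
        df2, _ = sc.generate_cohort(cfg)
        assert sc.cohort_to_csv_bytes(df1) == sc.cohort_to_csv_bytes(df2)

    def test_state_order_conservation(self, small_cohort):
        df, _ = small_cohort
        assert df["ocmd_date"].notna().sum() <= df["amd_date"].notna().sum()

    def test_truth_groups_cover_all_cells(self, small_cohort):
        _, truth = small_cohort
        assert truth["group"].nunique() == 9
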
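"""Joint Cox analysis: partial likelihood, interaction measures, splines,
Rubin pooling, proportionality diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from airses import cox, interaction, splines


def simulate_exponential(n, beta, rate=0.1, censor=10.0, seed=0, binary=True):
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(float) if binary else rng.normal(size=n)
    t = rng.exponential(1.0 / (rate * np.exp(beta * x)))
    df = pd.DataFrame(
        {"x": x, "T": np.minimum(t, censor), "E": (t <= censor).astype(int)}
    )
    return df


class TestJointGroup:
    def test_reference_cell(self):
        g = cox.make_joint_exposure(["first"], ["high"])
        assert g[0] == "T1xhigh"
        assert list(g.categories)[0] == "T1xhigh"

    def test_highest_risk_cell_and_area_labels(self):
        g = cox.make_joint_exposure(["third", "third"], ["low", "severely"])
        assert list(g) == ["T3xlow", "T3xlow"]

    def test_all_nine_cells(self):
        terts = [t for t in ("first", "second", "third") for _ in range(3)]
        ses = ["high", "medium", "low"] * 3
        g = cox.make_joint_exposure(terts, ses)
        assert sorted(set(g)) == sorted(cox.JOINT_LEVELS)

    def test_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            cox.make_joint_exposure(pd.Categorical(["first", None]), ["high", "low"])


class TestFitHazardModel:
    def test_matches_hand_written_partial_likelihood(self):
        """Coefficient agrees with a grid/scalar maximization of the
        hand-written Efron-free partial likelihood on untied toy data."""
        df = pd.DataFrame(
            {
                "x": [1.0, 0.0, 1.0, 0.0],
                "T": [1.0, 2.0, 3.0, 4.0],
                "E": [1, 1, 1, 1],
            }
        )
        fit = cox.fit_hazard_model(df, "T", "E", ["x"])

        x = df["x"].to_numpy()

        def neg_pl(beta):
            # untied event times, all events: product over events of
            # exp(b x_i) / sum_{j still at risk} exp(b x_j)
            order = np.argsort(df["T"].to_numpy())
            ll = 0.0
            for k, i in enumerate(order):
                risk = order[k:]
                ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
            return -ll

        res = optimize.minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded")
        assert fit.params["x"] == pytest.approx(res.x, abs=1e-5)
        assert -fit.log_likelihood == pytest.approx(res.fun, abs=1e-6)

    def test_null_coverage(self):
        """A covariate independent of the hazard: 95% CI covers zero at the
        nominal rate."""
        cover = 0
        reps = 400
        for r in range(reps):
            df = simulate_exponential(150, beta=0.0, seed=1000 + r)
            fit = cox.fit_hazard_model(df, "T", "E", ["x"])
            se = float(np.sqrt(fit.covariance.iloc[0, 0]))
            b = float(fit.params["x"])
            cover += (b - 1.96 * se) <= 0.0 <= (b + 1.96 * se)
        assert abs(cover / reps - 0.95) < 0.03

    def test_rejects_no_events_and_collinear(self):
        df = simulate_exponential(50, 0.0, seed=1)
        with pytest.raises(ValueError, match="no events"):
            cox.fit_hazard_model(df.assign(E=0), "T", "E", ["x"])
        df["x2"] = 2 * df["x"]
        with pytest.raises(ValueError, match="collinear"):
            cox.fit_hazard_model(df, "T", "E", ["x", "x2"])

    def test_rejects_constant_covariate(self):
        df = simulate_exponential(50, 0.0, seed=2)
        df["c"] = 1.0
        with pytest.raises(ValueError, match="collinear"):
            cox.fit_hazard_model(df, "T", "E", ["x", "c"])


class TestLikelihoodRatio:
    def _fake(self, loglik, k):
        idx = [f"b{i}" for i in range(k)]
        return cox.HazardFit(
            params=pd.Series(np.zeros(k), index=idx),
            covariance=pd.DataFrame(np.eye(k), index=idx, columns=idx),
            log_likelihood=loglik,
            n_events=10,
            n=100,
        )

    def test_identical_models_give_zero_statistic(self):
        stat, df, p = cox.lr_interaction_test(self._fake(-50.0, 2), self._fake(-50.0, 2))
        assert stat == 0.0 and p == 1.0

    def test_chi_square_reference(self):
        stat, df, p = cox.lr_interaction_test(
            self._fake(-50.0 + 3.841 / 2, 3), self._fake(-50.0, 2)
        )
        assert df == 1
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_optimizer_failure_flagged(self):
        with pytest.raises(ValueError, match="optimizer failure"):
            cox.lr_interaction_test(self._fake(-51.0, 3), self._fake(-50.0, 2))

    def test_null_type_one_error(self):
        """No true interaction: the LR test rejects at ~alpha."""
        rejections = 0
        reps = 400
        rng = np.random.default_rng(55)
        for r in range(reps):
            n = 300
            a = (rng.random(n) < 0.5).astype(float)
            b = (rng.random(n) < 0.5).astype(float)
            lam = 0.12 * np.exp(0.3 * a + 0.4 * b)
            t = rng.exponential(1 / lam)
            df = pd.DataFrame(
                {"a": a, "b": b, "ab": a * b,
                 "T": np.minimum(t, 10.0), "E": (t <= 10.0).astype(int)}
            )
            full = cox.fit_hazard_model(df, "T", "E", ["a", "b", "ab"])
            red = cox.fit_hazard_model(df, "T", "E", ["a", "b"])
            _, _, p = cox.lr_interaction_test(full, red)
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) < 0.025


def fit_from_coefficients(betas, covariance, names=("g10", "g01", "g11")):
    names = list(names)
    return cox.HazardFit(
        params=pd.Series(betas, index=names),
        covariance=pd.DataFrame(covariance, index=names, columns=names),
        log_likelihood=0.0,
        n_events=100,
        n=1000,
    )


class TestAdditiveInteraction:
    def test_exact_additivity(self):
        fit = fit_from_coefficients(np.log([2.0, 3.0, 4.0]), 1e-4 * np.eye(3))
        m = interaction.additive_interaction(fit, "g10", "g01", "g11")
        assert m.reri.value == pytest.approx(0.0, abs=1e-12)
        assert m.ap.value == pytest.approx(0.0, abs=1e-12)
        assert m.synergy.value == pytest.approx(1.0, abs=1e-12)

    def test_exact_multiplicativity(self):
        fit = fit_from_coefficients(np.log([2.0, 3.0, 6.0]), 1e-4 * np.eye(3))
        m = interaction.additive_interaction(fit, "g10", "g01", "g11")
        assert m.reri.value == pytest.approx((2 - 1) * (3 - 1), abs=1e-12)

    def test_synergy_undefined_for_protective_components(self):
        fit = fit_from_coefficients(np.log([0.6, 0.7, 1.5]), 1e-4 * np.eye(3))
        m = interaction.additive_interaction(fit, "g10", "g01", "g11")
        assert m.synergy is None
        assert "denominator" in m.synergy_reason

    def test_delta_ci_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(17)
        A = rng.normal(size=(3, 3)) * 0.05
        V = A @ A.T + 0.01 * np.eye(3)
        betas = np.log([2.0, 3.0, 8.0])
        fit = fit_from_coefficients(betas, V)
        m = interaction.additive_interaction(fit, "g10", "g01", "g11")
        draws = rng.multivariate_normal(betas, V, size=100_000)
        h = np.exp(draws)
        reri_draws = h[:, 2] - h[:, 0] - h[:, 1] + 1
        mc_se = reri_draws.std()
        lo = m.reri.value - 1.96 * mc_se
        hi = m.reri.value + 1.96 * mc_se
        # the delta-method SE is a linearization; compare CI endpoints on
        # the MC-delta scale
        assert m.reri.lo == pytest.approx(lo, abs=0.02 * (hi - lo) + 0.02)
        assert m.reri.hi == pytest.approx(hi, abs=0.02 * (hi - lo) + 0.02)

    @settings(deadline=None, max_examples=40)
    @given(
        h10=st.floats(0.5, 4.0),
        h01=st.floats(0.5, 4.0),
        h11=st.floats(0.5, 8.0),
    )
    def test_reri_identity_grid(self, h10, h01, h11):
        fit = fit_from_coefficients(np.log([h10, h01, h11]), 1e-6 * np.eye(3))
        m = interaction.additive_interaction(fit, "g10", "g01", "g11")
        assert m.reri.value == pytest.approx(
            interaction.reri_from_hrs(h10, h01, h11), rel=1e-10, abs=1e-10
        )
        assert m.ap.value == pytest.approx(m.reri.value / h11, rel=1e-10, abs=1e-10)


class TestMultiplicativeInteraction:
    def test_product_term_recovered(self):
        rng = np.random.default_rng(23)
        n = 4000
        a = (rng.random(n) < 0.5).astype(float)
        b = (rng.random(n) < 0.5).astype(float)
        lam = 0.1 * np.exp(0.3 * a + 0.2 * b + 0.5 * a * b)
        t = rng.exponential(1 / lam)
        df = pd.DataFrame(
            {"a": a, "b": b, "T": np.minimum(t, 12.0), "E": (t <= 12.0).astype(int)}
        )
        m = interaction.multiplicative_interaction(df, "a", "b", "T", "E")
        assert m.lo < np.exp(0.5) < m.hi
        assert m.lr_p < 0.05


class TestRubin:
    def test_identical_estimates(self):
        p = cox.pool_rubin([1.5, 1.5, 1.5], [0.2, 0.2, 0.2])
        assert p.between == 0.0
        assert p.total == p.within == pytest.approx(0.2)

    def test_hand_example(self):
        p = cox.pool_rubin([1.0, 3.0], [1.0, 1.0])
        assert p.pooled == 2.0
        assert p.within == 1.0
        assert p.between == 2.0
        assert p.total == pytest.approx(4.0)

    def test_total_at_least_within(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            est = rng.normal(size=5)
            var = rng.uniform(0.1, 1.0, size=5)
            p = cox.pool_rubin(est, var)
            assert p.total >= p.within

    def test_rejects_single_imputation(self):
        with pytest.raises(ValueError, match="at least 2"):
            cox.pool_rubin([1.0], [1.0])


class TestSchoenfeld:
    def test_hand_worked_three_event_toy(self):
        """Residuals match explicit risk-set arithmetic on 3 events."""
        df = pd.DataFrame(
            {
                "x": [1.0, 0.0, 1.0, 0.0, 0.0],
                "T": [1.0, 2.0, 3.0, 4.0, 5.0],
                "E": [1, 1, 1, 0, 0],
            }
        )
        fit = cox.fit_hazard_model(df, "T", "E", ["x"])
        b = float(fit.params["x"])
        res = cox.schoenfeld_residuals(fit)
        x = df["x"].to_numpy()
        w = np.exp(b * x)
        expected = []
        for i in range(3):
            risk = np.arange(i, 5)
            xbar = (w[risk] * x[risk]).sum() / w[risk].sum()
            expected.append(x[i] - xbar)
        assert np.allclose(res["x"].to_numpy(), expected, atol=1e-8)

    def test_proportional_data_rejection_rate(self):
        rejections = 0
        reps = 300
        for r in range(reps):
            df = simulate_exponential(120, beta=0.5, seed=2000 + r)
            fit = cox.fit_hazard_model(df, "T", "E", ["x"])
            diag = cox.ph_diagnostic(fit)
            rejections += float(diag.loc[0, "p"]) < 0.05
        assert abs(rejections / reps - 0.05) < 0.03

    def test_requires_two_events(self):
        df = pd.DataFrame({"x": [1.0, 0.0], "T": [1.0, 2.0], "E": [1, 0]})
        fit = cox.fit_hazard_model(df, "T", "E", ["x"])
        with pytest.raises(ValueError, match="at least 2 events"):
            cox.schoenfeld_residuals(fit)


class TestSplines:
    def test_linear_beyond_boundary_knots(self):
        knots = np.array([1.0, 2.0, 3.0, 4.0])
        for x0 in (0.2, 4.8):
            h = 1e-4
            grid = np.array([x0 - h, x0, x0 + h])
            B = splines.rcs_basis(grid, knots)
            second = B[0] - 2 * B[1] + B[2]
            assert np.all(np.abs(second) < 1e-9)

    def test_reference_is_exact_zero(self):
        df = simulate_exponential(800, beta=0.3, seed=5, binary=False)
        df["score"] = df["x"]
        curve = splines.rcs_dose_response(
            df, "score", "T", "E", grid=np.array([np.median(df["score"])])
        )
        assert curve["log_hr"].iloc[0] == 0.0

    def test_log_linear_effect_recovered(self):
        rng = np.random.default_rng(31)
        n = 10000
        s = rng.normal(size=n)
        t = rng.exponential(1 / (0.1 * np.exp(0.4 * s)))
        df = pd.DataFrame(
            {"score": s, "T": np.minimum(t, 12.0), "E": (t <= 12.0).astype(int)}
        )
        lo, hi = np.percentile(s, [5, 95])
        grid = np.linspace(lo, hi, 40)
        curve = splines.rcs_dose_response(df, "score", "T", "E", grid=grid)
        truth = 0.4 * (grid - np.median(s))
        inside = (curve["lo"] <= truth) & (truth <= curve["hi"])
        assert inside.mean() > 0.9

    def test_coincident_knots_rejected(self):
        x = np.repeat([1.0, 2.0, 3.0], 50)
        with pytest.raises(ValueError, match="[Cc]oincident|distinct"):
            splines.rcs_knots(x)
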
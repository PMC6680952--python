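"""Risk layer: logistic, conditional logistic, and linear associations.

The conditional-logistic fits are checked against three independent
oracles: the discordant-pair closed form, a grid-search maximizer of
the written conditional log-likelihood, and the classical equivalence
with intercept-free logistic regression on within-pair score
differences.
"""

import numpy as np
import pandas as pd
import pytest

import triplot as tp
from conftest import simulate_matched_pairs


def binary_spec(y):
    return tp.OutcomeSpec(kind="binary", y=y, scaling="raw")


def matched_spec(y, sid, scaling="raw"):
    return tp.OutcomeSpec(kind="matched_binary", y=y, set_id=sid,
                          scaling=scaling)


def table_to_data(a, b, c, d):
    """2x2 table (cases exposed a, controls exposed b, cases unexposed c,
    controls unexposed d) as outcome/exposure vectors."""
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    return x, y


class TestCrudeLR:
    def test_two_by_two_closed_form(self):
        # logistic MLE on a binary predictor equals ad/bc
        x, y = table_to_data(10, 20, 30, 40)
        fit = tp.crude_lr(x, binary_spec(y))
        assert fit.estimate == pytest.approx((10 * 40) / (20 * 30), abs=1e-4)
        assert fit.scale == "ratio"

    def test_woolf_ci_over_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a, b, c, d = rng.integers(5, 60, size=4)
            x, y = table_to_data(a, b, c, d)
            fit = tp.crude_lr(x, binary_spec(y))
            log_or = np.log(a * d / (b * c))
            half = 1.96 * np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert fit.estimate == pytest.approx(np.exp(log_or), rel=1e-3)
            assert fit.ci_low == pytest.approx(np.exp(log_or - half),
                                               rel=1e-3)
            assert fit.ci_high == pytest.approx(np.exp(log_or + half),
                                                rel=1e-3)

    def test_null_simulation_ci_covers_one(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=2000)
        y = rng.integers(0, 2, 2000).astype(float)
        fit = tp.crude_lr(s, binary_spec(y))
        assert fit.ci_low < 1.0 < fit.ci_high

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single outcome class"):
            tp.crude_lr(rng.normal(size=20), binary_spec(np.ones(20)))

    def test_separation_detected(self):
        s = np.r_[np.linspace(-2, -1, 20), np.linspace(1, 2, 20)]
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.raises(ValueError, match="separation"):
            tp.crude_lr(s, binary_spec(y))


class TestCrudeCLR:
    def test_discordant_pair_closed_form(self):
        # 6 case-exposed-only pairs, 3 control-exposed-only, 4 concordant
        s, y, sid = [], [], []
        pair = 0
        for sc, scon in [(1, 0)] * 6 + [(0, 1)] * 3 + [(1, 1)] * 2 + [(0, 0)] * 2:
            s += [sc, scon]
            y += [1, 0]
            sid += [pair, pair]
            pair += 1
        fit = tp.crude_clr(np.array(s, float), matched_spec(np.array(y, float),
                                                            np.array(sid)))
        assert fit.estimate == pytest.approx(2.0, abs=1e-6)

    def test_constant_within_pairs_rejected(self, rng):
        s = np.repeat(rng.normal(size=10), 2)
        y = np.tile([1.0, 0.0], 10)
        sid = np.repeat(np.arange(10), 2)
        with pytest.raises(ValueError, match="constant within matched sets"):
            tp.crude_clr(s, matched_spec(y, sid))

    def test_no_informative_sets_rejected(self):
        y = np.tile([1.0, 1.0], 5)
        sid = np.repeat(np.arange(5), 2)
        s = np.arange(10, dtype=float)
        with pytest.raises(ValueError, match="informative"):
            tp.crude_clr(s, matched_spec(y, sid))

    def test_grid_search_oracle(self):
        """Estimate equals a brute-force maximizer of the written
        conditional log-likelihood over beta in [-5, 5]."""
        rng = np.random.default_rng(21)
        s, y, sid = simulate_matched_pairs(0.4, 100, rng)
        fit = tp.crude_clr(s, matched_spec(y, sid))
        case = s[y == 1]
        control = s[y == 0]
        grid = np.arange(-5, 5, 1e-4)
        # pairwise conditional log-likelihood: sum log sigmoid(b*(xc - xk))
        diff = case - control
        ll = -np.logaddexp(0, -np.outer(grid, diff)).sum(axis=1)
        beta_star = grid[np.argmax(ll)]
        assert fit.beta == pytest.approx(beta_star, abs=2e-4)

    def test_paired_difference_logistic_equivalence(self):
        """1:1 CLR equals intercept-free logistic on case-minus-control
        differences with outcome 1 (classical equivalence)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        s, y, sid = simulate_matched_pairs(0.7, 150, rng)
        fit = tp.crude_clr(s, matched_spec(y, sid))
        diff = s[y == 1] - s[y == 0]  # ordered by set within each slice
        res = sm.Logit(np.ones_like(diff), diff[:, None]).fit(disp=0,
                                                              method="newton",
                                                              tol=1e-12)
        assert fit.beta == pytest.approx(float(res.params[0]), abs=1e-8)

    def test_concordant_sets_counted_as_dropped(self):
        rng = np.random.default_rng(3)
        s, y, sid = simulate_matched_pairs(0.2, 50, rng)
        # make sets 0 and 1 outcome-concordant
        y[sid == 0] = 1.0
        y[sid == 1] = 0.0
        fit = tp.crude_clr(s, matched_spec(y, sid))
        assert fit.extra["n_sets_dropped"] == 2
        assert fit.n_used == 96

    def test_oversized_sets_rejected(self):
        y = np.r_[1.0, np.zeros(11)]
        sid = np.zeros(12)
        with pytest.raises(ValueError, match="larger than 10"):
            matched_spec(y, sid)

    def test_per_sd_scaling_transform(self):
        rng = np.random.default_rng(13)
        s, y, sid = simulate_matched_pairs(0.5, 200, rng)
        raw = tp.crude_clr(s, matched_spec(y, sid, scaling="raw"))
        per_sd = tp.crude_clr(s, matched_spec(y, sid, scaling="per_sd"))
        sd = np.std(s, ddof=1)
        assert per_sd.estimate == pytest.approx(raw.estimate ** sd,
                                                rel=1e-10)


class TestAdjustedFit:
    def test_zero_covariates_bit_identical_to_crude(self):
        rng = np.random.default_rng(17)
        s, y, sid = simulate_matched_pairs(0.3, 80, rng)
        spec = matched_spec(y, sid)
        crude = tp.crude_clr(s, spec)
        adj = tp.adjusted_fit(s, spec, pd.DataFrame(index=range(len(s))))
        assert adj.estimate == crude.estimate
        assert adj.ci_low == crude.ci_low and adj.p == crude.p

    def test_independent_covariate_leaves_estimate(self):
        rng = np.random.default_rng(29)
        n = 2000
        s = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-0.5 * s))).astype(float)
        cov = pd.DataFrame({"z": rng.normal(size=n)})
        crude = tp.crude_lr(s, binary_spec(y))
        adj = tp.adjusted_fit(s, binary_spec(y), cov)
        assert adj.estimate == pytest.approx(crude.estimate, rel=0.05)

    def test_mediator_attenuates_effect(self):
        # score -> mediator -> outcome; adjusting for the mediator
        # removes the association the crude model sees
        rng = np.random.default_rng(31)
        n = 2000
        s = rng.normal(size=n)
        m = s + 0.3 * rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-1.5 * m))).astype(float)
        crude = tp.crude_lr(s, binary_spec(y))
        adj = tp.adjusted_fit(s, binary_spec(y), pd.DataFrame({"m": m}))
        assert crude.ci_low > 1.0
        assert adj.ci_low < 1.0 < adj.ci_high

    def test_clr_covariate_constant_within_sets_rejected(self):
        rng = np.random.default_rng(37)
        s, y, sid = simulate_matched_pairs(0.3, 40, rng)
        cov = pd.DataFrame({"match_var": np.repeat(rng.normal(size=40), 2)})
        with pytest.raises(ValueError, match="absorbed by matching"):
            tp.adjusted_fit(s, matched_spec(y, sid), cov)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(41)
        n = 100
        s = rng.normal(size=n)
        y = rng.integers(0, 2, n).astype(float)
        cov = pd.DataFrame({"a": s * 2})  # collinear with the score
        with pytest.raises(ValueError, match="collinear"):
            tp.adjusted_fit(s, binary_spec(y), cov)


class TestLinearBeta:
    def test_exact_linear_relationship(self, rng):
        s = rng.normal(size=50)
        fit = tp.linear_beta(s, 2 * s + 1, scaling="raw")
        assert fit.estimate == pytest.approx(2.0, abs=1e-10)
        assert fit.ci_high - fit.ci_low == pytest.approx(0.0, abs=1e-8)
        assert fit.scale == "linear"

    def test_null_ci_covers_zero(self):
        rng = np.random.default_rng(43)
        s = rng.normal(size=500)
        m = rng.normal(size=500)
        fit = tp.linear_beta(s, m, scaling="raw")
        assert fit.ci_low < 0.0 < fit.ci_high

    def test_known_slope_recovery(self):
        rng = np.random.default_rng(47)
        s = rng.normal(size=1000)
        m = 0.5 * s + rng.normal(size=1000)
        fit = tp.linear_beta(s, m, scaling="raw")
        assert fit.estimate == pytest.approx(0.5, abs=0.1)

    def test_matches_statsmodels_with_covariates(self, rng):
        import statsmodels.api as sm

        n = 200
        s = rng.normal(size=n)
        c = rng.normal(size=n)
        m = 0.4 * s + 0.8 * c + rng.normal(size=n)
        fit = tp.linear_beta(s, m, pd.DataFrame({"c": c}), scaling="raw")
        X = sm.add_constant(np.column_stack([s, c]))
        ref = sm.OLS(m, X).fit()
        assert fit.estimate == pytest.approx(float(ref.params[1]), abs=1e-10)


class TestRiskBlockAssembly:
    def test_two_ratio_fits(self):
        rows = [tp.FitRow(1.2, 1.0, 1.5, 0.04, "ratio"),
                tp.FitRow(0.8, 0.6, 1.1, 0.3, "ratio")]
        block = tp.risk_block_from_fits(rows)
        assert block.n_comp == 2 and block.scale == "ratio"

    def test_mixed_scales_rejected(self):
        rows = [tp.FitRow(1.2, 1.0, 1.5, 0.04, "ratio"),
                tp.FitRow(0.1, -0.1, 0.3, 0.3, "linear")]
        with pytest.raises(ValueError, match="mixed scales"):
            tp.risk_block_from_fits(rows)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tp.risk_block_from_fits([])

    def test_external_tuples_ingested(self):
        # externally computed hazard ratios enter as plain tuples
        block = tp.risk_block_from_fits([(1.3, 1.1, 1.6, 0.01),
                                         (0.9, 0.7, 1.2, 0.5)],
                                        scale="ratio", model_tag="Cox HR")
        assert block.model_tag == "Cox HR"
        np.testing.assert_allclose(block.estimate, [1.3, 0.9])
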
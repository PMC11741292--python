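"""clr transform, adjusted regressions, exact prevalence tests, BH adjustment."""
import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igaseq.differential import (
    bh_adjust,
    clr_transform,
    compare_flow_proportions,
    display_fold_change,
    fit_group_model,
    fit_paired_model,
    prevalence_contrast,
)
from igaseq.profiles import validate_sample_metadata


def fisher_oracle(detected, totals):
    """Two-sided exact p with rational arithmetic (tie comparison is exact)."""
    d1, d0 = detected
    t1, t0 = totals
    col = d1 + d0
    n = t1 + t0

    def pmf(k):
        return Fraction(math.comb(t1, k) * math.comb(t0, col - k), math.comb(n, col))

    obs = pmf(d1)
    total = sum(
        pmf(k)
        for k in range(max(0, col - t0), min(col, t1) + 1)
        if pmf(k) <= obs
    )
    return float(total)


def ols_oracle(y, X):
    """Normal equations (X'X)^-1 X'y with classical t statistics."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(np.abs(t), df)
    return beta, se, t, p


def build_meta(n_per_group, rng):
    rows = []
    for g, grp in enumerate(("control", "ms_baseline")):
        for i in range(n_per_group):
            rows.append(
                {
                    "sample_id": f"{grp}_{i}",
                    "subject_id": f"{grp}_{i}",
                    "group": grp,
                    "fraction": "presort",
                    "timepoint": "baseline",
                    "age": float(rng.normal(38, 11)),
                    "sex": "female" if rng.random() < 0.7 else "male",
                    "bmi": float(rng.normal(27, 7)),
                    "steroid_use": "within_1mo"
                    if (grp == "ms_baseline" and rng.random() < 0.5)
                    else "none",
                }
            )
    return validate_sample_metadata(pd.DataFrame(rows))


class TestClr:
    def test_equal_composition_maps_to_zero(self):
        ra = pd.DataFrame({"s": [0.25, 0.25, 0.25, 0.25]})
        out = clr_transform(ra)
        np.testing.assert_allclose(out["s"], 0.0, atol=1e-12)

    def test_columns_sum_to_zero(self, rng):
        ra = pd.DataFrame(rng.dirichlet(np.ones(10), size=5).T)
        out = clr_transform(ra)
        np.testing.assert_allclose(out.sum(axis=0), 0.0, atol=1e-9)

    def test_zero_entry_value(self):
        ra = pd.DataFrame({"s": [0.5, 0.5, 0.0]})
        out = clr_transform(ra)
        expected = math.log(1.2e-5) - (2 * math.log(0.5) + math.log(1.2e-5)) / 3
        assert out.loc[2, "s"] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-7.091638, abs=1e-6)

    def test_nonzero_below_pseudocount_left_untouched(self):
        tiny = 5e-6  # smaller than the 1.2e-5 pseudocount but genuinely nonzero
        ra = pd.DataFrame({"s": [tiny, 0.3, 0.7 - tiny]})
        out = clr_transform(ra)
        logs = np.log([tiny, 0.3, 0.7 - tiny])
        assert out.loc[0, "s"] == pytest.approx(logs[0] - logs.mean(), abs=1e-12)

    def test_scale_invariance_through_closure(self, rng):
        counts = rng.integers(0, 100, size=(8, 4)).astype(float)
        counts[0] += 1
        ra1 = counts / counts.sum(axis=0)
        ra2 = (counts * 13.7) / (counts * 13.7).sum(axis=0)
        out1 = clr_transform(pd.DataFrame(ra1))
        out2 = clr_transform(pd.DataFrame(ra2))
        np.testing.assert_allclose(out1.to_numpy(), out2.to_numpy(), atol=1e-9)


class TestGroupModel:
    def test_matches_normal_equations_oracle(self, rng):
        meta = build_meta(6, rng)
        y = pd.Series(rng.normal(size=12), index=meta.index)
        fit = fit_group_model(y, meta)
        X = np.column_stack(
            [
                np.ones(12),
                (meta["group"] == "ms_baseline").astype(float),
                meta["age"],
                (meta["sex"] == "male").astype(float),
                meta["bmi"],
                meta["steroid"].astype(float),
            ]
        )
        beta, se, t, p = ols_oracle(y.to_numpy(), X)
        assert fit.estimate == pytest.approx(beta[1], abs=1e-8)
        assert fit.std_error == pytest.approx(se[1], abs=1e-8)
        assert fit.p_value == pytest.approx(p[1], abs=1e-8)

    def test_random_designs_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 25))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            y = rng.normal(size=n)
            beta, se, t, p = ols_oracle(y, X)
            import statsmodels.api as sm

            fit = sm.OLS(y, X).fit()
            np.testing.assert_allclose(fit.params, beta, atol=1e-8)
            np.testing.assert_allclose(fit.pvalues, p, atol=1e-8)

    def test_constant_response_degenerate(self, rng):
        meta = build_meta(6, rng)
        y = pd.Series(np.ones(12), index=meta.index)
        fit = fit_group_model(y, meta)
        assert fit.estimate == 0.0
        assert math.isnan(fit.p_value)

    def test_rank_deficiency_names_columns(self, rng):
        meta = build_meta(6, rng)
        meta = meta.copy()
        meta["bmi"] = meta["age"]  # perfectly collinear
        y = pd.Series(rng.normal(size=12), index=meta.index)
        with pytest.raises(ValueError, match="collinear"):
            fit_group_model(y, meta)


class TestPairedModel:
    def test_no_change_gives_zero(self, rng):
        y0 = pd.Series(rng.normal(size=8), index=[f"m{i}" for i in range(8)])
        fit = fit_paired_model(y0, y0.copy())
        assert fit.estimate == 0.0

    def test_reproduces_paired_t_test_exactly(self, rng):
        from scipy.stats import ttest_rel

        subjects = [f"m{i}" for i in range(19)]
        y0 = pd.Series(rng.normal(size=19), index=subjects)
        y6 = pd.Series(rng.normal(0.4, 1, size=19), index=subjects)
        fit = fit_paired_model(y0, y6)
        ref = ttest_rel(y6, y0)
        assert fit.estimate == pytest.approx((y6 - y0).mean(), abs=1e-12)
        assert fit.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert fit.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_covariate_adjustment_agrees_with_mixed_model(self, rng):
        import statsmodels.api as sm

        subjects = [f"m{i}" for i in range(16)]
        steroid = pd.DataFrame(
            {"steroid": rng.integers(0, 2, 16).astype(float)}, index=subjects
        )
        y0 = pd.Series(rng.normal(size=16), index=subjects)
        y6 = y0 + 0.5 + 0.3 * steroid["steroid"] + rng.normal(0, 0.2, 16)
        fit = fit_paired_model(y0, y6, covariates=steroid)
        # random-intercept mixed model cross-check on the long layout
        long = pd.DataFrame(
            {
                "y": np.concatenate([y0.to_numpy(), y6.to_numpy()]),
                "time": np.repeat([0.0, 1.0], 16),
                "steroid": np.tile(steroid["steroid"].to_numpy(), 2),
                "subject": subjects * 2,
            }
        )
        long["time_x_steroid"] = long["time"] * (
            long["steroid"] - long["steroid"].mean()
        )
        mm = sm.MixedLM.from_formula(
            "y ~ time + time_x_steroid + steroid", groups="subject", data=long
        ).fit(reml=True)
        assert fit.estimate == pytest.approx(mm.params["time"], abs=1e-6)

    def test_incomplete_pairs_dropped_and_minimum_enforced(self, rng):
        y0 = pd.Series(rng.normal(size=4), index=["a", "b", "c", "d"])
        y6 = pd.Series(rng.normal(size=2), index=["a", "b"])
        with pytest.raises(ValueError, match="pairs"):
            fit_paired_model(y0, y6)


class TestPrevalenceContrast:
    @pytest.mark.parametrize(
        "detected, totals, expected",
        [
            ((5, 5), (10, 10), 1.0),
            ((10, 0), (10, 10), 2 / math.comb(20, 10)),
            ((1, 0), (1, 1), 1.0),
        ],
    )
    def test_exact_cases(self, detected, totals, expected):
        res = prevalence_contrast(detected, totals)
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_table_margins(self):
        res = prevalence_contrast((3, 7), (12, 15))
        assert res.table.sum(axis=0).tolist() == [12, 15]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            prevalence_contrast((-1, 2), (5, 5))

    def test_matches_enumeration_oracle_for_small_margins(self):
        for t1, t0 in itertools.product(range(1, 7), repeat=2):
            for d1 in range(t1 + 1):
                for d0 in range(t0 + 1):
                    mine = prevalence_contrast((d1, d0), (t1, t0)).p_value
                    oracle = fisher_oracle((d1, d0), (t1, t0))
                    assert mine == pytest.approx(oracle, abs=1e-9), (
                        d1, d0, t1, t0,
                    )

    def test_matches_oracle_margin_twelve(self):
        for d1 in range(13):
            mine = prevalence_contrast((d1, 12 - d1), (12, 12)).p_value
            oracle = fisher_oracle((d1, 12 - d1), (12, 12))
            assert mine == pytest.approx(oracle, abs=1e-9)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04],
            atol=1e-12,
        )

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_monotone_and_dominates_p(self, ps):
        q = bh_adjust(ps)
        p = np.asarray(ps)
        assert (q >= p - 1e-12).all()
        assert (q <= 1 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_step_up_formula(self, rng):
        p = rng.random(25)
        q = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            expected[i] = running
        np.testing.assert_allclose(q, expected, atol=1e-12)


class TestFlowComparison:
    def test_constant_proportions_give_zero_estimate(self):
        flow = pd.DataFrame(
            {
                "subject_id": [f"x{i}" for i in range(10)],
                "timepoint": ["baseline"] * 10,
                "group": ["control"] * 5 + ["ms_baseline"] * 5,
                "pct_iga_coated": [0.3] * 10,
            }
        )
        fit = compare_flow_proportions(flow)
        assert fit.estimate == 0.0


def test_display_fold_change_is_log2_ratio_of_means():
    ra = pd.DataFrame(
        {"g1a": [0.4, 0.6], "g1b": [0.2, 0.8], "g0a": [0.1, 0.9], "g0b": [0.2, 0.8]}
    )
    lfc = display_fold_change(ra, ["g1a", "g1b"], ["g0a", "g0b"], pseudocount=0.0)
    assert lfc[0] == pytest.approx(math.log2(0.3 / 0.15), abs=1e-12)
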
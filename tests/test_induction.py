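"""Normalization, fold ratios, Hill fitting and edit-distance coordinates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.stats import norm

from selexpress import simulate as sim
from selexpress.induction import (
    HillModel,
    fit_hill,
    fold_induction,
    fold_repression,
    hill_curve,
    levenshtein,
    normalize,
    speedometer_coordinates,
    summarize_induction,
)


class TestNormalize:
    def test_simple_arithmetic(self):
        assert normalize(1000.0, 0.5) == pytest.approx(2000.0)

    def test_blank_subtraction_reaches_zero(self):
        assert normalize(50.0, 0.5, blank_gfp=50.0) == pytest.approx(0.0)

    def test_plate_vector_equals_elementwise(self, rng):
        gfp = rng.uniform(100, 5000, 96)
        od = rng.uniform(0.2, 1.2, 96)
        got = normalize(gfp, od, blank_gfp=20.0, blank_od=0.05)
        want = np.array(
            [(g - 20.0) / (o - 0.05) for g, o in zip(gfp, od)]
        )
        np.testing.assert_allclose(got, want)

    def test_od_at_blank_is_an_error(self):
        with pytest.raises(ValueError):
            normalize(100.0, 0.05, blank_od=0.05)


class TestFoldRatios:
    def test_simple_ratio(self):
        assert fold_induction(5000.0, 500.0) == pytest.approx(10.0)

    def test_identical_populations_give_unity(self, rng):
        pop = rng.lognormal(5, 1, 4000)
        assert fold_induction(pop, pop.copy()) == pytest.approx(1.0)

    def test_fold_repression_uses_medians(self, rng):
        no_atf = rng.lognormal(6, 0.2, 5001)
        with_atf = rng.lognormal(4, 0.2, 5001)
        got = fold_repression(no_atf, with_atf)
        assert got == pytest.approx(np.median(no_atf) / np.median(with_atf))

    def test_bimodal_population_matches_analytic_mixture_median(self, rng):
        """FI of lognormal mixtures equals the ratio of exact mixture medians
        (quantile inversion of the mixture CDF)."""
        w, mu1, mu2, s = 0.3, 4.0, 6.5, 0.3

        def mixture_median(mu_a, mu_b):
            cdf = lambda x: w * norm.cdf((np.log(x) - mu_a) / s) + (1 - w) * norm.cdf(
                (np.log(x) - mu_b) / s
            )
            return brentq(lambda x: cdf(x) - 0.5, 1e-6, 1e9)

        n = 400_000
        comp = rng.random(n) < w
        induced = np.exp(np.where(comp, rng.normal(mu1, s, n), rng.normal(mu2, s, n)))
        comp2 = rng.random(n) < w
        uninduced = np.exp(
            np.where(comp2, rng.normal(mu1 - 2, s, n), rng.normal(mu2 - 2, s, n))
        )
        got = fold_induction(induced, uninduced)
        want = mixture_median(mu1, mu2) / mixture_median(mu1 - 2, mu2 - 2)
        assert got == pytest.approx(want, rel=0.02)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(1.0, 1e4),
        st.floats(1.0, 1e4),
        st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, x, y, c):
        assert fold_induction(x * c, y * c) == pytest.approx(
            fold_induction(x, y), rel=1e-9
        )

    def test_zero_denominator_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            fold_induction(10.0, 0.0)


class TestSummarizeInduction:
    def test_percent_of_constitutive_reference(self):
        df = sim.simulate_expression(
            {"ref": 1e6, "op": 10.0},  # huge Kd -> effectively constitutive
            [0.0, 1.0, 10.0, 100.0],
            sim.ExpressionSimConfig(noise_cv=0.0),
        )
        out = summarize_induction(df, reference_clone="ref")
        ref_row = out[out["clone_id"] == "ref"].iloc[0]
        assert ref_row["percent_of_constitutive"] == pytest.approx(100.0)
        assert (out["percent_of_constitutive"] <= 100.0 + 1e-9).all()

    def test_missing_reference_is_an_error(self):
        df = sim.simulate_expression(
            {"op": 10.0}, [0.0, 1.0, 10.0, 100.0], sim.ExpressionSimConfig()
        )
        with pytest.raises(ValueError, match="reference"):
            summarize_induction(df, reference_clone="nope")


class TestHillFit:
    def test_noiseless_parameters_recovered_exactly(self):
        L = np.array([0.0, 1, 3, 10, 30, 100, 300, 1000])
        y = hill_curve(L, 5.0, 100.0, 50.0, 2.0)
        res = fit_hill(L, y)
        assert res.converged
        for got, want in zip(
            (res.y0, res.vmax, res.km, res.hill_n), (5.0, 100.0, 50.0, 2.0)
        ):
            assert got == pytest.approx(want, rel=1e-6)

    def test_half_maximum_identity_by_construction(self):
        L = np.array([0.0, 1, 3, 10, 30, 100, 300, 1000])
        res = fit_hill(L, hill_curve(L, 5.0, 100.0, 50.0, 2.0))
        assert res.predict(res.km) - res.y0 == pytest.approx(res.vmax / 2, rel=1e-6)

    def test_flat_response_flagged_non_inducible(self):
        L = np.array([0.0, 1, 10, 100, 1000])
        res = fit_hill(L, np.full(5, 200.0))
        assert (not res.converged) or res.non_inducible

    def test_residual_invariant_to_replicate_ordering(self, rng):
        L = np.tile([0.0, 1, 10, 100, 1000], 3)
        y = hill_curve(L, 5.0, 80.0, 20.0, 1.5) * rng.lognormal(0, 0.05, L.size)
        perm = rng.permutation(L.size)
        r1 = fit_hill(L, y)
        r2 = fit_hill(L[perm], y[perm])
        assert r1.residual_sse == pytest.approx(r2.residual_sse, rel=1e-6)

    def test_fixed_y0_mode(self):
        L = np.array([0.0, 1, 3, 10, 30, 100, 300, 1000])
        y = hill_curve(L, 0.0, 100.0, 50.0, 2.0) + 1e-9
        res = fit_hill(L, y, fix_y0=0.0)
        assert res.y0 == 0.0
        assert res.km == pytest.approx(50.0, rel=1e-4)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            HillModel([0.0, 1.0, 10.0], [1.0, 2.0, 3.0])

    def test_parameter_recovery_under_noise_small(self):
        """Reduced-scale version of the recovery study (20 seeds here; the
        full 100-seed study runs in the acceptance suite)."""
        true = dict(y0=5.0, vmax=100.0, km=50.0, n=2.0)
        L = np.tile([0.0, 0.5, 2, 8, 30, 100, 400, 1500], 3)
        km_err, vmax_err = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = hill_curve(L, true["y0"], true["vmax"], true["km"], true["n"])
            y = y * r.lognormal(0, 0.05, L.size)
            res = fit_hill(L, y)
            km_err.append(abs(res.km - true["km"]) / true["km"])
            vmax_err.append(abs(res.vmax - true["vmax"]) / true["vmax"])
        assert np.median(km_err) <= 0.15
        assert np.median(vmax_err) <= 0.10


class TestLevenshtein:
    def test_metric_identity(self):
        assert levenshtein("TACAGTGA", "TACAGTGA") == 0

    def test_single_substitution(self):
        assert levenshtein("TACA", "TGCA") == 1

    def test_indel(self):
        assert levenshtein("TACA", "TAACA") == 1

    def test_matches_recursive_oracle(self, rng):
        def rec(a, b):
            if not a:
                return len(b)
            if not b:
                return len(a)
            return min(
                rec(a[1:], b) + 1,
                rec(a, b[1:]) + 1,
                rec(a[1:], b[1:]) + (a[0] != b[0]),
            )

        for _ in range(100):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 9))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 9))))
            assert levenshtein(a, b) == rec(a, b)

    @settings(max_examples=60, deadline=None)
    @given(
        st.text(alphabet="ACGT", max_size=12),
        st.text(alphabet="ACGT", max_size=12),
        st.text(alphabet="ACGT", max_size=12),
    )
    def test_triangle_inequality(self, a, b, c):
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


class TestSpeedometer:
    def test_reference_defaults_to_top_inducer(self):
        df = speedometer_coordinates(
            ["AAAA", "AAAT", "CCCC"], [3.0, 9.0, 1.0]
        )
        assert (df["reference"] == "AAAT").all()
        assert df.loc[1, "radial"] == 0

    def test_coordinates_are_distance_and_fold_induction(self):
        df = speedometer_coordinates(["TACA", "TGCA"], [5.0, 2.0], reference="TACA")
        assert df["radial"].tolist() == [0, 1]
        assert df["angular"].tolist() == [5.0, 2.0]
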
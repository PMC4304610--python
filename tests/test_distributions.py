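"""Distribution library: quantiles, moments, truncation, LHS sampling."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy import stats
from scipy.optimize import brentq

from eliqrisk.distributions import (
    DistributionSpec,
    SpecValidationError,
    analytic_mean,
    cdf,
    mean,
    normal_from_quantiles,
    numeric_mean,
    quantile,
    sample,
)


class TestQuantile:
    def test_uniform_midpoint(self):
        spec = DistributionSpec("uniform", (6, 81))
        assert quantile(spec, 0.5) == pytest.approx(43.5)

    def test_truncation_floor(self, propanediol_spec):
        # lower-truncated triangular: quantile approaches the bound from above
        assert quantile(propanediol_spec, 1e-12) == pytest.approx(0.0, abs=1e-5)
        assert quantile(propanediol_spec, 1e-12) >= 0.0

    def test_loglogistic_median_is_location_plus_scale(self, ethylene_glycol_spec):
        # untruncated log-logistic median = location + scale; verify against
        # numeric inversion of the CDF as an independent oracle
        spec = DistributionSpec("loglogistic", (-0.40204, 5.15, 1.8215))
        assert quantile(spec, 0.5) == pytest.approx(-0.40204 + 5.15, abs=1e-9)
        root = brentq(lambda x: cdf(spec, x) - 0.5, -0.4, 100.0)
        assert quantile(spec, 0.5) == pytest.approx(root, abs=1e-6)

    def test_domain_errors(self, nicotine_spec):
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                quantile(nicotine_spec, bad)

    @given(
        st.sampled_from(["normal", "weibull_shifted", "triangular", "loglogistic", "uniform", "empirical_resample"]),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_u(self, family, seed):
        rng = np.random.default_rng(seed)
        if family == "normal":
            params = (rng.uniform(-10, 10), rng.uniform(0.1, 20))
        elif family == "weibull_shifted":
            params = (rng.uniform(0.3, 5), rng.uniform(0.1, 50))
        elif family == "triangular":
            a, b, c = np.sort(rng.uniform(-20, 100, 3))
            params = (a, b, c + 1e-6)
        elif family == "loglogistic":
            params = (rng.uniform(-5, 5), rng.uniform(0.1, 10), rng.uniform(0.3, 5))
        elif family == "uniform":
            lo = rng.uniform(-10, 10)
            params = (lo, lo + rng.uniform(0.1, 50))
        else:
            params = tuple(rng.uniform(0, 100, size=rng.integers(2, 20)))
        try:
            spec = DistributionSpec(
                family, params, shift=rng.uniform(-5, 5),
                truncation=(0.0, None) if rng.random() < 0.5 else None,
            )
        except SpecValidationError:
            # e.g. whole support below the truncation bound — not a valid spec
            assume(False)
        u = np.sort(rng.uniform(1e-9, 1 - 1e-9, 50))
        q = quantile(spec, u)
        assert np.all(np.diff(q) >= -1e-12)

    def test_invalid_specs_rejected(self):
        with pytest.raises(SpecValidationError):
            DistributionSpec("triangular", (5, 2, 10))
        with pytest.raises(SpecValidationError):
            DistributionSpec("normal", (0, -1))
        with pytest.raises(SpecValidationError):
            DistributionSpec("uniform", (3, 3))
        with pytest.raises(SpecValidationError):
            DistributionSpec("weibull_shifted", (-1, 2))
        with pytest.raises(SpecValidationError):
            DistributionSpec("uniform", (0, 1), truncation=(5, 9))  # zero mass


class TestNormalFromQuantiles:
    def test_interquartile_solution(self):
        mu, sigma = normal_from_quantiles(0.25, 3, 0.75, 5)
        assert mu == pytest.approx(4.0)
        assert sigma == pytest.approx(2 / (2 * stats.norm.ppf(0.75)), rel=1e-6)
        assert sigma == pytest.approx(1.4826, abs=1e-4)

    def test_standard_normal_symmetry(self):
        z = 1.6449  # ~95th percentile
        mu, sigma = normal_from_quantiles(0.05, -z, 0.95, z)
        assert mu == pytest.approx(0.0, abs=1e-9)
        assert sigma == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_quantiles_error(self):
        with pytest.raises(SpecValidationError):
            normal_from_quantiles(0.25, 4.2, 0.75, 4.2)


class TestMeans:
    def test_triangular_closed_form(self):
        spec = DistributionSpec("triangular", (-18.939, 91.8, 100.45))
        assert analytic_mean(spec) == pytest.approx(57.7703, abs=1e-3)

    def test_truncated_normal(self, nicotine_spec):
        m = analytic_mean(nicotine_spec)
        assert m == pytest.approx(15.632, abs=0.01)
        assert numeric_mean(nicotine_spec) == pytest.approx(m, rel=1e-4)

    def test_shifted_weibull(self):
        spec = DistributionSpec("weibull_shifted", (1.8104, 44.812), shift=-2.8327)
        m = analytic_mean(spec)
        assert m == pytest.approx(37.007, abs=0.01)
        assert numeric_mean(spec) == pytest.approx(m, rel=1e-3)

    def test_heavy_tail_loglogistic_unavailable(self):
        spec = DistributionSpec("loglogistic", (0, 1, 0.9))
        assert analytic_mean(spec) is None  # divergent mean

    def test_truncated_families_fall_back_to_numeric(self, glycerol_spec):
        assert analytic_mean(glycerol_spec) is None
        # numeric value close to (slightly above) the untruncated mean
        assert mean(glycerol_spec) == pytest.approx(37.26, abs=0.05)

    def test_empirical_mean(self, thujone_vector):
        spec = DistributionSpec("empirical_resample", tuple(thujone_vector))
        assert analytic_mean(spec) == pytest.approx(361 / 54)


class TestSampling:
    def test_empirical_support(self, thujone_vector):
        spec = DistributionSpec("empirical_resample", tuple(thujone_vector))
        x = sample(spec, 10_000, rng_seed=7)
        assert set(np.unique(x)) <= {0.0, 178.0, 183.0}

    def test_truncation_respected(self, nicotine_spec):
        x = sample(nicotine_spec, 10_000, rng_seed=3, method="lhs")
        assert x.min() >= 0.0

    def test_lhs_mean_within_three_se(self):
        spec = DistributionSpec("normal", (73.9, 12))
        x = sample(spec, 10_000, rng_seed=11, method="lhs")
        se = 12 / np.sqrt(10_000)
        assert abs(x.mean() - 73.9) < 3 * se

    def test_lhs_stratification_exact(self):
        n = 1000
        spec = DistributionSpec("uniform", (0, 1))
        x = sample(spec, n, rng_seed=5, method="lhs")
        # map back to strata; exactly one draw per stratum
        strata = np.floor(x * n).astype(int)
        assert sorted(strata) == list(range(n))

    def test_seed_reproducibility(self, glycerol_spec):
        a = sample(glycerol_spec, 500, rng_seed=42, method="lhs")
        b = sample(glycerol_spec, 500, rng_seed=42, method="lhs")
        assert np.array_equal(a, b)

    def test_unknown_method_rejected(self, nicotine_spec):
        with pytest.raises(ValueError):
            sample(nicotine_spec, 10, rng_seed=0, method="sobol")

    @pytest.mark.parametrize(
        "spec_name",
        ["nicotine_spec", "propanediol_spec", "ethylene_glycol_spec", "glycerol_spec"],
    )
    def test_lhs_mean_matches_numeric_mean_1pct(self, spec_name, request):
        spec = request.getfixturevalue(spec_name)
        x = sample(spec, 100_000, rng_seed=17, method="lhs")
        assert x.mean() == pytest.approx(mean(spec), rel=0.01)

    def test_truncated_inverse_cdf_equals_rejection(self, nicotine_spec):
        """Restricted-inverse-CDF truncation is distributionally identical to
        rejection sampling from the untruncated law."""
        x = sample(nicotine_spec, 10_000, rng_seed=19, method="srs")
        rng = np.random.default_rng(20)
        raw = rng.normal(11.023, 13.134, size=60_000)
        rej = raw[raw >= 0][:10_000]
        stat, p = stats.ks_2samp(x, rej)
        assert p > 0.01


class TestSerialization:
    def test_round_trip(self, glycerol_spec, thujone_vector):
        for spec in (
            glycerol_spec,
            DistributionSpec("empirical_resample", tuple(thujone_vector), unit="mg/L"),
        ):
            again = DistributionSpec.from_dict(spec.to_dict())
            assert again == spec

    def test_normal_alt_resolves_to_normal(self):
        spec = DistributionSpec("normal_from_quantiles", (0.25, 3, 0.75, 5))
        assert spec.family == "normal"
        assert spec.params[0] == pytest.approx(4.0)
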
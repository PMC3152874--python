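import itertools

import numpy as np
import pytest
from scipy import stats

from lactqtl.mle_scan import (
    LN10,
    classify_lod,
    em_mixture,
    estimate_power,
    mixture_loglik,
    scan_mle,
    standardized_effect,
    support_interval,
    transform_trait,
)


class TestTransform:
    def test_exact_logs(self):
        out, meta = transform_trait([1.0, np.e, np.e**2])
        assert np.allclose(out, [0.0, 1.0, 2.0])
        assert meta["zero_offset"] == 0.0

    def test_zero_offset_rule(self):
        out, meta = transform_trait([0.0, 0.4, 1.0])
        assert meta["zero_offset"] == pytest.approx(0.2)
        assert out[0] == pytest.approx(np.log(0.2))
        assert out[1] == pytest.approx(np.log(0.4))  # offset hits zeros only

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_trait([-0.1, 1.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            transform_trait([0.0, 0.0])


class TestMixtureLoglik:
    def test_degenerate_mixture_is_single_normal(self, rng):
        y = rng.standard_normal(20)
        ll = mixture_loglik(y, np.ones(20), (0.3, -5.0, 1.2))
        assert ll == pytest.approx(
            float(np.sum(stats.norm.logpdf(y, 0.3, 1.2))), rel=1e-12
        )

    def test_equal_means_null_identity(self, rng):
        y = rng.standard_normal(15)
        p = rng.random(15)
        ll = mixture_loglik(y, p, (0.1, 0.1, 0.9))
        assert ll == pytest.approx(
            float(np.sum(stats.norm.logpdf(y, 0.1, 0.9))), rel=1e-12
        )

    def test_matches_genotype_enumeration(self):
        """Marginal likelihood equals the sum over all 2^n genotype
        configurations weighted by their transmission probabilities."""
        y = np.array([0.2, -0.5, 1.1, 0.7])
        p = np.array([0.9, 0.3, 0.5, 0.8])
        theta = (0.6, -0.2, 0.8)
        total = 0.0
        for config in itertools.product([1, 0], repeat=4):
            w = np.prod([pi if g else 1 - pi for pi, g in zip(p, config)])
            mus = np.where(config, theta[0], theta[1])
            total += w * np.prod(stats.norm.pdf(y, mus, theta[2]))
        assert mixture_loglik(y, p, theta) == pytest.approx(np.log(total),
                                                            rel=1e-12)

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError):
            mixture_loglik([0.0], [0.5], (0.0, 0.0, 0.0))


class TestEMScan:
    def test_em_loglik_nondecreasing(self, rng):
        y = rng.standard_normal(60) + 0.5 * rng.integers(0, 2, 60)
        P = rng.random((60, 3))
        lls = [em_mixture(y, P, max_iter=k)["loglik"].copy()
               for k in range(1, 12)]
        for a, b in zip(lls[:-1], lls[1:]):
            assert np.all(b >= a - 1e-10)

    def test_fully_informative_equals_regression_lod(self, rng):
        n = 120
        x = rng.integers(0, 2, n)
        y = 0.5 * x + rng.standard_normal(n)
        res = scan_mle(y, [0.0], x.astype(float)[:, None])
        rss0 = np.sum((y - y.mean()) ** 2)
        rss1 = np.sum((y - np.where(x == 1, y[x == 1].mean(),
                                    y[x == 0].mean())) ** 2)
        assert res.peak_value == pytest.approx(
            (n / 2) * np.log10(rss0 / rss1), abs=1e-6
        )

    def test_null_simulation_rarely_suggestive(self):
        """Genome-wide max LOD on a null chromosome stays below 1.75 in the
        vast majority of scans, and its mean is near chi2(1)/(4 ln 10)."""
        rng = np.random.default_rng(5)
        n, m = 172, 21
        hits, peak_lods, point_lods = 0, [], []
        for _ in range(120):
            x = rng.integers(0, 2, n).astype(float)
            P = np.repeat(x[:, None], m, axis=1)  # single marker information
            y = rng.standard_normal(n)
            res = scan_mle(y, np.arange(m, dtype=float), P)
            peak_lods.append(res.peak_value)
            point_lods.append(res.profile["LOD"].iloc[0])
            hits += res.peak_value >= 1.75
        assert hits / 120 <= 0.05
        # pointwise null LR ~ chi2(1), so E[LOD] ~= 1 / (2 ln10) = 0.217
        assert np.mean(point_lods) == pytest.approx(1 / (2 * LN10), abs=0.05)

    def test_expected_lod_at_simulated_effect(self):
        """0.6 SD effect at an informative marker, n=172: mean LOD near the
        analytic 86*log10(1/(1-R^2)) ~= 3.2."""
        rng = np.random.default_rng(11)
        n = 172
        lods = []
        for _ in range(150):
            x = rng.integers(0, 2, n).astype(float)
            y = 0.6 * x + rng.standard_normal(n)
            lods.append(scan_mle(y, [0.0], x[:, None]).peak_value)
        r2 = 0.09 / 1.09
        expect = (n / 2) * np.log10(1 / (1 - r2))
        assert np.mean(lods) == pytest.approx(expect, abs=0.45)

    def test_too_few_daughters_rejected(self, rng):
        with pytest.raises(ValueError):
            scan_mle(rng.standard_normal(10), [0.0], rng.random((10, 1)))


class TestClassification:
    @pytest.mark.parametrize(
        "lod,expected",
        [
            (3.4, "highly significant"),
            (1.9, "suggestive"),
            (1.74, "none"),
            (2.0, "significant"),
            (3.0, "significant"),
            (0.0, "none"),
        ],
    )
    def test_lod_classes(self, lod, expected):
        assert classify_lod(lod) == expected

    def test_negative_lod_rejected(self):
        with pytest.raises(ValueError):
            classify_lod(-0.1)


class TestSupportInterval:
    def test_right_clipped_monotone_scan(self):
        pos = np.arange(0.0, 11.0)
        lod = np.linspace(0.0, 5.0, 11)
        lo, hi = support_interval(pos, lod)
        assert hi == 10.0 and lo > 0.0

    def test_quadratic_closed_form(self):
        pos = np.linspace(0.0, 100.0, 2001)
        lod = 4.0 - 0.004 * (pos - 50.0) ** 2  # drops by 1 at 50 +- sqrt(250)
        lo, hi = support_interval(pos, lod)
        root = np.sqrt(1 / 0.004)
        assert lo == pytest.approx(50 - root, abs=0.05)
        assert hi == pytest.approx(50 + root, abs=0.05)

    def test_flat_scan_spans_chromosome(self):
        pos = np.arange(0.0, 5.0)
        lo, hi = support_interval(pos, np.ones(5))
        assert (lo, hi) == (0.0, 4.0)


class TestStandardizedEffect:
    def test_zero_difference(self, rng):
        y = rng.standard_normal(50)
        assert standardized_effect(1.0, 1.0, y) == 0.0

    def test_antisymmetry_under_label_swap(self, rng):
        y = rng.standard_normal(50)
        assert standardized_effect(0.4, -0.1, y) == -standardized_effect(
            -0.1, 0.4, y
        )

    def test_recovers_simulated_effect(self):
        rng = np.random.default_rng(7)
        n = 400
        effs = []
        for _ in range(60):
            x = rng.integers(0, 2, n)
            y = 0.6 * x + rng.standard_normal(n)
            res = scan_mle(y, [0.0], x.astype(float)[:, None])
            effs.append(res.effect_sd_units)
        # contrast of 0.6 residual-SD = 0.6/sqrt(1.09) phenotypic SD
        assert np.mean(effs) == pytest.approx(0.6 / np.sqrt(1.09), abs=0.03)

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError):
            standardized_effect(0.5, 0.0, np.ones(20))


class TestPower:
    def test_size_under_null(self):
        out = estimate_power(effect=0.0, n_reps=3000, seed=21, scan=False)
        assert out["power"] == pytest.approx(0.05, abs=0.02)

    def test_full_information_matches_analytic_ceiling(self):
        # QTL on a fully informative marker: power ~= Phi(0.4 sqrt(43) - 1.96)
        out = estimate_power(qtl_position=0.0, n_reps=4000, seed=22,
                             scan=False)
        expect = stats.norm.cdf(0.4 * np.sqrt(43) - 1.96)
        assert out["power"] == pytest.approx(expect, abs=0.03)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            estimate_power(n=5)
        with pytest.raises(ValueError):
            estimate_power(alpha=1.5)
        with pytest.raises(ValueError):
            estimate_power(effect=-0.1)
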
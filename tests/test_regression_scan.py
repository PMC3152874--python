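import numpy as np
import pytest
from scipy import stats

from lactqtl.linkage import haldane
from lactqtl.mle_scan import scan_mle
from lactqtl.regression_scan import (
    bootstrap_ci,
    permute_thresholds,
    qtl_heritability,
    scan_regression,
    scan_two_qtl,
)


def simulate_chromosome(rng, n=172, n_markers=6, spacing=20.0, qtl_idx=None,
                        effect=0.0, step=2.0):
    """Fully informative marker chromosome with an optional marker QTL."""
    pos = np.arange(n_markers) * spacing
    states = np.empty((n, n_markers), dtype=int)
    states[:, 0] = rng.integers(0, 2, n)
    r = haldane(spacing)
    for j in range(1, n_markers):
        states[:, j] = states[:, j - 1] ^ (rng.random(n) < r)
    grid = np.arange(0.0, pos[-1] + 1e-9, step)
    # P(A) at every grid point from the flanking markers
    P = np.empty((n, grid.size))
    for jq, q in enumerate(grid):
        left = int(np.searchsorted(pos, q, side="right")) - 1
        right = min(left + 1, n_markers - 1)
        if pos[left] == q or left == right:
            P[:, jq] = states[:, left]
            continue
        rl, rr = haldane(q - pos[left]), haldane(pos[right] - q)
        la = np.where(states[:, left] == 1, 1 - rl, rl) * np.where(
            states[:, right] == 1, 1 - rr, rr)
        lm = np.where(states[:, left] == 0, 1 - rl, rl) * np.where(
            states[:, right] == 0, 1 - rr, rr)
        P[:, jq] = la / (la + lm)
    y = rng.standard_normal(n)
    if qtl_idx is not None:
        y = y + effect * states[:, qtl_idx]
    return grid, P, y, states


class TestRegressionScan:
    def test_anova_oracle_at_informative_marker(self):
        """F at a fully informative marker equals hand-computed one-way
        ANOVA on the two transmitted-allele groups."""
        y = np.array([3.1, 2.8, 3.5, 3.0, 2.1, 1.9, 2.4, 2.2] * 5)
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0] * 5)
        ya, ym = y[x == 1], y[x == 0]
        n = y.size
        ssb = len(ya) * (ya.mean() - y.mean()) ** 2 + len(ym) * (
            ym.mean() - y.mean()) ** 2
        ssw = ((ya - ya.mean()) ** 2).sum() + ((ym - ym.mean()) ** 2).sum()
        f_anova = (ssb / 1) / (ssw / (n - 2))
        res = scan_regression(y, [0.0], x.astype(float)[:, None])
        assert res.peak_value == pytest.approx(f_anova, rel=1e-12)

    def test_null_f_near_unity(self):
        rng = np.random.default_rng(3)
        grid, P, y, _ = simulate_chromosome(rng)
        res = scan_regression(y, grid, P)
        finite = res.profile["F"].dropna()
        assert finite.mean() < 3.0  # near its 1-df null expectation

    def test_peak_concordant_with_mle(self):
        rng = np.random.default_rng(9)
        grid, P, y, _ = simulate_chromosome(rng, qtl_idx=2, effect=0.8)
        reg = scan_regression(y, grid, P)
        mle = scan_mle(y, grid, P)
        assert abs(reg.peak_position - mle.peak_position) <= 4.0
        assert abs(reg.peak_position - 40.0) <= 10.0

    def test_lod_f_consistency_at_informative_positions(self):
        rng = np.random.default_rng(13)
        n = 100
        x = rng.integers(0, 2, n).astype(float)
        y = 0.4 * x + rng.standard_normal(n)
        reg = scan_regression(y, [0.0], x[:, None])
        mle = scan_mle(y, [0.0], x[:, None])
        lod_from_f = (n / 2) * np.log10(1 + reg.peak_value / (n - 2))
        assert mle.peak_value == pytest.approx(lod_from_f, abs=1e-6)

    def test_monomorphic_position_skipped(self, rng):
        y = rng.standard_normal(40)
        P = np.column_stack([np.full(40, 0.5), rng.integers(0, 2, 40)])
        res = scan_regression(y, [0.0, 10.0], P)
        assert bool(res.profile["skipped"].iloc[0])
        assert res.peak_position == 10.0


class TestPermutationThresholds:
    def test_bit_reproducible_under_seed(self, rng):
        grid, P, y, _ = simulate_chromosome(np.random.default_rng(2), n=80)
        t1 = permute_thresholds(y, grid, P, n=200, seed=42)
        t2 = permute_thresholds(y, grid, P, n=200, seed=42)
        assert t1.thresholds == t2.thresholds

    def test_thresholds_ordered_in_alpha_and_scope(self):
        grid, P, y, _ = simulate_chromosome(np.random.default_rng(4), n=80)
        t = permute_thresholds(y, grid, P, n=400, seed=1)
        assert t.threshold("chromosome", 0.01) >= t.threshold("chromosome", 0.05)
        assert t.threshold("experiment", 0.05) >= t.threshold("chromosome", 0.05)

    def test_quantile_convergence_small_vs_large_n(self):
        grid, P, y, _ = simulate_chromosome(np.random.default_rng(6), n=100)
        t_small = permute_thresholds(y, grid, P, n=100, seed=3)
        t_large = permute_thresholds(y, grid, P, n=1000, seed=3)
        assert t_small.threshold() == pytest.approx(t_large.threshold(),
                                                    rel=0.25)

    def test_invariant_to_daughter_relabeling(self):
        """Permutation null only depends on (y, X) jointly, so identical
        reordering of both leaves thresholds unchanged."""
        rng = np.random.default_rng(8)
        grid, P, y, _ = simulate_chromosome(rng, n=60)
        order = np.random.default_rng(1).permutation(60)
        t1 = permute_thresholds(y, grid, P, n=1000, seed=5)
        t2 = permute_thresholds(y[order], grid, P[order], n=1000, seed=5)
        for scope, alpha in [("chromosome", 0.05), ("chromosome", 0.01)]:
            assert t1.threshold(scope, alpha) == pytest.approx(
                t2.threshold(scope, alpha), rel=0.15
            )

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            permute_thresholds(rng.standard_normal(40), [0.0],
                               rng.random((40, 1)), n=50)


class TestBootstrap:
    def test_large_effect_ci_collapses_to_marker(self):
        rng = np.random.default_rng(14)
        grid, P, y, _ = simulate_chromosome(rng, qtl_idx=2, effect=2.0)
        out = bootstrap_ci(y, grid, P, n=300, seed=7)
        lo, hi = out["ci"]
        assert 40.0 - 6.0 <= lo <= 40.0 <= hi <= 40.0 + 6.0

    def test_null_ci_spans_most_of_chromosome(self):
        rng = np.random.default_rng(15)
        grid, P, y, _ = simulate_chromosome(rng)
        out = bootstrap_ci(y, grid, P, n=300, seed=8)
        lo, hi = out["ci"]
        assert hi - lo > 0.5 * (grid[-1] - grid[0])

    def test_bit_reproducible(self):
        rng = np.random.default_rng(16)
        grid, P, y, _ = simulate_chromosome(rng, n=60)
        a = bootstrap_ci(y, grid, P, n=100, seed=9)
        b = bootstrap_ci(y, grid, P, n=100, seed=9)
        assert np.array_equal(a["peaks"], b["peaks"])


class TestHeritability:
    def test_equal_mean_squares_zero(self):
        assert qtl_heritability(1.0, 1.0, 10, 10) == 0.0

    def test_arithmetic(self):
        assert qtl_heritability(0.95, 1.0, 1, 1) == pytest.approx(0.05)

    def test_negative_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert qtl_heritability(1.1, 1.0, 1, 1) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            qtl_heritability(0.0, 1.0, 1, 1)
        with pytest.raises(ValueError):
            qtl_heritability(1.0, 1.0, 0, 1)

    def test_expected_value_for_marker_qtl(self):
        """0.6 SD marker QTL at n=172: h_QTL centred near
        delta^2/4 / (1 + delta^2/4) ~= 0.083."""
        rng = np.random.default_rng(17)
        n = 172
        hs = []
        for _ in range(150):
            x = rng.integers(0, 2, n).astype(float)
            y = 0.6 * x + rng.standard_normal(n)
            res = scan_regression(y, [0.0], x[:, None])
            hs.append(res.metadata["heritability"])
        assert np.mean(hs) == pytest.approx(0.09 / 1.09, abs=0.015)
        assert 0.031 <= np.mean(hs) <= 0.089


class TestTwoQTL:
    def test_recovers_repulsion_pair(self):
        """Two linked QTL of opposite sign (repulsion phase) are recovered
        with opposite-sign effects at roughly the right positions."""
        rng = np.random.default_rng(19)
        grid, P, y0, states = simulate_chromosome(rng, n=400, n_markers=6)
        y = y0 + 0.8 * states[:, 1] - 0.7 * states[:, 4]
        res = scan_two_qtl(y, grid, P)
        assert res.phase == "repulsion"
        assert res.effect_a_sd * res.effect_b_sd < 0
        assert abs(res.position_a - 20.0) <= 15.0
        assert abs(res.position_b - 80.0) <= 15.0
        assert res.f_2v1 > 4.0

    def test_rss_nesting_invariants(self):
        rng = np.random.default_rng(20)
        grid, P, y, _ = simulate_chromosome(rng)
        res = scan_two_qtl(y, grid, P)
        assert res.rss2 <= res.rss1 <= res.rss0
        assert res.f_2v0 >= 0
        assert res.position_b - res.position_a >= 5.0

    def test_single_qtl_data_small_f2v1(self):
        """With one true QTL the 2-vs-1 F is usually modest."""
        rng = np.random.default_rng(21)
        count = 0
        for _ in range(20):
            grid, P, y, _ = simulate_chromosome(rng, qtl_idx=2, effect=0.6)
            res = scan_two_qtl(y, grid, P)
            count += res.f_2v1 < stats.f.ppf(0.95, 1, 169) * 2.5
        assert count >= 16

    def test_too_few_positions_rejected(self, rng):
        with pytest.raises(ValueError):
            scan_two_qtl(rng.standard_normal(40), [0.0, 1.0],
                         rng.random((40, 2)))
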
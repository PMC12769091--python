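"""Closed-form specificity and entropy bounds on the product ensemble."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import templimits as tl
from templimits.bounds import _h_of_m
from templimits.steady_state import ConcentrationProfile


def oracle_h(m, M, dG):
    """Independent transcription of the two-level ensemble entropy."""
    a = math.exp(-dG)
    denom = m + (M - m) * a
    p_hi, p_lo = 1.0 / denom, a / denom
    h = 0.0
    if p_hi > 0:
        h -= m * p_hi * math.log(p_hi)
    if p_lo > 0 and M > m:
        h -= (M - m) * p_lo * math.log(p_lo)
    return h


class TestProductDistribution:
    def test_uniform(self):
        net = tl.make_symmetric_network(4, [tl.PathwaySpec(1, 0.0)], seed=0)
        prof = ConcentrationProfile({z: 1.0 for z in net.product_ids})
        dist = tl.product_distribution(prof, net)
        assert np.allclose(dist.p, 0.25)
        assert dist.entropy == pytest.approx(math.log(4))
        assert dist.info == pytest.approx(0.0, abs=1e-12)

    def test_delta_distribution(self):
        net = tl.make_symmetric_network(3, [tl.PathwaySpec(1, 0.0)], seed=0)
        c = {z: 0.0 for z in net.product_ids}
        c[net.product_ids[0]] = 2.0
        dist = tl.product_distribution(ConcentrationProfile(c), net)
        assert dist.p_max == 1.0
        assert dist.entropy == 0.0
        assert dist.info == pytest.approx(math.log(3))

    def test_2_1_1_distribution(self):
        net = tl.make_symmetric_network(3, [tl.PathwaySpec(1, 0.0)], seed=0)
        c = dict(zip(net.product_ids, [2.0, 1.0, 1.0]))
        dist = tl.product_distribution(ConcentrationProfile(c), net)
        assert dist.p == pytest.approx([0.5, 0.25, 0.25])
        # direct-summation oracle
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert dist.entropy == pytest.approx(expected)
        assert expected == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_rejected(self):
        net = tl.make_symmetric_network(2, [tl.PathwaySpec(1, 0.0)], seed=0)
        with pytest.raises(ValueError):
            tl.product_distribution(
                ConcentrationProfile({z: 0.0 for z in net.product_ids}), net
            )


class TestSpecificityBound:
    def test_no_drive_gives_uniform(self):
        p_max, p_low = tl.specificity_bound(16, 0.0)
        assert p_max == pytest.approx(1 / 16)
        assert p_low == pytest.approx(1 / 16)

    def test_trna_worked_example(self):
        """M = 400 at ΔG̃ = 17.50 k_BT leaves a total error near 1e-5."""
        dG = tl.required_delta_G(400, 1e-5)
        p_max, _ = tl.specificity_bound(400, dG)
        assert 1 - p_max == pytest.approx(1e-5, rel=1e-9)

    def test_half_maximum_at_ln_M_minus_1(self):
        M = 2**30
        p_max, p_low = tl.specificity_bound(M, math.log(M - 1))
        assert p_max == pytest.approx(0.5, abs=1e-12)
        assert p_low == pytest.approx(p_max * math.exp(-math.log(M - 1)))

    def test_single_product_rejected(self):
        with pytest.raises(ValueError):
            tl.specificity_bound(1, 1.0)

    @settings(deadline=None, derandomize=True)
    @given(dG=st.floats(0.0, 200.0))
    def test_monotone_and_bounded(self, dG):
        for M in (2, 400, 2**40, 2**63):
            p_max, p_low = tl.specificity_bound(M, dG)
            assert 1.0 / M <= p_max + 1e-15
            assert p_max <= 1.0
            p2, _ = tl.specificity_bound(M, dG + 0.5)
            assert p2 >= p_max
            assert p_low == pytest.approx(math.exp(-dG) * p_max)


class TestRequiredDeltaG:
    def test_trna_value(self):
        dG = tl.required_delta_G(400, 1e-5)
        assert dG == pytest.approx(17.50, abs=0.01)
        assert dG >= 17.0
        # the large-M heuristic ln M is far smaller
        assert round(math.log(400)) == 6

    def test_uniform_error_needs_no_drive(self):
        M = 50
        assert tl.required_delta_G(M, (M - 1) / M) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bisection_oracle(self):
        M, target = 400, 1e-3
        lo, hi = 0.0, 100.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            p_max, _ = tl.specificity_bound(M, mid)
            if 1 - p_max > target:
                lo = mid
            else:
                hi = mid
        assert tl.required_delta_G(M, target) == pytest.approx(lo, abs=1e-10)

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError):
            tl.required_delta_G(400, 0.9999)


class TestEntropyBound:
    def test_zero_drive_is_flat(self):
        M = 64
        res = tl.entropy_bound(M, 0.0)
        assert res.h_min == pytest.approx(math.log(M))
        assert res.m_min == 1  # smallest-m tie-break
        assert np.allclose(res.h_of_m(np.arange(1, M + 1)), math.log(M))

    def test_formula_matches_direct_summation_oracle(self):
        M, dG = 500, 3.0
        for m in (1, 2, 17, 250, 499, 500):
            assert _h_of_m(m, M, dG) == pytest.approx(oracle_h(m, M, dG), rel=1e-12)

    def test_endpoint_h_of_M_is_ln_M(self):
        for M, dG in ((10, 1.0), (1000, 7.5)):
            res = tl.entropy_bound(M, dG)
            assert float(res.h_of_m(M)) == pytest.approx(math.log(M))
            assert res.h_min <= math.log(M) + 1e-12

    @pytest.mark.parametrize("dG_factor", [0.2, 0.5, 0.8, 1.2])
    def test_integer_minimum_matches_exhaustive_scan(self, dG_factor):
        M = 2**10
        dG = dG_factor * math.log(M)
        res = tl.entropy_bound(M, dG)
        h_all = [oracle_h(m, M, dG) for m in range(1, M + 1)]
        m_best = 1 + min(range(M), key=h_all.__getitem__)
        assert res.m_min == m_best
        assert res.h_min == pytest.approx(h_all[m_best - 1], rel=1e-10)

    def test_large_M_search_matches_chunked_scan(self):
        """Convexity search above the scan limit against a chunked oracle."""
        M = 12_000_000
        dG = 0.4 * math.log(M)
        res = tl.entropy_bound(M, dG)
        best_m, best_h = None, math.inf
        for start in range(1, M + 1, 10**6):
            m = np.arange(start, min(start + 10**6, M + 1))
            h = _h_of_m(m, M, dG)
            j = int(np.argmin(h))
            if h[j] < best_h:
                best_h, best_m = float(h[j]), int(m[j])
        assert res.m_min == best_m
        assert res.h_min == pytest.approx(best_h, rel=1e-12)

    def test_p_high_above_half_below_ln_M(self):
        """Entropy minimization keeps p_high > 0.5 even at ΔG̃ = 0.5 ln M."""
        M = 2**20
        res = tl.entropy_bound(M, 0.5 * math.log(M))
        assert res.p_high > 0.5
        assert res.m_min > 1
        assert res.m_min / M < 0.01

    def test_continuous_relaxation_is_weaker_and_close(self):
        for M, ratio in ((2**16, 0.3), (2**16, 0.7), (2**30, 0.5)):
            dG = ratio * math.log(M)
            cont = tl.entropy_bound(M, dG, method="continuous")
            integer = tl.entropy_bound(M, dG, method="integer") if M <= 10**7 else None
            assert cont.method == "continuous"
            if integer is not None:
                assert cont.h_min <= integer.h_min + 1e-12
                assert abs(cont.m_min - integer.m_min) <= 1.0

    def test_overflow_safety_at_2_63(self):
        M = 2**63
        for ratio in (0.1, 0.5, 1.0, 1.5):
            dG = ratio * math.log(M)
            res = tl.entropy_bound(M, dG)
            assert math.isfinite(res.h_min) and math.isfinite(res.p_high)
            p_max, _ = tl.specificity_bound(M, dG)
            assert math.isfinite(p_max)


class TestOverlapThreshold:
    def test_closed_form(self):
        assert tl.overlap_threshold(math.e**math.e) == pytest.approx(math.e + 1)

    def test_too_small_M_rejected(self):
        with pytest.raises(ValueError):
            tl.overlap_threshold(2)

    def test_m_min_collapses_above_threshold(self):
        M = 2**20
        above = tl.entropy_bound(M, tl.overlap_threshold(M) + 2.0)
        at_ln_M = tl.entropy_bound(M, math.log(M))
        assert above.m_min == 1
        assert at_ln_M.m_min > 1

    def test_max_specificity_entropy_dominates_h_min(self):
        for M in (2**4, 2**10, 2**20):
            for ratio in np.linspace(0.05, 2.0, 15):
                dG = ratio * math.log(M)
                h_spec = tl.max_specificity_entropy(M, dG)
                h_min = tl.entropy_bound(M, dG).h_min
                assert h_spec >= h_min - 1e-12
                if dG >= math.log(M) + 2 * math.log(math.log(M)):
                    assert h_spec == pytest.approx(h_min, abs=1e-9)


class TestSweep:
    def test_rows_consistent_with_pointwise_calls(self):
        table = tl.sweep_bounds([16, 1024], [0.0, 0.5, 1.0, 1.5])
        for _, row in table.iterrows():
            M, dG = int(row["M"]), row["ratio"] * math.log(row["M"])
            p_max, _ = tl.specificity_bound(M, dG)
            assert row["p_max"] == pytest.approx(p_max, rel=1e-12)
            res = tl.entropy_bound(M, dG)
            assert row["p_high"] == pytest.approx(res.p_high, rel=1e-12)
            assert row["m_frac"] == pytest.approx(res.m_min / M, rel=1e-12)

    def test_transition_sharpens_toward_half_at_ratio_one(self):
        devs = []
        for M in (2**4, 2**10, 2**20):
            row = tl.sweep_bounds([M], [1.0]).iloc[0]
            devs.append(abs(row["p_max"] - 0.5))
        assert devs == sorted(devs, reverse=True)
        assert devs[-1] < 1e-6

    def test_hmin_norm_non_increasing_in_ratio(self):
        grid = list(np.linspace(0, 3, 100))
        table = tl.sweep_bounds([2**12], grid)
        vals = table["Hmin_norm"].to_numpy()
        assert np.all(np.diff(vals) <= 1e-12)

    def test_zero_ratio_rows_are_uniform(self):
        table = tl.sweep_bounds([8, 64], [0.0])
        for _, row in table.iterrows():
            assert row["p_max"] == pytest.approx(1.0 / row["M"])
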
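import numpy as np
import pytest

from stripekit.config import DetectionParams
from stripekit.contact_io import ContactMatrix, expected_profile, observed_over_expected, sqrt_vc_normalize
from stripekit.scoring import (
    NullDistributions,
    build_null_distributions,
    classify_condition_specific,
    median_pvalue,
    merge_stripe_sets,
    row_pvalue,
    score_stripes,
    stripes_to_table,
    stripiness,
    ScoredStripe,
)
from stripekit.stripe_search import CandidateStripe
from stripekit.synthetic import SyntheticMapSpec, StripeTruth, build_scene

from conftest import random_symmetric


def cm(values, norm_tag="sqrt_vc", resolution=10_000):
    return ContactMatrix("chr1", resolution, np.asarray(values, dtype=float), norm_tag=norm_tag)


def cand(a1, a2, d1, d2, orientation="5p", resolution=10_000):
    return CandidateStripe("chr1", orientation, (a1, a2), (d1, d2), resolution)


# ---------------------------------------------------------------------------
# independent brute-force oracles (explicit loops, explicit rank counts)
# ---------------------------------------------------------------------------

def loop_mean(values, r0, r1, c0, c1):
    nb = values.shape[0]
    r0, r1 = max(r0, 0), min(r1, nb)
    c0, c1 = max(c0, 0), min(c1, nb)
    if r1 <= r0 or c1 <= c0:
        return None
    tot, cnt = 0.0, 0
    for r in range(r0, r1):
        for c in range(c0, c1):
            tot += values[r, c]
            cnt += 1
    return tot / cnt


def oracle_row_pvalue(values, nulls, x1, width, row, d):
    if d not in nulls.samples:
        return 1.0
    N = nulls.smooth_n
    r0, r1 = row - N // 2, row - N // 2 + N
    C = loop_mean(values, r0, r1, x1, x1 + width)
    L = loop_mean(values, r0, r1, x1 - N, x1)
    R = loop_mean(values, r0, r1, x1 + width, x1 + width + N)
    if C is None or (L is None and R is None):
        return None
    # null anchors may coincide with the tested row, producing exact ties;
    # bracket the rank count by +-eps so the oracle is robust to the float
    # summation order while staying tight everywhere else
    eps = 1e-8
    nl, nr = nulls.samples[d]
    lo_ps, hi_ps = [], []
    if L is not None:
        lo_ps.append((1 + sum(1 for x in nl if x >= C - L + eps)) / (1 + nulls.n))
        hi_ps.append((1 + sum(1 for x in nl if x >= C - L - eps)) / (1 + nulls.n))
    if R is not None:
        lo_ps.append((1 + sum(1 for x in nr if x >= C - R + eps)) / (1 + nulls.n))
        hi_ps.append((1 + sum(1 for x in nr if x >= C - R - eps)) / (1 + nulls.n))
    return max(lo_ps), max(hi_ps)


GXL_KERNEL = [[-1, 1], [-2, 2], [-1, 1]]
GXR_KERNEL = [[1, -1], [2, -2], [1, -1]]
GY_KERNEL = [[1, 2, 1], [0, 0, 0], [-1, -2, -1]]


def oracle_stripiness(oe_values, x1, x2, rows, flank_n):
    nb = oe_values.shape[0]
    C, L, R = [], [], []
    for r in rows:
        C.append(loop_mean(oe_values, r, r + 1, x1, x2))
        l = loop_mean(oe_values, r, r + 1, x1 - flank_n, x1)
        rr = loop_mean(oe_values, r, r + 1, x2, x2 + flank_n)
        L.append(0.0 if l is None else l)
        R.append(0.0 if rr is None else rr)
    if not any(C):
        return 0.0
    n = len(rows)
    pad = lambda arr, i: arr[min(max(i, 0), n - 1)]
    total = 0.0
    for i in range(n):
        lc = [[pad(L, i - 1), pad(C, i - 1)], [pad(L, i), pad(C, i)], [pad(L, i + 1), pad(C, i + 1)]]
        cr = [[pad(C, i - 1), pad(R, i - 1)], [pad(C, i), pad(R, i)], [pad(C, i + 1), pad(R, i + 1)]]
        lcr = [[pad(L, i - 1), pad(C, i - 1), pad(R, i - 1)],
               [pad(L, i), pad(C, i), pad(R, i)],
               [pad(L, i + 1), pad(C, i + 1), pad(R, i + 1)]]
        gxl = sum(GXL_KERNEL[a][b] * lc[a][b] for a in range(3) for b in range(2))
        gxr = sum(GXR_KERNEL[a][b] * cr[a][b] for a in range(3) for b in range(2))
        gy = sum(GY_KERNEL[a][b] * lcr[a][b] for a in range(3) for b in range(3))
        total += min(gxl, gxr) - gy
    return float(np.median(C)) * total / n


# ---------------------------------------------------------------------------
# null distributions
# ---------------------------------------------------------------------------

class TestNullDistributions:
    def test_constant_matrix_nulls_are_zero(self):
        m = cm(np.full((60, 60), 2.0))
        nulls = build_null_distributions(m, stripe_width=2, n=50, max_distance=10, seed=3)
        assert nulls.samples
        for left, right in nulls.samples.values():
            np.testing.assert_allclose(left, 0.0, atol=1e-12)
            np.testing.assert_allclose(right, 0.0, atol=1e-12)

    def test_seed_determinism(self, rng):
        m = cm(random_symmetric(rng, 80))
        a = build_null_distributions(m, 2, n=100, max_distance=20, seed=9)
        b = build_null_distributions(m, 2, n=100, max_distance=20, seed=9)
        assert set(a.samples) == set(b.samples)
        for d in a.samples:
            np.testing.assert_array_equal(a.samples[d][0], b.samples[d][0])
            np.testing.assert_array_equal(a.samples[d][1], b.samples[d][1])

    def test_isotropic_matrix_null_mean_near_zero(self, rng):
        m = cm(random_symmetric(rng, 300))
        nulls = build_null_distributions(m, 2, n=1000, max_distance=10, seed=5)
        left, right = nulls.samples[5]
        for sample in (left, right):
            se = sample.std(ddof=1) / np.sqrt(sample.size)
            assert abs(sample.mean()) < 3 * se

    def test_infeasible_distance_unscorable(self):
        m = cm(np.full((30, 30), 1.0))  # too short for d near 30
        nulls = build_null_distributions(m, 2, n=20, max_distance=60, seed=1)
        assert 59 not in nulls.samples
        assert row_pvalue(m, nulls, 5, 2, 20, 59) == 1.0


# ---------------------------------------------------------------------------
# row P-values
# ---------------------------------------------------------------------------

class TestRowPvalue:
    def hand_nulls(self, samples, width=2, smooth_n=1, d=4):
        arr = np.asarray(samples, dtype=float)
        return NullDistributions(stripe_width=width, smooth_n=smooth_n, n=arr.size,
                                 seed=0, samples={d: (arr, arr)})

    def contrast_matrix(self, center=5.0, flank=1.0, n=30, x1=10, width=2):
        v = np.full((n, n), flank)
        v[:, x1 : x1 + width] = center
        return cm(v)

    def test_plus_one_rule_caps_significance(self):
        # observed difference (4.0) beats every stored null value
        nulls = self.hand_nulls(np.linspace(-1, 1, 1000))
        m = self.contrast_matrix()
        assert row_pvalue(m, nulls, 10, 2, 14, 4) == pytest.approx(1 / 1001)

    def test_rank_position_mid_null(self):
        # nulls 0..8; observed diff 4.0 -> 5 of 9 nulls >= 4 -> p = 6/10
        nulls = self.hand_nulls(np.arange(9.0))
        m = self.contrast_matrix(center=5.0, flank=1.0)
        assert row_pvalue(m, nulls, 10, 2, 14, 4) == pytest.approx(6 / 10)

    def test_constant_matrix_row_p_is_one(self):
        m = cm(np.full((40, 40), 3.0))
        nulls = build_null_distributions(m, 2, n=100, max_distance=10, seed=1)
        assert row_pvalue(m, nulls, 10, 2, 14, 4) == 1.0

    def test_less_significant_side_is_reported(self):
        # left flank dark (big C-L), right flank equal to center (C-R = 0)
        v = np.full((40, 40), 1.0)
        v[:, 10:20] = 5.0  # center cols 10:12 and right flank equally bright
        m = cm(v)
        nulls = self.hand_nulls(np.linspace(-1, 1, 99))
        p = row_pvalue(m, nulls, 10, 2, 14, 4)
        # C-R = 0 -> about half the nulls exceed it -> p near 0.5, not 1/100
        assert p > 0.4

    def test_matches_brute_force_oracle_on_random_rows(self, rng):
        m = cm(random_symmetric(rng, 300))
        for width in (1, 2, 4):
            nulls = build_null_distributions(m, width, n=300, max_distance=60, seed=11)
            for _ in range(40):
                x1 = int(rng.integers(6, 280))
                d = int(rng.integers(0, 60))
                row = x1 + d
                if row >= 300:
                    continue
                expect = oracle_row_pvalue(m.values, nulls, x1, width, row, d)
                got = row_pvalue(m, nulls, x1, width, row, d)
                if expect is None:
                    assert np.isnan(got)
                elif isinstance(expect, tuple):
                    lo, hi = expect
                    assert lo <= got <= hi
                else:
                    assert got == expect


# ---------------------------------------------------------------------------
# stripiness
# ---------------------------------------------------------------------------

class TestStripiness:
    def oe_with_band(self, center=3.0, background=1.0, n=60, x1=20, width=3):
        v = np.full((n, n), background)
        v[:, x1 : x1 + width] = center
        return cm(v, norm_tag="oe")

    def test_constant_oe_matrix_scores_zero(self):
        oe = cm(np.full((40, 40), 1.7), norm_tag="oe")
        assert stripiness(cand(10, 12, 10, 30), oe) == 0.0

    @pytest.mark.parametrize("length", [1, 2, 5, 40])
    def test_uniform_stripe_worked_example(self, length):
        # C=3, L=R=1 gives dG=8 per row under replicate padding, M=3 -> S=24
        oe = self.oe_with_band()
        s = cand(20, 23, 20, 20 + length)
        assert stripiness(s, oe) == pytest.approx(24.0, abs=1e-10)

    def test_discontinuous_stripe_penalized(self):
        oe_uniform = self.oe_with_band(center=3.0)
        v = np.array(oe_uniform.values)
        v[1::2, 20:23] = 0.0  # alternate rows of the band switched off
        v[:, :20][v[:, :20] > 0] = 1.0
        oe_alt = cm(v, norm_tag="oe")
        s = cand(20, 23, 20, 50)
        assert stripiness(s, oe_alt) < stripiness(s, oe_uniform)

    def test_requires_oe_matrix(self):
        with pytest.raises(ValueError):
            stripiness(cand(5, 7, 5, 20), cm(np.ones((30, 30)), norm_tag="raw"))

    def test_zero_body_scores_zero(self):
        v = np.ones((40, 40))
        v[:, 10:12] = 0.0
        assert stripiness(cand(10, 12, 10, 30), cm(v, norm_tag="oe")) == 0.0

    def test_matches_brute_force_oracle_on_random_stripes(self, rng):
        for _ in range(50):
            n = 80
            oe = cm(random_symmetric(rng, n), norm_tag="oe")
            width = int(rng.integers(1, 6))
            x1 = int(rng.integers(0, n - width))
            length = int(rng.integers(1, 30))
            orientation = "5p" if rng.random() < 0.5 else "3p"
            if orientation == "5p":
                d1, d2 = x1, min(x1 + length, n)
            else:
                x2 = x1 + width
                d1, d2 = max(x2 - length, 0), x2
            s = cand(x1, x1 + width, d1, d2, orientation)
            rows = list(range(d1, d2))
            flank_n = 5  # 50 kb at 10 kb resolution
            expect = oracle_stripiness(oe.values, x1, x1 + width, rows, flank_n)
            assert stripiness(s, oe) == pytest.approx(expect, abs=1e-10)

    def test_quadratic_scaling_in_oe_magnitude(self, rng):
        # M and the gradients are each linear in the matrix, so S ~ c^2
        oe = cm(random_symmetric(rng, 60) + 0.5, norm_tag="oe")
        s = cand(20, 23, 20, 45)
        base = stripiness(s, oe)
        scaled = stripiness(s, cm(oe.values * 3.0, norm_tag="oe"))
        assert scaled == pytest.approx(9.0 * base, rel=1e-9)


class TestPvalueScalingInvariance:
    def test_pvalues_invariant_under_constant_scaling(self, rng):
        vals = random_symmetric(rng, 200) + 0.2
        s = cand(80, 82, 80, 120)
        params = DetectionParams(n_null=200, null_max_distance=60, seed=7)
        out = {}
        for c in (1.0, 5.0):
            m = cm(vals * c)
            nulls = build_null_distributions(m, 2, n=200, max_distance=60, seed=7)
            out[c], _ = median_pvalue(s, m, nulls)
        assert out[1.0] == out[5.0]


# ---------------------------------------------------------------------------
# score_stripes and set operations
# ---------------------------------------------------------------------------

class TestScoreStripes:
    def test_planted_stripe_significant_on_small_scene(self, small_stripe_scene):
        m, truth = small_stripe_scene
        mn = sqrt_vc_normalize(m)
        s = cand(truth.anchor_start, truth.anchor_end, *truth.domain)
        params = DetectionParams(seed=2)
        (scored,) = score_stripes([s], mn, params, drop_insignificant=False)
        assert scored.median_pvalue < 0.05
        assert scored.stripiness > 0
        assert scored.mean_oe > 1.5

    def test_determinism_same_seed(self, small_stripe_scene):
        m, truth = small_stripe_scene
        mn = sqrt_vc_normalize(m)
        s = cand(truth.anchor_start, truth.anchor_end, *truth.domain)
        params = DetectionParams(seed=5)
        t1 = stripes_to_table(score_stripes([s], mn, params, drop_insignificant=False))
        t2 = stripes_to_table(score_stripes([s], mn, params, drop_insignificant=False))
        assert t1.equals(t2)

    def test_empty_candidates_empty_table_with_header(self):
        table = stripes_to_table([])
        assert len(table) == 0
        assert list(table.columns)[:3] == ["chrom", "anchor_start", "anchor_end"]

    def test_out_of_range_candidate_skipped(self, small_stripe_scene):
        m, _ = small_stripe_scene
        mn = sqrt_vc_normalize(m)
        bad = cand(280, 282, 280, 400)  # domain beyond the 300-bin matrix
        assert score_stripes([bad], mn, DetectionParams(), drop_insignificant=False) == []


def scored_stub(a1, a2, S, orientation="5p"):
    return ScoredStripe(cand(a1, a2, a1, a2 + 30, orientation), 0.01, S, 1.0, 1.0)


class TestMergeStripeSets:
    def test_identical_sets_collapse_to_itself(self):
        a = [scored_stub(100, 103, 5.0)]
        out = merge_stripe_sets(a, [scored_stub(100, 103, 5.0)])
        assert len(out) == 1 and out[0].anchor == (100, 103)

    def test_larger_stripiness_wins(self):
        out = merge_stripe_sets([scored_stub(100, 104, 5.0)], [scored_stub(102, 106, 2.0)])
        assert len(out) == 1 and out[0].anchor == (100, 104)

    def test_disjoint_sets_concatenate(self):
        out = merge_stripe_sets([scored_stub(100, 103, 5.0)], [scored_stub(300, 303, 2.0)])
        assert len(out) == 2

    def test_orientation_separates(self):
        out = merge_stripe_sets([scored_stub(100, 103, 5.0, "5p")], [scored_stub(100, 103, 2.0, "3p")])
        assert len(out) == 2


class TestClassifyConditionSpecific:
    @pytest.mark.parametrize(
        "sa,sb,label",
        [(3.0, -1.0, "A"), (3.0, 1.0, "shared"), (-1.0, 2.5, "B"), (1.0, 1.0, "shared")],
    )
    def test_rule(self, sa, sb, label):
        a = [scored_stub(100, 103, sa)]
        b = [scored_stub(100, 103, sb)]
        assert classify_condition_specific(a, b) == [label]

    def test_misaligned_lists_raise(self):
        with pytest.raises(ValueError):
            classify_condition_specific([scored_stub(1, 2, 1.0)], [])
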
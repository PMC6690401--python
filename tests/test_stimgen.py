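"""Stereogram generator: dot counts, coverage, overlap rule, polarity
conversion, normalisation, and reproducibility invariants."""

import numpy as np
import pytest

from stereopol.corrstats import pearson_r
from stereopol.exceptions import (
    DegenerateImageError,
    GeometryError,
    InfeasibleDensityError,
    PackingInfeasibleError,
    SequencingError,
)
from stereopol.stimgen import (
    BACKGROUND,
    Decorrelate,
    GaussianNoise,
    NoNoise,
    OverlapMode,
    PolarityMode,
    StimulusParams,
    TwoPlanes,
    generate_pair,
    generate_uncorrelated_pair,
    normalize,
    required_dot_count,
    to_same_polarity,
)


# ---------------------------------------------------------------------------
# required_dot_count
# ---------------------------------------------------------------------------


class TestRequiredDotCount:
    def test_no_overlap_linear_formula(self):
        # 100x100 image, 4x4 dots, d = 0.4 -> an average of 250 dots
        assert required_dot_count(0.4, 10_000, 16, OverlapMode.NO_OVERLAP) == 250

    @pytest.mark.parametrize("mode", list(OverlapMode))
    def test_zero_density(self, mode):
        assert required_dot_count(0.0, 10_000, 16, mode) == 0

    def test_overlap_exceeds_no_overlap(self):
        n_no = required_dot_count(0.4, 10_000, 16, OverlapMode.NO_OVERLAP)
        n_ov = required_dot_count(0.4, 10_000, 16, OverlapMode.OVERLAP)
        assert n_ov > n_no

    def test_overlap_formula_against_coverage_simulation(self):
        # independent oracle: scatter N dots at random on a boolean grid and
        # measure the covered fraction; the formula's N should give coverage
        # ~ d up to Monte-Carlo and border-clipping error
        d, W, s = 0.4, 100, 4
        n = required_dot_count(d, W * W, s * s, OverlapMode.OVERLAP)
        rng = np.random.default_rng(0)
        cover = []
        for _ in range(100):
            grid = np.zeros((W, W), dtype=bool)
            xs = rng.integers(0, W, size=n)
            ys = rng.integers(0, W, size=n)
            for x, y in zip(xs, ys):
                grid[y : y + s, x : x + s] = True
            cover.append(grid.mean())
        # border clipping removes ~(s-1)/W of each dot's area per axis
        clip = (1 - (s - 1) / (2 * W)) ** 2
        assert np.mean(cover) == pytest.approx(1 - (1 - d) ** clip, abs=0.01)

    def test_errors(self):
        with pytest.raises(InfeasibleDensityError):
            required_dot_count(1.0, 10_000, 16, OverlapMode.NO_OVERLAP)
        with pytest.raises(GeometryError):
            required_dot_count(0.1, 16, 10_000, OverlapMode.NO_OVERLAP)


# ---------------------------------------------------------------------------
# generate_pair
# ---------------------------------------------------------------------------


class TestGeneratePair:
    def test_zero_density_gives_blank_pair(self):
        params = StimulusParams(density=0.0, seed=0)
        pair = generate_pair(params)
        assert not pair.dots
        assert not pair.left.any() and not pair.right.any()
        assert (pair.left_ids == BACKGROUND).all()

    @pytest.mark.parametrize(
        "mode", [OverlapMode.NO_OVERLAP, OverlapMode.OVERLAP]
    )
    def test_empirical_coverage_matches_density(self, mode):
        # coverage target d, corrected for border clipping of dot footprints
        d, W, s = 0.1, 200, 4
        params = StimulusParams(
            width_px=W, height_px=W, dot_size_px=s, density=d,
            overlap_mode=mode, seed=42,
        )
        cover = [
            (generate_pair(params, i).left_ids != BACKGROUND).mean()
            for i in range(50)
        ]
        clip = (1 - (s - 1) / (2 * W)) ** 2
        assert np.mean(cover) == pytest.approx(d * clip, abs=0.005)

    def test_no_overlap_footprints_disjoint_and_complete(self):
        params = StimulusParams(
            width_px=100, height_px=100, dot_size_px=4, density=0.4,
            overlap_mode=OverlapMode.NO_OVERLAP, seed=3,
        )
        pair = generate_pair(params)
        s, s2 = params.dot_size_px, params.dot_area_px
        W = params.width_px
        for ids in (pair.left_ids, pair.right_ids):
            idx, counts = np.unique(ids[ids != BACKGROUND], return_counts=True)
            # non-overlap: every dot keeps its full (possibly clipped) footprint
            assert len(idx) == len(pair.dots)
            assert (counts <= s2).all()
            unclipped = np.array(
                [
                    pair.dots[i].x_px <= W - s and pair.dots[i].y_px <= W - s
                    for i in idx
                ]
            )
            assert (counts[unclipped] == s2).all()

    def test_mixed_luminances_are_plus_minus_one(self, small_params):
        pair = generate_pair(small_params)
        lums = {d.luminance for d in pair.dots}
        assert lums <= {1.0, -1.0}
        vals = set(np.unique(pair.left)) | set(np.unique(pair.right))
        assert vals <= {-1.0, 0.0, 1.0}

    def test_packing_infeasible_raises(self):
        params = StimulusParams(
            width_px=30, height_px=30, dot_size_px=5, density=0.9,
            overlap_mode=OverlapMode.NO_OVERLAP, seed=0, max_rejects=200,
        )
        with pytest.raises(PackingInfeasibleError) as exc:
            generate_pair(params)
        assert 0 < exc.value.achieved_density < 0.9

    def test_reproducible_and_index_dependent(self, small_params):
        a = generate_pair(small_params, pair_index=0)
        b = generate_pair(small_params, pair_index=0)
        c = generate_pair(small_params, pair_index=1)
        assert (a.left == b.left).all() and (a.right == b.right).all()
        assert not (a.left == c.left).all()


class TestNoiseModels:
    def test_gaussian_zero_sd_identical_to_no_noise(self, small_params):
        from dataclasses import replace

        a = generate_pair(replace(small_params, noise_model=NoNoise()))
        b = generate_pair(replace(small_params, noise_model=GaussianNoise(0.0)))
        assert (a.left == b.left).all() and (a.right == b.right).all()

    def test_two_planes_equal_disparities_reduce_to_uniform(self):
        base = dict(width_px=100, height_px=100, dot_size_px=4, density=0.2, seed=5)
        a = generate_pair(
            StimulusParams(**base, mean_disparity_px=3, noise_model=NoNoise())
        )
        b = generate_pair(
            StimulusParams(**base, mean_disparity_px=0, noise_model=TwoPlanes(3, 3))
        )
        assert (a.left == b.left).all() and (a.right == b.right).all()

    def test_two_planes_split_half_half(self):
        params = StimulusParams(
            width_px=200, height_px=200, density=0.1,
            noise_model=TwoPlanes(0, 4), seed=9,
        )
        pair = generate_pair(params)
        disps = np.array([d.noise_disp_px for d in pair.dots])
        assert set(disps) == {0, 4}
        assert abs((disps == 0).sum() - (disps == 4).sum()) <= 1

    def test_decorrelate_fraction_and_eye_restriction(self):
        params = StimulusParams(
            width_px=100, height_px=100, density=0.3,
            overlap_mode=OverlapMode.OVERLAP, noise_model=Decorrelate(0.5), seed=2,
        )
        pair = generate_pair(params)
        n_corr = sum(d.correlated for d in pair.dots)
        n_dec = sum(not d.correlated for d in pair.dots)
        n = params.n_dots()
        # each decorrelated slot yields one monocular dot per eye
        assert n_dec == 2 * round(0.5 * n)
        assert n_corr + n_dec // 2 == n
        # monocular dots never appear in the other eye's id map
        for d_id, rec in enumerate(pair.dots):
            if rec.eye_restriction.value == "left_only":
                assert not (pair.right_ids == d_id).any()
            elif rec.eye_restriction.value == "right_only":
                assert not (pair.left_ids == d_id).any()


# ---------------------------------------------------------------------------
# polarity conversion and normalisation
# ---------------------------------------------------------------------------


class TestPolarityConversion:
    @pytest.mark.parametrize(
        "target,expected",
        [
            (PolarityMode.WHITE, {0.0, 1.0}),
            (PolarityMode.BLACK, {-1.0, 0.0}),
            (PolarityMode.DARK_DARKER, {-1.0, -0.5, 0.0}),
        ],
    )
    def test_value_mapping(self, small_params, target, expected):
        pair = generate_pair(small_params)
        conv = to_same_polarity(pair, target)
        assert set(np.unique(conv.left)) <= expected
        # layout untouched
        assert (conv.left_ids == pair.left_ids).all()
        assert (np.abs(conv.left) > 0) is not None
        assert ((conv.left != 0) == (pair.left != 0)).all()

    def test_white_black_same_correlation(self):
        params = StimulusParams(
            width_px=100, height_px=100, density=0.4,
            noise_model=GaussianNoise(4.0), seed=11,
        )
        for i in range(20):
            mixed = generate_pair(params, i)
            rw = pearson_r(
                *(lambda p: (p.left, p.right))(normalize(to_same_polarity(mixed, PolarityMode.WHITE)))
            )
            rb = pearson_r(
                *(lambda p: (p.left, p.right))(normalize(to_same_polarity(mixed, PolarityMode.BLACK)))
            )
            assert rw == pytest.approx(rb, abs=1e-12)

    def test_conversion_after_normalisation_rejected(self, small_params):
        pair = normalize(generate_pair(small_params))
        with pytest.raises(SequencingError):
            to_same_polarity(pair, PolarityMode.BLACK)


class TestNormalize:
    def test_zero_mean_unit_variance(self, small_params):
        pair = normalize(generate_pair(small_params))
        for r in (pair.left, pair.right):
            assert abs(r.mean()) < 1e-9
            assert abs(r.var() - 1.0) < 1e-9
        assert pair.normalized

    def test_affine_invariance(self, small_params):
        pair = generate_pair(small_params)
        shifted = pair.copy()
        shifted.left = 3.5 * pair.left + 2.0
        shifted.right = 0.25 * pair.right - 7.0
        a, b = normalize(pair), normalize(shifted)
        assert np.allclose(a.left, b.left) and np.allclose(a.right, b.right)

    def test_constant_raster_rejected(self, small_params):
        pair = generate_pair(small_params)
        pair.left = np.ones_like(pair.left)
        with pytest.raises(DegenerateImageError):
            normalize(pair)


class TestUncorrelatedPair:
    def test_mean_correlation_near_zero(self):
        params = StimulusParams(width_px=100, height_px=100, density=0.3, seed=21)
        rs = []
        for i in range(100):
            pair = normalize(generate_uncorrelated_pair(params, i))
            rs.append(pearson_r(pair.left, pair.right))
        rs = np.asarray(rs)
        se = rs.std(ddof=1) / 10
        assert abs(rs.mean()) < 3 * se

    def test_coverage_matches_density(self):
        d, W, s = 0.3, 100, 4
        params = StimulusParams(width_px=W, height_px=W, dot_size_px=s, density=d, seed=4)
        cover = [
            (generate_uncorrelated_pair(params, i).right_ids != BACKGROUND).mean()
            for i in range(30)
        ]
        clip = (1 - (s - 1) / (2 * W)) ** 2
        assert np.mean(cover) == pytest.approx(d * clip, abs=0.01)

    def test_marked_uncorrelated(self, small_params):
        assert generate_uncorrelated_pair(small_params).uncorrelated
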
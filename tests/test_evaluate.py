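import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    brute_force_modified_dice,
    brute_force_volumes,
    make_worked_example,
    random_nested_triple,
)
from ctpseg.errors import ConfigError, LabelValidationError, PairingError
from ctpseg.evaluate import (
    SUBGROUP_EXCLUDED,
    assd,
    best_threshold,
    compare_models,
    extract_surface,
    iso_contour,
    modified_dice,
    relative_distance_map,
    subgroup_assign,
    volume_decomposition,
)


def toy_1d_band(shape=(9, 9, 9)):
    """Slab embedded in 3D: inner plane x=4, outer slab |x-4| <= 4."""
    inner = np.zeros(shape, dtype=bool)
    outer = np.ones(shape, dtype=bool)
    inner[:, :, 4] = True
    return inner, outer


class TestRelativeDistanceMap:
    def test_one_on_inner_zero_outside_outer(self):
        rng = np.random.default_rng(1)
        outer = np.zeros((8, 8, 8), dtype=bool)
        outer[2:6, 2:6, 2:6] = True
        inner = outer & (rng.random((8, 8, 8)) < 0.5)
        dmap = relative_distance_map(inner, outer, (2.0, 1.0, 1.0))
        assert (dmap.values[inner] == 1.0).all()
        assert (dmap.values[~outer] == 0.0).all()
        assert ((dmap.values >= 0) & (dmap.values <= 1)).all()

    def test_equidistant_midpoint_is_half(self):
        """Voxel two steps from the inner plane and two from the outer
        boundary of the 1-mm slab gets d_r = 2/(2+2) = 0.5."""
        inner, outer = toy_1d_band()
        dmap = relative_distance_map(inner, outer, (1.0, 1.0, 1.0))
        assert dmap.values[4, 4, 6] == pytest.approx(0.5)
        assert dmap.values[4, 4, 2] == pytest.approx(0.5)

    def test_identical_contours_give_binary_map(self):
        rng = np.random.default_rng(3)
        mask = rng.random((6, 6, 6)) < 0.3
        mask[3, 3, 3] = True
        dmap = relative_distance_map(mask, mask.copy(), (1.0, 1.0, 1.0))
        np.testing.assert_array_equal(dmap.values.astype(bool), mask)

    def test_threshold_limits_recover_contours(self):
        inner, outer = toy_1d_band()
        dmap = relative_distance_map(inner, outer, (1.0, 1.0, 1.0))
        np.testing.assert_array_equal(iso_contour(dmap, 0.0), outer)
        np.testing.assert_array_equal(iso_contour(dmap, 1.0), inner)

    def test_violating_inputs_rejected(self):
        inner = np.ones((3, 3, 3), dtype=bool)
        outer = np.zeros((3, 3, 3), dtype=bool)
        with pytest.raises(ConfigError):
            relative_distance_map(np.zeros((3, 3, 3), bool), outer, (1, 1, 1))
        outer2 = np.zeros((3, 3, 3), dtype=bool)
        outer2[0, 0, 0] = True
        with pytest.raises(LabelValidationError):
            relative_distance_map(inner, outer2, (1, 1, 1))

    def test_iso_contours_nested_over_tau_grid(self):
        rng = np.random.default_rng(7)
        taus = np.arange(0.0, 1.01, 0.05)
        for _ in range(10):
            a, inner, outer = random_nested_triple(rng, max_side=12)
            if not outer.any():
                continue
            dmap = relative_distance_map(inner, outer, (1.5, 1.0, 1.0))
            prev = None
            for tau in taus:
                mask = iso_contour(dmap, tau)
                if prev is not None:
                    assert not (mask & ~prev).any()  # shrinking family
                prev = mask

    def test_tau_outside_unit_interval_rejected(self):
        inner, outer = toy_1d_band()
        dmap = relative_distance_map(inner, outer, (1.0, 1.0, 1.0))
        with pytest.raises(ConfigError):
            iso_contour(dmap, 1.2)


class TestModifiedDice:
    def test_matches_brute_force_oracle_on_random_triples(self):
        rng = np.random.default_rng(12345)
        for _ in range(60):
            a, b_inner, b_outer = random_nested_triple(rng)
            expected = brute_force_modified_dice(a, b_inner, b_outer)
            assert modified_dice(a, b_inner, b_outer) == expected

    def test_worked_example_is_ten_twelfths(self):
        a, b_inner, b_outer = make_worked_example()
        assert modified_dice(a, b_inner, b_outer) == pytest.approx(10.0 / 12.0)

    def test_perfect_band_property(self):
        """D = 1 exactly when B_I <= A <= B_O (nonempty B_I)."""
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(100):
            a, b_inner, b_outer = random_nested_triple(rng, max_side=10)
            if not b_inner.any():
                continue
            inside_band = not (b_inner & ~a).any() and not (a & ~b_outer).any()
            score = modified_dice(a, b_inner, b_outer)
            assert (score == 1.0) == inside_band
            hits += 1
            # a prediction constructed inside the band always scores 1
            mid = b_inner | (b_outer & (rng.random(a.shape) < 0.5))
            assert modified_dice(mid, b_inner, b_outer) == 1.0
        assert hits > 10

    def test_reduces_to_standard_dice_when_band_empty(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a, _, b = random_nested_triple(rng, max_side=10)
            denom = a.sum() + b.sum()
            expected = 2.0 * (a & b).sum() / denom if denom else 1.0
            assert modified_dice(a, b, b.copy()) == pytest.approx(expected)

    def test_disjoint_prediction_scores_zero(self):
        b_inner = np.zeros((4, 4, 4), dtype=bool)
        b_inner[0, 0, 0] = True
        a = np.zeros((4, 4, 4), dtype=bool)
        a[3, 3, 3] = True
        assert modified_dice(a, b_inner, b_inner.copy()) == 0.0

    def test_empty_set_conventions(self):
        empty = np.zeros((3, 3, 3), dtype=bool)
        full = np.ones((3, 3, 3), dtype=bool)
        assert modified_dice(empty, empty, empty) == 1.0
        assert modified_dice(empty, empty, full) == 0.0
        assert modified_dice(full, empty, empty) == 0.0


class TestVolumeDecomposition:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            a, b_inner, b_outer = random_nested_triple(rng, max_side=10)
            spacing = (2.0, 1.0, 0.5)
            assert volume_decomposition(a, b_inner, b_outer, spacing) == pytest.approx(
                brute_force_volumes(a, b_inner, b_outer, spacing)
            )

    def test_worked_example_volumes(self):
        a, b_inner, b_outer = make_worked_example()
        correct, missing, excess = volume_decomposition(a, b_inner, b_outer, (1, 1, 1))
        assert correct == pytest.approx(0.005)
        assert missing == pytest.approx(0.001)
        assert excess == pytest.approx(0.001)

    def test_exact_prediction_has_no_missing_or_excess(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[1:4, 1:4, 1:4] = True
        correct, missing, excess = volume_decomposition(m, m, m, (1, 1, 1))
        assert missing == 0.0 and excess == 0.0
        assert correct == pytest.approx(27 / 1000)

    def test_empty_prediction_misses_whole_inner_mask(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[1:4, 1:4, 1:4] = True
        empty = np.zeros_like(m)
        correct, missing, excess = volume_decomposition(empty, m, m, (1, 1, 1))
        assert correct == 0.0 and excess == 0.0
        assert missing == pytest.approx(27 / 1000)


class TestSurfaceAndAssd:
    def test_single_voxel_is_its_own_surface(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        np.testing.assert_array_equal(extract_surface(m), m)

    def test_cube_surface_is_26_voxel_shell(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[1:4, 1:4, 1:4] = True
        surface = extract_surface(m)
        assert surface.sum() == 26
        assert not surface[2, 2, 2]

    def test_distant_voxel_only_adds_itself(self):
        m = np.zeros((9, 9, 9), dtype=bool)
        m[1:4, 1:4, 1:4] = True
        s1 = extract_surface(m)
        m2 = m.copy()
        m2[7, 7, 7] = True
        s2 = extract_surface(m2)
        diff = s2 & ~s1
        assert diff.sum() == 1 and diff[7, 7, 7]

    def test_empty_mask_rejected(self):
        with pytest.raises(ConfigError):
            extract_surface(np.zeros((3, 3, 3), bool))

    def test_identical_surfaces_have_zero_assd(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[1:5, 1:5, 1:5] = True
        s = extract_surface(m)
        assert assd(s, s, (2.0, 1.0, 1.0)) == 0.0

    def test_parallel_planes_three_mm_apart(self):
        a = np.zeros((9, 9, 9), dtype=bool)
        b = np.zeros((9, 9, 9), dtype=bool)
        a[:, :, 2] = True
        b[:, :, 5] = True
        assert assd(a, b, (1.0, 1.0, 1.0)) == pytest.approx(3.0, abs=1e-9)

    def test_symmetry_on_random_surface_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.random((7, 7, 7)) < 0.2
            b = rng.random((7, 7, 7)) < 0.2
            if not a.any() or not b.any():
                continue
            spacing = (1.7, 1.0, 0.6)
            assert assd(a, b, spacing) == pytest.approx(assd(b, a, spacing), abs=1e-12)

    def test_anisotropic_spacing_honoured(self):
        a = np.zeros((9, 3, 3), dtype=bool)
        b = np.zeros((9, 3, 3), dtype=bool)
        a[2] = True
        b[4] = True
        assert assd(a, b, (2.5, 1.0, 1.0)) == pytest.approx(5.0)


class TestBestThreshold:
    def _map_for(self, inner, outer):
        return relative_distance_map(inner, outer, (1.0, 1.0, 1.0))

    def test_plateau_ties_break_to_half(self):
        inner, outer = toy_1d_band()
        cases = [(self._map_for(inner, outer), (inner, outer))]
        sweep = best_threshold(cases, np.arange(0.0, 1.01, 0.05))
        assert sweep.mean_dice.max() == 1.0
        assert sweep.tau_star == 0.5

    def test_singleton_grid(self):
        inner, outer = toy_1d_band()
        sweep = best_threshold([(self._map_for(inner, outer), (inner, outer))], [0.5])
        assert sweep.tau_star == 0.5

    def test_constructed_two_case_preference(self):
        """Ground truth equal to the outer contour rewards lenient
        thresholds: a small tau must win the sweep."""
        inner, outer = toy_1d_band()
        gt = (outer, outer)  # only the full slab is correct
        cases = [(self._map_for(inner, outer), gt)] * 2
        sweep = best_threshold(cases, [0.3, 0.7])
        assert sweep.tau_star == 0.3
        assert sweep.mean_dice[0] > sweep.mean_dice[1]

    def test_winner_dominates_grid(self):
        rng = np.random.default_rng(21)
        cases = []
        for _ in range(3):
            a, inner, outer = random_nested_triple(rng, max_side=10)
            if not outer.any():
                continue
            cases.append((self._map_for(inner, outer), (inner, outer)))
        sweep = best_threshold(cases)
        star_idx = np.where(np.isclose(sweep.taus, sweep.tau_star))[0][0]
        assert np.all(sweep.mean_dice[star_idx] >= sweep.mean_dice - 1e-12)

    def test_empty_grid_rejected(self):
        inner, outer = toy_1d_band()
        with pytest.raises(ConfigError):
            best_threshold([(self._map_for(inner, outer), (inner, outer))], [])


class TestSubgroups:
    @pytest.mark.parametrize(
        "volume,expected",
        [
            (0.5, SUBGROUP_EXCLUDED),
            (0.999, SUBGROUP_EXCLUDED),
            (1.0, "1-10"),
            (5.0, "1-10"),
            (10.0, "10-70"),
            (30.0, "10-70"),
            (70.0, ">70"),
            (120.0, ">70"),
        ],
    )
    def test_half_open_boundaries(self, volume, expected):
        assert subgroup_assign(volume) == expected

    def test_negative_volume_rejected(self):
        with pytest.raises(ConfigError):
            subgroup_assign(-0.1)


class TestCompareModels:
    def test_identical_scores_degenerate(self):
        scores = {"a": np.ones(10), "b": np.ones(10)}
        mc = compare_models(scores)
        assert mc.pairs[0].p_raw == 1.0
        assert mc.pairs[0].degenerate

    def test_uniform_sign_exact_p_value(self):
        """n = 10 differences all of one sign: exact two-sided p = 2/1024."""
        base = np.linspace(0.3, 0.8, 10)
        mc = compare_models({"better": base + 0.05, "worse": base})
        assert mc.pairs[0].p_raw == pytest.approx(2.0 / 1024.0)

    def test_bonferroni_factor_is_number_of_pairs(self):
        rng = np.random.default_rng(17)
        scores = {k: rng.random(12) for k in "abcd"}
        mc = compare_models(scores)
        assert mc.n_comparisons == 6
        for pair in mc.pairs:
            assert pair.p_adjusted == pytest.approx(min(1.0, pair.p_raw * 6))

    def test_mismatched_case_sets_rejected(self):
        with pytest.raises(PairingError):
            compare_models({"a": np.ones(10), "b": np.ones(9)})

    def test_too_few_cases_rejected(self):
        with pytest.raises(ConfigError):
            compare_models({"a": np.ones(3), "b": np.zeros(3)})


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_modified_dice_bounded_and_monotone_in_band(seed):
    """Property: scores stay in [0, 1], and growing the outer contour can
    never lower the score of a fixed prediction."""
    rng = np.random.default_rng(seed)
    a, b_inner, b_outer = random_nested_triple(rng, max_side=8)
    d = modified_dice(a, b_inner, b_outer)
    assert 0.0 <= d <= 1.0
    grown = b_outer | (rng.random(a.shape) < 0.3)
    assert modified_dice(a, b_inner, grown) >= d - 1e-12
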
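import numpy as np
import pytest

import voxabs as vx
from voxabs.tracing import reflection_exponents

from conftest import marching_lengths, random_reflections, random_unit


def single_slice(ny=3, nx=6) -> vx.SegmentedVolume:
    return vx.SegmentedVolume(
        np.full((1, ny, nx), vx.DEFAULT_LABEL_MAP["crystal"], dtype=np.uint8), 1.0)


class TestTraverse:
    def test_worked_2d_example(self):
        """Ray from pixel (0,0) toward (x,y)=(5,2): X drives, n=5, one pixel
        per interval with rows round(0.4*s), and the pixel below the fifth
        one is never recorded."""
        vol = single_slice()
        path = vx.step_coordinates(vol, (0, 0, 0), (0, 2, 5))
        assert path.shape[0] == 6  # s = 0..5
        expected_rows = [round(np.floor(0.4 * s + 0.5)) for s in range(6)]
        assert path[:, 1].tolist() == expected_rows == [0, 0, 1, 1, 2, 2]
        assert path[:, 2].tolist() == list(range(6))
        assert [0, 1, 4] not in path.tolist()  # pixel below e
        rec = vx.traverse(vol, (0, 0, 0), (0, 2, 5))
        assert rec.end_voxel.tolist() == [0, 2, 5]
        assert rec.euclidean_length_voxels == pytest.approx(np.sqrt(29))

    def test_axis_aligned_records_full_row(self):
        vol = vx.SegmentedVolume(
            np.full((3, 3, 11), vx.DEFAULT_LABEL_MAP["crystal"], dtype=np.uint8), 1.0)
        rec = vx.traverse(vol, (1, 2, 0), (0, 0, 1))
        assert rec.total_count == 11
        assert rec.end_voxel.tolist() == [1, 2, 10]

    def test_start_outside_and_zero_direction(self, sphere_phantom):
        with pytest.raises(ValueError, match="outside"):
            vx.traverse(sphere_phantom, (0, 0, 99), (0, 0, 1))
        with pytest.raises(ValueError, match="nonzero"):
            vx.traverse(sphere_phantom, (16, 16, 16), (0, 0, 0))

    def test_end_on_boundary_and_path_in_bounds(self, sphere_phantom, rng):
        cv = vx.crystal_voxels(sphere_phantom)
        dims = np.asarray(sphere_phantom.shape)
        for _ in range(25):
            start = cv[rng.integers(len(cv))]
            path = vx.step_coordinates(sphere_phantom, start, rng.normal(size=3))
            assert np.all(path >= 0) and np.all(path < dims)
            end = path[-1]
            assert np.any((end == 0) | (end == dims - 1))

    def test_matches_marching_oracle_on_most_rays(self, sphere_phantom, rng):
        cv = vx.crystal_voxels(sphere_phantom)
        ok = 0
        n_rays = 40
        for _ in range(n_rays):
            start = cv[rng.integers(len(cv))]
            d = random_unit(rng)
            rec = vx.traverse(sphere_phantom, start, d)
            lengths = vx.path_lengths(rec, 1.0)  # voxel units
            oracle = marching_lengths(sphere_phantom, start, d)
            if all(abs(lengths[m] - oracle[m]) <= 1.0 for m in lengths):
                ok += 1
        assert ok >= 0.95 * n_rays


class TestPathLengths:
    def test_total_is_euclidean_distance(self):
        rec = vx.traverse(single_slice(), (0, 0, 0), (0, 2, 5))
        lengths = vx.path_lengths(rec, 0.3)
        assert sum(lengths.values()) == pytest.approx(np.sqrt(29) * 0.3)

    def test_all_crystal_record(self):
        rec = vx.traverse(single_slice(), (0, 0, 0), (0, 2, 5))
        lengths = vx.path_lengths(rec, 1.0)
        assert lengths["crystal"] == pytest.approx(rec.euclidean_length_voxels)
        assert lengths["liquor"] == lengths["loop"] == lengths["background"] == 0

    def test_hand_computed_proportions(self):
        rec = vx.PathSegmentRecord(
            counts={"crystal": 3, "liquor": 1}, total_count=4,
            start_voxel=np.zeros(3, int), end_voxel=np.array([0, 0, 6]),
            euclidean_length_voxels=6.0)
        lengths = vx.path_lengths(rec, 0.3)
        assert lengths["crystal"] == pytest.approx(1.35)
        assert lengths["liquor"] == pytest.approx(0.45)


class TestVoxelExponent:
    def test_zero_coefficients(self, sphere_phantom):
        coeffs = vx.MaterialCoefficients({m: 0.0 for m in ("crystal", "liquor", "loop")})
        assert vx.voxel_exponent(sphere_phantom, coeffs, (16, 16, 16),
                                 (0, 0, 1), (0, 1, 0)) == 0.0

    def test_homogeneous_cube_hand_value(self):
        vol = vx.SegmentedVolume(
            np.full((11, 11, 11), vx.DEFAULT_LABEL_MAP["crystal"], dtype=np.uint8), 0.3)
        coeffs = vx.MaterialCoefficients({"crystal": 0.01})
        # L1 = L2 = 5 voxels x 0.3 um each way along +-x
        ex = vx.voxel_exponent(vol, coeffs, (5, 5, 5), (0, 0, 1), (0, 0, 1))
        assert ex == pytest.approx(0.03)

    def test_linearity_in_mu(self, sphere_phantom, thermolysin_like_coeffs):
        doubled = thermolysin_like_coeffs.scaled(2.0)
        args = ((16, 16, 16), (0, 0, 1), (0, 1, 0))
        e1 = vx.voxel_exponent(sphere_phantom, thermolysin_like_coeffs, *args)
        e2 = vx.voxel_exponent(sphere_phantom, doubled, *args)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_non_crystal_start_policy(self, sphere_phantom, thermolysin_like_coeffs):
        with pytest.raises(ValueError, match="crystal"):
            vx.voxel_exponent(sphere_phantom, thermolysin_like_coeffs,
                              (0, 0, 0), (0, 0, 1), (0, 1, 0))
        with pytest.warns(vx.tracing.NonCrystalStartWarning):
            vx.voxel_exponent(sphere_phantom, thermolysin_like_coeffs,
                              (0, 0, 0), (0, 0, 1), (0, 1, 0),
                              on_noncrystal="warn")

    def test_kernel_matches_traverse_composition(self, sphere_phantom,
                                                 thermolysin_like_coeffs, rng):
        """The batch kernel must agree with the explicit traverse +
        path_lengths composition."""
        cv = vx.crystal_voxels(sphere_phantom)
        for _ in range(10):
            start = cv[rng.integers(len(cv))]
            inc, dif = random_unit(rng), random_unit(rng)
            fast = vx.voxel_exponent(sphere_phantom, thermolysin_like_coeffs,
                                     start, inc, dif)
            slow = 0.0
            for d in (-inc, dif):
                lengths = vx.path_lengths(
                    vx.traverse(sphere_phantom, start, d),
                    sphere_phantom.voxel_size_um)
                slow += sum(thermolysin_like_coeffs.mu.get(m, 0.0) * l
                            for m, l in lengths.items())
            assert fast == pytest.approx(slow, rel=1e-12)


class TestAbsorptionFactor:
    def test_unity_for_zero_mu(self, sphere_phantom, crystal_list):
        coeffs = vx.MaterialCoefficients({})
        refl = vx.Reflection(np.array([0., 0., 1.]), np.array([0., 1., 0.]))
        assert vx.absorption_factor(sphere_phantom, coeffs, refl,
                                    vx.full_plan(crystal_list)) == 1.0

    def test_single_voxel_volume(self):
        arr = np.zeros((3, 3, 3), dtype=np.uint8)
        arr[1, 1, 1] = vx.DEFAULT_LABEL_MAP["crystal"]
        vol = vx.SegmentedVolume(arr, 0.5)
        coeffs = vx.MaterialCoefficients({"crystal": 0.02})
        refl = vx.Reflection(np.array([0., 0., 1.]), np.array([0., 0., 1.]))
        expected = np.exp(-vx.voxel_exponent(vol, coeffs, (1, 1, 1),
                                             refl.incident, refl.diffracted))
        assert vx.absorption_factor(vol, coeffs, refl, vx.full_plan(vol)) == \
            pytest.approx(expected, rel=1e-15)

    def test_full_plan_equals_bruteforce_mean(self, sphere_phantom,
                                              thermolysin_like_coeffs,
                                              crystal_list):
        refl = vx.Reflection(np.array([0., 0., 1.]), np.array([0., 1., 0.]))
        A = vx.absorption_factor(sphere_phantom, thermolysin_like_coeffs, refl,
                                 vx.full_plan(crystal_list))
        brute = np.mean([np.exp(-vx.voxel_exponent(
            sphere_phantom, thermolysin_like_coeffs, v,
            refl.incident, refl.diffracted)) for v in crystal_list[::25]])
        # spot-check on a systematic subset: the subset mean approximates
        A_sub = vx.absorption_factor(sphere_phantom, thermolysin_like_coeffs,
                                     refl, crystal_list[::25])
        assert A_sub == pytest.approx(brute, rel=1e-12)
        assert 0 < A <= 1

    def test_empty_selection_rejected(self, sphere_phantom, thermolysin_like_coeffs):
        refl = vx.Reflection(np.array([0., 0., 1.]), np.array([0., 1., 0.]))
        with pytest.raises(ValueError, match="no crystal voxels"):
            vx.absorption_factor(sphere_phantom, thermolysin_like_coeffs, refl,
                                 np.empty((0, 3), dtype=np.int64))

    def test_mu_monotonicity(self, sphere_phantom, thermolysin_like_coeffs,
                             crystal_list):
        refl = vx.Reflection(np.array([0., 0., 1.]), np.array([0., 1., 0.]))
        plan = vx.systematic_sample(crystal_list, 0.05)
        base = vx.absorption_factor(sphere_phantom, thermolysin_like_coeffs,
                                    refl, plan)
        for mat in ("crystal", "liquor", "loop"):
            mu = dict(thermolysin_like_coeffs.mu)
            mu[mat] = mu[mat] * 1.5
            higher = vx.absorption_factor(
                sphere_phantom, vx.MaterialCoefficients(mu), refl, plan)
            assert higher < base


class TestRunStandard:
    def test_empty_reflection_list(self, sphere_phantom, thermolysin_like_coeffs,
                                   crystal_list):
        res = vx.run_standard(sphere_phantom, thermolysin_like_coeffs, [],
                              vx.full_plan(crystal_list))
        assert len(res) == 0

    def test_workers_do_not_change_results(self, sphere_phantom,
                                           thermolysin_like_coeffs,
                                           crystal_list, rng):
        refls = random_reflections(rng, 20)
        plan = vx.systematic_sample(crystal_list, 0.02)
        seq = vx.run_standard(sphere_phantom, thermolysin_like_coeffs, refls,
                              plan, workers=1)
        par = vx.run_standard(sphere_phantom, thermolysin_like_coeffs, refls,
                              plan, workers=8)
        np.testing.assert_array_equal(seq.factors, par.factors)

    def test_matches_sequential_per_reflection_calls(self, sphere_phantom,
                                                     thermolysin_like_coeffs,
                                                     crystal_list, rng):
        refls = random_reflections(rng, 15)
        plan = vx.systematic_sample(crystal_list, 0.02)
        res = vx.run_standard(sphere_phantom, thermolysin_like_coeffs, refls, plan)
        singles = [vx.absorption_factor(sphere_phantom, thermolysin_like_coeffs,
                                        r, plan) for r in refls]
        np.testing.assert_array_equal(res.factors, singles)

    def test_single_precision_mode_close_to_double(self, sphere_phantom,
                                                   thermolysin_like_coeffs,
                                                   crystal_list, rng):
        refls = random_reflections(rng, 5)
        plan = vx.systematic_sample(crystal_list, 0.05)
        dd = vx.run_standard(sphere_phantom, thermolysin_like_coeffs, refls, plan)
        ss = vx.run_standard(sphere_phantom, thermolysin_like_coeffs, refls,
                             plan, precision="single")
        np.testing.assert_allclose(ss.factors, dd.factors, rtol=1e-5)

    def test_failure_reports_reflection_index(self, sphere_phantom,
                                              thermolysin_like_coeffs):
        refl = vx.Reflection(np.array([0., 0., 1.]), np.array([0., 1., 0.]))
        bad_plan = np.empty((0, 3), dtype=np.int64)
        with pytest.raises(RuntimeError, match="reflection 0"):
            vx.run_standard(sphere_phantom, thermolysin_like_coeffs, [refl],
                            bad_plan)


class TestSlabClosedForm:
    def test_normal_incidence_forward_scatter(self):
        """All-crystal cuboid, beam normal to a face, 2theta = 0: every
        column sees the full thickness, so A = exp(-mu*T) up to one voxel
        of discretization."""
        nx, h, mu = 21, 0.3, 0.05
        vol = vx.SegmentedVolume(
            np.full((5, 5, nx), vx.DEFAULT_LABEL_MAP["crystal"], dtype=np.uint8), h)
        coeffs = vx.MaterialCoefficients({"crystal": mu})
        refl = vx.Reflection(np.array([0., 0., 1.]), np.array([0., 0., 1.]))
        A = vx.absorption_factor(vol, coeffs, refl, vx.full_plan(vol))
        T = nx * h
        assert abs(np.log(A) + mu * T) <= mu * h + 1e-12
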
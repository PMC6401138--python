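import math

import numpy as np
import pytest

from nanodpk import (
    PathDecomposition,
    Point3,
    Rod,
    Sphere,
    classify_rod_region,
    dti_rod,
    dti_sphere,
    factor_pdr,
    factor_unity,
    gpl,
    mpl,
    sample_in_rod,
    sample_in_sphere,
    scoring_volume_long,
    scoring_volume_short,
)
from nanodpk.materials import RescalingFactor


def segment_sampling_dti(ps, pt, inside_fn, n_steps=100_000):
    """Independent DTI oracle: midpoint-sample the segment, count the
    in-particle fraction of its length."""
    a = np.array([ps.x, ps.y, ps.z])
    b = np.array([pt.x, pt.y, pt.z])
    t = (np.arange(n_steps) + 0.5) / n_steps
    pts = a[None, :] + t[:, None] * (b - a)[None, :]
    frac = inside_fn(pts).mean()
    return frac * np.linalg.norm(b - a)


def inside_sphere(radius):
    return lambda pts: np.einsum("ij,ij->i", pts, pts) <= radius**2


def inside_rod(r, h):
    return lambda pts: (pts[:, 0] ** 2 + pts[:, 1] ** 2 <= r**2) & (
        np.abs(pts[:, 2]) <= h
    )


class TestSampling:
    def test_sphere_uniform_volume_moment(self):
        rng = np.random.default_rng(0)
        pts = sample_in_sphere(Sphere(10.0), rng, size=100_000)
        u = (np.linalg.norm(pts, axis=1) / 10.0) ** 3  # uniform on [0, 1]
        assert abs(u.mean() - 0.5) < 3 * u.std() / math.sqrt(u.size)
        assert np.all(np.linalg.norm(pts, axis=1) <= 10.0)

    def test_rod_containment_and_symmetry(self):
        rng = np.random.default_rng(1)
        pts = sample_in_rod(Rod(3.0, 7.0), rng, size=100_000)
        assert np.all(pts[:, 0] ** 2 + pts[:, 1] ** 2 <= 9.0 + 1e-12)
        assert np.all(np.abs(pts[:, 2]) <= 7.0)
        sem = pts[:, 2].std() / math.sqrt(pts.shape[0])
        assert abs(pts[:, 2].mean()) < 3 * sem

    def test_fixed_seed_reproducible(self):
        a = sample_in_sphere(Sphere(5.0), np.random.default_rng(9), size=100)
        b = sample_in_sphere(Sphere(5.0), np.random.default_rng(9), size=100)
        np.testing.assert_array_equal(a, b)


class TestGpl:
    def test_3_4_5_triangle(self):
        assert gpl(Point3(0, 0, 0), Point3(3, 4, 0)) == 5.0

    def test_zero_and_symmetry(self):
        a, b = Point3(1, 2, 3), Point3(-4, 0, 2)
        assert gpl(a, a) == 0.0
        assert gpl(a, b) == gpl(b, a)


class TestDtiSphere:
    def test_center_source_gives_radius(self):
        s = Sphere(7.0)
        assert dti_sphere(Point3(0, 0, 0), Point3(0, 0, 100), s) == pytest.approx(7.0)

    def test_surface_source_radial_gives_zero(self):
        s = Sphere(7.0)
        assert dti_sphere(Point3(7, 0, 0), Point3(100, 0, 0), s) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_oblique_matches_sampling_oracle(self):
        s = Sphere(5.0)
        ps, pt = Point3(2.0, -1.5, 3.0), Point3(40.0, 13.0, -22.0)
        oracle = segment_sampling_dti(ps, pt, inside_sphere(5.0))
        step = gpl(ps, pt) / 100_000
        assert dti_sphere(ps, pt, s) == pytest.approx(oracle, abs=step)

    def test_preconditions(self):
        s = Sphere(5.0)
        with pytest.raises(ValueError):
            dti_sphere(Point3(6, 0, 0), Point3(10, 0, 0), s)
        with pytest.raises(ValueError):
            dti_sphere(Point3(0, 0, 0), Point3(1, 0, 0), s)

    def test_bounded_by_gpl_and_diameter(self):
        s = Sphere(8.0)
        rng = np.random.default_rng(5)
        for _ in range(200):
            ps = Point3(*sample_in_sphere(s, rng, size=1)[0])
            d = rng.normal(size=3)
            pt_arr = np.array([ps.x, ps.y, ps.z]) + d / np.linalg.norm(d) * rng.uniform(
                20, 200
            )
            if np.dot(pt_arr, pt_arr) <= s.radius**2:
                continue
            pt = Point3(*pt_arr)
            d_val = dti_sphere(ps, pt, s)
            assert 0.0 <= d_val <= min(gpl(ps, pt), 2 * s.radius) + 1e-9


class TestClassifyRodRegion:
    def test_on_axis_is_long(self):
        rod = Rod(2.0, 5.0)
        assert classify_rod_region(Point3(0, 0, 10.0), rod) == "long_axis"

    def test_equatorial_is_short(self):
        rod = Rod(2.0, 5.0)
        assert classify_rod_region(Point3(4.0, 0, 0), rod) == "short_axis"

    def test_cone_boundary_is_neither(self):
        rod = Rod(2.0, 5.0)
        # on the long-axis cone: rho/|z| = r/h exactly
        assert classify_rod_region(Point3(4.0, 0, 10.0), rod) == "neither"

    def test_inside_rejected(self):
        rod = Rod(2.0, 5.0)
        with pytest.raises(ValueError):
            classify_rod_region(Point3(0, 0, 0), rod)

    def test_partition_no_overlap(self):
        rod = Rod(3.0, 6.0)
        rng = np.random.default_rng(11)
        labels = set()
        for _ in range(500):
            p = Point3(*rng.uniform(-30, 30, size=3))
            if rod.contains(p):
                continue
            lab = classify_rod_region(p, rod)
            assert lab in {"long_axis", "short_axis", "neither"}
            # cross-check against the defining inequalities
            rho = math.hypot(p.x, p.y)
            in_long = abs(p.z) > rod.half_length and rho / abs(p.z) < 0.5
            in_short = rho > rod.radius and abs(p.z) / rho < 2.0
            assert (lab == "long_axis") == in_long
            assert (lab == "short_axis") == in_short
            labels.add(lab)
        # away from the measure-zero cone boundary the two regions tile the
        # exterior, so random points only ever see the two axis labels
        assert labels == {"long_axis", "short_axis"}


class TestDtiRod:
    def test_axial_exit_through_cap(self):
        rod = Rod(2.0, 5.0)
        assert dti_rod(Point3(0, 0, 0), Point3(0, 0, 15.0), rod) == pytest.approx(5.0)

    def test_radial_exit_through_wall(self):
        rod = Rod(2.0, 5.0)
        assert dti_rod(Point3(0, 0, 0), Point3(6.0, 0, 0), rod) == pytest.approx(2.0)

    def test_oblique_corner_crossing_matches_oracle(self):
        rod = Rod(2.0, 5.0)
        ps, pt = Point3(0.5, -0.3, 4.0), Point3(8.0, 2.0, 9.0)
        oracle = segment_sampling_dti(ps, pt, inside_rod(2.0, 5.0))
        step = gpl(ps, pt) / 100_000
        assert dti_rod(ps, pt, rod) == pytest.approx(oracle, abs=step)

    def test_preconditions(self):
        rod = Rod(2.0, 5.0)
        with pytest.raises(ValueError):
            dti_rod(Point3(3.0, 0, 0), Point3(6.0, 0, 0), rod)
        with pytest.raises(ValueError):
            dti_rod(Point3(0, 0, 0), Point3(1.0, 0, 0), rod)

    def test_random_pairs_bounded(self):
        rod = Rod(2.5, 6.0)
        rng = np.random.default_rng(3)
        bound = 2 * math.sqrt(rod.radius**2 + rod.half_length**2)
        for _ in range(200):
            ps = Point3(*sample_in_rod(rod, rng, size=1)[0])
            pt = Point3(*rng.uniform(-40, 40, size=3))
            if rod.contains(pt):
                continue
            d_val = dti_rod(ps, pt, rod)
            assert 0.0 <= d_val <= min(gpl(ps, pt), bound) + 1e-9


class TestMpl:
    @pytest.mark.parametrize(
        "g,d,alpha,expected",
        [(100.0, 10.0, 1.0, 100.0), (100.0, 0.0, 19.3, 100.0), (100.0, 10.0, 9.6, 186.0)],
    )
    def test_direct_substitution(self, g, d, alpha, expected):
        f = RescalingFactor("pdr", alpha) if alpha > 1 else factor_unity()
        assert mpl(g, d, f) == pytest.approx(expected)

    def test_monotone_in_alpha(self):
        alphas = [1.0, 2.0, 8.2, 19.3]
        vals = [mpl(50.0, 10.0, RescalingFactor("pdr", a)) for a in alphas]
        assert vals == sorted(vals)
        assert vals[0] == 50.0  # equals gpl iff alpha = 1

    def test_dti_above_gpl_rejected(self):
        with pytest.raises(ValueError):
            mpl(10.0, 11.0, factor_pdr())

    def test_path_decomposition_invariants(self):
        with pytest.raises(ValueError):
            PathDecomposition(gpl=10.0, dti=11.0, mpl=10.0)
        with pytest.raises(ValueError):
            PathDecomposition(gpl=10.0, dti=5.0, mpl=9.0)


class TestScoringVolumes:
    def rejection_volume(self, inside, box_lo, box_hi, n=200_000, seed=0):
        rng = np.random.default_rng(seed)
        lo, hi = np.asarray(box_lo, float), np.asarray(box_hi, float)
        pts = lo + (hi - lo) * rng.random((n, 3))
        frac = inside(pts).mean()
        box = np.prod(hi - lo)
        err = 3 * box * math.sqrt(max(frac * (1 - frac), 1e-12) / n)
        return frac * box, err

    def test_long_axis_frustum_matches_mc(self):
        rod = Rod(2.0, 5.0)
        d, t = 3.0, 1.0
        tan_w = rod.radius / rod.half_length

        def inside(pts):
            rho2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
            az = np.abs(pts[:, 2])
            return (az >= rod.half_length + d) & (az < rod.half_length + d + t) & (
                rho2 < (az * tan_w) ** 2
            )

        r_max = (rod.half_length + d + t) * tan_w + 0.5
        z_max = rod.half_length + d + t + 0.5
        mc, err = self.rejection_volume(
            inside, (-r_max, -r_max, -z_max), (r_max, r_max, z_max)
        )
        assert scoring_volume_long(d, rod, t) == pytest.approx(mc, abs=err)

    def test_short_axis_hollow_cylinder_matches_mc(self):
        rod = Rod(2.0, 5.0)
        d, t = 1.5, 1.0

        def inside(pts):
            s = np.sqrt(pts[:, 0] ** 2 + pts[:, 1] ** 2)
            az = np.abs(pts[:, 2])
            return (s >= rod.radius + d) & (s < rod.radius + d + t) & (
                az < s * rod.half_length / rod.radius
            )

        s_max = rod.radius + d + t + 0.5
        z_max = s_max * rod.half_length / rod.radius + 0.5
        mc, err = self.rejection_volume(
            inside, (-s_max, -s_max, -z_max), (s_max, s_max, z_max), seed=4
        )
        assert scoring_volume_short(d, rod, t) == pytest.approx(mc, abs=err)

    def test_thin_slab_limits(self):
        rod = Rod(2.0, 5.0)
        d, t = 4.0, 1e-7
        tan_w = rod.radius / rod.half_length
        v_t = scoring_volume_long(d, rod, t) / t
        assert v_t == pytest.approx(
            2 * math.pi * tan_w**2 * (rod.half_length + d) ** 2, rel=1e-5
        )
        v_s = scoring_volume_short(d, rod, t) / t
        assert v_s == pytest.approx(
            4 * math.pi * rod.half_length * (rod.radius + d) ** 2 / rod.radius,
            rel=1e-5,
        )

    def test_monotone_and_positive(self):
        rod = Rod(1.0, 4.0)
        vols = [scoring_volume_long(d, rod) for d in (0.0, 1.0, 2.0, 5.0)]
        assert vols == sorted(vols)
        assert all(v > 0 for v in vols)
        assert scoring_volume_short(0.0, rod) > 0

    def test_invalid_arguments(self):
        rod = Rod(1.0, 4.0)
        with pytest.raises(ValueError):
            scoring_volume_long(-1.0, rod)
        with pytest.raises(ValueError):
            scoring_volume_short(0.0, rod, t=0.0)
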
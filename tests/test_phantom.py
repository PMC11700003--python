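"""Phantom builders, raytracing and transport-line lattices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccbrachy import phantom as ph


def test_case_a_full_resolution_geometry():
    p = ph.build_case("A", 0.1)
    assert p.shape == (301, 301, 301)
    assert p.voxel_size == 0.1
    mask = p.box_mask()
    assert mask.sum() == 13671  # 21 x 21 x 31 voxels
    lo = p.box.center[0] - p.box.half_extents[0]
    hi = p.box.center[0] + p.box.half_extents[0]
    assert lo == pytest.approx(4.95)
    assert hi == pytest.approx(7.05)
    # box faces land exactly on voxel boundaries
    for face in (lo, hi):
        k = (face - p.origin[0]) / p.voxel_size
        assert abs(k - round(k)) < 1e-9


def test_case_c_air_density():
    p = ph.build_case("C", 0.1)
    mask = p.box_mask()
    assert np.allclose(p.density[mask], 1.20e-3)
    assert p.box.center == (3.0, 0.0, 0.0)


def test_water_box_is_identity():
    p = ph.build_case("A", 0.2, 16.2, snap_to_grid=True, box_medium="water")
    w = ph.build_water_phantom(0.2, 16.2)
    np.testing.assert_array_equal(p.medium_index, w.medium_index)
    np.testing.assert_array_equal(p.density, w.density)


def test_misaligned_voxel_size_errors():
    with pytest.raises(ValueError, match="boundary"):
        ph.build_case("A", 0.2, 16.2)


def test_snapped_desk_geometry():
    p = ph.build_case("A", 0.2, 16.2, snap_to_grid=True)
    assert p.shape == (81, 81, 81)
    assert p.box.half_extents == (1.1, 1.1, 1.5)
    assert p.box_mask().sum() == 11 * 11 * 15


def test_case_builders_deterministic():
    a = ph.build_case("B", 0.2, 16.2, snap_to_grid=True)
    b = ph.build_case("B", 0.2, 16.2, snap_to_grid=True)
    np.testing.assert_array_equal(a.medium_index, b.medium_index)
    np.testing.assert_array_equal(a.density, b.density)


class TestRadiologicalPath:
    def test_homogeneous_closed_form(self):
        p = ph.build_water_phantom(0.2, 16.2)
        mu = np.array([0.1, 0.0, 0.0])
        assert ph.radiological_path(p, (0, 0, 0), (5, 0, 0), mu) == \
            pytest.approx(0.5, rel=1e-9)

    def test_case_a_segment_oracle(self):
        """Hand-summed segment lengths through the bone box on the +x
        axis: water [0, 4.95], bone [4.95, 7.05], water [7.05, 10]."""
        p = ph.build_case("A", 0.1)
        mu = p.mu_linear_per_medium(0.3565)
        od = ph.radiological_path(p, (0, 0, 0), (10, 0, 0), mu)
        iw = 0  # water is medium 0; find bone index
        ib = [m.name for m in p.media].index("cortical_bone")
        expected = mu[iw] * (4.95 + 2.95) + mu[ib] * 2.1
        assert od == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.tuples(*[st.floats(-7.9, 7.9) for _ in range(6)]))
    def test_reversal_symmetry(self, pts):
        p = ph.build_water_phantom(0.4, 16.4)
        mu = np.array([0.11, 0.2, 0.001])
        p0, p1 = pts[:3], pts[3:]
        a = ph.radiological_path(p, p0, p1, mu)
        b = ph.radiological_path(p, p1, p0, mu)
        assert a == pytest.approx(b, abs=1e-9)

    def test_zero_length(self):
        p = ph.build_water_phantom(0.4, 16.4)
        assert ph.radiological_path(p, (1, 1, 1), (1, 1, 1),
                                    np.array([0.1, 0, 0])) == 0.0


class TestConeDirections:
    @pytest.mark.parametrize("m", [8, 72, 240, 320])
    def test_partition(self, m):
        dirs, dom = ph.cone_directions(m)
        assert len(dirs) == m
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0,
                                   atol=1e-12)
        assert dom.sum() == pytest.approx(4 * np.pi, abs=1e-9)
        # zenith-uniform: mean z-component near zero
        assert abs((dirs[:, 2] * dom).sum()) < 0.2


class TestLineLattice:
    def test_axis_direction(self):
        p = ph.build_water_phantom(1.0, 11.0)
        lat = ph.build_line_lattice(p, np.array([[1.0, 0, 0]]))[0]
        np.testing.assert_allclose(lat.step_length, 1.0, atol=1e-9)
        assert (lat.dlmax > 0).all()

    def test_oblique_dlmax_accumulation_oracle(self):
        """Per-voxel summed crossing length equals the stored Delta-l_max
        (brute-force accumulation on an 11^3 grid)."""
        p = ph.build_water_phantom(1.0, 11.0)
        d = np.array([0.3, 0.5, np.sqrt(1 - 0.34)])
        lat = ph.build_line_lattice(p, d)[0]
        oracle = np.zeros(p.n_voxels)
        for v, dl in zip(lat.voxel_flat, lat.step_length):
            oracle[v] += dl
        np.testing.assert_allclose(lat.dlmax, oracle, rtol=1e-6)
        assert (lat.dlmax > 0).all()  # every voxel crossed
        # interior voxels approach the V/A tiling value
        interior = lat.dlmax.reshape(p.shape)[3:-3, 3:-3, 3:-3]
        assert abs(interior.mean() - p.voxel_size**3 / lat.line_area) < 0.05

    def test_antiparallel_symmetry(self):
        p = ph.build_water_phantom(1.0, 11.0)
        d = np.array([0.3, -0.5, np.sqrt(1 - 0.34)])
        la, lb = ph.build_line_lattice(p, np.array([d, -d]))
        np.testing.assert_allclose(la.dlmax, lb.dlmax, atol=1e-12)
        assert la.n_lines == lb.n_lines
        for li in range(la.n_lines):
            s1 = slice(la.line_starts[li], la.line_starts[li + 1])
            s2 = slice(lb.line_starts[li], lb.line_starts[li + 1])
            np.testing.assert_array_equal(la.voxel_flat[s1],
                                          lb.voxel_flat[s2][::-1])
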
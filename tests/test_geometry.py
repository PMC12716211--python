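"""Unit cells, wavelengths, rotations, Niggli reduction and Ewald mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tserialed.exceptions import InvalidArgumentError, InvalidCellError
from tserialed.geometry import (
    BeamModel,
    CrystalModel,
    DetectorGeometry,
    UnitCell,
    cell_from_ub,
    electron_wavelength,
    map_spot_to_reciprocal,
    niggli_comparison_cell,
    niggli_reduce,
    niggli_reduce_with_transform,
    project_to_detector,
    reciprocal_basis,
    rotation_about_axis,
)


class TestElectronWavelength:
    def test_published_value_at_300kv(self):
        assert electron_wavelength(300.0) == pytest.approx(0.0197, abs=5e-5)

    def test_closed_form_at_200kv(self):
        # frozen from an independent evaluation of
        # h / sqrt(2 m e V (1 + eV/2mc^2)) with CODATA constants
        assert electron_wavelength(200.0) == pytest.approx(0.0250793, abs=1e-6)

    def test_strictly_decreasing_in_voltage(self):
        volts = [10, 80, 100, 200, 300, 1000]
        lams = [electron_wavelength(v) for v in volts]
        assert all(a > b for a, b in zip(lams, lams[1:]))

    def test_relativistic_correction_magnitude(self):
        # the non-relativistic formula is close at low voltage, far off at 300 kV
        def non_rel(kv):
            h, m, e = 6.62607015e-34, 9.1093837015e-31, 1.602176634e-19
            return h / math.sqrt(2 * m * e * kv * 1e3) * 1e10

        assert abs(non_rel(10) / electron_wavelength(10) - 1) < 0.05
        assert abs(non_rel(300) / electron_wavelength(300) - 1) > 0.10

    def test_rejects_non_positive_voltage(self):
        with pytest.raises(InvalidArgumentError):
            electron_wavelength(0.0)


class TestUnitCellAndReciprocalBasis:
    def test_cubic_reciprocal_is_diagonal(self, cubic_cell):
        b = reciprocal_basis(cubic_cell)
        assert np.allclose(b, np.diag([0.1, 0.1, 0.1]))

    @pytest.mark.parametrize(
        "params",
        [
            (10, 10, 10, 90, 90, 90),
            (5, 6, 7, 80, 95, 100),
            (11.1, 12.7, 14.4, 95.0, 98.5, 103.2),
            (3.2, 18.0, 7.7, 90, 112.3, 90),
        ],
    )
    def test_volume_identity(self, params):
        cell = UnitCell(*params)
        b = reciprocal_basis(cell)
        assert np.linalg.det(b) * cell.volume == pytest.approx(1.0, abs=1e-10)

    def test_triclinic_against_metric_tensor_oracle(self):
        # independent construction: G* = G^{-1}; B^T B must equal G*
        cell = UnitCell(5, 6, 7, 80, 95, 100)
        ca, cb, cg = (math.cos(math.radians(x)) for x in (80, 95, 100))
        g = np.array(
            [
                [25, 5 * 6 * cg, 5 * 7 * cb],
                [5 * 6 * cg, 36, 6 * 7 * ca],
                [5 * 7 * cb, 6 * 7 * ca, 49],
            ]
        )
        g_star = np.linalg.inv(g)
        b = reciprocal_basis(cell)
        assert np.allclose(b.T @ b, g_star, atol=1e-12)

    @pytest.mark.parametrize(
        "params",
        [(0, 1, 1, 90, 90, 90), (1, 1, 1, 0, 90, 90), (1, 1, 1, 10, 10, 170)],
    )
    def test_degenerate_cells_rejected(self, params):
        with pytest.raises(InvalidCellError):
            UnitCell(*params)

    def test_cell_from_ub_round_trip(self, triclinic_cell, rng):
        u = rotation_about_axis(np.array([0, 1.0, 0]), 33.0)
        ub = u @ reciprocal_basis(triclinic_cell)
        back = cell_from_ub(ub)
        assert back.approx_equal(triclinic_cell, length_tol=1e-9, angle_tol=1e-8)


class TestRotations:
    def test_zero_angle_is_identity(self):
        r = rotation_about_axis(np.array([1.0, 0, 0]), 0.0)
        assert np.allclose(r, np.eye(3), atol=1e-15)

    @given(theta=st.floats(-360, 360), phi=st.floats(0, math.pi), psi=st.floats(0, 2 * math.pi))
    def test_proper_rotation_and_inverse(self, theta, phi, psi):
        axis = np.array(
            [math.sin(phi) * math.cos(psi), math.sin(phi) * math.sin(psi), math.cos(phi)]
        )
        r = rotation_about_axis(axis, theta)
        assert abs(np.linalg.det(r) - 1) < 1e-10
        assert np.linalg.norm(r.T @ r - np.eye(3)) < 1e-10
        assert np.allclose(r @ rotation_about_axis(axis, -theta), np.eye(3), atol=1e-12)

    @given(t1=st.floats(-90, 90), t2=st.floats(-90, 90))
    def test_composition_about_shared_axis(self, t1, t2):
        axis = np.array([0.0, 0.0, 1.0])
        lhs = rotation_about_axis(axis, t2) @ rotation_about_axis(axis, t1)
        assert np.allclose(lhs, rotation_about_axis(axis, t1 + t2), atol=1e-12)

    def test_rejects_non_unit_axis(self):
        with pytest.raises(InvalidArgumentError):
            rotation_about_axis(np.array([0.0, 0.0, 0.0]), 10.0)


class TestNiggliReduction:
    def test_cubic_already_reduced(self, cubic_cell):
        assert niggli_reduce(cubic_cell).approx_equal(cubic_cell, 1e-9, 1e-8)

    @given(
        a=st.floats(3, 20),
        b=st.floats(3, 20),
        c=st.floats(3, 20),
        al=st.floats(60, 120),
        be=st.floats(60, 120),
        ga=st.floats(60, 120),
    )
    def test_volume_preserved(self, a, b, c, al, be, ga):
        try:
            cell = UnitCell(a, b, c, al, be, ga)
        except InvalidCellError:
            return
        red = niggli_reduce(cell)
        assert red.volume == pytest.approx(cell.volume, rel=1e-8)

    def test_unimodular_transform_reduces_to_same_cell(self, rng):
        """Any basis of the same lattice must reduce to identical parameters."""
        cell = UnitCell(6.0, 7.5, 9.0, 95.0, 100.0, 105.0)
        a_mat = cell.direct_matrix()
        reduced = niggli_reduce(cell)
        for _ in range(10):
            while True:
                m = rng.integers(-2, 3, size=(3, 3))
                if abs(round(float(np.linalg.det(m)))) == 1:
                    break
            alt = m @ a_mat
            g = alt @ alt.T
            aa, bb, cc = np.sqrt(np.diag(g))
            alt_cell = UnitCell(
                aa, bb, cc,
                math.degrees(math.acos(g[1, 2] / (bb * cc))),
                math.degrees(math.acos(g[0, 2] / (aa * cc))),
                math.degrees(math.acos(g[0, 1] / (aa * bb))),
            )
            red2 = niggli_reduce(alt_cell)
            assert red2.approx_equal(reduced, length_tol=1e-6, angle_tol=1e-5)

    def test_shortest_vector_oracle(self):
        """Reduced `a` equals the shortest lattice vector found by brute force."""
        cell = UnitCell(6.0, 7.5, 9.0, 95.0, 100.0, 105.0)
        a_mat = cell.direct_matrix()
        coeffs = np.array(np.meshgrid(*[range(-3, 4)] * 3)).reshape(3, -1).T
        coeffs = coeffs[np.any(coeffs != 0, axis=1)]
        lengths = np.linalg.norm(coeffs @ a_mat, axis=1)
        reduced = niggli_reduce(cell)
        assert reduced.a == pytest.approx(lengths.min(), rel=1e-9)

    def test_transform_maps_lattice(self):
        cell = UnitCell(10, 12, 8, 85, 95, 105)
        reduced, n = niggli_reduce_with_transform(cell)
        alt = n @ cell.direct_matrix()
        g = alt @ alt.T
        assert np.sqrt(g[0, 0]) == pytest.approx(reduced.a, rel=1e-9)
        assert abs(round(float(np.linalg.det(n)))) == 1

    def test_comparison_cell_stable_at_right_angle_boundary(self):
        # noise flips the Niggli form between gamma and 180-gamma when two
        # angles sit at 90 degrees; the comparison form must not
        acute = UnitCell(5.112, 5.469, 11.973, 89.945, 89.873, 68.554)
        obtuse = UnitCell(5.10, 5.46, 11.97, 90.0, 90.0, 111.74)
        ca = niggli_comparison_cell(acute)
        cb = niggli_comparison_cell(obtuse)
        assert abs(ca.gamma - cb.gamma) < 0.5
        assert ca.alpha == cb.alpha == 90.0


class TestEwaldMapping:
    def test_beam_center_maps_to_origin(self, geom, beam):
        s = map_spot_to_reciprocal(np.array([128.0, 128.0]), geom, beam)
        assert np.allclose(s, 0.0, atol=1e-15)

    def test_magnitude_matches_bragg_construction(self, geom, beam):
        # independent trigonometry: pixel radius r -> 2theta -> |s| = 2 sin(theta)/lambda
        r_px = 80.0
        spot = np.array([128.0 + r_px, 128.0])
        s = map_spot_to_reciprocal(spot, geom, beam)
        two_theta = math.atan2(r_px * geom.pixel_size_mm, geom.distance_mm)
        expected = 2.0 * math.sin(two_theta / 2.0) / beam.wavelength
        assert np.linalg.norm(s) == pytest.approx(expected, rel=1e-12)

    def test_out_of_bounds_spot_rejected(self, geom, beam):
        with pytest.raises(InvalidArgumentError):
            map_spot_to_reciprocal(np.array([900.0, 10.0]), geom, beam)

    @pytest.mark.parametrize("theta", [0.0, -20.0, 35.0])
    def test_forward_inverse_round_trip(self, geom, beam, triclinic_cell, rng, theta):
        """Zero-excitation-error vectors project and map back exactly."""
        model = CrystalModel(cell=triclinic_cell)
        hkl = np.array([[1, 0, 0], [0, 2, -1], [2, -1, 1], [-1, 1, 1]])
        s0 = hkl @ model.ub.T
        axis = np.array([1.0, 0.0, 0.0])
        # rotate each vector about the tilt axis so it sits exactly on the sphere
        lam = beam.wavelength
        for s in s0:
            # choose the azimuthal orientation that nulls the excitation error:
            # place s so that |s + z/lambda| = 1/lambda with same |s|
            norm = np.linalg.norm(s)
            sz = -norm**2 * lam / 2.0
            sxy = math.sqrt(norm**2 - sz**2)
            # on the sphere in the tilted (lab) frame, then back-rotated so the
            # crystal-frame vector has exactly zero excitation error at theta
            s_exact = rotation_about_axis(axis, -theta) @ np.array([sxy, 0.0, sz])
            fast, slow, eps, ok = project_to_detector(s_exact[None], geom, beam, theta_deg=theta)
            if not ok[0]:
                continue
            assert abs(eps[0]) < 1e-12
            back = map_spot_to_reciprocal(
                np.array([fast[0], slow[0]]), geom, beam, theta_deg=theta
            )
            # projection and mapping share the tilt, so the crystal-frame
            # vector comes back unchanged
            assert np.allclose(back, s_exact, atol=1e-10)


class TestCrystalModel:
    def test_from_ub_recovers_cell_and_orientation(self, triclinic_cell):
        u = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 47.0)
        ub = u @ reciprocal_basis(triclinic_cell)
        model = CrystalModel.from_ub(ub)
        assert model.cell.approx_equal(triclinic_cell, 1e-8, 1e-7)
        assert np.allclose(model.u, u, atol=1e-9)

    def test_rejects_improper_orientation(self, cubic_cell):
        with pytest.raises(InvalidArgumentError):
            CrystalModel(cell=cubic_cell, u=np.diag([1.0, 1.0, -1.0]))

    def test_niggli_reduced_model_spans_same_lattice(self):
        cell = UnitCell(10, 12, 8, 85, 95, 105)
        model = CrystalModel(cell=cell)
        reduced = model.niggli_reduced()
        comb = np.linalg.solve(model.ub, reduced.ub)
        assert np.allclose(comb, np.rint(comb), atol=1e-8)
        assert reduced.cell.volume == pytest.approx(cell.volume, rel=1e-9)
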
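"""Crystallographic geometry for still electron diffraction.

Conventions used throughout the package:

* Laboratory frame: the incident beam travels along ``+z``; the detector is a
  plane perpendicular to ``z`` at ``+distance``; the goniometer tilt axis lies
  in the detector plane, by default along lab ``+x`` (the detector fast axis),
  with a configurable azimuth.
* Pixels: 0-based continuous coordinates ``(fast, slow)``; a spot position is
  the intensity-weighted centroid of its pixel footprint.
* Reciprocal space: no factor of 2π, so ``|s| = 1/d`` for resolution ``d``.
  The ``B`` matrix columns are the reciprocal basis vectors ``a*, b*, c*`` of
  a cell placed in a canonical orientation (``a`` along ``+x``, ``b`` in the
  ``x``–``y`` plane); consequently ``c*`` is along ``+z``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import InvalidArgumentError, InvalidCellError

__all__ = [
    "UnitCell",
    "BeamModel",
    "DetectorGeometry",
    "CrystalModel",
    "electron_wavelength",
    "reciprocal_basis",
    "rotation_about_axis",
    "niggli_reduce",
    "niggli_comparison_cell",
    "niggli_reduce_with_transform",
    "map_spot_to_reciprocal",
    "project_to_detector",
    "excitation_error",
    "cell_from_ub",
    "tilt_axis_from_azimuth",
]

# CODATA constants (SI); kept local so the formula is explicit and auditable.
_H = 6.62607015e-34
_M_E = 9.1093837015e-31
_E = 1.602176634e-19
_C = 299792458.0


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic de Broglie wavelength of an electron in Å.

    λ = h / sqrt(2 m e V (1 + eV / 2mc²)).  At 300 kV this evaluates to
    0.0197 Å, the nearly-flat-Ewald-sphere regime that makes still ED
    patterns effectively planar sections of reciprocal space.
    """
    if voltage_kv <= 0:
        raise InvalidArgumentError(f"accelerating voltage must be > 0 kV, got {voltage_kv}")
    v = float(voltage_kv) * 1e3
    lam = _H / math.sqrt(2.0 * _M_E * _E * v * (1.0 + _E * v / (2.0 * _M_E * _C**2)))
    return lam * 1e10


@dataclass(frozen=True)
class UnitCell:
    """Real-space unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        lengths = (self.a, self.b, self.c)
        angles = (self.alpha, self.beta, self.gamma)
        if not all(np.isfinite(lengths + angles)):
            raise InvalidCellError(f"non-finite cell parameters: {self.parameters}")
        if min(lengths) <= 0:
            raise InvalidCellError(f"cell lengths must be positive: {lengths}")
        if not all(0.0 < ang < 180.0 for ang in angles):
            raise InvalidCellError(f"cell angles must lie in (0, 180): {angles}")
        ca, cb, cg = (math.cos(math.radians(x)) for x in angles)
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0.0:
            raise InvalidCellError(f"metric tensor not positive definite for {self.parameters}")

    @property
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return self.a * self.b * self.c * math.sqrt(arg)

    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G with G_ij = a_i · a_j."""
        a_mat = self.direct_matrix()
        return a_mat @ a_mat.T

    def direct_matrix(self) -> np.ndarray:
        """Rows are the direct basis vectors in the canonical orientation."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        av = (self.a, 0.0, 0.0)
        bv = (self.b * cg, self.b * sg, 0.0)
        cx = self.c * cb
        cy = self.c * (ca - cb * cg) / sg
        cz2 = self.c * self.c - cx * cx - cy * cy
        if cz2 <= 0:
            raise InvalidCellError(f"degenerate cell {self.parameters}")
        return np.array([av, bv, (cx, cy, math.sqrt(cz2))])

    def approx_equal(self, other: "UnitCell", length_tol: float = 1e-5, angle_tol: float = 1e-4) -> bool:
        return bool(
            np.allclose(self.parameters[:3], other.parameters[:3], atol=length_tol)
            and np.allclose(self.parameters[3:], other.parameters[3:], atol=angle_tol)
        )


def reciprocal_basis(cell: UnitCell) -> np.ndarray:
    """Reciprocal basis matrix B (Å⁻¹); columns are a*, b*, c*.

    Satisfies det(B) = 1/V and B = A⁻¹ for the canonical direct matrix A
    (rows = direct vectors), so that s = B·(h, k, l) for integer indices.
    """
    return np.linalg.inv(cell.direct_matrix())


def cell_from_ub(ub: np.ndarray) -> UnitCell:
    """Recover real-space cell parameters from any UB matrix."""
    ub = np.asarray(ub, dtype=float)
    if ub.shape != (3, 3) or abs(np.linalg.det(ub)) < 1e-12:
        raise InvalidCellError("UB must be an invertible 3x3 matrix")
    a_mat = np.linalg.inv(ub)  # rows = direct basis vectors in lab frame
    g = a_mat @ a_mat.T
    a, b, c = np.sqrt(np.diag(g))
    alpha = math.degrees(math.acos(g[1, 2] / (b * c)))
    beta = math.degrees(math.acos(g[0, 2] / (a * c)))
    gamma = math.degrees(math.acos(g[0, 1] / (a * b)))
    return UnitCell(a, b, c, alpha, beta, gamma)


def rotation_about_axis(axis: np.ndarray, theta_deg: float) -> np.ndarray:
    """Proper rotation matrix (right-handed) about a unit axis by theta degrees."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if abs(norm - 1.0) > 1e-8:
        raise InvalidArgumentError(f"rotation axis must be a unit vector, |axis| = {norm}")
    return Rotation.from_rotvec(axis * math.radians(theta_deg)).as_matrix()


def tilt_axis_from_azimuth(azimuth_deg: float = 0.0) -> np.ndarray:
    """Tilt axis in the detector plane at the given azimuth from lab +x."""
    az = math.radians(azimuth_deg)
    return np.array([math.cos(az), math.sin(az), 0.0])


def niggli_reduce(cell: UnitCell, tol: float = 1e-5) -> UnitCell:
    """Niggli-reduced cell (same lattice, canonical shortest basis)."""
    reduced, _ = niggli_reduce_with_transform(cell, tol=tol)
    return reduced


def niggli_reduce_with_transform(cell: UnitCell, tol: float = 1e-5) -> tuple[UnitCell, np.ndarray]:
    """Niggli reduction returning the integer basis transform N.

    The reduced direct vectors are ``A' = N · A`` (rows), hence Miller indices
    transform as ``h' = N · h`` and ``UB' = UB · N⁻¹``.
    """
    gv = gemmi.GruberVector(gemmi.UnitCell(*cell.parameters), None, track_change_of_basis=True)
    gv.niggli_reduce(epsilon=tol)
    params = gv.cell_parameters()
    n = np.array(gv.change_of_basis.rot, dtype=float).T / gemmi.Op.DEN
    n_int = np.rint(n).astype(int)
    if not np.allclose(n, n_int, atol=1e-9) or abs(round(float(np.linalg.det(n_int)))) != 1:
        raise InvalidCellError("Niggli change of basis is not unimodular")  # pragma: no cover
    return UnitCell(*params), n_int


def is_niggli_reduced(cell: UnitCell, tol: float = 1e-2) -> bool:
    reduced = niggli_reduce(cell)
    return cell.approx_equal(reduced, length_tol=tol, angle_tol=150 * tol)


def niggli_comparison_cell(cell: UnitCell, angle_snap_deg: float = 1.0) -> UnitCell:
    """Boundary-stable reduced cell for comparing noisy lattices.

    The Niggli cell is discontinuous where an angle crosses 90°: noise on a
    cell with right angles flips the reduction between the acute and obtuse
    variants (γ and 180°−γ), which would scatter one phase into two
    clusters.  This canonical form snaps angles within ``angle_snap_deg``
    of 90° to exactly 90° and then flips remaining acute angles to their
    obtuse partners whenever a basis-vector sign change permits it (an even
    number of acute angles, or any exact 90° available to pair with).
    Genuinely acute (Type I) cells are left untouched.
    """
    reduced = niggli_reduce(cell)
    a, b, c = reduced.a, reduced.b, reduced.c
    angles = np.array([reduced.alpha, reduced.beta, reduced.gamma])
    near90 = np.abs(angles - 90.0) <= angle_snap_deg
    angles[near90] = 90.0
    acute = np.flatnonzero((angles < 90.0) & ~near90)
    if len(acute) and (len(acute) % 2 == 0 or near90.any()):
        angles[acute] = 180.0 - angles[acute]
    return UnitCell(a, b, c, *angles)


@dataclass(frozen=True)
class BeamModel:
    """Monochromatic electron beam; wavelength derived from the voltage."""

    voltage_kv: float = 200.0
    beam_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.beam_direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-8:
            raise InvalidArgumentError("beam_direction must be a unit vector")
        electron_wavelength(self.voltage_kv)  # validates voltage

    @property
    def wavelength(self) -> float:
        return electron_wavelength(self.voltage_kv)

    @property
    def direction(self) -> np.ndarray:
        return np.asarray(self.beam_direction, dtype=float)


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat detector perpendicular to the beam at +distance."""

    distance_mm: float
    pixel_size_mm: float
    n_fast: int
    n_slow: int
    beam_center: tuple[float, float]  # (fast, slow) pixels, 0-based

    def __post_init__(self) -> None:
        if self.distance_mm <= 0 or self.pixel_size_mm <= 0:
            raise InvalidArgumentError("detector distance and pixel size must be positive")
        bf, bs = self.beam_center
        if not (0 <= bf < self.n_fast and 0 <= bs < self.n_slow):
            raise InvalidArgumentError(f"beam center {self.beam_center} outside image bounds")

    def lab_position(self, fast: np.ndarray, slow: np.ndarray) -> np.ndarray:
        """Lab-frame mm position(s) of pixel coordinates; shape (..., 3)."""
        fast = np.asarray(fast, dtype=float)
        slow = np.asarray(slow, dtype=float)
        x = (fast - self.beam_center[0]) * self.pixel_size_mm
        y = (slow - self.beam_center[1]) * self.pixel_size_mm
        z = np.full_like(x, self.distance_mm)
        return np.stack([x, y, z], axis=-1)

    def in_bounds(self, fast: np.ndarray, slow: np.ndarray) -> np.ndarray:
        fast = np.asarray(fast, dtype=float)
        slow = np.asarray(slow, dtype=float)
        return (fast >= 0) & (fast <= self.n_fast - 1) & (slow >= 0) & (slow <= self.n_slow - 1)


@dataclass(frozen=True)
class CrystalModel:
    """A lattice tied to the lab frame: UB = U · B.

    ``U`` is a proper rotation; ``B`` maps integer hkl to reciprocal
    coordinates of the canonically oriented cell.
    """

    cell: UnitCell
    u: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        object.__setattr__(self, "u", u)
        if u.shape != (3, 3):
            raise InvalidArgumentError("U must be 3x3")
        if np.linalg.norm(u.T @ u - np.eye(3)) > 1e-8 or abs(np.linalg.det(u) - 1.0) > 1e-8:
            raise InvalidArgumentError("U must be a proper rotation (orthogonal, det +1)")

    @property
    def b(self) -> np.ndarray:
        return reciprocal_basis(self.cell)

    @property
    def ub(self) -> np.ndarray:
        return self.u @ self.b

    @classmethod
    def from_ub(cls, ub: np.ndarray) -> "CrystalModel":
        """Factor an arbitrary UB into cell + orientation.

        The orientation is the polar-decomposition projection of UB·B⁻¹ onto
        SO(3), which absorbs the numerical asymmetry of least-squares UBs.
        """
        ub = np.asarray(ub, dtype=float)
        if np.linalg.det(ub) < 0:
            # right-handed reciprocal basis: flip the third column's index sense
            ub = ub @ np.diag([1, 1, -1])
        cell = cell_from_ub(ub)
        b = reciprocal_basis(cell)
        u_raw = ub @ np.linalg.inv(b)
        w, _, vt = np.linalg.svd(u_raw)
        u = w @ vt
        if np.linalg.det(u) < 0:  # pragma: no cover - det(ub)>0 guarantees +1
            u = w @ np.diag([1, 1, -1]) @ vt
        return cls(cell=cell, u=u)

    def niggli_reduced(self) -> "CrystalModel":
        """Equivalent model whose cell is Niggli-reduced (same lattice)."""
        _, n = niggli_reduce_with_transform(self.cell)
        ub_red = self.ub @ np.linalg.inv(n.astype(float))
        return CrystalModel.from_ub(ub_red)


def excitation_error(
    s_crystal: np.ndarray, beam: BeamModel, theta_deg: float = 0.0, axis: np.ndarray | None = None
) -> np.ndarray:
    """Signed distance ε of reciprocal nodes from the Ewald sphere (Å⁻¹).

    Positive when the node lies inside the sphere.  ``s_crystal`` are node
    coordinates in the zero-tilt crystal frame, shape (..., 3).
    """
    axis = np.array([1.0, 0.0, 0.0]) if axis is None else np.asarray(axis, dtype=float)
    r = np.asarray(s_crystal, dtype=float) @ rotation_about_axis(axis, theta_deg).T
    k = r + beam.direction / beam.wavelength
    return 1.0 / beam.wavelength - np.linalg.norm(k, axis=-1)


def map_spot_to_reciprocal(
    spot: np.ndarray,
    det: DetectorGeometry,
    beam: BeamModel,
    theta_deg: float = 0.0,
    axis: np.ndarray | None = None,
) -> np.ndarray:
    """Map detector centroid(s) to the zero-tilt crystal frame (Å⁻¹).

    s = R(−θ) · (p̂ − ẑ)/λ with p̂ the unit vector from the sample to the
    pixel.  The exact Ewald construction is kept (no flat-sphere shortcut),
    so |s| = 2 sin(θ_B)/λ holds identically.
    """
    spot = np.asarray(spot, dtype=float)
    single = spot.ndim == 1
    spot2 = np.atleast_2d(spot)
    if not np.all(det.in_bounds(spot2[:, 0], spot2[:, 1])):
        bad = spot2[~det.in_bounds(spot2[:, 0], spot2[:, 1])][0]
        raise InvalidArgumentError(f"spot {tuple(bad)} outside image bounds")
    p = det.lab_position(spot2[:, 0], spot2[:, 1])
    p_hat = p / np.linalg.norm(p, axis=-1, keepdims=True)
    s_lab = (p_hat - beam.direction) / beam.wavelength
    axis = np.array([1.0, 0.0, 0.0]) if axis is None else np.asarray(axis, dtype=float)
    rot = rotation_about_axis(axis, -theta_deg)
    s = s_lab @ rot.T
    return s[0] if single else s


def project_to_detector(
    s_crystal: np.ndarray,
    det: DetectorGeometry,
    beam: BeamModel,
    theta_deg: float = 0.0,
    axis: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Forward projection of reciprocal nodes onto the detector.

    Each node is projected along the diffracted-beam direction
    k' = R(θ)·s + ẑ/λ (the still-shot approximation: the recorded spot sits
    where the diffracted ray through the node meets the detector).

    Returns ``(fast, slow, eps, ok)`` where ``ok`` flags nodes that project
    forward onto the detector area.  Positions of nodes with ``ok`` False
    are NaN.
    """
    axis = np.array([1.0, 0.0, 0.0]) if axis is None else np.asarray(axis, dtype=float)
    s = np.atleast_2d(np.asarray(s_crystal, dtype=float))
    rot = rotation_about_axis(axis, theta_deg)
    r = s @ rot.T
    k = r + beam.direction / beam.wavelength
    eps = 1.0 / beam.wavelength - np.linalg.norm(k, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        forward = k[:, 2] > 1e-9
        x = np.where(forward, k[:, 0] * det.distance_mm / k[:, 2], np.nan)
        y = np.where(forward, k[:, 1] * det.distance_mm / k[:, 2], np.nan)
    fast = x / det.pixel_size_mm + det.beam_center[0]
    slow = y / det.pixel_size_mm + det.beam_center[1]
    ok = forward & det.in_bounds(np.nan_to_num(fast, nan=-1.0), np.nan_to_num(slow, nan=-1.0))
    return fast, slow, eps, ok
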
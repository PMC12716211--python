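"""Laue-group operators and symmetry-unique reflection handling.

Operator tables are generated from representative centrosymmetric space
groups, so every supported Laue group contains the inversion (Friedel pairs
always merge).  Indices are reduced to a canonical representative by taking
the lexicographically largest image over the group.
"""

from __future__ import annotations

import numpy as np
import gemmi

from .exceptions import InvalidArgumentError
from .geometry import UnitCell, reciprocal_basis

# Laue class -> representative space group (symmorphic, centrosymmetric)
_REPRESENTATIVE = {
    "-1": "P-1",
    "2/m": "P2/m",
    "mmm": "Pmmm",
    "4/m": "P4/m",
    "4/mmm": "P4/mmm",
    "-3": "P-3",
    "-3m": "P-31m",
    "6/m": "P6/m",
    "6/mmm": "P6/mmm",
    "m-3": "Pm-3",
    "m-3m": "Pm-3m",
}

# Merohedral indexing-ambiguity operators (beyond the Laue group) for lattices
# whose point symmetry exceeds the Laue symmetry of the intensities.  Identity
# is always included; triclinic/monoclinic/orthorhombic classes have none.
_AMBIGUITY = {
    "-1": [],
    "2/m": [],
    "mmm": [],
    "4/m": [((0, 1, 0), (1, 0, 0), (0, 0, -1))],
    "4/mmm": [],
    "-3": [((0, 1, 0), (1, 0, 0), (0, 0, -1)), ((-1, 0, 0), (0, -1, 0), (0, 0, 1))],
    "-3m": [((-1, 0, 0), (0, -1, 0), (0, 0, 1))],
    "6/m": [((0, 1, 0), (1, 0, 0), (0, 0, -1))],
    "6/mmm": [],
    "m-3": [((0, 1, 0), (1, 0, 0), (0, 0, -1))],
    "m-3m": [],
}


def supported_laue_groups() -> tuple[str, ...]:
    return tuple(_REPRESENTATIVE)


def laue_operators(laue_group: str) -> np.ndarray:
    """Stack of integer rotation matrices acting on hkl (shape n_ops×3×3)."""
    try:
        sg = gemmi.SpaceGroup(_REPRESENTATIVE[laue_group])
    except KeyError:
        raise InvalidArgumentError(
            f"unsupported Laue group {laue_group!r}; supported: {sorted(_REPRESENTATIVE)}"
        ) from None
    ops = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / gemmi.Op.DEN
        ops.append(np.rint(rot).astype(int))
    uniq = {tuple(o.ravel()) for o in ops}
    return np.array([np.array(u).reshape(3, 3) for u in sorted(uniq)])


def ambiguity_operators(laue_group: str) -> list[np.ndarray]:
    """Identity plus the merohedral reindexing operators of the lattice class."""
    if laue_group not in _AMBIGUITY:
        raise InvalidArgumentError(f"unsupported Laue group {laue_group!r}")
    ops = [np.eye(3, dtype=int)]
    ops.extend(np.array(m, dtype=int) for m in _AMBIGUITY[laue_group])
    return ops


def unique_hkl(hkl: np.ndarray, laue_group: str) -> np.ndarray:
    """Map each hkl to its canonical Laue-unique representative.

    Acting on reflections as h' = O·h for every group operator O (inversion
    included), the representative is the lexicographically largest image.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    if hkl.size == 0:
        return hkl.reshape(0, 3)
    ops = laue_operators(laue_group)
    images = np.einsum("oij,nj->noi", ops, hkl)  # n × n_ops × 3
    # lexicographic max over the operator axis
    w = np.int64(2 * max(1, int(np.abs(images).max())) + 1)
    img = images.astype(np.int64)
    keys = (img[:, :, 0] * w + img[:, :, 1]) * w + img[:, :, 2]
    best = np.argmax(keys, axis=1)
    return images[np.arange(len(hkl)), best]


def enumerate_unique_reflections(cell: UnitCell, laue_group: str, d_min: float) -> np.ndarray:
    """All Laue-unique hkl with d >= d_min, enumerated by brute force."""
    if d_min <= 0:
        raise InvalidArgumentError("d_min must be positive")
    b = reciprocal_basis(cell)
    s_max = 1.0 / d_min
    bounds = [int(np.ceil(length * s_max)) + 1 for length in (cell.a, cell.b, cell.c)]
    h, k, l = np.meshgrid(*[np.arange(-m, m + 1) for m in bounds], indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    s = hkl @ b.T
    hkl = hkl[np.linalg.norm(s, axis=1) <= s_max]
    reps = unique_hkl(hkl, laue_group)
    return np.unique(reps, axis=0)
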
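"""Population-scale validation studies run entirely on synthetic data.

These drivers exist so that precision and coverage claims are reproducible
as single function calls: cell-recovery precision across many independently
indexed tilt series, multi-lattice decomposition of aggregates, and
completeness accumulated over a pool of randomly oriented crystals.
Problem sizes are desk-scale (hundreds of datasets, 256² frames).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import symmetry
from .exceptions import IndexingFailureError, InsufficientDataError
from .geometry import (
    BeamModel,
    CrystalModel,
    DetectorGeometry,
    UnitCell,
    niggli_comparison_cell,
    project_to_detector,
)
from .indexing import IndexingParams, ReciprocalCloud, choose_cell, fft_find_basis, refine_cell
from .synthetic_data import (
    _hkl_grid,
    default_beam,
    default_geometry,
    default_tilt_angles,
    random_orientation,
    simulate_tilt_series_spots,
)

__all__ = [
    "CellRecoveryResult",
    "cell_recovery_study",
    "completeness_study",
    "REFERENCE_TRICLINIC_CELL",
]

# fixed triclinic reference cell for precision studies: Niggli-reduced,
# moderate volume (~1940 Å^3) so each still carries 10–20 reflections
REFERENCE_TRICLINIC_CELL = UnitCell(11.1, 12.7, 14.4, 95.0, 98.5, 103.2)


@dataclass
class CellRecoveryResult:
    """Population statistics of independently indexed synthetic datasets."""

    n_datasets: int
    n_indexed: int
    cells: np.ndarray                      # (n_indexed, 6) Niggli parameters
    true_cell: tuple[float, ...]
    parameter_names: tuple[str, ...] = ("a", "b", "c", "alpha", "beta", "gamma")

    @property
    def success_rate(self) -> float:
        return self.n_indexed / self.n_datasets

    @property
    def rsd_percent(self) -> np.ndarray:
        """100·sd/mean per cell parameter across indexed datasets."""
        return 100.0 * self.cells.std(axis=0, ddof=1) / self.cells.mean(axis=0)

    @property
    def max_rel_error_percent(self) -> np.ndarray:
        truth = np.asarray(self.true_cell)
        return 100.0 * np.abs(self.cells - truth).max(axis=0) / truth


def _index_spot_series(
    series: list[tuple[float, np.ndarray, np.ndarray]],
    geom: DetectorGeometry,
    beam: BeamModel,
    params: IndexingParams,
) -> np.ndarray | None:
    """Index one spot-level tilt series; returns reduced cell params or None."""
    from .geometry import map_spot_to_reciprocal

    pts = []
    for theta, centroids, _ in series:
        if len(centroids):
            pts.append(map_spot_to_reciprocal(centroids, geom, beam, theta_deg=theta))
    if not pts:
        return None
    cloud = ReciprocalCloud(position_id=0, points=np.concatenate(pts))
    try:
        cands, _ = fft_find_basis(
            cloud,
            d_max=params.d_max,
            grid_size=params.grid_size,
            s_max=params.s_max,
            d_min_vec=params.d_min_vec,
            peak_rel_threshold=params.peak_rel_threshold,
            n_candidates=params.n_candidates,
        )
        sol = choose_cell(cands, cloud, params=params)
        refined = refine_cell(sol.model, cloud, assignment=sol.inliers,
                              index_tolerance=params.index_tolerance)
    except (IndexingFailureError, InsufficientDataError):
        return None
    model = refined.model if refined.success else sol.model
    return np.array(niggli_comparison_cell(model.cell).parameters)


def cell_recovery_study(
    n_datasets: int = 100,
    seed: int = 0,
    cell: UnitCell = REFERENCE_TRICLINIC_CELL,
    centroid_noise_px: float = 0.3,
    d_min: float = 1.3,
    eps_max: float = 0.002,
    tilt_angles: tuple[float, ...] | None = None,
    params: IndexingParams | None = None,
) -> CellRecoveryResult:
    """Index ``n_datasets`` independent single-crystal discrete tilt series.

    Each dataset draws a fresh uniform orientation, projects the reflections
    of the fixed reference cell onto the detector over the tilt schedule,
    perturbs the centroids by ``centroid_noise_px``, and runs the complete
    indexing chain (cloud → FFT basis search → triplet selection →
    least-squares refinement → Niggli reduction) with no knowledge of the
    generating cell.
    """
    geom, beam = default_geometry(), default_beam()
    angles = tilt_angles or default_tilt_angles()
    params = params or IndexingParams()
    rng = np.random.default_rng(seed)
    recovered = []
    for _ in range(n_datasets):
        u = random_orientation(rng)
        series = simulate_tilt_series_spots(
            cell, u, angles, geom, beam,
            d_min=d_min, eps_max=eps_max,
            centroid_noise_px=centroid_noise_px, rng=rng,
        )
        result = _index_spot_series(series, geom, beam, params)
        if result is not None:
            recovered.append(result)
    return CellRecoveryResult(
        n_datasets=n_datasets,
        n_indexed=len(recovered),
        cells=np.array(recovered).reshape(-1, 6),
        true_cell=cell.parameters,
    )


def completeness_study(
    n_crystals: int = 20,
    seed: int = 0,
    cell: UnitCell | None = None,
    laue_group: str = "-1",
    d_min: float = 2.0,
    eps_max: float = 0.015,
    tilt_angles: tuple[float, ...] | None = None,
) -> dict:
    """Completeness accumulated over randomly oriented discrete tilt series.

    Emulates mosaic nanocrystals (broad effective rocking width) at modest
    resolution: each of ``n_crystals`` crystals contributes 7 still slabs of
    reciprocal space; the union of excited reflections is reduced to
    Laue-unique indices and compared against the full expected set.  The
    union-coverage arithmetic 1−(1−ε/s)^(N_slabs) dictates the rocking
    width needed for near-complete data from a handful of crystals.
    """
    geom, beam = default_geometry(), default_beam()
    cell = cell or REFERENCE_TRICLINIC_CELL
    angles = tilt_angles or default_tilt_angles()
    rng = np.random.default_rng(seed)
    hkl = _hkl_grid(cell, d_min)
    observed: set[tuple[int, int, int]] = set()
    for _ in range(n_crystals):
        u = random_orientation(rng)
        model = CrystalModel(cell=cell, u=u)
        s0 = hkl @ model.ub.T
        for theta in angles:
            _, _, eps, ok = project_to_detector(s0, geom, beam, theta_deg=theta)
            excited = hkl[ok & (np.abs(eps) <= eps_max)]
            if len(excited):
                reps = symmetry.unique_hkl(excited, laue_group)
                observed.update(map(tuple, reps))
    expected = symmetry.enumerate_unique_reflections(cell, laue_group, d_min)
    frac = len({tuple(r) for r in expected} & observed) / len(expected)
    return {
        "completeness": frac,
        "n_observed_unique": len(observed),
        "n_expected_unique": int(len(expected)),
        "n_crystals": n_crystals,
        "n_frames": n_crystals * len(angles),
    }
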
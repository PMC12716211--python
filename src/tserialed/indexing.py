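"""Spot finding, reciprocal-cloud construction and FFT autoindexing.

The discrete tilt series gives each crystal a genuinely three-dimensional
reciprocal cloud, so the cell can be found without prior knowledge by the
classic Fourier approach: the FFT of the binned cloud peaks at direct-lattice
translation vectors, and a triplet of candidate vectors is selected by the
fraction of points it indexes to integers.  Aggregate (multi-crystal) clouds
are decomposed by iteratively peeling off the strongest lattice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage

from .exceptions import (
    ConfigurationError,
    IndexingFailureError,
    InsufficientDataError,
    InvalidArgumentError,
)
from .geometry import (
    BeamModel,
    CrystalModel,
    DetectorGeometry,
    map_spot_to_reciprocal,
    cell_from_ub,
)
from .preprocessing import TiltSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SpotList",
    "ReciprocalCloud",
    "IndexingSolution",
    "IndexingParams",
    "CellSolution",
    "find_spots",
    "build_cloud",
    "fft_find_basis",
    "choose_cell",
    "multi_lattice_index",
    "refine_cell",
]


@dataclass
class SpotList:
    """Detector centroids found on one frame."""

    frame_id: int
    fast: np.ndarray      # continuous pixel centroids
    slow: np.ndarray
    counts: np.ndarray    # background-subtracted summed counts
    n_pixels: np.ndarray

    def __post_init__(self) -> None:
        for name in ("fast", "slow", "counts", "n_pixels"):
            setattr(self, name, np.asarray(getattr(self, name)))

    def __len__(self) -> int:
        return len(self.fast)


@dataclass
class ReciprocalCloud:
    """3D reciprocal points of one position, mapped to the zero-tilt frame."""

    position_id: int
    points: np.ndarray                 # (n, 3) in 1/Å
    source: np.ndarray = field(default=None)  # (n, 2): frame_id, spot index

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.source is None:
            self.source = np.zeros((len(self.points), 2), dtype=int)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CellSolution:
    """One lattice fitted to (part of) a cloud."""

    model: CrystalModel
    inliers: np.ndarray          # bool mask over the cloud the fit was run on
    hkl: np.ndarray              # integer indices for inlier points (n_inliers, 3)
    fraction_indexed: float


@dataclass
class IndexingSolution:
    """Multi-lattice decomposition of a cloud."""

    lattices: list[CrystalModel]
    assignment: np.ndarray       # per-point lattice id, -1 for unindexed
    fraction_indexed: list[float]  # per lattice, relative to the full cloud


@dataclass
class IndexingParams:
    """Knobs of the autoindexing chain (defaults suit 5–25 Å cells)."""

    grid_size: int = 128
    s_max: float | None = None        # half-extent of the FFT grid; None = auto
    d_max: float = 50.0               # longest admissible basis vector, Å
    d_min_vec: float = 3.0            # shortest admissible basis vector, Å
    peak_rel_threshold: float = 0.15  # FFT peak floor, relative to point count
    n_candidates: int = 30
    index_tolerance: float = 0.10
    min_fraction: float = 0.4         # single-lattice acceptance threshold
    min_volume: float = 30.0          # Å^3
    min_normalized_volume: float = 0.05  # coplanarity guard on triplets
    max_lattices: int = 4
    per_pass_min_fraction: float = 0.25  # acceptance per peeling pass
    stop_fraction: float = 0.10          # stop peeling below this remainder
    min_lattice_points: int = 12         # reject lattices fitted to fewer points


# ---------------------------------------------------------------------------
# spot finding

def find_spots(
    frame: np.ndarray,
    k_sigma: float = 6.0,
    min_pixels: int = 3,
    beam_mask_radius: float = 10.0,
    window: int = 15,
    beam_center: tuple[float, float] | None = None,
    frame_id: int = -1,
) -> SpotList:
    """Extended dispersion-threshold spot finding.

    A pixel is signal when it exceeds the local mean by ``k_sigma`` local
    standard deviations, both estimated in a ``window``×``window``
    neighbourhood; the statistics are iterated three times with
    already-flagged pixels excluded, so strong peaks do not inflate their
    own background estimate.  Connected signal regions with at least
    ``min_pixels`` pixels become spots with intensity-weighted centroids.
    A disk around the direct beam is masked out.
    """
    if k_sigma <= 0:
        raise InvalidArgumentError("k_sigma must be positive")
    img = np.asarray(frame, dtype=float)
    # Background statistics are built with a fixed conservative multiplier so
    # they do not depend on k_sigma: seed the signal mask from global robust
    # statistics (strong spots must not contaminate their own background),
    # then refine the local mean/sd with flagged regions excluded.
    kappa_bg = 4.0
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    exclude = img > med + kappa_bg * 1.4826 * mad
    local_mean = np.full_like(img, med)
    local_sd = np.full_like(img, 1.4826 * mad)
    for _ in range(3):
        bg_mask = (~ndimage.binary_dilation(exclude, iterations=3)).astype(float)
        cnt = ndimage.uniform_filter(bg_mask, size=window, mode="nearest")
        s1 = ndimage.uniform_filter(img * bg_mask, size=window, mode="nearest")
        s2 = ndimage.uniform_filter(img * img * bg_mask, size=window, mode="nearest")
        cnt = np.maximum(cnt, 1.0 / window**2)
        local_mean = s1 / cnt
        local_sd = np.sqrt(np.clip(s2 / cnt - local_mean**2, 0.0, None))
        exclude = img > local_mean + kappa_bg * local_sd
    signal = img > local_mean + k_sigma * local_sd

    ny, nx = img.shape
    bc = beam_center if beam_center is not None else ((nx - 1) / 2.0, (ny - 1) / 2.0)
    yy, xx = np.mgrid[0:ny, 0:nx]
    signal &= (xx - bc[0]) ** 2 + (yy - bc[1]) ** 2 > beam_mask_radius**2

    labels, n_lab = ndimage.label(signal)
    if n_lab == 0:
        empty = np.empty(0)
        return SpotList(frame_id, empty, empty, empty, np.empty(0, dtype=int))
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(sizes >= min_pixels) + 1

    net = np.clip(img - local_mean, 0.0, None)
    fast_list, slow_list, counts_list, npx_list = [], [], [], []
    for lab in keep:
        mask = labels == lab
        w = net[mask]
        total = w.sum()
        if total <= 0:
            continue
        fast_list.append(float(np.clip((xx[mask] * w).sum() / total, 0.0, nx - 1)))
        slow_list.append(float(np.clip((yy[mask] * w).sum() / total, 0.0, ny - 1)))
        counts_list.append(float(total))
        npx_list.append(int(mask.sum()))
    return SpotList(
        frame_id,
        np.array(fast_list),
        np.array(slow_list),
        np.array(counts_list),
        np.array(npx_list, dtype=int),
    )


def build_cloud(
    series: TiltSeries,
    spots: dict[int, SpotList],
    geom: DetectorGeometry,
    beam: BeamModel,
    axis: np.ndarray | None = None,
) -> ReciprocalCloud:
    """Map every spot of a tilt series into the zero-tilt crystal frame."""
    if geom is None or beam is None:
        raise ConfigurationError("detector geometry and beam model are required")
    pts, src = [], []
    for frame_id, theta in series.frames:
        if frame_id not in spots:
            raise ConfigurationError(f"no spot list for frame {frame_id}")
        sl = spots[frame_id]
        if len(sl) == 0:
            continue
        centroids = np.stack([sl.fast, sl.slow], axis=1)
        pts.append(map_spot_to_reciprocal(centroids, geom, beam, theta_deg=theta, axis=axis))
        src.append(np.stack([np.full(len(sl), frame_id), np.arange(len(sl))], axis=1))
    if not pts:
        return ReciprocalCloud(series.position_id, np.empty((0, 3)))
    return ReciprocalCloud(series.position_id, np.concatenate(pts), np.concatenate(src))


# ---------------------------------------------------------------------------
# FFT basis search

def fft_find_basis(
    cloud: ReciprocalCloud | np.ndarray,
    d_max: float = 50.0,
    grid_size: int = 128,
    s_max: float | None = None,
    d_min_vec: float = 3.0,
    peak_rel_threshold: float = 0.15,
    n_candidates: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate direct-lattice vectors from the 3D FFT of the binned cloud.

    Points are histogrammed on a cubic grid of half-extent ``s_max`` (auto:
    5% beyond the farthest point); peaks of the FFT magnitude at real-space
    lengths within [d_min_vec, d_max] are refined by per-axis parabolic
    interpolation, deduplicated up to sign, and ranked by peak height with
    ties broken by shorter length.

    Returns ``(vectors (n, 3) in Å, scores)``.
    """
    pts = cloud.points if isinstance(cloud, ReciprocalCloud) else np.asarray(cloud, float)
    if len(pts) < 10:
        raise InsufficientDataError(f"need >= 10 reciprocal points, got {len(pts)}")
    if s_max is None:
        s_max = float(np.abs(pts).max()) * 1.05
    n = grid_size
    hist, _ = np.histogramdd(pts, bins=(n, n, n), range=[(-s_max, s_max)] * 3)
    mag = np.fft.fftshift(np.abs(np.fft.fftn(hist)))
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=2.0 * s_max / n))
    step = freqs[1] - freqs[0]

    local_max = ndimage.maximum_filter(mag, size=3, mode="wrap")
    peaks = (mag == local_max) & (mag > peak_rel_threshold * len(pts))
    idx = np.argwhere(peaks)
    if not len(idx):
        return np.empty((0, 3)), np.empty(0)
    lengths = np.linalg.norm(freqs[idx], axis=1)
    sel = (lengths >= d_min_vec) & (lengths <= d_max)
    idx, scores = idx[sel], mag[tuple(idx[sel].T)]
    order = np.lexsort((np.linalg.norm(freqs[idx], axis=1), -scores))

    kept_vecs: list[np.ndarray] = []
    kept_scores: list[float] = []
    for row in order:
        i, j, k = idx[row]
        t = freqs[[i, j, k]].astype(float).copy()
        # parabolic sub-grid interpolation along each axis
        for ax, ii in enumerate((i, j, k)):
            pos = [i, j, k]

            def val(d: int) -> float:
                p = list(pos)
                p[ax] = (p[ax] + d) % n
                return mag[tuple(p)]

            denom = val(-1) - 2 * val(0) + val(1)
            if denom < 0:
                t[ax] += 0.5 * (val(-1) - val(1)) / denom * step
        nz = np.flatnonzero(np.abs(t) > 1e-9)
        if len(nz) and t[nz[0]] < 0:
            t = -t
        if any(
            np.linalg.norm(t - u) < 0.5 or np.linalg.norm(t + u) < 0.5 for u in kept_vecs
        ):
            continue
        kept_vecs.append(t)
        kept_scores.append(float(mag[i, j, k]))
        if len(kept_vecs) >= n_candidates:
            break
    return np.array(kept_vecs), np.array(kept_scores)


def _primitivize_triplet(
    tri: np.ndarray, pts: np.ndarray, tol: float, min_volume: float
) -> np.ndarray:
    """Reduce a basis triplet to the primitive cell supported by the data.

    FFT candidates are dominated by long combination vectors, so the winning
    triplet may generate a sublattice of the true direct lattice (a 2× or 3×
    supercell) that still indexes every point.  Fractional combination
    vectors (c·T)/m for m ∈ {2, 3} that index the points equally well reveal
    the missing lattice vectors; replacing a triplet member divides the cell
    volume by m.  Iterates until no admissible refinement remains.
    """

    def joint(triplet: np.ndarray) -> float:
        dots = triplet @ pts.T
        ok = np.abs(dots - np.rint(dots)) <= tol
        return float(np.mean(ok[0] & ok[1] & ok[2]))

    best = tri.copy()
    best_score = joint(best)
    changed = True
    while changed:
        changed = False
        for m in (2, 3):
            coeff_range = range(m)
            for c0 in coeff_range:
                for c1 in coeff_range:
                    for c2 in coeff_range:
                        c = (c0, c1, c2)
                        if not any(c):
                            continue
                        vec = (np.array(c, float) @ best) / m
                        for i in range(3):
                            if c[i] == 0:
                                continue
                            cand = best.copy()
                            cand[i] = vec
                            if abs(np.linalg.det(cand)) < min_volume:
                                continue
                            score = joint(cand)
                            if score >= best_score - 0.02:
                                best, changed = cand, True
                                best_score = max(best_score, score)
                                break
                        if changed:
                            break
                    if changed:
                        break
                if changed:
                    break
            if changed:
                break
    return best


def _lsq_ub(points: np.ndarray, a_mat: np.ndarray, tol: float, n_iter: int = 3):
    """Iterated least-squares UB from a starting direct matrix (rows)."""
    ub = np.linalg.inv(a_mat)
    inl = None
    for _ in range(n_iter):
        frac = points @ np.linalg.inv(ub).T
        hkl = np.rint(frac)
        inl = np.all(np.abs(frac - hkl) <= tol, axis=1) & np.any(hkl != 0, axis=1)
        if inl.sum() < 6:
            return None
        h = hkl[inl]
        if np.linalg.matrix_rank(h) < 3:
            return None
        ub = np.linalg.solve(h.T @ h, h.T @ points[inl]).T
    return ub, inl, np.rint(points @ np.linalg.inv(ub).T).astype(int)


def choose_cell(
    candidates: np.ndarray,
    cloud: ReciprocalCloud | np.ndarray,
    params: IndexingParams | None = None,
    min_fraction: float | None = None,
) -> CellSolution:
    """Select the basis triplet indexing the most points, Niggli-reduce it.

    Triplets of candidate vectors are scored by the fraction of cloud points
    whose three fractional indices are all within ``index_tolerance`` of
    integers; near-degenerate triplets (volume below ``min_volume`` or
    normalized scalar triple product below ``min_normalized_volume``) are
    excluded, and among triplets within 2% of the best score the smallest
    cell volume wins.  The final UB is an iterated least-squares fit to the
    indexed points, reported on the Niggli-reduced cell.

    Raises :class:`IndexingFailureError` when no admissible triplet indexes
    at least ``min_fraction`` of the points — the dataset then counts as
    unindexed in the phase-analysis denominator.
    """
    p = params or IndexingParams()
    threshold = p.min_fraction if min_fraction is None else min_fraction
    pts = cloud.points if isinstance(cloud, ReciprocalCloud) else np.asarray(cloud, float)
    cands = np.asarray(candidates, float)
    if len(cands) < 3:
        raise IndexingFailureError("fewer than three basis candidates")
    cands = cands[: p.n_candidates]
    dots = cands @ pts.T
    near_int = np.abs(dots - np.rint(dots)) <= p.index_tolerance

    scored = []
    for i, j, k in combinations(range(len(cands)), 3):
        a_mat = cands[[i, j, k]]
        vol = abs(np.linalg.det(a_mat))
        if vol < p.min_volume:
            continue
        if vol / np.prod(np.linalg.norm(a_mat, axis=1)) < p.min_normalized_volume:
            continue
        frac_ok = float(np.mean(near_int[i] & near_int[j] & near_int[k]))
        scored.append((frac_ok, vol, (i, j, k)))
    if not scored:
        raise IndexingFailureError("no admissible basis triplet")
    best_score = max(s for s, _, _ in scored)
    if best_score < threshold:
        raise IndexingFailureError(
            f"best triplet indexes {best_score:.2f} < required {threshold:.2f}"
        )
    near_best = [c for c in scored if c[0] >= best_score - 0.02]
    near_best.sort(key=lambda c: c[1])
    _, _, (i, j, k) = near_best[0]
    triplet = _primitivize_triplet(cands[[i, j, k]], pts, p.index_tolerance, p.min_volume)

    fit = _lsq_ub(pts, triplet, p.index_tolerance)
    if fit is None:
        raise IndexingFailureError("degenerate least-squares system")
    ub, inliers, hkl_all = fit
    try:
        model = CrystalModel.from_ub(ub).niggli_reduced()
    except Exception as exc:  # degenerate metric after refinement
        raise IndexingFailureError(f"refined basis degenerate: {exc}") from exc
    # re-index against the reduced basis so hkl match the reported cell
    frac = pts @ np.linalg.inv(model.ub).T
    hkl = np.rint(frac)
    inliers = np.all(np.abs(frac - hkl) <= p.index_tolerance, axis=1) & np.any(hkl != 0, axis=1)
    return CellSolution(
        model=model,
        inliers=inliers,
        hkl=hkl[inliers].astype(int),
        fraction_indexed=float(inliers.mean()),
    )


def multi_lattice_index(
    cloud: ReciprocalCloud, params: IndexingParams | None = None
) -> IndexingSolution:
    """Decompose a (possibly aggregate) cloud into up to ``max_lattices``.

    Each pass runs the FFT basis search and triplet selection on the points
    not yet assigned, accepts a lattice if it indexes at least
    ``per_pass_min_fraction`` of them, removes its points, and repeats until
    fewer than ``stop_fraction`` of the original points remain or a pass
    fails.  Every point ends up assigned to at most one lattice.
    """
    p = params or IndexingParams()
    pts = cloud.points
    n0 = len(pts)
    assignment = np.full(n0, -1, dtype=int)
    lattices: list[CrystalModel] = []
    fractions: list[float] = []
    while len(lattices) < p.max_lattices:
        remaining = np.flatnonzero(assignment == -1)
        if len(remaining) < max(p.min_lattice_points + 3, p.stop_fraction * n0):
            break
        sub = pts[remaining]
        try:
            cands, _ = fft_find_basis(
                sub,
                d_max=p.d_max,
                grid_size=p.grid_size,
                s_max=p.s_max,
                d_min_vec=p.d_min_vec,
                peak_rel_threshold=p.peak_rel_threshold,
                n_candidates=p.n_candidates,
            )
            sol = choose_cell(cands, sub, params=p, min_fraction=p.per_pass_min_fraction)
        except (IndexingFailureError, InsufficientDataError):
            break
        if sol.inliers.sum() < p.min_lattice_points:
            break
        assignment[remaining[sol.inliers]] = len(lattices)
        lattices.append(sol.model)
        fractions.append(float(sol.inliers.sum()) / n0)
    if not lattices:
        raise IndexingFailureError("no lattice could be indexed in this cloud")
    return IndexingSolution(lattices=lattices, assignment=assignment, fraction_indexed=fractions)


@dataclass
class RefinedCell:
    model: CrystalModel
    esd: dict[str, float]
    rms_initial: float
    rms_refined: float
    n_points: int
    success: bool = True


def refine_cell(
    model: CrystalModel,
    cloud: ReciprocalCloud | np.ndarray,
    assignment: np.ndarray | None = None,
    index_tolerance: float = 0.15,
) -> RefinedCell:
    """Least-squares refinement of UB against assigned cloud points.

    Miller indices are fixed by the input model (so the refined residual can
    only decrease); parameter standard deviations are propagated from the
    residual covariance through a finite-difference Jacobian of the six cell
    parameters with respect to the UB elements.
    """
    pts = cloud.points if isinstance(cloud, ReciprocalCloud) else np.asarray(cloud, float)
    if assignment is not None:
        pts = pts[np.asarray(assignment, bool)]
    frac = pts @ np.linalg.inv(model.ub).T
    hkl = np.rint(frac)
    sel = np.all(np.abs(frac - hkl) <= index_tolerance, axis=1) & np.any(hkl != 0, axis=1)
    h, s = hkl[sel], pts[sel]
    names = ("a", "b", "c", "alpha", "beta", "gamma")
    if sel.sum() < 6 or np.linalg.matrix_rank(h) < 3:
        logger.warning("refinement skipped: rank-deficient or underdetermined system")
        return RefinedCell(model, {k: float("nan") for k in names}, float("nan"), float("nan"),
                           int(sel.sum()), success=False)
    rms0 = float(np.sqrt(np.mean(np.sum((s - h @ model.ub.T) ** 2, axis=1))))
    gram = h.T @ h
    ub = np.linalg.solve(gram, h.T @ s).T
    resid = s - h @ ub.T
    rms1 = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    dof = max(3 * len(s) - 9, 1)
    sigma2 = float(np.sum(resid**2)) / dof
    cov_rows = sigma2 * np.linalg.inv(gram)  # covariance of each UB row

    # finite-difference Jacobian of cell parameters wrt UB elements
    def cell_vec(m: np.ndarray) -> np.ndarray:
        return np.array(cell_from_ub(m).parameters)

    base = cell_vec(ub)
    jac = np.zeros((6, 9))
    delta = 1e-7
    for r in range(3):
        for c in range(3):
            d_ub = ub.copy()
            d_ub[r, c] += delta
            jac[:, 3 * r + c] = (cell_vec(d_ub) - base) / delta
    cov_ub = np.zeros((9, 9))
    for r in range(3):
        cov_ub[3 * r : 3 * r + 3, 3 * r : 3 * r + 3] = cov_rows
    esd_vals = np.sqrt(np.clip(np.diag(jac @ cov_ub @ jac.T), 0.0, None))
    refined = CrystalModel.from_ub(ub)
    return RefinedCell(
        model=refined,
        esd=dict(zip(names, map(float, esd_vals))),
        rms_initial=rms0,
        rms_refined=rms1,
        n_points=int(sel.sum()),
    )
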
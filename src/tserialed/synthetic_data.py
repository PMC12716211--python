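"""Ground-truth-annotated simulation of batch-by-batch still-ED experiments.

The generator emulates the statistical structure of a multi-phase nanocrystal
screening experiment: crystals scattered on grid positions (some aggregated,
some amorphous), visited batch-by-batch at a short list of goniometer angles,
each visit recording one still pattern.  Reflections are placed by the exact
Ewald construction, weighted by an excitation-error partiality, rendered as
Gaussian blobs over a flat background, and counted with Poisson noise.  A
sidecar :class:`GroundTruth` records every injected quantity so each
downstream stage can be tested without real data.

Intensities are Wilson-like: per-phase symmetry-unique reflections draw
i.i.d. exponential mean intensities and Laue mates share the mean, which is
what merging statistics need; real structure factors are deliberately not
modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import symmetry
from .exceptions import InvalidArgumentError
from .frame_io import FrameStack, read_frames, write_frames  # noqa: F401  (module surface)
from .geometry import (
    BeamModel,
    CrystalModel,
    DetectorGeometry,
    UnitCell,
    project_to_detector,
    reciprocal_basis,
    tilt_axis_from_azimuth,
)

__all__ = [
    "PhaseDefinition",
    "AcquisitionSchedule",
    "NoiseModel",
    "GroundTruth",
    "FrameStack",
    "make_schedule",
    "simulate_experiment",
    "simulate_tilt_series_spots",
    "random_orientation",
    "draw_position_assignments",
    "default_geometry",
    "default_beam",
    "default_tilt_angles",
    "six_phase_mixture",
    "write_frames",
    "read_frames",
]

DEFAULT_TILT_ANGLES = tuple(float(x) for x in range(-30, 31, 10))


def default_tilt_angles() -> tuple[float, ...]:
    """Seven stills from −30° to +30° in 10° steps (configurable elsewhere)."""
    return DEFAULT_TILT_ANGLES


def default_geometry() -> DetectorGeometry:
    """Desk-scale 256² detector, 0.1 mm pixels, 650 mm camera length."""
    return DetectorGeometry(
        distance_mm=650.0, pixel_size_mm=0.1, n_fast=256, n_slow=256, beam_center=(128.0, 128.0)
    )


def default_beam() -> BeamModel:
    return BeamModel(voltage_kv=200.0)


@dataclass(frozen=True)
class PhaseDefinition:
    """One crystalline phase of the mixture."""

    name: str
    cell: UnitCell
    density: float  # g/cm^3
    laue_group: str = "-1"
    wilson_mean: float = 1.0  # mean of the exponential intensity prior

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise InvalidArgumentError(f"density must be positive, got {self.density}")
        if self.laue_group not in symmetry.supported_laue_groups():
            raise InvalidArgumentError(f"unsupported Laue group {self.laue_group!r}")


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Batch-by-batch visit order: all positions at one angle, then the next.

    The stage therefore changes angle only ``len(tilt_angles) - 1`` times for
    the whole experiment, which is the throughput advantage over
    crystal-by-crystal rotation.
    """

    positions: tuple[tuple[int, float, float], ...]  # (position_id, grid_x, grid_y)
    tilt_angles: tuple[float, ...]
    ordering: tuple[tuple[int, float, int], ...]  # (position_id, angle, batch_index)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def n_stage_rotations(self) -> int:
        return len(self.tilt_angles) - 1


def make_schedule(n_positions: int, tilt_angles: list[float] | tuple[float, ...]) -> AcquisitionSchedule:
    if n_positions < 1:
        raise InvalidArgumentError("need at least one stage position")
    angles = tuple(float(a) for a in tilt_angles)
    if len(set(angles)) != len(angles):
        raise InvalidArgumentError(f"duplicate tilt angles in {angles}")
    diffs = np.diff(angles)
    if len(diffs) and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise InvalidArgumentError("tilt angles must be strictly monotone")
    side = int(np.ceil(np.sqrt(n_positions)))
    positions = tuple((i, float(i % side), float(i // side)) for i in range(n_positions))
    ordering = tuple(
        (pid, angle, batch)
        for batch, angle in enumerate(angles)
        for pid, _, _ in positions
    )
    return AcquisitionSchedule(positions=positions, tilt_angles=angles, ordering=ordering)


@dataclass
class NoiseModel:
    """Rendering and noise parameters of the simulated acquisition.

    ``eps_max`` is the excitation-error half-width within which a reflection
    is recorded; ``sigma_e`` the Gaussian rocking width of the partiality
    P = exp(−ε²/2σ_e²).  Defaults put typical partialities in (0.1, 1.0).
    """

    d_min: float = 1.3                # resolution limit of generated spots, Å
    eps_max: float = 0.002            # acceptance half-width, 1/Å
    sigma_e: float = 0.001            # rocking width, 1/Å
    scale: float = 2000.0             # counts per unit mean intensity at P=1
    background: float = 5.0           # flat background counts per pixel
    blob_sigma_px: float = 1.2        # rendered spot width
    drift_sigma_px: float = 0.7       # beam-center random-walk step per frame
    drift_max_px: float = 5.0
    beam_counts: float = 30000.0      # direct-beam blob integral
    beam_sigma_px: float = 2.0
    poisson: bool = True


@dataclass
class GroundTruth:
    """Loss-less record of everything the simulator injected."""

    phases: list[str]
    positions: list[dict]          # per position: {position_id, status, lattices:[{phase, u}]}
    drift: dict[int, tuple[float, float]] = field(default_factory=dict)  # frame_id -> (dfast, dslow)
    spots: dict[int, list[dict]] = field(default_factory=dict)           # frame_id -> spot dicts
    seed: int | None = None

    def lattices_of(self, position_id: int) -> list[dict]:
        return self.positions[position_id]["lattices"]

    def indexed_phase_counts(self) -> dict[str, int]:
        """Ground-truth lattice count per phase over non-amorphous positions."""
        counts: dict[str, int] = {}
        for pos in self.positions:
            for lat in pos["lattices"]:
                counts[lat["phase"]] = counts.get(lat["phase"], 0) + 1
        return counts

    def to_json(self, path: str | Path) -> None:
        payload = {
            "phases": self.phases,
            "positions": self.positions,
            "drift": {str(k): list(v) for k, v in self.drift.items()},
            "spots": {str(k): v for k, v in self.spots.items()},
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            phases=payload["phases"],
            positions=payload["positions"],
            drift={int(k): tuple(v) for k, v in payload["drift"].items()},
            spots={int(k): v for k, v in payload["spots"].items()},
            seed=payload["seed"],
        )


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via the normalized-quaternion method."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def draw_position_assignments(
    rng: np.random.Generator,
    n_positions: int,
    phases: list[PhaseDefinition],
    mixture_fractions: np.ndarray,
    aggregate_fraction: float,
    failure_fraction: float,
) -> list[dict]:
    """Assign each position a status and list of (phase index, orientation).

    Aggregates carry 2 or 3 lattices with probability 0.7/0.3, each with an
    independently drawn phase, mirroring multi-crystal patterns where up to
    three lattices overlap on one still.
    """
    out = []
    for pid in range(n_positions):
        if rng.random() < failure_fraction:
            out.append({"position_id": pid, "status": "amorphous", "lattices": []})
            continue
        n_lat = 1
        if rng.random() < aggregate_fraction:
            n_lat = 2 if rng.random() < 0.7 else 3
        lattices = []
        for _ in range(n_lat):
            k = int(rng.choice(len(phases), p=mixture_fractions))
            lattices.append({"phase": phases[k].name, "phase_index": k, "u": random_orientation(rng).tolist()})
        out.append({"position_id": pid, "status": "crystal", "lattices": lattices})
    return out


def _hkl_grid(cell: UnitCell, d_min: float) -> np.ndarray:
    bounds = [int(np.ceil(length / d_min)) + 1 for length in (cell.a, cell.b, cell.c)]
    h, k, l = np.meshgrid(*[np.arange(-m, m + 1) for m in bounds], indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    s = hkl @ reciprocal_basis(cell).T
    return hkl[np.linalg.norm(s, axis=1) <= 1.0 / d_min]


class _IntensityLibrary:
    """Per-phase exponential mean intensities, shared across Laue mates."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng
        self._tables: dict[str, dict[tuple[int, int, int], float]] = {}

    def lookup(self, phase: PhaseDefinition, hkl: np.ndarray) -> np.ndarray:
        table = self._tables.setdefault(phase.name, {})
        reps = symmetry.unique_hkl(hkl, phase.laue_group)
        means = np.empty(len(hkl))
        for i, rep in enumerate(map(tuple, reps)):
            if rep not in table:
                table[rep] = float(self._rng.exponential(phase.wilson_mean))
            means[i] = table[rep]
        return means


def _render_blobs(image: np.ndarray, fast: np.ndarray, slow: np.ndarray, integral: np.ndarray, sigma: float) -> None:
    ny, nx = image.shape
    half = int(np.ceil(4 * sigma))
    for f0, s0, total in zip(fast, slow, integral):
        i0, j0 = int(round(s0)), int(round(f0))
        ilo, ihi = max(0, i0 - half), min(ny, i0 + half + 1)
        jlo, jhi = max(0, j0 - half), min(nx, j0 + half + 1)
        if ilo >= ihi or jlo >= jhi:
            continue
        ii = np.arange(ilo, ihi)[:, None]
        jj = np.arange(jlo, jhi)[None, :]
        g = np.exp(-((ii - s0) ** 2 + (jj - f0) ** 2) / (2 * sigma**2))
        image[ilo:ihi, jlo:jhi] += total * g / (2 * np.pi * sigma**2)


def _frame_spots(
    phase: PhaseDefinition,
    u: np.ndarray,
    theta: float,
    geom: DetectorGeometry,
    beam: BeamModel,
    noise: NoiseModel,
    axis: np.ndarray,
    hkl_cache: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Reflections of one lattice excited on one still: (hkl, fast, slow, eps)."""
    if phase.name not in hkl_cache:
        hkl_cache[phase.name] = _hkl_grid(phase.cell, noise.d_min)
    hkl = hkl_cache[phase.name]
    model = CrystalModel(cell=phase.cell, u=np.asarray(u))
    s0 = hkl @ model.ub.T
    fast, slow, eps, ok = project_to_detector(s0, geom, beam, theta_deg=theta, axis=axis)
    keep = ok & (np.abs(eps) <= noise.eps_max)
    return hkl[keep], fast[keep], slow[keep], eps[keep]


def simulate_experiment(
    phases: list[PhaseDefinition],
    mixture_fractions: list[float],
    schedule: AcquisitionSchedule,
    noise: NoiseModel | None = None,
    aggregate_fraction: float = 0.15,
    failure_fraction: float = 0.1,
    seed: int = 0,
    geom: DetectorGeometry | None = None,
    beam: BeamModel | None = None,
    tilt_axis_azimuth_deg: float = 0.0,
) -> tuple[FrameStack, GroundTruth]:
    """Render a full batch-by-batch experiment and its ground-truth sidecar."""
    noise = noise or NoiseModel()
    geom = geom or default_geometry()
    beam = beam or default_beam()
    fractions = np.asarray(mixture_fractions, dtype=float)
    if len(fractions) != len(phases):
        raise InvalidArgumentError("one mixture fraction per phase required")
    if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-9:
        raise InvalidArgumentError("mixture fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    axis = tilt_axis_from_azimuth(tilt_axis_azimuth_deg)

    assignments = draw_position_assignments(
        rng, schedule.n_positions, phases, fractions, aggregate_fraction, failure_fraction
    )
    library = _IntensityLibrary(rng)
    hkl_cache: dict[str, np.ndarray] = {}
    phase_by_index = {i: p for i, p in enumerate(phases)}

    # beam-center random walk per position (crystal tracking re-centers per visit)
    drift_state = np.zeros((schedule.n_positions, 2))

    frames, meta_rows = [], []
    truth = GroundTruth(phases=[p.name for p in phases], positions=assignments, seed=seed)
    frame_id = 0
    for pid, theta, batch in schedule.ordering:
        drift_state[pid] = np.clip(
            drift_state[pid] + rng.normal(0.0, noise.drift_sigma_px, 2),
            -noise.drift_max_px,
            noise.drift_max_px,
        )
        dfast, dslow = drift_state[pid]
        image = np.full((geom.n_slow, geom.n_fast), float(noise.background))
        _render_blobs(
            image,
            np.array([geom.beam_center[0] + dfast]),
            np.array([geom.beam_center[1] + dslow]),
            np.array([noise.beam_counts]),
            noise.beam_sigma_px,
        )
        spot_records = []
        for lat_idx, lat in enumerate(assignments[pid]["lattices"]):
            phase = phase_by_index[lat["phase_index"]]
            hkl, fast, slow, eps = _frame_spots(
                phase, np.array(lat["u"]), theta, geom, beam, noise, axis, hkl_cache
            )
            if not len(hkl):
                continue
            partial = np.exp(-(eps**2) / (2 * noise.sigma_e**2))
            counts = noise.scale * library.lookup(phase, hkl) * partial
            f_d, s_d = fast + dfast, slow + dslow
            inb = (f_d >= 0) & (f_d <= geom.n_fast - 1) & (s_d >= 0) & (s_d <= geom.n_slow - 1)
            _render_blobs(image, f_d[inb], s_d[inb], counts[inb], noise.blob_sigma_px)
            for m in np.flatnonzero(inb):
                spot_records.append(
                    {
                        "hkl": [int(x) for x in hkl[m]],
                        "lattice": lat_idx,
                        "fast": float(f_d[m]),
                        "slow": float(s_d[m]),
                        "partiality": float(partial[m]),
                        "intensity": float(counts[m]),
                        "eps": float(eps[m]),
                    }
                )
        if noise.poisson:
            frame = rng.poisson(image).astype(np.int32)
        else:
            frame = np.rint(image).astype(np.int32)
        frames.append(frame)
        meta_rows.append(
            {"frame_id": frame_id, "position_id": pid, "batch_index": batch, "tilt_angle": theta}
        )
        truth.drift[frame_id] = (float(dfast), float(dslow))
        truth.spots[frame_id] = spot_records
        frame_id += 1

    stack = FrameStack(np.stack(frames), pd.DataFrame(meta_rows))
    return stack, truth


def simulate_tilt_series_spots(
    cell: UnitCell,
    orientation: np.ndarray,
    tilt_angles: tuple[float, ...],
    geom: DetectorGeometry,
    beam: BeamModel,
    d_min: float = 1.3,
    eps_max: float = 0.002,
    centroid_noise_px: float = 0.0,
    rng: np.random.Generator | None = None,
    axis: np.ndarray | None = None,
) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Spot-level tilt series: per angle, (angle, centroids (n,2), hkl (n,3)).

    Bypasses image rendering; centroid noise is added directly in pixels.
    Used for large population studies of cell-recovery precision.
    """
    rng = rng or np.random.default_rng(0)
    axis = tilt_axis_from_azimuth(0.0) if axis is None else np.asarray(axis, float)
    model = CrystalModel(cell=cell, u=np.asarray(orientation))
    hkl = _hkl_grid(cell, d_min)
    s0 = hkl @ model.ub.T
    out = []
    for theta in tilt_angles:
        fast, slow, eps, ok = project_to_detector(s0, geom, beam, theta_deg=theta, axis=axis)
        keep = ok & (np.abs(eps) <= eps_max)
        f, s = fast[keep], slow[keep]
        if centroid_noise_px > 0:
            f = f + rng.normal(0.0, centroid_noise_px, f.shape)
            s = s + rng.normal(0.0, centroid_noise_px, s.shape)
            inb = geom.in_bounds(f, s)
            f, s = f[inb], s[inb]
            out.append((theta, np.stack([f, s], axis=1), hkl[keep][inb]))
        else:
            out.append((theta, np.stack([f, s], axis=1), hkl[keep]))
    return out


def six_phase_mixture() -> list[PhaseDefinition]:
    """Demo mixture of six low-symmetry phases with distinct reduced cells.

    Cells and densities are desk-scale stand-ins inspired by common molecular
    solids (amino acids, a vitamin, metal acetates, a sweetener); the reduced
    cells are mutually separated by >5 Å in 6-parameter Euclidean distance so
    dendrogram clustering at the default threshold is unambiguous.
    """
    specs = [
        ("glycine", (5.10, 11.97, 5.46, 90.0, 111.74, 90.0), 1.607),
        ("ascorbic-acid", (17.30, 6.10, 6.60, 90.0, 102.18, 90.0), 1.65),
        ("zinc-acetate", (14.50, 5.32, 11.02, 90.0, 100.0, 90.0), 1.74),
        ("saccharin", (9.55, 6.91, 11.80, 90.0, 103.9, 90.0), 1.43),
        ("magnesium-acetate", (11.29, 10.68, 4.75, 90.0, 95.2, 90.0), 1.45),
        ("glutamic-acid", (5.16, 17.30, 6.95, 90.0, 90.0, 90.0), 1.54),
    ]
    return [
        PhaseDefinition(name=name, cell=UnitCell(*params), density=rho, laue_group="-1")
        for name, params, rho in specs
    ]
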
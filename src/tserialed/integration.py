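"""Still-shot integration: per-frame orientation, prediction, extraction.

After indexing, the tilt series is ungrouped: every still is treated as an
independent crystal whose orientation matrix is the zero-tilt UB propagated
by the goniometer rotation, UB(θ) = R(axis, θ)·UB(0).  Reflections close
enough to the Ewald sphere are predicted, summed with local background
subtraction, and divided by a Gaussian-rocking partiality
P = exp(−ε²/2σ_e²) to approximate full intensities.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .exceptions import InvalidArgumentError
from .frame_io import FrameStack
from .geometry import (
    BeamModel,
    CrystalModel,
    DetectorGeometry,
    project_to_detector,
    reciprocal_basis,
    rotation_about_axis,
    tilt_axis_from_azimuth,
)
from .indexing import IndexingSolution
from .preprocessing import TiltSeries

logger = logging.getLogger(__name__)

__all__ = [
    "propagate_orientation",
    "predict_reflections",
    "partiality",
    "integrate_spot",
    "integrate_series",
    "estimate_sigma_e",
]

P_MIN = 0.05  # below this the 1/P correction amplifies noise unacceptably


def propagate_orientation(
    model: CrystalModel, theta_deg: float, axis: np.ndarray | None = None
) -> CrystalModel:
    """Orientation of the still at tilt θ: U(θ) = R(axis, θ)·U(0); cell unchanged."""
    axis = tilt_axis_from_azimuth(0.0) if axis is None else np.asarray(axis, float)
    return CrystalModel(cell=model.cell, u=rotation_about_axis(axis, theta_deg) @ model.u)


def predict_reflections(
    model: CrystalModel,
    beam: BeamModel,
    geom: DetectorGeometry,
    d_min: float,
    eps_max: float,
    sigma_e: float = 0.001,
    theta_deg: float = 0.0,
    axis: np.ndarray | None = None,
) -> pd.DataFrame:
    """All reflections excited on one still.

    Enumerates every integer hkl with d >= d_min (never (0,0,0)), computes
    the exact excitation error, and keeps |ε| <= eps_max with an in-bounds
    detector projection.  Columns: h, k, l, fast, slow, eps, partiality.
    """
    if d_min <= 0:
        raise InvalidArgumentError("d_min must be positive")
    cell = model.cell
    bounds = [int(np.ceil(length / d_min)) + 1 for length in (cell.a, cell.b, cell.c)]
    h, k, l = np.meshgrid(*[np.arange(-m, m + 1) for m in bounds], indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    s0 = hkl @ model.ub.T
    res_ok = np.linalg.norm(s0, axis=1) <= 1.0 / d_min
    hkl, s0 = hkl[res_ok], s0[res_ok]
    fast, slow, eps, ok = project_to_detector(s0, geom, beam, theta_deg=theta_deg, axis=axis)
    keep = ok & (np.abs(eps) <= eps_max)
    return pd.DataFrame(
        {
            "h": hkl[keep, 0],
            "k": hkl[keep, 1],
            "l": hkl[keep, 2],
            "fast": fast[keep],
            "slow": slow[keep],
            "eps": eps[keep],
            "partiality": partiality(eps[keep], sigma_e),
        }
    )


def partiality(eps: np.ndarray | float, sigma_e: float, p_min: float = P_MIN) -> np.ndarray | float:
    """Recorded fraction of a reflection at excitation error ε.

    Gaussian rocking profile: P = exp(−ε²/2σ_e²), clamped below at p_min.
    """
    if sigma_e <= 0:
        raise InvalidArgumentError("sigma_e must be positive")
    p = np.exp(-np.square(eps) / (2.0 * sigma_e**2))
    return np.maximum(p, p_min)


def estimate_sigma_e(eps_values: np.ndarray, eps_max: float) -> float:
    """Maximum-likelihood rocking width from matched excitation errors.

    Models observed ε as a zero-mean Gaussian truncated to |ε| <= eps_max
    (the acceptance window of the spot finder) and maximizes the profile
    likelihood over σ_e.
    """
    eps_values = np.asarray(eps_values, float)
    if len(eps_values) < 5:
        raise InvalidArgumentError("need at least 5 matched reflections")
    from scipy.stats import norm

    def nll(log_sigma: float) -> float:
        sig = np.exp(log_sigma)
        z = eps_max / sig
        log_norm = np.log(np.maximum(norm.cdf(z) - norm.cdf(-z), 1e-300))
        return float(np.sum(eps_values**2) / (2 * sig**2) + len(eps_values) * (np.log(sig) + log_norm))

    res = minimize_scalar(nll, bounds=(np.log(eps_max / 100), np.log(eps_max * 10)), method="bounded")
    return float(np.exp(res.x))


def integrate_spot(
    frame: np.ndarray,
    center: tuple[float, float],
    peak_radius: float = 3.0,
    bg_inner: float = 5.0,
    bg_outer: float = 8.0,
) -> tuple[float, float, bool]:
    """Background-subtracted summation at one predicted position.

    I = Σ(peak disk) − n_peak·median(annulus); σ from Poisson counts in the
    peak plus the variance of the median background estimate.  Returns
    ``(I, sigma, edge_flag)``; when the peak disk leaves the image the
    observation is flagged and must be discarded by the caller.
    """
    if not (peak_radius < bg_inner < bg_outer):
        raise InvalidArgumentError("radii must satisfy peak < bg_inner < bg_outer")
    ny, nx = frame.shape
    f0, s0 = center
    r = int(np.ceil(bg_outer))
    i0, j0 = int(round(s0)), int(round(f0))
    if i0 - peak_radius < 0 or i0 + peak_radius >= ny or j0 - peak_radius < 0 or j0 + peak_radius >= nx:
        return 0.0, 1.0, True
    ilo, ihi = max(0, i0 - r), min(ny, i0 + r + 1)
    jlo, jhi = max(0, j0 - r), min(nx, j0 + r + 1)
    sub = np.asarray(frame[ilo:ihi, jlo:jhi], dtype=float)
    ii = np.arange(ilo, ihi)[:, None] - s0
    jj = np.arange(jlo, jhi)[None, :] - f0
    rho = np.sqrt(ii**2 + jj**2)
    peak = rho <= peak_radius
    annulus = (rho >= bg_inner) & (rho <= bg_outer)
    if annulus.sum() < 4:
        return 0.0, 1.0, True
    bg = float(np.median(sub[annulus]))
    n_peak = int(peak.sum())
    intensity = float(sub[peak].sum()) - n_peak * bg
    # median estimator variance ≈ (π/2)·var/n for near-Gaussian backgrounds
    bg_var = float(np.var(sub[annulus])) * (np.pi / 2.0) / annulus.sum()
    var = max(float(sub[peak].sum()), 0.0) + n_peak**2 * bg_var
    return intensity, float(np.sqrt(max(var, 1.0))), False


def integrate_series(
    series: TiltSeries,
    solution: IndexingSolution,
    frames: FrameStack,
    geom: DetectorGeometry,
    beam: BeamModel,
    d_min: float = 1.3,
    eps_max: float = 0.002,
    sigma_e: float = 0.001,
    axis: np.ndarray | None = None,
    peak_radius: float = 3.0,
    bg_inner: float = 5.0,
    bg_outer: float = 8.0,
    p_min: float = P_MIN,
) -> pd.DataFrame:
    """Integrate every still of an indexed series, for every lattice.

    Each (frame, lattice) pair gets its propagated orientation, a prediction
    list, background-subtracted summation, and the 1/P partiality correction.
    Observations with P < p_min or a peak region off the detector are
    dropped (counted in the log).  Columns: position_id, lattice_id,
    frame_id, h, k, l, I, sigma, partiality, eps, I_corr, sigma_corr.
    """
    rows = []
    n_clamped = 0
    for frame_id, theta in series.frames:
        img = frames.frame_by_id(frame_id)
        for lat_id, model in enumerate(solution.lattices):
            pred = predict_reflections(
                model, beam, geom, d_min=d_min, eps_max=eps_max, sigma_e=sigma_e,
                theta_deg=theta, axis=axis,
            )
            for rec in pred.itertuples():
                intensity, sig, edge = integrate_spot(
                    img, (rec.fast, rec.slow), peak_radius, bg_inner, bg_outer
                )
                if edge:
                    continue
                p = float(partiality(rec.eps, sigma_e, p_min=p_min))
                if np.exp(-(rec.eps**2) / (2 * sigma_e**2)) < p_min:
                    n_clamped += 1
                    continue
                rows.append(
                    {
                        "position_id": series.position_id,
                        "lattice_id": lat_id,
                        "frame_id": frame_id,
                        "h": int(rec.h), "k": int(rec.k), "l": int(rec.l),
                        "I": intensity,
                        "sigma": sig,
                        "partiality": p,
                        "eps": float(rec.eps),
                        "I_corr": intensity / p,
                        "sigma_corr": sig / p,
                    }
                )
    if n_clamped:
        logger.info("discarded %d observations with partiality below %.2f", n_clamped, p_min)
    columns = [
        "position_id", "lattice_id", "frame_id", "h", "k", "l",
        "I", "sigma", "partiality", "eps", "I_corr", "sigma_corr",
    ]
    return pd.DataFrame(rows, columns=columns)
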
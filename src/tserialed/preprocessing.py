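"""Beam-center drift correction and regrouping into per-crystal tilt series."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DataIntegrityError, InvalidArgumentError
from .frame_io import FrameStack

logger = logging.getLogger(__name__)

__all__ = ["TiltSeries", "correct_center_drift", "regroup"]


@dataclass
class TiltSeries:
    """Frames of one stage position, ordered by tilt angle."""

    position_id: int
    frames: list[tuple[int, float]]  # (frame_id, tilt_angle), sorted by angle
    drift_corrected: bool = False

    def __post_init__(self) -> None:
        if not self.frames:
            raise InvalidArgumentError("a tilt series needs at least one frame")
        angles = [a for _, a in self.frames]
        if any(b < a for a, b in zip(angles, angles[1:])):
            self.frames = sorted(self.frames, key=lambda fa: fa[1])

    @property
    def tilt_angles(self) -> list[float]:
        return [a for _, a in self.frames]

    def __len__(self) -> int:
        return len(self.frames)


def _integer_shift(reference: np.ndarray, frame: np.ndarray, crop: int) -> tuple[int, int]:
    """Integer-pixel translation maximizing the cross-correlation of crops.

    Returned as the shift to APPLY to ``frame`` so it registers onto the
    reference (phase-correlation via FFT on the central crop).
    """
    ny, nx = reference.shape
    cy, cx = ny // 2, nx // 2
    half = min(crop // 2, cy, cx)
    ref = reference[cy - half : cy + half, cx - half : cx + half].astype(float)
    img = frame[cy - half : cy + half, cx - half : cx + half].astype(float)
    ref = ref - ref.mean()
    img = img - img.mean()
    corr = np.fft.irfft2(np.fft.rfft2(ref) * np.conj(np.fft.rfft2(img)), s=ref.shape)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    shifts = []
    for p, n in zip(peak, corr.shape):
        shifts.append(p - n if p > n // 2 else p)
    return int(shifts[1]), int(shifts[0])  # (dfast, dslow)


def _beam_centroid(
    frame: np.ndarray, crop: int, search_radius: int = 15
) -> tuple[float, float] | None:
    """Continuous centroid of the direct-beam blob near the frame center.

    The peak search is smoothed to the beam-blob width and restricted to the
    plausible drift range so a strong Bragg spot further out cannot win.
    """
    ny, nx = frame.shape
    cy, cx = ny // 2, nx // 2
    half = min(crop // 2, cy, cx)
    sub = frame[cy - half : cy + half, cx - half : cx + half].astype(float)
    if not sub.any():
        return None
    smooth = ndimage.gaussian_filter(sub, sigma=3.0, mode="nearest")
    sy, sx = sub.shape
    rlo, rhi = max(0, sy // 2 - search_radius), min(sy, sy // 2 + search_radius + 1)
    clo, chi = max(0, sx // 2 - search_radius), min(sx, sx // 2 + search_radius + 1)
    window = smooth[rlo:rhi, clo:chi]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    iy, ix = iy + rlo, ix + clo
    w = 7  # the beam blob is a few pixels wide
    ilo, ihi = max(0, iy - w), min(sub.shape[0], iy + w + 1)
    jlo, jhi = max(0, ix - w), min(sub.shape[1], ix + w + 1)
    win = sub[ilo:ihi, jlo:jhi] - np.median(sub)
    win = np.clip(win, 0.0, None)
    total = win.sum()
    if total <= 0:
        return None
    yy = np.arange(ilo, ihi)[:, None]
    xx = np.arange(jlo, jhi)[None, :]
    slow = float((yy * win).sum() / total) + (cy - half)
    fast = float((xx * win).sum() / total) + (cx - half)
    return fast, slow


def correct_center_drift(
    stack: FrameStack,
    reference: int | None = None,
    crop: int = 128,
    beam_center: tuple[float, float] | None = None,
) -> tuple[FrameStack, pd.DataFrame]:
    """Register every frame onto its position's reference frame.

    The direct-beam region dominates the central crop, so cross-correlation
    locks onto the pattern center.  Shifts are integer pixels (drift is only
    a few pixels; sub-pixel registration buys nothing for spot integration).
    When ``beam_center`` is given, each position's reference frame is
    additionally anchored to it through the direct-beam centroid, so the
    whole series shares the nominal center instead of inheriting the
    reference frame's own drift.  Out-of-frame pixels are zero-filled.
    Returns the corrected stack and a table (frame_id, dfast, dslow) of
    applied offsets.
    """
    meta = stack.metadata
    corrected = stack.frames.copy()
    offsets = []
    for pid, group in meta.groupby("position_id"):
        order = group.sort_values(["tilt_angle", "frame_id"]).index
        if reference is not None and reference in set(meta.loc[order, "frame_id"]):
            ref_idx = meta.index[meta["frame_id"] == reference][0]
        else:
            ref_idx = order[0]
        ref_img = stack.frames[ref_idx]
        anchor_fast = anchor_slow = 0
        if beam_center is not None:
            centroid = _beam_centroid(ref_img, crop)
            if centroid is not None:
                anchor_fast = int(round(beam_center[0] - centroid[0]))
                anchor_slow = int(round(beam_center[1] - centroid[1]))
        for idx in order:
            img = stack.frames[idx]
            if not img.any():
                logger.warning("frame %d is all zero; offset (0, 0)", meta.loc[idx, "frame_id"])
                dfast = dslow = 0
            elif idx == ref_idx:
                dfast, dslow = anchor_fast, anchor_slow
            else:
                dfast, dslow = _integer_shift(ref_img, img, crop)
                dfast += anchor_fast
                dslow += anchor_slow
            if dfast or dslow:
                corrected[idx] = ndimage.shift(img, (dslow, dfast), order=0, cval=0)
            offsets.append({"frame_id": int(meta.loc[idx, "frame_id"]), "dfast": dfast, "dslow": dslow})
    out = FrameStack(corrected, meta.copy())
    return out, pd.DataFrame(offsets).sort_values("frame_id").reset_index(drop=True)


def regroup(stack: FrameStack) -> list[TiltSeries]:
    """Regroup the batch-ordered stack into one tilt series per position.

    Patterns of the same crystal recorded in different batches become one
    stepwise-rotation dataset.  Invariant to any permutation of the input
    frame order; a duplicated (position, angle) visit is a hard error.
    """
    meta = stack.metadata
    dup = meta.duplicated(subset=["position_id", "tilt_angle"], keep=False)
    if dup.any():
        row = meta[dup].iloc[0]
        raise DataIntegrityError(
            f"duplicate visit for position {int(row['position_id'])} "
            f"at angle {float(row['tilt_angle'])}"
        )
    series = []
    for pid, group in meta.groupby("position_id", sort=True):
        ordered = group.sort_values("tilt_angle")
        series.append(
            TiltSeries(
                position_id=int(pid),
                frames=[(int(r.frame_id), float(r.tilt_angle)) for r in ordered.itertuples()],
            )
        )
    assert sum(len(s) for s in series) == len(stack)
    return series
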
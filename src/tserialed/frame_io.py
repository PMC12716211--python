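"""Frame containers and on-disk formats.

Three interchangeable containers are supported:

* ``hdf5``     — one ``.h5`` file with ``/frames`` and ``/metadata/*`` tables;
* ``mrc-like`` — a minimal MRC stack (1024-byte header, mode 1 = signed 16-bit)
  plus a JSON metadata sidecar, mirroring how stepwise-rotation acquisitions
  are stored by microscope control software;
* ``smv-like`` — one ``.img`` per frame with a 512-byte ASCII header and
  unsigned 16-bit pixels, the conversion target used by still-shot
  integration programs.

Pixel data round-trips losslessly as long as counts fit the 16-bit range;
overflowing pixels are clipped with a logged warning.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .exceptions import FrameParseError, InvalidArgumentError, UnsupportedFormatError

logger = logging.getLogger(__name__)

_META_COLUMNS = ["frame_id", "position_id", "batch_index", "tilt_angle"]


@dataclass
class FrameStack:
    """Stack of still frames with per-frame acquisition metadata.

    ``frames`` has shape (n, slow, fast) with non-negative integer counts;
    ``metadata`` has one row per frame with columns
    frame_id, position_id, batch_index, tilt_angle.
    """

    frames: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidArgumentError("frames must be a (n, slow, fast) array")
        if not np.issubdtype(self.frames.dtype, np.integer):
            raise InvalidArgumentError("frame counts must be integer-valued")
        if self.frames.size and self.frames.min() < 0:
            raise InvalidArgumentError("frame counts must be non-negative")
        missing = [c for c in _META_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise InvalidArgumentError(f"metadata missing columns {missing}")
        if len(self.metadata) != len(self.frames):
            raise InvalidArgumentError("metadata length does not match frame count")
        self.metadata = self.metadata.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frames)

    def frame_by_id(self, frame_id: int) -> np.ndarray:
        idx = self.metadata.index[self.metadata["frame_id"] == frame_id]
        if len(idx) != 1:
            raise InvalidArgumentError(f"frame id {frame_id} not found (or duplicated)")
        return self.frames[idx[0]]

    def equals(self, other: "FrameStack") -> bool:
        return bool(
            np.array_equal(self.frames, other.frames)
            and len(self.metadata) == len(other.metadata)
            and np.allclose(
                self.metadata[_META_COLUMNS].to_numpy(float),
                other.metadata[_META_COLUMNS].to_numpy(float),
            )
        )


def _clip_counts(frames: np.ndarray, lo: int, hi: int) -> np.ndarray:
    n_clipped = int(np.count_nonzero((frames < lo) | (frames > hi)))
    if n_clipped:
        logger.warning("clipping %d pixels outside [%d, %d] for 16-bit storage", n_clipped, lo, hi)
    return np.clip(frames, lo, hi)


# ---------------------------------------------------------------------------
# HDF5

def _write_hdf5(stack: FrameStack, path: Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("frames", data=_clip_counts(stack.frames, 0, 65535).astype(np.uint16))
        grp = fh.create_group("metadata")
        for col in _META_COLUMNS:
            grp.create_dataset(col, data=stack.metadata[col].to_numpy())


def _read_hdf5(path: Path) -> FrameStack:
    with h5py.File(path, "r") as fh:
        frames = fh["frames"][()].astype(np.int32)
        meta = pd.DataFrame({col: fh["metadata"][col][()] for col in _META_COLUMNS})
    return FrameStack(frames, meta)


# ---------------------------------------------------------------------------
# MRC-like: 1024-byte header, mode 1 (int16) stack + JSON sidecar

_MRC_HEADER = struct.Struct("<10i")  # nx ny nz mode nxstart nystart nzstart mx my mz


def _write_mrc_like(stack: FrameStack, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    n, ny, nx = stack.frames.shape
    data = _clip_counts(stack.frames, 0, 32767).astype("<i2")
    header = bytearray(1024)
    _MRC_HEADER.pack_into(header, 0, nx, ny, n, 1, 0, 0, 0, nx, ny, n)
    with open(path / "frames.mrc", "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())
    stack.metadata.to_json(path / "metadata.json", orient="records", indent=1)


def _read_mrc_like(path: Path) -> FrameStack:
    mrc = path / "frames.mrc"
    raw = mrc.read_bytes()
    if len(raw) < 1024:
        raise FrameParseError(f"{mrc}: truncated header")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    if mode != 1:
        raise FrameParseError(f"{mrc}: unsupported MRC mode {mode}")
    expected = 1024 + 2 * nx * ny * nz
    if len(raw) < expected:
        got_frames = (len(raw) - 1024) // (2 * nx * ny)
        raise FrameParseError(f"{mrc}: truncated at frame {got_frames} of {nz}")
    frames = np.frombuffer(raw, dtype="<i2", count=nx * ny * nz, offset=1024)
    frames = frames.reshape(nz, ny, nx).astype(np.int32)
    meta = pd.read_json(path / "metadata.json", orient="records")
    return FrameStack(frames, meta)


# ---------------------------------------------------------------------------
# SMV-like: per-frame .img, 512-byte ASCII header + uint16 little-endian

def _smv_header(meta_row: pd.Series, ny: int, nx: int) -> bytes:
    fields = {
        "HEADER_BYTES": 512,
        "DIM": 2,
        "BYTE_ORDER": "little_endian",
        "TYPE": "unsigned_short",
        "SIZE1": nx,
        "SIZE2": ny,
        "FRAME_ID": int(meta_row["frame_id"]),
        "POSITION_ID": int(meta_row["position_id"]),
        "BATCH_INDEX": int(meta_row["batch_index"]),
        "TILT_ANGLE": float(meta_row["tilt_angle"]),
    }
    body = "{\n" + "".join(f"{k}={v};\n" for k, v in fields.items()) + "}\n"
    if len(body) > 512:  # pragma: no cover
        raise InvalidArgumentError("SMV header overflow")
    return body.encode("ascii").ljust(512)


def _write_smv_like(stack: FrameStack, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    data = _clip_counts(stack.frames, 0, 65535).astype("<u2")
    for i in range(len(stack)):
        row = stack.metadata.iloc[i]
        fname = path / f"frame_{int(row['frame_id']):05d}.img"
        with open(fname, "wb") as fh:
            fh.write(_smv_header(row, *stack.frames.shape[1:]))
            fh.write(data[i].tobytes())


def _read_smv_like(path: Path) -> FrameStack:
    files = sorted(path.glob("*.img"))
    if not files:
        raise FrameParseError(f"no .img frames under {path}")
    frames, rows = [], []
    for fname in files:
        raw = fname.read_bytes()
        if len(raw) < 512:
            raise FrameParseError(f"{fname}: truncated header")
        header = raw[:512].decode("ascii", errors="replace")
        fields = {}
        for line in header.splitlines():
            line = line.strip().rstrip(";")
            if "=" in line:
                key, val = line.split("=", 1)
                fields[key.strip()] = val.strip()
        try:
            nx, ny = int(fields["SIZE1"]), int(fields["SIZE2"])
        except KeyError as exc:
            raise FrameParseError(f"{fname}: missing header field {exc}") from None
        if len(raw) < 512 + 2 * nx * ny:
            raise FrameParseError(f"{fname}: truncated pixel data")
        img = np.frombuffer(raw, dtype="<u2", count=nx * ny, offset=512).reshape(ny, nx)
        frames.append(img.astype(np.int32))
        rows.append(
            {
                "frame_id": int(fields["FRAME_ID"]),
                "position_id": int(fields["POSITION_ID"]),
                "batch_index": int(fields["BATCH_INDEX"]),
                "tilt_angle": float(fields["TILT_ANGLE"]),
            }
        )
    return FrameStack(np.stack(frames), pd.DataFrame(rows))


# ---------------------------------------------------------------------------

_WRITERS = {"hdf5": _write_hdf5, "mrc-like": _write_mrc_like, "smv-like": _write_smv_like}


def write_frames(stack: FrameStack, path: str | Path, fmt: str = "hdf5") -> Path:
    """Write a frame stack; returns the path written."""
    if len(stack) == 0:
        raise InvalidArgumentError("refusing to write an empty frame stack")
    if fmt not in _WRITERS:
        raise UnsupportedFormatError(f"unknown format {fmt!r}; supported: {sorted(_WRITERS)}")
    path = Path(path)
    if fmt == "hdf5" and path.suffix not in {".h5", ".hdf5"}:
        path = path.with_suffix(".h5")
    _WRITERS[fmt](stack, path)
    return path


def read_frames(path: str | Path, fmt: str | None = None) -> FrameStack:
    """Read a frame stack, autodetecting the container when fmt is None."""
    path = Path(path)
    if fmt is None:
        if path.suffix in {".h5", ".hdf5"}:
            fmt = "hdf5"
        elif (path / "frames.mrc").exists():
            fmt = "mrc-like"
        elif path.is_dir() and any(path.glob("*.img")):
            fmt = "smv-like"
        elif (path / "frames.h5").exists():
            return _read_hdf5(path / "frames.h5")
        elif (path / "frames").is_dir():
            return read_frames(path / "frames")
        else:
            raise UnsupportedFormatError(f"cannot autodetect frame format under {path}")
    if fmt == "hdf5":
        return _read_hdf5(path)
    if fmt == "mrc-like":
        return _read_mrc_like(path)
    if fmt == "smv-like":
        return _read_smv_like(path)
    raise UnsupportedFormatError(f"unknown format {fmt!r}")
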
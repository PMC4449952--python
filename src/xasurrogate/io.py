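"""Input/output for X-ray angiography (XA) sequences and derived data.

An XA sequence is an ordered stack of grayscale frames acquired during a
catheter intervention: vessels, catheters and the diaphragm appear *dark*
on a brighter background.  This module reads sequences from multi-frame
DICOM files or directories of PNG/TIFF frames, reads/writes ground-truth
diaphragm tracks (CSV), exports surrogate signals (JSON), and provides the
"sagittal" view of a rectangular ROI used for manual diaphragm labelling.

Conventions
-----------
* Coordinates are 0-based, row-major, with y increasing downward.
* An ROI is the half-open box ``[x0, x0+width) x [y0, y0+height)``.
* PNG/TIFF inputs carry no calibration, so pixel spacing (mm) and frame
  rate (Hz) come from a YAML sidecar file (``meta.yaml``) or from explicit
  arguments.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

SIDECAR_NAME = "meta.yaml"

_FRAME_EXTENSIONS = {".png", ".tif", ".tiff"}


@dataclass
class XASequence:
    """An ordered stack of grayscale XA frames with acquisition metadata.

    Parameters
    ----------
    frames : ndarray of shape (N, H, W)
        Pixel intensities in acquisition order; higher values are brighter.
    pixel_spacing_mm : float
        Square pixel edge length in millimetres.
    frame_rate_hz : float
        Acquisition frame rate.
    plane_id : str
        Label used to pair biplane acquisitions (e.g. ``"A"`` / ``"B"``).
    name : str
        Free-text identifier.
    """

    frames: np.ndarray
    pixel_spacing_mm: float
    frame_rate_hz: float
    plane_id: str = "A"
    name: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (N, H, W) stack, got ndim={self.frames.ndim}"
            )
        if self.n_frames < 2:
            raise ValueError("an XA sequence needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def subset(self, frames: slice) -> "XASequence":
        """A new sequence restricted to a frame range (metadata preserved)."""
        return XASequence(
            frames=self.frames[frames],
            pixel_spacing_mm=self.pixel_spacing_mm,
            frame_rate_hz=self.frame_rate_hz,
            plane_id=self.plane_id,
            name=self.name,
        )


@dataclass
class ROIRect:
    """Rectangular region of interest on the original frame grid.

    ``axis`` names the dimension along which diaphragm displacement is
    encoded; only ``"vertical"`` (superior-inferior) is meaningful for
    diaphragm tracking.
    """

    x0: int
    y0: int
    width: int
    height: int
    axis: str = "vertical"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 2:
            raise ValueError("ROI needs width >= 1 and height >= 2")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.axis not in ("vertical", "horizontal"):
            raise ValueError(f"unknown ROI axis {self.axis!r}")

    def check_within(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        if self.y0 + self.height > h or self.x0 + self.width > w:
            raise ValueError(
                f"ROI {self} exceeds frame bounds {frame_shape}"
            )


@dataclass
class DiaphragmTrack:
    """Per-frame ground-truth diaphragm position along the ROI axis.

    Positions are stored in pixels of the *original* image resolution.
    Exactly one position per frame (no gaps): downstream comparison is by
    correlation only, so absolute calibration is irrelevant.
    """

    positions: np.ndarray
    roi: ROIRect | None = None
    source: str = "manual"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 1:
            raise ValueError("positions must be a 1-D vector")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("track positions must be finite")

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class SurrogateSignal:
    """One scalar per frame: the projection of each frame on the first PC."""

    values: np.ndarray
    method: str = "vessel_removed"
    mode: str = "retrospective"
    plane_scope: str = "mono"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("signal values must be a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "mode": self.mode,
            "plane_scope": self.plane_scope,
            "values": self.values.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SurrogateSignal":
        payload = json.loads(Path(path).read_text())
        return cls(
            values=np.asarray(payload["values"], dtype=float),
            method=payload["method"],
            mode=payload["mode"],
            plane_scope=payload["plane_scope"],
        )


# ---------------------------------------------------------------------------
# sequence reading / writing
# ---------------------------------------------------------------------------

def _natural_key(name: str) -> list:
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", name)]


def read_sequence(
    path: str | Path,
    format_hint: str | None = None,
    pixel_spacing_mm: float | None = None,
    frame_rate_hz: float | None = None,
    plane_id: str | None = None,
) -> XASequence:
    """Read an XA sequence from a multi-frame DICOM file or a frame directory.

    Pixel spacing and frame rate are taken from DICOM tags when present,
    else from a ``meta.yaml`` sidecar in a frame directory, else from the
    explicit arguments.  A missing value with no override raises an error
    naming the missing field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such sequence path: {path}")
    if path.is_dir() and format_hint != "dicom":
        return _read_frame_directory(
            path, pixel_spacing_mm, frame_rate_hz, plane_id
        )
    return _read_dicom(path, pixel_spacing_mm, frame_rate_hz, plane_id)


def _read_frame_directory(
    path: Path,
    pixel_spacing_mm: float | None,
    frame_rate_hz: float | None,
    plane_id: str | None,
) -> XASequence:
    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS),
        key=lambda p: _natural_key(p.name),
    )
    if len(files) < 2:
        raise ValueError(f"directory {path} holds fewer than 2 frame images")
    frames = []
    shape = None
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim == 3:  # collapse an incidental RGB export
            img = img.mean(axis=-1)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"inconsistent frame shapes: {f.name} is {img.shape}, "
                f"expected {shape}"
            )
        frames.append(img)

    meta: dict = {}
    sidecar = path / SIDECAR_NAME
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}

    spacing = pixel_spacing_mm if pixel_spacing_mm is not None else meta.get(
        "pixel_spacing_mm"
    )
    rate = frame_rate_hz if frame_rate_hz is not None else meta.get(
        "frame_rate_hz"
    )
    if spacing is None:
        raise ValueError(
            "pixel_spacing_mm missing: not in sidecar and no override given"
        )
    if rate is None:
        raise ValueError(
            "frame_rate_hz missing: not in sidecar and no override given"
        )
    return XASequence(
        frames=np.stack(frames),
        pixel_spacing_mm=float(spacing),
        frame_rate_hz=float(rate),
        plane_id=plane_id or str(meta.get("plane_id", "A")),
        name=str(meta.get("name", path.name)),
    )


def _read_dicom(
    path: Path,
    pixel_spacing_mm: float | None,
    frame_rate_hz: float | None,
    plane_id: str | None,
) -> XASequence:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim == 2:
        raise ValueError(f"{path} holds a single frame, not a cine sequence")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    if slope != 1.0 or intercept != 0.0:
        arr = arr * slope + intercept

    spacing = pixel_spacing_mm
    if spacing is None:
        tag = getattr(ds, "PixelSpacing", None) or getattr(
            ds, "ImagerPixelSpacing", None
        )
        if tag is not None:
            spacing = float(tag[0])
    if spacing is None:
        raise ValueError(
            "pixel_spacing_mm missing: no PixelSpacing/ImagerPixelSpacing "
            "tag and no override given"
        )

    rate = frame_rate_hz
    if rate is None and getattr(ds, "CineRate", None):
        rate = float(ds.CineRate)
    if rate is None and getattr(ds, "FrameTime", None):
        rate = 1000.0 / float(ds.FrameTime)
    if rate is None:
        raise ValueError(
            "frame_rate_hz missing: no CineRate/FrameTime tag and no "
            "override given"
        )
    return XASequence(
        frames=arr,
        pixel_spacing_mm=float(spacing),
        frame_rate_hz=float(rate),
        plane_id=plane_id or "A",
        name=str(getattr(ds, "SeriesDescription", path.stem)),
    )


def write_sequence(
    seq: XASequence, path: str | Path, dtype: np.dtype | type = np.uint16
) -> None:
    """Write a sequence as numbered PNG frames plus a YAML metadata sidecar.

    Intensities are rounded and clipped into the target integer range, so
    the round trip is lossless for sequences that already hold integers in
    range.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    info = np.iinfo(dtype)
    n_digits = max(4, len(str(seq.n_frames - 1)))
    for i, frame in enumerate(seq.frames):
        out = np.clip(np.rint(frame), info.min, info.max).astype(dtype)
        iio.imwrite(path / f"frame_{i:0{n_digits}d}.png", out)
    sidecar = {
        "pixel_spacing_mm": float(seq.pixel_spacing_mm),
        "frame_rate_hz": float(seq.frame_rate_hz),
        "plane_id": seq.plane_id,
        "name": seq.name,
    }
    (path / SIDECAR_NAME).write_text(yaml.safe_dump(sidecar))


# ---------------------------------------------------------------------------
# ground-truth tracks
# ---------------------------------------------------------------------------

def read_track(path: str | Path) -> DiaphragmTrack:
    """Read a ground-truth diaphragm track from CSV (columns frame, position).

    Frame indices must start at 0, increase by one and contain no
    duplicates: the manual labelling protocol places exactly one marker in
    each frame.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "frame" not in cols or "position" not in cols:
        raise ValueError(
            f"track CSV {path} must have columns 'frame' and 'position'"
        )
    idx = df[cols["frame"]].to_numpy()
    dup = pd.Series(idx).duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate frame index {int(idx[dup.to_numpy()][0])} in {path}"
        )
    expected = np.arange(len(idx))
    if not np.array_equal(np.sort(idx), expected):
        missing = sorted(set(expected) - set(idx.tolist()))
        raise ValueError(f"missing frame {missing[0]} in {path}")
    order = np.argsort(idx)
    positions = df[cols["position"]].to_numpy(dtype=float)[order]
    return DiaphragmTrack(positions=positions, source="manual")


def write_track(track: DiaphragmTrack, path: str | Path) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(track)), "position": track.positions}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sagittal ROI view
# ---------------------------------------------------------------------------

def roi_sagittal_view(seq: XASequence, roi: ROIRect) -> np.ndarray:
    """Time-resolved profile of a rectangular ROI ("sagittal" view).

    Stacking all frames into a volume and slicing the ROI across time,
    column ``j`` of the result is the ROI content of frame ``j`` averaged
    over the non-axis dimension.  On a diaphragm ROI the dark border traces
    a breathing curve across the columns, which is what manual labelling
    annotates.

    Returns an array of shape ``(roi.height, N)`` for a vertical axis.
    """
    roi.check_within(seq.frame_shape)
    block = seq.frames[
        :, roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width
    ]
    if roi.axis == "vertical":
        return block.mean(axis=2).T  # (height, N)
    return block.mean(axis=1).T  # (width, N)
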
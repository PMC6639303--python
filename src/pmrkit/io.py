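"""Image-stack and ROI input/output.

All analysis modules consume a single in-memory data model: a
:class:`TimeLapseStack` holding a ``T×C×Y×X`` pixel array with its frame
interval and channel names, and a :class:`RoiSet` holding the hand-drawn
regions a per-cell workflow needs (cell outline, injury point, background,
optional bleach region).  Stacks are multi-page TIFF; ROIs are a small
documented JSON schema (an ImageJ ``.roi`` import is deliberately out of
scope — JSON keeps the fixtures transparent and diffable).

Pixel convention: coordinates are 0-based, pixel-centred, ``(row, col)``
order everywhere in this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import Point, Polygon

__all__ = [
    "TimeLapseStack",
    "RoiSet",
    "read_stack",
    "write_stack",
    "read_roiset",
    "write_roiset",
]


@dataclass
class TimeLapseStack:
    """A time-lapse acquisition normalised to ``T×C×Y×X``.

    Parameters
    ----------
    pixels
        Intensity array, arbitrary units.  Axes are time, channel, row, col.
    frame_interval
        Seconds between consecutive frames.
    channel_names
        One label per channel.
    injury_frame
        Index of the first frame at/after the injury event, when known.
    pixel_size
        Micrometres per pixel, optional; physical-length outputs are only
        produced when this is supplied.
    """

    pixels: np.ndarray
    frame_interval: float
    channel_names: list[str] = field(default_factory=list)
    injury_frame: int | None = None
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be T×C×Y×X (4-D), got shape {self.pixels.shape}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal channel axis")
        if self.injury_frame is not None and not (
            0 <= self.injury_frame < self.n_frames
        ):
            raise ValueError("injury_frame must lie within the time axis")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel_index(self, channel: int | str) -> int:
        """Resolve a channel given by index or name."""
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.n_channels:
                raise ValueError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise ValueError(
                f"unknown channel {channel!r}; have {self.channel_names}"
            ) from None

    def times(self) -> np.ndarray:
        """Frame times in seconds relative to the injury frame (0 if unset)."""
        origin = self.injury_frame or 0
        return (np.arange(self.n_frames) - origin) * self.frame_interval


def _validate_polygon(vertices: np.ndarray, name: str) -> np.ndarray:
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValueError(f"{name} must be an N×2 array of ≥3 (row, col) vertices")
    poly = Polygon(verts)
    if not poly.is_valid:
        # locate offending vertices for the error message
        bad = [i for i in range(len(verts))]
        raise ValueError(
            f"{name} is not a simple polygon (self-intersecting); "
            f"check vertices {bad[:8]}..."
        )
    return verts


@dataclass
class RoiSet:
    """Hand-drawn regions for one injured cell.

    ``cell_polygon`` outlines the cell; ``injury_point`` marks the laser
    injury site; ``background_polygon`` (optional) is a cell-free region used
    for background correction and must not overlap the cell;
    ``bleach_region`` (optional) is the photobleached ROI for FRAP.
    """

    cell_polygon: np.ndarray
    injury_point: tuple[float, float] | None = None
    background_polygon: np.ndarray | None = None
    bleach_region: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_polygon = _validate_polygon(self.cell_polygon, "cell_polygon")
        cell = Polygon(self.cell_polygon)
        if self.injury_point is not None:
            self.injury_point = (
                float(self.injury_point[0]),
                float(self.injury_point[1]),
            )
            if cell.distance(Point(self.injury_point)) > 1.5:
                raise ValueError("injury_point must lie on or inside cell_polygon")
        if self.background_polygon is not None:
            self.background_polygon = _validate_polygon(
                self.background_polygon, "background_polygon"
            )
            bg = Polygon(self.background_polygon)
            if bg.intersection(cell).area > 1e-9:
                raise ValueError("background_polygon overlaps cell_polygon")
        if self.bleach_region is not None:
            self.bleach_region = _validate_polygon(
                self.bleach_region, "bleach_region"
            )

    def to_dict(self) -> dict:
        out: dict = {"cell_polygon": np.asarray(self.cell_polygon).tolist()}
        if self.injury_point is not None:
            out["injury_point"] = list(self.injury_point)
        if self.background_polygon is not None:
            out["background_polygon"] = np.asarray(self.background_polygon).tolist()
        if self.bleach_region is not None:
            out["bleach_region"] = np.asarray(self.bleach_region).tolist()
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "RoiSet":
        return cls(
            cell_polygon=np.asarray(payload["cell_polygon"], dtype=float),
            injury_point=tuple(payload["injury_point"])
            if "injury_point" in payload
            else None,
            background_polygon=np.asarray(payload["background_polygon"], dtype=float)
            if "background_polygon" in payload
            else None,
            bleach_region=np.asarray(payload["bleach_region"], dtype=float)
            if "bleach_region" in payload
            else None,
        )


# --------------------------------------------------------------------------
# TIFF stacks
# --------------------------------------------------------------------------

def write_stack(stack: TimeLapseStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF with embedded metadata.

    Metadata (axes, frame interval, channel names, injury frame, pixel size)
    is stored in the TIFF's shaped-metadata JSON so a round trip through
    :func:`read_stack` is lossless.
    """
    meta = {
        "axes": "TCYX",
        "frame_interval": stack.frame_interval,
        "channel_names": stack.channel_names,
        "injury_frame": stack.injury_frame,
        "pixel_size": stack.pixel_size,
    }
    tifffile.imwrite(str(path), stack.pixels, metadata=meta)


def _normalise_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand an array described by ``axes`` into T×C×Y×X."""
    axes = axes.upper().replace("S", "C").replace("I", "T").replace("Q", "T")
    if sorted(axes) != sorted(set(axes)):
        raise ValueError(f"ambiguous repeated axes {axes!r}")
    for ax in axes:
        if ax not in "TCYX":
            raise ValueError(f"unsupported axis {ax!r} in layout {axes!r}")
    # add missing axes with length 1
    for ax in "TCYX":
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in "TCYX"]
    return np.transpose(data, order)


def read_stack(
    path: str | Path,
    frame_interval: float | None = None,
    channel_names: list[str] | None = None,
    axes: str | None = None,
) -> TimeLapseStack:
    """Read a single- or multi-page TIFF into a :class:`TimeLapseStack`.

    Axis layout is taken from (in order of precedence) the ``axes`` override,
    metadata written by :func:`write_stack`, or the TIFF series axes with
    pages interpreted as time.  A >3-D file with no axis information must be
    disambiguated with ``axes``.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        shaped = tif.shaped_metadata
        meta = dict(shaped[0]) if shaped else {}
    file_axes = meta.get("axes") or series.axes
    if axes is None:
        if data.ndim >= 4 and not meta.get("axes") and set(file_axes) - set("TCYXQIS"):
            raise ValueError(
                f"cannot infer axis layout {file_axes!r} for {path.name}; "
                "pass axes= explicitly"
            )
        axes = file_axes
    pixels = _normalise_axes(data, axes)
    interval = frame_interval or meta.get("frame_interval")
    if interval is None:
        raise ValueError(
            f"{path.name} carries no frame interval; pass frame_interval="
        )
    names = channel_names or meta.get("channel_names") or []
    return TimeLapseStack(
        pixels=pixels,
        frame_interval=float(interval),
        channel_names=list(names),
        injury_frame=meta.get("injury_frame"),
        pixel_size=meta.get("pixel_size"),
    )


# --------------------------------------------------------------------------
# ROI JSON sidecars
# --------------------------------------------------------------------------

def write_roiset(roi: RoiSet, path: str | Path) -> None:
    """Write a :class:`RoiSet` as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(roi.to_dict(), fh, indent=2)


def read_roiset(path: str | Path) -> RoiSet:
    """Read and validate an ROI JSON sidecar."""
    with open(path) as fh:
        payload = json.load(fh)
    if "cell_polygon" not in payload:
        raise ValueError(f"{path}: missing required key 'cell_polygon'")
    return RoiSet.from_dict(payload)
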
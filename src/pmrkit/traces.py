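"""ROI trace extraction and ΔF/F normalisation.

A :class:`KineticTrace` is the package's universal kinetic record: one
scalar fluorescence value per frame for one ROI, with time zero at the
injury (or bleach) frame.  Raw traces are mean intensity over the ROI with
optional background subtraction; ΔF/F traces are ``(F − F₀)/F₀`` with F₀
the mean over a pre-injury baseline window, matching the convention used
for membrane-dye entry and Fluo-4 calcium recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import polygon2mask

from .io import RoiSet, TimeLapseStack

__all__ = [
    "KineticTrace",
    "extract_mean_trace",
    "to_delta_f_over_f",
    "downsample_trace",
]

_KINDS = ("raw", "dff")


@dataclass
class KineticTrace:
    """Time-indexed fluorescence series for one ROI.

    ``times`` are seconds relative to injury (0 at the injury frame) and must
    be uniformly spaced.  ``baseline_window`` is a half-open frame-index range
    ``[start, stop)`` identifying pre-event frames; for ``kind='dff'`` the
    mean over that window is zero by construction.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "raw"
    baseline_window: tuple[int, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(self.times) < 2:
            raise ValueError("a trace needs at least two time points")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("times must be uniformly spaced")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.baseline_window is not None:
            a, b = self.baseline_window
            if not (0 <= a < b <= len(self.times)):
                raise ValueError("baseline_window out of range")
            self.baseline_window = (int(a), int(b))
            if self.kind == "dff":
                base = float(np.mean(self.values[a:b]))
                scale = max(1.0, float(np.max(np.abs(self.values))))
                if abs(base) > 1e-6 * scale:
                    raise ValueError(
                        "ΔF/F trace must have zero mean over its baseline window"
                    )

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


def _region_mask(stack: TimeLapseStack, polygon: np.ndarray) -> np.ndarray:
    mask = polygon2mask(stack.frame_shape, np.asarray(polygon, dtype=float))
    if not mask.any():
        raise ValueError("ROI does not intersect the image")
    return mask


def extract_mean_trace(
    stack: TimeLapseStack,
    roi: RoiSet,
    channel: int | str = 0,
    region: str = "cell",
    subtract_background: bool | None = None,
    background_polygon: np.ndarray | None = None,
) -> KineticTrace:
    """Mean-intensity trace over an ROI, one value per frame.

    Parameters
    ----------
    region
        Which polygon of the ROI set to average over: ``"cell"`` or
        ``"bleach"``.
    subtract_background
        Per-frame mean of the background polygon is subtracted when True.
        ``None`` (default) subtracts whenever a background polygon is
        present; the choice is recorded in ``trace.meta``.
    background_polygon
        Explicit background region overriding the ROI set's, without the
        sidecar-level disjointness requirement (e.g. for sanity checks).
    """
    cidx = stack.channel_index(channel)
    if region == "cell":
        poly = roi.cell_polygon
    elif region == "bleach":
        if roi.bleach_region is None:
            raise ValueError("RoiSet has no bleach_region")
        poly = roi.bleach_region
    else:
        raise ValueError(f"unknown region {region!r}")
    mask = _region_mask(stack, poly)
    frames = stack.pixels[:, cidx]
    values = frames[:, mask].mean(axis=1)

    bg_poly = background_polygon if background_polygon is not None \
        else roi.background_polygon
    if subtract_background is None:
        subtract_background = bg_poly is not None
    if subtract_background:
        if bg_poly is None:
            raise ValueError("background subtraction requested but no background ROI")
        bg_mask = _region_mask(stack, bg_poly)
        values = values - frames[:, bg_mask].mean(axis=1)

    injury = stack.injury_frame or 0
    return KineticTrace(
        times=stack.times(),
        values=values,
        kind="raw",
        baseline_window=(0, injury) if injury >= 1 else None,
        meta={
            "channel": stack.channel_names[cidx],
            "region": region,
            "background_subtracted": bool(subtract_background),
            "roi_area_px": int(mask.sum()),
        },
    )


def to_delta_f_over_f(
    trace: KineticTrace, baseline_window: tuple[int, int] | None = None
) -> KineticTrace:
    """Convert a raw trace to ΔF/F = (F − F₀)/F₀.

    F₀ is the mean over ``baseline_window`` (default: the trace's own
    baseline window, i.e. all frames strictly before injury; at least two
    frames are required).  Raises if F₀ ≤ 0, which indicates an offset or
    over-subtracted background that must be reviewed before normalising.
    """
    if trace.kind != "raw":
        raise ValueError("input trace must be kind='raw'")
    window = baseline_window or trace.baseline_window
    if window is None:
        raise ValueError("no baseline window available; pass baseline_window=")
    a, b = int(window[0]), int(window[1])
    if b - a < 2:
        raise ValueError("baseline window must span at least two frames")
    if not (0 <= a < b <= len(trace)):
        raise ValueError("baseline_window out of range")
    f0 = float(np.mean(trace.values[a:b]))
    if f0 <= 0:
        raise ValueError(
            f"baseline F0={f0:.3g} is not positive; review background "
            "subtraction / detector offset before computing ΔF/F"
        )
    meta = dict(trace.meta)
    meta["f0"] = f0
    return KineticTrace(
        times=trace.times.copy(),
        values=(trace.values - f0) / f0,
        kind="dff",
        baseline_window=(a, b),
        meta=meta,
    )


def downsample_trace(trace: KineticTrace, factor: int) -> KineticTrace:
    """Block-mean downsampling by an integer factor.

    Output times are the centres (means) of each block; a trailing partial
    block is dropped.  ``factor=1`` returns an identical copy.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be ≥ 1")
    if factor > len(trace):
        raise ValueError("factor exceeds trace length")
    if factor == 1:
        return replace(trace, times=trace.times.copy(), values=trace.values.copy())
    n_blocks = len(trace) // factor
    n = n_blocks * factor
    times = trace.times[:n].reshape(n_blocks, factor).mean(axis=1)
    values = trace.values[:n].reshape(n_blocks, factor).mean(axis=1)
    meta = dict(trace.meta)
    meta["downsample_factor"] = factor
    return KineticTrace(
        times=times, values=values, kind=trace.kind, baseline_window=None, meta=meta
    )
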
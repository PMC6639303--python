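"""Synthetic time-lapse generators with machine-readable ground truth.

Every assay this package quantifies is emulated here so the whole pipeline
is testable without microscope data:

* FM-dye influx stacks/traces for repairing vs non-repairing cells
  (piecewise-linear entry: linear rise from the injury frame, hard plateau
  at the repair time, unbounded rise clipped at the detector's dynamic
  range for cells that fail to repair);
* Fluo-4 calcium transients (difference-of-exponentials, renormalised so
  the peak equals the requested amplitude);
* two-channel ER fields with a tubular→punctate texture front advancing
  from the injury point;
* two-channel dextran-labelled bead-injury cell fields with known
  injured/failed counts;
* FRAP bleach/recovery traces (mono-exponential recovery of the mobile
  fraction).

Noise follows a standard camera model: Poisson shot noise at a configurable
AU-per-photon scale, plus additive Gaussian read noise.  With both set to
zero every generated pixel matches its analytic model exactly, and each
generator returns its ground truth computed from the specification, never
re-measured from pixels.  Identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import DEFAULTS, dynamic_range
from .erfrag import FragmentationResult
from .io import RoiSet, TimeLapseStack
from .traces import KineticTrace

__all__ = [
    "EllipseSpec",
    "InfluxModel",
    "TransientModel",
    "ERFieldModel",
    "BeadFieldSpec",
    "ERGroundTruth",
    "generate_influx_stack",
    "generate_influx_trace",
    "generate_transient_trace",
    "generate_er_stack",
    "generate_bead_field",
    "generate_frap_trace",
    "write_ground_truth",
]


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipseSpec:
    """An elliptical cell footprint in pixel coordinates (row, col)."""

    center: tuple[float, float] = (64.0, 64.0)
    semi_axes: tuple[float, float] = (40.0, 25.0)
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if min(self.semi_axes) < 2:
            raise ValueError("degenerate ellipse: semi-axes must be ≥ 2 px")

    def _rotation(self) -> np.ndarray:
        t = np.deg2rad(self.rotation_deg)
        return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
        d = np.stack([rr - self.center[0], cc - self.center[1]], axis=-1)
        local = d @ self._rotation()  # rotate into ellipse frame
        a, b = self.semi_axes
        return (local[..., 0] / a) ** 2 + (local[..., 1] / b) ** 2 <= 1.0

    def boundary_point(self, theta: float) -> tuple[float, float]:
        a, b = self.semi_axes
        local = np.array([a * np.cos(theta), b * np.sin(theta)])
        p = self._rotation() @ local + np.asarray(self.center)
        return float(p[0]), float(p[1])

    def polygon(self, n_vertices: int = 64, inset: float = 0.0) -> np.ndarray:
        """Polygonal outline; ``inset`` shrinks the semi-axes (px)."""
        a, b = self.semi_axes
        a, b = max(a - inset, 1.0), max(b - inset, 1.0)
        theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        local = np.stack([a * np.cos(theta), b * np.sin(theta)])
        pts = (self._rotation() @ local).T + np.asarray(self.center)
        return pts


def _apply_noise(
    frames: np.ndarray, noise_sd: float, photon_scale: float, rng: np.random.Generator
) -> np.ndarray:
    out = frames.astype(float)
    if photon_scale > 0:
        out = rng.poisson(np.maximum(out, 0) / photon_scale) * photon_scale
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return out


def _corner_background_polygon(shape: tuple[int, int]) -> np.ndarray:
    h = max(6, shape[0] // 10)
    w = max(6, shape[1] // 10)
    return np.array([[1, 1], [1, w], [h, w], [h, 1]], dtype=float)


# --------------------------------------------------------------------------
# FM-dye influx (membrane repair assay)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InfluxModel:
    """Piecewise-linear FM-dye entry model for one injured cell.

    ``repair_time=None`` models a cell that fails to repair: dye entry
    continues at ``influx_rate`` until the trace hits the detector's dynamic
    range.  A repairing cell plateaus hard at ``repair_time`` seconds after
    injury.  Intensities are arbitrary units (AU); rates are AU/s.
    """

    baseline_intensity: float = 100.0
    influx_rate: float = 2.0
    repair_time: float | None = 30.0
    noise_sd: float = 0.0
    photon_scale: float = 0.0
    frame_interval: float = 2.0
    n_frames: int = 90
    injury_frame: int = 5
    bit_depth: int = DEFAULTS["camera"]["bit_depth"]

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.influx_rate < 0:
            raise ValueError("influx_rate must be ≥ 0")
        if self.repair_time is not None and self.repair_time <= 0:
            raise ValueError("repair_time must be positive when present")
        if self.n_frames < self.injury_frame + 2:
            raise ValueError("need n_frames ≥ injury_frame + 2")
        if self.noise_sd < 0 or self.photon_scale < 0:
            raise ValueError("noise parameters must be ≥ 0")

    def truth_values(self) -> np.ndarray:
        """Noise-free in-cell intensity per frame."""
        t_post = np.maximum(
            (np.arange(self.n_frames) - self.injury_frame) * self.frame_interval, 0.0
        )
        entry = self.influx_rate * (
            np.minimum(t_post, self.repair_time)
            if self.repair_time is not None
            else t_post
        )
        return np.minimum(
            self.baseline_intensity + entry, dynamic_range(self.bit_depth)
        )

    def truth_trace(self) -> KineticTrace:
        times = (np.arange(self.n_frames) - self.injury_frame) * self.frame_interval
        return KineticTrace(
            times=times,
            values=self.truth_values(),
            kind="raw",
            baseline_window=(0, self.injury_frame) if self.injury_frame >= 2 else None,
            meta={"repaired": self.repair_time is not None,
                  "repair_time": self.repair_time},
        )


def generate_influx_stack(
    model: InfluxModel,
    cell_geometry: EllipseSpec | None = None,
    image_shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    background_level: float = 0.0,
) -> tuple[TimeLapseStack, KineticTrace, RoiSet]:
    """Render an FM-dye influx acquisition for one cell.

    Returns the stack, the noise-free ground-truth trace, and an ROI set
    whose cell polygon is inset 2 px inside the rendered mask (so every ROI
    pixel carries the in-cell value) with a background polygon in a
    cell-free corner.
    """
    geometry = cell_geometry or EllipseSpec(
        center=(image_shape[0] / 2, image_shape[1] / 2)
    )
    rng = np.random.default_rng(seed)
    mask = geometry.mask(image_shape)
    if not mask.any():
        raise ValueError("cell geometry does not intersect the image")
    values = model.truth_values()
    frames = np.where(mask[None], values[:, None, None], background_level)
    frames = _apply_noise(frames, model.noise_sd, model.photon_scale, rng)
    stack = TimeLapseStack(
        pixels=frames[:, None],
        frame_interval=model.frame_interval,
        channel_names=["FM-dye"],
        injury_frame=model.injury_frame,
    )
    inset_geometry = EllipseSpec(
        center=geometry.center,
        semi_axes=(
            max(geometry.semi_axes[0] - 2.0, 2.0),
            max(geometry.semi_axes[1] - 2.0, 2.0),
        ),
        rotation_deg=geometry.rotation_deg,
    )
    roi = RoiSet(
        cell_polygon=geometry.polygon(inset=2.0),
        injury_point=inset_geometry.boundary_point(0.0),
        background_polygon=_corner_background_polygon(image_shape),
    )
    return stack, model.truth_trace(), roi


def generate_influx_trace(
    model: InfluxModel, seed: int = 0
) -> tuple[KineticTrace, KineticTrace]:
    """Trace-level influx generator: (noisy trace, ground truth).

    ``model.noise_sd`` is applied directly as Gaussian noise on the ROI-mean
    trace (AU) — the per-pixel read noise of the stack generator divided by
    the effective √(ROI area).  Used for large synthetic cohorts where
    rendering full stacks adds nothing.
    """
    rng = np.random.default_rng(seed)
    truth = model.truth_trace()
    noisy_values = truth.values + rng.normal(0.0, model.noise_sd, len(truth)) \
        if model.noise_sd > 0 else truth.values.copy()
    noisy = KineticTrace(
        times=truth.times.copy(),
        values=noisy_values,
        kind="raw",
        baseline_window=truth.baseline_window,
        meta=dict(truth.meta),
    )
    return noisy, truth


# --------------------------------------------------------------------------
# Fluo-4 calcium transient
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TransientModel:
    """Difference-of-exponentials calcium transient.

    Noise-free shape for t ≥ injury_time, renormalised so its maximum is
    ``peak_amplitude`` above ``baseline``:

        f(t) = baseline + A·[exp(−(t−t₀)/decay_tau) − exp(−(t−t₀)/rise_tau)]

    ``rise_tau = 0`` is accepted as the instant-rise limit (pure
    exponential decay from the peak).
    """

    baseline: float = 100.0
    peak_amplitude: float = 50.0
    rise_tau: float = 2.0
    decay_tau: float = 20.0
    injury_time: float = 10.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.rise_tau < 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be positive (rise_tau may be 0)")
        if self.injury_time < 0:
            raise ValueError("injury_time must be ≥ 0")

    def shape(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak transient shape as a function of absolute time."""
        dt = np.maximum(np.asarray(t, dtype=float) - self.injury_time, 0.0)
        tr, td = self.rise_tau, self.decay_tau
        if tr < 1e-12:
            out = np.exp(-dt / td)
            out[np.asarray(t) < self.injury_time] = 0.0
            return out
        if abs(td - tr) < 1e-9 * td:
            x = dt / td
            return x * np.exp(1.0 - x)
        raw = np.exp(-dt / td) - np.exp(-dt / tr)
        t_peak = np.log(td / tr) * tr * td / (td - tr)
        peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
        return raw / peak


def generate_transient_trace(
    model: TransientModel,
    frame_interval: float = 0.2,
    n_frames: int = 950,
    seed: int = 0,
) -> KineticTrace:
    """Sample a calcium transient on a uniform frame grid.

    The injury time is snapped to the nearest frame so trace time zero falls
    exactly on a frame.  If the acquisition does not span
    ``injury_time + 3·decay_tau`` a warning is recorded and the (truncated)
    trace is still produced.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    span = n_frames * frame_interval
    if span < model.injury_time + 3 * model.decay_tau:
        warnings.warn(
            f"acquisition span {span:.1f}s is shorter than injury_time + "
            f"3·decay_tau = {model.injury_time + 3 * model.decay_tau:.1f}s; "
            "the transient will be truncated",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    injury_frame = int(round(model.injury_time / frame_interval))
    t = np.arange(n_frames) * frame_interval
    # snap: evaluate the shape with t0 on the frame grid
    t0 = injury_frame * frame_interval
    snapped = TransientModel(
        baseline=model.baseline,
        peak_amplitude=model.peak_amplitude,
        rise_tau=model.rise_tau,
        decay_tau=model.decay_tau,
        injury_time=t0,
        noise_sd=model.noise_sd,
    )
    values = snapped.baseline + snapped.peak_amplitude * snapped.shape(t)
    if model.noise_sd > 0:
        values = values + rng.normal(0.0, model.noise_sd, n_frames)
    return KineticTrace(
        times=t - t0,
        values=values,
        kind="raw",
        baseline_window=(0, injury_frame) if injury_frame >= 2 else None,
        meta={"model": "difference-of-exponentials", "injury_frame": injury_frame},
    )


# --------------------------------------------------------------------------
# ER fragmentation field
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ERFieldModel:
    """Two-channel ER field with a punctate front along the injury axis.

    Channel 0 carries the ER texture (tubular: sinusoidal ridges parallel to
    the injury axis; punctate: Gaussian spots on the ridge skeleton with
    gaps).  Channel 1 is a uniform cytosolic fill.  The punctate region is
    exactly the portion of the injury axis nearest the injury point, of
    ground-truth length ``fragmentation_fraction × axis_length``.
    """

    cell: EllipseSpec = EllipseSpec(center=(96.0, 96.0), semi_axes=(80.0, 48.0))
    image_shape: tuple[int, int] = (192, 192)
    injury_theta: float = 0.0          # boundary parameter of the injury point
    fragmentation_fraction: float = 0.5
    tubule_spacing: float = 8.0        # px between ridge centres
    puncta_radius: float = 1.5         # px, Gaussian sigma of spots
    noise_sd: float = 0.0
    base_intensity: float = 50.0
    ridge_amplitude: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fragmentation_fraction <= 1.0:
            raise ValueError("fragmentation_fraction must be in [0, 1]")
        if self.tubule_spacing < 2 * self.puncta_radius:
            raise ValueError(
                "tubule_spacing must be ≥ 2·puncta_radius, otherwise tubular "
                "and punctate textures are indistinguishable"
            )

    @property
    def injury_point(self) -> tuple[float, float]:
        return self.cell.boundary_point(self.injury_theta)


@dataclass
class ERGroundTruth:
    """Ground truth emitted alongside a synthetic ER stack."""

    result: FragmentationResult
    label_mask: np.ndarray          # True where the texture is punctate (post-onset)
    cell_mask: np.ndarray
    roi: RoiSet
    onset_frame: int


def _nearest_centre_distance(x: np.ndarray, spacing: float, offset: float) -> np.ndarray:
    """Distance from each coordinate to the nearest grid centre."""
    return np.abs(((x - offset + spacing / 2) % spacing) - spacing / 2)


def generate_er_stack(
    model: ERFieldModel,
    n_frames: int = 3,
    onset_frame: int = 1,
    seed: int = 0,
) -> tuple[TimeLapseStack, ERGroundTruth]:
    """Render a two-channel ER stack with a punctate front appearing at
    ``onset_frame``.

    Frames before ``onset_frame`` are fully tubular; frames at/after it are
    punctate over the ground-truth region.  The per-pixel punctate label
    mask is part of the returned ground truth.
    """
    if not onset_frame < n_frames:
        raise ValueError("need onset_frame < n_frames")
    rng = np.random.default_rng(seed)
    shape = model.image_shape
    mask = model.cell.mask(shape)
    p0 = np.asarray(model.injury_point)

    # far boundary point maximizing distance from the injury point
    theta = np.linspace(0, 2 * np.pi, 2048, endpoint=False)
    boundary = np.array([model.cell.boundary_point(t) for t in theta])
    d = np.hypot(boundary[:, 0] - p0[0], boundary[:, 1] - p0[1])
    far = boundary[np.argmax(d)]
    axis_vec = far - p0
    length = float(np.linalg.norm(axis_vec))
    u = axis_vec / length
    nvec = np.array([-u[1], u[0]])

    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    s = (rr - p0[0]) * u[0] + (cc - p0[1]) * u[1]
    r = (rr - p0[0]) * nvec[0] + (cc - p0[1]) * nvec[1]

    sp = model.tubule_spacing
    sigma = model.puncta_radius
    tubular = model.base_intensity + model.ridge_amplitude * 0.5 * (
        1.0 + np.cos(2 * np.pi * r / sp)
    )
    # punctate: separable Gaussian spots on the ridge skeleton (gaps along s)
    dr = _nearest_centre_distance(r, sp, 0.0)
    ds = _nearest_centre_distance(s, sp, sp / 2.0)
    punctate = model.base_intensity + 1.5 * model.ridge_amplitude * np.exp(
        -(dr ** 2 + ds ** 2) / (2 * sigma ** 2)
    )

    frag_len = model.fragmentation_fraction * length
    label = mask & (s <= frag_len) & (model.fragmentation_fraction > 0)

    er_pre = np.where(mask, tubular, 0.0)
    er_post = np.where(label, punctate, er_pre)
    fill = np.where(mask, 120.0, 0.0)

    frames = np.empty((n_frames, 2) + shape)
    for i in range(n_frames):
        frames[i, 0] = er_post if i >= onset_frame else er_pre
        frames[i, 1] = fill
    if model.noise_sd > 0:
        frames = frames + rng.normal(0.0, model.noise_sd, frames.shape)

    stack = TimeLapseStack(
        pixels=frames,
        frame_interval=2.0,
        channel_names=["ER", "cytosol"],
        injury_frame=onset_frame,
    )
    from skimage.draw import line as _raster_line

    rr_ax, cc_ax = _raster_line(
        int(round(p0[0])), int(round(p0[1])), int(round(far[0])), int(round(far[1]))
    )
    axis_path = np.column_stack([rr_ax, cc_ax])
    result = FragmentationResult(
        axis_length=length,
        fragmented_length=frag_len,
        fragmented_fraction=model.fragmentation_fraction,
        axis_coordinates=axis_path,
        meta={"far_point": (float(far[0]), float(far[1]))},
    )
    roi = RoiSet(
        cell_polygon=model.cell.polygon(inset=0.0),
        injury_point=(float(p0[0]), float(p0[1])),
        background_polygon=_corner_background_polygon(shape),
    )
    truth = ERGroundTruth(
        result=result, label_mask=label, cell_mask=mask, roi=roi,
        onset_frame=onset_frame,
    )
    return stack, truth


# --------------------------------------------------------------------------
# Glass-bead injury field
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadFieldSpec:
    """Two-channel dextran-labelled cell field with known counts.

    Of ``n_cells`` non-overlapping disk cells, exactly ``n_injured`` carry
    the green (injury marker) dextran and exactly ``n_failed`` of those also
    carry the red (failed-repair) dextran.  Uninjured cells are unlabelled.
    """

    n_cells: int = 150
    n_injured: int = 150
    n_failed: int = 30
    image_size: tuple[int, int] = (512, 512)
    cell_radius_range: tuple[float, float] = (8.0, 13.0)
    seed: int = 0
    noise_sd: float = 0.0
    green_level: float = 200.0
    red_level: float = 180.0

    def __post_init__(self) -> None:
        if not 0 <= self.n_failed <= self.n_injured <= self.n_cells:
            raise ValueError("need n_failed ≤ n_injured ≤ n_cells")


def generate_bead_field(spec: BeadFieldSpec):
    """Render a bead-injury field; returns (image, per-cell truth table).

    The image is a 2×Y×X array (channel 0 green, channel 1 red).  The truth
    table is a pandas DataFrame with one row per cell: centroid, radius, and
    boolean ``injured`` / ``failed`` labels.  Cell placement is rejection
    sampling; an infeasible packing raises after bounded retries.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    rmin, rmax = spec.cell_radius_range
    centres: list[tuple[float, float]] = []
    radii: list[float] = []
    max_tries = 4000 * spec.n_cells
    tries = 0
    while len(centres) < spec.n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping cells of "
                f"radius {rmin}-{rmax}px in a {h}×{w} image after {max_tries} "
                "attempts; reduce n_cells or cell radius"
            )
        radius = rng.uniform(rmin, rmax)
        row = rng.uniform(radius + 1, h - radius - 1)
        col = rng.uniform(radius + 1, w - radius - 1)
        ok = all(
            np.hypot(row - r0, col - c0) > radius + rad0 + 2.0
            for (r0, c0), rad0 in zip(centres, radii)
        )
        if ok:
            centres.append((row, col))
            radii.append(radius)

    order = rng.permutation(spec.n_cells)
    injured = np.zeros(spec.n_cells, dtype=bool)
    failed = np.zeros(spec.n_cells, dtype=bool)
    injured[order[: spec.n_injured]] = True
    failed[order[: spec.n_failed]] = True  # failed cells are a subset of injured

    image = np.zeros((2,) + spec.image_size)
    rr, cc = np.mgrid[0:h, 0:w]
    for i, ((row, col), radius) in enumerate(zip(centres, radii)):
        if not injured[i]:
            continue
        disk = (rr - row) ** 2 + (cc - col) ** 2 <= radius ** 2
        image[0][disk] = spec.green_level
        if failed[i]:
            image[1][disk] = spec.red_level
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, image.shape)

    table = pd.DataFrame(
        {
            "cell_id": np.arange(spec.n_cells),
            "row": [c[0] for c in centres],
            "col": [c[1] for c in centres],
            "radius": radii,
            "injured": injured,
            "failed": failed,
        }
    )
    return image, table


# --------------------------------------------------------------------------
# FRAP
# --------------------------------------------------------------------------

def generate_frap_trace(
    mobile_fraction: float,
    recovery_tau: float,
    bleach_depth: float = 0.8,
    frame_interval: float = 1.0,
    n_frames: int = 120,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_prebleach: int = 10,
    baseline: float = 1.0,
    acquisition_tau: float | None = None,
) -> KineticTrace:
    """Mono-exponential FRAP bleach/recovery trace.

    Pre-bleach frames sit at ``baseline``; at the bleach frame the signal
    drops by ``bleach_depth`` (fraction of baseline) and recovers as
    ``mobile_fraction·(1 − exp(−t/recovery_tau))`` of the bleached depth.
    ``acquisition_tau`` optionally applies a multiplicative whole-trace
    acquisition-bleaching decay ``exp(−t/acquisition_tau)`` for testing
    reference correction.  Trace time zero is the bleach frame; the bleach
    frame index equals ``n_prebleach``.
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must be in [0, 1]")
    if not 0.0 < bleach_depth <= 1.0:
        raise ValueError("bleach_depth must be in (0, 1]")
    if recovery_tau <= 0 or frame_interval <= 0:
        raise ValueError("recovery_tau and frame_interval must be positive")
    if n_prebleach < 2 or n_frames <= n_prebleach:
        raise ValueError("need ≥2 pre-bleach frames and ≥1 post-bleach frame")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_frames)
    t_post = np.maximum((idx - n_prebleach) * frame_interval, 0.0)
    values = np.full(n_frames, float(baseline))
    post = idx >= n_prebleach
    values[post] = baseline * (
        1.0
        - bleach_depth
        + bleach_depth * mobile_fraction * (1.0 - np.exp(-t_post[post] / recovery_tau))
    )
    if acquisition_tau is not None:
        values = values * np.exp(-(idx * frame_interval) / acquisition_tau)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, n_frames)
    return KineticTrace(
        times=(idx - n_prebleach) * frame_interval,
        values=values,
        kind="raw",
        baseline_window=(0, n_prebleach),
        meta={
            "bleach_frame": n_prebleach,
            "mobile_fraction": mobile_fraction,
            "recovery_tau": recovery_tau,
            "bleach_depth": bleach_depth,
        },
    )


# --------------------------------------------------------------------------
# Ground-truth sidecars
# --------------------------------------------------------------------------

class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_ground_truth(payload: dict, path: str | Path) -> None:
    """Write a ground-truth sidecar (spec, seed, per-frame/per-cell truth)."""
    with open(path, "w") as fh:
        json.dump(payload, fh, cls=_NumpyEncoder, indent=2)
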
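"""Synthetic-data generators with ground truth.

Every input the analysis pipeline consumes can be generated here with a
known answer attached: dual-illumination bleaching image stacks, multi-
plane diffusing-spot movies, persistent-random-walk cell tracks with a
phototoxic slowdown, exponentially growing colony-area series, and
ratiometric green/red temperature image pairs.

Noise model (sCMOS abstraction): Poisson shot noise on the expected
photoelectron counts, times the camera gain, plus Gaussian read noise
(default sd 2 counts) and a constant offset (default 100 counts).  All
randomness flows from the single seed of each generator call via
``numpy``'s ``default_rng(seed).spawn`` splitting, so outputs are
bit-reproducible given (scene, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .photophysics import Illumination, PhotophysicalParams, simulate_trace
from .quantify import ImageStack, ROISet, TemperatureCalibration
from .readouts import Track

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "synth_bleaching_stack",
    "synth_spot_movie",
    "synth_tracks",
    "synth_colony_series",
    "synth_temperature_pair",
]


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, optics and camera of a synthetic bleaching scene.

    The visible beam covers the whole field unless ``vis_disc`` is
    given; the NIR beam covers only ``nir_disc`` (row, col, diameter in
    px), emulating a co-illuminated sub-region of the field of view.
    """

    shape: tuple[int, int] = (64, 64)
    n_objects: int = 8
    object_radius: tuple[float, float] = (4.0, 6.0)
    object_brightness: tuple[float, float] = (1800.0, 2200.0)
    vis_disc: tuple[float, float, float] | None = None
    nir_disc: tuple[float, float, float] | None = (32.0, 46.0, 34.0)
    object_centers: tuple[tuple[float, float], ...] | None = None
    bead_count: int = 0
    bead_brightness: float = 4000.0
    camera_offset: float = 100.0
    gain: float = 1.0
    read_noise_sd: float = 2.0
    noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.shape[0] <= 0 or self.shape[1] <= 0:
            raise ValueError("shape must be positive")
        if self.nir_disc is not None:
            r0, c0, d = self.nir_disc
            rad = d / 2.0
            if (r0 - rad < 0 or c0 - rad < 0
                    or r0 + rad > self.shape[0] or c0 + rad > self.shape[1]):
                raise ValueError("NIR disc exceeds the field of view")


@dataclass
class GroundTruth:
    """Everything needed to score a recovery test without re-simulation."""

    params: PhotophysicalParams | None = None
    illum_inside: Illumination | None = None
    illum_outside: Illumination | None = None
    roi_inside_nir: dict[int, bool] = field(default_factory=dict)
    trace_inside: np.ndarray | None = None
    trace_outside: np.ndarray | None = None
    spot_positions: list[np.ndarray] | None = None
    spot_counts: list[int] | None = None
    tracks: list[Track] | None = None
    speeds: np.ndarray | None = None
    rates: np.ndarray | None = None
    delta_T: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def _disc_mask(shape, disc) -> np.ndarray:
    r0, c0, d = disc
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= (d / 2.0) ** 2


def synth_bleaching_stack(
    params: PhotophysicalParams,
    scene: SceneSpec,
    t_grid: np.ndarray,
    illum: Illumination | None = None,
) -> tuple[ImageStack, ROISet, GroundTruth]:
    """Dual-illumination photobleaching image time series.

    Each pixel's expected signal follows the model trace under its local
    illumination — the full dual-beam trace inside the NIR disc, the
    visible-only trace outside — scaled by its object's brightness, plus
    the camera offset.  Fluorescent objects are bright discs; label i+1
    marks object i in the returned ROI set and label 0 the object-free
    background.  With ``scene.noise`` the stated Poisson/Gaussian camera
    noise is applied from ``scene.seed``.
    """
    t = np.asarray(t_grid, float)
    illum = illum or Illumination(470.0, 32.0, 900.0, 2000.0)
    rng = np.random.default_rng(scene.seed)
    r_place, r_bright, r_noise = rng.spawn(3)

    inside = (
        _disc_mask(scene.shape, scene.nir_disc)
        if scene.nir_disc is not None
        else np.zeros(scene.shape, bool)
    )
    vis_mask = (
        _disc_mask(scene.shape, scene.vis_disc)
        if scene.vis_disc is not None
        else np.ones(scene.shape, bool)
    )

    illum_in = illum
    illum_out = illum.without_nir()
    trace_in, _ = simulate_trace(params, illum_in, t)
    trace_out, _ = simulate_trace(params, illum_out, t)

    # place non-overlapping disc objects
    labels = np.zeros(scene.shape, dtype=np.int32)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    if scene.object_centers is not None:
        centers = [tuple(c) for c in scene.object_centers]
        radii = [
            float(r_place.uniform(*scene.object_radius)) for _ in centers
        ]
    else:
        tries = 0
        while len(centers) < scene.n_objects and tries < 10_000:
            tries += 1
            rad = float(r_place.uniform(*scene.object_radius))
            r0 = float(r_place.uniform(rad + 1, scene.shape[0] - rad - 1))
            c0 = float(r_place.uniform(rad + 1, scene.shape[1] - rad - 1))
            if all(
                (r0 - rr) ** 2 + (c0 - cc) ** 2 > (rad + rd + 2) ** 2
                for (rr, cc), rd in zip(centers, radii)
            ):
                centers.append((r0, c0))
                radii.append(rad)
        if len(centers) < scene.n_objects:
            raise ValueError("could not place the requested objects without overlap")
    rr, cc = np.mgrid[: scene.shape[0], : scene.shape[1]]
    brightness = {}
    for i, ((r0, c0), rad) in enumerate(zip(centers, radii)):
        m = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        labels[m] = i + 1
        brightness[i + 1] = float(r_bright.uniform(*scene.object_brightness))

    bright_map = np.zeros(scene.shape)
    for lab, b in brightness.items():
        bright_map[labels == lab] = b
    if scene.bead_count:
        for _ in range(scene.bead_count):
            r0 = int(r_place.integers(0, scene.shape[0]))
            c0 = int(r_place.integers(0, scene.shape[1]))
            if labels[r0, c0] == 0:
                bright_map[r0, c0] = scene.bead_brightness

    decay = np.where(inside[None], trace_in.signal[:, None, None],
                     trace_out.signal[:, None, None])
    expected_e = bright_map[None] * decay * vis_mask[None]
    if scene.noise:
        counts = (
            scene.gain * r_noise.poisson(expected_e)
            + r_noise.normal(0.0, scene.read_noise_sd, expected_e.shape)
            + scene.camera_offset
        )
        counts = np.clip(counts, 0.0, None)
    else:
        counts = scene.gain * expected_e + scene.camera_offset

    stack = ImageStack(
        pixels=counts,
        frame_interval=float(t[1] - t[0]),
        nir_disc=scene.nir_disc,
        vis_disc=scene.vis_disc,
    )
    rois = ROISet(labels=labels)
    roi_inside = {
        i + 1: bool(inside[int(round(r0)), int(round(c0))])
        for i, (r0, c0) in enumerate(centers)
    }
    gt = GroundTruth(
        params=params,
        illum_inside=illum_in,
        illum_outside=illum_out,
        roi_inside_nir=roi_inside,
        trace_inside=trace_in.signal,
        trace_outside=trace_out.signal,
        extra={"brightness": brightness, "times": t},
    )
    return stack, rois, gt


def _gaussian_spot(shape, y, x, amplitude, sd):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return amplitude * np.exp(-(((rr - y) ** 2 + (cc - x) ** 2) / (2.0 * sd**2)))


def synth_spot_movie(
    params: PhotophysicalParams,
    illum: Illumination,
    n_cells: int = 6,
    spots_per_cell: int = 4,
    diffusion_px2_per_frame: float = 0.25,
    n_frames: int = 30,
    planes: int = 3,
    z_step_um: float = 0.35,
    interval_s: float = 60.0,
    shape: tuple[int, int] = (96, 144),
    cell_size: tuple[int, int] = (28, 40),
    spot_amplitude: float = 400.0,
    psf_sd_px: float = 1.3,
    defocus_factor: float = 1.5,
    camera_offset: float = 100.0,
    read_noise_sd: float = 2.0,
    noise: bool = True,
    seed: int = 0,
) -> tuple[ImageStack, np.ndarray, GroundTruth]:
    """Multi-plane movie of diffusing bright foci inside rectangular cells.

    Spots random-walk inside their cell (reflecting boundaries) while
    their brightness follows the model bleaching trace under ``illum``;
    each focal plane sees the spot blurred by a Gaussian PSF widened by
    ``defocus_factor`` per plane away from the spot's (random) focal
    plane.  Returns the TZYX stack, the cell label masks (YX), and
    ground-truth per-frame spot positions/counts.
    """
    if spots_per_cell < 0:
        raise ValueError("spots_per_cell must be >= 0")
    rng = np.random.default_rng(seed)
    r_layout, r_walk, r_noise = rng.spawn(3)
    t = np.arange(n_frames) * interval_s
    trace, _ = simulate_trace(params, illum, t)

    masks = np.zeros(shape, dtype=np.int32)
    ch, cw = cell_size
    n_cols = max(1, shape[1] // (cw + 8))
    positions = []
    for i in range(n_cells):
        row, col = divmod(i, n_cols)
        r0 = 4 + row * (ch + 8)
        c0 = 4 + col * (cw + 8)
        if r0 + ch >= shape[0] or c0 + cw >= shape[1]:
            raise ValueError("cells do not fit in the field; enlarge shape")
        masks[r0 : r0 + ch, c0 : c0 + cw] = i + 1
        for _ in range(spots_per_cell):
            y = r_layout.uniform(r0 + 3, r0 + ch - 3)
            x = r_layout.uniform(c0 + 3, c0 + cw - 3)
            z = int(r_layout.integers(0, planes))
            positions.append([y, x, z, r0, c0])
    spots = np.array(positions, float).reshape(-1, 5)

    frames = np.zeros((n_frames, planes, *shape))
    gt_positions: list[np.ndarray] = []
    sd_step = math.sqrt(diffusion_px2_per_frame)
    for f in range(n_frames):
        amp = spot_amplitude * trace.signal[f]
        img = np.zeros((planes, *shape))
        for (y, x, z, r0, c0) in spots:
            for p in range(planes):
                sd = psf_sd_px * defocus_factor ** abs(p - z)
                peak = amp * (psf_sd_px / sd) ** 2  # defocus dims the peak
                img[p] += _gaussian_spot(shape, y, x, peak, sd)
        frames[f] = img
        gt_positions.append(spots[:, :3].copy())
        steps = r_walk.normal(0.0, sd_step, size=(len(spots), 2))
        spots[:, 0] += steps[:, 0]
        spots[:, 1] += steps[:, 1]
        for k, (y, x, z, r0, c0) in enumerate(spots):
            spots[k, 0] = float(np.clip(y, r0 + 2, r0 + cell_size[0] - 2))
            spots[k, 1] = float(np.clip(x, c0 + 2, c0 + cell_size[1] - 2))
    if noise:
        counts = (
            r_noise.poisson(frames)
            + r_noise.normal(0.0, read_noise_sd, frames.shape)
            + camera_offset
        )
        counts = np.clip(counts, 0.0, None)
    else:
        counts = frames + camera_offset

    stack = ImageStack(
        pixels=counts, frame_interval=interval_s, z_step=z_step_um,
    )
    gt = GroundTruth(
        params=params,
        illum_inside=illum,
        spot_positions=gt_positions,
        spot_counts=[len(spots)] * n_frames,
        extra={"masks": masks, "trace": trace.signal, "n_cells": n_cells,
               "spots_per_cell": spots_per_cell},
    )
    return stack, masks, gt


def synth_tracks(
    n_cells: int = 20,
    speed_um_per_min: float = 10.0,
    persistence_time_s: float = 30.0,
    slowdown_rate_per_s: float = 0.0,
    duration_s: float = 300.0,
    interval_s: float = 1.0,
    field_radius_um: float = 40.0,
    seed: int = 0,
) -> tuple[list[Track], GroundTruth]:
    """Persistent-random-walk cell tracks with a phototoxicity proxy.

    Headings diffuse with persistence time ``persistence_time_s``; the
    instantaneous speed decays exponentially with cumulative
    illumination dose (proportional to elapsed exposure time) at
    ``slowdown_rate_per_s``.  Cells start near the field centre; a
    track is flagged ``left_field`` once it exits ``field_radius_um``.
    """
    if speed_um_per_min <= 0 or persistence_time_s <= 0 or interval_s <= 0:
        raise ValueError("kinematic parameters must be positive")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration_s / interval_s))
    sigma_theta = math.sqrt(2.0 * interval_s / persistence_time_s)
    v0 = speed_um_per_min / 60.0  # um/s
    tracks: list[Track] = []
    speeds = []
    for cid, r in enumerate(rng.spawn(n_cells)):
        theta = r.uniform(0, 2 * math.pi)
        pos = r.uniform(-0.3, 0.3, size=2) * field_radius_um
        xy = [pos.copy()]
        left = False
        for k in range(n_steps):
            dose_t = k * interval_s
            v = v0 * math.exp(-slowdown_rate_per_s * dose_t)
            theta += r.normal(0.0, sigma_theta)
            pos = pos + v * interval_s * np.array([math.cos(theta), math.sin(theta)])
            if np.hypot(*pos) > field_radius_um:
                left = True
            xy.append(pos.copy())
        tracks.append(
            Track(cell_id=cid, frames=np.arange(n_steps + 1), xy=np.array(xy),
                  left_field=left)
        )
        speeds.append(v0)
    gt = GroundTruth(
        tracks=tracks,
        speeds=np.array(speeds),
        extra={"slowdown_rate_per_s": slowdown_rate_per_s,
               "persistence_time_s": persistence_time_s,
               "interval_s": interval_s},
    )
    return tracks, gt


def synth_colony_series(
    n_colonies: int = 10,
    doubling_time_s: float = 22.0 * 60.0,
    phototoxic_decay_per_s: float = 0.0,
    duration_s: float = 4.0 * 3600.0,
    interval_s: float = 600.0,
    initial_area_um2: tuple[float, float] = (8.0, 20.0),
    area_noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Exponentially growing colony areas with dose-dependent slowdown.

    The instantaneous growth rate (doublings/s) is
    ``r(t) = r0 * exp(-phototoxic_decay_per_s * t)`` with
    ``r0 = 1/doubling_time_s``, so
    ``log2 A(t)/A0 = r0 (1 - e^{-p t})/p`` (-> ``r0 t`` as p -> 0).
    Optional multiplicative lognormal measurement noise on areas.
    """
    if doubling_time_s <= 0:
        raise ValueError("doubling time must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + 0.5 * interval_s, interval_s)
    r0 = 1.0 / doubling_time_s
    p = phototoxic_decay_per_s
    if p > 0:
        log2a = r0 * (1.0 - np.exp(-p * t)) / p
    else:
        log2a = r0 * t
    rows = []
    for cid, r in enumerate(rng.spawn(n_colonies)):
        a0 = float(r.uniform(*initial_area_um2))
        areas = a0 * 2.0**log2a
        if area_noise_cv > 0:
            areas = areas * r.lognormal(0.0, area_noise_cv, size=t.size)
        for ti, ai in zip(t, areas):
            rows.append((float(ti), cid, float(ai)))
    df = pd.DataFrame(rows, columns=["time_s", "colony_id", "area_um2"])
    gt = GroundTruth(
        rates=np.full(n_colonies, r0),
        extra={"phototoxic_decay_per_s": p, "doubling_time_s": doubling_time_s},
    )
    return df, gt


def synth_temperature_pair(
    cal: TemperatureCalibration,
    delta_T: np.ndarray,
    baseline_T: float = 37.0,
    red_level: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Green/red image pair encoding a known temperature elevation map.

    The pixel temperature is ``baseline_T + delta_T`` (must stay inside
    the calibration range); the green/red ratio follows the calibration
    law exactly, so the noiseless pair inverts to the truth.
    """
    dT = np.asarray(delta_T, float)
    T = baseline_T + dT
    if T.min() < cal.t_min or T.max() > cal.t_max:
        raise ValueError("delta_T takes the temperature outside the calibration range")
    rng = np.random.default_rng(seed)
    red = np.full(dT.shape, float(red_level))
    green = cal.ratio(T) * red
    if noise_sd > 0:
        green = green + rng.normal(0.0, noise_sd, dT.shape)
        red = red + rng.normal(0.0, noise_sd, dT.shape)
    gt = GroundTruth(delta_T=dT, extra={"baseline_T": baseline_T, "cal": cal})
    return green, red, gt
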
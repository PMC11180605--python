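"""Downstream biological readouts of photobleaching and phototoxicity.

Three quantifications mirroring the live-cell assays a reduced-
photobleaching method is judged by:

* replisome-style foci: Laplacian-of-Gaussian spot detection across a
  small number of focal planes with a dual intensity + Laplacian
  criterion, and per-cell spot counting over time;
* motility: frame-to-frame particle linking by the Hungarian /
  linear-assignment algorithm and mean-squared-displacement (MSD)
  analysis of the resulting cell tracks;
* proliferation: binary-logarithm colony-area growth curves and
  doubling rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_laplace
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

__all__ = [
    "SpotDetectionParams",
    "Track",
    "MSDCurve",
    "log_response",
    "auto_thresholds",
    "detect_spots",
    "collect_detections",
    "count_spots_per_cell",
    "link_frame_pair",
    "link_tracks",
    "compute_msd",
    "colony_log2_growth",
]


@dataclass(frozen=True)
class SpotDetectionParams:
    """Thresholds and scales for LoG spot detection.

    ``log_sigma`` is the blob scale in pixels; a candidate must exceed
    BOTH ``intensity_threshold`` (raw counts at the peak) and
    ``laplacian_threshold`` (scale-normalized negative-LoG response).
    Detections closer than ``merge_radius`` px in adjacent planes
    (within ``z_merge`` planes) are merged to the brightest one.
    """

    log_sigma: float = 1.3
    intensity_threshold: float = 0.0
    laplacian_threshold: float = 0.0
    merge_radius: float = 2.0
    z_merge: int = 1

    def __post_init__(self):
        if self.log_sigma <= 0 or self.merge_radius <= 0 or self.z_merge <= 0:
            raise ValueError("log_sigma, merge_radius and z_merge must be positive")


@dataclass
class Track:
    """One cell's trajectory: strictly increasing frame indices and x/y in um."""

    cell_id: int
    frames: np.ndarray
    xy: np.ndarray
    left_field: bool = False
    overlapped: bool = False

    def __post_init__(self):
        f = np.asarray(self.frames, int)
        xy = np.asarray(self.xy, float)
        if f.ndim != 1 or xy.shape != (f.size, 2):
            raise ValueError("frames must be (n,), xy must be (n, 2)")
        if f.size and not np.all(np.diff(f) > 0):
            raise ValueError("frame indices must be strictly increasing")
        self.frames = f
        self.xy = xy

    @property
    def excluded(self) -> bool:
        return self.left_field or self.overlapped

    def __len__(self) -> int:
        return self.frames.size


@dataclass(frozen=True)
class MSDCurve:
    lags: np.ndarray      # s
    msd: np.ndarray       # um^2
    n_cells: np.ndarray   # tracks contributing per lag
    sem: np.ndarray       # um^2


def log_response(image: np.ndarray, sigma: float) -> np.ndarray:
    """Scale-normalized negative Laplacian-of-Gaussian (bright blobs > 0)."""
    return -(sigma**2) * gaussian_laplace(np.asarray(image, float), sigma)


def auto_thresholds(
    first_frame_planes: np.ndarray,
    cell_masks: np.ndarray,
    log_sigma: float = 1.3,
    intensity_quantile: float = 0.5,
) -> SpotDetectionParams:
    """Choose detection thresholds on the first frame, then freeze them.

    The Laplacian threshold is the Otsu split of the LoG-response
    distribution inside the cell masks of the first frame; the intensity
    threshold is the in-mask intensity quantile (default median).  Meant
    to be applied once at t = 0 and reused for the whole movie in every
    illumination condition.
    """
    planes = np.atleast_3d(first_frame_planes)
    if planes.ndim == 2:
        planes = planes[None]
    inside = np.asarray(cell_masks) > 0
    resp = np.stack([log_response(p, log_sigma) for p in planes])
    vals = resp[:, inside].ravel()
    lap_thr = float(threshold_otsu(vals))
    int_thr = float(np.quantile(planes[:, inside], intensity_quantile))
    return SpotDetectionParams(
        log_sigma=log_sigma,
        intensity_threshold=int_thr,
        laplacian_threshold=lap_thr,
    )


def detect_spots(
    frames: np.ndarray,
    params: SpotDetectionParams,
    cell_masks: np.ndarray,
    n_planes: int = 3,
) -> pd.DataFrame:
    """Detect diffraction-limited spots in a multi-plane frame.

    ``frames`` is (n_planes, Y, X) (a single plane may be passed as
    (Y, X) with ``n_planes=1``).  Local maxima of the LoG response that
    pass both the intensity and Laplacian thresholds are kept;
    detections within ``merge_radius`` px in planes at most ``z_merge``
    apart are merged to the brightest; spots outside any cell mask are
    dropped.  Returns columns x, y, plane, intensity, laplacian, cell_id.
    """
    fr = np.asarray(frames, float)
    if fr.ndim == 2:
        fr = fr[None]
    if fr.ndim != 3 or fr.shape[0] != n_planes:
        raise ValueError(f"expected {n_planes} planes, got shape {fr.shape}")
    masks = np.asarray(cell_masks)
    if masks.shape != fr.shape[-2:]:
        raise ValueError("cell masks must match the YX frame shape")

    cand = []
    for z in range(fr.shape[0]):
        resp = log_response(fr[z], params.log_sigma)
        peaks = peak_local_max(
            resp,
            min_distance=max(1, int(round(params.log_sigma))),
            threshold_abs=params.laplacian_threshold,
            exclude_border=False,
        )
        for (r, c) in peaks:
            inten = fr[z, r, c]
            if inten < params.intensity_threshold:
                continue
            cand.append((c, r, z, inten, resp[r, c]))
    if not cand:
        return pd.DataFrame(
            columns=["x", "y", "plane", "intensity", "laplacian", "cell_id"]
        )
    cand.sort(key=lambda t: -t[3])  # brightest first
    # merge transitively: a detection adjacent (in xy and z) to anything
    # already absorbed into a spot joins that spot, so a focus visible in
    # all planes collapses to its brightest plane
    kept: list[tuple] = []
    processed: list[tuple] = []
    for c in cand:
        dup = any(
            abs(c[2] - k[2]) <= params.z_merge
            and (c[0] - k[0]) ** 2 + (c[1] - k[1]) ** 2 <= params.merge_radius**2
            for k in processed
        )
        if not dup:
            kept.append(c)
        processed.append(c)
    rows = []
    for (x, y, z, inten, lap) in kept:
        cid = int(masks[int(y), int(x)])
        if cid > 0:
            rows.append((x, y, z, inten, lap, cid))
    return pd.DataFrame(rows, columns=["x", "y", "plane", "intensity", "laplacian", "cell_id"])


def collect_detections(per_frame: list[pd.DataFrame]) -> pd.DataFrame:
    """Stack per-frame detection tables, adding a ``frame`` column."""
    cols = ["x", "y", "plane", "intensity", "laplacian", "cell_id", "frame"]
    frames = []
    for f, d in enumerate(per_frame):
        if len(d):
            d = d.copy()
            d["frame"] = f
            frames.append(d)
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


def count_spots_per_cell(
    detections: pd.DataFrame,
    cell_ids_per_frame: dict[int, list[int]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell per-frame spot counts plus the mean +/- sem summary curve.

    ``detections`` needs columns frame, cell_id (one row per spot).
    ``cell_ids_per_frame`` lists the cells present in each frame so that
    cells with zero detections contribute zero counts; if omitted, the
    cell set is taken as all cell ids ever detected, present in all
    frames.
    """
    if "frame" not in detections.columns or "cell_id" not in detections.columns:
        raise ValueError("detections need 'frame' and 'cell_id' columns")
    frames = sorted(detections["frame"].unique()) if cell_ids_per_frame is None \
        else sorted(cell_ids_per_frame)
    if cell_ids_per_frame is None:
        all_cells = sorted(detections["cell_id"].unique())
        cell_ids_per_frame = {f: all_cells for f in frames}
    if not any(cell_ids_per_frame.values()):
        raise ValueError("empty cell set")
    rows = []
    for f in frames:
        det_f = detections[detections["frame"] == f]
        counts = det_f.groupby("cell_id").size().to_dict()
        for cid in cell_ids_per_frame[f]:
            rows.append((f, cid, int(counts.get(cid, 0))))
    table = pd.DataFrame(rows, columns=["frame", "cell_id", "n_spots"])
    g = table.groupby("frame")["n_spots"]
    summary = pd.DataFrame({
        "frame": list(g.groups),
        "mean": g.mean().to_numpy(),
        "sem": (g.std(ddof=1) / np.sqrt(g.size())).fillna(0.0).to_numpy(),
        "n_cells": g.size().to_numpy(),
    })
    return table, summary


_LARGE = 1e12


def link_frame_pair(
    xy_a: np.ndarray, xy_b: np.ndarray, max_link_distance: float
) -> list[tuple[int, int]]:
    """Optimal frame-to-frame assignment (Jaqaman-style LAP).

    Minimizes summed squared link distances with alternative
    birth/death cost ``max_link_distance**2`` per unlinked point; links
    longer than ``max_link_distance`` are forbidden.  Returns (i, j)
    index pairs into ``xy_a``/``xy_b``.
    """
    a = np.atleast_2d(np.asarray(xy_a, float))
    b = np.atleast_2d(np.asarray(xy_b, float))
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return []
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    alt = max_link_distance**2
    top_left = np.where(d2 <= alt, d2, _LARGE)
    death = np.full((n, n), _LARGE)
    np.fill_diagonal(death, alt)
    birth = np.full((m, m), _LARGE)
    np.fill_diagonal(birth, alt)
    lower_right = np.where(top_left.T < _LARGE, 0.0, _LARGE)
    cost = np.block([[top_left, death], [birth, lower_right]])
    ri, ci = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(ri, ci)
            if i < n and j < m and top_left[i, j] < _LARGE]


def link_tracks(
    detections_per_frame: list[np.ndarray],
    max_link_distance: float,
) -> list[Track]:
    """Assemble tracks by chaining frame-to-frame LAP assignments.

    ``detections_per_frame[t]`` is an (n_t, 2) array of x/y positions in
    um.  Unlinked detections start new tracks (births); unmatched track
    ends terminate (deaths).  Deterministic.
    """
    if len(detections_per_frame) < 2:
        raise ValueError("need at least 2 frames to link")
    pts = [np.asarray(p, float).reshape(-1, 2) for p in detections_per_frame]
    tracks: list[dict] = []
    open_tracks: dict[int, int] = {}  # detection index in current frame -> track index
    for i, (x, y) in enumerate(pts[0]):
        tracks.append({"frames": [0], "xy": [(x, y)]})
        open_tracks[i] = len(tracks) - 1
    for t in range(1, len(pts)):
        links = link_frame_pair(pts[t - 1], pts[t], max_link_distance)
        new_open: dict[int, int] = {}
        linked_b = set()
        for i, j in links:
            ti = open_tracks.get(i)
            if ti is None:
                continue
            tracks[ti]["frames"].append(t)
            tracks[ti]["xy"].append(tuple(pts[t][j]))
            new_open[j] = ti
            linked_b.add(j)
        for j in range(len(pts[t])):
            if j not in linked_b:
                tracks.append({"frames": [t], "xy": [tuple(pts[t][j])]})
                new_open[j] = len(tracks) - 1
        open_tracks = new_open
    return [
        Track(cell_id=k, frames=np.array(tr["frames"]), xy=np.array(tr["xy"]))
        for k, tr in enumerate(tracks)
    ]


def _pair_cost(xy_a, xy_b, links, max_link_distance) -> float:
    alt = max_link_distance**2
    cost = 0.0
    for i, j in links:
        cost += float(((xy_a[i] - xy_b[j]) ** 2).sum())
    cost += alt * (len(xy_a) - len(links))
    cost += alt * (len(xy_b) - len(links))
    return cost


def compute_msd(
    tracks: list[Track],
    frame_interval: float,
    max_lag: int | None = None,
) -> MSDCurve:
    """Ensemble MSD curve: time-averaged per cell, mean +/- sem across cells.

    Tracks flagged as having left the field or overlapped are filtered
    out first.  For each cell and each lag, the squared displacement is
    averaged over all start frames (overlapping windows, contiguous
    frames only); the curve is the mean and standard error across cells.
    msd(0) = 0 by construction.
    """
    kept = [tr for tr in tracks if not tr.excluded and len(tr) >= 2]
    if not kept:
        raise ValueError("all tracks excluded; nothing to analyze")
    longest = max(len(tr) for tr in kept)
    if max_lag is None:
        max_lag = longest - 1
    max_lag = min(max_lag, longest - 1)
    per_cell = np.full((len(kept), max_lag + 1), np.nan)
    per_cell[:, 0] = 0.0
    for k, tr in enumerate(kept):
        # require contiguous frames within each displacement window
        for lag in range(1, min(max_lag, len(tr) - 1) + 1):
            d_frames = tr.frames[lag:] - tr.frames[:-lag]
            ok = d_frames == lag
            if not ok.any():
                continue
            disp = tr.xy[lag:] - tr.xy[:-lag]
            per_cell[k, lag] = float((disp[ok] ** 2).sum(axis=1).mean())
    n_cells = np.sum(~np.isnan(per_cell), axis=0)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # lags with < 2 cells
        mean = np.nanmean(per_cell, axis=0)
        sd = np.nanstd(per_cell, axis=0, ddof=1)
    sem = np.where(n_cells > 1, sd / np.sqrt(np.maximum(n_cells, 1)), 0.0)
    lags = np.arange(max_lag + 1) * frame_interval
    return MSDCurve(lags=lags, msd=mean, n_cells=n_cells, sem=np.nan_to_num(sem))


def colony_log2_growth(
    areas: pd.DataFrame,
    fit_window: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary-log colony growth curves and per-colony doubling rates.

    ``areas`` needs columns time_s, colony_id, area_um2 (all areas > 0).
    Returns (curves, rates): curves adds a log2_norm_area column
    (log2(A/A0)); rates holds the least-squares slope of log2 area vs
    time per colony — doublings per second — optionally restricted to
    ``fit_window`` (seconds).
    """
    for col in ("time_s", "colony_id", "area_um2"):
        if col not in areas.columns:
            raise ValueError(f"areas table needs column {col!r}")
    if (areas["area_um2"] <= 0).any():
        raise ValueError("colony areas must be > 0")
    curves = []
    rates = []
    for cid, sub in areas.groupby("colony_id"):
        sub = sub.sort_values("time_s")
        t = sub["time_s"].to_numpy(float)
        a = sub["area_um2"].to_numpy(float)
        log2a = np.log2(a / a[0])
        curves.append(pd.DataFrame({
            "time_s": t, "colony_id": cid, "log2_norm_area": log2a,
        }))
        tt, yy = t, log2a
        if fit_window is not None:
            sel = (t >= fit_window[0]) & (t <= fit_window[1])
            tt, yy = t[sel], log2a[sel]
        if tt.size < 2 or np.ptp(tt) == 0:
            raise ValueError(f"colony {cid}: need >= 2 distinct times to fit a rate")
        slope = float(np.polyfit(tt, yy, 1)[0])
        rates.append((cid, slope))
    return (
        pd.concat(curves, ignore_index=True),
        pd.DataFrame(rates, columns=["colony_id", "rate_doublings_per_s"]),
    )
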
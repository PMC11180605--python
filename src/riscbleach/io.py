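"""Readers/writers for the formats the pipeline exchanges.

TIFF stacks are interpreted as T[Z]YX (time first); an optional JSON
sidecar (``<stack>.json`` or an explicit path) carries frame interval,
pixel size, z step and illumination-disc geometry.  Tables are CSV with
a header, UTF-8 and '.' decimal; units are embedded in the column names
(time_s, I_W_cm2, ...).  Every CLI run writes a provenance record with
input hashes, package version and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .quantify import ImageStack, ROISet

__all__ = [
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "write_table",
    "read_table",
    "write_provenance",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_stack(path: str | Path, meta_path: str | Path | None = None) -> ImageStack:
    """Read a multi-page TIFF as an ImageStack (axes T[Z]YX).

    Axis order is taken from the TIFF series metadata when present;
    sample/channel axes (RGB data) are rejected.  3-d data without axis
    metadata is treated as TYX and 4-d as TZYX only when the sidecar
    confirms the layout (``axes`` key); otherwise ambiguous input is an
    error, never a guess.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes.upper()
    meta = {}
    mp = Path(meta_path) if meta_path else _sidecar(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
    if "S" in axes or "C" in axes:
        raise ValueError(f"stack has sample/channel axes ({axes}); expected grayscale T[Z]YX")
    known = set("TZYXQI")
    if not set(axes) <= known:
        raise ValueError(f"unsupported TIFF axes {axes!r}")
    if data.ndim not in (3, 4):
        raise ValueError(f"expected 3-d or 4-d stack, got shape {data.shape}")
    if data.ndim == 4 and axes not in ("TZYX",) and meta.get("axes") != "TZYX":
        raise ValueError(
            f"ambiguous 4-d axes {axes!r}: provide a sidecar with axes='TZYX'"
        )
    return ImageStack(
        pixels=np.asarray(data),
        frame_interval=float(meta.get("frame_interval_s", 1.0)),
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        z_step=meta.get("z_step_um"),
        vis_disc=tuple(meta["vis_disc"]) if meta.get("vis_disc") else None,
        nir_disc=tuple(meta["nir_disc"]) if meta.get("nir_disc") else None,
    )


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write an ImageStack as TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    axes = "TYX" if stack.pixels.ndim == 3 else "TZYX"
    tifffile.imwrite(path, stack.pixels.astype(np.float32),
                     metadata={"axes": axes})
    meta = {
        "axes": axes,
        "frame_interval_s": stack.frame_interval,
        "pixel_size_um": stack.pixel_size,
        "z_step_um": stack.z_step,
        "vis_disc": list(stack.vis_disc) if stack.vis_disc else None,
        "nir_disc": list(stack.nir_disc) if stack.nir_disc else None,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_labels(path: str | Path) -> ROISet:
    lab = tifffile.imread(path)
    return ROISet(labels=np.asarray(lab).astype(np.int32))


def write_labels(path: str | Path, rois: ROISet) -> None:
    tifffile.imwrite(path, rois.labels.astype(np.int32))


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(
    out_path: str | Path,
    command: str,
    inputs: list[str | Path],
    seed: int | None = None,
    extra: dict | None = None,
) -> None:
    """Write ``<out>.provenance.json`` recording inputs, version and seed."""
    from . import __version__

    rec = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "inputs": {
            str(p): _hash_file(Path(p)) for p in inputs if Path(p).is_file()
        },
    }
    if extra:
        rec.update(extra)
    out = Path(out_path)
    out.with_suffix(out.suffix + ".provenance.json").write_text(
        json.dumps(rec, indent=1)
    )
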
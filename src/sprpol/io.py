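"""TIFF/JSON bundle I/O for quad-polarization acquisitions.

A bundle directory holds one multi-page grayscale TIFF per channel
(``chan000.tif`` ... ``chan135.tif``), 16-bit for quantized acquisitions or
32-bit float otherwise, plus a ``meta.json`` sidecar (frame rate,
protocol/noise description, seed).  Mosaic bundles store a single
``mosaic.tif`` in the superpixel-interleaved layout instead.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .containers import CHANNEL_ANGLES, MosaicFrame, PolVideo
from .phase import PhaseImage, PhaseSeries

__all__ = [
    "save_bundle",
    "load_bundle",
    "save_mosaic_video",
    "save_phase_series",
    "load_phase_series",
    "save_phase_image",
]

_CHANNEL_FILES = {a: f"chan{a:03d}.tif" for a in CHANNEL_ANGLES}


def save_bundle(video: PolVideo, directory, dtype: str | None = None) -> Path:
    """Write a four-channel video as one multi-page TIFF per channel plus a
    JSON sidecar.  ``dtype`` defaults to uint16 for quantized integer data
    and float32 otherwise."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if dtype is None:
        quantized = video.meta.get("noise", {}).get("bit_depth", 0) > 0
        integral = np.allclose(video.data, np.round(video.data))
        dtype = "uint16" if (quantized and integral and video.data.min() >= 0 and video.data.max() < 65536) else "float32"
    for i, angle in enumerate(CHANNEL_ANGLES):
        tifffile.imwrite(directory / _CHANNEL_FILES[angle], video.data[:, i].astype(dtype))
    meta = dict(video.meta, frame_rate=video.frame_rate, channel_order=list(CHANNEL_ANGLES), dtype=dtype)
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_bundle(directory) -> PolVideo:
    """Read a bundle written by :func:`save_bundle`."""
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    stacks = []
    for angle in CHANNEL_ANGLES:
        arr = tifffile.imread(directory / _CHANNEL_FILES[angle])
        if arr.ndim == 2:
            arr = arr[None]
        stacks.append(np.asarray(arr, dtype=float))
    data = np.stack(stacks, axis=1)
    return PolVideo(data=data, frame_rate=float(meta.get("frame_rate", 2.0)), meta=meta)


def save_mosaic_video(frames: list[MosaicFrame], directory, frame_rate: float = 2.0) -> Path:
    """Write superpixel-interleaved frames as a single multi-page TIFF."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.stack([f.pixels for f in frames])
    dtype = "uint16" if np.issubdtype(stack.dtype, np.integer) else "float32"
    tifffile.imwrite(directory / "mosaic.tif", stack.astype(dtype))
    meta = {"frame_rate": frame_rate, "layout": [list(r) for r in frames[0].layout], "dtype": dtype}
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    return directory


def save_phase_series(series: PhaseSeries, path) -> Path:
    """Write a phase time series as CSV with columns ``t_s, phi_rad``."""
    path = Path(path)
    header = "t_s,phi_rad"
    if series.roi is not None:
        header += f"\n# roi={','.join(map(str, series.roi))}"
    np.savetxt(path, np.column_stack([series.t, series.phi]), delimiter=",", header="t_s,phi_rad", comments="")
    return path


def load_phase_series(path) -> PhaseSeries:
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return PhaseSeries(t=arr[:, 0], phi=arr[:, 1])


def save_phase_image(image: PhaseImage, path) -> Path:
    """Write a phase map as 32-bit float TIFF (NaN marks invalid pixels)."""
    path = Path(path)
    tifffile.imwrite(path, image.values.astype(np.float32))
    return path
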
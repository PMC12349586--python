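"""Shared image containers for quad-polarization acquisitions.

A quad-polarization frame holds four registered intensity images, one per
micro-polarizer orientation (0°, 45°, 90°, 135°).  Channel axis order is
fixed package-wide to ``(0°, 45°, 90°, 135°)`` and exposed as
:data:`CHANNEL_ANGLES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed channel order of the polarization axis everywhere in the package.
CHANNEL_ANGLES: tuple[int, int, int, int] = (0, 45, 90, 135)

#: Map orientation (degrees) -> channel index.
CHANNEL_INDEX: dict[int, int] = {a: i for i, a in enumerate(CHANNEL_ANGLES)}


@dataclass
class PolFrame:
    """One registered four-channel intensity frame, shape ``(4, H, W)``."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != 4:
            raise ValueError(f"PolFrame data must be (4, H, W), got {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def channel(self, angle: int) -> np.ndarray:
        """Return the image for polarizer orientation *angle* in degrees."""
        return self.data[CHANNEL_INDEX[angle]]


@dataclass
class PolVideo:
    """Registered four-channel time stack, shape ``(T, 4, H, W)``.

    ``meta`` carries acquisition metadata (protocol, noise model, seed,
    reference to ground truth) and is round-tripped by the TIFF/JSON bundle
    I/O.
    """

    data: np.ndarray
    frame_rate: float = 2.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[1] != 4:
            raise ValueError(f"PolVideo data must be (T, 4, H, W), got {self.data.shape}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[2:]

    @property
    def t(self) -> np.ndarray:
        """Frame timestamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.frame_rate

    def frame(self, i: int) -> PolFrame:
        return PolFrame(self.data[i])


# Default 2x2 superpixel layout of the polarization filter array, given as
# orientation degrees at positions [[r0c0, r0c1], [r1c0, r1c1]].  The sensor
# family used for this kind of imaging interleaves (90, 45 / 135, 0); the
# layout is configurable because the mosaic order is a per-device property.
DEFAULT_MOSAIC_LAYOUT: tuple[tuple[int, int], tuple[int, int]] = ((90, 45), (135, 0))


@dataclass
class MosaicFrame:
    """Raw superpixel-interleaved polarization image before channel split."""

    pixels: np.ndarray
    layout: tuple[tuple[int, int], tuple[int, int]] = DEFAULT_MOSAIC_LAYOUT

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("MosaicFrame pixels must be 2-D")
        h, w = self.pixels.shape
        if h % 2 or w % 2:
            raise ValueError(f"mosaic dimensions must be even, got {self.pixels.shape}")
        flat = [a for row in self.layout for a in row]
        if sorted(flat) != sorted(CHANNEL_ANGLES):
            raise ValueError(f"layout must be a permutation of {CHANNEL_ANGLES}, got {self.layout}")
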
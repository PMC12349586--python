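"""Synthetic quad-polarization acquisitions.

Renders four-channel video for constant, step-change and binding-kinetics
protocols through the forward optics model, with the instrument's noise
structure: a frame-global multiplicative source fluctuation (laser power),
additive per-pixel Gaussian noise (dark current, readout and shot noise
folded into one Gaussian), and ADC quantization.  Camera gain is set from
the first clean frame so the mean of I0/I90 sits at half the ADC full
scale, emulating the exposure rule of the instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinetics as _kin
from .containers import DEFAULT_MOSAIC_LAYOUT, CHANNEL_INDEX, MosaicFrame, PolFrame, PolVideo
from .optics import OpticalSystem
from .phase import roi_series

__all__ = [
    "NoiseModel",
    "Protocol",
    "render_video",
    "concentration_to_ri",
    "mosaic_pack",
    "mosaic_unpack",
    "calibrate_noise_to_phase_sd",
    "default_roi",
    "glycerol_calibration_protocol",
    "nacl_steps_protocol",
]

# Linear analyte-to-refractive-index coefficients, RIU per mass-%.  These
# are engineering constants fixed from the endpoints of the instrument's
# own calibration range (46% glycerol spans 1.333 -> 1.393, i.e. 0.060 RIU;
# 0.0025% NaCl is approx 4e-6 RIU) and are approximate by construction.
RI_COEFF = {
    "glycerol": 0.060 / 46.0,
    "nacl": 1.7e-3,
}


def concentration_to_ri(analyte: str, mass_percent: float) -> float:
    """Refractive-index increment of a mass-% solution over pure water."""
    key = analyte.lower()
    if key not in RI_COEFF:
        raise ValueError(f"unknown analyte {analyte!r}; known: {sorted(RI_COEFF)}")
    if not (0 <= mass_percent <= 50):
        raise ValueError("mass_percent must be within [0, 50]")
    return RI_COEFF[key] * mass_percent


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition noise description.

    sigma_add : additive Gaussian SD per pixel per channel, ADC counts.
    source_cv : coefficient of variation of the frame-global multiplicative
        source-power fluctuation (applied to all channels identically).
    bit_depth : ADC bits (12 on the reference camera); 0 disables
        quantization but keeps the 12-bit-equivalent count scale.
    seed : RNG seed; rendering is bit-reproducible given the seed.
    """

    sigma_add: float = 20.0
    source_cv: float = 1e-3
    bit_depth: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_add < 0 or self.source_cv < 0 or self.bit_depth < 0:
            raise ValueError("noise parameters must be nonnegative")

    @property
    def full_scale(self) -> float:
        """ADC full scale in counts (12-bit equivalent when bit_depth = 0)."""
        bits = self.bit_depth if self.bit_depth > 0 else 12
        return float(2**bits - 1)


@dataclass(frozen=True)
class Protocol:
    """Time course of the sensed refractive index.

    ``segments`` is an ordered list of (duration_s, refractive_index) held
    piecewise-constant; kind 'kinetics' instead drives n(t) with the 1:1
    binding model (response expressed directly in RIU).  Default frame rate
    is the instrument's 2 Hz; 10 Hz is also meaningful for smoothing-filter
    studies.
    """

    kind: str = "constant"
    segments: tuple[tuple[float, float], ...] = ((30.0, 1.333),)
    frame_rate: float = 2.0
    kinetics: dict | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "steps", "kinetics"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        object.__setattr__(self, "segments", tuple((float(d), float(v)) for d, v in self.segments))
        if any(d <= 0 for d, _ in self.segments):
            raise ValueError("segment durations must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @classmethod
    def constant(cls, n: float = 1.333, duration_s: float = 30.0, frame_rate: float = 2.0) -> "Protocol":
        return cls(kind="constant", segments=((duration_s, n),), frame_rate=frame_rate)

    @classmethod
    def steps(cls, segments, frame_rate: float = 2.0) -> "Protocol":
        return cls(kind="steps", segments=tuple(segments), frame_rate=frame_rate)

    @classmethod
    def binding(
        cls,
        n_baseline: float = 1.333,
        gamma_max_riu: float = 2e-4,
        c_bulk: float = 1.33e-7,
        ka: float = 1e5,
        kd: float = 1.97e-4,
        t_pbs: float = 180.0,
        duration_s: float = 780.0,
        frame_rate: float = 2.0,
    ) -> "Protocol":
        """Kinetics-driven protocol: association starts at t = 0, buffer
        switch at ``t_pbs``; the surface response is expressed in RIU."""
        return cls(
            kind="kinetics",
            segments=((duration_s, n_baseline),),
            frame_rate=frame_rate,
            kinetics={
                "gamma_max_riu": gamma_max_riu,
                "c_bulk": c_bulk,
                "ka": ka,
                "kd": kd,
                "t_pbs": t_pbs,
            },
        )

    @property
    def duration(self) -> float:
        return sum(d for d, _ in self.segments)

    def n_at(self, t) -> np.ndarray:
        """Refractive index at time(s) ``t`` seconds."""
        t = np.asarray(t, dtype=float)
        edges = np.cumsum([d for d, _ in self.segments])
        values = np.array([v for _, v in self.segments])
        idx = np.minimum(np.searchsorted(edges, t, side="right"), len(values) - 1)
        n = values[idx]
        if self.kind == "kinetics":
            k = self.kinetics
            p = _kin.KineticsParams(
                gamma_max=k["gamma_max_riu"],
                c_bulk=k["c_bulk"],
                ka=k["ka"],
                kd=k["kd"],
                t_pbs=k["t_pbs"],
            )
            n = n + _kin.sensorgram_model(t, p)
        return n


def glycerol_calibration_protocol(
    max_percent: float = 46.0,
    step_percent: float = 2.0,
    hold_s: float = 300.0,
    frame_rate: float = 2.0,
    n_water: float = 1.333,
) -> Protocol:
    """Stepwise glycerol ladder 0 .. max% in ``step_percent`` increments."""
    percents = np.arange(0.0, max_percent + 1e-9, step_percent)
    segs = [(hold_s, n_water + concentration_to_ri("glycerol", p)) for p in percents]
    return Protocol.steps(segs, frame_rate=frame_rate)


def nacl_steps_protocol(
    percents=(0.08, 0.04, 0.025, 0.01, 0.005, 0.0025),
    hold_s: float = 180.0,
    water_s: float = 120.0,
    frame_rate: float = 2.0,
    n_water: float = 1.333,
) -> Protocol:
    """Dilute NaCl switching: each solution step followed by a water return."""
    segs = [(water_s, n_water)]
    for p in percents:
        segs.append((hold_s, n_water + concentration_to_ri("nacl", p)))
        segs.append((water_s, n_water))
    return Protocol.steps(segs, frame_rate=frame_rate)


def _gradient_field(shape: tuple[int, int]) -> np.ndarray:
    """Smooth deterministic spatial field normalized to [-0.5, 0.5]:
    a gentle tilt plus a low-order sinusoidal undulation."""
    h, w = shape
    yy, xx = np.meshgrid(np.linspace(0, 1, h), np.linspace(0, 1, w), indexing="ij")
    g = 0.6 * (xx - 0.5) + 0.25 * np.sin(2 * np.pi * yy) * np.cos(np.pi * xx)
    g -= g.min()
    g = g / g.max() - 0.5
    return g


def render_video(
    system: OpticalSystem,
    protocol: Protocol,
    noise: NoiseModel,
    shape: tuple[int, int] = (128, 128),
    n_frames: int | None = None,
    gradient_riu: float = 0.0,
) -> tuple[PolVideo, PolVideo]:
    """Render a noisy quad-polarization video and its clean ground truth.

    Per frame: n(t) from the protocol (plus an optional static smooth
    spatial refractive-index gradient) -> reflection state -> channel
    intensities, scaled by a fixed camera gain so that the first frame's
    mean of I0/I90 sits at half the ADC full scale; then a shared
    multiplicative source factor (1 + eps_t), additive per-pixel Gaussian
    noise, and quantization.  Ground truth is the pre-noise stack.

    Returns ``(video, truth)``; both carry the acquisition metadata.
    """
    h, w = shape
    if h % 2 or w % 2 or h < 2 or w < 2:
        raise ValueError(f"shape must be even and positive, got {shape}")
    if n_frames is None:
        n_frames = max(int(round(protocol.duration * protocol.frame_rate)), 1)
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")

    t = np.arange(n_frames) / protocol.frame_rate
    n_t = protocol.n_at(t)
    grad = gradient_riu * _gradient_field(shape) if gradient_riu else None
    ambient = system.stack.ambient_index
    n_min = float(np.min(n_t)) - (abs(gradient_riu) / 2 if grad is not None else 0)
    n_max = float(np.max(n_t)) + (abs(gradient_riu) / 2 if grad is not None else 0)
    if not (1.0 < n_min and n_max < ambient):
        raise ValueError(
            f"protocol index range [{n_min:.4f}, {n_max:.4f}] outside (1.0, ambient {ambient})"
        )

    clean = np.empty((n_frames, 4, h, w))
    for i in range(n_frames):
        sub = n_t[i] + grad if grad is not None else n_t[i]
        inten = system.intensities(substrate=sub)
        stackd = inten.stack()
        if stackd.ndim == 1:  # scalar substrate: broadcast over the frame
            stackd = np.broadcast_to(stackd[:, None, None], (4, h, w))
        clean[i] = stackd

    # fixed camera gain: anchor the first frame's I0/I90 mean at half the
    # ADC full scale, but never let any clean channel overexpose during
    # the protocol (the instrument's exposure rule avoids saturation)
    i0i90_mean = 0.5 * (clean[0, 0].mean() + clean[0, 2].mean())
    gain = (noise.full_scale / 2.0) / i0i90_mean
    peak = clean.max()
    if peak * gain > 0.98 * noise.full_scale:
        gain = 0.98 * noise.full_scale / peak
    clean *= gain

    rng = np.random.default_rng(noise.seed)
    data = np.empty_like(clean)
    for i in range(n_frames):
        eps = rng.normal(0.0, noise.source_cv) if noise.source_cv > 0 else 0.0
        frame = clean[i] * (1.0 + eps)
        if noise.sigma_add > 0:
            frame = frame + rng.normal(0.0, noise.sigma_add, size=(4, h, w))
        if noise.bit_depth > 0:
            frame = np.clip(np.round(frame), 0.0, noise.full_scale)
        data[i] = frame

    meta = {
        "protocol": {"kind": protocol.kind, "frame_rate": protocol.frame_rate, "n_segments": len(protocol.segments)},
        "noise": {
            "sigma_add": noise.sigma_add,
            "source_cv": noise.source_cv,
            "bit_depth": noise.bit_depth,
            "seed": noise.seed,
        },
        "gain": float(gain),
        "gradient_riu": gradient_riu,
    }
    video = PolVideo(data=data, frame_rate=protocol.frame_rate, meta=dict(meta))
    truth = PolVideo(data=clean, frame_rate=protocol.frame_rate, meta=dict(meta, ground_truth=True))
    return video, truth


def mosaic_pack(frame: PolFrame, layout=DEFAULT_MOSAIC_LAYOUT) -> MosaicFrame:
    """Interleave four channel images into 2x2 superpixels."""
    h, w = frame.shape
    out = np.empty((2 * h, 2 * w), dtype=frame.data.dtype)
    for r in range(2):
        for c in range(2):
            out[r::2, c::2] = frame.data[CHANNEL_INDEX[layout[r][c]]]
    return MosaicFrame(pixels=out, layout=layout)


def mosaic_unpack(mosaic: MosaicFrame) -> PolFrame:
    """Invert :func:`mosaic_pack`; the round trip is lossless."""
    h, w = mosaic.pixels.shape
    data = np.empty((4, h // 2, w // 2), dtype=mosaic.pixels.dtype)
    for r in range(2):
        for c in range(2):
            data[CHANNEL_INDEX[mosaic.layout[r][c]]] = mosaic.pixels[r::2, c::2]
    return PolFrame(data=data)


def default_roi(shape: tuple[int, int]) -> tuple[int, int, int, int]:
    """Central H/4 x W/4 measurement region in channel-image coordinates."""
    h, w = shape
    rh, rw = max(h // 4, 1), max(w // 4, 1)
    r0, c0 = (h - rh) // 2, (w - rw) // 2
    return (r0, c0, r0 + rh, c0 + rw)


def calibrate_noise_to_phase_sd(
    system: OpticalSystem,
    shape: tuple[int, int],
    target_phase_sd: float,
    seed: int = 0,
    n: float = 1.333,
    n_frames: int = 200,
    frame_rate: float = 2.0,
    roi: tuple[int, int, int, int] | None = None,
    source_cv: float = 1e-3,
    bit_depth: int = 0,
    rel_tol: float = 0.01,
    max_iter: int = 60,
) -> float:
    """Additive-noise level reproducing a target ROI-phase temporal SD.

    Bisection on ``sigma_add``: a constant-index video is rendered (fixed
    seed, so the objective is a deterministic, monotone function of
    ``sigma_add``) and the temporal SD of the mean-ROI phase is measured.
    Calibration runs without quantization by default: on a perfectly flat
    synthetic field an undithered quantizer produces ROI-correlated
    rounding artifacts that no real (spatially heterogeneous) acquisition
    shows, whereas once sigma_add exceeds about one count the quantizer is
    dithered and contributes only ~LSB/sqrt(12) per pixel.  Raises if the
    target cannot be bracketed."""
    if not (target_phase_sd > 0):
        raise ValueError("target_phase_sd must be positive")
    roi = roi or default_roi(shape)
    protocol = Protocol.constant(n=n, duration_s=n_frames / frame_rate, frame_rate=frame_rate)

    def measure(sigma: float) -> float:
        noise = NoiseModel(sigma_add=sigma, source_cv=source_cv, bit_depth=bit_depth, seed=seed)
        video, _ = render_video(system, protocol, noise, shape=shape, n_frames=n_frames)
        return roi_series(video, roi).sd()

    lo, f_lo = 0.0, measure(0.0)
    if f_lo >= target_phase_sd:
        raise ValueError(
            f"noise-free floor {f_lo:.3g} rad already exceeds target {target_phase_sd:.3g} rad"
        )
    hi = 4.0
    f_hi = measure(hi)
    doublings = 0
    while f_hi < target_phase_sd:
        hi *= 2.0
        doublings += 1
        if doublings > 12:
            raise ValueError("cannot bracket target phase SD (sigma_add > 16384 counts)")
        f_hi = measure(hi)

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = measure(mid)
        if abs(f_mid - target_phase_sd) <= rel_tol * target_phase_sd:
            return mid
        if f_mid < target_phase_sd:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
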
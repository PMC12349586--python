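"""Forward model of the quad-polarization SPR imaging chain.

Physics
-------
A collimated 633 nm beam enters a high-index prism (Kretschmann coupling),
reflects off a Cr/Au-coated face in contact with the sensed medium, passes a
half-wave plate and is imaged through a 2x2 micro-polarizer array.  The
reflection of the metal-coated interface is computed with the recursive
(Parratt) Fresnel multilayer model; the polarization optics are handled with
Jones calculus.

Conventions (kept consistent package-wide):

* Jones vectors are written in the (p, s) basis, x = p.  Polarizer filter
  orientations theta and the input polarizer angle alpha are measured from
  the p axis.
* Fresnel coefficients use the characteristic-matrix standard sign
  convention: for a bare interface at normal incidence
  ``r_s = (n1 - n2)/(n1 + n2)`` and ``r_p = (n2 - n1)/(n2 + n1)``.
* Layer-normal wavevectors take the ``Im(kz) >= 0`` branch (decay into
  absorbing media).
* ``delta_phi = arg(r_p) - arg(r_s)`` wrapped to (-pi, pi]; a vanishing
  reflection has ``delta_phi = 0`` by convention.
* The interference sign is fixed such that the quad-channel estimator
  ``(I0 - I90) / (2 sqrt(I45 I135))`` recovers ``+cos(delta_phi)`` on
  noise-free data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "MATERIALS_633",
    "Layer",
    "LayerStack",
    "JonesConfig",
    "ReflectionState",
    "ChannelIntensities",
    "OpticalSystem",
    "multilayer_reflection",
    "jones_reflection_state",
    "channel_intensities",
    "channel_intensities_jones",
    "find_operating_angle",
    "simulate_curve",
]

# Built-in complex refractive indices at 633 nm (Palik-class literature
# values).  Shipped so that results never silently depend on an external
# optical-constants database; override per layer as needed.
MATERIALS_633: dict[str, complex] = {
    "Au": 0.1834 + 3.4332j,
    "Cr": 3.58 + 4.36j,
}


@dataclass(frozen=True)
class Layer:
    """One thin film: name, complex refractive index, thickness in nm."""

    name: str
    index: complex
    thickness_nm: float

    def __post_init__(self) -> None:
        if not (self.thickness_nm > 0):
            raise ValueError(f"layer {self.name!r}: thickness must be > 0 nm")


@dataclass(frozen=True)
class LayerStack:
    """Prism / thin films / sensed medium, with the probe wavelength.

    Defaults reproduce the reference instrument: ZF5 prism (n = 1.734),
    3 nm Cr adhesion layer, 30 nm Au film, water substrate, 633 nm laser.
    """

    ambient_index: float = 1.734
    layers: tuple[Layer, ...] = (
        Layer("Cr", MATERIALS_633["Cr"], 3.0),
        Layer("Au", MATERIALS_633["Au"], 30.0),
    )
    substrate_index: complex = 1.333
    wavelength_nm: float = 633.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if not (self.wavelength_nm > 0):
            raise ValueError("wavelength must be > 0 nm")
        if not (self.ambient_index > 0):
            raise ValueError("ambient index must be > 0")

    @property
    def critical_angle(self) -> float:
        """Total-internal-reflection angle vs the real part of the substrate."""
        ratio = float(np.real(self.substrate_index)) / self.ambient_index
        return math.asin(min(ratio, 1.0))


@dataclass(frozen=True)
class JonesConfig:
    """Polarizer angle alpha, half-wave-plate fast axis gamma, amplitude.

    The operating point of the instrument is alpha = 45 deg (maximal
    interference contrast between I0 and I90) with the half-wave plate at
    gamma = 22.5 deg, which rotates (p, s) onto the 45/135 deg analyzer pair.
    """

    alpha: float = math.pi / 4
    gamma: float = math.pi / 8
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (self.amplitude > 0):
            raise ValueError("amplitude must be > 0")


@dataclass(frozen=True)
class ReflectionState:
    """Complex s/p reflection coefficients and their phase difference."""

    r_s: complex | np.ndarray
    r_p: complex | np.ndarray
    phi_s: float | np.ndarray
    phi_p: float | np.ndarray
    delta_phi: float | np.ndarray


@dataclass(frozen=True)
class ChannelIntensities:
    """Intensities seen by the four analyzer orientations."""

    i0: float | np.ndarray
    i45: float | np.ndarray
    i90: float | np.ndarray
    i135: float | np.ndarray

    def stack(self) -> np.ndarray:
        """Channel-first array in the package order (0, 45, 90, 135)."""
        return np.stack(np.broadcast_arrays(self.i0, self.i45, self.i90, self.i135))


def _wrap_phase(phi):
    """Wrap angles to the (-pi, pi] interval."""
    out = np.asarray((-phi + np.pi) % (2 * np.pi))
    return np.pi - out  # maps to (-pi, pi]


def _kz(n, kx, k0):
    kz = np.sqrt((k0 * np.asarray(n, dtype=complex)) ** 2 - kx**2)
    # decay (not growth) into lossy / evanescent regions
    return np.where(np.imag(kz) < 0, -kz, kz)


def _interface_r(n_i, n_j, kz_i, kz_j, pol: str):
    if pol == "s":
        return (kz_i - kz_j) / (kz_i + kz_j)
    n_i = np.asarray(n_i, dtype=complex)
    n_j = np.asarray(n_j, dtype=complex)
    return (n_j**2 * kz_i - n_i**2 * kz_j) / (n_j**2 * kz_i + n_i**2 * kz_j)


def multilayer_reflection(stack: LayerStack, aoi, pol: str, substrate=None):
    """Complex amplitude reflection coefficient of the layer stack.

    Recursive (Parratt) Fresnel formulation.  ``aoi`` is the angle of
    incidence in the ambient medium, radians, broadcastable; ``substrate``
    optionally overrides ``stack.substrate_index`` (scalar or array, e.g. a
    per-pixel refractive-index map).

    Parameters
    ----------
    stack : LayerStack
    aoi : float or ndarray
        0 <= aoi < pi/2.
    pol : {'s', 'p'}
    substrate : complex or ndarray, optional
    """
    if pol not in ("s", "p"):
        raise ValueError(f"pol must be 's' or 'p', got {pol!r}")
    aoi = np.asarray(aoi, dtype=float)
    if np.any(aoi < 0) or np.any(aoi >= np.pi / 2):
        raise ValueError("aoi must satisfy 0 <= aoi < pi/2")
    n_sub = stack.substrate_index if substrate is None else substrate

    k0 = 2 * np.pi / stack.wavelength_nm
    kx = k0 * stack.ambient_index * np.sin(aoi)

    indices = [complex(stack.ambient_index)] + [l.index for l in stack.layers]
    thicknesses = [l.thickness_nm for l in stack.layers]

    kz_sub = _kz(n_sub, kx, k0)
    kz = [_kz(n, kx, k0) for n in indices]

    # start at the deepest interface (last film / substrate) and fold upward
    r = _interface_r(indices[-1], n_sub, kz[-1], kz_sub, pol)
    for j in range(len(indices) - 2, -1, -1):
        phase = np.exp(2j * kz[j + 1] * thicknesses[j])
        r_ij = _interface_r(indices[j], indices[j + 1], kz[j], kz[j + 1], pol)
        r = (r_ij + r * phase) / (1 + r_ij * r * phase)
    if r.ndim == 0:
        return complex(r)
    return r


def jones_reflection_state(stack: LayerStack, aoi, substrate=None) -> ReflectionState:
    """s/p reflection coefficients and their phase difference at ``aoi``."""
    r_s = multilayer_reflection(stack, aoi, "s", substrate=substrate)
    r_p = multilayer_reflection(stack, aoi, "p", substrate=substrate)
    phi_s = np.angle(r_s)
    phi_p = np.angle(r_p)
    delta = _wrap_phase(phi_p - phi_s)
    # delta_phi of a vanishing reflection is 0 by convention
    zero = (np.abs(np.asarray(r_s)) == 0) | (np.abs(np.asarray(r_p)) == 0)
    delta = np.where(zero, 0.0, delta)
    if np.ndim(r_s) == 0:
        return ReflectionState(r_s, r_p, float(phi_s), float(phi_p), float(delta))
    return ReflectionState(r_s, r_p, phi_s, phi_p, delta)


def channel_intensities(state: ReflectionState, cfg: JonesConfig | None = None) -> ChannelIntensities:
    """Closed-form channel intensities of the quad-polarization detector.

    With moduli ``rp = |r_p|``, ``rs = |r_s|`` and the phase difference
    ``dphi``::

        I0   = Ei^2/2 (rp^2 cos^2 a + rs^2 sin^2 a + 2 rp rs cos a sin a cos dphi)
        I90  = Ei^2/2 (rp^2 cos^2 a + rs^2 sin^2 a - 2 rp rs cos a sin a cos dphi)
        I45  = Ei^2 rp^2 cos^2 a
        I135 = Ei^2 rs^2 sin^2 a

    These are exactly the explicit Jones products
    ``|J_theta J_half J_SPR E_i|^2`` (see :func:`channel_intensities_jones`);
    I0 carries the ``+`` interference term so that the phase estimator
    recovers ``+cos(delta_phi)``.
    """
    cfg = cfg or JonesConfig()
    rp = np.abs(state.r_p)
    rs = np.abs(state.r_s)
    c, s = math.cos(cfg.alpha), math.sin(cfg.alpha)
    e2 = cfg.amplitude**2
    common = 0.5 * e2 * (rp**2 * c**2 + rs**2 * s**2)
    cross = e2 * rp * rs * c * s * np.cos(state.delta_phi)
    return ChannelIntensities(
        i0=common + cross,
        i45=e2 * rp**2 * c**2,
        i90=common - cross,
        i135=e2 * rs**2 * s**2,
    )


def _polarizer_matrix(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c * c, c * s], [c * s, s * s]])


#: Half-wave plate at gamma = 22.5 deg in the (p, s) basis.
_J_HALF = np.array([[1.0, 1.0], [1.0, -1.0]]) * (math.sqrt(2) / 2)


def channel_intensities_jones(state: ReflectionState, cfg: JonesConfig | None = None) -> ChannelIntensities:
    """Channel intensities by explicit Jones matrix products.

    Independent route to the same quantities as :func:`channel_intensities`
    (used as a cross-check): the field is propagated through
    ``J_theta . J_half . J_SPR`` and the detected intensity is its squared
    norm.  Only the operating-point half-wave plate (gamma = 22.5 deg) is
    modeled, matching the closed forms.
    """
    cfg = cfg or JonesConfig()
    e_in = cfg.amplitude * np.array([math.cos(cfg.alpha), math.sin(cfg.alpha)])
    j_spr = np.array(
        [
            [np.abs(state.r_p) * np.exp(1j * np.asarray(state.phi_p)), 0],
            [0, np.abs(state.r_s) * np.exp(1j * np.asarray(state.phi_s))],
        ]
    )
    field_mid = _J_HALF @ (j_spr @ e_in.astype(complex))
    out = {}
    for angle in (0, 45, 90, 135):
        e_out = _polarizer_matrix(math.radians(angle)) @ field_mid
        out[angle] = float(np.sum(np.abs(e_out) ** 2))
    return ChannelIntensities(i0=out[0], i45=out[45], i90=out[90], i135=out[135])


def find_operating_angle(
    stack: LayerStack,
    n_mid: float = 1.363,
    n_range: tuple[float, float] = (1.333, 1.393),
    aoi_max: float = math.radians(80.0),
    n_points: int = 1500,
    dn: float = 5e-4,
    branch_margin: float = 0.1,
) -> float:
    """Operating angle of incidence: maximal mid-range phase sensitivity on
    a single monotone phase branch.

    Dense sweep between just above the critical angle and ``aoi_max``.  The
    sensitivity |d delta_phi / dn| is a central difference at the mid-range
    substrate index ``n_mid``.  Candidate angles are restricted to those
    where delta_phi(n) is strictly monotone and stays within
    (branch_margin, pi - branch_margin) over the full working range
    ``n_range`` — the operating condition of a wide-dynamic-range
    instrument, since the arccos-branch phase readout folds at 0 and pi.
    If no angle satisfies the branch constraint the unconstrained maximum
    is returned.  Deterministic, so the operating point of a given stack is
    reproducible.
    """
    lo = stack.critical_angle + math.radians(0.3)
    aois = np.linspace(lo, aoi_max, n_points)
    d_hi = jones_reflection_state(stack, aois, substrate=n_mid + dn).delta_phi
    d_lo = jones_reflection_state(stack, aois, substrate=n_mid - dn).delta_phi
    slope = np.abs(_wrap_phase(d_hi - d_lo)) / (2 * dn)

    ns = np.linspace(n_range[0], n_range[1], 41)
    # delta_phi(aoi, n) on the sweep grid
    dphi = np.stack([jones_reflection_state(stack, aois, substrate=n).delta_phi for n in ns], axis=1)
    inside = np.all((dphi > branch_margin) & (dphi < np.pi - branch_margin), axis=1)
    steps = np.diff(dphi, axis=1)
    monotone = np.all(steps > 0, axis=1) | np.all(steps < 0, axis=1)
    ok = inside & monotone
    if np.any(ok):
        slope = np.where(ok, slope, -np.inf)
    return float(aois[int(np.argmax(slope))])


@dataclass
class OpticalSystem:
    """Full optical configuration: layer stack, angle of incidence, Jones optics.

    ``aoi = None`` selects the deterministic default operating point (the
    angle of maximal phase sensitivity at mid-range index, see
    :func:`find_operating_angle`); it is resolved lazily and cached.
    """

    stack: LayerStack = field(default_factory=LayerStack)
    aoi: float | None = None
    jones: JonesConfig = field(default_factory=JonesConfig)

    def __post_init__(self) -> None:
        if self.aoi is not None and not (0 <= self.aoi < math.pi / 2):
            raise ValueError("aoi must satisfy 0 <= aoi < pi/2")

    @property
    def aoi_resolved(self) -> float:
        if self.aoi is None:
            self.aoi = find_operating_angle(self.stack)
        return self.aoi

    def reflection(self, substrate=None) -> ReflectionState:
        return jones_reflection_state(self.stack, self.aoi_resolved, substrate=substrate)

    def intensities(self, substrate=None) -> ChannelIntensities:
        return channel_intensities(self.reflection(substrate=substrate), self.jones)

    def with_substrate(self, n) -> "OpticalSystem":
        return replace(self, stack=replace(self.stack, substrate_index=n))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "wavelength_nm": self.stack.wavelength_nm,
            "ambient_index": self.stack.ambient_index,
            "substrate_index": [float(np.real(self.stack.substrate_index)), float(np.imag(self.stack.substrate_index))],
            "layers": [[l.name, l.index.real, l.index.imag, l.thickness_nm] for l in self.stack.layers],
            "aoi_deg": None if self.aoi is None else math.degrees(self.aoi),
            "alpha_deg": math.degrees(self.jones.alpha),
            "gamma_deg": math.degrees(self.jones.gamma),
            "amplitude": self.jones.amplitude,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalSystem":
        sub = d.get("substrate_index", 1.333)
        if isinstance(sub, (list, tuple)):
            sub = complex(sub[0], sub[1])
            if sub.imag == 0:
                sub = sub.real
        stack = LayerStack(
            ambient_index=d.get("ambient_index", 1.734),
            layers=tuple(Layer(n, complex(nr, ni), t) for n, nr, ni, t in d.get("layers", [])),
            substrate_index=sub,
            wavelength_nm=d.get("wavelength_nm", 633.0),
        )
        aoi_deg = d.get("aoi_deg")
        jones = JonesConfig(
            alpha=math.radians(d.get("alpha_deg", 45.0)),
            gamma=math.radians(d.get("gamma_deg", 22.5)),
            amplitude=d.get("amplitude", 1.0),
        )
        return cls(stack=stack, aoi=None if aoi_deg is None else math.radians(aoi_deg), jones=jones)

    @classmethod
    def from_yaml(cls, path) -> "OpticalSystem":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


def simulate_curve(system: OpticalSystem, n_values: np.ndarray) -> dict[str, np.ndarray]:
    """Sweep the substrate refractive index at the fixed operating angle.

    Returns columns ``n, rp_abs, rs_abs, delta_phi, i0, i45, i90, i135``
    (``delta_phi`` wrapped to (-pi, pi]).
    """
    n_values = np.asarray(n_values, dtype=float)
    state = system.reflection(substrate=n_values)
    inten = channel_intensities(state, system.jones)
    return {
        "n": n_values,
        "rp_abs": np.abs(state.r_p),
        "rs_abs": np.abs(state.r_s),
        "delta_phi": np.asarray(state.delta_phi),
        "i0": np.asarray(inten.i0),
        "i45": np.asarray(inten.i45),
        "i90": np.asarray(inten.i90),
        "i135": np.asarray(inten.i135),
    }
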
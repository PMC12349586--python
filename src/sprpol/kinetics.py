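"""1:1 Langmuir binding kinetics: model evaluation and global fitting.

The association phase of a 1:1 interaction at bulk analyte concentration
``C`` follows

    G_assoc(t) = Gmax * C / (C + kd/ka) * (1 - exp(-t (ka C + kd)))

and, after buffer switch at ``t_pbs``, the dissociation phase decays as

    G_dissoc(t) = G_assoc(t_pbs) * exp(-(t - t_pbs) kd)

with association rate ``ka`` (1/(M s)), dissociation rate ``kd`` (1/s) and
equilibrium dissociation constant ``KD = kd/ka``.  Both expressions solve
``dG/dt = ka C (Gmax - G) - kd G`` with ``C = 0`` after ``t_pbs``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KineticsParams",
    "Sensorgram",
    "KineticsFit",
    "assoc",
    "dissoc",
    "sensorgram_model",
    "fit_kinetics",
    "kd_relative_difference",
    "multi_roi_kd",
    "ug_per_ml_to_molar",
]

#: Default analyte molecular weight: 150 kDa (IgG-class antibody).
DEFAULT_MW_KDA = 150.0


def ug_per_ml_to_molar(ug_per_ml: float, mw_kda: float = DEFAULT_MW_KDA) -> float:
    """Convert a mass concentration in ug/mL to molarity for a protein of
    molecular weight ``mw_kda`` (kDa).  0.15625 ug/mL of a 150 kDa IgG is
    about 1 nM."""
    return ug_per_ml * 1e-3 / (mw_kda * 1e3)


@dataclass(frozen=True)
class KineticsParams:
    """Parameters of the 1:1 binding model (response units are arbitrary
    but consistent; the instrument reports radians)."""

    gamma_max: float  # maximal response
    c_bulk: float  # bulk analyte concentration, M
    ka: float  # association rate, 1/(M s)
    kd: float  # dissociation rate, 1/s
    t_pbs: float  # dissociation start, s

    def __post_init__(self) -> None:
        for name in ("gamma_max", "c_bulk", "ka", "kd", "t_pbs"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")

    @property
    def kD(self) -> float:
        """Equilibrium dissociation constant kd/ka, in M."""
        return self.kd / self.ka


@dataclass
class Sensorgram:
    """One response-vs-time curve at a single analyte concentration.

    ``t`` starts at the injection (association starts at t = 0) and
    ``t_pbs`` marks the buffer switch."""

    t: np.ndarray
    response: np.ndarray
    c_bulk: float
    t_pbs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.t.shape != self.response.shape:
            raise ValueError("t and response must match")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not (self.c_bulk > 0 and self.t_pbs > 0):
            raise ValueError("c_bulk and t_pbs must be positive")


def assoc(t, p: KineticsParams):
    """Association-phase response at time(s) ``t`` (s) since injection."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("association time must be >= 0")
    kD = p.kd / p.ka
    plateau = p.gamma_max * p.c_bulk / (p.c_bulk + kD)
    return plateau * (1.0 - np.exp(-t * (p.ka * p.c_bulk + p.kd)))


def dissoc(t, p: KineticsParams, gamma_at_tpbs: float | None = None):
    """Dissociation-phase response for ``t >= t_pbs``.

    ``gamma_at_tpbs`` defaults to the association value at ``t_pbs`` so the
    two phases are continuous."""
    t = np.asarray(t, dtype=float)
    if np.any(t < p.t_pbs):
        raise ValueError("dissociation time must be >= t_pbs")
    if gamma_at_tpbs is None:
        gamma_at_tpbs = float(assoc(p.t_pbs, p))
    return gamma_at_tpbs * np.exp(-(t - p.t_pbs) * p.kd)


def sensorgram_model(t, p: KineticsParams):
    """Piecewise association/dissociation response over a full cycle."""
    t = np.asarray(t, dtype=float)
    out = np.where(
        t < p.t_pbs,
        assoc(np.clip(t, 0, None), p),
        float(assoc(p.t_pbs, p)) * np.exp(-np.clip(t - p.t_pbs, 0, None) * p.kd),
    )
    return out


@dataclass
class KineticsFit:
    """Result of a kinetics fit.  Confidence intervals are 95% normal
    intervals from the Jacobian at the solution, on the log of each rate."""

    ka: float
    kd: float
    gamma_max: float
    ka_ci: tuple[float, float]
    kd_ci: tuple[float, float]
    residuals: list[np.ndarray] = field(default_factory=list)
    cost: float = 0.0

    @property
    def kD(self) -> float:
        return self.kd / self.ka


def _init_guess(curves: list[Sensorgram]) -> tuple[float, float, float]:
    """Initial (ka, kd, gamma_max): kd from a log-linear fit of the
    dissociation tails, gamma_max from the largest plateau, ka by a coarse
    log-spaced scan."""
    kds = []
    for c in curves:
        mask = c.t >= c.t_pbs
        y = c.response[mask]
        t = c.t[mask]
        pos = y > max(1e-12, 0.05 * np.max(np.abs(c.response)))
        if np.sum(pos) >= 3:
            slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
            if slope < 0:
                kds.append(-slope)
    kd0 = float(np.median(kds)) if kds else 1e-3
    top = max(curves, key=lambda c: c.c_bulk)
    gmax0 = float(np.max(top.response)) * 1.5 if np.max(top.response) > 0 else 1.0

    def sse(ka):
        tot = 0.0
        for c in curves:
            p = KineticsParams(gamma_max=gmax0, c_bulk=c.c_bulk, ka=ka, kd=kd0, t_pbs=c.t_pbs)
            tot += float(np.sum((sensorgram_model(c.t, p) - c.response) ** 2))
        return tot

    grid = np.logspace(2, 8, 25)
    ka0 = float(grid[int(np.argmin([sse(k) for k in grid]))])
    return ka0, kd0, gmax0


def fit_kinetics(
    sensorgrams: list[Sensorgram] | Sensorgram,
    init: tuple[float, float, float] | None = None,
    shared: bool = True,
) -> KineticsFit:
    """Global nonlinear least squares of the 1:1 model.

    ``ka``, ``kd`` and ``gamma_max`` are shared across all concentrations
    (``shared=True``, the default, recommended for identifiability); with a
    single curve an identifiability warning is emitted.  Rates are fitted on
    a log scale; residuals are unweighted.
    """
    if isinstance(sensorgrams, Sensorgram):
        sensorgrams = [sensorgrams]
    if not sensorgrams:
        raise ValueError("need at least one sensorgram")
    if len(sensorgrams) == 1:
        warnings.warn(
            "single-concentration fit: ka and gamma_max are weakly identifiable",
            stacklevel=2,
        )
    if not shared:
        fits = [fit_kinetics([c], init=init) for c in sensorgrams]
        # combine per-curve fits by averaging log-rates
        ka = float(np.exp(np.mean([np.log(f.ka) for f in fits])))
        kd = float(np.exp(np.mean([np.log(f.kd) for f in fits])))
        gm = float(np.mean([f.gamma_max for f in fits]))
        return KineticsFit(ka, kd, gm, (np.nan, np.nan), (np.nan, np.nan))

    ka0, kd0, gmax0 = init if init is not None else _init_guess(sensorgrams)
    x0 = np.log([ka0, kd0, gmax0])

    def residual(x):
        ka, kd, gm = np.exp(x)
        res = []
        for c in sensorgrams:
            p = KineticsParams(gamma_max=gm, c_bulk=c.c_bulk, ka=ka, kd=kd, t_pbs=c.t_pbs)
            res.append(sensorgram_model(c.t, p) - c.response)
        return np.concatenate(res)

    sol = least_squares(residual, x0, method="lm", max_nfev=5000)
    if not sol.success:
        raise RuntimeError(f"kinetics fit did not converge: {sol.message} (status {sol.status})")
    ka, kd, gm = np.exp(sol.x)

    # 95% CI from the Jacobian at the solution (log-parameter scale)
    dof = max(sol.fun.size - sol.x.size, 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    ka_ci = (float(ka * np.exp(-1.96 * se[0])), float(ka * np.exp(1.96 * se[0])))
    kd_ci = (float(kd * np.exp(-1.96 * se[1])), float(kd * np.exp(1.96 * se[1])))

    residuals = []
    i = 0
    for c in sensorgrams:
        residuals.append(sol.fun[i : i + c.t.size])
        i += c.t.size
    return KineticsFit(
        ka=float(ka),
        kd=float(kd),
        gamma_max=float(gm),
        ka_ci=ka_ci,
        kd_ci=kd_ci,
        residuals=residuals,
        cost=float(sol.cost),
    )


def kd_relative_difference(kd_a: float, kd_b: float) -> float:
    """Relative difference 100 |kd_a - kd_b| / kd_b, in percent (asymmetric:
    the second argument is the reference)."""
    if not (kd_b > 0):
        raise ValueError("reference kd_b must be positive")
    return 100.0 * abs(kd_a - kd_b) / kd_b


def multi_roi_kd(video, rois, injections, baseline_frames: int = 1):
    """Per-ROI equilibrium dissociation constants from a kinetics video.

    Parameters
    ----------
    video : PolVideo
    rois : list of (r0, c0, r1, c1)
        At least two regions.
    injections : list of dict
        Each with keys ``t_start``, ``t_pbs``, ``t_end`` (s, video clock)
        and ``c_bulk`` (M); one sensorgram per injection per ROI.  The
        response baseline is the mean phase of the ``baseline_frames``
        frames preceding ``t_start``.

    Returns
    -------
    dict with ``kd_per_roi`` (list, M), ``geometric_mean`` and
    ``geometric_sd`` (exp of the sample SD of ln KD).
    """
    from .phase import roi_series  # local import to avoid a cycle

    if len(rois) < 2:
        raise ValueError("need at least two ROIs")
    kds = []
    for roi in rois:
        series = roi_series(video, roi)
        curves = []
        for inj in injections:
            i0 = int(np.searchsorted(series.t, inj["t_start"]))
            i1 = int(np.searchsorted(series.t, inj["t_end"]))
            base = float(np.mean(series.phi[max(i0 - baseline_frames, 0) : max(i0, 1)]))
            t = series.t[i0:i1] - inj["t_start"]
            y = series.phi[i0:i1] - base
            # phase decreases or increases with index depending on the branch;
            # orient the response to be positive-going
            if np.mean(y[-max(3, len(y) // 10) :]) < 0 or np.mean(y) < 0:
                y = -y
            curves.append(
                Sensorgram(t=t, response=y, c_bulk=inj["c_bulk"], t_pbs=inj["t_pbs"] - inj["t_start"])
            )
        kds.append(fit_kinetics(curves).kD)
    log_kd = np.log(kds)
    gmean = float(np.exp(np.mean(log_kd)))
    gsd = float(np.exp(np.std(log_kd, ddof=1)))
    return {"kd_per_roi": [float(k) for k in kds], "geometric_mean": gmean, "geometric_sd": gsd}
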
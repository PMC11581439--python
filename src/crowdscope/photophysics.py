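"""Time-resolved photophysics: decay fits, Perrin law, phasors, calibration.

The steady-state anisotropy of a fluorophore reflects a race between
emission and rotation,

    r = r0 / (1 + tau / theta_c),        theta_c = eta * V / (kB * T)

(Perrin), while the lifetime itself shrinks with the square of the local
refractive index (Strickler-Berg, tau ~ 1/n^2).  Together these make a
slow-rotating protein like EGFP a refractive-index — hence crowding —
sensor.  This module fits mono-exponential intensity and anisotropy decays,
evaluates the Perrin relation per pixel, projects decays onto phasor
coordinates, and calibrates anisotropy against crowder concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BOLTZMANN_J_PER_K",
    "DecayTrace",
    "AnisotropyDecayFit",
    "LifetimeFit",
    "PhasorPoint",
    "CrowderCalibration",
    "PerrinInputs",
    "rotational_correlation_time",
    "fit_anisotropy_decay",
    "fit_lifetime_decay",
    "perrin_steady_state",
    "reconstruct_anisotropy_map",
    "strickler_berg_scale",
    "phasor_transform",
    "calibrate_crowder",
]

BOLTZMANN_J_PER_K = 1.380649e-23

# theta_c beyond this multiple of the trace window is indistinguishable from
# no rotation at all and is flagged as such.
_NON_ROTATING_FACTOR = 100.0


@dataclass
class DecayTrace:
    """A time-resolved trace: photon counts (intensity) or r(t) (anisotropy)."""

    t: np.ndarray  # ns, strictly increasing
    counts: np.ndarray
    kind: str = "intensity"  # "intensity" | "anisotropy"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.t.shape != self.counts.shape:
            raise ValueError("t and counts must have the same length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if self.kind not in ("intensity", "anisotropy"):
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if self.kind == "intensity" and np.any(self.counts < 0):
            raise ValueError("intensity counts must be non-negative")


@dataclass
class AnisotropyDecayFit:
    r0: float  # intrinsic anisotropy
    theta_c: float  # rotational correlation time, ns (inf if non-rotating)
    residual: np.ndarray = field(default_factory=lambda: np.empty(0))
    non_rotating: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.r0 <= 0.4 + 1e-9):
            raise ValueError(f"r0={self.r0} outside the physical range (0, 0.4]")
        if not self.non_rotating and self.theta_c <= 0:
            raise ValueError("theta_c must be positive")


@dataclass
class LifetimeFit:
    tau: float  # ns
    amplitude: float
    offset: float
    residual: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class PhasorPoint:
    """First-harmonic Fourier coordinates of a decay.

    Any physical (non-negative) decay lands inside the universal semicircle:
    0 <= g <= 1, 0 <= s <= 1/2; single exponentials lie exactly on it.
    """

    gcoord: float
    scoord: float
    omega: float  # rad/ns


@dataclass
class CrowderCalibration:
    """Linear map between crowder concentration and anisotropy.

    concentration = m * (r - alpha_r), i.e. r = c/m + alpha_r, with alpha_r
    the anisotropy of the probe at zero crowder.
    """

    m: float  # mM per anisotropy unit
    alpha_r: float
    crowder: str = ""
    r_squared: float = np.nan

    def concentration(self, r: np.ndarray) -> np.ndarray:
        return self.m * (np.asarray(r, dtype=float) - self.alpha_r)

    def anisotropy(self, concentration: np.ndarray) -> np.ndarray:
        return np.asarray(concentration, dtype=float) / self.m + self.alpha_r


@dataclass
class PerrinInputs:
    eta: float  # Pa s
    vol_h: float  # m^3, hydrodynamic volume
    temperature: float  # K

    def __post_init__(self) -> None:
        if min(self.eta, self.vol_h, self.temperature) <= 0:
            raise ValueError("viscosity, volume and temperature must be positive")


def rotational_correlation_time(inputs: PerrinInputs) -> float:
    """theta_c = eta * V / (kB * T), returned in ns."""
    seconds = inputs.eta * inputs.vol_h / (BOLTZMANN_J_PER_K * inputs.temperature)
    return seconds * 1e9


def _window(trace: DecayTrace, fit_start: float) -> tuple[np.ndarray, np.ndarray]:
    sel = trace.t >= fit_start
    return trace.t[sel], trace.counts[sel]


def fit_anisotropy_decay(trace: DecayTrace, fit_start: float = 0.0) -> AnisotropyDecayFit:
    """Least-squares mono-exponential fit r(t) = r0 * exp(-t / theta_c).

    Fitted directly on the anisotropy trace with uniform weights.  A trace
    that does not decay over ~100x its window is returned with
    ``theta_c = inf`` and ``non_rotating=True`` instead of failing.
    """
    if trace.kind != "anisotropy":
        raise ValueError("fit_anisotropy_decay requires an anisotropy trace")
    t, r = _window(trace, fit_start)
    if t.size < 20:
        raise ValueError(f"need >= 20 bins after fit_start, got {t.size}")
    window = t[-1] - t[0]
    # Log-linear seed (positive values only).
    pos = r > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(r[pos]), 1)
        theta0 = -1.0 / slope if slope < 0 else _NON_ROTATING_FACTOR * window
        r0_0 = float(np.exp(intercept))
    else:
        theta0, r0_0 = window, max(float(r.max()), 1e-3)
    theta0 = float(np.clip(theta0, 1e-3, _NON_ROTATING_FACTOR * window))
    r0_0 = float(np.clip(r0_0, 1e-4, 0.4))

    def model(tt, r0, theta):
        return r0 * np.exp(-tt / theta)

    try:
        popt, _ = optimize.curve_fit(
            model, t, r, p0=[r0_0, theta0],
            bounds=([1e-6, 1e-6], [0.4, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"anisotropy decay fit did not converge (seed r0={r0_0:.3g}, "
            f"theta={theta0:.3g} ns): {exc}"
        ) from exc
    r0, theta = float(popt[0]), float(popt[1])
    resid = r - model(t, *popt)
    if theta > _NON_ROTATING_FACTOR * window:
        return AnisotropyDecayFit(
            r0=r0, theta_c=np.inf, residual=resid, non_rotating=True
        )
    return AnisotropyDecayFit(r0=r0, theta_c=theta, residual=resid)


def fit_lifetime_decay(trace: DecayTrace, fit_start: float | None = None) -> LifetimeFit:
    """Tail fit of an intensity decay to A * exp(-t / tau) + offset.

    ``fit_start`` defaults to the time of the trace's peak, so the rising
    edge (instrument response) is excluded.
    """
    if trace.kind != "intensity":
        raise ValueError("fit_lifetime_decay requires an intensity trace")
    if fit_start is None:
        fit_start = float(trace.t[np.argmax(trace.counts)])
    t, y = _window(trace, fit_start)
    if t.size < 5:
        raise ValueError("too few bins after fit_start for a lifetime fit")
    offset0 = float(y.min())
    amp0 = max(float(y.max() - offset0), 1e-9)
    above = y - offset0 > 0.05 * amp0
    if above.sum() >= 2:
        slope, _ = np.polyfit(t[above], np.log(y[above] - offset0 + 1e-300), 1)
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0])
    else:
        tau0 = t[-1] - t[0]
    tau0 = float(np.clip(tau0, 1e-3, 1e4))

    def model(tt, amp, tau, off):
        return amp * np.exp(-tt / tau) + off

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[amp0, tau0, offset0], maxfev=10000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"lifetime fit did not converge: {exc}") from exc
    amp, tau, off = map(float, popt)
    return LifetimeFit(tau=tau, amplitude=amp, offset=off, residual=y - model(t, *popt))


def perrin_steady_state(r0: float, tau: float, theta_c: float) -> float:
    """Steady-state anisotropy r = r0 / (1 + tau / theta_c)."""
    if theta_c <= 0:
        raise ValueError("theta_c must be positive")
    return r0 / (1.0 + tau / theta_c)


def reconstruct_anisotropy_map(
    r0_map: np.ndarray,
    tau_map: np.ndarray,
    theta_map: np.ndarray,
    scale: float = 1.0,
) -> np.ndarray:
    """Pixel-wise Perrin evaluation of co-registered r0, tau and theta_c maps.

    ``scale`` is a single global instrumental factor relating the
    time-resolved (confocal) reconstruction to the wide-field steady-state
    measurement; estimate it with :func:`estimate_instrumental_scale`.
    """
    r0 = np.asarray(r0_map, dtype=float)
    tau = np.asarray(tau_map, dtype=float)
    theta = np.asarray(theta_map, dtype=float)
    if not (r0.shape == tau.shape == theta.shape):
        raise ValueError("r0, tau and theta maps must be co-registered (same shape)")
    return scale * r0 / (1.0 + tau / theta)


def estimate_instrumental_scale(
    reconstructed: np.ndarray, measured: np.ndarray
) -> float:
    """Least-squares global factor k minimizing |k*reconstructed - measured|."""
    x = np.asarray(reconstructed, dtype=float).ravel()
    y = np.asarray(measured, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    denom = float(np.dot(x[ok], x[ok]))
    if denom == 0:
        raise ValueError("reconstructed map is identically zero")
    return float(np.dot(x[ok], y[ok]) / denom)


def strickler_berg_scale(tau_ref: float, n_ref: float, n_new: float) -> float:
    """Rescale a lifetime to a new refractive index: tau ~ 1/n^2."""
    if n_ref < 1 or n_new < 1:
        raise ValueError("refractive indices must be >= 1")
    return tau_ref * (n_ref / n_new) ** 2


def phasor_transform(trace: DecayTrace, omega: float | None = None) -> PhasorPoint:
    """Project an intensity decay onto first-harmonic phasor coordinates.

    g = sum I(t) cos(wt) / sum I(t), s = sum I(t) sin(wt) / sum I(t), with
    discrete sums over the trace bins.  ``omega`` defaults to 2*pi/T where T
    is the trace window (first-harmonic convention).  Single-exponential
    decays land on the universal semicircle (g - 1/2)^2 + s^2 = 1/4.
    """
    if trace.kind != "intensity":
        raise ValueError("phasor_transform requires an intensity trace")
    total = trace.counts.sum()
    if total <= 0:
        raise ValueError("zero total intensity: phasor undefined")
    if omega is None:
        omega = 2.0 * np.pi / (trace.t[-1] - trace.t[0])
    t0 = trace.t - trace.t[0]
    g = float(np.sum(trace.counts * np.cos(omega * t0)) / total)
    s = float(np.sum(trace.counts * np.sin(omega * t0)) / total)
    return PhasorPoint(gcoord=g, scoord=s, omega=float(omega))


def phasor_of_lifetime(tau: float, omega: float) -> PhasorPoint:
    """Closed-form semicircle point of a mono-exponential lifetime."""
    wt = omega * tau
    return PhasorPoint(
        gcoord=1.0 / (1.0 + wt**2), scoord=wt / (1.0 + wt**2), omega=omega
    )


def calibrate_crowder(
    concentrations: np.ndarray, r_values: np.ndarray, crowder: str = ""
) -> CrowderCalibration:
    """OLS calibration of anisotropy against crowder concentration.

    Fits r = c/m + alpha_r; the reported ``m`` converts anisotropy to
    concentration units and ``alpha_r`` is the zero-crowder anisotropy.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(r_values, dtype=float)
    if c.size != r.size or c.size < 3:
        raise ValueError("need >= 3 paired (concentration, r) points")
    if np.ptp(c) == 0:
        raise ValueError("degenerate abscissa: all concentrations identical")
    res = stats.linregress(c, r)
    if res.slope == 0:
        raise ValueError("zero slope: anisotropy insensitive to this crowder")
    return CrowderCalibration(
        m=1.0 / res.slope,
        alpha_r=float(res.intercept),
        crowder=crowder,
        r_squared=float(res.rvalue**2),
    )
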
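"""Fluorescence correlation spectroscopy: model, fitting, concentrations.

The normalized intensity autocorrelation of molecules diffusing through a
3D Gaussian confocal volume is

    G(tau) = 1 + (1/N) * T(tau) * [1 + (tau/tauD)^a]^-1
                 * [1 + (1/S^2) * (tau/tauD)^a]^-1/2

with N the mean number of molecules in focus, tauD the diffusion time,
a the anomaly exponent (1 for free diffusion), S = wz/wxy the axial/lateral
aspect ratio, and T(tau) = (1 - F + F exp(-tau/tauf)) / (1 - F) the triplet
term with fraction F and triplet time tauf.  The amplitude alone gives the
number density, N = 1/(G0 - 1), independent of any fitting choice; with the
effective confocal volume this converts to a molar concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "AVOGADRO",
    "CorrelationCurve",
    "FcsFit",
    "ConfocalGeometry",
    "fcs_model",
    "fit_fcs",
    "number_density_from_g0",
    "theoretical_beam_radii",
    "effective_volume",
    "concentration_from_counts",
    "diffusion_coefficient",
]

AVOGADRO = 6.02214076e23


@dataclass
class CorrelationCurve:
    """Lag-domain autocorrelation: strictly increasing positive lags, G -> 1."""

    lag: np.ndarray  # s
    gvalue: np.ndarray  # dimensionless

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.gvalue = np.asarray(self.gvalue, dtype=float)
        if self.lag.shape != self.gvalue.shape:
            raise ValueError("lag and gvalue must have the same length")
        if np.any(self.lag <= 0) or np.any(np.diff(self.lag) <= 0):
            raise ValueError("lags must be positive and strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrelationCurve":
        df = pd.read_csv(path)
        return cls(lag=df.iloc[:, 0].to_numpy(), gvalue=df.iloc[:, 1].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"lag_s": self.lag, "g": self.gvalue}).to_csv(path, index=False)


@dataclass
class FcsFit:
    """Fitted FCS parameters for the 3D anomalous-diffusion model."""

    nmol: float  # mean molecules in focus
    tau_d: float  # s
    triplet_f: float = 0.0  # triplet fraction, [0, 1)
    tau_f: float = 1e-6  # s
    anomaly: float = 1.0  # alpha; fixed to 1 unless explicitly freed
    structure_s: float = 3.633  # wz / wxy
    g0: float = np.nan  # fitted zero-lag amplitude

    def __post_init__(self) -> None:
        if self.nmol <= 0:
            raise ValueError("nmol must be positive")
        if not (0 <= self.triplet_f < 1):
            raise ValueError("triplet fraction must be in [0, 1)")
        if self.structure_s <= 1:
            raise ValueError("structure parameter S must exceed 1")
        if np.isnan(self.g0):
            self.g0 = 1.0 + 1.0 / self.nmol


@dataclass
class ConfocalGeometry:
    """1/e^2 half-axes of the confocal ellipsoid and the optics behind them."""

    omega_xy: float  # um, lateral radius
    omega_z: float  # um, axial radius
    wavelength: float = np.nan  # um
    num_aperture: float = np.nan
    ref_index: float = np.nan

    def __post_init__(self) -> None:
        if not (self.omega_z > self.omega_xy > 0):
            raise ValueError("require omega_z > omega_xy > 0")

    @property
    def structure_s(self) -> float:
        return self.omega_z / self.omega_xy

    @property
    def v_eff(self) -> float:
        return effective_volume(self)

    @classmethod
    def from_optics(
        cls, wavelength: float, num_aperture: float, ref_index: float
    ) -> "ConfocalGeometry":
        wxy, wz = theoretical_beam_radii(wavelength, num_aperture, ref_index)
        return cls(
            omega_xy=wxy,
            omega_z=wz,
            wavelength=wavelength,
            num_aperture=num_aperture,
            ref_index=ref_index,
        )


def fcs_model(
    lag: np.ndarray,
    nmol: float,
    tau_d: float,
    triplet_f: float = 0.0,
    tau_f: float = 1e-6,
    anomaly: float = 1.0,
    structure_s: float = 3.633,
) -> np.ndarray:
    """Evaluate the 3D anomalous-diffusion autocorrelation model."""
    tau = np.asarray(lag, dtype=float)
    x = (tau / tau_d) ** anomaly
    if triplet_f > 0:
        triplet = (1.0 - triplet_f + triplet_f * np.exp(-tau / tau_f)) / (
            1.0 - triplet_f
        )
    else:
        triplet = 1.0
    diffusion = 1.0 / (1.0 + x) / np.sqrt(1.0 + x / structure_s**2)
    return 1.0 + (1.0 / nmol) * triplet * diffusion


def fit_fcs(
    curve: CorrelationCurve,
    structure_s: float = 3.633,
    fix_anomaly: bool = True,
    fix_triplet_zero: bool = True,
) -> FcsFit:
    """Nonlinear least-squares fit of (N, tauD) to an autocorrelation curve.

    The anomaly exponent is fixed at 1 and the triplet term omitted by
    default (appropriate for EGFP in buffer); pass ``fix_anomaly=False`` or
    ``fix_triplet_zero=False`` to free them.  S is fixed from the confocal
    geometry throughout.
    """
    lag, g = curve.lag, curve.gvalue
    if lag.size < 10:
        raise ValueError("need >= 10 lag points to fit")
    amp0 = float(g[0] - 1.0)
    if amp0 <= 1e-6:
        raise RuntimeError("no correlation amplitude: curve is flat at 1")
    n0 = 1.0 / amp0
    # Seed tauD where the decay reaches half its amplitude.
    half = 1.0 + amp0 / 2.0
    below = np.nonzero(g <= half)[0]
    tau0 = float(lag[below[0]]) if below.size else float(np.sqrt(lag[0] * lag[-1]))

    names = ["nmol", "tau_d"]
    p0 = [n0, tau0]
    lower = [1e-6, lag[0] / 100]
    upper = [np.inf, lag[-1] * 100]
    if not fix_triplet_zero:
        names += ["triplet_f", "tau_f"]
        p0 += [0.1, lag[0] * 3]
        lower += [0.0, lag[0] / 100]
        upper += [0.999, tau0]
    if not fix_anomaly:
        names += ["anomaly"]
        p0 += [1.0]
        lower += [0.1]
        upper += [2.0]

    def model(tau, *params):
        kw = dict(zip(names, params))
        return fcs_model(tau, structure_s=structure_s, **kw)

    try:
        popt, _ = optimize.curve_fit(
            model, lag, g, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"FCS fit did not converge (seed N={n0:.3g}, tauD={tau0:.3g} s): {exc}"
        ) from exc
    kw = dict(zip(names, map(float, popt)))
    return FcsFit(structure_s=structure_s, **kw)


def number_density_from_g0(g0: float) -> float:
    """Mean molecules in the confocal volume from the amplitude: N = 1/(G0-1)."""
    if g0 <= 1:
        raise ValueError(f"G0={g0} must exceed 1")
    return 1.0 / (g0 - 1.0)


def theoretical_beam_radii(
    wavelength: float, num_aperture: float, ref_index: float
) -> tuple[float, float]:
    """Diffraction-limited confocal radii (same length unit as wavelength).

    Lateral: wxy = 0.61 * lambda / NA (Rayleigh); axial:
    wz = 2 * n * lambda / NA^2.  For 488 nm, NA 1.2, n 1.33 these give
    248 nm and 901 nm.
    """
    if num_aperture <= 0 or wavelength <= 0:
        raise ValueError("wavelength and NA must be positive")
    if num_aperture >= ref_index:
        raise ValueError("NA must be below the immersion refractive index")
    omega_xy = 0.61 * wavelength / num_aperture
    omega_z = 2.0 * ref_index * wavelength / num_aperture**2
    return omega_xy, omega_z


def effective_volume(geometry: ConfocalGeometry) -> float:
    """Effective ellipsoidal confocal volume in femtoliters.

    Radii are 1/e^2 half-axes, so Veff = pi^(3/2) * (wxy/sqrt2)^2 * (wz/sqrt2)
    = (pi/2)^(3/2) * wxy^2 * wz.  With wxy = 0.248 um, wz = 0.901 um this is
    0.109 fL (1 um^3 = 1 fL).
    """
    return (np.pi / 2.0) ** 1.5 * geometry.omega_xy**2 * geometry.omega_z


def concentration_from_counts(nmol: float, v_eff_fl: float) -> float:
    """Molar concentration C = N / (N_Avogadro * V), V in fL; returns mol/L."""
    if nmol <= 0 or v_eff_fl <= 0:
        raise ValueError("nmol and v_eff must be positive")
    return nmol / (AVOGADRO * v_eff_fl * 1e-15)


def diffusion_coefficient(omega_xy: float, tau_d: float) -> float:
    """D = wxy^2 / (4 * tauD); um^2/s for wxy in um and tauD in s."""
    if tau_d <= 0:
        raise ValueError("tau_d must be positive")
    return omega_xy**2 / (4.0 * tau_d)
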
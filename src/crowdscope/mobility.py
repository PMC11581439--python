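"""Translational mobility from FRAP recovery curves and particle tracks.

FRAP: after bleaching a uniform circular spot of radius w, diffusive
recovery follows the closed form

    f(t) = exp(-2 tauD / t) * [I0(2 tauD / t) + I1(2 tauD / t)]

(I0, I1 modified Bessel functions), with D = w^2 / (4 tauD).  An immobile
population caps the plateau below full recovery; the mobile fraction is
(Finf - F0) / (1 - F0) with prebleach intensity normalized to 1.

Tracking: the time-averaged mean squared displacement MSD(tau) =
<(x(t+tau)-x(t))^2 + (y(t+tau)-y(t))^2> grows as 4 D tau for free 2D
diffusion; its log-log slope separates sub- (<1), free (=1) and
super-diffusive (>1, ballistic = 2) motion, and MSD(tau)/(4 tau) is the
apparent diffusion coefficient at a chosen timescale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "RecoveryTrace",
    "FrapFit",
    "Trajectory",
    "MsdCurve",
    "disk_recovery",
    "fit_frap",
    "compute_msd",
    "ensemble_msd",
    "msd_loglog_slope",
    "diffusion_at_lag",
    "read_trajectories",
]


@dataclass
class RecoveryTrace:
    """FRAP intensity time series, normalized so the prebleach mean is 1.

    ``t`` is measured from the bleach event (t=0 excluded: the closed-form
    recovery starts at 0+).
    """

    t: np.ndarray  # s
    intensity: np.ndarray
    spot_radius: float  # um

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t.shape != self.intensity.shape:
            raise ValueError("t and intensity must have the same length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if self.spot_radius <= 0:
            raise ValueError("spot radius must be positive")

    @classmethod
    def from_csv(cls, path: str | Path, spot_radius: float) -> "RecoveryTrace":
        df = pd.read_csv(path)
        return cls(
            t=df.iloc[:, 0].to_numpy(),
            intensity=df.iloc[:, 1].to_numpy(),
            spot_radius=spot_radius,
        )


@dataclass
class FrapFit:
    dcoeff: float  # um^2/s
    mobile_fraction: float
    f0: float  # post-bleach depth
    f_inf: float  # fitted plateau
    tau_d: float  # s, characteristic diffusion time
    valid: bool = True  # False when Finf < F0 (no recovery model applies)

    def __post_init__(self) -> None:
        if self.valid and self.dcoeff <= 0:
            raise ValueError("diffusion coefficient must be positive")
        if self.valid and not (-1e-9 <= self.mobile_fraction <= 1 + 1e-9):
            raise ValueError("mobile fraction must lie in [0, 1]")


@dataclass
class Trajectory:
    """Uniformly sampled 2D positions of one particle."""

    t: np.ndarray  # s
    x: np.ndarray  # um
    y: np.ndarray  # um
    particle_id: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have the same length")
        if self.t.size < 2:
            raise ValueError("a trajectory needs at least 2 points")
        dt = np.diff(self.t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("frame interval must be uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class MsdCurve:
    lag: np.ndarray  # s
    msd: np.ndarray  # um^2
    n_pairs: np.ndarray  # displacement pairs averaged at each lag

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)
        if np.any(self.msd < 0):
            raise ValueError("MSD cannot be negative")


def disk_recovery(t: np.ndarray, tau_d: float) -> np.ndarray:
    """Normalized uniform-disk recovery f(t) = e^-x (I0(x) + I1(x)), x = 2 tauD/t.

    Uses exponentially scaled Bessel functions, stable for all x; f rises
    from 0 at t=0+ to 1 as t -> inf.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = 2.0 * tau_d / t[pos]
    out[pos] = special.i0e(x) + special.i1e(x)
    return out


def fit_frap(trace: RecoveryTrace) -> FrapFit:
    """Fit a recovery trace to F(t) = F0 + (Finf - F0) * f_disk(t; tauD).

    Returns D = w^2 / (4 tauD) and the mobile fraction
    (Finf - F0) / (1 - F0).  A plateau below the bleach depth has no
    diffusive interpretation and is returned flagged invalid.
    """
    t, y = trace.t, trace.intensity
    if y[0] >= 1:
        raise ValueError("post-bleach intensity must start below the prebleach level")
    f0_0 = float(y[0])
    finf_0 = float(y[-1])
    # Seed tauD at the half-recovery time.
    half = f0_0 + 0.5 * (finf_0 - f0_0)
    crossed = np.nonzero(y >= half)[0] if finf_0 > f0_0 else np.empty(0, dtype=int)
    tau0 = float(t[crossed[0]]) if crossed.size else float(np.median(t))
    tau0 = max(tau0, float(t[0]))

    def model(tt, f0, finf, tau_d):
        return f0 + (finf - f0) * disk_recovery(tt, tau_d)

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[f0_0, finf_0, tau0],
            bounds=([-np.inf, -np.inf, t[0] / 1e3], [1.0, 1.5, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"FRAP fit did not converge: {exc}") from exc
    f0, finf, tau_d = map(float, popt)
    if finf < f0:
        return FrapFit(
            dcoeff=np.nan, mobile_fraction=np.nan, f0=f0, f_inf=finf,
            tau_d=tau_d, valid=False,
        )
    dcoeff = trace.spot_radius**2 / (4.0 * tau_d)
    mobile = (finf - f0) / (1.0 - f0) if f0 < 1 else np.nan
    mobile = float(np.clip(mobile, 0.0, 1.0))
    return FrapFit(
        dcoeff=dcoeff, mobile_fraction=mobile, f0=f0, f_inf=finf, tau_d=tau_d
    )


def compute_msd(
    traj: Trajectory, max_lag_fraction: float = 0.25, max_lag: int | None = None
) -> MsdCurve:
    """Time-averaged MSD of one track over all ordered pairs at each lag.

    Lags run from one frame up to ``max_lag_fraction`` of the track length;
    long lags average few pairs and are statistically unreliable, hence the
    default cap at a quarter of the track.  ``max_lag`` (frames) overrides
    the fraction, useful when only short timescales are analyzed.
    """
    n = traj.t.size
    if max_lag is None:
        max_lag = max(1, int(np.floor(max_lag_fraction * (n - 1))))
    max_lag = min(max_lag, n - 1)
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(lags.size)
    n_pairs = np.empty(lags.size, dtype=int)
    for i, k in enumerate(lags):
        dx = traj.x[k:] - traj.x[:-k]
        dy = traj.y[k:] - traj.y[:-k]
        msd[i] = np.mean(dx**2 + dy**2)
        n_pairs[i] = dx.size
    return MsdCurve(lag=lags * traj.dt, msd=msd, n_pairs=n_pairs)


def ensemble_msd(
    trajectories: list[Trajectory],
    max_lag_fraction: float = 0.25,
    max_lag: int | None = None,
) -> MsdCurve:
    """Mean of per-track time-averaged MSDs (tracks first, then ensemble).

    Tracks must share the frame interval; the ensemble curve spans the lags
    common to all tracks.
    """
    if not trajectories:
        raise ValueError("no trajectories supplied")
    curves = [compute_msd(tr, max_lag_fraction, max_lag=max_lag) for tr in trajectories]
    n_common = min(c.lag.size for c in curves)
    lag = curves[0].lag[:n_common]
    for c in curves[1:]:
        if not np.allclose(c.lag[:n_common], lag):
            raise ValueError("trajectories must share the frame interval")
    msd = np.mean([c.msd[:n_common] for c in curves], axis=0)
    n_pairs = np.sum([c.n_pairs[:n_common] for c in curves], axis=0)
    return MsdCurve(lag=lag, msd=msd, n_pairs=n_pairs)


def msd_loglog_slope(curve: MsdCurve, lag_window: tuple[float, float] = (0.1, 1.0)) -> float:
    """Least-squares slope of log MSD vs log lag inside a lag window (s).

    Nonpositive MSD values (possible for a perfectly stationary particle)
    are excluded from the fit with a warning.
    """
    sel = (curve.lag >= lag_window[0]) & (curve.lag <= lag_window[1])
    lag, msd = curve.lag[sel], curve.msd[sel]
    pos = msd > 0
    if pos.sum() < lag.size:
        import warnings

        warnings.warn("nonpositive MSD values excluded from log-log fit")
    lag, msd = lag[pos], msd[pos]
    if lag.size < 3:
        raise ValueError("need >= 3 positive-MSD lags inside the window")
    slope, _ = np.polyfit(np.log(lag), np.log(msd), 1)
    return float(slope)


def diffusion_at_lag(curve: MsdCurve, lag: float) -> float:
    """Apparent diffusion coefficient D_app = MSD(lag) / (4 lag).

    MSD is linearly interpolated between the two neighboring measured lags.
    """
    if not (curve.lag[0] <= lag <= curve.lag[-1]):
        raise ValueError(
            f"lag {lag} s outside the measured range "
            f"[{curve.lag[0]}, {curve.lag[-1]}] s"
        )
    msd = float(np.interp(lag, curve.lag, curve.msd))
    return msd / (4.0 * lag)


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Read tracks from CSV with columns particle_id, frame, t_s, x_um, y_um."""
    df = pd.read_csv(path)
    out = []
    for pid, grp in df.groupby("particle_id"):
        grp = grp.sort_values("t_s")
        out.append(
            Trajectory(
                t=grp["t_s"].to_numpy(),
                x=grp["x_um"].to_numpy(),
                y=grp["y_um"].to_numpy(),
                particle_id=int(pid),
            )
        )
    return out
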
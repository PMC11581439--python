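"""Osmotic volume-crowding models: Boyle-van't Hoff, dilution law, RVI.

At osmotic equilibrium a cell behaves as an imperfect osmometer: its volume
is linear in reciprocal osmotic pressure (Boyle-van't Hoff), and the
extrapolation to infinite pressure gives the osmotically inactive volume.
Normalizing both axes to the isotonic point puts the line through (1, 1),
so a one-parameter fit suffices and the y-intercept is the limiting
(inactive) volume fraction.  The same construction applied to the
reciprocal of the crowding readout (1/MMC scales with solvent volume)
yields the limiting anisotropy.

If the number of crowders is conserved, concentration times solvent volume
is constant, so anisotropy follows the dilution law

    r(V) = (r_iso - alpha) * V_iso / V + alpha

where alpha is the anisotropy at zero crowder.  Measured deviations from
this curve flag processes beyond passive dilution (crowder production or
excluded-volume reorganization).  RVI (regulatory volume increase) is
quantified as the percentage volume regained between the post-shock nadir
and the end of the recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OsmoticSeries",
    "BvhFit",
    "DilutionModel",
    "normalize_bvh",
    "fit_constrained_line",
    "fit_bvh",
    "dilution_alpha",
    "expected_dilution_curve",
    "dilution_deviation",
    "rvi_index",
]

logger = logging.getLogger(__name__)

ISO_OSMOLARITY_DEFAULT = 300.0  # mOsm, typical culture-media total


@dataclass
class OsmoticSeries:
    """Per-condition (excess osmolarity, volume, modal r) measurements.

    ``osmolarity_excess`` is in mM above isotonic (0 = isotonic, which must
    be present); ``iso_osmolarity`` is the total isotonic osmolarity used to
    form pressure ratios.
    """

    osmolarity_excess: np.ndarray  # mM
    volume: np.ndarray  # um^3
    modal_r: np.ndarray
    iso_osmolarity: float = ISO_OSMOLARITY_DEFAULT

    def __post_init__(self) -> None:
        self.osmolarity_excess = np.asarray(self.osmolarity_excess, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        self.modal_r = np.asarray(self.modal_r, dtype=float)
        if not (
            self.osmolarity_excess.shape == self.volume.shape == self.modal_r.shape
        ):
            raise ValueError("series fields must have equal length")
        if not np.any(self.osmolarity_excess == 0):
            raise ValueError("series must contain the isotonic (excess=0) entry")
        if self.iso_osmolarity <= 0:
            raise ValueError("isotonic osmolarity must be positive")

    @property
    def iso_index(self) -> int:
        return int(np.nonzero(self.osmolarity_excess == 0)[0][0])


@dataclass
class BvhFit:
    """Boyle-van't Hoff line through (1,1): y = 1 + slope * (x - 1)."""

    slope: float
    v_inactive_frac: float  # y-intercept of the volume track
    v_inactive: float  # um^3
    r_limit: float  # limiting anisotropy from the crowding track
    rms: float

    def __post_init__(self) -> None:
        if not (0 < self.v_inactive_frac < 1):
            raise ValueError(
                f"osmotically inactive fraction {self.v_inactive_frac} outside (0, 1)"
            )


@dataclass
class DilutionModel:
    """Concentration-dilution law anchored at the isotonic point."""

    alpha_r: float  # anisotropy at zero crowder
    r_iso: float
    v_iso: float  # um^3

    def __post_init__(self) -> None:
        if self.alpha_r >= self.r_iso:
            raise ValueError("alpha_r must lie below the isotonic anisotropy")
        if self.v_iso <= 0:
            raise ValueError("isotonic volume must be positive")


def normalize_bvh(series: OsmoticSeries) -> dict[str, np.ndarray]:
    """Normalize a series to Boyle-van't Hoff coordinates.

    x = Pi_iso / Pi = iso / (iso + excess); y_volume = V / V_iso;
    y_crowding = r_iso / r (reciprocal crowding scales like solvent volume).
    The isotonic point maps to (1, 1) on both tracks.
    """
    i = series.iso_index
    total = series.iso_osmolarity + series.osmolarity_excess
    if np.any(total <= 0):
        raise ValueError("total osmolarity must be positive everywhere")
    x = series.iso_osmolarity / total
    y_volume = series.volume / series.volume[i]
    y_crowding = series.modal_r[i] / series.modal_r
    return {"x": x, "y_volume": y_volume, "y_crowding": y_crowding}


def fit_constrained_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least squares of y = 1 + b (x - 1); returns (b, rms residual).

    The (1, 1) anchor is the isotonic condition; only points away from it
    constrain the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u = x - 1.0
    v = y - 1.0
    denom = float(np.sum(u * u))
    if denom == 0:
        raise ValueError("degenerate abscissa: all points at the isotonic x")
    b = float(np.sum(u * v) / denom)
    rms = float(np.sqrt(np.mean((v - b * u) ** 2)))
    return b, rms


def fit_bvh(series: OsmoticSeries) -> BvhFit:
    """Fit both normalized tracks to lines through (1,1).

    The volume-track y-intercept (x -> 0, infinite pressure) is the
    osmotically inactive volume fraction; the crowding-track intercept is
    the limiting reciprocal anisotropy, converted back to the limiting
    anisotropy with the isotonic value.
    """
    pts = normalize_bvh(series)
    non_iso = np.sum(series.osmolarity_excess != 0)
    if non_iso < 2:
        raise ValueError("need >= 2 non-isotonic conditions to fit")
    b_vol, rms_vol = fit_constrained_line(pts["x"], pts["y_volume"])
    b_crowd, _ = fit_constrained_line(pts["x"], pts["y_crowding"])
    v_inactive_frac = 1.0 - b_vol
    recip_r_limit = 1.0 - b_crowd  # r_iso / r at infinite pressure
    if recip_r_limit <= 0:
        raise ValueError("crowding track extrapolates to a nonpositive intercept")
    i = series.iso_index
    return BvhFit(
        slope=b_vol,
        v_inactive_frac=v_inactive_frac,
        v_inactive=v_inactive_frac * series.volume[i],
        r_limit=series.modal_r[i] / recip_r_limit,
        rms=rms_vol,
    )


def dilution_alpha(r1: float, v1: float, r2: float, v2: float) -> float:
    """Zero-crowder anisotropy from two conditions on one dilution curve.

    Conservation (r1 - alpha) V1 = (r2 - alpha) V2 solves to
    alpha = (r2 V2 - r1 V1) / (V2 - V1); symmetric in the two points.
    """
    if v1 == v2:
        raise ValueError("dilution alpha is undefined for equal volumes")
    return (r2 * v2 - r1 * v1) / (v2 - v1)


def expected_dilution_curve(model: DilutionModel, v: np.ndarray) -> np.ndarray:
    """Anisotropy expected from pure dilution: r(V) = (r_iso - a) V_iso/V + a."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    return (model.r_iso - model.alpha_r) * (model.v_iso / v) + model.alpha_r


def dilution_deviation(series: OsmoticSeries, model: DilutionModel) -> dict:
    """Signed per-condition deviation of measured r from the dilution law.

    Positive deviations mean the cell is more crowded than passive water
    loss explains.  Returns per-point deviations plus mean and max summary,
    in anisotropy units.
    """
    expected = expected_dilution_curve(model, series.volume)
    dev = series.modal_r - expected
    return {
        "deviation": dev,
        "expected_r": expected,
        "mean": float(dev.mean()),
        "max": float(dev.max()),
    }


def rvi_index(
    t: np.ndarray, volume: np.ndarray, t_shrink: float, t_final: float
) -> float:
    """Regulatory volume increase as a percentage.

    100 * (V(t_final) - V(t_shrink)) / V(t_shrink), with t_shrink the
    post-shock nadir time (10 min in the standard protocol) and t_final the
    last recorded time.  Both time points must be present in ``t``.
    """
    t = np.asarray(t, dtype=float)
    volume = np.asarray(volume, dtype=float)
    out = []
    for tp in (t_shrink, t_final):
        hits = np.nonzero(np.isclose(t, tp))[0]
        if hits.size == 0:
            raise ValueError(f"time point {tp} s not present in the series")
        out.append(volume[hits[0]])
    v_shrink, v_final = out
    return 100.0 * (v_final - v_shrink) / v_shrink
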
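"""Synthetic data with known ground truth for every pipeline input modality.

Each generator inverts the forward model of its analysis counterpart, so a
zero-noise dataset round-trips through the pipeline to the imposed
parameters within numerical tolerance.  All randomness flows through one
seeded generator per call; the same seed reproduces the dataset exactly.

Noise defaults follow the physics of each modality: Poisson counting noise
for photon-counting traces and images, 1% multiplicative Gaussian on the
correlation amplitude (FCS) or normalized intensity (FRAP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .fcs import CorrelationCurve, fcs_model
from .mobility import RecoveryTrace, Trajectory, disk_recovery
from .morphology import VolumeStack
from .osmotics import OsmoticSeries
from .photophysics import DecayTrace
from .polarimetry_io import PolarizedFramePair, RawDualViewFrame, RoiMask

__all__ = [
    "GroundTruth",
    "synth_polarized_scene",
    "synth_bead_image",
    "synth_bead_pair",
    "synth_cell_phantom",
    "synth_traces",
    "synth_trajectories",
    "synth_osmotic_series",
]


@dataclass
class GroundTruth:
    """Record of the parameters imposed on a generated dataset."""

    params: dict[str, Any]
    seed: int | None = None

    def __getitem__(self, key: str) -> Any:
        return self.params[key]


# ---------------------------------------------------------------------------
# polarization scenes


def synth_polarized_scene(
    r_field: np.ndarray,
    intensity_field: np.ndarray,
    g_field: np.ndarray | float = 1.0,
    background: float = 0.0,
    shift: tuple[float, float] = (0.0, 0.0),
    noise: str | None = None,
    seed: int | None = None,
    bit_depth: int = 16,
    left_is_perpendicular: bool = True,
) -> tuple[RawDualViewFrame, GroundTruth]:
    """Build a dual-view camera frame from an imposed anisotropy field.

    Inverts the anisotropy relation: with total intensity I and G-factor g,

        Ipar  = I (1 + 2 r) / 3 + background
        Iperp = I (1 - r) / (3 g) + background

    The perpendicular half is displaced by ``shift`` = (dx, dy) pixels
    (cubic-spline resampling) before assembly, emulating the optical
    misalignment that registration must undo.  ``noise='poisson'`` applies
    counting noise; values are clipped to the camera range and the clip
    count reported in the ground truth.
    """
    r = np.asarray(r_field, dtype=float)
    if np.any(r < -0.5) or np.any(r > 1.0):
        raise ValueError("anisotropy field must lie within [-0.5, 1]")
    intensity = np.asarray(intensity_field, dtype=float)
    g = np.broadcast_to(np.asarray(g_field, dtype=float), r.shape)
    ipar = intensity * (1.0 + 2.0 * r) / 3.0 + background
    iperp = intensity * (1.0 - r) / (3.0 * g) + background
    dx, dy = shift
    if dx or dy:
        # A feature at (x, y) in the parallel half appears at (x+dx, y+dy)
        # in the recorded perpendicular half.
        iperp = ndimage.shift(iperp, shift=(dy, dx), order=3, mode="nearest")
    rng = np.random.default_rng(seed)
    if noise == "poisson":
        ipar = rng.poisson(np.clip(ipar, 0, None)).astype(float)
        iperp = rng.poisson(np.clip(iperp, 0, None)).astype(float)
    elif noise is not None:
        raise ValueError(f"unknown noise model {noise!r}")
    top = 2**bit_depth - 1
    n_clipped = int(np.sum(ipar > top) + np.sum(iperp > top))
    ipar = np.clip(ipar, 0, top)
    iperp = np.clip(iperp, 0, top)
    if left_is_perpendicular:
        pixels = np.hstack([iperp, ipar])
    else:
        pixels = np.hstack([ipar, iperp])
    frame = RawDualViewFrame(pixels=pixels, bit_depth=bit_depth)
    truth = GroundTruth(
        params={
            "r_field": r,
            "intensity_field": intensity,
            "g_field": np.array(g),
            "background": background,
            "shift": shift,
            "noise": noise,
            "n_clipped": n_clipped,
        },
        seed=seed,
    )
    return frame, truth


def synth_bead_image(
    shape: tuple[int, int] = (256, 256),
    positions: np.ndarray | None = None,
    n_beads: int = 20,
    sigma: float = 1.6,
    amplitude: float = 10000.0,
    background: float = 100.0,
    margin: float = 12.0,
    min_separation: float = 15.0,
    noise: str | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Gaussian-spot fiducial image with known sub-pixel bead positions."""
    rng = np.random.default_rng(seed)
    h, w = shape
    if positions is None:
        pts: list[tuple[float, float]] = []
        attempts = 0
        while len(pts) < n_beads and attempts < 10000:
            attempts += 1
            cand = (
                rng.uniform(margin, w - margin),
                rng.uniform(margin, h - margin),
            )
            if all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_separation for p in pts):
                pts.append(cand)
        positions = np.asarray(pts)
    else:
        positions = np.asarray(positions, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full(shape, background, dtype=float)
    for x0, y0 in positions:
        img += amplitude * np.exp(
            -((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2)
        )
    if noise == "poisson":
        img = rng.poisson(img).astype(float)
    truth = GroundTruth(
        params={"positions": positions, "sigma": sigma, "amplitude": amplitude},
        seed=seed,
    )
    return img, truth


def synth_bead_pair(
    shape: tuple[int, int] = (256, 256),
    n_beads: int = 20,
    shift: tuple[float, float] = (3.4, -1.7),
    spurious_fraction: float = 0.0,
    sigma: float = 1.6,
    amplitude: float = 10000.0,
    noise: str | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Fixed/moving fiducial image pair related by a known sub-pixel shift.

    The moving image renders the same beads displaced by ``shift``;
    ``spurious_fraction`` adds unmatched extra beads to each image to
    exercise the robust consensus matching.
    """
    rng = np.random.default_rng(seed)
    margin = 12.0 + max(abs(shift[0]), abs(shift[1]))
    fixed_img, truth = synth_bead_image(
        shape=shape, n_beads=n_beads, sigma=sigma, amplitude=amplitude,
        margin=margin, noise=None, seed=rng.integers(2**31),
    )
    positions = truth["positions"]
    moving_pos = positions + np.asarray(shift)
    n_spurious = int(round(spurious_fraction * n_beads))
    h, w = shape

    def with_spurious(base: np.ndarray) -> np.ndarray:
        if n_spurious == 0:
            return base
        extra = np.column_stack(
            [rng.uniform(margin, w - margin, n_spurious),
             rng.uniform(margin, h - margin, n_spurious)]
        )
        return np.vstack([base, extra])

    fixed_img, _ = synth_bead_image(
        shape=shape, positions=with_spurious(positions), sigma=sigma,
        amplitude=amplitude, noise=noise, seed=rng.integers(2**31),
    )
    moving_img, _ = synth_bead_image(
        shape=shape, positions=with_spurious(moving_pos), sigma=sigma,
        amplitude=amplitude, noise=noise, seed=rng.integers(2**31),
    )
    truth = GroundTruth(
        params={
            "positions": positions,
            "shift": shift,
            "n_spurious": n_spurious,
        },
        seed=seed,
    )
    return fixed_img, moving_img, truth


# ---------------------------------------------------------------------------
# cell phantoms


def synth_cell_phantom(
    shape: str = "spread-cell",
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.4),
    radius: float = 5.0,
    semiaxes: tuple[float, float, float] = (10.0, 8.0, 3.0),
    nucleus_radius: float | None = None,
    grid_shape: tuple[int, int, int] | None = None,
    intensity: float = 1000.0,
    threshold: float = 500.0,
    seed: int | None = None,
) -> tuple[VolumeStack, RoiMask, GroundTruth]:
    """Digitized cell phantom with analytically known volume and height.

    Shapes: ``ellipsoid`` (half-axes ``semiaxes`` um, V = 4 pi a b c / 3),
    ``hemisphere`` (radius um, V = 2 pi r^3 / 3, height sqrt(R^2 - rho^2)),
    ``sphere`` (V = 4 pi r^3 / 3), and ``spread-cell`` — a tall perinuclear
    body with a thin (0.5 um) lamellar skirt and a spherical nucleus,
    mimicking adherent-fibroblast topology.
    Voxel centers are tested against the analytic surface, so digitization
    error shrinks with voxel size.
    """
    dx, dy, dz = voxel_size
    truth_params: dict[str, Any] = {"shape": shape, "voxel_size": voxel_size}
    if shape == "ellipsoid":
        a, b, c = semiaxes
        extent = (2.2 * a, 2.2 * b, 2.2 * c)
        truth_params["analytic_volume"] = 4.0 * np.pi * a * b * c / 3.0
    elif shape in ("hemisphere", "sphere"):
        extent = (2.2 * radius,) * 3
        vol_full = 4.0 * np.pi * radius**3 / 3.0
        truth_params["analytic_volume"] = (
            vol_full / 2.0 if shape == "hemisphere" else vol_full
        )
        truth_params["radius"] = radius
    elif shape == "spread-cell":
        extent = (4.4 * radius, 4.4 * radius, 2.4 * radius)
    else:
        raise ValueError(f"unknown phantom shape {shape!r}")
    if grid_shape is None:
        grid_shape = (
            int(np.ceil(extent[2] / dz)),
            int(np.ceil(extent[1] / dy)),
            int(np.ceil(extent[0] / dx)),
        )
    nz, ny, nx = grid_shape
    z = (np.arange(nz) + 0.5) * dz
    y = (np.arange(ny) + 0.5) * dy - ny * dy / 2.0
    x = (np.arange(nx) + 0.5) * dx - nx * dx / 2.0
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    nucleus3d = np.zeros(grid_shape, dtype=bool)
    if shape == "ellipsoid":
        a, b, c = semiaxes
        zc = nz * dz / 2.0
        inside = (xx / a) ** 2 + (yy / b) ** 2 + ((zz - zc) / c) ** 2 <= 1.0
    elif shape == "sphere":
        zc = nz * dz / 2.0
        inside = xx**2 + yy**2 + (zz - zc) ** 2 <= radius**2
    elif shape == "hemisphere":
        inside = (xx**2 + yy**2 + zz**2 <= radius**2)
    else:  # spread-cell
        rho = np.hypot(xx, yy)
        body_r, skirt_r, lamella_h = radius, 2.0 * radius, 0.5
        body = (rho <= body_r) & (zz <= np.sqrt(
            np.clip(body_r**2 - np.clip(rho, 0, body_r) ** 2, 0, None)
        ) + lamella_h)
        skirt = (rho <= skirt_r) & (zz <= lamella_h)
        inside = body | skirt
        nuc_r = nucleus_radius if nucleus_radius is not None else 0.6 * radius
        nucleus3d = xx**2 + yy**2 + (zz - nuc_r) ** 2 <= nuc_r**2
        truth_params.update({"body_radius": body_r, "skirt_radius": skirt_r,
                             "lamella_height": lamella_h, "nucleus_radius": nuc_r})
    voxels = np.where(inside, intensity, 0.0)
    stack = VolumeStack(voxels=voxels, voxel_size=voxel_size, threshold=threshold)
    cell2d = inside.any(axis=0).astype(np.int32)
    nucleus2d = nucleus3d.any(axis=0).astype(np.int32)
    roi = RoiMask(labels=cell2d, nucleus_labels=nucleus2d)
    truth_params["voxel_volume"] = float(inside.sum()) * dx * dy * dz
    return stack, roi, GroundTruth(params=truth_params, seed=seed)


# ---------------------------------------------------------------------------
# traces and curves


def synth_traces(
    modality: str,
    params: dict[str, Any] | None = None,
    noise: float | str | None = None,
    seed: int | None = None,
):
    """Forward-model a trace/curve for one modality with optional noise.

    modality and defaults (overridable through ``params``):

    - ``fcs``: N=35.714, tau_d=170e-6 s, S=3.633, log-spaced lags; the
      zero-noise amplitude is G0 = 1 + 1/N = 1.028.  ``noise`` (float) is
      the multiplicative Gaussian sigma applied to the correlation
      amplitude G - 1.
    - ``frap``: D=25 um^2/s, w=1 um, mobile_fraction=1, f0=0.3; ``noise``
      is multiplicative Gaussian on the normalized intensity.
    - ``anisotropy_decay``: r0=0.38, theta_c=16 ns, tau=2.6 ns; ``noise``
      = 'poisson' builds the polarized decay pair at ``total_counts``
      (default 1e4) per channel peak and recomputes r(t) from the noisy pair.
    - ``lifetime_decay``: tau=2.6 ns, amplitude=1e4, offset=0; ``noise`` =
      'poisson' applies counting noise.

    Returns (trace_or_curve, GroundTruth).
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if modality == "fcs":
        nmol = p.setdefault("nmol", 35.714)
        tau_d = p.setdefault("tau_d", 170e-6)
        s = p.setdefault("structure_s", 3.633)
        lag = p.setdefault("lag", np.logspace(-6, 0, 200))
        g = fcs_model(lag, nmol=nmol, tau_d=tau_d, structure_s=s,
                      triplet_f=p.get("triplet_f", 0.0), tau_f=p.get("tau_f", 1e-6))
        if noise:
            g = 1.0 + (g - 1.0) * (1.0 + rng.normal(0, float(noise), g.shape))
        return CorrelationCurve(lag=lag, gvalue=g), GroundTruth(p, seed)
    if modality == "frap":
        d = p.setdefault("dcoeff", 25.0)
        w = p.setdefault("spot_radius", 1.0)
        mf = p.setdefault("mobile_fraction", 1.0)
        f0 = p.setdefault("f0", 0.3)
        tau_d = w**2 / (4.0 * d)
        t = p.setdefault("t", np.linspace(tau_d / 20, 30 * tau_d, 400))
        f_inf = f0 + mf * (1.0 - f0)
        y = f0 + (f_inf - f0) * disk_recovery(t, tau_d)
        if noise:
            y = y * (1.0 + rng.normal(0, float(noise), y.shape))
        return RecoveryTrace(t=t, intensity=y, spot_radius=w), GroundTruth(p, seed)
    if modality == "anisotropy_decay":
        r0 = p.setdefault("r0", 0.38)
        theta = p.setdefault("theta_c", 16.0)
        tau = p.setdefault("tau", 2.6)
        # 12 ns window: beyond ~4-5 lifetimes the polarized channels hold too
        # few photons for r(t) to be measurable, as in real TCSPC anisotropy.
        t = p.setdefault("t", np.linspace(0.0, 12.0, 240))
        r_t = r0 * np.exp(-t / theta)
        if noise == "poisson":
            total_counts = p.setdefault("total_counts", 1e4)
            decay = np.exp(-t / tau)
            ipar = total_counts * decay * (1.0 + 2.0 * r_t) / 3.0
            iperp = total_counts * decay * (1.0 - r_t) / 3.0
            ipar = rng.poisson(ipar).astype(float)
            iperp = rng.poisson(iperp).astype(float)
            denom = ipar + 2.0 * iperp
            r_t = np.divide(ipar - iperp, denom, out=np.zeros_like(denom),
                            where=denom > 0)
        elif noise:
            r_t = r_t + rng.normal(0, float(noise), r_t.shape)
        return DecayTrace(t=t, counts=r_t, kind="anisotropy"), GroundTruth(p, seed)
    if modality == "lifetime_decay":
        tau = p.setdefault("tau", 2.6)
        amp = p.setdefault("amplitude", 1e4)
        offset = p.setdefault("offset", 0.0)
        t = p.setdefault("t", np.linspace(0.0, 20.0, 400))
        y = amp * np.exp(-t / tau) + offset
        if noise == "poisson":
            y = rng.poisson(y).astype(float)
        elif noise:
            y = y * (1.0 + rng.normal(0, float(noise), y.shape))
        return DecayTrace(t=t, counts=y, kind="intensity"), GroundTruth(p, seed)
    raise ValueError(f"unknown modality {modality!r}")


# ---------------------------------------------------------------------------
# trajectories


def synth_trajectories(
    model: str = "brownian",
    d_coeff: float = 1.0,
    v: float = 0.0,
    box: float = np.inf,
    n_tracks: int = 100,
    n_steps: int = 10000,
    dt: float = 0.01,
    seed: int | None = None,
) -> tuple[list[Trajectory], GroundTruth]:
    """Simulate 2D particle tracks: free, drifting or box-confined.

    Brownian steps are Gaussian with variance 2 D dt per axis; ``drift``
    adds v*dt along x; ``confined`` reflects at the walls of a square box
    of side ``box`` um centered at the origin.
    """
    if model not in ("brownian", "drift", "confined"):
        raise ValueError(f"unknown trajectory model {model!r}")
    if model == "confined" and not np.isfinite(box):
        raise ValueError("confined model needs a finite box size")
    rng = np.random.default_rng(seed)
    t = np.arange(n_steps) * dt
    sigma = np.sqrt(2.0 * d_coeff * dt)
    tracks = []
    half = box / 2.0
    for pid in range(n_tracks):
        steps = rng.normal(0.0, sigma, size=(n_steps - 1, 2))
        if model == "drift":
            steps[:, 0] += v * dt
        pos = np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        if model == "confined":
            # Reflect the unfolded walk into [-half, half] on both axes.
            pos = np.abs((pos + half) % (4 * half) - 2 * half) - half
        tracks.append(Trajectory(t=t, x=pos[:, 0], y=pos[:, 1], particle_id=pid))
    truth = GroundTruth(
        params={"model": model, "d_coeff": d_coeff, "v": v, "box": box,
                "n_tracks": n_tracks, "n_steps": n_steps, "dt": dt},
        seed=seed,
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# osmotic series


def synth_osmotic_series(
    v_iso: float = 800.0,
    v_inactive_frac: float = 0.35,
    r_iso: float = 0.20,
    alpha_r: float = 0.169,
    excess_list: tuple[float, ...] = (0.0, 50.0, 150.0, 300.0, 600.0),
    iso_osmolarity: float = 300.0,
    deviation_term: float = 0.0,
    noise: float = 0.0,
    seed: int | None = None,
) -> tuple[OsmoticSeries, GroundTruth]:
    """Osmotic series obeying the Boyle-van't Hoff and dilution laws.

    Volumes follow V = V_iso (v_b + (1 - v_b) x) with x the pressure ratio
    iso/(iso+excess); anisotropies follow the dilution law off those
    volumes, plus ``deviation_term * (1 - x)`` emulating excluded-volume
    amplification at high tonicity; ``noise`` is a relative Gaussian sigma
    on both V and r (isotonic entry kept exact so the normalization anchor
    holds).
    """
    rng = np.random.default_rng(seed)
    excess = np.asarray(excess_list, dtype=float)
    x = iso_osmolarity / (iso_osmolarity + excess)
    volume = v_iso * (v_inactive_frac + (1.0 - v_inactive_frac) * x)
    modal_r = (r_iso - alpha_r) * (v_iso / volume) + alpha_r
    modal_r = modal_r + deviation_term * (1.0 - x)
    if noise:
        jitter_v = 1.0 + rng.normal(0, noise, volume.shape)
        jitter_r = 1.0 + rng.normal(0, noise, modal_r.shape)
        iso = excess == 0
        jitter_v[iso] = 1.0
        jitter_r[iso] = 1.0
        volume = volume * jitter_v
        modal_r = modal_r * jitter_r
    series = OsmoticSeries(
        osmolarity_excess=excess, volume=volume, modal_r=modal_r,
        iso_osmolarity=iso_osmolarity,
    )
    truth = GroundTruth(
        params={"v_iso": v_iso, "v_inactive_frac": v_inactive_frac,
                "r_iso": r_iso, "alpha_r": alpha_r,
                "deviation_term": deviation_term, "noise": noise},
        seed=seed,
    )
    return series, truth
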
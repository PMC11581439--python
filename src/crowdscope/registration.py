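"""Channel registration from fluorescent-bead fiducials.

The two halves of a dual-view frame image the same field through different
optical paths and do not overlap perfectly.  Sub-resolution beads dried on a
coverslip are imaged once per setup; their sub-pixel positions in the two
halves define the transform that resamples the perpendicular channel onto
the parallel-channel pixel grid.

Coordinates are (x, y) = (column, row), 0-based, origin at the top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import feature, transform

from .polarimetry_io import PolarizedFramePair

__all__ = [
    "BeadSet",
    "ChannelTransform",
    "detect_beads",
    "match_beads",
    "estimate_transform",
    "apply_transform",
]

_MIN_POINTS = {"translation": 1, "similarity": 2, "affine": 3}

_TFORM_CLS = {
    "translation": transform.EuclideanTransform,  # rotation freed but harmless at n=1
    "similarity": transform.SimilarityTransform,
    "affine": transform.AffineTransform,
}


@dataclass
class BeadSet:
    """Sub-pixel bead positions (x, y) with their peak amplitudes."""

    positions: np.ndarray  # (n, 2) array of (x, y)
    intensities: np.ndarray  # (n,) peak amplitudes

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.intensities = np.atleast_1d(np.asarray(self.intensities, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 2)

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class ChannelTransform:
    """A fitted perpendicular-to-parallel channel transform.

    ``params`` is the 3x3 homogeneous matrix mapping moving (perpendicular)
    coordinates onto fixed (parallel) coordinates.
    """

    model: str
    params: np.ndarray
    residual_rms: float = 0.0
    n_inliers: int = 0

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float).reshape(3, 3)
        if self.model not in _MIN_POINTS:
            raise ValueError(f"unknown transform model {self.model!r}")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be non-negative")

    @classmethod
    def identity(cls, model: str = "similarity") -> "ChannelTransform":
        return cls(model=model, params=np.eye(3), residual_rms=0.0, n_inliers=0)

    def as_skimage(self) -> transform.ProjectiveTransform:
        return transform.AffineTransform(matrix=self.params)

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        """Map (n, 2) moving coordinates to fixed coordinates."""
        return self.as_skimage()(np.atleast_2d(xy))

    def inverse(self, xy: np.ndarray) -> np.ndarray:
        return self.as_skimage().inverse(np.atleast_2d(xy))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model": self.model,
            "matrix": self.params.tolist(),
            "residual_rms": self.residual_rms,
            "n_inliers": self.n_inliers,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChannelTransform":
        payload = json.loads(Path(path).read_text())
        return cls(
            model=payload["model"],
            params=np.asarray(payload["matrix"]),
            residual_rms=payload["residual_rms"],
            n_inliers=payload["n_inliers"],
        )


def detect_beads(
    image: np.ndarray,
    min_sigma: float = 1.0,
    max_sigma: float = 4.0,
    threshold: float | None = None,
    refine_radius: int | None = None,
) -> BeadSet:
    """Detect bead-like spots and refine each to sub-pixel precision.

    Candidate peaks come from a Laplacian-of-Gaussian blob search between
    ``min_sigma`` and ``max_sigma``; each candidate is then refined by an
    intensity-weighted centroid in a local window after subtracting the
    window's minimum as local background.

    Parameters
    ----------
    image : 2D array
        Intensity image containing bright spots on a darker background.
    threshold : float, optional
        Absolute peak amplitude below which candidates are discarded.
        Defaults to 10% of the image's dynamic range above its minimum.
    refine_radius : int, optional
        Half-width of the centroid window; defaults to ``ceil(4 * max_sigma)``.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = float(img.min()), float(img.max())
    if threshold is None:
        threshold = lo + 0.1 * (hi - lo)
    if hi <= lo:
        return BeadSet(np.empty((0, 2)), np.empty(0))
    # blob_log threshold acts on the scale-normalized LoG response; relate it
    # loosely to the amplitude threshold so dim spurious maxima are skipped.
    blobs = feature.blob_log(
        img - lo,
        min_sigma=min_sigma,
        max_sigma=max_sigma,
        num_sigma=8,
        threshold=0.2 * (threshold - lo) if threshold > lo else 1e-12,
    )
    positions, intensities = [], []
    for row, col, sigma in blobs:
        ri, ci = int(round(row)), int(round(col))
        peak = img[ri, ci]
        if peak < threshold:
            continue
        rw = refine_radius if refine_radius is not None else max(3, int(np.ceil(3 * sigma)))
        center = _refine_centroid(img, (col, row), rw)
        if center is None:
            continue
        positions.append(center)
        intensities.append(float(peak))
    if not positions:
        return BeadSet(np.empty((0, 2)), np.empty(0))
    return BeadSet(np.asarray(positions), np.asarray(intensities))


def _refine_centroid(
    img: np.ndarray, xy: tuple[float, float], radius: int, n_iter: int = 3
) -> tuple[float, float] | None:
    """Iterative intensity-weighted centroid in a circular window.

    The window is recentered on each estimate so sub-pixel offsets do not
    truncate the spot asymmetrically; the window minimum is subtracted as
    local background.  A small circular window (~3 sigma) keeps neighboring
    spots from contaminating the centroid.
    """
    h, w = img.shape
    x, y = xy
    for _ in range(n_iter):
        ri, ci = int(round(y)), int(round(x))
        r0, r1 = max(0, ri - radius), min(h, ri + radius + 1)
        c0, c1 = max(0, ci - radius), min(w, ci + radius + 1)
        window = img[r0:r1, c0:c1]
        rows, cols = np.mgrid[r0:r1, c0:c1]
        circ = (rows - y) ** 2 + (cols - x) ** 2 <= radius**2
        weights = (window - window[circ].min()) * circ
        total = weights.sum()
        if total <= 0:
            return None
        x = float((cols * weights).sum() / total)
        y = float((rows * weights).sum() / total)
    return (x, y)


def match_beads(
    fixed: BeadSet, moving: BeadSet, search_radius: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mutual-nearest-neighbor correspondences within a search radius.

    Returns index arrays (into fixed, into moving) of the matched pairs.
    """
    if len(fixed) == 0 or len(moving) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    d = np.linalg.norm(
        fixed.positions[:, None, :] - moving.positions[None, :, :], axis=-1
    )
    nn_fm = d.argmin(axis=1)  # for each fixed, closest moving
    nn_mf = d.argmin(axis=0)  # for each moving, closest fixed
    fi = np.arange(len(fixed))
    mutual = (nn_mf[nn_fm] == fi) & (d[fi, nn_fm] <= search_radius)
    return fi[mutual], nn_fm[mutual]


def _fit_model(model: str, src: np.ndarray, dst: np.ndarray):
    if model == "translation":
        shift = dst.mean(axis=0) - src.mean(axis=0)
        return transform.SimilarityTransform(translation=shift)
    cls = _TFORM_CLS[model]
    if hasattr(cls, "from_estimate"):
        tf = cls.from_estimate(src, dst)
        return tf if tf else None
    tf = cls()
    return tf if tf.estimate(src, dst) else None


def estimate_transform(
    fixed: BeadSet,
    moving: BeadSet,
    model: str = "similarity",
    max_residual: float = 1.0,
    search_radius: float = 20.0,
    n_samples: int = 200,
    rng: np.random.Generator | int | None = 0,
) -> ChannelTransform:
    """Estimate the moving-to-fixed transform from matched beads.

    Matching uses mutual nearest neighbors under ``search_radius``; a
    random-minimal-sample consensus loop (``n_samples`` draws, inliers within
    ``max_residual`` pixels) rejects spurious correspondences, and the final
    transform is a least-squares fit over the consensus inliers.

    Raises
    ------
    RuntimeError
        If fewer correspondences survive than the model requires; the message
        carries the detection and match counts for diagnosis.
    """
    if model not in _MIN_POINTS:
        raise ValueError(f"unknown transform model {model!r}")
    min_pts = _MIN_POINTS[model]
    fi, mi = match_beads(fixed, moving, search_radius=search_radius)
    src = moving.positions[mi]
    dst = fixed.positions[fi]
    n = src.shape[0]
    if n < min_pts:
        raise RuntimeError(
            f"too few correspondences for {model} transform: "
            f"{len(fixed)} fixed beads, {len(moving)} moving beads, "
            f"{n} mutual matches, need >= {min_pts}"
        )
    rng = np.random.default_rng(rng)
    best_inliers = np.zeros(n, dtype=bool)
    for _ in range(n_samples):
        idx = rng.choice(n, size=min_pts, replace=False)
        tf = _fit_model(model, src[idx], dst[idx])
        if tf is None:
            continue
        resid = np.linalg.norm(tf(src) - dst, axis=1)
        inliers = resid <= max_residual
        if inliers.sum() > best_inliers.sum():
            best_inliers = inliers
    if best_inliers.sum() < min_pts:
        raise RuntimeError(
            f"consensus failed: best sample explains {int(best_inliers.sum())} "
            f"of {n} matches within {max_residual} px"
        )
    tf = _fit_model(model, src[best_inliers], dst[best_inliers])
    if tf is None:
        raise RuntimeError("degenerate inlier configuration")
    # Trim marginally contaminated correspondences: tighten the inlier band
    # around the current fit and refit, twice.
    for _ in range(2):
        resid_all = np.linalg.norm(tf(src) - dst, axis=1)
        rms = np.sqrt(np.mean(resid_all[best_inliers] ** 2))
        band = min(max_residual, max(3.0 * rms, 0.05 * max_residual))
        tightened = resid_all <= band
        if tightened.sum() < min_pts or tightened.sum() == best_inliers.sum():
            break
        refit = _fit_model(model, src[tightened], dst[tightened])
        if refit is None:
            break
        tf, best_inliers = refit, tightened
    resid = np.linalg.norm(tf(src[best_inliers]) - dst[best_inliers], axis=1)
    return ChannelTransform(
        model=model,
        params=np.asarray(tf.params),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_inliers=int(best_inliers.sum()),
    )


def apply_transform(
    pair: PolarizedFramePair, tform: ChannelTransform
) -> PolarizedFramePair:
    """Resample the perpendicular half onto the parallel grid.

    Bilinear interpolation; pixels whose source falls outside the moving
    image are marked invalid and excluded from downstream statistics.
    """
    sk_tf = tform.as_skimage()
    warped = transform.warp(
        pair.perpendicular,
        inverse_map=sk_tf.inverse,
        order=1,
        mode="constant",
        cval=np.nan,
        preserve_range=True,
    )
    valid = np.isfinite(warped) & pair.valid
    warped = np.where(valid, warped, 0.0)
    return PolarizedFramePair(
        parallel=pair.parallel.copy(),
        perpendicular=warped,
        registered=True,
        valid=valid,
    )
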
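"""Radial lens self-calibration and Hartley rectification.

The self-calibration needs nothing but one stereo pair of a relatively flat
patch of ground.  On a fronto-parallel rig the epipolar lines of an
undistorted pair are the image rows, so radial distortion betrays itself as
vertical displacement of feature correspondences that grows toward the
frame edges; the coefficients ``(k1, k2)`` are recovered by robustly
minimizing those row residuals after undistortion.  The deviation of the
undistorted disparity field from an affine plane — tight for a flat-ground
capture, large for a canopy — serves as the planarity diagnostic.

Rectification uses Hartley's projective algorithm: the fundamental matrix
is estimated from feature correspondences (normalized 8-point inside
RANSAC), the epipole of the right view is mapped to infinity, and a
matching projective transform for the left view is chosen to minimize
horizontal disparity.  Distortion removal and the rectifying homography are
composed into a single resampling so the images are only interpolated once.
A pair whose correspondences already share rows within half a pixel is
passed through untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .scene import StereoPair

__all__ = [
    "CalibrationError",
    "DistortionModel",
    "RectificationTransform",
    "match_features",
    "self_calibrate",
    "rectify",
]


class CalibrationError(RuntimeError):
    """Raised when feature matching or calibration cannot proceed."""


@dataclass(frozen=True)
class DistortionModel:
    """Two-coefficient radial lens model on a normalized radius.

    Pixel radii are normalized by ``scale`` (half the image diagonal by
    convention) so the coefficients are dimensionless and comparable across
    image sizes.  ``distort`` maps ideal (undistorted) pixel positions to
    where the lens actually images them: ``x_d = c + (x_u - c) * (1 +
    k1*r^2 + k2*r^4)`` with ``r`` the normalized ideal radius.
    """

    k1: float = 0.0
    k2: float = 0.0
    principal_point: tuple = (0.0, 0.0)  # (col, row), pixels
    scale: float = 1.0  # pixels per unit normalized radius

    @classmethod
    def for_image(cls, shape, k1: float = 0.0, k2: float = 0.0) -> "DistortionModel":
        rows, cols = shape[:2]
        c = ((cols - 1) / 2.0, (rows - 1) / 2.0)
        return cls(k1=k1, k2=k2, principal_point=c, scale=float(np.hypot(*c)))

    @property
    def is_identity(self) -> bool:
        return self.k1 == 0.0 and self.k2 == 0.0

    def _factor(self, r2: np.ndarray) -> np.ndarray:
        return 1.0 + self.k1 * r2 + self.k2 * r2 * r2

    def distort(self, xy: np.ndarray) -> np.ndarray:
        """Ideal -> captured pixel coordinates, (N, 2) as (col, row)."""
        xy = np.asarray(xy, dtype=float)
        c = np.asarray(self.principal_point)
        v = (xy - c) / self.scale
        r2 = (v * v).sum(axis=-1, keepdims=True)
        return c + v * self._factor(r2) * self.scale

    def undistort(self, xy: np.ndarray, iterations: int = 25) -> np.ndarray:
        """Captured -> ideal coordinates by fixed-point inversion."""
        xy = np.asarray(xy, dtype=float)
        c = np.asarray(self.principal_point)
        v_d = (xy - c) / self.scale
        v = v_d.copy()
        for _ in range(iterations):
            r2 = (v * v).sum(axis=-1, keepdims=True)
            v = v_d / self._factor(r2)
        return c + v * self.scale

    def apply_to_image(self, image: np.ndarray) -> np.ndarray:
        """Render the captured (distorted) view of an ideal image."""
        return _resample(image, lambda xy: self.undistort(xy))

    def undistort_image(self, image: np.ndarray) -> np.ndarray:
        """Render the ideal (undistorted) view of a captured image."""
        return _resample(image, lambda xy: self.distort(xy))

    def to_dict(self) -> dict:
        return {
            "k1": self.k1,
            "k2": self.k2,
            "principal_point": list(self.principal_point),
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DistortionModel":
        return cls(
            k1=float(d["k1"]),
            k2=float(d["k2"]),
            principal_point=tuple(d["principal_point"]),
            scale=float(d["scale"]),
        )


@dataclass
class RectificationTransform:
    """Projective rectifying transforms and their quality diagnostics."""

    h_left: np.ndarray  # 3x3, ideal -> rectified
    h_right: np.ndarray
    fundamental: np.ndarray | None
    residual_vertical_px: float
    inlier_fraction: float = 1.0
    meta: dict = field(default_factory=dict)


def _resample(image: np.ndarray, out_to_src, shape=None) -> np.ndarray:
    """Sample ``image`` at ``out_to_src(output pixel grid)`` bilinearly."""
    image = np.asarray(image)
    rows, cols = (shape or image.shape)[:2]
    cc, rr = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    src = out_to_src(np.stack([cc.ravel(), rr.ravel()], axis=1))
    coords = [src[:, 1].reshape(rows, cols), src[:, 0].reshape(rows, cols)]
    if image.ndim == 2:
        return ndimage.map_coordinates(image.astype(float), coords, order=1, mode="nearest")
    out = np.empty((rows, cols, image.shape[2]), dtype=float)
    for ch in range(image.shape[2]):
        out[..., ch] = ndimage.map_coordinates(
            image[..., ch].astype(float), coords, order=1, mode="nearest"
        )
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.round(out), 0, 255).astype(image.dtype)
    return out


def match_features(
    pair: StereoPair,
    max_n: int = 300,
    patch: int = 11,
    d_search: tuple = (0.0, None),
    v_search: int = 8,
    min_score: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse correspondences between the two views.

    Harris corners in the left view are matched into the right view by
    normalized cross-correlation over a horizontal window ``d_search``
    (pixels of disparity; ``None`` upper bound means half the width) and
    ``±v_search`` rows, with parabolic sub-pixel refinement of the peak.
    Returns two ``(N, 2)`` arrays of (col, row) positions.  Fully
    deterministic.  Raises :class:`CalibrationError` with fewer than 8
    matches (blank or hopeless imagery).
    """
    from skimage.feature import corner_harris, corner_peaks, match_template

    from .matching import to_gray

    gl, gr = to_gray(pair.left), to_gray(pair.right)
    rows, cols = gl.shape
    d_lo = float(d_search[0])
    d_hi = float(d_search[1]) if d_search[1] is not None else cols / 2.0
    # rank-based selection: a single extreme Harris response must not
    # suppress the rest of the frame, so no relative threshold
    corners = corner_peaks(
        corner_harris(gl),
        min_distance=6,
        threshold_abs=1e-4,
        threshold_rel=0.0,
        num_peaks=max_n,
    )
    half = patch // 2
    left_pts, right_pts = [], []
    for r, c in corners:
        if not (half <= r < rows - half and half <= c < cols - half):
            continue
        tmpl = gl[r - half : r + half + 1, c - half : c + half + 1]
        if tmpl.std() < 1e-6:
            continue
        r0, r1 = max(0, r - v_search - half), min(rows, r + v_search + half + 1)
        c0 = int(max(0, np.floor(c - d_hi) - half))
        c1 = int(min(cols, np.ceil(c - d_lo) + half + 1))
        if c1 - c0 < patch + 2 or r1 - r0 < patch + 2:
            continue
        region = gr[r0:r1, c0:c1]
        resp = match_template(region, tmpl)
        iy, ix = np.unravel_index(np.argmax(resp), resp.shape)
        if resp[iy, ix] < min_score:
            continue
        dy = _parabola(resp[:, ix], iy)
        dx = _parabola(resp[iy, :], ix)
        right_pts.append((c0 + half + ix + dx, r0 + half + iy + dy))
        left_pts.append((float(c), float(r)))
    if len(left_pts) < 8:
        raise CalibrationError(
            f"only {len(left_pts)} feature matches found (need >= 8); "
            "is the imagery textured and overlapping?"
        )
    return np.asarray(left_pts), np.asarray(right_pts)


def _parabola(v: np.ndarray, i: int) -> float:
    if i <= 0 or i >= v.size - 1:
        return 0.0
    denom = v[i - 1] - 2 * v[i] + v[i + 1]
    if abs(denom) < 1e-12:
        return 0.0
    return float(np.clip(0.5 * (v[i - 1] - v[i + 1]) / denom, -0.5, 0.5))


def _estimate_f_ransac(left: np.ndarray, right: np.ndarray, seed: int = 0):
    """Fundamental matrix by normalized 8-point inside RANSAC (1 px)."""
    from skimage.measure import ransac
    from skimage.transform import FundamentalMatrixTransform

    model, inliers = ransac(
        (left, right),
        FundamentalMatrixTransform,
        min_samples=8,
        residual_threshold=1.0,
        max_trials=500,
        rng=seed,
    )
    if model is None or inliers is None or inliers.sum() < 8:
        raise CalibrationError("fundamental matrix estimation failed")
    return model, inliers


def _affine_disparity_sq(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Squared deviations of the disparity field from an affine plane."""
    disp = left[:, 0] - right[:, 0]
    A = np.c_[left, np.ones(len(left))]
    coef, *_ = np.linalg.lstsq(A, disp, rcond=None)
    return (disp - A @ coef) ** 2


def self_calibrate(
    flat_ground_pair: StereoPair,
    rig=None,
    seed: int = 0,
    fit_k2: bool = True,
    max_n: int = 300,
) -> DistortionModel:
    """Recover radial distortion from one flat-ground stereo pair.

    On this fronto-parallel rig the epipolar lines of an undistorted pair
    are the image rows, so radial distortion betrays itself as vertical
    (cross-row) displacement of correspondences that grows toward the frame
    edges.  The objective minimized (Nelder-Mead from ``(0, 0)``, tolerance
    1e-6) is the Cauchy-robust mean of squared row residuals of the
    undistorted correspondences — a residual the horizontal NCC bias of the
    matcher cannot contaminate.  Gross mismatches saturate in the loss
    (scale 1 px) instead of pulling the fit.

    After the fit, the deviation of the undistorted disparity field from an
    affine plane is evaluated as a planarity diagnostic: a flat-ground
    capture fits tightly, while a canopy or heavily occluded scene leaves a
    large residual and triggers a warning — never a silent success.
    """
    left, right = match_features(flat_ground_pair, max_n=max_n)
    base = DistortionModel.for_image(flat_ground_pair.left.shape)
    c2 = 1.0  # Cauchy scale (px), squared

    def objective(k):
        m = DistortionModel(k[0], k[1] if fit_k2 else 0.0, base.principal_point, base.scale)
        lu, ru = m.undistort(left), m.undistort(right)
        dy2 = (lu[:, 1] - ru[:, 1]) ** 2
        return float(np.mean(np.log1p(dy2 / c2)))

    x0 = np.zeros(2 if fit_k2 else 1)
    res = optimize.minimize(
        lambda k: objective(np.atleast_1d(k)),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 500},
    )
    if not res.success:
        raise CalibrationError(f"distortion optimization did not converge: {res.message}")
    k1 = float(res.x[0])
    k2 = float(res.x[1]) if fit_k2 else 0.0
    model = DistortionModel(k1, k2, base.principal_point, base.scale)
    lu, ru = model.undistort(left), model.undistort(right)
    planarity = float(np.sqrt(np.median(_affine_disparity_sq(lu, ru))))
    if planarity > 1.0 or res.fun > np.log1p(1.0):
        warnings.warn(
            f"self-calibration scene check failed (affine-plane residual "
            f"{planarity:.2f} px, robust row residual {res.fun:.2f}); the "
            "scene may not be planar enough for a reliable estimate",
            stacklevel=2,
        )
    return model


def _hartley_homographies(F: np.ndarray, left: np.ndarray, right: np.ndarray, shape):
    """Rectifying homographies mapping the right epipole to infinity."""
    rows, cols = shape[:2]
    cx, cy = (cols - 1) / 2.0, (rows - 1) / 2.0

    # right epipole: left null vector of F (x' F x = 0 convention)
    _, _, vt = np.linalg.svd(F.T)
    e2 = vt[-1]
    T = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    e2t = T @ e2
    if abs(e2t[2]) > 1e-12:
        e2t = e2t / e2t[2]
    theta = np.arctan2(e2t[1], e2t[0])
    # rotate the epipole onto the x-axis through the minimal angle (the -x
    # direction is fine) so the image orientation is preserved
    if theta > np.pi / 2:
        theta -= np.pi
    elif theta < -np.pi / 2:
        theta += np.pi
    ct, st = np.cos(-theta), np.sin(-theta)
    R = np.array([[ct, -st, 0], [st, ct, 0], [0, 0, 1.0]])
    e2r = R @ e2t
    if abs(e2r[2]) > 1e-12 and abs(e2r[0]) > 1e-12:
        fdist = e2r[0] / e2r[2]
        G = np.array([[1, 0, 0], [0, 1, 0], [-1.0 / fdist, 0, 1.0]])
    else:  # epipole already at infinity
        G = np.eye(3)
    H2 = np.linalg.inv(T) @ G @ R @ T

    # matching left homography: H0 = H2 M with F = [e2]_x M, then an affine
    # x-correction minimizing the disparity of the correspondences
    ex = np.array([[0, -e2[2], e2[1]], [e2[2], 0, -e2[0]], [-e2[1], e2[0], 0]])
    M = ex @ F + np.outer(e2, np.ones(3))
    H0 = H2 @ M
    lh = np.c_[left, np.ones(len(left))] @ H0.T
    rh = np.c_[right, np.ones(len(right))] @ H2.T
    lh = lh / lh[:, 2:3]
    rh = rh / rh[:, 2:3]
    A = np.c_[lh[:, 0], lh[:, 1], np.ones(len(lh))]
    abc, *_ = np.linalg.lstsq(A, rh[:, 0], rcond=None)
    HA = np.array([[abc[0], abc[1], abc[2]], [0, 1, 0], [0, 0, 1.0]])
    H1 = HA @ H0

    # re-center both outputs so the frame centre stays put
    for i, H in enumerate((H1, H2)):
        c = H @ np.array([cx, cy, 1.0])
        c = c / c[2]
        shift = np.array([[1, 0, cx - c[0]], [0, 1, cy - c[1]], [0, 0, 1.0]])
        if i == 0:
            H1 = shift @ H
        else:
            H2 = shift @ H
    # keep the two rows consistent: align mean transformed rows
    lh = np.c_[left, np.ones(len(left))] @ H1.T
    rh = np.c_[right, np.ones(len(right))] @ H2.T
    dy = float(np.mean(lh[:, 1] / lh[:, 2] - rh[:, 1] / rh[:, 2]))
    H2 = np.array([[1, 0, 0], [0, 1, dy], [0, 0, 1.0]]) @ H2
    return H1, H2


def _apply_h(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    p = np.c_[pts, np.ones(len(pts))] @ H.T
    return p[:, :2] / p[:, 2:3]


def rectify(
    pair: StereoPair,
    model: DistortionModel | None = None,
    seed: int = 0,
    max_n: int = 300,
    max_vertical_px: float = 0.5,
) -> tuple[StereoPair, RectificationTransform]:
    """Undistort and row-align a stereo pair for 1-D disparity search.

    Lens correction and the rectifying homography are composed into one
    resampling per image.  If the (undistorted) correspondences already
    share rows to within ``max_vertical_px`` for 95% of inliers, the
    transforms are the identity and only lens correction is applied.
    """
    model = model or DistortionModel.for_image(pair.left.shape)
    # large patches give the vertical match precision rectification needs,
    # but distorted imagery decorrelates them; relax if matches run short
    left = right = None
    last_err: CalibrationError | None = None
    for patch, min_score in ((15, 0.6), (11, 0.5), (9, 0.4)):
        try:
            left, right = match_features(pair, max_n=max_n, patch=patch, min_score=min_score)
        except CalibrationError as e:
            last_err = e
            continue
        if len(left) >= 30:
            break
    if left is None:
        raise last_err or CalibrationError("feature matching failed")
    lu, ru = model.undistort(left), model.undistort(right)
    fmodel, inliers = _estimate_f_ransac(lu, ru, seed=seed)
    li, ri = lu[inliers], ru[inliers]
    dy = np.abs(li[:, 1] - ri[:, 1])
    inl_frac = float(inliers.mean())
    if np.quantile(dy, 0.95) <= max_vertical_px:
        # rows already aligned: identity transforms, lens correction only
        H1 = H2 = np.eye(3)
        F = fmodel.params
        resid = float(np.quantile(dy, 0.95))
    else:
        H1, H2 = _hartley_homographies(fmodel.params, li, ri, pair.left.shape)
        tl, tr = _apply_h(H1, li), _apply_h(H2, ri)
        resid = float(np.quantile(np.abs(tl[:, 1] - tr[:, 1]), 0.95))
        F = fmodel.params

    def warp_map(H):
        Hinv = np.linalg.inv(H)

        def out_to_src(xy):
            return model.distort(_apply_h(Hinv, xy))

        return out_to_src

    if model.is_identity and np.allclose(H1, np.eye(3)) and np.allclose(H2, np.eye(3)):
        left_img, right_img = pair.left, pair.right  # no-op: skip resampling
    else:
        left_img = _resample(pair.left, warp_map(H1))
        right_img = _resample(pair.right, warp_map(H2))
    rect = StereoPair(
        left=left_img,
        right=right_img,
        rectified=True,
        occlusion_mask=pair.occlusion_mask,
        meta={**pair.meta, "rectification_residual_px": resid},
    )
    transform = RectificationTransform(
        h_left=H1,
        h_right=H2,
        fundamental=F,
        residual_vertical_px=resid,
        inlier_fraction=inl_frac,
    )
    if resid > max_vertical_px:
        warnings.warn(
            f"post-rectification vertical residual {resid:.2f} px exceeds "
            f"{max_vertical_px} px",
            stacklevel=2,
        )
    return rect, transform
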
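"""Optic-disc geometry, fovea detection and circular analysis regions.

The fractal dimension is measured inside a circular region of interest
whose radius is expressed in multiples of the optic-disc radius (ODr):
4x ODr excludes the disc, 5x covers half of it, 6x covers it fully.  The
fovea sits roughly 5x ODr from the disc centre, so fovea-anchored and
disc-anchored ROIs are both supported.

Disc geometry is recovered from a colour patch: an opponent-colour
transform highlights the yellow-blue contrast of the nerve head, the disc
boundary is traced as zero-crossings of a Laplacian of the enhanced patch,
and an ellipse is fitted to the boundary points; ODr is the mean of the
fitted semi-axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import EllipseModel

__all__ = [
    "GAUSSIAN_COLOR_MATRIX",
    "GaussianColorPlanes",
    "ODGeometry",
    "ROISpec",
    "gaussian_color_transform",
    "fit_ellipse",
    "estimate_od_geometry",
    "inpaint_vessels",
    "detect_fovea",
    "circular_mask",
    "circular_roi_mask",
]

# Linear RGB -> opponent (intensity, yellow-blue, red-green) transform used
# to enhance the optic nerve head against the retinal background.
GAUSSIAN_COLOR_MATRIX = np.array(
    [
        [0.06, 0.63, 0.31],
        [0.19, 0.18, -0.37],
        [0.22, -0.44, 0.06],
    ]
)


@dataclass
class GaussianColorPlanes:
    """Spectral planes: non-derivative e, 1st- and 2nd-order derivatives."""

    e: np.ndarray
    e_lambda: np.ndarray
    e_lambda_lambda: np.ndarray


@dataclass
class ODGeometry:
    """Optic-disc centre and radius; ODr is the unit of all ROI radii."""

    center: tuple[float, float]      # (row, col), pixels
    major_radius: float
    minor_radius: float
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.minor_radius <= self.major_radius):
            raise ValueError("radii must satisfy 0 < minor <= major")

    @property
    def od_radius(self) -> float:
        return 0.5 * (self.major_radius + self.minor_radius)


@dataclass
class ROISpec:
    """Circular ROI at ``k`` times the optic-disc radius."""

    center: tuple[float, float]
    k: float
    od_radius: float
    anchor: str = "fovea"            # or "od_center"

    def __post_init__(self) -> None:
        if self.anchor not in ("fovea", "od_center"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if self.radius_px <= 0:
            raise ValueError("ROI radius must be positive")

    @property
    def radius_px(self) -> float:
        return self.k * self.od_radius


def gaussian_color_transform(rgb_image: np.ndarray) -> GaussianColorPlanes:
    """Per-pixel opponent-colour transform of a 3-channel image.

    Exactly linear: ``T(aX + bY) = a T(X) + b T(Y)``.
    """
    rgb = np.asarray(rgb_image, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("a 3-channel (H, W, 3) image is required")
    planes = np.tensordot(rgb, GAUSSIAN_COLOR_MATRIX.T, axes=([2], [0]))
    return GaussianColorPlanes(planes[..., 0], planes[..., 1], planes[..., 2])


def fit_ellipse(points: np.ndarray) -> tuple[tuple[float, float], float, float, float, float]:
    """Least-squares ellipse through (row, col) boundary points.

    Returns ``(center, major_radius, minor_radius, theta, residual)``.
    Raises on fewer than 6 points (under-determined conic) or a degenerate
    fit; there is no silent fallback.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 6:
        raise ValueError("at least 6 (row, col) points are required for an ellipse fit")
    # EllipseModel works in (x, y); feed (col, row)
    xy = pts[:, ::-1]
    try:
        model = EllipseModel.from_estimate(xy)
    except Exception as exc:  # conic fit can fail on degenerate inputs
        raise ValueError(f"degenerate ellipse fit: {exc}") from None
    if not model:
        raise ValueError("degenerate ellipse fit")
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise ValueError("degenerate ellipse fit")
    residual = float(np.sqrt(np.mean(model.residuals(xy) ** 2)))
    major, minor = (a, b) if a >= b else (b, a)
    if minor <= 0:
        raise ValueError("degenerate ellipse fit (non-positive axis)")
    return (float(yc), float(xc)), float(major), float(minor), float(theta), residual


def estimate_od_geometry(
    rgb_image: np.ndarray,
    approx_center: tuple[float, float],
    patch_halfwidth: int,
    *,
    epsilon: float = 1.0,
) -> ODGeometry:
    """Recover disc centre and radius from a patch around a seed point.

    The enhanced disc map is ``sqrt(e_lambda**2 + e_lambda_lambda**2) /
    (e + eps)`` — a chromaticity-like contrast built from the three
    opponent planes, normalized against luminance.  Its Laplacian's
    zero-crossings with strong gradient support trace the disc boundary,
    and an ellipse fit yields ODr as the mean of the fitted radii.
    """
    rgb = np.asarray(rgb_image, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("a 3-channel image is required for OD segmentation")
    h, w = rgb.shape[:2]
    r0 = int(round(approx_center[0]))
    c0 = int(round(approx_center[1]))
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("approx_center lies outside the image")
    rlo, rhi = max(0, r0 - patch_halfwidth), min(h, r0 + patch_halfwidth + 1)
    clo, chi = max(0, c0 - patch_halfwidth), min(w, c0 + patch_halfwidth + 1)
    patch = rgb[rlo:rhi, clo:chi]

    planes = gaussian_color_transform(patch)
    enhanced = np.sqrt(planes.e_lambda ** 2 + planes.e_lambda_lambda ** 2) / (
        np.abs(planes.e) + epsilon
    )
    # exclude the void outside the camera field of view: its border would
    # otherwise dominate the Laplacian zero-crossings
    valid = ndi.binary_erosion(patch.mean(axis=2) > 0.02, iterations=4)
    enhanced = np.where(valid, enhanced, np.median(enhanced[valid]) if valid.any() else 0.0)
    sigma = max(2.0, patch_halfwidth / 6.0)
    smooth = ndi.gaussian_filter(enhanced, sigma)
    log = ndi.gaussian_laplace(smooth, sigma)

    zc = np.zeros_like(log, dtype=bool)
    s = np.sign(log)
    zc[:-1, :] |= (s[:-1, :] * s[1:, :]) < 0
    zc[:, :-1] |= (s[:, :-1] * s[:, 1:]) < 0
    zc &= valid
    grad = np.hypot(*np.gradient(smooth))
    if zc.any():
        thr = np.percentile(grad[zc], 70)
        zc &= grad >= thr
    points = np.argwhere(zc)
    if len(points) < 6:
        raise ValueError("fewer than 6 boundary points; ellipse fit is under-determined")
    # robust trim: boundary points share a common radius around the seed
    # centre, stray vessel-edge arcs do not
    centre = np.array([r0 - rlo, c0 - clo], dtype=float)
    dist = np.hypot(*(points - centre).T)
    med = np.median(dist)
    keep = np.abs(dist - med) <= 0.3 * med
    if keep.sum() >= 6:
        points = points[keep]
    (cr, cc), major, minor, _theta, residual = fit_ellipse(points)
    # iterative refit: drop the worst-fitting quarter of the points
    for _ in range(3):
        radial = np.hypot(points[:, 0] - cr, points[:, 1] - cc)
        resid = np.abs(radial - np.median(radial))
        keep = resid <= np.percentile(resid, 75)
        if keep.sum() < 6:
            break
        points = points[keep]
        (cr, cc), major, minor, _theta, residual = fit_ellipse(points)

    def _undo_scale_space_shift(r_fit: float) -> float:
        # a LoG zero-crossing of a convex edge sits ~sigma^2/R outside it;
        # invert r_fit = R + sigma^2/R for the true radius
        radicand = r_fit ** 2 - 4.0 * sigma ** 2
        if radicand <= 0:
            return r_fit
        return 0.5 * (r_fit + math.sqrt(radicand))

    major = _undo_scale_space_shift(major)
    minor = _undo_scale_space_shift(minor)
    return ODGeometry(
        center=(cr + rlo, cc + clo),
        major_radius=major,
        minor_radius=minor,
        fit_residual=residual,
    )


def inpaint_vessels(
    image: np.ndarray,
    vessels: np.ndarray,
    *,
    max_iters: int = 200,
    tol: float = 1e-4,
) -> np.ndarray:
    """Replace vessel pixels by diffusion from their background neighbours.

    Iterative Laplacian (Jacobi) fill restricted to vessel pixels; stops at
    ``max_iters`` or when the relative change drops below ``tol``.
    """
    img = np.asarray(image, dtype=float).copy()
    vessels = np.asarray(vessels, dtype=bool)
    if not vessels.any():
        return img
    # seed vessel pixels with a local background average so diffusion starts close
    known = (~vessels).astype(float)
    vals = np.where(vessels, 0.0, img)
    num = ndi.uniform_filter(vals, size=5, mode="nearest")
    den = ndi.uniform_filter(known, size=5, mode="nearest")
    global_bg = float(img[~vessels].mean())
    local = np.divide(num, den, out=np.full_like(img, global_bg), where=den > 1e-9)
    img[vessels] = local[vessels]
    kernel = np.array([[0.0, 0.25, 0.0], [0.25, 0.0, 0.25], [0.0, 0.25, 0.0]])
    scale = max(float(np.ptp(img)), 1e-12)
    for _ in range(max_iters):
        sm = ndi.convolve(img, kernel, mode="nearest")
        delta = np.abs(sm[vessels] - img[vessels]).max() / scale
        img[vessels] = sm[vessels]
        if delta < tol:
            break
    return img


def detect_fovea(
    image: np.ndarray,
    od: ODGeometry,
    vessels: np.ndarray,
    *,
    ring: tuple[float, float] = (4.0, 6.0),
    blur_rel: float = 0.5,
    fov_mask: np.ndarray | None = None,
) -> tuple[int, int]:
    """Locate the fovea as the intensity minimum in the 4-6x ODr ring.

    Vessels are inpainted first so dark vessels do not masquerade as the
    fovea; the ring-masked image is blurred at ``blur_rel * ODr`` (a
    resolution-invariant "large" scale) and the global minimum returned.
    The search is restricted to ``fov_mask`` (or, when absent, to pixels
    that are not black) so the void outside the camera's field of view
    cannot win.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., 1]  # green channel carries the vessel/fovea contrast
    odr = od.od_radius
    rr, cc = np.ogrid[: img.shape[0], : img.shape[1]]
    dist = np.hypot(rr - od.center[0], cc - od.center[1])
    ring_mask = (dist >= ring[0] * odr) & (dist <= ring[1] * odr)
    if fov_mask is None:
        fov_mask = ndi.binary_erosion(img > 0.02, iterations=3)
    fov_mask = np.asarray(fov_mask, dtype=bool)
    # the fovea is never at the field rim, where vignetting is darkest
    interior = ndi.distance_transform_edt(fov_mask) >= 0.5 * odr
    ring_mask &= fov_mask & interior
    if not ring_mask.any():
        raise ValueError("the fovea search ring lies entirely outside the image")
    filled = inpaint_vessels(img, np.asarray(vessels, dtype=bool))
    # mask-normalized blur so the void outside the field of view cannot
    # bleed darkness across its border
    sigma = blur_rel * odr
    weight = ndi.gaussian_filter(fov_mask.astype(float), sigma)
    blurred = ndi.gaussian_filter(np.where(fov_mask, filled, 0.0), sigma)
    blurred = np.divide(blurred, weight, out=np.full_like(blurred, np.inf),
                        where=weight > 1e-6)
    blurred = np.where(ring_mask, blurred, np.inf)
    idx = int(np.argmin(blurred))
    return np.unravel_index(idx, blurred.shape)


def circular_mask(
    center: tuple[float, float], radius: float, shape: tuple[int, int]
) -> np.ndarray:
    """Boolean disc: pixels whose centre lies within ``radius`` of ``center``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius


def circular_roi_mask(spec: ROISpec, image_shape: tuple[int, int]) -> np.ndarray:
    """Raster the circular ROI described by ``spec``, clipped at the borders."""
    return circular_mask(spec.center, spec.radius_px, image_shape)
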
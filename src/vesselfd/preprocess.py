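"""Pixel-pitch rescaling and background luminosity/contrast normalization.

Fundus images from different cameras differ in pixel pitch, illumination
drift and local contrast.  Before segmentation every image is (a) resampled
to a reference pixel pitch and (b) normalized against a background model:
local luminosity ``L`` and contrast ``C`` fields are estimated robustly
from tentative background pixels (everything that does not look like a
vessel at a coarse scale) and the image is mapped to ``(I - L) / C``.
Over background regions the result has roughly zero mean and unit spread,
so downstream filter constants mean the same thing on every image.

The estimates are tile-based: the image is divided into windows of
``window_px``, each window contributes a median and a scaled median
absolute deviation (MAD x 1.4826, consistent with a Gaussian sigma) of its
background pixels, and the tile grids are interpolated smoothly back to
full resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

__all__ = [
    "NormalizationModel",
    "rescale_to_reference",
    "normalize_luminosity_contrast",
    "green_channel",
]


@dataclass
class NormalizationModel:
    """Estimated background fields used to normalize one image."""

    background_luminosity: np.ndarray
    background_contrast: np.ndarray       # floored at epsilon everywhere
    window_px: int
    epsilon: float
    degenerate: bool = False               # constant input, zero contrast


def green_channel(image: np.ndarray) -> np.ndarray:
    """The high-vessel-contrast channel: green for RGB, identity for gray."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        return img[..., 1]
    return img


def rescale_to_reference(
    image: np.ndarray,
    current_pitch: float,
    target_pitch: float,
    *,
    is_mask: bool = False,
) -> np.ndarray:
    """Resample so one output pixel spans ``target_pitch`` of retina.

    Output dimensions are the input's times ``current_pitch/target_pitch``
    (rounded); masks are resampled nearest-neighbour, intensities
    bilinearly.
    """
    if current_pitch <= 0 or target_pitch <= 0:
        raise ValueError("pixel pitches must be positive")
    img = np.asarray(image)
    ratio = current_pitch / target_pitch
    if ratio == 1.0:
        return img.copy()
    out_shape = tuple(max(1, int(round(s * ratio))) for s in img.shape[:2])
    if img.ndim == 3:
        out_shape = out_shape + (img.shape[2],)
    if is_mask:
        out = resize(img.astype(float), out_shape, order=0, anti_aliasing=False,
                     preserve_range=True)
        return out > 0.5 if img.dtype == bool else out
    return resize(img.astype(float), out_shape, order=1,
                  anti_aliasing=ratio < 1, preserve_range=True)


def _coarse_vessel_response(img: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Cheap single-scale tubularity used only to exclude vessels from the
    background estimate: positive gamma-normalized dominant curvature."""
    s2 = sigma ** 2
    hrr = s2 * ndi.gaussian_filter(img, sigma, order=(2, 0))
    hcc = s2 * ndi.gaussian_filter(img, sigma, order=(0, 2))
    hrc = s2 * ndi.gaussian_filter(img, sigma, order=(1, 1))
    mean = 0.5 * (hrr + hcc)
    gap = np.sqrt(np.maximum(0.25 * (hrr - hcc) ** 2 + hrc ** 2, 0.0))
    return np.maximum(mean + gap, 0.0)   # dark vessels curve upward


def _tile_field(
    img: np.ndarray, bg: np.ndarray, window: int, stat: str
) -> np.ndarray:
    h, w = img.shape
    nr = max(1, int(np.ceil(h / window)))
    nc = max(1, int(np.ceil(w / window)))
    grid = np.full((nr, nc), np.nan)
    for i in range(nr):
        for j in range(nc):
            sl = (slice(i * window, min((i + 1) * window, h)),
                  slice(j * window, min((j + 1) * window, w)))
            vals = img[sl][bg[sl]]
            if vals.size >= 20:
                if stat == "median":
                    grid[i, j] = np.median(vals)
                else:
                    med = np.median(vals)
                    grid[i, j] = 1.4826 * np.median(np.abs(vals - med))
    if np.isnan(grid).all():
        fallback = np.median(img[bg]) if bg.any() else np.median(img)
        grid[:] = fallback if stat == "median" else 0.0
    elif np.isnan(grid).any():
        # fill empty tiles from their nearest estimated neighbour
        idx = ndi.distance_transform_edt(np.isnan(grid), return_distances=False,
                                         return_indices=True)
        grid = grid[tuple(idx)]
    grid = ndi.gaussian_filter(grid, 1.0, mode="nearest")
    return resize(grid, img.shape, order=3, mode="edge", anti_aliasing=False,
                  preserve_range=True)


def normalize_luminosity_contrast(
    image: np.ndarray,
    window_px: int | None = None,
    epsilon: float = 1e-3,
) -> tuple[np.ndarray, NormalizationModel]:
    """Normalize an image against its estimated background fields.

    Tentative background pixels are those below the 90th percentile of a
    coarse tubularity response; per-window robust statistics (median,
    MAD x 1.4826) over those pixels are interpolated into full-resolution
    luminosity and contrast fields, and the image becomes
    ``(I - L) / max(C, epsilon)``.

    A constant input has no contrast to normalize: the output is all zeros
    and the model's ``degenerate`` flag is set.
    """
    img = green_channel(image)
    h, w = img.shape
    if window_px is None:
        window_px = max(8, w // 8)
    if window_px < 8:
        raise ValueError("window_px must be >= 8")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")

    if np.ptp(img) == 0:
        model = NormalizationModel(
            background_luminosity=np.full_like(img, img.flat[0]),
            background_contrast=np.full_like(img, epsilon),
            window_px=window_px,
            epsilon=epsilon,
            degenerate=True,
        )
        return np.zeros_like(img), model

    # tentative background: neither tubular (coarse vesselness outlier) nor
    # an intensity outlier (bright disc / dark fovea).  Both rules are in
    # robust MAD units, so they are equivariant under affine rescaling and
    # pick the same pixels when the output is normalized again.
    resp = _coarse_vessel_response(img)
    r_med = np.median(resp)
    r_mad = 1.4826 * np.median(np.abs(resp - r_med)) + 1e-12
    vessel_like = resp > r_med + 3.0 * r_mad
    i_med = np.median(img)
    i_mad = 1.4826 * np.median(np.abs(img - i_med)) + 1e-12
    outlier = np.abs(img - i_med) > 4.0 * i_mad
    bg = ~(vessel_like | outlier)
    if bg.mean() < 0.2:   # pathological image: fall back to everything
        bg = np.ones_like(img, dtype=bool)

    lum = _tile_field(img, bg, window_px, "median")
    con = _tile_field(img, bg, window_px, "mad")
    con = np.maximum(con, epsilon)
    out = (img - lum) / con
    model = NormalizationModel(
        background_luminosity=lum,
        background_contrast=con,
        window_px=window_px,
        epsilon=epsilon,
        degenerate=bool(np.median(con) <= epsilon),
    )
    if model.degenerate:
        return np.zeros_like(img), model
    return out, model
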
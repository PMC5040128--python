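"""Multiscale Hessian vesselness, thresholding and MCC-based quality.

The vesselness of a pixel at scale ``sigma`` is built from the eigenvalues
of the gamma-normalized Gaussian Hessian (gamma = 2), ordered by magnitude
``lambda1 >= lambda2 >= 0``:

    v = exp(-R_A**2 / (2 alpha**2)) * (1 - exp(-S**2 / (2 beta**2)))

with the anisotropy term ``R_A = lambda2 / lambda1`` and the structure
term ``S = lambda1 + lambda2``.  The response is gated to zero where the
sign of the dominant curvature contradicts the requested polarity (dark
vessels on a bright background curve upward, so the dominant signed
eigenvalue is positive), maximized over scales, and rescaled to [0, 1] by
its own maximum.  An ``original-frangi`` variant with the Frobenius-norm
structure term is available for comparison.

Binary maps are scored against ground truth with the Matthews correlation
coefficient, a class-imbalance-robust measure equal to the Pearson
correlation of the two pixel indicator vectors.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "FrangiParams",
    "HessianEigenfields",
    "VesselProbabilityMap",
    "SegmentationQuality",
    "hessian_eigen",
    "frangi_vesselness",
    "threshold_map",
    "segmentation_quality",
    "threshold_sweep",
]


@dataclass(frozen=True)
class FrangiParams:
    """Scales and sharpness constants of the vesselness filter."""

    scales: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    alpha: float = 0.5
    beta: float = 5.0
    polarity: str = "dark_vessels"
    variant: str = "printed"          # or "original-frangi"

    def __post_init__(self) -> None:
        if len(self.scales) == 0:
            raise ValueError("at least one scale is required")
        if any(b <= a for a, b in zip(self.scales, self.scales[1:])):
            raise ValueError("scales must be strictly increasing")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.polarity not in ("dark_vessels", "bright_vessels"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.variant not in ("printed", "original-frangi"):
            raise ValueError(f"unknown variant {self.variant!r}")

    def provenance(self) -> str:
        payload = repr(self).encode()
        return f"frangi:{hashlib.sha256(payload).hexdigest()[:12]}"


@dataclass
class HessianEigenfields:
    """Magnitude-ordered principal curvatures of the Gaussian Hessian."""

    lambda1: np.ndarray    # dominant magnitude, >= lambda2 >= 0
    lambda2: np.ndarray
    sign1: np.ndarray      # sign of the dominant signed curvature
    sigma: float


@dataclass
class VesselProbabilityMap:
    """Soft segmentation in [0, 1] with a provenance tag."""

    values: np.ndarray
    provenance: str = ""

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclass
class SegmentationQuality:
    """Confusion counts and MCC of a binary map against truth."""

    tp: int
    tn: int
    fp: int
    fn: int
    mcc: float
    threshold: float | None = None
    degenerate: bool = False

    @property
    def n_pixels(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def hessian_eigen(image: np.ndarray, sigma: float) -> HessianEigenfields:
    """Eigen-decomposition of the scale-``sigma`` Gaussian Hessian.

    Second derivatives are gamma-normalized (multiplied by ``sigma**2``) so
    responses are comparable across scales.  Scales below 0.5 px are not
    resolvable on the pixel grid and are rejected.
    """
    if sigma < 0.5:
        raise ValueError("sigma must be >= 0.5 px (unresolvable scale)")
    img = np.asarray(image, dtype=float)
    s2 = sigma ** 2
    hrr = s2 * ndi.gaussian_filter(img, sigma, order=(2, 0))
    hcc = s2 * ndi.gaussian_filter(img, sigma, order=(0, 2))
    hrc = s2 * ndi.gaussian_filter(img, sigma, order=(1, 1))
    mean = 0.5 * (hrr + hcc)
    det_gap = np.sqrt(np.maximum(0.25 * (hrr - hcc) ** 2 + hrc ** 2, 0.0))
    e_hi = mean + det_gap
    e_lo = mean - det_gap
    swap = np.abs(e_lo) > np.abs(e_hi)
    dominant = np.where(swap, e_lo, e_hi)
    minor = np.where(swap, e_hi, e_lo)
    return HessianEigenfields(
        lambda1=np.abs(dominant),
        lambda2=np.abs(minor),
        sign1=np.sign(dominant),
        sigma=sigma,
    )


def frangi_vesselness(image: np.ndarray, params: FrangiParams | None = None) -> VesselProbabilityMap:
    """Multiscale vesselness map, max over scales, rescaled to [0, 1].

    The input should be intensity-normalized first so that ``beta`` has a
    consistent meaning across images; the map is invariant to affine
    intensity rescaling up to the final [0, 1] normalization.
    """
    params = params or FrangiParams()
    img = np.asarray(image, dtype=float)
    want_sign = 1.0 if params.polarity == "dark_vessels" else -1.0
    out = np.zeros_like(img)
    for sigma in params.scales:
        eig = hessian_eigen(img, sigma)
        l1, l2 = eig.lambda1, eig.lambda2
        with np.errstate(divide="ignore", invalid="ignore"):
            ra = np.where(l1 > 0, l2 / np.where(l1 > 0, l1, 1.0), 0.0)
        if params.variant == "printed":
            s = l1 + l2
        else:
            s = np.sqrt(l1 ** 2 + l2 ** 2)
        v = np.exp(-(ra ** 2) / (2.0 * params.alpha ** 2)) * (
            1.0 - np.exp(-(s ** 2) / (2.0 * params.beta ** 2))
        )
        v[eig.sign1 != want_sign] = 0.0
        np.maximum(out, v, out=out)
    vmax = out.max()
    if vmax > 0:
        out /= vmax
    return VesselProbabilityMap(values=out, provenance=params.provenance())


def threshold_map(prob_map: VesselProbabilityMap | np.ndarray, t: float) -> np.ndarray:
    """Binary map: pixel set iff probability >= t.  No post-processing."""
    if not (0.0 <= t <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return np.asarray(prob_map) >= t


def segmentation_quality(
    pred: np.ndarray,
    truth: np.ndarray,
    mask: np.ndarray | None = None,
    *,
    threshold: float | None = None,
) -> SegmentationQuality:
    """Confusion counts and MCC restricted to ``mask``.

    If any factor of the MCC denominator is zero (a constant prediction or
    constant truth) the coefficient is reported as 0 and flagged.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must share a shape")
    if mask is None:
        mask = np.ones_like(pred)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("evaluation mask is empty")
    p = pred[mask]
    t = truth[mask]
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    denom_terms = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if 0 in denom_terms:
        return SegmentationQuality(tp, tn, fp, fn, 0.0, threshold, degenerate=True)
    num = float(tp) * tn - float(fp) * fn
    den = math_sqrt_product(denom_terms)
    return SegmentationQuality(tp, tn, fp, fn, num / den, threshold)


def math_sqrt_product(terms: Sequence[int]) -> float:
    """sqrt of a product of counts; exact when the product is exact.

    Pixel counts keep the integer product well below float overflow, and a
    single correctly-rounded sqrt preserves exact results (MCC of a perfect
    segmentation is exactly 1).
    """
    import math

    prod = 1
    for t in terms:
        prod *= int(t)
    return math.sqrt(prod)


def threshold_sweep(
    prob_map: VesselProbabilityMap | np.ndarray,
    truth: np.ndarray,
    mask: np.ndarray | None = None,
    t_min: float = 0.15,
    t_max: float = 0.35,
    t_step: float = 0.01,
) -> pd.DataFrame:
    """Quality at every threshold in [t_min, t_max] with step t_step.

    Returns one row per threshold, ordered by t, with columns
    ``t, TP, TN, FP, FN, MCC``.  The canonical sweep 0.15-0.35 at step
    0.01 yields 21 rows.
    """
    if not (t_min < t_max) or t_step <= 0:
        raise ValueError("need t_min < t_max and t_step > 0")
    n = int(round((t_max - t_min) / t_step))
    ts = t_min + t_step * np.arange(n + 1)
    ts = ts[ts <= t_max + 1e-12]
    rows = []
    values = np.asarray(prob_map)
    for t in ts:
        q = segmentation_quality(values >= t, truth, mask, threshold=float(t))
        rows.append(
            {"t": round(float(t), 10), "TP": q.tp, "TN": q.tn, "FP": q.fp,
             "FN": q.fn, "MCC": q.mcc}
        )
    return pd.DataFrame(rows)
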
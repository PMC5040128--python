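"""Analytic fractal fixtures and seeded retinal vascular phantoms.

Two families of test substrate:

* **Analytic fractals** — dyadic subdivision sets (Sierpinski triangle,
  random dust), the Koch curve, and degenerate cases (line, filled square,
  single point) whose Hausdorff dimension is known in closed form.  The
  subdivision sets are built by exact recursion on power-of-two grids, so
  their box counts at dyadic scales are combinatorial, not approximate:
  a depth-``d`` Sierpinski triangle occupies exactly ``3**d`` unit cells
  and ``3**(d-j)`` boxes of side ``2**j``.

* **Vascular phantoms** — a branching tree grown from the optic-disc rim
  by recursive bifurcation (Murray-style caliber decay), rasterized
  dark-on-bright inside a circular field of view, with an optic disc, a
  fovea at ~5x the disc radius, illumination drift and sensor noise.
  Companion operators emulate a human observer who misses the thinnest
  vessels, soft (probability-map) segmentation outputs, and repeated
  acquisitions on cameras differing in resolution, contrast, gamma, noise
  and pointing jitter.

Every generator is a pure function of its spec and seed: identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.transform import resize

from .roi import ODGeometry

__all__ = [
    "FRACTAL_KINDS",
    "analytic_dimension",
    "make_analytic_fractal",
    "PhantomSpec",
    "PhantomBundle",
    "CameraProfile",
    "make_vascular_phantom",
    "emulate_observer",
    "render_probability_map",
    "emulate_camera",
    "save_bundle",
]

FRACTAL_KINDS = (
    "line",
    "filled_square",
    "single_point",
    "sierpinski_triangle",
    "koch_curve",
    "random_dust",
)


def analytic_dimension(kind: str, *, keep: int = 3) -> float:
    """Hausdorff dimension of the limit set of each construction."""
    if kind == "line":
        return 1.0
    if kind == "filled_square":
        return 2.0
    if kind == "single_point":
        return 0.0
    if kind == "sierpinski_triangle":
        return math.log(3) / math.log(2)
    if kind == "koch_curve":
        return math.log(4) / math.log(3)
    if kind == "random_dust":
        return math.log(keep) / math.log(2)
    raise ValueError(f"unknown fractal kind {kind!r}")


def _check_dyadic(kind: str, depth: int, grid_size: int) -> int:
    m = int(round(math.log2(grid_size)))
    if 2 ** m != grid_size:
        raise ValueError("grid_size must be a power of 2")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if depth > m:
        raise ValueError(
            f"depth {depth} too large for grid_size {grid_size}; maximum feasible depth is {m}"
        )
    return m


def _koch_points(depth: int) -> np.ndarray:
    """Vertices of the Koch curve after ``depth`` subdivisions, in [0,1]x[0,~0.29]."""
    pts = np.array([0.0 + 0.0j, 1.0 + 0.0j])
    rot = np.exp(1j * math.pi / 3)
    for _ in range(depth):
        new = []
        for a, b in zip(pts[:-1], pts[1:]):
            d = (b - a) / 3.0
            p1, p2 = a + d, a + 2 * d
            peak = p1 + d * rot
            new.extend([a, p1, peak, p2])
        new.append(pts[-1])
        pts = np.array(new)
    return pts


def make_analytic_fractal(
    kind: str,
    depth: int = 0,
    grid_size: int = 256,
    *,
    keep: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Deterministic boolean raster of a known-dimension set.

    ``depth`` is the iteration count for the subdivision constructions and
    the Koch curve; ``keep`` is the number of quadrants retained per level
    of the random dust (dimension ``log(keep)/log 2``); ``seed`` only
    affects ``random_dust``.
    """
    if kind not in FRACTAL_KINDS:
        raise ValueError(f"unknown fractal kind {kind!r}; expected one of {FRACTAL_KINDS}")
    g = int(grid_size)

    if kind == "line":
        mask = np.zeros((g, g), dtype=bool)
        mask[g // 2, :] = True
        return mask
    if kind == "filled_square":
        return np.ones((g, g), dtype=bool)
    if kind == "single_point":
        mask = np.zeros((g, g), dtype=bool)
        mask[g // 2, g // 2] = True
        return mask

    if kind == "koch_curve":
        pts = _koch_points(depth)
        margin = 2
        scale = g - 1 - 2 * margin
        cols = margin + pts.real * scale
        rows = g // 2 + pts.imag * scale  # curve bulges upward in row direction
        mask = np.zeros((g, g), dtype=bool)
        for i in range(len(pts) - 1):
            rr, cc = draw_line(
                int(round(rows[i])), int(round(cols[i])),
                int(round(rows[i + 1])), int(round(cols[i + 1])),
            )
            ok = (rr >= 0) & (rr < g) & (cc >= 0) & (cc < g)
            mask[rr[ok], cc[ok]] = True
        return mask

    _check_dyadic(kind, depth, g)
    if kind == "sierpinski_triangle":
        cell = np.ones((1, 1), dtype=bool)
        pattern = np.array([[True, False], [True, True]])
        for _ in range(depth):
            cell = np.kron(pattern, cell)
    else:  # random_dust
        if not (1 <= keep <= 4):
            raise ValueError("keep must be in 1..4")
        rng = np.random.default_rng(seed)
        cell = np.ones((1, 1), dtype=bool)
        for _ in range(depth):
            n = cell.shape[0]
            new = np.zeros((2 * n, 2 * n), dtype=bool)
            occupied = np.argwhere(cell)
            # choose `keep` of 4 sub-quadrants independently per occupied cell
            for r, c in occupied:
                chosen = rng.choice(4, size=keep, replace=False)
                for q in chosen:
                    dr, dc = divmod(int(q), 2)
                    new[2 * r + dr, 2 * c + dc] = True
            cell = new
    block = g // cell.shape[0]
    if block > 1:
        cell = np.kron(cell, np.ones((block, block), dtype=bool))
    return cell


# ---------------------------------------------------------------------------
# Vascular phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Growth and rendering parameters of one seeded retinal phantom.

    The fovea sits at the image centre with the optic disc offset by
    5x ``od_radius`` — the canonical fovea-to-disc distance.  Tree growth
    starts from ``n_roots`` trunks on the disc rim; at each bifurcation the
    child caliber follows a Murray-style decay ``width_decay ~= 2**(-1/3)``
    and segment length shrinks by ``length_decay``, down to twigs of
    ``min_width_px``.
    """

    seed: int = 0
    image_size: int = 512
    od_center: tuple[float, float] = (256.0, 76.0)
    fovea_center: tuple[float, float] = (256.0, 256.0)
    od_radius: float = 36.0
    n_roots: int = 8
    branch_prob: float = 0.6
    branch_prob_decay: float = 0.85   # bifurcations concentrate peripapillary
    angle_jitter_deg: float = 18.0
    length_decay: float = 1.05        # arcs elongate as they run peripherally
    width_decay: float = 0.794        # 2**(-1/3), Murray bifurcation baseline
    bifurcation_asymmetry: float = 0.5  # flow-split range: f in 0.5 +/- asym/2
    continuation_taper: float = 0.93  # slow taper between branch events
    min_width_px: float = 1.0
    trunk_width_px: float = 6.0
    trunk_length_px: float = 40.0
    max_depth: int = 10
    side_twig_prob: float = 0.06      # per-step chance of a 1-px side twig
    n_peripapillary: int = 20         # short radial stub vessels at the disc rim
    subject_variability: float = 0.3  # per-phantom global density modulation
    fovea_avoid_rel: float = 1.5      # macular avascular zone, in ODr units
    illumination_gradient_strength: float = 0.08
    noise_sigma: float = 0.02

    def __post_init__(self) -> None:
        if self.min_width_px < 1.0:
            raise ValueError("min_width_px must be >= 1; sub-pixel vessels are not representable")
        d = math.hypot(
            self.od_center[0] - self.fovea_center[0],
            self.od_center[1] - self.fovea_center[1],
        )
        target = 5.0 * self.od_radius
        if not (0.95 * target <= d <= 1.05 * target):
            raise ValueError(
                f"fovea-to-disc distance {d:.1f} px must equal 5 x od_radius "
                f"({target:.1f} px) within 5%"
            )


@dataclass
class PhantomBundle:
    """One phantom: rendered image plus every piece of ground truth."""

    image: np.ndarray                 # (H, W, 3) float in [0, 1]
    truth_vessels: np.ndarray         # (H, W) bool
    od_geometry: ODGeometry
    fovea_center: tuple[float, float]
    fov_mask: np.ndarray              # (H, W) bool
    spec: PhantomSpec

    def __post_init__(self) -> None:
        shapes = {self.image.shape[:2], self.truth_vessels.shape, self.fov_mask.shape}
        if len(shapes) != 1:
            raise ValueError("all rasters in a bundle must share a shape")
        if np.any(self.truth_vessels & ~self.fov_mask):
            raise ValueError("truth vessels must lie inside the field-of-view mask")


@dataclass(frozen=True)
class CameraProfile:
    """A fundus camera's resolution / contrast / noise signature."""

    name: str
    resolution_scale: float = 1.0
    contrast_gain: float = 1.0
    gamma: float = 1.0
    noise_sigma: float = 0.0
    acquisition_jitter_px: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.resolution_scale <= 2.0):
            raise ValueError("resolution_scale must lie in (0, 2]")
        if self.contrast_gain <= 0 or self.gamma <= 0:
            raise ValueError("contrast_gain and gamma must be positive")
        if self.noise_sigma < 0 or self.acquisition_jitter_px < 0:
            raise ValueError("noise_sigma and acquisition_jitter_px must be >= 0")

    @property
    def is_neutral(self) -> bool:
        return (
            self.resolution_scale == 1.0
            and self.contrast_gain == 1.0
            and self.gamma == 1.0
            and self.noise_sigma == 0.0
            and self.acquisition_jitter_px == 0.0
        )


def _stamp_disk(mask: np.ndarray, r: float, c: float, radius: float) -> None:
    rr, cc = draw_disk((r, c), max(radius, 0.9), shape=mask.shape)
    mask[rr, cc] = True


def _grow_tree(spec: PhantomSpec, fov_center, fov_radius, rng,
               branch_prob: float, side_prob: float) -> np.ndarray:
    """Rasterize the branching tree as a boolean map (capsule-chain strokes).

    Branches either bifurcate (probability ``branch_prob *
    branch_prob_decay**depth``, so bifurcations cluster near the disc) or
    continue as a single tapering vessel; either way the child caliber
    shrinks by ``width_decay`` until ``min_width_px``.  Inside the macular
    zone the heading is steered away from the fovea, producing the
    avascular centre and arcing arcades of a real fundus.
    """
    g = spec.image_size
    truth = np.zeros((g, g), dtype=bool)
    jitter = math.radians(spec.angle_jitter_deg)

    # roots spread on the disc rim, biased toward the retina (away from the edge)
    to_fovea = math.atan2(
        spec.fovea_center[0] - spec.od_center[0],
        spec.fovea_center[1] - spec.od_center[1],
    )
    stack = []
    for i in range(spec.n_roots):
        frac = (i + 0.5) / spec.n_roots
        theta = to_fovea + (frac - 0.5) * 2.0 * math.pi * 0.95 + 0.15 * rng.normal()
        # trunks emerge at the nerve head centre and cross the disc surface
        pos = (
            spec.od_center[0] + 0.15 * spec.od_radius * math.sin(theta),
            spec.od_center[1] + 0.15 * spec.od_radius * math.cos(theta),
        )
        width = spec.trunk_width_px * rng.uniform(0.85, 1.15)
        length = spec.od_radius + spec.trunk_length_px * rng.uniform(0.8, 1.2)
        stack.append((pos, theta, length, width, 0))

    avoid_r = spec.fovea_avoid_rel * spec.od_radius
    steer_range = 2.0 * avoid_r
    while stack:
        (r, c), theta, length, width, depth = stack.pop()
        step = 2.0
        n_steps = max(2, int(round(length / step)))
        alive = True
        for _ in range(n_steps):
            theta += 0.35 * jitter * rng.normal()
            # vessels arc around the macula: steer away inside the avascular zone
            d_fov = math.hypot(r - spec.fovea_center[0], c - spec.fovea_center[1])
            if d_fov < steer_range:
                away = math.atan2(r - spec.fovea_center[0], c - spec.fovea_center[1])
                diff = (away - theta + math.pi) % (2.0 * math.pi) - math.pi
                theta += 0.45 * max(0.0, 1.0 - d_fov / steer_range) * diff
            r += step * math.sin(theta)
            c += step * math.cos(theta)
            if math.hypot(r - fov_center[0], c - fov_center[1]) > fov_radius - 1:
                alive = False
                break
            _stamp_disk(truth, r, c, width / 2.0)
            # fine side twigs leave thicker vessels along their whole course
            if width >= 2.5 and rng.random() < side_prob:
                side = theta + rng.choice([-1.0, 1.0]) * math.radians(rng.uniform(55, 100))
                tr, tc = r, c
                for _ in range(int(rng.uniform(3, 10))):
                    side += 0.3 * jitter * rng.normal()
                    tr += step * math.sin(side)
                    tc += step * math.cos(side)
                    if math.hypot(tr - fov_center[0], tc - fov_center[1]) > fov_radius - 1:
                        break
                    _stamp_disk(truth, tr, tc, 0.55)
        if not alive or depth >= spec.max_depth:
            continue
        child_len = length * spec.length_decay * rng.uniform(0.85, 1.15)
        if rng.random() < branch_prob * spec.branch_prob_decay ** depth:
            # asymmetric Murray split: flow fraction f to one child,
            # widths w * width_decay * (2f)^(1/3) so f = 1/2 reduces to the
            # symmetric 2^(-1/3) rule
            f = 0.5 + spec.bifurcation_asymmetry * (rng.random() - 0.5)
            split = math.radians(22.0 + 8.0 * rng.random())
            for sgn, frac in ((-1.0, f), (1.0, 1.0 - f)):
                child_w = width * spec.width_decay * (2.0 * frac) ** (1.0 / 3.0)
                if child_w < spec.min_width_px:
                    continue
                stack.append(
                    (
                        (r, c),
                        theta + sgn * split + 0.5 * jitter * rng.normal(),
                        child_len,
                        child_w,
                        depth + 1,
                    )
                )
        else:
            child_w = width * spec.continuation_taper
            if child_w >= spec.min_width_px:
                stack.append(((r, c), theta, child_len, child_w, depth + 1))
    return truth


def _stamp_peripapillary(spec: PhantomSpec, truth, fov_center, fov_radius,
                         rng, n_stubs: int) -> None:
    """Short radial stub vessels leaving the disc rim (peripapillary bundle)."""
    for _ in range(n_stubs):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        r = spec.od_center[0] + spec.od_radius * math.sin(theta)
        c = spec.od_center[1] + spec.od_radius * math.cos(theta)
        heading = theta + rng.normal(0.0, 0.4)
        curvature = 0.01 * rng.normal()
        width = rng.uniform(1.2, max(2.6, 0.10 * spec.od_radius))
        length = spec.od_radius * rng.uniform(0.4, 1.2)
        for s in np.arange(0.0, length, 1.5):
            rr = r + s * math.sin(heading + curvature * s)
            cc = c + s * math.cos(heading + curvature * s)
            if math.hypot(rr - fov_center[0], cc - fov_center[1]) > fov_radius - 1:
                break
            _stamp_disk(truth, rr, cc, width / 2.0)


def make_vascular_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Grow, rasterize and render one phantom; pure function of ``spec``."""
    g = spec.image_size
    base = int(spec.seed) & 0x7FFFFFFF
    rng_subject = np.random.default_rng([base, 0])
    rng_tree = np.random.default_rng([base, 1])
    rng_stub = np.random.default_rng([base, 2])
    rng_noise = np.random.default_rng([base, 3])
    fov_center = ((g - 1) / 2.0, (g - 1) / 2.0)
    fov_radius = 0.48 * g

    rr, cc = np.ogrid[:g, :g]
    dist_fov = np.hypot(rr - fov_center[0], cc - fov_center[1])
    fov_mask = dist_fov <= fov_radius

    # subjects differ in overall vascular density, coherently across the image
    sv = spec.subject_variability
    branch_prob = min(1.0, spec.branch_prob * rng_subject.uniform(1 - sv, 1 + sv))
    n_stubs = (0 if spec.n_peripapillary == 0 else
               max(4, int(round(spec.n_peripapillary * rng_subject.uniform(1 - sv, 1 + sv)))))
    width_factor = rng_subject.uniform(1 - sv, 1 + sv)
    grow_spec = replace(spec, trunk_width_px=spec.trunk_width_px * width_factor)

    side_prob = spec.side_twig_prob * rng_subject.uniform(1 - sv, 1 + sv)
    truth = _grow_tree(grow_spec, fov_center, fov_radius, rng_tree, branch_prob,
                       side_prob)
    _stamp_peripapillary(spec, truth, fov_center, fov_radius, rng_stub, n_stubs)
    truth &= fov_mask

    # --- render dark-on-bright colour image -------------------------------
    soft = ndi.gaussian_filter(truth.astype(float), 0.7)
    if soft.max() > 0:
        soft /= soft.max()
    grad = spec.illumination_gradient_strength * (cc - fov_center[1]) / g
    vignette = -0.06 * (dist_fov / fov_radius) ** 2
    base = 1.0 + grad + vignette

    d_od = np.hypot(rr - spec.od_center[0], cc - spec.od_center[1])
    od_prof = 1.0 / (1.0 + np.exp((d_od - spec.od_radius) / 1.2))
    d_fv = np.hypot(rr - spec.fovea_center[0], cc - spec.fovea_center[1])
    fovea_prof = np.exp(-(d_fv ** 2) / (2.0 * (0.6 * spec.od_radius) ** 2))

    chan = {
        "r": 0.72 * base + 0.20 * od_prof - 0.12 * soft - 0.12 * fovea_prof,
        "g": 0.46 * base + 0.30 * od_prof - 0.30 * soft - 0.18 * fovea_prof,
        "b": 0.18 * base + 0.04 * od_prof - 0.04 * soft - 0.03 * fovea_prof,
    }
    image = np.stack([chan["r"], chan["g"], chan["b"]], axis=-1)
    if spec.noise_sigma > 0:
        image = image + rng_noise.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    image[~fov_mask] = 0.0

    od_geom = ODGeometry(
        center=spec.od_center,
        major_radius=spec.od_radius,
        minor_radius=spec.od_radius,
        fit_residual=0.0,
    )
    return PhantomBundle(
        image=image,
        truth_vessels=truth,
        od_geometry=od_geom,
        fovea_center=spec.fovea_center,
        fov_mask=fov_mask,
        spec=spec,
    )


def emulate_observer(truth: np.ndarray, min_caliber_px: float) -> np.ndarray:
    """Drop every vessel segment thinner than ``min_caliber_px``.

    Local caliber is read off the Euclidean distance transform: a pixel at
    distance ``d`` from the background sits in a vessel of caliber about
    ``2 d - 1`` pixels.  Pixels of caliber >= the threshold form the core;
    the surviving map is the union of each core pixel's maximal inscribed
    disc, clipped to the input — so thick vessels keep their full width
    while thin twigs vanish.  Monotone: a larger threshold yields a subset.
    """
    truth = np.asarray(truth, dtype=bool)
    if min_caliber_px < 0:
        raise ValueError("min_caliber_px must be >= 0")
    if min_caliber_px == 0 or not truth.any():
        return truth.copy()
    edt = ndi.distance_transform_edt(truth)
    core = (2.0 * edt - 1.0) >= min_caliber_px
    out = np.zeros_like(truth)
    if not core.any():
        return out
    radii = np.ceil(edt).astype(int)
    for r in np.unique(radii[core]):
        layer = core & (radii == r)
        st = np.hypot(*np.ogrid[-r:r + 1, -r:r + 1]) <= r
        out |= ndi.binary_dilation(layer, structure=st)
    return out & truth


def render_probability_map(
    truth: np.ndarray,
    blur_sigma: float,
    noise_sigma: float,
    seed: int = 0,
) -> np.ndarray:
    """Soft segmentation output: blurred, noisy truth clipped to [0, 1].

    With both sigmas zero the map equals the truth cast to {0, 1}.
    """
    if blur_sigma < 0 or noise_sigma < 0:
        raise ValueError("blur_sigma and noise_sigma must be >= 0")
    p = np.asarray(truth, dtype=float)
    if blur_sigma > 0:
        p = ndi.gaussian_filter(p, blur_sigma)
        if p.max() > 0:
            p = p / p.max()
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        p = p + rng.normal(0.0, noise_sigma, size=p.shape)
    return np.clip(p, 0.0, 1.0)


def _resample_bundle(bundle: PhantomBundle, scale: float) -> PhantomBundle:
    g = bundle.image.shape[0]
    new_g = max(8, int(round(g * scale)))
    eff = new_g / g
    image = resize(bundle.image, (new_g, new_g, 3), order=1, anti_aliasing=scale < 1,
                   preserve_range=True)
    truth = resize(bundle.truth_vessels.astype(float), (new_g, new_g), order=0,
                   anti_aliasing=False, preserve_range=True) > 0.5
    fov = resize(bundle.fov_mask.astype(float), (new_g, new_g), order=0,
                 anti_aliasing=False, preserve_range=True) > 0.5
    truth &= fov
    od = bundle.od_geometry
    geom = ODGeometry(
        center=(od.center[0] * eff, od.center[1] * eff),
        major_radius=od.major_radius * eff,
        minor_radius=od.minor_radius * eff,
        fit_residual=od.fit_residual,
    )
    fovea = (bundle.fovea_center[0] * eff, bundle.fovea_center[1] * eff)
    return PhantomBundle(np.clip(image, 0, 1), truth, geom, fovea, fov, bundle.spec)


def _shift_geometry(bundle: PhantomBundle, dr: int, dc: int) -> PhantomBundle:
    def sh(a, order):
        return ndi.shift(a.astype(float), (dr, dc) if a.ndim == 2 else (dr, dc, 0),
                         order=order, mode="constant", cval=0.0)

    image = np.clip(sh(bundle.image, 1), 0, 1)
    truth = sh(bundle.truth_vessels, 0) > 0.5
    fov = sh(bundle.fov_mask, 0) > 0.5
    od = bundle.od_geometry
    geom = ODGeometry(
        center=(od.center[0] + dr, od.center[1] + dc),
        major_radius=od.major_radius,
        minor_radius=od.minor_radius,
        fit_residual=od.fit_residual,
    )
    fovea = (bundle.fovea_center[0] + dr, bundle.fovea_center[1] + dc)
    return PhantomBundle(image, truth & fov, geom, fovea, fov, bundle.spec)


def emulate_camera(
    bundle: PhantomBundle,
    profile: CameraProfile,
    acquisition_index: int = 1,
) -> PhantomBundle:
    """One acquisition of the phantom through a camera profile.

    Resamples by ``resolution_scale`` (truth and geometry consistently),
    applies contrast gain and gamma, then a per-acquisition integer
    pointing jitter and sensor noise.  The same
    ``(bundle seed, profile, acquisition_index)`` always reproduces the
    same acquisition.
    """
    if acquisition_index < 1:
        raise ValueError("acquisition_index must be >= 1")
    if profile.is_neutral:
        return PhantomBundle(
            bundle.image.copy(), bundle.truth_vessels.copy(), bundle.od_geometry,
            bundle.fovea_center, bundle.fov_mask.copy(), bundle.spec,
        )
    out = bundle
    if profile.resolution_scale != 1.0:
        out = _resample_bundle(out, profile.resolution_scale)

    image = out.image
    if profile.contrast_gain != 1.0:
        image = 0.5 + (image - 0.5) * profile.contrast_gain
    if profile.gamma != 1.0:
        image = np.clip(image, 0.0, 1.0) ** profile.gamma
    image = np.clip(image, 0.0, 1.0)
    out = PhantomBundle(image, out.truth_vessels, out.od_geometry,
                        out.fovea_center, out.fov_mask, out.spec)

    rng = np.random.default_rng(
        [bundle.spec.seed & 0x7FFFFFFF, zlib.crc32(profile.name.encode()) & 0x7FFFFFFF,
         int(acquisition_index)]
    )
    if profile.acquisition_jitter_px > 0:
        j = int(math.floor(profile.acquisition_jitter_px))
        dr = int(rng.integers(-j, j + 1))
        dc = int(rng.integers(-j, j + 1))
        if dr or dc:
            out = _shift_geometry(out, dr, dc)
    if profile.noise_sigma > 0:
        image = np.clip(
            out.image + rng.normal(0.0, profile.noise_sigma, size=out.image.shape),
            0.0, 1.0,
        )
        out = PhantomBundle(image, out.truth_vessels, out.od_geometry,
                            out.fovea_center, out.fov_mask, out.spec)
    return out


def save_bundle(bundle: PhantomBundle, outdir: str | Path, *, stem: str = "phantom") -> dict:
    """Write image (8-bit PNG), truth mask (PNG) and a JSON sidecar."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img_path = outdir / f"{stem}_image.png"
    mask_path = outdir / f"{stem}_truth.png"
    iio.imwrite(img_path, (bundle.image * 255).round().astype(np.uint8))
    iio.imwrite(mask_path, (bundle.truth_vessels.astype(np.uint8) * 255))
    sidecar = {
        "spec": asdict(bundle.spec),
        "od_geometry": {
            "center": list(bundle.od_geometry.center),
            "major_radius": bundle.od_geometry.major_radius,
            "minor_radius": bundle.od_geometry.minor_radius,
        },
        "fovea_center": list(bundle.fovea_center),
        "files": {"image": img_path.name, "truth": mask_path.name},
    }
    with open(outdir / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return sidecar
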
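"""Seeded generator of leaf-like test images and optimizer benchmark objectives.

``make_leaf`` emulates the structure of a rice-leaf disease photograph at
desk scale: a bright background, a darker elliptical leaf, and a handful of
still darker elliptical lesion blobs inside the leaf, each region with its
own intensity level, optionally degraded by Gaussian noise, Gaussian blur
and a brightness rescale (the perturbation conditions used for robustness
studies).  The exact pre-noise label mask (0 background, 1 leaf, 2 lesion)
is returned alongside the image, so generated fixtures carry their own
ground truth.  A fixed seed reproduces the output bit for bit.

``benchmark_objective`` supplies the standard closed-form test functions
(sphere, Rastrigin, Rosenbrock) with their conventional box bounds for
exercising the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

__all__ = ["LeafSpec", "make_leaf", "Benchmark", "benchmark_objective"]


@dataclass(frozen=True)
class LeafSpec:
    """Generation parameters for one synthetic leaf image.

    Intensity levels are 8-bit values and must be pairwise separated by at
    least 20 levels so that the regions are in principle distinguishable.
    ``noise_sigma`` is the Gaussian noise standard deviation in intensity
    levels (the normalized-scale 0.01 of camera-noise studies corresponds
    to 2.55 levels); ``blur_kernel`` an odd Gaussian kernel size in pixels
    (0 disables blur); ``brightness`` a multiplicative factor (0.6 emulates
    a 40% brightness reduction, i.e. low light).
    """

    side: int = 380
    background_level: int = 220
    leaf_level: int = 120
    lesion_level: int = 60
    n_lesions: int = 3
    lesion_radius: tuple[float, float] | None = None  # defaults to (side/32, side/13)
    noise_sigma: float = 5.0
    blur_kernel: int = 0
    brightness: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        levels = (self.background_level, self.leaf_level, self.lesion_level)
        if any(not 0 <= v <= 255 for v in levels):
            raise ValueError("intensity levels must lie in [0, 255]")
        pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
        if any(abs(a - b) < 20 for a, b in pairs):
            raise ValueError("intensity levels must be pairwise separated by >= 20")
        if self.lesion_radius is None:
            # lesion size scales with the frame: ~3-8% of the side
            object.__setattr__(
                self, "lesion_radius", (self.side / 32.0, self.side / 13.0)
            )
        lo, hi = self.lesion_radius
        if not 0 < lo <= hi < self.side / 4:
            raise ValueError("lesion radii must satisfy 0 < lo <= hi < side/4")
        if self.blur_kernel and (self.blur_kernel < 0 or self.blur_kernel % 2 == 0):
            raise ValueError("blur_kernel must be odd or 0")
        if self.side < 16:
            raise ValueError("side must be at least 16 pixels")
        if self.noise_sigma < 0 or self.brightness <= 0:
            raise ValueError("noise_sigma must be >= 0 and brightness > 0")


def _gaussian_blur(img: np.ndarray, k: int) -> np.ndarray:
    """Separable Gaussian blur with an explicit k-tap kernel, sigma = (k-1)/4."""
    sigma = (k - 1) / 4.0
    offsets = np.arange(k) - (k - 1) / 2.0
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    kernel /= kernel.sum()
    out = ndimage.convolve1d(img, kernel, axis=0, mode="nearest")
    return ndimage.convolve1d(out, kernel, axis=1, mode="nearest")


def make_leaf(spec: LeafSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Render one leaf image and its exact label mask.

    The leaf is a centered ellipse with semi-axes (0.40, 0.27) x side;
    lesions are non-overlapping ellipses with semi-axes drawn from
    ``lesion_radius``, placed uniformly inside a 75%-scaled inner ellipse
    and required to lie entirely within the leaf.  Degradations are applied
    in the order noise -> blur -> brightness, then the image is clamped to
    [0, 255] and rounded to uint8.  The mask reflects the noise-free
    geometry.  Raises if the lesions cannot be placed in 1000 attempts.
    """
    spec = spec or LeafSpec()
    rng = np.random.default_rng(spec.seed)
    side = spec.side
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    cy = cx = (side - 1) / 2.0
    a, b = 0.40 * side, 0.27 * side  # semi-axes along cols, rows

    mask = np.zeros((side, side), dtype=np.uint8)
    leaf = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    mask[leaf] = 1

    placed: list[tuple[float, float, float, float]] = []
    attempts = 0
    while len(placed) < spec.n_lesions:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError(
                f"could not place {spec.n_lesions} non-overlapping lesions "
                f"in 1000 attempts (radii {spec.lesion_radius}, side {side})"
            )
        ra = rng.uniform(*spec.lesion_radius)
        rb = rng.uniform(*spec.lesion_radius)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        rho = np.sqrt(rng.uniform())
        lx = cx + 0.75 * a * rho * np.cos(theta)
        ly = cy + 0.75 * b * rho * np.sin(theta)
        if a <= ra or b <= rb:
            continue
        if ((lx - cx) / (a - ra)) ** 2 + ((ly - cy) / (b - rb)) ** 2 > 1.0:
            continue  # lesion would poke out of the leaf
        if any(
            ((lx - px) / (ra + pa)) ** 2 + ((ly - py) / (rb + pb)) ** 2 < 1.0
            for px, py, pa, pb in placed
        ):
            continue  # overlaps an earlier lesion
        blob = ((xx - lx) / ra) ** 2 + ((yy - ly) / rb) ** 2 <= 1.0
        mask[blob & leaf] = 2  # clip to the leaf raster at the boundary
        placed.append((lx, ly, ra, rb))

    levels = np.array(
        [spec.background_level, spec.leaf_level, spec.lesion_level], dtype=float
    )
    img = levels[mask]
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    if spec.blur_kernel:
        img = _gaussian_blur(img, spec.blur_kernel)
    img = img * spec.brightness
    return np.clip(np.round(img), 0, 255).astype(np.uint8), mask


@dataclass(frozen=True)
class Benchmark:
    """A benchmark objective with its conventional box bounds and optimum."""

    name: str
    fn: Callable[[np.ndarray], float]
    lb: float
    ub: float
    x_opt: np.ndarray
    f_opt: float = 0.0

    def __call__(self, x: np.ndarray) -> float:
        return self.fn(x)


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(np.square(x)))


def _rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def _rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


_BENCHMARKS = {
    "sphere": (_sphere, -5.12, 5.12, 0.0),
    "rastrigin": (_rastrigin, -5.12, 5.12, 0.0),
    "rosenbrock": (_rosenbrock, -2.048, 2.048, 1.0),
}


def benchmark_objective(name: str, dim: int) -> Benchmark:
    """Standard test function with conventional bounds; minimum value 0."""
    if dim < 1:
        raise ValueError("dim must be at least 1")
    try:
        fn, lb, ub, opt_coord = _BENCHMARKS[name]
    except KeyError:
        raise ValueError(
            f"unknown objective {name!r}; choose from {sorted(_BENCHMARKS)}"
        ) from None
    return Benchmark(
        name=name, fn=fn, lb=lb, ub=ub, x_opt=np.full(dim, opt_coord)
    )
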
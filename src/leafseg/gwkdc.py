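"""Gravity-weighted kernelized density clustering (GWKDC) segmentation.

The method segments a grayscale leaf photograph in four stages:

1. fit a low-degree polynomial to the 256-bin intensity histogram by least
   squares (the polynomial smooths the spiky histogram so that its modes
   become detectable);
2. locate histogram peaks as roots of the fitted polynomial's first
   derivative that satisfy the second-derivative (concavity) condition;
3. seed one cluster per peak and iteratively assign every pixel to the
   center of maximal *gravity kernel similarity*

       G(p, q) = exp(-d_space(p, q)^2 / B1) * exp(-(I_p - I_q)^2 / B2),

   a product of a spatial Gaussian kernel (bandwidth B1, squared pixels) and
   an intensity Gaussian kernel (bandwidth B2, squared levels), recomputing
   spatial centroids and mean intensities until assignments stabilize;
4. merge near-duplicate clusters and flag the cluster whose mean intensity
   is farthest from the histogram mode as the lesion.

Coordinates are row-major, 0-based ``(row, col)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .image_io import Histogram, _validate_gray, histogram

__all__ = [
    "PolynomialFit",
    "PeakSet",
    "ClusterModel",
    "SegmentationResult",
    "fit_histogram_polynomial",
    "find_peaks",
    "gravity_distance",
    "cluster",
    "segment",
]

#: Internal rescaling of the intensity axis for conditioning of the fit.
_SCALE = 255.0


@dataclass(frozen=True)
class PolynomialFit:
    """Least-squares polynomial fit y(r) to histogram counts.

    ``coeffs`` are on the rescaled axis t = r / scale (ascending powers);
    ``sse`` is the residual sum of squares of the fit over the 256 points.
    """

    coeffs: np.ndarray
    degree: int
    sse: float
    scale: float = _SCALE

    @property
    def coeffs_unscaled(self) -> np.ndarray:
        """Coefficients on the raw intensity axis r (ascending powers)."""
        powers = np.arange(self.degree + 1)
        return np.asarray(self.coeffs) / self.scale ** powers

    def __call__(self, r: np.ndarray | float) -> np.ndarray | float:
        return np.polynomial.Polynomial(self.coeffs)(np.asarray(r) / self.scale)


@dataclass(frozen=True)
class PeakSet:
    """Validated histogram peaks: intensity locations (ascending, may be empty)."""

    locations: np.ndarray

    def __post_init__(self) -> None:
        loc = np.sort(np.atleast_1d(np.asarray(self.locations, dtype=float)))
        if loc.size and (loc.min() < 0 or loc.max() > 255):
            raise ValueError("peak locations must lie in [0, 255]")
        object.__setattr__(self, "locations", loc)

    def __len__(self) -> int:
        return len(self.locations)

    def __iter__(self):
        return iter(self.locations)


@dataclass
class ClusterModel:
    """Kernel bandwidths, merge thresholds and (after clustering) centers.

    b1 : squared-pixel spatial bandwidth of the gravity kernel.
    b2 : squared-intensity bandwidth.
    merge_tau_space : centroid-distance merge threshold as a fraction of the
        image diagonal.
    merge_tau_int : mean-intensity merge threshold in levels.
    centers : (K, 3) array of (row centroid, col centroid, mean intensity),
        populated by :func:`cluster`.
    """

    b1: float
    b2: float
    merge_tau_space: float = 0.05
    merge_tau_int: float = 10.0
    centers: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.b1 <= 0 or self.b2 <= 0:
            raise ValueError("bandwidths b1 and b2 must be positive")


@dataclass(frozen=True)
class SegmentationResult:
    """Per-pixel labels (contiguous from 0), the fitted model, and the lesion label."""

    mask: np.ndarray
    model: ClusterModel
    lesion_label: int

    @property
    def lesion_mask(self) -> np.ndarray:
        """Binary 0/1 mask of the cluster flagged as diseased."""
        return (self.mask == self.lesion_label).astype(np.uint8)


def fit_histogram_polynomial(hist: Histogram, n: int) -> PolynomialFit:
    """Fit y = p0 + p1 r + ... + pn r^n to the 256 points (k, m_k) by least squares.

    The intensity axis is rescaled to [0, 1] internally so the normal
    equations stay well conditioned; coefficients are reported on the
    rescaled axis with the scale recorded (``coeffs_unscaled`` undoes it).
    """
    if not 2 <= n <= 12:
        raise ValueError(f"polynomial degree must be in [2, 12], got {n}")
    t = np.arange(256, dtype=np.float64) / _SCALE
    y = hist.counts.astype(np.float64)
    design = np.vander(t, n + 1, increasing=True)
    coeffs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < n + 1:
        raise np.linalg.LinAlgError(f"rank-deficient normal equations for degree {n}")
    resid = y - design @ coeffs
    return PolynomialFit(coeffs=coeffs, degree=n, sse=float(resid @ resid))


def find_peaks(fit: PolynomialFit, n_grid: int = 4096, tol: float = 1e-9) -> PeakSet:
    """Histogram peaks: roots of dy/dr with d2y/dr2 < 0 on [0, 255].

    The derivative is evaluated on a dense grid; each sign change brackets a
    root which is refined by bisection to |dy/dr| < ``tol`` on the rescaled
    axis.  Returns intensity-axis locations; the set may be empty (e.g. for
    monotone fits).
    """
    poly = np.polynomial.Polynomial(fit.coeffs)
    d1 = poly.deriv()
    d2 = poly.deriv(2)
    grid = np.linspace(0.0, 1.0, n_grid)
    dv = d1(grid)
    peaks = []
    # grid points that are exact roots
    exact = np.where(dv == 0.0)[0]
    for i in exact:
        if d2(grid[i]) < 0:
            peaks.append(grid[i])
    sign_change = np.where(dv[:-1] * dv[1:] < 0)[0]
    for i in sign_change:
        lo, hi = grid[i], grid[i + 1]
        flo = d1(lo)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            fmid = d1(mid)
            if abs(fmid) < tol or (hi - lo) < 1e-15:
                break
            if flo * fmid <= 0:
                hi = mid
            else:
                lo, flo = mid, fmid
        root = 0.5 * (lo + hi)
        if d2(root) < 0:
            peaks.append(root)
    return PeakSet(np.asarray(peaks) * fit.scale)


def gravity_distance(
    p: tuple[float, float, float],
    q: tuple[float, float, float],
    b1: float,
    b2: float,
) -> float:
    """Gravity kernel similarity between two pixels (row, col, intensity).

    exp(-d_space^2/B1) * exp(-dI^2/B2): symmetric, in (0, 1], equal to 1 iff
    the pixels coincide in both space and intensity.
    """
    if b1 <= 0 or b2 <= 0:
        raise ValueError("bandwidths must be positive")
    dr = p[0] - q[0]
    dc = p[1] - q[1]
    di = p[2] - q[2]
    return float(np.exp(-(dr * dr + dc * dc) / b1) * np.exp(-(di * di) / b2))


def _initial_centers(
    img: np.ndarray, peaks: PeakSet, quality: np.ndarray
) -> np.ndarray:
    """One center per peak: intensity at the peak (snapped to the nearest
    occupied level), position at the quality-weighted centroid of pixels
    within +-10 levels of that intensity (whole-image weighted centroid when
    the window is empty).

    Snapping matters because the polynomial smoothing biases peak locations
    into intensity ranges where no pixel actually lives (most visibly on
    noise-free images whose histogram is a few isolated spikes); a center
    seeded in such a dead zone can lose the tug-of-war for its own mode.
    """
    h, w = img.shape
    rows, cols = np.mgrid[0:h, 0:w]
    rows = rows.ravel().astype(np.float64)
    cols = cols.ravel().astype(np.float64)
    intens = img.ravel().astype(np.float64)
    wpix = quality[img.ravel()]
    occupied = np.flatnonzero(quality > 0)
    centers = []
    for pk in peaks:
        pk = float(occupied[np.abs(occupied - pk).argmin()])
        sel = np.abs(intens - pk) <= 10.0
        wsel = np.where(sel, wpix, 0.0)
        if wsel.sum() <= 0:
            wsel = wpix
        total = wsel.sum()
        centers.append([(rows * wsel).sum() / total, (cols * wsel).sum() / total, pk])
    return np.asarray(centers, dtype=np.float64)


def cluster(
    img: np.ndarray,
    peaks: PeakSet,
    model: ClusterModel,
    max_iter: int = 50,
    peak_subset: int | None = None,
    seed: int | None = None,
) -> SegmentationResult:
    """Assign every pixel to the gravity-kernel-nearest cluster center.

    Centers are seeded from the histogram peaks (or, when no peak validated,
    from the 25th/75th intensity percentiles so that segmentation always
    returns a mask), then refined by alternating maximal-similarity
    assignment and centroid/mean-intensity updates until assignments are
    unchanged or ``max_iter`` is reached.  Center pairs closer than
    ``merge_tau_space`` x diagonal in space and ``merge_tau_int`` in mean
    intensity are merged.  ``peak_subset``/``seed`` optionally restrict the
    seeding to a random subset of the validated peaks.
    """
    img = _validate_gray(img)
    if img.size == 0:
        raise ValueError("cannot cluster an empty image")
    h, w = img.shape
    diag = float(np.hypot(h, w))
    hist = histogram(img)

    locations = np.asarray(peaks.locations, dtype=float)
    if peak_subset is not None and len(locations) > peak_subset:
        rng = np.random.default_rng(seed)
        locations = np.sort(rng.choice(locations, size=peak_subset, replace=False))
    if len(locations) == 0:
        locations = np.percentile(img, [25.0, 75.0])
    peaks = PeakSet(np.clip(locations, 0, 255))

    centers = _initial_centers(img, peaks, hist.quality)

    rows, cols = np.mgrid[0:h, 0:w]
    rows = rows.ravel().astype(np.float64)
    cols = cols.ravel().astype(np.float64)
    intens = img.ravel().astype(np.float64)

    labels = np.full(img.size, -1, dtype=np.int64)
    for _ in range(max_iter):
        # log-similarity is monotone in similarity; avoids exp underflow
        logsim = np.empty((len(centers), img.size))
        for j, (cy, cx, ci) in enumerate(centers):
            logsim[j] = (
                -((rows - cy) ** 2 + (cols - cx) ** 2) / model.b1
                - (intens - ci) ** 2 / model.b2
            )
        new_labels = logsim.argmax(axis=0)
        counts = np.bincount(new_labels, minlength=len(centers))
        if (counts > 0).all() and np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
        new_centers = []
        remap = np.full(len(centers), -1, dtype=np.int64)
        for j in range(len(centers)):
            sel = labels == j
            if not sel.any():
                continue  # drop clusters that captured no pixels
            remap[j] = len(new_centers)
            new_centers.append(
                [rows[sel].mean(), cols[sel].mean(), intens[sel].mean()]
            )
        centers = np.asarray(new_centers)
        labels = remap[labels]

    centers, labels = _merge_clusters(centers, labels, rows, cols, intens, model, diag)

    mode = int(hist.counts.argmax())
    lesion_label = int(np.abs(centers[:, 2] - mode).argmax())
    final_model = replace(model, centers=centers)
    return SegmentationResult(
        mask=labels.reshape(h, w), model=final_model, lesion_label=lesion_label
    )


def _merge_clusters(centers, labels, rows, cols, intens, model, diag):
    """Union-find merge of centers closer than the spatial AND intensity
    thresholds, followed by contiguous relabeling and center recomputation."""
    k = len(centers)
    parent = list(range(k))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(k):
        for b in range(a + 1, k):
            d_space = np.hypot(centers[a, 0] - centers[b, 0], centers[a, 1] - centers[b, 1])
            d_int = abs(centers[a, 2] - centers[b, 2])
            if d_space < model.merge_tau_space * diag and d_int < model.merge_tau_int:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    roots = sorted({find(a) for a in range(k)})
    remap = np.empty(k, dtype=np.int64)
    for a in range(k):
        remap[a] = roots.index(find(a))
    labels = remap[labels]
    merged = []
    for j in range(len(roots)):
        sel = labels == j
        merged.append([rows[sel].mean(), cols[sel].mean(), intens[sel].mean()])
    return np.asarray(merged), labels


def segment(
    img: np.ndarray,
    n: int = 6,
    b1: float | None = None,
    b2: float | None = None,
    merge_tau_space: float = 0.05,
    merge_tau_int: float = 10.0,
    max_iter: int = 50,
    peak_subset: int | None = None,
    seed: int | None = None,
) -> SegmentationResult:
    """End-to-end segmentation: histogram -> polynomial fit -> peaks -> cluster.

    Automatic bandwidths: B1 = (0.3 x image diagonal)^2 — a spatial scale
    comparable to the object extent, so that the spatial kernel acts as a
    gentle locality prior rather than overriding a clear intensity contrast
    — and B2 = (0.1 x 255)^2 on the intensity axis.
    """
    img = _validate_gray(img)
    diag = float(np.hypot(*img.shape))
    model = ClusterModel(
        b1=(0.3 * diag) ** 2 if b1 is None else b1,
        b2=(0.1 * 255.0) ** 2 if b2 is None else b2,
        merge_tau_space=merge_tau_space,
        merge_tau_int=merge_tau_int,
    )
    fit = fit_histogram_polynomial(histogram(img), n)
    peaks = find_peaks(fit)
    return cluster(
        img, peaks, model, max_iter=max_iter, peak_subset=peak_subset, seed=seed
    )
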
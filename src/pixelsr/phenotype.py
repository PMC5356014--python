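"""Label-free morphology classification of reconstructed cell images.

The screening/feature chain mirrors a standard imaging-flow-cytometry
workflow for bright-field transmittance images:

* **screen** — a brightness threshold isolates the (absorbing, hence dark)
  object; the minimum-area rotated rectangle is fitted around it; empty
  masks are rejected rather than erroring.
* **bulk metrics** — *opacity* (mean masked intensity minus the background
  level, an optical-density proxy) and *area* (the rotated box footprint in
  μm²).
* **morphology metric** — the object patch is cropped, rotated upright and
  rescaled with its box (making the descriptor invariant to scale, rotation
  and aspect ratio), encoded as a histogram of oriented gradients (HoG),
  and the population of descriptors is projected onto its first principal
  component.  The score measures structural complexity: colonies with more
  daughter cells score higher.
* **clustering** — K-means (k = 3) in the (morphology, log10 area) plane
  with uniform-random centroid initialization, best inertia over restarts.
* **ROC/AUC** — the Mann–Whitney rank statistic, for comparing how well the
  morphology score separates known classes on LR versus SR reconstructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.stats import rankdata
from skimage import measure, transform
from skimage.feature import hog
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .reconstruct import HRImage


@dataclass
class RotatedBox:
    """Minimum-area rotated rectangle: center (row, col), size, angle (rad)."""

    center: tuple[float, float]
    width: float    # px, along the box's first axis
    height: float   # px
    angle: float    # rad, rotation of the width axis w.r.t. the column axis

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass
class CellFeatures:
    """Per-object feature vector."""

    opacity: float
    area: float                    # μm²
    morphology: float = float("nan")
    box: RotatedBox | None = None
    label: str | None = None
    cluster: int = -1


def min_area_rect(points: np.ndarray) -> RotatedBox:
    """Minimum-area rotated bounding rectangle of a 2-D point set.

    Rotating calipers over the convex hull: the optimal rectangle has one
    side collinear with a hull edge.  ``points`` are (row, col) pairs.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3 or np.ptp(pts, axis=0).min() == 0:
        # degenerate: axis-aligned bounding box
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        c = (lo + hi) / 2
        return RotatedBox((c[0], c[1]), hi[1] - lo[1] + 1, hi[0] - lo[0] + 1, 0.0)
    hull = pts[ConvexHull(pts).vertices]
    z = hull[:, 1] + 1j * hull[:, 0]          # x = col, y = row
    dz = np.roll(z, -1) - z
    angles = np.unique(np.mod(np.angle(dz), np.pi / 2))
    best = None
    for ang in angles:
        zr = z * np.exp(-1j * ang)            # edge direction → x axis
        w = float(np.ptp(zr.real)) + 1
        h = float(np.ptp(zr.imag)) + 1
        if best is None or w * h < best[0]:
            mid = complex((zr.real.min() + zr.real.max()) / 2,
                          (zr.imag.min() + zr.imag.max()) / 2)
            c = mid * np.exp(1j * ang)        # back to image coords
            best = (w * h, RotatedBox((c.imag, c.real), w, h, ang))
    box = best[1]
    if box.height > box.width:
        # canonical pose: elongation along the width axis, so every object
        # lands in its normalized patch with a consistent orientation
        box = RotatedBox(box.center, box.height, box.width,
                         math.remainder(box.angle + math.pi / 2, math.pi))
    return box


def screen_and_box(image: HRImage, threshold: float,
                   min_pixels: int = 5) -> tuple[np.ndarray, RotatedBox] | None:
    """Threshold-screen an image and fit the minimum-area rotated box.

    Foreground is everything *below* ``threshold`` (absorbing objects are
    darker than the illuminated background).  Only the largest connected
    component is kept.  Returns None (rejected) when no object of at least
    ``min_pixels`` survives — the zero-area screening step.
    """
    mask = image.grid < threshold
    labels = measure.label(mask)
    if labels.max() == 0:
        return None
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    biggest = int(np.argmax(sizes))
    if sizes[biggest] < min_pixels:
        return None
    mask = labels == biggest
    box = min_area_rect(np.argwhere(mask))
    return mask, box


def background_level(image: HRImage, mask: np.ndarray | None = None) -> float:
    """Median intensity outside the object mask (the illumination floor)."""
    if mask is None:
        return float(np.median(image.grid))
    out = image.grid[~mask]
    return float(np.median(out)) if out.size else float(np.median(image.grid))


def bulk_metrics(image: HRImage, mask: np.ndarray, background: float,
                 box: RotatedBox | None = None) -> tuple[float, float]:
    """(opacity, area): mean masked intensity minus background; box area in μm²."""
    if not mask.any():
        raise ValueError("empty mask")
    opacity = float(image.grid[mask].mean()) - background
    if box is None:
        box = min_area_rect(np.argwhere(mask))
    area = box.width * image.pitch_x * box.height * image.pitch_y
    return opacity, area


def normalize_patch(image: HRImage, box: RotatedBox,
                    out_size: int = 64) -> np.ndarray:
    """Crop → rotate upright → scale the boxed object to a fixed patch.

    The normalization makes the downstream descriptor invariant to the
    object's scale, rotation and aspect ratio, as the box itself carries
    that pose information.
    """
    g = image.grid.astype(float)
    cy, cx = box.center
    margin = 1.25
    half = int(math.ceil(max(box.width, box.height) * margin / 2)) + 2
    r0, r1 = int(round(cy)) - half, int(round(cy)) + half
    c0, c1 = int(round(cx)) - half, int(round(cx)) + half
    pad_r0, pad_c0 = max(0, -r0), max(0, -c0)
    pad_r1, pad_c1 = max(0, r1 - g.shape[0]), max(0, c1 - g.shape[1])
    crop = np.pad(g, ((pad_r0, pad_r1), (pad_c0, pad_c1)), mode="edge")[
        r0 + pad_r0:r1 + pad_r0, c0 + pad_c0:c1 + pad_c0]
    rot = transform.rotate(crop, np.degrees(box.angle), resize=False,
                           mode="edge", order=1)
    # after rotation the box is axis-aligned: width along columns
    ch, cw = rot.shape[0] / 2, rot.shape[1] / 2
    hw, hh = box.width / 2, box.height / 2
    sub = rot[int(max(0, ch - hh)):int(min(rot.shape[0], ch + hh)) or None,
              int(max(0, cw - hw)):int(min(rot.shape[1], cw + hw)) or None]
    if sub.size == 0:
        sub = rot
    patch = transform.resize(sub, (out_size, out_size), order=1,
                             anti_aliasing=True)
    # the box fixes the pose only up to 180°; orient the patch so the
    # object's centre of mass sits in a fixed half-plane
    weight = patch.max() - patch
    total = weight.sum()
    if total > 0:
        rows = np.arange(out_size) - (out_size - 1) / 2
        cy = float((weight.sum(axis=1) * rows).sum() / total)
        cx = float((weight.sum(axis=0) * rows).sum() / total)
        if cy > 1e-9 or (abs(cy) <= 1e-9 and cx > 1e-9):
            patch = patch[::-1, ::-1]
    # standardize intensity: the descriptor should encode structure, not
    # the object's optical density
    sd = patch.std()
    return (patch - patch.mean()) / sd if sd > 0 else patch * 0.0


def hog_descriptor(patch: np.ndarray, orientations: int = 9,
                   pixels_per_cell: tuple[int, int] = (8, 8),
                   cells_per_block: tuple[int, int] = (2, 2)) -> np.ndarray:
    """Histogram-of-oriented-gradients descriptor of a normalized patch."""
    return hog(patch, orientations=orientations, pixels_per_cell=pixels_per_cell,
               cells_per_block=cells_per_block, feature_vector=True)


def morphology_metric(images: list[HRImage], boxes: list[RotatedBox], *,
                      out_size: int = 64, orientations: int = 9,
                      pixels_per_cell: tuple[int, int] = (8, 8),
                      cells_per_block: tuple[int, int] = (2, 2)) -> np.ndarray:
    """First-principal-component HoG score per object across a population.

    The PCA sign is arbitrary; it is fixed so the score correlates
    positively with total descriptor gradient energy, i.e. structurally
    richer objects (more lobes, more internal edges) score higher.
    """
    if len(images) < 2:
        raise ValueError("morphology metric needs a population of ≥ 2 images")
    descs = np.array([
        hog_descriptor(normalize_patch(img, box, out_size), orientations,
                       pixels_per_cell, cells_per_block)
        for img, box in zip(images, boxes)
    ])
    if np.allclose(descs.std(axis=0), 0):
        return np.zeros(len(images))
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(descs)[:, 0]
    energy = (descs ** 2).sum(axis=1)
    if np.corrcoef(scores, energy)[0, 1] < 0:
        scores = -scores
    return scores


def kmeans_cluster(points: np.ndarray, k: int = 3, seed: int = 0,
                   n_restarts: int = 10, max_iter: int = 300,
                   tol: float = 1e-6) -> np.ndarray:
    """K-means in the (morphology, log10 area) plane, random-coordinate init.

    Initial centroids are drawn uniformly inside the data bounding box (not
    from the data points), best inertia over ``n_restarts``; deterministic
    for a fixed seed.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < k:
        raise ValueError(f"need at least k={k} points")
    rng = np.random.default_rng(seed)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    best_labels, best_inertia = None, np.inf
    for _ in range(n_restarts):
        init = rng.uniform(lo, hi, size=(k, pts.shape[1]))
        km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=max_iter,
                    tol=tol)
        labels = km.fit_predict(pts)
        if km.inertia_ < best_inertia:
            best_inertia, best_labels = km.inertia_, labels
    return best_labels


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic.

    ``labels`` are binary (1 = positive class); ties in the scores receive
    averaged ranks, so the result matches the trapezoidal ROC area exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def extract_features(images: list[HRImage], threshold: float, *,
                     labels: list[str] | None = None,
                     seed: int = 0, k: int = 3) -> list[CellFeatures]:
    """Full screening + feature chain over a collection of reconstructions.

    Rejected images (no object above the brightness screen) yield a
    CellFeatures with NaN metrics and cluster −1.  Morphology scores and
    clusters are computed jointly over the accepted population.
    """
    feats: list[CellFeatures] = []
    kept_idx, kept_imgs, kept_boxes = [], [], []
    for i, img in enumerate(images):
        lab = labels[i] if labels is not None else None
        res = screen_and_box(img, threshold)
        if res is None:
            feats.append(CellFeatures(opacity=float("nan"), area=0.0, label=lab))
            continue
        mask, box = res
        bg = background_level(img, mask)
        opacity, area = bulk_metrics(img, mask, bg, box)
        feats.append(CellFeatures(opacity=opacity, area=area, box=box, label=lab))
        kept_idx.append(i)
        kept_imgs.append(img)
        kept_boxes.append(box)
    if len(kept_idx) >= 2:
        scores = morphology_metric(kept_imgs, kept_boxes)
        for j, i in enumerate(kept_idx):
            feats[i].morphology = float(scores[j])
        if len(kept_idx) >= k:
            pts = np.column_stack([
                scores, np.log10([max(feats[i].area, 1e-6) for i in kept_idx])])
            clusters = kmeans_cluster(pts, k=k, seed=seed)
            for j, i in enumerate(kept_idx):
                feats[i].cluster = int(clusters[j])
    return feats
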
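"""Nucleus segmentation: RGB image -> nucleus centroid point pattern.

The pipeline is: k-means color quantization in La*b* space, assignment of the
clusters to cell vs background, grid down-sampling of the binary cell mask
into a probability grid, automatic (Otsu) or manual thresholding, and
connected-component centroid extraction in micron coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2lab
from sklearn.cluster import KMeans

from .pattern import PointPattern


@dataclass
class ProbabilityGrid:
    """Down-sampled cell-probability image.

    ``cell_prob[i, j]`` is the fraction of cell-class pixels covered by grid
    entry ``(i, j)``; ``grid_size`` is the down-sampling factor in pixels and
    ``microns_per_pixel`` links grid indices back to micron coordinates.
    """

    cell_prob: np.ndarray
    grid_size: int
    microns_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        p = np.asarray(self.cell_prob, dtype=float)
        if p.ndim != 2:
            raise ValueError("cell_prob must be 2-D")
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("cell_prob entries must lie in [0, 1]")
        object.__setattr__(self, "cell_prob", p)

    @property
    def cell_size_um(self) -> float:
        return self.grid_size * self.microns_per_pixel


def quantize_colors(
    image: np.ndarray, k: int = 2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster pixel colors into ``k`` groups by k-means in La*b* space.

    Returns ``(labels, centers)`` where ``labels`` has the image's spatial
    shape and ``centers`` is ``(k, 3)`` in La*b*.  The La*b* space is used
    because it is perceptually uniform, separating luminance from chroma and
    improving the quantization of stained imagery.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be an (H, W, 3) RGB array")
    if img.dtype != np.uint8 and img.max() > 1.0:
        img = np.clip(img, 0, 255).astype(np.uint8)
    lab = rgb2lab(img)
    flat = lab.reshape(-1, 3)
    n_distinct = len(np.unique(flat, axis=0))
    if n_distinct < k:
        warnings.warn(
            f"image has only {n_distinct} distinct colors for k={k}; "
            "clustering is degenerate",
            stacklevel=2,
        )
        k_eff = max(1, n_distinct)
    else:
        k_eff = k
    km = KMeans(n_clusters=k_eff, n_init=10, random_state=int(seed) & 0x7FFFFFFF)
    labels = km.fit_predict(flat)
    return labels.reshape(img.shape[:2]), km.cluster_centers_


def classify_clusters(
    label_image: np.ndarray,
    centers: np.ndarray,
    rule: str | dict[int, int] = "darkest_is_cell",
) -> np.ndarray:
    """Map color clusters to a binary cell mask (1 = cell, 0 = background).

    ``rule`` is either ``"darkest_is_cell"`` (the cluster with the lowest
    La*b* luminance L becomes the cell class -- hematoxylin-stained nuclei are
    dark) or an explicit ``{cluster_label: 0|1}`` map standing in for manual
    assignment.
    """
    centers = np.asarray(centers)
    present = np.unique(label_image)
    if isinstance(rule, str):
        if rule != "darkest_is_cell":
            raise ValueError(f"unknown rule {rule!r}")
        cell_cluster = int(np.argmin(centers[:, 0]))
        return (label_image == cell_cluster).astype(np.uint8)
    missing = [int(c) for c in present if int(c) not in rule]
    if missing:
        raise ValueError(f"manual cluster map missing labels {missing}")
    mask = np.zeros(label_image.shape, dtype=np.uint8)
    for cluster, value in rule.items():
        if value:
            mask[label_image == cluster] = 1
    return mask


def grid_downsample(mask: np.ndarray, grid_size: int) -> ProbabilityGrid:
    """Average a binary mask over a square grid.

    Each grid entry receives the mean of the pixels it covers; border entries
    that cover the image only partially are averaged over the covered pixels
    alone, so mass is conserved exactly.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    h, w = mask.shape
    if grid_size > h or grid_size > w:
        warnings.warn(
            "grid_size exceeds an image dimension; grid collapses to one entry",
            stacklevel=2,
        )
    gh = int(np.ceil(h / grid_size))
    gw = int(np.ceil(w / grid_size))
    m = mask.astype(float)
    row_idx = np.arange(0, h, grid_size)
    col_idx = np.arange(0, w, grid_size)
    sums = np.add.reduceat(np.add.reduceat(m, row_idx, axis=0), col_idx, axis=1)
    rows_per = np.minimum(row_idx + grid_size, h) - row_idx
    cols_per = np.minimum(col_idx + grid_size, w) - col_idx
    counts = np.outer(rows_per, cols_per)
    prob = sums / counts
    assert prob.shape == (gh, gw)
    return ProbabilityGrid(cell_prob=prob, grid_size=grid_size)


def otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Otsu's automatic threshold on a collection of values in [0, 1].

    Builds a ``bins``-bin histogram over [0, 1] and returns the bin edge
    maximizing the between-class variance
    ``w0 * w1 * (mu0 - mu1)**2``.  Ties resolve to the lowest such edge.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    if v.min() < 0 or v.max() > 1:
        raise ValueError("values must lie in [0, 1]")
    if np.unique(v).size < 2:
        raise ValueError("constant input: histogram is degenerate, no threshold exists")
    hist, edges = np.histogram(v, bins=bins, range=(0.0, 1.0))
    hist = hist.astype(float)
    total = hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(hist)  # mass at or below each bin
    w1 = total - w0
    cum_mass = np.cumsum(hist * centers)
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise ValueError("all mass falls in one bin; histogram is degenerate")
    mu0 = np.where(w0 > 0, cum_mass / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (cum_mass[-1] - cum_mass) / np.maximum(w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    best = int(np.argmax(between))
    return float(edges[best + 1])


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
    8: np.ones((3, 3), dtype=int),
}


def extract_nuclei(
    grid: ProbabilityGrid,
    threshold: float | None = None,
    connectivity: int = 8,
    **pattern_metadata,
) -> PointPattern:
    """Binarize the probability grid and return component centroids.

    Entries strictly greater than ``threshold`` (Otsu on the grid values when
    ``None``) become foreground; each connected component is one nucleus and
    its centroid is converted to microns via
    ``(index + 0.5) * grid_size * microns_per_pixel``.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    if threshold is None:
        threshold = otsu_threshold(grid.cell_prob)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    fg = grid.cell_prob > threshold
    h, w = grid.cell_prob.shape
    cell = grid.cell_size_um
    field = (w * cell, h * cell)
    if not fg.any():
        return PointPattern(np.empty((0, 2)), field_size=field, **pattern_metadata)
    labeled, n = ndimage.label(fg, structure=_STRUCTURES[connectivity])
    centroids = ndimage.center_of_mass(fg, labeled, index=np.arange(1, n + 1))
    coords = np.array([[ (c + 0.5) * cell, (r + 0.5) * cell ] for r, c in centroids])
    coords[:, 0] = np.clip(coords[:, 0], 0, field[0])
    coords[:, 1] = np.clip(coords[:, 1], 0, field[1])
    return PointPattern(coords, field_size=field, **pattern_metadata)


def segment_image(
    image: np.ndarray,
    k: int = 2,
    grid_size: int = 4,
    threshold: float | None = None,
    connectivity: int = 8,
    microns_per_pixel: float = 1.0,
    rule: str | dict[int, int] = "darkest_is_cell",
    seed: int = 0,
    **pattern_metadata,
) -> PointPattern:
    """Full segmentation chain: quantize -> classify -> downsample -> extract."""
    labels, centers = quantize_colors(image, k=k, seed=seed)
    mask = classify_clusters(labels, centers, rule=rule)
    grid = grid_downsample(mask, grid_size)
    grid.microns_per_pixel = microns_per_pixel
    return extract_nuclei(
        grid, threshold=threshold, connectivity=connectivity, **pattern_metadata
    )
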
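"""Synthetic data generators for the full pipeline.

Every input the pipeline consumes can be generated here with known ground
truth: class-structured spatial point patterns (a Poisson-parent / Gaussian-
offspring cluster process), pseudo-stained renderings of those patterns,
time-course series emulating an 11-time-point x 5-sample in vitro design, and
low-rank tensors / coupled tensor-matrix pairs with known factor matrices.

All generators are bit-reproducible given ``(seed, params)``.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .pattern import CANCER, CLASS_LABELS, HEALTHY, PointPattern

#: In vitro sampling design: fixation times in hours.
DEFAULT_TIME_HOURS: tuple[float, ...] = (0, 1, 2, 4, 6, 10, 16, 24, 72, 120, 168)
#: Replicate gels per time point.
DEFAULT_N_SAMPLES = 5
#: Confocal field cross-section, microns.
DEFAULT_FIELD_UM: tuple[float, float] = (900.0, 900.0)


def substream_seed(root_seed: int, name: str) -> np.random.SeedSequence:
    """Derive a named, reproducible child seed from one root seed.

    All pipeline randomness flows from a single root seed through named
    substreams so that stages can be re-run independently yet bit-identically.
    """
    return np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class ClassParams:
    """Spatial point-process parameters for one tissue class.

    ``intensity`` is the expected number of nuclei per mm^2; ``cluster_rate``
    the expected number of parent clusters per mm^2; ``cluster_sd`` the
    Gaussian dispersion (microns) of offspring around their parent.  Denser
    and more tightly clumped parameters model the cancerous state.
    """

    intensity: float
    cluster_rate: float
    cluster_sd: float

    def __post_init__(self) -> None:
        if self.intensity <= 0 or self.cluster_rate <= 0 or self.cluster_sd <= 0:
            raise ValueError(
                "intensity, cluster_rate and cluster_sd must all be strictly positive; "
                f"got {self}"
            )


#: Default class contrast: cancer denser and more clumped than healthy.
DEFAULT_CLASS_PARAMS: dict[str, ClassParams] = {
    HEALTHY: ClassParams(intensity=120.0, cluster_rate=30.0, cluster_sd=60.0),
    CANCER: ClassParams(intensity=300.0, cluster_rate=45.0, cluster_sd=30.0),
}


@dataclass
class GroundTruthFactors:
    """Planted factor matrices of a simulated CP / coupled model.

    ``factors`` holds one matrix per mode (for coupled data the order is
    A, B, C, D with A the shared features-mode factor).  Columns are unit
    norm; ``weights`` carries the absorbed scales.
    """

    factors: list[np.ndarray]
    weights: np.ndarray
    noise_level: float

    @property
    def rank(self) -> int:
        return int(self.weights.shape[0])


def simulate_point_pattern(
    params: ClassParams,
    label: str = HEALTHY,
    field: tuple[float, float] = DEFAULT_FIELD_UM,
    seed: int | np.random.SeedSequence = 0,
    time_hours: Optional[float] = None,
    sample_id: str = "sample",
) -> PointPattern:
    """Draw one clustered point pattern (Poisson parents, Gaussian offspring).

    Parents fall as a homogeneous Poisson process of rate ``cluster_rate``
    over the field expanded by a guard margin of ``4 * cluster_sd`` (so the
    realized intensity is edge-effect free); each parent receives a Poisson
    number of offspring with mean ``intensity / cluster_rate``, displaced by
    isotropic Gaussian noise of scale ``cluster_sd`` and thinned to the field.
    """
    if label not in CLASS_LABELS:
        raise ValueError(f"label must be one of {CLASS_LABELS}")
    w, h = field
    if w <= 0 or h <= 0:
        raise ValueError("field dimensions must be positive")
    rng = np.random.default_rng(seed)
    margin = 4.0 * params.cluster_sd
    ext_w, ext_h = w + 2 * margin, h + 2 * margin
    ext_area_mm2 = (ext_w / 1000.0) * (ext_h / 1000.0)
    n_parents = rng.poisson(params.cluster_rate * ext_area_mm2)
    mean_offspring = params.intensity / params.cluster_rate
    points = []
    for _ in range(n_parents):
        px = rng.uniform(-margin, w + margin)
        py = rng.uniform(-margin, h + margin)
        n_off = rng.poisson(mean_offspring)
        if n_off:
            offs = rng.normal([px, py], params.cluster_sd, size=(n_off, 2))
            points.append(offs)
    if points:
        pts = np.concatenate(points)
        inside = (
            (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
        )
        pts = pts[inside]
    else:
        pts = np.empty((0, 2))
    return PointPattern(
        coordinates=pts,
        field_size=(w, h),
        label=label,
        time_hours=time_hours,
        sample_id=sample_id,
    )


def simulate_timecourse(
    params: ClassParams,
    label: str = HEALTHY,
    time_hours: Sequence[float] = DEFAULT_TIME_HOURS,
    n_samples: int = DEFAULT_N_SAMPLES,
    drift: float = 0.5,
    field: tuple[float, float] = DEFAULT_FIELD_UM,
    seed: int | np.random.SeedSequence = 0,
) -> list[PointPattern]:
    """Simulate the in vitro design: ``n_samples`` gels per time point.

    Gel compaction over the week in culture is emulated by a multiplicative
    intensity drift ``(1 + drift * t / 168)``; ``drift = 0`` freezes the
    process, positive drift densifies it monotonically.  Returns one pattern
    per (sample, time) pair, ``n_samples * len(time_hours)`` in total.
    """
    times = list(time_hours)
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("time_hours must be strictly increasing")
    if times and times[0] < 0:
        raise ValueError("time_hours must be non-negative")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    min_factor = min(1.0 + drift * t / 168.0 for t in times) if times else 1.0
    if min_factor <= 0:
        raise ValueError(
            f"drift {drift} drives the intensity non-positive at some time point"
        )
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(n_samples * len(times))
    patterns = []
    k = 0
    for s in range(n_samples):
        for t in times:
            factor = 1.0 + drift * t / 168.0
            p_t = ClassParams(
                intensity=params.intensity * factor,
                cluster_rate=params.cluster_rate,
                cluster_sd=params.cluster_sd,
            )
            patterns.append(
                simulate_point_pattern(
                    p_t,
                    label=label,
                    field=field,
                    seed=children[k],
                    time_hours=float(t),
                    sample_id=f"{label}_s{s:02d}",
                )
            )
            k += 1
    return patterns


def render_image(
    pattern: PointPattern,
    microns_per_pixel: float = 3.0,
    nucleus_radius: float = 9.0,
    background: tuple[int, int, int] = (235, 225, 235),
    foreground: tuple[int, int, int] = (70, 40, 110),
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Render a pattern as a pseudo-stained 8-bit RGB image.

    Each nucleus becomes a filled disc of ``nucleus_radius`` microns in the
    foreground color on a uniform background, plus i.i.d. Gaussian pixel noise
    of ``noise_sd`` (on the 0-255 scale).  Image dimensions are the field size
    divided by ``microns_per_pixel``, rounded up.
    """
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be positive")
    if nucleus_radius <= 0:
        raise ValueError("nucleus_radius must be positive")
    w_um, h_um = pattern.field_size
    width = int(np.ceil(w_um / microns_per_pixel))
    height = int(np.ceil(h_um / microns_per_pixel))
    r_px = nucleus_radius / microns_per_pixel
    if r_px < 1.0:
        warnings.warn(
            "nucleus_radius below one pixel; discs rendered as single pixels",
            stacklevel=2,
        )
    img = np.empty((height, width, 3), dtype=float)
    img[:] = np.asarray(background, dtype=float)
    fg = np.asarray(foreground, dtype=float)
    yy, xx = np.mgrid[0:height, 0:width]
    for x_um, y_um in pattern.coordinates:
        cx, cy = x_um / microns_per_pixel, y_um / microns_per_pixel
        if r_px < 1.0:
            px = min(int(cx), width - 1)
            py = min(int(cy), height - 1)
            img[py, px] = fg
            continue
        x0, x1 = max(0, int(cx - r_px) - 1), min(width, int(cx + r_px) + 2)
        y0, y1 = max(0, int(cy - r_px) - 1), min(height, int(cy + r_px) + 2)
        sub_y, sub_x = yy[y0:y1, x0:x1], xx[y0:y1, x0:x1]
        disc = (sub_x + 0.5 - cx) ** 2 + (sub_y + 0.5 - cy) ** 2 <= r_px**2
        img[y0:y1, x0:x1][disc] = fg
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _random_factors(
    rng: np.random.Generator, dims: Sequence[int], rank: int
) -> list[np.ndarray]:
    """I.i.d. standard-normal factor matrices with unit-norm columns."""
    factors = []
    for d in dims:
        M = rng.standard_normal((d, rank))
        M /= np.linalg.norm(M, axis=0, keepdims=True)
        factors.append(M)
    return factors


def _cp_reconstruct(factors: Sequence[np.ndarray], weights: np.ndarray) -> np.ndarray:
    """Dense tensor from CP factors: sum of weighted outer products."""
    rank = len(weights)
    dims = [f.shape[0] for f in factors]
    X = np.zeros(dims)
    for r in range(rank):
        comp = weights[r]
        outer = factors[0][:, r]
        for f in factors[1:]:
            outer = np.multiply.outer(outer, f[:, r])
        X += comp * outer
    return X


def simulate_cp_tensor(
    shape: tuple[int, int, int],
    rank: int,
    noise_level: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, GroundTruthFactors]:
    """Simulate a 3-way tensor with a planted rank-``rank`` CP structure.

    ``noise_level`` is the relative Frobenius norm of the added Gaussian
    noise: ``||noise|| = noise_level * ||signal||``.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > min(shape):
        raise ValueError(f"rank {rank} exceeds the smallest mode dimension of {shape}")
    rng = np.random.default_rng(seed)
    factors = _random_factors(rng, shape, rank)
    weights = np.ones(rank)
    X = _cp_reconstruct(factors, weights)
    if noise_level > 0:
        noise = rng.standard_normal(shape)
        noise *= noise_level * np.linalg.norm(X) / np.linalg.norm(noise)
        X = X + noise
    return X, GroundTruthFactors(factors=factors, weights=weights, noise_level=noise_level)


def simulate_class_cp_tensor(
    n_features: int,
    classes: Sequence[str],
    n_times: int = 11,
    rank: int = 2,
    class_gap: float = 2.0,
    noise_level: float = 0.05,
    separating_component: int = 0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, GroundTruthFactors]:
    """CP tensor with class structure planted in one samples-mode component.

    ``classes`` gives the class label of each sample (second mode).  In the
    planted component the samples-mode loadings are drawn around -gap/2 for
    the first class and +gap/2 for the second (jitter sd 0.25 before column
    normalization), so that component separates the classes; the remaining
    components are class-free.
    """
    classes = list(classes)
    shape = (n_features, len(classes), n_times)
    rng = np.random.default_rng(seed)
    factors = _random_factors(rng, shape, rank)
    uniq = sorted(set(classes))
    if len(uniq) != 2:
        raise ValueError("exactly two classes required")
    signs = np.array([-0.5 if c == uniq[0] else 0.5 for c in classes])
    col = signs * class_gap + rng.normal(0, 0.25, size=len(classes))
    factors[1][:, separating_component] = col / np.linalg.norm(col)
    weights = np.ones(rank)
    X = _cp_reconstruct(factors, weights)
    if noise_level > 0:
        noise = rng.standard_normal(shape)
        noise *= noise_level * np.linalg.norm(X) / np.linalg.norm(noise)
        X = X + noise
    return X, GroundTruthFactors(factors=factors, weights=weights, noise_level=noise_level)


def simulate_class_coupled_data(
    n_features: int,
    tensor_classes: Sequence[str],
    matrix_classes: Sequence[str],
    n_times: int = 11,
    rank: int = 1,
    class_gap: float = 2.0,
    noise_level: float = 0.05,
    plant_in_matrix: bool = True,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruthFactors]:
    """Coupled tensor/matrix with class structure planted in the sample modes.

    Class structure always enters the tensor's samples-mode factor B (first
    component); with ``plant_in_matrix=True`` it also enters the matrix's
    sample factor D, otherwise D stays class-free (the scenario where the
    culture model separates but the histology does not).
    """
    t_classes, m_classes = list(tensor_classes), list(matrix_classes)
    shape = (n_features, len(t_classes), n_times)
    rng = np.random.default_rng(seed)
    A, B, C = _random_factors(rng, shape, rank)
    (D,) = _random_factors(rng, [len(m_classes)], rank)

    def planted_column(classes: Sequence[str]) -> np.ndarray:
        uniq = sorted(set(classes))
        if len(uniq) != 2:
            raise ValueError("exactly two classes required")
        signs = np.array([-0.5 if c == uniq[0] else 0.5 for c in classes])
        col = signs * class_gap + rng.normal(0, 0.25, size=len(classes))
        return col / np.linalg.norm(col)

    B[:, 0] = planted_column(t_classes)
    if plant_in_matrix:
        D[:, 0] = planted_column(m_classes)
    weights = np.ones(rank)
    X = _cp_reconstruct([A, B, C], weights)
    Y = A @ D.T
    if noise_level > 0:
        nX = rng.standard_normal(shape)
        nX *= noise_level * np.linalg.norm(X) / np.linalg.norm(nX)
        nY = rng.standard_normal(Y.shape)
        nY *= noise_level * np.linalg.norm(Y) / np.linalg.norm(nY)
        X = X + nX
        Y = Y + nY
    return X, Y, GroundTruthFactors(factors=[A, B, C, D], weights=weights, noise_level=noise_level)


def simulate_border_rank_tensor(
    shape: tuple[int, int, int], seed: int | np.random.SeedSequence = 0
) -> np.ndarray:
    """Tensor whose best rank-2 CP fit is degenerate.

    Returns the unit-norm tensor ``a1 o b1 o c2 + a1 o b2 o c1 + a2 o b1 o c1``
    (CP rank 3 but border rank 2): alternating or gradient fits at rank 2
    produce two ever-growing, highly negatively correlated components -- the
    canonical degenerate-model scenario used to exercise degeneracy detection.
    """
    rng = np.random.default_rng(seed)
    a1, a2 = rng.standard_normal((2, shape[0]))
    b1, b2 = rng.standard_normal((2, shape[1]))
    c1, c2 = rng.standard_normal((2, shape[2]))
    X = (
        np.multiply.outer(np.multiply.outer(a1, b1), c2)
        + np.multiply.outer(np.multiply.outer(a1, b2), c1)
        + np.multiply.outer(np.multiply.outer(a2, b1), c1)
    )
    return X / np.linalg.norm(X)


def simulate_coupled_data(
    tensor_shape: tuple[int, int, int],
    matrix_shape: tuple[int, int],
    rank: int,
    noise_level: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruthFactors]:
    """Simulate a tensor and matrix sharing their first-mode factor.

    The tensor is ``[[A, B, C]]`` and the matrix ``A @ D.T`` with the same A
    (the features mode); independent Gaussian noise at relative Frobenius
    level ``noise_level`` is added to each.
    """
    if tensor_shape[0] != matrix_shape[0]:
        raise ValueError(
            f"first dimensions must match: tensor {tensor_shape[0]} vs matrix {matrix_shape[0]}"
        )
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > min(min(tensor_shape), matrix_shape[1]):
        raise ValueError("rank exceeds a mode dimension")
    rng = np.random.default_rng(seed)
    A, B, C = _random_factors(rng, tensor_shape, rank)
    (D,) = _random_factors(rng, [matrix_shape[1]], rank)
    weights = np.ones(rank)
    X = _cp_reconstruct([A, B, C], weights)
    Y = A @ D.T
    if noise_level > 0:
        nX = rng.standard_normal(tensor_shape)
        nX *= noise_level * np.linalg.norm(X) / np.linalg.norm(nX)
        nY = rng.standard_normal(matrix_shape)
        nY *= noise_level * np.linalg.norm(Y) / np.linalg.norm(nY)
        X = X + nX
        Y = Y + nY
    return X, Y, GroundTruthFactors(factors=[A, B, C, D], weights=weights, noise_level=noise_level)
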
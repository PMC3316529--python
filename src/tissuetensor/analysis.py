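"""Results-level analyses over feature tensors and matrices.

Covers tensor assembly from per-sample feature tables, feature-wise
centering/scaling (optionally against a reference data set), quantified class
separation along factor components, CP analysis of the in vitro tensor,
coupled CMTF analysis of in vitro + histology data, SVD clustering of
in vitro vs histology samples, cumulative explained-variance curves, and
time-resolved projection of in vitro samples onto histology singular vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .factorization import (
    CMTFModel,
    CPModel,
    SVDModel,
    cmtf,
    cp_als,
    matricize,
    svd_lowrank,
)
from .features import DEFAULT_EXCLUSIONS, FEATURE_NAMES, apply_exclusions


# ---------------------------------------------------------------------------
# Containers


@dataclass
class FeatureTensor:
    """3-way feature array: values[feature, sample, time] with mode labels."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    times: list[float]
    sample_classes: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.feature_names), len(self.sample_ids), len(self.times)):
            raise ValueError(
                f"tensor shape {v.shape} does not match label lists "
                f"({len(self.feature_names)}, {len(self.sample_ids)}, {len(self.times)})"
            )
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("time labels must be strictly increasing")
        if len(self.sample_classes) != len(self.sample_ids):
            raise ValueError("one class label per sample required")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class FeatureMatrix:
    """2-way feature array: values[feature, sample] with labels."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    sample_classes: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.feature_names), len(self.sample_ids)):
            raise ValueError("matrix shape does not match label lists")
        if len(self.sample_classes) != len(self.sample_ids):
            raise ValueError("one class label per sample required")
        object.__setattr__(self, "values", v)


@dataclass
class SeparationResult:
    """Quantified 1-D class separation along factor components.

    For every component: the misclassification count of the best single
    threshold on that component's sample scores, and the between/within
    variance ratio.  ``best_component`` minimizes misclassifications (ties
    broken by the variance ratio).
    """

    scores: np.ndarray  # (n_samples, n_components)
    labels: list[str]
    misclassified: list[int]
    variance_ratio: list[float]
    best_component: int

    @property
    def best_misclassified(self) -> int:
        return self.misclassified[self.best_component]


# ---------------------------------------------------------------------------
# Assembly and preprocessing


def assemble_tensor(
    table: pd.DataFrame,
    excluded: Sequence[str] = DEFAULT_EXCLUSIONS,
) -> FeatureTensor:
    """Build a (features x samples x time) tensor from a long feature table.

    ``table`` must carry ``sample_id``, ``label``, ``time_hours`` columns plus
    feature columns; every (sample, time) pair must appear exactly once.  The
    default exclusion list is applied before assembly.
    """
    required = {"sample_id", "label", "time_hours"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing metadata columns: {sorted(missing)}")
    table = apply_exclusions(table, excluded) if excluded else table
    feat_cols = [c for c in table.columns if c in FEATURE_NAMES]
    samples = sorted(table["sample_id"].unique())
    times = sorted(table["time_hours"].unique())
    counts = table.groupby(["sample_id", "time_hours"]).size()
    gaps = [
        (s, t) for s in samples for t in times if (s, t) not in counts.index
    ]
    dups = [k for k, c in counts.items() if c > 1]
    if gaps or dups:
        raise ValueError(
            f"incomplete design: missing cells {gaps[:5]}, duplicated cells {dups[:5]}"
        )
    classes = (
        table.drop_duplicates("sample_id").set_index("sample_id")["label"].to_dict()
    )
    X = np.empty((len(feat_cols), len(samples), len(times)))
    indexed = table.set_index(["sample_id", "time_hours"])
    for j, s in enumerate(samples):
        for k, t in enumerate(times):
            X[:, j, k] = indexed.loc[(s, t), feat_cols].to_numpy(dtype=float)
    return FeatureTensor(
        values=X,
        feature_names=feat_cols,
        sample_ids=list(samples),
        times=[float(t) for t in times],
        sample_classes=[classes[s] for s in samples],
    )


@dataclass
class FeatureTransform:
    """Feature-wise centering/scaling parameters (one mean/scale per feature)."""

    means: np.ndarray
    scales: np.ndarray

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Standardize along the first (features) axis."""
        shape = (-1,) + (1,) * (values.ndim - 1)
        return (values - self.means.reshape(shape)) / self.scales.reshape(shape)


def fit_transform_params(
    values: np.ndarray, drop_constant: bool = False
) -> FeatureTransform:
    """Per-feature mean and standard deviation over all remaining axes."""
    flat = values.reshape(values.shape[0], -1)
    means = flat.mean(axis=1)
    scales = flat.std(axis=1)
    zero = scales == 0
    if zero.any():
        if not drop_constant:
            raise ValueError(
                f"zero-variance features at indices {np.where(zero)[0].tolist()}; "
                "pass drop_constant=True to scale them by 1 instead"
            )
        warnings.warn("zero-variance features scaled by 1", stacklevel=2)
        scales = np.where(zero, 1.0, scales)
    return FeatureTransform(means=means, scales=scales)


def preprocess(
    data: FeatureTensor | FeatureMatrix,
    reference: Optional[FeatureMatrix] = None,
    drop_constant: bool = False,
) -> tuple[np.ndarray, FeatureTransform]:
    """Center and scale features to zero mean / unit sd.

    With ``reference`` given, its per-feature means and scales are used
    instead (projecting one data set into another's standardized space); the
    feature lists must then match exactly.
    """
    if not np.isfinite(data.values).all():
        raise ValueError("non-finite entries; clean or drop undefined features first")
    if reference is not None:
        if list(reference.feature_names) != list(data.feature_names):
            raise ValueError("feature lists of data and reference must match")
        params = fit_transform_params(reference.values, drop_constant=drop_constant)
    else:
        params = fit_transform_params(data.values, drop_constant=drop_constant)
    return params.apply(data.values), params


# ---------------------------------------------------------------------------
# Separation


def _best_threshold_errors(scores: np.ndarray, labels: np.ndarray) -> int:
    """Fewest misclassifications over all 1-D thresholds and both polarities."""
    order = np.argsort(scores, kind="stable")
    s, y = scores[order], labels[order]
    n = len(s)
    pos = (y == np.unique(y)[1]).astype(int)
    total_pos = pos.sum()
    cum_pos = np.concatenate([[0], np.cumsum(pos)])
    cum_neg = np.arange(n + 1) - cum_pos
    # realizable cuts only: a threshold cannot split tied scores
    valid = np.ones(n + 1, dtype=bool)
    valid[1:n] = s[1:] > s[:-1]
    # cut k puts the first k sorted points left of the threshold;
    # both polarities (which side is called which class) are scanned
    errors_a = np.where(valid, cum_pos + (cum_neg[-1] - cum_neg), n)
    errors_b = np.where(valid, cum_neg + (total_pos - cum_pos), n)
    return int(min(errors_a.min(), errors_b.min()))


def separation_score(scores: np.ndarray, labels: Sequence[str]) -> SeparationResult:
    """Assess how well factor components separate the two classes.

    ``scores`` is (n_samples,) or (n_samples, n_components).  For each
    component the optimal single-threshold misclassification count (exhaustive
    over sample midpoints and both polarities) and the between/within variance
    ratio are computed.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    mis, ratio = [], []
    for c in range(S.shape[1]):
        col = S[:, c]
        mis.append(_best_threshold_errors(col, y))
        g0, g1 = col[y == classes[0]], col[y == classes[1]]
        within = ((g0 - g0.mean()) ** 2).sum() + ((g1 - g1.mean()) ** 2).sum()
        grand = col.mean()
        between = len(g0) * (g0.mean() - grand) ** 2 + len(g1) * (g1.mean() - grand) ** 2
        ratio.append(float(between / within) if within > 0 else float("inf"))
    best = min(range(len(mis)), key=lambda i: (mis[i], -ratio[i]))
    return SeparationResult(
        scores=S, labels=list(y), misclassified=mis, variance_ratio=ratio,
        best_component=best,
    )


def permutation_null(
    scores: np.ndarray,
    labels: Sequence[str],
    n_permutations: int = 200,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Null distribution of the best misclassification count under label
    shuffling; used to judge whether an observed separation is meaningful."""
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    out = np.empty(n_permutations, dtype=int)
    for i in range(n_permutations):
        out[i] = separation_score(scores, rng.permutation(y)).best_misclassified
    return out


# ---------------------------------------------------------------------------
# Results procedures


@dataclass
class InVitroAnalysis:
    model: CPModel
    separation: SeparationResult
    influential_features: pd.DataFrame


def rank_influential_features(
    component: np.ndarray, feature_names: Sequence[str], top_k: int = 5
) -> pd.DataFrame:
    """Features whose coefficients diverge the most from zero in a component."""
    order = np.argsort(-np.abs(component))
    return pd.DataFrame(
        {
            "feature": [feature_names[i] for i in order[:top_k]],
            "coefficient": component[order[:top_k]],
        }
    )


def analyze_invitro(
    tensor: FeatureTensor,
    rank: int = 2,
    scale: bool = True,
    top_k: int = 5,
    seed: int | np.random.SeedSequence = 0,
    **cp_kwargs,
) -> InVitroAnalysis:
    """Three-way analysis of the in vitro tensor.

    Fits an R-component CP model (after optional feature standardization),
    quantifies class separation on every samples-mode component, and ranks
    the features driving the best-separating component.
    """
    X = preprocess(tensor)[0] if scale else tensor.values
    model = cp_als(X, rank, seed=seed, **cp_kwargs)
    sep = separation_score(model.factors[1], tensor.sample_classes)
    feats = rank_influential_features(
        model.factors[0][:, sep.best_component], tensor.feature_names, top_k
    )
    return InVitroAnalysis(model=model, separation=sep, influential_features=feats)


@dataclass
class CoupledAnalysis:
    model: CMTFModel
    separation_invitro: SeparationResult
    separation_histology: SeparationResult
    influential_features: pd.DataFrame


def analyze_coupled(
    tensor: FeatureTensor,
    matrix: FeatureMatrix,
    rank: int = 1,
    scale: bool = True,
    top_k: int = 5,
    seed: int | np.random.SeedSequence = 0,
    **cmtf_kwargs,
) -> CoupledAnalysis:
    """Coupled CMTF analysis of in vitro tensor and histology matrix.

    The two data sets share the features mode; CMTF extracts a common
    features-mode factor A, tensor factors B (in vitro samples) and C (time),
    and a histology factor D.  Separation is quantified per component in both
    sample modes, and the shared-mode feature ranking is taken from the
    in vitro best-separating component.
    """
    if list(tensor.feature_names) != list(matrix.feature_names):
        raise ValueError("tensor and matrix must share an identically ordered feature mode")
    if scale:
        X = preprocess(tensor)[0]
        Y = preprocess(matrix)[0]
    else:
        X, Y = tensor.values, matrix.values
    model = cmtf(X, Y, rank, seed=seed, **cmtf_kwargs)
    sep_b = separation_score(model.B, tensor.sample_classes)
    sep_d = separation_score(model.D, matrix.sample_classes)
    feats = rank_influential_features(
        model.A[:, sep_b.best_component], tensor.feature_names, top_k
    )
    return CoupledAnalysis(
        model=model,
        separation_invitro=sep_b,
        separation_histology=sep_d,
        influential_features=feats,
    )


@dataclass
class SourceClustering:
    svd: SVDModel
    scores: np.ndarray  # (n_columns, 2)
    source_labels: list[str]  # "invitro" or "histology" per column
    explained_variance_first_two: float
    separation: SeparationResult


def cluster_invitro_vs_histology(
    tensor: FeatureTensor,
    matrix: FeatureMatrix,
    scale: bool = True,
) -> SourceClustering:
    """SVD clustering of in vitro vs histology samples of one class.

    The tensor is matricized in the features mode (features x samples-time),
    concatenated column-wise with the histology matrix, feature-standardized,
    and factored by SVD; the first two right-singular-vector scores are
    labeled by source and their linear separability quantified.
    """
    if list(tensor.feature_names) != list(matrix.feature_names):
        raise ValueError("tensor and matrix must share the feature mode")
    Z = np.hstack([matricize(tensor.values, 0), matrix.values])
    if scale:
        Z = fit_transform_params(Z, drop_constant=True).apply(Z)
    n_iv = tensor.values.shape[1] * tensor.values.shape[2]
    labels = ["invitro"] * n_iv + ["histology"] * matrix.values.shape[1]
    k = min(2, min(Z.shape))
    svd = svd_lowrank(Z, k=k)
    scores = svd.scores()
    sep = separation_score(scores, labels)
    return SourceClustering(
        svd=svd,
        scores=scores,
        source_labels=labels,
        explained_variance_first_two=float(svd.explained_variance[:2].sum()),
        separation=sep,
    )


def cumulative_variance_curves(
    matrices: dict[str, np.ndarray],
    n_components: int = 20,
    merge_tol: float = 0.02,
) -> tuple[pd.DataFrame, dict[tuple[str, str], int]]:
    """Per-class cumulative explained-variance curves and merge indices.

    Each matrix is decomposed by SVD; curves give the cumulative fraction of
    variance captured by components 1..``n_components`` (truncated with a
    warning when the rank is smaller).  For each class pair the merge index
    is the first component from which onward the two curves stay within
    ``merge_tol`` of each other (0 if they never merge).
    """
    curves = {}
    for name, M in matrices.items():
        s = np.linalg.svd(np.asarray(M, dtype=float), compute_uv=False)
        frac = np.cumsum(s**2) / (s**2).sum()
        if len(frac) < n_components:
            warnings.warn(
                f"{name}: rank {len(frac)} < requested {n_components}; truncating",
                stacklevel=2,
            )
        padded = np.ones(n_components)
        padded[: min(n_components, len(frac))] = frac[:n_components]
        curves[name] = padded
    df = pd.DataFrame(curves, index=pd.RangeIndex(1, n_components + 1, name="component"))
    merges: dict[tuple[str, str], int] = {}
    names = list(curves)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diff = np.abs(curves[a] - curves[b])
            merged_from = 0
            for k in range(n_components):
                if (diff[k:] <= merge_tol).all():
                    merged_from = k + 1
                    break
            merges[(a, b)] = merged_from
    return df, merges


@dataclass
class TimecourseProjection:
    coordinates: pd.DataFrame  # columns: sample_id, time_hours, pc1, pc2
    histology_scores: np.ndarray
    distances: pd.Series  # mean distance to histology centroid per time point


def project_timecourse(
    matrix: FeatureMatrix, tensor: FeatureTensor
) -> TimecourseProjection:
    """Project in vitro samples onto the histology singular vectors over time.

    The histology matrix is centered/scaled per feature; its first two left
    singular vectors define the projection plane.  Every in vitro (sample,
    time) column is standardized with the histology transform and projected;
    per-time-point mean Euclidean distance to the histology score centroid
    quantifies how close the culture gets to native tissue organization.
    """
    if list(matrix.feature_names) != list(tensor.feature_names):
        raise ValueError("tensor and matrix must share the feature mode")
    Yp, params = preprocess(matrix, drop_constant=True)
    svd = svd_lowrank(Yp, k=min(2, min(Yp.shape)))
    U2 = svd.U  # (features, 2)
    hist_scores = (U2.T @ Yp).T  # equals sigma_i v_i
    centroid = hist_scores.mean(axis=0)
    Xp = params.apply(tensor.values)
    rows = []
    for j, sid in enumerate(tensor.sample_ids):
        for k, t in enumerate(tensor.times):
            proj = U2.T @ Xp[:, j, k]
            rows.append({"sample_id": sid, "time_hours": t,
                         "pc1": proj[0], "pc2": proj[1] if len(proj) > 1 else 0.0})
    coords = pd.DataFrame(rows)
    d = np.sqrt(
        (coords["pc1"] - centroid[0]) ** 2
        + (coords["pc2"] - (centroid[1] if len(centroid) > 1 else 0.0)) ** 2
    )
    coords = coords.assign(distance=d)
    distances = coords.groupby("time_hours")["distance"].mean()
    return TimecourseProjection(
        coordinates=coords, histology_scores=hist_scores, distances=distances
    )
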
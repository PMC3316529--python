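"""Matrix and tensor factorization core.

Implements truncated SVD with explained-variance accounting, mode-n
matricization, the CANDECOMP/PARAFAC (CP) decomposition fitted by
alternating least squares, the core consistency diagnostic for CP rank
selection, and coupled matrix-tensor factorization (CMTF): the joint
least-squares problem

    min_{A,B,C,D}  ||X - [[A, B, C]]||^2 + ||Y - A D^T||^2

over a 3-way tensor X and a matrix Y sharing their first-mode factor A,
solved by nonlinear conjugate gradient on the concatenated factors with the
analytic gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "SVDModel",
    "CPModel",
    "CMTFModel",
    "svd_lowrank",
    "matricize",
    "fold",
    "khatri_rao",
    "cp_als",
    "cp_reconstruct",
    "core_consistency",
    "cmtf_objective_gradient",
    "cmtf",
    "factor_match_score",
    "congruence_matrix",
    "degenerate_pairs",
]


# ---------------------------------------------------------------------------
# SVD


@dataclass
class SVDModel:
    """Truncated SVD with explained-variance bookkeeping.

    ``explained_variance`` holds sigma_i^2 / sum_j sigma_j^2 with the
    denominator taken over *all* singular values of the input, so the
    fractions of a truncation sum to less than 1.
    """

    U: np.ndarray
    singular_values: np.ndarray
    V: np.ndarray
    explained_variance: np.ndarray

    @property
    def rank(self) -> int:
        return len(self.singular_values)

    def scores(self) -> np.ndarray:
        """Per-column (sample) coordinates: sigma_i * v_i rows -> (n, K)."""
        return self.V * self.singular_values[None, :]

    def reconstruct(self) -> np.ndarray:
        return (self.U * self.singular_values[None, :]) @ self.V.T


def svd_lowrank(matrix: np.ndarray, k: Optional[int] = None) -> SVDModel:
    """Best rank-``k`` approximation of a matrix (Eckart-Young).

    ``k=None`` keeps the full decomposition.  Singular values are returned
    non-increasing; explained-variance fractions are relative to the total
    variance of the input.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2:
        raise ValueError("input must be a matrix")
    if not np.isfinite(M).all():
        raise ValueError("non-finite entries in input")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    total = float((s**2).sum())
    if k is None:
        k = len(s)
    if not 1 <= k <= len(s):
        raise ValueError(f"k must be in [1, {len(s)}], got {k}")
    ev = s**2 / total if total > 0 else np.zeros_like(s)
    return SVDModel(U[:, :k], s[:k], Vt[:k].T, ev[:k])


# ---------------------------------------------------------------------------
# Tensor algebra


def matricize(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding: mode ``mode`` becomes rows, remaining modes are
    flattened into columns with the first remaining mode varying fastest."""
    X = np.asarray(tensor)
    if not 0 <= mode < X.ndim:
        raise ValueError(f"mode must be in [0, {X.ndim - 1}], got {mode}")
    return np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1, order="F")


def fold(matrix: np.ndarray, mode: int, shape: Sequence[int]) -> np.ndarray:
    """Inverse of :func:`matricize`: restore the unfolding to shape."""
    shape = tuple(shape)
    if not 0 <= mode < len(shape):
        raise ValueError("invalid mode")
    moved = (shape[mode],) + shape[:mode] + shape[mode + 1 :]
    return np.moveaxis(matrix.reshape(moved, order="F"), 0, mode)


def khatri_rao(matrices: Sequence[np.ndarray]) -> np.ndarray:
    """Column-wise Khatri-Rao product, first matrix varying fastest.

    Matches the unfolding convention: for X = [[A, B, C]],
    ``matricize(X, 0) = A @ khatri_rao([B, C]).T``.
    """
    rank = matrices[0].shape[1]
    out = matrices[0]
    for M in matrices[1:]:
        if M.shape[1] != rank:
            raise ValueError("all matrices must share the column count")
        out = (out[:, None, :] * M[None, :, :]).reshape(-1, rank, order="F")
    return out


def cp_reconstruct(factors: Sequence[np.ndarray], weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Dense tensor from CP factors (sum of weighted rank-one terms)."""
    rank = factors[0].shape[1]
    if weights is None:
        weights = np.ones(rank)
    A = factors[0] * weights[None, :]
    M1 = A @ khatri_rao(list(factors[1:])).T
    return fold(M1, 0, [f.shape[0] for f in factors])


# ---------------------------------------------------------------------------
# CP by alternating least squares


@dataclass
class CPModel:
    """CP decomposition: unit-norm factor columns with weights.

    Reconstruction is ``sum_r weights[r] * a_r o b_r o c_r``; ``fit`` is the
    percentage ``100 * (1 - ||X - Xhat|| / ||X||)``.
    """

    factors: list[np.ndarray]
    weights: np.ndarray
    fit: float = float("nan")
    fit_history: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    @property
    def rank(self) -> int:
        return len(self.weights)

    def reconstruct(self) -> np.ndarray:
        return cp_reconstruct(self.factors, self.weights)


def _normalize_cp(factors: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
    """Unit-norm columns, non-negative weights, deterministic signs.

    Signs of every mode but the first are fixed so each column's largest-
    magnitude entry is positive; the residual sign lands in the first mode so
    the weights stay non-negative.
    """
    weights = np.ones(factors[0].shape[1])
    normed = []
    for f in factors:
        norms = np.linalg.norm(f, axis=0)
        norms = np.where(norms > 0, norms, 1.0)
        weights = weights * norms
        normed.append(f / norms)
    for i in range(1, len(normed)):
        idx = np.argmax(np.abs(normed[i]), axis=0)
        signs = np.sign(normed[i][idx, np.arange(normed[i].shape[1])])
        signs = np.where(signs == 0, 1.0, signs)
        normed[i] = normed[i] * signs
        normed[0] = normed[0] * signs
    return normed, weights


def _cp_fit(X: np.ndarray, factors: list[np.ndarray], weights: np.ndarray, normX: float) -> float:
    resid = np.linalg.norm(X - cp_reconstruct(factors, weights))
    return 100.0 * (1.0 - resid / normX) if normX > 0 else 100.0


def _hosvd_init(X: np.ndarray, rank: int, rng: np.random.Generator) -> list[np.ndarray]:
    factors = []
    for mode in range(X.ndim):
        Xn = matricize(X, mode)
        U, _, _ = np.linalg.svd(Xn, full_matrices=False)
        dim = X.shape[mode]
        if U.shape[1] >= rank:
            factors.append(U[:, :rank])
        else:  # pad with random columns when the mode is too small
            pad = rng.standard_normal((dim, rank - U.shape[1]))
            factors.append(np.hstack([U, pad / np.linalg.norm(pad, axis=0)]))
    return factors


def cp_als(
    tensor: np.ndarray,
    rank: int,
    n_restarts: int = 3,
    init: str = "random",
    tol: float = 1e-9,
    max_iter: int = 500,
    seed: int | np.random.SeedSequence = 0,
) -> CPModel:
    """Fit an R-component CP model by alternating least squares.

    Each restart iterates least-squares updates of one factor matrix at a
    time (so the model fit is non-decreasing across iterations) until the
    relative fit change drops below ``tol`` or ``max_iter`` is reached; the
    best-fitting restart is returned.  ``init`` is ``"random"`` or
    ``"hosvd"`` (higher-order SVD for the first restart, random for the
    rest).  Deterministic given ``seed``.
    """
    X = np.asarray(tensor, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite entries in tensor")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > min(X.shape):
        warnings.warn(
            f"rank {rank} exceeds the smallest mode dimension {min(X.shape)}; "
            "the CP model is still defined but may be degenerate",
            stacklevel=2,
        )
    N = X.ndim
    normX = float(np.linalg.norm(X))
    unfoldings = [matricize(X, n) for n in range(N)]
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = root.spawn(n_restarts)
    best: Optional[CPModel] = None
    for r_idx in range(n_restarts):
        rng = np.random.default_rng(streams[r_idx])
        if init == "hosvd" and r_idx == 0:
            factors = _hosvd_init(X, rank, rng)
        elif init in ("random", "hosvd"):
            factors = [rng.standard_normal((d, rank)) for d in X.shape]
        else:
            raise ValueError(f"unknown init {init!r}")
        fit_history: list[float] = []
        prev_fit = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            for mode in range(N):
                others = [factors[n] for n in range(N) if n != mode]
                kr = khatri_rao(others)
                gram = np.ones((rank, rank))
                for n in range(N):
                    if n != mode:
                        gram *= factors[n].T @ factors[n]
                factors[mode] = unfoldings[mode] @ kr @ np.linalg.pinv(gram)
            normed, weights = _normalize_cp([f.copy() for f in factors])
            fit = _cp_fit(X, normed, weights, normX)
            fit_history.append(fit)
            if abs(fit - prev_fit) < tol * 100.0:
                converged = True
                break
            prev_fit = fit
        normed, weights = _normalize_cp(factors)
        model = CPModel(
            factors=normed,
            weights=weights,
            fit=fit_history[-1],
            fit_history=fit_history,
            n_iter=it,
            converged=converged,
        )
        if best is None or model.fit > best.fit:
            best = model
    return best


def core_consistency(tensor: np.ndarray, model: CPModel) -> float:
    """Core consistency diagnostic of a fitted CP model (<= 100).

    Computes the least-squares Tucker core G given the CP factors (weights
    absorbed into the first mode) and measures how close G is to the
    superdiagonal identity: ``100 * (1 - ||G - I||^2 / R)``.  Values near 100
    support the chosen number of components; low or negative values indicate
    over-factoring.
    """
    X = np.asarray(tensor, dtype=float)
    R = model.rank
    factors = [model.factors[0] * model.weights[None, :]] + [
        f.copy() for f in model.factors[1:]
    ]
    for f in factors:
        sv = np.linalg.svd(f, compute_uv=False)
        if sv[-1] <= 1e-12 * max(sv[0], 1.0):
            raise ValueError("rank-deficient factor matrix: core is not identifiable")
    G = X
    for mode, f in enumerate(factors):
        pinv = np.linalg.pinv(f)
        G = fold(pinv @ matricize(G, mode), mode, G.shape[:mode] + (R,) + G.shape[mode + 1 :])
    T = np.zeros((R,) * X.ndim)
    idx = np.arange(R)
    T[tuple(idx for _ in range(X.ndim))] = 1.0
    return float(100.0 * (1.0 - ((G - T) ** 2).sum() / R))


# ---------------------------------------------------------------------------
# Coupled matrix-tensor factorization


@dataclass
class CMTFModel:
    """CMTF solution: shared features-mode factor A, tensor factors B, C,
    matrix factor D, and the final value of the coupled objective."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    objective: float
    converged: bool = False
    n_iter: int = 0

    @property
    def rank(self) -> int:
        return self.A.shape[1]

    @property
    def factors(self) -> list[np.ndarray]:
        return [self.A, self.B, self.C, self.D]

    def reconstruct(self) -> tuple[np.ndarray, np.ndarray]:
        return cp_reconstruct([self.A, self.B, self.C]), self.A @ self.D.T


def _pack(factors: Sequence[np.ndarray]) -> np.ndarray:
    return np.concatenate([f.ravel() for f in factors])


def _unpack(x: np.ndarray, shapes: Sequence[tuple[int, int]]) -> list[np.ndarray]:
    out, k = [], 0
    for s in shapes:
        size = s[0] * s[1]
        out.append(x[k : k + size].reshape(s))
        k += size
    return out


def cmtf_objective_gradient(
    factors: Sequence[np.ndarray], tensor: np.ndarray, matrix: np.ndarray
) -> tuple[float, list[np.ndarray]]:
    """Coupled objective ``||X - [[A,B,C]]||^2 + ||Y - A D^T||^2`` and its
    analytic gradient with respect to each factor matrix.

    Returns ``(objective, [dA, dB, dC, dD])``; callers concatenate the
    per-factor derivatives for gradient-based optimization.
    """
    A, B, C, D = factors
    X = np.asarray(tensor, dtype=float)
    Y = np.asarray(matrix, dtype=float)
    R = A.shape[1]
    if B.shape[1] != R or C.shape[1] != R or D.shape[1] != R:
        raise ValueError("all factors must share the component count")
    if X.shape != (A.shape[0], B.shape[0], C.shape[0]) or Y.shape != (A.shape[0], D.shape[0]):
        raise ValueError(
            f"shape mismatch: tensor {X.shape} vs factors "
            f"({A.shape[0]}, {B.shape[0]}, {C.shape[0]}); matrix {Y.shape} vs "
            f"({A.shape[0]}, {D.shape[0]})"
        )
    X1 = matricize(X, 0)
    X2 = matricize(X, 1)
    X3 = matricize(X, 2)
    BtB, CtC, AtA, DtD = B.T @ B, C.T @ C, A.T @ A, D.T @ D
    kr_cb = khatri_rao([B, C])
    resid_t = X1 - A @ kr_cb.T
    resid_m = Y - A @ D.T
    obj = float((resid_t**2).sum() + (resid_m**2).sum())
    dA = -2.0 * X1 @ kr_cb + 2.0 * A @ (BtB * CtC) - 2.0 * Y @ D + 2.0 * A @ DtD
    dB = -2.0 * X2 @ khatri_rao([A, C]) + 2.0 * B @ (AtA * CtC)
    dC = -2.0 * X3 @ khatri_rao([A, B]) + 2.0 * C @ (AtA * BtB)
    dD = -2.0 * Y.T @ A + 2.0 * D @ AtA
    return obj, [dA, dB, dC, dD]


def cmtf(
    tensor: np.ndarray,
    matrix: np.ndarray,
    rank: int,
    init: str = "cp",
    tol: float = 1e-10,
    max_iter: int = 2000,
    n_restarts: int = 3,
    seed: int | np.random.SeedSequence = 0,
) -> CMTFModel:
    """Fit an R-component CMTF model by nonlinear conjugate gradient.

    All four factor matrices are optimized simultaneously on the concatenated
    parameter vector (Polak-Ribiere NCG with Wolfe line search via
    ``scipy.optimize.minimize(method="CG")``).  With ``init="cp"`` the first
    restart starts from a CP fit of the tensor plus the least-squares D;
    remaining restarts are random.  The best (lowest-objective) restart is
    returned.  Deterministic given ``seed``.
    """
    X = np.asarray(tensor, dtype=float)
    Y = np.asarray(matrix, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite entries in input")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("tensor and matrix must share their first dimension")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    shapes = [(X.shape[0], rank), (X.shape[1], rank), (X.shape[2], rank), (Y.shape[1], rank)]
    scale = float(np.linalg.norm(X) ** 2 + np.linalg.norm(Y) ** 2)

    def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
        factors = _unpack(x, shapes)
        obj, grads = cmtf_objective_gradient(factors, X, Y)
        return obj, _pack(grads)

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = root.spawn(n_restarts)
    best: Optional[CMTFModel] = None
    for r_idx in range(n_restarts):
        rng = np.random.default_rng(streams[r_idx])
        if init == "cp" and r_idx == 0:
            cp = cp_als(X, rank, n_restarts=1, seed=streams[r_idx], max_iter=200)
            A0 = cp.factors[0] * cp.weights[None, :]
            D0 = np.linalg.lstsq(A0, Y, rcond=None)[0].T
            x0 = _pack([A0, cp.factors[1], cp.factors[2], D0])
        elif init in ("cp", "random"):
            x0 = _pack([rng.standard_normal(s) for s in shapes])
        else:
            raise ValueError(f"unknown init {init!r}")
        res = minimize(
            fun,
            x0,
            jac=True,
            method="CG",
            options={"gtol": tol * max(scale, 1.0), "maxiter": max_iter},
        )
        A, B, C, D = _unpack(res.x, shapes)
        model = CMTFModel(
            A=A, B=B, C=C, D=D, objective=float(res.fun),
            converged=bool(res.success), n_iter=int(res.nit),
        )
        if best is None or model.objective < best.objective:
            best = model
    return best


# ---------------------------------------------------------------------------
# Factor comparison


def _component_cosines(F1: np.ndarray, F2: np.ndarray) -> np.ndarray:
    """|cosine| similarity matrix between columns of two factor matrices."""
    n1 = np.linalg.norm(F1, axis=0)
    n2 = np.linalg.norm(F2, axis=0)
    n1 = np.where(n1 > 0, n1, 1.0)
    n2 = np.where(n2 > 0, n2, 1.0)
    return (F1 / n1).T @ (F2 / n2)


def factor_match_score(
    factors1: Sequence[np.ndarray], factors2: Sequence[np.ndarray]
) -> float:
    """Permutation-, sign- and scale-invariant similarity of two factor sets.

    For the best component matching (Hungarian assignment) the score is the
    mean over components of the product over modes of absolute cosine
    similarities; 1.0 means the factor sets span identical components.
    """
    from scipy.optimize import linear_sum_assignment

    if len(factors1) != len(factors2):
        raise ValueError("factor sets must cover the same modes")
    r1 = factors1[0].shape[1]
    r2 = factors2[0].shape[1]
    if r1 != r2:
        raise ValueError(f"rank mismatch: {r1} vs {r2}")
    for f1, f2 in zip(factors1, factors2):
        if f1.shape != f2.shape:
            raise ValueError("factor shapes must match mode by mode")
    score = np.ones((r1, r1))
    for f1, f2 in zip(factors1, factors2):
        score *= np.abs(_component_cosines(f1, f2))
    rows, cols = linear_sum_assignment(-score)
    return float(score[rows, cols].mean())


def congruence_matrix(factors: Sequence[np.ndarray]) -> np.ndarray:
    """Signed multi-mode congruence between components of one model:
    product over modes of cosine similarities between component pairs."""
    r = factors[0].shape[1]
    cong = np.ones((r, r))
    for f in factors:
        cong *= _component_cosines(f, f)
    return cong


def degenerate_pairs(
    factors: Sequence[np.ndarray], threshold: float = -0.85
) -> list[tuple[int, int, float]]:
    """Component pairs whose congruence falls below ``threshold``.

    Strongly negatively correlated component pairs are the signature of a
    degenerate (over-factored) CP/CMTF solution.
    """
    cong = congruence_matrix(factors)
    r = cong.shape[0]
    return [
        (i, j, float(cong[i, j]))
        for i in range(r)
        for j in range(i + 1, r)
        if cong[i, j] < threshold
    ]
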
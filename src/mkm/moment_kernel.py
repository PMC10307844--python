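"""Vandermonde moment kernel: probability rows -> truncated moment vectors.

Each patient row ``p_i`` of a row-stochastic matrix is the distribution of a
dummy random variable A over the sample space Omega = {alpha_1, ..., alpha_M}
given by the HSIC importance weights. The k-th moment of A under ``p_i`` is

    m_ik = E[A^k] = sum_j alpha_j^k p_ij,       k = 0, ..., M' - 1,

so the full moment vector is ``m_i = p_i @ V`` where V is the M x M'
Vandermonde matrix with entries alpha_j^k. With distinct alpha and M' = M the
map is a bijection (det V = prod_{k<l} (alpha_l - alpha_k), the classical
Vandermonde determinant; discrete Hausdorff moment problem), so no
information is lost; truncating to M' << M gives the low-dimensional moment
features used for classification.

By default alpha is rescaled to [0, 1] by dividing by its maximum before
powering: this is an invertible relabeling of Omega that keeps high powers
from overflowing and makes the moment sequence of every row non-increasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "MomentKernel",
    "build_kernel",
    "compute_moments",
    "invert_moments",
    "select_order",
]

_CONDITION_GUARD = 12  # full-order inversion is numerically hopeless beyond this


@dataclass
class MomentKernel:
    """M x M' Vandermonde matrix generated by the sample-space points alpha."""

    alpha: np.ndarray  # sample-space points actually powered (possibly rescaled)
    order: int
    matrix: np.ndarray
    rescaled: bool = True

    @property
    def n_features(self) -> int:
        return len(self.alpha)


def build_kernel(alpha, order: int, *, rescale: bool = True) -> MomentKernel:
    """Build the Vandermonde moment kernel from importance weights.

    ``alpha`` may be a plain vector or an ``ImportanceWeights`` object; it
    must be non-negative with at least one positive entry. ``order`` is the
    number of moments M' (columns k = 0..M'-1). ``rescale`` divides alpha by
    its maximum so all sample-space points lie in [0, 1].
    """
    a = np.asarray(getattr(alpha, "alpha", alpha), dtype=float).ravel()
    if np.any(a < 0):
        raise ValueError("alpha must be non-negative")
    # order > len(a) is allowed for the forward map (the extra moments are
    # simply higher powers); inversion requires a square kernel.
    if order < 1:
        raise ValueError("order must be at least 1")
    peak = a.max()
    if peak == 0:
        raise ValueError("all importance weights are zero; lower the HSIC penalty")
    if rescale:
        a = a / peak
    matrix = np.vander(a, N=order, increasing=True)
    return MomentKernel(alpha=a, order=order, matrix=matrix, rescaled=rescale)


def compute_moments(P: np.ndarray, kernel: MomentKernel) -> np.ndarray:
    """Map probability rows to their first M' moments: ``P @ V``.

    The zeroth column is identically 1 (total probability); with rescaled
    alpha every row's moment sequence is non-negative and non-increasing.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if P.shape[1] != kernel.matrix.shape[0]:
        raise ValueError(
            f"P has {P.shape[1]} columns but the kernel expects {kernel.matrix.shape[0]}"
        )
    return P @ kernel.matrix


def invert_moments(m: np.ndarray, kernel: MomentKernel) -> np.ndarray:
    """Recover probability rows from full-order moment vectors.

    Requires pairwise-distinct alpha (otherwise the Vandermonde matrix is
    singular by the determinant product formula) and M' = M. The linear
    system ``p @ V = m`` is solved directly; beyond M ~ 12 the Vandermonde
    conditioning makes the reconstruction unreliable and a warning is issued.
    """
    V = kernel.matrix
    if V.shape[0] != V.shape[1]:
        raise ValueError("inversion requires a full-order (square) kernel")
    a = kernel.alpha
    if len(np.unique(a)) != len(a):
        raise ValueError("duplicate sample-space points: Vandermonde matrix is singular")
    if V.shape[0] > _CONDITION_GUARD:
        warnings.warn(
            f"inverting a {V.shape[0]}-point Vandermonde system is ill-conditioned",
            stacklevel=2,
        )
    m = np.asarray(m, dtype=float)
    squeeze = m.ndim == 1
    m2 = np.atleast_2d(m)
    p = np.linalg.solve(V.T, m2.T).T
    return p[0] if squeeze else p


def select_order(
    P: np.ndarray,
    y: np.ndarray,
    alpha,
    candidate_orders,
    classifier_spec=None,
    folds: int = 5,
    seed: int = 0,
    return_curve: bool = False,
):
    """Pick the moment order maximizing stratified cross-validated AUC.

    Higher orders add near-collinear powers of alpha and eventually overfit,
    so the AUC-vs-order curve typically peaks at a low order. Ties are broken
    toward the smaller order (parsimony). ``classifier_spec`` defaults to
    weighted logistic regression.
    """
    from .classifiers import ClassifierSpec, fit_predict
    from .evaluate import auc

    P = np.asarray(P, dtype=float)
    y = np.asarray(y)
    candidates = sorted(set(int(o) for o in candidate_orders))
    if not candidates:
        raise ValueError("no candidate orders")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if min(np.bincount(y.astype(int))) < folds:
        raise ValueError("too few samples in the minority class to stratify")
    spec = classifier_spec or ClassifierSpec(family="LR", seed=seed)

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(P, y))
    mean_aucs = []
    for order in candidates:
        kernel = build_kernel(alpha, order)
        moments = compute_moments(P, kernel)
        fold_aucs = [
            auc(fit_predict(moments[tr], y[tr], moments[te], spec), y[te])
            for tr, te in splits
        ]
        mean_aucs.append(float(np.mean(fold_aucs)))
    best = int(np.argmax(mean_aucs))  # argmax takes the first (smallest) on ties
    if return_curve:
        return candidates[best], dict(zip(candidates, mean_aucs))
    return candidates[best]
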
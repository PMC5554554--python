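"""Gaussian-entropy mutual information and conditional mutual information.

Under a multivariate normal model the differential entropy of a block of
variables is determined by the log-determinant of its covariance, so

    MI(x, y)        = 1/2 * ln( |C(x)| |C(y)| / |C(x, y)| )
    CMI(x, y | Z)   = 1/2 * ln( |C(x,Z)| |C(y,Z)| / ( |C(Z)| |C(x,y,Z)| ) )

with |C(empty)| = 1.  All values are in nats.  For one-dimensional x, y the
marginal MI reduces to -1/2 * ln(1 - r^2) with r the sample correlation.

The estimators accept any numeric columns; in the TPDA pipeline they are
normally fed the discretized integer codes (treated as numeric), which is
what makes the learned network sensitive to the N-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ParameterError, SizeError, UnknownNameError

#: relative ridge added to the diagonal of a numerically singular covariance
RIDGE_SCALE = 1e-10
#: condition number beyond which a covariance is treated as singular
CONDITION_LIMIT = 1e12


@dataclass
class GaussianStats:
    """Sample covariance (unbiased, n-1 denominator) over an ordered variable subset."""

    variables: list[str]
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        k = len(self.variables)
        if self.cov.shape != (k, k):
            raise SizeError(f"covariance shape {self.cov.shape} for {k} variables")
        if not np.allclose(self.cov, self.cov.T, atol=1e-12):
            raise SizeError("covariance matrix is not symmetric")


def covariance(
    values: np.ndarray, variables: Sequence[str], subset: Sequence[str]
) -> GaussianStats:
    """Unbiased sample covariance of the ``subset`` columns, in subset order."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise SizeError("covariance needs at least 2 samples")
    if not subset:
        raise SizeError("subset must be nonempty")
    index = {name: j for j, name in enumerate(variables)}
    missing = [s for s in subset if s not in index]
    if missing:
        raise UnknownNameError(f"unknown variables: {missing}")
    cols = values[:, [index[s] for s in subset]]
    cov = np.cov(cols, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return GaussianStats(variables=list(subset), cov=cov)


def _logdet(cov: np.ndarray) -> float:
    """log|C| with ridge regularization for numerically singular matrices.

    Returns -inf when the determinant is not positive even after the ridge.
    """
    if cov.size == 0:
        return 0.0
    cov = np.atleast_2d(cov)
    diag = np.diag(cov)
    if np.any(diag <= 0):
        return -math.inf
    if np.linalg.cond(cov) > CONDITION_LIMIT:
        cov = cov + RIDGE_SCALE * float(diag.mean()) * np.eye(cov.shape[0])
    sign, ld = np.linalg.slogdet(cov)
    if sign <= 0:
        return -math.inf
    return float(ld)


def mi_from_covariance(cov: np.ndarray, i: int, j: int) -> float:
    """MI between variables ``i`` and ``j`` of a joint covariance matrix."""
    return cmi_from_covariance(cov, i, j, ())


def cmi_from_covariance(
    cov: np.ndarray, i: int, j: int, cond: Sequence[int]
) -> float:
    """CMI between variables ``i`` and ``j`` given the ``cond`` variables.

    Evaluates the determinant ratio directly on the supplied covariance, so
    exact (population) covariances give exact information values.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise SizeError(f"covariance must be square, got shape {cov.shape}")
    cond = list(cond)
    if i == j or i in cond or j in cond:
        raise SizeError("i, j and the conditioning set must be disjoint")
    if cov[i, i] == 0 or cov[j, j] == 0:
        return 0.0  # a constant variable carries no information
    sub = lambda idx: cov[np.ix_(idx, idx)]
    joint = sub([i, j] + cond)
    sign, ld_joint = np.linalg.slogdet(joint)
    if sign <= 0 or np.linalg.cond(joint) > CONDITION_LIMIT:
        # x and y perfectly collinear given Z: infinite dependence sentinel
        warnings.warn(
            "singular joint covariance (perfect collinearity); returning +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf
    num = _logdet(sub([i] + cond)) + _logdet(sub([j] + cond))
    den = _logdet(sub(cond)) + ld_joint
    if num == -math.inf or den == -math.inf:
        # a conditioning block is degenerate: x or y fully explained by Z
        return 0.0
    return max(0.5 * (num - den), 0.0)


def _stack(*cols: np.ndarray) -> np.ndarray:
    arrs = [np.asarray(c, dtype=float) for c in cols]
    n = arrs[0].shape[0]
    for a in arrs:
        if a.ndim not in (1, 2) or a.shape[0] != n:
            raise SizeError("all inputs must share the sample dimension")
    return np.column_stack(arrs)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian-entropy MI of two columns, in nats; 0 if either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SizeError(f"x and y must be equal-length vectors, got {x.shape}, {y.shape}")
    if x.shape[0] < 3:
        raise SizeError("need at least 3 samples")
    if x.tobytes() > y.tobytes():  # canonical order => exact symmetry
        x, y = y, x
    cov = np.cov(_stack(x, y), rowvar=False, ddof=1)
    return mi_from_covariance(cov, 0, 1)


def conditional_mutual_information(
    x: np.ndarray, y: np.ndarray, cutset: np.ndarray | None = None
) -> float:
    """Gaussian-entropy CMI of x and y given the cut-set columns, in nats.

    ``cutset`` is a samples x k matrix (or None / zero columns for the
    unconditional case, where the result equals :func:`mutual_information`).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SizeError(f"x and y must be equal-length vectors, got {x.shape}, {y.shape}")
    if cutset is None or (hasattr(cutset, "size") and np.asarray(cutset).size == 0):
        return mutual_information(x, y)
    z = np.asarray(cutset, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if z.shape[0] != x.shape[0]:
        raise SizeError("cutset sample dimension does not match x, y")
    if x.tobytes() > y.tobytes():  # canonical order => exact symmetry
        x, y = y, x
    data = _stack(x, y, z)
    cov = np.cov(data, rowvar=False, ddof=1)
    return cmi_from_covariance(cov, 0, 1, list(range(2, data.shape[1])))


def is_independent(
    x: np.ndarray, y: np.ndarray, cutset: np.ndarray | None, eps: float
) -> bool:
    """Thresholded conditional-independence verdict.

    True iff CMI(x, y | cutset) <= eps: dependence requires the information to
    be strictly greater than the threshold, so the boundary counts as
    independent.
    """
    if eps <= 0:
        raise ParameterError(f"threshold must be positive, got {eps}")
    return conditional_mutual_information(x, y, cutset) <= eps
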
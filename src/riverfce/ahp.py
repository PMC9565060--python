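"""Analytic hierarchy process: eigenvector weights and consistency testing.

A judgment matrix A is a positive reciprocal pairwise-comparison matrix
(a_ii = 1, a_ij * a_ji = 1), usually filled on Saaty's 1-9 scale.  Its
normalized principal (Perron) eigenvector gives the priority weights; the
quality of the judgments is measured by

    lambda_max = sum_k (A w)_k / (n w_k)
    CI = (lambda_max - n) / (n - 1)
    CR = CI / RI(n)

with RI the random-consistency index.  A matrix is accepted when CR < 0.1
(2x2 reciprocal matrices are always consistent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import MatrixValidationError, NumericalError, UnsupportedOrderError

#: Saaty random-consistency index, extended beyond order 10 with the
#: commonly tabulated values.
RANDOM_INDEX: dict[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32,
    8: 1.41, 9: 1.45, 10: 1.49, 11: 1.52, 12: 1.54, 13: 1.56,
    14: 1.58, 15: 1.59,
}

#: Admissible entries when a matrix is built from 1-9 scale judgments.
SAATY_SCALE: tuple[float, ...] = tuple(
    sorted({float(k) for k in range(1, 10)} | {1.0 / k for k in range(1, 10)})
)

_RECIPROCAL_TOL = 1e-9


@dataclass(frozen=True)
class JudgmentMatrix:
    """A validated positive reciprocal pairwise-comparison matrix."""

    matrix: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", a)
        n = a.shape[0] if a.ndim == 2 else 0
        if a.ndim != 2 or a.shape[0] != a.shape[1] or n < 2:
            raise MatrixValidationError("judgment matrix must be square with n >= 2")
        if len(self.labels) != n:
            raise MatrixValidationError("label count does not match matrix order")
        if not np.all(a > 0):
            raise MatrixValidationError("judgment matrix entries must be positive")
        if not np.allclose(np.diag(a), 1.0, atol=_RECIPROCAL_TOL):
            raise MatrixValidationError("judgment matrix diagonal must be 1")
        if not np.allclose(a * a.T, 1.0, atol=_RECIPROCAL_TOL):
            raise MatrixValidationError("judgment matrix is not reciprocal")

    @property
    def order(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_upper_triangle(
        cls, entries: Sequence[float], labels: Sequence[str]
    ) -> "JudgmentMatrix":
        """Build from the strict upper triangle, row by row; reciprocals and
        the unit diagonal are filled in."""
        n = len(labels)
        if len(entries) != n * (n - 1) // 2:
            raise MatrixValidationError(
                f"expected {n * (n - 1) // 2} upper-triangle entries, got {len(entries)}"
            )
        a = np.eye(n)
        it = iter(entries)
        for i in range(n):
            for j in range(i + 1, n):
                v = float(next(it))
                a[i, j] = v
                a[j, i] = 1.0 / v
        return cls(a, tuple(labels))


@dataclass(frozen=True)
class ConsistencyReport:
    """lambda_max, CI, RI and CR for one judgment matrix."""

    lambda_max: float
    ci: float
    ri: float
    cr: float
    acceptable: bool


def principal_weights(
    A: JudgmentMatrix, tol: float = 1e-12, max_iter: int = 10_000
) -> np.ndarray:
    """Normalized principal eigenvector of a judgment matrix.

    Power iteration with L1 normalization: for a positive matrix the
    dominant eigenvalue is simple (Perron-Frobenius), so the iteration
    converges to the unique positive priority vector summing to 1.
    """
    a = A.matrix
    n = A.order
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        v = a @ w
        w_new = v / v.sum()
        if np.max(np.abs(w_new - w)) < tol:
            return w_new
        w = w_new
    raise NumericalError(
        f"power iteration did not converge within {max_iter} iterations"
    )


def consistency(A: JudgmentMatrix, w: np.ndarray) -> ConsistencyReport:
    """Consistency test of ``A`` given its priority vector ``w``."""
    n = A.order
    if n not in RANDOM_INDEX:
        raise UnsupportedOrderError(
            f"no random-consistency index for order {n} (supported: 1..{max(RANDOM_INDEX)})"
        )
    aw = A.matrix @ w
    lambda_max = float(np.sum(aw / (n * w)))
    ci = (lambda_max - n) / (n - 1)
    ri = RANDOM_INDEX[n]
    if n <= 2:
        cr = 0.0
    else:
        cr = ci / ri
    return ConsistencyReport(
        lambda_max=lambda_max, ci=ci, ri=ri, cr=cr, acceptable=(n <= 2 or cr < 0.1)
    )


def weigh(A: JudgmentMatrix) -> tuple[np.ndarray, ConsistencyReport]:
    """Convenience: priority vector plus its consistency report."""
    w = principal_weights(A)
    return w, consistency(A, w)


def combine_levels(
    parent_w: Mapping[str, float], child_w: Mapping[str, Mapping[str, float]]
) -> dict[str, float]:
    """Combine a parent-level weight vector with within-parent child vectors
    into global leaf weights (leaf weight = parent weight x local weight).

    The result sums to 1 when the inputs do."""
    out: dict[str, float] = {}
    for parent, pw in parent_w.items():
        if parent not in child_w:
            raise MatrixValidationError(f"no child weight vector for parent {parent!r}")
        for child, cw in child_w[parent].items():
            if child in out:
                raise MatrixValidationError(f"leaf {child!r} appears under two parents")
            out[child] = pw * cw
    return out


def hierarchy_consistency(
    parent_w: Mapping[str, float], reports: Mapping[str, ConsistencyReport]
) -> float:
    """Combined consistency ratio of a two-level hierarchy: the parent-weighted
    mean CI of the child matrices over the parent-weighted mean RI.

    This is the standard aggregate test; matrices of order <= 2 (RI = 0)
    contribute nothing to either sum."""
    num = 0.0
    den = 0.0
    for parent, pw in parent_w.items():
        r = reports[parent]
        num += pw * r.ci
        den += pw * r.ri
    return num / den if den > 0 else 0.0
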
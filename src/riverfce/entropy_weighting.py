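"""Entropy-weight method: objective indicator weights from observed dispersion.

Given the raw matrix X (evaluation units x indicators), each column is
min-max normalized according to its direction, shifted proportions

    f_ij = (1 + r_ij) / sum_j (1 + r_ij)

are formed over the n evaluation units, and the normalized Shannon entropy

    H'_i = - sum_j f_ij ln f_ij / ln n            (H' in [0, 1])

yields the weights

    omega_i = (1 - H'_i) / (m - sum H')           (sum omega = 1).

A column that is constant across units carries no discriminating
information: its normalized values are defined as 1, giving H' = 1 and
weight exactly 0.  The +1 shift keeps the proportions strictly positive, so
the entropy is always finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, MatrixValidationError
from .indicator_system import IndicatorSpec


@dataclass(frozen=True)
class EntropyResult:
    """All intermediates of the entropy-weighting chain."""

    normalized: pd.DataFrame  # r_ij in [0, 1]
    proportions: pd.DataFrame  # f_ij, columns sum to 1
    entropy: pd.Series  # H'_i per indicator
    weights: pd.Series  # omega_i, sums to 1


def validate_data_matrix(
    X: pd.DataFrame, specs: Mapping[str, IndicatorSpec] | Sequence[IndicatorSpec]
) -> Mapping[str, IndicatorSpec]:
    """Check a units x indicators data matrix against the indicator system."""
    if not isinstance(specs, Mapping):
        specs = {s.id: s for s in specs}
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise MatrixValidationError(f"data matrix has missing cells in {bad}")
    unknown = [c for c in X.columns if c not in specs]
    if unknown:
        raise MatrixValidationError(f"data matrix columns without a spec: {unknown}")
    return specs


def normalize_matrix(
    X: pd.DataFrame, specs: Mapping[str, IndicatorSpec] | Sequence[IndicatorSpec]
) -> pd.DataFrame:
    """Direction-aware min-max normalization to [0, 1] per indicator column.

    positive:      (x - min) / (max - min)
    negative:      (max - x) / (max - min)
    bidirectional: distance from the ideal central band's center, then
                   treated as negative (closer to the band is better)
    categorical:   the ordinal score is treated as positive

    Constant columns normalize to all ones (degenerate-column rule)."""
    specs = validate_data_matrix(X, specs)
    out = pd.DataFrame(index=X.index, columns=X.columns, dtype=float)
    for col in X.columns:
        spec = specs[col]
        x = X[col].to_numpy(dtype=float)
        if spec.direction == "bidirectional":
            x = np.abs(x - spec.ideal_center)
            sense = "negative"
        elif spec.direction == "negative":
            sense = "negative"
        else:  # positive and categorical scores: larger is better
            sense = "positive"
        xmin, xmax = x.min(), x.max()
        if xmax == xmin:
            out[col] = 1.0
        elif sense == "positive":
            out[col] = (x - xmin) / (xmax - xmin)
        else:
            out[col] = (xmax - x) / (xmax - xmin)
    return out


def proportions(normalized: pd.DataFrame) -> pd.DataFrame:
    """Shifted proportions f_ij = (1 + r_ij) / sum_j (1 + r_ij) per column."""
    shifted = 1.0 + normalized
    return shifted / shifted.sum(axis=0)


def entropy_values(normalized: pd.DataFrame) -> pd.Series:
    """Normalized Shannon entropy H' per indicator, from shifted proportions.

    n is the number of evaluation units (rows); requires n >= 2."""
    n = len(normalized.index)
    if n < 2:
        raise DegenerateDataError(
            "entropy undefined for a single evaluation unit (ln 1 = 0)"
        )
    if ((normalized < -1e-12) | (normalized > 1 + 1e-12)).any().any():
        raise MatrixValidationError("normalized values must lie in [0, 1]")
    f = proportions(normalized)
    h = -(f * np.log(f)).sum(axis=0) / math.log(n)
    # clip the inevitable last-ulp overshoot at the uniform maximum
    return h.clip(upper=1.0)


def entropy_weights(H: pd.Series) -> pd.Series:
    """Entropy weights omega_i = (1 - H'_i) / (m - sum H').

    An indicator at the entropy ceiling H' = 1 (constant column) gets weight
    exactly 0; if every indicator is at the ceiling there is no information
    to weight and :class:`DegenerateDataError` is raised."""
    h = H.astype(float)
    if ((h < -1e-9) | (h > 1 + 1e-9)).any():
        raise MatrixValidationError("entropy values must lie in [0, 1]")
    m = len(h)
    denom = m - h.sum()
    if denom <= 0:
        raise DegenerateDataError("all columns constant: entropy weights undefined")
    return (1.0 - h) / denom


def entropy_weighting(
    X: pd.DataFrame, specs: Mapping[str, IndicatorSpec] | Sequence[IndicatorSpec]
) -> EntropyResult:
    """Full chain: normalize -> proportions -> entropy -> weights."""
    r = normalize_matrix(X, specs)
    f = proportions(r)
    h = entropy_values(r)
    w = entropy_weights(h)
    return EntropyResult(normalized=r, proportions=f, entropy=h, weights=w)
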
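"""Fusion of subjective (AHP) and objective (entropy) indicator weights.

The combined weight is the weighted average

    fused_i = lam * ahp_i + (1 - lam) * entropy_i,   lam in [0, 1]

with lam = 0.5 by default (plain arithmetic mean).  Criterion-layer
combined weights are the sums of their member indicators' fused weights,
and indicators are ranked by criticality (descending fused weight, ties at
the table precision sharing the better rank).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MatrixValidationError
from .indicator_system import Hierarchy


def fuse_indicator_weights(
    ahp_w: pd.Series, ent_w: pd.Series, lam: float = 0.5
) -> pd.Series:
    """Weighted average of the two weight vectors; lam = 1 reproduces the
    AHP column, lam = 0 the entropy column."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must lie in [0, 1], got {lam}")
    if len(ahp_w) != len(ent_w):
        raise MatrixValidationError("AHP and entropy weight vectors differ in length")
    if not ahp_w.index.equals(ent_w.index):
        ent_w = ent_w.reindex(ahp_w.index)
        if ent_w.isna().any():
            raise MatrixValidationError(
                "AHP and entropy weight vectors cover different indicators"
            )
    return lam * ahp_w + (1.0 - lam) * ent_w


def aggregate_criterion_weights(fused: pd.Series, hierarchy: Hierarchy) -> pd.Series:
    """Criterion weight = sum of its member indicators' weights."""
    missing = [i for i in hierarchy.indicator_ids if i not in fused.index]
    if missing:
        raise MatrixValidationError(f"fused weights missing indicators: {missing}")
    extra = [i for i in fused.index if i not in hierarchy.indicator_ids]
    if extra:
        raise MatrixValidationError(f"weights for indicators outside the hierarchy: {extra}")
    return pd.Series(
        {c: float(fused[list(hierarchy.indicators_of(c))].sum()) for c in hierarchy.criterion_ids}
    )


def rank_criticality(weights: pd.Series, decimals: int | None = 4) -> pd.Series:
    """Descending-weight competition ranks (1 = most critical).

    Ties — judged after rounding to ``decimals`` places, the precision at
    which assessment tables are printed — share the smaller rank number and
    the next rank is skipped (1, 1, 3 ...).  Pass ``decimals=None`` to rank
    on the exact values."""
    w = weights.astype(float)
    if (w < 0).any():
        raise MatrixValidationError("criticality ranks require nonnegative weights")
    v = w.round(decimals) if decimals is not None else w
    arr = v.to_numpy()
    ranks = np.array([(arr > x).sum() + 1 for x in arr], dtype=int)
    return pd.Series(ranks, index=weights.index)


@dataclass(frozen=True)
class WeightTable:
    """Indicator- and criterion-level AHP/entropy/fused weights and ranks,
    mirroring the layout of a published assessment weight table."""

    indicators: pd.DataFrame  # columns: ahp, entropy, fused, criticality
    criteria: pd.DataFrame  # same columns, aggregated
    lam: float

    def to_csv(self, path) -> None:
        out = pd.concat(
            [self.criteria.assign(level="criterion"), self.indicators.assign(level="indicator")]
        )
        out.index.name = "id"
        out.to_csv(path, float_format="%.10g")


def build_weight_table(
    ahp_w: pd.Series, ent_w: pd.Series, hierarchy: Hierarchy, lam: float = 0.5
) -> WeightTable:
    """Assemble the full weight table from per-indicator AHP and entropy
    weight vectors.

    Criterion-level AHP and entropy columns are member sums of their
    respective indicator columns; the criterion fused column is the sum of
    member fused weights (not the mean of the criterion AHP/entropy
    aggregates — the two differ whenever the columns disagree)."""
    fused = fuse_indicator_weights(ahp_w, ent_w, lam)
    order = list(hierarchy.indicator_ids)
    ind = pd.DataFrame(
        {
            "ahp": ahp_w.reindex(order),
            "entropy": ent_w.reindex(order),
            "fused": fused.reindex(order),
        }
    )
    ind["criticality"] = rank_criticality(ind["fused"])
    crit = pd.DataFrame(
        {
            "ahp": aggregate_criterion_weights(ind["ahp"], hierarchy),
            "entropy": aggregate_criterion_weights(ind["entropy"], hierarchy),
            "fused": aggregate_criterion_weights(ind["fused"], hierarchy),
        }
    )
    crit["criticality"] = rank_criticality(crit["fused"])
    return WeightTable(indicators=ind, criteria=crit, lam=lam)
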
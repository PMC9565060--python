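"""Packaged Xiaoqing River fixtures.

* the indicator system (hierarchy + grade criteria),
* the published indicator- and criterion-level weight table (AHP column,
  entropy column, combined column, criticality ranks),
* reconstructed judgment matrices: the study's pairwise-comparison matrices
  were not published, so perfectly consistent stand-ins are rebuilt from
  the published AHP weight ratios (a_ij = w_i / w_j).  They reproduce the
  published AHP column exactly and have CR = 0 by construction; they are
  synthetic reconstructions, not the original expert judgments.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .ahp import JudgmentMatrix
from .indicator_system import Hierarchy, IndicatorSpec, load_system

#: The five administrative river sections, upstream to downstream.
SEGMENTS: tuple[str, ...] = ("Jinan", "Binzhou", "Zibo", "Dongying", "Weifang")


def default_system() -> tuple[Hierarchy, list[IndicatorSpec]]:
    """The packaged 4-criterion / 12-sub-criterion / 22-indicator system."""
    return load_system(None)


def published_weights() -> pd.DataFrame:
    """Published weight table: rows A1..A4 and C1..C22 with columns
    ``level, ahp, entropy, comprehensive, criticality``."""
    path = resources.files("riverfce.data") / "xiaoqing_weights.csv"
    return pd.read_csv(path, index_col="id")


def published_indicator_weights() -> pd.DataFrame:
    w = published_weights()
    return w[w["level"] == "indicator"].drop(columns="level")


def published_criterion_weights() -> pd.DataFrame:
    w = published_weights()
    return w[w["level"] == "criterion"].drop(columns="level")


def reconstructed_judgment_matrices(
    hierarchy: Hierarchy | None = None,
) -> dict[str, JudgmentMatrix]:
    """Consistent judgment matrices rebuilt from the published AHP weights.

    Returns one matrix keyed ``"criteria"`` (criterion layer vs the target)
    plus one per criterion (its member indicators).  Each matrix is built
    from weight ratios and is therefore exactly consistent (CR = 0), with
    its principal eigenvector equal to the published weights renormalized
    within the parent."""
    if hierarchy is None:
        hierarchy, _ = default_system()
    ind = published_indicator_weights()["ahp"]
    crit = published_criterion_weights()["ahp"]

    def ratio_matrix(w: pd.Series) -> JudgmentMatrix:
        v = w.to_numpy(dtype=float)
        return JudgmentMatrix(np.outer(v, 1.0 / v), tuple(w.index))

    out = {"criteria": ratio_matrix(crit.reindex(list(hierarchy.criterion_ids)))}
    for c in hierarchy.criterion_ids:
        out[c] = ratio_matrix(ind.reindex(list(hierarchy.indicators_of(c))))
    return out
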
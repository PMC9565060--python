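"""End-to-end orchestration: load -> AHP -> entropy -> fuse -> fuzzy grading.

A run is driven by a :class:`RunConfig` and produces a directory of plain
artifacts (weight table, consistency reports, per-segment layer results,
manifest, log).  Two weighting modes exist:

* full mode — subjective weights are computed from judgment matrices (the
  run aborts if any matrix fails the CR < 0.1 test) and objective weights
  from the data matrix via the entropy method;
* injection mode — an externally supplied weight table (e.g. published AHP
  and entropy columns) bypasses both computations, which lets a published
  combined-weight table be reproduced exactly without the unpublished raw
  judgments/data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures
from .ahp import (
    ConsistencyReport,
    JudgmentMatrix,
    combine_levels,
    consistency,
    hierarchy_consistency,
    principal_weights,
)
from .entropy_weighting import entropy_weighting
from .errors import ConsistencyError, MatrixValidationError
from .fuzzy_model import GRADES, LayerResults, evaluate_layers
from .indicator_system import Hierarchy, IndicatorSpec, load_system
from .weight_fusion import WeightTable, build_weight_table


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one evaluation run."""

    data: str | Path | None = None  # segments x indicators CSV
    system: str | Path | None = None  # indicator-system YAML (None = packaged)
    judgments: str | Path | dict[str, JudgmentMatrix] | None = None
    weights: str | Path | pd.DataFrame | None = None  # injection mode
    lam: float = 0.5  # AHP share in the fused weights
    operator: str = "weighted_average"  # or "max_min"
    tie_break: str = "worse"  # documented; the only implemented rule
    outdir: str | Path | None = None
    seed: int = 0
    display_decimals: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if self.operator not in ("weighted_average", "max_min"):
            raise ValueError(f"unknown operator {self.operator!r}")
        if self.tie_break != "worse":
            raise ValueError("only the conservative 'worse' tie-break is implemented")


@dataclass
class RunArtifacts:
    """Everything one run computed."""

    config: RunConfig
    hierarchy: Hierarchy
    specs: list[IndicatorSpec]
    weight_table: WeightTable
    consistency: pd.DataFrame | None  # per judgment matrix, None in injection mode
    combined_cr: float | None
    results: dict[str, LayerResults] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def load_judgments(source) -> dict[str, JudgmentMatrix]:
    """Judgment matrices from a YAML mapping name -> {labels, matrix}."""
    if isinstance(source, dict) and all(
        isinstance(v, JudgmentMatrix) for v in source.values()
    ):
        return source
    with open(source) as fh:
        raw = yaml.safe_load(fh)
    return {
        name: JudgmentMatrix(np.array(entry["matrix"], dtype=float), tuple(entry["labels"]))
        for name, entry in raw.items()
    }


def ahp_weights_from_judgments(
    judgments: dict[str, JudgmentMatrix], hierarchy: Hierarchy
) -> tuple[pd.Series, pd.DataFrame, float]:
    """Global per-indicator AHP weights from per-node judgment matrices.

    Expects one matrix keyed ``"criteria"`` and one per criterion id.  Any
    matrix with CR >= 0.1 aborts the computation."""
    if "criteria" not in judgments:
        raise MatrixValidationError("no 'criteria' judgment matrix supplied")
    reports: dict[str, ConsistencyReport] = {}
    crit_m = judgments["criteria"]
    crit_w_vec = principal_weights(crit_m)
    reports["criteria"] = consistency(crit_m, crit_w_vec)
    parent_w = dict(zip(crit_m.labels, crit_w_vec))
    child_w: dict[str, dict[str, float]] = {}
    child_reports: dict[str, ConsistencyReport] = {}
    for c in hierarchy.criterion_ids:
        if c not in judgments:
            raise MatrixValidationError(f"no judgment matrix for criterion {c}")
        m = judgments[c]
        w = principal_weights(m)
        reports[c] = consistency(m, w)
        child_reports[c] = reports[c]
        child_w[c] = dict(zip(m.labels, w))
    failed = [name for name, r in reports.items() if not r.acceptable]
    if failed:
        worst = max(failed, key=lambda n: reports[n].cr)
        raise ConsistencyError(
            f"judgment matrix {worst!r} failed the consistency test "
            f"(CR = {reports[worst].cr:.4f} >= 0.1)"
        )
    global_w = combine_levels(parent_w, child_w)
    combined_cr = hierarchy_consistency(parent_w, child_reports)
    table = pd.DataFrame(
        {
            "lambda_max": {k: r.lambda_max for k, r in reports.items()},
            "ci": {k: r.ci for k, r in reports.items()},
            "ri": {k: r.ri for k, r in reports.items()},
            "cr": {k: r.cr for k, r in reports.items()},
            "acceptable": {k: r.acceptable for k, r in reports.items()},
        }
    )
    return (
        pd.Series(global_w).reindex(list(hierarchy.indicator_ids)),
        table,
        combined_cr,
    )


def run(config: RunConfig) -> RunArtifacts:
    """Execute the pipeline and (optionally) write its artifacts."""
    log: list[str] = []
    hierarchy, specs = load_system(config.system)
    log.append(
        f"system: {len(hierarchy.criterion_ids)} criteria, "
        f"{len(hierarchy.subcriteria)} sub-criteria, "
        f"{len(hierarchy.indicator_ids)} indicators"
    )

    data = None
    if config.data is not None:
        data = (
            config.data
            if isinstance(config.data, pd.DataFrame)
            else pd.read_csv(config.data, index_col=0)
        )
        data = data.reindex(columns=list(hierarchy.indicator_ids))

    consistency_table: pd.DataFrame | None = None
    combined_cr: float | None = None
    if config.weights is not None:  # injection mode
        wtab = (
            config.weights
            if isinstance(config.weights, pd.DataFrame)
            else pd.read_csv(config.weights, index_col="id")
        )
        if "level" in wtab.columns:
            wtab = wtab[wtab["level"] == "indicator"]
        ahp_w = wtab["ahp"].reindex(list(hierarchy.indicator_ids))
        ent_w = wtab["entropy"].reindex(list(hierarchy.indicator_ids))
        log.append("weights: injected table (AHP and entropy stages skipped)")
    else:
        if config.judgments is None or data is None:
            raise MatrixValidationError(
                "full mode needs both a data matrix and judgment matrices"
            )
        judgments = load_judgments(config.judgments)
        ahp_w, consistency_table, combined_cr = ahp_weights_from_judgments(
            judgments, hierarchy
        )
        for name, row in consistency_table.iterrows():
            log.append(
                f"AHP {name}: lambda_max={row.lambda_max:.6f} CI={row.ci:.6f} "
                f"CR={row.cr:.6f} acceptable={bool(row.acceptable)}"
            )
        log.append(f"AHP combined hierarchy CR: {combined_cr:.6f}")
        ent = entropy_weighting(data, specs)
        ent_w = ent.weights.reindex(list(hierarchy.indicator_ids))
        zero = [i for i, v in ent_w.items() if v == 0.0]
        if zero:
            log.append(f"entropy: constant columns with weight 0: {zero}")

    weight_table = build_weight_table(ahp_w, ent_w, hierarchy, config.lam)
    tot = weight_table.indicators["fused"].sum()
    log.append(f"fused weights (lam={config.lam}) sum to {tot:.6f}")
    if abs(tot - 1.0) > 2e-3:
        log.append(
            "WARNING: fused weights deviate from 1 beyond rounding tolerance; "
            "check the input weight columns"
        )

    results: dict[str, LayerResults] = {}
    if data is not None:
        fused = weight_table.indicators["fused"]
        for seg in data.index:
            results[seg] = evaluate_layers(
                data.loc[seg], specs, fused, hierarchy, config.operator
            )
            log.append(f"segment {seg}: target grade {results[seg].target.grade}")

    artifacts = RunArtifacts(
        config=config,
        hierarchy=hierarchy,
        specs=specs,
        weight_table=weight_table,
        consistency=consistency_table,
        combined_cr=combined_cr,
        results=results,
        log=log,
    )
    if config.outdir is not None:
        write_artifacts(artifacts, config.outdir)
    return artifacts


def _layer_frame(res: LayerResults) -> pd.DataFrame:
    rows = []
    for i in res.affiliation.index:
        rows.append(
            ["indicator", i, *res.affiliation.loc[i].tolist(), res.indicator_grades[i]]
        )
    for c, v in res.criterion.items():
        rows.append(["criterion", c, *v.memberships.tolist(), v.grade])
    rows.append(["target", "target", *res.target.memberships.tolist(), res.target.grade])
    return pd.DataFrame(rows, columns=["layer", "id", *GRADES, "grade"])


def write_artifacts(artifacts: RunArtifacts, outdir) -> None:
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    artifacts.weight_table.to_csv(d / "weight_table.csv")
    if artifacts.consistency is not None:
        artifacts.consistency.rename_axis("matrix").to_csv(d / "consistency.csv")
    for seg, res in artifacts.results.items():
        _layer_frame(res).to_csv(d / f"segment_{seg}.csv", index=False, float_format="%.12g")
    manifest = {
        "seed": artifacts.config.seed,
        "lam": artifacts.config.lam,
        "operator": artifacts.config.operator,
        "tie_break": artifacts.config.tie_break,
        "segments": list(artifacts.results),
        "combined_cr": artifacts.combined_cr,
        "target_grades": {s: r.target.grade for s, r in artifacts.results.items()},
    }
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    (d / "run.log").write_text("\n".join(artifacts.log) + "\n")


def report(artifacts: RunArtifacts) -> str:
    """Human-readable summary: weights, per-segment layer grades and the
    constraint indicators/criteria (those graded bad or poor)."""
    dec = artifacts.config.display_decimals
    lines: list[str] = []
    wt = artifacts.weight_table
    lines.append("Criterion-layer weights (AHP | entropy | combined | rank):")
    for c, row in wt.criteria.iterrows():
        lines.append(
            f"  {c}: {row.ahp:.{dec}f} | {row.entropy:.{dec}f} | "
            f"{row.fused:.{dec}f} | {int(row.criticality)}"
        )
    for seg, res in artifacts.results.items():
        lines.append(f"\nSegment {seg}: target grade {res.target.grade}")
        d = ", ".join(
            f"{g}={v:.{dec}f}" for g, v in zip(GRADES, res.target.memberships)
        )
        lines.append(f"  target memberships: {d}")
        lines.append("  criterion grades: " + ", ".join(
            f"{c}={v.grade}" for c, v in res.criterion.items()
        ))
        constraints = res.constraint_indicators()
        lines.append(
            "  constraint indicators: " + (", ".join(constraints) if constraints else "none")
        )
        cc = res.constraint_criteria()
        if cc:
            lines.append("  constraint criteria: " + ", ".join(cc))
    return "\n".join(lines)
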
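"""Three-step screening orchestration and reporting.

Order is strict: known-list lookup, then the rule engine on experimental
evidence, then the ML model (AD-gated) for whatever remains.  Each compound is
decided by exactly the first step that resolves it.  The report aggregates
class and step counts, the positive share, origin and ring/chain breakdowns of
the positives, EF/NER concentration summaries and a latitude ordering of site
totals.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import features as ft
from . import ml as ml_mod
from .io import CompoundRecord, ConcentrationRecord, PropertyRecord, get_properties
from .prevalence import noncyclic_fraction
from .rules import (
    CANDIDATE,
    POSITIVE_CLASSES,
    UNRESOLVED,
    HazardAssessment,
    RuleConfig,
    assess_compound,
    build_known_index,
    lookup_known,
)

logger = logging.getLogger(__name__)


def run_screening(
    roster: list[CompoundRecord],
    properties: dict[str, PropertyRecord],
    known_list,
    bundle: ml_mod.ModelBundle | None = None,
    rule_config: RuleConfig = RuleConfig(),
    descriptors: pd.DataFrame | None = None,
) -> list[HazardAssessment]:
    """Screen every roster compound through the three steps in order.

    ``descriptors`` may carry a precomputed descriptor matrix (indexed by
    compound id); otherwise it is computed for the compounds that reach the
    ML step.  Without a model bundle, unresolved compounds stay unresolved
    and the pipeline still completes.
    """
    known_index = build_known_index(known_list) if known_list is not None else {}
    assessments: dict[str, HazardAssessment] = {}
    remaining: list[CompoundRecord] = []

    for rec in roster:
        hit = lookup_known(rec, known_index) if known_index else None
        if hit is not None:
            assessments[rec.compound_id] = hit
            continue
        props = get_properties(properties, rec.compound_id)
        assessment = assess_compound(rec.compound_id, props, rule_config)
        if assessment.hazard_class != UNRESOLVED:
            assessments[rec.compound_id] = assessment
        else:
            remaining.append(rec)

    if remaining:
        if bundle is None:
            logger.warning(
                "%d compounds unresolved and no model bundle supplied", len(remaining)
            )
            for rec in remaining:
                props = get_properties(properties, rec.compound_id)
                a = assess_compound(rec.compound_id, props, rule_config)
                a.detail += "; no ML model available"
                assessments[rec.compound_id] = a
        else:
            ids = [r.compound_id for r in remaining]
            if descriptors is not None:
                feats = descriptors.loc[ids, bundle.feature_names]
            else:
                feats = ft.descriptor_matrix(remaining)[bundle.feature_names]
            for a in ml_mod.predict(bundle, feats):
                assessments[a.compound_id] = a

    return [assessments[rec.compound_id] for rec in roster]


@dataclass
class ScreeningReport:
    total: int
    class_counts: dict[str, int]
    decided_by_counts: dict[str, int]
    percent_positive: float
    origin_of_positives: dict[str, int]
    noncyclic_percent_of_positives: float | None
    concentration_summary: dict[str, dict[str, float]]
    site_summary: list[dict]
    latitude_concentration_spearman: float | None
    top_concentrated: list[dict]
    config: dict = field(default_factory=dict)
    seed: int | None = None


def summarize(
    assessments: list[HazardAssessment],
    roster: list[CompoundRecord],
    concentrations: list[ConcentrationRecord] | None = None,
    top_n: int = 10,
    rule_config: RuleConfig = RuleConfig(),
    seed: int | None = None,
) -> ScreeningReport:
    """Aggregate assessments into the screening report.

    Positive share counts PMT, vPvM, PMT&vPvM and ML candidates over the
    roster.  Concentration summaries (mean/min/max per fraction) cover
    observations of positive compounds only; site totals are ordered north to
    south and their rank correlation with latitude is reported descriptively.
    """
    by_id = {r.compound_id: r for r in roster}
    ids = {a.compound_id for a in assessments}
    if ids != set(by_id):
        raise ValueError("assessments do not cover the roster exactly")

    class_counts: dict[str, int] = {}
    decided_counts: dict[str, int] = {}
    for a in assessments:
        class_counts[a.hazard_class] = class_counts.get(a.hazard_class, 0) + 1
        decided_counts[a.decided_by] = decided_counts.get(a.decided_by, 0) + 1

    positives = {a.compound_id for a in assessments
                 if a.hazard_class in POSITIVE_CLASSES}
    total = len(roster)
    percent_positive = 100.0 * len(positives) / total if total else 0.0

    origin_of_pos: dict[str, int] = {}
    for cid in positives:
        origin = by_id[cid].origin
        origin_of_pos[origin] = origin_of_pos.get(origin, 0) + 1

    noncyclic_pct = None
    if positives:
        noncyclic_pct = noncyclic_fraction(roster, positives)

    conc_summary: dict[str, dict[str, float]] = {}
    site_rows: list[dict] = []
    spearman = None
    top_rows: list[dict] = []
    if concentrations:
        pos_obs = [c for c in concentrations if c.compound_id in positives]
        for fraction in ("EF", "NER"):
            vals = [c.value_ng_per_g_dw for c in pos_obs if c.fraction == fraction]
            if vals:
                conc_summary[fraction] = {
                    "n_observations": len(vals),
                    "mean_ng_g_dw": float(np.mean(vals)),
                    "min_ng_g_dw": float(np.min(vals)),
                    "max_ng_g_dw": float(np.max(vals)),
                }
        sites: dict[str, dict] = {}
        for c in pos_obs:
            s = sites.setdefault(
                c.site_id, {"site_id": c.site_id, "latitude": c.latitude,
                            "total_ng_g_dw": 0.0, "n_observations": 0}
            )
            s["total_ng_g_dw"] += c.value_ng_per_g_dw
            s["n_observations"] += 1
        site_rows = sorted(sites.values(), key=lambda s: -s["latitude"])  # N -> S
        if len(site_rows) >= 3:
            lats = [s["latitude"] for s in site_rows]
            tots = [s["total_ng_g_dw"] for s in site_rows]
            spearman = float(sps.spearmanr(lats, tots).statistic)
        per_compound: dict[str, float] = {}
        for c in pos_obs:
            per_compound[c.compound_id] = (
                per_compound.get(c.compound_id, 0.0) + c.value_ng_per_g_dw
            )
        for cid, tot in sorted(per_compound.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]:
            top_rows.append({"compound_id": cid, "name": by_id[cid].name,
                             "total_ng_g_dw": tot})

    return ScreeningReport(
        total=total,
        class_counts=dict(sorted(class_counts.items())),
        decided_by_counts=dict(sorted(decided_counts.items())),
        percent_positive=percent_positive,
        origin_of_positives=dict(sorted(origin_of_pos.items())),
        noncyclic_percent_of_positives=noncyclic_pct,
        concentration_summary=conc_summary,
        site_summary=site_rows,
        latitude_concentration_spearman=spearman,
        top_concentrated=top_rows,
        config=dataclasses.asdict(rule_config),
        seed=seed,
    )


def assessment_table(assessments: list[HazardAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": [a.compound_id for a in assessments],
            "hazard_class": [a.hazard_class for a in assessments],
            "decided_by": [a.decided_by for a in assessments],
            "persistence": [a.tier.persistence for a in assessments],
            "mobility": [a.tier.mobility for a in assessments],
            "toxicity": [a.tier.toxicity for a in assessments],
            "detail": [a.detail for a in assessments],
        }
    )


def _report_markdown(report: ScreeningReport) -> str:
    lines = [
        "# PMT/vPvM screening report",
        "",
        f"Compounds screened: **{report.total}**",
        f"PMT/vPvM or candidate share: **{report.percent_positive:.1f}%**",
        "",
        "## Hazard classes",
        "",
        "| class | count |",
        "| --- | --- |",
    ]
    for cls, n in report.class_counts.items():
        lines.append(f"| {cls} | {n} |")
    lines += ["", "## Decided by", "", "| step | count |", "| --- | --- |"]
    for step, n in report.decided_by_counts.items():
        lines.append(f"| {step} | {n} |")
    lines += ["", "## Positives by origin", ""]
    for origin, n in report.origin_of_positives.items():
        lines.append(f"- {origin}: {n}")
    if report.noncyclic_percent_of_positives is not None:
        lines += ["", f"Noncyclic share of positives: "
                      f"{report.noncyclic_percent_of_positives:.1f}%"]
    if report.concentration_summary:
        lines += ["", "## Concentrations of positives (ng/g dw)", ""]
        for fraction, s in report.concentration_summary.items():
            lines.append(
                f"- {fraction}: mean {s['mean_ng_g_dw']:.1f}, "
                f"range {s['min_ng_g_dw']:.1f}-{s['max_ng_g_dw']:.1f} "
                f"(n={s['n_observations']})"
            )
    if report.latitude_concentration_spearman is not None:
        lines.append(
            f"\nSpearman rank correlation of site latitude vs total "
            f"concentration: {report.latitude_concentration_spearman:.3f} "
            "(negative = concentrations rise from north to south; "
            "descriptive, no significance claimed)"
        )
    return "\n".join(lines) + "\n"


def write_report(
    report: ScreeningReport,
    assessments: list[HazardAssessment],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write machine JSON, human Markdown and the CSV assessment table.

    Output is deterministic: identical inputs and seed reproduce the JSON
    byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": out / "report.json",
        "markdown": out / "report.md",
        "assessments": out / "assessments.csv",
    }
    payload = dataclasses.asdict(report)
    paths["json"].write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    paths["markdown"].write_text(_report_markdown(report))
    assessment_table(assessments).to_csv(paths["assessments"], index=False)
    return paths
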
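"""End-to-end orchestration and report assembly.

Runs the stages in order — select / exclude, pair and screen, stage
agreement, attribution, categorisation — and assembles cohort-characteristic,
agreement, and explanation-frequency tables, plus ground-truth recovery
metrics on synthetic runs. Every emitted number is fully determined by the
input (or simulation config) and seed.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from . import attribution as attr_mod
from .attribution import (
    AttributionResult,
    InverseIndex,
    attribute_pair,
    build_inverse_index,
    explanation_super_category,
)
from .cohort import apply_exclusions, read_cohort, rows_from_frame
from .concordance import (
    EgfrPair,
    bland_altman,
    build_pairs,
    cohen_kappa,
    stage_agreement,
)
from .egfr import (
    DEFAULT_CONSTANTS,
    DEFAULT_POLICY,
    DEFAULT_STAGES,
    ComparisonPolicy,
    EquationConstants,
    PatientSnapshot,
    StageScheme,
)
from .simulate import GroundTruth, SimulationConfig, cohort_frame, simulate_cohort

__all__ = [
    "AnalysisReport",
    "run_pipeline",
    "summarize_demographics",
    "explanation_table",
    "recovery_metrics",
    "attributions_frame",
]


def summarize_demographics(
    pairs: Sequence[EgfrPair],
    snapshots: Sequence[PatientSnapshot],
) -> dict:
    """Cohort characteristics split by value concordance, with Welch t-tests
    for continuous fields and chi-square tests for categorical ones.

    Tests are suppressed (reported as None) when either group has fewer
    than two members or a test is degenerate.
    """
    by_id = {s.patient_id: s for s in snapshots}
    rows = []
    for p in pairs:
        s = by_id[p.patient_id]
        rows.append({
            "concordant": p.concordant_value,
            "age": s.age, "scr": s.scr,
            "automated": p.automated_raw, "retro": p.retro_raw,
            "male": not s.female, "race": s.race_detail.value,
        })
    df = pd.DataFrame(rows)
    out: dict = {"n": len(df)}
    groups = {
        "all": df,
        "concordant": df[df.concordant],
        "discordant": df[~df.concordant],
    }
    for name, g in groups.items():
        summ = {"n": int(len(g))}
        for colname in ("age", "scr", "automated", "retro"):
            summ[colname] = {
                "mean": float(g[colname].mean()) if len(g) else None,
                "sd": float(g[colname].std(ddof=1)) if len(g) > 1 else None,
            }
        summ["male_n"] = int(g.male.sum()) if len(g) else 0
        summ["race_counts"] = {k: int(v) for k, v in g.race.value_counts().items()}
        out[name] = summ
    conc, disc = groups["concordant"], groups["discordant"]
    tests: dict = {}
    if len(conc) >= 2 and len(disc) >= 2:
        for colname in ("age", "scr", "automated", "retro"):
            t = stats.ttest_ind(conc[colname], disc[colname], equal_var=False)
            tests[colname] = {"t": float(t.statistic), "p": float(t.pvalue)}
        tab = pd.crosstab(df.concordant, df.male)
        if tab.shape == (2, 2) and (tab.values > 0).all():
            chi = stats.chi2_contingency(tab.values, correction=False)
            tests["male"] = {"chi2": float(chi.statistic), "p": float(chi.pvalue)}
    out["tests"] = tests or None
    return out


def attributions_frame(results: Sequence[AttributionResult]) -> pd.DataFrame:
    """Per-pair attribution output, mismatch sets serialised canonically."""
    def ser(sets):
        return " | ".join(sorted(
            "+".join(p for p in attr_mod.PARAMETERS if p in s) for s in sets))
    return pd.DataFrame({
        "pair_id": [r.pair_id for r in results],
        "status": [r.status for r in results],
        "max_match_count": [r.max_match_count for r in results],
        "mismatch_sets": [ser(r.mismatch_sets) for r in results],
        "definitive": [r.definitive for r in results],
        "category": [r.category_label or "" for r in results],
        "super_category": [explanation_super_category(r) or "" for r in results],
        "abs_value_difference": [r.abs_value_difference for r in results],
        "abs_age_difference": [r.abs_parameter_difference.get("age") for r in results],
        "abs_scr_difference": [r.abs_parameter_difference.get("scr") for r in results],
    })


def explanation_table(
    results: Sequence[AttributionResult],
    pairs: Sequence[EgfrPair],
) -> dict:
    """Explanation-frequency strata over the value-discordant pairs.

    Three strata partitioning by stage concordance: all value-discordant
    pairs, those also stage-discordant, and those value-discordant only.
    Per category: count, percent of stratum, and median absolute eGFR
    difference; definitive Age / 1-clinical rows also carry the median
    absolute parameter difference (years / mg/dL).
    """
    by_id = {p.patient_id: p for p in pairs}
    rows = []
    for r in results:
        if r.status == "match":
            continue
        p = by_id[r.pair_id]
        if p.concordant_value:
            continue
        rows.append({
            "category": r.category_label or "Unexplained",
            "super_category": explanation_super_category(r) or "",
            "stage_discordant": not p.concordant_stage,
            "abs_diff": r.abs_value_difference,
            "abs_age": r.abs_parameter_difference.get("age"),
            "abs_scr": r.abs_parameter_difference.get("scr"),
        })
    df = pd.DataFrame(rows)
    strata = {}
    views = {
        "value_discordant": df,
        "value_and_stage_discordant": df[df.stage_discordant] if len(df) else df,
        "value_only_discordant": df[~df.stage_discordant] if len(df) else df,
    }
    for name, view in views.items():
        total = len(view)
        cats = {}
        if total:
            for cat, g in view.groupby("category"):
                entry = {
                    "n": int(len(g)),
                    "percent": round(100.0 * len(g) / total, 2),
                    "median_abs_difference": float(g.abs_diff.median()),
                }
                if g.abs_age.notna().any():
                    entry["median_abs_age_difference"] = float(g.abs_age.median())
                if g.abs_scr.notna().any():
                    entry["median_abs_scr_difference"] = float(g.abs_scr.median())
                cats[cat] = entry
        strata[name] = {"n": total, "categories": cats}
    return strata


def recovery_metrics(
    results: Sequence[AttributionResult],
    truths: Sequence[GroundTruth],
) -> dict:
    """Score attribution against injected ground truth on a synthetic run.

    For each injected parameter: the fraction of discordant pairs whose
    reported mismatch sets contain the true changed set (containment), and
    the fraction definitively and exactly correct. Also a confusion table of
    true changed set vs. reported category.
    """
    truth_by_id = {t.patient_id: t for t in truths}
    per_param: Dict[str, dict] = {}
    confusion: Dict[str, Dict[str, int]] = {}
    missing = [r.pair_id for r in results if r.pair_id not in truth_by_id]
    if missing:
        raise ValueError(f"ground truth missing for pairs: {missing[:5]}")
    for r in results:
        if r.status == "match":
            continue
        true_set = frozenset(truth_by_id[r.pair_id].changed_parameters)
        key = "+".join(sorted(true_set)) or "(none)"
        d = per_param.setdefault(key, {"n": 0, "contained": 0, "exact_definitive": 0})
        d["n"] += 1
        contained = any(true_set <= s for s in r.mismatch_sets)
        d["contained"] += int(contained)
        d["exact_definitive"] += int(r.definitive and r.mismatch_sets == frozenset({true_set}))
        cat = r.category_label or "Unexplained"
        confusion.setdefault(key, {})
        confusion[key][cat] = confusion[key].get(cat, 0) + 1
    for d in per_param.values():
        d["containment_rate"] = d["contained"] / d["n"] if d["n"] else None
        d["exact_rate"] = d["exact_definitive"] / d["n"] if d["n"] else None
    return {"per_parameter": per_param, "confusion": confusion}


@dataclass
class AnalysisReport:
    """Assembled results of one end-to-end run."""

    cohort_summary: dict
    concordance_summary: dict
    explanation_tables: dict
    recovery: Optional[dict]
    provenance: dict
    pairs: List[EgfrPair] = field(default_factory=list, repr=False)
    attributions: List[AttributionResult] = field(default_factory=list, repr=False)

    def to_json_dict(self) -> dict:
        return {
            "cohort_summary": self.cohort_summary,
            "concordance_summary": self.concordance_summary,
            "explanation_tables": self.explanation_tables,
            "recovery": self.recovery,
            "provenance": self.provenance,
        }

    def write(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.to_json_dict(), indent=2, sort_keys=True) + "\n")
        attributions_frame(self.attributions).to_csv(out / "attributions.csv", index=False)
        pd.DataFrame(
            [(p.patient_id, a, d) for p, (a, d) in
             zip(self.pairs, ((0.5 * (q.automated_raw + q.retro_raw),
                               q.difference) for q in self.pairs))],
            columns=["patient_id", "mean_egfr", "difference"],
        ).to_csv(out / "bland_altman_points.csv", index=False)


def run_pipeline(
    source: Union[str, Path, SimulationConfig],
    policy: ComparisonPolicy = DEFAULT_POLICY,
    constants: EquationConstants = DEFAULT_CONSTANTS,
    scheme: StageScheme = DEFAULT_STAGES,
    grid: Optional[attr_mod.ParameterGrid] = None,
    index: Optional[InverseIndex] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> AnalysisReport:
    """Run select -> exclude -> pair -> screen -> stage/agree -> attribute ->
    categorise -> summarise on a cohort file or a simulation config.

    Passing a prebuilt ``index`` skips grid enumeration; otherwise one is
    built for ``grid`` (default full grid). On simulated input the report
    includes ground-truth recovery metrics.
    """
    truths: Optional[List[GroundTruth]] = None
    provenance: dict = {"policy": {
        "screen_precision": policy.screen_precision,
        "inversion_precision": policy.inversion_precision,
        "report_precision": policy.report_precision,
        "rounding_mode": policy.rounding_mode.value,
    }}
    if isinstance(source, SimulationConfig):
        then, automated, now, truths = simulate_cohort(source, constants, policy)
        frame = cohort_frame(now, automated)
        provenance["simulation"] = {"n_patients": source.n_patients, "seed": source.seed}
        tally: dict = {}
    else:
        frame = read_cohort(source)
        provenance["input"] = str(source)
        frame, tally = apply_exclusions(frame)
    rows = rows_from_frame(frame)
    snapshots = [r.snapshot for r in rows]
    provenance["exclusions"] = tally if not isinstance(source, SimulationConfig) else {}
    provenance["n_rows"] = len(rows)

    pairs = build_pairs(rows, policy, constants, scheme)
    discordant = [p for p in pairs if not p.concordant_value]

    matrix, pct_agree = stage_agreement(pairs, scheme)
    kappa = cohen_kappa(matrix)
    ba = bland_altman(pairs) if len(pairs) >= 2 else None
    concordance_summary = {
        "n_pairs": len(pairs),
        "n_discordant": len(discordant),
        "percent_discordant": round(100.0 * len(discordant) / len(pairs), 2) if pairs else None,
        "percent_agreement_stage": round(pct_agree, 2),
        "stage_matrix": {
            "labels": list(matrix.labels),
            "counts": matrix.counts.tolist(),
        },
        "kappa": None if kappa is None else {
            "estimate_x100": round(kappa.kappa_x100, 2),
            "ci_x100": [round(v, 2) for v in kappa.ci_x100],
        },
        "bland_altman": None if ba is None else {
            "n": ba.n,
            "mean_difference": ba.mean_difference,
            "sd_difference": ba.sd_difference,
            "loa_lower": ba.loa_lower,
            "loa_upper": ba.loa_upper,
            "mean_automated": ba.mean_automated,
            "mean_retro": ba.mean_retro,
        },
    }

    if index is None:
        index = build_inverse_index(grid or attr_mod.DEFAULT_GRID, constants, policy)
    snap_by_id = {s.patient_id: s for s in snapshots}
    attributions = [
        attribute_pair(p, snap_by_id[p.patient_id], index) for p in discordant
    ]

    report = AnalysisReport(
        cohort_summary=summarize_demographics(pairs, snapshots),
        concordance_summary=concordance_summary,
        explanation_tables=explanation_table(attributions, pairs),
        recovery=(recovery_metrics(attributions, truths) if truths is not None else None),
        provenance=provenance,
        pairs=pairs,
        attributions=attributions,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
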
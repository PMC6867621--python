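"""Per-patient case containers, cohort summaries, reports and the end-to-end pipeline.

Percentages are computed over all enrolled patients and rounded to one
decimal, half-up — the convention of clinical cohort tables (20 of 55
actionable patients prints as 36.4).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import yaml

from .cnv_purity import CnvCallConfig, cnv_variant_calls, run_cnv_pipeline, build_reference
from .exceptions import ConfigError, StateError, ValidationError
from .io_formats import (
    EvidenceEntry,
    ExonCoverageProfile,
    FrequencyRecord,
    VariantCall,
    read_frequency_table,
    read_hotspot_table,
    read_knowledge_base,
    read_panel_bed,
    read_variant_table,
)
from .somatic_filter import FilterConfig, HotspotList, apply_all_filters, compute_tmb
from .tiering import (
    TIER_CLASS,
    TIER_RANK,
    AlterationRecord,
    TierAssignment,
    classify_patient,
    is_actionable,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"


@dataclass
class PatientCase:
    """One enrolled patient: inputs, processing state, and tiering results."""

    id: str
    diagnosis: str
    age_years: float | None = None
    sex: str | None = None
    sample_timepoint: str = "relapse"  # diagnosis | relapse
    sample_type: str = "FFPE"  # FF | FFPE
    sequencing_success: bool = True
    diagnosis_group: str | None = None  # summary category; defaults to diagnosis
    variants: list[VariantCall] = field(default_factory=list)
    alteration_records: list[AlterationRecord] | None = None
    assignments: list[TierAssignment] = field(default_factory=list)
    best_tier: str | None = None
    timeline_days: tuple[int, int, int] | None = None  # dna_prep, sequencing, decision
    tmb: float | None = None
    purity: float | None = None
    frequency_records: list[FrequencyRecord] = field(default_factory=list)
    coverage_profile: ExonCoverageProfile | None = None
    processed: bool = False

    @property
    def group(self) -> str:
        return self.diagnosis_group or self.diagnosis


@dataclass(frozen=True)
class CohortSummary:
    n_enrolled: int
    n_profiled: int
    profiling_success_pct: float
    diagnosis_counts: dict[str, int]
    diagnosis_pct: dict[str, float]
    sex_counts: dict[str, int]
    sample_timepoint_counts: dict[str, int]
    sample_type_counts: dict[str, int]
    tier_class_counts: dict[int, int]
    n_actionable_alteration_records: int
    n_actionable_patients: int
    actionable_patient_pct: float
    tmb_median: float | None
    tmb_range: tuple[float, float] | None
    turnaround_median_days: float | None
    turnaround_range_days: tuple[int, int] | None


def round_pct(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage with half-up rounding, the printed-table convention."""
    if denominator == 0:
        raise ValidationError("percentage over an empty denominator")
    q = Decimal(1).scaleb(-digits)
    return float(
        (Decimal(numerator) * 100 / Decimal(denominator)).quantize(q, rounding=ROUND_HALF_UP)
    )


def summarize_actionability(cases: list[PatientCase]) -> dict:
    """Tier-class distribution (1a/1b collapsed to 1, 2a/2b to 2) and actionable counts.

    Counts alteration records, one per assigned tier label; a patient is
    actionable when their best tier is 1a-4; the percentage denominator is
    all enrolled patients.
    """
    tier_class_counts = {1: 0, 2: 0, 3: 0, 4: 0}
    actionable_patients = []
    for case in cases:
        for a in case.assignments:
            cls = TIER_CLASS[a.tier]
            if cls in tier_class_counts:
                tier_class_counts[cls] += 1
        if is_actionable(case.best_tier):
            actionable_patients.append(case.id)
    n_records = sum(tier_class_counts.values())
    return {
        "tier_class_counts": tier_class_counts,
        "n_actionable_alteration_records": n_records,
        "n_actionable_patients": len(actionable_patients),
        "actionable_patient_ids": actionable_patients,
        "actionable_patient_pct": round_pct(len(actionable_patients), len(cases)),
    }


def summarize_cohort(cases: list[PatientCase]) -> CohortSummary:
    """Aggregate enrolled cases into cohort-table statistics."""
    if not cases:
        raise ValidationError("cannot summarize an empty cohort")
    n = len(cases)
    n_profiled = sum(1 for c in cases if c.sequencing_success)
    diagnosis_counts: dict[str, int] = {}
    sex_counts: dict[str, int] = {}
    timepoint_counts: dict[str, int] = {}
    type_counts: dict[str, int] = {}
    for c in cases:
        diagnosis_counts[c.group] = diagnosis_counts.get(c.group, 0) + 1
        if c.sex:
            sex_counts[c.sex] = sex_counts.get(c.sex, 0) + 1
        timepoint_counts[c.sample_timepoint] = timepoint_counts.get(c.sample_timepoint, 0) + 1
        type_counts[c.sample_type] = type_counts.get(c.sample_type, 0) + 1
    act = summarize_actionability(cases)
    tmbs = [c.tmb for c in cases if c.tmb is not None]
    turnarounds = [sum(c.timeline_days) for c in cases if c.timeline_days is not None]
    return CohortSummary(
        n_enrolled=n,
        n_profiled=n_profiled,
        profiling_success_pct=round_pct(n_profiled, n),
        diagnosis_counts=diagnosis_counts,
        diagnosis_pct={d: round_pct(k, n) for d, k in diagnosis_counts.items()},
        sex_counts=sex_counts,
        sample_timepoint_counts=timepoint_counts,
        sample_type_counts=type_counts,
        tier_class_counts=act["tier_class_counts"],
        n_actionable_alteration_records=act["n_actionable_alteration_records"],
        n_actionable_patients=act["n_actionable_patients"],
        actionable_patient_pct=act["actionable_patient_pct"],
        tmb_median=float(np.median(tmbs)) if tmbs else None,
        tmb_range=(float(min(tmbs)), float(max(tmbs))) if tmbs else None,
        turnaround_median_days=float(np.median(turnarounds)) if turnarounds else None,
        turnaround_range_days=(min(turnarounds), max(turnarounds)) if turnarounds else None,
    )


def summary_markdown(summary: CohortSummary) -> str:
    """The cohort summary as a two-column markdown table."""
    rows = [
        ("Enrolled", summary.n_enrolled),
        ("Profiled", f"{summary.n_profiled} ({summary.profiling_success_pct}%)"),
        ("Actionable patients",
         f"{summary.n_actionable_patients} ({summary.actionable_patient_pct}%)"),
    ]
    for cls in sorted(summary.tier_class_counts):
        rows.append((f"Tier {cls} records", summary.tier_class_counts[cls]))
    for diag in sorted(summary.diagnosis_counts):
        rows.append(
            (diag, f"{summary.diagnosis_counts[diag]} ({summary.diagnosis_pct[diag]}%)")
        )
    lines = ["| Metric | Value |", "| --- | --- |"]
    lines += [f"| {name} | {value} |" for name, value in rows]
    return "\n".join(lines) + "\n"


def render_report(case: PatientCase, fmt: str = "json"):
    """Render one patient's report as a JSON-serializable dict or stable text."""
    if case.sequencing_success and not case.processed and case.best_tier is None:
        raise StateError(f"case {case.id} has not been processed; run the pipeline first")
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "patient_id": case.id,
        "diagnosis": case.diagnosis,
        "profiling": "success" if case.sequencing_success else "failed",
        "best_tier": case.best_tier,
        "tmb_per_mb": case.tmb,
        "purity": case.purity,
        "alterations": [
            {
                "description": a.record.description,
                "tier": a.tier,
                "drug": a.drug,
                "rationale": a.rationale,
            }
            for a in case.assignments
        ],
        "cnv_calls": [
            {"gene": v.gene, "class": v.variant_class}
            for v in case.variants
            if v.variant_class in ("CNV_amp", "CNV_del") and v.filter_status == "PASS"
        ],
        "turnaround_days": list(case.timeline_days) if case.timeline_days else None,
    }
    if fmt == "json":
        return doc
    if fmt == "text":
        lines = [
            f"Patient {doc['patient_id']} ({doc['diagnosis']})",
            f"Profiling: {'profiling failed' if not case.sequencing_success else 'success'}",
        ]
        if case.sequencing_success:
            lines.append(f"Best tier: {doc['best_tier']}")
            if doc["tmb_per_mb"] is not None:
                lines.append(f"TMB: {doc['tmb_per_mb']:.1f} mutations/Mb")
            if doc["purity"] is not None:
                lines.append(f"Estimated tumor purity: {doc['purity']:.2f}")
            for alt in doc["alterations"]:
                lines.append(
                    f"  {alt['description']}\ttier {alt['tier']}\t{alt['drug'] or '-'}"
                )
        return "\n".join(lines) + "\n"
    raise ValidationError(f"unknown report format {fmt!r}")


def process_case(
    case: PatientCase,
    kb: list[EvidenceEntry],
    hotspots: HotspotList | None = None,
    filter_cfg: FilterConfig | None = None,
    cnv_cfg: CnvCallConfig | None = None,
    reference=None,
    synonyms: dict[str, str] | None = None,
) -> PatientCase:
    """Filter -> CNV -> tier one case in place; no-op for failed sequencing."""
    if not case.sequencing_success:
        case.processed = True
        return case
    filter_cfg = filter_cfg or FilterConfig()
    cnv_cfg = cnv_cfg or CnvCallConfig()
    case.variants = apply_all_filters(case.variants, case.frequency_records, hotspots, filter_cfg)
    if case.coverage_profile is not None and reference is not None:
        profile, solution = run_cnv_pipeline(case.coverage_profile, reference, cnv_cfg)
        case.purity = solution.purity
        case.variants = case.variants + cnv_variant_calls(profile.segments, case.coverage_profile.panel)
        case.tmb = compute_tmb(case.variants, case.coverage_profile.panel,
                               filter_cfg.tmb_nonsynonymous_only)
    case.assignments, case.best_tier = classify_patient(case, kb, synonyms)
    case.processed = True
    return case


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def _write_outputs(cases: list[PatientCase], summary: CohortSummary, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["patient_id\tdiagnosis\tdescription\ttier\tdrug"]
    for case in cases:
        for a in case.assignments:
            rows.append(
                f"{case.id}\t{case.diagnosis}\t{a.record.description}\t{a.tier}\t{a.drug}"
            )
    (out_dir / "assignments.tsv").write_text("\n".join(rows) + "\n")

    summary_doc = {
        "n_enrolled": summary.n_enrolled,
        "n_profiled": summary.n_profiled,
        "profiling_success_pct": summary.profiling_success_pct,
        "diagnosis_counts": summary.diagnosis_counts,
        "diagnosis_pct": summary.diagnosis_pct,
        "sample_timepoint_counts": summary.sample_timepoint_counts,
        "sample_type_counts": summary.sample_type_counts,
        "tier_class_counts": {str(k): v for k, v in summary.tier_class_counts.items()},
        "n_actionable_alteration_records": summary.n_actionable_alteration_records,
        "n_actionable_patients": summary.n_actionable_patients,
        "actionable_patient_pct": summary.actionable_patient_pct,
        "tmb_median": summary.tmb_median,
        "tmb_range": summary.tmb_range,
        "turnaround_median_days": summary.turnaround_median_days,
    }
    (out_dir / "cohort_summary.json").write_text(json.dumps(summary_doc, indent=1, sort_keys=True))
    tsv = ["metric\tvalue"]
    tsv.append(f"n_enrolled\t{summary.n_enrolled}")
    tsv.append(f"n_profiled\t{summary.n_profiled}")
    tsv.append(f"profiling_success_pct\t{summary.profiling_success_pct}")
    for cls in sorted(summary.tier_class_counts):
        tsv.append(f"tier_{cls}_records\t{summary.tier_class_counts[cls]}")
    tsv.append(f"n_actionable_patients\t{summary.n_actionable_patients}")
    tsv.append(f"actionable_patient_pct\t{summary.actionable_patient_pct}")
    (out_dir / "cohort_summary.tsv").write_text("\n".join(tsv) + "\n")
    (out_dir / "cohort_summary.md").write_text(summary_markdown(summary))

    reports = out_dir / "reports"
    reports.mkdir(exist_ok=True)
    for case in cases:
        (reports / f"{case.id}.json").write_text(
            json.dumps(render_report(case, "json"), indent=1, sort_keys=True)
        )


def run_pipeline(config_path: str | Path) -> CohortSummary:
    """Run filter -> cnv -> tier -> report from a YAML configuration.

    Three modes: ``cohort: bundled`` processes the packaged example cohort;
    a ``simulate`` block generates a synthetic cohort end to end; an
    ``inputs`` block processes a single patient's files. Outputs
    (assignments TSV, cohort summary TSV/JSON, per-patient reports) are
    deterministic for a fixed seed.
    """
    t0 = time.monotonic()
    config_path = Path(config_path)
    if not config_path.exists():
        raise ConfigError(f"config file {config_path} does not exist")
    cfg = yaml.safe_load(config_path.read_text()) or {}
    out_dir = Path(cfg.get("out_dir", "paneltier_out"))
    seed = int(cfg.get("seed", 0))
    filter_cfg = FilterConfig(**cfg.get("filter", {}))
    cnv_cfg = CnvCallConfig(**{
        k: tuple(v) if k == "purity_grid" else v for k, v in cfg.get("cnv", {}).items()
    })

    if cfg.get("cohort") == "bundled":
        from .datasets import load_reference_cohort

        cases, kb = load_reference_cohort()
        for case in cases:
            case.assignments, case.best_tier = classify_patient(case, kb)
            case.processed = True
    elif "simulate" in cfg:
        from .synthetic_cohort import (
            generate_cohort,
            generate_panel,
            simulate_normal_profile,
            synthetic_knowledge_base,
        )

        sim = dict(cfg["simulate"])
        n_patients = int(sim.pop("n_patients", 55))
        panel = generate_panel(
            n_genes=int(sim.pop("n_genes", 30)),
            exons_per_gene=int(sim.pop("exons_per_gene", 4)),
            exon_length=int(sim.pop("exon_length", 150)),
            seed=seed,
        )
        base_depth = float(sim.pop("base_depth", 500.0))
        noise_sd = float(sim.pop("noise_sd", 0.05))
        cases, _ = generate_cohort(
            n_patients, seed=seed, panel=panel,
            base_depth=base_depth, noise_sd=noise_sd, **sim,
        )
        kb = synthetic_knowledge_base(panel)
        references = {
            st: build_reference(
                [
                    simulate_normal_profile(panel, base_depth, noise_sd,
                                            seed=seed + 1000 + 10 * j + (0 if st == "FF" else 1),
                                            sample_type=st)
                    for j in range(4)
                ],
                st,
            )
            for st in ("FF", "FFPE")
        }
        for case in cases:
            process_case(case, kb, filter_cfg=filter_cfg, cnv_cfg=cnv_cfg,
                         reference=references.get(case.sample_type))
    elif "inputs" in cfg:
        inputs = cfg["inputs"]
        for key in ("variants", "knowledge_base", "diagnosis"):
            if key not in inputs:
                raise ConfigError(f"pipeline config missing inputs.{key}")
        kb = read_knowledge_base(inputs["knowledge_base"])
        variants = read_variant_table(
            inputs["variants"], inputs.get("variant_dialect", "tsv")
        )
        freqs = (
            read_frequency_table(inputs["frequencies"]) if "frequencies" in inputs else []
        )
        hotspots = (
            HotspotList.from_pairs(read_hotspot_table(inputs["hotspots"]))
            if "hotspots" in inputs
            else None
        )
        case = PatientCase(
            id=str(inputs.get("patient_id", "case-1")),
            diagnosis=inputs["diagnosis"],
            variants=variants,
            frequency_records=freqs,
        )
        process_case(case, kb, hotspots=hotspots, filter_cfg=filter_cfg, cnv_cfg=cnv_cfg)
        if "panel" in inputs:
            panel = read_panel_bed(inputs["panel"])
            case.tmb = compute_tmb(case.variants, panel, filter_cfg.tmb_nonsynonymous_only)
        cases = [case]
    else:
        raise ConfigError("config must provide one of: cohort: bundled, simulate, inputs")

    summary = summarize_cohort(cases)
    _write_outputs(cases, summary, out_dir)
    logger.info("pipeline finished in %.2fs (%d cases)", time.monotonic() - t0, len(cases))
    return summary
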
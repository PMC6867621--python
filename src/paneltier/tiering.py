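"""Clinical-actionability tiering of filtered alterations.

Each alteration record is matched against an evidence knowledge base and
assigned one of seven tiers:

    1a  clinical evidence for the same alteration in the same disease
    1b  clinical evidence for the same alteration in a different disease
    2a  preclinical evidence, same disease
    2b  preclinical evidence, different disease
    3   consensus opinion
    4   evidence exists, but no matched drug is available in the region
    5   no actionable alteration

Among matched entries, the best regionally available candidate (ordered
1a < 1b < 2a < 2b < 3) wins with its drug. Tier 4 is reached only when at
least one entry matches but none is available locally; tier 5 means no
match at all. A patient is actionable when their best tier is 1a-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ValidationError
from .io_formats import EvidenceEntry, VariantCall

TIERS = ("1a", "1b", "2a", "2b", "3", "4", "5")
TIER_RANK = {t: i for i, t in enumerate(TIERS)}

#: Tier classes used in cohort summaries: 1a/1b -> 1, 2a/2b -> 2.
TIER_CLASS = {"1a": 1, "1b": 1, "2a": 2, "2b": 2, "3": 3, "4": 4, "5": 5}


@dataclass(frozen=True)
class AlterationRecord:
    """One reportable alteration: a single variant, or co-occurring variants
    in the same gene reported under one tier label (e.g. an activating point
    mutation together with amplification of the same oncogene)."""

    patient_id: str
    genes: tuple[str, ...]
    description: str
    components: tuple[VariantCall, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError("alteration record needs >= 1 component variant")
        if not self.genes:
            raise ValidationError("alteration record needs >= 1 gene symbol")


@dataclass(frozen=True)
class TierAssignment:
    record: AlterationRecord
    tier: str
    drug: str = ""
    matched_entry: EvidenceEntry | None = None
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValidationError(f"unknown tier {self.tier!r}")
        if (self.tier == "5") != (self.drug == "") or (self.tier == "5") != (
            self.matched_entry is None
        ):
            raise ValidationError("tier 5 must (and only tier 5 may) lack a drug and entry")


def _normalize_disease(name: str, synonyms: dict[str, str] | None) -> str:
    name = name.strip().lower()
    if synonyms:
        name = synonyms.get(name, name)
    return name


def _matcher_accepts(entry: EvidenceEntry, variant: VariantCall) -> bool:
    m = entry.alteration_matcher
    if m == "exact_protein_change":
        return variant.is_small_variant and variant.protein_change == entry.pattern
    if m == "any_amplification":
        return variant.variant_class == "CNV_amp"
    if m == "any_deletion":
        return variant.variant_class == "CNV_del"
    if m == "any_fusion":
        return variant.variant_class == "fusion"
    if m == "any_activating":
        return variant.is_small_variant and bool(variant.protein_change)
    return False


def match_evidence(
    record: AlterationRecord,
    diagnosis: str,
    kb: list[EvidenceEntry],
    synonyms: dict[str, str] | None = None,
) -> list[tuple[EvidenceEntry, bool]]:
    """All KB entries matching any component of the record, with same-disease flags.

    An entry matches when its gene equals a component's gene and its
    alteration matcher accepts that component; entries with a non-empty
    diagnosis scope additionally require the patient's diagnosis to be in
    scope. Disease identity is case-insensitive exact match, optionally
    through a synonym table.
    """
    diag = _normalize_disease(diagnosis, synonyms)
    matches: list[tuple[EvidenceEntry, bool]] = []
    seen: set[tuple] = set()
    for entry in kb:
        if entry.diagnosis_scope and diag not in entry.diagnosis_scope:
            continue
        for component in record.components:
            if component.gene.upper() != entry.gene.upper():
                continue
            if not _matcher_accepts(entry, component):
                continue
            if entry.dedup_key in seen:
                break
            seen.add(entry.dedup_key)
            same = _normalize_disease(entry.disease, synonyms) == diag
            matches.append((entry, same))
            break
    return matches


def _candidate_tier(entry: EvidenceEntry, same_disease: bool) -> str:
    if entry.evidence_level == "clinical":
        return "1a" if same_disease else "1b"
    if entry.evidence_level == "preclinical":
        return "2a" if same_disease else "2b"
    return "3"


def assign_tier(
    matches: list[tuple[EvidenceEntry, bool]], record: AlterationRecord | None = None
) -> TierAssignment:
    """Resolve matched evidence to a single tier and drug.

    Best available-in-region candidate wins (ties break toward the first
    match in KB order); if matches exist but none is available locally the
    record is tier 4 with the best-evidence unavailable drug; no matches is
    tier 5 with no drug.
    """
    if record is None:
        record = _PLACEHOLDER_RECORD
    candidates = [(TIER_RANK[_candidate_tier(e, same)], e, same) for e, same in matches]
    available = [c for c in candidates if c[1].available_in_region]
    if available:
        rank, entry, same = min(available, key=lambda c: c[0])
        tier = TIERS[rank]
        rationale = (
            f"{entry.evidence_level} evidence for {entry.gene} in "
            f"{'the same' if same else 'a different'} disease ({entry.disease}); "
            f"{entry.drug} available in region"
        )
        return TierAssignment(record, tier, entry.drug, entry, rationale)
    if candidates:
        rank, entry, same = min(candidates, key=lambda c: c[0])
        rationale = (
            f"{entry.evidence_level} evidence for {entry.gene} ({entry.disease}), "
            f"but {entry.drug} is not available in the region"
        )
        return TierAssignment(record, "4", entry.drug, entry, rationale)
    return TierAssignment(record, "5", "", None, "no actionable genetic variant")


_PLACEHOLDER_RECORD = AlterationRecord(
    patient_id="",
    genes=("NA",),
    description="unspecified",
    components=(
        VariantCall(chrom="chr0", pos=1, ref="N", alt="N", gene="NA",
                    variant_class="fusion"),
    ),
)


def describe_variant(v: VariantCall) -> str:
    if v.variant_class == "CNV_amp":
        return f"{v.gene} amplification"
    if v.variant_class == "CNV_del":
        return f"{v.gene} deletion"
    if v.variant_class == "fusion":
        return f"{v.gene} translocation"
    return f"{v.gene} {v.protein_change or v.ref + '>' + v.alt}"


def build_alteration_records(
    variants: list[VariantCall], patient_id: str
) -> list[AlterationRecord]:
    """Group PASS variants into reportable records, one per gene.

    Co-occurring alterations in the same gene (e.g. a point mutation plus
    amplification) are reported together under one tier label.
    """
    by_gene: dict[str, list[VariantCall]] = {}
    for v in variants:
        if v.filter_status == "PASS":
            by_gene.setdefault(v.gene, []).append(v)
    records = []
    for gene, comps in by_gene.items():
        records.append(
            AlterationRecord(
                patient_id=patient_id,
                genes=(gene,),
                description=",".join(describe_variant(c) for c in comps),
                components=tuple(comps),
            )
        )
    return records


def best_tier(assignments: list[TierAssignment]) -> str:
    """The patient's best (lowest-ranked) tier; tier 5 when nothing was assigned."""
    if not assignments:
        return "5"
    return min((a.tier for a in assignments), key=lambda t: TIER_RANK[t])


def classify_patient(
    case,
    kb: list[EvidenceEntry],
    synonyms: dict[str, str] | None = None,
) -> tuple[list[TierAssignment], str | None]:
    """Tier every alteration record of one patient; returns (assignments, best tier).

    Sequencing-failure cases propagate as an empty assignment list with
    best tier None. Patients whose records all resolve to tier 5 — or who
    have no reportable records at all — are not actionable.
    """
    if not case.sequencing_success:
        return [], None
    records = case.alteration_records
    if records is None:
        records = build_alteration_records(case.variants, case.id)
    assignments = [
        assign_tier(match_evidence(rec, case.diagnosis, kb, synonyms), rec) for rec in records
    ]
    return assignments, best_tier(assignments)


def is_actionable(tier: str | None) -> bool:
    return tier is not None and TIER_RANK[tier] <= TIER_RANK["4"]
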
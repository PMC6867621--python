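"""Bundled example cohort: 55 relapsed/refractory pediatric solid tumors.

A curated desk-scale dataset used throughout the documentation and tests:
20 patients carry 23 reportable alteration records (point mutations,
gene-level copy-number events and one fusion) with a matching evidence
knowledge base; 33 further patients were profiled without an actionable
finding, and 2 failed sequencing for poor DNA quality. Variant coordinates
are placeholders (the alterations are gene-level facts); ages, sexes and
turnaround times are plausible defaults and are not asserted by any test.

The knowledge base illustrates every matcher and tier, including
indication-scoped regional availability: palbociclib evidence for CDK6
amplification is reachable for neuroblastoma (an open trial) but not for
glioblastoma, so the same alteration tiers differently in the two diseases.
"""

from __future__ import annotations

from .cohort_report import PatientCase
from .io_formats import EvidenceEntry, VariantCall
from .tiering import AlterationRecord

# placeholder coordinates per gene (chrom is the gene's real chromosome)
_GENE_LOCUS = {
    "MYCN": ("chr2", 16080000),
    "NRAS": ("chr1", 115256500),
    "CDK4": ("chr12", 58142000),
    "MDM2": ("chr12", 69202000),
    "PIK3CA": ("chr3", 178936000),
    "PDGFRA": ("chr4", 55141000),
    "PTCH1": ("chr9", 98209000),
    "CDK6": ("chr7", 92234000),
    "SMARCB1": ("chr22", 24129000),
    "ATM": ("chr11", 108098000),
    "CDKN2A": ("chr9", 21968000),
    "CDKN2B": ("chr9", 22002000),
    "BRAF": ("chr7", 140453000),
    "FLT3": ("chr13", 28592000),
    "ALK": ("chr2", 29443000),
}


def _snv(gene: str, protein_change: str) -> VariantCall:
    chrom, pos = _GENE_LOCUS[gene]
    return VariantCall(
        chrom=chrom, pos=pos, ref="A", alt="T", gene=gene,
        protein_change=protein_change, variant_class="SNV",
        vaf=0.40, depth=500, strand_counts=(150, 150, 100, 100),
    )


def _amp(gene: str) -> VariantCall:
    chrom, pos = _GENE_LOCUS[gene]
    return VariantCall(chrom=chrom, pos=pos, ref="N", alt="<AMP>", gene=gene,
                       variant_class="CNV_amp")


def _deletion(gene: str) -> VariantCall:
    chrom, pos = _GENE_LOCUS[gene]
    return VariantCall(chrom=chrom, pos=pos, ref="N", alt="<DEL>", gene=gene,
                       variant_class="CNV_del")


def _fusion(gene: str, partner: str) -> VariantCall:
    chrom, pos = _GENE_LOCUS[gene]
    return VariantCall(chrom=chrom, pos=pos, ref="N", alt=f"<{partner}-{gene}>",
                       gene=gene, variant_class="fusion")


def reference_knowledge_base() -> list[EvidenceEntry]:
    """The evidence knowledge base matching the bundled cohort's alterations."""
    e = EvidenceEntry
    return [
        e("MYCN", "any_amplification", "neuroblastoma", "preclinical",
          "BET bromodomain inhibitor", False),
        e("NRAS", "exact_protein_change", "neuroblastoma", "preclinical",
          "Everolimus", True, pattern="Q61K"),
        e("NRAS", "exact_protein_change", "melanoma", "preclinical",
          "Everolimus", True, pattern="Q61R"),
        e("CDK4", "any_amplification", "liposarcoma", "preclinical", "Palbociclib", False),
        e("MDM2", "any_amplification", "liposarcoma", "preclinical", "Selinexor", False),
        e("PIK3CA", "exact_protein_change", "breast cancer", "preclinical",
          "PI3K/AKT/mTOR pathway inhibitor", False, pattern="H1047R"),
        e("PDGFRA", "any_amplification", "soft tissue sarcoma", "consensus",
          "Pazopanib", True),
        e("PTCH1", "any_deletion", "basal cell carcinoma", "clinical", "Vismodegib", False),
        # palbociclib access for CDK6 amplification is trial-scoped to neuroblastoma
        e("CDK6", "any_amplification", "breast cancer", "preclinical", "Palbociclib", True,
          diagnosis_scope=("neuroblastoma",)),
        e("CDK6", "any_amplification", "breast cancer", "preclinical", "Palbociclib", False),
        e("SMARCB1", "any_deletion", "epithelioid sarcoma", "clinical", "Tazemetostat",
          False, reference="NCT03213665"),
        e("ATM", "any_deletion", "prostate cancer", "clinical", "Olaparib", True),
        e("CDKN2A", "any_deletion", "glioblastoma multiforme", "preclinical",
          "Palbociclib", True),
        e("CDKN2B", "any_deletion", "glioblastoma multiforme", "preclinical",
          "Palbociclib", True),
        e("BRAF", "exact_protein_change", "melanoma", "consensus", "Vemurafenib", True,
          pattern="L485F"),
        e("FLT3", "exact_protein_change", "acute myeloid leukemia", "preclinical",
          "Sorafenib", True, pattern="T820N"),
        e("ALK", "exact_protein_change", "neuroblastoma", "preclinical", "Lorlatinib",
          True, pattern="F1174L"),
        e("ALK", "any_fusion", "inflammatory myofibroblastic tumor", "clinical",
          "Crizotinib", True),
    ]


def _record(pid: str, genes: tuple[str, ...], desc: str, *components: VariantCall):
    return AlterationRecord(patient_id=pid, genes=genes, description=desc,
                            components=tuple(components))


# (patient id, diagnosis, summary group, [records])
_ACTIONABLE_PATIENTS = [
    ("002", "rhabdomyosarcoma", "rhabdomyosarcoma",
     [("MYCN amplification", ("MYCN",), [lambda: _amp("MYCN")])]),
    ("003", "neuroblastoma", "neuroblastoma",
     [("NRAS Q61K", ("NRAS",), [lambda: _snv("NRAS", "Q61K")]),
      ("CDK4 amplification", ("CDK4",), [lambda: _amp("CDK4")]),
      ("MYCN amplification", ("MYCN",), [lambda: _amp("MYCN")])]),
    ("004", "rhabdomyosarcoma", "rhabdomyosarcoma",
     [("MDM2 amplification", ("MDM2",), [lambda: _amp("MDM2")])]),
    ("007", "rhabdomyosarcoma", "rhabdomyosarcoma",
     [("MYCN amplification", ("MYCN",), [lambda: _amp("MYCN")])]),
    ("009", "rhabdomyosarcoma", "rhabdomyosarcoma",
     [("PIK3CA H1047R", ("PIK3CA",), [lambda: _snv("PIK3CA", "H1047R")])]),
    ("010", "osteosarcoma", "osteosarcoma",
     [("PDGFRA amplification", ("PDGFRA",), [lambda: _amp("PDGFRA")])]),
    ("017", "medulloblastoma", "medulloblastoma",
     [("PTCH1 deletion", ("PTCH1",), [lambda: _deletion("PTCH1")])]),
    ("023", "neuroblastoma", "neuroblastoma",
     [("MYCN amplification", ("MYCN",), [lambda: _amp("MYCN")])]),
    ("024", "glioblastoma multiforme", "high-grade glioma",
     [("CDK6 amplification", ("CDK6",), [lambda: _amp("CDK6")])]),
    ("030", "epithelioid sarcoma", "other",
     [("SMARCB1 deletion", ("SMARCB1",), [lambda: _deletion("SMARCB1")])]),
    ("031", "neuroblastoma", "neuroblastoma",
     [("CDK6 amplification", ("CDK6",), [lambda: _amp("CDK6")])]),
    ("034", "neuroblastoma", "neuroblastoma",
     [("ATM deletion", ("ATM",), [lambda: _deletion("ATM")]),
      ("CDKN2B deletion", ("CDKN2B",), [lambda: _deletion("CDKN2B")])]),
    ("037", "hepatoblastoma", "hepatoblastoma",
     [("NRAS Q61R", ("NRAS",), [lambda: _snv("NRAS", "Q61R")])]),
    ("038", "glioblastoma multiforme", "high-grade glioma",
     [("CDKN2A/B deletion", ("CDKN2A", "CDKN2B"),
       [lambda: _deletion("CDKN2A"), lambda: _deletion("CDKN2B")])]),
    ("042", "neuroblastoma", "neuroblastoma",
     [("ATM deletion", ("ATM",), [lambda: _deletion("ATM")])]),
    ("046", "pilocytic astrocytoma", "high-grade glioma",
     [("BRAF L485F", ("BRAF",), [lambda: _snv("BRAF", "L485F")])]),
    ("052", "yolk sac tumor", "other",
     [("FLT3 T820N", ("FLT3",), [lambda: _snv("FLT3", "T820N")])]),
    ("059", "CNS embryonal tumor", "other",
     [("CDKN2A/B deletion", ("CDKN2A", "CDKN2B"),
       [lambda: _deletion("CDKN2A"), lambda: _deletion("CDKN2B")])]),
    ("060", "neuroblastoma", "neuroblastoma",
     [("ALK F1174L,ALK amplification", ("ALK",),
       [lambda: _snv("ALK", "F1174L"), lambda: _amp("ALK")])]),
    ("064", "inflammatory myofibroblastic tumor", "other",
     [("ALK translocation", ("ALK",), [lambda: _fusion("ALK", "TPM4")])]),
]

# diagnoses of the 35 enrolled patients without an actionable alteration;
# two of them (marked) failed sequencing. Category mix fills the cohort to
# 16 neuroblastoma / 9 rhabdomyosarcoma / 5 medulloblastoma /
# 4 high-grade glioma / 3 Ewing / 3 hepatoblastoma / 3 osteosarcoma /
# 2 alveolar soft part sarcoma / 2 Wilms / 8 "other".
_NONACTIONABLE = (
    ["neuroblastoma"] * 10
    + ["rhabdomyosarcoma"] * 5
    + ["medulloblastoma"] * 4
    + ["high-grade glioma"] * 1
    + ["ewing sarcoma"] * 3
    + ["hepatoblastoma"] * 2
    + ["osteosarcoma"] * 2
    + ["alveolar soft part sarcoma"] * 2
    + ["wilms tumor"] * 2
    + [
        "angiosarcoma",
        "desmoplastic small round cell tumor",
        "EBV-associated lymphoepithelioid carcinoma",
        "malignant rhabdoid tumor",
    ]
)
_FAILED_INDICES = (0, 10)  # one neuroblastoma, one rhabdomyosarcoma failed sequencing
_GROUP_OF = {
    "glioblastoma multiforme": "high-grade glioma",
    "pilocytic astrocytoma": "high-grade glioma",
    "epithelioid sarcoma": "other",
    "yolk sac tumor": "other",
    "CNS embryonal tumor": "other",
    "inflammatory myofibroblastic tumor": "other",
    "angiosarcoma": "other",
    "desmoplastic small round cell tumor": "other",
    "EBV-associated lymphoepithelioid carcinoma": "other",
    "malignant rhabdoid tumor": "other",
}


def load_reference_cohort() -> tuple[list[PatientCase], list[EvidenceEntry]]:
    """The bundled 55-patient cohort (fresh objects) and its knowledge base.

    Actionable patients carry explicit :class:`AlterationRecord` groupings;
    profiled patients without findings have empty record lists; two cases
    are sequencing failures. Marginal sample attributes follow the cohort's
    characteristics table: 34 FFPE / 21 fresh-frozen, 41 relapse /
    14 diagnosis samples, 30 male / 25 female.
    """
    table_ids = {pid for pid, *_ in _ACTIONABLE_PATIENTS}
    other_ids = [f"{i:03d}" for i in range(1, 70) if f"{i:03d}" not in table_ids]

    cases: list[PatientCase] = []
    for pid, diagnosis, group, record_specs in _ACTIONABLE_PATIENTS:
        records = []
        variants = []
        for desc, genes, makers in record_specs:
            components = tuple(maker() for maker in makers)
            variants.extend(components)
            records.append(AlterationRecord(pid, genes, desc, components))
        cases.append(
            PatientCase(
                id=pid, diagnosis=diagnosis, diagnosis_group=group,
                variants=variants, alteration_records=records,
            )
        )
    for j, diagnosis in enumerate(_NONACTIONABLE):
        failed = j in _FAILED_INDICES
        cases.append(
            PatientCase(
                id=other_ids[j], diagnosis=diagnosis,
                diagnosis_group=_GROUP_OF.get(diagnosis, diagnosis),
                sequencing_success=not failed,
                alteration_records=None if failed else [],
            )
        )

    # deterministic, non-asserted per-patient attributes with the published marginals
    cases.sort(key=lambda c: c.id)
    for k, case in enumerate(cases):
        case.sample_type = "FFPE" if k < 34 else "FF"
        case.sample_timepoint = "diagnosis" if k % 4 == 0 else "relapse"
        case.sex = "M" if k < 30 else "F"
        case.age_years = 0.8 + (k * 0.36)
        case.timeline_days = (7, 19, 2) if k % 2 == 0 else (6 + k % 9, 15 + k % 14, k % 5)
    return cases, reference_knowledge_base()
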
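"""Variant filtering, composite deleteriousness classification, and
per-patient genotype bookkeeping.

The classification is the study's composite rule:

* **missense** — deleterious when at least two of the three predictors
  (SIFT; PolyPhen2, with HumDiv/HumVar OR-combined as a single predictor;
  MutationAssessor at medium or high impact) flag the variant, or at least
  one of them does for a variant absent from dbSNP ("New");
* **splice / nonsense / frameshift / in-frame indel** — deleterious when
  CADD PHRED >= 20 (top 1% of damaging variants genome-wide), falling back
  to a LoF-Tool "PD" label when CADD is unavailable.

SIFT's printed categorical label is trusted over its numeric score when
both are present (the numeric < 0.05 cut is only a fallback); the
discordant case is surfaced in the call's notes.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import InsufficientAnnotationError, ValidationError
from .models import (
    CILIA_PANELS,
    Cohort,
    GeneGenotypeSummary,
    GenePanel,
    PredictorProfile,
    TriageCall,
    VariantRecord,
)

SIFT_FALLBACK_THRESHOLD = 0.05
CADD_DELETERIOUS_THRESHOLD = 20.0
#: Clinical tiers a cilia-panel variant must reach to be analyzed.
ANALYZABLE_CLASSES = frozenset({"VUS", "likely_pathogenic", "pathogenic"})


def predictor_abnormalities(profile: PredictorProfile) -> frozenset:
    """Abnormal missense predictors among {SIFT, PP2, MA}.

    SIFT is abnormal iff its label is ``D`` (score < 0.05 only when no
    label is present); PolyPhen2 iff HumDiv *or* HumVar is ``PD``/``D``;
    MutationAssessor iff its impact label is medium or high.

    Raises :class:`InsufficientAnnotationError` when none of the three
    predictors is annotated at all.
    """
    if not (profile.has_sift or profile.has_pp2 or profile.has_ma):
        raise InsufficientAnnotationError(
            "no SIFT/PolyPhen2/MutationAssessor annotation present"
        )
    abnormal = set()
    if profile.sift_label is not None:
        if profile.sift_label == "D":
            abnormal.add("SIFT")
    elif profile.sift_score is not None and profile.sift_score < SIFT_FALLBACK_THRESHOLD:
        abnormal.add("SIFT")
    if profile.pp2_humdiv_label in {"PD", "D"} or profile.pp2_humvar_label in {"PD", "D"}:
        abnormal.add("PP2")
    if profile.ma_label in {"M", "H"}:
        abnormal.add("MA")
    return frozenset(abnormal)


def classify_variant(record: VariantRecord) -> TriageCall:
    """Apply the composite deleteriousness rule to one variant record."""
    notes = []
    p = record.predictors
    if record.consequence == "missense":
        abnormal = predictor_abnormalities(p)
        if (
            p.sift_label == "D"
            and p.sift_score is not None
            and p.sift_score >= SIFT_FALLBACK_THRESHOLD
        ):
            notes.append(
                f"SIFT label D trusted over score {p.sift_score} >= "
                f"{SIFT_FALLBACK_THRESHOLD}"
            )
        if len(abnormal) >= 2:
            rule = "missense_two_of_three"
            deleterious = True
        elif record.is_novel and len(abnormal) >= 1:
            rule = "missense_novel_one"
            deleterious = True
            notes.append("novel variant: single abnormality suffices")
        else:
            rule = "none"
            deleterious = False
    else:
        if p.cadd_phred is not None:
            deleterious = p.cadd_phred >= CADD_DELETERIOUS_THRESHOLD
            rule = "lof_cadd" if deleterious else "none"
            abnormal = frozenset({"CADD"}) if deleterious else frozenset()
            notes.append(f"CADD PHRED {p.cadd_phred}")
        elif p.loftool_label is not None:
            deleterious = p.loftool_label == "PD"
            rule = "lof_tool" if deleterious else "none"
            abnormal = frozenset({"LoFTool"}) if deleterious else frozenset()
            notes.append(f"LoF-Tool label {p.loftool_label}")
        else:
            raise InsufficientAnnotationError(
                f"{record.gene} {record.nt_change}: no CADD or LoF-Tool annotation"
            )
    return TriageCall(
        deleterious=deleterious,
        abnormal_predictors=abnormal,
        rule_fired=rule,
        notes="; ".join(notes),
    )


def filter_variants(
    records: Sequence[VariantRecord],
    panels: Optional[Mapping[str, GenePanel]] = None,
) -> List[VariantRecord]:
    """Apply the study's panel-dependent inclusion rule, preserving order.

    All non-synonymous variants in previously TGA-associated genes are kept
    regardless of clinical tier; cilia-panel variants are kept only at VUS,
    likely-pathogenic or pathogenic tiers.  If *panels* is given, each
    record's gene must belong to its assigned panel.
    """
    kept = []
    for i, r in enumerate(records):
        if panels is not None:
            panel = panels.get(r.panel)
            if panel is None:
                raise ValidationError(f"record {i}: unknown panel {r.panel!r}")
            if r.gene not in panel:
                raise ValidationError(
                    f"record {i}: gene {r.gene} not in panel {r.panel!r}"
                )
        if r.panel in CILIA_PANELS and r.clinical_class not in ANALYZABLE_CLASSES:
            continue
        kept.append(r)
    return kept


def summarize_gene_genotype(
    records: Sequence[VariantRecord],
    calls: Sequence[TriageCall],
) -> GeneGenotypeSummary:
    """Count deleterious calls by zygosity for one (patient, gene) pair.

    Compound heterozygosity: at least two *distinct* deleterious
    heterozygous variants (by cDNA change) in the same gene and patient.
    """
    if not records:
        raise ValidationError("no records to summarize")
    if len(records) != len(calls):
        raise ValidationError("records and calls must be aligned")
    patients = {r.patient_id for r in records}
    genes = {r.gene for r in records}
    if len(patients) != 1 or len(genes) != 1:
        raise ValidationError(
            f"summary requires a single (patient, gene) pair, got {patients} x {genes}"
        )
    counts = {"het": 0, "hom": 0, "hemi": 0}
    het_changes = set()
    for r, call in zip(records, calls):
        if call.deleterious:
            counts[r.zygosity] += 1
            if r.zygosity == "het":
                het_changes.add(r.nt_change)
    return GeneGenotypeSummary(
        patient_id=next(iter(patients)),
        gene=next(iter(genes)),
        n_deleterious_het=counts["het"],
        n_deleterious_hom=counts["hom"],
        n_deleterious_hemi=counts["hemi"],
        compound_het=len(het_changes) >= 2,
    )


def summarize_cohort_genotypes(
    records: Sequence[VariantRecord],
    calls: Sequence[TriageCall],
) -> List[GeneGenotypeSummary]:
    """Per-(patient, gene) summaries over a whole cohort, sorted."""
    grouped: Dict[Tuple[str, str], List[int]] = defaultdict(list)
    for i, r in enumerate(records):
        grouped[(r.patient_id, r.gene)].append(i)
    return [
        summarize_gene_genotype([records[i] for i in idx], [calls[i] for i in idx])
        for key, idx in sorted(grouped.items())
    ]


def allele_count(
    records: Sequence[VariantRecord], cohort: Cohort
) -> Tuple[int, int]:
    """Observed alternate-allele count and cohort allele number for one variant.

    Carrier doses: het 1, hom 2, hemi 1.  The denominator is the cohort's
    autosomal allele number (2 x patients) or, for X-linked variants,
    2 x females + males.
    """
    if not records:
        raise ValidationError("no carrier records given")
    genes = {r.gene for r in records}
    changes = {r.nt_change for r in records}
    chrom = {r.chromosome_class for r in records}
    if len(genes) != 1 or len(changes) != 1:
        raise ValidationError(
            f"allele_count requires a single variant, got {genes} x {changes}"
        )
    if len(chrom) != 1:
        raise ValidationError("inconsistent chromosome_class across carriers")
    patients = [r.patient_id for r in records]
    if len(set(patients)) != len(patients):
        dupes = sorted({p for p in patients if patients.count(p) > 1})
        raise ValidationError(
            f"duplicate carrier rows for patient(s) {dupes}; deduplicate first"
        )
    for r in records:
        cohort.sex_of(r.patient_id)  # raises if carrier outside cohort
    k = sum(r.allele_dose for r in records)
    n = cohort.allele_number(next(iter(chrom)))
    if k > n:
        raise ValidationError(f"allele count k={k} exceeds allele number n={n}")
    return k, n


def annotation_consistency_report(
    records: Iterable[VariantRecord], cohort: Cohort
) -> List[str]:
    """Flag annotation inconsistencies instead of silently correcting them.

    Currently: hemizygous calls in female carriers (the X dose of a female
    is two alleles, so a printed hemizygous label is surfaced as suspect),
    and known variants with no reference frequency.
    """
    messages = []
    for r in records:
        sex = cohort.sex_of(r.patient_id)
        if r.zygosity == "hemi" and sex == "female":
            messages.append(
                f"{r.patient_id} {r.gene} {r.nt_change}: hemizygous label on a "
                "female carrier (kept as annotated)"
            )
        if r.freq_not_found:
            messages.append(
                f"{r.patient_id} {r.gene} {r.nt_change}: known variant with no "
                "reference frequency (NF)"
            )
    return messages
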
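#!/usr/bin/env python
"""Triage the cohort's candidate-gene variants.

Loads the packaged annotated variant tables (11 probands, four gene
panels), applies the panel inclusion rule and the composite deleteriousness
classification, and writes per-variant calls plus per-(patient, gene)
genotype summaries — including compound-heterozygosity detection — to
results/.
"""

from collections import Counter
from pathlib import Path

from ciliavar import datasets
from ciliavar.triage import (
    annotation_consistency_report,
    classify_variant,
    filter_variants,
    summarize_cohort_genotypes,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    records = datasets.load_study_variants()
    print(f"loaded {len(records)} variant observations from the four panel tables")

    kept = filter_variants(records, datasets.load_panels())
    kept = datasets.unique_patient_variants(kept)
    print(f"{len(kept)} unique (patient, variant) observations after panel filtering")

    calls = [classify_variant(r) for r in kept]
    n_del = sum(c.deleterious for c in calls)
    print(f"deleterious calls: {n_del} / {len(calls)}")
    rule_counts = Counter(c.rule_fired for c in calls)
    for rule, count in rule_counts.most_common():
        print(f"  rule {rule}: {count}")

    order = sorted(
        range(len(kept)), key=lambda i: (kept[i].patient_id, kept[i].gene, kept[i].nt_change)
    )
    with (OUT / "triage_report.tsv").open("w") as fh:
        fh.write(
            "patient_id\tgene\tdbsnp\tnt_change\tconsequence\tzygosity\tpanel\t"
            "deleterious\trule_fired\tabnormal_predictors\tnotes\n"
        )
        for i in order:
            r, c = kept[i], calls[i]
            fh.write(
                "\t".join(
                    [
                        r.patient_id, r.gene, r.dbsnp, r.nt_change, r.consequence,
                        r.zygosity, r.panel, "yes" if c.deleterious else "no",
                        c.rule_fired, ",".join(sorted(c.abnormal_predictors)) or "-",
                        c.notes or "-",
                    ]
                )
                + "\n"
            )

    summaries = summarize_cohort_genotypes(kept, calls)
    compound = [s for s in summaries if s.compound_het]
    print("compound heterozygous (patient, gene):",
          [(s.patient_id, s.gene) for s in compound] or "none")
    with (OUT / "gene_summaries.tsv").open("w") as fh:
        fh.write(
            "patient_id\tgene\tn_deleterious_het\tn_deleterious_hom\t"
            "n_deleterious_hemi\tcompound_het\n"
        )
        for s in summaries:
            fh.write(
                f"{s.patient_id}\t{s.gene}\t{s.n_deleterious_het}\t"
                f"{s.n_deleterious_hom}\t{s.n_deleterious_hemi}\t"
                f"{'yes' if s.compound_het else 'no'}\n"
            )

    for message in annotation_consistency_report(kept, datasets.load_study_cohort()):
        print("annotation inconsistency:", message)
    print(f"wrote {OUT / 'triage_report.tsv'} and {OUT / 'gene_summaries.tsv'}")


if __name__ == "__main__":
    main()
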
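"""Curate a small missense-variant catalog: filter, merge, summarize.

Builds a toy ClinVar-style table and a cohort table in memory, applies the
curation rules (>= 2 review stars for ClinVar records, cancer/tumor
condition keyword, missense only, VUS/conflicting dropped, MAF < 1%),
merges the two sources and prints the summary counts.
"""

from afmissense import (
    FilterConfig,
    Significance,
    Source,
    filter_records,
    merge_catalogs,
    parse_protein_change,
    summarize_catalog,
)
from afmissense.variants import VariantClass, VariantRecord


def record(change, sig, stars, source, condition="hereditary breast cancer"):
    pc = parse_protein_change(change)
    return VariantRecord(
        gene_symbol="TP53",
        uniprot_id="P04637",
        change=pc,
        clinical_significance=sig,
        review_stars=stars,
        condition_text=condition,
        source=source,
        variant_class=VariantClass.MISSENSE,
        change_text=change,
    )


clinvar = [
    record("R175H", Significance.PATHOGENIC, 3, Source.CLINVAR),
    record("P72R", Significance.BENIGN, 2, Source.CLINVAR),
    record("G245S", Significance.PATHOGENIC, 1, Source.CLINVAR),  # dropped: 1 star
    record("R282W", Significance.VUS, 2, Source.CLINVAR),  # dropped: VUS
    record("R280K", Significance.PATHOGENIC, 2, Source.CLINVAR, condition="Li-Fraumeni TUMOUR syndrome"),
]
cohort = [
    record("R175H", Significance.PATHOGENIC, None, Source.COHORT),  # duplicate of ClinVar
    record("V157F", Significance.LIKELY_PATHOGENIC, None, Source.COHORT),
]

kept_clinvar = filter_records(clinvar, FilterConfig())
kept_cohort = filter_records(cohort, FilterConfig())
merged, conflicts = merge_catalogs(kept_clinvar, kept_cohort)
summary = summarize_catalog(merged)

print(f"ClinVar records kept by the filters : {len(kept_clinvar)} / {len(clinvar)}")
print(f"Cohort records kept by the filters  : {len(kept_cohort)} / {len(cohort)}")
print(f"Merged unique variants              : {summary.n_unique}")
print(f"Label conflicts between sources     : {len(conflicts)}")
print(f"Benign / pathogenic (likely folded) : {summary.n_benign} / {summary.n_pathogenic}")
# The merged catalog keeps one record per (protein, position, wt, mut) key,
# preferring the ClinVar label when both sources report the same variant.
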
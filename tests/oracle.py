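"""Independent brute-force re-implementation of the cascade predicate.

Written as one flat pass of plain conditionals over each variant, with
the default thresholds hard-coded, deliberately sharing no logic with
the package's staged implementation.  Used only as the expected side of
equivalence tests.
"""

from __future__ import annotations

from famprio.model import (
    AnnotationRecord,
    FamilyCohort,
    FunctionalClass,
    Genotype,
    PredictorCall,
    VariantKey,
    VariantRecord,
)


def oracle_fate(
    variant: VariantRecord,
    ann: AnnotationRecord | None,
    cohort: FamilyCohort,
    rescue_genes: set[str],
) -> str:
    """Classify one variant under default thresholds.

    Returns one of 'coding', 'coding_rescued', 'noncoding', 'dead'.
    """
    # quality: QUAL strictly above 20, caller PASS, per-sample depth
    # strictly above 5 wherever a genotype was called
    if variant.site_qual <= 20.0:
        return "dead"
    if not variant.caller_filters_passed:
        return "dead"
    for call in variant.per_sample.values():
        if call.genotype != Genotype.MISSING:
            if call.depth is None or call.depth <= 5:
                return "dead"
    # rarity: at most 0.1% in both panels; missing means novel
    if ann is not None:
        if ann.maf_kg_phase3 is not None and ann.maf_kg_phase3 > 0.001:
            return "dead"
        if ann.maf_exac_nontcga is not None and ann.maf_exac_nontcga > 0.001:
            return "dead"
    # segregation: carried by every case, by no control
    for s in cohort.cases:
        gt = variant.per_sample[s.sample_id].genotype
        if gt not in (Genotype.HET, Genotype.HOM_ALT):
            return "dead"
    for s in cohort.controls:
        gt = variant.per_sample[s.sample_id].genotype
        if gt in (Genotype.HET, Genotype.HOM_ALT):
            return "dead"
    # routing
    if ann is None:
        return "dead"
    if ann.functional_class == FunctionalClass.NONCODING_EXONIC:
        if ann.cadd_phred is not None and ann.cadd_phred > 10.0:
            return "noncoding"
        return "dead"
    if ann.functional_class not in (FunctionalClass.MISSENSE, FunctionalClass.NONSENSE):
        return "dead"
    # CADD strictly above 10; never forgiven by rescue
    if ann.cadd_phred is None or ann.cadd_phred <= 10.0:
        return "dead"
    # conservation (all three, inclusive bounds) and ensemble vote
    conserved = (
        ann.gerp is not None and ann.gerp >= 2.0
        and ann.phastcons is not None and ann.phastcons >= 0.3
        and ann.phylop is not None and ann.phylop >= 3.0
    )
    d = sum(1 for c in ann.predictor_calls.values() if c == PredictorCall.DELETERIOUS)
    m = sum(1 for c in ann.predictor_calls.values() if c != PredictorCall.MISSING)
    vote_ok = m >= 5 and d / m >= 0.6
    if conserved and vote_ok:
        return "coding"
    if ann.gene in rescue_genes:
        return "coding_rescued"
    return "dead"


def oracle_shortlists(
    variants: list[VariantRecord],
    annotations: dict[VariantKey, AnnotationRecord],
    cohort: FamilyCohort,
    rescue_genes: set[str],
) -> tuple[set[VariantKey], set[VariantKey], set[VariantKey]]:
    """(coding keys, rescued subset, noncoding keys) under defaults."""
    coding: set[VariantKey] = set()
    rescued: set[VariantKey] = set()
    noncoding: set[VariantKey] = set()
    for v in variants:
        fate = oracle_fate(v, annotations.get(v.key), cohort, rescue_genes)
        if fate == "coding":
            coding.add(v.key)
        elif fate == "coding_rescued":
            coding.add(v.key)
            rescued.add(v.key)
        elif fate == "noncoding":
            noncoding.add(v.key)
    return coding, rescued, noncoding
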
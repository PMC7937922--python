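"""Shared builders for in-memory cohorts used across the test modules."""

from __future__ import annotations

import numpy as np

from famprio.model import (
    AnnotationRecord,
    FamilyCohort,
    FunctionalClass,
    Genotype,
    PedigreeSample,
    PredictorCall,
    Role,
    SampleCall,
    VariantRecord,
)


def mk_cohort(n_cases=3, n_carriers=1, n_controls=1) -> FamilyCohort:
    samples = (
        [PedigreeSample(f"CASE{i+1}", Role.CASE) for i in range(n_cases)]
        + [PedigreeSample(f"CARRIER{i+1}", Role.POTENTIAL_CARRIER) for i in range(n_carriers)]
        + [PedigreeSample(f"CONTROL{i+1}", Role.CONTROL) for i in range(n_controls)]
    )
    return FamilyCohort("FAM1", tuple(samples))


def mk_variant(
    cohort: FamilyCohort,
    pos: int = 1000,
    qual: float = 100.0,
    caller_pass: bool = True,
    depth: int = 30,
    genotypes: dict[str, Genotype] | None = None,
    segregating: bool = True,
    chrom: str = "1",
    ref: str = "A",
    alt: str = "G",
) -> VariantRecord:
    """A variant record; by default het in cases/carriers, hom-ref in controls."""
    gts: dict[str, Genotype] = {}
    for s in cohort.samples:
        if s.role is Role.CONTROL:
            gts[s.sample_id] = Genotype.HOM_REF
        else:
            gts[s.sample_id] = Genotype.HET if segregating else Genotype.HOM_REF
    if genotypes:
        gts.update(genotypes)
    per_sample = {sid: SampleCall(gts[sid], depth) for sid in cohort.sample_ids}
    return VariantRecord(chrom, pos, ref, alt, qual, caller_pass, per_sample)


def mk_ann(variant: VariantRecord, n_deleterious: int = 8, **over) -> AnnotationRecord:
    """An annotation record passing every default threshold; override freely."""
    calls = {}
    from famprio.model import PREDICTOR_TOOLS

    for i, tool in enumerate(PREDICTOR_TOOLS):
        calls[tool] = PredictorCall.DELETERIOUS if i < n_deleterious else PredictorCall.TOLERATED
    fields = dict(
        variant_key=variant.key,
        maf_kg_phase3=0.0001,
        maf_exac_nontcga=0.0001,
        cadd_phred=25.0,
        gerp=4.0,
        phastcons=0.9,
        phylop=5.0,
        predictor_calls=calls,
        gene=f"GENE_{variant.pos}",
        functional_class=FunctionalClass.MISSENSE,
        intolerance_scores={"esp6500": 80.0, "exac": 85.0, "local": 90.0},
        pli=0.5,
        mis_z=3.0,
    )
    fields.update(over)
    return AnnotationRecord(**fields)


def random_memory_cohort(rng: np.random.Generator, n_variants: int = 40):
    """A fully random in-memory cohort for property tests.

    Unlike the simulator's single-failure decoys, every field is drawn
    independently, so variants can fail several stages at once.
    """
    cohort = mk_cohort(
        n_cases=int(rng.integers(1, 4)),
        n_carriers=int(rng.integers(0, 3)),
        n_controls=int(rng.integers(1, 3)),
    )
    gts = [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.MISSING]
    classes = list(FunctionalClass)
    variants, annotations = [], {}
    for i in range(n_variants):
        per_sample = {
            sid: SampleCall(
                gts[int(rng.integers(0, 4))],
                None if rng.random() < 0.05 else int(rng.integers(0, 40)),
            )
            for sid in cohort.sample_ids
        }
        v = VariantRecord(
            "1", 1000 + i, "A", "G",
            float(rng.uniform(0, 60)), bool(rng.random() < 0.9), per_sample,
        )
        variants.append(v)
        if rng.random() < 0.9:  # some variants stay unannotated
            annotations[v.key] = mk_ann(
                v,
                n_deleterious=int(rng.integers(0, 11)),
                maf_kg_phase3=None if rng.random() < 0.2 else float(rng.uniform(0, 0.01)),
                maf_exac_nontcga=None if rng.random() < 0.2 else float(rng.uniform(0, 0.01)),
                cadd_phred=None if rng.random() < 0.1 else float(rng.uniform(0, 40)),
                gerp=None if rng.random() < 0.1 else float(rng.uniform(-5, 7)),
                phastcons=None if rng.random() < 0.1 else float(rng.uniform(0, 1)),
                phylop=None if rng.random() < 0.1 else float(rng.uniform(-5, 9)),
                functional_class=classes[int(rng.integers(0, len(classes)))],
                pli=None if rng.random() < 0.2 else float(rng.uniform(0, 1)),
                mis_z=None if rng.random() < 0.2 else float(rng.uniform(-3, 7)),
            )
    return cohort, variants, annotations
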
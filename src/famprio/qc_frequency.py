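"""Site-quality, coverage and population-frequency filtering.

Quality retention requires QUAL strictly above the threshold, passing
caller filters, and per-sample depth strictly above the coverage floor in
every sample with a called genotype.  Rarity requires the alternate
allele frequency to be at most the cutoff (default 0.1%) in both
reference panels; a missing frequency means the variant is absent from
the panel and is kept as novel.  A pairwise shared-rare-variant matrix
supports sample-swap and relatedness review.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .model import (
    AnnotationRecord,
    FamilyCohort,
    Genotype,
    StageOutcome,
    StageResult,
    VariantKey,
    VariantRecord,
)


@dataclass
class QcThresholds:
    """Quality and rarity cutoffs.

    ``qual_min`` and ``depth_min`` are strict lower bounds (a site at
    exactly the threshold is removed); ``maf_max`` is inclusive (a
    variant at exactly the cutoff frequency is kept).  ``depth_mode``
    selects per-sample enforcement (default) or a site-mean relaxation.
    """

    qual_min: float = 20.0
    depth_min: int = 5
    require_caller_pass: bool = True
    maf_max: float = 0.001
    depth_mode: Literal["per_sample", "site_mean"] = "per_sample"

    def __post_init__(self) -> None:
        if self.qual_min < 0 or self.depth_min < 0:
            raise ValueError("qual_min and depth_min must be non-negative")
        if not (0.0 <= self.maf_max <= 1.0):
            raise ValueError("maf_max must lie in [0, 1]")
        if self.depth_mode not in ("per_sample", "site_mean"):
            raise ValueError(f"unknown depth_mode {self.depth_mode!r}")


def quality_check(
    variant: VariantRecord, cohort: FamilyCohort, thresholds: QcThresholds
) -> StageResult:
    """Evaluate the quality stage for one variant."""
    if not (variant.site_qual > thresholds.qual_min):
        return StageResult("quality", StageOutcome.FAIL, f"site_qual {variant.site_qual:g} <= {thresholds.qual_min:g}")
    if thresholds.require_caller_pass and not variant.caller_filters_passed:
        return StageResult("quality", StageOutcome.FAIL, "caller filters not passed")
    if thresholds.depth_mode == "per_sample":
        for sample in cohort.samples:
            call = variant.per_sample.get(sample.sample_id)
            if call is None or call.genotype is Genotype.MISSING:
                continue
            if call.depth is None or not (call.depth > thresholds.depth_min):
                shown = "missing" if call is None or call.depth is None else str(call.depth)
                return StageResult(
                    "quality",
                    StageOutcome.FAIL,
                    f"depth {shown} <= {thresholds.depth_min} in sample {sample.sample_id}",
                )
    else:
        depths = [
            c.depth
            for c in variant.per_sample.values()
            if c.depth is not None
        ]
        mean_depth = float(np.mean(depths)) if depths else 0.0
        if not (mean_depth > thresholds.depth_min):
            return StageResult("quality", StageOutcome.FAIL, f"mean depth {mean_depth:g} <= {thresholds.depth_min}")
    return StageResult("quality", StageOutcome.PASS)


def quality_filter(
    variants: list[VariantRecord], cohort: FamilyCohort, thresholds: QcThresholds
) -> tuple[list[VariantRecord], dict[VariantKey, StageResult]]:
    """Partition variants by the quality stage; returns retained + per-variant results."""
    results: dict[VariantKey, StageResult] = {}
    retained: list[VariantRecord] = []
    for v in variants:
        res = quality_check(v, cohort, thresholds)
        results[v.key] = res
        if res.outcome is StageOutcome.PASS:
            retained.append(v)
    return retained, results


def is_rare(annotation: Optional[AnnotationRecord], thresholds: QcThresholds) -> tuple[bool, str]:
    """Rarity predicate: at most ``maf_max`` in both panels; missing = novel."""
    if annotation is not None:
        if annotation.maf_kg_phase3 is not None and annotation.maf_kg_phase3 > thresholds.maf_max:
            return False, f"1KG phase3 MAF {annotation.maf_kg_phase3:g} > {thresholds.maf_max:g}"
        if annotation.maf_exac_nontcga is not None and annotation.maf_exac_nontcga > thresholds.maf_max:
            return False, f"non-TCGA ExAC MAF {annotation.maf_exac_nontcga:g} > {thresholds.maf_max:g}"
    return True, ""


def frequency_filter(
    variants: list[VariantRecord],
    annotations: dict[VariantKey, AnnotationRecord],
    thresholds: QcThresholds,
) -> tuple[list[VariantRecord], dict[VariantKey, StageResult]]:
    """Remove variants common in either reference panel."""
    results: dict[VariantKey, StageResult] = {}
    retained: list[VariantRecord] = []
    for v in variants:
        rare, detail = is_rare(annotations.get(v.key), thresholds)
        if rare:
            results[v.key] = StageResult("frequency", StageOutcome.PASS)
            retained.append(v)
        else:
            results[v.key] = StageResult("frequency", StageOutcome.FAIL, detail)
    return retained, results


def shared_rare_matrix(
    variants: list[VariantRecord],
    annotations: dict[VariantKey, AnnotationRecord],
    cohort: FamilyCohort,
    thresholds: Optional[QcThresholds] = None,
) -> pd.DataFrame:
    """Pairwise counts of rare variants co-carried by sample pairs.

    Entry (i, j) counts rare variants where both samples carry at least
    one alternate allele; the diagonal holds per-sample carrier counts.
    Reported for human review of swaps/relatedness, never as a filter.
    """
    if len(cohort.samples) < 2:
        raise ValueError("shared_rare_matrix requires at least 2 samples")
    thresholds = thresholds or QcThresholds()
    ids = list(cohort.sample_ids)
    carrier = np.zeros((len(variants), len(ids)), dtype=bool)
    keep = np.zeros(len(variants), dtype=bool)
    for i, v in enumerate(variants):
        keep[i], _ = is_rare(annotations.get(v.key), thresholds)
        for j, sid in enumerate(ids):
            call = v.per_sample.get(sid)
            carrier[i, j] = call is not None and call.genotype.carries_alt
    carrier = carrier[keep]
    counts = carrier.T.astype(int) @ carrier.astype(int)
    return pd.DataFrame(counts, index=ids, columns=ids)
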
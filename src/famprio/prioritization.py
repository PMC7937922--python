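"""The annotation-threshold cascade on segregating variants.

Segregating coding variants pass, in order, a CADD deleteriousness cut
(strictly above 10, i.e. the top 10% of possible substitutions), a
three-score conservation filter (GERP, PhastCons, PhyloP), and an
ensemble vote requiring at least 60% of ten in-silico predictors to call
the variant deleterious.  Survivors are ranked by gene constraint:
nonsense variants by pLI, missense by the missense Z score, with
intolerance percentiles, CADD and the variant key as tie-breaks.
Variants in known cancer-predisposition genes that fail only the
conservation or vote stages are reinstated ("rescued"); non-coding
exonic variants are routed to a separate CADD-ranked track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from .model import (
    INTOLERANCE_SOURCES,
    AnnotationRecord,
    FamilyCohort,
    FilterTrace,
    FunctionalClass,
    PredictorCall,
    PrioritizedCandidate,
    StageOutcome,
    StageResult,
    Track,
    VariantKey,
    VariantRecord,
)
from .qc_frequency import QcThresholds, frequency_filter, quality_filter
from .segregation import SegregationPolicy, segregation_filter


@dataclass
class PrioritizationThresholds:
    """Cutoffs for the annotation cascade.

    ``cadd_min`` is a strict lower bound (CADD exactly at the threshold
    is removed); the conservation bounds are inclusive; ``vote_fraction``
    is inclusive ("at least 60%").  ``vote_min_calls`` is the minimum
    number of non-missing predictor calls for the vote to be decidable.
    Conservation can require all three scores (default) or any
    ``conservation_k`` of the three.
    """

    cadd_min: float = 10.0
    gerp_min: float = 2.0
    phastcons_min: float = 0.3
    phylop_min: float = 3.0
    conservation_rule: Literal["all_of", "any_k_of_3"] = "all_of"
    conservation_k: int = 2
    vote_fraction: float = 0.6
    vote_min_calls: int = 5
    include_synonymous: bool = False
    nonsense_first: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.vote_fraction <= 1.0):
            raise ValueError("vote_fraction must lie in (0, 1]")
        if not (1 <= self.vote_min_calls <= 10):
            raise ValueError("vote_min_calls must lie in [1, 10]")
        if self.conservation_rule == "any_k_of_3" and not (1 <= self.conservation_k <= 3):
            raise ValueError("conservation_k must lie in [1, 3]")


@dataclass
class RescueGeneList:
    """Known oncogenes / tumor suppressors / dominant-syndrome genes
    whose variants are handled leniently at the conservation and vote
    stages."""

    genes: set[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.genes = set(self.genes)


#: A small default list of well-established cancer-predisposition genes
#: (oncogenes, tumor suppressors, autosomal-dominant syndrome genes).
DEFAULT_RESCUE_GENES = RescueGeneList(
    genes={
        "APC", "ATM", "BAP1", "BRCA1", "BRCA2", "CDH1", "CDKN2A", "CHEK2",
        "DICER1", "MEN1", "MLH1", "MSH2", "MSH6", "NF1", "NF2", "PALB2",
        "PMS2", "PTEN", "RB1", "RET", "SDHB", "SDHD", "SMAD4", "STK11",
        "TP53", "TSC1", "TSC2", "VHL", "WRN", "WT1",
    },
    provenance="built-in default cancer-predisposition gene list",
)


def route_tracks(
    variants: list[VariantRecord],
    annotations: dict[VariantKey, AnnotationRecord],
    thresholds: Optional[PrioritizationThresholds] = None,
) -> tuple[list[VariantRecord], list[VariantRecord], dict[VariantKey, StageResult]]:
    """Split variants into coding and non-coding exonic tracks.

    Missense and nonsense go to the coding track; non-coding exonic
    variants to their own track; synonymous (unless configured into the
    missense block) and everything else is dropped with a trace entry.
    Variants with no annotation record fail here with detail
    'unannotated' — routing is the first stage that cannot proceed
    without knowing the functional class.
    """
    thresholds = thresholds or PrioritizationThresholds()
    coding: list[VariantRecord] = []
    noncoding: list[VariantRecord] = []
    results: dict[VariantKey, StageResult] = {}
    coding_classes = {FunctionalClass.MISSENSE, FunctionalClass.NONSENSE}
    if thresholds.include_synonymous:
        coding_classes.add(FunctionalClass.SYNONYMOUS)
    for v in variants:
        ann = annotations.get(v.key)
        if ann is None:
            results[v.key] = StageResult("routing", StageOutcome.FAIL, "unannotated")
        elif ann.functional_class in coding_classes:
            results[v.key] = StageResult("routing", StageOutcome.PASS, "coding")
            coding.append(v)
        elif ann.functional_class is FunctionalClass.NONCODING_EXONIC:
            results[v.key] = StageResult("routing", StageOutcome.PASS, "noncoding")
            noncoding.append(v)
        else:
            results[v.key] = StageResult(
                "routing", StageOutcome.FAIL, f"class {ann.functional_class.value} not prioritized"
            )
    return coding, noncoding, results


def cadd_check(ann: Optional[AnnotationRecord], thresholds: PrioritizationThresholds) -> StageResult:
    if ann is None or ann.cadd_phred is None:
        return StageResult("cadd", StageOutcome.FAIL, "unscored")
    if ann.cadd_phred > thresholds.cadd_min:
        return StageResult("cadd", StageOutcome.PASS)
    return StageResult("cadd", StageOutcome.FAIL, f"CADD {ann.cadd_phred:g} <= {thresholds.cadd_min:g}")


def cadd_filter(
    variants: list[VariantRecord],
    annotations: dict[VariantKey, AnnotationRecord],
    thresholds: PrioritizationThresholds,
) -> tuple[list[VariantRecord], dict[VariantKey, StageResult]]:
    """Keep variants with CADD strictly above the cutoff; unscored fail."""
    results: dict[VariantKey, StageResult] = {}
    retained: list[VariantRecord] = []
    for v in variants:
        res = cadd_check(annotations.get(v.key), thresholds)
        results[v.key] = res
        if res.outcome is StageOutcome.PASS:
            retained.append(v)
    return retained, results


def conservation_check(
    ann: Optional[AnnotationRecord], thresholds: PrioritizationThresholds
) -> StageResult:
    """Three-score conservation predicate; a missing score fails its component."""
    if ann is None:
        return StageResult("conservation", StageOutcome.FAIL, "unannotated")
    components = {
        "gerp": ann.gerp is not None and ann.gerp >= thresholds.gerp_min,
        "phastcons": ann.phastcons is not None and ann.phastcons >= thresholds.phastcons_min,
        "phylop": ann.phylop is not None and ann.phylop >= thresholds.phylop_min,
    }
    n_pass = sum(components.values())
    need = 3 if thresholds.conservation_rule == "all_of" else thresholds.conservation_k
    failing = ",".join(name for name, ok in components.items() if not ok)
    if n_pass >= need:
        return StageResult("conservation", StageOutcome.PASS)
    return StageResult("conservation", StageOutcome.FAIL, f"{n_pass}/3 components pass (failing: {failing})")


def conservation_filter(
    variants: list[VariantRecord],
    annotations: dict[VariantKey, AnnotationRecord],
    thresholds: PrioritizationThresholds,
) -> tuple[list[VariantRecord], dict[VariantKey, StageResult]]:
    results: dict[VariantKey, StageResult] = {}
    retained: list[VariantRecord] = []
    for v in variants:
        res = conservation_check(annotations.get(v.key), thresholds)
        results[v.key] = res
        if res.outcome is StageOutcome.PASS:
            retained.append(v)
    return retained, results


def deleteriousness_vote(
    annotation: AnnotationRecord, thresholds: PrioritizationThresholds
) -> tuple[Literal["pass", "fail", "undecidable"], tuple[int, int]]:
    """Majority vote over the ten-predictor ensemble.

    Returns (verdict, (deleterious, non_missing)).  The vote passes when
    deleterious / non_missing >= ``vote_fraction`` and is undecidable
    when fewer than ``vote_min_calls`` predictors made a call.
    """
    calls = list(annotation.predictor_calls.values())
    m = sum(1 for c in calls if c is not PredictorCall.MISSING)
    d = sum(1 for c in calls if c is PredictorCall.DELETERIOUS)
    if m < thresholds.vote_min_calls:
        return "undecidable", (d, m)
    return ("pass" if d / m >= thresholds.vote_fraction else "fail"), (d, m)


def vote_filter(
    variants: list[VariantRecord],
    annotations: dict[VariantKey, AnnotationRecord],
    thresholds: PrioritizationThresholds,
) -> tuple[list[VariantRecord], dict[VariantKey, StageResult]]:
    """Apply the ensemble vote; undecidable votes fail with that detail."""
    results: dict[VariantKey, StageResult] = {}
    retained: list[VariantRecord] = []
    for v in variants:
        ann = annotations.get(v.key)
        if ann is None:
            results[v.key] = StageResult("vote", StageOutcome.FAIL, "unannotated")
            continue
        verdict, (d, m) = deleteriousness_vote(ann, thresholds)
        tally = f"{d}/{m} deleterious"
        if verdict == "pass":
            results[v.key] = StageResult("vote", StageOutcome.PASS, tally)
            retained.append(v)
        elif verdict == "undecidable":
            results[v.key] = StageResult("vote", StageOutcome.FAIL, f"undecidable ({tally})")
        else:
            results[v.key] = StageResult("vote", StageOutcome.FAIL, tally)
    return retained, results


#: Stages whose failures the rescue may forgive.
RESCUABLE_STAGES = frozenset({"conservation", "vote"})


def rescue(
    failed_variants: list[VariantRecord],
    annotations: dict[VariantKey, AnnotationRecord],
    gene_list: RescueGeneList,
    traces: dict[VariantKey, FilterTrace],
) -> list[VariantRecord]:
    """Reinstate listed-gene variants that failed only conservation/vote.

    A variant is rescued iff every failed stage in its trace is
    rescuable (conservation or vote) and its gene is on the list;
    failures at QC, frequency, segregation, routing or CADD are final.
    """
    if not gene_list.genes:
        raise ValueError("rescue gene list is empty")
    rescued: list[VariantRecord] = []
    for v in failed_variants:
        trace = traces[v.key]
        failed = set(trace.failed_stages)
        if not failed or not failed <= RESCUABLE_STAGES:
            continue
        ann = annotations.get(v.key)
        if ann is not None and ann.gene in gene_list.genes:
            trace.add("rescue", StageOutcome.RESCUED, f"known cancer gene {ann.gene}")
            rescued.append(v)
    return rescued


def _desc(value: Optional[float]) -> tuple[int, float]:
    """Sort helper: descending numeric, missing sorts last."""
    return (1, 0.0) if value is None else (0, -value)


def _intolerance_mean(ann: AnnotationRecord) -> Optional[float]:
    vals = [v for v in ann.intolerance_scores.values() if v is not None]
    return sum(vals) / len(vals) if vals else None


def rank_candidates(
    survivors: list[VariantRecord],
    annotations: dict[VariantKey, AnnotationRecord],
    rescued_keys: Optional[set[VariantKey]] = None,
    thresholds: Optional[PrioritizationThresholds] = None,
) -> list[PrioritizedCandidate]:
    """Rank coding survivors by gene constraint.

    Nonsense variants sort by descending pLI, missense (and, if enabled,
    synonymous) by descending missense Z; ties break by descending mean
    intolerance percentile, then descending CADD, then variant key.  The
    nonsense block precedes the missense block by default (pLI is the
    stronger constraint signal for truncating variants).  Ranks are 1..n
    and the ordering is a total order, so any input permutation yields
    identical ranks.
    """
    thresholds = thresholds or PrioritizationThresholds()
    rescued_keys = rescued_keys or set()

    def sort_key(v: VariantRecord):
        ann = annotations[v.key]
        is_nonsense = ann.functional_class is FunctionalClass.NONSENSE
        block = (0 if is_nonsense else 1) if thresholds.nonsense_first else (1 if is_nonsense else 0)
        primary = ann.pli if is_nonsense else ann.mis_z
        return (
            block,
            *_desc(primary),
            *_desc(_intolerance_mean(ann)),
            *_desc(ann.cadd_phred),
            v.key,
        )

    ordered = sorted(survivors, key=sort_key)
    out: list[PrioritizedCandidate] = []
    for rank, v in enumerate(ordered, 1):
        ann = annotations[v.key]
        out.append(
            PrioritizedCandidate(
                variant_key=v.key,
                gene=ann.gene,
                functional_class=ann.functional_class,
                rank=rank,
                ranking_keys={
                    "pli": ann.pli,
                    "mis_z": ann.mis_z,
                    "intolerance": {s: ann.intolerance_scores.get(s) for s in INTOLERANCE_SOURCES},
                    "cadd_phred": ann.cadd_phred,
                },
                rescued=v.key in rescued_keys,
                track=Track.CODING,
            )
        )
    return out


def rank_noncoding(
    survivors: list[VariantRecord],
    annotations: dict[VariantKey, AnnotationRecord],
) -> list[PrioritizedCandidate]:
    """Rank the non-coding exonic track by descending CADD, then key."""
    ordered = sorted(survivors, key=lambda v: (*_desc(annotations[v.key].cadd_phred), v.key))
    out = []
    for rank, v in enumerate(ordered, 1):
        ann = annotations[v.key]
        out.append(
            PrioritizedCandidate(
                variant_key=v.key,
                gene=ann.gene,
                functional_class=ann.functional_class,
                rank=rank,
                ranking_keys={"cadd_phred": ann.cadd_phred},
                rescued=False,
                track=Track.NONCODING,
            )
        )
    return out


@dataclass
class CascadeSettings:
    """Everything :func:`run_cascade` needs besides the data."""

    qc: QcThresholds = field(default_factory=QcThresholds)
    segregation: SegregationPolicy = field(default_factory=SegregationPolicy)
    prioritization: PrioritizationThresholds = field(default_factory=PrioritizationThresholds)
    rescue_genes: RescueGeneList = field(default_factory=lambda: DEFAULT_RESCUE_GENES)
    enable_rescue: bool = True
    enable_noncoding_track: bool = True


@dataclass
class CascadeResult:
    candidates: list[PrioritizedCandidate]
    traces: list[FilterTrace]
    funnel: list[tuple[str, int]]
    extras: dict[str, int]

    @property
    def coding(self) -> list[PrioritizedCandidate]:
        return [c for c in self.candidates if c.track is Track.CODING]

    @property
    def noncoding(self) -> list[PrioritizedCandidate]:
        return [c for c in self.candidates if c.track is Track.NONCODING]


def run_cascade(
    variants: list[VariantRecord],
    annotations: dict[VariantKey, AnnotationRecord],
    cohort: FamilyCohort,
    settings: Optional[CascadeSettings] = None,
) -> CascadeResult:
    """Run the full prioritization cascade.

    Stage order: quality -> frequency -> segregation -> track routing ->
    CADD -> conservation -> vote -> rescue -> rank.  The non-coding
    track shares the quality/frequency/segregation/CADD stages and is
    ranked by CADD; conservation and vote apply to coding variants only.
    Deterministic for fixed inputs and settings.
    """
    settings = settings or CascadeSettings()
    traces: dict[VariantKey, FilterTrace] = {v.key: FilterTrace(v.key) for v in variants}

    def record(results: dict[VariantKey, StageResult]) -> None:
        for key, res in results.items():
            traces[key].add(res.stage, res.outcome, res.detail)

    funnel: list[tuple[str, int]] = [("ingested", len(variants))]

    kept, results = quality_filter(variants, cohort, settings.qc)
    record(results)
    funnel.append(("quality", len(kept)))

    kept, results = frequency_filter(kept, annotations, settings.qc)
    record(results)
    funnel.append(("frequency", len(kept)))

    kept, results = segregation_filter(kept, cohort, settings.segregation)
    record(results)
    funnel.append(("segregation", len(kept)))

    coding, noncoding, results = route_tracks(kept, annotations, settings.prioritization)
    record(results)
    funnel.append(("coding_track", len(coding)))

    coding_kept, results = cadd_filter(coding, annotations, settings.prioritization)
    record(results)
    funnel.append(("cadd", len(coding_kept)))

    cons_kept, results = conservation_filter(coding_kept, annotations, settings.prioritization)
    record(results)
    funnel.append(("conservation", len(cons_kept)))

    vote_kept, results = vote_filter(cons_kept, annotations, settings.prioritization)
    record(results)
    funnel.append(("vote", len(vote_kept)))

    rescued_keys: set[VariantKey] = set()
    if settings.enable_rescue:
        vote_kept_keys = {v.key for v in vote_kept}
        failed_coding = [v for v in coding_kept if v.key not in vote_kept_keys]
        reinstated = rescue(failed_coding, annotations, settings.rescue_genes, traces)
        rescued_keys = {v.key for v in reinstated}
        survivors = vote_kept + reinstated
    else:
        survivors = vote_kept

    candidates = rank_candidates(
        survivors, annotations, rescued_keys=rescued_keys, thresholds=settings.prioritization
    )

    extras = {
        "rescued": len(rescued_keys),
        "coding_final": len(candidates),
        "noncoding_track": len(noncoding),
    }
    if settings.enable_noncoding_track:
        nc_kept, results = cadd_filter(noncoding, annotations, settings.prioritization)
        record(results)
        candidates = candidates + rank_noncoding(nc_kept, annotations)
        extras["noncoding_final"] = len(nc_kept)
    else:
        for v in noncoding:
            traces[v.key].add("routing", StageOutcome.FAIL, "noncoding track disabled")
        extras["noncoding_final"] = 0

    return CascadeResult(
        candidates=candidates,
        traces=[traces[v.key] for v in variants],
        funnel=funnel,
        extras=extras,
    )
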
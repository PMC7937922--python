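"""Core data model for familial variant prioritization.

The pipeline reasons about a single sequenced family: each member is a
*case* (diagnosed), a *potential carrier* (intermediate phenotype, e.g.
benign nodules), or a *control* (unaffected).  Variants are biallelic
records (multi-allelic sites are split on ingest) and annotations travel
in a separate table keyed by ``(chrom, pos, ref, alt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Role(str, Enum):
    """Pedigree role driving the segregation filter."""

    CASE = "case"
    POTENTIAL_CARRIER = "potential_carrier"
    CONTROL = "control"


class Genotype(str, Enum):
    """Four-state diploid genotype relative to a single alternate allele."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)


#: (chrom, pos, ref, alt) — the join key between call files and annotation tables.
VariantKey = tuple[str, int, str, str]


def format_key(key: VariantKey) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"


def parse_key(text: str) -> VariantKey:
    parts = text.strip().split(":")
    if len(parts) != 4 or not parts[1].isdigit() or not parts[2] or not parts[3]:
        raise ValueError(f"malformed variant key {text!r} (expected chrom:pos:ref:alt)")
    return (parts[0], int(parts[1]), parts[2], parts[3])


@dataclass(frozen=True)
class PedigreeSample:
    """One sequenced family member."""

    sample_id: str
    role: Role
    pedigree_label: Optional[str] = None


@dataclass(frozen=True)
class FamilyCohort:
    """A family's sequenced samples.

    The segregation filter is undefined without at least one case and one
    control, so the invariant is enforced at construction.
    """

    family_id: str
    samples: tuple[PedigreeSample, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id in family {self.family_id}: {dupes}")
        if not self.cases:
            raise ValueError(f"family {self.family_id} has no case sample")
        if not self.controls:
            raise ValueError(f"family {self.family_id} has no control sample")

    @property
    def cases(self) -> tuple[PedigreeSample, ...]:
        return tuple(s for s in self.samples if s.role is Role.CASE)

    @property
    def carriers(self) -> tuple[PedigreeSample, ...]:
        return tuple(s for s in self.samples if s.role is Role.POTENTIAL_CARRIER)

    @property
    def controls(self) -> tuple[PedigreeSample, ...]:
        return tuple(s for s in self.samples if s.role is Role.CONTROL)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples)


@dataclass
class SampleCall:
    """Per-sample genotype and read depth at one site."""

    genotype: Genotype
    depth: Optional[int] = None


@dataclass
class VariantRecord:
    """One biallelic site after multi-allelic splitting.

    ``caller_filters_passed`` is True when the caller's FILTER column is
    PASS (or '.'); ``site_qual`` is the QUAL column.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    site_qual: float
    caller_filters_passed: bool
    per_sample: dict[str, SampleCall]

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    def carriers(self) -> list[str]:
        """Sample ids carrying at least one alternate allele."""
        return [s for s, c in self.per_sample.items() if c.genotype.carries_alt]


class FunctionalClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SYNONYMOUS = "synonymous"
    NONCODING_EXONIC = "noncoding_exonic"
    OTHER = "other"


class PredictorCall(str, Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    MISSING = "missing"


#: The fixed panel of in-silico deleteriousness predictors entering the
#: ensemble vote.  Every annotation record materializes all ten keys.
PREDICTOR_TOOLS: tuple[str, ...] = (
    "SIFT",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "MetaSVM",
    "MetaLR",
    "PROVEAN",
)

#: Population panels behind the gene-intolerance percentile scores.
INTOLERANCE_SOURCES: tuple[str, ...] = ("esp6500", "exac", "local")


@dataclass
class AnnotationRecord:
    """Annotation fields the cascade consumes for one variant.

    Frequencies are alternate-allele frequencies in two reference panels;
    ``cadd_phred`` is the scaled CADD deleteriousness score; ``gerp``,
    ``phastcons`` and ``phylop`` are per-position conservation scores;
    ``predictor_calls`` holds the ten-tool ensemble; ``pli`` and ``mis_z``
    are ExAC gene-constraint scores used for ranking, and
    ``intolerance_scores`` are intolerance percentiles (higher = more
    intolerant) from three frequency-based panels.
    """

    variant_key: VariantKey
    maf_kg_phase3: Optional[float] = None
    maf_exac_nontcga: Optional[float] = None
    cadd_phred: Optional[float] = None
    gerp: Optional[float] = None
    phastcons: Optional[float] = None
    phylop: Optional[float] = None
    predictor_calls: dict[str, PredictorCall] = field(default_factory=dict)
    gene: str = ""
    functional_class: FunctionalClass = FunctionalClass.OTHER
    intolerance_scores: dict[str, Optional[float]] = field(default_factory=dict)
    pli: Optional[float] = None
    mis_z: Optional[float] = None

    def __post_init__(self) -> None:
        calls = dict(self.predictor_calls)
        for tool in PREDICTOR_TOOLS:
            calls.setdefault(tool, PredictorCall.MISSING)
        unknown = set(calls) - set(PREDICTOR_TOOLS)
        if unknown:
            raise ValueError(f"unknown predictor tool(s): {sorted(unknown)}")
        self.predictor_calls = calls
        scores = dict(self.intolerance_scores)
        for src in INTOLERANCE_SOURCES:
            scores.setdefault(src, None)
        self.intolerance_scores = scores
        for name in ("maf_kg_phase3", "maf_exac_nontcga", "phastcons", "pli"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name}={val} outside [0, 1] for {format_key(self.variant_key)}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"negative CADD score for {format_key(self.variant_key)}")


class StageOutcome(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_APPLICABLE = "not_applicable"
    RESCUED = "rescued"


@dataclass
class StageResult:
    stage: str
    outcome: StageOutcome
    detail: str = ""


@dataclass
class FilterTrace:
    """Ordered per-variant provenance through the cascade."""

    variant_key: VariantKey
    stages: list[StageResult] = field(default_factory=list)

    def add(self, stage: str, outcome: StageOutcome, detail: str = "") -> None:
        self.stages.append(StageResult(stage, outcome, detail))

    @property
    def failed_stages(self) -> list[str]:
        return [s.stage for s in self.stages if s.outcome is StageOutcome.FAIL]

    @property
    def surviving(self) -> bool:
        """True if no stage failed, or a rescue followed the last failure."""
        state = True
        for s in self.stages:
            if s.outcome is StageOutcome.FAIL:
                state = False
            elif s.outcome is StageOutcome.RESCUED:
                state = True
        return state


class Track(str, Enum):
    CODING = "coding"
    NONCODING = "noncoding"


@dataclass
class PrioritizedCandidate:
    """A surviving variant with its rank and the keys that produced it."""

    variant_key: VariantKey
    gene: str
    functional_class: FunctionalClass
    rank: int
    ranking_keys: dict
    rescued: bool
    track: Track
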
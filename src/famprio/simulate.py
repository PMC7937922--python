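"""Synthetic family cohorts with known truth labels.

The generator emulates the study design the cascade assumes: one family
with three sequenced cases, one potential carrier and one control; a
rare-variant background; a handful of planted causal variants whose
genotype and annotation profile pass every default threshold; and
single-failure decoys, each breaking exactly one named filter while
drawn from the causal-passing profile everywhere else.  Because each
decoy fails exactly one stage, the cascade's per-stage trace attribution
is exactly testable, and expected decoy survival is zero.

Everything is a deterministic function of the seed: the same
:class:`SimulationConfig` writes byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import (
    FamilyCohort,
    FunctionalClass,
    Genotype,
    PedigreeSample,
    PredictorCall,
    PrioritizedCandidate,
    Role,
    SampleCall,
    VariantKey,
    VariantRecord,
    format_key,
)
from .io_formats import ANNOTATION_COLUMNS, PREDICTOR_TOOLS, write_variants

#: Single-failure decoy modes and the cascade stage each one must die at.
DECOY_STAGE = {
    "low_qual": "quality",
    "low_depth": "quality",
    "common_frequency": "frequency",
    "control_carrier": "segregation",
    "case_noncarrier": "segregation",
    "low_cadd": "cadd",
    "unconserved": "conservation",
    "vote_fail": "vote",
}

CAUSAL_LABEL = "causal_pass"


def _default_mix() -> dict[str, float]:
    return {mode: 1.0 / len(DECOY_STAGE) for mode in DECOY_STAGE}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the sequenced family the cascade was designed
    around: 3 cases, 1 potential carrier, 1 control, a few hundred rare
    variants and a handful of planted causal variants.  ``decoy_mix``
    gives the proportion of each single-failure mode among non-causal
    variants; ``missingness`` maps annotation field names to per-field
    missingness rates applied to decoys (never to causal variants unless
    ``causal_missingness`` is set).
    """

    seed: int = 0
    n_cases: int = 3
    n_carriers: int = 1
    n_controls: int = 1
    n_variants: int = 200
    n_causal: int = 3
    causal_class: FunctionalClass = FunctionalClass.MISSENSE
    decoy_mix: dict[str, float] = field(default_factory=_default_mix)
    missingness: dict[str, float] = field(default_factory=dict)
    causal_missingness: bool = False
    n_multiallelic: int = 0
    n_noncoding: int = 0

    def validate(self) -> None:
        errors = []
        if self.n_cases < 1:
            errors.append("n_cases must be >= 1")
        if self.n_controls < 1:
            errors.append("n_controls must be >= 1")
        if self.n_carriers < 0:
            errors.append("n_carriers must be >= 0")
        if not (0 <= self.n_causal <= self.n_variants):
            errors.append("need 0 <= n_causal <= n_variants")
        if self.decoy_mix:
            unknown = set(self.decoy_mix) - set(DECOY_STAGE)
            if unknown:
                errors.append(f"unknown decoy mode(s): {sorted(unknown)}")
            total = sum(self.decoy_mix.values())
            if abs(total - 1.0) > 1e-9:
                errors.append(f"decoy_mix proportions sum to {total:g}, expected 1")
        elif self.n_variants > self.n_causal:
            errors.append("decoy_mix must be non-empty when decoys are requested")
        for name, rate in self.missingness.items():
            if not (0.0 <= rate <= 1.0):
                errors.append(f"missingness[{name}] = {rate} outside [0, 1]")
        if self.n_multiallelic > self.n_variants - self.n_causal:
            errors.append("n_multiallelic cannot exceed the number of decoy sites")
        if self.n_noncoding > self.n_variants - self.n_causal:
            errors.append("n_noncoding cannot exceed the number of decoy sites")
        if errors:
            raise ValueError("invalid simulation config: " + "; ".join(errors))


@dataclass
class SimulatedCohort:
    """Paths and in-memory truth for one simulated dataset."""

    cohort: FamilyCohort
    vcf_path: Path
    pedigree_path: Path
    annotation_path: Path
    truth_path: Path
    truth: dict[VariantKey, str]


_BASES = np.array(list("ACGT"))


def _draw_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


@dataclass
class _Annot:
    """Mutable working annotation row for one simulated allele."""

    maf_kg: Optional[float]
    maf_exac: Optional[float]
    cadd: Optional[float]
    gerp: Optional[float]
    phastcons: Optional[float]
    phylop: Optional[float]
    calls: list[str]
    gene: str
    func_class: str
    intol: list[Optional[float]]
    pli: Optional[float]
    mis_z: Optional[float]


def _passing_profile(rng: np.random.Generator, gene: str, func_class: str) -> _Annot:
    """Annotation values comfortably inside every default threshold."""
    n_del = int(rng.integers(7, 11))
    calls = ["D"] * n_del + ["T"] * (10 - n_del)
    return _Annot(
        maf_kg=float(rng.uniform(0.0, 0.0005)),
        maf_exac=float(rng.uniform(0.0, 0.0005)),
        cadd=float(rng.uniform(15.0, 35.0)),
        gerp=float(rng.uniform(3.0, 6.0)),
        phastcons=float(rng.uniform(0.6, 1.0)),
        phylop=float(rng.uniform(3.5, 8.0)),
        calls=calls,
        gene=gene,
        func_class=func_class,
        intol=[float(rng.uniform(50.0, 99.0)) for _ in range(3)],
        pli=float(rng.uniform(0.0, 1.0)),
        mis_z=float(rng.uniform(2.0, 6.0)),
    )


def _apply_decoy_mode(ann: _Annot, mode: str, rng: np.random.Generator) -> None:
    if mode == "common_frequency":
        if rng.random() < 0.5:
            ann.maf_kg = float(rng.uniform(0.002, 0.1))
        else:
            ann.maf_exac = float(rng.uniform(0.002, 0.1))
    elif mode == "low_cadd":
        ann.cadd = float(rng.uniform(0.0, 10.0))
    elif mode == "unconserved":
        ann.gerp = float(rng.uniform(-3.0, 1.5))
        ann.phastcons = float(rng.uniform(0.0, 0.25))
        ann.phylop = float(rng.uniform(-2.0, 2.5))
    elif mode == "vote_fail":
        n_del = int(rng.integers(0, 6))  # at most 5/10 deleterious
        ann.calls = ["D"] * n_del + ["T"] * (10 - n_del)


def _allocate_fates(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Assign causal/decoy fates, matching decoy_mix by largest remainder."""
    n_decoy = config.n_variants - config.n_causal
    modes = sorted(config.decoy_mix)
    quotas = {m: config.decoy_mix[m] * n_decoy for m in modes}
    counts = {m: int(np.floor(quotas[m])) for m in modes}
    short = n_decoy - sum(counts.values())
    for m in sorted(modes, key=lambda m: (-(quotas[m] - counts[m]), m))[:short]:
        counts[m] += 1
    fates = [CAUSAL_LABEL] * config.n_causal
    for m in modes:
        fates += [m] * counts[m]
    rng.shuffle(fates)
    return fates


def simulate_cohort(
    config: SimulationConfig, out_dir: Union[str, Path]
) -> SimulatedCohort:
    """Generate a synthetic family dataset under ``out_dir``.

    Writes a pedigree file, a multi-sample VCF, an annotation table and
    a truth-label table in exactly the dialects the readers consume.
    Truth labels give each allele's intended fate: ``causal_pass`` or
    ``decoy_<mode>``.  Identical configs produce byte-identical files.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    samples = (
        [PedigreeSample(f"CASE{i+1}", Role.CASE) for i in range(config.n_cases)]
        + [PedigreeSample(f"CARRIER{i+1}", Role.POTENTIAL_CARRIER) for i in range(config.n_carriers)]
        + [PedigreeSample(f"CONTROL{i+1}", Role.CONTROL) for i in range(config.n_controls)]
    )
    cohort = FamilyCohort(family_id="FAM1", samples=tuple(samples))

    fates = _allocate_fates(config, rng)
    positions = 100_000 + np.arange(config.n_variants) * 150 + rng.integers(0, 100, size=config.n_variants)

    records: list[VariantRecord] = []
    annot_rows: list[tuple[VariantKey, _Annot]] = []
    truth: dict[VariantKey, str] = {}

    # extra alleles at multi-allelic sites share QUAL/DP with the first
    # allele, so only plant them at sites that pass the quality stage;
    # non-coding decoys never reach conservation/vote, so only modes
    # failing on the shared path (or at CADD) keep exact stage attribution
    multi_eligible = [i for i, f in enumerate(fates) if f not in (CAUSAL_LABEL, "low_qual", "low_depth")]
    if len(multi_eligible) < config.n_multiallelic:
        raise ValueError("not enough eligible decoy sites for the requested multi-allelic count")
    multi_sites = set(multi_eligible[: config.n_multiallelic])
    nc_modes = {"low_qual", "low_depth", "common_frequency", "control_carrier", "case_noncarrier", "low_cadd"}
    nc_eligible = [i for i, f in enumerate(fates) if f in nc_modes and i not in multi_sites]
    if len(nc_eligible) < config.n_noncoding:
        raise ValueError("not enough eligible decoy sites for the requested non-coding count")
    noncoding_sites = set(nc_eligible[: config.n_noncoding])

    for i, fate in enumerate(fates):
        chrom, pos = "1", int(positions[i])
        ref, alt = _draw_alleles(rng)
        gene = f"GENE{i:04d}"
        func_class = config.causal_class.value if fate == CAUSAL_LABEL else FunctionalClass.MISSENSE.value
        if i in noncoding_sites:
            func_class = FunctionalClass.NONCODING_EXONIC.value
        ann = _passing_profile(rng, gene, func_class)
        _apply_decoy_mode(ann, fate, rng)

        qual = float(rng.uniform(50.0, 200.0))
        if fate == "low_qual":
            qual = float(rng.uniform(5.0, 20.0))
        depths = {s.sample_id: int(rng.integers(10, 60)) for s in samples}
        if fate == "low_depth":
            victim = str(rng.choice([s.sample_id for s in cohort.cases]))
            depths[victim] = int(rng.integers(0, 6))

        genotypes = {s.sample_id: Genotype.HOM_REF for s in samples}
        for case in cohort.cases:
            genotypes[case.sample_id] = Genotype.HET
        for carrier in cohort.carriers:
            if fate == CAUSAL_LABEL or rng.random() < 0.5:
                genotypes[carrier.sample_id] = Genotype.HET
        if fate == "control_carrier":
            victim = str(rng.choice([s.sample_id for s in cohort.controls]))
            genotypes[victim] = Genotype.HET
        elif fate == "case_noncarrier":
            victim = str(rng.choice([s.sample_id for s in cohort.cases]))
            genotypes[victim] = Genotype.HOM_REF

        per_sample = {sid: SampleCall(genotypes[sid], depths[sid]) for sid in cohort.sample_ids}
        records.append(
            VariantRecord(chrom, pos, ref, alt, qual, True, per_sample)
        )
        key = (chrom, pos, ref, alt)
        truth[key] = fate if fate == CAUSAL_LABEL else f"decoy_{fate}"
        annot_rows.append((key, ann))

        if i in multi_sites:
            # a second alternate allele at the same site, carried by no
            # sample (all genotypes refer to allele 1) -> it fails
            # segregation as a case non-carrier
            bases = [b for b in "ACGT" if b not in (ref, alt)]
            alt2 = str(rng.choice(bases))
            per_sample2 = {sid: SampleCall(Genotype.HOM_REF, depths[sid]) for sid in cohort.sample_ids}
            records.append(VariantRecord(chrom, pos, ref, alt2, qual, True, per_sample2))
            key2 = (chrom, pos, ref, alt2)
            truth[key2] = "decoy_case_noncarrier"
            annot_rows.append((key2, _passing_profile(rng, gene, FunctionalClass.MISSENSE.value)))

    if config.missingness:
        _apply_missingness(annot_rows, truth, config, rng)

    pedigree_path = out_dir / "family.ped"
    _write_pedigree(cohort, pedigree_path)
    vcf_path = out_dir / "family.vcf"
    _write_merged_vcf(records, cohort, vcf_path)
    annotation_path = out_dir / "annotations.tsv"
    _write_annotations(annot_rows, annotation_path)
    truth_path = out_dir / "truth.tsv"
    truth_lines = ["variant_key\tlabel"] + [
        f"{format_key(k)}\t{lab}" for k, lab in sorted(truth.items())
    ]
    truth_path.write_text("\n".join(truth_lines) + "\n")

    return SimulatedCohort(cohort, vcf_path, pedigree_path, annotation_path, truth_path, truth)


_MISSABLE = {
    "maf_kg": "maf_kg",
    "maf_exac": "maf_exac",
    "cadd": "cadd",
    "gerp": "gerp",
    "phastcons": "phastcons",
    "phylop": "phylop",
    "pli": "pli",
    "mis_z": "mis_z",
}


def _apply_missingness(
    annot_rows: list[tuple[VariantKey, _Annot]],
    truth: dict[VariantKey, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    for name, rate in sorted(config.missingness.items()):
        if name not in _MISSABLE:
            raise ValueError(f"unknown missingness field {name!r} (known: {sorted(_MISSABLE)})")
        for key, ann in annot_rows:
            if truth[key] == CAUSAL_LABEL and not config.causal_missingness:
                continue
            if rng.random() < rate:
                setattr(ann, _MISSABLE[name], None)


def _write_pedigree(cohort: FamilyCohort, path: Path) -> None:
    pheno = {Role.CASE: "2", Role.CONTROL: "1", Role.POTENTIAL_CARRIER: "0"}
    role = {Role.CASE: "case", Role.CONTROL: "control", Role.POTENTIAL_CARRIER: "carrier"}
    lines = [
        f"{cohort.family_id}\t{s.sample_id}\t0\t0\t0\t{pheno[s.role]}\t{role[s.role]}"
        for s in cohort.samples
    ]
    path.write_text("\n".join(lines) + "\n")


def _write_merged_vcf(records: list[VariantRecord], cohort: FamilyCohort, path: Path) -> None:
    """Write records, merging same-locus alleles into multi-allelic lines."""
    by_locus: dict[tuple[str, int, str], list[VariantRecord]] = {}
    for rec in records:
        by_locus.setdefault((rec.chrom, rec.pos, rec.ref), []).append(rec)
    if all(len(group) == 1 for group in by_locus.values()):
        write_variants(records, cohort, path)
        return
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.sample_ids),
    ]
    gt_index = {Genotype.HOM_REF: (0, 0), Genotype.HET: (0, 1), Genotype.HOM_ALT: (1, 1)}
    for (chrom, pos, ref), group in sorted(by_locus.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])):
        alts = [g.alt for g in group]
        first = group[0]
        cols = [chrom, str(pos), ".", ref, ",".join(alts), f"{first.site_qual:g}", "PASS", ".", "GT:DP"]
        for sid in cohort.sample_ids:
            # genotype indices: allele 1 is the first alt; extra alts are
            # carried by nobody in the merged representation
            call = first.per_sample[sid]
            if call.genotype is Genotype.MISSING:
                gt = "./."
            else:
                a, b = gt_index[call.genotype]
                gt = f"{a}/{b}"
            dp = "." if call.depth is None else str(call.depth)
            cols.append(f"{gt}:{dp}")
        lines.append("\t".join(cols))
    path.write_text("\n".join(lines) + "\n")


def _cell(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def _write_annotations(rows: list[tuple[VariantKey, _Annot]], path: Path) -> None:
    lines = ["\t".join(ANNOTATION_COLUMNS)]
    for key, ann in sorted(rows, key=lambda kv: kv[0]):
        chrom, pos, ref, alt = key
        cols = [chrom, str(pos), ref, alt, _cell(ann.maf_kg), _cell(ann.maf_exac), _cell(ann.cadd),
                _cell(ann.gerp), _cell(ann.phastcons), _cell(ann.phylop)]
        cols += ann.calls
        cols += [ann.gene, ann.func_class]
        cols += [_cell(v) for v in ann.intol]
        cols += [_cell(ann.pli), _cell(ann.mis_z)]
        lines.append("\t".join(cols))
    path.write_text("\n".join(lines) + "\n")


def make_benchmark_cohort(out_dir: Union[str, Path], seed: int = 0) -> SimulatedCohort:
    """A fixture emulating the motivating study family.

    Five sequenced samples (3 cases, 1 potential carrier, 1 control) and
    three planted segregating missense variants: one in CHEK2 whose
    ensemble vote falls below 60% (rescued via the known-cancer-gene
    list), and fully passing variants in TIAM1 and EWSR1.  The rest of
    the cohort is single-failure decoys.  The expected cascade outcome
    is a coding shortlist of exactly 3 with exactly 1 rescued.
    """
    config = SimulationConfig(seed=seed, n_variants=150, n_causal=3)
    sim = simulate_cohort(config, out_dir)

    # overwrite the three causal variants' gene symbols and give the
    # CHEK2-like one a failing vote profile (4/10 deleterious)
    causal_keys = sorted(k for k, lab in sim.truth.items() if lab == CAUSAL_LABEL)
    genes = ["CHEK2", "TIAM1", "EWSR1"]
    df = pd.read_csv(sim.annotation_path, sep="\t", dtype=str, keep_default_na=False)
    for key, gene in zip(causal_keys, genes):
        mask = (
            (df["CHROM"] == key[0])
            & (df["POS"] == str(key[1]))
            & (df["REF"] == key[2])
            & (df["ALT"] == key[3])
        )
        df.loc[mask, "GENE"] = gene
        if gene == "CHEK2":
            codes = ["D"] * 4 + ["T"] * 6
            for tool, code in zip(PREDICTOR_TOOLS, codes):
                df.loc[mask, tool] = code
    df.to_csv(sim.annotation_path, sep="\t", index=False)
    return sim


@dataclass
class RecoveryReport:
    sensitivity: float
    false_positive_count: int
    leakage: dict[str, int]


def evaluate_recovery(
    truth: dict[VariantKey, str], candidates: list[PrioritizedCandidate]
) -> RecoveryReport:
    """Score a cascade run against the generator's truth labels.

    Sensitivity is recovered causal / planted causal; leakage counts
    surviving decoys per planted failure mode.  A candidate key outside
    the truth universe is an error (the run did not come from this
    dataset).
    """
    causal = {k for k, lab in truth.items() if lab == CAUSAL_LABEL}
    recovered: set[VariantKey] = set()
    leakage: dict[str, int] = {}
    fp = 0
    for cand in candidates:
        label = truth.get(cand.variant_key)
        if label is None:
            raise ValueError(f"candidate {format_key(cand.variant_key)} not in truth universe")
        if label == CAUSAL_LABEL:
            recovered.add(cand.variant_key)
        else:
            fp += 1
            mode = label.removeprefix("decoy_")
            leakage[mode] = leakage.get(mode, 0) + 1
    sensitivity = len(recovered) / len(causal) if causal else float("nan")
    return RecoveryReport(sensitivity=sensitivity, false_positive_count=fp, leakage=leakage)
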
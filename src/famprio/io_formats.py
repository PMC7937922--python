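"""Readers and writers for the files the pipeline touches.

Variant calls are standard VCF (plain or bgzipped) read through pysam;
pedigrees are 6-column PED with an optional 7th role column; annotations
arrive as a tab-separated table keyed by (chrom, pos, ref, alt); reports
are deterministic tab-separated tables plus a key-value funnel summary.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import pysam

from .model import (
    INTOLERANCE_SOURCES,
    PREDICTOR_TOOLS,
    AnnotationRecord,
    FamilyCohort,
    FilterTrace,
    FunctionalClass,
    Genotype,
    PedigreeSample,
    PredictorCall,
    PrioritizedCandidate,
    Role,
    SampleCall,
    Track,
    VariantKey,
    VariantRecord,
    format_key,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

# dbNSFP-style categorical codes for the predictor columns.  D/A/H/M are
# the tools' damaging calls, T/N/L/P/B their benign calls; '.' = missing.
_PREDICTOR_CODE = {
    "D": PredictorCall.DELETERIOUS,
    "A": PredictorCall.DELETERIOUS,
    "H": PredictorCall.DELETERIOUS,
    "M": PredictorCall.DELETERIOUS,
    "T": PredictorCall.TOLERATED,
    "N": PredictorCall.TOLERATED,
    "L": PredictorCall.TOLERATED,
    "P": PredictorCall.TOLERATED,
    "B": PredictorCall.TOLERATED,
}

_ROLE_ALIASES = {
    "case": Role.CASE,
    "carrier": Role.POTENTIAL_CARRIER,
    "potential_carrier": Role.POTENTIAL_CARRIER,
    "control": Role.CONTROL,
}

#: Fixed annotation-table header, in order.
ANNOTATION_COLUMNS: tuple[str, ...] = (
    "CHROM",
    "POS",
    "REF",
    "ALT",
    "MAF_1KG_PHASE3",
    "MAF_EXAC_NONTCGA",
    "CADD_PHRED",
    "GERP",
    "PHASTCONS",
    "PHYLOP",
    *PREDICTOR_TOOLS,
    "GENE",
    "FUNC_CLASS",
    "INTOL_ESP6500",
    "INTOL_EXAC",
    "INTOL_LOCAL",
    "PLI",
    "MIS_Z",
)


def read_pedigree(path: PathLike) -> FamilyCohort:
    """Read a PED file into a :class:`FamilyCohort`.

    Columns: family, sample, father, mother, sex, phenotype, and an
    optional 7th role column taking {case, carrier, control}.  Without
    the role column, phenotype 2 maps to case, 1 to control, and 0/-9
    (unknown) to potential carrier.
    """
    path = Path(path)
    samples: list[PedigreeSample] = []
    family_id: Optional[str] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 pedigree columns, got {len(fields)}")
            fam, sid, _father, _mother, _sex, pheno = fields[:6]
            if family_id is None:
                family_id = fam
            if len(fields) >= 7:
                role_text = fields[6].lower()
                if role_text not in _ROLE_ALIASES:
                    raise ValueError(
                        f"{path}:{lineno}: unknown role {fields[6]!r} "
                        f"(expected one of {sorted(set(_ROLE_ALIASES))})"
                    )
                role = _ROLE_ALIASES[role_text]
            elif pheno == "2":
                role = Role.CASE
            elif pheno == "1":
                role = Role.CONTROL
            elif pheno in ("0", "-9"):
                role = Role.POTENTIAL_CARRIER
            else:
                raise ValueError(f"{path}:{lineno}: unknown phenotype code {pheno!r}")
            samples.append(PedigreeSample(sample_id=sid, role=role))
    if family_id is None:
        raise ValueError(f"{path}: empty pedigree file")
    ids = [s.sample_id for s in samples]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate sample_id {dupes}")
    try:
        return FamilyCohort(family_id=family_id, samples=tuple(samples))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def _genotype_for_alt(gt: tuple, alt_index: int) -> Genotype:
    """Map a pysam genotype tuple onto the four-state enum for one alt.

    Alleles pointing at other alternate alleles of the same site count as
    non-carrier for this record; any missing allele makes the whole call
    missing (a half-call cannot demonstrate carrier status).
    """
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return Genotype.MISSING
    n_alt = sum(1 for a in gt if a == alt_index)
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt >= len(gt):
        return Genotype.HOM_ALT
    return Genotype.HET


def read_variants(path: PathLike, cohort: FamilyCohort) -> list[VariantRecord]:
    """Read a multi-sample VCF into biallelic :class:`VariantRecord` s.

    Multi-allelic sites are split into one record per alternate allele,
    without re-normalizing alleles.  Raises if any cohort sample is
    absent from the VCF header.
    """
    path = Path(path)
    with pysam.VariantFile(str(path)) as vcf:
        header_samples = set(vcf.header.samples)
        for sid in cohort.sample_ids:
            if sid not in header_samples:
                raise ValueError(f"{path}: cohort sample {sid!r} missing from VCF header")
        records: list[VariantRecord] = []
        for i, rec in enumerate(vcf, 1):
            try:
                alts = rec.alts or ()
                for alt_index, alt in enumerate(alts, 1):
                    per_sample: dict[str, SampleCall] = {}
                    for sid in cohort.sample_ids:
                        call = rec.samples[sid]
                        gt = call.get("GT")
                        depth = call.get("DP")
                        per_sample[sid] = SampleCall(
                            genotype=_genotype_for_alt(gt, alt_index),
                            depth=int(depth) if depth is not None else None,
                        )
                    filters = list(rec.filter.keys())
                    records.append(
                        VariantRecord(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=str(alt),
                            site_qual=float(rec.qual) if rec.qual is not None else 0.0,
                            caller_filters_passed=filters in ([], ["PASS"]),
                            per_sample=per_sample,
                        )
                    )
            except ValueError:
                raise
            except Exception as exc:  # pragma: no cover - malformed input path
                raise ValueError(f"{path}: malformed record #{i}: {exc}") from exc
    return records


def write_variants(records: Iterable[VariantRecord], cohort: FamilyCohort, path: PathLike) -> None:
    """Write variant records back out as a minimal VCF.

    Records sharing a locus are emitted as separate biallelic lines (the
    reader's splitting is not re-merged).  Output is deterministic.
    """
    path = Path(path)
    contigs = sorted({r.chrom for r in records}, key=str)
    gt_text = {
        Genotype.HOM_REF: "0/0",
        Genotype.HET: "0/1",
        Genotype.HOM_ALT: "1/1",
        Genotype.MISSING: "./.",
    }
    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=lowqual,Description="Failed caller internal filters">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.sample_ids)
    )
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
        filt = "PASS" if rec.caller_filters_passed else "lowqual"
        cols = [rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, f"{rec.site_qual:g}", filt, "."]
        cols.append("GT:DP")
        for sid in cohort.sample_ids:
            call = rec.per_sample[sid]
            dp = "." if call.depth is None else str(call.depth)
            cols.append(f"{gt_text[call.genotype]}:{dp}")
        lines.append("\t".join(cols))
    path.write_text("\n".join(lines) + "\n")


def _coerce_float(value, column: str, where: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "" or value == ".":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        logger.warning("unparseable numeric cell %r in column %s at %s; treated as missing", value, column, where)
        return None


_FUNC_CLASS = {c.value: c for c in FunctionalClass}


def read_annotations(path: PathLike) -> dict[VariantKey, AnnotationRecord]:
    """Read the tab-separated annotation table.

    '.' or an empty cell denotes missing.  Unparseable numeric cells are
    logged and treated as missing; a duplicate variant key is a hard error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing annotation column(s) {missing_cols}")
    out: dict[VariantKey, AnnotationRecord] = {}
    for offset, (_, row) in enumerate(df.iterrows(), 2):  # header is line 1
        where = f"{path}:{offset}"
        key: VariantKey = (str(row["CHROM"]), int(row["POS"]), row["REF"], row["ALT"])
        if key in out:
            raise ValueError(f"{where}: duplicate variant key {format_key(key)}")
        calls: dict[str, PredictorCall] = {}
        for tool in PREDICTOR_TOOLS:
            code = str(row[tool]).strip()
            if code in ("", "."):
                calls[tool] = PredictorCall.MISSING
            elif code in _PREDICTOR_CODE:
                calls[tool] = _PREDICTOR_CODE[code]
            else:
                logger.warning("unknown predictor code %r for %s at %s; treated as missing", code, tool, where)
                calls[tool] = PredictorCall.MISSING
        fc_text = str(row["FUNC_CLASS"]).strip().lower()
        if fc_text in _FUNC_CLASS:
            func_class = _FUNC_CLASS[fc_text]
        else:
            logger.warning("unknown functional class %r at %s; treated as 'other'", row["FUNC_CLASS"], where)
            func_class = FunctionalClass.OTHER
        out[key] = AnnotationRecord(
            variant_key=key,
            maf_kg_phase3=_coerce_float(row["MAF_1KG_PHASE3"], "MAF_1KG_PHASE3", where),
            maf_exac_nontcga=_coerce_float(row["MAF_EXAC_NONTCGA"], "MAF_EXAC_NONTCGA", where),
            cadd_phred=_coerce_float(row["CADD_PHRED"], "CADD_PHRED", where),
            gerp=_coerce_float(row["GERP"], "GERP", where),
            phastcons=_coerce_float(row["PHASTCONS"], "PHASTCONS", where),
            phylop=_coerce_float(row["PHYLOP"], "PHYLOP", where),
            predictor_calls=calls,
            gene=str(row["GENE"]).strip(),
            functional_class=func_class,
            intolerance_scores={
                "esp6500": _coerce_float(row["INTOL_ESP6500"], "INTOL_ESP6500", where),
                "exac": _coerce_float(row["INTOL_EXAC"], "INTOL_EXAC", where),
                "local": _coerce_float(row["INTOL_LOCAL"], "INTOL_LOCAL", where),
            },
            pli=_coerce_float(row["PLI"], "PLI", where),
            mis_z=_coerce_float(row["MIS_Z"], "MIS_Z", where),
        )
    return out


def read_rescue_genes(path: PathLike) -> set[str]:
    """One gene symbol per line; '#' starts a comment."""
    genes: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.add(line)
    return genes


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def write_report(
    traces: list[FilterTrace],
    candidates: list[PrioritizedCandidate],
    path: PathLike,
    funnel: Optional[list[tuple[str, int]]] = None,
    extras: Optional[dict[str, int]] = None,
) -> None:
    """Write provenance, funnel, and shortlist reports under ``path``.

    Emits ``provenance.tsv`` (one row per variant per evaluated stage),
    ``funnel.txt`` (ordered stage counts), ``shortlist.tsv`` (ranked
    coding candidates) and ``noncoding.tsv``.  Output is byte-identical
    across runs on identical inputs.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)

    prov_lines = ["variant_key\tstage\toutcome\tdetail"]
    for trace in sorted(traces, key=lambda t: t.variant_key):
        for sr in trace.stages:
            prov_lines.append(f"{format_key(trace.variant_key)}\t{sr.stage}\t{sr.outcome.value}\t{sr.detail}")
    (out / "provenance.tsv").write_text("\n".join(prov_lines) + "\n")

    if funnel is None:
        funnel = []
    funnel_lines = [f"{stage}\t{count}" for stage, count in funnel]
    if extras:
        funnel_lines.append("")
        funnel_lines += [f"{k}\t{v}" for k, v in extras.items()]
    (out / "funnel.txt").write_text("\n".join(funnel_lines) + "\n")

    header = (
        "rank\tvariant_key\tgene\tfunctional_class\trescued\t"
        "pli\tmis_z\tintol_esp6500\tintol_exac\tintol_local\tcadd_phred"
    )
    for track, fname in ((Track.CODING, "shortlist.tsv"), (Track.NONCODING, "noncoding.tsv")):
        rows = [header]
        for c in sorted((c for c in candidates if c.track is track), key=lambda c: c.rank):
            keys = c.ranking_keys
            intol = keys.get("intolerance", {})
            rows.append(
                "\t".join(
                    [
                        str(c.rank),
                        format_key(c.variant_key),
                        c.gene,
                        c.functional_class.value,
                        str(int(c.rescued)),
                        _fmt(keys.get("pli")),
                        _fmt(keys.get("mis_z")),
                        _fmt(intol.get("esp6500")),
                        _fmt(intol.get("exac")),
                        _fmt(intol.get("local")),
                        _fmt(keys.get("cadd_phred")),
                    ]
                )
            )
        (out / fname).write_text("\n".join(rows) + "\n")
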
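"""Pedigree-based segregation filtering and cross-family screening.

Under a dominant model with reduced penetrance, a candidate variant must
be carried (>= 1 alternate allele) by every case and by no control.
Potential carriers — family members with an intermediate phenotype — are
unconstrained by default, since their carrier status is uncertain by
definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Union

import pandas as pd

from .model import (
    FamilyCohort,
    Genotype,
    StageOutcome,
    StageResult,
    VariantKey,
    VariantRecord,
    format_key,
)

logger = logging.getLogger(__name__)


@dataclass
class SegregationPolicy:
    """Options for the case/carrier/control segregation predicate.

    Defaults encode: present in all cases, absent from all controls,
    carriers unconstrained, missing case genotype counts against the
    variant (presence not demonstrated).
    """

    carrier_constraint: Literal["unconstrained", "must_carry"] = "unconstrained"
    missing_genotype_in_case: Literal["fail", "lenient_pass"] = "fail"
    require_absent_in_controls: bool = True  # fixed; exposed for introspection only


def segregates(
    variant: VariantRecord, cohort: FamilyCohort, policy: SegregationPolicy
) -> tuple[bool, str]:
    """Does the variant segregate with disease in this family?

    Returns (verdict, reason); the reason names the first violating
    sample.  A missing genotype in a control is treated as non-carrier
    (presence cannot be demonstrated) and logged, since it weakens the
    control side of the filter.
    """
    for case in cohort.cases:
        call = variant.per_sample.get(case.sample_id)
        gt = call.genotype if call else Genotype.MISSING
        if gt is Genotype.MISSING:
            if policy.missing_genotype_in_case == "fail":
                return False, f"case {case.sample_id} genotype missing"
            continue
        if not gt.carries_alt:
            return False, f"case {case.sample_id} does not carry the variant"
    if policy.require_absent_in_controls:
        for control in cohort.controls:
            call = variant.per_sample.get(control.sample_id)
            gt = call.genotype if call else Genotype.MISSING
            if gt is Genotype.MISSING:
                logger.debug(
                    "missing control genotype for %s in %s treated as absent",
                    format_key(variant.key),
                    control.sample_id,
                )
                continue
            if gt.carries_alt:
                return False, f"control {control.sample_id} carries the variant"
    if policy.carrier_constraint == "must_carry":
        for carrier in cohort.carriers:
            call = variant.per_sample.get(carrier.sample_id)
            gt = call.genotype if call else Genotype.MISSING
            if gt is not Genotype.MISSING and not gt.carries_alt:
                return False, f"potential carrier {carrier.sample_id} does not carry the variant"
    return True, ""


def segregation_filter(
    variants: list[VariantRecord], cohort: FamilyCohort, policy: SegregationPolicy
) -> tuple[list[VariantRecord], dict[VariantKey, StageResult]]:
    """Keep exactly the variants satisfying :func:`segregates`, order preserved."""
    results: dict[VariantKey, StageResult] = {}
    retained: list[VariantRecord] = []
    for v in variants:
        ok, reason = segregates(v, cohort, policy)
        if ok:
            results[v.key] = StageResult("segregation", StageOutcome.PASS)
            retained.append(v)
        else:
            results[v.key] = StageResult("segregation", StageOutcome.FAIL, reason)
    return retained, results


def screen_families(
    candidates: list[VariantKey],
    other_families: list[tuple[FamilyCohort, Union[str, Path]]],
) -> pd.DataFrame:
    """Check candidate variants for presence in other families' call sets.

    Returns a candidate x family table of {present, absent, no_call,
    error} plus a ``family_private`` column, true when the candidate is
    absent from every successfully screened family.  ``present`` means
    any sample of that family carries an alternate allele; ``no_call``
    means the site was seen but every genotype was missing.  A family
    whose file cannot be read is marked ``error`` and the remaining
    families are still screened.
    """
    from .io_formats import read_variants  # deferred: avoid import cycle

    index = [format_key(k) for k in candidates]
    table = pd.DataFrame(index=index)
    for cohort, path in other_families:
        col = pd.Series("absent", index=index, dtype=object)
        try:
            records = read_variants(path, cohort)
        except (OSError, ValueError) as exc:
            logger.error("could not screen family %s (%s): %s", cohort.family_id, path, exc)
            col[:] = "error"
            table[cohort.family_id] = col
            continue
        by_key = {}
        for rec in records:
            by_key.setdefault(rec.key, []).append(rec)
        for key in candidates:
            recs = by_key.get(key)
            if not recs:
                continue
            gts = [c.genotype for rec in recs for c in rec.per_sample.values()]
            if any(g.carries_alt for g in gts):
                col[format_key(key)] = "present"
            elif all(g is Genotype.MISSING for g in gts):
                col[format_key(key)] = "no_call"
        table[cohort.family_id] = col
    if len(other_families) > 0:
        screened = table.loc[:, table.ne("error").all()]
        table["family_private"] = screened.eq("absent").all(axis=1) & (screened.shape[1] > 0)
    return table
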
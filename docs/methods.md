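# Methods

## Model and assumptions

`famprio` prioritizes germline candidates in a single multiplex cancer
family under a dominant inheritance model with reduced penetrance. The
segregation criterion is carrier status, not dosage: "present" means at
least one alternate allele, and a homozygous carrier satisfies it the
same way a heterozygote does. The cascade assumes joint calling over
the family (one multi-sample VCF) so that a hom-ref genotype in a
control is an observed non-carrier call, not an absence of data.

The pipeline consumes annotations; it never computes them. Population
frequencies, CADD, the conservation triple, the ten predictor calls,
and the gene-constraint scores arrive in a tab-separated table keyed by
`(chrom, pos, ref, alt)`, matching an ANNOVAR/dbNSFP-style workflow.
Keys must match the call file as provided: multi-allelic sites are
split on ingest but alleles are deliberately **not** left-normalized,
because silently rewriting alleles risks disagreeing with the
annotation table's keys. Normalization, if needed, belongs upstream.

## Thresholds

| parameter | default | semantics |
|---|---|---|
| `qual_min` | 20 | site QUAL, strict `>` |
| `depth_min` | 5× | per-sample depth, strict `>`, over called genotypes |
| `maf_max` | 0.001 | each of two panels, removal is strict `>` (exactly 0.1% is kept) |
| `cadd_min` | 10 | scaled CADD, strict `>` (exactly 10 is removed) |
| `gerp_min` / `phastcons_min` / `phylop_min` | 2.0 / 0.3 / 3.0 | inclusive `>=`, all three required by default |
| `vote_fraction` | 0.6 | deleterious / called, inclusive `>=` (6/10 passes) |
| `vote_min_calls` | 5 | fewer called tools ⇒ vote undecidable (fails, detail `undecidable`) |

Boundary semantics follow the wording of each rule literally: strict
for "greater than" cuts (QUAL, depth, CADD, MAF removal), inclusive for
"at least" (the vote). The conservation defaults are package defaults
chosen to represent "good" conservation on each score's customary
scale; they are the parameters most worth revisiting per study, which
is why the config exposes each one plus an any-*k*-of-3 relaxation.

Coverage is enforced per sample over non-missing genotypes rather than
as a site mean, because a segregation call resting on a 2-read
genotype is untrustworthy even when the site average is high. A
site-mean mode (`depth_mode: site_mean`) is available.

## Missing data policy

* A missing population frequency means the variant is absent from that
  panel — exactly the novel variants a familial study is looking for —
  so it counts as rare.
* Half-called genotypes (e.g. `0/.`) map to `missing` on ingest: a
  half-call cannot demonstrate carrier status.
* A missing genotype in a case fails segregation by default (presence
  not demonstrated); `missing_genotype_in_case: lenient_pass` exists
  because joint callers do emit no-calls at true sites. A missing
  genotype in a control is treated as absent and logged, since it
  weakens the control side.
* A missing CADD score fails the CADD stage (`unscored`); a missing
  conservation score fails that component; missing predictor calls
  shrink the vote denominator, with `vote_min_calls` as the
  decidability floor — a fixed denominator of 10 would silently
  penalize poorly covered variants.
* A variant with no annotation record at all is retained through the
  quality, frequency (novel ⇒ rare) and segregation stages and then
  fails track routing with detail `unannotated` — the first stage that
  cannot proceed without knowing the functional class. Nothing is ever
  dropped silently; the funnel accounts for every ingested allele.

## Rescue and ranking

The rescue re-examines coding variants that passed every stage through
CADD but failed conservation and/or the ensemble vote: if the gene is
on the known cancer-predisposition list (a user file, or the built-in
list of ~30 established genes), the variant is reinstated with
`rescued = true`. Rescue never forgives quality, frequency,
segregation, routing or CADD failures — leniency applies to the two
pathogenicity-evidence stages only, where in-silico tools are known to
disagree with functional data.

Survivors are ranked, not filtered, by gene constraint: nonsense
variants by descending pLI, missense by descending missense *Z*. The
nonsense block precedes the missense block by default because pLI is
the stronger constraint signal for truncating variation
(`nonsense_first: false` flips it). Ties break by descending mean of
the available intolerance percentiles, then descending CADD, then the
variant key — a total order, so ranks are invariant under input
permutation. The three intolerance scores are interpreted as
percentiles with higher = more intolerant; suppliers whose scores run
the other way should flip them before building the table. Missing
ranking keys sort last within their class. Whether synonymous variants
belong in the missense ranking block is genuinely ambiguous;
the default drops them at routing and `include_synonymous: true`
admits them.

The non-coding exonic track is deliberately minimal: those variants
share the quality/rarity/segregation/CADD stages and are emitted as a
separate CADD-ranked list. No regulatory-impact model is implemented;
scoring non-coding variation properly requires dedicated tools outside
this package's scope.

## Synthetic cohorts

The generator (`famprio.simulate`) emulates the study design the
cascade assumes — by default 3 cases, 1 potential carrier, 1 control,
and 200 rare variant alleles of which 3 are causal. Causal variants
are heterozygous in all cases and the carrier, hom-ref in controls,
and draw annotations comfortably inside every default threshold
(MAF < 0.05%, CADD 15–35, GERP 3–6, PhastCons 0.6–1, PhyloP 3.5–8,
7–10/10 deleterious calls). Every non-causal variant is a
**single-failure decoy**: all fields come from the causal-passing
profile except one planted violation (`low_qual`, `low_depth`,
`common_frequency`, `control_carrier`, `case_noncarrier`, `low_cadd`,
`unconserved`, `vote_fail`), uniformly mixed by default. This makes
three properties exactly testable: recovery of every planted causal
variant, zero decoy survival, and per-stage death attribution in the
trace. Optional knobs add multi-allelic sites (the extra allele is
carried by nobody and shares the site's QUAL/DP, so it is only planted
at sites that pass the quality stage), non-coding decoys (restricted
to failure modes on the track they actually travel), and per-field
annotation missingness (never applied to causal variants unless
requested).

What the generator does *not* emulate: linkage disequilibrium and
haplotype structure, Mendelian transmission within the pedigree
(non-causal carriers are independent per sample — the cascade only
uses roles, never parent-offspring structure), sequencing artifacts,
multi-failure variants (available in the random in-memory cohorts used
by the property tests), and realistic genome-wide variant counts.
Passing tests therefore demonstrate that the cascade's logic is exact
and deterministic, not that its thresholds are well calibrated for any
particular real cohort.

All randomness flows from a single integer seed through one
`numpy` generator; identical configs produce byte-identical files, and
identical inputs produce byte-identical reports (outputs are sorted by
variant key; floats are formatted with `%g`).

## Problem sizes

The test suite and the acceptance script run simulations at 30–1,000
variant alleles per cohort (50 recovery runs at 150 alleles, 20
oracle-equivalence cohorts up to 1,000, 200 random property-test
cohorts at 30) — sizes chosen so the full validation cycle completes
in seconds while still exercising every stage, both tracks, multi-
allelic splitting and annotation missingness. The cascade itself is
linear in the number of alleles and has no per-size constants tuned
in; genome-scale inputs (~10⁵ rare variants per family) stream through
the same code path.

## Known limitations

* Biallelic, autosomal-dominant reasoning only: no recessive or
  compound-het model, no X-linked handling, no de novo logic.
* The relatedness check is the raw shared-rare-variant count matrix,
  reported for human review; it is not a kinship estimator and no
  flagging threshold is applied.
* The built-in rescue gene list is a convenience default, not a
  curated clinical resource; real studies should supply their own.
* No liftover, no allele normalization, no annotation recomputation.
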
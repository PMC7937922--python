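"""Annotation cascade: routing, CADD, conservation, vote, rescue, ranking."""

import functools
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famprio.model import (
    PREDICTOR_TOOLS,
    FunctionalClass,
    Genotype,
    PredictorCall,
    StageOutcome,
    Track,
)
from famprio.prioritization import (
    DEFAULT_RESCUE_GENES,
    CascadeSettings,
    PrioritizationThresholds,
    RescueGeneList,
    cadd_filter,
    conservation_filter,
    deleteriousness_vote,
    rank_candidates,
    route_tracks,
    run_cascade,
    vote_filter,
)

from _utils import mk_ann, mk_cohort, mk_variant

TH = PrioritizationThresholds()


def calls(n_deleterious: int, n_missing: int = 0):
    out = {}
    for i, tool in enumerate(PREDICTOR_TOOLS):
        if i < n_deleterious:
            out[tool] = PredictorCall.DELETERIOUS
        elif i < 10 - n_missing:
            out[tool] = PredictorCall.TOLERATED
        else:
            out[tool] = PredictorCall.MISSING
    return out


class TestRouting:
    @pytest.mark.parametrize(
        "fclass,where",
        [
            (FunctionalClass.MISSENSE, "coding"),
            (FunctionalClass.NONSENSE, "coding"),
            (FunctionalClass.NONCODING_EXONIC, "noncoding"),
            (FunctionalClass.SYNONYMOUS, "dropped"),
            (FunctionalClass.OTHER, "dropped"),
        ],
    )
    def test_class_routing(self, fclass, where):
        cohort = mk_cohort()
        v = mk_variant(cohort)
        coding, noncoding, results = route_tracks([v], {v.key: mk_ann(v, functional_class=fclass)})
        got = "coding" if coding else "noncoding" if noncoding else "dropped"
        assert got == where
        if where == "dropped":
            assert results[v.key].outcome is StageOutcome.FAIL

    def test_unannotated_variant_fails_routing_with_detail(self):
        cohort = mk_cohort()
        v = mk_variant(cohort)
        coding, noncoding, results = route_tracks([v], {})
        assert coding == [] and noncoding == []
        assert results[v.key].detail == "unannotated"

    def test_synonymous_joins_missense_block_when_configured(self):
        cohort = mk_cohort()
        v = mk_variant(cohort)
        ann = {v.key: mk_ann(v, functional_class=FunctionalClass.SYNONYMOUS)}
        coding, _, _ = route_tracks([v], ann, PrioritizationThresholds(include_synonymous=True))
        assert coding == [v]

    def test_partition_sizes_match_truth_on_simulated_mix(self, tmp_path):
        from famprio.io_formats import read_annotations, read_pedigree, read_variants
        from famprio.simulate import SimulationConfig, simulate_cohort

        sim = simulate_cohort(SimulationConfig(seed=21, n_variants=100, n_noncoding=10), tmp_path)
        cohort = read_pedigree(sim.pedigree_path)
        variants = read_variants(sim.vcf_path, cohort)
        annotations = read_annotations(sim.annotation_path)
        coding, noncoding, _ = route_tracks(variants, annotations)
        n_nc_truth = sum(
            1 for a in annotations.values() if a.functional_class is FunctionalClass.NONCODING_EXONIC
        )
        assert n_nc_truth == 10
        assert len(noncoding) == 10
        assert len(coding) == len(variants) - 10


class TestCaddFilter:
    @pytest.mark.parametrize("cadd,kept", [(10.0, False), (23.1, True), (10.01, True), (None, False)])
    def test_strict_boundary_and_unscored(self, cadd, kept):
        cohort = mk_cohort()
        v = mk_variant(cohort)
        retained, results = cadd_filter([v], {v.key: mk_ann(v, cadd_phred=cadd)}, TH)
        assert bool(retained) is kept
        if cadd is None:
            assert results[v.key].detail == "unscored"

    def test_exceedance_count_matches_planted_distribution(self):
        rng = np.random.default_rng(31)
        cohort = mk_cohort()
        variants, annotations = [], {}
        for i in range(400):
            v = mk_variant(cohort, pos=1000 + i)
            annotations[v.key] = mk_ann(v, cadd_phred=float(rng.uniform(0, 40)))
            variants.append(v)
        kept, _ = cadd_filter(variants, annotations, TH)
        truth = sum(1 for a in annotations.values() if a.cadd_phred > 10.0)
        assert len(kept) == truth


class TestConservationFilter:
    def test_all_three_above_defaults_passes(self):
        cohort = mk_cohort()
        v = mk_variant(cohort)
        ann = {v.key: mk_ann(v, gerp=4.5, phastcons=1.0, phylop=5.2)}
        assert len(conservation_filter([v], ann, TH)[0]) == 1

    def test_missing_component_fails_all_of_but_passes_any_2_of_3(self):
        cohort = mk_cohort()
        v = mk_variant(cohort)
        ann = {v.key: mk_ann(v, gerp=4.5, phastcons=None, phylop=5.2)}
        kept, results = conservation_filter([v], ann, TH)
        assert kept == [] and "phastcons" in results[v.key].detail
        relaxed = PrioritizationThresholds(conservation_rule="any_k_of_3", conservation_k=2)
        assert len(conservation_filter([v], ann, relaxed)[0]) == 1

    def test_inclusive_boundaries(self):
        cohort = mk_cohort()
        v = mk_variant(cohort)
        ann = {v.key: mk_ann(v, gerp=2.0, phastcons=0.3, phylop=3.0)}
        assert len(conservation_filter([v], ann, TH)[0]) == 1

    def test_matches_per_record_oracle_predicate(self):
        rng = np.random.default_rng(13)
        cohort = mk_cohort()
        variants, annotations = [], {}
        for i in range(300):
            v = mk_variant(cohort, pos=1000 + i)
            annotations[v.key] = mk_ann(
                v,
                gerp=None if rng.random() < 0.1 else float(rng.uniform(-5, 7)),
                phastcons=None if rng.random() < 0.1 else float(rng.uniform(0, 1)),
                phylop=None if rng.random() < 0.1 else float(rng.uniform(-4, 9)),
            )
            variants.append(v)
        kept, _ = conservation_filter(variants, annotations, TH)
        expected = {
            v.key
            for v in variants
            if (a := annotations[v.key]).gerp is not None and a.gerp >= 2.0
            and a.phastcons is not None and a.phastcons >= 0.3
            and a.phylop is not None and a.phylop >= 3.0
        }
        assert {v.key for v in kept} == expected


class TestDeleteriousnessVote:
    @pytest.mark.parametrize(
        "n_del,n_missing,verdict",
        [
            (6, 0, "pass"),   # 6/10 = 60%, at-least is inclusive
            (5, 0, "fail"),   # 5/10 = 50%
            (3, 6, "undecidable"),  # only 4 calls < vote_min_calls
            (3, 5, "pass"),   # 3/5 = 60%
            (0, 10, "undecidable"),
        ],
    )
    def test_vote_semantics(self, n_del, n_missing, verdict):
        cohort = mk_cohort()
        v = mk_variant(cohort)
        ann = mk_ann(v, predictor_calls=calls(n_del, n_missing))
        got, (d, m) = deleteriousness_vote(ann, TH)
        assert got == verdict
        assert d == n_del and m == 10 - n_missing

    def test_undecidable_fails_the_filter_with_detail(self):
        cohort = mk_cohort()
        v = mk_variant(cohort)
        ann = {v.key: mk_ann(v, predictor_calls=calls(3, 6))}
        kept, results = vote_filter([v], ann, TH)
        assert kept == [] and "undecidable" in results[v.key].detail

    @settings(max_examples=120, derandomize=True)
    @given(st.integers(0, 10), st.integers(0, 10))
    def test_vote_matches_direct_fraction_arithmetic(self, n_del, n_missing):
        if n_del + n_missing > 10:
            n_missing = 10 - n_del
        cohort = mk_cohort()
        v = mk_variant(cohort)
        ann = mk_ann(v, predictor_calls=calls(n_del, n_missing))
        verdict, _ = deleteriousness_vote(ann, TH)
        m = 10 - n_missing
        if m < 5:
            assert verdict == "undecidable"
        else:
            assert verdict == ("pass" if n_del / m >= 0.6 else "fail")


class TestRescue:
    def _run(self, gene, failure, rescue_on=True):
        cohort = mk_cohort()
        v = mk_variant(cohort)
        over = {"gene": gene}
        if failure == "vote":
            over["predictor_calls"] = calls(4)
        elif failure == "conservation":
            over["gerp"] = 0.0
        elif failure == "both":
            over["predictor_calls"] = calls(4)
            over["gerp"] = 0.0
        elif failure == "segregation":
            v = mk_variant(cohort, genotypes={"CONTROL1": Genotype.HET})
        elif failure == "cadd":
            over["cadd_phred"] = 5.0
        ann = {v.key: mk_ann(v, **over)}
        settings_ = CascadeSettings(enable_rescue=rescue_on)
        return run_cascade([v], ann, cohort, settings_)

    @pytest.mark.parametrize("failure", ["vote", "conservation", "both"])
    def test_listed_gene_failing_only_lenient_stages_is_rescued(self, failure):
        result = self._run("CHEK2", failure)
        assert [c.rescued for c in result.coding] == [True]

    def test_unlisted_gene_stays_failed(self):
        assert self._run("NOT_A_CANCER_GENE", "vote").coding == []

    @pytest.mark.parametrize("failure", ["segregation", "cadd"])
    def test_rescue_never_overrides_upstream_failures(self, failure):
        assert self._run("CHEK2", failure).coding == []

    def test_rescue_toggle_differs_by_exactly_that_variant(self):
        with_rescue = {c.variant_key for c in self._run("CHEK2", "vote", True).coding}
        without = {c.variant_key for c in self._run("CHEK2", "vote", False).coding}
        assert with_rescue - without == {("1", 1000, "A", "G")}
        assert without <= with_rescue

    def test_empty_rescue_list_is_rejected(self):
        from famprio.prioritization import rescue

        with pytest.raises(ValueError, match="empty"):
            rescue([], {}, RescueGeneList(genes=set()), {})


class TestRanking:
    def _survivors(self, specs):
        cohort = mk_cohort()
        variants, annotations = [], {}
        for i, over in enumerate(specs):
            v = mk_variant(cohort, pos=1000 + i)
            annotations[v.key] = mk_ann(v, **over)
            variants.append(v)
        return variants, annotations

    def test_missense_ordered_by_descending_z(self):
        variants, ann = self._survivors([{"mis_z": 3.1}, {"mis_z": 1.2}])
        ranked = rank_candidates(variants, ann)
        assert [c.ranking_keys["mis_z"] for c in ranked] == [3.1, 1.2]
        assert [c.rank for c in ranked] == [1, 2]

    def test_nonsense_block_precedes_missense(self):
        variants, ann = self._survivors(
            [
                {"mis_z": 5.0},
                {"functional_class": FunctionalClass.NONSENSE, "pli": 0.99},
            ]
        )
        ranked = rank_candidates(variants, ann)
        assert ranked[0].functional_class is FunctionalClass.NONSENSE
        assert ranked[0].rank == 1

    def test_missing_primary_key_sorts_last_within_class(self):
        variants, ann = self._survivors([{"mis_z": None}, {"mis_z": -2.0}])
        ranked = rank_candidates(variants, ann)
        assert ranked[-1].ranking_keys["mis_z"] is None

    def test_matches_independent_comparison_sort(self):
        """20 synthetic survivors vs an independently coded cmp-based sort."""
        rng = np.random.default_rng(77)
        specs = []
        for _ in range(20):
            specs.append(
                {
                    "functional_class": FunctionalClass.NONSENSE
                    if rng.random() < 0.3
                    else FunctionalClass.MISSENSE,
                    "pli": None if rng.random() < 0.2 else round(float(rng.uniform(0, 1)), 3),
                    "mis_z": None if rng.random() < 0.2 else round(float(rng.uniform(-2, 6)), 3),
                    "cadd_phred": round(float(rng.uniform(10, 40)), 2),
                    "intolerance_scores": {
                        "esp6500": None if rng.random() < 0.3 else round(float(rng.uniform(0, 100)), 2),
                        "exac": None if rng.random() < 0.3 else round(float(rng.uniform(0, 100)), 2),
                        "local": None,
                    },
                }
            )
        variants, ann = self._survivors(specs)

        def cmp(a, b):
            aa, ab = ann[a.key], ann[b.key]
            for lo, hi in (
                (
                    0 if aa.functional_class is FunctionalClass.NONSENSE else 1,
                    0 if ab.functional_class is FunctionalClass.NONSENSE else 1,
                ),
            ):
                if lo != hi:
                    return -1 if lo < hi else 1

            def desc(x, y):
                if x is None and y is None:
                    return 0
                if x is None:
                    return 1
                if y is None:
                    return -1
                if x != y:
                    return -1 if x > y else 1
                return 0

            pa = aa.pli if aa.functional_class is FunctionalClass.NONSENSE else aa.mis_z
            pb = ab.pli if ab.functional_class is FunctionalClass.NONSENSE else ab.mis_z
            r = desc(pa, pb)
            if r:
                return r

            def mean_or_none(d):
                vals = [v for v in d.values() if v is not None]
                return sum(vals) / len(vals) if vals else None

            r = desc(mean_or_none(aa.intolerance_scores), mean_or_none(ab.intolerance_scores))
            if r:
                return r
            r = desc(aa.cadd_phred, ab.cadd_phred)
            if r:
                return r
            return -1 if a.key < b.key else (1 if a.key > b.key else 0)

        expected = sorted(variants, key=functools.cmp_to_key(cmp))
        ranked = rank_candidates(variants, ann)
        assert [c.variant_key for c in ranked] == [v.key for v in expected]

    def test_ranking_is_permutation_invariant(self):
        rng = np.random.default_rng(8)
        choices = [1.0, 2.0, None]
        specs = [{"mis_z": choices[int(rng.integers(0, 3))]} for _ in range(6)]
        variants, ann = self._survivors(specs)
        baseline = [c.variant_key for c in rank_candidates(variants, ann)]
        for perm in itertools.permutations(variants):
            assert [c.variant_key for c in rank_candidates(list(perm), ann)] == baseline


class TestRunCascade:
    def test_planted_full_pass_variants_form_the_shortlist(self, default_sim):
        sim, cohort, variants, annotations = default_sim
        result = run_cascade(variants, annotations, cohort)
        causal = {k for k, lab in sim.truth.items() if lab == "causal_pass"}
        assert {c.variant_key for c in result.coding} == causal

    def test_all_decoy_cohort_yields_empty_shortlist_with_attributed_deaths(self, tmp_path):
        from famprio.io_formats import read_annotations, read_pedigree, read_variants
        from famprio.simulate import DECOY_STAGE, SimulationConfig, simulate_cohort

        sim = simulate_cohort(SimulationConfig(seed=41, n_variants=80, n_causal=0), tmp_path)
        cohort = read_pedigree(sim.pedigree_path)
        variants = read_variants(sim.vcf_path, cohort)
        annotations = read_annotations(sim.annotation_path)
        result = run_cascade(variants, annotations, cohort)
        assert result.candidates == []
        for trace in result.traces:
            mode = sim.truth[trace.variant_key].removeprefix("decoy_")
            assert trace.failed_stages == [DECOY_STAGE[mode]]

    def test_cascade_is_monotone_stage_by_stage(self, default_sim):
        _, cohort, variants, annotations = default_sim
        counts = [c for _, c in run_cascade(variants, annotations, cohort).funnel]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
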
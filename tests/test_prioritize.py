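"""Variant prioritization chain: boundaries, brute-force recounts,
stage commutativity and truth recovery."""

from itertools import permutations

import numpy as np
import pytest

from somascape.model import Effect, Region, ValidationError, VariantCall
from somascape.prioritize import (
    FilterConfig,
    classify_novel,
    filter_functional,
    filter_population_af,
    filter_quality,
    run_prioritization,
    subtract_germline,
)
from somascape.synth import LABEL_GERMLINE


def make_call(**kw):
    base = dict(
        sample_id="S1", chrom="1", pos=100, ref="C", alt="T", gene="APC",
        region=Region.EXONIC, effect=Effect.MISSENSE, quality=50.0,
        tumor_depth=60, tumor_alt=20, normal_depth=30, normal_alt=0,
    )
    base.update(kw)
    return VariantCall(**base)


CFG = FilterConfig()


class TestQuality:
    def test_strictly_above_q30(self):
        calls = [make_call(pos=i, quality=q) for i, q in enumerate([29.9, 30.0, 30.1], 1)]
        kept = filter_quality(calls, CFG)
        assert [c.quality for c in kept] == [30.1]

    def test_empty_input(self):
        assert filter_quality([], CFG) == []

    def test_brute_force_recount(self):
        rng = np.random.default_rng(3)
        quals = rng.uniform(0, 60, size=1000)
        calls = [make_call(pos=i + 1, quality=float(q)) for i, q in enumerate(quals)]
        kept = filter_quality(calls, CFG)
        assert len(kept) == int(np.sum(quals > 30))


class TestPopulationAf:
    def test_strict_boundary(self):
        removed = make_call(pop_af={"1000g": 0.06})
        kept = make_call(pos=101, pop_af={"1000g": 0.05})
        out = filter_population_af([removed, kept], CFG)
        assert out == [kept]

    def test_absent_in_all_databases_retained(self):
        call = make_call(pop_af={})
        assert filter_population_af([call], CFG) == [call]

    def test_max_across_databases(self):
        # high only in one database is enough
        call = make_call(pop_af={"1000g": 0.01, "exac": 0.2})
        assert filter_population_af([call], CFG) == []

    def test_unconfigured_database_ignored(self):
        call = make_call(pop_af={"gnomad": 0.9})
        assert filter_population_af([call], CFG) == [call]

    def test_af_outside_unit_interval_rejected(self):
        call = make_call()
        call.pop_af["1000g"] = 1.5  # bypass constructor validation
        with pytest.raises(ValidationError):
            filter_population_af([call], CFG)

    def test_truth_labelled_germline_removed(self, default_cohort):
        labels = default_cohort.truth.labels
        germline_keys = {
            k for k, lab in labels.items() if lab == LABEL_GERMLINE
        }
        kept = filter_population_af(default_cohort.tumour_calls, CFG)
        kept_keys = {(c.sample_id, *c.key) for c in kept}
        assert kept_keys.isdisjoint(germline_keys)


class TestFunctional:
    def test_synonymous_exonic_removed(self):
        assert filter_functional([make_call(effect=Effect.SYNONYMOUS)], CFG) == []

    def test_intronic_missense_removed(self):
        assert filter_functional([make_call(region=Region.INTRONIC)], CFG) == []

    def test_unannotated_gene_removed(self):
        assert filter_functional([make_call(gene="")], CFG) == []

    def test_brute_force_intersection(self):
        rng = np.random.default_rng(11)
        regions = list(Region)
        effects = list(Effect)
        calls = [
            make_call(
                pos=i + 1,
                region=regions[rng.integers(len(regions))],
                effect=effects[rng.integers(len(effects))],
                gene="G" if rng.random() < 0.8 else "",
            )
            for i in range(200)
        ]
        kept = filter_functional(calls, CFG)
        expected = [
            c for c in calls
            if c.region in CFG.keep_regions
            and c.gene
            and c.effect not in CFG.drop_effects
        ]
        assert kept == expected


class TestGermlineSubtraction:
    def test_identical_sets_give_empty(self):
        t = [make_call(pos=p) for p in (1, 2, 3)]
        n = [make_call(pos=p) for p in (1, 2, 3)]
        assert subtract_germline(t, n) == []

    def test_disjoint_sets_unchanged(self):
        t = [make_call(pos=p) for p in (1, 2)]
        n = [make_call(pos=p) for p in (10, 20)]
        assert subtract_germline(t, n) == t

    def test_mismatched_patients_rejected(self):
        with pytest.raises(ValidationError):
            subtract_germline([make_call()], [make_call(sample_id="S2")])

    def test_planted_germline_removed(self, default_cohort):
        labels = default_cohort.truth.labels
        sid = default_cohort.samples[0].sample_id
        t = [c for c in default_cohort.tumour_calls if c.sample_id == sid]
        n = [c for c in default_cohort.normal_calls if c.sample_id == sid]
        kept = subtract_germline(t, n)
        removed_keys = {(c.sample_id, *c.key) for c in t} - {
            (c.sample_id, *c.key) for c in kept
        }
        planted = {
            k for k, lab in labels.items() if lab == LABEL_GERMLINE and k[0] == sid
        }
        assert removed_keys == planted


class TestNovelty:
    def test_ids_absent_with_clean_normal_is_novel(self):
        call = make_call(normal_depth=10, normal_alt=0)
        assert classify_novel([call], CFG) == [(call, True)]

    @pytest.mark.parametrize(
        "kw",
        [
            {"normal_depth": 9, "normal_alt": 0},
            {"normal_depth": 10, "normal_alt": 1},
            {"dbsnp_id": "rs1"},
            {"cosmic_id": "COSM1"},
        ],
    )
    def test_known_boundaries(self, kw):
        call = make_call(normal_depth=kw.pop("normal_depth", 10),
                         normal_alt=kw.pop("normal_alt", 0), **kw)
        assert classify_novel([call], CFG) == [(call, False)]

    def test_table4_novel_rows(self, table4_calls):
        flagged = classify_novel(table4_calls, CFG)
        novel_genes = {(c.gene, c.aa_change) for c, f in flagged if f}
        assert novel_genes == {
            ("KDM4E", "R100H"),
            ("MUC16", "L12755F"),
            ("MUC16", "L12755S"),
            ("POTED", "E172Q"),
        }
        known = [c for c, f in flagged if not f]
        assert all(c.dbsnp_id or c.cosmic_id for c in known)


class TestFullChain:
    def test_truth_recovery_and_trace_conservation(self, default_cohort):
        flagged, trace = run_prioritization(
            default_cohort.tumour_calls, default_cohort.normal_calls, FilterConfig()
        )
        survivors = {(c.sample_id, *c.key) for c, _ in flagged}
        truth = default_cohort.truth.keys_with_labels({"somatic", "hotspot", "novel"})
        assert survivors == truth  # precision = recall = 1.0
        # conservation: removals across stages account for every lost call
        total_removed = sum(n_in - n_out for _, n_in, n_out in trace.stages)
        assert trace.stages[0][1] - len(flagged) == total_removed
        assert len(trace.stages) == 5

    def test_survivor_set_invariant_under_stage_permutation(self, reference):
        from somascape.synth import CohortConfig, simulate_cohort

        sim = simulate_cohort(CohortConfig(n_samples=6, seed=13), reference)
        normal_keys = {(c.sample_id, *c.key) for c in sim.normal_calls}

        stages = {
            "q": lambda cs: filter_quality(cs, CFG),
            "af": lambda cs: filter_population_af(cs, CFG),
            "fn": lambda cs: filter_functional(cs, CFG),
            "germ": lambda cs: [
                c for c in cs if (c.sample_id, *c.key) not in normal_keys
            ],
        }
        reference_set = None
        for order in permutations(stages):
            calls = list(sim.tumour_calls)
            for name in order:
                calls = stages[name](calls)
            keys = frozenset((c.sample_id, *c.key) for c in calls)
            if reference_set is None:
                reference_set = keys
            assert keys == reference_set

    def test_disabled_thresholds_reduce_to_germline_subtraction(self, default_cohort):
        cfg = FilterConfig(
            min_quality=-1.0,
            max_pop_af=1.0,
            keep_regions=frozenset(Region),
            drop_effects=frozenset(),
        )
        flagged, _ = run_prioritization(
            default_cohort.tumour_calls, default_cohort.normal_calls, cfg
        )
        normal_keys = {(c.sample_id, *c.key) for c in default_cohort.normal_calls}
        expected = {
            (c.sample_id, *c.key)
            for c in default_cohort.tumour_calls
            if (c.sample_id, *c.key) not in normal_keys
        }
        assert {(c.sample_id, *c.key) for c, _ in flagged} == expected

    def test_empty_cohort_gives_zero_trace(self):
        flagged, trace = run_prioritization([], [], FilterConfig())
        assert flagged == []
        assert [(n_in, n_out) for _, n_in, n_out in trace.stages] == [(0, 0)] * 5

    def test_output_sorted(self, default_cohort):
        flagged, _ = run_prioritization(
            default_cohort.tumour_calls, default_cohort.normal_calls
        )
        keys = [(c.sample_id, c.chrom, c.pos, c.alt) for c, _ in flagged]
        assert keys == sorted(keys)
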
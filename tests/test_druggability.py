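"""Druggability rule matching and cohort actionability summaries."""

import random

import pytest

from somascape.druggability import (
    DruggabilityRule,
    DrugEffect,
    Evidence,
    EVIDENCE_RANK,
    PatternKind,
    match_rules,
    summarize_actionability,
)
from somascape.fixtures import default_rules
from somascape.model import Effect, Region, ValidationError, VariantCall


def vc(sample, gene, effect=Effect.MISSENSE, aa="", pos=100):
    return VariantCall(
        sample_id=sample, chrom="1", pos=pos, ref="CA" if "fs" in aa else "C",
        alt="C" if "fs" in aa else "T", gene=gene, region=Region.EXONIC,
        effect=effect, aa_change=aa, quality=50.0,
        tumor_depth=60, tumor_alt=20, normal_depth=30, normal_alt=0,
    )


RULES = default_rules()


class TestMatching:
    def test_rnf43_frameshift_matches_porcupine_inhibitor(self):
        call = vc("C474T", "RNF43", Effect.FRAMESHIFT_DEL, "G156fs")
        report = match_rules([call], RULES)
        drugs = [m.rule.drug for m in report.matches["C474T"]]
        assert any("Porcupine inhibitor" in d for d in drugs)

    def test_kras_g12d_matches_resistance_and_response(self):
        call = vc("S1", "KRAS", Effect.MISSENSE, "G12D")
        report = match_rules([call], RULES)
        effects = {(m.rule.drug, m.rule.effect) for m in report.matches["S1"]}
        assert any(
            "EGFR mAb" in d and e is DrugEffect.RESISTANT for d, e in effects
        )
        assert any(
            "MEK" in d and e is DrugEffect.RESPONSIVE for d, e in effects
        )
        assert any(
            "ERBB2" in d and e is DrugEffect.RESISTANT for d, e in effects
        )

    def test_synonymous_apc_does_not_match_truncating_rule(self):
        call = vc("S1", "APC", Effect.SYNONYMOUS)
        report = match_rules([call], RULES)
        assert report.matches["S1"] == []
        assert not report.has_druggable("S1")

    def test_apc_truncating_matches_tankyrase_preclinical(self):
        call = vc("S1", "APC", Effect.NONSENSE, "R1450X")
        report = match_rules([call], RULES)
        tanky = [m for m in report.matches["S1"] if "Tankyrase" in m.rule.drug]
        assert len(tanky) == 1
        assert tanky[0].rule.evidence is Evidence.PRE_CLINICAL

    def test_exact_aa_handles_transcript_label_lists(self):
        # one genomic change annotated with several transcript labels
        call = vc("S1", "BRAF", Effect.MISSENSE, "V28E,V600E")
        report = match_rules([call], RULES)
        assert any("BRAF inhibitor" in m.rule.drug for m in report.matches["S1"])

    def test_disease_mismatch_excluded(self):
        rule = DruggabilityRule(
            "KRAS", PatternKind.ANY_NONSYNONYMOUS, "", "x", DrugEffect.RESISTANT,
            Evidence.FDA, disease="NSCLC",
        )
        report = match_rules([vc("S1", "KRAS", aa="G12D")], [rule])
        assert report.matches["S1"] == []

    def test_position_class_pattern(self):
        rule = DruggabilityRule(
            "KRAS", PatternKind.POSITION_CLASS, "90-110", "x",
            DrugEffect.RESPONSIVE, Evidence.EARLY_TRIALS,
        )
        hit = vc("S1", "KRAS", pos=100)
        miss = vc("S2", "KRAS", pos=200)
        report = match_rules([hit, miss], [rule])
        assert report.has_druggable("S1") and not report.has_druggable("S2")

    def test_malformed_rule_rejected(self):
        with pytest.raises(ValidationError):
            DruggabilityRule.from_row(
                {"gene": "KRAS", "pattern_kind": "exact_aa", "pattern_payload": ".",
                 "drug": "x", "effect": "responsive", "evidence": "FDA",
                 "disease": "COREAD"},
                line=3,
            )


class TestTable4Statements:
    """The bundled rules reproduce the published per-variant statements on
    the recurrent-variant fixture."""

    def test_all_kras_g12d_carriers_get_egfr_mab_resistance(self, table4_calls):
        report = match_rules(table4_calls, RULES)
        g12d_carriers = {
            c.sample_id for c in table4_calls
            if c.key == ("12", 25398284, "C", "T")
        }
        assert len(g12d_carriers) == 6
        for sid in g12d_carriers:
            assert any(
                "EGFR mAb" in m.rule.drug and m.rule.effect is DrugEffect.RESISTANT
                for m in report.matches[sid]
            )

    def test_braf_and_pik3ca_carriers_annotated(self, table4_calls):
        report = match_rules(table4_calls, RULES)
        for c in table4_calls:
            if c.gene == "BRAF":
                assert any(
                    "BRAF inhibitor" in m.rule.drug for m in report.matches[c.sample_id]
                )
            if c.gene == "PIK3CA":
                drugs = {m.rule.drug for m in report.matches[c.sample_id]}
                assert any("PI3K-pathway" in d for d in drugs)
                assert "Cetuximab" in drugs

    def test_apc_truncating_rows_match_tankyrase(self, table4_calls):
        report = match_rules(table4_calls, RULES)
        for c in table4_calls:
            if c.gene == "APC":
                assert any(
                    "Tankyrase" in m.rule.drug
                    and m.rule.evidence is Evidence.PRE_CLINICAL
                    for m in report.matches[c.sample_id]
                )


class TestDeterminismAndSummary:
    def test_order_independence(self, table4_calls):
        shuffled_calls = list(table4_calls)
        shuffled_rules = list(RULES)
        random.Random(1).shuffle(shuffled_calls)
        random.Random(2).shuffle(shuffled_rules)
        a = match_rules(table4_calls, RULES)
        b = match_rules(shuffled_calls, shuffled_rules)
        for sid in a.matches:
            assert [
                (m.variant.key, m.rule.drug) for m in a.matches[sid]
            ] == [(m.variant.key, m.rule.drug) for m in b.matches[sid]]

    def test_matches_sorted_by_evidence_strength(self, table4_calls):
        report = match_rules(table4_calls, RULES)
        for matches in report.matches.values():
            ranks = [EVIDENCE_RANK[m.rule.evidence] for m in matches]
            assert ranks == sorted(ranks)

    def test_fraction_from_constructed_44_of_50(self):
        calls = [vc(f"S{i}", "KRAS", aa="G12D") for i in range(44)]
        calls += [vc(f"S{i}", "TTN") for i in range(44, 50)]  # no rule for TTN
        report = match_rules(calls, RULES)
        summary = summarize_actionability(report, n_samples=50)
        assert summary.n_druggable == 44
        assert summary.fraction_druggable == pytest.approx(0.88)

    def test_empty_report_zero_fraction(self):
        summary = summarize_actionability(match_rules([], RULES), 50)
        assert summary.fraction_druggable == 0.0
        assert summary.min_matches == summary.max_matches == 0

    def test_simulated_hotspots_fraction_equals_brute_force(self, default_cohort):
        report = match_rules(default_cohort.tumour_calls, RULES)
        summary = summarize_actionability(report, 50)
        matched = {
            c.sample_id
            for c in default_cohort.tumour_calls
            for rule in RULES
            if rule.matches(c)
        }
        assert summary.n_druggable == len(matched)
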
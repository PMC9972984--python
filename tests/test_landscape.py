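"""Burden, hypermutation, MSI-group statistics and recurrence summaries.

The rank-test and Fisher checks compare against independent exhaustive
oracles (label-assignment enumeration via rank sums; hypergeometric
point-probability summation)."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy.stats import hypergeom, rankdata

from somascape.landscape import (
    classify_hypermutated,
    compute_burdens,
    cohort_characteristics,
    count_pathogenic,
    gene_mutation_frequency,
    mann_whitney_two_sided,
    msi_group_stats,
    mutation_rate,
    recurrent_variants,
    variant_class_distribution,
)
from somascape.fixtures import table1_meta
from somascape.model import (
    ClinSig,
    Effect,
    MsiStatus,
    Region,
    SampleMeta,
    ValidationError,
    VariantCall,
)
from somascape.synth import LABEL_HOTSPOT


def vc(sample, gene="APC", chrom="5", pos=100, ref="C", alt="T", **kw):
    base = dict(
        sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        region=Region.EXONIC, effect=Effect.MISSENSE, quality=50.0,
        tumor_depth=60, tumor_alt=20, normal_depth=30, normal_alt=0,
    )
    base.update(kw)
    return VariantCall(**base)


class TestRates:
    @pytest.mark.parametrize("count,mb,expected", [(0, 30, 0.0), (120, 10, 12.0)])
    def test_rate_arithmetic(self, count, mb, expected):
        assert mutation_rate(count, mb) == expected

    def test_top_observed_rate(self):
        # 7319 somatic calls over a 30 Mb callable genome
        assert mutation_rate(7319, 30) == pytest.approx(243.97, abs=0.01)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValidationError):
            mutation_rate(10, 0)

    @pytest.mark.parametrize(
        "rate,expected", [(243.97, True), (12.0, False), (3.8, False), (12.0001, True)]
    )
    def test_hypermutation_strict_boundary(self, rate, expected):
        assert classify_hypermutated(rate) is expected

    def test_burden_counts_conserved(self, default_cohort):
        burdens = compute_burdens(default_cohort.tumour_calls, default_cohort.samples)
        assert sum(b.somatic_count for b in burdens) == len(default_cohort.tumour_calls)
        for b in burdens:
            assert b.rate_per_mb == b.somatic_count / 30.0
            assert b.hypermutated == (b.rate_per_mb > 12.0)


def oracle_mw_p(x, y):
    """Independent enumeration oracle: U from rank sums over every label
    assignment of the pooled data."""
    pooled = np.array(list(x) + list(y), dtype=float)
    n1, n = len(x), len(pooled)
    mu = n1 * (n - n1) / 2.0

    def u_of(idx):
        ranks = rankdata(pooled)
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    obs = u_of(range(n1))
    dev = abs(obs - mu)
    hits = sum(
        1 for idx in combinations(range(n), n1) if abs(u_of(idx) - mu) >= dev - 1e-12
    )
    return hits / comb(n, n1)


def oracle_fisher_p(table):
    """Hypergeometric point-probability two-sided oracle."""
    (a, b), (c, d) = table
    n1, n2, k = a + b, c + d, a + c
    obs = hypergeom.pmf(a, n1 + n2, n1, k)
    return sum(
        p
        for a2 in range(max(0, k - n2), min(k, n1) + 1)
        if (p := hypergeom.pmf(a2, n1 + n2, n1, k)) <= obs * (1 + 1e-9)
    )


class TestGroupStats:
    def test_spec_example_groups(self):
        # separated groups: only the 2 extreme assignments of C(6,3)=20 qualify
        assert mann_whitney_two_sided([50, 60, 70], [3, 4, 5]) == pytest.approx(2 / 20)

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 9) for n2 in range(1, 9)])
    def test_rank_test_matches_enumeration_all_small_sizes(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x = list(np.round(rng.normal(1.0, 1.0, n1), 1))
        y = list(np.round(rng.normal(0.0, 1.0, n2), 1))
        assert mann_whitney_two_sided(x, y) == pytest.approx(oracle_mw_p(x, y), abs=1e-12)

    def test_rank_test_with_ties(self):
        x, y = [1.0, 2.0, 2.0], [2.0, 3.0]
        assert mann_whitney_two_sided(x, y) == pytest.approx(oracle_mw_p(x, y))

    def test_identical_groups_p_is_one(self):
        assert mann_whitney_two_sided([5.0, 6.0, 7.0], [5.0, 6.0, 7.0]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table", [[[4, 1], [1, 44]], [[5, 0], [2, 43]], [[2, 2], [2, 2]], [[3, 0], [0, 3]]]
    )
    def test_fisher_matches_hypergeometric_enumeration(self, table):
        burdens = []
        i = 0
        for hyper, msih, n in [
            (True, True, table[0][0]), (False, True, table[0][1]),
            (True, False, table[1][0]), (False, False, table[1][1]),
        ]:
            for _ in range(n):
                i += 1
                burdens.append(
                    compute_burdens(
                        [vc(f"S{i}", pos=j + 1) for j in range(100 if hyper else 1)],
                        [SampleMeta(f"S{i}", MsiStatus.MSI_H if msih else MsiStatus.MSS, 5.0)],
                    )[0]
                )
        stats = msi_group_stats(burdens)
        assert stats.contingency == table
        assert stats.fisher_p_msih_hypermutation == pytest.approx(oracle_fisher_p(table))

    def test_medians_per_group(self):
        burdens = []
        for i, (g, n) in enumerate(
            [(MsiStatus.MSI_H, 250), (MsiStatus.MSI_H, 300), (MsiStatus.MSI_H, 350),
             (MsiStatus.MSI_L, 15), (MsiStatus.MSI_L, 20), (MsiStatus.MSI_L, 25)]
        ):
            burdens.append(
                compute_burdens(
                    [vc(f"S{i}", pos=j + 1) for j in range(n)],
                    [SampleMeta(f"S{i}", g, 5.0)],
                )[0]
            )
        stats = msi_group_stats(burdens)
        assert stats.medians[MsiStatus.MSI_H] == 60.0
        assert stats.medians[MsiStatus.MSI_L] == 4.0
        assert stats.medians[MsiStatus.MSS] is None
        assert stats.mannwhitney_p_msih_vs_msil == pytest.approx(2 / 20)

    def test_default_cohort_separates_groups(self, default_cohort):
        burdens = compute_burdens(default_cohort.tumour_calls, default_cohort.samples)
        stats = msi_group_stats(burdens)
        assert stats.mannwhitney_p_msih_vs_msil < 0.05
        assert stats.fisher_p_msih_hypermutation < 0.001

    def test_power_over_seeds(self, reference):
        """MSI-H vs MSI-L separation and the MSI-H x hypermutation association
        are detected in at least 90% of default cohorts."""
        from somascape.synth import CohortConfig, simulate_cohort

        mw_hits = fisher_hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            sim = simulate_cohort(CohortConfig(n_samples=50, seed=100 + seed), reference)
            burdens = compute_burdens(sim.tumour_calls, sim.samples)
            stats = msi_group_stats(burdens)
            mw_hits += stats.mannwhitney_p_msih_vs_msil < 0.05
            fisher_hits += stats.fisher_p_msih_hypermutation < 0.001
        assert mw_hits >= 0.9 * n_seeds
        assert fisher_hits >= 0.9 * n_seeds


class TestDistributionsAndRecurrence:
    def test_single_call_distribution(self):
        eff, reg = variant_class_distribution([vc("S1", effect=Effect.SYNONYMOUS)])
        assert eff == {Effect.SYNONYMOUS: 1}
        assert reg == {Region.EXONIC: 1}

    def test_counts_equal_brute_force(self, default_cohort):
        calls = default_cohort.tumour_calls[:500]
        eff, reg = variant_class_distribution(calls)
        assert sum(eff.values()) == len(calls) == sum(reg.values())
        for e, n in eff.items():
            assert n == sum(1 for c in calls if c.effect is e)

    def test_missense_is_modal_on_default_cohort(self, default_cohort):
        eff, _ = variant_class_distribution(default_cohort.tumour_calls)
        assert max(eff, key=eff.get) is Effect.MISSENSE

    def test_table4_recurrence(self, table4_calls):
        rec = recurrent_variants(table4_calls)
        by_change = {(r.gene, r.key): r.carrier_count for r in rec}
        assert by_change[("KRAS", ("12", 25398284, "C", "T"))] == 6  # G12D
        assert by_change[("ACVR2A", ("2", 148683686, "TA", "T"))] == 4  # K435fs
        assert by_change[("TP53", ("17", 7578406, "C", "T"))] == 4  # R175H
        assert rec[0].gene == "KRAS" and rec[0].carrier_count == 6

    def test_all_unique_cohort_has_no_recurrence(self):
        calls = [vc(f"S{i}", pos=100 + i) for i in range(10)]
        assert recurrent_variants(calls) == []

    def test_planted_hotspot_recovered(self, reference):
        from somascape.synth import CohortConfig, Hotspot, simulate_cohort

        cfg = CohortConfig(
            n_samples=10,
            hotspots=(Hotspot("KRAS", "12", 25398284, "C", "T", "G12D", 3, "ACC"),),
            germline_common_rate=0.0,
            mss_outlier_rate=None,
            callable_mb=1.0,
            seed=3,
        )
        sim = simulate_cohort(cfg, reference)
        rec = recurrent_variants(sim.tumour_calls)
        hot = [r for r in rec if r.key == ("12", 25398284, "C", "T")]
        assert len(hot) == 1 and hot[0].carrier_count == 3

    def test_same_sample_counts_once(self):
        calls = [vc("S1"), vc("S1"), vc("S2")]
        (r,) = recurrent_variants(calls)
        assert r.carrier_count == 2


class TestGeneFrequencyAndPathogenic:
    def test_table4_acvr2a_frequency(self, table4_calls):
        freq = gene_mutation_frequency(table4_calls, n_samples=50)
        assert freq["ACVR2A"] == pytest.approx(0.08)

    def test_absent_gene_zero(self):
        assert gene_mutation_frequency([vc("S1")], 10).get("TP53", 0.0) == 0.0

    def test_multiple_hits_count_once(self):
        calls = [vc("S1", pos=1), vc("S1", pos=2), vc("S2", pos=3)]
        assert gene_mutation_frequency(calls, 4)["APC"] == pytest.approx(0.5)

    def test_frequencies_match_brute_force(self, default_cohort):
        calls = default_cohort.tumour_calls
        freq = gene_mutation_frequency(calls, 50)
        for gene in list(freq)[:5]:
            carriers = {c.sample_id for c in calls if c.gene == gene}
            assert freq[gene] == len(carriers) / 50

    def test_table4_pathogenic_accounting(self, table4_calls):
        assert count_pathogenic(table4_calls) == (11, 5)

    def test_no_pathogenic(self):
        assert count_pathogenic([vc("S1")]) == (0, 0)

    def test_recurring_pathogenic_counted_once(self):
        calls = [vc(s, clinsig=ClinSig.PATHOGENIC) for s in ("S1", "S2", "S3")]
        assert count_pathogenic(calls) == (1, 1)


def test_cohort_characteristics_age_margin():
    chars = cohort_characteristics(table1_meta())
    assert chars["n_samples"] == 50
    assert chars["age_over_cut"] == 46
    assert chars["pct_age_over_cut"] == pytest.approx(92.0)
    assert chars["msi_counts"] == {"MSI-H": 5, "MSI-L": 5, "MSS": 40}
    assert chars["vital_status_counts"]["deceased"] == 18
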
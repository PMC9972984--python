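"""Per-sample mutation burden, hypermutation, MSI-group statistics and
recurrence/pathogenicity summaries.

Burden is ``somatic_count / callable_mb`` mutations per megabase; a sample is
hypermutated when its rate strictly exceeds 12/Mb.  Group comparison uses a
two-sided Mann-Whitney rank test (exact enumeration for up to 8 samples per
side, normal approximation with continuity correction beyond) and the
association of MSI-H status with hypermutation uses Fisher's exact test.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Optional

import numpy as np
from scipy import stats as sps

from .model import ClinSig, Effect, MsiStatus, Region, SampleMeta, ValidationError, VariantCall

log = logging.getLogger(__name__)

HYPERMUTATION_THRESHOLD = 12.0


def mutation_rate(somatic_count: int, callable_mb: float) -> float:
    """Somatic mutations per megabase of callable genome."""
    if callable_mb <= 0:
        raise ValidationError(f"callable_mb must be positive, got {callable_mb}")
    return somatic_count / callable_mb


def classify_hypermutated(rate: float, threshold: float = HYPERMUTATION_THRESHOLD) -> bool:
    """True iff the rate strictly exceeds the hypermutation threshold
    (>12 mutations/Mb by default); exactly 12/Mb is not hypermutated."""
    return rate > threshold


@dataclass
class BurdenRecord:
    sample_id: str
    somatic_count: int
    rate_per_mb: float
    hypermutated: bool
    msi_status: MsiStatus


def compute_burdens(
    calls: Iterable[VariantCall],
    samples: list[SampleMeta],
    threshold: float = HYPERMUTATION_THRESHOLD,
) -> list[BurdenRecord]:
    """One burden record per sample in ``samples`` (zero-count samples
    included)."""
    counts = Counter(c.sample_id for c in calls)
    out = []
    for meta in samples:
        n = counts.get(meta.sample_id, 0)
        rate = mutation_rate(n, meta.callable_mb)
        out.append(
            BurdenRecord(
                sample_id=meta.sample_id,
                somatic_count=n,
                rate_per_mb=rate,
                hypermutated=classify_hypermutated(rate, threshold),
                msi_status=meta.msi_status,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Rank test


def mann_whitney_two_sided(x: list[float], y: list[float],
                           exact_max_n: int = 8) -> float:
    """Two-sided Mann-Whitney p for samples ``x`` vs ``y``.

    With at most ``exact_max_n`` observations per side the null is evaluated
    by exhaustive enumeration of label assignments, counting assignments with
    a U statistic at least as far from its null mean as observed (ties
    contribute 1/2 to U, so tied data are handled exactly).  Larger samples
    use the normal approximation with tie correction and continuity
    correction.
    """
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be non-empty for the rank test")

    def ustat(a: list[float], b: list[float]) -> float:
        return sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in a for yj in b)

    u_obs = ustat(x, y)
    mu = n1 * n2 / 2.0
    if n1 <= exact_max_n and n2 <= exact_max_n:
        pooled = list(x) + list(y)
        idx = range(n1 + n2)
        hits = 0
        total = comb(n1 + n2, n1)
        dev = abs(u_obs - mu)
        for chosen in combinations(idx, n1):
            chosen_set = set(chosen)
            a = [pooled[i] for i in chosen]
            b = [pooled[i] for i in idx if i not in chosen_set]
            if abs(ustat(a, b) - mu) >= dev - 1e-12:
                hits += 1
        return hits / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


@dataclass
class MsiGroupStats:
    medians: dict[MsiStatus, Optional[float]]
    mannwhitney_p_msih_vs_msil: Optional[float]
    fisher_p_msih_hypermutation: Optional[float]
    contingency: Optional[list[list[int]]] = None


def msi_group_stats(burdens: list[BurdenRecord]) -> MsiGroupStats:
    """Group medians plus the two §key tests: a two-sided rank test on rates
    (MSI-H vs MSI-L) and Fisher's exact test on the 2x2 of MSI-H membership
    against hypermutation.  Degenerate groups yield absent p-values with a
    logged reason rather than errors."""
    by_group: dict[MsiStatus, list[float]] = {g: [] for g in MsiStatus}
    for b in burdens:
        by_group[b.msi_status].append(b.rate_per_mb)
    medians = {
        g: (float(np.median(v)) if v else None) for g, v in by_group.items()
    }
    mw_p = None
    if by_group[MsiStatus.MSI_H] and by_group[MsiStatus.MSI_L]:
        mw_p = mann_whitney_two_sided(by_group[MsiStatus.MSI_H], by_group[MsiStatus.MSI_L])
    else:
        log.warning("rank test skipped: empty MSI-H or MSI-L group")
    fisher_p = None
    table = None
    if burdens:
        a = sum(1 for b in burdens if b.msi_status is MsiStatus.MSI_H and b.hypermutated)
        b_ = sum(1 for b in burdens if b.msi_status is MsiStatus.MSI_H and not b.hypermutated)
        c = sum(1 for b in burdens if b.msi_status is not MsiStatus.MSI_H and b.hypermutated)
        d = sum(1 for b in burdens if b.msi_status is not MsiStatus.MSI_H and not b.hypermutated)
        table = [[a, b_], [c, d]]
        fisher_p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    else:
        log.warning("Fisher test skipped: no burden records")
    return MsiGroupStats(
        medians=medians,
        mannwhitney_p_msih_vs_msil=mw_p,
        fisher_p_msih_hypermutation=fisher_p,
        contingency=table,
    )


# ---------------------------------------------------------------------------
# Distributions and recurrence


def variant_class_distribution(
    calls: Iterable[VariantCall],
) -> tuple[dict[Effect, int], dict[Region, int]]:
    """Exhaustive counts of calls by coding effect and by genomic region."""
    by_effect: Counter = Counter()
    by_region: Counter = Counter()
    for c in calls:
        by_effect[c.effect] += 1
        by_region[c.region] += 1
    return dict(by_effect), dict(by_region)


@dataclass
class RecurrentVariant:
    key: tuple[str, int, str, str]
    gene: str
    aa_change: str
    carriers: list[str]
    carrier_count: int
    novel: bool
    clinsig: ClinSig

    def __post_init__(self) -> None:
        assert self.carrier_count == len(self.carriers) >= 2


def recurrent_variants(
    calls: Iterable[VariantCall], min_carriers: int = 2
) -> list[RecurrentVariant]:
    """Group calls by genomic change and return those seen in at least
    ``min_carriers`` distinct samples, most-recurrent first.

    Recurrence is keyed on (chrom, pos, ref, alt), never on the amino-acid
    label, which can differ across transcript annotations of one change.
    """
    groups: dict[tuple, dict] = {}
    for c in calls:
        g = groups.setdefault(
            c.key,
            {"gene": c.gene, "aa": c.aa_change, "carriers": set(),
             "clinsig": c.clinsig, "novel": c.dbsnp_id is None and c.cosmic_id is None},
        )
        g["carriers"].add(c.sample_id)
    out = []
    for key, g in groups.items():
        if len(g["carriers"]) >= min_carriers:
            out.append(
                RecurrentVariant(
                    key=key,
                    gene=g["gene"],
                    aa_change=g["aa"],
                    carriers=sorted(g["carriers"]),
                    carrier_count=len(g["carriers"]),
                    novel=g["novel"],
                    clinsig=g["clinsig"],
                )
            )
    out.sort(key=lambda r: (-r.carrier_count, r.key[0], r.key[1], r.key[3]))
    return out


def gene_mutation_frequency(
    calls: Iterable[VariantCall], n_samples: int
) -> dict[str, float]:
    """Fraction of samples carrying at least one call per gene; multiple hits
    in one sample count once."""
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    carriers: dict[str, set[str]] = {}
    for c in calls:
        if c.gene:
            carriers.setdefault(c.gene, set()).add(c.sample_id)
    return {g: len(s) / n_samples for g, s in sorted(carriers.items())}


def count_pathogenic(calls: Iterable[VariantCall]) -> tuple[int, int]:
    """Distinct pathogenic genomic changes and the distinct genes carrying
    them; a change recurring across samples is counted once."""
    keys = set()
    genes = set()
    for c in calls:
        if c.clinsig is ClinSig.PATHOGENIC:
            keys.add(c.key)
            genes.add(c.gene)
    return len(keys), len(genes)


def cohort_characteristics(samples: list[SampleMeta], age_cut: float = 50.0) -> dict:
    """Clinical margin summary: counts and percentages by age group, plus raw
    counts of each categorical clinical field."""
    n = len(samples)
    ages = [float(m.clinical["age"]) for m in samples if "age" in m.clinical]
    over = sum(1 for a in ages if a > age_cut)
    under = len(ages) - over
    out = {
        "n_samples": n,
        "age_over_cut": over,
        "age_under_cut": under,
        "pct_age_over_cut": 100.0 * over / n if n else 0.0,
        "msi_counts": dict(Counter(m.msi_status.value for m in samples)),
    }
    for fld in ("gender", "ethnicity", "stage", "differentiation", "vital_status"):
        vals = [m.clinical[fld] for m in samples if fld in m.clinical]
        if vals:
            out[f"{fld}_counts"] = dict(Counter(vals))
    return out
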
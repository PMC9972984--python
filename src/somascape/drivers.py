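"""Simplified significantly-mutated-gene and hotspot-driver tests.

These are documented simplifications, not ports of MutSigCV or
oncodrive-style tools: the SMG test scores each gene's variant count against
a uniform per-bp background with an exact binomial tail, and the hotspot
test scores positional clustering against a permutation null that scatters
the gene's variants uniformly over its length.  Both adjust across genes by
Benjamini-Hochberg.  No covariate background model (replication timing,
expression) is attempted; output from these tests ranks candidate genes in
a cohort, it does not reproduce any published covariate-adjusted p-values.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Optional

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .fixtures import Gene, gene_panel
from .model import ValidationError, VariantCall

log = logging.getLogger(__name__)


@dataclass
class GeneTestResult:
    gene: str
    carriers: int
    variant_count: int
    gene_length: int
    p_value: float
    q_value: float
    score: Optional[float] = None  # hotspot clustering fraction, where applicable


def _bh(results: list[GeneTestResult]) -> list[GeneTestResult]:
    if results:
        q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    results.sort(key=lambda r: (r.p_value, r.gene))
    return results


def smg_binomial(
    calls: Iterable[VariantCall],
    panel: list[Gene],
    n_samples: int,
    background_rate: float,
) -> list[GeneTestResult]:
    """Uniform-background SMG test.

    Per gene, the observed variant count is compared to Binomial(n, r) with
    n = n_samples x gene_length trials at per-bp-per-sample rate
    ``background_rate``; p is the exact upper tail P(X >= observed).  Genes
    seen in the calls but absent from the panel are skipped with a warning.
    """
    if background_rate <= 0:
        raise ValidationError("background_rate must be positive")
    by_gene: dict[str, list[VariantCall]] = {}
    for c in calls:
        if c.gene:
            by_gene.setdefault(c.gene, []).append(c)
    lengths = {g.name: g.length for g in panel}
    results = []
    for gene, gcalls in sorted(by_gene.items()):
        if gene not in lengths:
            log.warning("gene %s absent from panel; skipped", gene)
            continue
        if lengths[gene] <= 0:
            raise ValidationError(f"gene {gene} has non-positive length")
        n_trials = n_samples * lengths[gene]
        observed = len(gcalls)
        p = float(sps.binom.sf(observed - 1, n_trials, background_rate))
        results.append(
            GeneTestResult(
                gene=gene,
                carriers=len({c.sample_id for c in gcalls}),
                variant_count=observed,
                gene_length=lengths[gene],
                p_value=p,
                q_value=float("nan"),
            )
        )
    return _bh(results)


def max_position_count(positions: Iterable[int]) -> int:
    return max(Counter(positions).values())


def hotspot_cluster_p(
    n_variants: int,
    gene_length: int,
    observed_max: int,
    rng: np.random.Generator,
    n_permutations: int = 2000,
    exact_limit: int = 10**5,
) -> float:
    """P(max per-position multiplicity >= observed) when ``n_variants`` are
    scattered uniformly over ``gene_length`` positions.

    Exhaustive enumeration over all ``gene_length ** n_variants`` placements
    when that state space is small enough, else seeded Monte Carlo with
    add-one smoothing (so a Monte Carlo p is never exactly zero).
    """
    if observed_max <= 1:
        return 1.0
    if gene_length**n_variants <= exact_limit:
        hits = 0
        total = gene_length**n_variants
        for placement in product(range(gene_length), repeat=n_variants):
            if max(Counter(placement).values()) >= observed_max:
                hits += 1
        return hits / total
    hits = 0
    for _ in range(n_permutations):
        placed = rng.integers(0, gene_length, size=n_variants)
        if np.bincount(placed).max() >= observed_max:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def hotspot_driver_score(
    calls: Iterable[VariantCall],
    n_samples: int,
    fdr_threshold: float = 0.1,
    panel: Optional[list[Gene]] = None,
    n_permutations: int = 2000,
    seed: int = 0,
) -> list[GeneTestResult]:
    """Positional-clustering driver test.

    Per gene with at least two variants, ``score`` is the fraction of the
    gene's variants at its single most-recurrent genomic position; the
    p-value compares the observed maximum multiplicity to the uniform
    scattering null of :func:`hotspot_cluster_p`.  Genes with fewer than two
    variants carry no clustering signal and are excluded.
    """
    panel = panel or gene_panel()
    lengths = {g.name: g.length for g in panel}
    by_gene: dict[str, list[VariantCall]] = {}
    for c in calls:
        if c.gene:
            by_gene.setdefault(c.gene, []).append(c)
    rng = np.random.default_rng(seed)
    results = []
    for gene, gcalls in sorted(by_gene.items()):
        if len(gcalls) < 2:
            continue
        if gene not in lengths:
            log.warning("gene %s absent from panel; skipped", gene)
            continue
        positions = [c.pos for c in gcalls]
        m = max_position_count(positions)
        p = hotspot_cluster_p(
            len(gcalls), lengths[gene], m, rng, n_permutations=n_permutations
        )
        results.append(
            GeneTestResult(
                gene=gene,
                carriers=len({c.sample_id for c in gcalls}),
                variant_count=len(gcalls),
                gene_length=lengths[gene],
                p_value=p,
                q_value=float("nan"),
                score=m / len(gcalls),
            )
        )
    return _bh(results)
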
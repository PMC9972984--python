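"""Somatic variant prioritization chain with per-stage accounting.

The chain applies, in fixed order: quality (> Q30, strict), population
allele frequency (remove if any configured database reports AF above 5%,
strict; absent frequencies never fail), functional relevance (exonic or
splicing region, annotated gene, amino-acid-changing effect), germline
subtraction (drop tumour calls whose genomic change also appears in the
matched normal), and finally novelty flagging (novel iff absent from both
dbSNP and COSMIC with a well-covered, variant-free normal).  The four
removal stages are pure predicates on individual calls, so the survivor set
is invariant under any permutation of them; the trace records the fixed
canonical order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import (
    AF_DATABASES,
    Effect,
    Region,
    ValidationError,
    VariantCall,
)

STAGES = ("quality", "population_af", "functional", "germline_subtraction", "novelty")


@dataclass
class FilterConfig:
    """Thresholds of the prioritization chain.

    All numeric thresholds are strict, matching the study's wording
    ("above Q30", "more than 5%"): boundary values survive.
    """

    min_quality: float = 30.0
    max_pop_af: float = 0.05
    af_databases: tuple[str, ...] = AF_DATABASES
    keep_regions: frozenset = frozenset({Region.EXONIC, Region.SPLICING})
    drop_effects: frozenset = frozenset({Effect.SYNONYMOUS, Effect.OTHER})
    novel_min_normal_depth: int = 10
    novel_max_normal_alt: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_pop_af <= 1.0:
            raise ValidationError(f"max_pop_af must be in [0,1], got {self.max_pop_af}")
        if self.novel_min_normal_depth < 0 or self.novel_max_normal_alt < 0:
            raise ValidationError("novelty coverage thresholds must be non-negative")
        self.keep_regions = frozenset(Region(r) for r in self.keep_regions)
        self.drop_effects = frozenset(Effect(e) for e in self.drop_effects)


@dataclass
class FilterTrace:
    """Per-stage survivor counts plus each removed variant's first failing
    stage."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    removal_reason: dict[tuple, str] = field(default_factory=dict)

    def record(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append((name, n_in, n_out))

    @property
    def removed_per_stage(self) -> dict[str, int]:
        return {name: n_in - n_out for name, n_in, n_out in self.stages}


def filter_quality(calls: list[VariantCall], config: FilterConfig) -> list[VariantCall]:
    """Keep calls with quality strictly above the threshold."""
    for c in calls:
        if c.quality is None or (isinstance(c.quality, float) and math.isnan(c.quality)):
            raise ValidationError(f"call at {c.chrom}:{c.pos} has no quality score")
    return [c for c in calls if c.quality > config.min_quality]


def _af_fails(call: VariantCall, config: FilterConfig) -> bool:
    present = [call.pop_af[db] for db in config.af_databases if db in call.pop_af]
    for af in present:
        if not 0.0 <= af <= 1.0:
            raise ValidationError(
                f"allele frequency {af} outside [0,1] at {call.chrom}:{call.pos}"
            )
    return bool(present) and max(present) > config.max_pop_af


def filter_population_af(calls: list[VariantCall], config: FilterConfig) -> list[VariantCall]:
    """Remove population-common variants: a call is dropped iff the maximum
    AF over the configured databases (ignoring absent entries) strictly
    exceeds the threshold.  Calls unobserved in every database are kept."""
    return [c for c in calls if not _af_fails(c, config)]


def _functional_ok(call: VariantCall, config: FilterConfig) -> bool:
    return (
        call.region in config.keep_regions
        and bool(call.gene)
        and call.effect not in config.drop_effects
    )


def filter_functional(calls: list[VariantCall], config: FilterConfig) -> list[VariantCall]:
    """Keep amino-acid-changing calls in annotated genes within the kept
    regions (default exonic/splicing)."""
    return [c for c in calls if _functional_ok(c, config)]


def subtract_germline(
    tumour_calls: list[VariantCall], normal_calls: list[VariantCall]
) -> list[VariantCall]:
    """Remove tumour calls whose (chrom, pos, ref, alt) also occurs in the
    matched normal sample's calls.  Both lists must belong to one patient."""
    sids = {c.sample_id for c in tumour_calls} | {c.sample_id for c in normal_calls}
    if len(sids) > 1:
        raise ValidationError(
            f"subtract_germline expects a single patient pair, got samples {sorted(sids)}"
        )
    normal_keys = {c.key for c in normal_calls}
    return [c for c in tumour_calls if c.key not in normal_keys]


def classify_novel(
    calls: list[VariantCall], config: FilterConfig
) -> list[tuple[VariantCall, bool]]:
    """Flag each call as novel (True) or known (False).

    Novel requires absence from BOTH catalog databases plus a normal sample
    with at least ``novel_min_normal_depth`` reads and at most
    ``novel_max_normal_alt`` variant reads.  This is a flag, never a removal.
    """
    out = []
    for c in calls:
        novel = (
            c.dbsnp_id is None
            and c.cosmic_id is None
            and c.normal_depth >= config.novel_min_normal_depth
            and c.normal_alt <= config.novel_max_normal_alt
        )
        out.append((c, novel))
    return out


def run_prioritization(
    tumour_calls: list[VariantCall],
    normal_calls: list[VariantCall],
    config: FilterConfig | None = None,
) -> tuple[list[tuple[VariantCall, bool]], FilterTrace]:
    """Run the full chain over a (possibly multi-sample) cohort.

    Germline subtraction is applied per patient pair.  Returns the surviving
    calls with their novelty flags, sorted by (sample, chrom, pos, alt), and
    the per-stage :class:`FilterTrace`.
    """
    config = config or FilterConfig()
    trace = FilterTrace()

    def _mark(removed: list[VariantCall], stage: str) -> None:
        for c in removed:
            trace.removal_reason.setdefault((c.sample_id, *c.key), stage)

    current = list(tumour_calls)
    survivors = filter_quality(current, config)
    _mark([c for c in current if not c.quality > config.min_quality], STAGES[0])
    trace.record(STAGES[0], len(current), len(survivors))
    current = survivors

    survivors = filter_population_af(current, config)
    _mark([c for c in current if _af_fails(c, config)], STAGES[1])
    trace.record(STAGES[1], len(current), len(survivors))
    current = survivors

    survivors = filter_functional(current, config)
    _mark([c for c in current if not _functional_ok(c, config)], STAGES[2])
    trace.record(STAGES[2], len(current), len(survivors))
    current = survivors

    normal_by_sample: dict[str, set] = {}
    for c in normal_calls:
        normal_by_sample.setdefault(c.sample_id, set()).add(c.key)
    survivors = [
        c for c in current if c.key not in normal_by_sample.get(c.sample_id, set())
    ]
    _mark(
        [c for c in current if c.key in normal_by_sample.get(c.sample_id, set())],
        STAGES[3],
    )
    trace.record(STAGES[3], len(current), len(survivors))
    current = survivors

    flagged = classify_novel(current, config)
    trace.record(STAGES[4], len(current), len(flagged))

    flagged.sort(key=lambda cf: (cf[0].sample_id, cf[0].chrom, cf[0].pos, cf[0].alt))
    return flagged, trace
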
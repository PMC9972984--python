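"""Rule-based matching of somatic alterations to drug response/resistance.

A transparent, editable TSV of biomarker rules (gene + alteration pattern →
drug, predicted effect, evidence level) stands in for web-service clinical
annotation, so runs are reproducible and offline.  The bundled default rules
are an illustrative fixture derived from published colorectal-cancer
biomarker statements, not clinical guidance.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

from .model import (
    FRAMESHIFT_EFFECTS,
    TRUNCATING_EFFECTS,
    Effect,
    ValidationError,
    VariantCall,
)


class PatternKind(str, enum.Enum):
    EXACT_AA = "exact_aa"
    TRUNCATING = "truncating"
    FRAMESHIFT = "frameshift"
    ANY_NONSYNONYMOUS = "any_nonsynonymous"
    POSITION_CLASS = "position_class"


class DrugEffect(str, enum.Enum):
    RESPONSIVE = "responsive"
    RESISTANT = "resistant"


class Evidence(str, enum.Enum):
    FDA = "FDA"
    NCCN = "NCCN"
    LATE_TRIALS = "late_trials"
    EARLY_TRIALS = "early_trials"
    CASE_REPORT = "case_report"
    PRE_CLINICAL = "pre_clinical"


#: Total order on evidence, strongest first; match lists sort by this.
EVIDENCE_RANK = {e: i for i, e in enumerate(Evidence)}

_AA_SPLIT = re.compile(r"[,;|]")


def _normalize_aa(label: str) -> str:
    label = label.strip()
    if label.startswith("p."):
        label = label[2:]
    return label.upper()


@dataclass(frozen=True)
class DruggabilityRule:
    """One biomarker rule: alterations of ``gene`` matching ``pattern_kind``
    (with ``pattern_payload`` where the kind needs one) predict ``effect``
    for ``drug`` at the stated ``evidence`` level in ``disease``."""

    gene: str
    pattern_kind: PatternKind
    pattern_payload: str
    drug: str
    effect: DrugEffect
    evidence: Evidence
    disease: str = "COREAD"

    def __post_init__(self) -> None:
        if self.pattern_kind is PatternKind.EXACT_AA and not self.pattern_payload:
            raise ValidationError(f"rule for {self.gene}: exact_aa needs an amino-acid payload")
        if self.pattern_kind is PatternKind.POSITION_CLASS:
            try:
                start, end = self._position_range()
            except Exception as exc:
                raise ValidationError(
                    f"rule for {self.gene}: position_class payload must be 'start-end', "
                    f"got {self.pattern_payload!r}"
                ) from exc
            if start > end:
                raise ValidationError(f"rule for {self.gene}: empty position range")

    def _position_range(self) -> tuple[int, int]:
        start, end = self.pattern_payload.split("-")
        return int(start), int(end)

    def matches(self, call: VariantCall) -> bool:
        if call.gene != self.gene:
            return False
        kind = self.pattern_kind
        if kind is PatternKind.EXACT_AA:
            wanted = _normalize_aa(self.pattern_payload)
            return any(_normalize_aa(a) == wanted for a in _AA_SPLIT.split(call.aa_change) if a)
        if kind is PatternKind.TRUNCATING:
            return call.effect in TRUNCATING_EFFECTS
        if kind is PatternKind.FRAMESHIFT:
            return call.effect in FRAMESHIFT_EFFECTS
        if kind is PatternKind.ANY_NONSYNONYMOUS:
            return call.effect is not Effect.SYNONYMOUS
        # position_class
        start, end = self._position_range()
        return start <= call.pos <= end

    @classmethod
    def from_row(cls, rec: dict[str, str], line: int | None = None) -> "DruggabilityRule":
        try:
            return cls(
                gene=rec["gene"],
                pattern_kind=PatternKind(rec["pattern_kind"]),
                pattern_payload="" if rec["pattern_payload"] == "." else rec["pattern_payload"],
                drug=rec["drug"],
                effect=DrugEffect(rec["effect"]),
                evidence=Evidence(rec["evidence"]),
                disease=rec["disease"],
            )
        except (ValueError, KeyError, ValidationError) as exc:
            where = f" (row {line})" if line else ""
            raise ValidationError(f"malformed druggability rule{where}: {exc}") from exc

    def to_row(self) -> list[str]:
        return [
            self.gene, self.pattern_kind.value, self.pattern_payload or ".",
            self.drug, self.effect.value, self.evidence.value, self.disease,
        ]


@dataclass(frozen=True)
class RuleMatch:
    variant: VariantCall
    rule: DruggabilityRule


@dataclass
class ActionabilityReport:
    """Per-patient druggability matches plus a cohort summary surface."""

    matches: dict[str, list[RuleMatch]] = field(default_factory=dict)

    def has_druggable(self, sample_id: str) -> bool:
        return bool(self.matches.get(sample_id))

    @property
    def druggable_samples(self) -> list[str]:
        return sorted(s for s, m in self.matches.items() if m)


@dataclass
class CohortActionability:
    n_samples: int
    n_druggable: int
    fraction_druggable: float
    min_matches: int
    max_matches: int
    per_rule_carriers: dict[tuple[str, str], int]


def _match_sort_key(m: RuleMatch):
    v, r = m.variant, m.rule
    return (EVIDENCE_RANK[r.evidence], r.gene, v.chrom, v.pos, v.alt, r.drug, r.effect.value)


def match_rules(calls: list[VariantCall], rules: list[DruggabilityRule],
                disease: str = "COREAD") -> ActionabilityReport:
    """Match every call against every rule (same disease); a variant may match
    several rules and every match is recorded with its evidence level.

    Output is deterministic: independent of rule order and call order, matches
    per patient sorted strongest evidence first.
    """
    report = ActionabilityReport()
    for call in calls:
        report.matches.setdefault(call.sample_id, [])
        for rule in rules:
            if rule.disease == disease and rule.matches(call):
                report.matches[call.sample_id].append(RuleMatch(call, rule))
    for sid in report.matches:
        report.matches[sid].sort(key=_match_sort_key)
    return report


def summarize_actionability(report: ActionabilityReport, n_samples: int) -> CohortActionability:
    """Cohort-level actionability: fraction of patients with >=1 match,
    per-patient match-count range, and per-rule distinct-carrier counts."""
    counts = [len(m) for m in report.matches.values()]
    druggable = [c for c in counts if c > 0]
    per_rule: dict[tuple[str, str], dict] = {}
    carriers: dict[tuple[str, str], set[str]] = {}
    for sid, matches in report.matches.items():
        for m in matches:
            key = (m.rule.gene, m.rule.drug)
            carriers.setdefault(key, set()).add(sid)
    return CohortActionability(
        n_samples=n_samples,
        n_druggable=len(druggable),
        fraction_druggable=len(druggable) / n_samples if n_samples else 0.0,
        min_matches=min(druggable) if druggable else 0,
        max_matches=max(druggable) if druggable else 0,
        per_rule_carriers={k: len(v) for k, v in sorted(carriers.items())},
    )
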
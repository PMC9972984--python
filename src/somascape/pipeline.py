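"""End-to-end orchestration: simulate (or load) a cohort, prioritize, then
summarize burden, signatures, drivers and actionability into one bundle.

A run produces eight artifacts in ``out_dir`` — survivors.tsv, trace.tsv,
burden.tsv, recurrent.tsv, signature_fit.tsv, smg.tsv, actionability.tsv and
summary.json — and every numeric in the JSON summary is re-derivable from the
stage outputs in the same bundle.  Execution is single-process and fully
deterministic: identical config + seed gives byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import drivers as drv
from . import druggability as drug
from . import landscape as land
from . import signatures as sig
from .fixtures import default_rules, gene_panel, reference_signatures
from .io import expand_carriers, read_signature_matrix, read_table, write_table
from .model import ConfigurationError, SomascapeError
from .prioritize import FilterConfig, run_prioritization
from .synth import CohortConfig, simulate_cohort

log = logging.getLogger(__name__)

ARTIFACTS = (
    "survivors.tsv", "trace.tsv", "burden.tsv", "recurrent.tsv",
    "signature_fit.tsv", "smg.tsv", "actionability.tsv", "summary.json",
)


@dataclass
class RunConfig:
    """One pipeline run.

    ``mode`` is ``"simulate"`` (generate a synthetic cohort under ``cohort``)
    or ``"analyze"`` (load ``variants_path``/``metadata_path`` tables).  The
    seed drives every stochastic stage.
    """

    out_dir: str | Path = "somascape_run"
    mode: str = "simulate"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    variants_path: Optional[str] = None
    metadata_path: Optional[str] = None
    rules_path: Optional[str] = None
    reference_path: Optional[str] = None
    signature_mode: str = "refit"
    k: int = 3
    hypermutation_threshold: float = 12.0
    smg_background_rate: Optional[float] = None
    fdr_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.signature_mode not in ("refit", "denovo"):
            raise ConfigurationError(f"unknown signature mode {self.signature_mode!r}")
        if self.mode == "analyze" and not self.variants_path:
            raise ConfigurationError("analyze mode requires variants_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "cohort" in raw:
            raw["cohort"] = CohortConfig(**raw["cohort"])
        if "filters" in raw:
            raw["filters"] = FilterConfig(**raw["filters"])
        return cls(**raw)


def _fmt(x: float) -> str:
    return repr(round(float(x), 10))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except SomascapeError as exc:
                raise SomascapeError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the summary dict (also written as
    summary.json).  See module docstring for the artifact list."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = (
        read_signature_matrix(config.reference_path)
        if config.reference_path
        else reference_signatures()
    )
    rules = (
        read_table(config.rules_path, schema="rules")
        if config.rules_path
        else default_rules()
    )
    panel = gene_panel()
    summary: dict = {"mode": config.mode, "seed": config.seed}

    if config.mode == "simulate":
        cohort_cfg = CohortConfig(**{**config.cohort.__dict__, "seed": config.seed})
        sim = simulate_cohort(cohort_cfg, reference)
        tumour, normal, samples = sim.tumour_calls, sim.normal_calls, sim.samples
        log.info("simulate: %d tumour calls, %d normal calls, %d samples",
                 len(tumour), len(normal), len(samples))
    else:
        records = read_table(config.variants_path, schema="variants")
        tumour = expand_carriers(records)
        normal = []
        samples = (
            read_table(config.metadata_path, schema="metadata")
            if config.metadata_path
            else []
        )
        log.info("load: %d calls from %s", len(tumour), config.variants_path)

    flagged, trace = run_prioritization(tumour, normal, config.filters)
    survivors = [c for c, _ in flagged]
    novelty = {(c.sample_id, *c.key): flag for c, flag in flagged}
    write_table(survivors, out / "survivors.tsv", schema="variants")
    trace_lines = ["stage\tin\tout\tremoved"]
    for name, n_in, n_out in trace.stages:
        trace_lines.append(f"{name}\t{n_in}\t{n_out}\t{n_in - n_out}")
    (out / "trace.tsv").write_text("\n".join(trace_lines) + "\n", encoding="utf-8")
    summary["prioritization"] = {
        "input_calls": trace.stages[0][1] if trace.stages else 0,
        "survivors": len(survivors),
        "per_stage": {name: [n_in, n_out] for name, n_in, n_out in trace.stages},
        "novel_flagged": sum(1 for f in novelty.values() if f),
    }
    n_samples = len(samples) if samples else len({c.sample_id for c in tumour}) or 1

    # burden + MSI statistics (needs per-sample metadata)
    if samples:
        burdens = land.compute_burdens(survivors, samples, config.hypermutation_threshold)
        rows = ["sample_id\tmsi_status\tsomatic_count\trate_per_mb\thypermutated"]
        for b in burdens:
            rows.append(
                f"{b.sample_id}\t{b.msi_status.value}\t{b.somatic_count}"
                f"\t{_fmt(b.rate_per_mb)}\t{int(b.hypermutated)}"
            )
        (out / "burden.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")
        stats = land.msi_group_stats(burdens)
        summary["burden"] = {
            "n_hypermutated": sum(b.hypermutated for b in burdens),
            "median_rate_per_group": {
                g.value: (None if m is None else round(m, 6))
                for g, m in stats.medians.items()
            },
            "mannwhitney_p_msih_vs_msil": stats.mannwhitney_p_msih_vs_msil,
            "fisher_p_msih_hypermutation": stats.fisher_p_msih_hypermutation,
        }
    else:
        (out / "burden.tsv").write_text(
            "sample_id\tmsi_status\tsomatic_count\trate_per_mb\thypermutated\n",
            encoding="utf-8",
        )
        summary["burden"] = None

    # recurrence, class distribution, pathogenic/novel accounting
    rec = land.recurrent_variants(survivors)
    rows = ["chrom\tpos\tref\talt\tgene\taa_change\tcarrier_count\tcarriers\tnovel\tclinsig"]
    for r in rec:
        rows.append(
            "\t".join(
                [r.key[0], str(r.key[1]), r.key[2], r.key[3], r.gene, r.aa_change or ".",
                 str(r.carrier_count), ",".join(r.carriers), str(int(r.novel)),
                 r.clinsig.value]
            )
        )
    (out / "recurrent.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    by_effect, by_region = land.variant_class_distribution(survivors)
    n_path, n_path_genes = land.count_pathogenic(survivors)
    novel_keys = {k[1:] for k, f in novelty.items() if f}
    summary["landscape"] = {
        "recurrent_variants": len(rec),
        "recurrent_genes": len({r.gene for r in rec}),
        "top_recurrent": [
            {"gene": r.gene, "aa_change": r.aa_change, "carriers": r.carrier_count}
            for r in rec[:5]
        ],
        "effect_distribution": {e.value: n for e, n in sorted(by_effect.items())},
        "region_distribution": {r.value: n for r, n in sorted(by_region.items())},
        "pathogenic_variants": n_path,
        "pathogenic_genes": n_path_genes,
        "novel_variants": len(novel_keys),
        "gene_frequency": {
            g: round(f, 6)
            for g, f in sorted(
                land.gene_mutation_frequency(survivors, n_samples).items(),
                key=lambda kv: (-kv[1], kv[0]),
            )[:10]
        },
    }

    # signatures (SNVs with context only; skipped when contexts are absent)
    snvs = [c for c in survivors if c.is_snv and c.context3 is not None]
    if snvs:
        catalog = sig.build_catalog(snvs, scope="cohort")
        if config.signature_mode == "refit":
            fit = sig.refit_exposures(catalog, reference)
            rows = ["signature\texposure\tproportion\tcosine_to_catalog"]
            for i, name in enumerate(fit.names):
                rows.append(
                    f"{name}\t{_fmt(fit.exposures[i])}\t{_fmt(fit.proportions[i])}"
                    f"\t{_fmt(fit.cosine_to_reference[name])}"
                )
            summary["signatures"] = {
                "mode": "refit",
                "snvs_in_catalog": catalog.total,
                "proportions": {
                    n: round(float(p), 6) for n, p in zip(fit.names, fit.proportions)
                },
                "residual_norm": round(fit.residual_norm, 6),
            }
        else:
            per_sample = {}
            for c in snvs:
                per_sample.setdefault(c.sample_id, []).append(c)
            catalogs = [
                sig.build_catalog(v, scope=s) for s, v in sorted(per_sample.items())
            ]
            res = sig.extract_denovo(catalogs, config.k, config.seed, reference=reference)
            rows = ["signature\tbest_match\tcosine"]
            for name in res.signatures.names:
                rows.append(
                    f"{name}\t{res.best_match.get(name, '.')}"
                    f"\t{_fmt(res.match_cosine.get(name, float('nan')))}"
                )
            summary["signatures"] = {
                "mode": "denovo",
                "k": config.k,
                "match_cosine": {
                    n: round(c, 6) for n, c in sorted(res.match_cosine.items())
                },
            }
        (out / "signature_fit.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    else:
        (out / "signature_fit.tsv").write_text("signature\texposure\n", encoding="utf-8")
        summary["signatures"] = None

    # driver tests
    total_len = sum(g.length for g in panel)
    bg = config.smg_background_rate or max(
        len(survivors) / (n_samples * total_len), 1e-12
    )
    smg = drv.smg_binomial(survivors, panel, n_samples, bg)
    hot = drv.hotspot_driver_score(
        survivors, n_samples, config.fdr_threshold, panel=panel, seed=config.seed
    )
    rows = [
        "# uniform-background binomial SMG test and uniform-scatter hotspot test; "
        "no covariate background model",
        "test\tgene\tcarriers\tvariant_count\tgene_length\tscore\tp_value\tq_value",
    ]
    for r in smg:
        rows.append(
            f"binomial\t{r.gene}\t{r.carriers}\t{r.variant_count}\t{r.gene_length}"
            f"\t.\t{_fmt(r.p_value)}\t{_fmt(r.q_value)}"
        )
    for r in hot:
        rows.append(
            f"hotspot\t{r.gene}\t{r.carriers}\t{r.variant_count}\t{r.gene_length}"
            f"\t{_fmt(r.score)}\t{_fmt(r.p_value)}\t{_fmt(r.q_value)}"
        )
    (out / "smg.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    summary["drivers"] = {
        "background_rate": float(bg),
        "smg_significant": [r.gene for r in smg if r.q_value < config.fdr_threshold],
        "hotspot_significant": [r.gene for r in hot if r.q_value < config.fdr_threshold],
    }

    # actionability
    report = drug.match_rules(survivors, rules)
    act = drug.summarize_actionability(report, n_samples)
    rows = [
        "# rules: paper-derived fixture, not clinical guidance",
        "sample_id\tgene\tchrom\tpos\tref\talt\taa_change\tdrug\teffect\tevidence",
    ]
    for sid in sorted(report.matches):
        for m in report.matches[sid]:
            v, r = m.variant, m.rule
            rows.append(
                f"{sid}\t{r.gene}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}"
                f"\t{v.aa_change or '.'}\t{r.drug}\t{r.effect.value}\t{r.evidence.value}"
            )
    (out / "actionability.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    summary["actionability"] = {
        "n_samples": act.n_samples,
        "n_druggable": act.n_druggable,
        "fraction_druggable": round(act.fraction_druggable, 6),
        "match_count_range": [act.min_matches, act.max_matches],
    }

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary
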
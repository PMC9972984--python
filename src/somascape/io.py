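"""Readers and writers for the package's external representations.

Everything on disk is plain text: VCF 4.2 for variant calls, tab-delimited
tables with a header row for variant/annotation/rules/metadata tables, and a
TSV with a ``context`` column for signature matrices.  Writers emit UTF-8,
tab-delimited, ``"."`` for absent values; coordinates are 1-based throughout.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .channels import CHANNEL_INDEX, CHANNELS
from .model import (
    AF_DATABASES,
    ClinSig,
    ConfigurationError,
    Effect,
    FormatError,
    MsiStatus,
    Prediction,
    Region,
    SampleMeta,
    SchemaError,
    SignatureMatrix,
    ValidationError,
    VariantCall,
)

log = logging.getLogger(__name__)

ABSENT = "."

# ---------------------------------------------------------------------------
# ANNOVAR-style INFO dialect

_ANNOVAR_REGION = {
    "exonic": Region.EXONIC,
    "splicing": Region.SPLICING,
    "exonic;splicing": Region.EXONIC,
    "intronic": Region.INTRONIC,
    "UTR3": Region.UTR3,
    "UTR5": Region.UTR5,
    "upstream": Region.UPSTREAM,
    "downstream": Region.DOWNSTREAM,
    "intergenic": Region.INTERGENIC,
}

_ANNOVAR_EFFECT = {
    "nonsynonymous_SNV": Effect.MISSENSE,
    "synonymous_SNV": Effect.SYNONYMOUS,
    "stopgain": Effect.NONSENSE,
    "stoploss": Effect.STOPLOSS,
    "frameshift_insertion": Effect.FRAMESHIFT_INS,
    "frameshift_deletion": Effect.FRAMESHIFT_DEL,
    "nonframeshift_insertion": Effect.INFRAME_INS,
    "nonframeshift_deletion": Effect.INFRAME_DEL,
}

_ANNOVAR_AF_KEYS = {
    "1000g": "1000g2015aug_all",
    "exac": "ExAC_ALL",
    "esp6500": "esp6500siv2_all",
}

_CLNSIG = {
    "Pathogenic": ClinSig.PATHOGENIC,
    "Likely_pathogenic": ClinSig.PATHOGENIC,
    "Benign": ClinSig.BENIGN,
    "Likely_benign": ClinSig.BENIGN,
    "Uncertain_significance": ClinSig.VUS,
}

DIALECTS = ("annovar",)


def _info_str(info, key: str) -> str | None:
    val = info.get(key)
    if val is None:
        return None
    if isinstance(val, bytes):
        val = val.decode()
    val = str(val)
    return None if val in (".", "") else val


def _parse_prediction(raw: str | None, damaging: set[str]) -> Prediction:
    if raw is None:
        return Prediction.ABSENT
    return Prediction.DAMAGING if raw in damaging else Prediction.TOLERATED


def read_vcf(
    path: str | Path, sample_id: str, annotation_dialect: str = "annovar"
) -> list[VariantCall]:
    """Read a (possibly multi-sample) VCF into :class:`VariantCall` records.

    Multi-allelic records are split into one call per alternate allele.
    Tumour and normal genotype columns are located by sample name
    (case-insensitive ``tumor``/``normal`` substrings), falling back to
    column order (first = tumour).  Annotations missing from INFO map to
    absent, never to sentinel numbers.
    """
    if annotation_dialect not in DIALECTS:
        raise ConfigurationError(
            f"unknown annotation dialect {annotation_dialect!r}; known: {DIALECTS}"
        )
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise FormatError(f"cannot parse VCF header of {path}: {exc}") from exc

    samples = list(vcf.samples)
    t_idx, n_idx = _locate_pair(samples)

    calls: list[VariantCall] = []
    for rec in vcf:
        info = rec.INFO
        gene = _info_str(info, "Gene.refGene") or ""
        if gene == "NONE":
            gene = ""
        region = _ANNOVAR_REGION.get(_info_str(info, "Func.refGene") or "", Region.UNKNOWN)
        effect = _ANNOVAR_EFFECT.get(_info_str(info, "ExonicFunc.refGene") or "", Effect.OTHER)
        aa_change = _info_str(info, "AAChange.refGene") or ""
        pop_af: dict[str, float] = {}
        for db, key in _ANNOVAR_AF_KEYS.items():
            raw = _info_str(info, key)
            if raw is not None:
                pop_af[db] = float(raw)
        dbsnp = _info_str(info, "avsnp144")
        cosmic = _info_str(info, "cosmic70")
        clinsig = _CLNSIG.get(_info_str(info, "CLNSIG") or "", ClinSig.ABSENT)
        sift = _parse_prediction(_info_str(info, "SIFT_pred"), {"D"})
        polyphen = _parse_prediction(_info_str(info, "Polyphen2_HDIV_pred"), {"D", "P"})
        context3 = _info_str(info, "CONTEXT3")

        ad = rec.format("AD")
        for i, alt in enumerate(rec.ALT):
            td, ta = _allele_depths(ad, t_idx, i)
            nd, na = _allele_depths(ad, n_idx, i)
            calls.append(
                VariantCall(
                    sample_id=sample_id,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF.upper(),
                    alt=alt.upper(),
                    gene=gene,
                    region=region,
                    effect=effect,
                    aa_change=aa_change,
                    quality=float(rec.QUAL) if rec.QUAL is not None else 0.0,
                    tumor_depth=td,
                    tumor_alt=ta,
                    normal_depth=nd,
                    normal_alt=na,
                    pop_af=dict(pop_af),
                    dbsnp_id=dbsnp,
                    cosmic_id=cosmic,
                    clinsig=clinsig,
                    sift=sift,
                    polyphen=polyphen,
                    context3=context3,
                )
            )
    return calls


def _locate_pair(samples: Sequence[str]) -> tuple[int | None, int | None]:
    t_idx = n_idx = None
    for i, name in enumerate(samples):
        low = name.lower()
        if "tumor" in low or "tumour" in low:
            t_idx = i
        elif "normal" in low or "blood" in low:
            n_idx = i
    if t_idx is None and samples:
        t_idx = 0
        if n_idx is None and len(samples) > 1:
            n_idx = 1
    return t_idx, n_idx


def _allele_depths(ad, sample_idx: int | None, alt_idx: int) -> tuple[int, int]:
    if ad is None or sample_idx is None:
        return 0, 0
    row = ad[sample_idx]
    row = [int(x) for x in np.atleast_1d(row) if int(x) >= 0]
    if not row:
        return 0, 0
    depth = sum(row)
    alt = row[alt_idx + 1] if alt_idx + 1 < len(row) else 0
    return depth, alt


def write_vcf(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls as a minimal annotated VCF 4.2 with TUMOR/NORMAL columns."""
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=Gene.refGene,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=Func.refGene,Number=1,Type=String,Description="Region">',
        '##INFO=<ID=ExonicFunc.refGene,Number=1,Type=String,Description="Coding effect">',
        '##INFO=<ID=AAChange.refGene,Number=1,Type=String,Description="Amino acid change">',
        '##INFO=<ID=1000g2015aug_all,Number=1,Type=Float,Description="1000 Genomes AF">',
        '##INFO=<ID=ExAC_ALL,Number=1,Type=Float,Description="ExAC AF">',
        '##INFO=<ID=esp6500siv2_all,Number=1,Type=Float,Description="ESP6500 AF">',
        '##INFO=<ID=avsnp144,Number=1,Type=String,Description="dbSNP id">',
        '##INFO=<ID=cosmic70,Number=1,Type=String,Description="COSMIC id">',
        '##INFO=<ID=CLNSIG,Number=1,Type=String,Description="Clinical significance">',
        '##INFO=<ID=SIFT_pred,Number=1,Type=String,Description="SIFT prediction">',
        '##INFO=<ID=Polyphen2_HDIV_pred,Number=1,Type=String,Description="PolyPhen2 prediction">',
        '##INFO=<ID=CONTEXT3,Number=1,Type=String,Description="Trinucleotide context">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL",
    ]
    _effect_inv = {v: k for k, v in _ANNOVAR_EFFECT.items()}
    _region_inv = {v: k for k, v in _ANNOVAR_REGION.items() if k != "exonic;splicing"}
    _clnsig_inv = {ClinSig.PATHOGENIC: "Pathogenic", ClinSig.BENIGN: "Benign", ClinSig.VUS: "Uncertain_significance"}
    lines = list(header)
    for c in calls:
        info = []
        if c.gene:
            info.append(f"Gene.refGene={c.gene}")
        info.append(f"Func.refGene={_region_inv.get(c.region, 'unknown')}")
        if c.effect in _effect_inv:
            info.append(f"ExonicFunc.refGene={_effect_inv[c.effect]}")
        if c.aa_change:
            info.append(f"AAChange.refGene={c.aa_change}")
        for db, key in _ANNOVAR_AF_KEYS.items():
            if db in c.pop_af:
                info.append(f"{key}={c.pop_af[db]:g}")
        if c.dbsnp_id:
            info.append(f"avsnp144={c.dbsnp_id}")
        if c.cosmic_id:
            info.append(f"cosmic70={c.cosmic_id}")
        if c.clinsig in _clnsig_inv:
            info.append(f"CLNSIG={_clnsig_inv[c.clinsig]}")
        if c.sift is not Prediction.ABSENT:
            info.append(f"SIFT_pred={'D' if c.sift is Prediction.DAMAGING else 'T'}")
        if c.polyphen is not Prediction.ABSENT:
            info.append(f"Polyphen2_HDIV_pred={'D' if c.polyphen is Prediction.DAMAGING else 'B'}")
        if c.context3:
            info.append(f"CONTEXT3={c.context3}")
        t_ref = c.tumor_depth - c.tumor_alt
        n_ref = c.normal_depth - c.normal_alt
        lines.append(
            "\t".join(
                [
                    c.chrom,
                    str(c.pos),
                    c.dbsnp_id or ".",
                    c.ref,
                    c.alt,
                    f"{c.quality:g}",
                    "PASS",
                    ";".join(info) or ".",
                    "AD",
                    f"{t_ref},{c.tumor_alt}",
                    f"{n_ref},{c.normal_alt}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Flat tables

VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "region", "effect",
    "aa_change", "quality", "tumor_depth", "tumor_alt", "normal_depth",
    "normal_alt", "pop_af_1000g", "pop_af_exac", "pop_af_esp6500",
    "dbsnp_id", "cosmic_id", "clinsig", "sift", "polyphen", "context3",
]
METADATA_COLUMNS = ["sample_id", "msi_status", "callable_mb"]
RULES_COLUMNS = ["gene", "pattern_kind", "pattern_payload", "drug", "effect", "evidence", "disease"]
ANNOTATION_COLUMNS = ["chrom", "pos", "ref", "alt"]

SCHEMAS = ("variants", "annotations", "rules", "metadata")


def _read_rows(path: str | Path) -> tuple[list[str], list[list[str]]]:
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.split("\n") if ln != ""]
    if not lines:
        raise FormatError(f"{path}: empty file, expected a header row")
    header = lines[0].split("\t")
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise SchemaError(f"{path}: duplicated header column {col!r}")
        seen.add(col)
    rows = [ln.split("\t") for ln in lines[1:]]
    for i, row in enumerate(rows, start=2):
        if len(row) != len(header):
            raise FormatError(f"{path}: line {i} has {len(row)} fields, expected {len(header)}")
    return header, rows


def _require(header: list[str], required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_table(path: str | Path, schema: str):
    """Read a TSV with header into typed records for the given schema.

    ``variants`` yields :class:`VariantCall`, ``metadata`` yields
    :class:`SampleMeta` (extra columns preserved, as strings, in
    ``clinical``), ``rules`` yields :class:`DruggabilityRule` and
    ``annotations`` yields plain dicts.  ``"."`` encodes an absent value.
    """
    if schema not in SCHEMAS:
        raise ConfigurationError(f"unknown table schema {schema!r}; known: {SCHEMAS}")
    header, rows = _read_rows(path)
    if schema == "variants":
        _require(header, VARIANT_COLUMNS, path)
        return [_variant_from_row(dict(zip(header, row))) for row in rows]
    if schema == "metadata":
        _require(header, METADATA_COLUMNS, path)
        extras = [c for c in header if c not in METADATA_COLUMNS]
        out = []
        for row in rows:
            rec = dict(zip(header, row))
            out.append(
                SampleMeta(
                    sample_id=rec["sample_id"],
                    msi_status=MsiStatus(rec["msi_status"]),
                    callable_mb=float(rec["callable_mb"]),
                    clinical={c: rec[c] for c in extras},
                )
            )
        return out
    if schema == "rules":
        from .druggability import DruggabilityRule  # local import, avoids cycle

        _require(header, RULES_COLUMNS, path)
        return [
            DruggabilityRule.from_row(dict(zip(header, row)), line=i)
            for i, row in enumerate(rows, start=2)
        ]
    # annotations
    _require(header, ANNOTATION_COLUMNS, path)
    out = []
    for row in rows:
        rec = dict(zip(header, row))
        rec["pos"] = int(rec["pos"])
        for col in rec:
            if col.startswith("pop_af_") and rec[col] != ABSENT:
                rec[col] = float(rec[col])
        out.append(rec)
    return out


def _opt(value: str) -> str | None:
    return None if value == ABSENT else value


def _variant_from_row(rec: dict[str, str]) -> VariantCall:
    pop_af = {}
    for db in AF_DATABASES:
        raw = rec[f"pop_af_{db}"]
        if raw != ABSENT:
            pop_af[db] = float(raw)
    return VariantCall(
        sample_id=rec["sample_id"],
        chrom=rec["chrom"],
        pos=int(rec["pos"]),
        ref=rec["ref"],
        alt=rec["alt"],
        gene="" if rec["gene"] == ABSENT else rec["gene"],
        region=Region(rec["region"]),
        effect=Effect(rec["effect"]),
        aa_change="" if rec["aa_change"] == ABSENT else rec["aa_change"],
        quality=float(rec["quality"]),
        tumor_depth=int(rec["tumor_depth"]),
        tumor_alt=int(rec["tumor_alt"]),
        normal_depth=int(rec["normal_depth"]),
        normal_alt=int(rec["normal_alt"]),
        pop_af=pop_af,
        dbsnp_id=_opt(rec["dbsnp_id"]),
        cosmic_id=_opt(rec["cosmic_id"]),
        clinsig=ClinSig(rec["clinsig"]),
        sift=Prediction(rec["sift"]),
        polyphen=Prediction(rec["polyphen"]),
        context3=_opt(rec["context3"]),
    )


def _variant_to_row(c: VariantCall) -> list[str]:
    def fmt_af(db: str) -> str:
        return repr(c.pop_af[db]) if db in c.pop_af else ABSENT

    return [
        c.sample_id, c.chrom, str(c.pos), c.ref, c.alt,
        c.gene or ABSENT, c.region.value, c.effect.value, c.aa_change or ABSENT,
        repr(c.quality), str(c.tumor_depth), str(c.tumor_alt),
        str(c.normal_depth), str(c.normal_alt),
        fmt_af("1000g"), fmt_af("exac"), fmt_af("esp6500"),
        c.dbsnp_id or ABSENT, c.cosmic_id or ABSENT, c.clinsig.value,
        c.sift.value, c.polyphen.value, c.context3 or ABSENT,
    ]


def write_table(records, path: str | Path, schema: str) -> None:
    """Write typed records back to TSV; inverse of :func:`read_table`."""
    if schema not in SCHEMAS:
        raise ConfigurationError(f"unknown table schema {schema!r}; known: {SCHEMAS}")
    records = list(records)
    if schema == "variants":
        header = VARIANT_COLUMNS
        rows = [_variant_to_row(c) for c in records]
    elif schema == "metadata":
        extras = list(records[0].clinical.keys()) if records else []
        header = METADATA_COLUMNS + extras
        rows = [
            [m.sample_id, m.msi_status.value, repr(m.callable_mb)]
            + [str(m.clinical.get(c, ABSENT)) for c in extras]
            for m in records
        ]
    elif schema == "rules":
        header = RULES_COLUMNS
        rows = [r.to_row() for r in records]
    else:  # annotations
        header = list(records[0].keys()) if records else ANNOTATION_COLUMNS
        rows = [[ABSENT if rec[c] is None else str(rec[c]) for c in header] for rec in records]
    lines = ["\t".join(header)] + ["\t".join(row) for row in rows]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Signature matrices


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Read a reference signature matrix TSV (``context`` column + one column
    per signature) and canonicalize the channel order.

    Columns whose sums are within 1e-3 of 1 are renormalized to sum exactly 1;
    anything further off is rejected.  Row order in the file is irrelevant.
    """
    header, rows = _read_rows(path)
    _require(header, ["context"], path)
    names = [c for c in header if c != "context"]
    if not names:
        raise FormatError(f"{path}: no signature columns")
    if len(rows) != 96:
        raise FormatError(f"{path}: expected 96 channel rows, got {len(rows)}")
    ctx_i = header.index("context")
    weights = np.zeros((96, len(names)))
    seen: set[str] = set()
    for row in rows:
        label = row[ctx_i]
        if label not in CHANNEL_INDEX:
            raise FormatError(f"{path}: unknown channel label {label!r}")
        if label in seen:
            raise FormatError(f"{path}: duplicated channel {label!r}")
        seen.add(label)
        vals = [float(row[header.index(n)]) for n in names]
        weights[CHANNEL_INDEX[label], :] = vals
    if (weights < 0).any():
        raise ValidationError(f"{path}: negative signature weight")
    sums = weights.sum(axis=0)
    bad = [n for n, s in zip(names, sums) if abs(s - 1.0) > 1e-3]
    if bad:
        raise ValidationError(f"{path}: column(s) {bad} do not sum to 1 within 1e-3")
    # renormalize only when meaningfully off; exact columns round-trip bitwise
    adjust = np.abs(sums - 1.0) > 1e-9
    weights[:, adjust] = weights[:, adjust] / sums[adjust]
    return SignatureMatrix(channels=list(CHANNELS), names=names, weights=weights)


def write_signature_matrix(matrix: SignatureMatrix, path: str | Path) -> None:
    lines = ["\t".join(["context"] + matrix.names)]
    for i, label in enumerate(matrix.channels):
        lines.append("\t".join([label] + [repr(float(w)) for w in matrix.weights[i]]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def expand_carriers(records: Iterable[VariantCall]) -> list[VariantCall]:
    """Split records whose ``sample_id`` is a comma-joined carrier list into
    one call per carrier (used by the printed-table fixtures)."""
    out = []
    for rec in records:
        for sid in rec.sample_id.split(","):
            out.append(
                VariantCall(**{**rec.__dict__, "sample_id": sid, "pop_af": dict(rec.pop_af)})
            )
    return out
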
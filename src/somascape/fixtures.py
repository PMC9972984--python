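"""Bundled deterministic fixtures: printed-table transcriptions, a synthetic
reference signature matrix, a gene panel and the default druggability rules.

The recurrent-variant table (16 variants with their carrier lists, catalog
ids and clinical significance) and the cohort characteristics table are
transcribed from the published colorectal-cancer study tables.  The
reference signatures are synthetic stand-ins labelled Sig1/Sig6/Sig10 with
the qualitative features of their COSMIC namesakes (Sig1: deamination-style
C>T at NpCpG; Sig6: MMR-deficiency-style C>T with a 5'-G preference; Sig10:
POLE-style C>A at TpCpT); a real COSMIC matrix can be supplied by path
wherever a :class:`SignatureMatrix` is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .channels import CHANNEL_INDEX, CHANNELS
from .druggability import DruggabilityRule
from .io import write_signature_matrix, write_table
from .model import (
    ClinSig,
    ConfigurationError,
    Effect,
    MsiStatus,
    Region,
    SampleMeta,
    SignatureMatrix,
    VariantCall,
)

# ---------------------------------------------------------------------------
# Recurrent somatic variants (known and novel) with clinical significance.
# Fields: gene, chrom, pos, ref, alt, carriers, aa labels, cosmic, dbsnp, clinsig, effect

_TABLE4_ROWS = [
    ("KDM4E", "11", 94759020, "G", "A", "C434T,C569T", "R100H", None, None, "absent", "missense"),
    ("KRAS", "12", 25398284, "C", "G", "C414T,C678T", "G12A", "COSM1140134;COSM522", "rs121913529", "pathogenic", "missense"),
    ("TP53", "17", 7577120, "C", "T", "C547T,C668T", "R141H,R273H", "COSM99729;COSM1645335;COSM3356963;COSM10660", "rs28934576", "pathogenic", "missense"),
    ("MUC16", "19", 9015323, "C", "A", "C187T,C330T", "L12755F", None, None, "absent", "missense"),
    ("MUC16", "19", 9015324, "A", "G", "C187T,C330T", "L12755S", None, None, "absent", "missense"),
    ("POTED", "21", 14983063, "G", "C", "C662T,C666T", "E172Q", None, None, "absent", "missense"),
    ("PIK3CA", "3", 178936091, "G", "A", "C396T,C398T", "E545K", "COSM763;COSM125370", "rs104886003", "pathogenic", "missense"),
    ("APC", "5", 112116592, "C", "T", "C187T,C506T", "R223X,R213X", "COSM13134", "rs587781392", "pathogenic", "nonsense"),
    ("APC", "5", 112175507, "C", "T", "C467T,C501T", "Q1406X", "COSM19087", "rs587782518", "pathogenic", "nonsense"),
    ("APC", "5", 112175639, "C", "T", "C569T,C594T", "R1450X", "COSM13127", "rs121913332", "pathogenic", "nonsense"),
    ("KRAS", "12", 25398281, "C", "T", "C459T,C467T,C497T", "G13D", "COSM1140132;COSM532", "rs112445441", "pathogenic", "missense"),
    ("TP53", "17", 7577539, "G", "A", "C414T,C450T,C511T", "R116W,R248W,R155W", "COSM3388183;COSM120007;COSM120006;COSM10656;COSM120005;COSM1640831", "rs121912651", "pathogenic", "missense"),
    ("BRAF", "7", 140453136, "A", "T", "C396T,C449T,C474T", "V28E,V600E", "COSM476", "rs113488022", "pathogenic", "missense"),
    ("TP53", "17", 7578406, "C", "T", "C404T,C484T,C501T,C649T", "R43H,R175H,R82H", "COSM3355994;COSM1640851;COSM99024;COSM99023;COSM10648;COSM99914;COSM99022", "rs28934578", "pathogenic", "missense"),
    ("ACVR2A", "2", 148683686, "TA", "T", "C420T,C474T,C594T,C666T", "K435fs", "COSM252949", "rs764719749", "absent", "frameshift_del"),
    ("KRAS", "12", 25398284, "C", "T", "C273T,C469T,C547T,C570T,C649T,C663T", "G12D", "COSM521;COSM1135366", "rs121913529", "pathogenic", "missense"),
]


def table4_records() -> list[VariantCall]:
    """The recurrent-variant table as one record per row (carrier list kept
    comma-joined in ``sample_id``; use :func:`somascape.io.expand_carriers`
    for per-carrier calls).  Depth fields encode clean tumour-only support
    (normal well covered, zero variant reads) as the study required for
    novel-variant candidates."""
    out = []
    for gene, chrom, pos, ref, alt, carriers, aa, cosmic, dbsnp, clinsig, effect in _TABLE4_ROWS:
        out.append(
            VariantCall(
                sample_id=carriers,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=gene,
                region=Region.EXONIC,
                effect=Effect(effect),
                aa_change=aa,
                quality=60.0,
                tumor_depth=80,
                tumor_alt=32,
                normal_depth=40,
                normal_alt=0,
                dbsnp_id=dbsnp,
                cosmic_id=cosmic,
                clinsig=ClinSig(clinsig),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cohort characteristics: 50 patients reconstructed to the printed margins
# (age >50: 46/4; gender 28M/22F; ethnicity 37 Malay / 13 Chinese; stage
# 3/6/35/6; differentiation 25/25; vital 18 deceased / 27 alive / 5
# untraceable; MSI 5 MSI-H / 5 MSI-L / 40 MSS).

DEFAULT_CALLABLE_MB = 30.0


def table1_meta() -> list[SampleMeta]:
    ages = [30, 41, 45, 49] + [51 + (i * 38) // 45 for i in range(46)]
    genders = ["male"] * 28 + ["female"] * 22
    ethnicities = ["malay"] * 37 + ["chinese"] * 13
    stages = ["T1"] * 3 + ["T2"] * 6 + ["T3"] * 35 + ["T4"] * 6
    diffs = ["moderate"] * 25 + ["well"] * 25
    vitals = ["deceased"] * 18 + ["alive"] * 27 + ["untraceable"] * 5
    msi = [MsiStatus.MSI_H] * 5 + [MsiStatus.MSI_L] * 5 + [MsiStatus.MSS] * 40
    out = []
    for i in range(50):
        out.append(
            SampleMeta(
                sample_id=f"CRC{i + 1:02d}",
                msi_status=msi[i],
                callable_mb=DEFAULT_CALLABLE_MB,
                clinical={
                    "age": str(ages[i]),
                    "gender": genders[i],
                    "ethnicity": ethnicities[i],
                    "stage": stages[i],
                    "differentiation": diffs[i],
                    "vital_status": vitals[i],
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# Synthetic reference signatures


def reference_signatures() -> SignatureMatrix:
    """Three synthetic reference signatures over the 96 canonical channels.

    Each column is a peaked multinomial: 50-60% of mass on a handful of
    characteristic channels plus a uniform background, giving pairwise
    cosines around 0.2-0.3 so that refitting and de novo extraction are
    well-posed.
    """
    bases = "ACGT"
    w = np.zeros((96, 3))

    def put(col: int, label: str, mass: float) -> None:
        w[CHANNEL_INDEX[label], col] += mass

    # Sig1: spontaneous-deamination-like C>T at NpCpG
    for five in bases:
        put(0, f"{five}[C>T]G", 0.15)
    # Sig6: MMR-deficiency-like C>T with 5'-G preference, some G[C>G]N
    for three in bases:
        put(1, f"G[C>T]{three}", 0.125)
        put(1, f"G[C>G]{three}", 0.025)
    # Sig10: POLE-like C>A at TpCpT / TpCpA plus T[C>T]T
    put(2, "T[C>A]T", 0.35)
    put(2, "T[C>A]A", 0.15)
    put(2, "T[C>T]T", 0.10)

    for col in range(3):
        remaining = 1.0 - w[:, col].sum()
        zero = w[:, col] == 0
        w[zero, col] = remaining / zero.sum()
    return SignatureMatrix(channels=list(CHANNELS), names=["Sig1", "Sig6", "Sig10"], weights=w)


# ---------------------------------------------------------------------------
# Gene panel (hg19-style spans; lengths drive the uniform background model)


@dataclass(frozen=True)
class Gene:
    name: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


_PANEL = [
    ("APC", "5", 112043202, 112181936),
    ("TP53", "17", 7571720, 7590868),
    ("KRAS", "12", 25358180, 25403870),
    ("ACVR2A", "2", 148602086, 148688393),
    ("TCF7L2", "10", 114710009, 114927437),
    ("PIK3CA", "3", 178866311, 178957881),
    ("BRAF", "7", 140419127, 140624564),
    ("MUC16", "19", 8959520, 9092018),
    ("MUC4", "3", 195473637, 195538844),
    ("KDM4E", "11", 94756045, 94760175),
    ("POTED", "21", 14982498, 15013906),
    ("RNF43", "17", 56429861, 56494956),
    ("POLE", "12", 133200348, 133263951),
    ("FBXW7", "4", 153242410, 153456172),
    ("SMAD4", "18", 48556583, 48611412),
    ("FAT3", "11", 92085262, 92629618),
    ("LRP1B", "2", 140988996, 141488996),
    ("KMT2C", "7", 151832010, 152133090),
    ("PCLO", "7", 82383330, 82792246),
    ("SCN1A", "2", 166845671, 166984524),
    ("SPEG", "2", 220299603, 220363811),
    ("CCDC168", "13", 103390087, 103412125),
    ("CNTLN", "9", 17134980, 17504740),
    ("DSCAM", "21", 41382926, 42219039),
    ("IGSF3", "1", 117122035, 117210375),
    ("JARID2", "6", 15246206, 15522273),
    ("OCA2", "15", 28000021, 28344461),
    ("PTPRS", "19", 5158506, 5340814),
    ("COL6A3", "2", 238232646, 238323018),
    ("CSMD1", "8", 2792875, 3292875),
    ("IGFN1", "1", 201169434, 201204720),
    ("OTOGL", "12", 80594806, 80758224),
]


def gene_panel() -> list[Gene]:
    return [Gene(*row) for row in _PANEL]


# ---------------------------------------------------------------------------
# Default druggability rules (illustrative fixture, not clinical guidance)

_RULES = [
    ("KRAS", "any_nonsynonymous", ".", "EGFR mAb inhibitors (cetuximab, panitumumab)", "resistant", "FDA", "COREAD"),
    ("KRAS", "exact_aa", "G12D", "ERBB2 mAb inhibitors (trastuzumab, lapatinib)", "resistant", "NCCN", "COREAD"),
    ("KRAS", "any_nonsynonymous", ".", "MEK inhibitor + PI3K-pathway inhibitor combination", "responsive", "early_trials", "COREAD"),
    ("KRAS", "any_nonsynonymous", ".", "MEK inhibitor + BCL-XL inhibitor combination", "responsive", "pre_clinical", "COREAD"),
    ("APC", "truncating", ".", "Tankyrase inhibitor", "responsive", "pre_clinical", "COREAD"),
    ("RNF43", "frameshift", ".", "Porcupine inhibitor LGK974 (Wnt-pathway inhibitor)", "responsive", "pre_clinical", "COREAD"),
    ("PIK3CA", "any_nonsynonymous", ".", "PI3K-pathway inhibitor", "responsive", "early_trials", "COREAD"),
    ("PIK3CA", "any_nonsynonymous", ".", "Cetuximab", "resistant", "late_trials", "COREAD"),
    ("BRAF", "exact_aa", "V600E", "BRAF inhibitor + EGFR mAb combination", "responsive", "late_trials", "COREAD"),
    ("POLE", "any_nonsynonymous", ".", "PD-1 checkpoint inhibitor (immunotherapy)", "responsive", "early_trials", "COREAD"),
]


def default_rules() -> list[DruggabilityRule]:
    cols = ["gene", "pattern_kind", "pattern_payload", "drug", "effect", "evidence", "disease"]
    return [DruggabilityRule.from_row(dict(zip(cols, row))) for row in _RULES]


# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("table1", "table4", "rules_default", "reference_signatures", "gene_panel")


def build_fixtures(name: str, out_dir: str | Path = ".") -> Path:
    """Write the named deterministic fixture to ``out_dir`` and return its
    path.  Calling twice produces byte-identical files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if name == "table1":
        path = out_dir / "table1_metadata.tsv"
        write_table(table1_meta(), path, schema="metadata")
    elif name == "table4":
        path = out_dir / "table4_variants.tsv"
        write_table(table4_records(), path, schema="variants")
    elif name == "rules_default":
        path = out_dir / "rules_default.tsv"
        write_table(default_rules(), path, schema="rules")
    elif name == "reference_signatures":
        path = out_dir / "reference_signatures.tsv"
        write_signature_matrix(reference_signatures(), path)
    elif name == "gene_panel":
        path = out_dir / "gene_panel.tsv"
        lines = ["\t".join(["gene", "chrom", "start", "end"])]
        for g in gene_panel():
            lines.append(f"{g.name}\t{g.chrom}\t{g.start}\t{g.end}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ConfigurationError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    return path
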
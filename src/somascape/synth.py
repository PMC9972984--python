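"""Synthetic paired tumour/normal cohorts with the statistical structure the
downstream analysis assumes.

The generator emulates, at desk scale, a 50-patient colorectal cohort:
MSI-group-specific somatic mutation rates (log-normal around the group
medians 57.7 / 4.1 / 3.8 per Mb), trinucleotide catalogs drawn from
group-specific mixtures of reference signatures, planted recurrent hotspot
variants, common germline variants leaking into the tumour calls (with
identical evidence in the matched normal), novel variants absent from both
catalog databases, and one hypermutated microsatellite-stable outlier.
Everything is driven by a single seeded generator: identical config + seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .channels import CHANNELS, parse_channel

_PARSED_CHANNELS = [parse_channel(c) for c in CHANNELS]
from .fixtures import Gene, gene_panel
from .model import (
    ClinSig,
    ConfigurationError,
    Effect,
    MsiStatus,
    Region,
    SampleMeta,
    SignatureMatrix,
    ValidationError,
    VariantCall,
    revcomp,
)

#: Median somatic mutation rates (mutations/Mb) per MSI group.
DEFAULT_RATE_MEDIANS = {MsiStatus.MSI_H: 57.7, MsiStatus.MSI_L: 4.1, MsiStatus.MSS: 3.8}

DEFAULT_SIGNATURE_WEIGHTS = {
    MsiStatus.MSI_H: {"Sig6": 0.70, "Sig1": 0.20, "Sig10": 0.10},
    MsiStatus.MSI_L: {"Sig1": 0.50, "Sig6": 0.30, "Sig10": 0.20},
    MsiStatus.MSS: {"Sig1": 0.60, "Sig6": 0.15, "Sig10": 0.25},
}

#: Truth labels for generated variants.
LABEL_SOMATIC = "somatic"
LABEL_GERMLINE = "germline_common"
LABEL_HOTSPOT = "hotspot"
LABEL_NOVEL = "novel"


@dataclass(frozen=True)
class Hotspot:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    aa_change: str
    carriers: int
    context3: Optional[str] = None


DEFAULT_HOTSPOTS = (
    Hotspot("KRAS", "12", 25398284, "C", "T", "G12D", 6, "ACC"),
    Hotspot("ACVR2A", "2", 148683686, "TA", "T", "K435fs", 4, None),
    Hotspot("TP53", "17", 7578406, "C", "T", "R175H", 4, "GCG"),
)


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    ``rate_median`` are mutations/Mb per MSI group; per-sample rates are
    log-normal around them with log-sd ``rate_dispersion``.  ``callable_mb``
    is the callable-genome size used both to convert rates to counts and as
    each sample's burden denominator.  ``mss_outlier_rate`` plants one
    hypermutated MSS sample at that fixed rate (None disables it).
    """

    n_samples: int = 50
    msi_proportions: tuple[float, float, float] = (0.1, 0.1, 0.8)  # MSI-H, MSI-L, MSS
    rate_median: dict = field(default_factory=lambda: dict(DEFAULT_RATE_MEDIANS))
    rate_dispersion: float = 0.6
    callable_mb: float = 30.0
    signature_weights: dict = field(
        default_factory=lambda: {g: dict(w) for g, w in DEFAULT_SIGNATURE_WEIGHTS.items()}
    )
    hotspots: tuple[Hotspot, ...] = DEFAULT_HOTSPOTS
    germline_common_rate: float = 20.0
    novel_fraction: float = 0.08
    mss_outlier_rate: Optional[float] = 244.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be positive")
        if abs(sum(self.msi_proportions) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"msi_proportions must sum to 1, got {self.msi_proportions}"
            )
        self.rate_median = {MsiStatus(k): float(v) for k, v in self.rate_median.items()}
        if any(v <= 0 for v in self.rate_median.values()):
            raise ConfigurationError("rate medians must be positive")
        if self.rate_dispersion < 0:
            raise ConfigurationError("rate_dispersion must be non-negative")
        self.signature_weights = {
            MsiStatus(g): dict(w) for g, w in self.signature_weights.items()
        }
        for g, w in self.signature_weights.items():
            if any(x < 0 for x in w.values()) or abs(sum(w.values()) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"exposure vector for {g.value} must be non-negative and sum to 1"
                )
        for h in self.hotspots:
            if h.carriers > self.n_samples:
                raise ConfigurationError(
                    f"hotspot {h.gene} {h.aa_change}: carrier count {h.carriers} "
                    f"exceeds n_samples {self.n_samples}"
                )


@dataclass
class SampleTruth:
    somatic_count: int
    group: MsiStatus
    exposures: dict[str, float]


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort: per-sample counts/groups/exposures
    and a per-variant label partition (somatic | germline_common | hotspot |
    novel), exhaustive and disjoint by construction."""

    samples: dict[str, SampleTruth]
    labels: dict[tuple[str, str, int, str, str], str]

    def keys_with_labels(self, wanted: set[str]) -> set[tuple]:
        return {k for k, lab in self.labels.items() if lab in wanted}


@dataclass
class SimulatedCohort:
    tumour_calls: list[VariantCall]
    normal_calls: list[VariantCall]
    samples: list[SampleMeta]
    truth: CohortTruth


def apportion(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of ``n`` items across groups; exact and
    deterministic (0.1/0.1/0.8 of 50 is always 5/5/40)."""
    raw = [n * p for p in proportions]
    base = [int(np.floor(x)) for x in raw]
    leftover = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:leftover]:
        base[i] += 1
    return base


_SOMATIC_EFFECTS = [Effect.MISSENSE, Effect.NONSENSE, Effect.STOPLOSS]
_SOMATIC_EFFECT_P = [0.85, 0.12, 0.03]
_SOMATIC_REGIONS = [Region.EXONIC, Region.SPLICING]
_SOMATIC_REGION_P = [0.9, 0.1]
_GERMLINE_EFFECTS = [Effect.MISSENSE, Effect.SYNONYMOUS, Effect.OTHER]
_GERMLINE_REGIONS = [Region.EXONIC, Region.INTRONIC, Region.UTR3]


def _mixture_channel_probs(config: CohortConfig, reference: SignatureMatrix,
                           group: MsiStatus) -> np.ndarray:
    weights = config.signature_weights[group]
    missing = [s for s in weights if s not in reference.names]
    if missing:
        raise ConfigurationError(f"reference matrix lacks signature(s) {missing}")
    p = np.zeros(96)
    for name, w in weights.items():
        p += w * reference.column(name)
    return p / p.sum()


def _build_germline_pool(rng: np.random.Generator, panel: list[Gene],
                         forbidden: set[tuple[str, int]], size: int = 40) -> list[dict]:
    pool = []
    taken = set(forbidden)
    bases = "ACGT"
    while len(pool) < size:
        g = panel[int(rng.integers(len(panel)))]
        pos = int(g.start + rng.integers(g.length))
        if (g.chrom, pos) in taken:
            continue
        taken.add((g.chrom, pos))
        ref = bases[int(rng.integers(4))]
        alt = bases[int((bases.index(ref) + 1 + rng.integers(3)) % 4)]
        pool.append(
            {
                "gene": g.name,
                "chrom": g.chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "af": round(float(rng.uniform(0.06, 0.5)), 4),
                "dbsnp": f"rs9{int(rng.integers(10**6, 10**7))}",
                "effect": _GERMLINE_EFFECTS[int(rng.integers(3))],
                "region": _GERMLINE_REGIONS[int(rng.integers(3))],
            }
        )
    return pool


def simulate_cohort(config: CohortConfig, reference: SignatureMatrix,
                    panel: Optional[list[Gene]] = None) -> SimulatedCohort:
    """Generate a paired tumour/normal cohort under ``config``.

    Per sample, the somatic count is ``round(callable_mb * rate)`` with the
    rate log-normal around the sample's group median; each somatic SNV's
    channel is drawn from the group's signature mixture (half are emitted on
    the purine strand to exercise normalization downstream).  Hotspots are
    planted in exactly their target carrier counts; germline-common variants
    appear in both tumour and normal calls with pop_af > 0.05; novel somatic
    variants lack both catalog ids and have a clean, well-covered normal.
    """
    rng = np.random.default_rng(config.seed)
    panel = panel or gene_panel()
    groups = [MsiStatus.MSI_H, MsiStatus.MSI_L, MsiStatus.MSS]
    sizes = apportion(config.n_samples, tuple(config.msi_proportions))
    assignment: list[MsiStatus] = []
    for g, k in zip(groups, sizes):
        assignment.extend([g] * k)
    width = max(2, len(str(config.n_samples)))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(config.n_samples)]

    hotspot_pos = {(h.chrom, h.pos) for h in config.hotspots}
    pool = _build_germline_pool(rng, panel, hotspot_pos)
    forbidden = hotspot_pos | {(s["chrom"], s["pos"]) for s in pool}

    mix = {g: _mixture_channel_probs(config, reference, g) for g in groups}
    gene_p = np.array([g.length for g in panel], dtype=float)
    gene_p /= gene_p.sum()

    samples: list[SampleMeta] = []
    truth_samples: dict[str, SampleTruth] = {}
    labels: dict[tuple, str] = {}
    tumour: list[VariantCall] = []
    normal: list[VariantCall] = []

    # per-sample rates, with the optional hypermutated MSS outlier on the
    # last MSS sample (mirroring the one extreme microsatellite-stable tumour)
    rates = []
    for sid, group in zip(sample_ids, assignment):
        med = config.rate_median[group]
        rate = float(np.exp(np.log(med) + config.rate_dispersion * rng.standard_normal()))
        rates.append(rate)
    if config.mss_outlier_rate is not None:
        mss_idx = [i for i, g in enumerate(assignment) if g is MsiStatus.MSS]
        if mss_idx:
            rates[mss_idx[-1]] = float(config.mss_outlier_rate)

    hotspot_carriers = {
        h: set(rng.choice(config.n_samples, size=h.carriers, replace=False).tolist())
        for h in config.hotspots
    }
    cosmic_counter = 1

    for idx, (sid, group) in enumerate(zip(sample_ids, assignment)):
        meta = SampleMeta(
            sample_id=sid,
            msi_status=group,
            callable_mb=config.callable_mb,
            clinical={
                "age": str(int(rng.integers(30, 90))),
                "gender": "male" if rng.random() < 0.56 else "female",
            },
        )
        samples.append(meta)

        n_som = int(round(config.callable_mb * rates[idx]))
        channels = rng.choice(96, size=n_som, p=mix[group])
        gene_idx = rng.choice(len(panel), size=n_som, p=gene_p)
        offsets = rng.random(n_som)
        effects = rng.choice(len(_SOMATIC_EFFECTS), size=n_som, p=_SOMATIC_EFFECT_P)
        regions = rng.choice(len(_SOMATIC_REGIONS), size=n_som, p=_SOMATIC_REGION_P)
        quals = rng.uniform(35.0, 60.0, size=n_som)
        t_depth = rng.integers(40, 121, size=n_som)
        t_alt = np.clip(rng.binomial(t_depth, 0.35), 1, t_depth)
        n_depth = rng.integers(15, 61, size=n_som)
        flips = rng.random(n_som) < 0.5
        novel_mask = rng.random(n_som) < config.novel_fraction

        for j in range(n_som):
            ref, alt, ctx = _PARSED_CHANNELS[channels[j]]
            if flips[j]:
                ref, alt, ctx = revcomp(ref), revcomp(alt), revcomp(ctx)
            g = panel[gene_idx[j]]
            pos = int(g.start + offsets[j] * g.length)
            while (g.chrom, pos) in forbidden:
                pos = pos + 1 if pos < g.end else g.start
            if novel_mask[j]:
                dbsnp = cosmic = None
                label = LABEL_NOVEL
            else:
                cosmic = f"COSM{9000000 + cosmic_counter}"
                dbsnp = f"rs8{7000000 + cosmic_counter}" if j % 5 else None
                cosmic_counter += 1
                label = LABEL_SOMATIC
            call = VariantCall(
                sample_id=sid,
                chrom=g.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=g.name,
                region=_SOMATIC_REGIONS[regions[j]],
                effect=_SOMATIC_EFFECTS[effects[j]],
                quality=float(quals[j]),
                tumor_depth=int(t_depth[j]),
                tumor_alt=int(t_alt[j]),
                normal_depth=int(n_depth[j]),
                normal_alt=0,
                dbsnp_id=dbsnp,
                cosmic_id=cosmic,
                context3=ctx,
            )
            tumour.append(call)
            labels.setdefault((sid, *call.key), label)

        # planted hotspots
        n_hot = 0
        for h, carriers in hotspot_carriers.items():
            if idx not in carriers:
                continue
            n_hot += 1
            effect = (
                Effect.FRAMESHIFT_DEL if h.aa_change.endswith("fs") and len(h.ref) > len(h.alt)
                else Effect.FRAMESHIFT_INS if h.aa_change.endswith("fs")
                else Effect.NONSENSE if h.aa_change.endswith("X")
                else Effect.MISSENSE
            )
            call = VariantCall(
                sample_id=sid,
                chrom=h.chrom,
                pos=h.pos,
                ref=h.ref,
                alt=h.alt,
                gene=h.gene,
                region=Region.EXONIC,
                effect=effect,
                aa_change=h.aa_change,
                quality=float(rng.uniform(45.0, 60.0)),
                tumor_depth=90,
                tumor_alt=36,
                normal_depth=45,
                normal_alt=0,
                cosmic_id=f"COSMHOT{h.pos}",
                clinsig=ClinSig.PATHOGENIC,
                context3=h.context3,
            )
            tumour.append(call)
            labels[(sid, *call.key)] = LABEL_HOTSPOT

        # germline-common leak: identical evidence in tumour and normal
        n_germ = int(rng.poisson(config.germline_common_rate))
        n_germ = min(n_germ, len(pool))
        picked = rng.choice(len(pool), size=n_germ, replace=False)
        for k in picked:
            site = pool[k]
            depth = int(rng.integers(40, 100))
            alt_reads = depth // 2
            common = dict(
                chrom=site["chrom"], pos=site["pos"], ref=site["ref"], alt=site["alt"],
                gene=site["gene"], region=site["region"], effect=site["effect"],
                quality=float(rng.uniform(40.0, 60.0)),
                tumor_depth=depth, tumor_alt=alt_reads,
                normal_depth=depth, normal_alt=alt_reads,
                pop_af={"1000g": site["af"], "exac": site["af"]},
                dbsnp_id=site["dbsnp"],
            )
            tumour.append(VariantCall(sample_id=sid, **common))
            normal.append(VariantCall(sample_id=sid, **{**common, "pop_af": dict(common["pop_af"])}))
            labels[(sid, site["chrom"], site["pos"], site["ref"], site["alt"])] = LABEL_GERMLINE

        truth_samples[sid] = SampleTruth(
            somatic_count=n_som + n_hot,
            group=group,
            exposures=dict(config.signature_weights[group]),
        )

    return SimulatedCohort(
        tumour_calls=tumour,
        normal_calls=normal,
        samples=samples,
        truth=CohortTruth(samples=truth_samples, labels=labels),
    )
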
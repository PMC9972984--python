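"""Shared domain types for the somatic-mutation landscape pipeline.

Every stage of the analysis exchanges the same small vocabulary of records:
an annotated tumour/normal variant observation (:class:`VariantCall`),
per-patient metadata (:class:`SampleMeta`) and a reference mutational
signature matrix (:class:`SignatureMatrix`).  Coordinates are 1-based and
fully closed (VCF convention) everywhere; there is no 0-based interop
surface.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class SomascapeError(Exception):
    """Base class for all package errors."""


class FormatError(SomascapeError):
    """A file does not conform to its declared external format."""


class SchemaError(SomascapeError):
    """A table is missing or duplicating required columns."""


class ValidationError(SomascapeError):
    """A record or parameter violates a domain invariant."""


class ConfigurationError(SomascapeError):
    """A configuration value is inconsistent or unknown."""


class UndefinedInputError(SomascapeError):
    """The requested quantity is undefined for this input (e.g. zero vector)."""


class Region(str, enum.Enum):
    """Genomic region of a variant, ANNOVAR-style vocabulary."""

    EXONIC = "exonic"
    SPLICING = "splicing"
    INTRONIC = "intronic"
    UTR3 = "UTR3"
    UTR5 = "UTR5"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    INTERGENIC = "intergenic"
    UNKNOWN = "unknown"


class Effect(str, enum.Enum):
    """Coding consequence of a variant."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    STOPLOSS = "stoploss"
    FRAMESHIFT_INS = "frameshift_ins"
    FRAMESHIFT_DEL = "frameshift_del"
    INFRAME_INS = "inframe_ins"
    INFRAME_DEL = "inframe_del"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Effects producing a truncated protein.
TRUNCATING_EFFECTS = frozenset(
    {Effect.NONSENSE, Effect.FRAMESHIFT_INS, Effect.FRAMESHIFT_DEL}
)
FRAMESHIFT_EFFECTS = frozenset({Effect.FRAMESHIFT_INS, Effect.FRAMESHIFT_DEL})


class ClinSig(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    VUS = "vus"
    ABSENT = "absent"


class Prediction(str, enum.Enum):
    """SIFT / PolyPhen protein-impact call."""

    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    ABSENT = "absent"


class MsiStatus(str, enum.Enum):
    MSI_H = "MSI-H"
    MSI_L = "MSI-L"
    MSS = "MSS"


#: Population allele-frequency databases consulted by the common-variant filter.
AF_DATABASES = ("1000g", "exac", "esp6500")

_DNA = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class VariantCall:
    """One annotated tumour/normal small-variant observation.

    ``pos`` is the 1-based position of the first reference base.  ``pop_af``
    maps database name to population allele frequency; a database the variant
    was never observed in is simply absent from the map (never encoded as 0).
    ``context3`` is the trinucleotide context centred on ``pos`` for SNVs.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    region: Region = Region.UNKNOWN
    effect: Effect = Effect.OTHER
    aa_change: str = ""
    quality: float = 0.0
    tumor_depth: int = 0
    tumor_alt: int = 0
    normal_depth: int = 0
    normal_alt: int = 0
    pop_af: dict[str, float] = field(default_factory=dict)
    dbsnp_id: Optional[str] = None
    cosmic_id: Optional[str] = None
    clinsig: ClinSig = ClinSig.ABSENT
    sift: Prediction = Prediction.ABSENT
    polyphen: Prediction = Prediction.ABSENT
    context3: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.tumor_alt > self.tumor_depth:
            raise ValidationError(
                f"tumor_alt {self.tumor_alt} exceeds tumor_depth {self.tumor_depth}"
            )
        if self.normal_alt > self.normal_depth:
            raise ValidationError(
                f"normal_alt {self.normal_alt} exceeds normal_depth {self.normal_depth}"
            )
        if self.quality < 0:
            raise ValidationError(f"quality must be non-negative, got {self.quality}")
        for db, af in self.pop_af.items():
            if not 0.0 <= af <= 1.0:
                raise ValidationError(f"allele frequency {af} for {db} outside [0,1]")
        if self.context3 is not None:
            if len(self.context3) != 3 or not _DNA.issuperset(self.context3):
                raise ValidationError(f"context3 must be a 3-mer DNA string, got {self.context3!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Genomic identity (chrom, pos, ref, alt) used for recurrence and subtraction."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class SampleMeta:
    """Per-patient clinical and assay metadata.

    ``callable_mb`` is the size in megabases of the genome region over which
    somatic variants could be called; it is the denominator of every
    mutations-per-Mb rate and has no hidden default.
    """

    sample_id: str
    msi_status: MsiStatus
    callable_mb: float
    clinical: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.callable_mb <= 0:
            raise ValidationError(f"callable_mb must be positive, got {self.callable_mb}")
        self.msi_status = MsiStatus(self.msi_status)


@dataclass
class SignatureMatrix:
    """Reference mutational signatures over the 96 trinucleotide channels.

    ``weights`` is a 96 x K non-negative matrix whose columns each sum to 1;
    rows follow the canonical channel order of :mod:`somascape.channels`.
    """

    channels: list[str]
    names: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.channels) != 96 or self.weights.shape[0] != 96:
            raise FormatError(
                f"signature matrix must have 96 channel rows, got {self.weights.shape[0]}"
            )
        if self.weights.shape[1] != len(self.names):
            raise FormatError("signature name count does not match weight columns")
        if (self.weights < 0).any():
            raise ValidationError("signature weights must be non-negative")
        sums = self.weights.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValidationError(f"signature columns must sum to 1, got {sums}")

    def column(self, name: str) -> np.ndarray:
        return self.weights[:, self.names.index(name)]
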
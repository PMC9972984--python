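"""The 96 trinucleotide mutation channels and pyrimidine-strand normalization.

A single-base substitution is described by its pyrimidine-centred class
(C>A, C>G, C>T, T>A, T>C, T>G) and the two flanking bases, giving
6 x 4 x 4 = 96 channels.  Substitutions reported on the purine strand
(ref G or A) are mapped to the reverse complement.  The canonical channel
order is lexicographic by (substitution class, 5' base, 3' base) and is
fixed once here; every catalog and signature matrix in the package uses it.
"""

from __future__ import annotations

from .model import ValidationError, revcomp

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")

#: Canonical channel labels in COSMIC style, e.g. ``"A[C>A]A"``.
CHANNELS: list[str] = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in _BASES
    for three in _BASES
]

CHANNEL_INDEX: dict[str, int] = {label: i for i, label in enumerate(CHANNELS)}

_PYRIMIDINES = frozenset("CT")
_DNA = frozenset("ACGT")


def normalize_substitution(ref: str, alt: str, context3: str) -> tuple[str, str, str]:
    """Return the pyrimidine-strand (ref, alt, context3) of a substitution.

    Already-normalized inputs are returned unchanged (the operation is an
    involution fixed point), making normalization idempotent.
    """
    if len(ref) != 1 or len(alt) != 1 or ref not in _DNA or alt not in _DNA or ref == alt:
        raise ValidationError(f"not a single-base substitution: {ref}>{alt}")
    if len(context3) != 3 or not _DNA.issuperset(context3):
        raise ValidationError(f"context3 must be a 3-mer DNA string, got {context3!r}")
    if context3[1] != ref:
        raise ValidationError(
            f"context3 middle base {context3[1]!r} does not match ref {ref!r}"
        )
    if ref in _PYRIMIDINES:
        return ref, alt, context3
    return revcomp(ref), revcomp(alt), revcomp(context3)


def channel_label(ref: str, alt: str, context3: str) -> str:
    """Canonical channel label of a substitution after strand normalization."""
    ref, alt, context3 = normalize_substitution(ref, alt, context3)
    return f"{context3[0]}[{ref}>{alt}]{context3[2]}"


def channel_index(ref: str, alt: str, context3: str) -> int:
    return CHANNEL_INDEX[channel_label(ref, alt, context3)]


def parse_channel(label: str) -> tuple[str, str, str]:
    """Invert :func:`channel_label`: return (ref, alt, context3)."""
    if label not in CHANNEL_INDEX:
        raise ValidationError(f"unknown channel label {label!r}")
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, five + ref + three
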
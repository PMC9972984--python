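"""96-channel mutation catalogs, signature refitting and de novo extraction.

Catalogs count single-base substitutions per pyrimidine-normalized
trinucleotide channel.  Refitting solves a non-negative least squares
problem against a fixed reference matrix; de novo extraction factorizes a
samples x 96 count matrix with NMF (multiplicative updates, Frobenius loss,
multi-restart, seeded) and matches each extracted signature to its
best-cosine reference column.  Both pathways are provided because either can
stand behind a published signature analysis; refitting is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.optimize import nnls
from scipy.optimize import linear_sum_assignment

from .channels import CHANNELS, channel_index
from .model import (
    ConfigurationError,
    SignatureMatrix,
    UndefinedInputError,
    ValidationError,
    VariantCall,
)


@dataclass
class Catalog96:
    """Counts of SNVs over the 96 canonical channels for one scope
    (a sample id, or ``"cohort"`` for the aggregate)."""

    scope: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValidationError(f"catalog must have 96 channels, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValidationError("catalog counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def build_catalog(calls: Iterable[VariantCall], scope: str = "cohort") -> Catalog96:
    """Tally SNVs (indels are skipped) into a channel catalog.

    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine strand; the count total equals the number of contributing
    SNVs.  An SNV without a trinucleotide context is an error.
    """
    counts = np.zeros(96)
    for c in calls:
        if not c.is_snv:
            continue
        if c.context3 is None:
            raise ValidationError(
                f"SNV at {c.chrom}:{c.pos} lacks context3; cannot assign a channel"
            )
        counts[channel_index(c.ref, c.alt, c.context3)] += 1
    return Catalog96(scope=scope, counts=counts)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two 96-vectors; undefined for a zero vector."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UndefinedInputError("cosine similarity is undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class SignatureFit:
    """Result of refitting a catalog against reference signatures."""

    names: list[str]
    exposures: np.ndarray            # raw, same scale as the catalog counts
    proportions: np.ndarray          # exposures normalized to sum 1
    reconstruction: np.ndarray       # 96-vector W @ e
    residual_norm: float
    cosine_to_reference: dict[str, float] = field(default_factory=dict)


def refit_exposures(catalog: Catalog96, reference: SignatureMatrix) -> SignatureFit:
    """Estimate non-negative exposures e minimizing ||W e - c||_2 (NNLS).

    ``cosine_to_reference`` reports, per reference signature, the cosine of
    the catalog to that signature's column — a quick attribution diagnostic.
    """
    c = catalog.counts
    if c.sum() == 0:
        raise UndefinedInputError("cannot refit a zero catalog")
    e, resid = nnls(reference.weights, c)
    total = e.sum()
    proportions = e / total if total > 0 else e
    cosines = {}
    for i, name in enumerate(reference.names):
        cosines[name] = cosine(c, reference.weights[:, i])
    return SignatureFit(
        names=list(reference.names),
        exposures=e,
        proportions=proportions,
        reconstruction=reference.weights @ e,
        residual_norm=float(resid),
        cosine_to_reference=cosines,
    )


@dataclass
class DenovoResult:
    signatures: SignatureMatrix      # 96 x k, columns sum to 1
    exposures: np.ndarray            # n_samples x k, counts scale
    best_match: dict[str, str]       # extracted name -> reference name
    match_cosine: dict[str, float]   # extracted name -> cosine to its match
    frobenius_error: float


def extract_denovo(
    catalogs: list[Catalog96],
    k: int,
    seed: int,
    reference: Optional[SignatureMatrix] = None,
    n_restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> DenovoResult:
    """Factorize the samples x 96 matrix into ``k`` de novo signatures.

    NMF uses multiplicative updates on the Frobenius loss with
    ``n_restarts`` random initializations (one seeded stream per restart);
    the factorization with the best objective is kept, so identical inputs
    and seed give identical output.  With a reference matrix, each extracted
    signature is matched one-to-one to the reference column maximizing total
    cosine similarity.
    """
    from sklearn.decomposition import NMF

    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k > len(catalogs):
        raise ConfigurationError(f"k={k} exceeds the number of catalogs ({len(catalogs)})")
    X = np.vstack([c.counts for c in catalogs])
    best = None
    for r in range(n_restarts):
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=max_iter,
            tol=tol,
            random_state=seed * 1000 + r,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings on easy data
            E = model.fit_transform(X)       # n_samples x k
        err = model.reconstruction_err_
        if best is None or err < best[0]:
            best = (err, E, model.components_)
    err, E, S = best
    col_sums = S.sum(axis=1)
    col_sums[col_sums == 0] = 1.0
    sigs = (S / col_sums[:, None]).T         # 96 x k, columns sum to 1
    exposures = E * col_sums[None, :]
    names = [f"Denovo{i + 1}" for i in range(k)]
    matrix = SignatureMatrix(channels=list(CHANNELS), names=names, weights=sigs)

    best_match: dict[str, str] = {}
    match_cosine: dict[str, float] = {}
    if reference is not None:
        sim = np.zeros((k, len(reference.names)))
        for i in range(k):
            for j in range(len(reference.names)):
                sim[i, j] = cosine(sigs[:, i], reference.weights[:, j])
        if k <= len(reference.names):
            rows, cols = linear_sum_assignment(-sim)
            for i, j in zip(rows, cols):
                best_match[names[i]] = reference.names[j]
                match_cosine[names[i]] = float(sim[i, j])
        else:
            for i in range(k):
                j = int(np.argmax(sim[i]))
                best_match[names[i]] = reference.names[j]
                match_cosine[names[i]] = float(sim[i, j])
    return DenovoResult(
        signatures=matrix,
        exposures=exposures,
        best_match=best_match,
        match_cosine=match_cosine,
        frobenius_error=float(err),
    )
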
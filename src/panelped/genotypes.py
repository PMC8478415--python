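"""Pared multi-locus genotype space, founder priors, Mendelian transmission.

A genotype is a vector of binary carrier flags, one per model gene.
The *paring* parameter ``max_mut`` truncates the space to genotypes with
at most ``max_mut`` simultaneous mutations, so the space has
``sum_{j<=max_mut} C(K, j)`` states, ordered noncarrier first, then
single carriers in gene order, then pairs lexicographically, and so on.

Carriers are modelled as heterozygous for "any pathogenic variant" at
unlinked autosomal loci: a carrier parent transmits the variant allele
with probability 1/2, a non-carrier with probability 0, and a child is a
carrier iff it receives at least one variant allele.  Probability mass
falling on genotypes pared away is renormalized over the retained
states, keeping every founder prior and transmission row a proper
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import NONCARRIER


@dataclass(frozen=True)
class GenotypeVector:
    """Carrier flags over the model genes, with a deterministic label."""

    flags: Tuple[int, ...]
    label: str

    @property
    def n_mut(self) -> int:
        return sum(self.flags)


@dataclass
class GenotypeSpace:
    """Ordered, pared collection of genotype vectors."""

    vectors: List[GenotypeVector]
    gene_variants: List[str]
    max_mut: int

    def __len__(self) -> int:
        return len(self.vectors)

    def __iter__(self):
        return iter(self.vectors)

    def __getitem__(self, i: int) -> GenotypeVector:
        return self.vectors[i]

    @property
    def labels(self) -> List[str]:
        return [g.label for g in self.vectors]

    @property
    def carrier_matrix(self) -> np.ndarray:
        """(N, K) int array of carrier flags."""
        return np.array([g.flags for g in self.vectors], dtype=np.int8)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def _label(flags: Sequence[int], gene_variants: Sequence[str]) -> str:
    carried = [v for f, v in zip(flags, gene_variants) if f]
    return ".".join(carried) if carried else NONCARRIER


def enumerate_genotypes(genes: Union[int, Sequence[str]],
                        max_mut: int) -> GenotypeSpace:
    """Enumerate the pared genotype space for K genes.

    ``genes`` is either the list of gene-variant labels or a plain count
    (labels then default to ``g1..gK``).  ``max_mut`` above K is clamped
    to K with a warning.
    """
    if isinstance(genes, int):
        gene_variants = [f"g{i + 1}" for i in range(genes)]
    else:
        gene_variants = list(genes)
    K = len(gene_variants)
    if max_mut < 1:
        raise ValueError("max_mut must be at least 1")
    if max_mut > K:
        warnings.warn(f"max_mut={max_mut} exceeds the number of genes {K}; clamping to {K}")
        max_mut = K
    vectors = []
    for j in range(max_mut + 1):
        for idx in combinations(range(K), j):
            flags = tuple(1 if k in idx else 0 for k in range(K))
            vectors.append(GenotypeVector(flags, _label(flags, gene_variants)))
    return GenotypeSpace(vectors, gene_variants, max_mut)


def carrier_prior(freq: np.ndarray) -> np.ndarray:
    """Per-gene carrier probability under Hardy-Weinberg: 2f(1-f) + f^2."""
    f = np.asarray(freq, dtype=float)
    return 2 * f * (1 - f) + f ** 2


def founder_prior(g: GenotypeVector, freqs: Sequence[float],
                  space: Optional[GenotypeSpace] = None) -> float:
    """Prior probability of genotype ``g`` for a founder.

    Product over genes of the Hardy-Weinberg carrier/noncarrier
    probability.  With ``space`` given, the product is renormalized over
    the retained (pared) genotype vectors; without it the raw product is
    returned.
    """
    c = carrier_prior(np.asarray(freqs, dtype=float))
    flags = np.asarray(g.flags)
    raw = float(np.prod(np.where(flags == 1, c, 1 - c)))
    if space is None:
        return raw
    return raw / founder_prior_vector(space, freqs, _normalize=False).sum()


def founder_prior_vector(space: GenotypeSpace, freqs: Sequence[float],
                         _normalize: bool = True) -> np.ndarray:
    """Founder prior over the whole space, renormalized to sum to 1."""
    c = carrier_prior(np.asarray(freqs, dtype=float))
    M = space.carrier_matrix
    raw = np.prod(np.where(M == 1, c, 1 - c), axis=1)
    return raw / raw.sum() if _normalize else raw


def _child_carrier_prob(m_flag: np.ndarray, f_flag: np.ndarray) -> np.ndarray:
    """Per-locus P(child carries) from heterozygous-carrier parents."""
    tm = 0.5 * m_flag
    tf = 0.5 * f_flag
    return 1.0 - (1.0 - tm) * (1.0 - tf)


def transmission_prob(child: GenotypeVector, mother: GenotypeVector,
                      father: GenotypeVector,
                      space: Optional[GenotypeSpace] = None) -> float:
    """Mendelian transmission probability P(child | mother, father).

    Product over loci of the single-locus transmission.  With ``space``
    given, mass on child genotypes outside the pared space is
    renormalized over the retained child vectors.
    """
    p = _child_carrier_prob(np.asarray(mother.flags, dtype=float),
                            np.asarray(father.flags, dtype=float))
    cf = np.asarray(child.flags)
    raw = float(np.prod(np.where(cf == 1, p, 1 - p)))
    if space is None:
        return raw
    M = space.carrier_matrix
    allraw = np.prod(np.where(M == 1, p, 1 - p), axis=1)
    return raw / allraw.sum()


def transmission_matrix(space: GenotypeSpace) -> np.ndarray:
    """Dense transmission tensor T[child, mother, father], renormalized.

    Each (mother, father) column is a distribution over retained child
    genotypes summing to exactly 1.
    """
    M = space.carrier_matrix.astype(float)  # (N, K)
    N = len(space)
    # p[m, f, k] = per-locus child-carrier probability
    p = _child_carrier_prob(M[:, None, :], M[None, :, :])  # (N, N, K)
    child = space.carrier_matrix[:, None, None, :]  # (N, 1, 1, K)
    probs = np.where(child == 1, p[None, :, :, :], 1.0 - p[None, :, :, :])
    T = probs.prod(axis=3)  # (child, mother, father)
    T /= T.sum(axis=0, keepdims=True)
    return T
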
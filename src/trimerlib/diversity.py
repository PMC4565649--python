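"""Library-structure and diversity statistics.

A library with n randomized positions, per-position exchange probability p
and m foreign residues per position decomposes into mutant classes k =
0..n (members carrying exactly k exchanges).  Class probabilities are
binomial, the species count per class is C(n,k)*m^k, and the expected
number of distinct species S in L independent clones follows from capping
each class's species count at its expected clone count.  Companion
functions give the frameshift-free probability of a clone, degenerate-
codon (NNN/NNK/NNS) comparisons, practical diversity and the expected
wild-type frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "LibraryStatistics",
    "FrameshiftModel",
    "binomial_classes",
    "poisson_binomial_pmf",
    "unique_species",
    "frameshift_free_probability",
    "degenerate_codon_stats",
    "practical_diversity",
    "PracticalDiversity",
    "wildtype_frequency",
    "theoretical_diversity",
]


@dataclass
class LibraryStatistics:
    """Per-mutant-class library structure.

    Arrays are indexed by k = 0..n: class probability ``P_k``, species
    count ``N_k = C(n,k) * m**k``, per-species fraction ``F_k = P_k/N_k``,
    per-species copy number ``C_k = F_k * L`` and expected clones
    ``L_k = P_k * L``.
    """

    n: int
    p: float
    L: float
    m: int
    P_k: np.ndarray
    N_k: list[int]
    F_k: np.ndarray
    C_k: np.ndarray
    L_k: np.ndarray

    @property
    def k(self) -> np.ndarray:
        return np.arange(self.n + 1)


def binomial_classes(
    n: int, p: float, L: float, m: int = 18, p_vector=None
) -> LibraryStatistics:
    """Populate the mutant-class arrays.

    With ``p_vector`` (one exchange probability per position) the class
    probabilities follow the Poisson-binomial distribution instead of the
    binomial at the scalar mean; the scalar ``p`` is then ignored.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if L <= 0:
        raise ValueError("library size L must be positive")
    if m < 1:
        raise ValueError("m must be at least 1")
    if p_vector is not None:
        if len(p_vector) != n:
            raise ValueError("p_vector length must equal n")
        P = poisson_binomial_pmf(np.asarray(p_vector, dtype=float))
    else:
        P = sps.binom.pmf(np.arange(n + 1), n, p)
    N = [math.comb(n, k) * m**k for k in range(n + 1)]
    N_f = np.array([float(x) for x in N])
    F = P / N_f
    return LibraryStatistics(
        n=n, p=p, L=L, m=m, P_k=P, N_k=N, F_k=F, C_k=F * L, L_k=P * L
    )


def poisson_binomial_pmf(p_vector: np.ndarray) -> np.ndarray:
    """Distribution of the number of successes of independent non-identical
    Bernoulli trials, by direct convolution."""
    pmf = np.array([1.0])
    for p in p_vector:
        pmf = np.convolve(pmf, [1 - p, p])
    return pmf


def unique_species(stats: LibraryStatistics, method: str = "saturation") -> float:
    """Expected number of distinct molecular species S in the library.

    ``saturation`` (default): class k contributes its full species count
    N_k when the per-species copy number C_k is at least 1 (every species
    expected present) and its expected clone count L_k otherwise (every
    clone expected unique).  ``expected_distinct``: the occupancy formula
    sum_k N_k * (1 - (1 - 1/N_k)**L_k).
    """
    if method == "saturation":
        total = 0.0
        for N, C, Lk in zip(stats.N_k, stats.C_k, stats.L_k):
            total += N if C >= 1.0 else Lk
        return total
    if method == "expected_distinct":
        total = 0.0
        for N, Lk in zip(stats.N_k, stats.L_k):
            # N * (1 - (1 - 1/N)^Lk), stable for astronomically large N
            if N == 1:
                total += 1.0 if Lk > 0 else 0.0
            else:
                total += -N * math.expm1(Lk * math.log1p(-1.0 / N))
        return total
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class FrameshiftModel:
    """Per-codon frameshift (Δ1+Δ2) rates for the two site classes.

    Defaults describe a 260-codon gene with 24 randomized codons: rates
    0.0026 per non-randomized and 0.0054 per randomized codon.
    """

    codons_nonrandomized: int = 236
    rate_nonrandomized: float = 0.0026
    codons_randomized: int = 24
    rate_randomized: float = 0.0054

    def __post_init__(self) -> None:
        for r in (self.rate_nonrandomized, self.rate_randomized):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")


def frameshift_free_probability(model: FrameshiftModel | None = None) -> float:
    """Probability that a clone carries no frameshifting deletion:
    (1 - r_nr)**c_nr * (1 - r_r)**c_r."""
    m = model or FrameshiftModel()
    return (1 - m.rate_nonrandomized) ** m.codons_nonrandomized * (
        1 - m.rate_randomized
    ) ** m.codons_randomized


def degenerate_codon_stats(scheme: str, n: int) -> dict[str, float]:
    """Gene/protein counts for NNN, NNK or NNS randomization of n codons.

    NNN: 64 codons, 3 stops per position; NNK/NNS: 32 codons, 1 stop.
    All encode the full 20 amino acids, so protein count is 20**n and the
    gene:protein ratio measures codon redundancy.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    scheme = scheme.upper()
    if scheme == "NNN":
        codons, stops = 64, 3
    elif scheme in ("NNK", "NNS"):
        codons, stops = 32, 1
    else:
        raise ValueError(f"unknown degenerate-codon scheme {scheme!r}")
    genes = float(codons) ** n
    proteins = 20.0**n
    return {
        "gene_count": genes,
        "protein_count": proteins,
        "ratio": genes / proteins,
        "stop_codons_per_position": stops,
    }


@dataclass(frozen=True)
class PracticalDiversity:
    frameshift_free_genes: float
    stable_proteins: float
    gene_protein_ratio: float | None


def practical_diversity(
    L: float,
    frameshift_free_fraction: float,
    stable_fraction: float = 1.0,
    species: float | None = None,
) -> PracticalDiversity:
    """Clones that count: frameshift-free genes L*f, optionally reduced to
    conformationally stable proteins, and the gene:protein ratio against a
    unique-species count."""
    for f in (frameshift_free_fraction, stable_fraction):
        if not 0 <= f <= 1:
            raise ValueError("fractions must be in [0, 1]")
    genes = L * frameshift_free_fraction
    return PracticalDiversity(
        frameshift_free_genes=genes,
        stable_proteins=genes * stable_fraction,
        gene_protein_ratio=(genes / species) if species else None,
    )


def wildtype_frequency(
    n: int,
    p: float,
    frameshift_free_fraction: float = 1.0,
    stable_fraction: float = 1.0,
) -> float:
    """Expected wild-type frequency: the zero-term of the binomial
    distribution, (1-p)**n, corrected for complete reading frames and
    (optionally) the stable-protein fraction."""
    return (1 - p) ** n * frameshift_free_fraction * stable_fraction


def theoretical_diversity(k_positions: int, alphabet_size: int = 19) -> float:
    """Number of codon combinations over k randomized positions drawn from
    an alphabet of one codon per allowed residue."""
    if k_positions < 0:
        raise ValueError("k must be nonnegative")
    return float(alphabet_size) ** k_positions
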
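"""Trimer-phosphoramidite mixture design.

A partially randomized codon position is synthesized by coupling a mixture
of trinucleotide building blocks: the resident (wild-type) trimer spiked at
a fixed molar fraction (default 0.7) on top of a standard mixture of one
trimer per amino acid (default 19 trimers, cysteine excluded).  The
functions here compute mixture compositions, per-position codon
incorporation probabilities and the expected number of codon exchanges per
gene, plus the supplier-side coupling corrections needed to turn protein-
level fractions into physical molar amounts.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MixtureEntry",
    "StandardMixture",
    "RandomizationScheme",
    "SchemePosition",
    "MixtureSourceTable",
    "build_standard_mixture",
    "position_mixture",
    "exchange_probabilities",
    "apply_coupling_corrections",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MixtureEntry:
    """One trimer of a standard mixture.

    ``protein_fraction`` is the molar fraction intended to be realized at
    the protein level; ``coupling_correction`` is the multiplicative factor
    the synthesis supplier applies to compensate for slower or faster
    incorporation of the trimer.
    """

    amino_acid: str
    codon: str
    protein_fraction: float
    coupling_correction: float = 1.0


@dataclass(frozen=True)
class StandardMixture:
    """A standard mixture: one codon per included amino acid.

    Invariants: exactly one entry per included amino acid, fractions sum to
    1 (within 1e-9), excluded residues carry no entry.
    """

    entries: tuple[MixtureEntry, ...]
    excluded_residues: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        aas = [e.amino_acid for e in self.entries]
        if len(set(aas)) != len(aas):
            raise ValueError("duplicate amino acid in mixture")
        bad = set(aas) - AMINO_ACIDS
        if bad:
            raise ValueError(f"unknown amino acid(s): {sorted(bad)}")
        if set(aas) & self.excluded_residues:
            raise ValueError("excluded residue present in mixture entries")
        for e in self.entries:
            if len(e.codon) != 3:
                raise ValueError(f"codon for {e.amino_acid} is not 3 nt")
            if e.protein_fraction < 0:
                raise ValueError(f"negative fraction for {e.amino_acid}")
            if e.coupling_correction <= 0:
                raise ValueError(
                    f"nonpositive coupling correction for {e.amino_acid}"
                )
        total = sum(e.protein_fraction for e in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions sum to {total}, not 1")

    def fraction(self, amino_acid: str) -> float:
        """Protein-level fraction of ``amino_acid``; 0 if not in the mix."""
        for e in self.entries:
            if e.amino_acid == amino_acid:
                return e.protein_fraction
        return 0.0

    def entry(self, amino_acid: str) -> MixtureEntry:
        for e in self.entries:
            if e.amino_acid == amino_acid:
                return e
        raise KeyError(amino_acid)

    @property
    def codons(self) -> dict[str, str]:
        return {e.amino_acid: e.codon for e in self.entries}


@dataclass(frozen=True)
class SchemePosition:
    """One randomized codon: 1-based protein position, the gene's actual
    codon there, and the residue it encodes."""

    protein_position: int
    resident_codon: str
    resident_aa: str


@dataclass(frozen=True)
class RandomizationScheme:
    """Which codons of a gene are randomized, and how strongly.

    At each listed position the resident trimer is added at
    ``resident_fraction`` on top of ``mixture_fraction`` equivalents of the
    standard mixture.
    """

    positions: tuple[SchemePosition, ...]
    mixture: StandardMixture
    resident_fraction: float = 0.7
    mixture_fraction: float = 0.3

    def __post_init__(self) -> None:
        if abs(self.resident_fraction + self.mixture_fraction - 1.0) > 1e-9:
            raise ValueError("resident and mixture fractions must sum to 1")
        pps = [p.protein_position for p in self.positions]
        if len(set(pps)) != len(pps):
            raise ValueError("duplicate randomized position")
        if list(pps) != sorted(pps):
            raise ValueError("positions must be sorted")

    def position(self, protein_position: int) -> SchemePosition:
        for p in self.positions:
            if p.protein_position == protein_position:
                return p
        raise KeyError(f"position {protein_position} is not in the scheme")

    @property
    def protein_positions(self) -> list[int]:
        return [p.protein_position for p in self.positions]

    def subset(self, keep: set[int]) -> "RandomizationScheme":
        """Scheme restricted to the given protein positions."""
        return RandomizationScheme(
            positions=tuple(
                p for p in self.positions if p.protein_position in keep
            ),
            mixture=self.mixture,
            resident_fraction=self.resident_fraction,
            mixture_fraction=self.mixture_fraction,
        )


@dataclass(frozen=True)
class MixtureSourceTable:
    """Source residue frequencies a standard mixture is blended from:
    protein-surface residue frequencies and catalytic-site residue
    frequencies, combined with the given weights (default 0.75 / 0.25)."""

    surface_freqs: dict[str, float]
    catalytic_freqs: dict[str, float]
    weights: tuple[float, float] = (0.75, 0.25)

    def __post_init__(self) -> None:
        # frequency maps are normalized when the mixture is built, so
        # unnormalized occurrence counts are accepted; only signs matter
        for name, freqs in (
            ("surface", self.surface_freqs),
            ("catalytic", self.catalytic_freqs),
        ):
            for aa, f in freqs.items():
                if f < 0:
                    raise ValueError(
                        f"negative {name} frequency for residue {aa}"
                    )
            if freqs and sum(freqs.values()) <= 0:
                raise ValueError(f"{name} frequencies sum to zero")
        if self.weights[0] < 0 or self.weights[1] < 0:
            raise ValueError("weights must be nonnegative")
        if abs(self.weights[0] + self.weights[1] - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def build_standard_mixture(
    sources: MixtureSourceTable,
    excluded: set[str] = frozenset({"C"}),
    codons: dict[str, str] | None = None,
    corrections: dict[str, float] | None = None,
) -> StandardMixture:
    """Blend surface and catalytic residue frequencies into a mixture.

    Included fractions are proportional to
    ``w_surface * surface + w_catalytic * catalytic``; excluded residues are
    set to zero and the remainder renormalized to sum 1.  ``codons`` maps
    residues to the single codon used for each (defaults to the packaged
    standard-mixture codons); ``corrections`` supplies coupling corrections
    (default 1.0).
    """
    if not excluded <= AMINO_ACIDS:
        raise ValueError(f"unknown excluded residue(s): {sorted(set(excluded) - AMINO_ACIDS)}")
    w_s, w_c = sources.weights
    included = sorted(
        (set(sources.surface_freqs) | set(sources.catalytic_freqs)) - set(excluded)
    )
    if not included:
        raise ValueError("no residues left after exclusion")
    # normalize each source before blending, so occurrence counts work too
    s_tot = sum(sources.surface_freqs.values()) or 1.0
    c_tot = sum(sources.catalytic_freqs.values()) or 1.0
    raw = {
        aa: w_s * sources.surface_freqs.get(aa, 0.0) / s_tot
        + w_c * sources.catalytic_freqs.get(aa, 0.0) / c_tot
        for aa in included
    }
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("all included residues have zero weight")
    if codons is None:
        from .thisf import STANDARD_MIXTURE_CODONS

        codons = STANDARD_MIXTURE_CODONS
    corrections = corrections or {}
    entries = tuple(
        MixtureEntry(
            amino_acid=aa,
            codon=codons[aa],
            protein_fraction=raw[aa] / total,
            coupling_correction=corrections.get(aa, 1.0),
        )
        for aa in included
    )
    return StandardMixture(entries=entries, excluded_residues=frozenset(excluded))


def position_mixture(
    scheme: RandomizationScheme, protein_position: int
) -> dict[str, float]:
    """Codon incorporation probabilities at one randomized position.

    The resident codon receives the resident fraction plus its share of the
    standard mixture; every other mixture codon receives
    ``mixture_fraction * f_i``.  If the gene's resident codon is a silent
    variant of the mixture's codon for the same residue, the two are listed
    separately (the spike carries the gene's codon, the mixture its own).
    """
    pos = scheme.position(protein_position)
    probs: dict[str, float] = {}
    for e in scheme.mixture.entries:
        probs[e.codon] = probs.get(e.codon, 0.0) + scheme.mixture_fraction * e.protein_fraction
    probs[pos.resident_codon] = probs.get(pos.resident_codon, 0.0) + scheme.resident_fraction
    return probs


def exchange_probabilities(
    scheme: RandomizationScheme,
) -> tuple[list[float], float, float]:
    """Per-position exchange probabilities, their mean, and the expected
    number of codon exchanges per gene.

    The exchange probability at position j is
    ``mixture_fraction * (1 - f_resident(j))`` with f taken at the protein
    level: drawing the resident residue's own trimer from the standard
    mixture does not count as an exchange, and a silent codon variant of
    the resident residue is likewise not counted.
    """
    if not scheme.positions:
        raise ValueError("scheme has no randomized positions")
    per_position = [
        scheme.mixture_fraction * (1.0 - scheme.mixture.fraction(p.resident_aa))
        for p in scheme.positions
    ]
    expected = sum(per_position)
    return per_position, expected / len(per_position), expected


def apply_coupling_corrections(
    mixture: StandardMixture, renormalize: bool = False
) -> dict[str, float]:
    """Physical molar amount per codon: ``f_i * c_i``.

    With ``renormalize`` the amounts are divided by their sum, giving the
    molar composition actually weighed out by the supplier.
    """
    amounts = {
        e.codon: e.protein_fraction * e.coupling_correction
        for e in mixture.entries
    }
    if renormalize:
        total = sum(amounts.values())
        amounts = {c: a / total for c, a in amounts.items()}
    return amounts
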
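"""Synthetic sequenced-clone generator with exact ground truth.

Clones are drawn from a randomization scheme: at every randomized codon a
trimer is sampled from the position's mixture (resident spike plus
standard mixture), and synthesis errors are planted independently at the
observed rates — whole-codon skips (Δ3), single/double-nucleotide
deletions (Δ1/Δ2) and point substitutions, with separate per-triplet
rates at randomized sites and per-nucleotide rates elsewhere.  The
emitted alignment is gapped against the reference, and every planted
event is recorded, so analyzer output can be checked record for record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .analyzer import AlignedCloneSet, parse_aligned_set
from .mixtures import RandomizationScheme, position_mixture

__all__ = [
    "ErrorModel",
    "GroundTruth",
    "simulate_clones",
    "export_fixture",
    "load_fixture",
]


@dataclass(frozen=True)
class ErrorModel:
    """Synthesis-error rates.

    Randomized-site rates are per triplet, outside rates per nucleotide.
    Defaults are the observed rates of a trimer-synthesized library:
    substitutions 4.9e-3 / 4.3e-4, Δ1 5e-3 / 8.4e-4, Δ2 4e-4 / 4.5e-5,
    Δ3 1.8e-2 / 1.8e-5 (randomized / outside).
    """

    sub_rate_randomized: float = 4.9e-3
    d1_rate_randomized: float = 5e-3
    d2_rate_randomized: float = 4e-4
    d3_rate_randomized: float = 1.8e-2
    sub_rate_outside: float = 4.3e-4
    d1_rate_outside: float = 8.4e-4
    d2_rate_outside: float = 4.5e-5
    d3_rate_outside: float = 1.8e-5

    def __post_init__(self) -> None:
        rates = [getattr(self, f) for f in self.__dataclass_fields__]
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("rates must be in [0, 1]")
        inside = (
            self.sub_rate_randomized
            + self.d1_rate_randomized
            + self.d2_rate_randomized
            + self.d3_rate_randomized
        )
        outside = (
            self.sub_rate_outside
            + self.d1_rate_outside
            + self.d2_rate_outside
            + self.d3_rate_outside
        )
        if inside > 1 or outside > 1:
            raise ValueError("error rates sum to more than 1 at a site class")

    @classmethod
    def zero(cls) -> "ErrorModel":
        return cls(0, 0, 0, 0, 0, 0, 0, 0)


@dataclass
class GroundTruth:
    """Planted events, clone by clone.

    ``codon_exchanges``: (clone, protein position, resident codon, drawn
    codon) for every non-resident draw; ``deletions``: (clone, 1-based nt
    start, run length, at_randomized); ``substitution_errors``: (clone,
    1-based nt position, ref base, new base, at_randomized);
    ``exchange_counts``: planted exchanges per clone.
    """

    codon_exchanges: list[tuple[str, int, str, str]] = field(default_factory=list)
    deletions: list[tuple[str, int, int, bool]] = field(default_factory=list)
    substitution_errors: list[tuple[str, int, str, str, bool]] = field(
        default_factory=list
    )
    exchange_counts: dict[str, int] = field(default_factory=dict)


def simulate_clones(
    gene: str,
    scheme: RandomizationScheme,
    error_model: ErrorModel,
    n_clones: int,
    seed: int,
) -> tuple[AlignedCloneSet, GroundTruth]:
    """Draw ``n_clones`` library members and report the exact ground truth.

    The same seed always yields byte-identical output.  Synthesis errors
    are drawn independently of the codon choice; when a deletion and a
    substitution hit the same site, the deletion wins (larger deletions
    take precedence), matching the analyzer's classification rule.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be at least 1")
    rng = np.random.default_rng(seed)
    gene = gene.upper()
    L = len(gene)
    if L % 3:
        raise ValueError("gene length must be a multiple of 3")
    n_codons = L // 3
    rand_positions = scheme.protein_positions
    rand_set = set(rand_positions)
    bad = [p for p in rand_positions if p > n_codons]
    if bad:
        raise ValueError(f"randomized positions outside the gene: {bad}")

    # per-position codon menus (sorted for determinism)
    menus = []
    for p in rand_positions:
        pm = position_mixture(scheme, p)
        codons = sorted(pm)
        probs = np.array([pm[c] for c in codons])
        menus.append((p, codons, probs / probs.sum()))

    # draw codons for all clones at once, one vectorized draw per position
    draws: dict[int, np.ndarray] = {}
    for p, codons, probs in menus:
        draws[p] = rng.choice(len(codons), size=n_clones, p=probs)

    # outside positions: nucleotide indices (0-based) not in randomized codons
    rand_nt = np.zeros(L, dtype=bool)
    for p in rand_positions:
        rand_nt[3 * (p - 1) : 3 * p] = True
    outside_idx = np.flatnonzero(~rand_nt)

    residents = {p.protein_position: p.resident_codon for p in scheme.positions}
    em = error_model
    truth = GroundTruth()
    names = [f"clone{i + 1}" for i in range(n_clones)]
    targets = []
    bases = np.frombuffer(b"ACGT", dtype="S1")
    ref_arr = np.frombuffer(gene.encode(), dtype="S1")
    for ci, name in enumerate(names):
        arr = ref_arr.copy()
        k = 0
        # planned codon draws
        for p, codons, _ in menus:
            codon = codons[draws[p][ci]]
            if codon != residents[p]:
                k += 1
                truth.codon_exchanges.append((name, p, residents[p], codon))
            arr[3 * (p - 1) : 3 * p] = np.frombuffer(codon.encode(), dtype="S1")
        deleted = np.zeros(L, dtype=bool)
        # errors at randomized triplets (per-triplet rates)
        u = rng.random((len(rand_positions), 4))
        hits = np.flatnonzero(
            (u[:, 0] < em.d3_rate_randomized)
            | (u[:, 1] < em.d2_rate_randomized)
            | (u[:, 2] < em.d1_rate_randomized)
            | (u[:, 3] < em.sub_rate_randomized)
        )
        for h in hits:
            p = rand_positions[h]
            row = u[h]
            start = 3 * (p - 1)
            if row[0] < em.d3_rate_randomized:
                deleted[start : start + 3] = True
                truth.deletions.append((name, start + 1, 3, True))
            elif row[1] < em.d2_rate_randomized:
                off = int(rng.integers(0, 2))
                deleted[start + off : start + off + 2] = True
                truth.deletions.append((name, start + off + 1, 2, True))
            elif row[2] < em.d1_rate_randomized:
                off = int(rng.integers(0, 3))
                deleted[start + off] = True
                truth.deletions.append((name, start + off + 1, 1, True))
            else:
                off = int(rng.integers(0, 3))
                old = arr[start + off]
                choices = bases[bases != old]
                new = choices[int(rng.integers(0, len(choices)))]
                arr[start + off] = new
                truth.substitution_errors.append(
                    (name, start + off + 1, old.decode(), new.decode(), True)
                )
        # errors outside randomized codons (per-nucleotide rates)
        u = rng.random((len(outside_idx), 4))
        hits = np.flatnonzero(
            (u[:, 0] < em.d3_rate_outside)
            | (u[:, 1] < em.d2_rate_outside)
            | (u[:, 2] < em.d1_rate_outside)
            | (u[:, 3] < em.sub_rate_outside)
        )
        for h in hits:
            j = int(outside_idx[h])
            row = u[h]
            if row[0] < em.d3_rate_outside and j + 3 <= L:
                if deleted[j : j + 3].any():
                    continue  # never merge planted deletions
                deleted[j : j + 3] = True
                truth.deletions.append((name, j + 1, 3, False))
            elif row[1] < em.d2_rate_outside and j + 2 <= L:
                if deleted[j : j + 2].any():
                    continue
                deleted[j : j + 2] = True
                truth.deletions.append((name, j + 1, 2, False))
            elif row[2] < em.d1_rate_outside:
                if deleted[j]:
                    continue
                deleted[j] = True
                truth.deletions.append((name, j + 1, 1, False))
            elif row[3] < em.sub_rate_outside:
                if deleted[j]:
                    continue
                old = arr[j]
                choices = bases[bases != old]
                new = choices[int(rng.integers(0, len(choices)))]
                arr[j] = new
                truth.substitution_errors.append(
                    (name, j + 1, old.decode(), new.decode(), False)
                )
        arr[deleted] = b"-"
        targets.append((name, arr.tobytes().decode()))
        truth.exchange_counts[name] = k

    mask = "".join("*" if rand_nt[i] else "." for i in range(L))
    # built gap-aligned against the reference by construction; bypass the
    # target-count warning meant for externally supplied alignments
    cset = AlignedCloneSet(reference=gene, mask=mask, targets=tuple(targets))
    return cset, truth


def export_fixture(
    cset: AlignedCloneSet, truth: GroundTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write the clone set and ground truth as plain-text files.

    ``alignment.fasta`` holds the reference (first record) and the aligned
    clones; ``mask.fasta`` the targeted-codon mask; ``truth.tsv`` the
    planted events.  The round trip through :func:`load_fixture` is
    lossless.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": out / "alignment.fasta",
        "mask": out / "mask.fasta",
        "truth": out / "truth.tsv",
    }
    with open(paths["alignment"], "w") as fh:
        fh.write(f">reference\n{cset.reference}\n")
        for tid, seq in cset.targets:
            fh.write(f">{tid}\n{seq}\n")
    with open(paths["mask"], "w") as fh:
        fh.write(f">mask\n{cset.mask or ''}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("clone\tkind\tposition\tlength\tref\tobs\tat_randomized\n")
        for name, p, ref, obs in truth.codon_exchanges:
            fh.write(f"{name}\texchange\t{p}\t3\t{ref}\t{obs}\ttrue\n")
        for name, pos, length, at in truth.deletions:
            fh.write(
                f"{name}\tdeletion\t{pos}\t{length}\t\t\t"
                f"{'true' if at else 'false'}\n"
            )
        for name, pos, ref, obs, at in truth.substitution_errors:
            fh.write(
                f"{name}\tsubstitution\t{pos}\t1\t{ref}\t{obs}\t"
                f"{'true' if at else 'false'}\n"
            )
    return paths


def load_fixture(fixture_dir: str | Path) -> tuple[AlignedCloneSet, GroundTruth]:
    """Read back a fixture written by :func:`export_fixture`."""
    from .io import read_fasta

    d = Path(fixture_dir)
    records = read_fasta(d / "alignment.fasta")
    if not records:
        raise ValueError("empty alignment file")
    (ref_id, reference), *targets = records
    mask_records = read_fasta(d / "mask.fasta")
    mask = mask_records[0][1] if mask_records and mask_records[0][1] else None
    cset = parse_aligned_set(reference, mask, targets)
    truth = GroundTruth()
    with open(d / "truth.tsv") as fh:
        header = fh.readline()
        for line in fh:
            name, kind, pos, length, ref, obs, at = line.rstrip("\n").split("\t")
            at_b = at == "true"
            if kind == "exchange":
                truth.codon_exchanges.append((name, int(pos), ref, obs))
            elif kind == "deletion":
                truth.deletions.append((name, int(pos), int(length), at_b))
            else:
                truth.substitution_errors.append(
                    (name, int(pos), ref, obs, at_b)
                )
    for name, _ in cset.targets:
        truth.exchange_counts[name] = 0
    for name, *_ in truth.codon_exchanges:
        truth.exchange_counts[name] += 1
    return cset, truth
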
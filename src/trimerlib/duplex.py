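"""Double-stranded DNA with 5' protrusions: fill-in, digestion, ligation.

The :class:`Duplex` model covers exactly the molecule shapes produced by
Klenow fill-in and Type-IIS / blunt restriction digestion: a fully
complementary core with an optional 5' protrusion at either end (top
strand on the left end, bottom strand on the right end; both strands are
stored 5'->3').  Ligation joins ends whose protrusions anneal, in either
fragment orientation, and terminates at unphosphorylated blunt ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .enzymes import EnzymeSpec

__all__ = [
    "Duplex",
    "LigationResult",
    "revcomp",
    "fill_in",
    "digest",
    "ligate",
]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (ACGTN, case-preserving)."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Duplex:
    """A linear dsDNA molecule.

    ``top`` and ``bottom`` are 5'->3'.  ``left_overhang`` nucleotides at the
    top 5' end and ``right_overhang`` nucleotides at the bottom 5' end are
    single-stranded; the remainder is a complementary core.  ``left_phos`` /
    ``right_phos`` flag the 5' phosphates of the top (left end) and bottom
    (right end) strands.
    """

    top: str
    bottom: str
    left_overhang: int = 0
    right_overhang: int = 0
    left_phos: bool = True
    right_phos: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        lo, ro = self.left_overhang, self.right_overhang
        if lo < 0 or ro < 0:
            raise ValueError("overhang lengths must be nonnegative")
        if len(self.top) - lo != len(self.bottom) - ro:
            raise ValueError("strand lengths inconsistent with overhangs")
        if self.top[lo:].upper() != revcomp(self.bottom[ro:]).upper():
            raise ValueError("double-stranded core is not complementary")

    # -- derived geometry -------------------------------------------------
    @property
    def length(self) -> int:
        """Full extent in alignment coordinates (core + both overhangs)."""
        return len(self.top) + self.right_overhang

    @property
    def nt_count(self) -> int:
        """Total nucleotides on both strands (conserved by digest/ligate)."""
        return len(self.top) + len(self.bottom)

    @property
    def left_protrusion(self) -> str:
        """Single-stranded 5' protrusion at the left end (top strand)."""
        return self.top[: self.left_overhang]

    @property
    def right_protrusion(self) -> str:
        """Single-stranded 5' protrusion at the right end (bottom strand)."""
        return self.bottom[: self.right_overhang]

    @property
    def blunt_left(self) -> bool:
        return self.left_overhang == 0

    @property
    def blunt_right(self) -> bool:
        return self.right_overhang == 0

    def flipped(self) -> "Duplex":
        """The same molecule read from the other strand."""
        return Duplex(
            top=self.bottom,
            bottom=self.top,
            left_overhang=self.right_overhang,
            right_overhang=self.left_overhang,
            left_phos=self.right_phos,
            right_phos=self.left_phos,
            name=self.name,
        )

    def dephosphorylated(self, left: bool = True, right: bool = True) -> "Duplex":
        """Copy with 5' phosphates removed from the selected ends."""
        return replace(
            self,
            left_phos=self.left_phos and not left,
            right_phos=self.right_phos and not right,
        )

    @classmethod
    def from_sequence(cls, top: str, name: str = "") -> "Duplex":
        """Blunt duplex from a top-strand sequence (e.g. a PCR product)."""
        return cls(top=top, bottom=revcomp(top), name=name)


def fill_in(template: str, primer: str, name: str = "") -> Duplex:
    """Primer extension (Klenow fill-in) of a single-stranded template.

    The primer must anneal exactly once, at the template's 3' end, i.e.
    its reverse complement must be a unique suffix of the template.  The
    product is the blunt full-length duplex.
    """
    template = template.upper()
    primer = primer.upper()
    site = revcomp(primer)
    n = template.count(site)
    if n == 0:
        raise ValueError("primer does not anneal to the template")
    if n > 1:
        raise ValueError(f"primer anneals at {n} sites on the template")
    if not template.endswith(site):
        raise ValueError("primer does not anneal at the template 3' end")
    return Duplex(top=template, bottom=revcomp(template), name=name)


def _cut_events(duplex: Duplex, enzyme: EnzymeSpec) -> list[tuple[int, int]]:
    """Cut boundaries (top_cut, bottom_cut) in alignment coordinates.

    Only sites fully inside the double-stranded core are cleaved, and only
    if both cut positions also fall inside it.
    """
    top = duplex.top.upper()
    lo, ro = duplex.left_overhang, duplex.right_overhang
    core_start, core_end = lo, len(top)  # ds core in top coordinates
    rec = enzyme.recognition_seq.upper()
    events: set[tuple[int, int]] = set()

    def scan(pattern: str) -> list[int]:
        hits, i = [], top.find(pattern)
        while i != -1:
            hits.append(i)
            i = top.find(pattern, i + 1)
        return hits

    if enzyme.end_type == "blunt":
        for i in scan(rec):
            if i < core_start or i + len(rec) > core_end:
                continue
            cut = i + enzyme.cut_offset
            events.add((cut, cut))
        rc = revcomp(rec)
        if rc != rec:
            for i in scan(rc):
                if i < core_start or i + len(rc) > core_end:
                    continue
                cut = i + len(rec) - enzyme.cut_offset
                events.add((cut, cut))
    else:
        # top-strand site: cuts downstream (rightward)
        for i in scan(rec):
            if i < core_start or i + len(rec) > core_end:
                continue
            tc = i + len(rec) + enzyme.spacer_top
            bc = tc + enzyme.overhang_len
            if tc < core_start or bc > core_end:
                continue
            events.add((tc, bc))
        # bottom-strand site: appears as revcomp on top, cuts leftward
        for j in scan(revcomp(rec)):
            if j < core_start or j + len(rec) > core_end:
                continue
            bc = j - enzyme.spacer_top
            tc = bc - enzyme.overhang_len
            if tc < core_start or bc > core_end:
                continue
            events.add((tc, bc))
    return sorted(events)


def digest(duplex: Duplex, enzyme: EnzymeSpec) -> list[Duplex]:
    """Cleave at every recognition site; zero sites returns the input.

    Products are returned left to right.  Newly created 5' ends are
    phosphorylated; the outer ends keep their flags.
    """
    events = _cut_events(duplex, enzyme)
    if not events:
        return [duplex]
    # global top-orientation sequence over the full alignment extent
    gtop = duplex.top + revcomp(duplex.right_protrusion)
    bounds = (
        [(0, duplex.left_overhang)]
        + events
        + [(len(duplex.top), duplex.length)]
    )
    products = []
    for k in range(len(bounds) - 1):
        tc1, bc1 = bounds[k]
        tc2, bc2 = bounds[k + 1]
        products.append(
            Duplex(
                top=gtop[tc1:tc2],
                bottom=revcomp(gtop[bc1:bc2]),
                left_overhang=bc1 - tc1,
                right_overhang=bc2 - tc2,
                left_phos=duplex.left_phos if k == 0 else True,
                right_phos=duplex.right_phos if k == len(bounds) - 2 else True,
                name=f"{duplex.name}/{k}" if duplex.name else "",
            )
        )
    return products


@dataclass
class LigationResult:
    """Outcome of a ligation: linear products, circular products, and any
    ambiguous overhangs (an end with more than one compatible partner)."""

    products: list[Duplex]
    circular: list[Duplex] = field(default_factory=list)
    ambiguity: list[tuple[str, list[str]]] = field(default_factory=list)

    @property
    def unique_product(self) -> Duplex:
        if self.circular or len(self.products) != 1:
            raise ValueError(
                f"ligation did not yield a single linear product "
                f"({len(self.products)} linear, {len(self.circular)} circular)"
            )
        return self.products[0]


def _join(a: Duplex, b: Duplex) -> Duplex:
    """Join a.right to b.left (protrusions already verified compatible)."""
    return Duplex(
        top=a.top + b.top,
        bottom=b.bottom + a.bottom,
        left_overhang=a.left_overhang,
        right_overhang=b.right_overhang,
        left_phos=a.left_phos,
        right_phos=b.right_phos,
        name="+".join(n for n in (a.name, b.name) if n) or "",
    )


def _ends(idx: int, d: Duplex):
    """The two ligatable ends of fragment ``idx``.

    Each end is (idx, side, protrusion, phosphorylated, blunt) where the
    protrusion is read 5'->3' on its own strand; two ends anneal iff one
    protrusion is the reverse complement of the other (or both are blunt).
    """
    return [
        (idx, "L", d.left_protrusion.upper(), d.left_phos, d.blunt_left),
        (idx, "R", d.right_protrusion.upper(), d.right_phos, d.blunt_right),
    ]


def ligate(fragments: list[Duplex], require_unique: bool = False) -> LigationResult:
    """Sticky/blunt-end ligation of a pool of fragments.

    Ends join when their 5' protrusions are reverse complements of each
    other (fragments may flip, so any end can pair with any other); blunt
    ends join only other blunt ends.  A covalent join requires both 5'
    phosphates.  Chains grow until no compatible ends remain; a chain whose
    outer ends join each other is reported as circular.  With
    ``require_unique`` any overhang with more than one compatible pairing
    raises; otherwise ambiguous ends are left open and reported.
    """
    if len(fragments) < 2:
        raise ValueError("ligation needs at least 2 fragments")
    ends = []
    for i, f in enumerate(fragments):
        ends.extend(_ends(i, f))

    def compatible(e1, e2) -> bool:
        if e1[0] == e2[0] and e1[1] == e2[1]:
            return False
        if not (e1[3] and e2[3]):  # both 5' phosphates required
            return False
        if e1[4] and e2[4]:
            return True  # blunt-blunt
        if e1[4] or e2[4]:
            return False
        return e1[2] == revcomp(e2[2])

    partners: dict[tuple[int, str], list[tuple[int, str]]] = {}
    for a in range(len(ends)):
        for b in range(len(ends)):
            if a == b:
                continue
            if compatible(ends[a], ends[b]):
                partners.setdefault((ends[a][0], ends[a][1]), []).append(
                    (ends[b][0], ends[b][1])
                )

    ambiguity = []
    for (i, side), ps in sorted(partners.items()):
        if len(ps) > 1:
            frag_names = sorted(
                {fragments[j].name or f"fragment {j}" for j, _ in ps}
                | {fragments[i].name or f"fragment {i}"}
            )
            key = ends[[e[:2] for e in ends].index((i, side))][2] or "blunt"
            ambiguity.append((key, frag_names))
    if require_unique and ambiguity:
        detail = "; ".join(f"{k}: {', '.join(v)}" for k, v in ambiguity)
        raise ValueError(f"ambiguous overhang(s) in ligation: {detail}")

    # unambiguous mutual pairings only
    joins = {}
    for key, ps in partners.items():
        if len(ps) == 1 and len(partners.get(ps[0], [])) == 1:
            joins[key] = ps[0]

    used = [False] * len(fragments)
    products, circular = [], []
    order = list(range(len(fragments)))
    # chain starts: fragments with an unpaired end
    for start in order:
        if used[start]:
            continue
        left_open = (start, "L") not in joins
        right_open = (start, "R") not in joins
        if not (left_open or right_open):
            continue  # interior of a chain or part of a circle
        # orient so the open end is on the left
        cur = fragments[start] if left_open else fragments[start].flipped()
        side = "R" if left_open else "L"  # the side we extend from, in original labels
        used[start] = True
        nxt = joins.get((start, side))
        while nxt is not None:
            j, jside = nxt
            piece = fragments[j] if jside == "L" else fragments[j].flipped()
            cur = _join(cur, piece)
            used[j] = True
            follow = "R" if jside == "L" else "L"
            nxt = joins.get((j, follow))
        products.append(cur)
    # remaining fully-paired components are circles
    for start in order:
        if used[start]:
            continue
        cur = fragments[start]
        used[start] = True
        nxt = joins.get((start, "R"))
        while nxt is not None and nxt[0] != start:
            j, jside = nxt
            piece = fragments[j] if jside == "L" else fragments[j].flipped()
            cur = _join(cur, piece)
            used[j] = True
            follow = "R" if jside == "L" else "L"
            nxt = joins.get((j, follow))
        circular.append(cur)
    return LigationResult(products=products, circular=circular, ambiguity=ambiguity)
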
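"""Mutation-site analysis of aligned clone sequences.

Sequenced clones, pre-aligned against the wild-type reference, are
compared position by position at nucleotide, codon and amino-acid level.
In site-directed mode a mask marks the codons targeted by randomization;
events are stratified into targeted and non-targeted classes, deletions
are classified by run length (Δ1/Δ2/Δ3), and the results are emitted as
five report tables plus the library-analysis summary statistics
(per-position exchange rates, replacing-residue spectrum, mutant-class
histogram).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats as sps

__all__ = [
    "AlignedCloneSet",
    "MutationRecord",
    "ReportBundle",
    "DeletionStats",
    "SummaryStatistics",
    "parse_aligned_set",
    "call_mutations",
    "classify_deletions",
    "musi_reports",
    "summary_statistics",
    "MUSI_TARGET_LIMIT",
]

#: historical per-run limit on the number of target sequences, enforced
#: only in strict mode.
MUSI_TARGET_LIMIT = 250

_GAP = "-"
_PUR = {"A", "G"}
_PYR = {"C", "T"}


@dataclass(frozen=True)
class AlignedCloneSet:
    """Reference, optional targeted-codon mask, and aligned clones.

    All strings have equal length; gaps are ``-``.  The mask marks targeted
    columns with ``*`` (anything else is untargeted); in random-mutagenesis
    mode the mask is ``None``.  Masked regions must cover whole codons of
    the ungapped reference frame.
    """

    reference: str
    mask: str | None
    targets: tuple[tuple[str, str], ...]

    @property
    def site_directed(self) -> bool:
        return self.mask is not None

    @property
    def ref_length(self) -> int:
        """Ungapped reference length in nucleotides."""
        return sum(1 for c in self.reference if c != _GAP)

    def ref_columns(self) -> list[int]:
        """Alignment columns holding reference nucleotides, in order."""
        return [i for i, c in enumerate(self.reference) if c != _GAP]

    def targeted_codons(self) -> list[int]:
        """1-based codon indices (reference frame) covered by the mask."""
        if self.mask is None:
            return []
        cols = self.ref_columns()
        targeted = set()
        for refpos0, col in enumerate(cols):
            if self.mask[col] == "*":
                targeted.add(refpos0 // 3 + 1)
        return sorted(targeted)


def parse_aligned_set(
    reference: str,
    mask: str | None,
    targets: list[tuple[str, str]],
    strict_musi: bool = False,
) -> AlignedCloneSet:
    """Validate and build an :class:`AlignedCloneSet`.

    Raises on unequal lengths or a mask that does not cover whole codons;
    more than 250 targets raises in strict mode and warns otherwise.
    """
    n = len(reference)
    if n == 0:
        raise ValueError("empty reference")
    if mask is not None and len(mask) != n:
        raise ValueError(
            f"mask length {len(mask)} differs from alignment length {n}"
        )
    for tid, seq in targets:
        if len(seq) != n:
            raise ValueError(
                f"target {tid}: length {len(seq)} differs from alignment "
                f"length {n}"
            )
    if len(targets) > MUSI_TARGET_LIMIT:
        msg = (
            f"{len(targets)} target sequences exceed the classic limit of "
            f"{MUSI_TARGET_LIMIT}"
        )
        if strict_musi:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    cset = AlignedCloneSet(
        reference=reference.upper(),
        mask=mask,
        targets=tuple((tid, seq.upper()) for tid, seq in targets),
    )
    if mask is not None:
        cols = cset.ref_columns()
        by_codon: dict[int, list[bool]] = {}
        for refpos0, col in enumerate(cols):
            by_codon.setdefault(refpos0 // 3, []).append(mask[col] == "*")
        for codon0, flags in by_codon.items():
            if any(flags) and not (all(flags) and len(flags) == 3):
                raise ValueError(
                    f"mask is not codon-aligned at reference codon {codon0 + 1}"
                )
    return cset


@dataclass(frozen=True)
class MutationRecord:
    """One called event at nucleotide, codon or amino-acid level.

    Positions are 1-based in the ungapped reference frame (nucleotides for
    nucleotide-level records, codon indices otherwise).  ``run_length`` is
    set for deletion events (the full length of the maximal gap run);
    ``flagged`` marks records involving non-ACGT characters.
    """

    target_id: str
    level: str  # nucleotide | codon | amino_acid
    position: int
    ref_state: str
    obs_state: str
    event_class: str  # substitution | deletion_1 | deletion_2 | deletion_3
    #                 # | deletion_run | insertion
    in_targeted_codon: bool
    run_length: int | None = None
    flagged: bool = False


def _ref_codons(cset: AlignedCloneSet) -> list[str]:
    ungapped = cset.reference.replace(_GAP, "")
    return [ungapped[i : i + 3] for i in range(0, len(ungapped) - 2, 3)]


def call_mutations(cset: AlignedCloneSet) -> list[MutationRecord]:
    """Compare every target to the reference at all three levels.

    Gap runs in a target are grouped into maximal runs before
    classification (Δ1/Δ2/Δ3; longer runs become per-nucleotide
    ``deletion_run`` records).  A codon containing any gap is classified by
    the deletion and produces no codon-substitution record; silent codon
    changes yield nucleotide and codon records but no amino-acid record.
    Non-ACGT characters flag the record instead of aborting.
    """
    cols = cset.ref_columns()
    targeted = set(cset.targeted_codons())
    records: list[MutationRecord] = []
    for tid, seq in cset.targets:
        # nucleotide level over reference positions
        gaps: list[int] = []  # 1-based ref positions deleted in this target
        for refpos0, col in enumerate(cols):
            r, t = cset.reference[col], seq[col]
            pos = refpos0 + 1
            codon_idx = refpos0 // 3 + 1
            if t == _GAP:
                gaps.append(pos)
            elif t != r:
                records.append(
                    MutationRecord(
                        target_id=tid,
                        level="nucleotide",
                        position=pos,
                        ref_state=r,
                        obs_state=t,
                        event_class="substitution",
                        in_targeted_codon=codon_idx in targeted,
                        flagged=t not in "ACGT",
                    )
                )
        # maximal gap runs
        for start, length in _runs(gaps):
            codon_idx = (start - 1) // 3 + 1
            if length <= 3:
                records.append(
                    MutationRecord(
                        target_id=tid,
                        level="nucleotide",
                        position=start,
                        ref_state=_ref_slice(cset, start, length),
                        obs_state=_GAP * length,
                        event_class=f"deletion_{length}",
                        in_targeted_codon=codon_idx in targeted,
                        run_length=length,
                    )
                )
            else:
                for k in range(length):
                    records.append(
                        MutationRecord(
                            target_id=tid,
                            level="nucleotide",
                            position=start + k,
                            ref_state=_ref_slice(cset, start + k, 1),
                            obs_state=_GAP,
                            event_class="deletion_run",
                            in_targeted_codon=((start + k - 1) // 3 + 1)
                            in targeted,
                            run_length=length,
                        )
                    )
        # insertions: target bases opposite reference gaps
        prev_refpos = 0
        for col, r in enumerate(cset.reference):
            if r != _GAP:
                prev_refpos += 1
            elif seq[col] != _GAP:
                records.append(
                    MutationRecord(
                        target_id=tid,
                        level="nucleotide",
                        position=prev_refpos,
                        ref_state=_GAP,
                        obs_state=seq[col],
                        event_class="insertion",
                        in_targeted_codon=False,
                        flagged=seq[col] not in "ACGT",
                    )
                )
        # codon and amino-acid level
        obs_by_refpos = {refpos0 + 1: seq[col] for refpos0, col in enumerate(cols)}
        for codon_idx, ref_codon in enumerate(_ref_codons(cset), start=1):
            obs = "".join(
                obs_by_refpos[p] for p in range(3 * codon_idx - 2, 3 * codon_idx + 1)
            )
            if _GAP in obs:
                continue  # classified by the deletion run
            if obs == ref_codon:
                continue
            has_n = any(c not in "ACGT" for c in obs)
            records.append(
                MutationRecord(
                    target_id=tid,
                    level="codon",
                    position=codon_idx,
                    ref_state=ref_codon,
                    obs_state=obs,
                    event_class="substitution",
                    in_targeted_codon=codon_idx in targeted,
                    flagged=has_n,
                )
            )
            ref_aa = str(Seq(ref_codon).translate())
            obs_aa = "X" if has_n else str(Seq(obs).translate())
            if obs_aa != ref_aa and not has_n:
                records.append(
                    MutationRecord(
                        target_id=tid,
                        level="amino_acid",
                        position=codon_idx,
                        ref_state=ref_aa,
                        obs_state=obs_aa,
                        event_class="substitution",
                        in_targeted_codon=codon_idx in targeted,
                    )
                )
    return records


def _runs(sorted_positions: list[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers as (start, length)."""
    runs = []
    for p in sorted_positions:
        if runs and p == runs[-1][0] + runs[-1][1]:
            runs[-1] = (runs[-1][0], runs[-1][1] + 1)
        else:
            runs.append((p, 1))
    return runs


def _ref_slice(cset: AlignedCloneSet, start: int, length: int) -> str:
    ungapped = cset.reference.replace(_GAP, "")
    return ungapped[start - 1 : start - 1 + length]


@dataclass
class DeletionStats:
    """Δ1/Δ2/Δ3 counts and rates, inside (per targeted triplet) and
    outside (per nucleotide) the randomized codons."""

    counts_inside: dict[str, int]
    counts_outside: dict[str, int]
    triplets_inside: int
    nucleotides_outside: int
    anomalous_runs: int

    def rate_inside(self, k: int) -> float:
        return self.counts_inside[f"deletion_{k}"] / self.triplets_inside

    def rate_outside(self, k: int) -> float:
        return self.counts_outside[f"deletion_{k}"] / self.nucleotides_outside


def classify_deletions(
    records: list[MutationRecord], cset: AlignedCloneSet
) -> DeletionStats:
    """Stratify maximal gap runs into Δ1/Δ2/Δ3 inside vs. outside the
    targeted codons; runs longer than 3 are excluded and counted as
    anomalous."""
    n_targets = len(cset.targets)
    n_targeted = len(cset.targeted_codons())
    inside = {f"deletion_{k}": 0 for k in (1, 2, 3)}
    outside = {f"deletion_{k}": 0 for k in (1, 2, 3)}
    run_positions: dict[str, list[int]] = {}
    for rec in records:
        if rec.event_class in inside and rec.level == "nucleotide":
            (inside if rec.in_targeted_codon else outside)[rec.event_class] += 1
        elif rec.event_class == "deletion_run":
            run_positions.setdefault(rec.target_id, []).append(rec.position)
    anomalous = sum(
        len(_runs(sorted(ps))) for ps in run_positions.values()
    )
    return DeletionStats(
        counts_inside=inside,
        counts_outside=outside,
        triplets_inside=n_targets * n_targeted,
        nucleotides_outside=n_targets * (cset.ref_length - 3 * n_targeted),
        anomalous_runs=anomalous,
    )


@dataclass
class ReportBundle:
    """The five report tables.

    sheet1: per-target nucleotide events (all positions);
    sheet2: per-target codon events (targeted codons in site-directed
    mode, all codons otherwise); sheet3: observed residues at targeted
    positions per target, plus per-target deletion summary; sheet4:
    codon-substitution counts per position x replacing residue with
    margins, plus Δ1/Δ2/Δ3 totals; sheet5: transitions, transversions and
    deletions outside the targeted codons.
    """

    sheet1_nt: pd.DataFrame
    sheet2_codon: pd.DataFrame
    sheet3_aa: pd.DataFrame
    sheet4_substitution_matrix: pd.DataFrame
    sheet4_deletion_totals: pd.Series
    sheet5_titv: pd.DataFrame


def musi_reports(
    cset: AlignedCloneSet, records: list[MutationRecord]
) -> ReportBundle:
    """Assemble the five report tables from called mutation records."""
    targeted = cset.targeted_codons()
    # sheet 1: nucleotide level, all positions
    nt = [
        {
            "target": r.target_id,
            "position": r.position,
            "ref": r.ref_state,
            "obs": r.obs_state,
            "event": r.event_class,
            "targeted_codon": r.in_targeted_codon,
        }
        for r in records
        if r.level == "nucleotide"
    ]
    sheet1 = pd.DataFrame(
        nt, columns=["target", "position", "ref", "obs", "event", "targeted_codon"]
    )
    # sheet 2: codon level
    codon_recs = [r for r in records if r.level == "codon"]
    del_recs = [
        r
        for r in records
        if r.level == "nucleotide" and r.event_class.startswith("deletion")
    ]
    rows = []
    for r in codon_recs:
        if cset.site_directed and not r.in_targeted_codon:
            continue
        rows.append(
            {
                "target": r.target_id,
                "codon": r.position,
                "ref_codon": r.ref_state,
                "obs_codon": r.obs_state,
                "event": "substitution",
            }
        )
    ref_codons = _ref_codons(cset)
    for r in del_recs:
        codon_idx = (r.position - 1) // 3 + 1
        if cset.site_directed and codon_idx not in targeted:
            continue
        rows.append(
            {
                "target": r.target_id,
                "codon": codon_idx,
                "ref_codon": ref_codons[codon_idx - 1],
                "obs_codon": r.obs_state,
                "event": r.event_class,
            }
        )
    sheet2 = pd.DataFrame(
        rows, columns=["target", "codon", "ref_codon", "obs_codon", "event"]
    ).sort_values(["target", "codon"], kind="stable", ignore_index=True)
    # sheet 3: residues at targeted positions per target
    positions = targeted if cset.site_directed else list(
        range(1, len(ref_codons) + 1)
    )
    obs_codon = {
        (r.target_id, r.position): r.obs_state for r in codon_recs
    }
    deleted: dict[tuple[str, int], str] = {}
    for r in del_recs:
        deleted[(r.target_id, (r.position - 1) // 3 + 1)] = "del"
    del_counts: dict[tuple[str, int], int] = {}
    for r in del_recs:
        if r.event_class.startswith("deletion_") and r.run_length in (1, 2, 3):
            key = (r.target_id, r.run_length)
            del_counts[key] = del_counts.get(key, 0) + 1
    rows3 = []
    for tid, _ in cset.targets:
        row: dict[str, object] = {"target": tid}
        for p in positions:
            if (tid, p) in deleted:
                aa = "del"
            elif (tid, p) in obs_codon:
                obs = obs_codon[(tid, p)]
                aa = "X" if any(c not in "ACGT" for c in obs) else str(
                    Seq(obs).translate()
                )
            else:
                aa = str(Seq(ref_codons[p - 1]).translate())
            row[f"pos{p}"] = aa
        for k in (1, 2, 3):
            row[f"n_del{k}"] = del_counts.get((tid, k), 0)
        rows3.append(row)
    sheet3 = pd.DataFrame(rows3)
    # sheet 4: substitution counts per position x replacing residue
    aas = list("ACDEFGHIKLMNPQRSTVWY") + ["*", "X"]
    counted = [
        r
        for r in codon_recs
        if (not cset.site_directed) or r.in_targeted_codon
    ]
    mat = pd.DataFrame(
        0, index=[f"pos{p}" for p in positions], columns=aas, dtype=int
    )
    for r in counted:
        obs = r.obs_state
        aa = "X" if any(c not in "ACGT" for c in obs) else str(Seq(obs).translate())
        mat.loc[f"pos{r.position}", aa] += 1
    mat["total"] = mat.sum(axis=1)
    mat.loc["total"] = mat.sum(axis=0)
    dstats = classify_deletions(records, cset)
    deletion_totals = pd.Series(
        {
            f"delta{k}": dstats.counts_inside[f"deletion_{k}"]
            + dstats.counts_outside[f"deletion_{k}"]
            for k in (1, 2, 3)
        }
    )
    # sheet 5: transitions / transversions / deletions outside targeted codons
    subs_out = [
        r
        for r in records
        if r.level == "nucleotide"
        and r.event_class == "substitution"
        and not r.in_targeted_codon
        and not r.flagged
    ]
    rows5 = []
    for ref_b in "ACGT":
        for obs_b in "ACGT":
            if ref_b == obs_b:
                continue
            klass = (
                "transition"
                if {ref_b, obs_b} in ({"A", "G"}, {"C", "T"})
                else "transversion"
            )
            count = sum(
                1 for r in subs_out if r.ref_state == ref_b and r.obs_state == obs_b
            )
            rows5.append(
                {"event": f"{ref_b}>{obs_b}", "class": klass, "count": count}
            )
    for k in (1, 2, 3):
        rows5.append(
            {
                "event": f"delta{k}",
                "class": "deletion",
                "count": dstats.counts_outside[f"deletion_{k}"],
            }
        )
    sheet5 = pd.DataFrame(rows5, columns=["event", "class", "count"])
    return ReportBundle(
        sheet1_nt=sheet1,
        sheet2_codon=sheet2,
        sheet3_aa=sheet3,
        sheet4_substitution_matrix=mat,
        sheet4_deletion_totals=deletion_totals,
        sheet5_titv=sheet5,
    )


@dataclass
class SummaryStatistics:
    """Library-analysis summary for a targeted-codon clone set."""

    per_position: pd.DataFrame  # position, resident_aa, exchanges, rate, expected
    per_residue: pd.DataFrame  # resident_aa, n_positions, exchanges, rate, expected
    replacing_distribution: pd.Series  # normalized over all exchanges
    class_histogram: pd.DataFrame  # k, observed, expected (binomial)
    overall_rate: float
    n_clones: int
    n_triplets: int
    n_exchanges: int


def summary_statistics(
    cset: AlignedCloneSet,
    records: list[MutationRecord],
    scheme,
) -> SummaryStatistics:
    """Observed exchange rates against the randomization scheme.

    The observed rate at a position is the number of non-wild-type codons
    found there divided by the number of clones sequenced; codons hit by a
    deletion or containing ambiguous bases are excluded from the
    numerator, N-containing codons also from the denominator.
    """
    from .mixtures import exchange_probabilities

    if not cset.targets:
        raise ValueError("no clones to summarize")
    if not cset.site_directed:
        raise ValueError("summary statistics require a targeted-codon mask")
    targeted = cset.targeted_codons()
    n_clones = len(cset.targets)
    per_pos_expected = dict(
        zip(scheme.protein_positions, exchange_probabilities(scheme)[0])
    )
    exchanges = {
        p: [
            r
            for r in records
            if r.level == "codon"
            and r.position == p
            and not r.flagged
        ]
        for p in targeted
    }
    flagged_codons = {
        p: sum(
            1
            for r in records
            if r.level == "codon" and r.position == p and r.flagged
        )
        for p in targeted
    }
    rows = []
    for p in targeted:
        resident = scheme.position(p).resident_aa if p in per_pos_expected else "?"
        denom = n_clones - flagged_codons[p]
        rows.append(
            {
                "position": p,
                "resident_aa": resident,
                "exchanges": len(exchanges[p]),
                "n_clones": denom,
                "observed_rate": len(exchanges[p]) / denom if denom else np.nan,
                "expected_rate": per_pos_expected.get(p, np.nan),
            }
        )
    per_position = pd.DataFrame(rows)
    per_residue = (
        per_position.groupby("resident_aa")
        .agg(
            n_positions=("position", "size"),
            exchanges=("exchanges", "sum"),
            n_codons=("n_clones", "sum"),
            expected_rate=("expected_rate", "mean"),
        )
        .assign(observed_rate=lambda d: d.exchanges / d.n_codons)
        .reset_index()
    )
    all_exch = [r for p in targeted for r in exchanges[p]]
    repl = pd.Series(
        [str(Seq(r.obs_state).translate()) for r in all_exch], dtype=object
    )
    replacing = (
        repl.value_counts(normalize=True).sort_index()
        if len(repl)
        else pd.Series(dtype=float)
    )
    # mutant-class histogram vs. matched binomial expectation
    per_clone = {tid: 0 for tid, _ in cset.targets}
    for r in all_exch:
        per_clone[r.target_id] += 1
    n = len(targeted)
    ks = np.arange(n + 1)
    observed = np.bincount(list(per_clone.values()), minlength=n + 1)[: n + 1]
    p_mean = float(np.mean([per_pos_expected[p] for p in targeted]))
    expected = n_clones * sps.binom.pmf(ks, n, p_mean)
    class_histogram = pd.DataFrame(
        {"k": ks, "observed": observed, "expected": expected}
    )
    n_triplets = int(per_position["n_clones"].sum())
    n_exch = int(per_position["exchanges"].sum())
    return SummaryStatistics(
        per_position=per_position,
        per_residue=per_residue,
        replacing_distribution=replacing,
        class_histogram=class_histogram,
        overall_rate=n_exch / n_triplets if n_triplets else np.nan,
        n_clones=n_clones,
        n_triplets=n_triplets,
        n_exchanges=n_exch,
    )
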
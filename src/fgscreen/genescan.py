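"""Detection of gene-inactivating mutations in codon alignments and the
%intact statistic.

A gene is represented by a codon-aware pairwise alignment of a reference
coding sequence against the orthologous query locus.  Lesions that disrupt
the reading frame — frameshifting insertions/deletions, premature stop
codons, mutated splice-site dinucleotides, exon and whole-gene deletions —
are called from the alignment and summarised into the maximum percentage of
the reading frame that remains free of lesions and assembly gaps (%intact).
Species-level gene status (intact / lost / uncertain / missing) follows
fixed %intact and presence thresholds.

Coordinate convention: 0-based, half-open, in codon units throughout.
Nucleotide-level lesions are snapped to the codon containing their first
affected base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, floor
from typing import Sequence

import numpy as np

__all__ = [
    "CodingAlignment",
    "MutationEvent",
    "IntactnessRecord",
    "MutationKind",
    "detect_mutations",
    "percent_intact",
    "classify_status",
    "classify_transcript_central80",
    "intactness_record",
    "STOP_CODONS",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: canonical splice dinucleotides; GC donors occur in a small fraction of
#: real introns and are tolerated by default
CANONICAL_DONORS = frozenset({"GT"})
TOLERATED_DONORS = frozenset({"GT", "GC"})
CANONICAL_ACCEPTOR = "AG"

GAP = "-"
ABSENT = "N"


class MutationKind:
    """String constants for the recognised lesion kinds."""

    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    PREMATURE_STOP = "premature_stop"
    SPLICE_SITE = "splice_site"
    EXON_DELETION = "exon_deletion"
    GENE_DELETION = "gene_deletion"

    ALL = (
        FRAMESHIFT_INSERTION,
        FRAMESHIFT_DELETION,
        PREMATURE_STOP,
        SPLICE_SITE,
        EXON_DELETION,
        GENE_DELETION,
    )


@dataclass(frozen=True, order=True)
class MutationEvent:
    """One gene-inactivating lesion in one species.

    ``codon_start``/``codon_end`` span the affected reading frame in 0-based
    half-open codon coordinates.  Premature stops span exactly one codon; a
    whole-gene deletion spans ``[0, L)``.
    """

    codon_start: int
    codon_end: int
    kind: str
    gene_id: str = ""
    species_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in MutationKind.ALL:
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if not (0 <= self.codon_start < self.codon_end):
            raise ValueError(
                f"invalid codon span [{self.codon_start}, {self.codon_end})"
            )
        if self.kind == MutationKind.PREMATURE_STOP and (
            self.codon_end != self.codon_start + 1
        ):
            raise ValueError("premature_stop must span exactly one codon")

    @property
    def key(self) -> tuple[str, int]:
        """Identity used when matching lesions across species."""
        return (self.kind, self.codon_start)


class AlignmentError(ValueError):
    """Raised for malformed codon alignments."""


@dataclass
class CodingAlignment:
    """Codon-aware pairwise alignment of one gene in one species.

    ``ref_aln`` and ``query_aln`` are equal-length aligned sequences.
    Columns where the reference carries ``-`` are insertions in the query;
    columns where the query carries ``-`` are deletions.  ``N`` in the query
    marks sequence absent from the assembly (not a lesion).  The ungapped
    reference has length ``3 * n_codons`` and ends in its single stop codon.

    ``exon_bounds`` are disjoint, sorted half-open codon intervals tiling
    ``[0, n_codons)``.  ``splice_sites[i] = (donor, acceptor)`` holds the
    query dinucleotides flanking the boundary between exon ``i`` and exon
    ``i + 1``.
    """

    gene_id: str
    species_id: str
    ref_aln: str
    query_aln: str
    exon_bounds: list[tuple[int, int]]
    splice_sites: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ref_aln) != len(self.query_aln):
            raise AlignmentError(
                f"{self.gene_id}/{self.species_id}: reference and query "
                f"alignment lengths differ ({len(self.ref_aln)} vs "
                f"{len(self.query_aln)})"
            )
        ref = self.ref_aln.replace(GAP, "")
        if len(ref) % 3 != 0 or not ref:
            raise AlignmentError(
                f"{self.gene_id}/{self.species_id}: ungapped reference length "
                f"{len(ref)} is not a positive multiple of 3"
            )
        L = len(ref) // 3
        codons = [ref[3 * i : 3 * i + 3].upper() for i in range(L)]
        stops = [i for i, c in enumerate(codons) if c in STOP_CODONS]
        if stops != [L - 1]:
            raise AlignmentError(
                f"{self.gene_id}/{self.species_id}: reference must contain "
                f"exactly one stop codon, at the last position (found at "
                f"{stops})"
            )
        bounds = sorted(self.exon_bounds)
        if bounds != self.exon_bounds:
            raise AlignmentError(
                f"{self.gene_id}/{self.species_id}: exon bounds not sorted"
            )
        pos = 0
        for s, e in bounds:
            if s != pos or e <= s:
                raise AlignmentError(
                    f"{self.gene_id}/{self.species_id}: exon intervals must "
                    f"tile [0, {L}) (bad interval [{s}, {e}))"
                )
            pos = e
        if pos != L:
            raise AlignmentError(
                f"{self.gene_id}/{self.species_id}: exons end at {pos}, "
                f"expected {L}"
            )
        if self.splice_sites and len(self.splice_sites) != len(bounds) - 1:
            raise AlignmentError(
                f"{self.gene_id}/{self.species_id}: expected "
                f"{len(bounds) - 1} splice-site pairs, got "
                f"{len(self.splice_sites)}"
            )
        self._n_codons = L
        # alignment column of each reference base
        cols = np.flatnonzero(np.frombuffer(self.ref_aln.encode(), dtype="S1") != GAP.encode())
        self._ref_cols = cols

    @property
    def n_codons(self) -> int:
        return self._n_codons

    def codon_columns(self, i: int) -> np.ndarray:
        """Alignment columns of the three bases of reference codon ``i``."""
        return self._ref_cols[3 * i : 3 * i + 3]

    @property
    def present_mask(self) -> np.ndarray:
        """True for reference codons covered by aligned query sequence.

        A codon is absent when any of its bases aligns to an assembly gap
        (``N``) in the query.
        """
        q = np.frombuffer(self.query_aln.upper().encode(), dtype="S1")
        absent_base = q[self._ref_cols] == ABSENT.encode()
        return ~absent_base.reshape(self._n_codons, 3).any(axis=1)

    def query_codon(self, i: int) -> str:
        """Query bases opposite the three bases of reference codon ``i``."""
        return "".join(self.query_aln[c] for c in self.codon_columns(i)).upper()


def _deleted_exons(aln: CodingAlignment, present: np.ndarray) -> list[int]:
    """Exons whose entire aligned query is gap while the locus is present."""
    out = []
    for idx, (s, e) in enumerate(aln.exon_bounds):
        if not present[s:e].all():
            continue
        cols = aln._ref_cols[3 * s : 3 * e]
        if all(aln.query_aln[c] == GAP for c in cols):
            out.append(idx)
    return out


def detect_mutations(
    aln: CodingAlignment,
    *,
    tolerate_gc_donor: bool = True,
) -> list[MutationEvent]:
    """Call all gene-inactivating lesions in a codon alignment.

    Returns events sorted by codon position.  Codons absent from the
    assembly (``present_mask`` false) are never called as mutations; an
    exon aligned entirely to gaps is an exon deletion, and all exons
    deleted with the locus present is a whole-gene deletion.
    """
    L = aln.n_codons
    present = aln.present_mask
    events: list[MutationEvent] = []

    def ev(kind: str, start: int, end: int) -> MutationEvent:
        return MutationEvent(
            kind=kind,
            codon_start=start,
            codon_end=end,
            gene_id=aln.gene_id,
            species_id=aln.species_id,
        )

    deleted = _deleted_exons(aln, present)
    if len(deleted) == len(aln.exon_bounds):
        return [ev(MutationKind.GENE_DELETION, 0, L)]
    deleted_codons = np.zeros(L, dtype=bool)
    for idx in deleted:
        s, e = aln.exon_bounds[idx]
        events.append(ev(MutationKind.EXON_DELETION, s, e))
        deleted_codons[s:e] = True

    # --- indels: maximal runs of alignment columns that are gapped on
    # either side; the net length decides frameshift status
    ncols = len(aln.ref_aln)
    ref_base_of_col = np.full(ncols, -1, dtype=int)
    ref_base_of_col[aln._ref_cols] = np.arange(3 * L)
    qup = aln.query_aln.upper()

    def col_in_deleted_exon(c: int) -> bool:
        b = ref_base_of_col[c]
        return b >= 0 and deleted_codons[b // 3]

    def col_absent(c: int) -> bool:
        b = ref_base_of_col[c]
        if b >= 0:
            return not present[b // 3]
        return qup[c] == ABSENT

    c = 0
    while c < ncols:
        is_gap = (aln.ref_aln[c] == GAP or aln.query_aln[c] == GAP) and not (
            col_in_deleted_exon(c) or col_absent(c)
        )
        if not is_gap:
            c += 1
            continue
        start = c
        ins = dele = 0
        first_base: int | None = None
        while c < ncols and (
            (aln.ref_aln[c] == GAP or aln.query_aln[c] == GAP)
            and not (col_in_deleted_exon(c) or col_absent(c))
        ):
            if aln.ref_aln[c] == GAP:
                ins += 1
            else:
                dele += 1
                if first_base is None:
                    first_base = ref_base_of_col[c]
            c += 1
        net = ins - dele
        if net % 3 != 0:
            if first_base is None:
                # pure insertion: snap to the codon of the next reference base
                nxt = ref_base_of_col[c:][ref_base_of_col[c:] >= 0]
                first_base = int(nxt[0]) if nxt.size else 3 * L - 1
            codon = first_base // 3
            if present[codon]:
                kind = (
                    MutationKind.FRAMESHIFT_INSERTION
                    if net > 0
                    else MutationKind.FRAMESHIFT_DELETION
                )
                events.append(ev(kind, codon, codon + 1))

    # --- premature stops, read in the reference frame; the terminal codon
    # is never premature
    for i in range(L - 1):
        if not present[i] or deleted_codons[i]:
            continue
        q = aln.query_codon(i)
        if GAP in q or ABSENT in q:
            continue
        if q in STOP_CODONS:
            events.append(ev(MutationKind.PREMATURE_STOP, i, i + 1))

    # --- splice sites
    donors = TOLERATED_DONORS if tolerate_gc_donor else CANONICAL_DONORS
    for i, (donor, acceptor) in enumerate(aln.splice_sites):
        left_s, left_e = aln.exon_bounds[i]
        right_s, right_e = aln.exon_bounds[i + 1]
        donor = donor.upper()
        acceptor = acceptor.upper()
        if (
            donor not in donors
            and ABSENT not in donor
            and present[left_e - 1]
            and not deleted_codons[left_e - 1]
        ):
            events.append(ev(MutationKind.SPLICE_SITE, left_e - 1, left_e))
        if (
            acceptor != CANONICAL_ACCEPTOR
            and ABSENT not in acceptor
            and present[right_s]
            and not deleted_codons[right_s]
        ):
            events.append(ev(MutationKind.SPLICE_SITE, right_s, right_s + 1))

    events.sort(key=lambda e: (e.codon_start, e.codon_end, e.kind))
    return events


def percent_intact(
    muts: Sequence[MutationEvent],
    n_codons: int,
    present_mask: np.ndarray | None = None,
) -> float:
    """Maximum percentage of the reading frame free of lesions and gaps.

    Breakpoints are the codon spans of all mutations plus all runs of
    absent codons; the statistic is ``100 * longest clean run / n_codons``.
    Mutation-free, fully present genes score 100; a whole-gene deletion
    scores 0.
    """
    if n_codons <= 0:
        raise ValueError("n_codons must be positive")
    broken = np.zeros(n_codons, dtype=bool)
    for m in muts:
        if m.codon_end > n_codons:
            raise ValueError(
                f"mutation span [{m.codon_start}, {m.codon_end}) exceeds "
                f"gene length {n_codons}"
            )
        broken[m.codon_start : m.codon_end] = True
    if present_mask is not None:
        present_mask = np.asarray(present_mask, dtype=bool)
        if present_mask.shape != (n_codons,):
            raise ValueError("present_mask length must equal n_codons")
        broken |= ~present_mask
    best = run = 0
    for b in broken:
        run = 0 if b else run + 1
        best = max(best, run)
    return 100.0 * best / n_codons


def classify_status(
    pct_intact: float,
    present_fraction: float = 1.0,
    *,
    loss_thr: float = 60.0,
    intact_thr: float = 90.0,
    missing_thr: float = 0.5,
) -> str:
    """Species-level gene status from %intact and assembly presence.

    ``missing`` when less than ``missing_thr`` of the coding sequence is
    present in the assembly; otherwise ``lost`` below ``loss_thr`` %intact,
    ``intact`` at or above ``intact_thr``, ``uncertain`` between.
    """
    if not (0.0 <= loss_thr <= intact_thr <= 100.0):
        raise ValueError("thresholds must satisfy 0 <= loss <= intact <= 100")
    if not (0.0 <= pct_intact <= 100.0):
        raise ValueError(f"%intact out of range: {pct_intact}")
    if not (0.0 <= present_fraction <= 1.0):
        raise ValueError(f"present_fraction out of range: {present_fraction}")
    if present_fraction < missing_thr:
        return "missing"
    if pct_intact < loss_thr:
        return "lost"
    if pct_intact >= intact_thr:
        return "intact"
    return "uncertain"


@dataclass(frozen=True)
class IntactnessRecord:
    """%intact summary for one (gene, species)."""

    gene_id: str
    species_id: str
    percent_intact: float
    present_fraction: float
    n_mutations: int
    status: str


def intactness_record(
    aln: CodingAlignment,
    muts: Sequence[MutationEvent] | None = None,
    **thresholds: float,
) -> IntactnessRecord:
    """Detect mutations (unless given) and summarise one alignment."""
    if muts is None:
        muts = detect_mutations(aln)
    present = aln.present_mask
    pf = float(present.mean())
    pi = percent_intact(muts, aln.n_codons, present)
    return IntactnessRecord(
        gene_id=aln.gene_id,
        species_id=aln.species_id,
        percent_intact=pi,
        present_fraction=pf,
        n_mutations=len(muts),
        status=classify_status(pi, pf, **thresholds),
    )


def classify_transcript_central80(aln: CodingAlignment) -> str:
    """Transcript-level classification from the central 80% of the CDS.

    ``missing`` when less than half the coding sequence is present;
    ``potentially_lost`` when any inactivating mutation overlaps the codon
    window ``[ceil(0.1 L), floor(0.9 L))``; ``intact`` otherwise.  Lesions
    confined to the outer 10% at either end do not trigger a loss call.
    """
    present = aln.present_mask
    if present.mean() < 0.5:
        return "missing"
    L = aln.n_codons
    lo, hi = ceil(0.1 * L), floor(0.9 * L)
    for m in detect_mutations(aln):
        if m.codon_start < hi and m.codon_end > lo:
            return "potentially_lost"
    return "intact"
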
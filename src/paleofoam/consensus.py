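"""Consensus reconstruction, coding-defect annotation and duplicate-set detection.

Endogenous viral elements survive only as decayed genomic copies.  Three
operations recover structure from those copies:

* :func:`build_consensus` collapses an alignment of copies into a single
  element sequence, using IUPAC ambiguity codes where copies disagree.
* :func:`annotate_defects` reports the in-frame premature stop codons and
  frameshifting indels that mark a copy as coding-defective.
* :func:`identify_duplicate_sets` groups copies that share nearly identical
  flanking host sequence — the signature of post-insertion segmental
  duplication, which licenses dating the duplication from copy divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import Alignment, SequenceRecord

# Base-set -> IUPAC ambiguity code (and the identity codes).
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class ConsensusResult:
    """Consensus sequence plus the per-column support that produced it."""

    record: SequenceRecord
    support: np.ndarray  # fraction of non-gap residues backing each kept column
    kept_columns: np.ndarray  # original alignment column index of each consensus position


@dataclass
class DefectReport:
    """Coding defects of one element copy.

    ``stop_positions`` are 0-based codon indices within the scanned ORF;
    ``frameshift_indels`` are ``(position, length)`` pairs (position is the
    0-based alignment column where the indel starts, negative lengths are
    deletions in the query).  ``frame_used`` records the reading frame and
    strand the scan assumed.
    """

    stop_positions: list[int] = field(default_factory=list)
    frameshift_indels: list[tuple[int, int]] = field(default_factory=list)
    frame_used: tuple[int, str] = (0, "+")

    def to_dict(self) -> dict:
        return {
            "stop_positions": self.stop_positions,
            "frameshift_indels": [list(t) for t in self.frameshift_indels],
            "frame": self.frame_used[0],
            "strand": self.frame_used[1],
        }


def build_consensus(
    aln: Alignment, min_support: float = 0.5, id: str = "consensus"
) -> ConsensusResult:
    """Collapse an alignment of element copies into a consensus sequence.

    Per column, the plurality non-gap base is emitted if its support
    (fraction of the column's non-gap characters) reaches ``min_support``;
    otherwise the IUPAC ambiguity code covering all bases tied at or above
    the plurality-needed level is emitted.  Columns that are gaps in a
    majority of records are dropped (they represent insertions in a
    minority of copies, not the element itself); all-gap columns are
    dropped with a warning.
    """
    if len(aln) < 2:
        raise ValueError("consensus needs at least 2 records")
    if not 0.0 <= min_support <= 1.0:
        raise ValueError("min_support must be in [0, 1]")

    mat = np.array([list(r.residues) for r in aln.records])
    n = len(aln)
    out: list[str] = []
    support: list[float] = []
    kept: list[int] = []
    for j in range(aln.length):
        col = mat[:, j]
        gaps = int(np.sum(col == "-"))
        if gaps * 2 > n:  # gap-majority column: insertion noise, drop
            continue
        bases = [b for b in col if b in "ACGT"]
        if not bases:
            if gaps == n:
                warnings.warn(f"all-gap column {j} dropped", stacklevel=2)
            # column of only N/ambiguity: nothing to call
            continue
        vals, counts = np.unique(bases, return_counts=True)
        best = counts.max()
        frac = best / len(bases)
        n_tied = int(np.sum(counts == best))
        if frac >= min_support and n_tied == 1:
            out.append(str(vals[np.argmax(counts)]))
        elif n_tied > 1:
            # tied plurality: ambiguity over the tied bases
            tied = frozenset(str(v) for v, c in zip(vals, counts) if c == best)
            out.append(_IUPAC[tied])
        else:
            # insufficient support: ambiguity over every base observed
            out.append(_IUPAC[frozenset(str(v) for v in vals)])
        support.append(frac)
        kept.append(j)
    if not out:
        raise ValueError("no callable columns in alignment")
    rec = SequenceRecord(id=id, residues="".join(out), alphabet="nucleotide")
    return ConsensusResult(
        record=rec,
        support=np.asarray(support, dtype=float),
        kept_columns=np.asarray(kept, dtype=int),
    )


def annotate_defects(
    seq: SequenceRecord,
    orf_start: int,
    orf_end: int,
    reference_aln: Alignment | None = None,
    strand: str = "+",
) -> DefectReport:
    """Scan an ORF span for premature stop codons and frameshifting indels.

    The span ``[orf_start, orf_end)`` is read in frame 0 of the given
    strand; TAA/TAG/TGA codons strictly before the terminal codon are
    reported as premature stops.  If ``reference_aln`` (a pairwise
    alignment of this copy against an intact homolog, query first) is
    supplied, indels whose length is not a multiple of 3 are reported as
    frameshifts.
    """
    if seq.alphabet != "nucleotide":
        raise ValueError("defect annotation requires a nucleotide sequence")
    if not (0 <= orf_start < orf_end <= len(seq)):
        raise ValueError(
            f"ORF span [{orf_start}, {orf_end}) outside sequence of length {len(seq)}"
        )
    sub = seq.residues[orf_start:orf_end]
    if strand == "-":
        sub = _revcomp(sub)
    elif strand != "+":
        raise ValueError("strand must be '+' or '-'")

    n_codons = len(sub) // 3
    stops = [
        i for i in range(n_codons - 1)  # terminal codon excluded
        if sub[3 * i: 3 * i + 3] in STOP_CODONS
    ]

    frameshifts: list[tuple[int, int]] = []
    if reference_aln is not None:
        if len(reference_aln) != 2:
            raise ValueError("reference_aln must be pairwise (query, reference)")
        q, r = reference_aln[0].residues, reference_aln[1].residues
        for pos, length in _indel_runs(q, r):
            if length % 3 != 0:
                frameshifts.append((pos, length))
    return DefectReport(
        stop_positions=stops,
        frameshift_indels=frameshifts,
        frame_used=(0, strand),
    )


def _indel_runs(query: str, ref: str) -> list[tuple[int, int]]:
    """Indel events of query relative to ref: (alignment column, signed length).

    Positive lengths are insertions in the query (gap in ref), negative are
    deletions (gap in query).  Columns gapped in both sequences are ignored.
    """
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(query):
        if query[i] == "-" and ref[i] != "-":
            j = i
            while j < len(query) and query[j] == "-" and ref[j] != "-":
                j += 1
            runs.append((i, -(j - i)))
            i = j
        elif ref[i] == "-" and query[i] != "-":
            j = i
            while j < len(ref) and ref[j] == "-" and query[j] != "-":
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


_COMP = str.maketrans("ACGTN-RYSWKMBDHV", "TGCAN-YRSWMKVHDB")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class FlankedContig:
    """A contig with its element span annotated (0-based, half-open).

    The flanks are the host sequence outside ``[element_start, element_end)``.
    """

    record: SequenceRecord
    element_start: int
    element_end: int
    strand: str = "+"

    @property
    def left_flank(self) -> str:
        return self.record.residues[: self.element_start]

    @property
    def right_flank(self) -> str:
        return self.record.residues[self.element_end:]


def sliding_identity(a: str, b: str, min_overlap: int) -> float:
    """Best ungapped identity between two strings over any offset.

    Slides ``b`` along ``a``; at each offset the identity is computed over
    the overlap, and offsets with overlap below ``min_overlap`` are skipped.
    Returns 0.0 if no offset achieves the minimum overlap.
    """
    if min_overlap <= 0:
        raise ValueError("min_overlap must be positive")
    if len(a) < min_overlap or len(b) < min_overlap:
        return 0.0
    aa = np.frombuffer(a.encode(), dtype="S1")
    bb = np.frombuffer(b.encode(), dtype="S1")
    best = 0.0
    for off in range(-(len(b) - min_overlap), len(a) - min_overlap + 1):
        lo_a, lo_b = max(0, off), max(0, -off)
        n = min(len(a) - lo_a, len(b) - lo_b)
        if n < min_overlap:
            continue
        ident = float(np.mean(aa[lo_a:lo_a + n] == bb[lo_b:lo_b + n]))
        if ident > best:
            best = ident
    return best


def _gapped_identity(a: str, b: str) -> float:
    """Identity from a banded global alignment (Biopython pairwise aligner)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(a, b)[0]
    cols = alignment.aligned
    matched = 0
    total = 0
    for (sa, ea), (sb, eb) in zip(cols[0], cols[1]):
        seg_a, seg_b = a[sa:ea], b[sb:eb]
        matched += sum(x == y for x, y in zip(seg_a, seg_b))
        total += len(seg_a)
    return matched / total if total else 0.0


def identify_duplicate_sets(
    contigs: Sequence[FlankedContig] | Mapping[str, FlankedContig],
    flank_window: int = 100,
    min_flank_identity: float = 0.90,
    gapped: bool = False,
) -> list[list[str]]:
    """Partition contigs into segmental-duplication sets by shared flanks.

    Two contigs land in the same set (single linkage) if either flank pair
    (left/left or right/right) aligns with identity ≥ ``min_flank_identity``
    over at least ``flank_window`` bp.  Contigs whose flanks are both
    shorter than the window are excluded with a warning.  Singletons are
    allowed; the result is a true partition of the annotated contigs,
    sorted by contig id within and across sets.
    """
    if isinstance(contigs, Mapping):
        contigs = list(contigs.values())
    usable: list[FlankedContig] = []
    for c in contigs:
        if len(c.left_flank) < flank_window and len(c.right_flank) < flank_window:
            warnings.warn(
                f"contig {c.record.id!r}: no flank of >= {flank_window} bp; excluded",
                stacklevel=2,
            )
            continue
        usable.append(c)

    score = _gapped_identity if gapped else (
        lambda a, b: sliding_identity(a, b, flank_window)
    )

    # union-find over contig indices
    parent = list(range(len(usable)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            ci, cj = usable[i], usable[j]
            linked = False
            for fa, fb in ((ci.left_flank, cj.left_flank),
                           (ci.right_flank, cj.right_flank)):
                if len(fa) >= flank_window and len(fb) >= flank_window:
                    if score(fa, fb) >= min_flank_identity:
                        linked = True
                        break
            if linked:
                parent[find(i)] = find(j)

    groups: dict[int, list[str]] = {}
    for i, c in enumerate(usable):
        groups.setdefault(find(i), []).append(c.record.id)
    return sorted([sorted(g) for g in groups.values()])
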
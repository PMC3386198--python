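"""Seeded generators of synthetic endogenous-virus data.

Real inputs to a paleovirological analysis — decayed proviral copies in a
host assembly, dated host trees, codiverging virus trees — are expensive
to obtain, so every stage of this toolkit is exercised against synthetic
data whose generating process is the one the analyses assume:

* clock-like sequence evolution under the Kimura two-parameter process
  (:func:`evolve_sequence`);
* a virus tree that mirrors a dated host tree, with per-branch lognormal
  rate noise to emulate clock violation (:func:`simulate_codivergence`);
* endogenization of a provirus into a host locus, neutral decay with
  stop-gains and frameshifting indels, segmental duplication that copies
  the locus together with its flanks, and WGS-style fragmentation
  (:func:`simulate_endogenization`).

Each generator is deterministic given its seed, and each returns truth
records (true ages, true genealogy, defect and duplicate-set membership)
so that recovery by the estimators can be scored exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .consensus import STOP_CODONS, FlankedContig, annotate_defects
from .dating import RatePrior
from .records import Alignment, SequenceRecord

_BASES = np.array(list("ACGT"))
# encoding with transition partner = code ^ 1
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}
_DECODE = np.array(list("AGCT"))

_YEARS_PER_MY = 1.0e6


def k2p_change_probs(d: float, kappa: float) -> tuple[float, float, float]:
    """Per-site K2P substitution probabilities after expected distance ``d``.

    Returns ``(p_transition, p_each_transversion, p_same)`` for a process
    with transition/transversion rate ratio ``kappa`` run for total
    expected substitutions/site ``d`` (Kimura's closed form, with
    alpha*t = kappa*d/(kappa+2) and beta*t = d/(kappa+2)).
    """
    if d < 0:
        raise ValueError("expected distance must be non-negative")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e4b = math.exp(-4.0 * bt)
    e2ab = math.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv_each = 0.25 - 0.25 * e4b
    return p_ts, p_tv_each, 1.0 - p_ts - 2.0 * p_tv_each


def _evolve_codes(codes: np.ndarray, d: float, kappa: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply the K2P process to an integer-coded sequence (in place safe)."""
    p_ts, p_tv, _ = k2p_change_probs(d, kappa)
    u = rng.random(codes.shape)
    out = codes.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2.0 * p_tv)
    out[ts] ^= 1          # A<->G, C<->T
    out[tv1] = codes[tv1] ^ 2  # A->C, G->T, C->A, T->G
    out[tv2] = codes[tv2] ^ 3  # A->T, G->C, C->G, T->A
    return out


def random_sequence(length: int, rng: np.random.Generator, id: str = "anc") -> SequenceRecord:
    """Uniform-random nucleotide sequence."""
    return SequenceRecord(
        id=id, residues="".join(rng.choice(_BASES, size=length))
    )


def evolve_sequence(
    ancestor: SequenceRecord,
    duration: float,
    rate: float,
    kappa: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> SequenceRecord:
    """Evolve a nucleotide sequence for ``duration`` years at ``rate``
    substitutions/site/year under the K2P process.

    Sites evolve independently; gap and N characters are carried through
    unchanged.  The expected K2P distance to the ancestor is
    ``rate * duration`` (exactly, not only for small products).  The same
    seed always produces the same descendant.
    """
    if duration < 0 or rate < 0:
        raise ValueError("duration and rate must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chars = np.array(list(ancestor.residues))
    is_base = np.isin(chars, _BASES)
    codes = np.array([_CODE.get(c, 0) for c in chars])
    evolved = _evolve_codes(codes, rate * duration, kappa, rng)
    chars[is_base] = _DECODE[evolved[is_base]]
    return SequenceRecord(
        id=f"{ancestor.id}_t{duration:g}",
        residues="".join(chars),
        alphabet=ancestor.alphabet,
    )


def simulate_codivergence(
    host_tree: dendropy.Tree,
    viral_rate: float,
    kappa: float = 2.0,
    root_seq_length: int = 10000,
    seed: int = 0,
    rate_noise_sd: float = 0.0,
    tip_map: dict[str, str] | None = None,
) -> tuple[dendropy.Tree, dict[str, SequenceRecord]]:
    """Generate a virus tree that codiverged with a dated host tree.

    The virus topology mirrors the host topology exactly.  Each virus
    branch length (substitutions/site) is ``viral_rate`` x host branch
    duration (My -> years), times a lognormal rate multiplier with mean 1
    and log-sd ``rate_noise_sd`` (0 gives a perfectly clock-like tree).
    Tip sequences are evolved along the tree from a random root sequence
    under K2P, so sequence-estimated distances scatter around the true
    branch lengths.  ``tip_map`` (virus tip -> host tip) relabels the
    virus tips; by default they keep the host labels.

    Returns ``(virus_tree, {virus_tip_label: SequenceRecord})``.
    """
    if viral_rate < 0:
        raise ValueError("viral_rate must be non-negative")
    for leaf in host_tree.leaf_node_iter():
        if leaf.edge.length is None:
            raise ValueError("host tree must be dated (branch lengths in My)")
    rng = np.random.default_rng(seed)
    # reparse for a fresh taxon namespace: relabeling virus tips must not
    # touch the host tree
    virus = dendropy.Tree.get(
        data=host_tree.as_string(schema="newick"),
        schema="newick",
        preserve_underscores=True,
    )
    virus.is_rooted = True
    inverse = {h: v for v, h in (tip_map or {}).items()}

    root = random_sequence(root_seq_length, rng)
    seqs: dict[str, SequenceRecord] = {}
    codes0 = np.array([_CODE[c] for c in root.residues])
    stack = [(virus.seed_node, codes0)]
    while stack:
        node, codes = stack.pop()
        if node is not virus.seed_node:
            dur_my = node.edge.length or 0.0
            mult = 1.0
            if rate_noise_sd > 0:
                mult = rng.lognormal(-0.5 * rate_noise_sd**2, rate_noise_sd)
            blen = viral_rate * dur_my * _YEARS_PER_MY * mult
            node.edge.length = blen
            codes = _evolve_codes(codes, blen, kappa, rng)
        if node.is_leaf():
            label = inverse.get(node.taxon.label, node.taxon.label)
            node.taxon.label = label
            seqs[label] = SequenceRecord(
                id=label, residues="".join(_DECODE[codes])
            )
        else:
            for child in node.child_nodes():
                stack.append((child, codes))
    return virus, seqs


def make_provirus(
    length: int, rng: np.random.Generator, orf_fraction: float = 0.6
) -> tuple[SequenceRecord, int, int]:
    """Random proviral sequence with one intact ORF in its middle.

    The ORF (ATG ... sense codons ... TAG) spans ``orf_fraction`` of the
    length, placed centrally; the rest is random.  Returns the record and
    the 0-based half-open ORF span.
    """
    n_codons = max(3, int(length * orf_fraction) // 3)
    orf_len = 3 * n_codons
    orf_start = (length - orf_len) // 2
    sense = [
        c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
        if c not in STOP_CODONS
    ]
    codons = ["ATG"] + list(rng.choice(sense, size=n_codons - 2)) + ["TAG"]
    orf = "".join(codons)
    left = "".join(rng.choice(_BASES, size=orf_start))
    right = "".join(rng.choice(_BASES, size=length - orf_start - orf_len))
    seq = left + orf + right
    return (
        SequenceRecord(id="provirus", residues=seq),
        orf_start,
        orf_start + orf_len,
    )


@dataclass
class SimulationConfig:
    """Knobs of the endogenization simulator.

    Times are in millions of years before present; rates in
    substitutions (or indel events) per site per year.
    """

    genome_length: int = 10000
    endogenization_time: float = 20.0
    duplication_times: list[float] = field(default_factory=lambda: [19.3] * 4)
    host_neutral_rate: RatePrior = field(default_factory=RatePrior)
    kappa: float = 2.0
    indel_rate: float = 2.0e-11
    flank_length: int = 300
    n_fragments: int = 1
    min_fragment_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.endogenization_time < 0:
            raise ValueError("endogenization_time must be non-negative")
        for t in self.duplication_times:
            if not 0 <= t <= self.endogenization_time:
                raise ValueError(
                    "duplication times must lie within [0, endogenization_time]"
                )
        if self.kappa <= 0 or self.indel_rate < 0:
            raise ValueError("kappa must be > 0 and indel_rate >= 0")
        if self.genome_length < 30 or self.flank_length < 0:
            raise ValueError("genome_length too short or negative flank")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside simulated data."""

    endogenization_time_my: float
    duplication_times_my: list[float]
    genealogy_newick: str              # time tree of the copies, branch lengths in My
    duplicate_sets: list[list[str]]    # copy ids sharing the duplicated locus
    defects: dict[str, dict]           # copy id -> {"stops": int, "frameshifts": int}
    fragments: dict[str, list[tuple[str, int, int]]]  # copy id -> (frag id, start, end)

    def to_dict(self) -> dict:
        return {
            "endogenization_time_my": self.endogenization_time_my,
            "duplication_times_my": self.duplication_times_my,
            "genealogy_newick": self.genealogy_newick,
            "duplicate_sets": self.duplicate_sets,
            "defects": self.defects,
            "fragments": {
                k: [list(t) for t in v] for k, v in self.fragments.items()
            },
        }


@dataclass
class SimulationResult:
    """Everything the downstream stages need, plus the truth."""

    locus_alignment: Alignment      # gapped full loci (flanks + element), shared columns
    element_alignment: Alignment    # columns of the element only
    contigs: list[FlankedContig]    # ungapped loci with element coordinates
    fragments: list[SequenceRecord]
    truth: TruthRecord


class _Copy:
    """One locus copy during simulation: gapped char array + column spans."""

    __slots__ = ("name", "chars", "birth_my", "split_events")

    def __init__(self, name: str, chars: np.ndarray, birth_my: float):
        self.name = name
        self.chars = chars
        self.birth_my = birth_my
        self.split_events: list[tuple[float, "_Copy"]] = []


def simulate_endogenization(config: SimulationConfig) -> SimulationResult:
    """Simulate germline invasion, neutral decay and segmental duplication.

    A provirus with one intact ORF is inserted between random host flanks
    at ``endogenization_time``.  The locus then decays neutrally at the
    host rate (K2P substitutions plus Poisson indels, geometric lengths
    capped at 10 bp); each entry in ``duplication_times`` duplicates one
    extant copy, flanks included.  All copies share one column space, so
    the emitted locus alignment is the true multiple alignment.  Finally
    each copy is cut into ``n_fragments`` overlapping contigs.
    """
    rng = np.random.default_rng(config.seed)
    provirus, orf_start, orf_end = make_provirus(config.genome_length, rng)
    left = "".join(rng.choice(_BASES, size=config.flank_length))
    right = "".join(rng.choice(_BASES, size=config.flank_length))
    locus = left + provirus.residues + right

    # shared column space; '-' marks absent positions per copy
    chars0 = np.array(list(locus))
    elem_cols = np.zeros(len(locus), dtype=bool)
    elem_cols[config.flank_length: config.flank_length + config.genome_length] = True
    orf_cols = np.zeros(len(locus), dtype=bool)
    orf_cols[config.flank_length + orf_start: config.flank_length + orf_end] = True

    copies = [_Copy("copy1", chars0, config.endogenization_time)]
    fs_counts = {"copy1": 0}

    state = {
        "elem_cols": elem_cols,
        "orf_cols": orf_cols,
        "fs": fs_counts,
    }

    events = sorted(config.duplication_times, reverse=True)
    now = config.endogenization_time
    for t_dup in events + [0.0]:
        dt_years = (now - t_dup) * _YEARS_PER_MY
        if dt_years > 0:
            for cp in copies:
                _decay(cp, copies, dt_years, config, state, rng)
        if t_dup > 0.0:
            src = copies[int(rng.integers(0, len(copies)))]
            child = _Copy(
                f"copy{len(copies) + 1}", src.chars.copy(), t_dup
            )
            state["fs"][child.name] = state["fs"][src.name]
            src.split_events.append((t_dup, child))
            copies.append(child)
        now = t_dup

    aln_records = [
        SequenceRecord(id=cp.name, residues="".join(cp.chars)) for cp in copies
    ]
    locus_aln = Alignment(aln_records)
    elem_records = [
        SequenceRecord(id=cp.name, residues="".join(cp.chars[state["elem_cols"]]))
        for cp in copies
    ]
    element_aln = Alignment(elem_records)

    contigs: list[FlankedContig] = []
    defects: dict[str, dict] = {}
    for cp in copies:
        present = cp.chars != "-"
        ungapped = "".join(cp.chars[present])
        e_start = int(np.sum(present & ~state["elem_cols"] &
                             (np.arange(len(cp.chars)) < np.argmax(state["elem_cols"]))))
        e_len = int(np.sum(present & state["elem_cols"]))
        rec = SequenceRecord(id=cp.name, residues=ungapped)
        contigs.append(
            FlankedContig(record=rec, element_start=e_start,
                          element_end=e_start + e_len)
        )
        o_first = int(np.argmax(state["orf_cols"]))
        o_start = int(np.sum(present[:o_first]))
        o_len = int(np.sum(present & state["orf_cols"]))
        if o_len >= 6:
            rep = annotate_defects(rec, o_start, o_start + o_len)
            n_stops = len(rep.stop_positions)
        else:
            n_stops = 0
        defects[cp.name] = {
            "stops": n_stops,
            "frameshifts": int(state["fs"][cp.name]),
        }

    fragments: list[SequenceRecord] = []
    frag_coords: dict[str, list[tuple[str, int, int]]] = {}
    for contig in contigs:
        frag_coords[contig.record.id] = []
        for fid, (s, e) in enumerate(
            _fragment_spans(len(contig.record), config.n_fragments,
                            config.min_fragment_length, rng), start=1
        ):
            name = f"{contig.record.id}_frag{fid}"
            fragments.append(
                SequenceRecord(id=name, residues=contig.record.residues[s:e])
            )
            frag_coords[contig.record.id].append((name, s, e))

    truth = TruthRecord(
        endogenization_time_my=config.endogenization_time,
        duplication_times_my=list(config.duplication_times),
        genealogy_newick=_genealogy_newick(copies[0], config.endogenization_time),
        duplicate_sets=[sorted(cp.name for cp in copies)],
        defects=defects,
        fragments=frag_coords,
    )
    return SimulationResult(
        locus_alignment=locus_aln,
        element_alignment=element_aln,
        contigs=contigs,
        fragments=fragments,
        truth=truth,
    )


def _decay(
    cp: _Copy,
    all_copies: list[_Copy],
    dt_years: float,
    config: SimulationConfig,
    state: dict,
    rng: np.random.Generator,
) -> None:
    """Neutral decay of one copy over an interval: substitutions then indels."""
    present = np.flatnonzero(np.isin(cp.chars, _BASES))
    d = config.host_neutral_rate.mean * dt_years
    codes = np.array([_CODE[c] for c in cp.chars[present]])
    cp.chars[present] = _DECODE[_evolve_codes(codes, d, config.kappa, rng)]

    if config.indel_rate <= 0 or len(present) == 0:
        return
    n_events = rng.poisson(len(present) * config.indel_rate * dt_years)
    for _ in range(n_events):
        present = np.flatnonzero(np.isin(cp.chars, _BASES))
        if len(present) == 0:
            break
        length = int(min(rng.geometric(0.5), 10))
        pos_idx = int(rng.integers(0, len(present)))
        col = int(present[pos_idx])
        in_element = bool(state["elem_cols"][col])
        if rng.random() < 0.5:
            # deletion of `length` present sites starting at pos_idx
            doomed = present[pos_idx: pos_idx + length]
            cp.chars[doomed] = "-"
        else:
            # insertion after col: new columns, gap everywhere else
            ins = rng.choice(_BASES, size=length)
            for other in all_copies:
                fill = ins if other is cp else np.full(length, "-")
                other.chars = np.concatenate(
                    [other.chars[: col + 1], fill, other.chars[col + 1:]]
                )
            for key in ("elem_cols", "orf_cols"):
                mask = state[key]
                state[key] = np.concatenate(
                    [mask[: col + 1], np.full(length, mask[col]), mask[col + 1:]]
                )
        if in_element and length % 3 != 0:
            state["fs"][cp.name] += 1


def _fragment_spans(
    total: int, n_fragments: int, min_len: int, rng: np.random.Generator,
    overlap: int = 100,
) -> list[tuple[int, int]]:
    """Cut [0, total) into n overlapping spans with a minimum length."""
    if n_fragments <= 1 or total < 2 * min_len:
        return [(0, total)]
    n = min(n_fragments, max(1, total // min_len))
    while n > 1:
        cuts = np.sort(rng.integers(min_len, total - min_len + 1, size=n - 1))
        bounds = np.concatenate([[0], cuts, [total]])
        if np.all(np.diff(bounds) >= min_len):
            break
        n -= 1
    else:
        return [(0, total)]
    spans = []
    for i in range(n):
        s = max(0, int(bounds[i]) - (overlap if i > 0 else 0))
        e = min(total, int(bounds[i + 1]) + (overlap if i < n - 1 else 0))
        spans.append((s, e))
    return spans


def _genealogy_newick(root_copy: _Copy, t_start: float) -> str:
    """Time tree (branch lengths in My) implied by the duplication events."""

    def sub(cp: _Copy, start: float, remaining: list[tuple[float, _Copy]]) -> str:
        if not remaining:
            return f"{cp.name}:{start:g}"
        (t, child), rest = remaining[0], remaining[1:]
        inner = (
            f"({sub(cp, t, rest)},{sub(child, t, child.split_events)})"
        )
        return f"{inner}:{start - t:g}"

    events = sorted(root_copy.split_events, key=lambda e: -e[0])
    if not events:
        return f"({root_copy.name}:{t_start:g});"
    (t, child), rest = events[0], events[1:]
    return (
        f"({sub(root_copy, t, rest)},{sub(child, t, child.split_events)});"
    )
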
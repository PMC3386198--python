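"""Pairwise nucleotide distances: substitution counting, p-distance, Hamming,
and the Kimura two-parameter (K2P) model with its delta-method variance.

The K2P model treats transitions (A<->G, C<->T) and transversions (all other
mismatches) as separate rate classes.  With P and Q the observed transition
and transversion proportions over the compared sites, the distance is

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with variance (Kimura 1980, delta method)

    var(d) = [c1^2 P + c3^2 Q - (c1 P + c3 Q)^2] / n,
    c1 = 1/(1-2P-Q),  c2 = 1/(1-2Q),  c3 = (c1 + c2)/2.

Sites where either sequence has a gap, N, or other ambiguity code are
excluded from the comparison (pairwise deletion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .records import SequenceRecord

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """K2P distance undefined: substitution saturation (log argument <= 0)."""


@dataclass(frozen=True)
class SubstitutionCounts:
    """Transition/transversion counts over the sites compared in a pair."""

    transitions: int
    transversions: int
    sites_compared: int

    def __post_init__(self) -> None:
        if min(self.transitions, self.transversions, self.sites_compared) < 0:
            raise ValueError("counts must be non-negative")
        if self.transitions + self.transversions > self.sites_compared:
            raise ValueError("more substitutions than sites compared")

    @property
    def P(self) -> float:
        return self.transitions / self.sites_compared

    @property
    def Q(self) -> float:
        return self.transversions / self.sites_compared


@dataclass(frozen=True)
class DistanceEstimate:
    """A pairwise distance: d in substitutions/site plus its ingredients."""

    d: float
    P: float
    Q: float
    variance: float
    sites_compared: int
    model: str  # "p", "K2P", or "hamming"

    def to_dict(self) -> dict:
        return {
            "d": self.d, "P": self.P, "Q": self.Q,
            "variance": self.variance, "sites": self.sites_compared,
            "model": self.model,
        }


def count_substitutions(
    a: SequenceRecord | str, b: SequenceRecord | str, aligned: bool = True
) -> SubstitutionCounts:
    """Classify pairwise mismatches into transitions and transversions.

    Requires pre-aligned sequences of equal length (``aligned`` is a
    guard, not an aligner).  Columns with a gap or ambiguity code in
    either sequence are excluded from ``sites_compared``.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a.upper()
    sb = b.residues if isinstance(b, SequenceRecord) else b.upper()
    if not aligned:
        raise ValueError("unaligned input: align sequences before comparing")
    if len(sa) != len(sb):
        raise ValueError(f"aligned length mismatch: {len(sa)} vs {len(sb)}")

    ts = tv = n = 0
    for x, y in zip(sa, sb):
        if x not in "ACGT" or y not in "ACGT":
            continue  # pairwise deletion of gaps/N/ambiguity
        n += 1
        if x == y:
            continue
        if (x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES):
            ts += 1
        else:
            tv += 1
    return SubstitutionCounts(transitions=ts, transversions=tv, sites_compared=n)


def p_distance(counts: SubstitutionCounts) -> DistanceEstimate:
    """Proportion of differing sites, with binomial variance."""
    if counts.sites_compared == 0:
        raise ValueError("no comparable sites")
    p = counts.P + counts.Q
    var = p * (1.0 - p) / counts.sites_compared
    return DistanceEstimate(
        d=p, P=counts.P, Q=counts.Q, variance=var,
        sites_compared=counts.sites_compared, model="p",
    )


def k2p_distance(counts: SubstitutionCounts) -> DistanceEstimate:
    """Kimura two-parameter distance with delta-method variance.

    Raises :class:`SaturationError` (never returns NaN/inf) when the
    observed proportions saturate the model, i.e. 1-2P-Q <= 0 or
    1-2Q <= 0, so downstream dating cannot silently propagate nonsense.
    """
    if counts.sites_compared == 0:
        raise ValueError("no comparable sites")
    P, Q, n = counts.P, counts.Q, counts.sites_compared
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P saturated: P={P:.4f}, Q={Q:.4f} "
            f"(1-2P-Q={w1:.4f}, 1-2Q={w2:.4f})"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    c1 = 1.0 / w1
    c2 = 1.0 / w2
    c3 = 0.5 * (c1 + c2)
    var = (c1 * c1 * P + c3 * c3 * Q - (c1 * P + c3 * Q) ** 2) / n
    return DistanceEstimate(
        d=d, P=P, Q=Q, variance=var, sites_compared=n, model="K2P",
    )


def k2p_from_pair(a: SequenceRecord | str, b: SequenceRecord | str) -> DistanceEstimate:
    """Convenience: count substitutions on an aligned pair, then K2P."""
    return k2p_distance(count_substitutions(a, b))


def hamming(a: SequenceRecord | str, b: SequenceRecord | str) -> int:
    """Number of mismatching positions; gaps count as mismatches."""
    sa = a.residues if isinstance(a, SequenceRecord) else a.upper()
    sb = b.residues if isinstance(b, SequenceRecord) else b.upper()
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    return sum(x != y for x, y in zip(sa, sb))


def k2p_matrix(records: list[SequenceRecord]) -> np.ndarray:
    """Symmetric matrix of pairwise K2P distances over aligned records."""
    n = len(records)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_from_pair(records[i], records[j]).d
            dm[i, j] = dm[j, i] = d
    return dm
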
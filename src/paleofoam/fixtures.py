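"""Packaged host-tree fixture for the foamy-virus codivergence analysis.

The six-host topology joins the coelacanth to a clade of five mammals
known to carry (endogenous or exogenous) foamy-like viruses: the aye-aye,
sloth, horse, cow and cat.  Node ages are approximate divergence times in
millions of years drawn from standard vertebrate timescales: the
coelacanth/tetrapod split is constrained by the earliest coelacanth
fossils (>= 407 My); the placental mammal radiation is placed at ~100 My,
the primate/laurasiatherian split at ~96 My, the cat/(horse,cow) split at
~84 My and the horse/cow split at ~78 My.  These are configuration, not
inferences: callers studying sensitivity should substitute their own
calibrations.
"""

from __future__ import annotations

import dendropy

from .cophylogeny import parse_newick

# Branch lengths in My; ultrametric by construction.
HOST_NEWICK = (
    "((((cat:84,(horse:78,cow:78):6):12,aye-aye:96):4,sloth:100):307,"
    "coelacanth:407);"
)

# virus tip -> host tip
TIP_MAP: dict[str, str] = {
    "CoeEFV": "coelacanth",
    "SloEFV": "sloth",
    "PSFVaye": "aye-aye",
    "EFV": "horse",
    "BFV": "cow",
    "FFV": "cat",
}


def host_tree() -> dendropy.Tree:
    """The dated six-host tree (branch lengths in My)."""
    return parse_newick(HOST_NEWICK)


def tip_map() -> dict[str, str]:
    return dict(TIP_MAP)
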
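"""Host-virus cophylogeny: tree I/O, midpoint rooting, topology congruence,
and the branch-length codivergence regression.

Codivergence predicts that when a virus clade tracks its hosts through
speciation, (i) the virus tree topology mirrors the host topology, and
(ii) the amount of viral evolution along each branch is proportional to
the time the corresponding host branch spans.  Given a dated host tree
(branch lengths in millions of years) and a virus tree (branch lengths in
substitutions/site), this module verifies topological congruence through
a tip mapping, pairs corresponding branches, and regresses virus branch
length on host branch duration, reporting R^2 and the significance of a
non-zero slope (analytic F-test and an optional permutation test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

Clade = frozenset


class NewickError(ValueError):
    """Malformed Newick input."""


def parse_newick(text: str, rooted: bool = True) -> dendropy.Tree:
    """Parse a Newick string into a dendropy tree.

    Polytomies are preserved; duplicate leaf labels and unbalanced
    parentheses raise :class:`NewickError` with the parser's position
    information where available.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"newick parse failed: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise NewickError(f"duplicate leaf labels: {sorted(dupes)}")
    tree.is_rooted = rooted
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize to Newick with branch lengths at 10 significant digits."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".10g",
            unquoted_underscores=True,
        ).strip()
    )


def _path_to_root(node: dendropy.Node) -> list[dendropy.Node]:
    path = [node]
    while path[-1].parent_node is not None:
        path.append(path[-1].parent_node)
    return path


def _leaf_path(u: dendropy.Node, v: dendropy.Node) -> list[dendropy.Node]:
    """Node path from leaf u to leaf v through their MRCA."""
    up, vp = _path_to_root(u), _path_to_root(v)
    vset = {id(n): i for i, n in enumerate(vp)}
    for i, n in enumerate(up):
        if id(n) in vset:
            return up[: i + 1] + vp[: vset[id(n)]][::-1]
    raise ValueError("leaves are not in the same tree")


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    Returns a new tree; the input is not modified.  The two leaves that
    span the tree diameter end up equidistant from the root, and total
    branch length is conserved.  Ties on the diameter are broken by leaf
    labels for determinism.  (Implemented from the path definition; the
    midpoint is located on the diameter path and the tree rerooted on
    that edge.)
    """
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise ValueError("midpoint rooting requires branch lengths on all edges")
    rooted = tree.clone(depth=1)
    # a stem edge above the root lies on no leaf-to-leaf path; drop it
    rooted.seed_node.edge.length = None
    leaves = list(rooted.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")

    depth: dict[int, float] = {}
    for node in rooted.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    mrca_cache: dict = {}
    best = None
    for i, u in enumerate(leaves):
        for v in leaves[i + 1:]:
            path = _leaf_path(u, v)
            top = min(depth[id(n)] for n in path)
            d = depth[id(u)] + depth[id(v)] - 2 * top
            key = (-d, sorted((u.taxon.label, v.taxon.label)))
            if best is None or key < best[0]:
                best = (key, u, v, d)
    _, u, v, diameter = best

    # walk from u toward v until half the diameter is consumed
    target = diameter / 2.0
    path = _leaf_path(u, v)
    acc = 0.0
    for a, b in zip(path, path[1:]):
        # the edge between a and b is b.edge if a is b's parent, else a.edge
        child = b if b.parent_node is a else a
        elen = child.edge.length or 0.0
        if acc + elen >= target - 1e-12:
            if b is child:  # descending: a -> b, child end is farther from u
                upper = target - acc          # portion on a's side
                lower = elen - upper          # portion on b's side
            else:  # ascending: a == child, a end is nearer to u
                lower = target - acc
                upper = elen - lower
            if lower <= 1e-12:
                rooted.reroot_at_node(child, update_bipartitions=True)
            elif upper <= 1e-12:
                rooted.reroot_at_node(child.parent_node, update_bipartitions=True)
            else:
                rooted.reroot_at_edge(
                    child.edge,
                    length1=upper,  # tail (parent) side
                    length2=lower,  # head (child) side
                    update_bipartitions=True,
                )
            break
        acc += elen
    rooted.seed_node.edge.length = None
    rooted.is_rooted = True
    return rooted


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _clade_map(tree: dendropy.Tree) -> dict[Clade, dendropy.Node]:
    """Map each non-root node to the frozenset of leaf labels below it."""
    out: dict[Clade, dendropy.Node] = {}
    for node in tree.postorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.is_leaf():
            clade = frozenset([node.taxon.label])
        else:
            clade = frozenset(
                l for child in node.child_nodes()
                for l in _leafset(child)
            )
        out[clade] = node
    return out


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


@dataclass
class CongruenceResult:
    """Outcome of topology comparison between host and virus trees.

    On success ``branch_map`` maps each shared clade (as a frozenset of
    HOST tip labels) to the ``(host_node, virus_node)`` pair whose parent
    edges correspond.  On failure, the clades found in only one tree are
    listed (in host label space).
    """

    congruent: bool
    branch_map: dict[Clade, tuple[dendropy.Node, dendropy.Node]] = field(
        default_factory=dict
    )
    host_only: list[Clade] = field(default_factory=list)
    virus_only: list[Clade] = field(default_factory=list)


def map_congruent_branches(
    host: dendropy.Tree,
    virus: dendropy.Tree,
    tip_map: dict[str, str],
) -> CongruenceResult:
    """Test whether the virus tree mirrors the host tree clade-for-clade.

    ``tip_map`` sends each virus tip label to its host tip label and must
    be a bijection onto the host tips.  After relabeling virus tips, every
    clade of one tree must be a clade of the other; polytomies must match
    exactly.  Returns the branch bijection or the offending clades.
    """
    virus_tips = set(leaf_labels(virus))
    host_tips = set(leaf_labels(host))
    if set(tip_map.keys()) != virus_tips:
        raise ValueError("tip_map keys must be exactly the virus tips")
    if set(tip_map.values()) != host_tips or len(set(tip_map.values())) != len(tip_map):
        raise ValueError("tip_map must be a bijection onto the host tips")

    host_clades = _clade_map(host)
    virus_clades_raw = _clade_map(virus)
    virus_clades = {
        frozenset(tip_map[l] for l in clade): node
        for clade, node in virus_clades_raw.items()
    }

    host_set, virus_set = set(host_clades), set(virus_clades)
    if host_set != virus_set:
        return CongruenceResult(
            congruent=False,
            host_only=sorted(host_set - virus_set, key=sorted),
            virus_only=sorted(virus_set - host_set, key=sorted),
        )
    return CongruenceResult(
        congruent=True,
        branch_map={
            clade: (host_clades[clade], virus_clades[clade])
            for clade in host_set
        },
    )


def extract_branch_pairs(
    result: CongruenceResult,
    host: dendropy.Tree,
    virus: dendropy.Tree,
) -> pd.DataFrame:
    """Tabulate (host duration, virus length) for every mapped branch.

    Host durations are in millions of years, virus lengths in
    substitutions/site.  Zero-length root edges are excluded.  Columns:
    branch_id, host_duration, virus_length, is_external.
    """
    if not result.congruent:
        raise ValueError("cannot extract branch pairs from an incongruent mapping")
    host_nodes = {id(n) for n in host.preorder_node_iter()}
    virus_nodes = {id(n) for n in virus.preorder_node_iter()}
    rows = []
    for clade in sorted(result.branch_map, key=lambda c: (len(c), sorted(c))):
        hn, vn = result.branch_map[clade]
        if id(hn) not in host_nodes or id(vn) not in virus_nodes:
            raise ValueError("branch mapping is stale with respect to a tree")
        h_len = hn.edge.length or 0.0
        v_len = vn.edge.length or 0.0
        if hn.parent_node is host.seed_node and h_len == 0.0 and v_len == 0.0:
            continue
        rows.append(
            {
                "branch_id": "|".join(sorted(clade)),
                "host_duration": float(h_len),
                "virus_length": float(v_len),
                "is_external": len(clade) == 1,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty and (df["host_duration"] == 0).all():
        df.attrs["degenerate"] = True
    return df


@dataclass(frozen=True)
class CodivergenceFit:
    """OLS fit of virus branch length on host branch duration."""

    r_squared: float
    slope: float       # substitutions/site per My
    intercept: float   # substitutions/site
    p_value: float     # two-sided test of zero slope
    n_branches: int
    permutation_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "p_value": self.p_value,
            "n_branches": self.n_branches,
            "permutation_p": self.permutation_p,
        }


def codivergence_test(
    pairs: pd.DataFrame,
    n_permutations: int = 0,
    seed: int = 0,
    through_origin: bool = False,
) -> CodivergenceFit:
    """Regress virus branch length on host branch duration.

    Ordinary least squares with an intercept (set ``through_origin`` to
    force the fit through zero).  The analytic p-value is the two-sided
    test of zero slope (equivalent to the F-test on 1 and n-2 df).  With
    ``n_permutations`` > 0, a permutation p-value is added by shuffling
    virus lengths across branches and counting permutations whose R^2
    meets or exceeds the observed one (add-one correction).
    """
    x = pairs["host_duration"].to_numpy(dtype=float)
    y = pairs["virus_length"].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 branch pairs for a regression")
    if np.var(x) == 0:
        raise ValueError("host durations have zero variance")

    if through_origin:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
        resid = y - slope * x
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        se = np.sqrt(ss_res / (n - 1) / (x @ x))
        tstat = slope / se if se > 0 else np.inf
        p = float(2 * stats.t.sf(abs(tstat), n - 1))
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue**2)
        p = float(fit.pvalue)

    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            yp = rng.permutation(y)
            r = np.corrcoef(x, yp)[0, 1]
            if r * r >= r2 - 1e-15:
                hits += 1
        perm_p = (hits + 1) / (n_permutations + 1)

    return CodivergenceFit(
        r_squared=min(max(r2, 0.0), 1.0),
        slope=slope,
        intercept=intercept,
        p_value=max(min(p, 1.0), np.nextafter(0, 1)),
        n_branches=n,
        permutation_p=perm_p,
    )
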
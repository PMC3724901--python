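"""Rooted-tree data model and I/O.

All trees in this package are :class:`dendropy.Tree` objects; tree samples
(e.g. a Bayesian posterior with burn-in already removed) are
:class:`dendropy.TreeList`.  This module provides the strict, rooted parsing
conventions the downstream analyses rely on — unique tip labels, nonnegative
branch lengths, explicit handling of missing lengths — plus the small set of
tree manipulations the pipelines need: seeded polytomy resolution, scaling an
ultrametric tree to an absolute root age, and MRCA lookup.

Branch-length units are contextual (substitutions/site, thousands of years,
or coalescent units); no unit conversion is ever implicit.
"""

from __future__ import annotations

import io
import logging
import random
from typing import Iterable, Mapping

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "parse_newick",
    "write_newick",
    "parse_nexus_trees",
    "write_nexus_trees",
    "resolve_polytomies",
    "scale_to_age",
    "mrca",
    "tip_depths",
    "is_ultrametric",
    "prune_to_one_per_taxon",
]


class TreeParseError(ValueError):
    """Raised for malformed Newick/NEXUS input."""


def _check_balanced(text: str) -> None:
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise TreeParseError(f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise TreeParseError(
            f"unbalanced parentheses: {depth} '(' left open at end of statement"
        )


def _fill_missing_lengths(
    tree: dendropy.Tree, default: float = 1.0, warn: bool = True
) -> None:
    """Default missing branch lengths to ``default`` (root edge to 0)."""
    n_missing = 0
    for node in tree:
        if node.parent_node is None:
            if node.edge.length is None:
                node.edge.length = 0.0
        elif node.edge.length is None:
            node.edge.length = default
            n_missing += 1
    if n_missing and warn:
        logger.warning(
            "%d branch(es) had no length; defaulted to %.1f", n_missing, default
        )


def _validate(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise TreeParseError(f"duplicate tip labels: {sorted(dupes)}")
    for node in tree:
        if node.edge.length is not None and node.edge.length < 0:
            raise TreeParseError(
                f"negative branch length {node.edge.length} on edge above "
                f"{node.taxon.label if node.taxon else 'internal node'}"
            )
    return tree


def parse_newick(
    text: str,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
    warn_missing_lengths: bool = True,
) -> dendropy.Tree:
    """Parse a single rooted Newick statement.

    Missing branch lengths default to 1.0 (root edge: 0.0) and are logged.
    Raises :class:`TreeParseError` on unbalanced parentheses, duplicate tip
    labels or other malformed input.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise TreeParseError("Newick statement must end in ';'")
    _check_balanced(text)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            taxon_namespace=taxon_namespace,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise TreeParseError(f"cannot parse Newick: {exc}") from exc
    _fill_missing_lengths(tree, warn=warn_missing_lengths)
    return _validate(tree)


def write_newick(tree: dendropy.Tree, digits: int = 12) -> str:
    """Serialize to a rooted Newick string; lengths kept to ``digits`` sig. digits."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        preserve_spaces=False,
        unquoted_underscores=True,
        real_value_format_specifier=f".{digits}g",
    ).strip()
    return s + "\n"


def parse_nexus_trees(stream) -> dendropy.TreeList:
    """Read a NEXUS TREES block (TRANSLATE table honoured) into a TreeList.

    ``stream`` may be a path, file object, or the NEXUS text itself.  All
    trees must share one taxon set; indices in the translate table are
    replaced by taxon names.
    """
    if hasattr(stream, "read"):
        data = stream.read()
    else:
        data = str(stream)
        if "#NEXUS" not in data.upper():
            with open(data) as fh:
                data = fh.read()
    try:
        trees = dendropy.TreeList.get(
            data=data,
            schema="nexus",
            rooting="force-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeParseError(f"cannot parse NEXUS trees: {exc}") from exc
    if len(trees) == 0:
        raise TreeParseError("NEXUS input contains no trees")
    ref = {t.label for t in trees[0].taxon_namespace if t}
    for i, tree in enumerate(trees):
        _fill_missing_lengths(tree)
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        if tips != {leaf.taxon.label for leaf in trees[0].leaf_node_iter()}:
            raise TreeParseError(f"tree {i} has a different tip set than tree 0")
    del ref
    return trees


def write_nexus_trees(trees: dendropy.TreeList, path: str) -> None:
    """Write a TreeList as a NEXUS TREES block with a TRANSLATE table (LF endings)."""
    text = trees.as_string(schema="nexus", translate_tree_taxa=True)
    with open(path, "w", newline="\n") as fh:
        fh.write(text)


def resolve_polytomies(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    """Return a strictly bifurcating copy; inserted edges have length 0.

    Resolution order is drawn from a generator seeded with ``seed``, so the
    output is reproducible.  Tip depths are unchanged (inserted edges carry
    zero length).
    """
    rng = random.Random(seed)
    out = tree.clone(depth=1)
    for node in list(out.preorder_node_iter()):
        children = node.child_nodes()
        while len(children) > 2:
            i, j = sorted(rng.sample(range(len(children)), 2))
            a, b = children[i], children[j]
            joint = dendropy.Node()
            joint.edge.length = 0.0
            node.remove_child(a)
            node.remove_child(b)
            joint.add_child(a)
            joint.add_child(b)
            node.add_child(joint)
            children = node.child_nodes()
    return out


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length for every tip, keyed by label."""
    depths: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = list(tip_depths(tree).values())
    dmax = max(depths)
    if dmax == 0:
        return True
    return (dmax - min(depths)) <= rel_tol * dmax


def scale_to_age(
    tree: dendropy.Tree, root_age: float, allow_nonultrametric: bool = False
) -> dendropy.Tree:
    """Rescale so every root-to-tip depth equals ``root_age``.

    An ultrametric tree (within 1e-6 relative) is scaled linearly.  A
    non-ultrametric tree is rejected unless ``allow_nonultrametric`` is set,
    in which case each root-to-tip path is stretched independently: node at
    depth ``d`` with maximal remaining height ``h`` below it moves to depth
    ``root_age * d / (d + h)``.  That preserves the relative order of nodes
    along every path but is not a dating method; a warning is logged.
    """
    if root_age <= 0:
        raise ValueError("root_age must be positive")
    out = tree.clone(depth=1)
    if is_ultrametric(out):
        depth = max(tip_depths(out).values())
        if depth == 0:
            raise ValueError("tree has zero depth; cannot scale")
        factor = root_age / depth
        for edge in out.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        return out
    if not allow_nonultrametric:
        raise ValueError(
            "tree is not ultrametric; pass allow_nonultrametric=True to stretch "
            "each root-to-tip path independently"
        )
    logger.warning(
        "scaling non-ultrametric tree by per-path stretching; this is not a "
        "dating method"
    )
    # depth of each node from root, and max height below it
    depth_of: dict[int, float] = {}
    height_of: dict[int, float] = {}
    for node in out.preorder_node_iter():
        if node.parent_node is None:
            depth_of[id(node)] = 0.0
        else:
            depth_of[id(node)] = depth_of[id(node.parent_node)] + (
                node.edge.length or 0.0
            )
    for node in out.postorder_node_iter():
        if node.is_leaf():
            height_of[id(node)] = 0.0
        else:
            height_of[id(node)] = max(
                height_of[id(c)] + (c.edge.length or 0.0) for c in node.child_nodes()
            )
    new_depth: dict[int, float] = {}
    for node in out.preorder_node_iter():
        d, h = depth_of[id(node)], height_of[id(node)]
        new_depth[id(node)] = root_age * d / (d + h) if (d + h) > 0 else 0.0
    for node in out.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = new_depth[id(node)] - new_depth[id(node.parent_node)]
    return out


def mrca(tree: dendropy.Tree, tips: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of ``tips`` (a single tip is its own MRCA)."""
    tips = list(tips)
    if not tips:
        raise ValueError("tips must be nonempty")
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    unknown = [t for t in tips if t not in leaves]
    if unknown:
        raise KeyError(f"unknown tip label(s): {unknown}")
    if len(tips) == 1:
        return leaves[tips[0]]
    # walk up from the first tip collecting ancestors, then intersect
    paths = []
    for t in tips:
        node = leaves[t]
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent_node
        paths.append(chain)
    anc_set = set(id(n) for n in paths[0])
    for chain in paths[1:]:
        anc_set &= {id(n) for n in chain}
    for node in paths[0]:
        if id(node) in anc_set:
            return node
    raise RuntimeError("trees disconnected; no common ancestor found")


def prune_to_one_per_taxon(
    trees: dendropy.TreeList, keep: Mapping[str, str]
) -> dendropy.TreeList:
    """Prune every tree to the tip set ``keep.values()``.

    ``keep`` maps taxon name -> the one tip label to retain.  Degree-2 nodes
    left by pruning are suppressed, with their branch lengths summed, so
    pairwise path lengths among retained tips are preserved.
    """
    wanted = set(keep.values())
    out = dendropy.TreeList(taxon_namespace=dendropy.TaxonNamespace())
    for tree in trees:
        present = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        missing = wanted - present
        if missing:
            raise KeyError(f"tip(s) {sorted(missing)} absent from a tree in the sample")
        newick = write_newick(tree)
        t = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            taxon_namespace=out.taxon_namespace,
        )
        t.retain_taxa_with_labels(sorted(wanted))
        out.append(t)
    return out


def read_tree(path: str) -> dendropy.Tree:
    """Read a single tree from a Newick file."""
    with open(path) as fh:
        return parse_newick(fh.read())


def write_tree(tree: dendropy.Tree, path: str) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(write_newick(tree))
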
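"""Multispecies-coalescent simulation of gene trees within a population tree.

Within each population branch, the ``k`` extant gene lineages coalesce in
pairs with exponential waiting times at rate ``k(k-1)/2`` per coalescent
unit (2Ne generations); lineages that have not coalesced by a divergence
depth merge into the parent population, and the root population extends
indefinitely so all lineages eventually find a common ancestor.  No
migration, no recombination; per-branch population widths (relative Ne)
rescale the local coalescent rate.

The simulator keeps an integer core (:class:`SimulatedGenealogy`) that
records merge order, times and population bit-masks without building tree
objects; :func:`simulate_msc` wraps it into a dendropy gene tree.  The core
output is what the deep-coalescence null machinery consumes, so a null of
10,000 replicates never pays object-construction costs.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import dendropy

from refugia.divergence import PopulationTree, SampleAssignment

__all__ = ["GeneTree", "SimulatedGenealogy", "simulate_msc", "simulate_null"]


@dataclass
class GeneTree:
    """An ultrametric gene tree (coalescent units) with its tip assignment."""

    tree: dendropy.Tree
    assignment: SampleAssignment


@dataclass
class SimulatedGenealogy:
    """Array-form genealogy: tips ``0..n-1``, merges appended in time order.

    ``children[i]`` gives the two child node ids of internal node ``n + i``;
    ``times`` holds node ages (0 for tips); ``mask[i]`` is the bitmask of
    populations below node ``i`` (bit order = ``pop_order``).
    """

    tip_labels: list[str]
    pop_order: tuple[str, ...]
    children: list[tuple[int, int]]
    times: list[float]
    mask: list[int]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def edge_masks(self):
        """Yield (child_mask, parent_mask) for every non-root edge."""
        n = self.n_tips
        for i, (a, b) in enumerate(self.children):
            pm = self.mask[n + i]
            yield self.mask[a], pm
            yield self.mask[b], pm


@dataclass
class _PopBranch:
    bottom: float
    top: float
    children: list[int] = field(default_factory=list)
    label: str | None = None
    width: float = 1.0


def _compile(pop_tree: PopulationTree) -> list[_PopBranch]:
    """Postorder list of population branches with [bottom, top) age spans."""
    ages = pop_tree.node_ages()
    nodes = list(pop_tree.tree.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    out: list[_PopBranch] = []
    for n in nodes:
        top = ages[id(n.parent_node)] if n.parent_node is not None else math.inf
        clade = frozenset(leaf.taxon.label for leaf in n.leaf_iter())
        out.append(
            _PopBranch(
                bottom=ages[id(n)],
                top=top,
                children=[index[id(c)] for c in n.child_nodes()],
                label=n.taxon.label if n.is_leaf() else None,
                width=pop_tree.widths.get(clade, 1.0),
            )
        )
    return out


def _simulate_core(
    compiled: list[_PopBranch],
    tips_by_pop: dict[str, list[str]],
    pop_bit: dict[str, int],
    pop_order: tuple[str, ...],
    rng: random.Random,
) -> SimulatedGenealogy:
    tip_labels: list[str] = []
    times: list[float] = []
    masks: list[int] = []
    children: list[tuple[int, int]] = []
    active: list[list[int]] = [[] for _ in compiled]

    # allocate tips in compiled (postorder) population order so labels are stable
    for i, br in enumerate(compiled):
        if br.label is not None:
            for lab in tips_by_pop.get(br.label, ()):
                active[i].append(len(tip_labels))
                tip_labels.append(lab)
                times.append(0.0)
                masks.append(pop_bit[br.label])
    n_tips = len(tip_labels)
    if n_tips == 0:
        raise ValueError("no samples assigned to any population")

    for i, br in enumerate(compiled):
        lineages = active[i]
        for c in br.children:
            lineages.extend(active[c])
        t = br.bottom
        k = len(lineages)
        while k > 1:
            rate = k * (k - 1) / 2.0 / br.width
            t += rng.expovariate(rate)
            if t >= br.top:
                break
            a_idx = rng.randrange(k)
            b_idx = rng.randrange(k - 1)
            if b_idx >= a_idx:
                b_idx += 1
            a, b = lineages[a_idx], lineages[b_idx]
            node = n_tips + len(children)
            children.append((a, b))
            times.append(t)
            masks.append(masks[a] | masks[b])
            # replace a with merged node, drop b
            lineages[a_idx] = node
            last = lineages.pop()
            if b_idx < len(lineages):
                lineages[b_idx] = last
            k -= 1
        active[i] = lineages
    assert len(children) == n_tips - 1
    return SimulatedGenealogy(
        tip_labels=tip_labels,
        pop_order=pop_order,
        children=children,
        times=times,
        mask=masks,
    )


def _prepare(pop_tree: PopulationTree, assignment: SampleAssignment):
    for pop in set(assignment.mapping.values()):
        if pop not in pop_tree.regions:
            raise ValueError(f"assignment population {pop!r} not in population tree")
    pop_order = tuple(pop_tree.regions)
    pop_bit = {p: 1 << i for i, p in enumerate(pop_order)}
    tips_by_pop: dict[str, list[str]] = {p: [] for p in pop_order}
    for tip in sorted(assignment.mapping):
        tips_by_pop[assignment.mapping[tip]].append(tip)
    return _compile(pop_tree), tips_by_pop, pop_bit, pop_order


def genealogy_to_tree(sim: SimulatedGenealogy) -> dendropy.Tree:
    """Convert the array-form genealogy to an ultrametric dendropy tree."""
    n = sim.n_tips
    tns = dendropy.TaxonNamespace(sim.tip_labels)
    nodes: list[dendropy.Node] = []
    for i, lab in enumerate(sim.tip_labels):
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(node)
    for i, (a, b) in enumerate(sim.children):
        node = dendropy.Node()
        node.add_child(nodes[a])
        node.add_child(nodes[b])
        nodes[a].edge.length = sim.times[n + i] - sim.times[a]
        nodes[b].edge.length = sim.times[n + i] - sim.times[b]
        nodes.append(node)
    root = nodes[-1]
    root.edge.length = 0.0
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def simulate_genealogy(
    pop_tree: PopulationTree,
    assignment: SampleAssignment,
    rng: random.Random,
) -> SimulatedGenealogy:
    """One coalescent genealogy in array form (fast path, no tree objects)."""
    compiled, tips_by_pop, pop_bit, pop_order = _prepare(pop_tree, assignment)
    return _simulate_core(compiled, tips_by_pop, pop_bit, pop_order, rng)


def simulate_msc(
    pop_tree: PopulationTree,
    assignment: SampleAssignment,
    seed: int,
) -> GeneTree:
    """Simulate one gene tree under the multispecies coalescent."""
    rng = random.Random(seed)
    sim = simulate_genealogy(pop_tree, assignment, rng)
    return GeneTree(tree=genealogy_to_tree(sim), assignment=assignment)


def simulate_null(
    pop_tree: PopulationTree,
    assignment: SampleAssignment,
    n_sims: int,
    seed: int,
) -> list[GeneTree]:
    """``n_sims`` independent gene trees; reproducible under a fixed seed."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = random.Random(seed)
    compiled, tips_by_pop, pop_bit, pop_order = _prepare(pop_tree, assignment)
    out = []
    for _ in range(n_sims):
        sim = _simulate_core(compiled, tips_by_pop, pop_bit, pop_order, rng)
        out.append(GeneTree(tree=genealogy_to_tree(sim), assignment=assignment))
    return out


def export_nexus(gene_trees: list[GeneTree], path: str) -> None:
    """Write simulated trees as a NEXUS TREES block for audit."""
    tns = gene_trees[0].tree.taxon_namespace
    tl = dendropy.TreeList(taxon_namespace=tns)
    for gt in gene_trees:
        tl.append(gt.tree)
    tl.write(path=path, schema="nexus")
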
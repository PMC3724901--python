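"""Geographic population-divergence models as population trees.

The glacial-refugium hypotheses are encoded as rooted trees over five
regions — NAI (North America Interior), NAC (North America Cascadia),
BER (Beringia), CAS (Central Asia & Siberia), JAP (Japan) — with divergence
depths in coalescent units (1 unit = 2Ne generations).  Six presets cover
the classic scenarios:

* ``REFUGIA`` — simultaneous fragmentation of one ancestral population among
  all refugia (a hard 5-way polytomy at a single depth);
* ``SRM`` — origin in the southern Rocky Mountains, stepwise westward
  dispersal: (NAI,(NAC,(BER,(CAS,JAP))));
* ``JAPAN_I`` / ``JAPAN_II`` — origin in Japan, north- and eastward chains;
* ``CAS_I`` / ``CAS_II`` — central-Asian origin, south- and eastward chains.

The JAPAN and CAS chains are mirror images of the SRM chain rooted at JAP and
CAS; the I/II variants swap the order of the two terminal-most splits.  These
presets are best-effort defaults — the exact branching orders of the original
figure-only models are not recoverable from text — and every preset can be
overridden with an explicit Newick topology over the region labels.

Divergence depths are free configuration (the test procedure deliberately
does not rely on Ne or absolute divergence-time estimates); defaults put all
divergences between 1 and 5 coalescent units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

from refugia import trees as _trees

DEFAULT_REGIONS: tuple[str, ...] = ("NAI", "NAC", "BER", "CAS", "JAP")

#: Specimen counts per region in the reference 46-tip sampling design.
DEFAULT_SAMPLE_COUNTS: dict[str, int] = {
    "NAI": 15,
    "NAC": 6,
    "BER": 11,
    "CAS": 11,
    "JAP": 3,
}

PRESET_TOPOLOGIES: dict[str, str] = {
    "SRM": "(NAI,(NAC,(BER,(CAS,JAP))));",
    "JAPAN_I": "(JAP,(CAS,(BER,(NAC,NAI))));",
    "JAPAN_II": "(JAP,(CAS,(NAC,(BER,NAI))));",
    "CAS_I": "(CAS,(JAP,(BER,(NAC,NAI))));",
    "CAS_II": "(CAS,(JAP,(NAC,(BER,NAI))));",
}

#: Default divergence depths (coalescent units), root-most first.
DEFAULT_DEPTHS: tuple[float, ...] = (5.0, 4.0, 3.0, 2.0)


@dataclass
class PopulationTree:
    """A rooted tree over population labels with coalescent-unit depths.

    ``tree`` is ultrametric with tips at depth 0 and internal-node ages equal
    to divergence depths; ``widths`` optionally rescales the coalescent rate
    per branch (keyed by the frozenset of regions below the branch; 1.0 =
    one coalescent unit per 2Ne generations).
    """

    tree: dendropy.Tree
    regions: tuple[str, ...]
    sample_counts: dict[str, int] = field(default_factory=dict)
    widths: dict[frozenset, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        tips = sorted(leaf.taxon.label for leaf in self.tree.leaf_node_iter())
        if tips != sorted(self.regions):
            raise ValueError(
                f"population tree tips {tips} != declared regions {sorted(self.regions)}"
            )
        for pop, n in self.sample_counts.items():
            if pop not in self.regions:
                raise ValueError(f"sample count for unknown region {pop!r}")
            if n < 0:
                raise ValueError("sample counts must be >= 0")

    @property
    def root_depth(self) -> float:
        return max(_trees.tip_depths(self.tree).values())

    def node_ages(self) -> dict[int, float]:
        """Age (time before present) of every node, keyed by id(node)."""
        depth = self.root_depth
        ages: dict[int, float] = {}
        for node in self.tree.preorder_node_iter():
            d = 0.0
            n = node
            while n.parent_node is not None:
                d += n.edge.length or 0.0
                n = n.parent_node
            ages[id(node)] = depth - d
        return ages

    def is_star(self) -> bool:
        root = self.tree.seed_node
        return all(c.is_leaf() for c in root.child_nodes())


def _apply_depths(tree: dendropy.Tree, depths: list[float]) -> None:
    """Assign ages to internal nodes (preorder) and set branch lengths."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    if len(depths) != len(internal):
        raise ValueError(
            f"need {len(internal)} depths for {len(internal)} internal nodes, "
            f"got {len(depths)}"
        )
    age: dict[int, float] = {}
    for node, d in zip(internal, depths):
        if d <= 0:
            raise ValueError("divergence depths must be strictly positive")
        age[id(node)] = d
        parent = node.parent_node
        if parent is not None and d >= age[id(parent)]:
            raise ValueError(
                "depths must be strictly decreasing toward the present "
                f"(node at {d} under parent at {age[id(parent)]})"
            )
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            age[id(node)] = 0.0
        if node.parent_node is not None:
            node.edge.length = age[id(node.parent_node)] - age[id(node)]
        else:
            node.edge.length = 0.0


def build_divergence_model(
    spec: str,
    depths: list[float] | None = None,
    sample_counts: dict[str, int] | None = None,
    regions: tuple[str, ...] = DEFAULT_REGIONS,
    seed: int | None = None,
) -> PopulationTree:
    """Construct a divergence model from a preset name or explicit Newick.

    ``spec`` is one of ``REFUGIA, SRM, JAPAN_I, JAPAN_II, CAS_I, CAS_II`` or a
    Newick string over the region labels.  ``depths`` are divergence depths in
    coalescent units, root-most first (one per internal node; REFUGIA takes a
    single depth).  ``seed`` is accepted for interface symmetry — preset
    construction is deterministic.
    """
    del seed
    counts = dict(sample_counts or DEFAULT_SAMPLE_COUNTS)
    name = spec if spec in PRESET_TOPOLOGIES or spec == "REFUGIA" else "custom"
    if spec == "REFUGIA":
        depth = (depths or [DEFAULT_DEPTHS[0]])[0]
        if len(depths or [1]) != 1:
            raise ValueError("REFUGIA takes a single fragmentation depth")
        newick = "(" + ",".join(regions) + ");"
        tree = _trees.parse_newick(newick, warn_missing_lengths=False)
        _apply_depths(tree, [depth])
    else:
        newick = PRESET_TOPOLOGIES.get(spec, spec)
        if not newick.rstrip().endswith(";"):
            raise ValueError(f"unknown model preset {spec!r}")
        tree = _trees.parse_newick(newick, warn_missing_lengths=False)
        n_internal = sum(1 for n in tree.preorder_node_iter() if not n.is_leaf())
        use = list(depths) if depths is not None else list(DEFAULT_DEPTHS[:n_internal])
        _apply_depths(tree, use)
    return PopulationTree(
        tree=tree, regions=tuple(regions), sample_counts=counts, name=name
    )


@dataclass
class SampleAssignment:
    """Map from gene-tree tip label to population label."""

    mapping: dict[str, str]
    populations: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = {p for p in self.mapping.values() if p not in self.populations}
        if bad:
            raise ValueError(f"assignment uses unknown region(s): {sorted(bad)}")
        if not self.mapping:
            raise ValueError("assignment is empty (no samples)")

    def counts(self) -> dict[str, int]:
        out = {p: 0 for p in self.populations}
        for pop in self.mapping.values():
            out[pop] += 1
        return out

    def __getitem__(self, tip: str) -> str:
        return self.mapping[tip]

    def __len__(self) -> int:
        return len(self.mapping)


def load_assignment(
    path, regions: tuple[str, ...] = DEFAULT_REGIONS
) -> SampleAssignment:
    """Read a two-column (tip, region) TSV into a validated SampleAssignment."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("assignment TSV needs two columns: tip, region")
    if df.shape[0] == 0:
        raise ValueError("assignment TSV is empty")
    tips = df.iloc[:, 0].tolist()
    dupes = {t for t in tips if tips.count(t) > 1}
    if dupes:
        raise ValueError(f"duplicate tip(s) in assignment: {sorted(dupes)}")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return SampleAssignment(mapping=mapping, populations=tuple(regions))


def write_assignment(assignment: SampleAssignment, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for tip, pop in sorted(assignment.mapping.items()):
            fh.write(f"{tip}\t{pop}\n")


def assignment_from_counts(
    counts: dict[str, int], regions: tuple[str, ...] = DEFAULT_REGIONS
) -> SampleAssignment:
    """Build an assignment with systematic tip names like ``NAI_01``."""
    mapping: dict[str, str] = {}
    for pop in regions:
        for i in range(counts.get(pop, 0)):
            mapping[f"{pop}_{i + 1:02d}"] = pop
    return SampleAssignment(mapping=mapping, populations=tuple(regions))
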
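"""Synthetic fixture generation for the full analysis pipeline.

Generates an internally consistent bundle emulating a five-region,
46-specimen glacial-refugium sampling design: a population tree under a
chosen divergence model (default the southern-Rocky-Mountain westward
chain), a coalescent gene tree scaled to an absolute root age of 220 ky, a
posterior-like tree sample built by coalescent re-simulation (a labelled
stand-in for MCMC tree uncertainty — no tree inference happens here),
DEC-evolved tip ranges under a stratified glacial-cycle model, and sixteen
binary morphological characters evolved under a symmetric two-state CTMC at
per-character rates drawn from gamma priors of the magnitude reported for
real leaf/stem/sepal/petal characters.

Every file the bundle writes is in the exact format the pipeline consumes,
and the manifest records all seeds and true parameters so regeneration is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from refugia import asr as _asr
from refugia import coalsim, dec, divergence
from refugia import trees as _trees

__all__ = ["FixtureConfig", "FixtureBundle", "generate_fixture", "write_bundle",
           "read_bundle"]


#: Sixteen binary characters in the style of the cushion-saxifrage
#: morphological literature, with gamma rate-prior magnitudes typical of
#: per-character MCMC calibration (shape, scale).
CHARACTER_TABLE: list[tuple[str, tuple[str, str], float, float]] = [
    ("habit", ("dense", "loose"), 5.442, 0.240),
    ("leaf_shape", ("linear", "broad"), 3.472, 0.348),
    ("leaf_margin", ("entire", "three_lobed"), 2.825, 0.685),
    ("leaf_cartilaginous", ("yes", "no"), 2.979, 0.440),
    ("leaf_cilia", ("hairy", "glandular"), 5.045, 0.271),
    ("leaf_apex", ("acute", "rounded"), 2.866, 0.724),
    ("leaf_keel", ("keeled", "unkeeled"), 5.442, 0.240),
    ("leaf_surface", ("glabrous", "glandular"), 3.472, 0.348),
    ("stem_surface", ("glabrous", "glandular"), 2.825, 0.685),
    ("sepal_shape", ("ovate", "lanceolate"), 2.979, 0.440),
    ("sepal_cilia", ("present", "absent"), 5.045, 0.271),
    ("sepal_surface", ("glabrous", "glandular"), 2.866, 0.724),
    ("petal_color", ("white", "yellow"), 5.442, 0.240),
    ("petal_claw", ("clawed", "unclawed"), 3.472, 0.348),
    ("petal_length", ("over_4mm", "under_4mm"), 2.825, 0.685),
    ("petal_spotting", ("yellow_orange_red", "pink_purple"), 2.979, 0.440),
]


@dataclass
class FixtureConfig:
    """Study-design parameters of the synthetic bundle.

    Defaults encode the reference design: 46 tips over five regions
    (NAI 15, NAC 6, BER 11, CAS 11, JAP 3), divergence depths of 5-2
    coalescent units, a 220-ky root age inside a 240-ky stratified DEC
    model with dispersal ~2e-2 and extinction ~5e-3 events/lineage/ky, and
    sixteen binary characters.
    """

    divergence_model: str = "SRM"
    depths: list[float] | None = None
    sample_counts: dict[str, int] = field(
        default_factory=lambda: dict(divergence.DEFAULT_SAMPLE_COUNTS)
    )
    regions: tuple[str, ...] = divergence.DEFAULT_REGIONS
    root_age: float = 220.0
    dec_model: str = "SRM"
    dec_d: float = 0.02
    dec_e: float = 0.005
    dec_root_area: str = "NAI"
    n_posterior_trees: int = 20
    n_characters: int = 16


@dataclass
class FixtureBundle:
    config: FixtureConfig
    seed: int
    pop_tree: divergence.PopulationTree
    assignment: divergence.SampleAssignment
    gene_tree: dendropy.Tree                 # ultrametric, depth = root_age (ky)
    tree_sample: dendropy.TreeList           # unit-depth posterior stand-in
    dec_model: dec.DECModel
    ranges: dict[str, int]
    characters: list[_asr.BinaryCharacter]
    clades: dict[str, list[str]]
    manifest: dict


def _simulate_character(
    tree: dendropy.Tree,
    name: str,
    states: tuple[str, str],
    rate: float,
    rng: np.random.Generator,
) -> _asr.BinaryCharacter:
    """Evolve a symmetric two-state character down ``tree`` at ``rate``."""
    state_at: dict[int, int] = {id(tree.seed_node): int(rng.random() < 0.5)}
    data: dict[str, str | None] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            parent_state = state_at[id(node.parent_node)]
            t = node.edge.length or 0.0
            p_same = 0.5 * (1.0 + math.exp(-rate * t))
            state = parent_state if rng.random() < p_same else 1 - parent_state
            state_at[id(node)] = state
        if node.is_leaf():
            data[node.taxon.label] = states[state_at[id(node)]]
    if len(set(data.values())) < 2:
        # force variation so every character is usable downstream: flip the
        # tip with the longest terminal branch
        tips = sorted(data, key=lambda lab: -(
            next(l for l in tree.leaf_node_iter() if l.taxon.label == lab)
            .edge.length or 0.0))
        cur = data[tips[0]]
        data[tips[0]] = states[1] if cur == states[0] else states[0]
    return _asr.BinaryCharacter(name=name, states=states, data=data)


def generate_fixture(
    config: FixtureConfig | None = None, seed: int = 0
) -> FixtureBundle:
    """Generate the full bundle from one master seed.

    The master seed is fanned out deterministically to the gene-tree
    simulation, the posterior-sample re-simulations, the DEC range
    simulation and the character simulations.
    """
    config = config or FixtureConfig()
    master = np.random.default_rng(seed)
    sub = {
        name: int(master.integers(0, 2**31 - 1))
        for name in ("gene", "posterior", "dec", "chars")
    }

    pop_tree = divergence.build_divergence_model(
        config.divergence_model,
        depths=config.depths,
        sample_counts=config.sample_counts,
        regions=config.regions,
    )
    assignment = divergence.assignment_from_counts(
        config.sample_counts, regions=config.regions
    )

    observed = coalsim.simulate_msc(pop_tree, assignment, seed=sub["gene"])
    gene_tree = _trees.scale_to_age(observed.tree, config.root_age)

    # posterior-like sample: coalescent re-simulation, scaled to unit depth
    tns = dendropy.TaxonNamespace()
    tree_sample = dendropy.TreeList(taxon_namespace=tns)
    for i in range(config.n_posterior_trees):
        gt = coalsim.simulate_msc(pop_tree, assignment, seed=sub["posterior"] + i)
        unit = _trees.scale_to_age(gt.tree, 1.0)
        tree_sample.append(
            dendropy.Tree.get(
                data=_trees.write_newick(unit),
                schema="newick",
                rooting="force-rooted",
                preserve_underscores=True,
                taxon_namespace=tns,
            )
        )

    preset_names = set(dec.PRESET_ARROWS) | {"REF"}
    if (config.dec_model.upper() in preset_names
            and tuple(config.regions) == divergence.DEFAULT_REGIONS):
        dec_model = dec.preset_dec_model(config.dec_model, areas=config.regions)
    else:
        # non-reference region sets get an unstratified free-dispersal model
        n = len(config.regions)
        dec_model = dec.DECModel(
            areas=tuple(config.regions),
            strata=[dec.Stratum(config.root_age, 0.0, np.ones((n, n)))],
            max_range_size=2,
            name="FREE",
        )
    params = dec.DECParams(d=config.dec_d, e=config.dec_e)
    root_mask = 1 << list(config.regions).index(config.dec_root_area)
    ranges = dec.simulate_dec(
        gene_tree, dec_model, params, seed=sub["dec"], root_state=root_mask
    )

    # characters on the unit-depth observed tree
    unit_observed = _trees.scale_to_age(gene_tree, 1.0)
    crng = np.random.default_rng(sub["chars"])
    characters = []
    true_rates = {}
    for name, states, a, b in CHARACTER_TABLE[: config.n_characters]:
        rate = float(crng.gamma(a, b))
        true_rates[name] = rate
        characters.append(_simulate_character(unit_observed, name, states, rate, crng))

    clades = {
        pop: [t for t, p in assignment.mapping.items() if p == pop]
        for pop in config.regions
    }
    clades["all"] = sorted(assignment.mapping)

    manifest = {
        "seed": seed,
        "subseeds": sub,
        "config": asdict(config),
        "true_params": {
            "dec_d": config.dec_d,
            "dec_e": config.dec_e,
            "dec_root_area": config.dec_root_area,
            "character_rates": true_rates,
        },
    }
    return FixtureBundle(
        config=config,
        seed=seed,
        pop_tree=pop_tree,
        assignment=assignment,
        gene_tree=gene_tree,
        tree_sample=tree_sample,
        dec_model=dec_model,
        ranges=ranges,
        characters=characters,
        clades=clades,
        manifest=manifest,
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def write_bundle(bundle: FixtureBundle, directory: str) -> str:
    """Write all bundle files plus a manifest (seeds, true parameters,
    sha256 of every file); returns the manifest path."""
    os.makedirs(directory, exist_ok=True)
    paths = {}

    p = os.path.join(directory, "gene_tree.nwk")
    _trees.write_tree(bundle.gene_tree, p)
    paths["gene_tree"] = p

    p = os.path.join(directory, "pop_tree.nwk")
    _trees.write_tree(bundle.pop_tree.tree, p)
    paths["pop_tree"] = p

    p = os.path.join(directory, "assignment.tsv")
    divergence.write_assignment(bundle.assignment, p)
    paths["assignment"] = p

    p = os.path.join(directory, "posterior_trees.nex")
    _trees.write_nexus_trees(bundle.tree_sample, p)
    paths["posterior_trees"] = p

    p = os.path.join(directory, "ranges.tsv")
    dec.write_ranges(bundle.ranges, p, areas=bundle.dec_model.areas)
    paths["ranges"] = p

    p = os.path.join(directory, "dec_model.json")
    dec.save_model(bundle.dec_model, p)
    paths["dec_model"] = p

    p = os.path.join(directory, "characters.tsv")
    _asr.write_characters_tsv(bundle.characters, p)
    paths["characters"] = p

    p = os.path.join(directory, "clades.json")
    with open(p, "w", newline="\n") as fh:
        json.dump(bundle.clades, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["clades"] = p

    manifest = dict(bundle.manifest)
    manifest["files"] = {
        key: {"path": os.path.basename(path), "sha256": _sha256(path)}
        for key, path in paths.items()
    }
    mp = os.path.join(directory, "manifest.json")
    with open(mp, "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return mp


def read_bundle(directory: str) -> dict:
    """Load bundle files back into pipeline-ready objects."""
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    regions = tuple(manifest["config"]["regions"])
    return {
        "manifest": manifest,
        "gene_tree": _trees.read_tree(os.path.join(directory, "gene_tree.nwk")),
        "pop_tree_newick": open(os.path.join(directory, "pop_tree.nwk")).read(),
        "assignment": divergence.load_assignment(
            os.path.join(directory, "assignment.tsv"), regions=regions
        ),
        "tree_sample": _trees.parse_nexus_trees(
            os.path.join(directory, "posterior_trees.nex")
        ),
        "ranges": dec.load_ranges(os.path.join(directory, "ranges.tsv"),
                                  areas=regions),
        "dec_model": dec.load_model(os.path.join(directory, "dec_model.json")),
        "characters": _asr.load_characters_tsv(
            os.path.join(directory, "characters.tsv")
        ),
        "clades": json.load(open(os.path.join(directory, "clades.json"))),
    }


def bundle_hash(bundle: FixtureBundle) -> str:
    """Deterministic content hash of the in-memory bundle."""
    h = hashlib.sha256()
    h.update(_trees.write_newick(bundle.gene_tree).encode())
    h.update(_trees.write_newick(bundle.pop_tree.tree).encode())
    for t in bundle.tree_sample:
        h.update(_trees.write_newick(t).encode())
    h.update(json.dumps(sorted(bundle.ranges.items())).encode())
    for c in bundle.characters:
        h.update(json.dumps([c.name, c.states, sorted(c.data.items())]).encode())
    h.update(json.dumps(bundle.manifest, sort_keys=True).encode())
    return h.hexdigest()
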
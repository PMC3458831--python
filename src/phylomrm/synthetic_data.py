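"""Seeded generators for trees, posterior tree sets and metadata tables.

Every pipeline stage is testable without external data: the generators
plant known ground truth — a focal clade at a controlled posterior
frequency, or a linear relationship between tree-derived node distance and
the taxonomic/geographic/habitat model matrices — and are bit-reproducible
under a fixed seed.

The additive-matrix model used by :func:`simulate_mrm_dataset` builds the
response entrywise as ``intercept + sum(beta_k * X_k) + noise`` with i.i.d.
Gaussian noise on the pair scale, clipped at zero and symmetrized.
Pair-level independence is a simplification (true tree distances are
correlated); the permutation test's taxon-exchangeability design is the
compensating choice.  Default magnitudes are sized to a crayfish-scale
study: a few dozen taxa, node distances of order 10, a strong taxonomy
effect, a weak per-kilometer geography effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .model_matrices import (
    HABITAT_CODES,
    TaxonTable,
    geographic_matrix,
    habitat_matrix,
    taxonomy_matrix,
)
from .phylo_distance import DistanceMatrix
from .trees_io import TreeSample, TreeSet, leaf_labels

__all__ = [
    "SimulationError",
    "SimConfig",
    "simulate_yule_tree",
    "simulate_tree_set",
    "simulate_metadata",
    "simulate_mrm_dataset",
]


class SimulationError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped defaults for the synthetic generators.

    Defaults emulate the scale of a subgenus-level crayfish phylogeny:
    40 taxa in 6 subgenera, habitats dominated by streams with burrowers
    and cave dwellers rarer, a tenth of taxa in two habitats, coordinates
    in a southern-Appalachian bounding box, posterior pools mixing a focal
    clade at a controlled frequency.
    """

    n_taxa: int = 40
    seed: int = 0
    # clade planting
    clade_frequency: float = 0.5
    clade_mode: str = "deterministic"  # or "bernoulli"
    # regression planting: (taxonomy, geography-per-km, habitat)
    true_betas: tuple[float, float, float] = (5.5, -0.002, 1.0)
    intercept: float = 8.0
    noise_sd: float = 5.0
    # metadata
    n_subgenera: int = 6
    subgenus_mode: str = "clustered"  # or "random"
    habitat_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)  # stream, burrow, cave
    multi_habitat_prob: float = 0.1
    lat_range: tuple[float, float] = (33.0, 41.0)
    lon_range: tuple[float, float] = (-89.0, -79.0)

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise SimulationError("need n_taxa >= 4")
        if not (0.0 <= self.clade_frequency <= 1.0):
            raise SimulationError("clade frequency must be in [0, 1]")
        if self.noise_sd < 0:
            raise SimulationError("noise sd must be nonnegative")
        if self.n_subgenera > self.n_taxa:
            raise SimulationError("more subgenera than taxa")
        if abs(sum(self.habitat_probs) - 1.0) > 1e-9:
            raise SimulationError("habitat probabilities must sum to 1")


def _taxon_label(i: int) -> str:
    return f"t{i + 1:03d}"


def simulate_yule_tree(
    n: int, seed: Optional[int] = None, rng: Optional[np.random.Generator] = None
) -> dendropy.Tree:
    """Pure-birth tree by iterative random leaf splitting.

    Starting from a cherry, a uniformly chosen leaf is split into two until
    ``n`` leaves exist; every edge then receives an independent
    Exponential(mean 0.1) branch length.  Deterministic under ``seed``.
    """
    if n < 2:
        raise SimulationError("need n >= 2 leaves")
    if rng is None:
        rng = np.random.default_rng(seed)
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    left, right = dendropy.Node(), dendropy.Node()
    tree.seed_node.add_child(left)
    tree.seed_node.add_child(right)
    leaves = [left, right]
    while len(leaves) < n:
        k = int(rng.integers(len(leaves)))
        node = leaves.pop(k)
        c1, c2 = dendropy.Node(), dendropy.Node()
        node.add_child(c1)
        node.add_child(c2)
        leaves.extend([c1, c2])
    for i, leaf in enumerate(tree.leaf_node_iter()):
        taxon = taxon_namespace.require_taxon(label=_taxon_label(i))
        leaf.taxon = taxon
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.exponential(0.1))
    tree.is_rooted = True
    return tree


def _random_join(units: list[dendropy.Node], rng: np.random.Generator) -> dendropy.Node:
    """Random rooted topology over subtree units by iterative pairwise joins."""
    units = list(units)
    while len(units) > 1:
        i, j = rng.choice(len(units), size=2, replace=False)
        i, j = int(i), int(j)
        a = units[i]
        b = units[j]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        units = [u for k, u in enumerate(units) if k not in (i, j)]
        units.append(parent)
    return units[0]


def _leaf_node(namespace: dendropy.TaxonNamespace, label: str) -> dendropy.Node:
    node = dendropy.Node()
    node.taxon = namespace.require_taxon(label=label)
    return node


def _assemble(root_child: dendropy.Node, namespace: dendropy.TaxonNamespace) -> dendropy.Tree:
    tree = dendropy.Tree(taxon_namespace=namespace)
    tree.seed_node = root_child
    tree.is_rooted = True
    return tree


def _tree_with_clade(
    clade: Sequence[str], others: Sequence[str], rng: np.random.Generator
) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace()
    clade_root = _random_join([_leaf_node(ns, l) for l in clade], rng)
    units = [clade_root] + [_leaf_node(ns, l) for l in others]
    return _assemble(_random_join(units, rng), ns)


def _tree_breaking_clade(
    clade: Sequence[str], others: Sequence[str], rng: np.random.Generator
) -> dendropy.Tree:
    """A tree in which the clade is NOT a split: one member is pulled out
    and attached as sister to a non-clade leaf."""
    if len(others) < 2:
        raise SimulationError(
            "breaking a clade requires at least 2 taxa outside it"
        )
    ns = dendropy.TaxonNamespace()
    moved = clade[int(rng.integers(len(clade)))]
    rest = [l for l in clade if l != moved]
    partner = others[int(rng.integers(len(others)))]
    pair = dendropy.Node()
    pair.add_child(_leaf_node(ns, moved))
    pair.add_child(_leaf_node(ns, partner))
    units: list[dendropy.Node] = [pair]
    if rest:
        units.append(
            _random_join([_leaf_node(ns, l) for l in rest], rng)
            if len(rest) > 1
            else _leaf_node(ns, rest[0])
        )
    units.extend(_leaf_node(ns, l) for l in others if l != partner)
    return _assemble(_random_join(units, rng), ns)


def simulate_tree_set(
    base: dendropy.Tree,
    clade: Sequence[str],
    frequency: float,
    total: int,
    mode: str = "deterministic",
    seed: Optional[int] = None,
    run_id: str = "sim",
) -> TreeSet:
    """Posterior stand-in: trees containing a focal clade at frequency f.

    ``deterministic`` mode plants exactly ``round(f * total)`` consistent
    trees (f*total must be integral); ``bernoulli`` mode includes the clade
    independently with probability f per tree.  Consistent trees carry the
    clade as a monophyletic group over a random background; inconsistent
    trees regraft one clade member next to an outside taxon.
    """
    if total < 1:
        raise SimulationError("total must be >= 1")
    if not (0.0 <= frequency <= 1.0):
        raise SimulationError("frequency must be in [0, 1]")
    labels = leaf_labels(base)
    clade = sorted(set(clade))
    if not set(clade) <= labels:
        raise SimulationError("clade taxa must be leaves of the base tree")
    if len(clade) < 2 or len(labels) - len(clade) < 2:
        raise SimulationError(
            "need >= 2 clade taxa and >= 2 outside taxa to control the clade"
        )
    others = sorted(labels - set(clade))
    rng = np.random.default_rng(seed)
    if mode == "deterministic":
        exact = frequency * total
        planted = round(exact)
        if abs(exact - planted) > 1e-9:
            raise SimulationError(
                f"frequency*total = {exact} is not an integer; use mode='bernoulli'"
            )
        flags = np.zeros(total, dtype=bool)
        flags[:planted] = True
        rng.shuffle(flags)
    elif mode == "bernoulli":
        flags = rng.random(total) < frequency
    else:
        raise SimulationError("mode must be 'deterministic' or 'bernoulli'")
    samples = []
    for i, consistent in enumerate(flags):
        tree = (
            _tree_with_clade(clade, others, rng)
            if consistent
            else _tree_breaking_clade(clade, others, rng)
        )
        samples.append(TreeSample(tree=tree, run_id=run_id, generation=i + 1))
    return TreeSet(samples)


def _clustered_subgenera(
    tree: dendropy.Tree, n_groups: int
) -> dict[str, str]:
    """Assign subgenus labels to contiguous clades by splitting the largest."""
    groups: list[dendropy.Node] = [tree.seed_node]
    while len(groups) < n_groups:
        splittable = [g for g in groups if g.child_nodes()]
        if not splittable:
            raise SimulationError("cannot split tree into that many clades")
        biggest = max(splittable, key=lambda g: len(g.leaf_nodes()))
        groups.remove(biggest)
        groups.extend(biggest.child_nodes())
    assignment: dict[str, str] = {}
    for gi, node in enumerate(groups):
        for leaf in node.leaf_iter():
            assignment[leaf.taxon.label] = f"SG{gi + 1:02d}"
    return assignment


def simulate_metadata(tree: dendropy.Tree, config: SimConfig) -> TaxonTable:
    """Metadata table for the leaves of a tree.

    ``clustered`` subgenus mode labels contiguous clades, so taxonomy
    tracks phylogeny and an MRM on the induced matrices recovers a positive
    taxonomy effect; ``random`` mode shuffles labels, so taxonomy is noise.
    Habitats are drawn per-taxon (stream/burrow/cave probabilities, plus a
    chance of a second habitat); coordinates are uniform in the bounding
    box.
    """
    labels = sorted(leaf_labels(tree))
    rng = np.random.default_rng(config.seed)
    if config.subgenus_mode == "clustered":
        assignment = _clustered_subgenera(tree, config.n_subgenera)
    elif config.subgenus_mode == "random":
        pool = [f"SG{(i % config.n_subgenera) + 1:02d}" for i in range(len(labels))]
        rng.shuffle(pool)
        assignment = dict(zip(labels, pool))
    else:
        raise SimulationError("subgenus_mode must be 'clustered' or 'random'")
    codes = ("stream", "burrow", "cave")
    habitats = []
    for _ in labels:
        primary = codes[int(rng.choice(3, p=config.habitat_probs))]
        hset = {primary}
        if rng.random() < config.multi_habitat_prob:
            extra = [c for c in codes if c != primary]
            hset.add(extra[int(rng.integers(2))])
        habitats.append(frozenset(hset))
    lat = rng.uniform(*config.lat_range, size=len(labels))
    lon = rng.uniform(*config.lon_range, size=len(labels))
    return TaxonTable(
        labels=tuple(labels),
        subgenus=tuple(assignment[l] for l in labels),
        habitats=tuple(habitats),
        lat=tuple(float(v) for v in lat),
        lon=tuple(float(v) for v in lon),
    )


def simulate_mrm_dataset(
    n: int,
    true_betas: Sequence[float] = SimConfig.true_betas,
    noise_sd: float = 1.0,
    seed: Optional[int] = None,
    intercept: float = SimConfig.intercept,
    config: Optional[SimConfig] = None,
) -> tuple[DistanceMatrix, list[DistanceMatrix], list[str]]:
    """Regression dataset with planted coefficients.

    Predictors are a random-subgenus taxonomy matrix, a geography matrix in
    kilometers from uniform bounding-box coordinates, and a habitat matrix;
    the response is ``intercept + sum(beta_k X_k) + noise`` per pair,
    symmetrized with zero diagonal and clipped at zero.  With
    ``noise_sd=0`` the fit recovers ``true_betas`` exactly.
    """
    if n < 4:
        raise SimulationError("need n >= 4")
    if len(true_betas) != 3:
        raise SimulationError("expected 3 coefficients (taxonomy, geography, habitat)")
    cfg = config or SimConfig(
        n_taxa=n,
        seed=seed if seed is not None else 0,
        subgenus_mode="random",
        n_subgenera=max(2, n // 6),
    )
    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(n, rng=rng)
    meta_cfg = SimConfig(
        n_taxa=n,
        seed=int(rng.integers(2**31)),
        subgenus_mode=cfg.subgenus_mode,
        n_subgenera=cfg.n_subgenera,
        habitat_probs=cfg.habitat_probs,
        multi_habitat_prob=cfg.multi_habitat_prob,
        lat_range=cfg.lat_range,
        lon_range=cfg.lon_range,
    )
    table = simulate_metadata(tree, meta_cfg)
    names = ["taxonomy", "geography", "habitat"]
    Xs = [
        taxonomy_matrix(table),
        geographic_matrix(table, units="kilometers"),
        habitat_matrix(table),
    ]
    values = np.full((n, n), float(intercept))
    for beta, X in zip(true_betas, Xs):
        values = values + float(beta) * X.values
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        noise = np.tril(noise, k=-1)
        values = values + noise + noise.T
    values = np.clip(values, 0.0, None)
    np.fill_diagonal(values, 0.0)
    Y = DistanceMatrix(Xs[0].labels, values, units="model-units")
    return Y, Xs, names
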
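"""Bayesian topology tests: posterior frequency of topological hypotheses.

A hypothesis (one or more named groups, optionally arranged on a backbone
tree) is tested against a pooled posterior tree set by counting the trees
consistent with it.  The reported statistic pP is the percentage of
consistent trees — the posterior probability of the hypothesis under the
sampled distribution.

Monophyly on an (effectively unrooted) posterior sample is evaluated as
bipartition existence: a group is monophyletic when some edge splits the
leaves exactly into (group | rest).  Supplying an outgroup roots the
question, but because the outgroup must be disjoint from the group the two
readings coincide; the outgroup is validated and the split test applied.
Taxa in the tree but in no group are ignored by restriction, so ungrouped
outgroup taxa cannot break a backbone hypothesis about the groups.  A
polytomy covering a group's taxa plus others does NOT count as
monophyletic: the split must be exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import yaml

from .trees_io import TreeSet, leaf_labels

__all__ = [
    "TopologyTestError",
    "Constraint",
    "TopologyTestResult",
    "tree_bipartitions",
    "is_monophyletic",
    "constraint_consistent",
    "posterior_frequency",
    "round_percent_half_up",
]


class TopologyTestError(ValueError):
    """Invalid topology-test input."""


@dataclass(frozen=True)
class Constraint:
    """A topological hypothesis: named groups plus an optional backbone.

    ``groups`` maps group names to disjoint taxon sets.  ``backbone`` is a
    Newick string over the group names prescribing relationships among the
    groups.  ``outgroup`` taxa, when given, root the hypothesis and must be
    disjoint from every group.
    """

    groups: Mapping[str, frozenset[str]]
    backbone: Optional[str] = None
    outgroup: frozenset[str] = frozenset()
    name: str = "hypothesis"

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "groups",
            {str(k): frozenset(v) for k, v in dict(self.groups).items()},
        )
        object.__setattr__(self, "outgroup", frozenset(self.outgroup))
        if not self.groups:
            raise TopologyTestError("constraint needs at least one group")
        seen: set[str] = set()
        for gname, taxa in self.groups.items():
            if not taxa:
                raise TopologyTestError(f"group {gname!r} is empty")
            overlap = seen & taxa
            if overlap:
                raise TopologyTestError(
                    f"groups are not disjoint; shared taxa: {sorted(overlap)}"
                )
            seen |= taxa
        if self.outgroup & seen:
            raise TopologyTestError("outgroup overlaps a constraint group")
        if self.backbone is not None:
            bb_leaves = _backbone_leaf_names(self.backbone)
            unknown = bb_leaves - set(self.groups)
            if unknown:
                raise TopologyTestError(
                    f"backbone names not among groups: {sorted(unknown)}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path, name: Optional[str] = None) -> "Constraint":
        """Load ``groups:``/``backbone:``/``outgroup:`` from a YAML file."""
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc, name=name or Path(path).stem)

    @classmethod
    def from_dict(cls, doc: Mapping, name: str = "hypothesis") -> "Constraint":
        groups = {k: frozenset(v) for k, v in dict(doc.get("groups", {})).items()}
        return cls(
            groups=groups,
            backbone=doc.get("backbone"),
            outgroup=frozenset(doc.get("outgroup", []) or []),
            name=doc.get("name", name),
        )

    @property
    def grouped_taxa(self) -> frozenset[str]:
        out: set[str] = set()
        for taxa in self.groups.values():
            out |= taxa
        return frozenset(out)


@dataclass(frozen=True)
class TopologyTestResult:
    """Count of consistent trees and the pP percentage (one table row)."""

    hypothesis: str
    n_consistent: int
    total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_consistent <= self.total) or self.total <= 0:
            raise TopologyTestError("need 0 <= N <= total with total > 0")

    @property
    def pp_percent(self) -> float:
        """Exact percentage 100*N/total (before display rounding)."""
        return 100.0 * self.n_consistent / self.total

    @property
    def pp_display(self) -> str:
        """pP rounded half-up at 2 decimals on the exact rational."""
        return round_percent_half_up(self.n_consistent, self.total)

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.hypothesis,
            "pP": self.pp_display,
            "pp_percent": self.pp_percent,
            "n_consistent": self.n_consistent,
            "total": self.total,
        }


def round_percent_half_up(n_consistent: int, total: int) -> str:
    """100*N/total rounded half-up at 2 decimals, in rational arithmetic.

    Rational arithmetic avoids binary-float ties: 33/12000 is exactly
    0.275% and rounds up to "0.28".
    """
    scaled = Fraction(100 * n_consistent, total) * 100  # percent * 100
    floor = scaled.numerator // scaled.denominator
    remainder = scaled - floor
    if remainder >= Fraction(1, 2):
        floor += 1
    return f"{floor // 100}.{floor % 100:02d}"


# -- bipartitions ------------------------------------------------------------


def _backbone_clades(backbone_tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf-name set below every non-root node of the backbone tree."""
    out = []
    for node in backbone_tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        out.append(frozenset(l.taxon.label for l in node.leaf_iter()))
    return out


def _backbone_leaf_names(newick: str) -> set[str]:
    tree = dendropy.Tree.get(data=newick if newick.rstrip().endswith(";") else newick + ";",
                             schema="newick", preserve_underscores=True)
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _normalize(side: frozenset[str], universe: frozenset[str], ref: str) -> frozenset[str]:
    return frozenset(universe - side) if ref in side else side


def tree_bipartitions(
    tree: dendropy.Tree, restrict: Optional[frozenset[str]] = None
) -> set[frozenset[str]]:
    """Splits of a tree (optionally restricted to a taxon subset).

    Each split is represented by the side not containing a fixed reference
    taxon.  Restriction uses the standard identity: the splits of the
    induced subtree are the restrictions of the full tree's splits.
    Includes trivial (singleton) splits.
    """
    all_taxa = leaf_labels(tree)
    universe = frozenset(restrict) if restrict is not None else all_taxa
    if restrict is not None and not universe <= all_taxa:
        missing = sorted(universe - all_taxa)
        raise TopologyTestError(f"restriction taxa absent from tree: {missing}")
    ref = min(universe)
    splits: set[frozenset[str]] = set()
    below: dict[int, set[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            below[id(node)] = {lab} if lab in universe else set()
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= below[id(child)]
            below[id(node)] = acc
        if node.parent_node is not None:
            side = frozenset(below[id(node)])
            if 0 < len(side) < len(universe):
                splits.add(_normalize(side, universe, ref))
    return splits


def is_monophyletic(
    tree: dendropy.Tree,
    group: Iterable[str],
    outgroup: Optional[Iterable[str]] = None,
) -> bool:
    """Whether a taxon group forms an exact clade/split of the tree.

    Without an outgroup this is bipartition existence on the unrooted
    topology; with an outgroup (disjoint from the group, validated) the
    rooted and unrooted readings coincide.
    """
    group = frozenset(group)
    taxa = leaf_labels(tree)
    missing = group - taxa
    if missing:
        raise TopologyTestError(f"group taxa absent from tree: {sorted(missing)}")
    if not (1 < len(group) < len(taxa)):
        raise TopologyTestError("need 1 < |group| < n leaves")
    if outgroup is not None:
        outgroup = frozenset(outgroup)
        if outgroup & group:
            raise TopologyTestError("outgroup overlaps the tested group")
        missing_og = outgroup - taxa
        if missing_og:
            raise TopologyTestError(f"outgroup taxa absent from tree: {sorted(missing_og)}")
    splits = tree_bipartitions(tree)
    return _normalize(group, taxa, min(taxa)) in splits


def constraint_consistent(tree: dendropy.Tree, constraint: Constraint) -> bool:
    """Whether a tree fits a constraint (groups + optional backbone).

    The tree is restricted to the union of grouped taxa; every group with
    >= 2 members must be monophyletic there, and every internal split of
    the backbone, expanded to taxon sets by group membership, must exist in
    the restricted tree.
    """
    taxa = leaf_labels(tree)
    grouped = constraint.grouped_taxa
    missing = grouped - taxa
    if missing:
        raise TopologyTestError(f"constraint taxa absent from tree: {sorted(missing)}")
    outgroup_present = frozenset(constraint.outgroup) & taxa
    # Restriction universe: grouped taxa plus any outgroup taxa (the
    # outgroup roots the hypothesis, so it must stay on the far side of
    # every tested split).  A lone group with no backbone and no outgroup
    # reduces to plain full-tree monophyly.
    if len(constraint.groups) == 1 and constraint.backbone is None and not outgroup_present:
        universe = taxa
    else:
        universe = frozenset(grouped | outgroup_present)
    if constraint.backbone is not None and len(universe) < 4:
        raise TopologyTestError("backbone constraints need >= 4 grouped taxa")
    ref = min(universe)
    splits = tree_bipartitions(tree, restrict=universe)

    for taxa_set in constraint.groups.values():
        if len(taxa_set) >= 2 and len(universe - taxa_set) >= 2:
            if _normalize(frozenset(taxa_set), universe, ref) not in splits:
                return False

    if constraint.backbone is not None:
        bb = constraint.backbone
        backbone_tree = dendropy.Tree.get(
            data=bb if bb.rstrip().endswith(";") else bb + ";",
            schema="newick",
            preserve_underscores=True,
        )
        group_names = leaf_labels(backbone_tree)
        # backbone leaves may name a subset of the groups; groups absent
        # from the backbone are constrained only by their own monophyly.
        # Outgroup taxa sit in the universe but on no backbone leaf, so a
        # rooted arrangement like ((G1,G2),G3) is distinguishable: the
        # split {G1+G2 | G3+outgroup} must exist.
        bb_universe = frozenset(
            frozenset().union(*(constraint.groups[g] for g in group_names))
            | outgroup_present
        )
        bb_ref = min(bb_universe)
        bb_splits = tree_bipartitions(tree, restrict=bb_universe)
        # raw backbone clades (below-sets), not normalized at group level:
        # the outgroup belongs to no group, so normalizing among group
        # names would flip a clade onto the wrong taxon-level side
        for name_side in _backbone_clades(backbone_tree):
            side = frozenset().union(*(constraint.groups[g] for g in name_side))
            if len(side) < 2 or len(bb_universe - side) < 2:
                continue  # trivial once expanded: always present
            if _normalize(side, bb_universe, bb_ref) not in bb_splits:
                return False
    return True


def posterior_frequency(
    trees: TreeSet, constraint: Constraint, name: Optional[str] = None
) -> TopologyTestResult:
    """Fraction of posterior trees consistent with a hypothesis (pP).

    N = number of consistent trees; pP = 100*N/total, displayed at 2
    decimals with half-up rounding on the exact rational.
    """
    n_consistent = sum(
        1 for sample in trees if constraint_consistent(sample.tree, constraint)
    )
    return TopologyTestResult(
        hypothesis=name or constraint.name,
        n_consistent=n_consistent,
        total=trees.count,
    )
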
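"""Reading, writing and pooling of posterior tree samples.

Bayesian MCMC software emits tree samples either as plain Newick (one tree
per line) or as a Nexus TREES block with a ``translate`` table mapping
integer tokens to taxon labels.  This module parses both dialects into a
:class:`TreeSet` — an ordered pool of trees on one taxon set with per-tree
provenance — and implements burn-in pooling of multi-run posteriors.

Underscores in unquoted labels are preserved verbatim (never converted to
spaces) so that labels match the metadata table byte-for-byte.  Polytomies
are accepted everywhere: consensus and constraint trees are legitimately
multifurcating.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "TreeIOError",
    "NewickParseError",
    "TaxonSetError",
    "PoolingError",
    "TreeSample",
    "TreeSet",
    "McmcSamplingSpec",
    "leaf_labels",
    "read_newick_trees",
    "read_nexus_trees",
    "write_newick_trees",
    "pool_posterior",
]


class TreeIOError(ValueError):
    """Base error for tree input/output and pooling."""


class NewickParseError(TreeIOError):
    """A Newick/Nexus statement could not be parsed."""


class TaxonSetError(TreeIOError):
    """Trees that must share one taxon set do not."""


class PoolingError(TreeIOError):
    """Burn-in pooling preconditions violated."""


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    """Leaf-label set of a tree; raises on duplicate or empty labels."""
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if any(not lab for lab in labels):
        raise TreeIOError("tree contains an empty leaf label")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeIOError(f"duplicate leaf labels: {dupes}")
    return frozenset(labels)


@dataclass(frozen=True)
class TreeSample:
    """One posterior tree with its provenance.

    ``generation`` is ``None`` when the source file carried no generation
    information; :func:`pool_posterior` then assigns ``i * interval``
    starting at ``interval``.
    """

    tree: dendropy.Tree
    run_id: str = "run1"
    generation: Optional[int] = None


@dataclass
class TreeSet:
    """An ordered pool of trees on one taxon set (the posterior stand-in)."""

    samples: list[TreeSample]
    taxon_labels: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if not self.samples:
            raise TreeIOError("TreeSet must contain at least one tree")
        label_sets = [leaf_labels(s.tree) for s in self.samples]
        first = label_sets[0]
        for k, ls in enumerate(label_sets[1:], start=2):
            if ls != first:
                diff = sorted(ls.symmetric_difference(first))
                raise TaxonSetError(
                    f"tree {k} taxon set differs from tree 1; "
                    f"symmetric difference: {diff}"
                )
        # generation indices strictly increasing within each run
        by_run: dict[str, list[int]] = {}
        for s in self.samples:
            if s.generation is not None:
                by_run.setdefault(s.run_id, []).append(s.generation)
        for run_id, gens in by_run.items():
            if any(b <= a for a, b in zip(gens, gens[1:])):
                raise TreeIOError(
                    f"generation indices not strictly increasing in run {run_id!r}"
                )
        self.taxon_labels = first

    @property
    def count(self) -> int:
        return len(self.samples)

    @property
    def trees(self) -> list[dendropy.Tree]:
        return [s.tree for s in self.samples]

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[TreeSample]:
        return iter(self.samples)


@dataclass(frozen=True)
class McmcSamplingSpec:
    """Sampling layout of one or more MCMC runs.

    Parameters
    ----------
    generations : int
        Chain length per run (e.g. ``10_000_000``).
    interval : int
        Sampling interval in generations (e.g. ``1000``).
    burnin : int
        Burn-in cutoff generation; the sample at exactly this generation is
        discarded (inclusive on the discard side), so with samples at
        0..1e7 step 1000 and burn-in 4e6 each run retains 6000 trees.
    n_runs : int
        Number of independent runs to be pooled.
    """

    generations: int
    interval: int
    burnin: int = 0
    n_runs: int = 1

    def __post_init__(self) -> None:
        if self.generations <= 0 or self.interval <= 0 or self.n_runs <= 0:
            raise TreeIOError("generations, interval and n_runs must be positive")
        if self.burnin < 0:
            raise TreeIOError("burn-in cutoff must be nonnegative")
        if self.burnin > self.generations:
            raise TreeIOError("burn-in cutoff exceeds chain length")
        if self.generations % self.interval != 0:
            raise TreeIOError("sampling interval must divide the chain length")

    def retained_generations(self) -> list[int]:
        """Generations kept after burn-in (g > burnin, g <= generations)."""
        return [
            g
            for g in range(self.interval, self.generations + 1, self.interval)
            if g > self.burnin
        ]


# -- readers -----------------------------------------------------------------

_GEN_PATTERNS = (
    re.compile(r"STATE[_ ]?(\d+)", re.IGNORECASE),
    re.compile(r"gen\s*=?\s*(\d+)", re.IGNORECASE),
    re.compile(r"rep[._ ](\d+)", re.IGNORECASE),
)


def _generation_from_label(label: Optional[str]) -> Optional[int]:
    if not label:
        return None
    for pat in _GEN_PATTERNS:
        m = pat.search(label)
        if m:
            return int(m.group(1))
    return None


def read_newick_trees(path: str | Path, run_id: Optional[str] = None) -> TreeSet:
    """Read a one-Newick-per-line file into a :class:`TreeSet`.

    Branch lengths are retained when present.  Malformed lines raise
    :class:`NewickParseError` naming the line number; inconsistent taxon
    sets raise :class:`TaxonSetError` listing the symmetric difference.
    """
    path = Path(path)
    run = run_id if run_id is not None else path.stem
    namespace = dendropy.TaxonNamespace()
    samples: list[TreeSample] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                tree = dendropy.Tree.get(
                    data=line,
                    schema="newick",
                    taxon_namespace=namespace,
                    preserve_underscores=True,
                )
            except Exception as exc:  # dendropy raises several error types
                raise NewickParseError(
                    f"{path}: malformed Newick on line {lineno}: {exc}"
                ) from exc
            samples.append(TreeSample(tree=tree, run_id=run, generation=None))
    if not samples:
        raise TreeIOError(f"{path}: no trees found")
    return TreeSet(samples)


def read_nexus_trees(path: str | Path, run_id: Optional[str] = None) -> TreeSet:
    """Read a Nexus TREES block (with optional translate table).

    Leaf labels are the translated names; statement order is preserved.
    Generation indices are parsed from tree names of the form ``STATE_N``
    or ``gen = N`` when present, else left unset (assigned at pooling).
    """
    path = Path(path)
    run = run_id if run_id is not None else path.stem
    try:
        tree_list = dendropy.TreeList.get(
            path=str(path), schema="nexus", preserve_underscores=True
        )
    except Exception as exc:
        raise NewickParseError(f"{path}: failed to parse Nexus: {exc}") from exc
    if len(tree_list) == 0:
        raise TreeIOError(f"{path}: no trees found in TREES block")
    parsed = [_generation_from_label(t.label) for t in tree_list]
    if any(g is None for g in parsed):
        parsed = [None] * len(tree_list)  # all-or-nothing: avoid mixed indexing
    samples = [
        TreeSample(tree=t, run_id=run, generation=g)
        for t, g in zip(tree_list, parsed)
    ]
    return TreeSet(samples)


def write_newick_trees(treeset: TreeSet, path: str | Path) -> None:
    """Write one ';'-terminated Newick string per line (UTF-8)."""
    with open(path, "w", encoding="utf-8") as fh:
        for sample in treeset:
            newick = sample.tree.as_string(
                schema="newick",
                unquoted_underscores=True,
                suppress_rooting=True,
            ).strip()
            fh.write(newick + "\n")


# -- burn-in pooling ---------------------------------------------------------


def pool_posterior(runs: Sequence[TreeSet], spec: McmcSamplingSpec) -> TreeSet:
    """Pool post-burn-in samples from multiple runs into one TreeSet.

    Every sample whose generation index is <= the burn-in cutoff is
    discarded; retained samples are concatenated across runs preserving run
    order.  With 2 runs of 1e7 generations sampled every 1000 and burn-in
    4e6 this yields the canonical 12,000-tree pooled posterior.
    """
    if len(runs) != spec.n_runs:
        raise PoolingError(
            f"spec declares {spec.n_runs} runs but {len(runs)} were supplied"
        )
    taxa = runs[0].taxon_labels
    for k, run in enumerate(runs[1:], start=2):
        if run.taxon_labels != taxa:
            diff = sorted(run.taxon_labels.symmetric_difference(taxa))
            raise TaxonSetError(
                f"run {k} taxon set differs from run 1; symmetric difference: {diff}"
            )
    pooled: list[TreeSample] = []
    for idx, run in enumerate(runs, start=1):
        gens = [s.generation for s in run]
        if all(g is None for g in gens):
            gens = [(i + 1) * spec.interval for i in range(len(run))]
        elif any(g is None for g in gens):
            raise PoolingError(f"run {idx}: mixed present/absent generation indices")
        _validate_generations(gens, spec, idx)
        retained = [
            TreeSample(tree=s.tree, run_id=s.run_id, generation=g)
            for s, g in zip(run, gens)
            if g > spec.burnin
        ]
        if not retained:
            raise PoolingError(f"run {idx}: no trees retained after burn-in")
        pooled.extend(retained)
    return TreeSet(pooled)


def _validate_generations(gens: list[int], spec: McmcSamplingSpec, run_idx: int) -> None:
    if gens[0] not in (0, spec.interval):
        raise PoolingError(
            f"run {run_idx}: first generation {gens[0]} is neither 0 nor the "
            f"sampling interval {spec.interval}"
        )
    for a, b in zip(gens, gens[1:]):
        if b - a != spec.interval:
            raise PoolingError(
                f"run {run_idx}: generations {a} -> {b} do not step by the "
                f"sampling interval {spec.interval}"
            )
    if gens[-1] > spec.generations:
        raise PoolingError(
            f"run {run_idx}: generation {gens[-1]} exceeds chain length "
            f"{spec.generations}"
        )
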
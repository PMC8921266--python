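"""Reading, validating and querying dated-tree posterior ensembles.

A chronogram is a rooted phylogenetic tree whose branch lengths are durations
in absolute time (here Myr); node ages are measured in Ma before present,
increasing into the past, with extant tips at age 0.  Bayesian molecular-clock
software emits posterior samples of such trees as a multi-tree file with one
Newick string per line (the "datedist" dialect); because early MCMC samples
reflect the starting point rather than the posterior, a burn-in fraction is
discarded from the front of the sample.

Tree parsing and MRCA queries are delegated to :mod:`dendropy`; this module
adds age bookkeeping, ultrametricity validation and the ensemble container.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "DatedTree",
    "PosteriorEnsemble",
    "GeologicalWindow",
    "ChronogramError",
    "TreeFormatError",
    "TreeContentError",
    "read_dated_trees",
    "write_dated_trees",
    "node_age",
    "normal_prior_from_interval",
]


class ChronogramError(ValueError):
    """Base error for chronogram handling."""


class TreeFormatError(ChronogramError):
    """A tree string failed to parse."""


class TreeContentError(ChronogramError):
    """A parsed tree violates dated-tree invariants."""


#: Default relative tolerance (fraction of root age) for the ultrametricity
#: check; serialized chronograms accumulate rounding in branch lengths.
DEFAULT_ULTRAMETRIC_RTOL = 1e-6


class DatedTree:
    """A single time-calibrated rooted tree with node ages in Ma.

    Wraps a :class:`dendropy.Tree`. Ages are derived from branch lengths by
    placing every leaf at age 0 (root age = depth of the leaves); the tree
    must be ultrametric within ``ultrametric_rtol * root_age``.  Trees are
    treated as rooted as given — no rerooting is performed.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        ultrametric_rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
    ) -> None:
        tree.is_rooted = True  # trees are taken as rooted as given
        self._tree = tree
        self._ages: dict[dendropy.Node, float] = {}
        self._leaf_labels: frozenset[str] = frozenset(
            leaf.taxon.label for leaf in tree.leaf_node_iter()
        )
        n_leaves = sum(1 for _ in tree.leaf_node_iter())
        if len(self._leaf_labels) != n_leaves:
            raise TreeContentError("duplicate leaf labels in tree")
        self._compute_ages(ultrametric_rtol)

    def _compute_ages(self, rtol: float) -> None:
        depths: dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                bl = node.edge.length if node.edge.length is not None else 0.0
                if bl < 0:
                    raise TreeContentError(
                        f"negative branch length {bl} (child older than parent)"
                    )
                depths[node] = depths[node.parent_node] + bl
        leaf_depths = [depths[l] for l in self._tree.leaf_node_iter()]
        root_age = max(leaf_depths) if leaf_depths else 0.0
        tol = max(rtol * root_age, 1e-12)
        if root_age > 0 and (root_age - min(leaf_depths)) > tol:
            raise TreeContentError(
                f"tree is not ultrametric: leaf depths span "
                f"[{min(leaf_depths):.6g}, {root_age:.6g}] (tol {tol:.3g})"
            )
        self._ages = {n: root_age - d for n, d in depths.items()}
        self._root_age = root_age

    # -- queries -----------------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> frozenset[str]:
        return self._leaf_labels

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_labels)

    @property
    def root_age(self) -> float:
        return self._root_age

    def age_of(self, node: dendropy.Node) -> float:
        return self._ages[node]

    def mrca(self, leaves: Iterable[str]) -> dendropy.Node:
        """Most recent common ancestor of a set of leaf labels."""
        labels = list(leaves)
        unknown = set(labels) - self._leaf_labels
        if unknown:
            raise ChronogramError(f"unknown leaf label(s): {sorted(unknown)}")
        if len(labels) == 1:
            return self._tree.find_node_with_taxon_label(labels[0])
        node = self._tree.mrca(taxon_labels=labels)
        if node is None:  # pragma: no cover - dendropy returns root otherwise
            raise ChronogramError(f"no MRCA found for {labels}")
        return node

    def internal_node_ages(self, within: dendropy.Node | None = None) -> list[float]:
        """Ages of divergence (internal) nodes, optionally within a subtree."""
        root = within if within is not None else self._tree.seed_node
        return [
            self._ages[n]
            for n in root.preorder_iter()
            if not n.is_leaf()
        ]

    def clade_leaf_labels(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def as_newick(self, precision: int = 17) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=f".{precision}g",
        ).strip()


@dataclass
class PosteriorEnsemble:
    """An ordered posterior sample of dated trees with a burn-in policy.

    ``trees`` holds the full ordered sample; ``post_burn_in`` yields the
    retained tail after dropping ``floor(burn_in_fraction * n)`` trees from
    the front.
    """

    trees: list[DatedTree]
    burn_in_fraction: float = 0.20
    require_common_leaves: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ChronogramError(
                f"burn_in_fraction must lie in [0, 1), got {self.burn_in_fraction}"
            )
        if not self.trees:
            raise ChronogramError("ensemble must contain at least one tree")
        if self.require_common_leaves:
            ref = self.trees[0].leaf_labels
            for i, t in enumerate(self.trees[1:], start=2):
                if t.leaf_labels != ref:
                    raise TreeContentError(
                        f"tree {i} has a different leaf set than tree 1"
                    )
        if self.n_post_burn_in < 1:
            raise ChronogramError("burn-in leaves no trees in the ensemble")

    @property
    def n_burn_in(self) -> int:
        return math.floor(self.burn_in_fraction * len(self.trees))

    @property
    def n_post_burn_in(self) -> int:
        return len(self.trees) - self.n_burn_in

    @property
    def post_burn_in(self) -> list[DatedTree]:
        return self.trees[self.n_burn_in :]

    @property
    def leaf_labels(self) -> frozenset[str]:
        return self.trees[0].leaf_labels


@dataclass(frozen=True)
class GeologicalWindow:
    """A named geological time interval, bounds in Ma before present."""

    name: str
    older: float
    younger: float

    def __post_init__(self) -> None:
        if not self.older > self.younger >= 0:
            raise ChronogramError(
                f"window requires older > younger >= 0, got "
                f"({self.older}, {self.younger})"
            )


def _iter_tree_lines(source) -> Iterable[str]:
    # a str is treated as tree data if it looks like Newick/NEXUS, else a path
    if isinstance(source, Path):
        with open(source) as fh:
            yield from fh
    elif isinstance(source, str):
        if "(" in source or "\n" in source or source.lstrip().startswith("#"):
            yield from io.StringIO(source)
        else:
            with open(source) as fh:
                yield from fh
    else:
        yield from source


def read_dated_trees(
    source,
    burn_in: float = 0.20,
    ultrametric_rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
) -> PosteriorEnsemble:
    """Read a posterior ensemble from a multi-tree file.

    ``source`` may be a path, a multi-line string, or an iterable of lines.
    The expected dialect is one rooted Newick tree per line (datedist style);
    a NEXUS stream (leading ``#NEXUS``) is accepted read-only.  Non-branch-
    length annotations (comments, rate metadata) are ignored on read.

    The first ``floor(burn_in * n)`` trees are discarded; all trees must
    share one leaf set.
    """
    lines = list(_iter_tree_lines(source))
    if lines and lines[0].lstrip().upper().startswith("#NEXUS"):
        tl = dendropy.TreeList.get(data="".join(lines), schema="nexus")
        trees = [DatedTree(t, ultrametric_rtol) for t in tl]
    else:
        trees = []
        tns = dendropy.TaxonNamespace()
        for lineno, line in enumerate(lines, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                t = dendropy.Tree.get(
                    data=line,
                    schema="newick",
                    taxon_namespace=tns,
                    rooting="default-rooted",
                )
            except Exception as exc:
                raise TreeFormatError(f"line {lineno}: cannot parse Newick: {exc}")
            try:
                trees.append(DatedTree(t, ultrametric_rtol))
            except TreeContentError as exc:
                raise TreeContentError(f"line {lineno}: {exc}")
    if not trees:
        raise ChronogramError("no trees found in source")
    return PosteriorEnsemble(trees=trees, burn_in_fraction=burn_in)


def write_dated_trees(ensemble: PosteriorEnsemble, path, precision: int = 17) -> None:
    """Write the full ensemble as one Newick per line (datedist style)."""
    with open(path, "w") as fh:
        for t in ensemble.trees:
            fh.write(t.as_newick(precision=precision) + "\n")


def node_age(tree: DatedTree, node: Iterable[str] | str) -> float:
    """Age (Ma) of the MRCA of the given leaf labels.

    A single label returns that tip's age (0 for extant tips); the full leaf
    set returns the root age.  The result is invariant to the order of the
    specifier.
    """
    labels = [node] if isinstance(node, str) else list(node)
    return tree.age_of(tree.mrca(labels))


def normal_prior_from_interval(
    older: float, younger: float, divisor: float = 2.0
) -> tuple[float, float]:
    """Normal calibration prior from an (older, younger) age interval.

    The mean is the interval midpoint; the standard deviation is the
    half-range divided by ``divisor``.  The default divisor 2.0 treats the
    bounds as a two-sigma (~95%) interval — e.g. a 4400–3400 Ma habitability
    range yields mean 3900 Ma, sd 250 Ma; pass 1.96 for the exact normal
    95% quantile convention.
    """
    if not older > younger:
        raise ChronogramError(
            f"interval requires older > younger, got ({older}, {younger})"
        )
    if divisor <= 0:
        raise ChronogramError(f"divisor must be positive, got {divisor}")
    half_range = (older - younger) / 2.0
    return (older + younger) / 2.0, half_range / divisor
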
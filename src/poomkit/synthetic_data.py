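"""Synthetic fixtures with known ground truth for every pipeline stage.

Real inputs to the pipeline are posterior ensembles of dated trees (~1000
samples of a few-hundred-tip chronogram spanning ~3 Gyr) and tables of HGT
events inferred by gene-tree/species-tree reconciliation repeated over 100
replicates.  This module generates structurally identical data from known
generating processes so that every downstream estimate can be checked against
its ground truth without any external download:

* :func:`simulate_yule_tree` — an exact event-driven pure-birth (Yule)
  process with piecewise-constant per-lineage rates, run forward in time
  from a stem lineage at ``root_age`` to the present.
* :func:`make_posterior_ensemble` — posterior-style spread around one
  topology: multiplicative lognormal node-age jitter with unit mean.
* :func:`make_hgt_table` — reconciliation-style event tables whose
  replicate counts sum to 100, with a configurable fraction of leaf
  recipients to exercise the leaf-deletion weighting rule.

Ground truth is returned alongside each artifact (and written as a sidecar
JSON by the CLI) so tests never re-derive it from the fixtures themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .chronogram_io import DatedTree, PosteriorEnsemble, TreeContentError

__all__ = [
    "TreeSimConfig",
    "SyntheticDataError",
    "simulate_yule_tree",
    "simulate_yule_forest",
    "make_posterior_ensemble",
    "make_hgt_table",
    "specifier_string",
]


class SyntheticDataError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class TreeSimConfig:
    """Configuration of the piecewise-constant-rate birth simulation.

    ``epochs`` is a list of ``(start_ma, end_ma, rate)`` with ages in Ma
    (start older than end) and per-lineage branching rates in 1/Myr; the
    epochs must tile ``[root_age, 0]`` contiguously.  ``age_jitter_cv`` is
    the coefficient of variation of the posterior-style node-age noise.
    """

    epochs: tuple[tuple[float, float, float], ...]
    root_age: float
    n_trees: int = 100
    age_jitter_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_age <= 0:
            raise SyntheticDataError(f"root_age must be positive, got {self.root_age}")
        eps = sorted(self.epochs, key=lambda e: -e[0])
        if not eps:
            raise SyntheticDataError("at least one epoch required")
        if abs(eps[0][0] - self.root_age) > 1e-9:
            raise SyntheticDataError("oldest epoch must start at root_age")
        if abs(eps[-1][1]) > 1e-9:
            raise SyntheticDataError("youngest epoch must end at 0")
        for (s, e, r) in eps:
            if not s > e:
                raise SyntheticDataError(f"epoch start must be older than end: {(s, e)}")
            if r < 0:
                raise SyntheticDataError(f"branching rate must be >= 0, got {r}")
        for prev, nxt in zip(eps, eps[1:]):
            if abs(prev[1] - nxt[0]) > 1e-9:
                raise SyntheticDataError("epochs must tile [0, root_age] contiguously")
        object.__setattr__(self, "epochs", tuple(eps))
        if self.n_trees < 1:
            raise SyntheticDataError("n_trees must be >= 1")
        if self.age_jitter_cv < 0:
            raise SyntheticDataError("age_jitter_cv must be >= 0")

    def rate_at(self, age: float) -> float:
        for (s, e, r) in self.epochs:
            if e <= age <= s:
                return r
        raise SyntheticDataError(f"age {age} outside [0, root_age]")

    @classmethod
    def constant(
        cls, rate: float, root_age: float, n_trees: int = 100,
        age_jitter_cv: float = 0.05, seed: int = 0,
    ) -> "TreeSimConfig":
        return cls(
            epochs=((root_age, 0.0, rate),),
            root_age=root_age,
            n_trees=n_trees,
            age_jitter_cv=age_jitter_cv,
            seed=seed,
        )


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_yule_tree(config: TreeSimConfig, rng=None) -> DatedTree:
    """Simulate one dated tree under the piecewise-constant birth process.

    A single stem lineage starts at ``config.root_age`` and each extant
    lineage branches with the epoch's per-lineage rate; event times are drawn
    exactly (exponential waiting times, restarted at epoch boundaries, which
    is valid by memorylessness).  Tips are extant (age 0), so the tree is
    ultrametric; its root node sits at the first branching event.  If no
    branching occurs, a degenerate single-tip tree is returned with a
    warning.
    """
    rng = _rng(rng if rng is not None else config.seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    # active lineages are open dendropy nodes; node.age set when it closes
    root = tree.seed_node
    active: list[dendropy.Node] = [root]
    birth_age: dict[int, float] = {id(root): config.root_age}

    boundaries = [e[1] for e in config.epochs]  # epoch end ages, descending
    age = config.root_age
    ei = 0  # current epoch index
    while age > 0:
        start, end, rate = config.epochs[ei]
        n = len(active)
        total = n * rate
        if total <= 0:
            age = end
            ei += 1 if ei + 1 < len(config.epochs) else 0
            if end == 0:
                break
            continue
        wait = rng.exponential(1.0 / total)
        if age - wait < end:
            age = end
            if end == 0:
                break
            ei += 1
            continue
        age -= wait
        node = active[rng.integers(n)]
        node.age_ma = age
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        active.remove(node)
        active.extend([left, right])
        birth_age[id(left)] = age
        birth_age[id(right)] = age

    for i, node in enumerate(active, start=1):
        node.age_ma = 0.0
        node.taxon = tns.require_taxon(label=f"T{i}")

    # assign branch lengths from ages (stem edge above the first split is
    # dropped; the tree's root age is the first branching time)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age_ma - node.age_ma

    if len(active) == 1:
        warnings.warn(
            "no branching event occurred; returning a degenerate 1-tip tree",
            stacklevel=2,
        )
    return DatedTree(tree)


def simulate_yule_forest(config: TreeSimConfig, rng=None) -> PosteriorEnsemble:
    """Ensemble of ``config.n_trees`` independent simulations of the process.

    Unlike :func:`make_posterior_ensemble` (posterior-style jitter of one
    topology) each member is an independent realization, so ensemble averages
    of lineage counts estimate the expectation of the generating process.
    Degenerate single-tip realizations are redrawn.
    """
    rng = _rng(rng if rng is not None else config.seed)
    trees: list[DatedTree] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while len(trees) < config.n_trees:
            t = simulate_yule_tree(config, rng)
            if t.n_leaves >= 2:
                trees.append(t)
    return PosteriorEnsemble(trees=trees, burn_in_fraction=0.0, require_common_leaves=False)


def make_posterior_ensemble(
    tree: DatedTree,
    n_trees: int,
    age_jitter_cv: float,
    seed=None,
) -> PosteriorEnsemble:
    """Posterior-style ensemble: one topology, lognormally jittered node ages.

    Working tips-to-root, each internal node's *gap* above its oldest child
    is multiplied by an independent unit-mean lognormal factor with
    coefficient of variation ``age_jitter_cv``; the node's new age is its
    children's (jittered) maximum plus the jittered gap.  Parent-older-than-
    child ordering therefore holds by construction, and ensemble mean node
    ages track the generating ages (exactly for cherries, and to within the
    small max-over-children effect elsewhere).  Tip ages stay at 0.  Burn-in
    of the returned ensemble is 0 — the jittered trees emulate an already
    burned-in posterior.
    """
    rng = _rng(seed)
    if age_jitter_cv < 0:
        raise SyntheticDataError("age_jitter_cv must be >= 0")
    sigma = float(np.sqrt(np.log1p(age_jitter_cv**2)))
    mu = -0.5 * sigma**2  # unit mean

    base = tree.tree
    replicates: list[DatedTree] = []
    for _ in range(n_trees):
        new_age: dict[dendropy.Node, float] = {}
        for node in base.postorder_node_iter():
            if node.is_leaf():
                new_age[node] = 0.0
                continue
            children = node.child_nodes()
            floor_new = max(new_age[c] for c in children)
            gap = tree.age_of(node) - max(tree.age_of(c) for c in children)
            factor = 1.0 if sigma == 0.0 else rng.lognormal(mu, sigma)
            new_age[node] = floor_new + gap * factor
        clone = dendropy.Tree(base)  # deep copy incl. its own namespace clone
        for orig, copy_ in zip(base.preorder_node_iter(), clone.preorder_node_iter()):
            copy_.age_ma = new_age[orig]
        for node in clone.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = node.parent_node.age_ma - node.age_ma
        replicates.append(DatedTree(clone))
    return PosteriorEnsemble(trees=replicates, burn_in_fraction=0.0)


def specifier_string(labels: frozenset[str] | set[str] | str) -> str:
    """Canonical clade specifier: sorted leaf labels joined by ``|``."""
    if isinstance(labels, str):
        return labels
    return "|".join(sorted(labels))


def make_hgt_table(
    ensemble: PosteriorEnsemble,
    n_events: int,
    leaf_mix: float = 0.3,
    seed=None,
    n_replicates: int = 100,
):
    """Generate reconciliation-style HGT events against an ensemble.

    Each event carries 1–3 (donor, recipient, replicate_count) mappings whose
    counts sum exactly to ``n_replicates``; recipients are random non-root
    internal clades of the ensemble's base topology, and with probability
    ``leaf_mix`` one mapping's recipient is a leaf (exercising the
    leaf-recipient deletion rule downstream).  Donors are random nodes and
    are carried through but not analysed.

    Returns ``(events, ground_truth)`` where ``ground_truth`` maps event id
    to the internal-recipient weights and the brute-force expected weighted
    mean age over the post-burn-in ensemble.
    """
    from .hgt_ages import HGTEvent, HGTMapping  # local import to avoid cycle

    rng = _rng(seed)
    if not 0.0 <= leaf_mix <= 1.0:
        raise SyntheticDataError(f"leaf_mix must lie in [0, 1], got {leaf_mix}")
    base = ensemble.trees[0]
    internal = [
        n for n in base.tree.preorder_node_iter()
        if not n.is_leaf() and n.parent_node is not None
    ]
    if not internal:
        raise SyntheticDataError("base tree has no non-root internal nodes")
    leaves = sorted(base.leaf_labels)

    events: list[HGTEvent] = []
    truth: dict[str, dict] = {}
    post = ensemble.post_burn_in
    for k in range(1, n_events + 1):
        n_internal = int(rng.integers(1, min(3, len(internal)) + 1))
        picks = rng.choice(len(internal), size=n_internal, replace=False)
        recips = [base.clade_leaf_labels(internal[i]) for i in picks]
        add_leaf = rng.random() < leaf_mix
        n_map = n_internal + (1 if add_leaf else 0)
        counts = rng.multinomial(n_replicates - n_map, rng.dirichlet(np.ones(n_map))) + 1
        mappings = []
        for spec, cnt in zip(recips, counts[:n_internal]):
            donor = leaves[rng.integers(len(leaves))]
            mappings.append(HGTMapping(donor=donor, recipient=specifier_string(spec),
                                       replicate_count=int(cnt)))
        if add_leaf:
            leaf = leaves[rng.integers(len(leaves))]
            donor = leaves[rng.integers(len(leaves))]
            mappings.append(HGTMapping(donor=donor, recipient=leaf,
                                       replicate_count=int(counts[-1])))
        event = HGTEvent(event_id=f"HGT{k}", mappings=mappings, support=1.0)
        events.append(event)

        # brute-force ground truth: renormalized internal weights x mean ages
        tot = sum(int(c) for c in counts[:n_internal])
        weights = {specifier_string(s): int(c) / tot
                   for s, c in zip(recips, counts[:n_internal])}
        mean_age = sum(
            w * float(np.mean([t.age_of(t.mrca(spec.split("|"))) for t in post]))
            for spec, w in weights.items()
        )
        truth[event.event_id] = {"weights": weights, "true_mean_age_ma": mean_age}
    return events, truth
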
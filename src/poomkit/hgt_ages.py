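"""Dating horizontal gene transfer events against a chronogram posterior.

Gene-tree/species-tree reconciliation (run over many replicates) reports, for
each HGT event, the donor and recipient nodes of the species tree in each
replicate; an event's replicate counts over its candidate recipients describe
where on the species tree the transfer landed.  Combining these counts with a
posterior ensemble of dated species trees yields a *weighted age distribution*
for the event:

(i)   an event with several internal-node recipients weights each recipient by
      its fraction of replicates;
(ii)  leaf recipients are deleted and the remaining internal recipients'
      weights renormalized (a leaf pins no divergence age);
(iii) events with leaf donors still contribute their recipients' ages.

For each posterior tree and each retained recipient, the recipient node's age
is one sample of the event's *younger* bound and its parent's age one sample
of the *older* bound (the transfer happened on the branch between them).  Box
summaries report the weighted mean and the 2.5/25/75/97.5 weighted
percentiles; window-overlap probabilities measure how much of an event's
branch interval intersects a geological window such as the Great Oxidation
Event (2400-2300 Ma).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .chronogram_io import ChronogramError, GeologicalWindow, PosteriorEnsemble

__all__ = [
    "HGTMapping",
    "HGTEvent",
    "WeightedAgeDistribution",
    "EventBounds",
    "BoxSummary",
    "HGTError",
    "LeafOnlyEventError",
    "RecipientWeights",
    "recipient_weights",
    "weighted_age_distribution",
    "event_bounds",
    "summarize_box",
    "window_overlap",
    "read_hgt_table",
    "write_hgt_table",
    "filter_by_support",
]

DEFAULT_SUPPORT_THRESHOLD = 0.80
_NORM_TOL = 1e-9


class HGTError(ValueError):
    """Invalid HGT event data or query."""


class LeafOnlyEventError(HGTError):
    """All of an event's recipients are leaves; no age distribution exists."""


def _is_leaf_specifier(spec: str) -> bool:
    return "|" not in spec


def _specifier_labels(spec: str) -> list[str]:
    return spec.split("|")


@dataclass(frozen=True)
class HGTMapping:
    """One reconciliation mapping: donor, recipient, replicate count.

    Donor and recipient are clade specifiers — sorted leaf labels joined by
    ``|``; a single label denotes a leaf.
    """

    donor: str
    recipient: str
    replicate_count: int

    def __post_init__(self) -> None:
        if self.replicate_count < 1:
            raise HGTError(
                f"replicate_count must be >= 1, got {self.replicate_count}"
            )


@dataclass(frozen=True)
class HGTEvent:
    """An inferred transfer with its per-replicate mappings and support."""

    event_id: str
    mappings: tuple[HGTMapping, ...]
    support: float

    def __init__(self, event_id: str, mappings: Sequence[HGTMapping], support: float):
        object.__setattr__(self, "event_id", event_id)
        object.__setattr__(self, "mappings", tuple(mappings))
        object.__setattr__(self, "support", float(support))
        if not self.mappings:
            raise HGTError(f"event {event_id}: at least one mapping required")
        if not 0.0 < self.support <= 1.0:
            raise HGTError(f"event {event_id}: support must lie in (0, 1], got {support}")


@dataclass(frozen=True)
class RecipientWeights:
    """Internal-node recipient weights after leaf deletion (rules i-ii)."""

    weights: tuple[tuple[str, float], ...]
    leaf_only: bool


@dataclass(frozen=True)
class WeightedAgeDistribution:
    """Samples of (age Ma, weight) with weights normalized to 1."""

    ages: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "weights", weights)
        if ages.shape != weights.shape or ages.ndim != 1 or ages.size == 0:
            raise HGTError("ages and weights must be equal-length non-empty 1-D")
        if np.any(weights < 0) or np.any(ages < 0):
            raise HGTError("ages and weights must be non-negative")
        if abs(weights.sum() - 1.0) > _NORM_TOL:
            raise HGTError(f"weights must sum to 1, got {weights.sum()!r}")

    def mean(self) -> float:
        return float(np.sum(self.ages * self.weights))

    def percentile(self, q: float) -> float:
        """Weighted percentile: first age whose cumulative weight >= q/100."""
        order = np.argsort(self.ages, kind="stable")
        cum = np.cumsum(self.weights[order])
        idx = int(np.searchsorted(cum, q / 100.0 - _NORM_TOL, side="left"))
        idx = min(idx, len(order) - 1)
        return float(self.ages[order][idx])


@dataclass(frozen=True)
class EventBounds:
    """Older (parent/stem-side) and younger (recipient node) age bounds.

    Samples of ``older`` and ``younger`` are index-aligned: entry *i* of each
    comes from the same (posterior tree, recipient) pair, so joint statistics
    may pair them directly.
    """

    older: WeightedAgeDistribution
    younger: WeightedAgeDistribution

    def __post_init__(self) -> None:
        if self.older.mean() < self.younger.mean() - _NORM_TOL:
            raise HGTError("older bound mean must be >= younger bound mean")


@dataclass(frozen=True)
class BoxSummary:
    """Weighted box statistics as drawn in event-timing summary figures."""

    mean: float
    p2_5: float
    p25: float
    p75: float
    p97_5: float


def recipient_weights(event: HGTEvent) -> RecipientWeights:
    """Apply weighting rules (i)-(ii): drop leaf recipients, renormalize.

    Replicate counts are aggregated per recipient specifier across mappings
    (donors do not affect weights — rule (iii) keeps recipients of leaf-donor
    transfers).  If every recipient is a leaf the result is empty with
    ``leaf_only=True``.
    """
    counts: dict[str, int] = {}
    for m in event.mappings:
        if _is_leaf_specifier(m.recipient):
            continue
        counts[m.recipient] = counts.get(m.recipient, 0) + m.replicate_count
    if not counts:
        return RecipientWeights(weights=(), leaf_only=True)
    total = sum(counts.values())
    return RecipientWeights(
        weights=tuple((spec, c / total) for spec, c in counts.items()),
        leaf_only=False,
    )


def _resolve(tree, event_id: str, spec: str):
    try:
        return tree.mrca(_specifier_labels(spec))
    except ChronogramError as exc:
        raise HGTError(f"event {event_id}: cannot resolve '{spec}': {exc}")


def weighted_age_distribution(
    event: HGTEvent, ensemble: PosteriorEnsemble
) -> WeightedAgeDistribution:
    """Pool recipient node ages over the post-burn-in ensemble.

    Each (posterior tree, internal recipient) pair contributes one sample
    with weight ``recipient weight / number of post-burn-in trees``.
    """
    rw = recipient_weights(event)
    if rw.leaf_only:
        raise LeafOnlyEventError(
            f"event {event.event_id}: all recipients are leaves; "
            "no internal-node age distribution exists"
        )
    trees = ensemble.post_burn_in
    ages, weights = [], []
    for spec, w in rw.weights:
        for t in trees:
            node = _resolve(t, event.event_id, spec)
            ages.append(t.age_of(node))
            weights.append(w / len(trees))
    return WeightedAgeDistribution(np.array(ages), np.array(weights))


def event_bounds(event: HGTEvent, ensemble: PosteriorEnsemble) -> EventBounds:
    """Older/younger bound distributions for the event's recipient branch.

    Per posterior tree and retained recipient, the younger sample is the
    recipient node's age and the older sample its parent's age (the transfer
    occurred on the branch between them); both carry the same weight, and
    the two distributions are index-aligned for joint statistics.
    """
    rw = recipient_weights(event)
    if rw.leaf_only:
        raise LeafOnlyEventError(
            f"event {event.event_id}: all recipients are leaves"
        )
    trees = ensemble.post_burn_in
    older, younger, weights = [], [], []
    for spec, w in rw.weights:
        for t in trees:
            node = _resolve(t, event.event_id, spec)
            if node.parent_node is None:
                raise HGTError(
                    f"event {event.event_id}: recipient '{spec}' is the root; "
                    "older bound undefined"
                )
            younger.append(t.age_of(node))
            older.append(t.age_of(node.parent_node))
            weights.append(w / len(trees))
    w = np.array(weights)
    return EventBounds(
        older=WeightedAgeDistribution(np.array(older), w),
        younger=WeightedAgeDistribution(np.array(younger), w.copy()),
    )


def summarize_box(dist: WeightedAgeDistribution) -> BoxSummary:
    """Weighted mean and 2.5/25/75/97.5 weighted percentiles."""
    return BoxSummary(
        mean=dist.mean(),
        p2_5=dist.percentile(2.5),
        p25=dist.percentile(25),
        p75=dist.percentile(75),
        p97_5=dist.percentile(97.5),
    )


def window_overlap(
    bounds: EventBounds, window: GeologicalWindow, mode: str = "joint"
) -> float:
    """Probability that the event's branch interval intersects a window.

    ``joint`` (default): per index-aligned posterior sample, the interval
    [younger, older] intersects [window.younger, window.older] iff
    ``younger <= window.older`` and ``older >= window.younger``; the result
    is the total weight of intersecting samples.  ``marginal`` treats the
    older and younger bound distributions as independent, in which case the
    intersection probability factorizes into
    ``P(older >= window.younger) * P(younger <= window.older)``.
    """
    o, y = bounds.older, bounds.younger
    if mode == "joint":
        hit = (y.ages <= window.older) & (o.ages >= window.younger)
        return float(np.sum(y.weights[hit]))
    if mode == "marginal":
        p_older = float(np.sum(o.weights[o.ages >= window.younger]))
        p_younger = float(np.sum(y.weights[y.ages <= window.older]))
        return p_older * p_younger
    raise HGTError(f"unknown overlap mode '{mode}' (expected 'joint' or 'marginal')")


# -- tabular I/O -----------------------------------------------------------

_COLUMNS = ["event_id", "donor", "recipient", "replicate_count"]


def read_hgt_table(path, n_replicates: int = 100) -> list[HGTEvent]:
    """Read the TSV event dialect (event_id, donor, recipient, replicate_count).

    Rows are grouped by event id (file order preserved); an event's support
    is its total replicate count divided by ``n_replicates``.
    """
    groups: dict[str, list[HGTMapping]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise HGTError(f"missing column(s) in HGT table: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                count = int(row["replicate_count"])
            except ValueError:
                raise HGTError(f"line {i}: replicate_count not an integer")
            groups.setdefault(row["event_id"], []).append(
                HGTMapping(donor=row["donor"], recipient=row["recipient"],
                           replicate_count=count)
            )
    return [
        HGTEvent(
            event_id=eid,
            mappings=maps,
            support=min(1.0, sum(m.replicate_count for m in maps) / n_replicates),
        )
        for eid, maps in groups.items()
    ]


def write_hgt_table(events: Iterable[HGTEvent], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_COLUMNS)
        for e in events:
            for m in e.mappings:
                writer.writerow([e.event_id, m.donor, m.recipient, m.replicate_count])


def filter_by_support(
    events: Iterable[HGTEvent], threshold: float = DEFAULT_SUPPORT_THRESHOLD
) -> list[HGTEvent]:
    """Keep events whose replicate support meets the threshold (default 0.80)."""
    return [e for e in events if e.support >= threshold]
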
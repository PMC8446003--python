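"""Prey-range extraction, overlap statistics and degree-abundance tests.

A predator's prey range is the set of prey OTUs it is connected to in the
inferred network. Ranges are compared between predator clades, fractions
and sites with Venn-style overlaps (counts plus percentages of the union),
and the association between a predator's abundance and how many prey it is
linked to is measured as a Pearson r^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .otu_io import OTUTable
from .screen import InteractionNetwork

__all__ = [
    "PreyRangeSet",
    "VennResult",
    "prey_sets",
    "overlap",
    "shared_fraction",
    "unique_prey_fraction",
    "degree_abundance_correlation",
]


def _round1(x: float) -> float:
    """Round to one decimal, half up — the convention of printed percentages."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PreyRangeSet:
    """Mapping predator OTU -> set of linked prey OTUs, with a context label."""

    ranges: dict[str, frozenset[str]]
    label: str = ""

    def __post_init__(self) -> None:
        empty = [p for p, s in self.ranges.items() if not s]
        if empty:
            raise ValueError(f"empty prey set for predator(s) {empty[:3]}")

    @property
    def prey_union(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.ranges.values():
            out |= s
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.ranges)


def prey_sets(network: InteractionNetwork, label: str = "") -> PreyRangeSet:
    """Adjacency restricted to the predator side; edgeless predators dropped."""
    if network.n_edges == 0:
        raise ValueError("network has no edges; no prey ranges to extract")
    ranges: dict[str, set[str]] = {}
    for e in network.edges:
        ranges.setdefault(e.predator_otu, set()).add(e.prey_otu)
    return PreyRangeSet({p: frozenset(s) for p, s in ranges.items()}, label=label)


@dataclass
class VennResult:
    """Region counts of a 2- or 3-way overlap and their share of the union.

    Region keys are frozensets of input labels: ``{"a"}`` is the a-only
    region, ``{"a","b"}`` the pairwise-exclusive region, etc. Percentages
    are of the union, rounded to one decimal (half-up).
    """

    labels: tuple[str, ...]
    regions: dict[frozenset, int]
    percentages: dict[frozenset, float] = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.regions.values())
        if total == 0:
            raise ValueError("empty union: nothing to overlap")
        self.percentages = {k: _round1(100.0 * v / total) for k, v in self.regions.items()}

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def shared_all(self) -> int:
        """Count of ids present in every input set."""
        return self.regions[frozenset(self.labels)]

    def shared_all_percentage(self) -> float:
        return shared_fraction(self.shared_all(), self.union_size)


def overlap(sets_a, sets_b, sets_c=None, labels: tuple[str, ...] | None = None) -> VennResult:
    """Venn region counts for two or three id collections.

    Each region count is the number of ids belonging to exactly that
    combination of inputs; counts therefore sum to the union size and the
    percentages to 100 up to rounding.
    """
    inputs = [frozenset(sets_a), frozenset(sets_b)]
    if sets_c is not None:
        inputs.append(frozenset(sets_c))
    if labels is None:
        labels = tuple("abc"[: len(inputs)])
    if len(labels) != len(inputs):
        raise ValueError("one label per input set required")
    union = frozenset().union(*inputs)
    if not union:
        raise ValueError("empty union: nothing to overlap")
    regions: dict[frozenset, int] = {}
    # all non-empty label combinations, exclusive regions
    from itertools import combinations

    for r in range(1, len(inputs) + 1):
        for combo in combinations(range(len(inputs)), r):
            inside = frozenset.intersection(*(inputs[i] for i in combo))
            outside = frozenset().union(*(inputs[i] for i in range(len(inputs)) if i not in combo)) if len(combo) < len(inputs) else frozenset()
            regions[frozenset(labels[i] for i in combo)] = len(inside - outside)
    return VennResult(labels=tuple(labels), regions=regions)


def shared_fraction(n_shared: int, n_reference: int) -> float:
    """100 * shared / reference, one decimal, half-up.

    The reference may be either a pairwise union or a site/clade total —
    printed shared-OTU percentages use both conventions, so the caller
    states the denominator explicitly.
    """
    if n_reference <= 0:
        raise ValueError("reference count must be positive")
    if n_shared < 0 or n_shared > n_reference:
        raise ValueError("shared count must lie in [0, reference]")
    return _round1(100.0 * n_shared / n_reference)


def unique_prey_fraction(range_set: PreyRangeSet) -> float:
    """Percentage of prey OTUs appearing in exactly one predator's range."""
    if len(range_set) < 2:
        raise ValueError("need at least two predators to assess uniqueness")
    counts: dict[str, int] = {}
    for s in range_set.ranges.values():
        for prey in s:
            counts[prey] = counts.get(prey, 0) + 1
    n_unique = sum(1 for c in counts.values() if c == 1)
    return _round1(100.0 * n_unique / len(counts))


def degree_abundance_correlation(
    network: InteractionNetwork,
    table: OTUTable,
    guild: str = "predator",
) -> float | None:
    """Pearson r^2 between mean relative abundance and network degree.

    Tests whether more abundant predators simply accumulate more links. The
    abundance of each guild node is its mean relative abundance over the
    series. Returns None when either variable has zero variance (r is then
    undefined).
    """
    if guild == "predator":
        nodes = sorted(network.predator_nodes)
    elif guild == "prey":
        nodes = sorted(network.prey_nodes)
    else:
        raise ValueError(f"guild must be 'predator' or 'prey', got {guild!r}")
    missing = [n for n in nodes if n not in table.counts.columns]
    if missing:
        raise ValueError(f"guild node(s) missing from table: {missing[:3]}")
    if len(nodes) < 3:
        raise ValueError("need at least 3 nodes for a correlation")
    g = network.to_graph()
    degrees = np.array([g.degree(n) for n in nodes], dtype=float)
    abund = table.counts[nodes].mean(axis=0).to_numpy(dtype=float)
    if np.all(degrees == degrees[0]) or np.all(abund == abund[0]):
        return None
    r, _ = stats.pearsonr(abund, degrees)
    return float(r * r)
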
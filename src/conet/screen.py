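"""Exhaustive negative Kendall correlation screening and network assembly.

The central inference step: every (predator OTU, prey OTU) pair of aligned
relative-abundance time series is tested with Kendall's rank correlation,
and an edge is kept only when tau is strongly negative (default tau < -0.7)
and significant (default p < 0.01). The hard tau gate is what gives the
screen its specificity — at 18 time points a tau below -0.7 is a roughly
4-sigma event for independent series — so no multiple-testing correction is
applied by default, matching common practice for this design; a
Benjamini-Hochberg option is available.

The retained edges form a strictly bipartite predator–prey network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .otu_io import (
    OTUTable,
    Taxonomy,
    filter_gram_positive,
    filter_min_reads,
    relativize,
)

__all__ = [
    "KendallResult",
    "KendallEdge",
    "InteractionNetwork",
    "kendall_tau",
    "infer_network",
    "sieve_fraction",
    "screen_site_fraction",
]

MIN_SHARED_TIMEPOINTS = 5


class KendallResult(NamedTuple):
    tau: float
    p_value: float

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.tau) or math.isnan(self.p_value))


def kendall_tau(x, y) -> KendallResult:
    """Tie-corrected Kendall tau-b with a two-sided p-value.

    For short tie-free series (n < 9) the p-value comes from exact
    enumeration of the pair statistic; otherwise from the tie-corrected
    normal approximation. A series with zero variance (all values tied)
    yields an undefined result (NaN, NaN) — such pairs can never become
    edges.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return KendallResult(float("nan"), float("nan"))
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    method = "exact" if (n < 9 and not has_ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return KendallResult(float(res.statistic), float(res.pvalue))


@dataclass(frozen=True)
class KendallEdge:
    """A retained predator–prey link with its test statistics."""

    predator_otu: str
    prey_otu: str
    tau: float
    p_value: float


@dataclass
class InteractionNetwork:
    """Bipartite predator–prey interaction network.

    ``predator_nodes`` and ``prey_nodes`` are the *screened* node sets (all
    OTUs that entered the screen, including ones that gained no edge), so
    degree statistics and the sieve fraction are well defined. ``provenance``
    records site, fraction and gate parameters.
    """

    edges: list[KendallEdge]
    predator_nodes: set[str]
    prey_nodes: set[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if e.predator_otu not in self.predator_nodes:
                raise ValueError(f"edge predator {e.predator_otu!r} not a predator node")
            if e.prey_otu not in self.prey_nodes:
                raise ValueError(f"edge prey {e.prey_otu!r} not a prey node")
            pair = (e.predator_otu, e.prey_otu)
            if pair in seen:
                raise ValueError(f"duplicate edge {pair}")
            seen.add(pair)
        if self.predator_nodes & self.prey_nodes:
            raise ValueError("predator and prey node sets overlap; network must be bipartite")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_possible_pairs(self) -> int:
        return len(self.predator_nodes) * len(self.prey_nodes)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.predator_otu, e.prey_otu) for e in self.edges}

    def to_graph(self, include_isolated: bool = True) -> nx.Graph:
        """Undirected bipartite graph with guild/tau annotations."""
        g = nx.Graph()
        if include_isolated:
            g.add_nodes_from(sorted(self.predator_nodes), bipartite=0, guild="predator")
            g.add_nodes_from(sorted(self.prey_nodes), bipartite=1, guild="prey")
        for e in self.edges:
            g.add_node(e.predator_otu, bipartite=0, guild="predator")
            g.add_node(e.prey_otu, bipartite=1, guild="prey")
            g.add_edge(e.predator_otu, e.prey_otu, tau=e.tau, p_value=e.p_value)
        return g

    def to_edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.predator_otu, e.prey_otu, e.tau, e.p_value) for e in self.edges],
            columns=["predator_otu", "prey_otu", "tau", "p_value"],
        )

    def write_edge_tsv(self, path: str | Path) -> None:
        self.to_edge_frame().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        g = self.to_graph()
        for node, deg in g.degree():
            g.nodes[node]["degree"] = deg
        nx.write_graphml(g, path)

    @classmethod
    def read_edge_tsv(
        cls,
        path: str | Path,
        predator_nodes: Iterable[str] | None = None,
        prey_nodes: Iterable[str] | None = None,
    ) -> "InteractionNetwork":
        df = pd.read_csv(path, sep="\t", dtype={"predator_otu": str, "prey_otu": str})
        edges = [
            KendallEdge(r.predator_otu, r.prey_otu, float(r.tau), float(r.p_value))
            for r in df.itertuples()
        ]
        preds = set(predator_nodes) if predator_nodes is not None else {e.predator_otu for e in edges}
        prey = set(prey_nodes) if prey_nodes is not None else {e.prey_otu for e in edges}
        return cls(edges=edges, predator_nodes=preds, prey_nodes=prey)


def infer_network(
    predators: OTUTable,
    prey: OTUTable,
    tau_max: float = -0.7,
    alpha: float = 0.01,
    bh_correct: bool = False,
    allow_raw: bool = False,
) -> InteractionNetwork:
    """Screen all predator x prey pairs; keep strong negative correlations.

    An edge (i, j) is retained iff ``tau(i, j) < tau_max`` and
    ``p(i, j) < alpha``; undefined correlations (constant series) are
    excluded. Both tables must hold relative abundances over the same
    time-ordered sample set (``allow_raw=True`` lifts the mode check).

    With ``bh_correct=True`` the significance gate is applied to
    Benjamini-Hochberg adjusted p-values over all defined pairs.
    """
    for name, t in (("predator", predators), ("prey", prey)):
        if t.mode != "relative" and not allow_raw:
            raise ValueError(f"{name} table must be in relative mode (or pass allow_raw=True)")
    if list(predators.counts.index) != list(prey.counts.index):
        if set(predators.counts.index) == set(prey.counts.index):
            prey = prey.subset_samples(predators.counts.index)
            prey = OTUTable(
                counts=prey.counts.loc[predators.counts.index],
                sample_meta=prey.sample_meta.loc[predators.counts.index],
                guild=prey.guild,
                mode=prey.mode,
                complete=prey.complete,
            )
        else:
            raise ValueError("predator and prey tables cover different sample sets")
    n = len(predators.counts.index)
    if n < MIN_SHARED_TIMEPOINTS:
        raise ValueError(
            f"only {n} shared time points; need >= {MIN_SHARED_TIMEPOINTS} for a meaningful screen"
        )

    pred_ids = list(predators.counts.columns)
    prey_ids = list(prey.counts.columns)
    pred_arr = predators.counts.to_numpy(dtype=float)
    prey_arr = prey.counts.to_numpy(dtype=float)

    results: list[tuple[str, str, float, float]] = []
    for i, pid in enumerate(pred_ids):
        xi = pred_arr[:, i]
        if np.all(xi == xi[0]):
            continue
        for j, qid in enumerate(prey_ids):
            res = kendall_tau(xi, prey_arr[:, j])
            if res.defined:
                results.append((pid, qid, res.tau, res.p_value))

    if bh_correct and results:
        pvals = np.array([r[3] for r in results])
        adj = _benjamini_hochberg(pvals)
        results = [(p, q, t, float(a)) for (p, q, t, _), a in zip(results, adj)]

    edges = [
        KendallEdge(p, q, tau, pv)
        for p, q, tau, pv in results
        if tau < tau_max and pv < alpha
    ]
    return InteractionNetwork(
        edges=edges,
        predator_nodes=set(pred_ids),
        prey_nodes=set(prey_ids),
        provenance={
            "tau_max": tau_max,
            "alpha": alpha,
            "bh_correct": bh_correct,
            "n_timepoints": n,
        },
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def sieve_fraction(
    network: InteractionNetwork,
    n_predators: int | None = None,
    n_prey: int | None = None,
) -> float:
    """Fraction of possible predator-prey pairs eliminated by the gate."""
    n_predators = len(network.predator_nodes) if n_predators is None else n_predators
    n_prey = len(network.prey_nodes) if n_prey is None else n_prey
    n_pairs = n_predators * n_prey
    if n_pairs <= 0:
        raise ValueError("need a positive number of possible pairs")
    return 1.0 - network.n_edges / n_pairs


def screen_site_fraction(
    table: OTUTable,
    taxonomy: Taxonomy,
    min_reads: int = 10,
    drop_gram_positive: bool = True,
    tau_max: float = -0.7,
    alpha: float = 0.01,
    bh_correct: bool = False,
) -> InteractionNetwork:
    """Full screening pipeline for one site-fraction raw-count series.

    Applies the abundance filter (> ``min_reads`` reads over the series) and
    the gram-positive prey filter, relativizes to sampling effort, splits
    predators from prey candidates and runs :func:`infer_network`.
    """
    if table.mode != "raw_counts":
        raise ValueError("screen_site_fraction expects raw counts")
    t = filter_min_reads(table, threshold=min_reads)
    if drop_gram_positive:
        t = filter_gram_positive(t, taxonomy)
    rel = relativize(t).time_ordered()
    predators = rel.predators()
    prey = rel.prey()
    if not predators.counts.shape[1] or not prey.counts.shape[1]:
        raise ValueError("screen requires at least one predator and one prey OTU after filtering")
    net = infer_network(predators, prey, tau_max=tau_max, alpha=alpha, bh_correct=bh_correct)
    meta = table.sample_meta.loc[table.counts.index]
    for key in ("site", "fraction"):
        vals = sorted(set(meta[key]))
        net.provenance[key] = vals[0] if len(vals) == 1 else vals
    net.provenance["min_reads"] = min_reads
    net.provenance["drop_gram_positive"] = drop_gram_positive
    return net
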
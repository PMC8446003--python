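"""Score inferred networks against simulated ground truth.

The wet-lab validation of screened interactions (FISH plus cell sorting) has
an in-silico analogue here: compare the inferred edge set against the
generator's true predation adjacency on (predator, prey) pair identity.
Precision and recall are reported as ``None`` when undefined (no inferred
edges, or no true edges) rather than coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .screen import InteractionNetwork
from .simulate import GroundTruth

__all__ = ["RecoveryReport", "edge_recovery", "threshold_sweep"]


@dataclass
class RecoveryReport:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float | None
    recall: float | None
    f1: float | None
    tau_max: float
    alpha: float

    def as_row(self) -> dict:
        return {
            "tau_max": self.tau_max,
            "alpha": self.alpha,
            "tp": self.true_positives,
            "fp": self.false_positives,
            "fn": self.false_negatives,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def _truth_pairs(truth) -> set[tuple[str, str]]:
    if isinstance(truth, GroundTruth):
        return truth.edge_pairs()
    return {(p, q) for p, q in truth}


def edge_recovery(inferred: InteractionNetwork, truth) -> RecoveryReport:
    """Edge-set comparison between an inferred network and the truth.

    ``truth`` is a :class:`~conet.simulate.GroundTruth` or an iterable of
    (predator, prey) pairs. The comparison is a plain edge-set comparison
    over the shared OTU universe: a true edge whose OTUs never entered the
    screen (e.g. filtered for low abundance) counts as a miss, so recall is
    comparable across sampling designs that screen different OTU subsets.
    """
    true_pairs = _truth_pairs(truth)
    inferred_pairs = inferred.edge_pairs()
    universe_preds = inferred.predator_nodes
    universe_prey = inferred.prey_nodes
    truth_otus = {o for pair in true_pairs for o in pair}
    if true_pairs and not (
        truth_otus & (universe_preds | universe_prey)
    ):
        raise ValueError("truth and network OTU universes are disjoint")
    scored_truth = true_pairs
    tp = len(inferred_pairs & scored_truth)
    fp = len(inferred_pairs - scored_truth)
    fn = len(scored_truth - inferred_pairs)
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    prov = inferred.provenance
    return RecoveryReport(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        tau_max=float(prov.get("tau_max", float("nan"))),
        alpha=float(prov.get("alpha", float("nan"))),
    )


def threshold_sweep(
    predators,
    prey,
    truth,
    tau_grid: Iterable[float],
    alpha_grid: Iterable[float],
) -> pd.DataFrame:
    """One recovery report per (tau_max, alpha) over a parameter grid.

    The screen is run once per gate setting on the same predator/prey
    tables; by gate monotonicity the false-positive count is non-increasing
    as tau_max decreases and as alpha decreases.
    """
    from .screen import infer_network

    tau_grid = list(tau_grid)
    alpha_grid = list(alpha_grid)
    if not tau_grid or not alpha_grid:
        raise ValueError("tau and alpha grids must be non-empty")
    rows = []
    for tau_max in tau_grid:
        for alpha in alpha_grid:
            net = infer_network(predators, prey, tau_max=tau_max, alpha=alpha)
            rows.append(edge_recovery(net, truth).as_row())
    return pd.DataFrame(rows)
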
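"""How well does the tau/p gate recover true predation links?

Runs the screen on strong-coupling simulated communities where the true
predation adjacency is known, scores the inferred edges, and sweeps the
gate thresholds to show the precision/recall trade-off.
"""

import numpy as np

from conet import (
    edge_recovery,
    relativize,
    sample_reads,
    simulate_dynamics,
    split_by_group,
    threshold_sweep,
)
from conet.otu_io import filter_gram_positive, filter_min_reads
from conet.screen import screen_site_fraction
from conet.simulate import strong_coupling_config

cfg = strong_coupling_config("desk")
precisions, recalls = [], []
for seed in range(21, 26):
    truth = simulate_dynamics(cfg, seed=seed)
    table = sample_reads(truth, seed=seed + 1000)
    floc = split_by_group(table, ["site", "fraction"])[("SH", "floc")]
    rep = edge_recovery(screen_site_fraction(floc, truth.taxonomy), truth)
    print(f"seed {seed}: TP={rep.true_positives} FP={rep.false_positives} "
          f"FN={rep.false_negatives} precision={rep.precision} recall={rep.recall:.2f}")
    if rep.precision is not None:
        precisions.append(rep.precision)
    recalls.append(rep.recall or 0.0)
print(f"\nmean precision {np.mean(precisions):.2f}, mean recall {np.mean(recalls):.2f}")

# threshold sweep on the last simulated dataset
rel = relativize(filter_gram_positive(filter_min_reads(floc), truth.taxonomy)).time_ordered()
sweep = threshold_sweep(
    rel.predators(), rel.prey(), truth,
    tau_grid=[-0.5, -0.7, -0.9], alpha_grid=[0.01],
)
print("\ngate sweep (alpha = 0.01):")
print(sweep[["tau_max", "tp", "fp", "precision", "recall"]].to_string(index=False))
print(
    "\nLoosening the tau gate recovers more true links but admits indirect\n"
    "correlations as false edges; the -0.7 default trades recall for high\n"
    "precision. Recall is bounded by read sampling: predators near the\n"
    "survey's 0.1-1% abundance band are observed with only a handful of\n"
    "reads per sample, which caps the observable rank correlation."
)
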
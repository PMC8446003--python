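"""Simulate a predator-prey community and screen it for interactions.

Generates a desk-scale activated-sludge-like community (200 prey OTUs,
10 + 10 predator OTUs, 18 sampling times over a year, 5,000 reads/sample)
with known predation links, then runs the full screening pipeline on the
floc fraction: >10-read abundance filter, gram-positive prey removal,
relativization, and the exhaustive negative Kendall screen
(tau < -0.7, p < 0.01).
"""

from conet import sample_reads, simulate_dynamics, split_by_group
from conet.screen import screen_site_fraction
from conet.simulate import strong_coupling_config

cfg = strong_coupling_config("desk")
truth = simulate_dynamics(cfg, seed=21)
table = sample_reads(truth, seed=1021)

floc = split_by_group(table, ["site", "fraction"])[("SH", "floc")]
net = screen_site_fraction(floc, truth.taxonomy)

sieved = 100 * (1 - net.n_edges / net.n_possible_pairs)
print(f"screened {len(net.predator_nodes)} predators x {len(net.prey_nodes)} prey")
print(f"retained {net.n_edges} edges; the gate sieved {sieved:.2f}% of possible pairs")
print("\nstrongest links (most negative tau):")
for e in sorted(net.edges, key=lambda e: e.tau)[:5]:
    print(f"  {e.predator_otu} -> {e.prey_otu}   tau={e.tau:+.2f}  p={e.p_value:.2g}")
print(
    "\nEach retained edge is a predator-prey OTU pair whose relative\n"
    "abundances varied in strong anti-phase over the year - the signature\n"
    "of sustained predation. The sieve percentage shows how selective the\n"
    "hard tau gate is: well over 99% of all possible pairs are discarded."
)
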
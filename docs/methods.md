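# Methods

## The screening model

The screen treats a predator–prey interaction as a hypothesis about ranks:
if predator OTU *i* preys on OTU *j*, then over a sampled year the two
relative-abundance series should be strongly anti-monotone. The statistic
is Kendall's τ_b with tie correction — wastewater series contain many zero
counts, so ties are the rule, not the exception. The two-sided p-value uses
exact enumeration for short tie-free series (n < 9) and the tie-corrected
normal approximation otherwise; with ties at n < 9 the normal approximation
is used as well, since exact enumeration is not defined under ties in the
reference implementation. A constant series yields an undefined correlation
and can never form an edge.

An edge is kept iff τ < τ_max (default −0.7) and p < α (default 0.01).
The τ gate is an *effect-size* gate and does the heavy lifting: at n = 18 a
τ below −0.7 is roughly a 4-standard-deviation event for independent
series, so the expected false-edge rate per pair is of order 10⁻⁵ and no
multiple-testing correction is applied by default (a Benjamini–Hochberg
option exists but is off). Correlations are computed on abundances
relativized to sampling effort; a guild subset of a relativized table keeps
its proportions relative to the whole sample rather than renormalizing,
which preserves the cross-sample ranks the statistic depends on.

Two pre-filters precede the screen, each applied per site-and-fraction
series: OTUs are kept only with strictly more than `min_reads` (default 10)
reads summed over the series (a per-sample variant is available), and
prey candidates whose phylum is Actinobacteria or Firmicutes are removed —
obligate predators of gram-negative bacteria cannot attack them, so any
strong negative correlation with them is necessarily indirect. OTUs with an
unresolved phylum are conservatively retained. The two filters commute.

## Network description

The retained edges form a strictly bipartite graph (validated on
construction; screened-but-isolated OTUs remain as degree-0 nodes so that
degree statistics and the sieve fraction are well defined). Community
detection is Louvain at resolution 1.0 with a fixed seed and stable
community relabeling, run directly on the bipartite graph; modularity is
Newman–Girvan Q. Dispersion of "connections per node" is reported as the
standard error of the mean (sample sd / √n). Average path length is the
mean shortest-path length over reachable pairs only, since screened networks
are usually disconnected; the global clustering coefficient is reported even
though it is identically zero on a bipartite graph — a built-in structural
sanity check. Prey-range overlap percentages are rounded half-up to one
decimal; where printed shared-OTU values mix two denominator conventions
(pairwise union vs clade total), both are computable and the caller states
which is meant.

## Community statistics

Shannon H = −Σ p ln p (natural log), Simpson in Gini–Simpson form 1 − Σ p²,
richness as the nonzero count, and Pielou evenness H / ln(richness).
Bray–Curtis is the quantitative Sørensen form; it is a semi-metric, so no
triangle-inequality assumptions are made downstream. PCoA is Torgerson
classical scaling (double-centered −½D², eigendecomposition); negative
eigenvalues — expected for Bray–Curtis — are reported but receive no axes
and are excluded from the explained-proportion denominator; no
Cailliez/Lingoes correction is applied. MRPP uses the group-size-weighted
mean within-group distance δ = Σ_g (n_g/N)·mean(d within g), the
permutation-mean expectation, A = 1 − δ_obs/mean(δ_perm), and the add-one
permutation p-value; an exact mode enumerates all distinct label
assignments for small n. The environmental-correlation aggregate
mean ± sd of |r| uses the sample standard deviation (ddof = 1).

## The community generator

`conet.simulate` produces the study design the screen targets: up to three
sites × two microhabitats (floc and particle-free liquor) sampled 12 times
monthly plus two bursts of three extra weekly samples (18 points spanning
one year), thousands of (or, at desk scale, 200) prey OTUs against tens of
predator OTUs from two clades, multinomial read sampling at a fixed depth,
and seasonal temperature metadata.

Latent dynamics are a daily-step stochastic Ricker / generalized
Lotka–Volterra system:

    x_i(t+1) = x_i exp( r_i(T)·(1 − (1−b)·x_i/k_i − b·S/K) − Σ_j a_ij·y_j + ε )
    y_j(t+1) = y_j exp( −d + c·g_j(t)·Σ_i a_ij·x_i/k_i + ε )

Key modelling choices, with reasons:

- **Prey competition** uses the standard partial-niche-overlap form
  (intraspecific stronger than interspecific, overlap b = 0.5, per-prey
  niches k_i summing to K). A pure shared carrying capacity (b = 1) admits
  no coexistence once unpredated prey fill K: predated prey crash to the
  floor and the predators starve — verified numerically, and the reason
  this form was adopted.
- **Prey niches are heavy-tailed** (lognormal weights, sd 0.8 at survey
  realism): dominant taxa holding percents of the reads are a robust
  feature of activated-sludge communities and are what makes abundant prey
  measurable through read sampling.
- **Predation pressure is a_ij·y_j — proportional to the predator's own
  abundance.** Seasonality instead enters predator growth through an
  activity wave g_j(t) = exp(A1·cos(annual) + A2·cos(sub-seasonal)), with
  per-predator amplitudes, phases and sub-seasonal period (2–6 months).
  This matters: if the kill term carried the activity factor too, prey
  would anti-track an unobservable forcing variable rather than the
  predator series the screen actually sees. Predator mortality d is
  constant (obligate predators always decline without prey). Per-predator
  rhythms (distinct periods and phases plus process noise) decorrelate the
  guild, which controls indirect-edge false positives.
- **Floors and immigration.** Abundances are floored at 10⁻⁶ of community
  biomass and topped up by a tiny immigration term (10⁻⁷ K/day): treatment
  plants are continuously reseeded by their influent, and without a
  recovery path crashed populations would be permanently lost within the
  observation year. (A much lower floor makes within-year recovery
  impossible at realistic growth rates.)
- **Observation** is multinomial sampling of the latent proportions at a
  fixed depth (5,000 reads at desk scale, 35,000 at full scale), i.e.
  compositional noise only; no copy-number or extraction biases are
  modelled.

`default_study_design("desk")` is calibrated to the survey's qualitative
anchors: predator guild at 0.1–1% of reads (median ≈ 0.6% at desk scale,
≈ 0.7% at full scale, where attack rates scale with guild size so the
larger guild keeps the same total share), predator oscillations at
weekly-to-seasonal frequencies, gram-positive prey never attacked, and
anti-phase predator–prey pairs.

`strong_coupling_config()` is the benchmark regime for edge-recovery
validation: specialist predators (one prey each, chosen preferentially
among large-niche prey and partitioned without replacement across the
guild — the Kill-the-Winner premise plus the observed partitioning of prey
ranges), slow decay (long, information-rich active seasons), low process
noise, and consequently predator peaks of a percent or more of reads.

## What recovery benchmarks do and do not show

Read sampling imposes a hard detection floor on rank correlations: for a
*perfectly* anti-phase pair observed through multinomial sampling at 5,000
reads and 18 time points, the expected observed τ only crosses −0.7 when
the predator peaks around a percent of reads *and* the prey holds several
percent. Below that, passes of the τ < −0.7 gate are variance events, and
— a general property of hard effect-size gates — they become *rarer* as the
series lengthens, because the estimate concentrates on an attenuated
population value above the gate. Power therefore increases with series
length only for pairs whose attenuated population τ lies beyond the gate,
which is why the recovery benchmark uses the strong-coupling preset: there,
mean precision is ≈ 0.92–0.95 and recall at 50 time points is at least
recall at 18 (verified over independent 20-seed batches). At
survey-realistic predator scarcity the same pipeline keeps its precision
but recall drops to a few percent and no longer grows with denser
sampling. Passing benchmarks on the simulator show the pipeline is correct
and selective; they do not show that real surveys at 0.1–1% predator
abundance recover most true interactions — the opposite: most sub-detection
interactions are invisible to any τ-gate screen at these depths.

The generator also omits, deliberately: 16S copy-number variation, PCR and
extraction bias, OTU-clustering artifacts, non-predatory interactions
(competition beyond shared capacity, phage), and time-lagged predation
responses. False-positive edges in the simulator arise exactly as they
would in nature — via predators with correlated seasonal waves preying on
each other's prey — so precision estimates are conservative in that respect.

## Numerical and procedural details

- All randomness flows through `numpy.random.default_rng` seeded
  explicitly; simulations are bit-reproducible given (config, seed).
- The daily map clips log-growth increments to ±20 and raises on divergence
  past an overflow guard.
- Louvain uses a fixed seed (module constant) and deterministic community
  relabeling by smallest member.
- Tie comparisons in MRPP use a 10⁻¹² tolerance when counting
  δ_perm ≤ δ_obs.
- The n = 50 power comparison re-simulates the same process observed at 50
  evenly spaced points over the identical year; a monthly multi-year
  calendar gives indistinguishable results.
- Edge recovery compares (predator, prey) pair identity against the full
  true adjacency — a true edge whose OTUs were filtered out counts as a
  miss — so recall is comparable across sampling designs that screen
  different OTU subsets.
- Problem sizes in tests and the acceptance script (desk scale: 200 prey,
  20 predators, 18 or 50 time points, depth 5,000, 20 seeds) are the
  package's benchmark conditions; full scale (3,600 prey, 175 predators,
  depth 35,000, 3 sites) is exercised for the predator-abundance anchor.
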
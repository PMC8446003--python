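"""Generative model of obligate predator-prey community time series.

The simulator emulates the study design the screening pipeline targets:
activated-sludge communities sampled at three treatment plants in two
microhabitats (floc and liquor) over one year — 12 monthly samples plus two
bursts of consecutive weekly samples, 18 time points in all — in which two
clades of obligate gram-negative predators (Bdellovibrionales and
Bacteriovoracales) together make up roughly 0.1-1% of reads and oscillate at
weekly-to-seasonal frequencies against a background of thousands of prey
OTUs.

Latent dynamics follow a discrete-time (Ricker-type) stochastic generalized
Lotka-Volterra model on a daily grid::

    prey_i(t+1) = prey_i(t) * exp( r_i(T_t) * (1 - (1-b)*x_i/k_i - b*S_t/K)
                                   - sum_j a_ij y_j(t) + eps )
    pred_j(t+1) = pred_j(t) * exp( -d_j + c * g_j(T_t) * sum_i a_ij x_i(t)/k_i + eps )

with S the total prey biomass, K the community carrying capacity, k_i each
prey's own niche share (K divided by the number of prey in the
compartment), and b in [0, 1) the niche overlap between prey: intraspecific
competition is stronger than interspecific, the standard coexistence
condition, without which predated prey could never regrow once their
unpredated neighbours fill K. Attack rates a_ij >= 0 are zero on every
gram-positive prey column (obligate predators of gram-negative cells);
``c`` converts consumed prey biomass into predator growth, and the noise
eps is Gaussian in the log domain.

Temporal forcing enters two ways. The prey growth rate r_i(T) carries a
weak seasonal (1-year) modulation. Each predator has an activity wave
g_j(t) — the product of an annual and a sub-seasonal (roughly 2-6 month)
log-sinusoid with per-predator amplitudes, phases and period — that scales
its hunting success and hence its growth. Predators therefore wax and wane
at weekly-to-seasonal frequencies, each with its own rhythm, while
mortality d_j stays constant (obligate predators always decay without
prey). Crucially the kill term seen by prey is a_ij * y_j: prey abundance
anti-tracks the predator's own population, which is what the Kendall screen
observes. Abundances are floored at a small extinction threshold and topped
up by a tiny immigration term (treatment plants are continuously reseeded
by their influent), so crashed populations recover.

Observed tables are produced by multinomial read sampling at a fixed depth
per sample, i.e. compositional noise on top of the latent proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

from .otu_io import OTUTable, Taxonomy

__all__ = [
    "SimulationConfig",
    "strong_coupling_config",
    "GroundTruth",
    "seasonal_temperature",
    "simulate_dynamics",
    "sample_reads",
    "default_study_design",
    "default_observation_days",
]

_GRAM_NEGATIVE_PHYLA = (
    "Proteobacteria",
    "Bacteroidetes",
    "Verrucomicrobia",
    "Planctomycetes",
    "Acidobacteria",
    "Chloroflexi",
)
_GRAM_POSITIVE_PHYLA = ("Firmicutes", "Actinobacteria")

#: Simulated year starts on this date (day 0 of the internal grid).
SIM_START = date(2013, 3, 1)


def default_observation_days(n_points: int | None = None) -> tuple[int, ...]:
    """Observation calendar in days since the simulation start.

    Default: 12 monthly samples (the 15th of each month for a year) plus
    three extra weekly samples in each of two months (late summer and late
    winter) — 18 points. ``n_points`` instead returns an evenly spaced
    calendar over the year (used for power comparisons at denser sampling).
    """
    if n_points is not None:
        return tuple(int(round(x)) for x in np.linspace(0, 364, n_points))
    start = pd.Timestamp(SIM_START)
    monthly = [
        (pd.Timestamp(year=y, month=m, day=15) - start).days
        for y, m in [(2013, m) for m in range(3, 13)] + [(2014, 1), (2014, 2)]
    ]
    weekly = [
        (pd.Timestamp(year=y, month=m, day=d) - start).days
        for (y, m) in ((2013, 8), (2014, 2))
        for d in (1, 8, 22)
    ]
    return tuple(sorted(set(monthly + weekly)))


@dataclass
class SimulationConfig:
    """Parameters of the predator-prey community generator.

    Rates are per day; biomass is in units of the shared prey carrying
    capacity ``carrying_capacity``.
    """

    n_prey: int = 200
    n_predators_bd: int = 10
    n_predators_bx: int = 10
    #: Fraction of prey OTUs labelled gram-positive; never preyed upon.
    fraction_gram_positive: float = 0.25
    #: Mean number of prey per predator (links drawn over gram-negative prey).
    links_per_predator: float = 3.0
    #: Exponent gamma of preferential prey choice: p(link to prey i) is
    #: proportional to k_i**gamma. 0 = uniform; 1 = proportional to niche
    #: size, the Kill-the-Winner premise that predation targets winners.
    prey_preference_exponent: float = 0.0
    #: Partition prey among predators (links drawn without replacement
    #: across the guild): predators hunt largely distinct prey, as observed
    #: for BALO prey ranges.
    exclusive_prey: bool = False
    #: Per-capita attack rate range; one BALO cell kills many prey cells, so
    #: attack rates are large relative to the predators' own biomass share.
    attack_rate_range: tuple[float, float] = (300.0, 1200.0)
    #: Prey regrow within days — fast relative to the predators' waves, so
    #: prey track predation pressure quasi-statically (near anti-phase).
    prey_growth_rate: float = 1.2
    carrying_capacity: float = 1.0
    #: Lognormal sd of prey niche weights: prey communities are heavy-
    #: tailed, with dominant OTUs holding a few percent of the reads each.
    prey_niche_sigma: float = 0.8
    #: Niche overlap b between prey (0 = independent logistic niches,
    #: 1 = pure shared carrying capacity, which admits no coexistence with
    #: predation).
    niche_overlap: float = 0.5
    #: Predator mortality (obligate: negative growth without prey).
    predator_decay: float = 0.15
    #: Biomass conversion of consumed prey into predator growth.
    conversion_efficiency: float = 1.3e-4
    #: Annual (1-year period) log-scale amplitude range of each predator's
    #: activity wave g_j(t): attack rates and intake are multiplied by
    #: exp(a1_j cos(annual) + a2_j cos(sub-seasonal)); phases are random per
    #: predator.
    predator_seasonal_amplitude: tuple[float, float] = (0.5, 0.9)
    #: Sub-seasonal activity amplitude range (second forcing component).
    predator_subseasonal_amplitude: tuple[float, float] = (0.8, 1.4)
    #: Period range of the sub-seasonal activity component (drawn per
    #: predator, days): distinct rhythms decorrelate the predator guild.
    subseasonal_period_days: tuple[float, float] = (60.0, 180.0)
    #: Seasonal modulation range of prey growth (kept small: whole-community
    #: composition is far more stable than the predator guilds).
    prey_seasonal_amplitude: tuple[float, float] = (0.0, 0.05)
    temperature_mean: float = 20.0
    temperature_amplitude: float = 5.0
    #: Day of year (from the simulation start) at which temperature peaks.
    temperature_peak_day: float = 165.0
    process_noise_sd: float = 0.05
    #: Predator process noise is kept smaller: predator populations move on
    #: slow activity waves that their fast-regrowing prey can track.
    predator_noise_sd: float = 0.04
    extinction_floor: float = 1e-6
    #: Constant immigration (fraction of K per day) for every OTU: treatment
    #: plants are continuously reseeded by the influent, so populations
    #: crash below detection but never go extinct for good.
    immigration: float = 1e-7
    overflow_guard: float = 1e6
    n_sites: int = 1
    site_names: tuple[str, ...] = ("SH", "AB", "LB")
    #: Fraction of prey OTUs present in both floc and liquor compartments.
    shared_prey_fraction: float = 0.15
    observation_days: tuple[int, ...] = field(default_factory=default_observation_days)
    step_days: float = 1.0
    burn_in_days: int = 120
    read_depth: int = 5000
    seed: int | None = None

    def n_predators(self) -> int:
        return self.n_predators_bd + self.n_predators_bx

    def with_observation_points(self, n_points: int) -> "SimulationConfig":
        return replace(self, observation_days=default_observation_days(n_points))


def strong_coupling_config(scale: str = "desk") -> SimulationConfig:
    """A deliberately strong-signal variant of a study-design preset.

    Low attack rates with high conversion put predators at the top of their
    abundance range (peaks of a percent or more of reads), where the tau
    gate operates above its read-sampling detection floor. This is the
    regime for benchmarking edge recovery; at survey-realistic predator
    scarcity the hard tau < -0.7 gate loses power (see docs/methods.md).
    """
    cfg = default_study_design(scale)
    return replace(
        cfg,
        # specialist predators on large-niche prey, partitioned across the
        # guild; slow decay gives long active seasons and information-rich
        # abundance series
        attack_rate_range=(25.0, 35.0),
        conversion_efficiency=2.3e-3,
        predator_decay=0.07,
        links_per_predator=1.0,
        prey_preference_exponent=3.0,
        exclusive_prey=True,
        prey_niche_sigma=1.1,
        prey_growth_rate=1.6,
        process_noise_sd=0.01,
        predator_noise_sd=0.01,
        predator_seasonal_amplitude=(0.7, 0.9),
        predator_subseasonal_amplitude=(1.0, 1.3),
        subseasonal_period_days=(70.0, 200.0),
    )


def default_study_design(scale: str = "desk") -> SimulationConfig:
    """Preset configurations mirroring the study design.

    ``"desk"``: 200 prey vs 10 + 10 predators at depth 5,000 over one site —
    small enough for interactive work and test suites. ``"full"``: one year
    at three sites with ~3,600 prey vs ~105 + 70 predators at depth 35,000,
    the dimensions of the real survey.
    """
    if scale == "desk":
        return SimulationConfig()
    if scale == "full":
        # per-predator equilibrium abundance scales as 1/attack-rate, so the
        # larger predator guild keeps the same total read share as at desk
        # scale when attack rates grow (and conversion shrinks) with guild
        # size
        guild_factor = (105 + 70) / 20.0
        return SimulationConfig(
            n_prey=3600,
            n_predators_bd=105,
            n_predators_bx=70,
            n_sites=3,
            read_depth=35000,
            attack_rate_range=(300.0 * guild_factor, 1200.0 * guild_factor),
            conversion_efficiency=1.3e-4 / guild_factor,
        )
    raise ValueError(f"unknown scale {scale!r}; use 'desk' or 'full'")


def seasonal_temperature(
    times,
    mean: float = 20.0,
    amplitude: float = 5.0,
    peak_day: float = 165.0,
) -> np.ndarray:
    """Sinusoidal temperature with a one-year period evaluated at ``times``
    (days). ``max - min`` equals ``2 * amplitude``; the maximum falls on
    ``peak_day`` (mod 365)."""
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    t = np.asarray(times, dtype=float)
    return mean + amplitude * np.cos(2 * np.pi * (t - peak_day) / 365.0)


@dataclass
class GroundTruth:
    """Latent trajectories plus the true predation adjacency.

    ``adjacency`` maps predator OTU -> {prey OTU: attack rate}; ``latent``
    maps (site, fraction) -> DataFrame of latent abundances (observation
    dates x all OTU ids; prey absent from a compartment are zero).
    """

    config: SimulationConfig
    seed: int
    adjacency: dict[str, dict[str, float]]
    latent: dict[tuple[str, str], pd.DataFrame]
    temperature: dict[str, pd.Series]
    taxonomy: Taxonomy
    guild: pd.Series
    gram_positive_otus: frozenset[str]

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(p, q) for p, prey in self.adjacency.items() for q in prey}

    def write_adjacency_tsv(self, path) -> None:
        rows = [
            (p, q, a)
            for p, prey in sorted(self.adjacency.items())
            for q, a in sorted(prey.items())
        ]
        pd.DataFrame(rows, columns=["predator_otu", "prey_otu", "attack_rate"]).to_csv(
            path, sep="\t", index=False
        )


def _make_otu_ids(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    prey = [f"Prey{i + 1:04d}" for i in range(config.n_prey)]
    bd = [f"Bd{i + 1:03d}" for i in range(config.n_predators_bd)]
    bx = [f"Bx{i + 1:03d}" for i in range(config.n_predators_bx)]
    return prey, bd, bx


def _make_taxonomy(
    prey_ids: list[str],
    bd_ids: list[str],
    bx_ids: list[str],
    gram_positive: set[str],
    rng: np.random.Generator,
) -> Taxonomy:
    strings: dict[str, str] = {}
    for otu in prey_ids:
        if otu in gram_positive:
            phylum = _GRAM_POSITIVE_PHYLA[int(rng.integers(len(_GRAM_POSITIVE_PHYLA)))]
        else:
            phylum = _GRAM_NEGATIVE_PHYLA[int(rng.integers(len(_GRAM_NEGATIVE_PHYLA)))]
        strings[otu] = f"Bacteria;{phylum};unclassified;unclassified;unclassified;{otu}"
    for otu in bd_ids:
        strings[otu] = (
            f"Bacteria;Proteobacteria;Deltaproteobacteria;Bdellovibrionales;Bdellovibrionaceae;{otu}"
        )
    for otu in bx_ids:
        strings[otu] = (
            f"Bacteria;Proteobacteria;Deltaproteobacteria;Bacteriovoracales;Bacteriovoracaceae;{otu}"
        )
    return Taxonomy.from_strings(strings)


def simulate_dynamics(config: SimulationConfig, seed: int | None = None) -> GroundTruth:
    """Run the stochastic gLV model and return latent truth.

    Deterministic for a given (config, seed). The predation adjacency is
    shared across sites and compartments; each site runs independent
    dynamics (own noise and initial conditions). Raises if any abundance
    exceeds the overflow guard.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (pass seed= or set config.seed)")
    rng = np.random.default_rng(seed)
    cfg = config

    prey_ids, bd_ids, bx_ids = _make_otu_ids(cfg)
    pred_ids = bd_ids + bx_ids
    n_prey, n_pred = cfg.n_prey, len(pred_ids)

    # gram-positive prey: never attacked
    n_gp = int(round(cfg.fraction_gram_positive * n_prey))
    gp_idx = rng.choice(n_prey, size=n_gp, replace=False)
    gram_positive = {prey_ids[i] for i in gp_idx}
    gn_idx = np.setdiff1d(np.arange(n_prey), gp_idx)

    # predation matrix: each predator gets >= 1 gram-negative prey,
    # optionally biased toward large-niche prey (Kill-the-Winner)
    A = np.zeros((n_pred, n_prey))
    a_lo, a_hi = cfg.attack_rate_range
    niche_w_global = np.exp(rng.normal(0.0, cfg.prey_niche_sigma, size=n_prey))
    link_w = niche_w_global[gn_idx] ** cfg.prey_preference_exponent
    available = np.ones(len(gn_idx), dtype=bool)
    for j in rng.permutation(n_pred):
        k = max(1, rng.poisson(cfg.links_per_predator))
        pool = available if cfg.exclusive_prey else np.ones(len(gn_idx), dtype=bool)
        if not pool.any():
            pool = np.ones(len(gn_idx), dtype=bool)
        k = min(k, int(pool.sum()))
        w = np.where(pool, link_w, 0.0)
        targets = rng.choice(gn_idx, size=k, replace=False, p=w / w.sum())
        available[np.searchsorted(gn_idx, targets)] = False
        if a_hi > 0:
            # log-uniform: a heavy-ish tail of attack rates spreads predator
            # abundances over more than an order of magnitude
            A[j, targets] = np.exp(rng.uniform(np.log(a_lo), np.log(a_hi), size=k))

    # per-OTU forcing: annual + sub-seasonal activity waves, random phases
    s_lo, s_hi = cfg.predator_seasonal_amplitude
    act1_amp = rng.uniform(s_lo, s_hi, size=n_pred)
    act1_phase = rng.uniform(0, 365, size=n_pred)
    s2_lo, s2_hi = cfg.predator_subseasonal_amplitude
    act2_amp = rng.uniform(s2_lo, s2_hi, size=n_pred)
    p2_lo, p2_hi = cfg.subseasonal_period_days
    act2_period = rng.uniform(p2_lo, p2_hi, size=n_pred)
    act2_phase = rng.uniform(0, p2_hi, size=n_pred)
    p_lo, p_hi = cfg.prey_seasonal_amplitude
    prey_amp = rng.uniform(p_lo, p_hi, size=n_prey)
    prey_phase = rng.uniform(0, 365, size=n_prey)

    # compartment membership: shared prey + even split of the rest
    n_shared = int(round(cfg.shared_prey_fraction * n_prey))
    perm = rng.permutation(n_prey)
    shared = perm[:n_shared]
    rest = perm[n_shared:]
    half = len(rest) // 2
    floc_members = np.sort(np.concatenate([shared, rest[:half]]))
    liquor_members = np.sort(np.concatenate([shared, rest[half:]]))
    membership = {"floc": floc_members, "liquor": liquor_members}

    obs_days = np.asarray(cfg.observation_days, dtype=int)
    n_steps = int(cfg.burn_in_days + obs_days.max() + 1)
    all_days = np.arange(n_steps) - cfg.burn_in_days

    adjacency = {
        pred_ids[j]: {
            prey_ids[i]: float(A[j, i]) for i in np.flatnonzero(A[j]) }
        for j in range(n_pred)
        if A[j].any()
    }

    latent: dict[tuple[str, str], pd.DataFrame] = {}
    temperature: dict[str, pd.Series] = {}
    obs_dates = pd.to_datetime([pd.Timestamp(SIM_START) + pd.Timedelta(days=int(d)) for d in obs_days])

    sites = cfg.site_names[: cfg.n_sites]
    for site in sites:
        temperature[site] = pd.Series(
            seasonal_temperature(
                obs_days, cfg.temperature_mean, cfg.temperature_amplitude, cfg.temperature_peak_day
            ),
            index=obs_dates,
        )

        # state: prey per compartment, one shared predator pool; niches are
        # heavy-tailed (lognormal weights renormalized to K per compartment)
        present = {comp: np.isin(np.arange(n_prey), members) for comp, members in membership.items()}
        niche_w = niche_w_global
        niche = {}
        for comp, mask in present.items():
            w = np.where(mask, niche_w, 0.0)
            k = cfg.carrying_capacity * w / w.sum()
            niche[comp] = np.where(mask, k, np.inf)
        x = {comp: np.where(mask, niche[comp], 0.0) for comp, mask in present.items()}
        y = np.full(n_pred, 1e-4 * cfg.carrying_capacity)

        floor = cfg.extinction_floor * cfg.carrying_capacity
        snapshots: dict[str, list[np.ndarray]] = {comp: [] for comp in membership}
        snap_pred: list[np.ndarray] = []
        obs_set = set(int(d) for d in obs_days)

        for step in range(n_steps):
            day = all_days[step]
            if int(day) in obs_set:
                for comp in membership:
                    snapshots[comp].append(x[comp].copy())
                snap_pred.append(y.copy())
            # seasonal rates at this step
            activity = np.exp(
                act1_amp * np.cos(2 * np.pi * (day - act1_phase) / 365.0)
                + act2_amp * np.cos(2 * np.pi * (day - act2_phase) / act2_period)
            )
            season_prey = np.cos(2 * np.pi * (day - prey_phase) / 365.0)
            r_eff = cfg.prey_growth_rate * (1.0 + prey_amp * season_prey)

            b = cfg.niche_overlap
            pressure = A.T @ y  # per-prey kill rate tracks predator abundance
            intake = np.zeros(n_pred)
            new_x = {}
            for comp in membership:
                xc = x[comp]
                crowding = (1.0 - b) * xc / niche[comp] + b * xc.sum() / cfg.carrying_capacity
                growth = r_eff * (1.0 - crowding) - pressure
                eps = rng.normal(0.0, cfg.process_noise_sd, size=n_prey)
                nx = xc * np.exp(np.clip((growth + eps) * cfg.step_days, -20, 20))
                nx = nx + cfg.immigration * cfg.carrying_capacity * cfg.step_days
                nx = np.where(present[comp], np.maximum(nx, floor), 0.0)
                new_x[comp] = nx
                # prey availability relative to its niche: predator yield per
                # attack is then independent of how finely K is subdivided
                intake += activity * (A @ np.where(np.isfinite(niche[comp]), xc / niche[comp], 0.0))
            eps_y = rng.normal(0.0, cfg.predator_noise_sd, size=n_pred)
            gy = -cfg.predator_decay + cfg.conversion_efficiency * intake
            y = y * np.exp(np.clip((gy + eps_y) * cfg.step_days, -20, 20))
            y = np.maximum(y + cfg.immigration * cfg.carrying_capacity * cfg.step_days, floor)
            x = new_x
            peak = max(max(v.max() for v in x.values()), y.max())
            if peak > cfg.overflow_guard * cfg.carrying_capacity:
                raise FloatingPointError(
                    f"dynamics diverged (abundance {peak:.3g}) at day {day}; "
                    f"check growth/attack parameters"
                )

        all_ids = prey_ids + pred_ids
        for comp in membership:
            prey_traj = np.array(snapshots[comp])
            pred_traj = np.array(snap_pred)
            # predator pool is shared; floor-level prey outside the
            # compartment stay exactly zero
            mat = np.hstack([prey_traj, pred_traj])
            latent[(site, comp)] = pd.DataFrame(mat, index=obs_dates, columns=all_ids)

    guild = pd.Series(
        {**{o: "prey_candidate" for o in prey_ids},
         **{o: "predator_bd" for o in bd_ids},
         **{o: "predator_bx" for o in bx_ids}},
        name="guild",
    )
    taxonomy = _make_taxonomy(prey_ids, bd_ids, bx_ids, gram_positive, rng)
    return GroundTruth(
        config=cfg,
        seed=int(seed),
        adjacency=adjacency,
        latent=latent,
        temperature=temperature,
        taxonomy=taxonomy,
        guild=guild,
        gram_positive_otus=frozenset(gram_positive),
    )


def sample_reads(
    truth: GroundTruth,
    depth: int | None = None,
    seed: int | None = None,
) -> OTUTable:
    """Multinomial read sampling of the latent trajectories.

    Each sample draws ``depth`` reads with probabilities proportional to the
    latent abundances of the OTUs present in that site-fraction compartment
    (predators are present everywhere). Returns a raw-count OTUTable with
    site/fraction/date/temperature metadata; deterministic for a given seed.
    """
    cfg = truth.config
    depth = cfg.read_depth if depth is None else int(depth)
    if depth <= 0:
        raise ValueError("read depth must be positive")
    rng = np.random.default_rng(truth.seed + 1_000_003 if seed is None else seed)

    rows = []
    meta_rows = []
    sample_ids = []
    all_ids = None
    for (site, fraction), traj in truth.latent.items():
        all_ids = list(traj.columns)
        temps = truth.temperature[site]
        for t_idx, (ts, latent_row) in enumerate(traj.iterrows()):
            probs = latent_row.to_numpy(dtype=float).copy()
            # floor-level biomass is below any realistic detection limit
            probs[probs <= cfg.extinction_floor * cfg.carrying_capacity] = 0.0
            total = probs.sum()
            if total <= 0:
                raise ValueError(f"all-zero latent sample at {site}/{fraction}/{ts.date()}")
            reads = rng.multinomial(depth, probs / total)
            rows.append(reads)
            sample_ids.append(f"{site}-{fraction}-t{t_idx + 1:02d}")
            meta_rows.append(
                {
                    "site": site,
                    "fraction": fraction,
                    "date": ts,
                    "temperature": float(temps.loc[ts]),
                }
            )
    counts = pd.DataFrame(rows, index=sample_ids, columns=all_ids, dtype=float)
    meta = pd.DataFrame(meta_rows, index=sample_ids)
    return OTUTable(counts=counts, sample_meta=meta, guild=truth.guild, mode="raw_counts")
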
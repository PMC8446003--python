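"""Community-level statistics: alpha diversity, Bray-Curtis, PCoA, MRPP,
rank-abundance KS tests, environmental correlations.

These are the supporting analyses around the network inference: describing
predator community diversity, testing whether communities differ between
sites or fractions (MRPP on Bray-Curtis distances), ordinating samples
(classical-scaling PCoA), comparing rank-abundance patterns between clades
(two-sample Kolmogorov-Smirnov) and linking OTU dynamics to temperature
(Pearson r, aggregated as mean +/- sd of |r|).

MRPP (multi-response permutation procedure) is implemented here directly:
the observed statistic is the group-size-weighted mean within-group
distance, delta = sum_g (n_g/N) * mean within-group distance, its
chance-corrected effect size A = 1 - delta_obs / mean(delta_perm), and the
p-value is the permutation fraction with delta <= delta_obs (add-one
convention). A = 1 means all within-group distances are zero; A = 0 means
no more within-group agreement than expected by chance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MrppResult",
    "PcoaResult",
    "EnvCorrelationResult",
    "alpha_diversity",
    "bray_curtis",
    "bray_curtis_matrix",
    "pcoa",
    "mrpp",
    "ks_rank_abundance",
    "env_correlation",
]


def alpha_diversity(counts) -> tuple[float, float, int, float]:
    """(Shannon H, Gini-Simpson, richness, Pielou evenness) of one sample.

    H = -sum p ln p (natural log); Simpson is reported in Gini-Simpson form
    1 - sum p^2; richness is the number of OTUs with nonzero abundance;
    evenness is Pielou's H / ln(richness), reported as 0.0 for a single-OTU
    sample where the ratio is 0/0.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if (x < 0).any():
        raise ValueError("negative abundances")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = x[x > 0] / total
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p * p).sum())
    richness = int((x > 0).sum())
    evenness = float(shannon / math.log(richness)) if richness > 1 else 0.0
    return shannon, simpson, richness, evenness


def bray_curtis(x, y) -> float:
    """Bray-Curtis (Sorensen quantitative) dissimilarity in [0, 1].

    1 - 2*sum min(x_i, y_i) / (sum x + sum y). Semi-metric: symmetric and
    bounded but without the triangle inequality.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative abundances")
    denom = x.sum() + y.sum()
    if denom <= 0:
        raise ValueError("both vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def bray_curtis_matrix(table) -> pd.DataFrame:
    """Square Bray-Curtis distance matrix over the rows of a samples x OTUs
    DataFrame (or an OTUTable's counts)."""
    counts = table.counts if hasattr(table, "counts") else table
    arr = np.asarray(counts, dtype=float)
    index = counts.index if isinstance(counts, pd.DataFrame) else pd.RangeIndex(len(arr))
    n = len(arr)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(arr[i], arr[j])
    return pd.DataFrame(d, index=index, columns=index)


@dataclass
class PcoaResult:
    """Classical-scaling ordination of a distance matrix.

    ``coordinates`` spans the positive-eigenvalue axes only; negative
    eigenvalues (possible for semi-metric inputs like Bray-Curtis) are
    reported in ``eigenvalues`` but excluded from ``proportion_explained``
    and carry no coordinates. No Cailliez/Lingoes correction is applied.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def __post_init__(self) -> None:
        pe = self.proportion_explained
        if len(pe) and (pe.min() < -1e-12 or pe.max() > 1 + 1e-12):
            raise ValueError("proportion_explained must lie in [0, 1]")
        if np.any(np.diff(pe) > 1e-12):
            raise ValueError("proportion_explained must be non-increasing")


def pcoa(distances, k: int | None = None) -> PcoaResult:
    """Principal coordinates analysis (Torgerson classical scaling).

    Double-centers -1/2 D^2, eigendecomposes, and returns coordinates on up
    to ``k`` positive-eigenvalue axes. The input must be symmetric with a
    zero diagonal.
    """
    if isinstance(distances, pd.DataFrame):
        labels = list(distances.index)
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        labels = list(range(len(d)))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigvals[0]), 1.0))
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    if k is not None:
        coords = coords[:, :k]
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=labels, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop[: coords.shape[1]],
    )


@dataclass
class MrppResult:
    a_statistic: float
    observed_delta: float
    expected_delta: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        if self.a_statistic > 1 + 1e-12:
            raise ValueError("A-statistic cannot exceed 1")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")


def _mrpp_delta(d: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    delta = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            raise ValueError("every group needs at least 2 members")
        sub = d[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        delta += (len(idx) / n) * sub[iu].mean()
    return delta


def mrpp(
    distances,
    groups,
    n_permutations: int | str = 999,
    seed: int | None = None,
) -> MrppResult:
    """Multi-response permutation procedure on a distance matrix.

    ``groups`` assigns each sample a label; at least two groups of two. With
    ``n_permutations="exact"`` all distinct label assignments are enumerated
    (feasible only for small n) and the p-value is the exact fraction of
    assignments with delta <= delta_obs; otherwise Monte-Carlo label
    shuffling with the add-one convention p = (1 + #{<=}) / (1 + n_perm).
    """
    if isinstance(distances, pd.DataFrame):
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
    labels = np.asarray(list(groups))
    if d.shape[0] != d.shape[1] or d.shape[0] != len(labels):
        raise ValueError("distance matrix and group labels are inconsistent")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        small = uniq[counts.argmin()]
        raise ValueError(f"group {small!r} has fewer than 2 members")

    delta_obs = _mrpp_delta(d, labels)

    if n_permutations == "exact":
        perm_deltas = [
            _mrpp_delta(d, np.array(perm)) for perm in _distinct_label_orders(labels)
        ]
        perm_deltas = np.array(perm_deltas)
        n_perm = len(perm_deltas)
        p = float(np.sum(perm_deltas <= delta_obs + 1e-12) / n_perm)
        expected = float(perm_deltas.mean())
    else:
        rng = np.random.default_rng(seed)
        n_perm = int(n_permutations)
        perm_deltas = np.empty(n_perm)
        work = labels.copy()
        for i in range(n_perm):
            rng.shuffle(work)
            perm_deltas[i] = _mrpp_delta(d, work)
        p = float((1 + np.sum(perm_deltas <= delta_obs + 1e-12)) / (1 + n_perm))
        expected = float(perm_deltas.mean())

    a = 1.0 - delta_obs / expected if expected > 0 else 0.0
    return MrppResult(
        a_statistic=float(a),
        observed_delta=float(delta_obs),
        expected_delta=expected,
        p_value=p,
        n_permutations=n_perm,
    )


def _distinct_label_orders(labels: np.ndarray):
    """All distinct orderings of a label multiset (exact MRPP null)."""
    seen = set()
    for perm in itertools.permutations(labels):
        if perm not in seen:
            seen.add(perm)
            yield perm


def ks_rank_abundance(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test between two abundance samples.

    D = sup |ECDF1 - ECDF2| over the pooled values; the p-value is exact for
    small samples and asymptotic otherwise (scipy's auto policy). Any
    upstream abundance filter (e.g. keep OTUs above 0.1%) is the caller's
    responsibility.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty abundance vector")
    res = stats.ks_2samp(x, y, method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass
class EnvCorrelationResult:
    per_otu_r: dict[str, float]
    mean_abs_r: float
    sd_abs_r: float
    skipped: list[str]


def env_correlation(series_set, env, subset=None) -> EnvCorrelationResult:
    """Pearson r of each OTU series against an environmental series.

    ``series_set`` is a samples x OTUs DataFrame aligned with ``env``
    (e.g. temperature). Constant OTU series are skipped and listed in the
    result. The aggregate is mean +/- sd (sample sd, n-1) of |r| over
    ``subset`` (default: all non-skipped OTUs); which OTUs enter the
    aggregate — e.g. the most abundant predators per site — is the caller's
    modelling choice.
    """
    if hasattr(series_set, "counts"):
        series_set = series_set.counts
    env = np.asarray(env, dtype=float)
    if len(env) != len(series_set):
        raise ValueError("environmental series not aligned with samples")
    if len(env) < 3:
        raise ValueError("need at least 3 time points")
    if np.all(env == env[0]):
        raise ValueError("environmental series has zero variance")
    cols = list(series_set.columns) if subset is None else list(subset)
    per_otu: dict[str, float] = {}
    skipped: list[str] = []
    for otu in cols:
        vals = series_set[otu].to_numpy(dtype=float)
        if np.all(vals == vals[0]):
            skipped.append(otu)
            continue
        r, _ = stats.pearsonr(vals, env)
        per_otu[otu] = float(r)
    if not per_otu:
        raise ValueError("no OTU with variance; nothing to correlate")
    abs_r = np.abs(list(per_otu.values()))
    sd = float(abs_r.std(ddof=1)) if len(abs_r) > 1 else 0.0
    return EnvCorrelationResult(
        per_otu_r=per_otu,
        mean_abs_r=float(abs_r.mean()),
        sd_abs_r=sd,
        skipped=skipped,
    )
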
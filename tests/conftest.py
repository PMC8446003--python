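"""Shared fixtures and independent oracles for the test suite.

The Kendall oracle here enumerates concordant/discordant pairs directly and
computes the tie-corrected normal approximation itself — it never calls the
library's (scipy-backed) implementation, so screen-vs-oracle comparisons are
a genuine dual route.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from conet import OTUTable, Taxonomy


# ---------------------------------------------------------------- oracles


def oracle_kendall_tau(x, y) -> tuple[float, float]:
    """Brute-force tau-b and two-sided tie-corrected normal p-value.

    Enumerates all n(n-1)/2 index pairs: C concordant, D discordant, with
    the standard tie corrections. Returns (nan, nan) for a constant series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    C = D = 0
    tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                C += 1
            else:
                D += 1
    n0 = n * (n - 1) // 2
    # tie counts per distinct value
    def tie_terms(v):
        _, counts = np.unique(v, return_counts=True)
        t1 = sum(c * (c - 1) // 2 for c in counts)
        t2 = sum(c * (c - 1) * (c - 2) for c in counts)
        t3 = sum(c * (c - 1) * (2 * c + 5) for c in counts)
        return t1, t2, t3

    t1x, t2x, t3x = tie_terms(x)
    t1y, t2y, t3y = tie_terms(y)
    denom = math.sqrt((n0 - t1x) * (n0 - t1y))
    tau = (C - D) / denom
    # tie-corrected variance of S = C - D (Kendall's test)
    v0 = n * (n - 1) * (2 * n + 5)
    var_s = (
        (v0 - t3x - t3y) / 18.0
        + t2x * t2y / (9.0 * n * (n - 1) * (n - 2))
        + (2.0 * t1x * t1y) / (n * (n - 1))
    )
    if var_s <= 0:
        return tau, float("nan")
    z = (C - D) / math.sqrt(var_s)
    p = 2.0 * (1.0 - 0.5 * (1.0 + math.erf(abs(z) / math.sqrt(2.0))))
    return tau, min(p, 1.0)


def oracle_screen(pred_df: pd.DataFrame, prey_df: pd.DataFrame, tau_max=-0.7, alpha=0.01):
    """Naive all-pairs double loop returning the retained edge set."""
    edges = set()
    for p in pred_df.columns:
        for q in prey_df.columns:
            tau, pval = oracle_kendall_tau(pred_df[p].to_numpy(), prey_df[q].to_numpy())
            if not math.isnan(tau) and tau < tau_max and pval < alpha:
                edges.add((p, q))
    return edges


# ---------------------------------------------------------------- builders


def make_table(counts: dict[str, list[float]], *, sites=None, fractions=None,
               dates=None, temps=None, guilds=None, mode="raw_counts") -> OTUTable:
    """Small OTUTable from a dict {otu_id: column of counts}."""
    df = pd.DataFrame(counts, dtype=float)
    n = len(df)
    df.index = [f"s{i + 1}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "site": sites if sites is not None else ["SH"] * n,
            "fraction": fractions if fractions is not None else ["floc"] * n,
            "date": pd.to_datetime(dates) if dates is not None
            else pd.date_range("2013-03-01", periods=n, freq="30D"),
            "temperature": temps if temps is not None else [20.0] * n,
        },
        index=df.index,
    )
    if guilds is None:
        guilds = {
            o: ("predator_bd" if o.startswith("Bd") else
                "predator_bx" if o.startswith("Bx") else "prey_candidate")
            for o in df.columns
        }
    return OTUTable(counts=df, sample_meta=meta, guild=pd.Series(guilds), mode=mode)


@pytest.fixture
def toy_taxonomy() -> Taxonomy:
    return Taxonomy.from_strings(
        {
            "Bd001": "Bacteria;Proteobacteria;Deltaproteobacteria;Bdellovibrionales;Bdellovibrionaceae;Bdellovibrio",
            "Bx001": "Bacteria;Proteobacteria;Deltaproteobacteria;Bacteriovoracales;Bacteriovoracaceae;Peredibacter",
            "PreyGN": "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;Pseudomonadaceae;Pseudomonas",
            "PreyGP": "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Bacillus",
            "PreyAct": "Bacteria;Actinobacteria;Actinomycetia;Micrococcales;Micrococcaceae;unclassified",
            "PreyUnk": "Bacteria;unclassified",
        }
    )


@pytest.fixture
def small_table(toy_taxonomy) -> OTUTable:
    rng = np.random.default_rng(7)
    n = 6
    counts = {
        "Bd001": rng.integers(0, 30, n).astype(float),
        "Bx001": rng.integers(0, 30, n).astype(float),
        "PreyGN": rng.integers(10, 200, n).astype(float),
        "PreyGP": rng.integers(10, 200, n).astype(float),
        "PreyAct": rng.integers(10, 200, n).astype(float),
        "PreyUnk": rng.integers(10, 200, n).astype(float),
    }
    return make_table(counts)
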
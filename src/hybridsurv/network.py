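"""Bootstrap Spearman correlation network over the trait panel.

For every pair of traits the Spearman rank correlation is estimated on
pairwise-complete observations; significance comes from a percentile
bootstrap over rows (default 95 % interval excluding zero), and the network
is the undirected graph whose edges are the significant pairs, weighted by
the point-estimate correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["spearman", "CorrelationNetwork", "bootstrap_network", "bootstrap_pair"]


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties) on complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    if keep.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    rho = stats.spearmanr(x[keep], y[keep]).statistic
    return float(rho)


def bootstrap_pair(x, y, n_boot: int = 10_000, alpha: float = 0.05, seed: int = 0,
                   chunk: int = 2000):
    """Percentile bootstrap of the Spearman correlation for one trait pair.

    Returns (rho, ci_low, ci_high, significant).  Rows with a missing value
    in either trait are dropped before resampling; a degenerate (constant)
    trait yields a non-significant edge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan, np.nan, False
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is very small for a percentile interval")
    rho = spearman(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(m, n))
        xr = stats.rankdata(x[idx], axis=1)
        yr = stats.rankdata(y[idx], axis=1)
        xr = xr - xr.mean(axis=1, keepdims=True)
        yr = yr - yr.mean(axis=1, keepdims=True)
        num = (xr * yr).sum(axis=1)
        den = np.sqrt((xr**2).sum(axis=1) * (yr**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            boots[done : done + m] = np.where(den > 0, num / den, 0.0)
        done += m
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    significant = bool(lo > 0 or hi < 0)
    return rho, float(lo), float(hi), significant


@dataclass
class CorrelationNetwork:
    nodes: list
    edges: pd.DataFrame  # feature_a, feature_b, rho, ci_low, ci_high, significant

    def significant_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]].reset_index(drop=True)


def bootstrap_network(
    table: pd.DataFrame,
    n_boot: int = 100_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> CorrelationNetwork:
    """Build the trait correlation network over all column pairs.

    Deterministic under the seed (each pair gets a derived child seed so a
    single pair can be recomputed in isolation).
    """
    if len(table) < 10:
        warnings.warn("fewer than 10 rows; bootstrap intervals will be unstable")
    cols = list(table.columns)
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cols) * (len(cols) - 1) // 2)
    for (a, b), child in zip(combinations(cols, 2), children):
        pair_seed = int(child.generate_state(1)[0] % (2**31))
        rho, lo, hi, sig = bootstrap_pair(
            table[a], table[b], n_boot=n_boot, alpha=alpha, seed=pair_seed
        )
        rows.append({"feature_a": a, "feature_b": b, "rho": rho,
                     "ci_low": lo, "ci_high": hi, "significant": sig})
    return CorrelationNetwork(nodes=cols, edges=pd.DataFrame(rows))
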
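"""Nonparametric among-population trait comparisons.

Kruskal-Wallis rank ANOVA (tie-corrected, chi-square approximation) tests
whether any population differs in a trait without distributional
assumptions; Dunn's post hoc z-tests identify which pairs differ, with
optional Bonferroni or Holm adjustment across the k(k-1)/2 comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import logger

__all__ = ["KWResult", "DunnResult", "kruskal_wallis", "dunn_posthoc"]


@dataclass
class KWResult:
    trait: str
    h: float
    df: int
    p_value: float
    mean_ranks: dict[str, float]
    tie_correction: float


@dataclass
class DunnResult:
    trait: str
    groups: list[str]
    z: np.ndarray = field(repr=False)
    p_raw: np.ndarray = field(repr=False)
    p_adjusted: np.ndarray = field(repr=False)
    adjustment: str = "none"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.groups)):
            for j in range(i + 1, len(self.groups)):
                rows.append(
                    (self.groups[i], self.groups[j], self.z[i, j],
                     self.p_raw[i, j], self.p_adjusted[i, j])
                )
        return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw", "p_adjusted"])


def _ranks_and_ties(groups: dict[str, np.ndarray]):
    names = [g for g, v in groups.items() if len(v) > 0]
    dropped = [g for g, v in groups.items() if len(v) == 0]
    if dropped:
        logger.warning("empty groups excluded: %s", dropped)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    ranks = stats.rankdata(pooled)  # midranks
    sizes = np.array([len(v) for v in values])
    edges = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[edges[i]: edges[i + 1]].mean() for i in range(len(names))]
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    return names, sizes, mean_ranks, tie_sum, pooled.size


def kruskal_wallis(groups: dict[str, np.ndarray], trait: str = "") -> KWResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p-value.

    H = [12/(N(N+1))] sum n_i Rbar_i^2 - 3(N+1), divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N).  Degenerate input (all values
    identical) reports H = 0, p = 1 with a warning.
    """
    names, sizes, mean_ranks, tie_sum, n = _ranks_and_ties(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if n < 3:
        raise ValueError("need total N >= 3")
    df = len(names) - 1
    correction = 1.0 - tie_sum / (n**3 - n)
    if correction <= 0:
        logger.warning("degenerate data: all pooled values identical")
        return KWResult(trait, 0.0, df, 1.0, dict(zip(names, mean_ranks)), 0.0)
    h = (12.0 / (n * (n + 1))) * float(np.sum(sizes * mean_ranks**2)) - 3.0 * (n + 1)
    h /= correction
    h = max(h, 0.0)
    p = float(stats.chi2.sf(h, df))
    return KWResult(trait, float(h), df, min(max(p, np.nextafter(0, 1)), 1.0),
                    dict(zip(names, mean_ranks)), correction)


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    m = p.size
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def dunn_posthoc(
    groups: dict[str, np.ndarray], adjustment: str = "none", trait: str = ""
) -> DunnResult:
    """Dunn's pairwise z-tests on the joint midranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T)(1/n_i + 1/n_j)] with
    the tie term T = sum(t^3 - t) / (12(N-1)); two-sided normal p-values.
    """
    names, sizes, mean_ranks, tie_sum, n = _ranks_and_ties(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 non-empty groups")
    k = len(names)
    tie_term = tie_sum / (12.0 * (n - 1))
    variance = n * (n + 1) / 12.0 - tie_term
    z = np.zeros((k, k))
    p = np.ones((k, k))
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            denom = np.sqrt(variance * (1.0 / sizes[i] + 1.0 / sizes[j]))
            zij = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
            z[i, j], z[j, i] = zij, -zij
            pij = float(2.0 * stats.norm.sf(abs(zij)))
            p[i, j] = p[j, i] = min(pij, 1.0)
            pairs.append((i, j))
    raw = np.array([p[i, j] for i, j in pairs])
    adj = _adjust(raw, adjustment)
    p_adj = np.ones((k, k))
    for (i, j), a in zip(pairs, adj):
        p_adj[i, j] = p_adj[j, i] = a
    return DunnResult(trait, names, z, p, p_adj, adjustment)
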
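"""P_ST estimation and the P_ST - F_ST comparison.

P_ST is the phenotypic analogue of Q_ST, computed from a one-way
partitioning of phenotypic variance among and within populations:

    P_ST = (c/h2 * sigma_B^2) / (c/h2 * sigma_B^2 + 2 * sigma_W^2)

where c/h2 is the (assumed, not estimated) ratio between the proportion of
the between-population variance that is additive and the within-population
narrow-sense heritability.  This package identifies sigma_B^2 with the
between-population mean square (MSB) and sigma_W^2 with the within
(pooled) mean square (MSW); applied to published per-population summary
tables this convention reproduces published P_ST values, whereas the
moment estimator (MSB - MSW)/n0 does not.

Confidence intervals are 95% percentile bootstrap intervals: stratified
resampling of individuals within populations when individual-level data
are available, or a parametric normal bootstrap from per-population
(mean, SD, N) summaries otherwise.  The comparison with neutral F_ST is
summarised by the critical c/h2 -- the smallest ratio at which the lower
CI bound reaches F_ST.  Critical c/h2 <= 0.5 is strong evidence for
diversifying selection, < 1 weak evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import TraitObservations, TraitSummary, logger

__all__ = [
    "AnovaComponents",
    "PstEstimate",
    "anova_components",
    "pst_point",
    "pst_bootstrap",
    "pst_curve",
    "critical_c_ratio",
    "classify_selection",
]

DEFAULT_C_GRID = np.round(np.arange(0.05, 2.0001, 0.05), 10)


@dataclass
class AnovaComponents:
    """One-way mean squares for a trait.

    MSB uses the sample-size-weighted grand mean:
    MSB = sum n_i (xbar_i - xbar)^2 / (k - 1);
    MSW = sum (n_i - 1) s_i^2 / (N - k).
    """

    trait: str
    msb: float
    msw: float
    k: int
    n_total: int
    populations: list[str] = field(default_factory=list)

    @property
    def df_between(self) -> int:
        return self.k - 1

    @property
    def df_within(self) -> int:
        return self.n_total - self.k


@dataclass
class PstEstimate:
    """P_ST point estimate with percentile-bootstrap CI.

    ``boot_msb``/``boot_msw`` hold the bootstrap replicates of the mean
    squares, so the CI can be re-evaluated at any c/h2 from the same
    resample set (this keeps the critical-ratio search monotone).
    """

    trait: str
    c_over_h2: float
    pst: float
    ci_low: float
    ci_high: float
    n_boot: int
    components: AnovaComponents
    boot_msb: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    boot_msw: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    critical_ratio: float | None = None
    classification: str | None = None

    def bootstrap_values(self, c_over_h2: float | None = None) -> np.ndarray:
        c = self.c_over_h2 if c_over_h2 is None else c_over_h2
        return _pst_vec(self.boot_msb, self.boot_msw, c)

    def ci_at(self, c_over_h2: float) -> tuple[float, float]:
        v = self.bootstrap_values(c_over_h2)
        return float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))


# ---------------------------------------------------------------------------
# Variance partitioning
# ---------------------------------------------------------------------------

def _summary_for(data: TraitObservations | TraitSummary, trait: str):
    """(populations, means, sds, ns) for one trait with NA populations
    dropped; raw observations are summarised on the fly."""
    if isinstance(data, TraitObservations):
        groups = data.groups(trait)
        pops = list(groups)
        means = np.array([np.mean(groups[p]) for p in pops])
        sds = np.array(
            [np.std(groups[p], ddof=1) if len(groups[p]) > 1 else np.nan for p in pops]
        )
        ns = np.array([len(groups[p]) for p in pops], dtype=float)
        return pops, means, sds, ns
    return data.trait_table(trait)


def anova_components(
    data: TraitObservations | TraitSummary, trait: str
) -> AnovaComponents:
    """One-way between/within mean squares for ``trait``.

    Populations with a missing summary cell are dropped for this trait
    only.  Identical results for raw observations and for summaries
    computed from the same observations.
    """
    pops, means, sds, ns = _summary_for(data, trait)
    k = len(pops)
    if k < 2:
        raise ValueError(f"trait {trait!r}: need >= 2 populations with data")
    n_total = float(ns.sum())
    if n_total - k <= 0:
        raise ValueError(f"trait {trait!r}: all groups have n = 1, MSW undefined")
    grand = float((ns * means).sum() / n_total)
    msb = float((ns * (means - grand) ** 2).sum() / (k - 1))
    within = np.where(ns > 1, (ns - 1) * np.nan_to_num(sds) ** 2, 0.0)
    msw = float(within.sum() / (n_total - k))
    return AnovaComponents(trait, msb, msw, k, int(n_total), pops)


def _pst_vec(msb, msw, c: float):
    with np.errstate(invalid="ignore", divide="ignore"):
        return (c * msb) / (c * msb + 2.0 * msw)


def pst_point(components: AnovaComponents, c_over_h2: float) -> float:
    """P_ST = (c * MSB) / (c * MSB + 2 * MSW) with c = c/h2."""
    if c_over_h2 <= 0:
        raise ValueError("c/h2 must be positive")
    if components.msb == 0 and components.msw == 0:
        logger.warning("trait %s: MSB = MSW = 0, P_ST undefined", components.trait)
        return np.nan
    return float(_pst_vec(components.msb, components.msw, c_over_h2))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _bootstrap_mean_squares(
    data: TraitObservations | TraitSummary,
    trait: str,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap replicates of (MSB, MSW).

    Individual-level data: stratified resampling with replacement within
    each population, preserving n_i.  Summary data: parametric bootstrap
    drawing n_i values per population from Normal(mean_i, sd_i^2).
    Populations with n_i < 2 are excluded (their within-group variance is
    undefined).
    """
    if isinstance(data, TraitObservations):
        groups = data.groups(trait)
        small = [p for p, v in groups.items() if len(v) < 2]
        if small:
            logger.warning("trait %s: populations excluded from bootstrap (n < 2): %s",
                           trait, small)
        groups = {p: v for p, v in groups.items() if len(v) >= 2}
        samplers = [
            (len(v), lambda v=v, m=len(v): v[rng.integers(0, m, size=(n_boot, m))])
            for v in groups.values()
        ]
    else:
        pops, means, sds, ns = data.trait_table(trait)
        small = [p for p, n in zip(pops, ns) if n < 2]
        if small:
            logger.warning("trait %s: populations excluded from bootstrap (n < 2): %s",
                           trait, small)
        keep = ns >= 2
        means, sds, ns = means[keep], sds[keep], ns[keep].astype(int)
        samplers = [
            (int(n), lambda m=m, s=s, n=int(n): rng.normal(m, s, size=(n_boot, n)))
            for m, s, n in zip(means, sds, ns)
        ]
    if len(samplers) < 2:
        raise ValueError(f"trait {trait!r}: need >= 2 populations with n >= 2")
    k = len(samplers)
    ns_arr = np.array([n for n, _ in samplers], dtype=float)
    n_total = ns_arr.sum()
    boot_means = np.empty((n_boot, k))
    boot_ss = np.empty((n_boot, k))  # within sum of squares per group
    for j, (_, draw) in enumerate(samplers):
        sample = draw()
        boot_means[:, j] = sample.mean(axis=1)
        boot_ss[:, j] = sample.var(axis=1, ddof=1) * (sample.shape[1] - 1)
    grand = (boot_means * ns_arr).sum(axis=1) / n_total
    msb = ((boot_means - grand[:, None]) ** 2 * ns_arr).sum(axis=1) / (k - 1)
    msw = boot_ss.sum(axis=1) / (n_total - k)
    return msb, msw


def pst_bootstrap(
    data: TraitObservations | TraitSummary,
    trait: str,
    c_over_h2: float = 0.5,
    n_boot: int = 9999,
    seed: int | None = None,
) -> PstEstimate:
    """P_ST with a 95% percentile bootstrap confidence interval."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    components = anova_components(data, trait)
    point = pst_point(components, c_over_h2)
    rng = np.random.default_rng(seed)
    msb, msw = _bootstrap_mean_squares(data, trait, n_boot, rng)
    values = _pst_vec(msb, msw, c_over_h2)
    return PstEstimate(
        trait=trait,
        c_over_h2=c_over_h2,
        pst=point,
        ci_low=float(np.percentile(values, 2.5)),
        ci_high=float(np.percentile(values, 97.5)),
        n_boot=n_boot,
        components=components,
        boot_msb=msb,
        boot_msw=msw,
    )


def pst_curve(
    estimate: PstEstimate, c_grid: np.ndarray | None = None
) -> pd.DataFrame:
    """P_ST and its CI as a function of c/h2 (for sensitivity plots),
    evaluated on the estimate's fixed bootstrap resample set."""
    grid = DEFAULT_C_GRID if c_grid is None else np.asarray(c_grid, dtype=float)
    rows = []
    for c in grid:
        lo, hi = estimate.ci_at(c)
        rows.append((c, pst_point(estimate.components, c), lo, hi))
    return pd.DataFrame(rows, columns=["c_over_h2", "pst", "ci_low", "ci_high"])


# ---------------------------------------------------------------------------
# Critical c/h2 and classification
# ---------------------------------------------------------------------------

def critical_c_ratio(
    data: TraitObservations | TraitSummary | None,
    trait: str,
    fst: float,
    n_boot: int = 1999,
    seed: int | None = None,
    c_max: float = 2.0,
    grid: np.ndarray | None = None,
    tol: float = 1e-3,
    estimate: PstEstimate | None = None,
) -> float:
    """Smallest c/h2 in (0, c_max] at which the lower 95% CI bound of P_ST
    reaches F_ST; +inf if never reached.

    One bootstrap resample set is drawn once and reused across c values, so
    ci_low(c) is nondecreasing in c and bisection is exact up to ``tol``.
    Pass ``grid`` to scan an explicit grid instead, or ``estimate`` to
    reuse an existing bootstrap.
    """
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must lie in [0, 1)")
    if estimate is None:
        if data is None:
            raise ValueError("either data or a PstEstimate is required")
        estimate = pst_bootstrap(data, trait, n_boot=n_boot, seed=seed)
    msb, msw = estimate.boot_msb, estimate.boot_msw

    def ci_low(c: float) -> float:
        return float(np.percentile(_pst_vec(msb, msw, c), 2.5))

    if grid is not None:
        for c in np.sort(np.asarray(grid, dtype=float)):
            if ci_low(float(c)) >= fst:
                return float(c)
        return math.inf
    if ci_low(c_max) < fst:
        return math.inf
    lo, hi = 0.0, c_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ci_low(mid) >= fst:
            hi = mid
        else:
            lo = mid
    return hi


def classify_selection(estimate: PstEstimate, fst: float) -> str:
    """Selection label from the P_ST - F_ST comparison.

    ``diversifying_strong``: critical c/h2 <= 0.5 (the CI clears F_ST even
    if only half the between-population variance is additive);
    ``diversifying_weak``: 0.5 < critical < 1; otherwise the CI at c/h2 = 1
    decides between ``indistinguishable`` (straddles F_ST) and
    ``uniform_stabilising`` (entirely below F_ST).
    """
    critical = estimate.critical_ratio
    if critical is None:
        critical = critical_c_ratio(None, estimate.trait, fst, estimate=estimate)
        estimate.critical_ratio = critical
    if critical <= 0.5:
        return "diversifying_strong"
    if critical < 1.0:
        return "diversifying_weak"
    _, ci_high_1 = estimate.ci_at(1.0)
    if ci_high_1 < fst:
        return "uniform_stabilising"
    return "indistinguishable"


def analyse_traits(
    data: TraitObservations | TraitSummary,
    fst: float,
    c_over_h2: float = 0.5,
    n_boot: int = 9999,
    seed: int | None = None,
) -> list[PstEstimate]:
    """Full per-trait analysis: P_ST, CI, critical c/h2 and classification."""
    traits = data.trait_names
    rng = np.random.default_rng(seed)
    out = []
    for trait in traits:
        est = pst_bootstrap(
            data, trait, c_over_h2, n_boot, seed=int(rng.integers(2**31))
        )
        est.critical_ratio = critical_c_ratio(None, trait, fst, estimate=est)
        est.classification = classify_selection(est, fst)
        out.append(est)
    return out
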
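"""Allele frequencies and gene-diversity partitioning for dominant markers.

Dominant markers (AFLP bands) hide the heterozygote: band presence covers
both AA and Aa, so the frequency q of the recessive band-absent allele must
be inferred from the fraction of band-absent (aa) individuals, assuming
Hardy-Weinberg proportions within populations (band absence probability
q^2).  Two estimators are provided:

* ``sqrt`` -- q_hat = sqrt(x/n), the naive method-of-moments estimator;
* ``bayesian`` -- the posterior mean of q given x ~ Binomial(n, q^2) under
  a Beta(a, b) prior whose shape is fitted across loci by the method of
  moments on pooled band-absence fractions (a non-uniform prior, which
  stabilises estimates at loci where the band is absent in nobody or
  everybody).

Gene diversity is then partitioned Nei-style: per-locus expected
heterozygosity 2q(1-q) with the small-sample correction n/(n-1), averaged
into a within-population component Hw, a total component HT computed from
the unweighted mean allele frequency across populations, and the
among-population component Hb = HT - Hw.  F_ST = Hb / HT.  Significance is
assessed by permuting individuals among populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import roots_legendre

from .core_io import MarkerMatrix, logger

__all__ = [
    "BetaPrior",
    "AlleleFrequencySet",
    "DiversityPartition",
    "PairwiseFst",
    "fit_beta_prior",
    "posterior_mean_table",
    "estimate_allele_frequencies",
    "diversity_partition",
    "fst_permutation_test",
    "pairwise_fst",
]


@dataclass
class BetaPrior:
    """Beta(a, b) prior on the band-absent allele frequency."""

    a: float
    b: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and (self.a <= 0 or self.b <= 0):
            raise ValueError("Beta prior requires a > 0 and b > 0")


@dataclass
class AlleleFrequencySet:
    """Estimated band-absent allele frequency per population x locus.

    ``q`` and ``n`` are (populations x loci) arrays; NaN in ``q`` marks
    cells with no scored individuals.
    """

    populations: list[str]
    locus_ids: list[str]
    q: np.ndarray
    n: np.ndarray


@dataclass
class DiversityPartition:
    """Within/among/total gene diversity and the F_ST they imply."""

    hj: dict[str, float]
    hw: float
    hb: float
    ht: float
    fst: float
    hb_raw: float  # before flooring at zero
    p_value: float | None = None
    n_permutations: int = 0


@dataclass
class PairwiseFst:
    populations: list[str]
    matrix: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))


# ---------------------------------------------------------------------------
# Prior fitting
# ---------------------------------------------------------------------------

def fit_beta_prior(band_absence_fractions: np.ndarray) -> BetaPrior:
    """Method-of-moments Beta fit to the across-locus distribution of
    pooled band-absence fractions.

    With mean m and variance v of the fractions, a = m(m(1-m)/v - 1) and
    b = (1-m)(m(1-m)/v - 1).  If the fractions are (near) constant or
    overdispersed beyond what any Beta allows (v >= m(1-m)), the fit is
    degenerate and a flat Beta(1, 1) fallback is used.
    """
    f = np.asarray(band_absence_fractions, dtype=float)
    f = f[~np.isnan(f)]
    if f.size < 2:
        raise ValueError("need at least 2 loci to fit a prior")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("band-absence fractions must lie in [0, 1]")
    m = float(np.mean(f))
    v = float(np.var(f))
    if v < 1e-12 or m <= 0 or m >= 1 or v >= m * (1 - m):
        logger.warning(
            "degenerate prior fit (mean=%.4g, var=%.4g); using flat Beta(1,1)", m, v
        )
        return BetaPrior(1.0, 1.0, degenerate=True)
    scale = m * (1 - m) / v - 1.0
    return BetaPrior(a=m * scale, b=(1 - m) * scale)


# ---------------------------------------------------------------------------
# Posterior means under the dominant-marker likelihood
# ---------------------------------------------------------------------------

def _posterior_mean(x: int, n: int, prior: BetaPrior, order: int = 256) -> float:
    """E[q | x band-absent out of n] with likelihood (q^2)^x (1-q^2)^(n-x)
    and prior q^(a-1) (1-q)^(b-1), by fixed-order Gauss-Legendre quadrature
    on [0, 1] evaluated in log space."""
    nodes, weights = roots_legendre(order)
    q = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    with np.errstate(divide="ignore"):
        logf = (
            (prior.a - 1.0 + 2.0 * x) * np.log(q)
            + (prior.b - 1.0) * np.log1p(-q)
            + (n - x) * np.log1p(-(q * q))
        )
    logf -= logf.max()
    f = np.exp(logf)
    denom = float(np.sum(w * f))
    if denom == 0.0:
        return np.nan
    return float(np.sum(w * q * f) / denom)


def posterior_mean_table(prior: BetaPrior, n_max: int, order: int = 256) -> np.ndarray:
    """Table T[n, x] of posterior means for all 0 <= x <= n <= n_max.

    The permutation test recomputes frequencies thousands of times with the
    same per-population sample sizes, so estimation reduces to this lookup.
    """
    table = np.full((n_max + 1, n_max + 1), np.nan)
    for n in range(1, n_max + 1):
        for x in range(n + 1):
            table[n, x] = _posterior_mean(x, n, prior, order)
    return table


def estimate_allele_frequencies(
    markers: MarkerMatrix,
    prior: BetaPrior | None = None,
    method: str = "sqrt",
    _table: np.ndarray | None = None,
    _labels: np.ndarray | None = None,
) -> AlleleFrequencySet:
    """Per-population, per-locus band-absent allele frequency estimates.

    Missing marker cells are excluded locus-wise (complete case per locus);
    a (population, locus) cell with no scored individuals gets NaN.
    """
    if method not in ("bayesian", "sqrt"):
        raise ValueError(f"unknown method {method!r}")
    pops = markers.populations
    labels = _labels if _labels is not None else np.asarray(markers.population_labels)
    onehot = np.stack([labels == p for p in pops]).astype(float)  # pops x ind
    scored = ~np.isnan(markers.bands)
    absent = (markers.bands == 0) & scored
    n = onehot @ scored.astype(float)  # pops x loci
    x = onehot @ absent.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "sqrt":
            q = np.sqrt(x / n)
        else:
            if _table is None:
                if prior is None:
                    pooled = np.nansum(absent, axis=0) / np.maximum(scored.sum(axis=0), 1)
                    prior = fit_beta_prior(pooled)
                _table = posterior_mean_table(prior, int(n.max()))
            q = _table[n.astype(int), x.astype(int)]
    q = np.where(n > 0, q, np.nan)
    return AlleleFrequencySet(pops, list(markers.locus_ids), q, n)


# ---------------------------------------------------------------------------
# Gene-diversity partition
# ---------------------------------------------------------------------------

def _partition_arrays(q: np.ndarray, n: np.ndarray):
    """Vectorised Hw/Hb/HT per locus from (pops x loci) q-hat and n.

    Cells need n >= 2 for the unbiased 2q(1-q) n/(n-1) correction; a locus
    is informative when at least two populations have usable estimates.
    Returns (hj_per_pop, hw, hb_raw, ht, per-locus fst components).
    """
    usable = (~np.isnan(q)) & (n >= 2)
    qa = np.where(usable, q, 0.0)
    na = np.where(usable, n, 2.0)
    counts = usable.sum(axis=0)
    informative = counts >= 2
    h = np.where(usable, 2.0 * qa * (1.0 - qa) * na / (na - 1.0), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        qbar = np.where(counts > 0, qa.sum(axis=0) / np.maximum(counts, 1), np.nan)
        ht_locus = np.where(informative, 2.0 * qbar * (1.0 - qbar), np.nan)
        hw_locus = np.where(
            informative,
            np.where(usable, h, 0.0).sum(axis=0) / np.maximum(counts, 1),
            np.nan,
        )
    return h, usable, informative, hw_locus, ht_locus


def diversity_partition(freqs: AlleleFrequencySet) -> DiversityPartition:
    """Nei gene-diversity partition and F_ST = Hb / HT.

    Hj is each population's expected heterozygosity averaged over loci; Hw
    is the unweighted mean of Hj across populations; HT averages per-locus
    total diversity computed from the unweighted mean allele frequency; Hb
    is the difference, floored at zero (estimator noise can produce small
    negatives).
    """
    if len(freqs.populations) < 2:
        raise ValueError("diversity partition needs at least 2 populations")
    h, usable, informative, _, ht_locus = _partition_arrays(freqs.q, freqs.n)
    if not informative.any():
        raise ValueError("no locus has estimates in >= 2 populations")
    hj_values = _pop_means(h, usable, informative)
    hj = dict(zip(freqs.populations, map(float, hj_values)))
    hw = float(np.mean(hj_values[~np.isnan(hj_values)]))
    ht = float(np.mean(ht_locus[informative]))
    hb_raw = ht - hw
    hb = hb_raw
    if hb < 0:
        logger.warning("negative Hb (%.4g) floored at 0", hb)
        hb = 0.0
    if ht <= 0:
        logger.warning("HT = 0: F_ST undefined")
        fst = np.nan
    else:
        fst = hb / ht
    return DiversityPartition(hj=hj, hw=hw, hb=hb, ht=ht, fst=fst, hb_raw=hb_raw)


def _pop_means(h: np.ndarray, usable: np.ndarray, informative: np.ndarray) -> np.ndarray:
    """Per-population mean heterozygosity over informative loci (NaN when a
    population has no usable cell there)."""
    mask = usable & informative[None, :]
    sums = np.where(mask, np.nan_to_num(h), 0.0).sum(axis=1)
    counts = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def _fst_from_counts(q: np.ndarray, n: np.ndarray) -> float:
    """Global F_ST only (fast path for permutations)."""
    h, usable, informative, _, ht_locus = _partition_arrays(q, n)
    if not informative.any():
        return np.nan
    hj = _pop_means(h, usable, informative)
    hw = float(np.mean(hj[~np.isnan(hj)]))
    ht = float(np.mean(ht_locus[informative]))
    if ht <= 0:
        return np.nan
    return max(ht - hw, 0.0) / ht


def fst_permutation_test(
    markers: MarkerMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    method: str = "sqrt",
) -> DiversityPartition:
    """Global F_ST with a permutation p-value.

    Individuals are permuted among populations preserving population sizes
    and the whole estimation pipeline is recomputed per permutation.  The
    pooled band-absence fractions (hence the fitted prior) are invariant
    under label permutation, so the prior is fitted once.  p-values use the
    +1 correction: p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).
    """
    if len(markers.populations) < 2:
        raise ValueError("permutation test needs >= 2 populations")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    prior = None
    table = None
    if method == "bayesian":
        scored = ~np.isnan(markers.bands)
        absent = (markers.bands == 0) & scored
        pooled = absent.sum(axis=0) / np.maximum(scored.sum(axis=0), 1)
        prior = fit_beta_prior(pooled)
        sizes = markers.population_sizes()
        table = posterior_mean_table(prior, max(sizes.values()))
    labels = np.asarray(markers.population_labels)
    freqs = estimate_allele_frequencies(markers, prior, method, _table=table)
    observed = diversity_partition(freqs)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        f = estimate_allele_frequencies(markers, prior, method, _table=table, _labels=perm)
        fst_perm = _fst_from_counts(f.q, f.n)
        if not np.isnan(fst_perm) and fst_perm >= observed.fst:
            count += 1
    observed.p_value = (count + 1) / (n_perm + 1)
    observed.n_permutations = n_perm
    return observed


def pairwise_fst(
    markers: MarkerMatrix, method: str = "sqrt", prior: BetaPrior | None = None
) -> PairwiseFst:
    """Pairwise F_ST matrix: the diversity partition restricted to each
    unordered pair of populations, symmetric with zero diagonal."""
    pops = markers.populations
    if len(pops) < 2:
        raise ValueError("pairwise F_ST needs >= 2 populations")
    freqs = estimate_allele_frequencies(markers, prior, method)
    scored_any = freqs.n.sum(axis=1) > 0
    if not scored_any.all():
        dropped = [p for p, ok in zip(pops, scored_any) if not ok]
        logger.warning("excluding populations with no scored individuals: %s", dropped)
        keep = [i for i, ok in enumerate(scored_any) if ok]
        pops = [pops[i] for i in keep]
        freqs = AlleleFrequencySet(pops, freqs.locus_ids, freqs.q[keep], freqs.n[keep])
    k = len(pops)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = AlleleFrequencySet(
                [pops[i], pops[j]],
                freqs.locus_ids,
                freqs.q[[i, j]],
                freqs.n[[i, j]],
            )
            out[i, j] = out[j, i] = diversity_partition(sub).fst
    return PairwiseFst(pops, out)
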
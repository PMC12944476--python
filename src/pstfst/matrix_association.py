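"""Distance matrices and Mantel / partial Mantel permutation tests.

Geographic distances are great-circle (haversine) kilometres; trait and
environmental distances are Euclidean over one or more (optionally
standardised) variables.  The Mantel statistic is the Pearson correlation
of the strict lower triangles of two aligned distance matrices; its null
distribution comes from simultaneous row/column permutations of the second
matrix.  The partial Mantel correlation conditions both matrices on a
third via the first-order partial-correlation formula, permuting the
second matrix under the null.  p-values are one-sided (positive
association) with the +1 correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DistanceMatrix, SiteTable

__all__ = [
    "MantelOutcome",
    "EARTH_RADIUS_KM",
    "haversine_km",
    "geographic_distance_matrix",
    "euclidean_distance_matrix",
    "mantel",
    "partial_mantel",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class MantelOutcome:
    r: float
    p_value: float
    n_permutations: int
    kind: str = "simple"  # simple | partial
    conditioning: str | None = None


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geographic_distance_matrix(sites: SiteTable) -> DistanceMatrix:
    """Pairwise haversine distances between sites, in km."""
    lat = sites.latitude[:, None]
    lon = sites.longitude[:, None]
    d = haversine_km(lat, lon, lat.T, lon.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(sites.population_codes), d, units="km")


def euclidean_distance_matrix(
    values: pd.DataFrame, standardize: bool = False, units: str = ""
) -> DistanceMatrix:
    """Pairwise Euclidean distances over the variable columns of a
    site-indexed table; a single variable reduces to |difference|.  Sites
    with any missing value are excluded (with a warning)."""
    from .core_io import logger

    df = values.astype(float)
    bad = df.isna().any(axis=1)
    if bad.any():
        logger.warning("sites excluded for missing values: %s", list(df.index[bad]))
        df = df.loc[~bad]
    x = df.to_numpy()
    if standardize:
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        units = "z-units"
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix([str(i) for i in df.index], d, units=units)


def _aligned_condensed(*matrices: DistanceMatrix) -> list[np.ndarray]:
    labels = matrices[0].labels
    for m in matrices[1:]:
        if set(m.labels) != set(labels):
            diff = set(m.labels) ^ set(labels)
            raise ValueError(f"distance matrices have mismatched labels: {sorted(diff)}")
    return [m.reordered(labels).condensed() for m in matrices]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def _permuted_condensed(values: np.ndarray, perm: np.ndarray, tri: tuple) -> np.ndarray:
    return values[np.ix_(perm, perm)][tri]


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
) -> MantelOutcome:
    """Simple Mantel test of positive matrix association."""
    if len(a.labels) < 4:
        raise ValueError("Mantel test needs >= 4 sites")
    va, vb = _aligned_condensed(a, b)
    r_obs = _pearson(va, vb)
    k = len(a.labels)
    tri = np.tril_indices(k, k=-1)
    b_vals = b.reordered(a.labels).values
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        if _pearson(va, _permuted_condensed(b_vals, perm, tri)) >= r_obs:
            count += 1
    return MantelOutcome(r=r_obs, p_value=(count + 1) / (n_perm + 1), n_permutations=n_perm)


def _partial_r(rab: float, rac: float, rbc: float) -> float:
    denom = (1.0 - rac**2) * (1.0 - rbc**2)
    if denom <= 0:
        raise ValueError("conditioning matrix is perfectly correlated with an input")
    return (rab - rac * rbc) / np.sqrt(denom)


def partial_mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    c: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    conditioning_label: str | None = None,
) -> MantelOutcome:
    """Partial Mantel test of A vs B conditioning on C.

    r_AB.C = (r_AB - r_AC r_BC) / sqrt[(1 - r_AC^2)(1 - r_BC^2)]; the null
    permutes B's rows/columns and recomputes the partial correlation.  If C
    is constant off-diagonal, the partial r equals the simple Mantel r.
    """
    if len(a.labels) < 4:
        raise ValueError("partial Mantel test needs >= 4 sites")
    va, vb, vc = _aligned_condensed(a, b, c)
    rac = _pearson(va, vc)
    constant_c = np.allclose(vc, vc[0])
    if constant_c:
        r_obs = _pearson(va, vb)
    else:
        r_obs = _partial_r(_pearson(va, vb), rac, _pearson(vb, vc))
    k = len(a.labels)
    tri = np.tril_indices(k, k=-1)
    b_vals = b.reordered(a.labels).values
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        vbp = _permuted_condensed(b_vals, perm, tri)
        if constant_c:
            r_perm = _pearson(va, vbp)
        else:
            r_perm = _partial_r(_pearson(va, vbp), rac, _pearson(vbp, vc))
        if r_perm >= r_obs:
            count += 1
    return MantelOutcome(
        r=float(r_obs),
        p_value=(count + 1) / (n_perm + 1),
        n_permutations=n_perm,
        kind="partial",
        conditioning=conditioning_label or (c.units or "C"),
    )
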
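"""Synthetic data with known divergence structure, plus packaged fixtures.

The generators emulate the sampling design the pipeline targets: 11
populations of a widespread tree sampled across climatic gradients, with
a few hundred dominant (band presence/absence) loci at a known global
F_ST, quantitative traits with a known expected P_ST, and per-site
climate covariates tied to geography (precipitation increasing eastward,
temperature increasing toward the equator).

Markers follow the Balding-Nichols island model: each locus has an
ancestral band-absent allele frequency q0 drawn uniformly, each
population's frequency is Beta(q0(1-F)/F, (1-q0)(1-F)/F) -- giving
E[F_ST] = F exactly at the allele-frequency level -- and individuals are
Hardy-Weinberg draws, band-absent with probability q^2.

Trait targets are calibrated on the expected mean squares so that the
mean-square-based P_ST estimator is centred on the target at c/h2 = 1:
sigma_B^2 solves  target = E[MSB] / (E[MSB] + 2 sigma_W^2)  with
E[MSB] = nbar sigma_B^2 + sigma_W^2.  Because E[MSB] >= sigma_W^2, targets
below 1/3 are unattainable under this convention; sigma_B is then clamped
at zero (no between-population signal) with a warning.

``make_paper_fixture`` returns the published summary tables this package
is validated against, transcribed as typed objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    MarkerMatrix,
    SiteTable,
    TraitObservations,
    TraitSummary,
    logger,
    parse_dms,
)
from .dominant_popgen import PairwiseFst

__all__ = [
    "TraitSpec",
    "SimulationConfig",
    "simulate_markers",
    "simulate_traits",
    "simulate_sites",
    "simulate_environment",
    "simulate_dataset",
    "make_paper_fixture",
]


@dataclass
class TraitSpec:
    """One simulated trait: within-population SD (trait units), target
    P_ST at c/h2 = 1, and an optional environmental effect (added as
    coefficient x z-scored site variable)."""

    name: str
    sigma_w: float = 1.0
    target_pst: float = 0.5
    env_coefficient: float = 0.0
    env_variable: str | None = None

    def sigma_b(self, nbar: float) -> float:
        """Between-population effect SD solving the expected-mean-square
        calibration; clamped at 0 for targets below the estimator floor."""
        if not 0.0 <= self.target_pst < 1.0:
            raise ValueError("target P_ST must lie in [0, 1)")
        t = self.target_pst
        e_msb = 2.0 * t * self.sigma_w**2 / (1.0 - t)
        var_b = (e_msb - self.sigma_w**2) / nbar
        if var_b < 0:
            if t > 0:
                logger.warning(
                    "trait %s: target P_ST %.3g is below the mean-square "
                    "estimator floor (1/3); using sigma_B = 0", self.name, t,
                )
            return 0.0
        return float(np.sqrt(var_b))


def _default_traits() -> list[TraitSpec]:
    # seven traits spanning weak-to-strong differentiation, like the leaf,
    # spine and fruit traits of the motivating study
    return [
        TraitSpec("RAL", sigma_w=0.58, target_pst=0.56),
        TraitSpec("PLA", sigma_w=2.55, target_pst=0.54),
        TraitSpec("PLB", sigma_w=2.58, target_pst=0.67),
        TraitSpec("SSL", sigma_w=0.82, target_pst=0.58),
        TraitSpec("FPL", sigma_w=0.29, target_pst=0.48),
        TraitSpec("FRL", sigma_w=0.87, target_pst=0.87, env_coefficient=0.8,
                  env_variable="precipitation"),
        TraitSpec("FRW", sigma_w=0.26, target_pst=0.87, env_coefficient=0.8,
                  env_variable="tmax"),
    ]


@dataclass
class SimulationConfig:
    """Generator parameters; defaults mirror the emulated study design
    (11 populations, 11-22 individuals each, 225 dominant loci at global
    F_ST 0.33, seven strongly differentiated traits, southern-hemisphere
    sites with east-west precipitation and north-south temperature
    gradients)."""

    n_pops: int = 11
    n_individuals: int | list[int] = field(
        default_factory=lambda: [16, 22, 14, 14, 14, 12, 12, 14, 17, 11, 12]
    )
    n_loci: int = 225
    target_fst: float = 0.33
    q0_range: tuple[float, float] = (0.1, 0.9)
    traits: list[TraitSpec] = field(default_factory=_default_traits)
    lat_range: tuple[float, float] = (-34.7, -24.6)
    lon_range: tuple[float, float] = (-66.0, -56.5)
    seed: int | None = None

    def pop_sizes(self) -> np.ndarray:
        if isinstance(self.n_individuals, int):
            return np.full(self.n_pops, self.n_individuals, dtype=int)
        sizes = np.asarray(self.n_individuals, dtype=int)
        if sizes.size != self.n_pops:
            raise ValueError("n_individuals list must have n_pops entries")
        return sizes

    def pop_labels(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_pops)]

    def __post_init__(self) -> None:
        if not 0.0 < self.target_fst < 1.0:
            raise ValueError("target F must lie strictly in (0, 1)")
        if self.n_pops < 2 or self.n_loci < 1 or np.any(self.pop_sizes() < 1):
            raise ValueError("population, locus and sample counts must be positive")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_markers(config: SimulationConfig, seed: int | None = None) -> MarkerMatrix:
    """Balding-Nichols dominant-marker matrix at the configured target F."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = config.pop_sizes()
    labels = config.pop_labels()
    f = config.target_fst
    q0 = rng.uniform(*config.q0_range, size=config.n_loci)
    scale = (1.0 - f) / f
    q = rng.beta(q0 * scale, (1.0 - q0) * scale, size=(config.n_pops, config.n_loci))
    pop_index = np.repeat(np.arange(config.n_pops), sizes)
    # HWE: band absent iff both alleles recessive, probability q^2
    absent = rng.random((pop_index.size, config.n_loci)) < (q**2)[pop_index]
    bands = (~absent).astype(float)
    return MarkerMatrix(
        individual_ids=[f"ind{i + 1:03d}" for i in range(pop_index.size)],
        population_labels=[labels[i] for i in pop_index],
        locus_ids=[f"L{j + 1:03d}" for j in range(config.n_loci)],
        bands=bands,
    )


def simulate_traits(
    config: SimulationConfig,
    population_labels: list[str] | None = None,
    seed: int | None = None,
    env: pd.DataFrame | None = None,
) -> TraitObservations:
    """Individual trait values: population effect Normal(0, sigma_B) plus
    Normal(0, sigma_W) noise, with sigma_B calibrated to the target P_ST.
    An optional per-site environmental table shifts population means by
    env_coefficient x z-scored variable (traits tied to climate)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if population_labels is None:
        sizes = config.pop_sizes()
        pops = config.pop_labels()
        population_labels = [p for p, n in zip(pops, sizes) for _ in range(n)]
    else:
        pops = list(dict.fromkeys(population_labels))
    counts = pd.Series(population_labels).value_counts()
    nbar = float(counts.mean())
    pop_index = np.array([pops.index(p) for p in population_labels])
    values = np.empty((len(population_labels), len(config.traits)))
    for j, spec in enumerate(config.traits):
        effects = rng.normal(0.0, spec.sigma_b(nbar), size=len(pops))
        if env is not None and spec.env_coefficient and spec.env_variable in env.columns:
            v = env.loc[pops, spec.env_variable].to_numpy(dtype=float)
            z = (v - v.mean()) / v.std(ddof=1)
            effects = effects + spec.env_coefficient * z
        noise = rng.normal(0.0, spec.sigma_w, size=len(population_labels))
        values[:, j] = effects[pop_index] + noise
    return TraitObservations(
        individual_ids=[f"ind{i + 1:03d}" for i in range(len(population_labels))],
        population_labels=list(population_labels),
        trait_names=[s.name for s in config.traits],
        values=values,
    )


def simulate_sites(config: SimulationConfig, seed: int | None = None) -> SiteTable:
    """Random site layout inside the configured bounding box."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lat = rng.uniform(*config.lat_range, size=config.n_pops)
    lon = rng.uniform(*config.lon_range, size=config.n_pops)
    return SiteTable(
        population_codes=config.pop_labels(),
        latitude=lat,
        longitude=lon,
        sample_size=config.pop_sizes(),
    )


def simulate_environment(
    sites: SiteTable,
    seed: int | None = None,
    noise_sd: float = 0.25,
) -> pd.DataFrame:
    """Seven climate covariates tied to geography.

    Precipitation rises eastward (with longitude) and temperature rises
    toward the equator (with latitude, in the southern hemisphere); the
    remaining five variables (max/min temperature, vapour pressure, solar
    radiation, wind speed) are noisy linear mixtures of the two gradients.
    ``noise_sd`` is the residual SD on the z-scale of each gradient.
    """
    if len(sites) == 0:
        raise ValueError("empty site table")
    rng = np.random.default_rng(seed)
    lat = np.asarray(sites.latitude, dtype=float)
    lon = np.asarray(sites.longitude, dtype=float)

    def z(v: np.ndarray) -> np.ndarray:
        s = v.std(ddof=1) if len(v) > 1 else 1.0
        return (v - v.mean()) / (s if s > 0 else 1.0)

    zlon, zlat = z(lon), z(lat)
    e = lambda: rng.normal(0.0, noise_sd, size=len(sites))
    precip_z = zlon + e()          # wetter eastward
    temp_z = zlat + e()            # warmer northward (toward the equator)
    df = pd.DataFrame(
        {
            "precipitation": 800.0 + 250.0 * precip_z,      # mm
            "tmean": 18.0 + 3.0 * temp_z,                   # degC
            "tmax": 25.0 + 3.0 * (temp_z + 0.3 * e()),      # degC
            "tmin": 11.0 + 3.0 * (temp_z + 0.3 * e()),      # degC
            "vapour_pressure": 1.6 + 0.3 * z(0.7 * precip_z + 0.5 * temp_z + e()),  # kPa
            "solar_radiation": 16000.0 + 1500.0 * z(-0.6 * precip_z + 0.4 * temp_z + e()),  # kJ/m2/day
            "wind_speed": 3.0 + 0.8 * z(-0.5 * zlat + e()),  # m/s
        },
        index=sites.population_codes,
    )
    df.index.name = "population"
    return df


def simulate_dataset(config: SimulationConfig, seed: int | None = None):
    """Markers, traits, sites and environment from one seed, with the
    trait-climate links wired through the generated environment table."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    s = lambda: int(rng.integers(2**31))
    markers = simulate_markers(config, seed=s())
    sites = simulate_sites(config, seed=s())
    env = simulate_environment(sites, seed=s())
    traits = simulate_traits(config, markers.population_labels, seed=s(), env=env)
    return markers, traits, sites, env


# ---------------------------------------------------------------------------
# Published tables (transcribed fixtures)
# ---------------------------------------------------------------------------

# Per-population trait summaries: mean (SD) N for seven morphological
# traits (cm for lengths/widths, counts for leaflet pairs) in 11
# populations; the FPL x PA cell was not measured.
_TRAIT_POPS = ["RN", "CS", "GY", "PA", "VA", "TO", "EC", "VF", "IB", "FS", "YP"]
_TRAIT_N = [9, 4, 12, 6, 6, 8, 4, 6, 7, 7, 5]
_TRAIT_ROWS: dict[str, list[tuple[float, float] | None]] = {
    "RAL": [(2.464, 0.393), (3.160, 0.330), (1.665, 0.422), (2.450, 0.502),
            (2.008, 0.499), (3.025, 0.908), (2.443, 1.102), (1.942, 0.337),
            (2.254, 0.649), (1.736, 0.410), (2.670, 0.577)],
    "PLB": [(17.143, 2.027), (16.208, 2.860), (11.000, 2.000), (10.000, 2.00),
            (10.000, 1.549), (14.125, 4.970), (15.250, 2.217), (13.750, 1.605),
            (12.287, 2.476), (12.786, 2.395), (18.700, 1.891)],
    "PLA": [(16.857, 2.204), (16.708, 2.495), (14.667, 2.774), (14.500, 3.146),
            (12.000, 1.789), (15.375, 3.583), (18.500, 2.517), (15.667, 1.506),
            (13.667, 1.389), (15.214, 2.325), (20.600, 3.070)],
    "SSL": [(2.056, 1.111), (0.983, 0.602), (0.413, 0.266), (0.892, 0.617),
            (1.675, 0.684), (2.363, 1.227), (1.963, 1.261), (1.083, 0.877),
            (0.403, 0.333), (1.071, 0.631), (2.130, 1.052)],
    "FPL": [(1.200, 0.150), (1.569, 0.236), (1.367, 0.317), None,
            (0.800, 0.063), (1.450, 0.359), (1.513, 0.217), (1.053, 0.404),
            (1.300, 0.208), (1.213, 0.374), (1.090, 0.361)],
    "FRL": [(7.175, 1.166), (4.939, 1.284), (4.254, 0.479), (5.933, 1.005),
            (6.492, 0.876), (7.613, 1.429), (6.543, 0.334), (2.952, 0.490),
            (4.400, 0.173), (3.137, 0.656), (2.870, 0.663)],
    "FRW": [(1.763, 0.316), (1.469, 0.492), (1.379, 0.239), (2.008, 0.458),
            (1.767, 0.303), (1.919, 0.162), (1.938, 0.275), (0.748, 0.075),
            (2.169, 0.088), (0.714, 0.100), (0.830, 0.125)],
}

# Sampling sites: variety, ecoregion, DMS coordinates (south/west) and
# molecular sample size.
_SITE_ROWS = [
    ("caven", "Pampa", "CS", "34°38′10.71″", "58°42′44.08″", 16),
    ("caven", "Pampa", "GY", "33°22′4.00″", "58°44′3.00″", 22),
    ("caven", "Puna", "RN", "24°39′48.00″", "65°22′49.00″", 14),
    ("macrocarpa", "Puna", "EC", "25° 4′58.80″", "65°28′1.20″", 14),
    ("macrocarpa", "Puna", "TO", "26°11′8.00″", "65°56′7.00″", 14),
    ("microcarpa", "Wet Chaco", "VF", "26°16′0.00″", "58°17′41.64″", 12),
    ("stenocarpa", "Wet Chaco", "FS", "26°16′13.20″", "58°17′7.92″", 12),
    ("stenocarpa", "Wet Chaco", "YP", "26°11′26.76″", "58° 9′23.82″", 14),
    ("sphaerocarpa", "Espinal", "IB", "28°15′40.13″", "56°30′20.38″", 17),
    ("dehiscens", "Dry Chaco", "PA", "31°15′58.90″", "64°20′28.60″", 11),
    ("dehiscens", "Dry Chaco", "VA", "31°23′38.93″", "63°51′30.87″", 12),
]

# Pairwise F_ST among the 11 populations (lower triangle as published).
_FST_LABELS = ["CS", "EC", "FS", "GY", "IB", "PA", "RN", "TO", "VA", "VF", "YP"]
_FST_LOWER = {
    ("EC", "CS"): 0.277,
    ("FS", "CS"): 0.492, ("FS", "EC"): 0.425,
    ("GY", "CS"): 0.226, ("GY", "EC"): 0.280, ("GY", "FS"): 0.376,
    ("IB", "CS"): 0.340, ("IB", "EC"): 0.321, ("IB", "FS"): 0.340,
    ("IB", "GY"): 0.227,
    ("PA", "CS"): 0.303, ("PA", "EC"): 0.236, ("PA", "FS"): 0.351,
    ("PA", "GY"): 0.209, ("PA", "IB"): 0.236,
    ("RN", "CS"): 0.311, ("RN", "EC"): 0.346, ("RN", "FS"): 0.447,
    ("RN", "GY"): 0.283, ("RN", "IB"): 0.274, ("RN", "PA"): 0.279,
    ("TO", "CS"): 0.457, ("TO", "EC"): 0.351, ("TO", "FS"): 0.500,
    ("TO", "GY"): 0.362, ("TO", "IB"): 0.418, ("TO", "PA"): 0.362,
    ("TO", "RN"): 0.483,
    ("VA", "CS"): 0.260, ("VA", "EC"): 0.207, ("VA", "FS"): 0.370,
    ("VA", "GY"): 0.205, ("VA", "IB"): 0.255, ("VA", "PA"): 0.050,
    ("VA", "RN"): 0.289, ("VA", "TO"): 0.334,
    ("VF", "CS"): 0.456, ("VF", "EC"): 0.384, ("VF", "FS"): 0.111,
    ("VF", "GY"): 0.348, ("VF", "IB"): 0.299, ("VF", "PA"): 0.320,
    ("VF", "RN"): 0.430, ("VF", "TO"): 0.441, ("VF", "VA"): 0.331,
    ("YP", "CS"): 0.446, ("YP", "EC"): 0.395, ("YP", "FS"): 0.117,
    ("YP", "GY"): 0.334, ("YP", "IB"): 0.264, ("YP", "PA"): 0.333,
    ("YP", "RN"): 0.395, ("YP", "TO"): 0.458, ("YP", "VA"): 0.338,
    ("YP", "VF"): 0.084,
}


def make_paper_fixture() -> tuple[TraitSummary, SiteTable, PairwiseFst]:
    """The published summary tables as typed objects: per-population trait
    summaries, the site table (converted to signed decimal degrees) and
    the pairwise F_ST matrix."""
    traits = list(_TRAIT_ROWS)
    shape = (len(_TRAIT_POPS), len(traits))
    mean = np.full(shape, np.nan)
    sd = np.full(shape, np.nan)
    n = np.full(shape, np.nan)
    for j, trait in enumerate(traits):
        for i, cell in enumerate(_TRAIT_ROWS[trait]):
            if cell is not None:
                mean[i, j], sd[i, j] = cell
                n[i, j] = _TRAIT_N[i]
    summary = TraitSummary(list(_TRAIT_POPS), traits, mean, sd, n)

    sites = SiteTable(
        population_codes=[r[2] for r in _SITE_ROWS],
        latitude=np.array([parse_dms(r[3], "S") for r in _SITE_ROWS]),
        longitude=np.array([parse_dms(r[4], "W") for r in _SITE_ROWS]),
        variety=[r[0] for r in _SITE_ROWS],
        ecoregion=[r[1] for r in _SITE_ROWS],
        sample_size=np.array([r[5] for r in _SITE_ROWS]),
    )

    k = len(_FST_LABELS)
    fst = np.zeros((k, k))
    for (a, b), value in _FST_LOWER.items():
        i, j = _FST_LABELS.index(a), _FST_LABELS.index(b)
        fst[i, j] = fst[j, i] = value
    pairwise = PairwiseFst(list(_FST_LABELS), fst)
    return summary, sites, pairwise
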
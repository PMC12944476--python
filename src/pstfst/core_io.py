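"""Data model and file I/O for the divergence-analysis pipeline.

The pipeline consumes four plain-table inputs: a binary dominant-marker
matrix (band presence/absence per individual and locus), quantitative trait
data (individual-level or per-population summaries), a site table with
coordinates, and a per-site environmental-variable table.  Everything is
CSV/TSV with a header row; missing cells stay missing and are never imputed.

Coordinates may be given in degrees-minutes-seconds (as printed in field
tables for southern-hemisphere sites) and are converted to signed decimal
degrees, south and west negative.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pstfst")

__all__ = [
    "MarkerMatrix",
    "TraitObservations",
    "TraitSummary",
    "SiteTable",
    "DistanceMatrix",
    "parse_dms",
    "format_dms",
    "read_marker_matrix",
    "write_marker_matrix",
    "read_trait_observations",
    "read_trait_summary",
    "read_site_table",
    "read_env_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_report",
    "configure_logging",
]


def configure_logging(level: str = "INFO") -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level.upper())


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MarkerMatrix:
    """Binary band matrix (individuals x loci) with population labels.

    ``bands`` is a float array with values 0.0 (band absent), 1.0 (band
    present) or NaN (not scored).  Band absence is the recessive homozygote
    phenotype at a dominant locus.
    """

    individual_ids: list[str]
    population_labels: list[str]
    locus_ids: list[str]
    bands: np.ndarray

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        n_ind, n_loci = self.bands.shape
        if len(self.individual_ids) != n_ind or len(self.population_labels) != n_ind:
            raise ValueError("individual ids / population labels do not match matrix rows")
        if len(self.locus_ids) != n_loci:
            raise ValueError("locus ids do not match matrix columns")
        if len(set(self.individual_ids)) != n_ind:
            dupes = {i for i in self.individual_ids if self.individual_ids.count(i) > 1}
            raise ValueError(f"duplicated individual id(s): {sorted(dupes)}")
        bad = ~(np.isnan(self.bands) | (self.bands == 0) | (self.bands == 1))
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"non-binary marker cell at individual {self.individual_ids[r]!r}, "
                f"locus {self.locus_ids[c]!r}: {self.bands[r, c]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return self.bands.shape[0]

    @property
    def n_loci(self) -> int:
        return self.bands.shape[1]

    @property
    def populations(self) -> list[str]:
        """Unique population labels in order of first appearance."""
        return list(dict.fromkeys(self.population_labels))

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for label in self.population_labels:
            sizes[label] = sizes.get(label, 0) + 1
        return sizes

    def subset_loci(self, keep: Sequence[str] | Sequence[int]) -> "MarkerMatrix":
        if len(keep) and isinstance(keep[0], str):
            index = [self.locus_ids.index(k) for k in keep]
        else:
            index = list(keep)  # type: ignore[arg-type]
        return MarkerMatrix(
            individual_ids=list(self.individual_ids),
            population_labels=list(self.population_labels),
            locus_ids=[self.locus_ids[i] for i in index],
            bands=self.bands[:, index].copy(),
        )

    def relabelled(self, mapping: Mapping[str, str]) -> "MarkerMatrix":
        return MarkerMatrix(
            individual_ids=list(self.individual_ids),
            population_labels=[mapping.get(p, p) for p in self.population_labels],
            locus_ids=list(self.locus_ids),
            bands=self.bands.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.bands, columns=self.locus_ids)
        df.insert(0, "population", self.population_labels)
        df.insert(0, "individual", self.individual_ids)
        return df


@dataclass
class TraitObservations:
    """Individual-level trait values (individuals x traits), NaN = missing."""

    individual_ids: list[str]
    population_labels: list[str]
    trait_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.individual_ids), -1)
        if self.values.shape != (len(self.individual_ids), len(self.trait_names)):
            raise ValueError("trait value matrix shape does not match ids/names")
        if len(self.population_labels) != len(self.individual_ids):
            raise ValueError("population labels do not match individuals")

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.population_labels))

    def groups(self, trait: str) -> dict[str, np.ndarray]:
        """Non-missing values of ``trait`` keyed by population."""
        j = self.trait_names.index(trait)
        labels = np.asarray(self.population_labels)
        out: dict[str, np.ndarray] = {}
        for pop in self.populations:
            v = self.values[labels == pop, j]
            v = v[~np.isnan(v)]
            if v.size:
                out[pop] = v
        return out

    def to_summary(self) -> "TraitSummary":
        rows = []
        for trait in self.trait_names:
            for pop, v in self.groups(trait).items():
                sd = float(np.std(v, ddof=1)) if v.size > 1 else np.nan
                rows.append((pop, trait, float(np.mean(v)), sd, int(v.size)))
        df = pd.DataFrame(rows, columns=["population", "trait", "mean", "sd", "n"])
        return TraitSummary.from_frame(df)


@dataclass
class TraitSummary:
    """Per population x trait summaries: mean, sample SD and N.

    Cells may be NA (trait not measured in that population); such
    populations are dropped trait-wise by downstream variance partitioning.
    """

    populations: list[str]
    trait_names: list[str]
    mean: np.ndarray  # pops x traits
    sd: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.populations), len(self.trait_names))
        for name in ("mean", "sd", "n"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} array shape {arr.shape} != {shape}")
            setattr(self, name, arr)
        with np.errstate(invalid="ignore"):
            if np.any(self.sd < 0):
                raise ValueError("negative standard deviation")
            present = ~np.isnan(self.mean)
            if np.any(self.n[present] < 1):
                raise ValueError("n < 1 where a mean is present")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TraitSummary":
        pops = list(dict.fromkeys(df["population"].astype(str)))
        traits = list(dict.fromkeys(df["trait"].astype(str)))
        shape = (len(pops), len(traits))
        mean = np.full(shape, np.nan)
        sd = np.full(shape, np.nan)
        n = np.full(shape, np.nan)
        for _, row in df.iterrows():
            i, j = pops.index(str(row["population"])), traits.index(str(row["trait"]))
            mean[i, j] = row["mean"]
            sd[i, j] = row["sd"]
            n[i, j] = row["n"]
        return cls(pops, traits, mean, sd, n)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, trait in enumerate(self.trait_names):
            for i, pop in enumerate(self.populations):
                if not np.isnan(self.mean[i, j]):
                    rows.append((pop, trait, self.mean[i, j], self.sd[i, j], int(self.n[i, j])))
        return pd.DataFrame(rows, columns=["population", "trait", "mean", "sd", "n"])

    def trait_table(self, trait: str) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
        """(populations, means, sds, ns) for one trait, NA populations dropped."""
        j = self.trait_names.index(trait)
        keep = ~np.isnan(self.mean[:, j])
        pops = [p for p, k in zip(self.populations, keep) if k]
        return pops, self.mean[keep, j], self.sd[keep, j], self.n[keep, j]


@dataclass
class SiteTable:
    """Sampling sites: population code, labels and signed decimal coordinates."""

    population_codes: list[str]
    latitude: np.ndarray
    longitude: np.ndarray
    variety: list[str] = field(default_factory=list)
    ecoregion: list[str] = field(default_factory=list)
    sample_size: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.latitude = np.asarray(self.latitude, dtype=float)
        self.longitude = np.asarray(self.longitude, dtype=float)
        if len(set(self.population_codes)) != len(self.population_codes):
            raise ValueError("population codes are not unique")
        if (np.abs(self.latitude) > 90).any():
            raise ValueError("latitude outside [-90, 90]")
        if (np.abs(self.longitude) > 180).any():
            raise ValueError("longitude outside [-180, 180]")
        if not self.variety:
            self.variety = [""] * len(self.population_codes)
        if not self.ecoregion:
            self.ecoregion = [""] * len(self.population_codes)

    def __len__(self) -> int:
        return len(self.population_codes)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "population": self.population_codes,
                "variety": self.variety,
                "ecoregion": self.ecoregion,
                "lat": self.latitude,
                "lon": self.longitude,
            }
        )
        if self.sample_size is not None:
            df["n"] = self.sample_size
        return df


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != k:
            raise ValueError("duplicate labels")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-8):
            raise ValueError("diagonal is not zero")
        if np.nanmin(self.values) < -1e-8:
            raise ValueError("negative distances")
        # normalise representation
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def condensed(self) -> np.ndarray:
        """Strict lower triangle as a flat vector (row-major)."""
        i, j = np.tril_indices(len(self.labels), k=-1)
        return self.values[i, j]

    def reordered(self, labels: Sequence[str]) -> "DistanceMatrix":
        index = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(index, index)], self.units)


# ---------------------------------------------------------------------------
# DMS coordinate parsing
# ---------------------------------------------------------------------------

_DMS_RE = re.compile(
    r"""^\s*
        (?P<deg>\d+(?:\.\d+)?)\s*[°º]\s*
        (?:(?P<min>\d+(?:\.\d+)?)\s*[′'’]\s*)?
        (?:(?P<sec>\d+(?:\.\d+)?)\s*[″"”]\s*)?
        (?P<hemi>[NSEWnsew])?\s*$""",
    re.VERBOSE,
)


def parse_dms(text: str, hemisphere: str | None = None) -> float:
    """Parse ``D°M′S″`` (tolerant of quote-glyph variants and internal
    spaces) into signed decimal degrees; S/W hemisphere negates.

    The hemisphere may be a trailing letter in the string or passed
    explicitly; an explicit argument wins.
    """
    m = _DMS_RE.match(text)
    if m is None:
        raise ValueError(f"malformed DMS coordinate: {text!r}")
    deg = float(m.group("deg"))
    minutes = float(m.group("min") or 0.0)
    seconds = float(m.group("sec") or 0.0)
    if deg > 180:
        raise ValueError(f"degrees out of range in {text!r}: {deg}")
    if not 0 <= minutes < 60:
        raise ValueError(f"minutes out of range in {text!r}: {minutes}")
    if not 0 <= seconds < 60:
        raise ValueError(f"seconds out of range in {text!r}: {seconds}")
    hemi = (hemisphere or m.group("hemi") or "").upper()
    if hemi not in ("", "N", "S", "E", "W"):
        raise ValueError(f"unknown hemisphere {hemi!r}")
    value = deg + minutes / 60.0 + seconds / 3600.0
    if hemi in ("S", "W"):
        value = -value
    return value


def format_dms(value: float, axis: str = "lat") -> str:
    """Format signed decimal degrees back to ``D°M′S″H``; inverse of parse_dms."""
    hemi = ("S" if value < 0 else "N") if axis == "lat" else ("W" if value < 0 else "E")
    # integer nano-arcseconds so rounding can never produce 60.0" or 60'
    nanosec = round(abs(value) * 3600 * 1e9)
    deg, rem = divmod(nanosec, 3600 * 10**9)
    minutes, rem = divmod(rem, 60 * 10**9)
    seconds = rem / 1e9
    return f"{deg}°{minutes}′{seconds:.9f}″{hemi}"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_marker_matrix(path: str | Path) -> MarkerMatrix:
    df = pd.read_csv(path, sep=_sep_for(path))
    if "individual" not in df.columns or "population" not in df.columns:
        raise ValueError("marker file must have 'individual' and 'population' columns")
    loci = [c for c in df.columns if c not in ("individual", "population")]
    mm = MarkerMatrix(
        individual_ids=[str(x) for x in df["individual"]],
        population_labels=[str(x) for x in df["population"]],
        locus_ids=loci,
        bands=df[loci].to_numpy(dtype=float),
    )
    logger.info("read marker matrix: %d individuals x %d loci, %d populations",
                mm.n_individuals, mm.n_loci, len(mm.populations))
    return mm


def write_marker_matrix(markers: MarkerMatrix, path: str | Path) -> None:
    df = markers.to_frame()
    loci = markers.locus_ids
    # keep 0/1 integer-looking cells, blank for missing
    df[loci] = df[loci].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_trait_observations(path: str | Path) -> TraitObservations:
    df = pd.read_csv(path, sep=_sep_for(path))
    traits = [c for c in df.columns if c not in ("individual", "population")]
    if df.empty:
        logger.warning("empty trait file %s", path)
    obs = TraitObservations(
        individual_ids=[str(x) for x in df.get("individual", pd.Series(dtype=str))],
        population_labels=[str(x) for x in df.get("population", pd.Series(dtype=str))],
        trait_names=traits,
        values=df[traits].to_numpy(dtype=float).reshape(len(df), len(traits)),
    )
    return obs


def read_trait_summary(path: str | Path) -> TraitSummary:
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"population", "trait", "mean", "sd", "n"}
    if not required.issubset(df.columns):
        raise ValueError(f"trait summary file needs columns {sorted(required)}")
    return TraitSummary.from_frame(df)


def read_site_table(path: str | Path) -> SiteTable:
    df = pd.read_csv(path, sep=_sep_for(path))
    if {"lat", "lon"}.issubset(df.columns):
        lat = df["lat"].astype(float).to_numpy()
        lon = df["lon"].astype(float).to_numpy()
    elif {"lat_dms", "lon_dms"}.issubset(df.columns):
        lat = np.array([parse_dms(s) for s in df["lat_dms"]])
        lon = np.array([parse_dms(s) for s in df["lon_dms"]])
    else:
        raise ValueError("site file needs lat/lon or lat_dms/lon_dms columns")
    return SiteTable(
        population_codes=[str(x) for x in df["population"]],
        latitude=lat,
        longitude=lon,
        variety=[str(x) for x in df["variety"]] if "variety" in df else [],
        ecoregion=[str(x) for x in df["ecoregion"]] if "ecoregion" in df else [],
        sample_size=df["n"].to_numpy() if "n" in df else None,
    )


def read_env_table(path: str | Path) -> pd.DataFrame:
    """Per-site environmental variables, indexed by population code."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if "population" not in df.columns:
        raise ValueError("environmental table needs a 'population' column")
    return df.set_index("population")


def read_distance_matrix(path: str | Path, units: str = "") -> DistanceMatrix:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    labels = [str(c) for c in df.columns]
    if labels != [str(i) for i in df.index]:
        raise ValueError("distance matrix row and column labels differ")
    return DistanceMatrix(labels, df.to_numpy(dtype=float), units)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels).to_csv(
        path, sep=_sep_for(path)
    )


def load_dataset(
    marker_path: str | Path | None = None,
    trait_path: str | Path | None = None,
    site_path: str | Path | None = None,
    env_path: str | Path | None = None,
    trait_kind: str = "auto",
):
    """Load and validate whichever inputs are given.

    ``trait_kind`` selects the trait dialect: ``individual``, ``summary`` or
    ``auto`` (sniff the header for the summary columns).
    Returns (markers, traits, sites, env) with None for absent inputs.
    """
    markers = read_marker_matrix(marker_path) if marker_path else None
    traits = None
    if trait_path:
        if trait_kind == "auto":
            head = pd.read_csv(trait_path, sep=_sep_for(trait_path), nrows=0)
            trait_kind = (
                "summary"
                if {"mean", "sd", "n", "trait"}.issubset(head.columns)
                else "individual"
            )
        traits = (
            read_trait_summary(trait_path)
            if trait_kind == "summary"
            else read_trait_observations(trait_path)
        )
    sites = read_site_table(site_path) if site_path else None
    env = read_env_table(env_path) if env_path else None
    if markers is not None and traits is not None:
        trait_pops = set(
            traits.populations if isinstance(traits, TraitObservations) else traits.populations
        )
        unknown = trait_pops - set(markers.populations)
        if unknown:
            raise ValueError(f"trait populations not in marker data: {sorted(unknown)}")
    return markers, traits, sites, env


# ---------------------------------------------------------------------------
# Report writer
# ---------------------------------------------------------------------------

def _round_sig(x, sig: int = 6):
    if isinstance(x, float):
        if np.isnan(x):
            return None
        if np.isinf(x):
            return "inf" if x > 0 else "-inf"
        return float(f"{x:.{sig}g}")
    if isinstance(x, (np.floating,)):
        return _round_sig(float(x), sig)
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, dict):
        return {k: _round_sig(v, sig) for k, v in x.items()}
    if isinstance(x, (list, tuple, np.ndarray)):
        return [_round_sig(v, sig) for v in np.asarray(x).tolist()] if isinstance(x, np.ndarray) else [
            _round_sig(v, sig) for v in x
        ]
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return _round_sig(dataclasses.asdict(x), sig)
    return x


def write_report(results: Mapping[str, object], out_path: str | Path,
                 fmt: str = "json", seed: int | None = None) -> Path:
    """Serialize a results bundle deterministically.

    JSON gets all sections plus a metadata block (package version, seed);
    TSV expects each section to be a DataFrame or a list of flat dicts and
    writes one file per section next to ``out_path``.  Numbers carry six
    significant digits.
    """
    if not results:
        raise ValueError("results bundle is empty")
    from . import __version__

    out_path = Path(out_path)
    meta = {"package": "pstfst", "version": __version__, "seed": seed}
    if fmt == "json":
        payload = {"metadata": meta}
        for key in results:
            value = results[key]
            if isinstance(value, pd.DataFrame):
                value = value.to_dict(orient="records")
            payload[key] = _round_sig(value)
        out_path.write_text(json.dumps(payload, indent=1, sort_keys=False) + "\n")
        return out_path
    if fmt == "tsv":
        out_path.mkdir(parents=True, exist_ok=True)
        for key, value in results.items():
            df = value if isinstance(value, pd.DataFrame) else pd.DataFrame(value)
            df = df.map(lambda v: _round_sig(v) if isinstance(v, float) else v)
            df.to_csv(out_path / f"{key}.tsv", sep="\t", index=False)
        (out_path / "metadata.json").write_text(json.dumps(meta, indent=1) + "\n")
        return out_path
    raise ValueError(f"unknown report format {fmt!r}")
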
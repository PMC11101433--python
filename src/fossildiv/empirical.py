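"""Empirical fossil occurrence tables and scenario-constrained training
configurations.

Occurrence CSVs (taxon, locality name or coordinates, region, min/max age
in Ma) are validated, localities are derived (a named locality, or a
unique combination of rounded coordinates and age range), occurrence ages
are randomised uniformly within their locality's age range across
replicates, and the binned result feeds the same feature extraction as
simulated records.

Two scenario presets mirror published case studies: a Late Permian-Early
Jurassic marine record (six regions, 11 geological stages, elevated mass
extinction probability, clades already diverse at the frame start) and
Cenozoic proboscideans (five regions with drawn arrival windows outside
Africa, 69 bins over 66 Myr, survival constrained to 3-30 extant
species).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bd import BDConfig, TimeBins
from .biogeo import RegionConfig
from .features import FeatureMatrix
from .fossil import FossilRecord, LocalityGrid
from .simulate import SimulationConfig

__all__ = [
    "OccurrenceTable",
    "ScenarioConfig",
    "read_occurrences",
    "derive_localities",
    "randomize_ages",
    "bin_occurrences",
    "scenario_config",
    "feature_overlap_report",
    "MARINE_STAGE_EDGES",
    "MARINE_REGIONS",
    "PROBOSCIDEA_REGIONS",
]

CANONICAL_COLUMNS = ("taxon", "locality", "lat", "lon", "region",
                     "min_ma", "max_ma")

# 11 geological stages, Wuchiapingian (259.51 Ma) to end Sinemurian (192.9 Ma)
MARINE_STAGE_EDGES = np.asarray([
    259.51, 254.14, 251.902, 251.2, 247.2, 242.0,
    237.0, 227.0, 208.5, 201.4, 199.3, 192.9,
])
MARINE_STAGE_NAMES = [
    "Wuchiapingian", "Changhsingian", "Induan", "Olenekian", "Anisian",
    "Ladinian", "Carnian", "Norian", "Rhaetian", "Hettangian", "Sinemurian",
]
MARINE_REGIONS = [
    "South Panthalassic", "North Panthalassic", "Boreal",
    "Tangaroan", "West Circumtethys", "East Circumtethys",
]
PROBOSCIDEA_REGIONS = ["Africa", "Europe", "Asia", "North America",
                       "South America"]


@dataclass
class OccurrenceTable:
    """Validated empirical occurrence rows plus row-level diagnostics."""

    data: pd.DataFrame
    regions: list[str]
    n_dropped: int = 0
    errors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)


def read_occurrences(path, column_map: dict[str, str],
                     regions: list[str] | None = None) -> OccurrenceTable:
    """Read and validate an occurrence CSV.

    ``column_map`` maps canonical names (taxon, locality, lat, lon,
    region, min_ma, max_ma) to the file's column names; locality or a
    lat/lon pair must be mapped.  Rows with missing taxon or unparseable
    ages are dropped with a diagnostic; rows with min_ma > max_ma or an
    undeclared region are rejected likewise.
    """
    raw = pd.read_csv(path)
    unknown = set(column_map) - set(CANONICAL_COLUMNS)
    if unknown:
        raise ValueError(f"unknown canonical columns: {sorted(unknown)}")
    for need in ("taxon", "region", "min_ma", "max_ma"):
        if need not in column_map:
            raise ValueError(f"column_map must map {need!r}")
    if "locality" not in column_map and not {"lat", "lon"} <= set(column_map):
        raise ValueError("column_map must map 'locality' or both 'lat' and 'lon'")
    df = pd.DataFrame({k: raw[v] for k, v in column_map.items()})
    for c in ("min_ma", "max_ma", "lat", "lon"):
        if c in df:
            df[c] = pd.to_numeric(df[c], errors="coerce")

    errors: list[str] = []
    bad = df["taxon"].isna() | df["min_ma"].isna() | df["max_ma"].isna()
    for i in df.index[bad]:
        errors.append(f"row {i}: missing taxon or unparseable age")
    swapped = ~bad & (df["min_ma"] > df["max_ma"])
    for i in df.index[swapped]:
        errors.append(
            f"row {i}: min age {df.at[i, 'min_ma']} exceeds max age "
            f"{df.at[i, 'max_ma']}"
        )
    bad |= swapped
    region_list = regions if regions is not None else \
        sorted(df.loc[~bad, "region"].dropna().unique().tolist())
    unknown_region = ~bad & ~df["region"].isin(region_list)
    for i in df.index[unknown_region]:
        errors.append(f"row {i}: unknown region {df.at[i, 'region']!r}")
    bad |= unknown_region
    return OccurrenceTable(
        data=df[~bad].reset_index(drop=True),
        regions=list(region_list),
        n_dropped=int(bad.sum()),
        errors=errors,
    )


def derive_localities(table: OccurrenceTable,
                      coord_precision: int = 2) -> OccurrenceTable:
    """Attach a ``locality_id`` column: the provided locality name when
    present, otherwise the key (rounded coordinates, min age, max age);
    duplicate (taxon, locality) rows collapse to one occurrence.
    Deterministic and idempotent."""
    df = table.data.copy()
    errors = list(table.errors)
    has_name = df["locality"].notna() if "locality" in df else \
        pd.Series(False, index=df.index)
    has_coord = (df["lat"].notna() & df["lon"].notna()) \
        if {"lat", "lon"} <= set(df.columns) else pd.Series(False, index=df.index)
    bad = ~has_name & ~has_coord
    for i in df.index[bad]:
        errors.append(f"row {i}: neither locality name nor coordinates")
    df = df[~bad].copy()
    has_name = has_name[~bad]

    def _key(row, named: bool) -> str:
        if named:
            return f"L:{row['locality']}|{row['min_ma']}|{row['max_ma']}"
        return (f"C:{round(row['lat'], coord_precision)}"
                f",{round(row['lon'], coord_precision)}"
                f"|{row['min_ma']}|{row['max_ma']}")

    df["locality_id"] = [
        _key(row, named) for (_, row), named in zip(df.iterrows(), has_name)
    ]
    df = df.drop_duplicates(["taxon", "locality_id"]).reset_index(drop=True)
    return OccurrenceTable(df, table.regions,
                           table.n_dropped + int(bad.sum()), errors)


def randomize_ages(table: OccurrenceTable, n_replicates: int,
                   rng: np.random.Generator) -> list[pd.DataFrame]:
    """Per replicate, draw one age per locality uniformly inside its
    [min, max] range; all occurrences of a locality share that age."""
    if "locality_id" not in table.data:
        raise ValueError("derive localities before randomizing ages")
    df = table.data
    locs = df.drop_duplicates("locality_id")[["locality_id", "min_ma", "max_ma"]]
    out = []
    for _ in range(n_replicates):
        ages = rng.uniform(locs["min_ma"].to_numpy(), locs["max_ma"].to_numpy())
        age_of = dict(zip(locs["locality_id"], ages))
        rep = df.copy()
        rep["age"] = rep["locality_id"].map(age_of)
        out.append(rep)
    return out


def bin_occurrences(aged: pd.DataFrame, bins: TimeBins,
                    regions: list[str]) -> FossilRecord:
    """Bin an age-resolved table into a FossilRecord-compatible structure.

    Rows with ages outside the binned frame are dropped (counted); the
    locality grid holds the number of distinct localities per (region,
    bin) cell, and occurrences are unique (taxon, region, bin, locality).
    """
    df = aged.copy()
    in_frame = (df["age"] <= bins.edges[0]) & (df["age"] >= bins.edges[-1])
    df = df[in_frame].copy()
    if not len(df):
        import warnings

        warnings.warn("no occurrences fall inside the binned time frame",
                      stacklevel=2)
    # age x belongs to the bin whose (young, old] interval contains it
    df["bin"] = np.clip(
        np.searchsorted(-bins.edges, -df["age"].to_numpy(), side="right") - 1,
        0, bins.n - 1,
    )
    region_idx = {r: i for i, r in enumerate(regions)}
    df["region_i"] = df["region"].map(region_idx)
    taxa = sorted(df["taxon"].unique())
    taxon_idx = {t: i for i, t in enumerate(taxa)}
    df["species_i"] = df["taxon"].map(taxon_idx)

    A, T = len(regions), bins.n
    l_at = np.zeros((A, T), dtype=int)
    loc_rows = []
    for (a, t), grp in df.groupby(["region_i", "bin"]):
        locs = {lid: j for j, lid in enumerate(sorted(grp["locality_id"].unique()))}
        l_at[int(a), int(t)] = len(locs)
        loc_rows.append(grp["locality_id"].map(locs))
    df["locality_i"] = pd.concat(loc_rows) if loc_rows else 0
    df = df.drop_duplicates(["species_i", "region_i", "bin", "locality_i"])
    return FossilRecord(
        species=df["species_i"].to_numpy(int),
        region=df["region_i"].to_numpy(int),
        bin=df["bin"].to_numpy(int),
        locality=df["locality_i"].to_numpy(int),
        grid=LocalityGrid(lambda_at=l_at.astype(float), l_at=l_at),
        n_species=len(taxa),
        n_regions=A,
        n_bins=T,
    )


@dataclass
class ScenarioConfig:
    """Named constraint bundle for scenario-matched training simulations.

    Simulations run on an internal clock whose zero is the young end of
    the study frame (``age_offset`` Ma before the true present); bins_ma
    are the true-age bins used to bin empirical occurrences, and
    ``sim.bins`` are the same bins shifted onto the simulation clock.
    """

    name: str
    sim: SimulationConfig
    bins_ma: TimeBins
    region_names: list[str]
    age_offset: float = 0.0
    n_train: int = 150_000
    n_test: int = 1_000

    def __post_init__(self) -> None:
        if not np.allclose(self.sim.bins.edges,
                           self.bins_ma.edges - self.age_offset):
            raise ValueError("simulation bins must be the Ma bins shifted by "
                             "the age offset")


def scenario_config(name: str) -> ScenarioConfig:
    """Frozen presets: ``marine_pt`` or ``proboscidea``."""
    if name == "marine_pt":
        offset = float(MARINE_STAGE_EDGES[-1])
        bins_ma = TimeBins(MARINE_STAGE_EDGES, labels=MARINE_STAGE_NAMES)
        span = float(MARINE_STAGE_EDGES[0] - offset)
        sim = SimulationConfig(
            bd=BDConfig(
                t_origin_range=(span, span),
                p_mass_extinction=0.029,
                n_start_range=(100, 1000),
                extant_range=(100, np.inf),
            ),
            regions=RegionConfig(n_regions=6, region_names=MARINE_REGIONS),
            bins=TimeBins(MARINE_STAGE_EDGES - offset,
                          labels=MARINE_STAGE_NAMES),
        )
        return ScenarioConfig(name=name, sim=sim, bins_ma=bins_ma,
                              region_names=MARINE_REGIONS, age_offset=offset)
    if name == "proboscidea":
        bins_ma = TimeBins(np.linspace(66.0, 0.0, 70))
        sim = SimulationConfig(
            bd=BDConfig(
                t_origin_range=(40.0, 66.0),
                n_start_range=(1, 1),
                extant_range=(3, 30),
            ),
            regions=RegionConfig(n_regions=5,
                                 region_names=PROBOSCIDEA_REGIONS),
            bins=bins_ma,
            opening_windows=[
                None,  # Africa: occupiable throughout
                (33.9, 27.0),  # Europe
                (33.9, 27.0),  # Asia
                (20.0, 16.0),  # North America
                (5.3, 0.8),  # South America
            ],
        )
        return ScenarioConfig(name=name, sim=sim, bins_ma=bins_ma,
                              region_names=PROBOSCIDEA_REGIONS)
    raise ValueError(f"unknown scenario {name!r}")


def feature_overlap_report(simulated: list[FeatureMatrix],
                           empirical: FeatureMatrix
                           ) -> tuple[pd.DataFrame, float]:
    """Per feature, the fraction of empirical bins falling inside the
    simulated min-max envelope; plus the overall containment fraction.

    A trained model can only be trusted on empirical data whose features
    lie within the range its training corpus explored.
    """
    if not simulated:
        raise ValueError("need at least one simulated feature matrix")
    for fm in simulated:
        if list(fm.names) != list(empirical.names):
            raise ValueError("feature names of simulated and empirical data differ")
    stack = np.stack([fm.matrix for fm in simulated])  # (N, T, F)
    lo, hi = stack.min(axis=0), stack.max(axis=0)
    inside = (empirical.matrix >= lo) & (empirical.matrix <= hi)
    df = pd.DataFrame({
        "feature": empirical.names,
        "fraction_contained": inside.mean(axis=0),
        "n_bins_outside": (~inside).sum(axis=0),
    })
    return df, float(inside.mean())
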
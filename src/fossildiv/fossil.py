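"""Degrade a simulated clade into an incomplete, biased fossil record.

Sampling happens in two layers.  First, fossiliferous localities are
placed per (region, time-bin) cell: the expected count is

    lambda_at = r_a * q_t * z_at * eps_at * Delta_t

with a gamma-distributed region rate r_a scaled by region size, a
time-varying rate q_t (log-linear trend toward the present, or piecewise
constant with Poisson-many shifts), Bernoulli gaps z_at, log-uniform
random effects eps_at, and the bin duration; the realized count l_at is
Poisson.  Second, each species alive in the cell enters each of the l_at
localities independently with probability p_s = 1 - exp(-psi_s), where
psi_s is a gamma-distributed species preservation rate.  (Entering each
locality independently with probability p_s is distributionally identical
to drawing Bin(l_at, p_s) occupied localities and placing them uniformly
without replacement.)

Named multipliers on regions, time frames and a bimodal preservation
mixture implement the spatial / temporal / taxonomic stress presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bd import CladeHistory, TimeBins
from .biogeo import RegionalSystem, SpeciesRange

__all__ = [
    "SamplingConfig",
    "SamplingModel",
    "LocalityGrid",
    "FossilRecord",
    "CompletenessStats",
    "draw_sampling_model",
    "realize_localities",
    "sample_fossils",
    "completeness_stats",
    "presence_matrix",
]


@dataclass
class SamplingConfig:
    """Hyperpriors of the sampling model; one realization per dataset."""

    alpha_r: float = 1.5  # gamma shape of the region rate
    beta_r: float = 1.5  # gamma rate of the region rate
    pattern: str = "random"  # "random" | "trend" | "shifts"
    # present-day locality rate per region per Myr, log-uniform; spans the
    # sparse-to-dense range seen in compiled occurrence archives
    q0_range: tuple[float, float] = (0.5, 20.0)
    zeta_range: tuple[float, float] = (-0.02, 0.0)  # log-linear trend slope
    sigma_range: tuple[float, float] = (0.1, 1.0)  # log-normal spread of q_t
    n_q_shift_mean: float = 4.0
    p_gap_range: tuple[float, float] = (0.0, 0.3)
    eta: float = 1.0  # median of the cell random effect
    b_range: tuple[float, float] = (1.5, 5.0)  # spread of the random effect
    psi_shape_range: tuple[float, float] = (0.5, 2.0)
    psi_mean_range: tuple[float, float] = (0.05, 2.0)  # log-uniform mean psi
    # stress presets
    bimodal_preservation: tuple[float, float, float] | None = None  # (lo, hi, w_hi)
    region_multipliers: np.ndarray | None = None
    time_multipliers: list[tuple[float, float, float]] | None = None  # (old, young, x)

    def __post_init__(self) -> None:
        for name in ("alpha_r", "beta_r", "eta", "n_q_shift_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pattern not in ("random", "trend", "shifts"):
            raise ValueError("pattern must be 'random', 'trend' or 'shifts'")
        if self.zeta_range[1] > 0:
            raise ValueError("zeta must be <= 0 (constant or decreasing back in time)")
        if not (0.0 <= self.p_gap_range[0] <= self.p_gap_range[1] < 1.0):
            raise ValueError("p_gap must lie in [0, 1)")
        if self.b_range[0] <= 1.0:
            raise ValueError("random-effect spread b must be > 1")


@dataclass
class SamplingModel:
    """One realization of the sampling process for a specific dataset."""

    r_a: np.ndarray  # region rates, length A
    q_t: np.ndarray  # per-bin temporal rates, length T
    z_at: np.ndarray  # gap indicators (A, T)
    eps_at: np.ndarray  # random effects (A, T)
    psi: np.ndarray  # per-species preservation rates, length S
    pattern: str
    params: dict = field(default_factory=dict)

    @property
    def p_species(self) -> np.ndarray:
        """Per-locality detection probability p_s = 1 - exp(-psi_s)."""
        if np.any(self.psi < 0):
            raise ValueError("preservation rates must be >= 0")
        return -np.expm1(-self.psi)


@dataclass
class LocalityGrid:
    """Expected and realized locality counts per (region, bin) cell."""

    lambda_at: np.ndarray  # (A, T) expected counts
    l_at: np.ndarray  # (A, T) realized Poisson counts

    def __post_init__(self) -> None:
        if np.any(self.lambda_at < 0):
            raise ValueError("expected locality counts must be >= 0")
        if np.any(self.l_at < 0) or not np.issubdtype(self.l_at.dtype, np.integer):
            raise ValueError("realized locality counts must be non-negative integers")


@dataclass
class FossilRecord:
    """Occurrence table (species-locality presences) plus the locality grid.

    One row per (species, region, bin, locality) presence; multiple
    specimens of a species at one locality collapse to a single occurrence.
    """

    species: np.ndarray
    region: np.ndarray
    bin: np.ndarray
    locality: np.ndarray  # locality index within the (region, bin) cell
    grid: LocalityGrid
    n_species: int
    n_regions: int
    n_bins: int

    @property
    def n_occurrences(self) -> int:
        return self.species.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "region": self.region,
                "bin": self.bin,
                "locality": self.locality,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _draw_q_t(config: SamplingConfig, bins: TimeBins,
              rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    pattern = config.pattern
    if pattern == "random":
        pattern = "trend" if rng.random() < 0.5 else "shifts"
    q0 = np.exp(rng.uniform(*np.log(config.q0_range)))
    sigma = rng.uniform(*config.sigma_range)
    mids = bins.midpoints
    if pattern == "trend":
        zeta = rng.uniform(*config.zeta_range)
        log_q = rng.normal(np.log(q0) + zeta * mids, sigma)
    else:
        zeta = 0.0
        n_shift = rng.poisson(config.n_q_shift_mean)
        shift_ages = np.sort(rng.uniform(bins.edges[-1], bins.edges[0], n_shift))[::-1]
        seg_log_q = rng.normal(np.log(q0), sigma, size=n_shift + 1)
        seg = np.searchsorted(-shift_ages, -mids, side="right")
        log_q = seg_log_q[seg]
    return np.exp(log_q), {"pattern": pattern, "q0": q0, "zeta": zeta, "sigma": sigma}


def draw_sampling_model(config: SamplingConfig, system: RegionalSystem,
                        n_species: int, bins: TimeBins,
                        rng: np.random.Generator) -> SamplingModel:
    """Realize region rates, temporal rates, gaps, random effects and
    per-species preservation rates."""
    A, T = system.n_regions, bins.n
    r_a = rng.gamma(config.alpha_r, 1.0 / config.beta_r, size=A) * system.d
    q_t, info = _draw_q_t(config, bins, rng)

    p_gap = rng.uniform(*config.p_gap_range)
    z_at = (rng.random((A, T)) < (1.0 - p_gap)).astype(float)

    b = rng.uniform(*config.b_range)
    m = rng.uniform(np.log(1.0 / b), np.log(b), size=(A, T))
    eps_at = config.eta * np.exp(m)

    shape = rng.uniform(*config.psi_shape_range)
    if config.bimodal_preservation is not None:
        lo, hi, w_hi = config.bimodal_preservation
        high = rng.random(n_species) < w_hi
        mean = np.where(high, hi, lo)
        psi = rng.gamma(shape, mean / shape, size=n_species)
    else:
        mean = np.exp(rng.uniform(*np.log(config.psi_mean_range)))
        psi = rng.gamma(shape, mean / shape, size=n_species)

    info.update({"p_gap": p_gap, "b": b, "psi_shape": shape})
    return SamplingModel(r_a=r_a, q_t=q_t, z_at=z_at, eps_at=eps_at, psi=psi,
                         pattern=info["pattern"], params=info)


def realize_localities(model: SamplingModel, bins: TimeBins,
                       rng: np.random.Generator,
                       config: SamplingConfig | None = None) -> LocalityGrid:
    """Poisson-draw locality counts per cell from the composed rate."""
    lam = (model.r_a[:, None] * model.q_t[None, :] * model.z_at
           * model.eps_at * bins.durations[None, :])
    if config is not None:
        if config.region_multipliers is not None:
            lam = lam * np.asarray(config.region_multipliers, float)[:, None]
        if config.time_multipliers:
            mids = bins.midpoints
            for old, young, factor in config.time_multipliers:
                lam[:, (mids <= old) & (mids > young)] *= factor
    return LocalityGrid(lambda_at=lam, l_at=rng.poisson(lam))


def presence_matrix(clade: CladeHistory, ranges: list[SpeciesRange],
                    system: RegionalSystem, bins: TimeBins) -> np.ndarray:
    """Boolean (S, A, T) array: species alive in bin, in range, region open.

    A species is alive in every bin its lifespan intersects (same rule as
    the true-diversity binning); a region contributes only to bins lying
    entirely after its opening age.
    """
    S, A, T = clade.n_species, system.n_regions, bins.n
    old, young = bins.starts, bins.ends
    alive = (clade.origins[:, None] > young[None, :]) & \
            (clade.extinctions[:, None] <= old[None, :])
    alive[:, -1] = (clade.origins >= young[-1]) & (clade.extinctions <= old[-1])
    in_region = np.zeros((S, A), dtype=bool)
    for rg in ranges:
        in_region[rg.species, rg.regions] = True
    open_at = system.opening_ages[:, None] >= old[None, :]
    return alive[:, None, :] & in_region[:, :, None] & open_at[None, :, :]


def sample_fossils(clade: CladeHistory, ranges: list[SpeciesRange],
                   grid: LocalityGrid, model: SamplingModel, bins: TimeBins,
                   system: RegionalSystem, rng: np.random.Generator) -> FossilRecord:
    """Sample species-locality occurrences for every (region, bin) cell."""
    p_s = model.p_species
    pres = presence_matrix(clade, ranges, system, bins)
    A, T = grid.l_at.shape
    sp_out, rg_out, bn_out, loc_out = [], [], [], []
    for a in range(A):
        for t in range(T):
            l = int(grid.l_at[a, t])
            if l == 0:
                continue
            sp = np.flatnonzero(pres[:, a, t])
            if sp.size == 0:
                continue
            hits = rng.random((sp.size, l)) < p_s[sp][:, None]
            si, li = np.nonzero(hits)
            if si.size:
                sp_out.append(sp[si])
                rg_out.append(np.full(si.size, a))
                bn_out.append(np.full(si.size, t))
                loc_out.append(li)
    cat = (lambda xs: np.concatenate(xs) if xs else np.empty(0, dtype=int))
    return FossilRecord(
        species=cat(sp_out), region=cat(rg_out), bin=cat(bn_out),
        locality=cat(loc_out), grid=grid,
        n_species=clade.n_species, n_regions=A, n_bins=T,
    )


@dataclass
class CompletenessStats:
    """Record-quality covariates of a simulated dataset."""

    completeness: float  # fraction of species with >= 1 occurrence
    preservation_rate: float  # mean occurrences per lineage per bin alive
    n_sampled_species: int
    mean_species_duration: float
    clade_duration: float


def completeness_stats(clade: CladeHistory, record: FossilRecord,
                       bins: TimeBins) -> CompletenessStats:
    n = clade.n_species
    occ_per_species = np.bincount(record.species, minlength=n)
    sampled = occ_per_species > 0
    old, young = bins.starts, bins.ends
    alive = (clade.origins[:, None] > young[None, :]) & \
            (clade.extinctions[:, None] <= old[None, :])
    alive[:, -1] = (clade.origins >= young[-1]) & (clade.extinctions <= old[-1])
    bins_alive = np.maximum(alive.sum(axis=1), 1)
    return CompletenessStats(
        completeness=float(sampled.mean()) if n else 0.0,
        preservation_rate=float(np.mean(occ_per_species / bins_alive)) if n else 0.0,
        n_sampled_species=int(sampled.sum()),
        mean_species_duration=float(np.mean(clade.durations)) if n else 0.0,
        clade_duration=float(clade.params.t_origin),
    )
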
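"""End-to-end dataset generation: clade -> biogeography -> fossil record
-> features, plus corpus assembly and archive I/O.

A "dataset" is one labelled training example: the true binned diversity
trajectory (label) and the feature matrix of the degraded fossil record
(input).  Corpora are regenerable from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bd import (BDConfig, CladeHistory, DiversityTrajectory, TimeBins,
                 bin_diversity, simulate_clade)
from .biogeo import RegionConfig, RegionalSystem, SpeciesRange, assign_all_ranges, \
    draw_regional_system
from .features import FeatureMatrix, FeatureScaler, extract_features
from .fossil import (FossilRecord, SamplingConfig, SamplingModel,
                     draw_sampling_model, realize_localities, sample_fossils)

__all__ = [
    "SimulationConfig",
    "Dataset",
    "generate_dataset",
    "generate_corpus",
    "training_arrays",
    "save_corpus",
    "load_corpus",
]


@dataclass
class SimulationConfig:
    """Full study conditions for one corpus."""

    bd: BDConfig = field(default_factory=BDConfig)
    regions: RegionConfig = field(default_factory=RegionConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    bins: TimeBins = field(default_factory=lambda: TimeBins.regular(100.0, 100))
    # per-region opening-age windows (old, young); an opening age is drawn
    # uniformly inside the window per dataset.  None = always available.
    opening_windows: list[tuple[float, float] | None] | None = None

    def with_bins(self, bins: TimeBins) -> "SimulationConfig":
        return replace(self, bins=bins)

    @classmethod
    def desk_scale(cls) -> "SimulationConfig":
        """Reduced problem size for CPU-scale experiments: 50 one-Myr bins
        with clade origins drawn U[20, 50] Ma; all other priors default."""
        return cls(bd=BDConfig(t_origin_range=(20.0, 50.0)),
                   bins=TimeBins.regular(50.0, 50))


@dataclass
class Dataset:
    """One simulated, labelled example."""

    clade: CladeHistory
    system: RegionalSystem
    ranges: list[SpeciesRange]
    sampling_model: SamplingModel
    record: FossilRecord
    trajectory: DiversityTrajectory
    features: FeatureMatrix | None = None
    seed: int | None = None


def _draw_opening_ages(cfg: SimulationConfig,
                       rng: np.random.Generator) -> np.ndarray | None:
    if cfg.opening_windows is None:
        return None
    ages = np.full(cfg.regions.n_regions, np.inf)
    for i, w in enumerate(cfg.opening_windows):
        if w is not None:
            old, young = w
            ages[i] = rng.uniform(young, old)
    return ages


def generate_dataset(cfg: SimulationConfig, rng: np.random.Generator,
                     with_features: bool = True,
                     seed: int | None = None) -> Dataset:
    """Simulate one complete dataset under the configured conditions."""
    clade = simulate_clade(cfg.bd, rng)
    system = draw_regional_system(cfg.regions, rng,
                                  opening_ages=_draw_opening_ages(cfg, rng))
    ranges = assign_all_ranges(clade, system, rng, bins=cfg.bins)
    model = draw_sampling_model(cfg.sampling, system, clade.n_species,
                                cfg.bins, rng)
    grid = realize_localities(model, cfg.bins, rng, config=cfg.sampling)
    record = sample_fossils(clade, ranges, grid, model, cfg.bins, system, rng)
    trajectory = bin_diversity(clade, cfg.bins)
    features = (extract_features(record, cfg.bins, cfg.regions.n_regions)
                if with_features else None)
    return Dataset(clade, system, ranges, model, record, trajectory,
                   features, seed=seed)


def generate_corpus(cfg: SimulationConfig, n: int, seed: int,
                    with_features: bool = True) -> list[Dataset]:
    """n datasets; dataset i is fully determined by (seed, i)."""
    root = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(root.spawn(n)):
        rng = np.random.default_rng(child)
        out.append(generate_dataset(cfg, rng, with_features=with_features, seed=i))
    return out


def training_arrays(datasets: list[Dataset],
                    scaler: FeatureScaler | None = None
                    ) -> tuple[np.ndarray, np.ndarray, FeatureScaler]:
    """Stack a corpus into (X, y, scaler): normalized features and
    log(x+1) labels.  A scaler fitted elsewhere (e.g. on the training
    corpus) can be reused for validation/test/empirical data."""
    fms = [ds.features for ds in datasets]
    if any(fm is None for fm in fms):
        raise ValueError("datasets must carry extracted features")
    if scaler is None:
        scaler = FeatureScaler().fit(fms)
    X = np.stack([scaler.transform(fm).matrix for fm in fms])
    y = np.stack([ds.trajectory.to_log().counts for ds in datasets])
    return X, y, scaler


def save_corpus(path, datasets: list[Dataset], bins: TimeBins) -> None:
    """Archive features + labels (+ per-dataset quality stats) as .npz."""
    fms = [ds.features for ds in datasets]
    if any(fm is None for fm in fms):
        raise ValueError("datasets must carry extracted features")
    np.savez_compressed(
        path,
        features=np.stack([fm.matrix for fm in fms]),
        labels=np.stack([ds.trajectory.counts for ds in datasets]),
        bin_edges=bins.edges,
        n_regions=np.asarray([fms[0].n_regions]),
        feature_names=np.asarray(fms[0].names),
        seeds=np.asarray([-1 if ds.seed is None else ds.seed for ds in datasets]),
    )


def load_corpus(path) -> tuple[np.ndarray, np.ndarray, TimeBins, list[str], int]:
    """Returns (features (N,T,F), labels (N,T), bins, feature names, A)."""
    with np.load(path, allow_pickle=False) as d:
        return (
            d["features"],
            d["labels"],
            TimeBins(d["bin_edges"]),
            [str(s) for s in d["feature_names"]],
            int(d["n_regions"][0]),
        )
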
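"""Performance metrics, the shareholder quorum subsampling (SQS)
baseline, and generators for the stress-test corpora.

SQS estimates coverage-standardised relative richness per bin: sample
coverage is estimated with Good's u (1 - singletons/occurrences),
occurrences are drawn in random order, and species are counted until the
u-corrected summed frequency of the distinct species drawn reaches the
quorum; the estimate is the trial-averaged species count.  Because
coverage only increases when a new species appears, the draw order of
species' first occurrences is sufficient: the first occurrence of a
species with n tokens among O arrives as the minimum of n uniform keys,
so species order is sampled directly without materialising tokens.

Since SQS estimates *relative* diversity, comparisons against the true
trajectory use the coefficient of determination of the linear fit
(squared Pearson correlation) on untransformed diversity, alongside the
scale-free rMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bd import BDConfig, DivDependenceConfig, MassEventConfig, TimeBins
from .fossil import FossilRecord, SamplingConfig
from .nn import PredictionEnsemble
from .simulate import Dataset, SimulationConfig, generate_corpus

__all__ = [
    "mse",
    "rmse_rescaled",
    "r_squared",
    "pearson_r2",
    "trajectory_r2",
    "trajectory_rmse",
    "coverage_95",
    "sqs_estimate",
    "sqs_trajectory",
    "bin_species_counts",
    "make_biased_testsets",
    "sqs_corpus_metrics",
    "EvalReport",
    "paired_comparison",
    "BIAS_REGIMES",
]


# ---- metrics ---------------------------------------------------------


def mse(truth: np.ndarray, estimate: np.ndarray) -> float:
    truth, estimate = np.asarray(truth, float), np.asarray(estimate, float)
    if truth.shape != estimate.shape:
        raise ValueError("trajectories must have equal length")
    return float(np.mean((truth - estimate) ** 2))


def _minmax(x: np.ndarray) -> np.ndarray | None:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return None
    return (x - lo) / (hi - lo)


def rmse_rescaled(truth: np.ndarray, estimate: np.ndarray) -> float:
    """MSE after independently min-max rescaling both trajectories to
    [0, 1]; NaN when either trajectory is constant (rescaling undefined)."""
    truth, estimate = np.asarray(truth, float), np.asarray(estimate, float)
    if truth.shape != estimate.shape:
        raise ValueError("trajectories must have equal length")
    t, e = _minmax(truth), _minmax(estimate)
    if t is None or e is None:
        return float("nan")
    return float(np.mean((t - e) ** 2))


def r_squared(truth: np.ndarray, estimate: np.ndarray) -> float:
    """1 - SSres/SStot on the raw values; NaN for zero-variance truth."""
    truth, estimate = np.asarray(truth, float), np.asarray(estimate, float)
    if truth.shape != estimate.shape:
        raise ValueError("trajectories must have equal length")
    sstot = float(np.sum((truth - truth.mean()) ** 2))
    if sstot == 0.0:
        return float("nan")
    ssres = float(np.sum((truth - estimate) ** 2))
    return 1.0 - ssres / sstot


def pearson_r2(truth: np.ndarray, estimate: np.ndarray) -> float:
    """Coefficient of determination of the linear fit (squared Pearson
    correlation); the scale-free R2 appropriate for relative estimators."""
    truth, estimate = np.asarray(truth, float), np.asarray(estimate, float)
    if truth.shape != estimate.shape:
        raise ValueError("trajectories must have equal length")
    if truth.std() == 0.0 or estimate.std() == 0.0:
        return float("nan")
    r = np.corrcoef(truth, estimate)[0, 1]
    return float(r * r)


def trajectory_r2(truth: np.ndarray, estimate: np.ndarray) -> float:
    """R2 of a (possibly relative-scale) trajectory estimate over the
    complete binned frame.

    Bins where the estimator is undefined (NaN) count as 0 — an estimator
    that cannot standardise a bin has not recovered its diversity — then
    both curves are min-max rescaled to [0, 1] and 1 - SSres/SStot is
    returned.  NaN when either curve is constant.
    """
    truth, estimate = np.asarray(truth, float), np.asarray(estimate, float)
    if truth.shape != estimate.shape:
        raise ValueError("trajectories must have equal length")
    est = np.where(np.isfinite(estimate), estimate, 0.0)
    t, e = _minmax(truth), _minmax(est)
    if t is None or e is None:
        return float("nan")
    return 1.0 - float(np.sum((t - e) ** 2) / np.sum((t - t.mean()) ** 2))


def trajectory_rmse(truth: np.ndarray, estimate: np.ndarray) -> float:
    """rMSE over the complete frame with undefined bins imputed as 0."""
    estimate = np.asarray(estimate, float)
    return rmse_rescaled(np.asarray(truth, float),
                         np.where(np.isfinite(estimate), estimate, 0.0))


def coverage_95(truth: np.ndarray, ensemble: PredictionEnsemble) -> float:
    """Fraction of bins whose true value lies inside the 95% interval."""
    truth = np.asarray(truth, float)
    lo, hi = ensemble.lower, ensemble.upper
    if truth.shape != lo.shape:
        raise ValueError("truth length must match the ensemble")
    return float(np.mean((truth >= lo) & (truth <= hi)))


# ---- SQS -------------------------------------------------------------


def sqs_estimate(counts, quorum: float, n_trials: int = 100,
                 rng: np.random.Generator | None = None,
                 exclude_dominant: bool = False) -> float:
    """Subsampled richness for one bin from per-species occurrence counts.

    NaN when the bin is empty or its Good's-u coverage falls below the
    quorum (the bin cannot be standardised to that coverage).
    """
    if not 0.0 < quorum < 1.0:
        raise ValueError("quorum must be in (0, 1)")
    counts = np.asarray(counts, float)
    counts = counts[counts > 0]
    if counts.size == 0:
        return float("nan")
    rng = np.random.default_rng() if rng is None else rng
    O = counts.sum()
    n1 = float(np.sum(counts == 1))
    if exclude_dominant:
        O_eff = O - counts.max()
        u = 1.0 - n1 / O_eff if O_eff > 0 else 0.0
    else:
        u = 1.0 - n1 / O
    if u <= 0 or u < quorum:
        return float("nan")
    shares = u * counts / O
    # first-occurrence key of a species with n tokens: min of n uniforms;
    # ascending min-key order == descending order of U^(1/n)
    keys = rng.random((n_trials, counts.size)) ** (1.0 / counts)
    order = np.argsort(-keys, axis=1)
    cum = np.cumsum(shares[order], axis=1)
    richness = np.sum(cum < quorum, axis=1) + 1
    return float(np.mean(np.minimum(richness, counts.size)))


def bin_species_counts(record: FossilRecord) -> list[np.ndarray]:
    """Per bin, the vector of per-species occurrence (locality) counts."""
    out = [np.empty(0)] * record.n_bins
    if record.n_occurrences == 0:
        return out
    df = pd.DataFrame({"b": record.bin, "s": record.species})
    for b, grp in df.groupby("b"):
        out[int(b)] = grp.groupby("s").size().to_numpy(float)
    return out


def sqs_trajectory(record: FossilRecord, quorum: float = 0.6,
                   n_trials: int = 100,
                   rng: np.random.Generator | None = None,
                   exclude_dominant: bool = False) -> np.ndarray:
    """Per-bin SQS richness (NaN where the bin cannot be standardised)."""
    rng = np.random.default_rng() if rng is None else rng
    return np.asarray([
        sqs_estimate(c, quorum, n_trials, rng, exclude_dominant)
        for c in bin_species_counts(record)
    ])


# ---- stress-test corpora ---------------------------------------------

BIAS_REGIMES = ("temporal", "taxonomic", "spatial", "mass_events", "div_dependence")


def biased_config(regime: str,
                  base: SimulationConfig | None = None,
                  disabled: bool = False) -> SimulationConfig:
    """The frozen stress-test preset for one regime.

    temporal: 100-fold variation across four time frames (x0.1 in
    33-22 Ma, x10 in 2-0 Ma); taxonomic: bimodal preservation spanning an
    order of magnitude; spatial: one of five regions sampled at x10, one
    at x0.1; mass_events / div_dependence: the rare-pattern birth-death
    regimes.  ``disabled`` pins all multipliers at 1 (control corpus).
    """
    cfg = base if base is not None else SimulationConfig()
    if regime == "temporal":
        mult = [(33.0, 22.0, 1.0), (2.0, 0.0, 1.0)] if disabled else \
            [(33.0, 22.0, 0.1), (2.0, 0.0, 10.0)]
        return replace(cfg, sampling=replace(cfg.sampling, time_multipliers=mult))
    if regime == "taxonomic":
        bim = None if disabled else (0.05, 0.5, 0.5)
        return replace(cfg, sampling=replace(cfg.sampling,
                                             bimodal_preservation=bim))
    if regime == "spatial":
        if cfg.regions.n_regions != 5:
            cfg = replace(cfg, regions=replace(cfg.regions, n_regions=5))
        mult = np.ones(5) if disabled else np.asarray([10.0, 1.0, 1.0, 1.0, 0.1])
        return replace(cfg, sampling=replace(cfg.sampling,
                                             region_multipliers=mult))
    if regime == "mass_events":
        ms = MassEventConfig() if not disabled else \
            MassEventConfig(p_per_bin=0.0, p_me_per_bin=0.0)
        return replace(cfg, bd=replace(cfg.bd, mass_speciation=ms))
    if regime == "div_dependence":
        return replace(cfg, bd=replace(
            cfg.bd, div_dependence=DivDependenceConfig(),
            t_origin_range=(70.0, 100.0),
        ))
    raise ValueError(f"unknown bias regime {regime!r}; choose from {BIAS_REGIMES}")


def make_biased_testsets(regime: str, n: int, seed: int,
                         base: SimulationConfig | None = None,
                         disabled: bool = False,
                         with_features: bool = True) -> list[Dataset]:
    """Generate a stress-test corpus under the named preset."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = biased_config(regime, base=base, disabled=disabled)
    return generate_corpus(cfg, n, seed, with_features=with_features)


# ---- paired harness --------------------------------------------------


def sqs_dataset_metrics(ds: Dataset, quorum: float, n_trials: int,
                        rng: np.random.Generator,
                        exclude_dominant: bool = False) -> dict:
    """R2 / rMSE of the SQS curve against true diversity for one dataset,
    over the complete binned frame (undefined bins imputed as 0)."""
    est = sqs_trajectory(ds.record, quorum, n_trials, rng, exclude_dominant)
    truth = ds.trajectory.counts
    return {
        "r2": trajectory_r2(truth, est),
        "rmse": trajectory_rmse(truth, est),
        "n_bins": int(np.isfinite(est).sum()),
    }


def sqs_corpus_metrics(datasets: list[Dataset], quorum: float = 0.6,
                       n_trials: int = 100, seed: int = 0,
                       exclude_dominant: bool = False) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for i, ds in enumerate(datasets):
        m = sqs_dataset_metrics(ds, quorum, n_trials, rng, exclude_dominant)
        m["dataset"] = i
        rows.append(m)
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Per-dataset metrics plus corpus-level medians and IQRs."""

    per_dataset: pd.DataFrame
    summary: pd.DataFrame
    n_excluded_rmse: int = 0  # constant-trajectory datasets dropped from medians


def paired_comparison(datasets: list[Dataset],
                      ensembles: list[PredictionEnsemble] | None = None,
                      quorum: float = 0.6, n_trials: int = 100,
                      seed: int = 0) -> EvalReport:
    """Matched per-dataset (model, SQS) metrics on a shared test corpus.

    The model rows carry absolute-scale MSE (log scale), R2 on raw counts,
    squared-correlation R2, rMSE and 95%-interval coverage; the SQS rows
    carry the relative metrics only.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, ds in enumerate(datasets):
        truth = ds.trajectory.counts
        m = sqs_dataset_metrics(ds, quorum, n_trials, rng)
        rows.append({"dataset": i, "method": "sqs", "r2": m["r2"],
                     "rmse": m["rmse"], "mse_log": np.nan, "coverage": np.nan})
        if ensembles is not None:
            ens = ensembles[i]
            est = ens.mean
            rows.append({
                "dataset": i,
                "method": "model",
                "r2": trajectory_r2(truth, est),
                "rmse": trajectory_rmse(truth, est),
                "mse_log": mse(np.log1p(truth), np.log1p(est)),
                "coverage": coverage_95(truth, ens),
            })
    df = pd.DataFrame(rows)
    n_excl = int(df["rmse"].isna().sum())
    summary = (
        df.drop(columns="dataset")
        .groupby("method")
        .agg(["median", lambda s: s.quantile(0.75) - s.quantile(0.25)])
    )
    summary.columns = [f"{a}_{'iqr' if b == '<lambda_0>' else b}"
                       for a, b in summary.columns]
    return EvalReport(per_dataset=df, summary=summary, n_excluded_rmse=n_excl)
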
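"""Per-bin summary statistics of a fossil record, the input to the
sequence model.

For t bins and A regions the feature matrix is t x (7 + 3A): global
per-bin counts of sampled species, occurrences, localities, singletons
(species found at exactly one locality), endemics (species found in
exactly one region), the bin duration, range-through diversity, and a
per-region block of species / locality / occurrence counts.  The same
extraction runs on simulated and empirical records, which is what lets a
model trained on simulations be applied to real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bd import TimeBins
from .fossil import FossilRecord

__all__ = [
    "FeatureMatrix",
    "FeatureScaler",
    "GLOBAL_FEATURES",
    "feature_names",
    "extract_features",
    "range_through",
]

GLOBAL_FEATURES = [
    "n_species",
    "n_occurrences",
    "n_localities",
    "n_singletons",
    "n_endemics",
    "duration",
    "range_through",
]


def feature_names(n_regions: int) -> list[str]:
    names = list(GLOBAL_FEATURES)
    for a in range(n_regions):
        names += [f"n_species_r{a}", f"n_localities_r{a}", f"n_occurrences_r{a}"]
    return names


@dataclass
class FeatureMatrix:
    """(t bins x f features) summary of one dataset, plus metadata."""

    matrix: np.ndarray
    names: list[str]
    n_regions: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix must be (t, f) with one name per column")
        if len(self.names) != 7 + 3 * self.n_regions:
            raise ValueError("feature count must be 7 + 3A")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def range_through(record: FossilRecord, bins: TimeBins) -> np.ndarray:
    """Per bin, number of species whose first-to-last sampled bin interval
    spans the bin (sampling gaps inside a species' observed range are
    filled in)."""
    T = bins.n
    counts = np.zeros(T)
    if record.n_occurrences == 0:
        return counts
    df = pd.DataFrame({"s": record.species, "b": record.bin})
    g = df.groupby("s")["b"].agg(["min", "max"])
    delta = np.zeros(T + 1)
    np.add.at(delta, g["min"].to_numpy(), 1)
    np.add.at(delta, g["max"].to_numpy() + 1, -1)
    return np.cumsum(delta)[:T]


def extract_features(record: FossilRecord, bins: TimeBins, n_regions: int,
                     singleton_scope: str = "bin",
                     endemic_scope: str = "global") -> FeatureMatrix:
    """Compute the unnormalized t x (7 + 3A) feature matrix.

    ``singleton_scope`` counts a species as singleton when it is sampled at
    exactly one locality within the bin ("bin") or in the whole dataset
    ("global"); ``endemic_scope`` analogously fixes whether region fidelity
    is judged per bin or across the record (default: a species property).
    """
    if record.n_regions != n_regions:
        raise ValueError(
            f"record has {record.n_regions} regions, expected {n_regions}"
        )
    if record.n_occurrences and record.bin.max() >= bins.n:
        raise ValueError("record references bins outside the bin definition")
    T = bins.n
    names = feature_names(n_regions)
    M = np.zeros((T, len(names)))
    M[:, names.index("duration")] = bins.durations
    M[:, names.index("range_through")] = range_through(record, bins)

    if record.n_occurrences:
        df = record.to_frame()
        # distinct species / localities / occurrences per bin
        by_bin = df.groupby("bin")
        M[by_bin["species"].nunique().index, names.index("n_species")] = \
            by_bin["species"].nunique().to_numpy()
        occ = by_bin.size()
        M[occ.index, names.index("n_occurrences")] = occ.to_numpy()
        loc = df.drop_duplicates(["region", "bin", "locality"]).groupby("bin").size()
        M[loc.index, names.index("n_localities")] = loc.to_numpy()

        # singletons: rows are unique (species, region, locality) presences,
        # so the per-(bin, species) row count is its locality count
        key = ["bin", "species"] if singleton_scope == "bin" else ["species"]
        loc_per_sp = df.groupby(key).size()
        if singleton_scope == "bin":
            single = loc_per_sp[loc_per_sp == 1].groupby("bin").size()
        else:
            singles = set(loc_per_sp[loc_per_sp == 1].index)
            mask = df["species"].isin(singles)
            single = df[mask].groupby("bin")["species"].nunique()
        M[single.index, names.index("n_singletons")] = single.to_numpy()

        # endemics: species sampled in exactly one region
        if endemic_scope == "global":
            n_reg = df.groupby("species")["region"].nunique()
            endemic_sp = set(n_reg[n_reg == 1].index)
            mask = df["species"].isin(endemic_sp)
            ende = df[mask].groupby("bin")["species"].nunique()
        else:
            n_reg = df.groupby(["bin", "species"])["region"].nunique()
            ende = n_reg[n_reg == 1].groupby("bin").size()
        M[ende.index, names.index("n_endemics")] = ende.to_numpy()

        for a in range(n_regions):
            sub = df[df["region"] == a]
            if not len(sub):
                continue
            g = sub.groupby("bin")
            M[g["species"].nunique().index, names.index(f"n_species_r{a}")] = \
                g["species"].nunique().to_numpy()
            M[g["locality"].nunique().index, names.index(f"n_localities_r{a}")] = \
                g["locality"].nunique().to_numpy()
            M[g.size().index, names.index(f"n_occurrences_r{a}")] = \
                g.size().to_numpy()
    return FeatureMatrix(M, names, n_regions)


@dataclass
class FeatureScaler:
    """log(x+1) + train-corpus-maximum scaling, reusable at inference.

    Count features are mapped through log(x+1) and divided by the
    per-feature maximum of the transformed training corpus; the duration
    column is divided by its training maximum untransformed.  The fitted
    constants are serialized with trained models so empirical data are
    normalized identically.
    """

    names: list[str] = field(default_factory=list)
    maxima: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def _is_duration(self) -> np.ndarray:
        return np.asarray([n == "duration" for n in self.names])

    def fit(self, corpus: list[FeatureMatrix]) -> "FeatureScaler":
        if not corpus:
            raise ValueError("cannot fit a scaler on an empty corpus")
        self.names = list(corpus[0].names)
        stacked = np.concatenate([self._pretransform(fm.matrix) for fm in corpus])
        self.maxima = stacked.max(axis=0)
        self.maxima[self.maxima == 0] = 1.0  # all-zero columns pass through
        return self

    def _pretransform(self, m: np.ndarray) -> np.ndarray:
        out = np.log1p(m)
        dur = self._is_duration if self.names else np.zeros(m.shape[1], bool)
        out[:, dur] = m[:, dur]
        return out

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        if fm.normalized:
            return fm
        if list(fm.names) != list(self.names):
            raise ValueError("feature names do not match the fitted scaler")
        return FeatureMatrix(self._pretransform(fm.matrix) / self.maxima,
                             fm.names, fm.n_regions, normalized=True)

    def inverse_transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        if not fm.normalized:
            return fm
        m = fm.matrix * self.maxima
        out = np.expm1(m)
        dur = self._is_duration
        out[:, dur] = m[:, dur]
        return FeatureMatrix(out, fm.names, fm.n_regions, normalized=False)

    def to_dict(self) -> dict:
        return {"names": list(self.names), "maxima": self.maxima.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(names=list(d["names"]), maxima=np.asarray(d["maxima"], float))
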
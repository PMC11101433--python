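"""Empirical occurrence handling and scenario presets."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fossildiv as fd
from fossildiv.bd import TimeBins
from fossildiv.empirical import (MARINE_REGIONS, MARINE_STAGE_EDGES,
                                 PROBOSCIDEA_REGIONS, bin_occurrences,
                                 derive_localities, feature_overlap_report,
                                 randomize_ages, read_occurrences,
                                 scenario_config)
from fossildiv.features import extract_features
from fossildiv.fossil import presence_matrix


COLMAP = {"taxon": "genus", "lat": "latitude", "lon": "longitude",
          "region": "area", "min_ma": "min_age", "max_ma": "max_age"}


def _write_csv(path, rows):
    pd.DataFrame(rows, columns=["genus", "latitude", "longitude", "area",
                                "min_age", "max_age"]).to_csv(path, index=False)
    return path


@pytest.fixture
def toy_csv(tmp_path):
    return _write_csv(tmp_path / "occ.csv", [
        ("Aus", 10.0, 20.0, "north", 5.0, 7.0),
        ("Bus", 10.0, 20.0, "north", 5.0, 7.0),
        ("Aus", 10.0, 20.0, "north", 9.0, 11.0),   # same point, older range
        ("Cus", -3.0, 40.0, "south", 2.0, 3.0),
        ("Cus", -3.0, 40.0, "south", 2.0, 3.0),    # duplicate occurrence
    ])


class TestReadOccurrences:
    def test_valid_rows_pass(self, toy_csv):
        t = read_occurrences(toy_csv, COLMAP)
        assert len(t) == 5
        assert t.n_dropped == 0
        assert set(t.regions) == {"north", "south"}

    def test_inverted_age_range_rejected_with_diagnostic(self, tmp_path):
        p = _write_csv(tmp_path / "bad.csv", [
            ("Aus", 1.0, 1.0, "north", 9.0, 5.0),
            ("Bus", 1.0, 1.0, "north", 5.0, 9.0),
        ])
        t = read_occurrences(p, COLMAP)
        assert len(t) == 1
        assert t.n_dropped == 1
        assert any("exceeds" in e for e in t.errors)

    def test_missing_taxon_and_unknown_region_dropped(self, tmp_path):
        p = _write_csv(tmp_path / "bad2.csv", [
            (None, 1.0, 1.0, "north", 1.0, 2.0),
            ("Bus", 1.0, 1.0, "atlantis", 1.0, 2.0),
            ("Cus", 1.0, 1.0, "north", 1.0, 2.0),
        ])
        t = read_occurrences(p, COLMAP, regions=["north"])
        assert len(t) == 1
        assert t.n_dropped == 2

    def test_unmapped_required_column_rejected(self, toy_csv):
        with pytest.raises(ValueError):
            read_occurrences(toy_csv, {"taxon": "genus"})


class TestDeriveLocalities:
    def test_same_point_same_ages_collapse(self, toy_csv):
        t = derive_localities(read_occurrences(toy_csv, COLMAP))
        ids = t.data["locality_id"]
        # 3 localities: (10,20,5,7), (10,20,9,11), (-3,40,2,3)
        assert ids.nunique() == 3
        # duplicate (taxon, locality) collapsed
        assert len(t.data) == 4

    def test_same_point_different_ages_stay_distinct(self, toy_csv):
        t = derive_localities(read_occurrences(toy_csv, COLMAP))
        north = t.data[t.data["region"] == "north"]
        assert north["locality_id"].nunique() == 2

    def test_deterministic_and_idempotent(self, toy_csv):
        t1 = derive_localities(read_occurrences(toy_csv, COLMAP))
        t2 = derive_localities(derive_localities(read_occurrences(toy_csv,
                                                                  COLMAP)))
        assert t1.data["locality_id"].tolist() == t2.data["locality_id"].tolist()

    def test_brute_force_key_count(self, tmp_path, rng):
        rows = []
        for _ in range(10):
            rows.append(("Aus", float(rng.integers(0, 3)),
                         float(rng.integers(0, 3)), "north",
                         float(rng.integers(0, 2)), 5.0))
        p = _write_csv(tmp_path / "r.csv", rows)
        t = derive_localities(read_occurrences(p, COLMAP))
        brute = {(r.latitude, r.longitude, r.min_age, r.max_age)
                 for r in pd.read_csv(p).itertuples()}
        assert t.data["locality_id"].nunique() == len(brute)


class TestRandomizeAges:
    def test_replicate_count_and_bounds(self, toy_csv, rng):
        t = derive_localities(read_occurrences(toy_csv, COLMAP))
        reps = randomize_ages(t, 100, rng)
        assert len(reps) == 100
        for rep in reps:
            assert np.all(rep["age"] >= rep["min_ma"])
            assert np.all(rep["age"] <= rep["max_ma"])

    def test_point_age_range_is_degenerate(self, tmp_path, rng):
        p = _write_csv(tmp_path / "pt.csv", [("Aus", 0.0, 0.0, "n", 4.0, 4.0)])
        t = derive_localities(read_occurrences(p, COLMAP))
        for rep in randomize_ages(t, 20, rng):
            assert np.all(rep["age"] == 4.0)

    def test_locality_level_draw_shared_by_co_located_occurrences(self,
                                                                  toy_csv,
                                                                  rng):
        t = derive_localities(read_occurrences(toy_csv, COLMAP))
        rep = randomize_ages(t, 1, rng)[0]
        for _, grp in rep.groupby("locality_id"):
            assert grp["age"].nunique() == 1

    def test_uniform_distribution_of_drawn_ages(self, tmp_path):
        p = _write_csv(tmp_path / "u.csv", [("Aus", 0.0, 0.0, "n", 3.0, 8.0)])
        t = derive_localities(read_occurrences(p, COLMAP))
        rng = np.random.default_rng(0)
        ages = np.array([randomize_ages(t, 1, rng)[0]["age"].iloc[0]
                         for _ in range(10_000)])
        _, pval = stats.kstest((ages - 3.0) / 5.0, "uniform")
        assert pval > 0.01


class TestBinOccurrences:
    def test_locality_inside_one_bin(self, toy_csv, rng):
        t = derive_localities(read_occurrences(toy_csv, COLMAP))
        rep = randomize_ages(t, 1, rng)[0]
        bins = TimeBins.regular(12.0, 12)
        rec = bin_occurrences(rep, bins, t.regions)
        # every locality gets one drawn age, hence one bin, per replicate
        assert (rep.groupby("locality_id")["age"].nunique() == 1).all()
        fm = extract_features(rec, bins, len(t.regions))
        assert fm.column("n_occurrences").sum() == rec.n_occurrences

    def test_locality_counts_feed_grid(self, toy_csv, rng):
        t = derive_localities(read_occurrences(toy_csv, COLMAP))
        rep = randomize_ages(t, 1, rng)[0]
        rec = bin_occurrences(rep, TimeBins.regular(12.0, 12), t.regions)
        assert rec.grid.l_at.sum() == 3  # three derived localities

    def test_out_of_frame_rows_dropped(self, toy_csv, rng):
        t = derive_localities(read_occurrences(toy_csv, COLMAP))
        rep = randomize_ages(t, 1, rng)[0]
        rec = bin_occurrences(rep, TimeBins.regular(6.0, 6), t.regions)
        assert rec.n_occurrences < 4


class TestScenarios:
    def test_marine_preset_prints(self):
        sc = scenario_config("marine_pt")
        assert sc.bins_ma.n == 11
        assert sc.bins_ma.edges[0] == pytest.approx(259.51)
        assert sc.bins_ma.edges[-1] == pytest.approx(192.9)
        assert sc.sim.bd.p_mass_extinction == pytest.approx(0.029)
        assert sc.sim.bd.n_start_range == (100, 1000)
        assert sc.sim.bd.extant_range[0] == 100
        assert sc.region_names == MARINE_REGIONS
        assert sc.n_train == 150_000 and sc.n_test == 1_000

    def test_proboscidea_preset_prints(self):
        sc = scenario_config("proboscidea")
        assert sc.bins_ma.n == 69
        assert sc.bins_ma.edges[0] == pytest.approx(66.0)
        assert sc.bins_ma.edges[-1] == pytest.approx(0.0)
        assert sc.sim.bd.n_start_range == (1, 1)
        assert sc.sim.bd.extant_range == (3, 30)
        assert sc.region_names == PROBOSCIDEA_REGIONS

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            scenario_config("atlantis")

    def test_marine_simulations_satisfy_constraints(self):
        sc = scenario_config("marine_pt")
        for seed in range(25):
            ds = fd.generate_dataset(sc.sim, np.random.default_rng(seed),
                                     with_features=False)
            assert 100 <= ds.clade.n_species <= 5000
            assert ds.clade.n_extant >= 100
            assert ds.clade.params.n_start >= 100

    def test_proboscidea_arrival_windows_enforced(self):
        sc = scenario_config("proboscidea")
        sa = PROBOSCIDEA_REGIONS.index("South America")
        eu = PROBOSCIDEA_REGIONS.index("Europe")
        for seed in range(25):
            ds = fd.generate_dataset(sc.sim, np.random.default_rng(seed),
                                     with_features=False)
            assert 3 <= ds.clade.n_extant <= 30
            opening = ds.system.opening_ages
            assert 0.8 <= opening[sa] <= 5.3
            assert 27.0 <= opening[eu] <= 33.9
            assert np.isinf(opening[0])  # Africa always open
            pres = presence_matrix(ds.clade, ds.ranges, ds.system, sc.sim.bins)
            early = sc.sim.bins.starts > opening[sa]
            assert pres[:, sa, early].sum() == 0
            if ds.record.n_occurrences:
                sa_bins = ds.record.bin[ds.record.region == sa]
                assert np.all(sc.sim.bins.starts[sa_bins] <= opening[sa])


class TestFeatureOverlap:
    def test_member_dataset_fully_contained(self, small_corpus):
        fms = [ds.features for ds in small_corpus]
        df, frac = feature_overlap_report(fms, fms[0])
        assert frac == 1.0
        assert np.all(df["fraction_contained"] == 1.0)

    def test_out_of_envelope_values_flagged(self, small_corpus):
        from dataclasses import replace

        fms = [ds.features for ds in small_corpus]
        bumped = replace(fms[0], matrix=fms[0].matrix.copy())
        col = bumped.names.index("n_occurrences")
        bumped.matrix[:, col] = 10.0 ** 9
        df, frac = feature_overlap_report(fms[1:], bumped)
        assert frac < 1.0
        assert df.loc[df.feature == "n_occurrences",
                      "n_bins_outside"].iloc[0] == bumped.n_bins

    def test_hand_counted_envelope(self, small_corpus):
        fms = [ds.features for ds in small_corpus]
        emp = fms[0]
        stack = np.stack([fm.matrix for fm in fms[1:]])
        inside = (emp.matrix >= stack.min(axis=0)) & \
                 (emp.matrix <= stack.max(axis=0))
        _, frac = feature_overlap_report(fms[1:], emp)
        assert frac == pytest.approx(inside.mean())

    def test_name_mismatch_rejected(self, small_corpus):
        from fossildiv.features import FeatureMatrix, feature_names

        fms = [ds.features for ds in small_corpus]
        other = FeatureMatrix(np.zeros((50, 10)), feature_names(1), 1)
        with pytest.raises(ValueError):
            feature_overlap_report(fms, other)
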
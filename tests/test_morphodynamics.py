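"""Velocity, fate, exchange, mitosis, cell-number and wound quantification."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from tests.conftest import region_map_for
from vesseldyn.morphodynamics import (RegionMap, assign_fate, cell_number,
                                      correlate_drivers, count_mitoses,
                                      detect_exchanges, diameter_profile,
                                      exchange_histogram, region_states,
                                      windowed_velocity, wound_metrics)
from vesseldyn.synthetic_data import EmbryoSimConfig, MonolayerSimConfig, \
    generate_embryo, generate_monolayer
from vesseldyn.track_model import DiameterTable, TrackTable, TrackValidationError


def toy_map(n_isv=2, length=100.0):
    return RegionMap.from_scaffold(n_isv, 75.0, length)


def toy_tracks(cells: dict[str, np.ndarray], t0=26.0, dt=1.0 / 6.0,
               x=75.0) -> TrackTable:
    """cells: cell_id -> y series (x fixed at the first ISV slot)."""
    rows = []
    for cid, y in cells.items():
        for k, yy in enumerate(np.asarray(y, dtype=float)):
            rows.append(("e", cid, None, t0 + k * dt, x, yy, 0.0, None))
    return TrackTable(pd.DataFrame(rows, columns=[
        "embryo_id", "cell_id", "parent_id", "t", "x", "y", "z", "vessel_label"]))


def full_fate(rmap, cls="aISV"):
    from vesseldyn.morphodynamics import IsvFate
    return IsvFate(fates={v: cls for v in rmap.vessel_ids})


class TestWindowedVelocity:
    def test_linear_track_exact(self):
        t = 26.0 + np.arange(109) / 6.0
        tracks = toy_tracks({"c": 10.0 + 2.5 * (t - 26.0)})
        rmap = toy_map()
        vel = windowed_velocity(tracks, full_fate(rmap), rmap, n_boot=50)
        assert len(vel)
        np.testing.assert_allclose(vel["mean_velocity"], 2.5, atol=1e-9)

    def test_stationary_track_zero(self):
        tracks = toy_tracks({"c": np.full(109, 40.0)})
        rmap = toy_map()
        vel = windowed_velocity(tracks, full_fate(rmap), rmap, n_boot=50)
        np.testing.assert_allclose(vel["mean_velocity"], 0.0, atol=1e-12)

    def test_reflection_through_band_midline_negates(self):
        rng = np.random.default_rng(0)
        y = np.clip(np.cumsum(rng.normal(0.3, 0.5, 109)) + 30.0, 10.0, 90.0)
        rmap = toy_map()
        mid = (rmap.y_da + rmap.y_dlav) / 2.0
        v1 = windowed_velocity(toy_tracks({"c": y}), full_fate(rmap), rmap, n_boot=50)
        v2 = windowed_velocity(toy_tracks({"c": 2 * mid - y}), full_fate(rmap),
                               rmap, n_boot=50)
        np.testing.assert_allclose(v2["mean_velocity"], -v1["mean_velocity"],
                                   atol=1e-9)

    def test_short_presence_contributes_nothing(self):
        tracks = toy_tracks({"c": [40.0, 41.0]})  # two frames only
        rmap = toy_map()
        vel = windowed_velocity(tracks, full_fate(rmap), rmap, n_boot=10)
        assert len(vel) == 0


class TestFate:
    def test_injected_fates_recovered(self, zero_noise_embryo):
        cfg, tracks, _, ledger = zero_noise_embryo
        fate = assign_fate(tracks, region_map_for(cfg))
        assert fate.fates == ledger.fates
        assert not fate.unresolved
        assert len(fate.vessels("vISV")) == 5 and len(fate.vessels("aISV")) == 5

    def test_no_ventral_signal_means_arterial(self):
        y = np.full(109, 40.0)
        tracks = toy_tracks({"c1": y, "c2": y + 10})
        rmap = toy_map(n_isv=1)
        fate = assign_fate(tracks, rmap)
        assert fate.fates == {"ISV_01": "aISV"}

    def test_truncated_isv_unresolved(self):
        tracks = toy_tracks({"c": np.full(50, 40.0)})   # ends before the last frame
        extra = toy_tracks({"d": np.full(109, 40.0)}, x=150.0)  # keeps ISV_02 alive
        both = TrackTable(pd.concat([tracks.df, extra.df], ignore_index=True))
        fate = assign_fate(both, toy_map(n_isv=2))
        assert "ISV_01" in fate.unresolved
        assert fate.fates.get("ISV_02") == "aISV"


class TestExchanges:
    def test_single_descent_is_one_immigration(self):
        y = np.concatenate([np.full(30, 100.0),
                            np.linspace(100.0, 40.0, 5),
                            np.full(74, 40.0)])
        rmap = toy_map()
        ledger = detect_exchanges(toy_tracks({"c": y}), rmap)
        assert len(ledger.events) == 1
        ev = ledger.events.iloc[0]
        assert ev["type"] == "immigration_dlav" and ev["vessel_id"] == "ISV_01"

    def test_brief_incursion_is_no_event(self):
        y = np.concatenate([np.full(30, 100.0), np.full(2, 40.0),
                            np.full(77, 100.0)])
        ledger = detect_exchanges(toy_tracks({"c": y}), toy_map(), K=6)
        assert len(ledger.events) == 0

    def test_flicker_invariance(self):
        rng = np.random.default_rng(1)
        y = np.full(109, 40.0)
        ledger_clean = detect_exchanges(toy_tracks({"c": y}), toy_map())
        y2 = y.copy()
        for i in rng.choice(np.arange(10, 100), 5, replace=False):
            y2[i:i + 2] = 97.0   # 2-frame flicker into the DLAV band
        ledger_flicker = detect_exchanges(toy_tracks({"c": y2}), toy_map())
        pd.testing.assert_frame_equal(ledger_clean.counts, ledger_flicker.counts)

    def test_zero_noise_cohort_precision_recall_one(self, zero_noise_embryo):
        cfg, tracks, _, truth = zero_noise_embryo
        rmap = region_map_for(cfg)
        ledger = detect_exchanges(tracks, rmap)
        detected = set(zip(ledger.events["cell_id"],
                           ledger.events["type"].str.split("_").str[0],
                           ledger.events["vessel_id"]))
        te = truth.events[truth.events["event"] != "division"]
        expected = set(zip(te["cell_id"], te["event"], te["vessel_id"]))
        assert detected == expected
        # ledger consistency: d(cell number) = net immigration + mitoses
        states = region_states(tracks, rmap)
        n0 = cell_number(tracks, rmap, cfg.t0, states=states).set_index("vessel_id")
        n1 = cell_number(tracks, rmap, cfg.t1, states=states).set_index("vessel_id")
        mit = count_mitoses(tracks, rmap, states=states).set_index("vessel_id")
        net = ledger.counts.set_index("vessel_id")["net_immigration"]
        for vid in rmap.vessel_ids:
            assert (n1.loc[vid, "n_cells"] - n0.loc[vid, "n_cells"]
                    == net[vid] + mit.loc[vid, "mitoses"])

    def test_histogram_fractions_sum_to_one(self, zero_noise_embryo):
        cfg, tracks, _, _ = zero_noise_embryo
        rmap = region_map_for(cfg)
        fate = assign_fate(tracks, rmap)
        hist = exchange_histogram(detect_exchanges(tracks, rmap).counts, fate)
        sums = hist.groupby(["vessel_class", "type"])["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0)


class TestMitosesAndCounts:
    def test_no_branching_all_zero(self):
        tracks = toy_tracks({"c": np.full(109, 40.0)})
        mit = count_mitoses(tracks, toy_map())
        assert (mit["mitoses"] == 0).all()

    def test_single_division_attributed_to_mother_vessel(self):
        df = toy_tracks({"m": np.full(20, 40.0)}).df
        kids = []
        for cid in ("d1", "d2"):
            kid = toy_tracks({cid: np.full(20, 42.0)}).df
            kid["t"] += 20 / 6.0
            kid["parent_id"] = "m"
            kids.append(kid)
        tracks = TrackTable(pd.concat([df, *kids], ignore_index=True)).validate()
        mit = count_mitoses(tracks, toy_map())
        assert dict(zip(mit["vessel_id"], mit["mitoses"])) == {"ISV_01": 1,
                                                               "ISV_02": 0}

    def test_mitoses_equal_ledger(self, default_embryo):
        cfg, tracks, _, truth = default_embryo
        mit = count_mitoses(tracks, region_map_for(cfg)).set_index("vessel_id")
        expected = truth.events_of("division").groupby("vessel_id").size()
        for vid in region_map_for(cfg).vessel_ids:
            assert mit.loc[vid, "mitoses"] == expected.get(vid, 0)

    def test_empty_isv_counts_zero_and_partition(self):
        tracks = toy_tracks({"c": np.full(109, 40.0)})
        rmap = toy_map(n_isv=2)
        counts = cell_number(tracks, rmap, 44.0)
        assert dict(zip(counts["vessel_id"], counts["n_cells"])) == {"ISV_01": 1,
                                                                     "ISV_02": 0}
        # a boundary cell is assigned to exactly one vessel
        mid = toy_tracks({"b": np.full(109, 50.0)}, x=112.5)  # equidistant slots
        counts2 = cell_number(mid, rmap, 44.0)
        assert counts2["n_cells"].sum() == 1

    def test_time_outside_recording_rejected(self):
        tracks = toy_tracks({"c": np.full(10, 40.0)})
        with pytest.raises(ValueError, match="outside"):
            cell_number(tracks, toy_map(), 99.0)


class TestDiametersAndCorrelations:
    def test_two_vessel_mean(self):
        df = pd.DataFrame({
            "embryo_id": "e", "vessel_id": ["v1", "v2"],
            "vessel_class": "vISV", "t": 44.0, "diameter": [6.0, 8.0]})
        prof = diameter_profile(DiameterTable(df), n_boot=100)
        assert prof["mean_diameter"].iloc[0] == pytest.approx(7.0)

    def test_single_vessel_degenerate_ci(self):
        df = pd.DataFrame({"embryo_id": "e", "vessel_id": "v1",
                           "vessel_class": "aISV", "t": [26.0, 27.0],
                           "diameter": [4.0, 4.2]})
        prof = diameter_profile(DiameterTable(df), n_boot=100)
        assert (prof["ci_low"] == prof["mean_diameter"]).all()
        assert (prof["ci_high"] == prof["mean_diameter"]).all()

    def test_linear_growth_slope_recovered(self, default_embryo):
        cfg, _, diameters, _ = default_embryo
        prof = diameter_profile(diameters, n_boot=100)
        for cls in ("aISV", "vISV"):
            sub = prof[prof["vessel_class"] == cls]
            slope = np.polyfit(sub["t"], sub["mean_diameter"], 1)[0]
            assert slope == pytest.approx(cfg.diameter_growth[cls][1], rel=0.05)

    def test_affine_and_anticorrelated_r(self):
        per_isv = pd.DataFrame({
            "vessel_class": "vISV",
            "mitoses": [0, 1, 2, 3, 4, 5],
            "net_immigration": [5, 4, 3, 2, 1, 0],
            "final_diameter": [4.0, 5.0, 6.0, 7.0, 8.0, 9.0]})
        res = correlate_drivers(per_isv).set_index("driver")
        assert res.loc["mitoses", "r"] == pytest.approx(1.0)
        assert res.loc["net_immigration", "r"] == pytest.approx(-1.0)

    def test_permuted_pairing_matches_permutation_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(2.0, 12).astype(float)
        y = rng.normal(7.0, 1.0, 12)
        rs = []
        for _ in range(1000):
            per_isv = pd.DataFrame({"vessel_class": "aISV", "mitoses": x,
                                    "net_immigration": x,
                                    "final_diameter": rng.permutation(y)})
            rs.append(correlate_drivers(per_isv)["r"].iloc[0])
        rs = np.array(rs)
        # independent oracle: direct correlation of permuted pairs
        oracle = []
        xc = x - x.mean()
        for _ in range(4000):
            yp = rng.permutation(y) - y.mean()
            oracle.append(float(xc @ yp / np.sqrt((xc @ xc) * (yp @ yp))))
        assert abs(rs.mean()) < 0.03
        assert np.quantile(np.abs(rs), 0.95) == pytest.approx(
            np.quantile(np.abs(oracle), 0.95), abs=0.08)


class TestWoundMetrics:
    def test_straight_track_effective_speed(self):
        df = pd.DataFrame({"cell_id": "c", "t": [0.0, 960.0],
                           "x": [0.0, 80.0], "y": [0.0, 0.0]})
        tracks = TrackTable(df, time_unit="min")
        wm = wound_metrics(tracks, 0.5e6, 0.2e6)
        row = wm.per_track.iloc[0]
        assert row["effective_speed"] == pytest.approx(5.0)
        assert row["angle"] == pytest.approx(np.pi / 2)
        assert wm.closure_pct == pytest.approx(60.0)

    def test_returning_track_excluded(self):
        df = pd.DataFrame({"cell_id": "c", "t": [0.0, 480.0, 960.0],
                           "x": [0.0, 30.0, 0.0], "y": [0.0, 10.0, 0.0]})
        wm = wound_metrics(TrackTable(df, time_unit="min"), 1.0, 1.0)
        assert bool(wm.per_track["excluded"].iloc[0])

    def test_chord_never_exceeds_path(self):
        tracks, _, _ = generate_monolayer(dataclasses.replace(
            MonolayerSimConfig(), n_tracks=50, seed=3))
        wm = wound_metrics(tracks, 5e5, 2e5)
        ok = wm.per_track.dropna(subset=["effective_speed"])
        assert (ok["effective_speed"] <= ok["path_speed"] + 1e-9).all()
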
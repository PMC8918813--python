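#!/usr/bin/env python
"""Quantify cell behaviour on the aligned control cohort: windowed velocity
profiles per future vessel class, inter-vessel exchange, mitoses, cell
numbers, diameter growth, and the diameter-vs-driver correlations.  Writes
tidy tables under results/ and prints the headline numbers."""

from pathlib import Path

import numpy as np
import pandas as pd

from vesseldyn.morphodynamics import (RegionMap, assign_fate, cell_number,
                                      correlate_drivers, count_mitoses,
                                      detect_exchanges, diameter_profile,
                                      exchange_histogram, region_states,
                                      windowed_velocity)
from vesseldyn.track_model import read_diameters, read_tracks

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"
SEED = 1


def main() -> None:
    tracks = read_tracks(DATA / "control_tracks_aligned.csv")
    diameters = read_diameters(DATA / "control_diameters.csv")

    profiles, hists, per_isv = [], [], []
    for embryo_id in tracks.embryo_ids:
        sub = tracks.for_embryo(embryo_id)
        rmap = RegionMap.infer(sub)
        states = region_states(sub, rmap)
        fate = assign_fate(sub, rmap)
        profiles.append(windowed_velocity(sub, fate, rmap, n_boot=500,
                                          seed=SEED, states=states)
                        .assign(embryo_id=embryo_id))
        ledger = detect_exchanges(sub, rmap, states=states)
        hists.append(exchange_histogram(ledger.counts, fate)
                     .assign(embryo_id=embryo_id))
        mit = count_mitoses(sub, rmap, states=states)
        num = cell_number(sub, rmap, 44.0, states=states)
        final = diameters.df[(diameters.df["embryo_id"] == embryo_id)
                             & np.isclose(diameters.df["t"], 44.0)]
        merged = (ledger.counts.merge(mit, on="vessel_id")
                  .merge(num, on="vessel_id")
                  .merge(final[["vessel_id", "diameter"]], on="vessel_id",
                         how="left")
                  .rename(columns={"diameter": "final_diameter"}))
        merged["vessel_class"] = [fate.of(v) for v in merged["vessel_id"]]
        per_isv.append(merged.assign(embryo_id=embryo_id))

    velocity = pd.concat(profiles, ignore_index=True)
    velocity.to_csv(OUT / "velocity_profile.csv", index=False)
    per_isv_df = pd.concat(per_isv, ignore_index=True)
    per_isv_df.to_csv(OUT / "per_isv_summary.csv", index=False)
    pd.concat(hists, ignore_index=True).to_csv(OUT / "exchange_histograms.csv",
                                               index=False)
    prof = diameter_profile(diameters, n_boot=500, seed=SEED)
    prof.to_csv(OUT / "diameter_profile.csv", index=False)

    pooled = velocity.groupby(["vessel_class", "t_center"]).apply(
        lambda g: np.average(g["mean_velocity"], weights=g["n_cells"]),
        include_groups=False).rename("v").reset_index()
    for cls in ("vISV", "aISV"):
        sub = pooled[pooled["vessel_class"] == cls]
        spr = sub[(sub["t_center"] >= 26.5) & (sub["t_center"] <= 29.5)]["v"].max()
        rem = sub[(sub["t_center"] >= 34.5) & (sub["t_center"] <= 38.5)]["v"].mean()
        print(f"{cls}: sprouting peak {spr:+.2f} um/h, "
              f"remodelling mean {rem:+.2f} um/h")

    for cls, ev, label in (("aISV", "immigration_dlav", "gained >=1 cell from DLAV"),
                           ("vISV", "emigration_dlav", "lost >=1 cell to DLAV"),
                           ("vISV", "immigration_pcv", "gained >=1 cell from PCV")):
        sub = per_isv_df[per_isv_df["vessel_class"] == cls]
        frac = float((sub[ev] >= 1).mean() * 100)
        print(f"{frac:.0f}% of {cls}s {label} (n={len(sub)})")
    for cls in ("aISV", "vISV"):
        sub = per_isv_df[per_isv_df["vessel_class"] == cls]
        print(f"{cls}: {sub['mitoses'].mean():.2f} divisions/vessel, "
              f"{sub['n_cells'].mean():.1f} cells and "
              f"{sub['final_diameter'].mean():.1f} um diameter at 44 hpf")

    corr = correlate_drivers(per_isv_df.dropna(subset=["vessel_class"]))
    corr.to_csv(OUT / "driver_correlations.csv", index=False)
    print(corr.to_string(index=False))


if __name__ == "__main__":
    main()
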
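#!/usr/bin/env python
"""Simulate the study cohorts: a control embryo cohort in a scrambled imaging
frame, a noise-free scoring cohort, and control-like / knockdown-like HUVEC
wound assays.  Writes the raw tables and ground-truth ledgers under
results/data/ for the downstream analysis scripts."""

import dataclasses
from pathlib import Path

import pandas as pd

from vesseldyn.synthetic_data import (EmbryoSimConfig, MonolayerSimConfig,
                                      generate_cohort, generate_monolayer)
from vesseldyn.track_model import write_diameters, write_tracks

SEED = 1
N_EMBRYOS = 12
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg = dataclasses.replace(EmbryoSimConfig(), scramble_frame=True)
    tracks, diameters, ledgers = generate_cohort(N_EMBRYOS, cfg, seed=SEED)
    write_tracks(tracks, OUT / "control_tracks_raw.csv")
    write_diameters(diameters, OUT / "control_diameters.csv")
    events = pd.concat([led.events for led in ledgers], ignore_index=True)
    events.to_csv(OUT / "control_ground_truth.csv", index=False)
    print(f"control cohort: {N_EMBRYOS} embryos, {tracks.n_points} points, "
          f"{len(tracks.cell_ids)} cells, {len(events)} injected events")

    quiet = dataclasses.replace(EmbryoSimConfig(), noise_sd=0.0)
    qt, qd, qled = generate_cohort(8, quiet, seed=SEED + 1)
    write_tracks(qt, OUT / "scoring_tracks.csv")
    pd.concat([led.events for led in qled], ignore_index=True).to_csv(
        OUT / "scoring_ground_truth.csv", index=False)
    print(f"noise-free scoring cohort: 8 embryos, {qt.n_points} points")

    for name, cfg_m in (
        ("sictr", dataclasses.replace(MonolayerSimConfig(), seed=SEED + 3)),
        ("siwas", dataclasses.replace(MonolayerSimConfig(), directed=False,
                                      speed_scale=0.4, condition="siWAS",
                                      assay_id="assay_02", seed=SEED + 4)),
    ):
        mt, area, _ = generate_monolayer(cfg_m)
        write_tracks(mt, OUT / f"huvec_{name}_tracks.csv")
        area.to_csv(OUT / f"huvec_{name}_wound_area.csv", index=False)
        print(f"HUVEC {name}: {len(mt.cell_ids)} tracks over "
              f"{cfg_m.duration_h:.0f} h, wound area "
              f"{area['area_um2'].iloc[0]:.0f} -> {area['area_um2'].iloc[-1]:.0f} um^2")


if __name__ == "__main__":
    main()
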
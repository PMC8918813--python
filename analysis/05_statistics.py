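#!/usr/bin/env python
"""Statistical comparisons: adapted discrete-KS tests on per-ISV count
distributions (arterial vs venous), detection scoring against the noise-free
ground truth, and the HUVEC wound-assay tests (Welch's t on effective speed,
Watson's U^2 on directionality).  Writes results/statistics.json."""

import json
from pathlib import Path

import pandas as pd

from vesseldyn.morphodynamics import (RegionMap, detect_exchanges,
                                      wound_metrics)
from vesseldyn.stats import circular_mean_sd, discrete_ks, watson_u2, welch_t
from vesseldyn.track_model import read_tracks

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
SEED = 1


def main() -> None:
    results = {}
    per_isv = pd.read_csv(ROOT / "results" / "per_isv_summary.csv")
    for quantity in ("mitoses", "net_immigration", "n_cells"):
        a = per_isv.loc[per_isv["vessel_class"] == "aISV", quantity].dropna()
        v = per_isv.loc[per_isv["vessel_class"] == "vISV", quantity].dropna()
        res = discrete_ks(a, v, n_resamples=10_000, seed=SEED)
        results[f"aks_{quantity}_aISV_vs_vISV"] = {
            "D": res.statistic, "p": res.pvalue, "method": res.method}
        print(f"AKS {quantity}: aISV vs vISV D={res.statistic:.3f} "
              f"p={res.pvalue:.4f} ({res.method})")

    scoring = read_tracks(DATA / "scoring_tracks.csv")
    truth = pd.read_csv(DATA / "scoring_ground_truth.csv")
    detected, expected = set(), set()
    for embryo_id in scoring.embryo_ids:
        sub = scoring.for_embryo(embryo_id)
        rmap = RegionMap.infer(sub)
        ev = detect_exchanges(sub, rmap).events
        detected |= set(zip([embryo_id] * len(ev), ev["cell_id"],
                            ev["type"].str.split("_").str[0], ev["vessel_id"]))
    te = truth[truth["event"] != "division"]
    # ledger rows carry no embryo column; key on (cell_id, event, vessel)
    expected = set(zip(te["cell_id"], te["event"], te["vessel_id"]))
    detected_flat = {(c, e, v) for _, c, e, v in detected}
    tp = len(detected_flat & expected)
    results["exchange_detection"] = {
        "precision": tp / max(len(detected_flat), 1),
        "recall": tp / max(len(expected), 1), "n_true": len(expected)}
    print(f"zero-noise exchange detection: precision "
          f"{results['exchange_detection']['precision']:.3f}, recall "
          f"{results['exchange_detection']['recall']:.3f}")

    speeds, angles = {}, {}
    for name in ("sictr", "siwas"):
        tracks = read_tracks(DATA / f"huvec_{name}_tracks.csv", time_unit="min")
        area = pd.read_csv(DATA / f"huvec_{name}_wound_area.csv")
        wm = wound_metrics(tracks, *area["area_um2"].to_numpy())
        ok = wm.per_track[~wm.per_track["excluded"]]
        speeds[name], angles[name] = ok["effective_speed"], ok["angle"]
        summ = circular_mean_sd(angles[name])
        print(f"HUVEC {name}: effective speed {speeds[name].mean():.2f} um/h, "
              f"wound closure {wm.closure_pct:.1f}%, resultant length "
              f"{summ.resultant_length:.2f}")
    wt = welch_t(speeds["sictr"], speeds["siwas"])
    wu = watson_u2(angles["sictr"], angles["siwas"])
    results["huvec_welch_t"] = {"t": wt.statistic, "df": wt.df, "p": wt.pvalue}
    results["huvec_watson_u2"] = {"U2": wu.statistic, "p": wu.pvalue,
                                  "method": wu.method}
    print(f"Welch's t on effective speed: t={wt.statistic:.1f} p={wt.pvalue:.2e}")
    print(f"Watson's U2 on directionality: U2={wu.statistic:.2f} p={wu.pvalue:.2e}")

    (ROOT / "results" / "statistics.json").write_text(
        json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
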
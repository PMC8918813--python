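"""Cell-behaviour quantification on canonically aligned tracks.

Everything here consumes tracks in the canonical frame (aorta along x at
y = 0, DLAV dorsal at y = ``y_dlav``) and a :class:`RegionMap` that partitions
the trunk into a ventral PCV/DA band, an ISV band with per-vessel x-slots, and
a dorsal DLAV band.  From these it derives:

* windowed dorsoventral velocity profiles per future vessel class,
* arterial/venous fate of each ISV from its final ventral connectivity,
* inter-vessel exchange events (immigration/emigration across the DLAV and
  PCV junctions) with a K-frame persistence (hysteresis) rule,
* mitotic events from lineage branching,
* per-vessel cell numbers and diameter summaries,
* correlations between final diameter and its cellular drivers, and
* scratch-wound metrics (effective speed, directionality, closure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .track_model import DiameterTable, TrackTable, TrackValidationError

__all__ = [
    "RegionMap",
    "IsvFate",
    "ExchangeLedger",
    "WoundMetrics",
    "region_states",
    "windowed_velocity",
    "window_velocities_long",
    "assign_fate",
    "detect_exchanges",
    "count_mitoses",
    "cell_number",
    "diameter_profile",
    "correlate_drivers",
    "wound_metrics",
    "exchange_histogram",
]

BASE = "BASE"   # pooled PCV/DA band ventral of the ISVs
DLAV = "DLAV"

EXCHANGE_TYPES = ("immigration_dlav", "emigration_dlav",
                  "immigration_pcv", "emigration_pcv")


@dataclass(frozen=True)
class RegionMap:
    """Partition of the canonical (x, y) plane into trunk regions.

    ``y < y_da + delta`` is the pooled PCV/DA band, ``y > y_dlav - delta`` the
    DLAV band, and everything between belongs to the ISV whose x-slot is
    nearest.  ``delta`` is a 5 um guard band so boundary noise does not flip
    region assignments.
    """

    isv_x: dict[str, float]
    y_da: float = 0.0
    y_dlav: float = 100.0
    delta: float = 5.0

    def __post_init__(self) -> None:
        if self.y_dlav - self.delta <= self.y_da + self.delta:
            raise ValueError("DLAV band overlaps the DA band; bad region map")

    @property
    def vessel_ids(self) -> list[str]:
        return sorted(self.isv_x)

    def classify(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.empty(len(x), dtype=object)
        out[y < self.y_da + self.delta] = BASE
        out[y > self.y_dlav - self.delta] = DLAV
        mid = (out == None)  # noqa: E711  -- unassigned entries
        if mid.any():
            ids = np.array(self.vessel_ids, dtype=object)
            slots = np.array([self.isv_x[v] for v in ids], dtype=float)
            nearest = np.argmin(np.abs(x[mid, None] - slots[None, :]), axis=1)
            out[mid] = ids[nearest]
        return out

    @classmethod
    def from_scaffold(cls, n_isv: int, isv_spacing: float, isv_length: float,
                      delta: float = 5.0) -> "RegionMap":
        slots = {f"ISV_{k + 1:02d}": isv_spacing * (k + 1) for k in range(n_isv)}
        return cls(isv_x=slots, y_da=0.0, y_dlav=isv_length, delta=delta)

    @classmethod
    def infer(cls, tracks: TrackTable, delta: float = 5.0) -> "RegionMap":
        """Recover slots and the DLAV height from vessel labels in the table."""
        df = tracks.df
        labels = df["vessel_label"]
        isv = df[labels.notna() & labels.str.startswith("ISV")]
        dlav = df[labels == "DLAV"]
        if not len(isv) or not len(dlav):
            raise ValueError(
                "cannot infer a region map without ISV/DLAV vessel labels; "
                "construct one with RegionMap.from_scaffold"
            )
        slots = isv.groupby("vessel_label")["x"].median().to_dict()
        return cls(isv_x={str(k): float(v) for k, v in slots.items()},
                   y_da=0.0, y_dlav=float(dlav["y"].median()), delta=delta)


@dataclass
class IsvFate:
    """Final arterial/venous identity per ISV, applied retroactively."""

    fates: dict[str, str] = field(default_factory=dict)
    unresolved: set[str] = field(default_factory=set)

    def of(self, vessel_id: str) -> str | None:
        return self.fates.get(vessel_id)

    def vessels(self, vessel_class: str) -> list[str]:
        return sorted(v for v, c in self.fates.items() if c == vessel_class)


@dataclass
class ExchangeLedger:
    """Detected inter-vessel exchange events and per-ISV counts."""

    events: pd.DataFrame        # cell_id, type, vessel_id, t
    counts: pd.DataFrame        # vessel_id x EXCHANGE_TYPES (+ net_immigration)

    def net_immigration(self) -> pd.Series:
        c = self.counts
        return (c["immigration_dlav"] + c["immigration_pcv"]
                - c["emigration_dlav"] - c["emigration_pcv"])


@dataclass
class WoundMetrics:
    per_track: pd.DataFrame     # cell_id, effective_speed, angle, excluded, ...
    closure_pct: float


# ---------------------------------------------------------------------------
# region assignment with hysteresis
# ---------------------------------------------------------------------------

def _run_lengths(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Starts and labels of maximal runs of equal values."""
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate([[0], change])
    return starts, values[starts]


def region_states(tracks: TrackTable, region_map: RegionMap, K: int = 6) -> pd.DataFrame:
    """Per-observation raw region and K-persistent (hysteretic) state.

    The state starts at the cell's first region and only switches once the new
    raw assignment persists for at least ``K`` consecutive frames; shorter
    boundary flicker leaves the state unchanged.
    """
    df = tracks.df
    raw = region_map.classify(df["x"].to_numpy(), df["y"].to_numpy())
    state = np.empty(len(df), dtype=object)
    for _, idx in df.groupby(["embryo_id", "cell_id"], sort=False).indices.items():
        idx = np.sort(idx)
        r = raw[idx]
        starts, labels = _run_lengths(r)
        ends = np.concatenate([starts[1:], [len(r)]])
        s = np.empty(len(r), dtype=object)
        current = labels[0]
        for st, en, lab in zip(starts, ends, labels):
            if lab != current and (en - st) >= K:
                current = lab
            s[st:en] = current
        state[idx] = s
    out = df[["embryo_id", "cell_id", "t"]].copy()
    out["region"] = raw
    out["state"] = state
    return out


# ---------------------------------------------------------------------------
# velocity profiles
# ---------------------------------------------------------------------------

def _bootstrap_ci(values: np.ndarray, n_boot: int, rng: np.random.Generator,
                  alpha: float = 0.05) -> tuple[float, float]:
    if len(values) == 1:
        return float(values[0]), float(values[0])
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def windowed_velocity(
    tracks: TrackTable,
    fate: IsvFate,
    region_map: RegionMap,
    window_h: float = 2.0,
    step_min: float = 10.0,
    t0: float = 26.0,
    t1: float = 44.0,
    K: int = 6,
    n_boot: int = 2000,
    seed: int = 0,
    require_full_window: bool = True,
    settle_h: float = 2.0,
    states: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean dorsoventral velocity per vessel class on a sliding 2 h window.

    Per cell and window the velocity is the signed y-displacement between the
    cell's first and last sample inside the window divided by the window
    length.  A cell contributes to a class only while its hysteretic region
    state is a single ISV of that class for the whole window; with
    ``require_full_window`` (default) the cell must also span the window, which
    keeps cells appearing/disappearing mid-window (divisions, transits) from
    diluting the estimate.  ``settle_h`` additionally requires settled
    residency: on any side where the cell changed vessels, its residency run
    must extend at least ``settle_h`` beyond the window, so translocation legs
    of immigrating/emigrating cells are not read as vessel drift.  The 95% CI
    is a percentile bootstrap over cells.
    """
    long = window_velocities_long(
        tracks, fate, region_map, window_h=window_h, step_min=step_min, t0=t0,
        t1=t1, K=K, require_full_window=require_full_window, settle_h=settle_h,
        states=states)
    rng = np.random.default_rng(seed)
    rows = []
    for (cls, c), sub in long.groupby(["vessel_class", "t_center"]):
        vals = sub["velocity"].to_numpy(dtype=float)
        lo_ci, hi_ci = _bootstrap_ci(vals, n_boot, rng)
        rows.append((cls, float(c), float(vals.mean()), lo_ci, hi_ci, len(vals)))
    return pd.DataFrame(rows, columns=["vessel_class", "t_center", "mean_velocity",
                                       "ci_low", "ci_high", "n_cells"])


def window_velocities_long(
    tracks: TrackTable,
    fate: IsvFate,
    region_map: RegionMap,
    window_h: float = 2.0,
    step_min: float = 10.0,
    t0: float = 26.0,
    t1: float = 44.0,
    K: int = 6,
    require_full_window: bool = True,
    settle_h: float = 2.0,
    states: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per (cell, window) velocity contribution; see windowed_velocity."""
    if states is None:
        states = region_states(tracks, region_map, K=K)
    df = tracks.df.assign(state=states["state"].to_numpy())
    half = window_h / 2.0
    step = step_min / 60.0
    centers = np.arange(t0 + half, t1 - half + 1e-9, step)
    frame_h = tracks.frame_interval_min / 60.0
    # samples must sit within half a frame of each window edge: grid offsets
    # pass, but tracks ending a full frame short (division mothers) do not
    ftol = 0.51 * frame_h
    eps = 0.01 * frame_h   # absorbs fp drift between grid and window edges

    rows = []
    for (embryo, cid), sub in df.groupby(["embryo_id", "cell_id"], sort=False):
        t = sub["t"].to_numpy()
        y = sub["y"].to_numpy()
        st = sub["state"].to_numpy()
        run_starts, _ = _run_lengths(st)
        run_ends = np.concatenate([run_starts[1:], [len(st)]]) - 1
        run_of = np.repeat(np.arange(len(run_starts)), np.diff(
            np.concatenate([run_starts, [len(st)]])))
        for c in centers:
            lo, hi = c - half, c + half
            i0 = int(np.searchsorted(t, lo - eps, side="left"))
            i1 = int(np.searchsorted(t, hi + eps, side="right")) - 1
            if i1 - i0 < 1:
                continue
            if require_full_window and (t[i0] > lo + ftol or t[i1] < hi - ftol):
                continue
            vessel = st[i0]
            if vessel in (BASE, DLAV) or run_of[i0] != run_of[i1]:
                continue
            cls = fate.of(str(vessel))
            if cls is None:
                continue
            run = run_of[i0]
            if run > 0 and t[run_starts[run]] > lo - settle_h + 1e-9:
                continue   # recently arrived: translocation leg may leak in
            if run < len(run_starts) - 1 and t[run_ends[run]] < hi + settle_h - 1e-9:
                continue   # about to leave: departure leg may leak in
            rows.append((embryo, cid, str(vessel), cls, float(c),
                         (y[i1] - y[i0]) / window_h))
    return pd.DataFrame(rows, columns=["embryo_id", "cell_id", "vessel_id",
                                       "vessel_class", "t_center", "velocity"])


# ---------------------------------------------------------------------------
# fate, exchange, mitoses, cell numbers
# ---------------------------------------------------------------------------

def assign_fate(
    tracks: TrackTable,
    region_map: RegionMap,
    final_time: float | None = None,
) -> IsvFate:
    """Classify each ISV by its ventral connection at the final frame.

    An ISV is venous when a cell sits clearly below the DA plane
    (y < y_da - delta, i.e. PCV territory) at its x-slot at the end of the
    recording; otherwise it is arterial provided the vessel is populated at
    all; ISVs with no final-frame signal are flagged unresolved.
    """
    df = tracks.df
    if final_time is None:
        final_time = float(df["t"].max())
    if not (df["t"].min() - 1e-9 <= final_time <= df["t"].max() + 1e-9):
        raise ValueError(f"final_time {final_time} outside the recording")
    t_near = df["t"].iloc[(df["t"] - final_time).abs().argmin()]
    last = df[np.isclose(df["t"], t_near)]
    fate = IsvFate()
    ids = region_map.vessel_ids
    slots = np.array([region_map.isv_x[v] for v in ids])
    half_span = (np.median(np.diff(np.sort(slots))) / 2.0) if len(slots) > 1 else np.inf
    x = last["x"].to_numpy()
    y = last["y"].to_numpy()
    region = region_map.classify(x, y)
    for vid, slot in zip(ids, slots):
        near = np.abs(x - slot) <= half_span
        if (near & (y < region_map.y_da - region_map.delta)).any():
            fate.fates[vid] = "vISV"
        elif (region == vid).any():
            fate.fates[vid] = "aISV"
        else:
            fate.unresolved.add(vid)
    return fate


def detect_exchanges(
    tracks: TrackTable,
    region_map: RegionMap,
    K: int = 6,
    states: pd.DataFrame | None = None,
) -> ExchangeLedger:
    """Record exchange events as K-persistent region-state changes.

    A cell immigrates into an ISV when its state switches from the DLAV (or
    the PCV/DA band) to that ISV and the new assignment persists for at least
    K frames; emigration is the reverse.  Sub-K boundary flicker never
    produces an event (hysteresis).
    """
    if states is None:
        states = region_states(tracks, region_map, K=K)
    events = []
    for (_, cid), sub in states.groupby(["embryo_id", "cell_id"], sort=False):
        st = sub["state"].to_numpy()
        t = sub["t"].to_numpy()
        starts, labels = _run_lengths(st)
        for j in range(1, len(starts)):
            prev, cur = labels[j - 1], labels[j]
            t_ev = t[starts[j]]
            if cur not in (BASE, DLAV) and prev == DLAV:
                events.append((cid, "immigration_dlav", cur, t_ev))
            elif cur not in (BASE, DLAV) and prev == BASE:
                events.append((cid, "immigration_pcv", cur, t_ev))
            elif prev not in (BASE, DLAV) and cur == DLAV:
                events.append((cid, "emigration_dlav", prev, t_ev))
            elif prev not in (BASE, DLAV) and cur == BASE:
                events.append((cid, "emigration_pcv", prev, t_ev))
            # direct BASE<->DLAV or ISV<->ISV switches are not ISV junction events
    ev = pd.DataFrame(events, columns=["cell_id", "type", "vessel_id", "t"])
    counts = pd.DataFrame(0, index=pd.Index(region_map.vessel_ids, name="vessel_id"),
                          columns=list(EXCHANGE_TYPES))
    if len(ev):
        got = ev.pivot_table(index="vessel_id", columns="type", values="cell_id",
                             aggfunc="count", fill_value=0)
        for col in got.columns:
            counts.loc[got.index, col] = got[col]
    counts["net_immigration"] = (counts["immigration_dlav"] + counts["immigration_pcv"]
                                 - counts["emigration_dlav"] - counts["emigration_pcv"])
    return ExchangeLedger(events=ev, counts=counts.reset_index())


def count_mitoses(
    tracks: TrackTable,
    region_map: RegionMap,
    K: int = 6,
    states: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-vessel division counts; one mitosis per lineage branching node.

    Each division is attributed to the vessel containing the mother at her
    last observation (hysteretic state).
    """
    if states is None:
        states = region_states(tracks, region_map, K=K)
    lineage = tracks.lineage()
    for parent, children in lineage.items():
        if len(children) > 2:
            raise TrackValidationError(f"cell {parent} branches into {len(children)} children")
    last_state = states.groupby("cell_id", sort=False)["state"].last()
    counts = {vid: 0 for vid in region_map.vessel_ids}
    for parent in lineage:
        vessel = last_state.get(parent)
        if vessel in counts:
            counts[vessel] += 1
    return pd.DataFrame({"vessel_id": list(counts), "mitoses": list(counts.values())})


def cell_number(
    tracks: TrackTable,
    region_map: RegionMap,
    t: float,
    K: int = 6,
    states: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Distinct cells per ISV at the frame nearest ``t`` (hysteretic states)."""
    df = tracks.df
    if t < df["t"].min() - 1e-9 or t > df["t"].max() + 1e-9:
        raise ValueError(f"time {t} outside the recording span")
    if states is None:
        states = region_states(tracks, region_map, K=K)
    t_near = df["t"].iloc[(df["t"] - t).abs().argmin()]
    at = states[np.isclose(states["t"], t_near)]
    counts = {vid: 0 for vid in region_map.vessel_ids}
    for vid, n in at.groupby("state")["cell_id"].nunique().items():
        if vid in counts:
            counts[vid] = int(n)
    return pd.DataFrame({"vessel_id": list(counts), "n_cells": list(counts.values())})


def diameter_profile(
    diameters: DiameterTable,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-class mean diameter with bootstrap 95% CI on the measurement grid."""
    d = diameters.df[diameters.df["diameter"] > 0]
    rng = np.random.default_rng(seed)
    rows = []
    for (cls, t), sub in d.groupby(["vessel_class", "t"]):
        vals = sub["diameter"].to_numpy(dtype=float)
        lo, hi = _bootstrap_ci(vals, n_boot, rng)
        rows.append((cls, float(t), float(vals.mean()), lo, hi, len(vals)))
    return pd.DataFrame(rows, columns=["vessel_class", "t", "mean_diameter",
                                       "ci_low", "ci_high", "n_vessels"])


def exchange_histogram(counts: pd.DataFrame, fate: IsvFate) -> pd.DataFrame:
    """Fraction of ISVs (per class) with 0 / 1 / 2 / >=3 events of each type."""
    rows = []
    merged = counts.assign(vessel_class=[fate.of(v) for v in counts["vessel_id"]])
    merged = merged[merged["vessel_class"].notna()]
    for cls, sub in merged.groupby("vessel_class"):
        for ev in EXCHANGE_TYPES:
            c = sub[ev].to_numpy()
            n = len(c)
            for label, mask in (("0", c == 0), ("1", c == 1),
                                ("2", c == 2), ("3+", c >= 3)):
                rows.append((cls, ev, label, float(mask.sum()) / n if n else np.nan, n))
    return pd.DataFrame(rows, columns=["vessel_class", "type", "events", "fraction",
                                       "n_vessels"])


def correlate_drivers(
    per_isv: pd.DataFrame,
    drivers: tuple[str, ...] = ("mitoses", "net_immigration"),
    response: str = "final_diameter",
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate final vessel diameter with its cellular drivers, per class.

    ``per_isv`` needs one row per ISV with columns ``vessel_class``, the
    drivers and the response.  Pearson by default, Spearman available.
    """
    corr = {"pearson": sps.pearsonr, "spearman": sps.spearmanr}[method]
    rows = []
    for cls, sub in per_isv.groupby("vessel_class"):
        for drv in drivers:
            pair = sub[[drv, response]].dropna()
            if len(pair) < 3:
                raise ValueError(f"need >=3 ISVs for {cls}/{drv}, got {len(pair)}")
            r, p = corr(pair[drv], pair[response])
            rows.append((cls, drv, float(r), float(p), len(pair)))
    return pd.DataFrame(rows, columns=["vessel_class", "driver", "r", "p", "n"])


# ---------------------------------------------------------------------------
# scratch-wound metrics
# ---------------------------------------------------------------------------

def wound_metrics(
    tracks: TrackTable,
    area_t0: float,
    area_t1: float,
) -> WoundMetrics:
    """Effective speed and directionality per track plus % wound closure.

    Tracks must be aligned with the wound edge along the y-axis and the free
    space at x > 0.  Effective speed is the start-to-end chord over the
    tracking time; the directionality angle is measured between the
    start-to-end vector and the +y axis (so +x, into the wound, is +pi/2).
    Zero-duration or zero-displacement tracks are excluded from the rosette.
    """
    if area_t0 <= 0:
        raise ValueError("initial wound area must be positive")
    to_hours = 1.0 / 60.0 if tracks.time_unit == "min" else 1.0
    rows = []
    for cid, sub in tracks.df.groupby("cell_id", sort=False):
        t = sub["t"].to_numpy() * to_hours
        x = sub["x"].to_numpy()
        y = sub["y"].to_numpy()
        duration = t[-1] - t[0]
        dx, dy = x[-1] - x[0], y[-1] - y[0]
        chord = float(np.hypot(dx, dy))
        path = float(np.hypot(np.diff(x), np.diff(y)).sum())
        excluded = duration <= 0 or chord == 0.0
        rows.append({
            "cell_id": cid,
            "duration_h": duration,
            "effective_speed": chord / duration if duration > 0 else np.nan,
            "path_speed": path / duration if duration > 0 else np.nan,
            "angle": np.arctan2(dx, dy) if not excluded else np.nan,
            "excluded": excluded,
        })
    closure = (area_t0 - area_t1) / area_t0 * 100.0
    return WoundMetrics(per_track=pd.DataFrame(rows), closure_pct=float(closure))
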
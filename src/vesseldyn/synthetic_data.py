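"""Synthetic zebrafish-embryo and HUVEC-monolayer datasets with ground truth.

The embryo generator emits nucleus tracks on an idealized trunk scaffold:
the dorsal aorta (DA) runs along the x-axis at y = 0, the DLAV runs parallel
at y = ``isv_length``, and vertical intersegmental vessels (ISVs) sit at
multiples of ``isv_spacing``.  The posterior cardinal vein (PCV) is a band
below the DA (y < 0).  Each ISV carries a future arterial or venous identity;
its resident cells integrate a phase-dependent dorsoventral drift (sprouting /
anastomosis / remodelling / quiescent), divisions branch tracks, and
inter-vessel exchange events translocate cells continuously across the
DLAV and PCV junctions.  Gaussian observation noise is added to every
coordinate.  Everything injected is recorded in a ground-truth ledger so each
downstream stage can be scored exactly.

The monolayer generator emits 2D wound-assay tracks: per-cell persistent
migration directions (toward the free space at x > 0 for control-like
configurations, isotropic for WASp-knockdown-like ones), a random-walk noise
component, and a wound-area series consistent with the mean front advance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .track_model import DiameterTable, TrackTable

__all__ = [
    "ConfigError",
    "EmbryoSimConfig",
    "MonolayerSimConfig",
    "GroundTruthLedger",
    "generate_embryo",
    "generate_cohort",
    "generate_monolayer",
]

EVENT_COLUMNS = ["event", "cell_id", "vessel_id", "source", "destination", "t"]


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class EmbryoSimConfig:
    """Study conditions for one simulated embryo.

    Drift velocities (um/h, positive = dorsal) follow the in-vivo phase
    profile: vISV 5 -> 2 -> 3 -> 0 and aISV 3.9 -> 1 -> -0.6 -> 0 across the
    sprouting / anastomosis / remodelling / quiescent phases, with phase cut
    points at 30, 33 and 40 hpf.  Exchange probabilities are the observed
    fractions of vessels with at least one event (60% of aISVs gain a cell
    from the DLAV, 76% of vISVs lose one to the DLAV, 92% of vISVs gain one
    from the PCV).  Division hazards are calibrated to ~0.9 (aISV) and ~2.0
    (vISV) expected divisions per vessel over 26-44 hpf.
    """

    n_isv: int = 10
    isv_spacing: float = 75.0          # um
    isv_length: float = 100.0          # um, DA plane to DLAV
    t0: float = 26.0                   # hpf
    t1: float = 44.0                   # hpf
    frame_interval_min: float = 10.0
    phase_boundaries: tuple[float, float, float] = (30.0, 33.0, 40.0)
    drift: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {"vISV": (5.0, 2.0, 3.0, 0.0), "aISV": (3.9, 1.0, -0.6, 0.0)}
    )
    noise_sd: float = 0.5              # um observation noise per coordinate per frame
    division_hazard: dict[str, float] = field(
        default_factory=lambda: {"aISV": 0.015, "vISV": 0.028}  # per cell per hour
    )
    p_immigration_dlav: float = 0.60   # P(>=1 DLAV -> aISV immigration) per aISV
    p_emigration_dlav: float = 0.76    # P(>=1 vISV -> DLAV emigration) per vISV
    p_immigration_pcv: float = 0.92    # P(>=1 PCV -> vISV immigration) per vISV
    two_cell_fraction: float = 0.3     # P(event moves 2 cells | >=1)
    diameter_growth: dict[str, tuple[float, float]] = field(
        # (diameter at t0 in um, slope in um/h); aISV -> ~7 um, vISV -> ~8 um at 44 hpf
        default_factory=lambda: {
            "aISV": (4.0, 3.0 / 18.0),
            "vISV": (4.0, 4.0 / 18.0),
            "DA": (25.0, 0.0),
            "DLAV": (8.0, 0.0),
        }
    )
    diameter_noise_sd: float = 0.15    # um measurement noise on diameter readings
    cells_per_isv: int = 3
    n_da_cells: int = 20
    n_dlav_cells: int = 5
    transit_speed: float = 40.0        # um/h during exchange translocations
    first_class: str = "aISV"
    scramble_frame: bool = False
    embryo_id: str = "embryo_01"
    seed: int = 0

    def validate(self) -> "EmbryoSimConfig":
        if self.t1 <= self.t0:
            raise ConfigError("t1 must exceed t0")
        probs = (self.p_immigration_dlav, self.p_emigration_dlav,
                 self.p_immigration_pcv, self.two_cell_fraction)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("exchange probabilities must lie in [0, 1]")
        if self.n_isv == 0 and any(p > 0 for p in probs[:3]):
            raise ConfigError("zero ISVs but nonzero exchange probabilities")
        for cls, vel in self.drift.items():
            if not np.all(np.isfinite(vel)):
                raise ConfigError(f"non-finite drift for {cls}")
        if any(h < 0 for h in self.division_hazard.values()):
            raise ConfigError("division hazards must be >= 0")
        if self.noise_sd < 0 or self.transit_speed <= 0:
            raise ConfigError("noise_sd must be >= 0 and transit_speed > 0")
        return self

    @property
    def dt(self) -> float:
        return self.frame_interval_min / 60.0

    @property
    def n_frames(self) -> int:
        return int(round((self.t1 - self.t0) / self.dt)) + 1

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) * self.dt

    def phase_velocity(self, vessel_class: str, t: np.ndarray) -> np.ndarray:
        """Piecewise-constant dorsoventral drift (um/h) for a vessel class."""
        b = self.phase_boundaries
        vel = self.drift[vessel_class]
        idx = np.searchsorted(np.asarray(b), np.asarray(t), side="right")
        return np.asarray(vel, dtype=float)[idx]


@dataclass(frozen=True)
class MonolayerSimConfig:
    """Study conditions for one simulated HUVEC scratch-wound assay."""

    n_tracks: int = 300
    duration_h: float = 16.0
    frame_interval_min: float = 10.0
    speed_um_per_h: float = 9.0        # persistent migration speed
    speed_scale: float = 1.0           # knockdown-like configs scale all motion
    directed: bool = True              # drift toward the free space (+x) vs isotropic
    angle_jitter_sd: float = 0.3       # rad, spread of per-cell direction (directed)
    noise_sd: float = 1.5              # um random-walk step noise per frame per axis
    gap_um: float = 500.0              # initial cell-free gap width
    field_um: float = 1000.0           # imaged field height along the wound edge
    condition: str = "siCTR"
    assay_id: str = "assay_01"
    seed: int = 0

    def validate(self) -> "MonolayerSimConfig":
        if self.speed_um_per_h < 0 or self.speed_scale < 0:
            raise ConfigError("speeds must be non-negative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.duration_h <= 0 or self.n_tracks < 1:
            raise ConfigError("need positive duration and at least one track")
        return self

    @property
    def dt(self) -> float:
        return self.frame_interval_min / 60.0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h / self.dt)) + 1


@dataclass
class GroundTruthLedger:
    """Everything injected into a synthetic dataset, for exact scoring."""

    events: pd.DataFrame
    fates: dict[str, str]
    drift: dict[str, tuple[float, float, float, float]] | dict
    diameter_growth: dict
    config: EmbryoSimConfig | MonolayerSimConfig
    canonical_tracks: TrackTable | None = None
    frame_rotation: np.ndarray | None = None
    frame_translation: np.ndarray | None = None

    def events_of(self, kind: str) -> pd.DataFrame:
        return self.events[self.events["event"] == kind].reset_index(drop=True)


def _embryo_rng(seed: int, embryo_id: str) -> np.random.Generator:
    # one stream per embryo keyed by (seed, embryo_id)
    return np.random.default_rng((int(seed), zlib.crc32(embryo_id.encode())))


class _Cell:
    __slots__ = ("cell_id", "parent_id", "f0", "y", "x", "z", "divisible", "home",
                 "birth_t")

    def __init__(self, cell_id, parent_id, f0, x, y, z, divisible=False, home=None,
                 birth_t=None):
        self.cell_id = cell_id
        self.parent_id = parent_id
        self.f0 = int(f0)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.z = np.asarray(z, dtype=float)
        self.divisible = divisible
        self.home = home  # ISV vessel id for resident cells
        self.birth_t = birth_t  # continuous birth time; keeps the division
        # clock faithful to the hazard process despite frame discretization


def _integrate_drift(cfg: EmbryoSimConfig, vessel_class: str, y0: float, f0: int,
                     f1: int | None = None) -> np.ndarray:
    """Deterministic dorsoventral path from frame f0 (inclusive) to f1 (inclusive)."""
    times = cfg.times()
    f1 = cfg.n_frames - 1 if f1 is None else f1
    t = times[f0:f1 + 1]
    if len(t) == 0:
        return np.empty(0)
    v = cfg.phase_velocity(vessel_class, t[:-1]) if len(t) > 1 else np.empty(0)
    return y0 + np.concatenate([[0.0], np.cumsum(v * cfg.dt)])


def _ramp(y_from: float, y_to: float, speed: float, dt: float, n_hold: int) -> np.ndarray:
    """Constant-speed translocation from y_from to y_to, then flat for n_hold frames."""
    step = speed * dt
    n_move = max(int(np.ceil(abs(y_to - y_from) / step)), 1)
    path = y_from + np.sign(y_to - y_from) * step * np.arange(1, n_move + 1)
    path = np.clip(path, min(y_from, y_to), max(y_from, y_to))
    path[-1] = y_to
    return np.concatenate([path, np.full(max(n_hold, 0), y_to)])


def generate_embryo(
    config: EmbryoSimConfig,
) -> tuple[TrackTable, DiameterTable, GroundTruthLedger]:
    """Simulate one embryo; returns tracks, diameters and the ground-truth ledger."""
    cfg = config.validate()
    rng = _embryo_rng(cfg.seed, cfg.embryo_id)
    times = cfg.times()
    n_frames = cfg.n_frames
    dt = cfg.dt
    classes = ["aISV", "vISV"]
    if cfg.first_class not in classes:
        raise ConfigError(f"first_class must be one of {classes}")
    offset = classes.index(cfg.first_class)

    vessel_ids = [f"ISV_{k + 1:02d}" for k in range(cfg.n_isv)]
    fates = {vid: classes[(k + offset) % 2] for k, vid in enumerate(vessel_ids)}
    slots = {vid: cfg.isv_spacing * (k + 1) for k, vid in enumerate(vessel_ids)}
    da_span = cfg.isv_spacing * (cfg.n_isv + 1)

    cells: list[_Cell] = []
    events: list[tuple] = []

    def frame_of(t: float) -> int:
        return int(np.clip(round((t - cfg.t0) / dt), 0, n_frames - 1))

    # --- DA residents (anchor the axis regression) ---------------------
    for i in range(cfg.n_da_cells):
        x0 = rng.uniform(0.0, da_span)
        cells.append(_Cell(f"DA_{i + 1:02d}", None, 0,
                           np.full(n_frames, x0), np.zeros(n_frames), np.zeros(n_frames)))

    # --- DLAV background residents (roll/orientation reference) --------
    f_dlav = frame_of(cfg.phase_boundaries[0])
    n_after = n_frames - f_dlav
    for i in range(cfg.n_dlav_cells):
        x0 = rng.uniform(0.5 * cfg.isv_spacing, da_span - 0.5 * cfg.isv_spacing)
        cells.append(_Cell(f"DLAV_{i + 1:02d}", None, f_dlav,
                           np.full(n_after, x0), np.full(n_after, cfg.isv_length),
                           np.zeros(n_after)))

    # --- per-ISV basal connection cells (encode final ventral identity) -
    f_remodel = frame_of(cfg.phase_boundaries[1])
    for vid in vessel_ids:
        x = np.full(n_frames, slots[vid])
        y = np.full(n_frames, 0.0)
        if fates[vid] == "vISV":
            f_move = f_remodel + int(rng.integers(0, 7))
            ramp = _ramp(0.0, -8.0, 10.0, dt, n_hold=n_frames)
            avail = n_frames - (f_move + 1)
            if avail > 0:
                y[f_move + 1:] = ramp[:avail]
        cells.append(_Cell(f"CONN_{vid}", None, 0, x, y, np.zeros(n_frames)))

    # --- ISV resident cells --------------------------------------------
    division_queue: list[_Cell] = []
    for vid in vessel_ids:
        for i in range(cfg.cells_per_isv):
            y0 = 8.0 + 8.0 * i
            y = _integrate_drift(cfg, fates[vid], y0, 0)
            x = np.full(n_frames, slots[vid] + rng.uniform(-3.0, 3.0))
            z = np.full(n_frames, rng.uniform(-3.0, 3.0))
            cell = _Cell(f"{vid}_c{i + 1}", None, 0, x, y, z, divisible=True, home=vid)
            cells.append(cell)
            division_queue.append(cell)

    # --- divisions (branching process on resident cells) ---------------
    # processed before exchange selection so the emigration program never
    # censors the division hazard
    while division_queue:
        cell = division_queue.pop(0)
        hazard = cfg.division_hazard.get(fates[cell.home], 0.0)
        if hazard <= 0:
            continue
        t_birth = times[cell.f0] if cell.birth_t is None else cell.birth_t
        t_div = t_birth + rng.exponential(1.0 / hazard)
        f_div = max(int(np.floor((t_div - cfg.t0) / dt)), cell.f0)
        last = cell.f0 + len(cell.y) - 1
        if f_div >= last:  # no division before the cell's record ends
            continue
        # mother ends at the division frame; daughters start one frame later
        keep = f_div - cell.f0 + 1
        y_div, x_div, z_div = cell.y[keep - 1], cell.x[keep - 1], cell.z[keep - 1]
        cell.y, cell.x, cell.z = cell.y[:keep], cell.x[:keep], cell.z[:keep]
        events.append(("division", cell.cell_id, cell.home, cell.home, cell.home,
                       times[f_div]))
        for tag, sign in (("a", 1.0), ("b", -1.0)):
            y0 = float(np.clip(y_div + sign * 1.5, 6.0, cfg.isv_length - 6.0))
            y = _integrate_drift(cfg, fates[cell.home], y0, f_div + 1)
            n = len(y)
            child = _Cell(f"{cell.cell_id}{tag}", cell.cell_id, f_div + 1,
                          np.full(n, x_div + sign * rng.uniform(0.5, 1.5)), y,
                          np.full(n, z_div), divisible=True, home=cell.home,
                          birth_t=t_div)
            cells.append(child)
            division_queue.append(child)

    # --- exchange programs ---------------------------------------------
    def n_moved(p: float) -> int:
        if rng.random() >= p:
            return 0
        return 2 if rng.random() < cfg.two_cell_fraction else 1

    def exchange_path(f_spawn: int, f_ev: int, y_src: float, y_dest: float,
                      settle_class: str) -> np.ndarray | None:
        """Flat pre-event residence, constant-speed transit, then class drift."""
        pre = np.full(f_ev - f_spawn + 1, y_src)
        ramp = _ramp(y_src, y_dest, cfg.transit_speed, dt, 0)
        n_settle = n_frames - f_spawn - len(pre) - len(ramp)
        if n_settle < 1:   # event too late to settle before recording ends
            return None
        settle = _integrate_drift(cfg, settle_class, y_dest,
                                  f_ev + len(ramp))[1:n_settle + 1]
        return np.concatenate([pre, ramp, settle])

    t_lo, t_hi = cfg.phase_boundaries[1], cfg.phase_boundaries[1] + 4.0
    for vid in vessel_ids:
        slot = slots[vid]
        if fates[vid] == "aISV":
            for i in range(n_moved(cfg.p_immigration_dlav)):
                f_ev = frame_of(rng.uniform(t_lo, t_hi))
                y_dest = rng.uniform(25.0, 45.0)
                y = exchange_path(f_dlav, f_ev, cfg.isv_length, y_dest, "aISV")
                if y is None:
                    continue
                cid = f"IMMD_{vid}_{i + 1}"
                x_start = slot + rng.uniform(-15.0, 15.0)
                n_pre = f_ev - f_dlav + 1
                n_ramp = len(_ramp(cfg.isv_length, y_dest, cfg.transit_speed, dt, 0))
                x = np.full(len(y), slot)
                x[:n_pre] = x_start
                x[n_pre:n_pre + n_ramp] = np.linspace(x_start, slot, n_ramp)
                cells.append(_Cell(cid, None, f_dlav, x, y, np.zeros(len(y))))
                events.append(("immigration", cid, vid, "DLAV", vid, times[f_ev]))
        else:
            # emigrants are drawn from cells whose record spans the event
            # through the end (lineage leaves), so the division process above
            # stays untouched
            taken: set[str] = set()
            for i in range(n_moved(cfg.p_emigration_dlav)):
                f_ev = frame_of(rng.uniform(t_lo, t_hi))
                cell = next(
                    (c for c in cells
                     if c.home == vid and c.cell_id not in taken
                     and c.f0 <= f_ev and c.f0 + len(c.y) == n_frames), None)
                if cell is None:
                    continue
                taken.add(cell.cell_id)
                i_ev = f_ev - cell.f0
                ramp = _ramp(cell.y[i_ev], cfg.isv_length, cfg.transit_speed, dt,
                             n_frames)
                cell.y[i_ev + 1:] = ramp[: len(cell.y) - i_ev - 1]
                events.append(("emigration", cell.cell_id, vid, vid, "DLAV", times[f_ev]))
            for i in range(n_moved(cfg.p_immigration_pcv)):
                f_ev = frame_of(rng.uniform(cfg.phase_boundaries[0] + 1.0, t_lo + 1.0))
                y_src = -10.0 - rng.uniform(0.0, 8.0)
                y_dest = rng.uniform(15.0, 35.0)
                y = exchange_path(f_dlav, f_ev, y_src, y_dest, "vISV")
                if y is None:
                    continue
                cid = f"IMMP_{vid}_{i + 1}"
                x = np.full(len(y), slot + rng.uniform(-5.0, 5.0))
                cells.append(_Cell(cid, None, f_dlav, x, y, np.zeros(len(y))))
                events.append(("immigration", cid, vid, "PCV", vid, times[f_ev]))

    # --- assemble the table --------------------------------------------
    slot_x = np.array([slots[v] for v in vessel_ids]) if vessel_ids else np.empty(0)
    rows = []
    for cell in cells:
        n = len(cell.y)
        f = np.arange(cell.f0, cell.f0 + n)
        noise = rng.normal(0.0, cfg.noise_sd, size=(n, 3)) if cfg.noise_sd > 0 else 0.0
        xyz = np.column_stack([cell.x, cell.y, cell.z]) + noise
        labels = np.empty(n, dtype=object)
        y_true = cell.y
        labels[y_true < 0.0] = "PCV"
        labels[(y_true >= 0.0) & (y_true < 5.0)] = "DA"
        labels[y_true > cfg.isv_length - 5.0] = "DLAV"
        mid = (y_true >= 5.0) & (y_true <= cfg.isv_length - 5.0)
        if mid.any() and len(slot_x):
            nearest = np.argmin(np.abs(cell.x[mid, None] - slot_x[None, :]), axis=1)
            labels[mid] = np.array(vessel_ids, dtype=object)[nearest]
        elif mid.any():
            labels[mid] = "ISV"
        rows.append(pd.DataFrame({
            "embryo_id": cfg.embryo_id, "cell_id": cell.cell_id,
            "parent_id": cell.parent_id, "t": times[f],
            "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2], "vessel_label": labels,
        }))
    df = pd.concat(rows, ignore_index=True)
    tracks = TrackTable(df, frame_interval_min=cfg.frame_interval_min).validate()

    # --- diameters -------------------------------------------------------
    grid = np.arange(cfg.t0, cfg.t1 + 1e-9, 1.0)
    diam_rows = []
    vessel_entries = [("DA", "DA"), ("DLAV", "DLAV")] + [(v, fates[v]) for v in vessel_ids]
    for vid, cls in vessel_entries:
        icpt, slope = cfg.diameter_growth[cls]
        v_off = rng.normal(0.0, 0.25)
        noise = rng.normal(0.0, cfg.diameter_noise_sd, size=len(grid))
        d = np.clip(icpt + v_off + slope * (grid - cfg.t0) + noise, 0.5, None)
        diam_rows.append(pd.DataFrame({
            "embryo_id": cfg.embryo_id, "vessel_id": vid, "vessel_class": cls,
            "t": grid, "diameter": d,
        }))
    diameters = DiameterTable(pd.concat(diam_rows, ignore_index=True)).validate()

    events_df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    ledger = GroundTruthLedger(events=events_df, fates=fates, drift=dict(cfg.drift),
                               diameter_growth=dict(cfg.diameter_growth), config=cfg)

    if cfg.scramble_frame:
        ledger.canonical_tracks = tracks
        m = rng.normal(size=(3, 3))
        q, r = np.linalg.qr(m)
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1.0
        tvec = rng.uniform(-300.0, 300.0, size=3)
        scrambled = tracks.with_positions(tracks.positions() @ q.T + tvec)
        ledger.frame_rotation = q
        ledger.frame_translation = tvec
        tracks = scrambled

    return tracks, diameters, ledger


def generate_cohort(
    n_embryos: int,
    config: EmbryoSimConfig = EmbryoSimConfig(),
    seed: int = 0,
) -> tuple[TrackTable, DiameterTable, list[GroundTruthLedger]]:
    """Simulate a cohort; each embryo gets its own RNG stream keyed by its id."""
    tracks, diams, ledgers = [], [], []
    for i in range(n_embryos):
        cfg = replace(config, embryo_id=f"embryo_{i + 1:02d}", seed=seed)
        t, d, led = generate_embryo(cfg)
        tracks.append(t.df)
        diams.append(d.df)
        ledgers.append(led)
    table = TrackTable(pd.concat(tracks, ignore_index=True),
                       frame_interval_min=config.frame_interval_min)
    return table, DiameterTable(pd.concat(diams, ignore_index=True)), ledgers


def generate_monolayer(
    config: MonolayerSimConfig,
) -> tuple[TrackTable, pd.DataFrame, GroundTruthLedger]:
    """Simulate a scratch-wound assay; returns 2D tracks, wound-area series, ledger.

    The wound-area series reflects the mean front advance implied by the
    configured persistent motion; isotropic configurations therefore close
    essentially nothing (the generator does not emulate proliferation-driven
    closure).
    """
    cfg = config.validate()
    rng = _embryo_rng(cfg.seed, cfg.assay_id)
    n, nf, dt = cfg.n_tracks, cfg.n_frames, cfg.dt
    speed = cfg.speed_um_per_h * cfg.speed_scale

    if cfg.directed:
        phi = rng.normal(0.0, cfg.angle_jitter_sd, size=n)  # about +x, toward the wound
    else:
        phi = rng.uniform(-np.pi, np.pi, size=n)
    vel = speed * np.column_stack([np.cos(phi), np.sin(phi)])   # um/h per cell

    start = np.column_stack([rng.uniform(-150.0, 0.0, size=n),
                             rng.uniform(0.0, cfg.field_um, size=n)])
    steps = np.broadcast_to(vel[:, None, :] * dt, (n, nf - 1, 2)).copy()
    if cfg.noise_sd > 0:
        steps += rng.normal(0.0, cfg.noise_sd * cfg.speed_scale, size=(n, nf - 1, 2))
    pos = np.concatenate([start[:, None, :],
                          start[:, None, :] + np.cumsum(steps, axis=1)], axis=1)

    t_grid = np.arange(nf) * dt * 60.0  # minutes
    df = pd.DataFrame({
        "embryo_id": cfg.assay_id,
        "cell_id": np.repeat([f"huvec_{i + 1:03d}" for i in range(n)], nf),
        "parent_id": pd.NA,
        "t": np.tile(t_grid, n),
        "x": pos[:, :, 0].ravel(),
        "y": pos[:, :, 1].ravel(),
        "z": 0.0,
        "vessel_label": pd.NA,
    })
    tracks = TrackTable(df, frame_interval_min=cfg.frame_interval_min,
                        time_unit="min", is_3d=False).validate()

    # wound area: both fronts advance at the mean persistent x-velocity
    front_speed = max(float(np.mean(vel[:, 0])), 0.0)
    hours = np.array([0.0, cfg.duration_h])
    width = np.clip(cfg.gap_um - 2.0 * front_speed * hours, 0.0, None)
    area = pd.DataFrame({"t_h": hours, "area_um2": width * cfg.field_um})

    ledger = GroundTruthLedger(
        events=pd.DataFrame(columns=EVENT_COLUMNS), fates={},
        drift={"speed_um_per_h": speed, "directed": cfg.directed,
               "front_speed_um_per_h": front_speed},
        diameter_growth={}, config=cfg,
    )
    return tracks, area, ledger
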
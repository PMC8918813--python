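"""Domain types and validated readers/writers for cell-track, diameter and key-file tables.

The canonical track layout is a flat CSV with one row per nucleus observation:

    embryo_id, cell_id, parent_id, t, x, y, z, vessel_label

with time in decimal hours post-fertilization (zebrafish) or minutes (HUVEC
monolayers) and positions in micrometres.  A two-file "objects + links" layout
(objects.csv holding per-observation positions, links.csv grouping object ids
into tracks) is accepted on read.  Divisions are encoded purely through
lineage: the mother track ends at the division frame and two daughter
``cell_id``s start afterwards, both carrying the mother's id in ``parent_id``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TRACK_COLUMNS",
    "VESSEL_CLASSES",
    "CONDITIONS",
    "TrackFormatError",
    "TrackValidationError",
    "TrackTable",
    "DiameterTable",
    "KeyFile",
    "read_tracks",
    "write_tracks",
    "read_diameters",
    "write_diameters",
    "read_keyfile",
]

#: canonical column order of the flat track CSV
TRACK_COLUMNS = ["embryo_id", "cell_id", "parent_id", "t", "x", "y", "z", "vessel_label"]

#: vessel classes used by diameter tables and the flow model
VESSEL_CLASSES = ("DA", "DLAV", "aISV", "vISV")

#: closed vocabulary of experimental conditions in key files
CONDITIONS = (
    "control",
    "MO-control",
    "MO-wasb",
    "MO-gata1",
    "MO-gata1-wasb",
    "siCTR",
    "siWAS",
    "siPECAM",
)


class TrackFormatError(ValueError):
    """A file does not have the structure of a supported track dialect."""


class TrackValidationError(ValueError):
    """A structurally readable table violates track invariants."""


def _as_str_or_na(series: pd.Series) -> pd.Series:
    out = series.astype("string")
    out = out.where(~out.isin(["", "nan", "None"]), pd.NA)
    return out


@dataclass
class TrackTable:
    """Ordered collection of nucleus observations plus lineage.

    Parameters
    ----------
    df
        One row per observation with the columns of :data:`TRACK_COLUMNS`.
    frame_interval_min
        Nominal imaging frame interval in minutes (10 for the zebrafish and
        HUVEC recordings modelled here).
    time_unit
        ``"hpf"`` (decimal hours post-fertilization) or ``"min"``.
    is_3d
        False for monolayer data where z is a placeholder 0.
    """

    df: pd.DataFrame
    frame_interval_min: float = 10.0
    time_unit: str = "hpf"
    is_3d: bool = True

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in ("cell_id", "t", "x", "y") if c not in df.columns]
        if missing:
            raise TrackFormatError(f"missing mandatory columns: {missing}")
        if "z" not in df.columns:
            df["z"] = 0.0
            self.is_3d = False
        if "embryo_id" not in df.columns:
            df["embryo_id"] = "embryo_01"
        if "parent_id" not in df.columns:
            df["parent_id"] = pd.NA
        if "vessel_label" not in df.columns:
            df["vessel_label"] = pd.NA
        for col in ("embryo_id", "cell_id"):
            df[col] = df[col].astype("string")
        df["parent_id"] = _as_str_or_na(df["parent_id"])
        df["vessel_label"] = _as_str_or_na(df["vessel_label"])
        for col in ("t", "x", "y", "z"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        extra = [c for c in df.columns if c not in TRACK_COLUMNS]
        df = df[TRACK_COLUMNS + extra]
        df = df.sort_values(["embryo_id", "cell_id", "t"], kind="mergesort").reset_index(drop=True)
        self.df = df

    # -- basic accessors -------------------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.df)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.df["cell_id"].unique())

    @property
    def embryo_ids(self) -> list[str]:
        return list(self.df["embryo_id"].unique())

    def for_embryo(self, embryo_id: str) -> "TrackTable":
        sub = self.df[self.df["embryo_id"] == embryo_id].reset_index(drop=True)
        return replace(self, df=sub)

    def positions(self) -> np.ndarray:
        return self.df[["x", "y", "z"]].to_numpy()

    def with_positions(self, xyz: np.ndarray) -> "TrackTable":
        df = self.df.copy()
        df[["x", "y", "z"]] = np.asarray(xyz, dtype=float)
        return replace(self, df=df)

    # -- lineage ---------------------------------------------------------
    def lineage(self) -> dict[str, list[str]]:
        """Map each parent cell_id to its children, per embryo-unique ids."""
        kids: dict[str, list[str]] = {}
        first = self.df.groupby("cell_id", sort=False)["parent_id"].first()
        for cid, pid in first.items():
            if pd.notna(pid):
                kids.setdefault(str(pid), []).append(str(cid))
        return kids

    def roots(self) -> list[str]:
        first = self.df.groupby("cell_id", sort=False)["parent_id"].first()
        return [str(c) for c, p in first.items() if pd.isna(p)]

    # -- validation ------------------------------------------------------
    def validate(self) -> "TrackTable":
        df = self.df
        if not np.isfinite(df[["t", "x", "y", "z"]].to_numpy()).all():
            raise TrackValidationError("non-finite coordinate or time values")
        dup = df.duplicated(subset=["embryo_id", "cell_id", "t"], keep=False)
        if dup.any():
            rows = df.loc[dup, ["embryo_id", "cell_id", "t"]].drop_duplicates()
            raise TrackValidationError(
                "duplicate (cell_id, t) observations: "
                + "; ".join(f"{r.embryo_id}/{r.cell_id}@t={r.t}" for r in rows.itertuples())
            )
        # time strictly increasing within a cell is implied by sort + no dups
        for (embryo, _), sub in df.groupby(["embryo_id", "cell_id"], sort=False):
            ts = sub["t"].to_numpy()
            if np.any(np.diff(ts) <= 0):
                raise TrackValidationError(f"non-increasing time within a cell in {embryo}")
        self._validate_lineage()
        return self

    def _validate_lineage(self) -> None:
        # cell ids are only unique within one embryo
        for _, sub in self.df.groupby("embryo_id", sort=False):
            self._validate_lineage_one(sub)

    @staticmethod
    def _validate_lineage_one(df: pd.DataFrame) -> None:
        g = df.groupby("cell_id", sort=False)
        first_parent = g["parent_id"].first()
        t_min = g["t"].min()
        t_max = g["t"].max()
        known = set(first_parent.index)
        n_children: dict[str, int] = {}
        for cid, pid in first_parent.items():
            if pd.isna(pid):
                continue
            pid = str(pid)
            if pid not in known:
                raise TrackValidationError(f"cell {cid} references unknown parent {pid}")
            n_children[pid] = n_children.get(pid, 0) + 1
            if t_min[cid] < t_max[pid]:
                raise TrackValidationError(
                    f"cell {cid} starts at t={t_min[cid]} before parent {pid} ends at t={t_max[pid]}"
                )
        for pid, n in n_children.items():
            if n > 2:
                raise TrackValidationError(f"cell {pid} has {n} children (max 2 per division)")
        # forest: follow parent chains, fail on any cycle
        parent_of = {str(c): (str(p) if pd.notna(p) else None) for c, p in first_parent.items()}
        for cid in parent_of:
            seen = set()
            cur: str | None = cid
            while cur is not None:
                if cur in seen:
                    raise TrackValidationError(f"lineage cycle involving {cid}")
                seen.add(cur)
                cur = parent_of.get(cur)

    def __eq__(self, other: object) -> bool:  # value semantics for round-trips
        if not isinstance(other, TrackTable):
            return NotImplemented
        a = self.df[TRACK_COLUMNS].reset_index(drop=True)
        b = other.df[TRACK_COLUMNS].reset_index(drop=True)
        return (
            a.equals(b)
            and self.frame_interval_min == other.frame_interval_min
            and self.time_unit == other.time_unit
            and self.is_3d == other.is_3d
        )


@dataclass
class DiameterTable:
    """Per-vessel diameter measurements over time (micrometres, hpf).

    A diameter of exactly 0 encodes a missing measurement; the flow model maps
    it to its conductance floor.
    """

    df: pd.DataFrame

    COLUMNS = ["embryo_id", "vessel_id", "vessel_class", "t", "diameter"]

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise TrackFormatError(f"diameter table missing columns: {missing}")
        df["embryo_id"] = df["embryo_id"].astype("string")
        df["vessel_id"] = df["vessel_id"].astype("string")
        df["vessel_class"] = df["vessel_class"].astype("string")
        df["t"] = pd.to_numeric(df["t"], errors="raise").astype(float)
        df["diameter"] = pd.to_numeric(df["diameter"], errors="raise").astype(float)
        self.df = df[self.COLUMNS].sort_values(
            ["embryo_id", "vessel_class", "vessel_id", "t"], kind="mergesort"
        ).reset_index(drop=True)

    def validate(self) -> "DiameterTable":
        bad = self.df[self.df["diameter"] < 0]
        if len(bad):
            r = bad.iloc[0]
            raise TrackValidationError(
                f"negative diameter {r.diameter} for {r.vessel_id} at t={r.t}"
            )
        unknown = set(self.df["vessel_class"].dropna()) - set(VESSEL_CLASSES)
        if unknown:
            raise TrackValidationError(f"unknown vessel classes: {sorted(unknown)}")
        if not np.isfinite(self.df[["t", "diameter"]].to_numpy()).all():
            raise TrackValidationError("non-finite diameter table values")
        return self

    def class_mean(self) -> pd.DataFrame:
        """Mean diameter per (vessel_class, t), ignoring 0 sentinels."""
        d = self.df[self.df["diameter"] > 0]
        return d.groupby(["vessel_class", "t"], as_index=False)["diameter"].mean()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiameterTable):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))


@dataclass
class KeyFile:
    """Per-experiment metadata: condition labels and dataset file references."""

    experiments: list[dict] = field(default_factory=list)
    base_dir: Path | None = None

    def validate(self, check_files: bool = True) -> "KeyFile":
        for exp in self.experiments:
            for key in ("embryo_id", "condition"):
                if key not in exp:
                    raise TrackValidationError(f"key file experiment missing '{key}': {exp}")
            if exp["condition"] not in CONDITIONS:
                raise TrackValidationError(
                    f"unknown condition {exp['condition']!r}; allowed: {CONDITIONS}"
                )
            if check_files:
                for ref in exp.get("files", {}).values():
                    path = Path(ref)
                    if self.base_dir is not None and not path.is_absolute():
                        path = self.base_dir / path
                    if not path.exists():
                        raise TrackValidationError(f"referenced file does not exist: {path}")
        return self

    def conditions(self) -> list[str]:
        return sorted({exp["condition"] for exp in self.experiments})


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_flat(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip",
                     dtype={"embryo_id": "string", "cell_id": "string",
                            "parent_id": "string", "vessel_label": "string"})
    mandatory = {"cell_id", "t", "x", "y"}
    if not mandatory.issubset(df.columns):
        raise TrackFormatError(
            f"{path}: flat track CSV must contain {sorted(mandatory)}, got {list(df.columns)}"
        )
    return df


def _read_objects_links(path: Path) -> pd.DataFrame:
    """Two-file community layout: objects.csv (observations) + links.csv (track membership)."""
    obj_path, link_path = path / "objects.csv", path / "links.csv"
    for p in (obj_path, link_path):
        if not p.exists():
            raise TrackFormatError(f"objects+links dialect requires {p.name} in {path}")
    objects = pd.read_csv(obj_path, float_precision="round_trip")
    links = pd.read_csv(link_path)
    if not {"object_id", "t", "x", "y"}.issubset(objects.columns):
        raise TrackFormatError(f"{obj_path}: needs columns object_id,t,x,y[,z]")
    if not {"link_id", "object_id"}.issubset(links.columns):
        raise TrackFormatError(f"{link_path}: needs columns link_id,object_id")
    merged = links.merge(objects, on="object_id", how="left", validate="one_to_one")
    if merged["t"].isna().any():
        missing = merged.loc[merged["t"].isna(), "object_id"].tolist()[:5]
        raise TrackFormatError(f"links reference unknown object ids, e.g. {missing}")
    merged["cell_id"] = "link_" + merged["link_id"].astype(str)
    keep = ["cell_id", "t", "x", "y"] + (["z"] if "z" in merged.columns else [])
    for opt in ("embryo_id", "parent_id", "vessel_label"):
        if opt in merged.columns:
            keep.append(opt)
    return merged[keep]


def read_tracks(
    path: str | os.PathLike,
    dialect: str = "flat",
    frame_interval_min: float = 10.0,
    time_unit: str = "hpf",
) -> TrackTable:
    """Read and validate a track table.

    ``dialect`` is ``"flat"`` (canonical single CSV) or ``"objects_links"``
    (directory with objects.csv + links.csv).  Extra columns are tolerated and
    preserved.
    """
    path = Path(path)
    if dialect == "flat":
        df = _read_flat(path)
    elif dialect == "objects_links":
        df = _read_objects_links(path)
    else:
        raise ValueError(f"unknown track dialect {dialect!r}")
    table = TrackTable(df, frame_interval_min=frame_interval_min, time_unit=time_unit)
    return table.validate()


def write_tracks(table: TrackTable, path: str | os.PathLike, dialect: str = "flat") -> Path:
    """Write a track table; ``read_tracks(write_tracks(T)) == T`` for the flat dialect."""
    path = Path(path)
    if dialect != "flat":
        raise ValueError("only the canonical flat dialect is written")
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False)
    return path


def read_diameters(path: str | os.PathLike) -> DiameterTable:
    df = pd.read_csv(path, float_precision="round_trip")
    return DiameterTable(df).validate()


def write_diameters(table: DiameterTable, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False)
    return path


def read_keyfile(path: str | os.PathLike, check_files: bool = True) -> KeyFile:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or "experiments" not in raw:
        raise TrackFormatError(f"{path}: key file must be a mapping with an 'experiments' list")
    kf = KeyFile(experiments=list(raw["experiments"]), base_dir=path.parent)
    return kf.validate(check_files=check_files)
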
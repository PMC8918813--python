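"""Rigid alignment of raw 3D tracks into the canonical trunk frame.

The canonical frame puts the dorsal aorta parallel to the x-axis with its
nucleus centroid at the origin, and the DLAV in the positive-y half plane with
its centroid in the y > 0, z ~ 0 half-plane.  The y-coordinate of a
transformed track is then a direct ventral-to-dorsal read-out.

The aorta axis is fitted to the pooled positions of all DA nuclei over the
whole recording.  "Linear regression" is realised as an orthogonal
(total-least-squares) line fit — the principal axis of the centred cloud —
because an ordinary regression of y on x is not rotation invariant; the OLS
variant is available behind a switch for parity checks against pipelines that
used it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .track_model import TrackTable

__all__ = ["AlignmentError", "CanonicalFrame", "fit_aorta_axis", "canonical_transform"]


class AlignmentError(ValueError):
    """Degenerate or ambiguous geometry prevents alignment."""


@dataclass
class CanonicalFrame:
    """Rigid map ``x_canonical = rotation @ (x_raw - origin)``.

    ``dorsal_flip`` records whether fixing the DLAV into the positive-y half
    plane required a half-turn about the recovered aorta axis (roll beyond
    90 degrees), i.e. the raw data had the dorsal side pointing "down".
    """

    rotation: np.ndarray
    origin: np.ndarray
    dorsal_flip: bool = False

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) @ self.rotation.T

    def invert(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.rotation + self.origin

    @property
    def translation(self) -> np.ndarray:
        """Translation component of the affine map x -> R x + t."""
        return -self.rotation @ self.origin


def fit_aorta_axis(
    da_points: np.ndarray, method: str = "tls"
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a 3D line (centroid, unit direction) through the DA nucleus cloud.

    ``method="tls"`` (default) returns the principal axis of the centred
    cloud; ``method="ols"`` regresses (y, z) on x.
    """
    pts = np.asarray(da_points, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        raise AlignmentError("need at least two DA points to fit an axis")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    if np.allclose(centred, 0.0, atol=1e-12):
        raise AlignmentError("all DA points coincide; axis undefined")
    if method == "tls":
        _, s, vt = np.linalg.svd(centred, full_matrices=False)
        if s[0] <= 1e-12 * max(1.0, np.abs(pts).max()):
            raise AlignmentError("degenerate DA cloud; axis undefined")
        direction = vt[0]
    elif method == "ols":
        x = centred[:, 0]
        denom = float(x @ x)
        if denom <= 1e-24:
            raise AlignmentError("OLS axis undefined: no spread along x")
        direction = np.array([1.0, float(x @ centred[:, 1]) / denom,
                              float(x @ centred[:, 2]) / denom])
        direction /= np.linalg.norm(direction)
    else:
        raise ValueError(f"unknown axis fit method {method!r}")
    # The anterior-posterior sense is not identifiable from the point cloud;
    # by convention the axis keeps a non-negative component along the input
    # +x (ties broken on y, then z).  The dorsoventral y read-out is the same
    # under either choice, since the roll is fixed by the DLAV reference.
    for k in range(3):
        if abs(direction[k]) > 1e-12:
            if direction[k] < 0:
                direction = -direction
            break
    return centroid, direction


def _minimal_rotation_to_x(direction: np.ndarray) -> np.ndarray:
    """Smallest rotation taking ``direction`` onto +x (Rodrigues)."""
    d = direction / np.linalg.norm(direction)
    ex = np.array([1.0, 0.0, 0.0])
    v = np.cross(d, ex)
    c = float(d @ ex)
    if np.linalg.norm(v) < 1e-14:
        if c > 0:
            return np.eye(3)
        return np.diag([-1.0, -1.0, 1.0])  # half turn about z
    vx = np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def canonical_transform(
    tracks: TrackTable,
    axis: tuple[np.ndarray, np.ndarray] | None = None,
    da_label: str = "DA",
    dlav_label: str = "DLAV",
    dlav_reference: np.ndarray | None = None,
    method: str = "tls",
    orientation_tol: float = 1e-6,
) -> tuple[TrackTable, CanonicalFrame]:
    """Map tracks into the canonical frame; returns the transformed table and frame.

    The rotation is composed of the minimal rotation taking the fitted aorta
    axis onto +x followed by a roll about x that places the DLAV reference
    centroid in the y > 0, z ~ 0 half-plane.  The transform is rigid, so all
    pairwise distances are preserved.
    """
    df = tracks.df
    if axis is None:
        da_points = df.loc[df["vessel_label"] == da_label, ["x", "y", "z"]].to_numpy()
        if len(da_points) < 2:
            raise AlignmentError(f"no '{da_label}'-labelled points to fit the aorta axis")
        axis = fit_aorta_axis(da_points, method=method)
    centroid, direction = axis

    if dlav_reference is None:
        dlav_reference = df.loc[df["vessel_label"] == dlav_label, ["x", "y", "z"]].to_numpy()
    dlav_reference = np.asarray(dlav_reference, dtype=float).reshape(-1, 3)
    if len(dlav_reference) == 0:
        raise AlignmentError("empty DLAV reference; cannot fix the dorsal orientation")

    r0 = _minimal_rotation_to_x(direction)
    m = (dlav_reference.mean(axis=0) - centroid) @ r0.T
    radial = float(np.hypot(m[1], m[2]))
    if radial < orientation_tol:
        raise AlignmentError(
            "DLAV reference lies on the aorta axis; dorsal orientation ambiguous"
        )
    roll = np.arctan2(m[2], m[1])  # rotate by -roll about x => DLAV at y>0, z=0
    cr, sr = np.cos(-roll), np.sin(-roll)
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cr, -sr], [0.0, sr, cr]])
    frame = CanonicalFrame(rotation=rx @ r0, origin=np.asarray(centroid, dtype=float),
                           dorsal_flip=bool(abs(roll) > np.pi / 2))
    aligned = tracks.with_positions(frame.apply(tracks.positions()))
    return aligned, frame
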
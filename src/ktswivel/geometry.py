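"""Plate-frame fitting and the delta/swivel observables of sister kinetochores.

All positions are in nanometres. The metaphase-plate frame is right-handed
with x normal to the plate, y and z in-plane; angles are reported in degrees
and computed internally in radians.

Conventions
-----------
* The sister-sister axis of a kinetochore points from its own inner marker
  toward its sister's inner marker; swivel 0 deg means the inner-to-outer
  (intra-kinetochore) vector points directly *away* from the sister, i.e.
  toward the attached spindle pole.
* Signed y-swivel is positive when the intra-kinetochore vector falls on the
  right-handed-perpendicular side (in the xy-plane) of the away-from-sister
  direction; the magnitude comes from the cosine rule on the triangle
  (d_y, delta_y, epsilon_y).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: tolerance for clamping cosine-rule arguments to [-1, 1]
COS_CLAMP_TOL = 1e-6

#: |delta_z| filter threshold, nm (half the 200 nm z-pixel resolution)
DEFAULT_Z_THRESHOLD_NM = 100.0

#: plate-thickness bins (micrometres) separating metaphase stages
EARLY_THICKNESS_UM = 0.65
LATE_THICKNESS_UM = 0.45


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PlateFrame:
    """Orthonormal right-handed frame with x normal to the metaphase plate."""

    origin: np.ndarray  # (3,) nm
    basis: np.ndarray  # (3, 3); rows are x-hat, y-hat, z-hat

    def __post_init__(self):
        b = np.asarray(self.basis, dtype=float)
        if not np.allclose(b @ b.T, np.eye(3), atol=1e-12):
            raise ValueError("plate frame basis is not orthonormal")
        if not np.isclose(np.linalg.det(b), 1.0, atol=1e-12):
            raise ValueError("plate frame basis is not right-handed")

    def to_plate(self, points: np.ndarray) -> np.ndarray:
        """Map microscope-frame points (..., 3) into the plate frame."""
        return (np.asarray(points, dtype=float) - self.origin) @ self.basis.T

    def to_microscope(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.basis + self.origin


@dataclass
class KinetochorePair:
    """A paired sister kinetochore observation in the plate frame (nm).

    ``inner``/``outer`` are (2, 3) arrays, one row per sister.  A missing
    outer marker is encoded as NaN.
    """

    pair_id: int
    inner: np.ndarray
    outer: np.ndarray
    time: float = 0.0
    cell_id: int = 0

    def __post_init__(self):
        self.inner = np.asarray(self.inner, dtype=float).reshape(2, 3)
        self.outer = np.asarray(self.outer, dtype=float).reshape(2, 3)
        if not np.all(np.isfinite(self.inner)):
            raise ValueError("inner marker positions must be finite")
        if np.allclose(self.inner[0], self.inner[1]):
            raise ValueError("sister inner markers coincide; sister axis undefined")


@dataclass
class DeltaMeasurement:
    """Distance observables for one kinetochore of a pair (nm)."""

    sister: int
    delta3d: float
    delta2d: float
    delta1d: float  # pair-level, signed; NaN when an outer marker is missing
    delta_x: float
    delta_y: float
    delta_z: float
    d3d: float
    d2d: float
    epsilon_y: float
    z_filter_pass: bool


@dataclass
class SwivelMeasurement:
    """Angle observables for one kinetochore of a pair (degrees)."""

    sister: int
    swivel3d: float
    y_swivel: float  # signed, (-180, 180]
    z_swivel: float  # signed, xz-plane analogue
    twist: float  # sister axis vs the plate normal, [0, 90]
    kmt_angle: float = np.nan


# ---------------------------------------------------------------------------
# plate frame


def fit_plate_frame(inner_positions: np.ndarray) -> PlateFrame:
    """Fit the metaphase-plate frame to a cloud of inner-marker positions.

    The plate normal (x-hat) is the minimal-spread principal direction of
    the cloud; y-hat is the largest-spread in-plane direction and z-hat
    completes the right-handed set.  Axis signs are fixed deterministically
    by making each axis's largest-magnitude component positive.

    Parameters
    ----------
    inner_positions : (n, 3) array, microscope frame, nm; n >= 10.
    """
    pts = np.asarray(inner_positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("inner_positions must be (n, 3)")
    if pts.shape[0] < 10:
        raise ValueError("need at least 10 positions to fit the plate frame")
    origin = pts.mean(axis=0)
    centred = pts - origin
    # principal directions; singular values descending
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] <= s[0] * 1e-12:
        raise ValueError("degenerate position cloud (rank < 2)")
    x_hat = vt[2]
    y_hat = vt[0]

    def _fix_sign(v):
        i = int(np.argmax(np.abs(v)))
        return v if v[i] > 0 else -v

    x_hat = _fix_sign(x_hat)
    y_hat = _fix_sign(y_hat - (y_hat @ x_hat) * x_hat)
    y_hat = y_hat / np.linalg.norm(y_hat)
    z_hat = np.cross(x_hat, y_hat)
    return PlateFrame(origin=origin, basis=np.vstack([x_hat, y_hat, z_hat]))


# ---------------------------------------------------------------------------
# vectorised kernels (arrays of shape (..., 3); used by the table pipeline)


def _norm(v, axis=-1):
    return np.sqrt(np.sum(np.square(v), axis=axis))


def delta_components(inner_self, outer_self, inner_sister, outer_sister,
                     z_threshold: float = DEFAULT_Z_THRESHOLD_NM) -> dict:
    """Vectorised delta observables for one kinetochore of each pair.

    All inputs broadcast as (..., 3) plate-frame positions in nm.  Returns a
    dict of arrays: delta3d/2d/1d, per-axis components, inter-sister d3d/d2d,
    epsilon_y and the z filter flag.
    """
    inner_self = np.asarray(inner_self, float)
    outer_self = np.asarray(outer_self, float)
    inner_sister = np.asarray(inner_sister, float)
    outer_sister = np.asarray(outer_sister, float)
    v = outer_self - inner_self
    delta3d = _norm(v)
    delta2d = _norm(v[..., :2])
    d3d = _norm(inner_sister - inner_self)
    d2d = _norm(inner_sister[..., :2] - inner_self[..., :2])
    d2d_outer = _norm(outer_sister[..., :2] - outer_self[..., :2])
    epsilon_y = _norm(outer_self[..., :2] - inner_sister[..., :2])
    return {
        "delta3d": delta3d,
        "delta2d": delta2d,
        "delta1d": 0.5 * (d2d_outer - d2d),
        "delta_x": v[..., 0],
        "delta_y": v[..., 1],
        "delta_z": v[..., 2],
        "d3d": d3d,
        "d2d": d2d,
        "epsilon_y": epsilon_y,
        "z_filter_pass": np.abs(v[..., 2]) <= z_threshold,
    }


def _clamped_arccos(c):
    c = np.asarray(c, dtype=float)
    with np.errstate(invalid="ignore"):
        excess = np.maximum(np.abs(c) - 1.0, 0.0)
    if np.any(excess[np.isfinite(excess)] > COS_CLAMP_TOL):
        raise ValueError(
            f"cosine-rule argument outside [-1, 1] by more than {COS_CLAMP_TOL}"
        )
    return np.arccos(np.clip(c, -1.0, 1.0))


def swivel_components(inner_self, outer_self, inner_sister,
                      kmt_axis=None) -> dict:
    """Vectorised swivel observables for one kinetochore of each pair.

    y-swivel magnitude comes from the cosine rule on the xy-plane triangle
    with sides (d_y, delta_y, epsilon_y) and the 180-degree complement; the
    sign is the side of the away-from-sister direction on which the
    intra-kinetochore vector falls.  z-swivel is the analogous xz-plane
    measurement.  ``kmt_axis`` (optional, (..., 3)) yields the angle the
    k-fibre tends on the sister axis, measured exactly like y-swivel.
    """
    inner_self = np.asarray(inner_self, float)
    outer_self = np.asarray(outer_self, float)
    inner_sister = np.asarray(inner_sister, float)
    v = outer_self - inner_self
    away = inner_self - inner_sister  # points away from the sister
    # 3D swivel: angle between intra-kinetochore axis and the away direction
    # (equivalently 180 deg minus the sister-axis dot-product angle)
    cos3d = np.sum(v * away, axis=-1) / (_norm(v) * _norm(away))
    swivel3d = np.degrees(_clamped_arccos(cos3d))

    def _planar(idx):
        a = away[..., idx]
        w = v[..., idx]
        d = _norm(a)
        delta = _norm(w)
        eps = _norm(w + a)  # |outer_self - inner_sister| in the plane
        denom = 2.0 * d * delta
        with np.errstate(invalid="ignore", divide="ignore"):
            cosarg = (d ** 2 + delta ** 2 - eps ** 2) / denom
        # degenerate in-plane delta: the angle is undefined -> NaN
        cosarg = np.where(denom > 0, cosarg, np.nan)
        mag = 180.0 - np.degrees(_clamped_arccos(cosarg))
        # right-handed perpendicular of the away direction in this plane
        perp = np.stack([-a[..., 1], a[..., 0]], axis=-1)
        sign = np.where(np.sum(w * perp, axis=-1) < 0, -1.0, 1.0)
        return sign * mag

    y_swivel = _planar([0, 1])
    z_swivel = _planar([0, 2])
    # twist: tilt of the sister-sister axis from the plate normal (x);
    # 0 deg for a pair aligned with the spindle axis, 90 deg lying in-plate
    sister_axis = -away
    cos_twist = np.abs(sister_axis[..., 0]) / _norm(sister_axis)
    twist = np.degrees(np.arccos(np.clip(cos_twist, 0.0, 1.0)))
    out = {
        "swivel3d": swivel3d,
        "y_swivel": y_swivel,
        "z_swivel": z_swivel,
        "twist": twist,
    }
    if kmt_axis is not None:
        k = np.asarray(kmt_axis, float)[..., [0, 1]]
        a = away[..., [0, 1]]
        perp = np.stack([-a[..., 1], a[..., 0]], axis=-1)
        out["kmt_angle"] = np.degrees(
            np.arctan2(np.sum(k * perp, axis=-1), np.sum(k * a, axis=-1))
        )
    else:
        out["kmt_angle"] = np.full(np.shape(swivel3d), np.nan)
    return out


# ---------------------------------------------------------------------------
# per-pair API


def measure_delta(pair: KinetochorePair,
                  z_threshold: float = DEFAULT_Z_THRESHOLD_NM
                  ) -> tuple[DeltaMeasurement, DeltaMeasurement]:
    """Delta observables for both kinetochores of a pair.

    delta3d is the Euclidean inner-to-outer distance; delta2d its xy-plane
    projection; per-axis components are along the plate axes.  The z filter
    fails when |delta_z| exceeds ``z_threshold`` (default 100 nm, half the
    z-pixel resolution).  d3d/d2d are inter-sister inner-marker distances and
    epsilon_y the xy distance from this sister's outer marker to the other
    sister's inner marker.
    """
    out = []
    for i in (0, 1):
        j = 1 - i
        c = delta_components(pair.inner[i], pair.outer[i],
                             pair.inner[j], pair.outer[j], z_threshold)
        out.append(DeltaMeasurement(
            sister=i,
            delta3d=float(c["delta3d"]),
            delta2d=float(c["delta2d"]),
            delta1d=float(c["delta1d"]),
            delta_x=float(c["delta_x"]),
            delta_y=float(c["delta_y"]),
            delta_z=float(c["delta_z"]),
            d3d=float(c["d3d"]),
            d2d=float(c["d2d"]),
            epsilon_y=float(c["epsilon_y"]),
            z_filter_pass=bool(c["z_filter_pass"]),
        ))
    return out[0], out[1]


def measure_delta1d(pair: KinetochorePair) -> float:
    """Signed 1D intra-kinetochore distance of a pair.

    Half the difference between the xy-plane outer-outer and inner-inner
    inter-sister distances; negative when the outer markers have rotated
    inside the inner markers.  NaN when an outer marker is missing.
    """
    if not np.all(np.isfinite(pair.outer)):
        return float("nan")
    d_inner = float(_norm(pair.inner[1, :2] - pair.inner[0, :2]))
    d_outer = float(_norm(pair.outer[1, :2] - pair.outer[0, :2]))
    return 0.5 * (d_outer - d_inner)


def measure_swivel(pair: KinetochorePair, kmt_axis: np.ndarray | None = None
                   ) -> tuple[SwivelMeasurement, SwivelMeasurement]:
    """Swivel observables for both kinetochores of a pair.

    ``kmt_axis`` may be (2, 3) unit vectors (one per sister) giving the
    k-fibre direction; the angle it tends on the sister axis is then
    measured by the same construction as y-swivel.
    """
    if kmt_axis is not None:
        kmt_axis = np.asarray(kmt_axis, dtype=float).reshape(2, 3)
    out = []
    for i in (0, 1):
        j = 1 - i
        delta_y = _norm(pair.outer[i, :2] - pair.inner[i, :2])
        if delta_y == 0:
            raise ValueError("y-swivel undefined: delta_y is zero")
        c = swivel_components(
            pair.inner[i], pair.outer[i], pair.inner[j],
            kmt_axis=None if kmt_axis is None else kmt_axis[i])
        out.append(SwivelMeasurement(
            sister=i,
            swivel3d=float(c["swivel3d"]),
            y_swivel=float(c["y_swivel"]),
            z_swivel=float(c["z_swivel"]),
            twist=float(c["twist"]),
            kmt_angle=float(c["kmt_angle"]),
        ))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# projection theory: 1D delta in terms of projected deltas and y-swivels


def delta1d_exact(dy1, delta_y1, delta_y2, theta_y1, theta_y2):
    """Exact 1D delta of a pair from 2D projected quantities (closed form).

    ``dy1`` is the xy inner-inner inter-sister distance, ``delta_y*`` the xy
    intra-kinetochore distances and ``theta_y*`` the y-swivels in degrees.
    The outer-outer distance follows from Pythagoras on the sister-axis
    decomposition,

        dy2^2 = (dy1 + D1 cos t1 + D2 cos t2)^2 + (D1 sin t1 + D2 sin t2)^2,

    and the returned value is the algebraically rearranged

        (dy2 - dy1)/2 = dy1 (D1 cos t1 + D2 cos t2) / (dy1 + dy2)
                        + (D1^2 + D2^2 + 2 D1 D2 cos(t1 - t2)) / (2 (dy1 + dy2)).

    Broadcasts over array inputs.
    """
    dy1 = np.asarray(dy1, float)
    d1 = np.asarray(delta_y1, float)
    d2 = np.asarray(delta_y2, float)
    t1 = np.radians(np.asarray(theta_y1, float))
    t2 = np.radians(np.asarray(theta_y2, float))
    if np.any(dy1 <= 0):
        raise ValueError("dy1 must be positive")
    if np.any(d1 < 0) or np.any(d2 < 0):
        raise ValueError("delta magnitudes must be non-negative")
    along = dy1 + d1 * np.cos(t1) + d2 * np.cos(t2)
    perp = d1 * np.sin(t1) + d2 * np.sin(t2)
    dy2 = np.hypot(along, perp)
    first = dy1 * (d1 * np.cos(t1) + d2 * np.cos(t2)) / (dy1 + dy2)
    second = (d1 ** 2 + d2 ** 2 + 2 * d1 * d2 * np.cos(t1 - t2)) / (2 * (dy1 + dy2))
    return first + second


def delta1d_first_order(delta_y1, delta_y2, theta_y1, theta_y2):
    """First-order (in delta/d) approximation of the 1D delta:
    the mean projection onto the sister axis,
    (D1 cos t1 + D2 cos t2) / 2.  Broadcasts over array inputs."""
    d1 = np.asarray(delta_y1, float)
    d2 = np.asarray(delta_y2, float)
    t1 = np.radians(np.asarray(theta_y1, float))
    t2 = np.radians(np.asarray(theta_y2, float))
    return 0.5 * (d1 * np.cos(t1) + d2 * np.cos(t2))


def project_delta_xy(delta3d, theta_z):
    """xy-projected intra-kinetochore distance, delta_y = delta3d * cos(theta_z),
    where theta_z (degrees) is the z-directional swivel out of the xy-plane."""
    return np.asarray(delta3d, float) * np.cos(np.radians(np.asarray(theta_z, float)))


# ---------------------------------------------------------------------------
# plate thickness


def plate_thickness(positions_x: np.ndarray) -> tuple[float, str]:
    """Plate thickness (sd of kinetochore x coordinates, micrometres) and the
    metaphase stage it implies: 'early' above 0.65 um, 'late' below 0.45 um,
    'mid' in between."""
    x = np.asarray(positions_x, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 kinetochores for plate thickness")
    thickness = float(np.std(x, ddof=1)) / 1000.0
    if thickness > EARLY_THICKNESS_UM:
        stage = "early"
    elif thickness < LATE_THICKNESS_UM:
        stage = "late"
    else:
        stage = "mid"
    return thickness, stage
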
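"""Ground-truth simulator for sister kinetochore pair ensembles.

Generates metaphase-plate-distributed pairs with known inner/outer marker
geometry, applies chromatic shift and localization noise to produce
two-channel observed spot tables, simulates oscillatory trajectories, and
renders two-channel voxel stacks with an integrated-Gaussian PSF model.

Everything is seeded; identical configuration gives bit-identical output.
Coordinates are generated directly in the plate frame (nm): x normal to the
plate, the pair axis tilted from x by a configurable twist dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .config import SimulationConfig, OscillationConfig

GREEN = "green"
RED = "red"

#: default microscope voxel size (x, y, z) nm
DEFAULT_VOXEL_SIZE_NM = (69.4, 69.4, 100.0)


@dataclass
class GroundTruthPair:
    """Generative truth for one sister kinetochore pair (plate frame, nm).

    Row 0/1 of each array is sister 0/1.  ``y_swivel`` stores the drawn
    (unwrapped) signed y-swivel in degrees for the gaussian_y model, or the
    realised geometric value for the isotropic model; ``theta_z`` is the
    elevation of the intra-kinetochore vector out of the xy-plane.
    """

    pair_id: int
    inner: np.ndarray  # (2, 3)
    outer: np.ndarray  # (2, 3)
    delta: np.ndarray  # (2,)
    y_swivel: np.ndarray  # (2,) degrees
    theta_z: np.ndarray  # (2,) degrees
    swivel3d: np.ndarray  # (2,) degrees
    attached_pole: np.ndarray  # (2,) +-1 (pole side along x)
    kmt_axis: np.ndarray  # (2, 3) unit vectors


@dataclass
class ImageStack:
    """A single-channel voxel stack. ``data`` is indexed [z, y, x]; voxel
    centres sit at ``origin + (index + 0.5) * voxel_size`` (sizes in nm,
    ordered (x, y, z))."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_NM
    channel: str = GREEN
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3D [z, y, x]")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be strictly positive")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def extent_nm(self) -> np.ndarray:
        """Physical size (x, y, z) of the grid in nm."""
        nz, ny, nx = self.data.shape
        return np.array([nx, ny, nz]) * np.asarray(self.voxel_size)


@dataclass
class SimulationResult:
    """Output bundle of :func:`simulate_pairs`."""

    pairs: list
    truth: pd.DataFrame
    observed: pd.DataFrame
    config: SimulationConfig
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pair ensembles


def _unit(v, axis=-1):
    return v / np.linalg.norm(v, axis=axis, keepdims=True)


def simulate_pairs(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> SimulationResult:
    """Draw an ensemble of sister kinetochore pairs with full ground truth.

    Pair centres populate the metaphase plate (Gaussian x spread of
    ``plate_thickness_sd``, uniform in the y-z plate ellipse); the sister
    axis tilts from the plate normal by a half-Gaussian twist; each
    kinetochore's outer marker lies ``delta`` nm from its inner marker in a
    direction drawn from the configured swivel model.  Observed green spots
    are the inner markers plus localization noise; observed red spots are
    the outer markers plus the chromatic shift plus noise.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_pairs

    centre = np.empty((n, 3))
    centre[:, 0] = rng.normal(0.0, config.plate_thickness_sd, n)
    # uniform in the plate ellipse by rejection-free polar sampling
    r = np.sqrt(rng.uniform(0, 1, n))
    phi = rng.uniform(0, 2 * np.pi, n)
    centre[:, 1] = config.plate_halfwidth_y * r * np.cos(phi)
    centre[:, 2] = config.plate_halfwidth_z * r * np.sin(phi)

    d = np.maximum(rng.normal(config.inter_sister_median,
                              config.inter_sister_sd, n), 1.0)

    # sister axis: plate normal tilted by |N(0, twist_sd)| about a random
    # in-plane azimuth
    alpha = np.abs(np.radians(rng.normal(0.0, config.twist_sd, n)))
    beta = rng.uniform(0, 2 * np.pi, n)
    u = np.stack([np.cos(alpha),
                  np.sin(alpha) * np.cos(beta),
                  np.sin(alpha) * np.sin(beta)], axis=1)

    inner = np.empty((n, 2, 3))
    inner[:, 0] = centre - 0.5 * d[:, None] * u
    inner[:, 1] = centre + 0.5 * d[:, None] * u
    pole = np.empty((n, 2))
    pole[:, 0] = -np.sign(u[:, 0])
    pole[:, 1] = np.sign(u[:, 0])

    delta = np.maximum(
        rng.normal(config.delta_magnitude, config.delta_dispersion, (n, 2)), 0.0)

    away = np.stack([-u, u], axis=1)  # (n, 2, 3): away-from-sister directions
    if config.swivel_model == "gaussian_y":
        z_sd = config.swivel_sd if config.z_swivel_sd is None else config.z_swivel_sd
        theta_y = rng.normal(0.0, config.swivel_sd, (n, 2))
        # z elevation of the intra-kinetochore vector; a Gaussian draw folded
        # into [-90, 90] so that the xy azimuth remains exactly theta_y
        theta_z = rng.normal(0.0, z_sd, (n, 2))
        theta_z = np.mod(theta_z + 180.0, 360.0) - 180.0
        theta_z = np.where(np.abs(theta_z) > 90.0,
                           np.sign(theta_z) * (180.0 - np.abs(theta_z)), theta_z)
        a_xy = _unit(away[..., :2])
        ty = np.radians(theta_y)
        # rotate the in-plane away direction counter-clockwise by theta_y
        rot = np.stack([
            np.cos(ty) * a_xy[..., 0] - np.sin(ty) * a_xy[..., 1],
            np.sin(ty) * a_xy[..., 0] + np.cos(ty) * a_xy[..., 1],
        ], axis=-1)
        tz = np.radians(theta_z)
        direction = np.concatenate(
            [np.cos(tz)[..., None] * rot, np.sin(tz)[..., None]], axis=-1)
    else:  # isotropic on the hemisphere facing the attached pole
        w = rng.normal(size=(n, 2, 3))
        w = _unit(w)
        flip = np.sign(w[..., 0]) * pole < 0
        w[flip] *= -1.0
        direction = w
        theta_z = np.degrees(np.arcsin(np.clip(direction[..., 2], -1, 1)))
        a_xy = _unit(away[..., :2])
        perp = np.stack([-a_xy[..., 1], a_xy[..., 0]], axis=-1)
        theta_y = np.degrees(np.arctan2(
            np.sum(direction[..., :2] * perp, axis=-1),
            np.sum(direction[..., :2] * a_xy, axis=-1)))

    outer = inner + delta[..., None] * direction
    cos3d = np.sum(direction * away, axis=-1)
    swivel3d = np.degrees(np.arccos(np.clip(cos3d, -1, 1)))
    kmt = _unit(direction)

    pairs = [
        GroundTruthPair(
            pair_id=i, inner=inner[i], outer=outer[i], delta=delta[i],
            y_swivel=theta_y[i], theta_z=theta_z[i], swivel3d=swivel3d[i],
            attached_pole=pole[i], kmt_axis=kmt[i])
        for i in range(n)
    ]

    truth = pd.DataFrame({
        "pair_id": np.repeat(np.arange(n), 2),
        "sister": np.tile([0, 1], n),
        "inner_x": inner[..., 0].ravel(), "inner_y": inner[..., 1].ravel(),
        "inner_z": inner[..., 2].ravel(),
        "outer_x": outer[..., 0].ravel(), "outer_y": outer[..., 1].ravel(),
        "outer_z": outer[..., 2].ravel(),
        "delta": delta.ravel(),
        "y_swivel_true": theta_y.ravel(),
        "theta_z_true": theta_z.ravel(),
        "swivel3d_true": swivel3d.ravel(),
        "attached_pole": pole.ravel(),
        "kmt_x": kmt[..., 0].ravel(), "kmt_y": kmt[..., 1].ravel(),
        "kmt_z": kmt[..., 2].ravel(),
    })

    noise = np.asarray(config.localization_noise_sd, float)
    shift = np.asarray(config.chromatic_shift, float)
    green = inner.reshape(-1, 3) + rng.normal(0, 1, (2 * n, 3)) * noise
    red = outer.reshape(-1, 3) + shift + rng.normal(0, 1, (2 * n, 3)) * noise

    observed = pd.DataFrame({
        "spot_id": np.arange(4 * n),
        "pair_id": np.tile(np.repeat(np.arange(n), 2), 2),
        "sister": np.tile(np.tile([0, 1], n), 2),
        "channel": np.repeat([GREEN, RED], 2 * n),
        "x": np.concatenate([green[:, 0], red[:, 0]]),
        "y": np.concatenate([green[:, 1], red[:, 1]]),
        "z": np.concatenate([green[:, 2], red[:, 2]]),
    })

    metadata = {
        "delta_magnitude": config.delta_magnitude,
        "delta_dispersion": config.delta_dispersion,
        "swivel_model": config.swivel_model,
        "swivel_sd": config.swivel_sd,
        "inter_sister_median": config.inter_sister_median,
        "chromatic_shift": list(shift),
        "localization_noise_sd": list(noise),
        "seed": config.seed,
    }
    return SimulationResult(pairs=pairs, truth=truth, observed=observed,
                            config=config, metadata=metadata)


def simulate_calibration_spots(n_spots: int,
                               shift=(0.0, 0.0, 0.0),
                               displacement_sd=(25.5, 23.1, 43.0),
                               volume_nm=(10000.0, 10000.0, 3000.0),
                               seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dual-label single-epitope calibration spots for shift estimation.

    Same emitters seen in both channels: the red position is the green
    position plus the session shift plus per-axis Gaussian scatter with the
    given sds (defaults are the measured per-axis session spreads).
    Returns row-matched (green, red) tables with x/y/z in nm.
    """
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, 1, (n_spots, 3)) * np.asarray(volume_nm)
    disp = np.asarray(shift, float) + rng.normal(0, 1, (n_spots, 3)) * \
        np.asarray(displacement_sd, float)
    green = pd.DataFrame(pos, columns=["x", "y", "z"])
    green["amplitude"] = rng.uniform(0.5, 1.0, n_spots)
    red = pd.DataFrame(pos + disp, columns=["x", "y", "z"])
    return green, red


# ---------------------------------------------------------------------------
# trajectories


def _triangle_wave(t: np.ndarray, amplitude: float, half_period: float,
                   phase: float) -> np.ndarray:
    """Triangle wave of peak ``amplitude`` reversing every ``half_period``."""
    tau = np.mod(t / (2.0 * half_period) + phase, 1.0)
    return amplitude * (4.0 * np.abs(tau - 0.5) - 1.0)


def simulate_trajectory(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Oscillatory x-trajectories of pair centres with per-frame P/AP labels.

    Each pair's centre follows a sawtooth (triangle) excursion along the
    plate normal with the configured amplitude and half-period, sampled at
    the frame interval, plus optional white positional noise.  A frame is
    labelled P (poleward) for a sister when its x-displacement since the
    previous frame points toward that sister's attached pole, AP otherwise.
    """
    config.validate()
    if config.oscillation is None:
        raise ValueError("oscillation parameters are not set")
    osc = config.oscillation
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = np.arange(osc.n_frames) * osc.sample_interval
    frames = []
    for pid in range(config.n_pairs):
        phase = rng.uniform(0, 1)
        x = _triangle_wave(t, osc.amplitude, osc.half_period, phase)
        if osc.position_noise_sd > 0:
            x = x + rng.normal(0, osc.position_noise_sd, osc.n_frames)
        dx = np.concatenate([[np.nan], np.diff(x)])
        for sister, pole in ((0, -1.0), (1, 1.0)):
            toward_pole = dx * pole
            label = np.where(np.isnan(dx), "",
                             np.where(toward_pole > 0, "P", "AP"))
            frames.append(pd.DataFrame({
                "pair_id": pid, "sister": sister, "frame": np.arange(osc.n_frames),
                "time": t, "x": x, "dx": dx, "attached_pole": pole,
                "phase_label": label,
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# rendering


def render_stack(positions_nm: np.ndarray,
                 amplitudes: np.ndarray | float,
                 shape: tuple[int, int, int],
                 voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_NM,
                 psf_sigma_nm: tuple[float, float, float] = (120.0, 120.0, 300.0),
                 background: float = 0.0,
                 poisson: bool = False,
                 rng: np.random.Generator | None = None,
                 channel: str = GREEN,
                 origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> ImageStack:
    """Render point emitters into a voxel stack as integrated 3D Gaussians.

    ``positions_nm`` is (n, 3) in (x, y, z) world coordinates; ``amplitudes``
    is the total photon count per spot (scalar or per-spot).  Each spot's
    photon mass is distributed over voxels by the product of per-axis
    integrals of a Gaussian PSF; ``background`` photons per voxel are added
    and, when ``poisson`` is set, the whole stack is Poisson-resampled.
    """
    positions = np.atleast_2d(np.asarray(positions_nm, dtype=float))
    nz, ny, nx = shape
    vx, vy, vz = voxel_size
    origin = np.asarray(origin, float)
    extent = np.array([nx * vx, ny * vy, nz * vz])
    rel = positions - origin
    bad = np.any((rel < 0) | (rel > extent), axis=1)
    if np.any(bad):
        raise ValueError(
            f"spots outside the voxel grid: indices {np.nonzero(bad)[0].tolist()}")
    amps = np.broadcast_to(np.asarray(amplitudes, dtype=float), positions.shape[0])

    def _axis_profile(n_vox, size, sigma, coords):
        edges = origin_axis = np.arange(n_vox + 1) * size
        # (n_spots, n_vox) integral of a unit Gaussian over each voxel
        z = (edges[None, :] - coords[:, None]) / (sigma * np.sqrt(2.0))
        cdf = 0.5 * (1.0 + erf(z))
        return np.diff(cdf, axis=1)

    px = _axis_profile(nx, vx, psf_sigma_nm[0], rel[:, 0])
    py = _axis_profile(ny, vy, psf_sigma_nm[1], rel[:, 1])
    pz = _axis_profile(nz, vz, psf_sigma_nm[2], rel[:, 2])
    data = np.zeros((nz, ny, nx), dtype=float)
    for a, gx, gy, gz in zip(amps, px, py, pz):
        data += a * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    data += background
    if poisson:
        if rng is None:
            rng = np.random.default_rng(0)
        data = rng.poisson(data).astype(float)
    return ImageStack(data=data, voxel_size=tuple(voxel_size), channel=channel,
                      origin=tuple(origin))
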
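"""Sub-voxel 3D spot localization by Gaussian mixture-model fitting.

Candidate seeds come from local maxima passing an intensity fraction filter
(relative to the brightest spot) and a pairwise isolation filter; seeds are
then refined by jointly fitting integrated anisotropic 3D Gaussians
(shared lateral/axial widths per channel) by least squares.  A masked
partner search fits the second channel's spot inside a sphere or hemisphere
around an anchor from the first channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.special import erf

from .synthetic import ImageStack

DEFAULT_INTENSITY_FRACTION = 0.25
DEFAULT_ISOLATION_RADIUS_NM = 750.0
DEFAULT_MASK_RADIUS_NM = 300.0
FIT_TOL = 1e-6
FIT_MAX_ITER = 200


@dataclass
class SpotMeasurement:
    """A fitted fluorescent spot centre (world/microscope frame, nm)."""

    centre: np.ndarray  # (3,) nm, (x, y, z)
    channel: str
    amplitude: float  # total photons above background
    background: float
    sigma_lateral: float
    sigma_axial: float
    converged: bool
    residual: float = np.nan

    def __post_init__(self):
        self.centre = np.asarray(self.centre, dtype=float).reshape(3)


# ---------------------------------------------------------------------------
# candidate detection


def _voxel_centres_nm(stack: ImageStack, idx_zyx: np.ndarray) -> np.ndarray:
    """World (x, y, z) coordinates of voxel centres for [z, y, x] indices."""
    vx, vy, vz = stack.voxel_size
    idx = np.atleast_2d(idx_zyx)
    out = np.stack([
        (idx[:, 2] + 0.5) * vx,
        (idx[:, 1] + 0.5) * vy,
        (idx[:, 0] + 0.5) * vz,
    ], axis=1)
    return out + np.asarray(stack.origin)


def filter_candidates(cands: pd.DataFrame,
                      intensity_fraction: float = DEFAULT_INTENSITY_FRACTION,
                      isolation_radius: float = DEFAULT_ISOLATION_RADIUS_NM
                      ) -> pd.DataFrame:
    """Apply the intensity-fraction filter, then pairwise isolation.

    A spot survives the intensity filter when its amplitude exceeds
    ``intensity_fraction`` of the brightest candidate's amplitude.  Of the
    survivors, any spot lying within ``isolation_radius`` nm of another
    survivor is dropped (both members of a close pair are removed).
    Idempotent: re-applying to its own output changes nothing.
    """
    if cands.empty:
        return cands
    amp = cands["amplitude"].to_numpy(dtype=float)
    keep = amp > intensity_fraction * amp.max()
    out = cands.loc[keep].reset_index(drop=True)
    if len(out) > 1 and isolation_radius > 0:
        pos = out[["x", "y", "z"]].to_numpy(dtype=float)
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt(np.sum(diff ** 2, axis=-1))
        np.fill_diagonal(dist, np.inf)
        out = out.loc[dist.min(axis=1) >= isolation_radius].reset_index(drop=True)
    return out


def detect_candidates(stack: ImageStack,
                      intensity_fraction: float = DEFAULT_INTENSITY_FRACTION,
                      isolation_radius: float = DEFAULT_ISOLATION_RADIUS_NM
                      ) -> pd.DataFrame:
    """Local-maximum seeds passing the intensity and isolation filters.

    Returns a table with world-frame voxel-centre positions (nm), the
    background-subtracted peak amplitude, and voxel indices.  An image with
    no signal yields an empty table.
    """
    data = np.asarray(stack.data, dtype=float)
    if data.size == 0:
        raise ValueError("empty stack")
    # detection runs on a lightly smoothed copy: shot noise would otherwise
    # split one physical spot into several neighbouring maxima
    smooth = ndimage.gaussian_filter(data, sigma=1.0)
    background = float(np.median(smooth))
    # local maxima over a PSF-sized neighbourhood, above a robust noise
    # floor (median + 4 MAD-sigma; zero for noiseless renders)
    footprint = np.ones((3, 5, 5), dtype=bool)
    local_max = (smooth == ndimage.maximum_filter(smooth, footprint=footprint))
    mad_sigma = 1.4826 * float(np.median(np.abs(smooth - background)))
    local_max &= smooth > background + 4.0 * mad_sigma
    if not np.any(local_max):
        return pd.DataFrame(columns=["x", "y", "z", "amplitude", "iz", "iy", "ix"])
    # exact intensity ties (noiseless renders) form connected plateaus;
    # collapse each plateau to its centroid
    labels, n_lab = ndimage.label(local_max)
    coms = ndimage.center_of_mass(local_max, labels, np.arange(1, n_lab + 1))
    idx = np.rint(np.asarray(coms)).astype(int)
    pos = _voxel_centres_nm(stack, idx)
    # use the plateau centroid (possibly between voxel centres) as the seed
    half = np.asarray(coms) - idx
    pos = pos + half[:, ::-1] * np.asarray(stack.voxel_size)
    cands = pd.DataFrame({
        "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        "amplitude": smooth[idx[:, 0], idx[:, 1], idx[:, 2]] - background,
        "iz": idx[:, 0], "iy": idx[:, 1], "ix": idx[:, 2],
    }).sort_values("amplitude", ascending=False, ignore_index=True)
    return filter_candidates(cands, intensity_fraction, isolation_radius)


# ---------------------------------------------------------------------------
# integrated-Gaussian model


def _axis_integral(coord_lo, coord_hi, centre, sigma):
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((coord_hi - centre) / s) - erf((coord_lo - centre) / s))


def _model_on_voxels(params, edges_lo, edges_hi, n_spots):
    """Expected counts on an arbitrary voxel subset.

    params = [background, sig_lat, sig_ax, (amp, x, y, z) * n_spots];
    edges_lo/hi are (n_vox, 3) world coordinates of voxel corners.
    """
    bg, sig_lat, sig_ax = params[0], params[1], params[2]
    model = np.full(edges_lo.shape[0], bg)
    for k in range(n_spots):
        amp, cx, cy, cz = params[3 + 4 * k: 7 + 4 * k]
        gx = _axis_integral(edges_lo[:, 0], edges_hi[:, 0], cx, sig_lat)
        gy = _axis_integral(edges_lo[:, 1], edges_hi[:, 1], cy, sig_lat)
        gz = _axis_integral(edges_lo[:, 2], edges_hi[:, 2], cz, sig_ax)
        model = model + amp * gx * gy * gz
    return model


def _voxel_edges(stack: ImageStack, idx_zyx: np.ndarray):
    centres = _voxel_centres_nm(stack, idx_zyx)
    half = 0.5 * np.asarray(stack.voxel_size)
    return centres - half, centres + half


def _fit_spot_group(stack: ImageStack, seeds_xyz: np.ndarray,
                    idx_zyx: np.ndarray, data_vals: np.ndarray,
                    sigma_init: tuple[float, float],
                    background_init: float) -> list[SpotMeasurement]:
    n_spots = seeds_xyz.shape[0]
    edges_lo, edges_hi = _voxel_edges(stack, idx_zyx)
    amp0 = max((data_vals.sum() - background_init * data_vals.size) / n_spots, 1e-3)
    p0 = [background_init, sigma_init[0], sigma_init[1]]
    lo = [-np.inf, sigma_init[0] * 0.3, sigma_init[1] * 0.3]
    hi = [np.inf, sigma_init[0] * 3.0, sigma_init[1] * 3.0]
    extent = stack.extent_nm
    org = np.asarray(stack.origin)
    for s in seeds_xyz:
        p0 += [amp0, *s]
        lo += [0.0, *org]
        hi += [np.inf, *(org + extent)]

    def resid(p):
        return _model_on_voxels(p, edges_lo, edges_hi, n_spots) - data_vals

    try:
        res = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                            xtol=FIT_TOL, ftol=FIT_TOL, gtol=FIT_TOL,
                            max_nfev=FIT_MAX_ITER * (len(p0) + 1))
        ok = res.success
        params = res.x
        final_cost = float(np.sqrt(np.mean(res.fun ** 2)))
    except Exception:
        ok, params, final_cost = False, np.asarray(p0, float), np.nan
    out = []
    noise_floor = _noise_floor(stack)
    for k in range(n_spots):
        amp, cx, cy, cz = params[3 + 4 * k: 7 + 4 * k]
        converged = bool(ok and amp > noise_floor)
        out.append(SpotMeasurement(
            centre=(cx, cy, cz), channel=stack.channel, amplitude=float(amp),
            background=float(params[0]), sigma_lateral=float(params[1]),
            sigma_axial=float(params[2]), converged=converged,
            residual=final_cost))
    return out


def _noise_floor(stack: ImageStack) -> float:
    data = np.asarray(stack.data, dtype=float)
    bg = np.median(data)
    mad = np.median(np.abs(data - bg))
    peak = data.max() - bg
    return max(3.0 * 1.4826 * mad, 0.02 * peak, 1e-9)


def fit_mixture(stack: ImageStack, seeds,
                psf_sigma_nm: tuple[float, float] = (120.0, 300.0),
                roi_halfwidth_nm: float = 600.0) -> list[SpotMeasurement]:
    """Refine seed positions by mixture-model fitting.

    Seeds within ``roi_halfwidth_nm`` of one another are fitted jointly
    (shared background and PSF widths, per-spot amplitude and centre);
    isolated seeds are fitted alone on a local box ROI.  Non-converged or
    signal-free fits are returned flagged, not raised.
    """
    if isinstance(seeds, pd.DataFrame):
        seeds_xyz = seeds[["x", "y", "z"]].to_numpy(dtype=float)
    else:
        seeds_xyz = np.atleast_2d(np.asarray(seeds, dtype=float))
    if seeds_xyz.shape[0] == 0:
        raise ValueError("need at least one seed")
    data = np.asarray(stack.data, dtype=float)
    background = float(np.median(data))

    # group seeds into clusters of mutually overlapping ROIs
    n = seeds_xyz.shape[0]
    diff = seeds_xyz[:, None, :] - seeds_xyz[None, :, :]
    adj = np.sqrt(np.sum(diff ** 2, axis=-1)) < 2 * roi_halfwidth_nm
    labels = -np.ones(n, dtype=int)
    next_label = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        frontier = [i]
        labels[i] = next_label
        while frontier:
            j = frontier.pop()
            for k in np.nonzero(adj[j])[0]:
                if labels[k] < 0:
                    labels[k] = next_label
                    frontier.append(k)
        next_label += 1

    vx, vy, vz = stack.voxel_size
    nz, ny, nx = data.shape
    org = np.asarray(stack.origin)
    results = [None] * n
    for lab in range(next_label):
        members = np.nonzero(labels == lab)[0]
        group = seeds_xyz[members]
        lo_nm = group.min(axis=0) - roi_halfwidth_nm - org
        hi_nm = group.max(axis=0) + roi_halfwidth_nm - org
        ix0, iy0, iz0 = (max(int(lo_nm[0] / vx), 0), max(int(lo_nm[1] / vy), 0),
                         max(int(lo_nm[2] / vz), 0))
        ix1 = min(int(np.ceil(hi_nm[0] / vx)), nx)
        iy1 = min(int(np.ceil(hi_nm[1] / vy)), ny)
        iz1 = min(int(np.ceil(hi_nm[2] / vz)), nz)
        zz, yy, xx = np.meshgrid(np.arange(iz0, iz1), np.arange(iy0, iy1),
                                 np.arange(ix0, ix1), indexing="ij")
        idx = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
        vals = data[idx[:, 0], idx[:, 1], idx[:, 2]]
        fits = _fit_spot_group(stack, group, idx, vals,
                               psf_sigma_nm, background)
        for m, f in zip(members, fits):
            results[m] = f
    return results


# ---------------------------------------------------------------------------
# masked partner search


def masked_partner_search(stack: ImageStack, anchor,
                          shape: str = "sphere",
                          radius: float = DEFAULT_MASK_RADIUS_NM,
                          direction=None,
                          psf_sigma_nm: tuple[float, float] = (120.0, 300.0)
                          ) -> SpotMeasurement | None:
    """Fit the partner-channel spot inside a mask around an anchor position.

    ``anchor`` is a SpotMeasurement or an (x, y, z) position in nm,
    optionally already shift-corrected into this stack's channel frame.  The
    fit uses only voxels whose centres lie within ``radius`` of the anchor
    (for a hemisphere, additionally in the half-space along ``direction``).
    Returns None when no credible spot is found inside the mask — no signal
    above the noise floor, a non-converged fit, or a fitted centre outside
    the mask.
    """
    if radius <= 0:
        raise ValueError("mask radius must be positive")
    if shape not in ("sphere", "hemisphere"):
        raise ValueError(f"unknown mask shape {shape!r}")
    if shape == "hemisphere":
        if direction is None:
            raise ValueError("hemisphere mask requires a direction")
        direction = np.asarray(direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
    centre = anchor.centre if isinstance(anchor, SpotMeasurement) else \
        np.asarray(anchor, dtype=float).reshape(3)

    data = np.asarray(stack.data, dtype=float)
    nz, ny, nx = data.shape
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    idx = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    pos = _voxel_centres_nm(stack, idx)
    rel = pos - centre
    inside = np.sum(rel ** 2, axis=1) <= radius ** 2
    if shape == "hemisphere":
        inside &= rel @ direction >= 0
    if not np.any(inside):
        return None
    idx_in = idx[inside]
    vals = data[idx_in[:, 0], idx_in[:, 1], idx_in[:, 2]]
    background = float(np.median(data))
    noise_floor = _noise_floor(stack)
    if vals.max() - background <= noise_floor * 0.1:
        return None
    seed = _voxel_centres_nm(stack, idx_in[np.argmax(vals)][None, :])[0]
    fit = _fit_spot_group(stack, seed[None, :], idx_in, vals,
                          psf_sigma_nm, background)[0]
    if not fit.converged:
        return None
    rel_fit = fit.centre - centre
    if np.sum(rel_fit ** 2) > radius ** 2:
        return None
    if shape == "hemisphere" and rel_fit @ direction < 0:
        return None
    return fit
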
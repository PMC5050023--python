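"""End-to-end orchestration: simulate -> (render -> localize) -> register ->
measure -> statistics, with CSV/JSON reporting.

The pipeline reproduces, on synthetic ensembles with known truth, the
headline comparisons of the analysis: near-invariant 3D intra-kinetochore
distance versus strongly condition-dependent projected (1D) distance and
swivel dispersion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry, registration, stats
from .config import SimulationConfig
from .synthetic import (GREEN, RED, SimulationResult, render_stack,
                        simulate_pairs)
from .spots import detect_candidates, fit_mixture, masked_partner_search

log = logging.getLogger("ktswivel")


@dataclass
class PipelineConfig:
    """Configuration for a (possibly multi-condition) synthetic run."""

    conditions: dict = field(default_factory=dict)  # name -> SimulationConfig
    z_threshold: float = geometry.DEFAULT_Z_THRESHOLD_NM
    n_boot: int = 2000
    n_perm: int = 100_000
    seed: int = 0
    render: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        conds = {name: SimulationConfig.from_dict(c)
                 for name, c in d.pop("conditions", {}).items()}
        return cls(conditions=conds, **d)


# ---------------------------------------------------------------------------
# sister pairing


def pair_sisters(spots: pd.DataFrame,
                 min_distance: float = 500.0,
                 max_distance: float = 2000.0,
                 max_tilt_deg: float = 60.0) -> pd.DataFrame:
    """Assign sister-pair identities to a (green) spot table in plate frame.

    Ground-truth ``pair_id`` columns are used verbatim when present.
    Otherwise spots are paired across the metaphase plate: candidate
    partners must lie [min_distance, max_distance] nm apart with the
    connecting axis tilted less than ``max_tilt_deg`` from the plate normal
    (sister pairs straddle the plate; chance neighbours lie mostly
    in-plane), and of those, mutual nearest neighbours by *in-plane*
    distance are accepted.  Unpairable spots are logged and dropped.
    Returns the paired subset with ``assigned_pair``/``assigned_sister``.

    This is a deliberately simple stand-in for full temporal tracking or
    manual pairing; at realistic single-plate densities a few percent of
    assignments are chance neighbours that survive the gates.
    """
    out = spots.reset_index(drop=True).copy()
    if "pair_id" in out.columns:
        out["assigned_pair"] = out["pair_id"]
        out["assigned_sister"] = out.get("sister", out.groupby("pair_id").cumcount())
        return out
    pos = out[["x", "y", "z"]].to_numpy(dtype=float)
    n = len(out)
    if n < 2:
        raise ValueError("need at least two spots to pair")
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt(np.sum(diff ** 2, axis=-1))
    np.fill_diagonal(dist, np.inf)
    in_plane = np.sqrt(np.sum(diff[..., 1:] ** 2, axis=-1))
    with np.errstate(invalid="ignore"):
        align = np.abs(diff[..., 0]) / np.where(np.isfinite(dist), dist, 1.0)
    ok = ((dist >= min_distance) & (dist <= max_distance)
          & (align >= np.cos(np.radians(max_tilt_deg))))
    cost = np.where(ok, in_plane, np.inf)
    np.fill_diagonal(cost, np.inf)
    nn = np.argmin(cost, axis=1)
    pair_ids = np.full(n, -1)
    next_id = 0
    for i in range(n):
        j = nn[i]
        if pair_ids[i] >= 0 or np.isinf(cost[i, j]) or nn[j] != i or j < i:
            continue
        pair_ids[i] = pair_ids[j] = next_id
        next_id += 1
    dropped = int(np.sum(pair_ids < 0))
    if dropped:
        log.info("pair_sisters: dropped %d unpairable spots", dropped)
    out["assigned_pair"] = pair_ids
    out = out.loc[pair_ids >= 0].reset_index(drop=True)
    out["assigned_sister"] = out.groupby("assigned_pair").cumcount()
    return out


# ---------------------------------------------------------------------------
# measurement tables


def _wide_geometry(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pair_ids, inner (n,2,3), outer (n,2,3)) from a long truth-like table."""
    t = table.sort_values(["pair_id", "sister"])
    n = t["pair_id"].nunique()
    inner = t[["inner_x", "inner_y", "inner_z"]].to_numpy(float).reshape(n, 2, 3)
    outer = t[["outer_x", "outer_y", "outer_z"]].to_numpy(float).reshape(n, 2, 3)
    return t["pair_id"].to_numpy()[::2], inner, outer


def measure_pairs(table: pd.DataFrame,
                  z_threshold: float = geometry.DEFAULT_Z_THRESHOLD_NM
                  ) -> pd.DataFrame:
    """All delta and swivel observables, one row per kinetochore.

    ``table`` is long-format with two rows per pair (columns pair_id,
    sister, inner_x..z, outer_x..z and optionally kmt_x..z).
    """
    pair_ids, inner, outer = _wide_geometry(table)
    has_kmt = {"kmt_x", "kmt_y", "kmt_z"}.issubset(table.columns)
    if has_kmt:
        t = table.sort_values(["pair_id", "sister"])
        kmt = t[["kmt_x", "kmt_y", "kmt_z"]].to_numpy(float).reshape(-1, 2, 3)
    rows = []
    for i in (0, 1):
        j = 1 - i
        d = geometry.delta_components(inner[:, i], outer[:, i],
                                      inner[:, j], outer[:, j], z_threshold)
        s = geometry.swivel_components(inner[:, i], outer[:, i], inner[:, j],
                                       kmt_axis=kmt[:, i] if has_kmt else None)
        df = pd.DataFrame({"pair_id": pair_ids, "sister": i, **d, **s})
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["pair_id", "sister"], ignore_index=True)


def observations_to_pairs(observed: pd.DataFrame) -> pd.DataFrame:
    """Merge a two-channel observed spot table into a long pair table
    (green spots become inner markers, red spots outer markers)."""
    green = observed[observed["channel"] == GREEN]
    red = observed[observed["channel"] == RED]
    merged = green.merge(red, on=["pair_id", "sister"], suffixes=("_g", "_r"))
    return pd.DataFrame({
        "pair_id": merged["pair_id"], "sister": merged["sister"],
        "inner_x": merged["x_g"], "inner_y": merged["y_g"],
        "inner_z": merged["z_g"],
        "outer_x": merged["x_r"], "outer_y": merged["y_r"],
        "outer_z": merged["z_r"],
    })


# ---------------------------------------------------------------------------
# rendered-image route


def localize_rendered_pairs(sim: SimulationResult,
                            photons: float = 5e4,
                            background: float = 10.0,
                            poisson: bool = True,
                            stack_shape: tuple[int, int, int] = (16, 40, 40),
                            psf_sigma_nm: tuple[float, float, float] = (120.0, 120.0, 300.0),
                            mask_radius: float = 300.0,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Render each simulated pair into a local two-channel stack and re-measure
    it through the localization stages.

    Green (inner) spots are detected and mixture-fitted; each fitted green
    centre anchors a hemispherical masked search (normal to the plate, away
    from the pair centre) for the red (outer) spot, which is then corrected
    by the generative chromatic shift.  Returns a long pair table of
    recovered positions for pairs where all four spots were found.
    """
    if rng is None:
        rng = np.random.default_rng(sim.config.seed + 1)
    shift = np.asarray(sim.config.chromatic_shift, float)
    voxel = np.asarray((69.4, 69.4, 100.0))
    nz, ny, nx = stack_shape
    extent = np.array([nx, ny, nz]) * voxel[[0, 1, 2]]
    rows = []
    for pair in sim.pairs:
        centre = 0.5 * (pair.inner[0] + pair.inner[1])
        origin = centre - 0.5 * extent
        green_pos = pair.inner
        red_pos = pair.outer + shift
        try:
            g_stack = render_stack(green_pos, photons, stack_shape,
                                   voxel_size=tuple(voxel),
                                   psf_sigma_nm=psf_sigma_nm,
                                   background=background, poisson=poisson,
                                   rng=rng, channel=GREEN, origin=tuple(origin))
            r_stack = render_stack(red_pos, photons, stack_shape,
                                   voxel_size=tuple(voxel),
                                   psf_sigma_nm=psf_sigma_nm,
                                   background=background, poisson=poisson,
                                   rng=rng, channel=RED, origin=tuple(origin))
        except ValueError:
            log.info("pair %d falls outside its render volume; skipped",
                     pair.pair_id)
            continue
        cands = detect_candidates(g_stack)
        if len(cands) != 2:
            continue
        fits = fit_mixture(g_stack, cands,
                           psf_sigma_nm=(psf_sigma_nm[0], psf_sigma_nm[2]))
        fits = [f for f in fits if f.converged]
        if len(fits) != 2:
            continue
        found = {}
        for f in fits:
            direction = np.array([np.sign(f.centre[0] - centre[0]) or 1.0, 0, 0])
            anchor_in_red = f.centre + shift
            partner = masked_partner_search(
                r_stack, anchor_in_red, shape="hemisphere",
                radius=mask_radius, direction=direction,
                psf_sigma_nm=(psf_sigma_nm[0], psf_sigma_nm[2]))
            if partner is None:
                continue
            sister = int(np.argmin(np.linalg.norm(pair.inner - f.centre, axis=1)))
            found[sister] = (f.centre, partner.centre - shift)
        if set(found) != {0, 1}:
            continue
        for sister, (inner_c, outer_c) in sorted(found.items()):
            rows.append({"pair_id": pair.pair_id, "sister": sister,
                         "inner_x": inner_c[0], "inner_y": inner_c[1],
                         "inner_z": inner_c[2], "outer_x": outer_c[0],
                         "outer_y": outer_c[1], "outer_z": outer_c[2]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run


def _condition_summary(meas: pd.DataFrame, n_boot: int, seed: int) -> dict:
    passed = meas[meas["z_filter_pass"]]
    per_pair = meas.drop_duplicates("pair_id")
    out = {"n_kinetochores": int(len(meas)),
           "n_z_filter_pass": int(len(passed))}
    for name, values in (
            ("delta3d", passed["delta3d"]),
            ("delta2d", passed["delta2d"]),
            ("delta1d", per_pair["delta1d"]),
            ("d3d", per_pair["d3d"]),
            ("swivel3d", meas["swivel3d"])):
        med, se = stats.summarize_median(values.to_numpy(), n_boot=n_boot,
                                         seed=seed)
        out[f"{name}_median"] = med
        out[f"{name}_se"] = se
    out["y_swivel_sd"] = float(np.std(meas["y_swivel"].to_numpy(), ddof=1))
    out["twist_median"] = float(np.median(meas["twist"]))
    return out


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run the full synthetic pipeline and return the summary bundle.

    Per condition: simulate, correct the chromatic shift using the
    generative calibration, measure deltas and swivels, and summarise
    (medians +/- bootstrap SE, y-swivel sd).  With two or more conditions,
    cross-condition Mann-Whitney tests on delta3d/delta1d/swivel3d and an F
    test on y-swivel are added.  Deterministic given the seed.
    """
    if not config.conditions:
        raise ValueError("pipeline config names no conditions")
    summary = {"seed": config.seed, "conditions": {}, "tests": {}}
    tables = {}
    for k, (name, sim_cfg) in enumerate(sorted(config.conditions.items())):
        sim = simulate_pairs(sim_cfg)
        obs_pairs = observations_to_pairs(sim.observed)
        # undo the generative chromatic shift on the red (outer) channel
        shift = registration.ChromaticShift(
            zeta=np.asarray(sim_cfg.chromatic_shift, float),
            sd=np.zeros(3), n_spots=max(sim_cfg.n_pairs, 1))
        corrected = registration.apply_correction(
            obs_pairs.rename(columns={"outer_x": "x", "outer_y": "y",
                                      "outer_z": "z"}), shift)
        obs_pairs[["outer_x", "outer_y", "outer_z"]] = corrected[["x", "y", "z"]]
        meas = measure_pairs(obs_pairs, z_threshold=config.z_threshold)
        tables[name] = meas
        summary["conditions"][name] = {
            "metadata": sim.metadata,
            **_condition_summary(meas, config.n_boot, config.seed + k),
        }
        log.info("condition %s: %d kinetochores, %d pass z filter", name,
                 len(meas), int(meas["z_filter_pass"].sum()))
    names = sorted(tables)
    if len(names) >= 2:
        a, b = tables[names[0]], tables[names[1]]
        pa, pb = a[a["z_filter_pass"]], b[b["z_filter_pass"]]
        summary["tests"] = {
            "delta3d_mann_whitney_p": stats.mann_whitney(
                pa["delta3d"], pb["delta3d"]).p_value,
            "delta1d_mann_whitney_p": stats.mann_whitney(
                a.drop_duplicates("pair_id")["delta1d"],
                b.drop_duplicates("pair_id")["delta1d"]).p_value,
            "swivel3d_mann_whitney_p": stats.mann_whitney(
                a["swivel3d"], b["swivel3d"]).p_value,
            "y_swivel_f_test_p": stats.variance_f_test(
                a["y_swivel"], b["y_swivel"]).p_value,
            "compared": [names[0], names[1]],
        }
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, meas in tables.items():
            meas.to_csv(out / f"measurements_{name}.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    summary["tables"] = tables
    return summary
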
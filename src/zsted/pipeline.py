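"""End-to-end experiment runners: simulate → analyze → report.

Each runner consumes a plain (YAML-loadable) config dict, executes the
corresponding chain of library stages, writes CSV/TIFF outputs plus the
resolved config and a run log beside them, and returns the headline results
as a dict so callers can consume them programmatically.  A run is fully
reproduced by its resolved config: deterministic stages are bit-exact and
stochastic stages are seeded.
"""

from __future__ import annotations

import copy
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffusion, fcs, gp, metrics, scenes
from .correlator import autocorrelate, write_curve_csv
from .psf import ObservationVolume, make_preset

__all__ = [
    "run_fcs_experiment",
    "run_imaging_experiment",
    "run_gp_experiment",
    "min_resolvable_separation",
    "load_config",
]

log = logging.getLogger("zsted")

#: Default configuration for all runners.  FCS defaults emulate a supported
#: lipid bilayer: free diffusion at 5 μm²/s, 2 μs binning, 5 s acquisitions,
#: particle density giving N ≈ 5 in the confocal observation area.
DEFAULT_CONFIG: dict = {
    "seed": 1,
    "psf": {},  # per-mode observation-volume overrides, e.g. {"z_sted": {...}}
    "fcs": {
        "diffusion_coeff": 5.0,       # um^2/s
        "n_particles": 220,
        "box_side": 2400.0,           # nm
        "bin_time": 2e-6,             # s
        "duration": 5.0,              # s
        "brightness_peak": 150_000.0,  # counts/s at the profile peak
        "background_rate": 0.0,
        "triplet_fraction": 0.0,
        "triplet_tau": 5e-6,
        "membrane_z_conf": [0.0],     # planes seen in the confocal recording
        "membrane_z_sted": [0.0],     # planes seen in the z-STED recording
        "lag_window": [2e-6, 0.5],
    },
    "imaging": {
        "modes": ["confocal", "z_sted"],
        "photons_per_unit": 1.0,
        "noise": False,
        "scenes": [
            {"id": "slb_plane", "type": "plane"},
            {"id": "two_planes_150", "type": "two_planes", "separation_nm": 150.0},
        ],
        "write_tiffs": True,
    },
    "gp": {
        "mode": "z_sted",
        "plane_gp": 0.3,
        "vesicle_gp": -0.1,
        "vesicle_radius_nm": 200.0,
        "vesicle_z_nm": 500.0,
        "photons_per_voxel": 2000.0,
        "noise": True,
        "intensity_threshold": None,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge DEFAULT_CONFIG <- YAML file <- overrides (later wins)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise KeyError(f"missing config key {key!r} in {context}")
    return mapping[key]


def _setup_run(outdir: str | Path, config: dict) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "resolved_config.yaml").open("w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    return outdir


def _teardown_run() -> None:
    for handler in list(log.handlers):
        if isinstance(handler, logging.FileHandler):
            log.removeHandler(handler)
            handler.close()


def _preset(mode: str, config: dict) -> ObservationVolume:
    return make_preset(mode, **config.get("psf", {}).get(mode, {}))


class _Stage:
    """Context manager logging a stage's wall time and labeling its errors."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            log.error("stage %s: failed after %.2f s: %s", self.name, dt, exc)
            raise RuntimeError(f"stage {self.name!r} failed: {exc}") from exc
        log.info("stage %s: done in %.2f s", self.name, dt)
        return False


# -- FCS experiment -------------------------------------------------------

def _fcs_single_mode(mode: str, membrane_z, config: dict, seed: int,
                     outdir: Path | None):
    f = config["fcs"]
    vol = _preset(mode, config)
    sim = diffusion.DiffusionSimConfig(
        diffusion_coeff=f["diffusion_coeff"], n_particles=f["n_particles"],
        box_side=f["box_side"], bin_time=f["bin_time"], duration=f["duration"],
        brightness_peak=f["brightness_peak"], background_rate=f["background_rate"],
        triplet_fraction=f["triplet_fraction"], triplet_tau=f["triplet_tau"],
        membrane_z_nm=tuple(membrane_z), seed=seed)
    with _Stage(f"simulate_trace[{mode}]"):
        trace = diffusion.simulate_trace(sim, vol)
    with _Stage(f"autocorrelate[{mode}]"):
        curve = autocorrelate(trace)
    with _Stage(f"fit_curve[{mode}]"):
        fit = fcs.fit_curve(curve, fixed_triplet_tau=f["triplet_tau"],
                            lag_window=tuple(f["lag_window"]))
    if not fit.converged:
        raise RuntimeError(f"FCS fit did not converge for mode {mode}")
    if outdir is not None:
        write_curve_csv(curve, outdir / f"curve_{mode}.csv")
    return vol, trace, curve, fit


def run_fcs_experiment(config: dict, outdir: str | Path) -> dict:
    """Confocal + z-STED FCS chain with observation-size calibration.

    Simulates one trace per mode (membrane planes per mode are configurable,
    so the confocal recording can span two membranes while z-STED isolates
    one), correlates and fits each, then derives the calibrated STED lateral
    FWHM, the diffusion coefficient and area-normalized molecule densities.
    Writes curve CSVs, a fit report CSV and a calibration CSV.
    """
    outdir = _setup_run(outdir, config)
    try:
        f = config["fcs"]
        seed = int(config["seed"])
        vol_c, _, _, fit_c = _fcs_single_mode(
            "confocal", _require(f, "membrane_z_conf", "fcs"), config, seed, outdir)
        vol_s, _, _, fit_s = _fcs_single_mode(
            "z_sted", _require(f, "membrane_z_sted", "fcs"), config, seed + 1, outdir)

        with _Stage("calibrate"):
            tau_c = fit_c.params.transit_time
            tau_s = fit_s.params.transit_time
            fwhm_c = vol_c.lateral_fwhm
            fwhm_s = fcs.calibrate_sted_fwhm(tau_s, tau_c, fwhm_c)
            d_coeff = fcs.diffusion_coefficient(tau_c, fwhm_c)
            n_c = fit_c.params.n_molecules
            n_s = fit_s.params.n_molecules
            n_norm_c = fcs.normalized_density(n_c, fwhm_c, n_c, fwhm_c)
            n_norm_s = fcs.normalized_density(n_s, fwhm_s, n_c, fwhm_c)
            calib = fcs.CalibrationResult(
                fwhm_sted=fwhm_s, fwhm_conf=fwhm_c, tau_sted=tau_s,
                tau_conf=tau_c, d_coeff=d_coeff,
                n_norm=n_norm_s, n_conf_ref=n_c)

        rows = []
        for mode, fit, fwhm, n_norm in (("confocal", fit_c, fwhm_c, n_norm_c),
                                        ("z_sted", fit_s, fwhm_s, n_norm_s)):
            p = fit.params
            rows.append({
                "mode": mode, "N": p.n_molecules, "T": p.triplet_amp,
                "tau_xy_s": p.transit_time,
                "stderr_N": fit.stderr["n_molecules"],
                "stderr_tau_xy_s": fit.stderr["transit_time"],
                "D_um2_s": fcs.diffusion_coefficient(p.transit_time, fwhm),
                "fwhm_nm": fwhm, "n_norm": n_norm,
            })
        pd.DataFrame(rows).to_csv(outdir / "fit_report.csv", index=False)
        pd.DataFrame([{
            "fwhm_conf_nm": calib.fwhm_conf, "fwhm_sted_nm": calib.fwhm_sted,
            "tau_conf_s": calib.tau_conf, "tau_sted_s": calib.tau_sted,
            "tau_ratio_conf_over_sted": calib.tau_conf / calib.tau_sted,
            "D_um2_s": calib.d_coeff,
            "n_norm_ratio_conf_over_sted": n_norm_c / n_norm_s,
        }]).to_csv(outdir / "calibration.csv", index=False)

        return {"fit_confocal": fit_c, "fit_z_sted": fit_s, "calibration": calib,
                "tau_ratio": tau_c / tau_s,
                "n_norm_ratio": n_norm_c / n_norm_s}
    finally:
        _teardown_run()


# -- imaging experiment ---------------------------------------------------

#: axial half-extent (nm) of plane-scene grids; generous enough to contain
#: the confocal axial kernel (2 x 854 nm) and the z-STED side lobes, and
#: offset half a voxel so multiples of the 20-nm pitch are voxel centers
_PLANE_Z_HALF = 1810.0
_LATERAL_HALF = 600.0

#: half-width (nm) of the axial window used when counting membrane peaks;
#: wide enough for the membranes and their blur, narrow enough to exclude
#: the z-STED side-lobe shadows ~800 nm away
_PEAK_WINDOW_HALF = 300.0


def _crop_profile(prof: metrics.Profile1D, lo: float, hi: float) -> metrics.Profile1D:
    sel = (prof.positions >= lo) & (prof.positions <= hi)
    return metrics.Profile1D(positions=prof.positions[sel],
                             values=prof.values[sel], axis=prof.axis)


def _odd_lateral_half(reach: float) -> float:
    """Lateral half-extent making an odd voxel count centred on x=0."""
    import math as _math
    return 40.0 * _math.ceil(reach / 40.0) + 20.0


def build_scene(spec: dict) -> scenes.MembraneScene:
    """Build a MembraneScene from a config entry (``type`` + geometry keys)."""
    kind = _require(spec, "type", "imaging scene")
    if kind == "plane":
        z0 = float(spec.get("z_nm", 0.0))
        return scenes.MembraneScene(
            primitives=(scenes.Plane(z0=z0),),
            extent=((z0 - _PLANE_Z_HALF, z0 + _PLANE_Z_HALF),
                    (-_LATERAL_HALF, _LATERAL_HALF),
                    (-_LATERAL_HALF, _LATERAL_HALF)))
    if kind == "two_planes":
        sep = float(_require(spec, "separation_nm", "two_planes scene"))
        return scenes.MembraneScene(
            primitives=(scenes.Plane(z0=0.0), scenes.Plane(z0=sep)),
            extent=((-_PLANE_Z_HALF, sep + _PLANE_Z_HALF),
                    (-_LATERAL_HALF, _LATERAL_HALF),
                    (-_LATERAL_HALF, _LATERAL_HALF)))
    if kind == "tube":
        r = float(spec.get("radius_nm", 150.0))
        length = float(spec.get("length_nm", 800.0))
        half_lat = _odd_lateral_half(r + 480.0)
        return scenes.MembraneScene(
            primitives=(scenes.Tube(center_zx=(0.0, 0.0), radius=r, length=length),),
            extent=((-_PLANE_Z_HALF, _PLANE_Z_HALF),
                    (-length / 2, length / 2),
                    (-half_lat, half_lat)))
    if kind == "torus":
        ring = float(spec.get("ring_radius_nm", 600.0))
        tube = float(spec.get("tube_radius_nm", 150.0))
        half_lat = _odd_lateral_half(ring + tube + 480.0)
        return scenes.MembraneScene(
            primitives=(scenes.Torus(center=(0.0, 0.0, 0.0),
                                     ring_radius=ring, tube_radius=tube),),
            extent=((-_PLANE_Z_HALF, _PLANE_Z_HALF),
                    (-half_lat, half_lat), (-half_lat, half_lat)))
    if kind == "vesicle":
        r = float(spec.get("radius_nm", 200.0))
        return scenes.MembraneScene(
            primitives=(scenes.SphereShell(center=(0.0, 0.0, 0.0), radius=r),),
            extent=((-_PLANE_Z_HALF, _PLANE_Z_HALF),
                    (-_LATERAL_HALF, _LATERAL_HALF),
                    (-_LATERAL_HALF, _LATERAL_HALF)))
    raise ValueError(f"unknown scene type {kind!r}; "
                     "valid: plane, two_planes, tube, torus, vesicle")


def _center_index(stack: scenes.ImageStack, axis: int, coord: float) -> int:
    return int(np.argmin(np.abs(stack.axis_coords(axis) - coord)))


def _scene_metrics(spec: dict, scene: scenes.MembraneScene, mode: str,
                   image: scenes.ImageStack) -> dict:
    row: dict = {"scene": spec.get("id", spec["type"]), "mode": mode,
                 "fwhm_nm": np.nan, "n_peaks": np.nan,
                 "separation_nm": np.nan, "contrast": np.nan}
    kind = spec["type"]
    if kind in ("plane", "two_planes"):
        prof = metrics.extract_profile(image, axis="z")
        if kind == "plane":
            res = metrics.fit_fwhm(prof)
            row["fwhm_nm"] = res.fwhm if res.ok else np.nan
        # count membrane maxima in a window around the membranes, which
        # excludes the z-STED side-lobe shadows ~800 nm away
        z_lo = float(spec.get("z_nm", 0.0)) - _PEAK_WINDOW_HALF
        z_hi = float(spec.get("separation_nm", 0.0)) + _PEAK_WINDOW_HALF
        peaks = metrics.resolve_two_peaks(_crop_profile(prof, z_lo, z_hi))
        row["n_peaks"] = peaks.n_peaks
        if peaks.separation is not None:
            row["separation_nm"] = peaks.separation
    elif kind in ("tube", "torus"):
        iz = _center_index(image, 0, 0.0)
        iy = _center_index(image, 1, 0.0)
        prof = metrics.extract_profile(image, axis="x", line=(iz, iy))
        row["contrast"] = metrics.hollowness_contrast(prof)
    return row


def run_imaging_experiment(config: dict, outdir: str | Path) -> pd.DataFrame:
    """Render configured scenes, image them under each preset, measure them.

    Per (scene, mode) pair the metrics CSV records the axial FWHM (plane
    scenes), the number of detected membrane peaks and their separation
    (plane/two-plane scenes) and the rim-to-lumen hollowness contrast
    (tube/torus scenes).
    """
    outdir = _setup_run(outdir, config)
    try:
        img = config["imaging"]
        rows = []
        for spec in img["scenes"]:
            scene = build_scene(spec)
            with _Stage(f"render[{spec.get('id', spec['type'])}]"):
                truth = scenes.render_scene(scene)
            for mode in img["modes"]:
                vol = _preset(mode, config)
                with _Stage(f"image[{spec.get('id', spec['type'])},{mode}]"):
                    image = scenes.image_scene(
                        truth, vol, photons_per_unit=img["photons_per_unit"],
                        noise=img["noise"], seed=int(config["seed"]))
                if img.get("write_tiffs", True):
                    scenes.write_tiff(
                        image, outdir / f"{spec.get('id', spec['type'])}_{mode}.tif")
                rows.append(_scene_metrics(spec, scene, mode, image))
        df = pd.DataFrame(rows)
        df.to_csv(outdir / "metrics.csv", index=False)
        return df
    finally:
        _teardown_run()


def min_resolvable_separation(vol: ObservationVolume,
                              separations=None,
                              min_prominence: float = 0.1) -> dict:
    """Smallest two-plane separation yielding two detected maxima.

    Renders two parallel membranes at each candidate separation (multiples
    of the 20-nm axial voxel), images them noiselessly through ``vol`` and
    runs prominence-based peak detection on the axial profile, restricted
    to a window around the membranes (side-lobe shadows excluded).
    """
    if separations is None:
        separations = np.arange(40.0, 401.0, 20.0)
    results = {}
    min_sep = None
    for sep in separations:
        scene = build_scene({"type": "two_planes", "separation_nm": float(sep)})
        truth = scenes.render_scene(scene)
        image = scenes.image_scene(truth, vol)
        prof = metrics.extract_profile(image, axis="z")
        prof = _crop_profile(prof, -_PEAK_WINDOW_HALF, sep + _PEAK_WINDOW_HALF)
        peaks = metrics.resolve_two_peaks(prof, min_prominence=min_prominence)
        results[float(sep)] = peaks.n_peaks
        if peaks.n_peaks == 2 and min_sep is None:
            min_sep = float(sep)
    return {"min_separation_nm": min_sep, "n_peaks_by_separation": results}


# -- GP experiment --------------------------------------------------------

def run_gp_experiment(config: dict, outdir: str | Path) -> dict:
    """Spectral-imaging chain: plane + vesicle scene with known GP values.

    Builds a membrane plane (plasma-membrane-like GP) and a vesicle shell
    (lower GP), images both channels through the configured preset with
    Poisson noise, computes the GP map and reports per-structure ROI
    statistics.  Writes the GP map as TIFF plus an ROI stats CSV.
    """
    outdir = _setup_run(outdir, config)
    try:
        g = config["gp"]
        mode = g["mode"]
        vol = _preset(mode, config)
        plane_gp = float(_require(g, "plane_gp", "gp"))
        ves_gp = float(_require(g, "vesicle_gp", "gp"))
        r = float(g["vesicle_radius_nm"])
        zv = float(g["vesicle_z_nm"])

        lat = _odd_lateral_half(2 * _LATERAL_HALF)
        scene = scenes.MembraneScene(
            primitives=(scenes.Plane(z0=0.0),
                        scenes.SphereShell(center=(zv, 0.0, 0.0), radius=r)),
            extent=((-_PLANE_Z_HALF, zv + _PLANE_Z_HALF),
                    (-lat, lat), (-lat, lat)))

        with _Stage("make_spectral_scene"):
            pair = scenes.make_spectral_scene(
                scene, gp_map=[plane_gp, ves_gp],
                total_intensity=float(g["photons_per_voxel"]) / 1600.0)
        with _Stage("image_channels"):
            seed = int(config["seed"])
            green = scenes.image_scene(pair.green, vol, noise=g["noise"], seed=seed)
            red = scenes.image_scene(pair.red, vol, noise=g["noise"], seed=seed + 1)
            imaged = scenes.SpectralImagePair(green=green, red=red)
        with _Stage("gp_image"):
            gpmap = gp.gp_image(imaged, intensity_threshold=g["intensity_threshold"])

        # ROIs: membrane voxels of each primitive's own rendering
        roi_plane = scenes.render_scene(scenes.MembraneScene(
            primitives=(scene.primitives[0],), extent=scene.extent)).voxels > 0
        roi_ves = scenes.render_scene(scenes.MembraneScene(
            primitives=(scene.primitives[1],), extent=scene.extent)).voxels > 0
        with _Stage("roi_gp"):
            comparison = gp.compare_rois(gpmap, roi_plane, roi_ves)

        out = scenes.ImageStack(voxels=np.where(gpmap.mask, gpmap.gp, 0.0) + 1.0,
                                voxel_size=gpmap.voxel_size,
                                meta={"kind": "gp_plus_1", "fill": "masked=1.0"})
        scenes.write_tiff(out, outdir / "gp_map.tif")
        gp.roi_stats_frame({"plane": comparison["roi_a"],
                            "vesicle": comparison["roi_b"]}
                           ).to_csv(outdir / "roi_stats.csv", index=False)
        return {"plane": comparison["roi_a"], "vesicle": comparison["roi_b"],
                "delta_mean": comparison["delta_mean"],
                "true_gp": {"plane": plane_gp, "vesicle": ves_gp}}
    finally:
        _teardown_run()
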
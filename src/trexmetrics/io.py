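"""File formats, run configuration, and the pipeline orchestrator.

Images travel as grayscale TIFF (multi-page for 3D) with physical
calibration in a JSON sidecar (``<image>.json``) or supplied explicitly.
Point lists, landmark lists and result tables are CSV with a header row,
units encoded in column names (``diameter_um``).  Every pipeline run
echoes its configuration, package version and seed into a manifest so
runs are reproducible byte for byte (timestamps live only in logs, which
go to stderr).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import DomainError, FormatError

__all__ = [
    "RunConfig",
    "read_image",
    "write_image",
    "write_results",
    "run_pipeline",
    "STAGES",
]

log = logging.getLogger("trexmetrics")

STAGES = ("gel", "curves", "distort", "rings", "profile",
          "particles", "synapses", "simulate")


def _package_version() -> str:
    try:
        return metadata.version("trexmetrics")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunConfig:
    """One pipeline run: stage, inputs, calibration, parameters, seed."""

    stage: str
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "."

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise DomainError(
                f"unknown stage {self.stage!r}; expected one of {STAGES}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2, sort_keys=True)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=True))
        path.write_text(text)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = (json.loads(path.read_text()) if path.suffix == ".json"
               else yaml.safe_load(path.read_text()))
        return cls(**raw)


def read_image(path: str | Path, axes_hint: str | None = None,
               calibration: dict | None = None,
               require_calibration: bool = False,
               ) -> tuple[np.ndarray, dict]:
    """Read a grayscale TIFF as a 2D image or 3D (z, y, x) volume.

    Calibration (``pixel_size_um`` / ``voxel_size_um``) comes from an
    explicit ``calibration`` dict or a ``<path>.json`` sidecar.  RGB
    images and 3D reads without voxel calibration (when required) raise
    :class:`FormatError` naming the problem.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and (axes_hint or "").upper() != "ZYX":
        raise FormatError("RGB TIFF offered where a grayscale image is required")
    if arr.ndim not in (2, 3):
        raise FormatError(f"unsupported TIFF dimensionality: {arr.ndim}")

    cal = dict(calibration or {})
    sidecar = path.with_name(path.name + ".json")
    if not cal and sidecar.exists():
        cal = json.loads(sidecar.read_text())
    if require_calibration:
        key = "voxel_size_um" if arr.ndim == 3 else "pixel_size_um"
        if key not in cal:
            raise FormatError(f"missing calibration field {key!r} for "
                              f"{arr.ndim}D image {path.name}")
    return arr, cal


def write_image(path: str | Path, array: np.ndarray,
                calibration: dict | None = None) -> None:
    """Write an image/volume as TIFF (16-bit when the data allow it) plus
    a JSON calibration sidecar."""
    path = Path(path)
    arr = np.asarray(array)
    if np.issubdtype(arr.dtype, np.floating):
        lo, hi = float(arr.min()), float(arr.max())
        if lo >= 0 and hi <= np.iinfo(np.uint16).max and np.allclose(arr, np.rint(arr)):
            arr = arr.astype(np.uint16)
        else:
            arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr)
    if calibration:
        path.with_name(path.name + ".json").write_text(
            json.dumps(calibration, indent=2, sort_keys=True))


def write_results(tables: dict[str, pd.DataFrame], summaries: dict[str, dict],
                  outdir: str | Path, config: RunConfig | None = None) -> Path:
    """Write CSV tables, JSON summaries and a run manifest; returns the
    manifest path.  Field ordering is deterministic so identical runs
    produce byte-identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        p = outdir / f"{name}.csv"
        tables[name].to_csv(p, index=False)
        written.append(p.name)
    for name in sorted(summaries):
        p = outdir / f"{name}.json"
        p.write_text(json.dumps(summaries[name], indent=2, sort_keys=True,
                                default=float))
        written.append(p.name)
    manifest = {
        "package": "trexmetrics",
        "version": _package_version(),
        "config": config.to_dict() if config is not None else None,
        "seed": config.seed if config is not None else None,
        "files": sorted(written),
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


# ---------------------------------------------------------------------------
# stage runners

def _stage_gel(cfg: RunConfig) -> tuple[dict, dict]:
    from .gel import GelEdgePointSet, deformation_index

    pts = pd.read_csv(cfg.inputs["points"])
    radius = float(cfg.params["gel_radius_mm"])
    edge = GelEdgePointSet(points=pts[["x_mm", "y_mm"]].to_numpy(),
                           gel_radius_mm=radius)
    res = deformation_index(edge)
    table = pd.DataFrame([{
        "index_left": res.index_left, "index_right": res.index_right,
        "index_mean": res.index_mean, "handling_class": res.handling_class,
        "circle_radius_mm": res.circle.radius_mm,
        "circle_degenerate": res.circle.is_degenerate}])
    summary = {"index_mean": res.index_mean, "handling_class": res.handling_class,
               "n": int(len(pts))}
    return {"deformation": table}, {"deformation_summary": summary}


def _stage_curves(cfg: RunConfig) -> tuple[dict, dict]:
    from .gel import recipe_curves

    measurements = pd.read_csv(cfg.inputs["measurements"])
    curves = recipe_curves(measurements)
    return {"recipe_curves": curves}, {
        "curves_summary": {"n_groups": int(len(curves)),
                           "n_measurements": int(len(measurements))}}


def _stage_distort(cfg: RunConfig) -> tuple[dict, dict]:
    from .distortion import (LandmarkPairSet, fit_similarity,
                             measurement_error_curve, residual_field,
                             sample_field)

    lm = pd.read_csv(cfg.inputs["landmarks"])
    landmarks = LandmarkPairSet(
        pre_points=lm[["pre_x_um", "pre_y_um"]].to_numpy(),
        post_points=lm[["post_x_um", "post_y_um"]].to_numpy())
    transform = fit_similarity(landmarks)
    fld = residual_field(landmarks, transform,
                         regularization=float(cfg.params.get("regularization", 0.0)))
    bbox = landmarks.pre_points.max(axis=0) - landmarks.pre_points.min(axis=0)
    default_spacing = float(np.hypot(*bbox)) / 50.0
    spacing = float(cfg.params.get("grid_spacing_um", default_spacing))
    samples = sample_field(fld, spacing)
    curve = measurement_error_curve(
        samples, bin_width_um=float(cfg.params.get("bin_width_um", 5.0)),
        max_pairs=int(cfg.params.get("max_pairs", 1_000_000)), seed=cfg.seed)
    table = pd.DataFrame({
        "bin_center_um": curve.bin_centers_um,
        "mean_error_um": curve.mean_error_um,
        "sd_error_um": curve.sd_error_um,
        "mean_fraction": curve.mean_fraction,
        "n_pairs": curve.n_pairs})
    summary = {
        "expansion_factor": transform.scale,
        "rotation_rad": transform.rotation_rad,
        "rms_residual_um": transform.rms_residual_um,
        "overall_fraction_mean": curve.overall_fraction_mean,
        "overall_fraction_sd": curve.overall_fraction_sd,
        "n_landmarks": len(landmarks), "n_grid_points": int(len(samples.points))}
    return {"error_curve": table}, {"distortion_summary": summary}


def _stage_rings(cfg: RunConfig) -> tuple[dict, dict]:
    from .profiles import ring_diameters

    image, cal = read_image(cfg.inputs["image"])
    centers = pd.read_csv(cfg.inputs["centers"])[["x_px", "y_px"]].to_numpy()
    pixel_size_nm = float(cfg.params.get("pixel_size_nm",
                                         cal.get("pixel_size_nm", 1.0)))
    table, summary = ring_diameters(
        image, centers, pixel_size_nm,
        r_max_px=cfg.params.get("r_max_px"))
    return {"ring_fits": table}, {"ring_summary": summary}


def _stage_profile(cfg: RunConfig) -> tuple[dict, dict]:
    from .profiles import LineProfile, fwhm, peak_to_peak

    df = pd.read_csv(cfg.inputs["profile"])
    profile = LineProfile(positions=df["position"].to_numpy(),
                          intensities=df["intensity"].to_numpy())
    mode = cfg.params.get("mode", "fwhm")
    if mode == "fwhm":
        m = fwhm(profile)
        summary = {"mode": mode, "fwhm": m.fwhm, "baseline": m.baseline,
                   "n": len(profile)}
    elif mode == "p2p":
        m = peak_to_peak(profile)
        summary = {"mode": mode, "peak_to_peak": m.peak_to_peak,
                   "n_peaks": m.n_peaks, "n": len(profile)}
    else:
        raise DomainError(f"unknown profile mode {mode!r}")
    return {}, {"profile_summary": summary}


def _stage_particles(cfg: RunConfig) -> tuple[dict, dict]:
    from .objects import auto_threshold, particle_diameters, split_touching

    image, cal = read_image(cfg.inputs["image"])
    pixel_size_um = float(cfg.params.get("pixel_size_um",
                                         cal.get("pixel_size_um", 1.0)))
    mask, thr = auto_threshold(image)
    labels = split_touching(mask)
    table, summary = particle_diameters(
        labels, pixel_size_um,
        min_area_px=int(cfg.params.get("min_area_px", 0)),
        exclude_border=bool(cfg.params.get("exclude_border", False)))
    summary["threshold"] = thr
    return {"particles": table}, {"particle_summary": summary}


def _stage_synapses(cfg: RunConfig) -> tuple[dict, dict]:
    from .objects import pair_synapses, segment_channel

    post_vol, cal_post = read_image(cfg.inputs["post"], require_calibration=True,
                                    calibration=cfg.params.get("calibration"))
    pre_vol, _ = read_image(cfg.inputs["pre"],
                            calibration=cfg.params.get("calibration"))
    voxel = tuple(cfg.params.get("voxel_size_um")
                  or cal_post["voxel_size_um"])
    frac = float(cfg.params.get("threshold_frac_of_max", 0.5))
    min_vox = int(cfg.params.get("min_voxels", 5))
    post = segment_channel(post_vol, frac, min_vox, voxel)
    pre = segment_channel(pre_vol, frac, min_vox, voxel)
    table = pair_synapses(
        post, post_vol, pre, pre_vol, voxel,
        max_pair_distance_um=float(cfg.params.get("max_pair_distance_um", 2.0)))
    paired = table[table["paired"]] if len(table) else table
    summary = {
        "n_post": post.n_objects, "n_pre": pre.n_objects,
        "n_paired": int(len(paired)),
        "mean_separation_um": float(paired["separation_um"].mean())
        if len(paired) else float("nan"),
        "sd_separation_um": float(paired["separation_um"].std(ddof=1))
        if len(paired) > 1 else 0.0}
    return {"synapses": table}, {"synapse_summary": summary}


def _stage_simulate(cfg: RunConfig) -> tuple[dict, dict]:
    from . import synthetic

    gen = cfg.params.get("generator", "gen_ring_image")
    kwargs = dict(cfg.params.get("generator_params", {}))
    kwargs["seed"] = cfg.seed
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if gen == "gen_ring_image":
        img, truth = synthetic.gen_ring_image(**kwargs)
        write_image(outdir / "rings.tif", img.astype(np.float32),
                    {"pixel_size_nm": truth.params["pixel_size_nm"]})
        truth.truth_records.rename(columns={"center_x_px": "x_px",
                                            "center_y_px": "y_px"}).to_csv(
            outdir / "centers.csv", index=False)
    elif gen == "gen_gel_edge":
        edge, truth = synthetic.gen_gel_edge(**kwargs)
        pd.DataFrame(edge.points, columns=["x_mm", "y_mm"]).to_csv(
            outdir / "edge_points.csv", index=False)
    elif gen == "gen_landmark_field":
        _, truth = synthetic.gen_landmark_field(**kwargs)
        truth.truth_records.to_csv(outdir / "landmarks.csv", index=False)
    elif gen == "gen_disk_image":
        img, truth = synthetic.gen_disk_image(**kwargs)
        write_image(outdir / "disks.tif", img.astype(np.float32))
        truth.truth_records.to_csv(outdir / "disk_truth.csv", index=False)
    elif gen == "gen_synapse_volume":
        a, b, truth = synthetic.gen_synapse_volume(**kwargs)
        voxel = [truth.params["voxel_z_um"], truth.params["voxel_y_um"],
                 truth.params["voxel_x_um"]]
        write_image(outdir / "channel_post.tif", a.astype(np.float32),
                    {"voxel_size_um": voxel})
        write_image(outdir / "channel_pre.tif", b.astype(np.float32),
                    {"voxel_size_um": voxel})
        truth.truth_records.to_csv(outdir / "synapse_truth.csv", index=False)
    elif gen == "gen_profile":
        profile, truth = synthetic.gen_profile(**kwargs)
        pd.DataFrame({"position": profile.positions,
                      "intensity": profile.intensities}).to_csv(
            outdir / "profile.csv", index=False)
        truth.truth_records.to_csv(outdir / "profile_truth.csv", index=False)
    else:
        raise DomainError(f"unknown generator {gen!r}")
    (outdir / "generator_params.json").write_text(
        json.dumps({"generator_name": truth.generator_name,
                    "seed": truth.seed, "params": truth.params},
                   indent=2, sort_keys=True, default=float))
    return {"truth": truth.truth_records}, {
        "simulate_summary": {"generator": gen, "seed": cfg.seed,
                             "n_truth_records": int(len(truth.truth_records))}}


_RUNNERS = {
    "gel": _stage_gel,
    "curves": _stage_curves,
    "distort": _stage_distort,
    "rings": _stage_rings,
    "profile": _stage_profile,
    "particles": _stage_particles,
    "synapses": _stage_synapses,
    "simulate": _stage_simulate,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute one stage end to end; returns the manifest path."""
    if not logging.getLogger().handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                            format="%(levelname)s %(name)s: %(message)s")
    log.info("stage=%s seed=%d outdir=%s", config.stage, config.seed, config.outdir)
    tables, summaries = _RUNNERS[config.stage](config)
    manifest = write_results(tables, summaries, config.outdir, config=config)
    log.info("stage=%s wrote %s", config.stage, manifest)
    return manifest
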
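"""End-to-end study runners with config, logging and manifest outputs.

``run_range_study`` chains material → stopping power → Monte Carlo →
synthetic photograph → image analysis → range comparison for a list of
beam energies, reproducing the three-way CSDA / MC / image range table.
``run_tomo_study`` chains phantom → rotation frames → sinogram → filtered
back-projection at 180° and 360° coverage.  Every run writes a JSON
manifest with the package version, seeds, parameters and SHA-256 checksums
of the artifacts, so a rerun with the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import pathlib

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colorimetry import dose_map_from_image
from .materials import MaterialComposition, abls, material_from_yaml
from .ranges import pixel_calibration, practical_range, refraction_correct
from .stopping import build_table, csda_range, specific_to_linear_range
from .synthetic import CameraModel, RotPhantomSpec, electron_camera, render_rotation_frames
from .synthetic import render_fluorescence_image
from .tomography import (
    Sinogram,
    attenuation_sinogram,
    inverse_radon_fbp,
    phantom_slice_truth,
    sinogram_from_frames,
)
from .transport import BeamSpec, GeometrySpec, pdd_from_dose_grid, simulate_electron_beam

__all__ = ["RunConfig", "run_range_study", "run_tomo_study", "ConfigError"]


class ConfigError(ValueError):
    """The run configuration is malformed or references missing files."""


class RunConfig(dict):
    """A validated study configuration (YAML-backed dictionary)."""

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = pathlib.Path(path)
        if not path.exists():
            raise ConfigError(f"config file {path} does not exist")
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls(doc)


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _material_from_config(config) -> MaterialComposition:
    mat = config.get("material", "abls")
    if mat == "abls":
        return abls()
    p = pathlib.Path(mat)
    if not p.exists():
        raise ConfigError(f"material file {mat} not found")
    return material_from_yaml(p)


def run_range_study(config: RunConfig | dict, out_dir) -> pd.DataFrame:
    """CSDA vs MC-projected vs image-measured ranges for each beam energy.

    Returns the comparison table and writes, per energy: the PDD curves,
    the rendered photograph, a ``ranges.csv`` table and ``manifest.json``.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comp = _material_from_config(config)
    energies = list(config.get("energies", [6.0, 9.0, 12.0]))
    n_hist = int(config.get("histories", 100_000))
    seed = int(config.get("seed", 1))
    field = float(config.get("field_width", 6.0))
    v_cut = float(config.get("v_cut", 0.3))
    cell = float(config.get("cell_size", 0.05))
    depth_scale = config.get("refraction_depth_scale")

    geom = GeometrySpec(cell_size=cell, material=comp)
    table = build_table(comp)
    rows = []
    artifacts = []
    for i, energy in enumerate(energies):
        beam = BeamSpec("electron", float(energy), field, n_hist, seed=seed + i)
        grid = simulate_electron_beam(beam, geom, table=table)
        mc_pdd = pdd_from_dose_grid(grid)
        mc_res = practical_range(mc_pdd)

        cam = electron_camera(seed=seed + 100 + i)
        img = render_fluorescence_image(grid, cam)
        calib = pixel_calibration(img.pixels.shape[0], geom.depth_extent)
        dose_map = dose_map_from_image(img, v_cut=v_cut, calibration=calib)
        img_pdd = pdd_from_dose_grid(dose_map)
        if depth_scale is not None:
            img_pdd = refraction_correct(img_pdd, depth_scale=float(depth_scale))
        img_res = practical_range(img_pdd)

        r_csda = csda_range(float(energy), table)
        rows.append(
            {
                "energy_MeV": energy,
                "csda_gcm2": r_csda,
                "csda_cm": specific_to_linear_range(r_csda, comp.density),
                "mc_rp_cm": mc_res.r_p,
                "image_rp_cm": img_res.r_p,
                "image_rp_unc_cm": img_res.uncertainty,
                "z_max_cm": mc_res.z_max,
            }
        )
        tag = f"{energy:g}MeV"
        mc_pdd.to_csv(out / f"pdd_mc_{tag}.csv")
        img_pdd.to_csv(out / f"pdd_image_{tag}.csv")
        img.to_file(out / f"fluorescence_{tag}.png")
        artifacts += [f"pdd_mc_{tag}.csv", f"pdd_image_{tag}.csv", f"fluorescence_{tag}.png"]

    report = pd.DataFrame(rows)
    report.to_csv(out / "ranges.csv", index=False)
    artifacts.append("ranges.csv")
    _write_manifest(out, config, seed, artifacts)
    return report


def run_tomo_study(config: RunConfig | dict, out_dir) -> dict:
    """Rotation-rig study: sinogram plus 180° and 360° reconstructions."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 1))
    spec = RotPhantomSpec(
        frames_per_rev=int(config.get("frames_per_rev", 180)),
        n_frames=int(config.get("n_frames", 180)),
        noise_sigma=float(config.get("noise_sigma", 0.004)),
        refraction_amp=float(config.get("refraction_amp", 0.0)),
        seed=seed,
    )
    stack = render_rotation_frames(spec)
    sino = attenuation_sinogram(sinogram_from_frames(stack), i0=spec.i0)
    truth = phantom_slice_truth(spec.phantom)

    n = truth.shape[0]
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    mask = np.hypot(xx - c, yy - c) <= spec.phantom.vial_radius

    results = {}
    for label, s in {
        "360": sino,
        "180": Sinogram(sino.intensities[sino.angles < 180.0], sino.angles[sino.angles < 180.0]),
    }.items():
        rec = inverse_radon_fbp(s, filter_name=config.get("filter", "ramp"))
        resid = float(
            np.sqrt(np.mean((rec.image[mask] - truth[mask]) ** 2))
            / np.sqrt(np.mean(truth[mask] ** 2))
        )
        np.savez_compressed(out / f"slice_{label}.npz", image=rec.image)
        results[label] = {"residual": resid, "n_angles": int(s.angles.size)}

    np.savez_compressed(out / "sinogram.npz", intensities=sino.intensities, angles=sino.angles)
    with open(out / "tomo_report.json", "w") as fh:
        json.dump(results, fh, indent=2)
    _write_manifest(
        out, config, seed, ["sinogram.npz", "slice_360.npz", "slice_180.npz", "tomo_report.json"]
    )
    return results


def _write_manifest(out: pathlib.Path, config, seed: int, artifacts: list[str]) -> None:
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": dict(config),
        "checksums": {name: _sha256(out / name) for name in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
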
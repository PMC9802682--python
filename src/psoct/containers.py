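"""HDF5 containers for phantoms, geometries, tomograms and polarimetry maps,
plus TIFF/PNG image export.

Array datasets round-trip bit-exactly; dataclass configuration is stored as a
YAML attribute next to the arrays so a container is self-describing and can
regenerate its simulation.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import h5py
import numpy as np
import tifffile
import yaml

from .measurement import (
    CatheterModel,
    MeasuredTomogram,
    MeasurementConfig,
    SheathModel,
)
from .phantoms import Phantom
from .reconstruction import LocalPolarimetryMap
from .scanning import GroundTruthProfile, ScanGeometry


def _write_meta(group: h5py.Group, meta: dict):
    for key, value in meta.items():
        if isinstance(value, np.ndarray):
            group.create_dataset(key, data=value)
        elif isinstance(value, (bool, int, float, str, np.generic)):
            group.attrs[key] = value
        # anything else (nested objects) is regenerable and not persisted


def _read_meta(group: h5py.Group) -> dict:
    meta = {k: v for k, v in group.attrs.items()}
    for k, v in group.items():
        meta[k] = v[()]
    return meta


def save_phantom(path, phantom: Phantom):
    with h5py.File(path, "w") as f:
        f.attrs["psoct_type"] = "phantom"
        f.create_dataset("voxel_pitch", data=phantom.voxel_pitch)
        for name in ("dn", "theta", "reflectivity", "label"):
            f.create_dataset(name, data=getattr(phantom, name))
        _write_meta(f.create_group("meta"), {k: v for k, v in phantom.meta.items() if not isinstance(v, (list, dict))})


def load_phantom(path) -> Phantom:
    with h5py.File(path, "r") as f:
        return Phantom(
            voxel_pitch=f["voxel_pitch"][()],
            dn=f["dn"][()],
            theta=f["theta"][()],
            reflectivity=f["reflectivity"][()],
            label=f["label"][()],
            meta=_read_meta(f["meta"]),
        )


def _save_geometry_group(g: h5py.Group, geom: ScanGeometry):
    g.attrs["mode"] = geom.mode
    g.attrs["n_alines"] = geom.n_alines
    g.attrs["depth_pixels"] = geom.depth_pixels
    g.attrs["delta_z"] = geom.delta_z
    for name in ("origins", "directions", "e1", "e2"):
        g.create_dataset(name, data=getattr(geom, name))
    _write_meta(g.create_group("meta"), geom.meta)


def _load_geometry_group(g: h5py.Group) -> ScanGeometry:
    return ScanGeometry(
        mode=g.attrs["mode"],
        n_alines=int(g.attrs["n_alines"]),
        depth_pixels=int(g.attrs["depth_pixels"]),
        delta_z=float(g.attrs["delta_z"]),
        origins=g["origins"][()],
        directions=g["directions"][()],
        e1=g["e1"][()],
        e2=g["e2"][()],
        meta=_read_meta(g["meta"]),
    )


def save_geometry(path, geom: ScanGeometry):
    with h5py.File(path, "w") as f:
        f.attrs["psoct_type"] = "geometry"
        _save_geometry_group(f.create_group("geometry"), geom)


def load_geometry(path) -> ScanGeometry:
    with h5py.File(path, "r") as f:
        return _load_geometry_group(f["geometry"])


def _config_to_yaml(config: MeasurementConfig) -> str:
    d = dataclasses.asdict(config)
    for key in ("input_states", "a_mats", "b_mats"):
        d.pop(key, None)
    for key in ("catheter", "sheath"):
        if d[key] is not None:
            d[key] = dict(d[key])
    return yaml.safe_dump(d)


def _config_from_yaml(text: str) -> MeasurementConfig:
    d = yaml.safe_load(text)
    if d.get("catheter") is not None:
        d["catheter"] = CatheterModel(**d["catheter"])
    if d.get("sheath") is not None:
        d["sheath"] = SheathModel(**d["sheath"])
    return MeasurementConfig(**d)


def save_tomogram(path, tomo: MeasuredTomogram):
    with h5py.File(path, "w") as f:
        f.attrs["psoct_type"] = "tomogram"
        f.attrs["lambda_c_nm"] = tomo.config.lambda_c
        f.attrs["delta_z_um"] = tomo.geometry.delta_z
        f.attrs["config_yaml"] = _config_to_yaml(tomo.config)
        f.create_dataset("stokes", data=tomo.stokes)
        f.create_dataset("intensity_db", data=tomo.intensity_db)
        if tomo.ball_lens is not None:
            f.create_dataset("ball_lens", data=tomo.ball_lens)
        f.create_dataset("input_states_jones", data=tomo.config.input_states)
        if tomo.config.a_mats is not None:
            f.create_dataset("a_mats", data=tomo.config.a_mats)
        if tomo.config.b_mats is not None:
            f.create_dataset("b_mats", data=tomo.config.b_mats)
        _save_geometry_group(f.create_group("geometry"), tomo.geometry)
        _write_meta(f.create_group("meta"), tomo.meta)
        if tomo.truth is not None:
            g = f.create_group("truth")
            for name in ("dn", "theta_local", "reflectivity", "label"):
                g.create_dataset(name, data=getattr(tomo.truth, name))


def load_tomogram(path) -> MeasuredTomogram:
    with h5py.File(path, "r") as f:
        config = _config_from_yaml(f.attrs["config_yaml"])
        config.input_states = f["input_states_jones"][()]
        if "a_mats" in f:
            config.a_mats = f["a_mats"][()]
        if "b_mats" in f:
            config.b_mats = f["b_mats"][()]
        truth = None
        if "truth" in f:
            g = f["truth"]
            truth = GroundTruthProfile(
                dn=g["dn"][()],
                theta_local=g["theta_local"][()],
                reflectivity=g["reflectivity"][()],
                label=g["label"][()],
            )
        return MeasuredTomogram(
            stokes=f["stokes"][()],
            intensity_db=f["intensity_db"][()],
            ball_lens=f["ball_lens"][()] if "ball_lens" in f else None,
            geometry=_load_geometry_group(f["geometry"]),
            config=config,
            truth=truth,
            meta=_read_meta(f["meta"]),
        )


def save_map(path, pmap: LocalPolarimetryMap, geometry: Optional[ScanGeometry] = None):
    with h5py.File(path, "w") as f:
        f.attrs["psoct_type"] = "polarimetry_map"
        for name in ("dn", "theta", "dop", "mask"):
            f.create_dataset(name, data=getattr(pmap, name))
        _write_meta(f.create_group("meta"), pmap.meta)
        if geometry is not None:
            _save_geometry_group(f.create_group("geometry"), geometry)


def load_map(path) -> LocalPolarimetryMap:
    with h5py.File(path, "r") as f:
        return LocalPolarimetryMap(
            dn=f["dn"][()],
            theta=f["theta"][()],
            dop=f["dop"][()],
            mask=f["mask"][()].astype(bool),
            meta=_read_meta(f["meta"]),
        )


def write_tiff(path, image: np.ndarray):
    """32-bit float single-contrast plane."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def write_png(path, rgb: np.ndarray):
    """8-bit composite image."""
    import imageio.v3 as iio

    arr = np.clip(np.nan_to_num(rgb), 0.0, 1.0)
    iio.imwrite(path, (arr * 255).astype(np.uint8))
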
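"""HDF5 persistence for sinograms, thickness maps and volumes."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .config import ScannerGeometry, SubsamplingScheme
from .projection import Sinogram
from .raytrace import ThicknessMaps
from .recon import Volume

__all__ = ["save_sinogram", "load_sinogram", "save_thickness_maps",
           "load_thickness_maps", "save_volume", "load_volume"]


def _geometry_attrs(g: ScannerGeometry) -> str:
    return json.dumps({f: getattr(g, f)
                       for f in ScannerGeometry.__dataclass_fields__})


def _geometry_from_attrs(s: str) -> ScannerGeometry:
    return ScannerGeometry(**json.loads(s))


def save_sinogram(sino: Sinogram, path: str | Path,
                  provenance: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("sinogram", data=sino.data)
        d.attrs["axes"] = "view,row,channel"
        f.create_dataset("view_angles_rad", data=sino.view_angles_rad)
        f.attrs["geometry"] = _geometry_attrs(sino.geometry)
        f.attrs["protocol_id"] = sino.protocol_id or ""
        f.attrs["noisy"] = bool(sino.noisy)
        f.attrs["meta"] = json.dumps(sino.meta)
        if provenance is not None:
            f.attrs["provenance"] = json.dumps(provenance)


def load_sinogram(path: str | Path) -> Sinogram:
    with h5py.File(path, "r") as f:
        return Sinogram(f["sinogram"][()],
                        _geometry_from_attrs(f.attrs["geometry"]),
                        f["view_angles_rad"][()],
                        f.attrs["protocol_id"] or None,
                        bool(f.attrs["noisy"]),
                        json.loads(f.attrs.get("meta", "{}")))


def save_thickness_maps(maps: ThicknessMaps, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("thickness_mm", data=maps.data,
                             compression="gzip")
        d.attrs["axes"] = "material,focal,angular,view,row_sub,channel_sub"
        f.attrs["materials"] = json.dumps(list(maps.materials))
        f.attrs["scheme"] = json.dumps(
            {"L": maps.scheme.L, "K": maps.scheme.K, "M": maps.scheme.M})
        f.create_dataset("view_angles_rad", data=maps.view_angles_rad)
        f.attrs["geometry"] = _geometry_attrs(maps.geometry)


def load_thickness_maps(path: str | Path) -> ThicknessMaps:
    with h5py.File(path, "r") as f:
        scheme = SubsamplingScheme(**json.loads(f.attrs["scheme"]))
        return ThicknessMaps(f["thickness_mm"][()],
                             tuple(json.loads(f.attrs["materials"])),
                             scheme, f["view_angles_rad"][()],
                             _geometry_from_attrs(f.attrs["geometry"]))


def save_volume(vol: Volume, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("volume", data=vol.data)
        d.attrs["axes"] = "slice,y,x"
        f.attrs["voxel_size_mm"] = vol.voxel_size_mm
        f.attrs["center_mm"] = vol.center_mm
        f.attrs["units"] = vol.units
        f.attrs["meta"] = json.dumps(vol.meta)


def load_volume(path: str | Path) -> Volume:
    with h5py.File(path, "r") as f:
        return Volume(f["volume"][()], tuple(f.attrs["voxel_size_mm"]),
                      tuple(f.attrs["center_mm"]), str(f.attrs["units"]),
                      json.loads(f.attrs.get("meta", "{}")))
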
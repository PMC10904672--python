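"""Scanner model: geometry, focal spots, protocols, subsampling.

All machine-specific values (distances, pitches, focal-spot sizes) live in the
configuration file; nothing geometric is hard-coded elsewhere in the package.
The shipped default configuration uses documented desk-scale placeholder
values, not any vendor's confidential geometry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ScannerGeometry", "FocalSpot", "SubsamplingScheme", "AcquisitionProtocol",
    "ScannerModel", "ConfigError", "load_scanner_config", "save_scanner_config",
    "sample_budget", "default_scanner",
]


class ConfigError(ValueError):
    """Invalid scanner configuration; the message names the offending field."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class ScannerGeometry:
    """Axial scan geometry with an equiangular curved detector.

    All detector pixels in a row are equidistant from the source
    (``source_to_detector_mm``); rows are stacked flat with equal spacing
    ``row_pitch_mm`` along the rotation axis.
    """

    source_to_isocenter_mm: float
    source_to_detector_mm: float
    n_channels: int
    n_rows: int
    channel_angular_pitch_rad: float
    row_pitch_mm: float
    views_per_rotation: int
    rotation_time_s: float
    collimation_mm: float

    def __post_init__(self):
        for name in ("source_to_isocenter_mm", "source_to_detector_mm",
                     "channel_angular_pitch_rad", "row_pitch_mm",
                     "rotation_time_s", "collimation_mm"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        for name in ("n_channels", "n_rows", "views_per_rotation"):
            v = getattr(self, name)
            _require(isinstance(v, (int, np.integer)) and v > 0,
                     f"{name} must be a positive integer")
        _require(self.source_to_detector_mm > self.source_to_isocenter_mm,
                 "source_to_detector_mm must exceed source_to_isocenter_mm")

    @property
    def magnification(self) -> float:
        return self.source_to_detector_mm / self.source_to_isocenter_mm

    @property
    def view_angular_span_rad(self) -> float:
        """Gantry rotation per view window: 2*pi / views_per_rotation."""
        return 2.0 * math.pi / self.views_per_rotation

    @property
    def fan_angle_rad(self) -> float:
        return self.n_channels * self.channel_angular_pitch_rad

    @property
    def channel_pitch_mm(self) -> float:
        """In-row detector pixel pitch at the detector surface."""
        return self.source_to_detector_mm * self.channel_angular_pitch_rad

    def channel_angles_rad(self) -> np.ndarray:
        """Signed fan angle of each channel center."""
        c = np.arange(self.n_channels) - (self.n_channels - 1) / 2.0
        return c * self.channel_angular_pitch_rad

    def row_offsets_mm(self) -> np.ndarray:
        """Axial offset of each row center at the detector surface."""
        r = np.arange(self.n_rows) - (self.n_rows - 1) / 2.0
        return r * self.row_pitch_mm

    def view_angles_rad(self) -> np.ndarray:
        return np.arange(self.views_per_rotation) * self.view_angular_span_rad

    @property
    def fov_radius_mm(self) -> float:
        return self.source_to_isocenter_mm * math.sin(self.fan_angle_rad / 2.0)


@dataclass(frozen=True)
class FocalSpot:
    """Finite focal spot, sampled on a square grid (width in-plane, length axial)."""

    width_mm: float
    length_mm: float
    label: str

    def __post_init__(self):
        _require(self.width_mm > 0 and self.length_mm > 0,
                 "focal spot dimensions must be positive")
        _require(self.label in ("large", "small"),
                 f"focal spot label must be 'large' or 'small', got {self.label!r}")


@dataclass(frozen=True)
class SubsamplingScheme:
    """Subsampling factors: L x L focal spot, K angular, M x M detector."""

    L: int = 1
    K: int = 1
    M: int = 1

    def __post_init__(self):
        for name in ("L", "K", "M"):
            v = getattr(self, name)
            _require(isinstance(v, (int, np.integer)) and v >= 1,
                     f"subsampling factor {name} must be an integer >= 1")

    @property
    def samples_per_ray(self) -> int:
        return self.L**2 * self.K * self.M**2


@dataclass(frozen=True)
class AcquisitionProtocol:
    tube_voltage_kv: float
    tube_current_ma: float
    exposure_time_s: float
    bowtie_id: str
    focal_spot_label: str = "large"

    def __post_init__(self):
        _require(self.tube_current_ma > 0, "tube_current_ma must be positive")
        _require(self.exposure_time_s > 0, "exposure_time_s must be positive")

    @property
    def mas(self) -> float:
        return self.tube_current_ma * self.exposure_time_s


@dataclass
class ScannerModel:
    """Validated scanner description shared by every pipeline stage."""

    geometry: ScannerGeometry
    focal_spots: dict[str, FocalSpot]
    protocols: dict[str, AcquisitionProtocol]
    subsampling: SubsamplingScheme
    allowed_voltages_kv: tuple[float, ...] = (80.0, 100.0, 120.0, 135.0)
    bowtie_ids: tuple[str, ...] = ("body",)

    def __post_init__(self):
        for pid, p in self.protocols.items():
            _require(p.tube_voltage_kv in self.allowed_voltages_kv,
                     f"protocol {pid!r}: tube_voltage_kv "
                     f"{p.tube_voltage_kv} not in configured set")
            _require(p.bowtie_id in self.bowtie_ids,
                     f"protocol {pid!r}: unknown bowtie_id {p.bowtie_id!r}")
            _require(p.focal_spot_label in self.focal_spots,
                     f"protocol {pid!r}: unknown focal_spot_label "
                     f"{p.focal_spot_label!r}")

    def protocol(self, pid: str) -> AcquisitionProtocol:
        if pid not in self.protocols:
            raise ConfigError(f"unknown protocol {pid!r}")
        return self.protocols[pid]


def sample_budget(full: SubsamplingScheme, simplified: SubsamplingScheme) -> float:
    """Time/memory reduction factor of ``simplified`` relative to ``full``.

    The per-ray work scales with the number of subsamples L^2 * K * M^2, so
    the reduction factor is the ratio of the two sample counts.
    """
    return full.samples_per_ray / simplified.samples_per_ray


# ---------------------------------------------------------------------------
# serialization

_GEOM_INT_FIELDS = {"n_channels", "n_rows", "views_per_rotation"}


def _to_dict(model: ScannerModel) -> dict:
    return {
        "geometry": asdict(model.geometry),
        "focal_spots": {k: asdict(v) for k, v in model.focal_spots.items()},
        "protocols": {k: asdict(v) for k, v in model.protocols.items()},
        "subsampling": asdict(model.subsampling),
        "allowed_voltages_kv": list(model.allowed_voltages_kv),
        "bowtie_ids": list(model.bowtie_ids),
    }


def _build(raw: dict) -> ScannerModel:
    try:
        g = dict(raw["geometry"])
    except KeyError:
        raise ConfigError("missing field 'geometry'") from None
    for f in _GEOM_INT_FIELDS:
        if f in g:
            g[f] = int(g[f])
    missing = [f for f in ScannerGeometry.__dataclass_fields__ if f not in g]
    _require(not missing, f"geometry missing fields: {missing}")
    geometry = ScannerGeometry(**g)
    spots = {k: FocalSpot(**v) for k, v in raw.get("focal_spots", {}).items()}
    _require(bool(spots), "missing field 'focal_spots'")
    protos = {k: AcquisitionProtocol(**v)
              for k, v in raw.get("protocols", {}).items()}
    sub = SubsamplingScheme(**{k: int(v) for k, v in
                               raw.get("subsampling", {}).items()})
    return ScannerModel(
        geometry=geometry, focal_spots=spots, protocols=protos,
        subsampling=sub,
        allowed_voltages_kv=tuple(raw.get("allowed_voltages_kv",
                                          (80.0, 100.0, 120.0, 135.0))),
        bowtie_ids=tuple(raw.get("bowtie_ids", ("body",))),
    )


def load_scanner_config(path: str | Path) -> ScannerModel:
    """Load and validate a scanner model from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        return _build(raw)
    except TypeError as exc:  # unexpected/missing dataclass kwargs
        raise ConfigError(str(exc)) from exc


def save_scanner_config(model: ScannerModel, path: str | Path) -> None:
    path = Path(path)
    d = _to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def default_scanner() -> ScannerModel:
    """The shipped desk-scale placeholder scanner."""
    return load_scanner_config(Path(__file__).parent / "data" /
                               "default_scanner.yaml")
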
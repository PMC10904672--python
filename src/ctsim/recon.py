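"""Fan-beam filtered backprojection and linear HU calibration.

The clinical reconstructor this package emulates is proprietary, so the
reconstruction here is standard plumbing: per-row equiangular fan-beam FBP
(Kak–Slaney weighting and kernel) with an optional FDK-style cone weight.
Absolute resolution/noise numbers of a clinical kernel are therefore not
reproduced; the package's validation loop is self-consistency between what
is simulated in and what the metrology measures out.

CT numbers follow HU = 1000 * (mu - mu_water_eff) / mu_water_eff, with the
effective water attenuation computed from the detector-weighted spectrum,
and a two-step linear calibration (offset so water reads zero, then a scalar
slope against theoretical values) applied afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import ScannerGeometry
from .materials import MaterialDB, QECurve, Spectrum
from .projection import Sinogram

__all__ = ["Volume", "HUCalibration", "fbp_reconstruct",
           "fit_hu_calibration", "apply_hu_calibration",
           "effective_water_mu", "log_normalize", "ReconError"]


class ReconError(RuntimeError):
    pass


@dataclass
class Volume:
    """Reconstructed volume, axes ``(slice, y, x)``.

    ``voxel_size_mm`` is ``(dz, dy, dx)``; ``center_mm`` the (x, y) of the
    FOV center relative to the isocenter; ``units`` either ``'HU'`` or
    ``'mu_per_mm'``.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    center_mm: tuple[float, float] = (0.0, 0.0)
    units: str = "HU"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("volume must be 3-D (slice, y, x)")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite values in volume")


@dataclass(frozen=True)
class HUCalibration:
    """Two-step linear CT-number correction: HU_cal = a * (HU + b_water)."""

    a: float
    b_water: float
    tube_voltage_kv: float | None = None

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError("calibration slope must be positive")


def effective_water_mu(spectrum: Spectrum, qe: QECurve,
                       db: MaterialDB) -> float:
    """Detector-weighted effective linear attenuation of water (1/mm)."""
    w = spectrum.grid.energies_kev * spectrum.photons_per_mas * qe.qe
    return float(np.sum(w * db.mu("water")) / np.sum(w))


def log_normalize(sino: Sinogram, i0: np.ndarray) -> np.ndarray:
    """Line integrals p = ln(I0 / I); fails naming indices where I <= 0."""
    data = sino.data
    if i0.shape != data.shape[1:]:
        raise ValueError(f"I0 shape {i0.shape} does not match detector "
                         f"{data.shape[1:]}")
    bad = np.argwhere(data <= 0)
    if bad.size:
        raise ReconError(
            f"log-normalization undefined: I <= 0 at (view, row, channel) "
            f"indices {bad[:5].tolist()}{'...' if len(bad) > 5 else ''}")
    return np.log(i0[None] / data)


def _equiangular_kernel(n: int, alpha: float) -> np.ndarray:
    """Discrete equiangular ramp kernel g[-n+1 .. n-1] (Kak–Slaney)."""
    idx = np.arange(-n + 1, n)
    g = np.zeros(idx.size)
    g[idx == 0] = 1.0 / (8.0 * alpha**2)
    odd = idx % 2 != 0
    g[odd] = -0.5 / (np.pi * np.sin(idx[odd] * alpha)) ** 2
    return g


def _filter_projections(p: np.ndarray, gamma: np.ndarray, alpha: float,
                        kernel_id: str) -> np.ndarray:
    """Weight by cos(gamma), convolve with the equiangular ramp kernel."""
    n = gamma.size
    pw = p * np.cos(gamma)[None]
    g = _equiangular_kernel(n, alpha)
    nfft = int(2 ** np.ceil(np.log2(2 * n + g.size)))
    gf = np.fft.rfft(g, nfft)
    if kernel_id == "hann":
        # apodize the kernel's spectrum with a Hann window over the band
        f = np.fft.rfftfreq(nfft)
        gf = gf * 0.5 * (1.0 + np.cos(np.pi * np.clip(f / 0.5, 0, 1)))
    elif kernel_id != "ramp":
        raise ValueError(f"unknown kernel {kernel_id!r}")
    q = np.fft.irfft(np.fft.rfft(pw, nfft, axis=-1) * gf[None], nfft,
                     axis=-1)[:, n - 1:2 * n - 1]
    return q * alpha


def fbp_reconstruct(sino: Sinogram, geometry: ScannerGeometry,
                    i0: np.ndarray, fov_mm: float, grid_size: int,
                    kernel: str = "ramp",
                    center_mm: tuple[float, float] = (0.0, 0.0),
                    mu_water_eff: float | None = None,
                    rows: slice | None = None,
                    fdk_cone_weighting: bool = False) -> Volume:
    """Per-row equiangular fan-beam FBP over a full rotation.

    Each detector row is reconstructed as an independent 2-D fan-beam slice
    (adequate for in-plane metrology at small cone angles); with
    ``fdk_cone_weighting`` the projections are additionally weighted by the
    FDK cosine of the cone angle.  Output units are 1/mm, or HU when
    ``mu_water_eff`` is given.
    """
    p = log_normalize(sino, i0)                  # (V, rows, channels)
    views = np.asarray(sino.view_angles_rad, dtype=float)
    gamma = geometry.channel_angles_rad()
    alpha = geometry.channel_angular_pitch_rad
    r_src = geometry.source_to_isocenter_mm
    if rows is not None:
        p = p[:, rows, :]
        row_z = geometry.row_offsets_mm()[rows]
    else:
        row_z = geometry.row_offsets_mm()
    nrows = p.shape[1]
    if fdk_cone_weighting:
        d = geometry.source_to_detector_mm
        p = p * (d / np.hypot(d, row_z))[None, :, None]

    dpx = fov_mm / grid_size
    ax = center_mm[0] + (np.arange(grid_size) - (grid_size - 1) / 2.0) * dpx
    ay = center_mm[1] + (np.arange(grid_size) - (grid_size - 1) / 2.0) * dpx
    X, Y = np.meshgrid(ax, ay)
    out = np.zeros((nrows, grid_size, grid_size))
    dbeta = (2.0 * np.pi / views.size if views.size > 1
             else 2.0 * np.pi)
    for v, beta in enumerate(views):
        q = _filter_projections(p[v] * r_src, gamma, alpha, kernel)
        sx, sy = r_src * np.cos(beta), r_src * np.sin(beta)
        wx, wy = X - sx, Y - sy
        l2 = wx * wx + wy * wy
        d0x, d0y = -np.cos(beta), -np.sin(beta)
        gp = np.arctan2(d0x * wy - d0y * wx, d0x * wx + d0y * wy)
        for r in range(nrows):
            out[r] += np.interp(gp, gamma, q[r], left=0.0, right=0.0) / l2
    out *= dbeta
    units = "mu_per_mm"
    if mu_water_eff is not None:
        out = 1000.0 * (out - mu_water_eff) / mu_water_eff
        units = "HU"
    dz = geometry.row_pitch_mm / geometry.magnification
    return Volume(out, (dz, dpx, dpx), center_mm, units,
                  meta={"protocol_id": sino.protocol_id, "kernel": kernel,
                        "tube_voltage_kv": sino.meta.get("tube_voltage_kv")})


def fit_hu_calibration(measured: Mapping[str, float],
                       theoretical: Mapping[str, float],
                       water_key: str = "water",
                       tube_voltage_kv: float | None = None) -> HUCalibration:
    """Two-step linear CT-number calibration.

    First the water offset ``b_water`` is chosen so the measured water value
    maps to its theoretical value of zero; then a scalar slope ``a``
    minimizes the squared error between ``a * (measured + b_water)`` and the
    theoretical values of all inserts.
    """
    if water_key not in measured:
        raise ValueError(f"water key {water_key!r} missing from measurements")
    b = -float(measured[water_key])
    keys = [k for k in measured if k in theoretical]
    theo = np.array([theoretical[k] for k in keys], dtype=float)
    if np.unique(theo).size < 2:
        raise ValueError("slope unidentifiable: need >= 2 distinct "
                         "theoretical CT numbers")
    x = np.array([measured[k] for k in keys], dtype=float) + b
    denom = float(x @ x)
    if denom == 0.0:
        raise ValueError("slope unidentifiable: calibration inputs collapse "
                         "to water only")
    return HUCalibration(float(x @ theo / denom), b, tube_voltage_kv)


def apply_hu_calibration(vol: Volume, cal: HUCalibration) -> Volume:
    """Apply the fitted affine correction to a reconstructed volume."""
    v_kv = vol.meta.get("tube_voltage_kv")
    if (cal.tube_voltage_kv is not None and v_kv is not None
            and float(v_kv) != float(cal.tube_voltage_kv)):
        raise ValueError(
            f"calibration voltage {cal.tube_voltage_kv} kV does not match "
            f"volume voltage {v_kv} kV")
    return Volume(cal.a * (vol.data + cal.b_water), vol.voxel_size_mm,
                  vol.center_mm, vol.units,
                  meta={**vol.meta, "hu_calibrated": True})
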
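"""Polychromatic Beer–Lambert projection and subsample binning.

Converts per-material thickness maps into detector signal in digital units.
For each subsample ray the recorded signal is the energy-integrated,
QE-weighted transmitted fluence::

    I = gain * mAs * sum_e E_e * N_e * QE_e
        * exp(-sum_m mu_m(E_e) * T_m - mu_bowtie(E_e) * t_bowtie(channel))

The subsampled sinogram is then averaged over focal-spot, angular and
detector subsamples (after any MTF application — see
:mod:`ctsim.corruption`) to give the sinogram on the physical detector grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ScannerGeometry, SubsamplingScheme
from .materials import (BowtieFilter, DUGain, MaterialDB, MaterialError,
                        QECurve, Spectrum)
from .raytrace import ThicknessMaps, block_average

__all__ = ["SubsampledSinogram", "Sinogram", "integrate_energy",
           "bin_subsamples", "simulate_air_reference"]


@dataclass
class SubsampledSinogram:
    """Detector signal on the full subsample grid, in digital units.

    ``data`` axes: ``(focal_subsample, angular_subsample, view,
    row_subsample, channel_subsample)``.
    """

    data: np.ndarray
    scheme: SubsamplingScheme
    geometry: ScannerGeometry
    view_angles_rad: np.ndarray
    protocol_id: str | None = None

    def __post_init__(self):
        if self.data.ndim != 5:
            raise ValueError("subsampled sinogram must be 5-D")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite subsampled sinogram")

    @property
    def subsample_pitches_mm(self) -> tuple[float, float]:
        """(row, channel) pitch of the subsample grid at the detector."""
        g, m = self.geometry, self.scheme.M
        return g.row_pitch_mm / m, g.channel_pitch_mm / m

    @property
    def final_pitches_mm(self) -> tuple[float, float]:
        g = self.geometry
        return g.row_pitch_mm, g.channel_pitch_mm


@dataclass
class Sinogram:
    """Binned detector-unit projection stack, axes ``(view, row, channel)``."""

    data: np.ndarray
    geometry: ScannerGeometry
    view_angles_rad: np.ndarray
    protocol_id: str | None = None
    noisy: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("sinogram must be 3-D (view, row, channel)")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite sinogram")
        if not self.noisy and np.any(self.data < 0):
            raise ValueError("negative values in a noiseless sinogram")


def _bowtie_exponent(bowtie: BowtieFilter | None, db: MaterialDB,
                     n_channels: int, m: int) -> np.ndarray | None:
    """Per-energy, per-subsampled-channel bowtie attenuation exponent."""
    if bowtie is None:
        return None
    t = bowtie.thickness_mm
    if t.size != n_channels:
        raise ValueError(f"bowtie has {t.size} channels, geometry expects "
                         f"{n_channels}")
    t_sub = np.repeat(t, m)  # subsample rays inherit the parent channel value
    return db.mu(bowtie.material_id)[:, None] * t_sub[None, :]


def integrate_energy(maps: ThicknessMaps, spectrum: Spectrum, qe: QECurve,
                     db: MaterialDB, gain: DUGain | None = None,
                     bowtie: BowtieFilter | None = None,
                     mas: float = 1.0) -> SubsampledSinogram:
    """Energy-integrate thickness maps into a subsampled sinogram (DU)."""
    if np.any(maps.data < 0):
        raise ValueError("negative thickness in maps")
    mu = []
    for name in maps.materials:
        if name not in db:
            raise MaterialError(f"material {name!r} missing from database")
        mu.append(db.mu(name))
    mu = np.stack(mu)                        # (n_mat, n_e)
    e = spectrum.grid.energies_kev
    w = e * spectrum.photons_per_mas * qe.qe * mas
    if gain is not None:
        w = w * gain.gain
    bow = _bowtie_exponent(bowtie, db, maps.geometry.n_channels,
                           maps.scheme.M)

    t = maps.data                            # (n_mat, F, K, V, Y, X)
    shape = t.shape[1:]
    xs = shape[-1]
    n_mat = t.shape[0]
    active = np.nonzero(w)[0]
    # rays that never intersect the phantom see only the (bowtie-filtered)
    # unattenuated beam, which depends on the channel alone — evaluate the
    # energy sum once per channel and fill, then integrate only hit rays
    if bow is None:
        i0_ch = np.full(xs, w[active].sum())
    else:
        i0_ch = np.sum(w[active, None] * np.exp(-bow[active]), axis=0)
    out = np.broadcast_to(i0_ch, shape).astype(np.float64).copy()
    t2 = t.reshape(n_mat, -1)
    hit = np.nonzero(np.any(t2 > 0, axis=0))[0]
    if hit.size:
        t_hit = np.ascontiguousarray(t2[:, hit], dtype=np.float64)
        ch_hit = hit % xs
        acc = np.zeros(hit.size)
        for ei in active:
            tau = mu[:, ei] @ t_hit
            if bow is not None:
                tau = tau + bow[ei][ch_hit]
            acc += w[ei] * np.exp(-tau)
        out.reshape(-1)[hit] = acc
    return SubsampledSinogram(out, maps.scheme, maps.geometry,
                              maps.view_angles_rad)


def bin_subsamples(sub: SubsampledSinogram,
                   scheme: SubsamplingScheme | None = None) -> Sinogram:
    """Average the L^2 focal, K angular and M^2 detector subsamples.

    Plain mean with weight 1/(M^2 K L^2) per final detector pixel and view.
    """
    scheme = scheme or sub.scheme
    l2, k = scheme.L**2, scheme.K
    f, ka, v, ys, xs = sub.data.shape
    if f != l2 or ka != k:
        raise ValueError(f"subsampled sinogram axes {(f, ka)} inconsistent "
                         f"with scheme L={scheme.L}, K={scheme.K}")
    g = sub.geometry
    if ys != g.n_rows * scheme.M or xs != g.n_channels * scheme.M:
        raise ValueError("detector axes inconsistent with scheme M")
    binned = block_average(sub.data.mean(axis=(0, 1)), scheme.M)
    return Sinogram(binned, g, sub.view_angles_rad, sub.protocol_id)


def simulate_air_reference(geometry: ScannerGeometry, spectrum: Spectrum,
                           qe: QECurve, db: MaterialDB,
                           gain: DUGain | None = None,
                           bowtie: BowtieFilter | None = None,
                           mas: float = 1.0) -> np.ndarray:
    """Air-scan reference I0 per (row, channel): same protocol, empty bore.

    Used for log-normalization in reconstruction; includes the bowtie, so the
    normalization mirrors a physical air calibration.
    """
    e = spectrum.grid.energies_kev
    w = e * spectrum.photons_per_mas * qe.qe * mas
    if gain is not None:
        w = w * gain.gain
    if bowtie is None:
        i0 = np.full(geometry.n_channels, w.sum())
    else:
        t = bowtie.thickness_mm
        if t.size != geometry.n_channels:
            raise ValueError("bowtie length does not match n_channels")
        i0 = np.sum(w[:, None] * np.exp(-db.mu(bowtie.material_id)[:, None]
                                        * t[None, :]), axis=0)
    return np.broadcast_to(i0, (geometry.n_rows, geometry.n_channels)).copy()
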
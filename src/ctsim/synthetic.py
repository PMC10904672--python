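"""Synthetic system characterization and measurement fixtures.

Every input the simulator can ingest from bench measurements on a physical
scanner — tube spectrum, air-kerma readings under standard filtrations,
lateral bowtie kerma profiles, detector MTF samples, water-sinogram noise
stacks — can be generated here from known ground truth.  This both provides
the default characterization for the shipped placeholder scanner and gives
the test suite forward-model fixtures whose recovery can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ScannerModel
from .corruption import (MTFModel, MVModel, NoiseCharacterization,
                         SinogramNPS, radial_average)
from .materials import (BowtieFilter, DUGain, EnergyGrid, KermaMeasurement,
                        MaterialDB, QECurve, Spectrum, STANDARD_FILTRATIONS,
                        air_kerma, build_material_db, detector_qe,
                        kramers_spectrum)

__all__ = ["SystemCharacterization", "default_characterization",
           "reference_spectrum", "synthetic_kerma_measurements",
           "synthetic_bowtie", "synthetic_bowtie_kerma_profile",
           "synthetic_nps", "synthetic_detector_mtf", "synthetic_system_mtf",
           "default_material_db"]


@dataclass
class SystemCharacterization:
    """Everything protocol-dependent the pipeline needs beyond geometry."""

    db: MaterialDB
    spectra: dict[float, Spectrum]          # tube voltage -> spectrum
    qe: QECurve
    bowties: dict[str, BowtieFilter]
    du_gains: dict[str, DUGain]             # bowtie id -> gain
    detector_mtf: MTFModel
    system_mtf: MTFModel | None = None
    noise: NoiseCharacterization | None = None

    def spectrum(self, tube_voltage_kv: float) -> Spectrum:
        key = float(tube_voltage_kv)
        if key not in self.spectra:
            raise KeyError(f"no spectrum characterized for {key} kV")
        return self.spectra[key]


def default_material_db(e_max_kev: float = 135.0) -> MaterialDB:
    """Material database on the default grid up to ``e_max_kev``."""
    return build_material_db(EnergyGrid.default(e_max_kev))


def reference_spectrum(db: MaterialDB, tube_voltage_kv: float,
                       added_al_mm: float = 3.0,
                       photons_per_mas: float = 5.0e6) -> Spectrum:
    """Ground-truth tube spectrum: filtered bremsstrahlung, fixed fluence."""
    return kramers_spectrum(db.grid, tube_voltage_kv, added_al_mm, db,
                            photons_total=photons_per_mas)


def synthetic_kerma_measurements(spectrum: Spectrum, db: MaterialDB,
                                 ) -> list[KermaMeasurement]:
    """The four standard-filtration kerma readings for a known spectrum."""
    return [KermaMeasurement(f, air_kerma(spectrum, f, db))
            for f in STANDARD_FILTRATIONS]


def synthetic_bowtie(model: ScannerModel, material_id: str = "aluminum",
                     curvature_mm_inv: float = 4.0e-4) -> BowtieFilter:
    """Quadratic equivalent-thickness bowtie: t = curvature * lateral^2."""
    g = model.geometry
    lateral = g.source_to_isocenter_mm * np.sin(g.channel_angles_rad())
    return BowtieFilter(material_id, curvature_mm_inv * lateral**2)


def synthetic_bowtie_kerma_profile(spectrum: Spectrum, db: MaterialDB,
                                   bowtie_material: str,
                                   thickness_of_offset,
                                   offsets_mm: np.ndarray) -> np.ndarray:
    """Lateral air-kerma profile behind a known bowtie thickness law."""
    return np.array([air_kerma(spectrum,
                               [(bowtie_material, float(thickness_of_offset(x)))],
                               db)
                     for x in offsets_mm])


def synthetic_detector_mtf() -> MTFModel:
    """Plausible detector MTF for the placeholder scanner (cycles/mm at the
    detector): a broad and a narrow Lorentzian summing to one at DC."""
    return MTFModel(weights=(0.65, 0.35), corner_freqs=(0.55, 0.18))


def synthetic_system_mtf() -> MTFModel:
    """System MTF (edge at the isocenter): detector MTF plus focal-spot blur,
    hence lower corner frequencies than the detector-only curve."""
    return MTFModel(weights=(0.6, 0.4), corner_freqs=(0.4, 0.12))


def synthetic_nps(pitch_row_mm: float, pitch_channel_mm: float,
                  corner_per_mm: float = 0.25, roi: int = 64) -> SinogramNPS:
    """Analytic sinogram NPS: unit-amplitude Lorentzian low-pass shape."""
    u = np.fft.fftfreq(roi, d=pitch_channel_mm)
    v = np.fft.fftfreq(roi, d=pitch_row_mm)
    r = np.hypot(*np.meshgrid(u, v))
    nps2d = 1.0 / (1.0 + (r / corner_per_mm) ** 2)
    freq, prof = radial_average(nps2d, pitch_row_mm, pitch_channel_mm)
    return SinogramNPS(nps2d, pitch_row_mm, pitch_channel_mm, freq, prof,
                       n_projections=0, roi=roi)


def default_characterization(model: ScannerModel,
                             with_noise: bool = True,
                             db: MaterialDB | None = None,
                             du_gain: float = 2.0e-2,
                             mv_slope: float = 2.0,
                             mv_offset: float = 25.0,
                             ) -> SystemCharacterization:
    """Synthetic characterization of the placeholder scanner.

    Spectra are filtered-bremsstrahlung models per allowed voltage, the
    detector QE is the theoretical energy absorption of a 0.6 mm CsI active
    layer, the bowtie is a quadratic aluminium-equivalent profile, and the
    noise tables hold one mean–variance model per (voltage, bowtie) and one
    Lorentzian sinogram NPS per configured protocol.
    """
    if db is None:
        db = default_material_db(max(model.allowed_voltages_kv))
    spectra = {float(kv): reference_spectrum(db, kv)
               for kv in model.allowed_voltages_kv}
    qe = detector_qe(db.grid, "csi", 0.6, db)
    bowties = {bid: synthetic_bowtie(model) for bid in model.bowtie_ids}
    gains = {bid: DUGain(du_gain, bid) for bid in model.bowtie_ids}
    noise = None
    if with_noise:
        noise = NoiseCharacterization()
        g = model.geometry
        for kv in model.allowed_voltages_kv:
            for bid in model.bowtie_ids:
                noise.mv[noise.mv_key(kv, bid)] = MVModel(mv_slope, mv_offset)
        for p in model.protocols.values():
            key = noise.nps_key(p.tube_current_ma, p.tube_voltage_kv,
                                p.exposure_time_s, p.bowtie_id)
            noise.nps[key] = synthetic_nps(g.row_pitch_mm, g.channel_pitch_mm)
    return SystemCharacterization(db, spectra, qe, bowties, gains,
                                  synthetic_detector_mtf(),
                                  synthetic_system_mtf(), noise)
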
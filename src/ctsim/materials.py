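"""Energy-resolved materials, x-ray spectra and beam characterization.

This module owns everything spectral: the energy grid, the material database
(linear attenuation per material plus the energy-absorption coefficient of air
used for kerma), the tube-spectrum model and its fit to air-kerma
measurements under standard filtrations, the digital-unit gain fit, the
bowtie-filter equivalent-thickness estimate from a lateral kerma profile, and
the detector quantum-efficiency curve.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, nnls

from . import _xs

__all__ = [
    "EnergyGrid", "Material", "MaterialDB", "Spectrum", "QECurve",
    "BowtieFilter", "DUGain", "KermaMeasurement", "MaterialError",
    "SpectrumFitError", "build_material_db", "builtin_compositions",
    "solution_composition", "air_kerma", "fit_spectrum", "fit_du_gain",
    "estimate_bowtie_profile", "detector_qe", "kramers_spectrum",
    "STANDARD_FILTRATIONS",
]


class MaterialError(ValueError):
    """Unknown or inconsistent material specification."""


class SpectrumFitError(RuntimeError):
    """Spectrum estimation failed to reproduce the measurements."""


@dataclass(frozen=True)
class EnergyGrid:
    """Uniform grid of photon-energy bin centers in keV."""

    energies_kev: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies_kev, dtype=float)
        if e.ndim != 1 or e.size < 2:
            raise ValueError("energy grid needs at least two bins")
        d = np.diff(e)
        if np.any(d <= 0) or not np.allclose(d, d[0]):
            raise ValueError("energy grid must be strictly increasing and uniform")
        object.__setattr__(self, "energies_kev", e)

    @property
    def spacing_kev(self) -> float:
        return float(self.energies_kev[1] - self.energies_kev[0])

    @classmethod
    def default(cls, tube_voltage_kv: float, e_min_kev: float = 5.0,
                step_kev: float = 1.0) -> "EnergyGrid":
        """1 keV bins from 5 keV up to the tube voltage (inclusive)."""
        n = int(np.floor((tube_voltage_kv - e_min_kev) / step_kev)) + 1
        return cls(e_min_kev + step_kev * np.arange(n))

    def __len__(self) -> int:
        return self.energies_kev.size


@dataclass(frozen=True)
class Material:
    """A material resolved on an energy grid.

    ``mu_per_mm`` is the linear attenuation coefficient; ``mu_en_rho_cm2g``
    the mass energy-absorption coefficient (needed for kerma integrals).
    """

    name: str
    mu_per_mm: np.ndarray
    mu_en_rho_cm2g: np.ndarray
    density_g_cm3: float


@dataclass
class MaterialDB:
    """Map material id -> :class:`Material`, all on one shared energy grid."""

    grid: EnergyGrid
    materials: dict[str, Material] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.materials

    def __getitem__(self, name: str) -> Material:
        try:
            return self.materials[name]
        except KeyError:
            raise MaterialError(f"material {name!r} not in database") from None

    def mu(self, name: str) -> np.ndarray:
        return self[name].mu_per_mm

    def names(self) -> list[str]:
        return list(self.materials)

    def index_of(self, name: str) -> int:
        return list(self.materials).index(name)


@dataclass(frozen=True)
class Spectrum:
    """Photon fluence per energy bin per mAs at the reference distance.

    ``photons_per_mas[e]`` is zero above the tube voltage by construction.
    """

    grid: EnergyGrid
    photons_per_mas: np.ndarray
    tube_voltage_kv: float

    def __post_init__(self):
        n = np.asarray(self.photons_per_mas, dtype=float)
        if n.shape != self.grid.energies_kev.shape:
            raise ValueError("spectrum shape does not match energy grid")
        if np.any(n < 0):
            raise ValueError("spectrum must be non-negative")
        if np.any(n[self.grid.energies_kev > self.tube_voltage_kv] > 0):
            raise ValueError("spectrum has support above the tube voltage")
        object.__setattr__(self, "photons_per_mas", n)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.grid, self.photons_per_mas * factor,
                        self.tube_voltage_kv)

    def save_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["energy_keV", "photons_per_mAs"])
            for e, n in zip(self.grid.energies_kev, self.photons_per_mas):
                w.writerow([f"{e:.6g}", f"{n:.10g}"])

    @classmethod
    def load_csv(cls, path: str | Path, tube_voltage_kv: float) -> "Spectrum":
        e, n = [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                e.append(float(row["energy_keV"]))
                n.append(float(row["photons_per_mAs"]))
        return cls(EnergyGrid(np.array(e)), np.array(n), tube_voltage_kv)


@dataclass(frozen=True)
class QECurve:
    """Detector quantum efficiency per energy bin, in [0, 1]."""

    grid: EnergyGrid
    qe: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.qe, dtype=float)
        if q.shape != self.grid.energies_kev.shape:
            raise ValueError("QE shape does not match energy grid")
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("QE must lie in [0, 1]")
        object.__setattr__(self, "qe", q)


@dataclass(frozen=True)
class BowtieFilter:
    """Per-channel equivalent thickness (mm) of a single stated material."""

    material_id: str
    thickness_mm: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.thickness_mm, dtype=float)
        if np.any(t < 0):
            raise ValueError("bowtie thickness must be non-negative")
        object.__setattr__(self, "thickness_mm", t)


@dataclass(frozen=True)
class DUGain:
    """Scalar gain: absorbed primary photon energy -> digital units."""

    gain: float
    bowtie_id: str | None = None

    def __post_init__(self):
        if not self.gain > 0:
            raise ValueError("DU gain must be positive")


@dataclass(frozen=True)
class KermaMeasurement:
    """One air-kerma reading under a stated added filtration."""

    filtration: tuple[tuple[str, float], ...]  # (material_id, thickness_mm)
    kerma: float

    def __post_init__(self):
        if self.kerma < 0:
            raise ValueError("negative kerma measurement")
        for mat, t in self.filtration:
            if t < 0:
                raise ValueError(f"negative filtration thickness for {mat!r}")


#: The four standard characterization filtrations.
STANDARD_FILTRATIONS: tuple[tuple[tuple[str, float], ...], ...] = (
    (),
    (("aluminum", 6.0),),
    (("copper", 1.0),),
    (("copper", 2.0),),
)


# ---------------------------------------------------------------------------
# compositions

def builtin_compositions() -> dict[str, tuple[dict[str, float], float]]:
    """Composition registry: id -> (mass fractions by element symbol, density).

    The phantom-insert entries (solid water, adipose, brain, blood, iodine and
    calcium solutions) are documented approximations adequate for qualitative
    CT-number pipelines, not certified reference formulations.
    """
    reg: dict[str, tuple[dict[str, float], float]] = {
        "vacuum": ({}, 0.0),
        "air": ({"N": 0.755, "O": 0.232, "Ar": 0.013}, 1.205e-3),
        "water": ({"H": 0.1119, "O": 0.8881}, 1.0),
        "aluminum": ({"Al": 1.0}, 2.699),
        "copper": ({"Cu": 1.0}, 8.96),
        "tungsten": ({"W": 1.0}, 19.3),
        "acrylic": ({"H": 0.0805, "C": 0.5998, "O": 0.3196}, 1.19),
        "teflon": ({"C": 0.2402, "F": 0.7598}, 2.2),
        "delrin": ({"H": 0.0671, "C": 0.4000, "O": 0.5329}, 1.41),
        "polypropylene": ({"H": 0.1437, "C": 0.8563}, 0.905),
        "csi": ({"Cs": 0.5115, "I": 0.4885}, 4.51),
        "solid_water": ({"H": 0.1119, "O": 0.8881}, 1.015),
        "adipose": ({"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.281}, 0.95),
        "brain": ({"H": 0.1119, "O": 0.8881}, 1.045),
    }
    for rho in (1.03, 1.07, 1.10):
        reg[f"blood_{rho:.2f}"] = ({"H": 0.1119, "O": 0.8881}, rho)
    for mg in (2, 5, 10, 15):
        reg[f"iodine_{mg}mgml"] = solution_composition("I", mg)
    for mg in (50, 100, 300):
        reg[f"calcium_{mg}mgml"] = solution_composition("Ca", mg)
    reg["iodine_2mgml_blood"] = solution_composition("I", 2, base_density=1.03)
    reg["iodine_4mgml_blood"] = solution_composition("I", 4, base_density=1.03)
    return reg


def solution_composition(element: str, mg_per_ml: float,
                         base_density: float = 1.0
                         ) -> tuple[dict[str, float], float]:
    """Aqueous solution of ``element`` at ``mg_per_ml``; volumes assumed additive."""
    rho = base_density + mg_per_ml * 1e-3
    w_sol = mg_per_ml * 1e-3 / rho
    w_wat = 1.0 - w_sol
    comp = {"H": 0.1119 * w_wat, "O": 0.8881 * w_wat, element: w_sol}
    return comp, rho


def build_material_db(grid: EnergyGrid,
                      specs: Iterable[str | tuple[str, object]] | None = None,
                      ) -> MaterialDB:
    """Build a material database on ``grid``.

    ``specs`` entries are either a builtin id (see
    :func:`builtin_compositions`), ``(id, (mass_fractions, density))`` for a
    custom composition, or ``(id, path)`` pointing at a CSV table with columns
    ``energy_keV, mu_per_mm`` (log-log interpolated onto the grid).  Air is
    always included so that kerma integrals are defined.
    """
    reg = builtin_compositions()
    if specs is None:
        specs = list(reg)
    db = MaterialDB(grid)
    e = grid.energies_kev

    def from_comp(name, comp, rho):
        if comp:
            mu = _xs.mixture_mass_attenuation(e, comp) * rho / 10.0
            mu_en = _xs.mixture_mass_energy_absorption(e, comp)
        else:
            mu = np.zeros_like(e)
            mu_en = np.zeros_like(e)
        return Material(name, mu, mu_en, rho)

    for spec in specs:
        if isinstance(spec, str):
            if spec not in reg:
                raise MaterialError(f"unknown builtin material {spec!r}")
            comp, rho = reg[spec]
            db.materials[spec] = from_comp(spec, comp, rho)
            continue
        name, payload = spec
        if isinstance(payload, (str, Path)):
            te, tmu = [], []
            with open(payload, newline="") as fh:
                for row in csv.DictReader(fh):
                    te.append(float(row["energy_keV"]))
                    tmu.append(float(row["mu_per_mm"]))
            te, tmu = np.array(te), np.array(tmu)
            if np.any(tmu < 0):
                raise MaterialError(f"negative mu in table for {name!r}")
            with np.errstate(divide="ignore"):
                mu = np.exp(np.interp(np.log(e), np.log(te),
                                      np.log(np.maximum(tmu, 1e-300))))
            mu[mu < 1e-290] = 0.0
            db.materials[name] = Material(name, mu, np.zeros_like(e), 1.0)
        else:
            comp, rho = payload
            try:
                db.materials[name] = from_comp(name, dict(comp), float(rho))
            except KeyError as exc:
                raise MaterialError(
                    f"material {name!r}: unresolvable composition ({exc})"
                ) from exc
    if "air" not in db.materials:
        comp, rho = reg["air"]
        db.materials["air"] = from_comp("air", comp, rho)
    return db


# ---------------------------------------------------------------------------
# kerma and spectrum estimation

def _transmission(db: MaterialDB,
                  filtration: Sequence[tuple[str, float]]) -> np.ndarray:
    tau = np.zeros(len(db.grid))
    for mat, t_mm in filtration:
        if t_mm < 0:
            raise ValueError(f"negative filtration thickness for {mat!r}")
        tau += db.mu(mat) * t_mm
    return np.exp(-tau)


def air_kerma(spectrum: Spectrum, filtration: Sequence[tuple[str, float]],
              db: MaterialDB) -> float:
    """Air kerma (arbitrary units) of ``spectrum`` behind ``filtration``.

    kerma = sum_e N_e * exp(-sum mu t) * E_e * (mu_en/rho)_air(E_e)
    """
    if db.grid is not spectrum.grid and not np.array_equal(
            db.grid.energies_kev, spectrum.grid.energies_kev):
        raise ValueError("spectrum and material database grids differ")
    trans = _transmission(db, filtration)
    e = db.grid.energies_kev
    mu_en_air = db["air"].mu_en_rho_cm2g
    return float(np.sum(spectrum.photons_per_mas * trans * e * mu_en_air))


def kramers_spectrum(grid: EnergyGrid, tube_voltage_kv: float,
                     added_al_mm: float = 2.5,
                     db: MaterialDB | None = None,
                     photons_total: float = 1.0) -> Spectrum:
    """Bremsstrahlung-shaped reference spectrum with added Al filtration.

    Kramers' law (fluence per bin proportional to ``(kVp - E)/E``) filtered by
    ``added_al_mm`` of aluminium, normalized to ``photons_total`` photons per
    mAs.  Serves as the basis generator for the spectrum fit and as the
    synthetic ground-truth tube model.
    """
    if db is None:
        db = build_material_db(grid, ["aluminum"])
    e = grid.energies_kev
    n = np.clip(tube_voltage_kv - e, 0.0, None) / e
    n = n * np.exp(-db.mu("aluminum") * added_al_mm)
    n[e > tube_voltage_kv] = 0.0
    s = n.sum()
    if s > 0:
        n = n / s * photons_total
    return Spectrum(grid, n, tube_voltage_kv)


def fit_spectrum(measurements: Sequence[KermaMeasurement],
                 tube_voltage_kv: float, db: MaterialDB,
                 basis_al_mm: Sequence[float] = (0.25, 0.75, 1.5, 2.75,
                                                 4.5, 7.0, 10.0, 15.0),
                 max_rel_residual: float = 0.05) -> Spectrum:
    """Estimate the tube spectrum from air-kerma readings under filtrations.

    The spectrum is modelled as a non-negative combination of kVp-matched
    bremsstrahlung basis spectra with different amounts of inherent aluminium
    filtration; the weights are fitted by non-negative least squares so the
    forward kerma model reproduces the measurements.

    Raises :class:`SpectrumFitError` when the relative kerma residual of any
    measurement exceeds ``max_rel_residual``.
    """
    if len(measurements) < 1:
        raise ValueError("at least one kerma measurement required")
    for m in measurements:
        if m.kerma < 0:
            raise ValueError("negative kerma measurement")
    basis = [kramers_spectrum(db.grid, tube_voltage_kv, al, db)
             for al in basis_al_mm]
    a = np.array([[air_kerma(b, m.filtration, db) for b in basis]
                  for m in measurements])
    y = np.array([m.kerma for m in measurements])
    # weight rows by 1/kerma: the fit targets relative, not absolute, error
    row_w = 1.0 / np.maximum(y, 1e-300)
    w, _ = nnls(a * row_w[:, None], y * row_w)
    n = sum(wi * b.photons_per_mas for wi, b in zip(w, basis))
    fitted = Spectrum(db.grid, n, tube_voltage_kv)
    pred = a @ w
    rel = np.abs(pred - y) / np.maximum(np.abs(y), 1e-300)
    if np.any(rel > max_rel_residual):
        raise SpectrumFitError(
            "spectrum fit did not reproduce the kerma measurements; relative "
            f"residuals: {np.array2string(rel, precision=4)}")
    return fitted


def _absorbed_energy(spectrum: Spectrum, qe: QECurve,
                     filtration: Sequence[tuple[str, float]],
                     db: MaterialDB) -> float:
    trans = _transmission(db, filtration)
    e = db.grid.energies_kev
    return float(np.sum(e * spectrum.photons_per_mas * qe.qe * trans))


def fit_du_gain(du_readings: Sequence[float],
                filtrations: Sequence[Sequence[tuple[str, float]]],
                spectrum: Spectrum, qe: QECurve, db: MaterialDB,
                bowtie_id: str | None = None) -> DUGain:
    """Least-squares scalar gain from predicted absorbed energy to recorded DU."""
    pred = np.array([_absorbed_energy(spectrum, qe, f, db) for f in filtrations])
    if np.all(pred == 0):
        raise SpectrumFitError("all predicted absorbed energies are zero")
    y = np.asarray(du_readings, dtype=float)
    g = float(pred @ y / (pred @ pred))
    return DUGain(g, bowtie_id)


def detector_qe(grid: EnergyGrid, absorber: str, thickness_mm: float,
                db: MaterialDB) -> QECurve:
    """QE(E) = 1 - exp(-mu_absorber(E) * t) for the active-layer thickness."""
    if thickness_mm < 0:
        raise ValueError("absorber thickness must be non-negative")
    return QECurve(grid, 1.0 - np.exp(-db.mu(absorber) * thickness_mm))


def estimate_bowtie_profile(offsets_mm: np.ndarray, kerma_profile: np.ndarray,
                            spectrum: Spectrum, material_id: str,
                            db: MaterialDB, geometry=None,
                            t_max_mm: float = 200.0) -> BowtieFilter:
    """Equivalent bowtie thickness from a lateral air-kerma profile.

    For each lateral offset the thickness ``t`` of ``material_id`` solving
    ``air_kerma(spectrum, [(material, t)]) = measured`` is found by monotone
    1-D root finding (Beer–Lambert kerma decreases strictly in ``t``).  If a
    :class:`~ctsim.config.ScannerGeometry` is given the per-offset thickness
    is resampled to a per-channel thickness via each channel's lateral ray
    offset at the isocenter; otherwise the per-offset thickness is returned.
    """
    offsets = np.asarray(offsets_mm, dtype=float)
    prof = np.asarray(kerma_profile, dtype=float)
    if np.any(prof <= 0):
        raise ValueError("kerma profile must be positive")
    k0 = air_kerma(spectrum, [], db)
    if np.any(prof > k0 * (1 + 1e-9)):
        raise ValueError("measured kerma exceeds the unattenuated reference")

    def t_of(k_meas: float) -> float:
        if k_meas >= k0:
            return 0.0
        f = lambda t: air_kerma(spectrum, [(material_id, t)], db) - k_meas
        return brentq(f, 0.0, t_max_mm, xtol=1e-10)

    t = np.array([t_of(k) for k in prof])
    if geometry is None:
        return BowtieFilter(material_id, t)
    gamma = geometry.channel_angles_rad()
    lateral = geometry.source_to_isocenter_mm * np.sin(np.abs(gamma))
    t_ch = np.interp(lateral, offsets, t)
    return BowtieFilter(material_id, t_ch)
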
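"""Shift-invariant detector corruption: MTF and colored noise.

The detector's resolution loss is applied as a frequency-domain
multiplication of each subsampled projection frame by a Lorentzian-family
MTF divided by the sinc of the final detector spacing (the later binning
re-applies that sinc, so the net response equals the measured MTF).

Noise is characterized by a linear mean–variance relationship
(``variance = a * mean + b_electronic``, the offset being electronic noise)
and by the sinogram noise-power spectrum estimated from repeated water
projections.  Injection colors a unit white Gaussian field by sqrt(NPS),
renormalizes it to zero mean and unit variance in space, scales it pointwise
by sqrt(MV(local 3x3 mean)) and adds it to the clean sinogram, so the local
noise variance matches the characterized mean–variance curve and the noise
correlation matches the characterized NPS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .projection import Sinogram, SubsampledSinogram

__all__ = ["MTFModel", "MVModel", "SinogramNPS", "NoiseCharacterization",
           "fit_mtf_model", "apply_detector_mtf", "estimate_mean_variance",
           "estimate_sinogram_nps", "add_noise", "radial_average",
           "MTFFitError"]


class MTFFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class MTFModel:
    """Sum-of-Lorentzians MTF: MTF(f) = sum_i w_i / (1 + (f/c_i)^2).

    Evaluation is clipped to at most one: the fit can exceed unity near zero
    frequency, and such values are forced to one when the MTF is applied.
    """

    weights: tuple[float, ...]
    corner_freqs: tuple[float, ...]
    clip: bool = True

    def __call__(self, freq_per_mm: np.ndarray) -> np.ndarray:
        f = np.abs(np.asarray(freq_per_mm, dtype=float))
        val = sum(w / (1.0 + (f / c) ** 2)
                  for w, c in zip(self.weights, self.corner_freqs))
        if self.clip:
            val = np.clip(val, 0.0, 1.0)
        return val


def fit_mtf_model(freqs_per_mm: np.ndarray, mtf_samples: np.ndarray,
                  n_terms: int = 2, max_residual: float = 0.05) -> MTFModel:
    """Least-squares Lorentzian-sum fit to sampled MTF points."""
    f = np.asarray(freqs_per_mm, dtype=float)
    y = np.asarray(mtf_samples, dtype=float)
    if f.size < 2 * n_terms + 1:
        raise ValueError("need at least 2*n_terms+1 MTF samples")
    fmax = f.max()

    def model(x, *p):
        w = p[:n_terms]
        c = p[n_terms:]
        return sum(wi / (1.0 + (x / ci) ** 2) for wi, ci in zip(w, c))

    p0 = ([1.0 / n_terms] * n_terms
          + list(np.linspace(0.3, 1.0, n_terms) * max(fmax, 1e-3)))
    bounds = ([0.0] * n_terms + [1e-6] * n_terms,
              [2.0] * n_terms + [np.inf] * n_terms)
    try:
        p, _ = curve_fit(model, f, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise MTFFitError(f"Lorentzian MTF fit did not converge: {exc}") from exc
    resid = model(f, *p) - y
    rms = float(np.sqrt(np.mean(resid**2)))
    if rms > max_residual:
        raise MTFFitError(f"Lorentzian MTF fit residual RMS {rms:.4f} exceeds "
                          f"{max_residual}; residuals {resid}")
    return MTFModel(tuple(p[:n_terms]), tuple(p[n_terms:]))


def apply_detector_mtf(sub: SubsampledSinogram, mtf: MTFModel,
                       sinc_compensation: bool = True,
                       ratio_cap: float = 10.0) -> SubsampledSinogram:
    """Apply the detector MTF to every subsampled projection frame.

    Each (focal subsample, angular subsample, view) frame — a 2-D image on
    the subsample grid — is multiplied in frequency domain by
    ``MTF(|f|) / (sinc(u*dx) * sinc(v*dy))`` where ``(dx, dy)`` are the
    *final* detector pitches: sampling on the physical grid multiplies the
    system response by that sinc, so it is divided out here before binning.
    The compensation ratio is capped at ``ratio_cap``.
    """
    dy_s, dx_s = sub.subsample_pitches_mm
    dy_f, dx_f = sub.final_pitches_mm
    f, k, v, ny, nx = sub.data.shape
    u = np.fft.fftfreq(nx, d=dx_s)               # cycles/mm, channel axis
    vv = np.fft.fftfreq(ny, d=dy_s)              # cycles/mm, row axis
    U, V = np.meshgrid(u, vv)
    h = mtf(np.hypot(U, V))
    if sinc_compensation:
        s = np.sinc(U * dx_f) * np.sinc(V * dy_f)
        with np.errstate(divide="ignore", invalid="ignore"):
            comp = np.where(np.abs(s) > 1.0 / ratio_cap, 1.0 / s,
                            ratio_cap * np.sign(s))
        comp = np.where(s == 0.0, ratio_cap, comp)
        h = h * comp
    frames = sub.data.reshape(f * k * v, ny, nx)
    out = np.fft.ifft2(np.fft.fft2(frames, axes=(-2, -1)) * h[None],
                       axes=(-2, -1)).real
    if not np.isfinite(out).all():
        raise RuntimeError("non-finite output from MTF application")
    return SubsampledSinogram(out.reshape(sub.data.shape), sub.scheme,
                              sub.geometry, sub.view_angles_rad,
                              sub.protocol_id)


# ---------------------------------------------------------------------------
# noise characterization

@dataclass(frozen=True)
class MVModel:
    """Linear mean–variance model: variance = a * mean + b_electronic."""

    a: float
    b_electronic: float
    identifiable: bool = True

    def __post_init__(self):
        if self.a < 0 or self.b_electronic < 0:
            raise ValueError("mean–variance coefficients must be >= 0")

    def __call__(self, mean: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(mean, dtype=float) + self.b_electronic


@dataclass
class SinogramNPS:
    """2-D sinogram NPS on the detector frequency grid plus radial average."""

    nps2d: np.ndarray
    pitch_row_mm: float
    pitch_channel_mm: float
    radial_freq_per_mm: np.ndarray
    radial_nps: np.ndarray
    n_projections: int = 0
    roi: int = 64

    def resample(self, shape: tuple[int, int],
                 pitches_mm: tuple[float, float]) -> np.ndarray:
        """Radially resample the measured NPS onto another frame's grid.

        The measured 2-D NPS (64x64 ROI) is reduced to its radial profile and
        interpolated at the physical frequency magnitude of every sample of
        the target grid, preserving radial content.
        """
        ny, nx = shape
        dy, dx = pitches_mm
        u = np.fft.fftfreq(nx, d=dx)
        v = np.fft.fftfreq(ny, d=dy)
        r = np.hypot(*np.meshgrid(u, v))
        return np.interp(r, self.radial_freq_per_mm, self.radial_nps,
                         right=self.radial_nps[-1])


@dataclass
class NoiseCharacterization:
    """Protocol-keyed lookup of MV models and sinogram NPSs.

    Lookups fail loudly for protocols that were never characterized; no
    interpolation between measured settings is attempted.
    """

    mv: dict[tuple, MVModel] = field(default_factory=dict)
    nps: dict[tuple, SinogramNPS] = field(default_factory=dict)

    @staticmethod
    def mv_key(tube_voltage_kv: float, bowtie_id: str) -> tuple:
        return (float(tube_voltage_kv), bowtie_id)

    @staticmethod
    def nps_key(tube_current_ma: float, tube_voltage_kv: float,
                exposure_time_s: float, bowtie_id: str) -> tuple:
        return (float(tube_current_ma), float(tube_voltage_kv),
                float(exposure_time_s), bowtie_id)

    def lookup_mv(self, tube_voltage_kv: float, bowtie_id: str) -> MVModel:
        key = self.mv_key(tube_voltage_kv, bowtie_id)
        if key not in self.mv:
            raise KeyError(f"no mean–variance model measured for {key}")
        return self.mv[key]

    def lookup_nps(self, tube_current_ma, tube_voltage_kv, exposure_time_s,
                   bowtie_id) -> SinogramNPS:
        key = self.nps_key(tube_current_ma, tube_voltage_kv, exposure_time_s,
                           bowtie_id)
        if key not in self.nps:
            raise KeyError(f"no NPS measured for {key}")
        return self.nps[key]


def _center_roi(frame: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    ny, nx = frame.shape
    ry, rx = shape
    if ry > ny or rx > nx:
        raise ValueError(f"ROI {shape} exceeds projection size {(ny, nx)}")
    y0 = (ny - ry) // 2
    x0 = (nx - rx) // 2
    return frame[y0:y0 + ry, x0:x0 + rx]


def estimate_mean_variance(stacks: "np.ndarray | list[np.ndarray]",
                           roi_shape: tuple[int, int] = (20, 30)) -> MVModel:
    """Fit the mean–variance line from water-sinogram projection stacks.

    ``stacks`` is one projection stack ``(views, rows, channels)`` or a list
    of stacks at different exposure levels.  Per projection, mean and
    variance are taken in a central ROI and averaged over projections; with
    two or more exposure levels a straight line through the (mean, variance)
    points gives slope ``a`` and electronic-noise offset ``b``.  A single
    level cannot separate the two; the returned point estimate (all variance
    in the slope) is flagged ``identifiable=False``.
    """
    if isinstance(stacks, np.ndarray):
        stacks = [stacks]
    means, variances = [], []
    for stack in stacks:
        if stack.ndim != 3 or stack.shape[0] < 2:
            raise ValueError("each stack needs >= 2 projections "
                             "(views, rows, channels)")
        m = np.empty(stack.shape[0])
        v = np.empty(stack.shape[0])
        for i, frame in enumerate(stack):
            roi = _center_roi(frame, roi_shape)
            m[i] = roi.mean()
            v[i] = roi.var(ddof=1)
        means.append(m.mean())
        variances.append(v.mean())
    means = np.asarray(means)
    variances = np.asarray(variances)
    if len(means) == 1:
        if variances[0] == 0.0:
            return MVModel(0.0, 0.0, identifiable=True)
        return MVModel(float(variances[0] / means[0]), 0.0,
                       identifiable=False)
    a, b = np.polyfit(means, variances, 1)
    return MVModel(max(float(a), 0.0), max(float(b), 0.0))


def estimate_sinogram_nps(stack: np.ndarray,
                          pitch_row_mm: float, pitch_channel_mm: float,
                          roi: int = 64, min_projections: int = 100,
                          ) -> SinogramNPS:
    """Estimate the sinogram NPS from repeated (water) projections.

    The mean projection is subtracted from every frame first — this removes
    fixed structure such as detector-tiling lines — then the 2-D periodogram
    of a central ``roi`` x ``roi`` region is averaged over projections and
    radially averaged on physical frequency magnitude.
    """
    if stack.ndim != 3:
        raise ValueError("stack must be (views, rows, channels)")
    n = stack.shape[0]
    if n < min_projections:
        raise ValueError(f"need >= {min_projections} projections for a "
                         f"stable NPS estimate, got {n}")
    resid = stack - stack.mean(axis=0, keepdims=True)
    acc = np.zeros((roi, roi))
    norm = pitch_row_mm * pitch_channel_mm / (roi * roi)
    for frame in resid:
        r = _center_roi(frame, (roi, roi))
        acc += np.abs(np.fft.fft2(r)) ** 2 * norm
    nps2d = acc / n
    freq, prof = radial_average(nps2d, pitch_row_mm, pitch_channel_mm)
    return SinogramNPS(nps2d, pitch_row_mm, pitch_channel_mm, freq, prof,
                       n_projections=n, roi=roi)


def radial_average(spec2d: np.ndarray, pitch_y_mm: float, pitch_x_mm: float,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Radially average a 2-D spectrum on physical frequency magnitude.

    Bin width is the coarser of the two frequency-grid steps, so anisotropic
    sampling is binned on physical cycles/mm.
    """
    ny, nx = spec2d.shape
    u = np.fft.fftfreq(nx, d=pitch_x_mm)
    v = np.fft.fftfreq(ny, d=pitch_y_mm)
    r = np.hypot(*np.meshgrid(u, v)).ravel()
    w = np.asarray(spec2d, dtype=float).ravel()
    step = max(1.0 / (nx * pitch_x_mm), 1.0 / (ny * pitch_y_mm))
    idx = np.round(r / step).astype(int)
    nbin = idx.max() + 1
    sums = np.bincount(idx, weights=w, minlength=nbin)
    counts = np.bincount(idx, minlength=nbin)
    return np.arange(nbin) * step, sums / np.maximum(counts, 1)


def add_noise(sino: Sinogram, mv: MVModel, nps: SinogramNPS,
              seed: int) -> Sinogram:
    """Add NPS-colored, mean–variance-scaled noise to a clean sinogram.

    Per view: a white Gaussian field is colored in frequency domain by the
    square root of the (radially resampled) NPS, renormalized to zero mean
    and unit variance in space, scaled pointwise by the square root of
    ``MV(local 3x3 mean)`` and added.  Views use independent seed-derived
    streams, so the output is bit-reproducible for a given seed and
    independent of view batching.
    """
    if sino.noisy:
        raise ValueError("input sinogram is already noisy")
    v, ny, nx = sino.data.shape
    target = nps.resample((ny, nx), (nps.pitch_row_mm, nps.pitch_channel_mm))
    amp = np.sqrt(np.maximum(target, 0.0))
    out = np.empty_like(sino.data, dtype=np.float64)
    for i in range(v):
        rng = np.random.default_rng([int(seed), i])
        white = rng.standard_normal((ny, nx))
        colored = np.fft.ifft2(np.fft.fft2(white) * amp).real
        sd = colored.std()
        if sd > 0:
            colored = (colored - colored.mean()) / sd
        local = ndimage.uniform_filter(sino.data[i], size=3, mode="nearest")
        var = mv(local)
        if np.any(var < 0):
            raise ValueError("mean–variance model yields negative variance")
        out[i] = sino.data[i] + np.sqrt(var) * colored
    return Sinogram(out, sino.geometry, sino.view_angles_rad,
                    sino.protocol_id, noisy=True,
                    meta={**sino.meta, "noise_seed": int(seed)})
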
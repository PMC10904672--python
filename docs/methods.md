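# Methods

`ctsim` simulates the image formation of an axial, third-generation CT
scanner and the metrology used to characterize and validate such a
simulator. The simulation splits the physics the way scanner-specific
simulators do in practice: effects that vary with position in the field of
view (finite focal spot, gantry rotation during the view window, the curved
detector geometry, bowtie filtration, polychromatic attenuation) are
computed by ray tracing, while detector effects that are shift-invariant to
good approximation (detector MTF, noise power spectrum, mean–variance
response) are imposed on the sinogram in the frequency domain.

## Forward model

For every view the source–detector pair rotates about the z-axis while the
voxelized phantom stays fixed. A view is not a single time point: during
the view window (2π / `views_per_rotation`) the gantry sweeps an arc, which
is modelled by K angular subsamples placed at the centers of K equal
sub-intervals of the window (an unbiased average over the window). The
finite focal spot is an L×L uniform grid of equally weighted source points
centered on the nominal focus, with its width tangential in-plane and its
length along z; the grid is square because diagnostic focal spots are
approximately square. Each detector element is subsampled M×M, rays ending
at the centers of the subsampled elements of the curved equiangular
detector (equal angular pitch in-row, flat equal spacing across rows in z —
whether real detector rows are focused at the source in z is not modelled).

Per-material intersection lengths T are computed by exact parametric voxel
traversal (Siddon-style), not by interpolation sampling, so analytic chord
oracles apply. The detector signal of one subsample ray is the
energy-integrated Beer–Lambert transmission

    I = g · mAs · Σ_e E_e · N_e · QE_e ·
        exp(−Σ_m μ_m(E_e)·T_m − μ_bow(E_e)·t_bow(channel)),

with the per-channel bowtie equivalent thickness inside the exponent (the
leading energy factor makes the detector energy-integrating). The detector
MTF is applied per subsampled projection frame as a frequency-domain
multiplication by MTF(|f|) divided by the sinc of the *final* detector
spacing — the subsequent binning to the physical grid re-applies exactly
that sinc, so the net detector response equals the measured MTF. Binning is
the plain average over all L²·K·M² subsamples. Noise is added last.

Pipeline order (trace → energy integration → MTF → binning → noise) is
asserted by a test: swapping MTF and binning measurably changes the result.

## Noise model

Sinogram noise is characterized by two measured quantities: a linear
mean–variance relationship, variance = a·mean + b, whose offset b is the
electronic noise (the local mean is a 3×3 box average, edge-replicated at
borders), and the 2-D noise power spectrum of repeated water projections
(mean projection subtracted first — this also removes fixed detector-tiling
structure — then averaged 64×64 central-ROI periodograms, radially averaged
on physical frequency magnitude with the coarser grid step as bin width).

Injection per view: a white Gaussian field is multiplied in frequency
domain by the *square root* of the NPS, normalized to zero mean and unit
variance in space, scaled pointwise by the *square root* of MV(local mean),
and added. Two deliberate readings are involved: the coloring uses √NPS
(the power spectrum is a squared quantity), and the scaling uses √MV so
that the local noise variance — not its standard deviation — equals the
characterized mean–variance value; both choices are what makes the
injector/estimator loop close, and the closure is tested. Each view draws
from an independent counter-derived stream (`default_rng([seed, view])`),
so output is bit-reproducible for a given seed and independent of how views
are batched.

Because the injected field is explicitly zero-mean per view, its NPS has no
DC component; NPS closure comparisons therefore exclude the DC bin.

## Attenuation data

No attenuation database is bundled. Elemental cross sections come from a
compact parametric model: exact Klein–Nishina incoherent scattering, a
power-law photoelectric term with a Moseley-law K edge and fitted jump
ratio, and a power-law coherent term; the global constants and per-element
photoelectric corrections (O, Al, Cu, W; interpolated in Z elsewhere) were
calibrated once, by least squares in log space, against published
diagnostic-range anchor values for water, aluminium, copper, tungsten and
the energy-absorption coefficient of air. Agreement at the anchors is a few
percent — adequate for a simulator whose acceptance is self-consistency,
and clearly labelled synthetic. Compounds use the mass-fraction mixture
rule; the phantom-insert recipes (iodine/calcium solutions, blood
densities, adipose, brain) are documented approximations. Kerma integrals
use μ_en/ρ of air with photoelectric events depositing the full photon
energy and Compton events the Klein–Nishina mean transfer fraction.

## Characterization fits

*Spectrum.* The tube spectrum is estimated from four air-kerma readings
(open beam, 6 mm Al, 1 mm Cu, 2 mm Cu) as a non-negative combination of
kVp-matched bremsstrahlung (Kramers-law) basis spectra behind an eight-step
aluminium filtration ladder (0.25–15 mm), fitted by non-negative least
squares with rows weighted by 1/kerma so the fit targets *relative* error —
otherwise the heavily filtered (small-kerma) readings are ignored. The
fitted spectrum is non-negative and zero above the kVp by construction; a
residual above 5 % raises instead of returning silently.

*Digital-unit gain.* A single scalar per bowtie mapping predicted absorbed
energy to recorded digital units, by least squares over the same four
readings. The DU model is gain-only (no offset): an electronic offset
belongs to the noise model's b term, not the deterministic response.

*Bowtie.* Per lateral offset (5 mm steps to 160 mm), the equivalent
aluminium thickness solving kerma(t) = measurement by bracketed root
finding (Beer–Lambert kerma is strictly monotone in t), then interpolated
to per-channel thickness via each channel's lateral ray offset at the
isocenter.

*Detector QE.* 1 − exp(−μ_abs·t) for the nominal active layer (default
0.6 mm CsI — the real absorber and thickness are scanner-specific
configuration).

*MTF.* A sum of Lorentzians fitted to sampled MTF points; evaluation is
clipped to ≤ 1 because the fit can slightly exceed unity near zero
frequency.

*HU calibration.* Strictly two-step: the offset b_water is fixed so the
measured water value maps to zero, then a single slope minimizes the
squared error of a·(measured + b_water) against theoretical CT numbers.
The slope is unidentifiable from water alone and raises in that case.

## Reconstruction

The clinical reconstruction kernel such simulators target is proprietary,
so reconstruction here is standard plumbing: per-row equiangular fan-beam
FBP (cos γ weighting, the closed-form equiangular ramp kernel, optional
Hann apodization, 1/L² backprojection weight), with an FDK-style cone-angle
weight behind a flag. I₀ for log-normalization is an air scan simulated
with the same protocol — including the bowtie, and passed through the same
MTF/binning corruption — mirroring a physical air calibration. CT numbers
use HU = 1000·(μ − μ_w)/μ_w with μ_w the detector-weighted effective water
attenuation of the protocol's spectrum. Consequently absolute resolution
and noise numbers of any particular clinical kernel are *not* reproduced;
the package's validation target is self-consistency: what the corruption
stage injects, the metrology stage must re-measure.

## Metrology

*Wire MTF.* From a small-FOV reconstruction of a 50 µm tungsten wire: the
background-subtracted slice is rotated by the wire's azimuth so radial
aligns with +x, the PSF is summed along the orthogonal axis into an LSF,
tapered with a flat-center Tukey window (α = 0.25 — a full Hann window
measurably narrows wide profiles and biases the spectrum high), zero-padded
4×, and the normalized FFT magnitude read out at the first downward 0.1
crossing by linear interpolation (curves are never extrapolated; a curve
that never crosses reports NaN). Wire presence is gated on the peak height
relative to the border-ring noise scale.

*Slanted edge.* Sub-pixel edge locations per row from the centroid of the
differentiated profile, a fitted straight edge, projection of all pixels
onto the edge normal, ESF binning at pitch/4, derivative, Hann window
centered on the LSF peak, normalized FFT.

*SSP.* A wire at a small angle to the slice plane sweeps through the slice
laterally, so the lateral streak super-samples the through-slice response
(z = y·tan(tilt)); the spectrum is normalized at DC like the MTF, with the
10 % frequency reported. Zero tilt is rejected — it provides no
super-sampling.

*Wire phantoms.* Tilts are realized by one-voxel shifts between
anisotropic steps. In-plane mode shifts one fine voxel in both transverse
directions per longitudinal step: at the canonical voxel sizes
(0.1432 × 0.005 × 0.005 mm) this gives atan(√2·0.005/0.1432) ≈ 3°.
Through-plane mode shifts one fine z-voxel per lateral step:
atan(0.005/0.035) ≈ 8°. A requested tilt incompatible with the voxel
aspect raises an error reporting the achievable tilt.

*Reconstruction NPS.* Averaged per-slice periodograms of a central ROI;
the unstructured variant subtracts the across-slice mean image first (the
structured variant only each slice's scalar mean). Both 2-D spectra, the
radial average and the across-slice spectrum (per-pixel z-periodograms over
a central ROI) are each normalized to unit area on their own frequency
grids; the unit-area invariant is asserted to 1e-6 across the suite.

## The simplification study

One subsampling factor at a time is reduced from the full scheme
(L=3, K=3, M=4 by default) while the others stay full; the figure of merit
is the absolute relative change of the wire f10 against the full run, per
FOV position and direction, next to the analytic cost reduction factor
(L²KM²)_full / (L²KM²)_simplified. Two shortcut variants are included:
substituting the system MTF (edge at the isocenter, hence containing
focal-spot blur) for the detector MTF in a point-source run, and replacing
angular subsampling by cyclic pairwise view averaging (the last view pairs
with the first — the pairing of the final projection is otherwise
arbitrary and this choice is the documented one).

## Synthetic data scope

The `synthetic` module generates every characterization input from known
ground truth: filtered-bremsstrahlung spectra (5 × 10⁶ photons/mAs
reference fluence), kerma readings under the four standard filtrations, a
quadratic aluminium bowtie (4·10⁻⁴ mm⁻¹ lateral curvature, ~10 mm Al
equivalent at 160 mm — typical body-bowtie scale), two-Lorentzian detector
and system MTFs, and a Lorentzian low-pass sinogram NPS with MV slope 2 DU
and electronic offset 25 DU². These emulate the *structure* of bench
measurements, not any particular scanner: passing tests demonstrate that
the estimators invert the generators and that the pipeline is
self-consistent, not that a specific machine's Tables of measured values
would be reproduced — that requires the machine's confidential geometry and
physical measurements, which is why all geometry lives in the configuration
file with documented desk-scale placeholders (288 channels × 16 rows, 360
views, 600/1100 mm distances).

## Numerical choices and tolerances

- Energy grid: 1 keV bins from 5 keV to the kVp. Configurable; 1 keV is the
  standard diagnostic resolution and keeps the energy loop cheap.
- Ray oracle tolerance: voxel-center classification displaces a surface by
  up to half a voxel along a crossing, so an oblique chord is reproduced to
  within one fine-voxel *length along the ray* — the in-plane voxel
  diagonal, √2·voxel — and near-tangent chords additionally amplify the
  displacement by 1/sin(incidence), which is a property of voxelization,
  not of the tracer; oracle tests therefore use interior rays.
- Rays that miss the phantom bounding box are filled with the per-channel
  unattenuated (bowtie-filtered) level analytically; the energy loop runs
  only over rays with nonzero path length.
- The sinc-compensation ratio is capped (default 10) where the sinc is
  small; the fitted MTF decays much faster than the sinc grows, so the cap
  is inactive in practice.
- MTF closure is evaluated up to half the detector Nyquist mapped to the
  image plane by the magnification — beyond the detector Nyquist the
  applied filter is aliased and the comparison is undefined.
- Degenerate inputs fail loudly: non-positive intensities name the
  offending sinogram indices, unmeasured noise protocols raise KeyError,
  invalid configurations name the field.

## Problem sizes

Tests and the acceptance script run desk-scale problems chosen so the whole
suite and the script each complete in minutes on one core: 256-channel
single-row geometry with 360 views for wire studies (tracing at M=8 with
rebinning, 8 wire steps), 64×64 frames × 500 views for noise closure,
0.25 mm voxels for chord oracles. All checked properties are scale-free;
the shipped configuration's full 16-row profile runs the identical code.

## Limitations

Scatter is not simulated (the target workflow assumes scatter-corrected
reconstruction). No helical trajectories, tube-current modulation,
dual-source geometries, photon-counting response, pile-up, afterglow,
detector cross-talk, heel effect or off-focal radiation. Detector MTF/NPS
are assumed stationary across the detector. The FBP is generic plumbing,
not a vendor kernel. The attenuation model is smooth parametric physics,
not a certified database — CT numbers are qualitative until calibrated.
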
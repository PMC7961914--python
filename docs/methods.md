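# Methods

`qpatsim` is an in-silico replication of a quantitative photoacoustic
tomography (QPAT) oxygenation experiment on a semi-anthropomorphic breast
phantom. The pipeline generates a digital twin of the phantom, simulates
light transport for a tomographic illumination at 755 and 1064 nm,
synthesizes dual-wavelength initial-pressure images for two blood
oxygenation setpoints, and recovers SO2 under three fluence-compensation
approaches. This note records the model, the defaults, and the design
choices that were genuinely open.

## Physical model

Photoacoustic signal generation is modeled by the initial-pressure
relation

    p0(λ, x) = Γ(x) · Φ(λ, x) · μa(λ, x),

with Γ the Grüneisen efficiency (dimensionless), Φ the fluence in J/cm²,
and μa the absorption coefficient in cm⁻¹. Blood absorption follows the
two-chromophore mixing law

    μa(λ) = k · (εHb(λ)·C_Hb + εHbO2(λ)·C_HbO2),

and oxygen saturation is SO2 = C_HbO2 / (C_Hb + C_HbO2) · 100%.
Measuring p0 at two wavelengths and dividing by a modeled fluence map
turns SO2 estimation into an exact 2×2 linear inversion per voxel.

The packaged extinction coefficients (cm⁻¹/M) are εHb = 1551.0 / 134.0
and εHbO2 = 555.2 / 867.0 at 755 / 1064 nm. Whether these combine with a
factor ln(10) is not standardized across sources; the `ln10_convention`
flag makes the choice explicit and defaults to off (μa = ε·C). SO2
estimates are invariant to any scalar common to both wavelengths, so the
flag affects only absolute μa values in the forward model. The default
total hemoglobin concentration for forward simulation is C_tHb = 2.0 mM,
an order-of-magnitude-realistic choice for diluted whole blood in a
phantom circuit; it likewise cancels in SO2 estimation.

## Digital phantom

The phantom is a pendant breast in a water bath: the contour is the lower
half of an ellipsoid of revolution (default radius 45 mm, height 40 mm;
a hemisphere when equal), with the apex (nipple) at the origin and z
increasing toward the chest wall. An outer fat layer and an inner
fibroglandular core are separated by an undulating interface: the breast
cap shrunk by the mean fat-layer depth (13 mm) with a radial sinusoid
(amplitude 2 mm, period 25 mm). The physical phantom's molds were derived
from segmented MRI volumes that are not published; the parametric cap
preserves the property the homogeneous compensation approach depends on —
a known outer contour — without claiming the original morphology.

Eight wall-less blood channels of 1.3 mm diameter are routed four per
layer: fat-layer channels are circular arcs at constant height offset
4 mm outside the interface (so undulation peaks never reach them), and
fibroglandular channels are straight chords at staggered (y, z) offsets.
Two tumor spheres (16 mm diameter, within the 15–20 mm design range) are
fibroglandular material with an absorption offset, each threaded by
exactly one channel through its core. Offsets were chosen so that no two
channels or tumor surfaces approach within a tube diameter, which keeps
the eight rasterized tubes topologically separate and each tumor crossed
by exactly one tube. Rasterization paints labels in priority order
water < fat < fibro < tumor < blood and clips everything to the breast
contour. The tumor absorption offset defaults to the design value
0.2 cm⁻¹; the measured contrast of the physical tumors (0.12 cm⁻¹) is
available by configuration — the two are not averaged.

Default voxel pitch is 0.5 mm, balancing runtime against rasterization
fidelity of the 1.3 mm tubes; tests that only exercise orchestration use
1.0 mm. All lengths are mm and all optical coefficients cm⁻¹; the single
unit conversion happens inside the transport kernel.

Tissue optical properties (μa, μs′ in cm⁻¹; g; n):

| tissue | 755 nm | 1064 nm | g | n |
|---|---|---|---|---|
| water | 0.03 / 1e-9 | 0.12 / 1e-9 | 0.95 | 1.33 |
| fat | 0.38 / 25.02 | 0.56 / 17.01 | 0.7 | 1.49 |
| fibroglandular | 0.49 / 18.81 | 0.71 / 10.74 | 0.7 | 1.74 |
| breast (homogenized) | 0.44 / 21.92 | 0.63 / 13.88 | 0.7 | 1.62 |

The homogenized "breast" row is the fat/fibroglandular average (to table
precision) and is what the known-contour compensation approach assigns to
the whole interior. Water's μs′ of 1e-9 cm⁻¹ is treated as exactly its
value — effectively ballistic water. Blood scattering inside channels is
not part of the measured table; defaults are μs′ = 2.0 cm⁻¹, g = 0.9,
n = 1.38, all configurable.

## Monte Carlo transport

A weighted-photon voxel Monte Carlo: free paths sampled from exp(−μt s)
with voxel-by-voxel optical-depth accounting, Henyey–Greenstein
scattering with the local g, implicit capture (Δw = w·μa/μt deposited at
every interaction) and Russian roulette below weight 1e-4 with survival
probability 0.1, and unpolarized Fresnel reflection/refraction at voxel
faces where n changes. μs is recovered from the tabulated μs′ through the
similarity relation μs = μs′/(1−g). Voxels with μt = 0 propagate
ballistically. Fluence is the deposition estimator Φ = E_dep/(μa·V),
which is low-variance in high-albedo tissue where interactions are dense
relative to the 0.5 mm pitch; μa = 0 voxels report zero.

Validation: against the diffusion Green's function of an isotropic point
source in an infinite medium (μa = 0.1, μs′ = 10 cm⁻¹), shell-averaged
fluence agrees within a few percent at 5–15 mm; a collimated pencil in a
pure absorber reproduces Beer–Lambert decay; launched energy is conserved
(deposited + escaped) to the roulette noise floor.

The illumination replicates a tomographic mammography scan: one broad
bottom cone carrying 50% of the pulse energy aimed at the nipple, and
nine side fibers replicated over 45 rotation steps spanning a 60° arc —
406 simultaneous cone sources, one fluence map per wavelength. Exact
fiber coordinates, apertures and divergences of the physical system are
not published; the defaults (fiber ring 8 mm outside the breast equator,
evenly spread in azimuth, aimed inward and nippleward; 10° divergence)
are declared approximations and fully configurable. Pulse energies are
320 mJ at 755 nm and 400 mJ at 1064 nm. Photons are allocated to sources
by stratified assignment proportional to source weight, making the split
deterministic; the whole simulation is reproducible from one seed.

Every simulated fluence map is Gaussian-smoothed with σ = 1.0 mm before
use. The true fluence field is diffuse and therefore smooth at the
millimeter scale, so this suppresses Monte Carlo shot noise without
erasing physical structure; the forward model and the ground-truth
compensation share the same smoothed maps, so the smoothing cannot
manufacture accuracy for the ground-truth approach (its recovery is exact
by construction with or without it).

## Forward model and degradation proxy

Initial pressure is the voxelwise product Γ·Φ·μa with Γ = 1 everywhere by
default: no Γ values were measured for the phantom materials, and any
wavelength-independent Γ cancels in dual-wavelength SO2 estimation. The
acoustic propagation and iterative backprojection of the physical system
are out of scope; they are replaced by a degradation proxy — Gaussian PSF
blur (default FWHM 0.5 mm, inside the 0.3–1 mm resolution range of 3D
photoacoustic breast systems) plus multiplicative Gaussian noise — which
exposes the same amplitude corruption that fluence compensation must
survive. The default experiment runs noiseless (no degradation), the
cleanest setting for the compensation comparison; the proxy is exercised
separately. Double-line reconstruction artifacts of the physical system
are not modeled; ROIs are placed on artifact-free vessel segments, which
mirrors how the physical study selected its ROIs.

## SO2 estimation

Three approaches: (i) no compensation (Φ ≡ 1); (ii) compensation with a
fluence map simulated on the homogenized model (known contour, average
properties — the approach available in vivo); (iii) compensation with the
map simulated on the true labeled phantom. Because blood μa depends on
the setpoint, the ground-truth volume is simulated once per SO2 level and
the forward model for a level uses that same map — three Monte Carlo runs
per wavelength in the full experiment.

Per vessel voxel, compensated absorptions p0/Φ at the two wavelengths are
unmixed by the exact 2×2 solve and converted to SO2. Voxels with
nonpositive fluence or with nonpositive signal at both wavelengths are
flagged invalid, never silently dropped; negative unmixed concentrations
are kept (clipping would bias ROI means) and flagged. The vessel mask is
the ground-truth blood labels, dilated by the PSF radius when the
degradation proxy is active. The two default ROIs are mm-boxes around one
fat-layer vessel segment near the well-lit nipple side and one deeper
fibroglandular vessel segment, both away from the tumors. The accuracy
metric is the average absolute deviation of the ROI means from the set
SO2. The published physical-phantom ROI table ships with the package;
its deviation column is recomputed from the printed ROI estimates, and
the two homogeneous-compensation rows are reported as
rounding-inconsistent (2.3 vs 2.6 and 7.85 vs 8.0) rather than failed —
they do not recompute from their own printed inputs at print precision.

## Problem sizes

Default experiment: 0.5 mm pitch (228×228×112 voxels) and 1e6 photons
per Monte Carlo run (six runs per experiment), about four minutes on one
CPU core. The acceptance script uses 8e5 photons per run and the test
suite 4e5; the deviation ordering of the three approaches is stable at
these budgets across seeds. The diffusion benchmark uses 2e5 photons.

## What the generator does and does not emulate

The synthetic experiment reproduces the design of the physical study —
geometry, optical properties, illumination, setpoints, metric — but not
its confounds: the per-projection moving side illumination (the physical
analysis itself approximated all projections as simultaneous and noted
the residual error), acoustic reconstruction artifacts, sound-speed
heterogeneity, oximeter error on the setpoints (±1.6%, reported alongside
results but not propagated), and detachment or layering imperfections of
real phantom materials. Passing tests therefore demonstrate correctness
of the computational pipeline and the direction and ordering of
fluence-compensation effects, not the absolute deviation magnitudes of
the physical measurement, which include those confounds.

## Numerical choices

Voxel traversal keeps the voxel index authoritative (no epsilon nudging);
optical depth is medium-independent and survives refraction events.
Degenerate inputs: zero-concentration blood gives μa = 0; zero total
hemoglobin in `so2_of` returns a NaN sentinel, never a silent zero; a
singular extinction matrix raises. Stratified source assignment removes
multinomial noise from the energy split. Seeds: every stochastic stage
(Monte Carlo per volume/wavelength, degradation noise) derives its seed
deterministically from the single experiment seed, and all derived seeds
are recorded in the provenance block.

## Known limitations

* The illumination geometry is an approximation of the physical system;
  absolute fluence values at depth inherit that uncertainty.
* The deposition estimator is noisy in near-transparent media (water);
  vessel estimates there are not used.
* At desk-scale photon budgets, deep fibroglandular vessels have low
  fluence SNR; ROI means over noisy voxels inherit a bias toward
  mid-range SO2, which is visible in the no-compensation rows.
* The degradation proxy models amplitude corruption only — no streaks,
  no double-line artifacts, no depth-dependent resolution.
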
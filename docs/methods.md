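# Methods

## The measurement problem

A polystyrene disk (8 mm diameter, 2 mm thick) sits in the subcutaneous
space 1.5 mm below the surface, under a ~0.75 mm skin layer and a ~0.75 mm
fat layer, on a thick muscle bed. The foreign body response deposits a
collagen cap on the disk's top face; the quantity of interest is that cap's
thickness `t` (0–200 µm, far below the optical transport length). The
package models how much collagen Raman signal a surface instrument can
collect at a photon budget fixed by the skin MPE (3 mW/mm² at 785 nm), which
surface geometry maximizes it, and how well a spectral calibration can read
`t` back.

In the phantom, the collagen cap occupies the cylindrical slab
`[1.5 mm, 1.5 mm + t)` directly above the disk: the cap sits at the
subcutaneous depth and the disk's top face is displaced by `t` beneath it.
With `t = 0` the phantom is the "initial conditions" (day-0) sample. The
`thickness_from_mass` helper converts a deposited collagen mass to a
mimicked thickness via `t = m·f/(ρ·A)` with the fibrotic-capsule collagen
density ρ = 500 µg/mm³; its parameters are explicit and no fixed
thickness-per-mass constant is assumed.

## Photon transport

Light propagation is modelled by the steady-state diffusion approximation,
`-∇·(κ∇φ) + µ_a φ = q`, `κ = 1/(3(µ_a + µ_s'))`, discretized by a
node-centred finite-volume scheme on a uniform grid (7-point stencil,
harmonic-mean face diffusivity, symmetric positive-definite system). The
grid convention is `floor(extent/spacing) + 1` nodes per axis, so the 20 mm
cube at the 0.6 mm default spacing has 34³ = 39,304 nodes.

**Boundaries.** The top (measurement) surface uses the extrapolated-boundary
condition realized literally: the surface material is extended upward by
fictitious ghost planes and the fluence is pinned to zero on the plane at
`z = -z_b`, `z_b = 2Aκ`, with the internal-reflection factor
`A = (1+R_eff)/(1-R_eff)` from the Groenhuis polynomial in the refractive
index ratio. This choice makes the solver converge to the classical
image-source (dipole) half-space solution, which is the package's analytic
oracle; the remaining discrepancy at the 0.6 mm working resolution is ≤ 3–4%
at 3–10 mm source–detector separations (≈1% at 0.3 mm). The partial-current
(Robin) flux `φ/(2A)` is retained on the five remote faces, where the
fluence is negligible, and is available for the top face as
`boundary_model="robin"`. The two conventions are both standard in diffuse
optics; they differ by ~10% in absolute surface fluence, which is why the
package fixes one and validates against the matching closed form.

**Sources and detectors.** A collimated beam is represented as an isotropic
source buried one transport mean free path (`1/µ_s'`) below each illuminated
surface point, distributed trilinearly onto the enclosing nodes; extended
patterns are uniformly weighted point sets with the **total launched power
normalized to one** regardless of area, so point and line geometries are
photon-budget comparable. A detector reads `area × φ/(2A)` at its surface
points; its sensitivity field is the adjoint solve with that functional as
the right-hand side (the system is symmetric, so reciprocity is exact at the
discrete level). One sparse LU factorization per wavelength band is shared
by the excitation solve and all adjoint solves of a sweep; emission optics
default to the excitation values (the Raman shift stays in a spectrally
similar window), in which case the factorization is shared across bands too.
A conjugate-gradient mode (`method="cg"`, 1e-10 relative residual) avoids
the factorization cost for one-off solves on large grids.

**Raman yields.** Emission is treated in the Born (single-conversion)
approximation: each node emits isotropically in proportion to the excitation
fluence, so the detected yield of a material is
`n = Σ φ_x·φ_d·V` over that material's nodes. The micron-scale collagen
slab cannot be resolved by the 0.6 mm grid; its integral runs on a
cell-centred 0.08 mm sub-grid restricted to the slab, with both fields
interpolated trilinearly. Because the slab's optical properties match skin
and its volume is tiny, the FBR and day-0 samples share one field solution
and differ only in their emitting regions. The collagen yield is then linear
in `t` up to the slow depth decay of the field product (~8%/100 µm at the
cap depth under the default optics): zero-intercept R² ≈ 0.999 over
0–200 µm, and the two-to-one thickness ratio holds within 3% for
deep-sampling (large source–detector offset) geometries.

**Optical properties.** The source study does not publish its optical
properties. The shipped defaults are literature-style 785 nm values — skin
µ_a 0.02 / µ_s' 1.6 mm⁻¹ (n 1.4), fat 0.01/1.0 (1.44), muscle 0.03/0.7
(1.37), polystyrene 0.002/2.0 (1.59), collagen = skin — and are explicitly
assumptions: every geometry-level conclusion asserted by the test suite is a
symmetry, ranking or trend, never an absolute SNR value.

## The SNR objective and detection limit

The figure of merit is the shot-noise SNR of the collagen band
(910–950 cm⁻¹) in the difference between the FBR and day-0 measurements.
Per material, reference spectra supply `I_Raman` (band count after
subtracting a local linear baseline — the line through the mean counts of
3-channel windows centred on the band edges; width configurable) and `I_Raw`
(band count without subtraction). The signal is `n_FBR^coll · I_Raman^coll`;
the noise is the square root of the total band count of *both* samples
(differencing makes their shot noise additive). Detector areas combine with
additive signal and quadrature noise, so two symmetric rectangles gain
exactly √2 (6.7 → 9.5 in round numbers). With the collagen signal
proportional to `t`, the smallest detectable thickness at the one-sided 95%
criterion (standard-normal quantile 1.645) is
`t_LOD = 1.645 · t_ref / SNR(t_ref)` with `t_ref = 100 µm`; both the
criterion and the reference thickness are parameters. Display values round
to whole microns; raw doubles are kept internally. Re-simulating the phantom
at the predicted `t_LOD` returns an SNR within ~3% of 1.645, confirming the
linearity assumption is self-consistent.

## Geometry search

The search space follows the instrument constraints: simple shapes (points,
lines/rectangles, disks, circle outlines) inside the 10 × 10 mm² surface
area centred over the implant, source power density ≤ MPE on the true
illuminated area, and geometrically disjoint source and detector footprints
(checked with exact polygon predicates). Detector space is the 21 × 21 grid
at 0.5 mm pitch; point detectors are 0.1 × 0.1 mm² apertures sampled from
the adjoint field. `optimize` sweeps a preset family (centred point source
with its best point detector; the 10 × 2 mm modelled line — the built
instrument's Powell-lens line is 10 × 1.5 mm² — with single rectangles,
symmetric pairs at 0.5 mm offset steps, and the 7-fiber bundle footprint
spanning ±0.5 mm), flags MPE/disjointness violations, and ranks by SNR with
deterministic tie-breaks (smaller collection area, then name). Under the
defaults the point source is MPE-infeasible at 45 mW and the line source
with a symmetric rectangle pair is the feasible optimum, with the SNR
maximum at a nonzero radial offset from a centred point excitation — the
spatially-offset-Raman depth-bias effect.

## Spectral calibration

Measured spectra are min-max normalized on a window (default 990–1020 cm⁻¹)
around the polystyrene 1004 cm⁻¹ ring-breathing band, which removes
per-spectrum gain and lets the implant's own bands cancel in the
FBR − day-0 difference (residual < 0.5% of the collagen band area on
noise-free synthetic pairs). PLS regression maps full difference spectra to
thickness; channels are mean-centred but not variance-scaled (they share
units), and the component count is chosen by minimum leave-one-out RMSE up
to 8 components with ties broken toward fewer. The single-band route fits
band area against thickness by OLS and converts residual scatter to a
thickness limit as `t_LOD = criterion · RMSE_resid / |slope|`; because the
ratio RMSE/|slope| is itself sometimes quoted as a detection limit, the
criterion-1 variant is reported alongside. No outlier rejection is
performed.

## Synthetic data

The generator emulates the measurement campaign's statistical structure, not
any specific spectrometer. Reference spectra are sums of Gaussian/Lorentzian
bands at the materials' known positions (polystyrene 1004 cm⁻¹ dominant;
collagen 850/930 cm⁻¹ proline–hydroxyproline, amide III, 1450, amide I;
lipid CH₂ bands in skin and fat) on low-order polynomial backgrounds, on an
800–1800 cm⁻¹ axis at 2 cm⁻¹ steps. Composite measurements are yield-weighted
mixtures — exactly the linear model the SNR objective assumes — with
per-channel Poisson draws; detector read noise is omitted (the shot-noise
regime is the modelling assumption throughout). Mixture weights default to
skin 1.0, fat 0.5, muscle 0.2, polystyrene 0.3 and collagen 0.0025·t[µm],
chosen as a plausible mid-depth sampling balance; they can be taken from a
transport yield table instead. True relative Raman cross-sections are
unpublished, so all tests built on the generator are relative or structural.
Shot-noise calibration to a target SNR₁₀₀ is exact (SNR ∝ √count-scale).
Seeds derive from a master seed through a counter-based `SeedSequence`
hierarchy: datasets are byte-reproducible and extensible without
reshuffling, and every output's metadata records seed and generator version.

What passing these tests does *not* show about real data: the generator has
no fluorescence photobleaching, cosmic rays, wavenumber-calibration drift,
instrument line-shape or throughput variation, and its material spectra are
stylized; calibration RMSEs on real spectra depend on those effects and on
the true cross-sections.

## Problem sizes and numerical choices

The default solves use the 34³ grid (factorization a few seconds to tens of
seconds; each additional right-hand side milliseconds), the analytic-oracle
check a 51 × 51 × 26 grid via CG, and the calibration study 20 seeds of
16 spectra. Linear systems are solved to 1e-10 relative residual (CG) or by
direct LU; assembly order is deterministic and the pipeline contains no
randomness outside the generator. Degenerate inputs fail loudly: flat
normalization windows, zero band counts, all-equal responses, zero-area
patterns and infeasible candidate sets all raise descriptive errors rather
than returning numbers.

## Known limitations

- The diffusion approximation is least accurate within ~one transport mean
  free path of sources and boundaries; sub-millimetre offsets are outside
  the model's validity.
- Absolute SNR values are only meaningful relative to the assumed optical
  properties and reference-count scale.
- The Born treatment neglects re-absorption and re-emission of Raman
  photons and any emission-wavelength dependence of the optics (emission
  optics may be supplied separately when that matters).
- The geometry search sweeps a discrete preset family; it is not a
  continuous optimizer.
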
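# Methods

`monopet` simulates and analyses two long axial field-of-view (aFOV) PET
scanners built from monolithic LYSO detectors, and reproduces the complete
NEMA NU-2 (2018) performance chain on desk-scale hardware: sensitivity,
count rates / NECR / scatter fraction, spatial resolution, and image
quality, with list-mode MLEM and TOF-MLEM reconstruction.

## Scanner model

Both designs place 40 flat monolithic 50 × 50 × 16 mm³ LYSO slabs per ring,
tangent to a 70 cm bore; design A stacks 7 rings (aFOV 36.2 cm with 2 mm
ring gaps), design B stacks 14 (72.6 cm).  Flat slabs on a polygonal ring
leave small azimuthal gaps (40 × 50 mm = 2000 mm of crystal on a 2199 mm
circumference, a 91 % fill factor); rays through those gaps, through the
ring gaps, or past the axial ends are misses.  Photons enter a crystal
through its inner face only; the ≈2.6 % of interior rays that would clip a
slab through a side wall are treated as misses, and the absolute-efficiency
calibration below absorbs that choice.  The coordinate frame is
right-handed with z on the scanner axis and the origin at the axial and
transverse centre; lengths are in mm, times in ns, energies in keV,
activities in Bq.

Derived geometry: detector surface = n_modules × 50 × 50 mm²,
scintillator volume = surface × 16 mm, opening angle =
arctan(aFOV / bore diameter), rounded to the nearest degree for reporting
(27° and 46°).

## Photon Monte Carlo

The generator emulates what a full Geant4/GATE simulation provides to the
analysis: per-photon ground truth (decay identity, phantom scatter count,
deposited energy, timestamp, interaction position).

* **Decays** are a homogeneous Poisson process at the source activity;
  positions are uniform on the line / point / active phantom regions.
* **Emission**: in `back_to_back` mode two exactly antiparallel 511 keV
  photons.  In `f18` mode the annihilation point is displaced by an
  isotropic positron range drawn from a two-exponential approximation of
  the ¹⁸F range distribution in water (scales 0.2 / 1.2 mm, weights
  0.6 / 0.4 → mean 0.6 mm, sharply peaked at zero), and the pair deviates
  from 180° by a Gaussian acolinearity of 0.5° FWHM per transverse axis.
  Both are configurable and off in `back_to_back` mode.
* **Transport** through phantoms samples free paths from the exponential
  attenuation law through the piecewise-constant material layout
  (single-energy μ at 511 keV from the standard photon cross-section
  tables: water 9.58e-3 /mm, polyethylene 9.43e-3, glass 2.2e-2,
  lung-equivalent 0.3 × water).  At an interaction the photon is
  photoelectrically absorbed or Compton-scattered with an exact
  Klein–Nishina angle (rejection sampling); transport terminates below
  50 keV.  Rayleigh scattering, fluorescence and optical transport are out
  of scope.
* **Detection**: the interaction depth inside the 16 mm slab is drawn from
  the exponential law with μ(LYSO) = 0.087 /mm along the chord.  With
  probability `p_full` the photon deposits its full energy (photoelectric
  capture or Compton + reabsorption — large monolithic crystals recover
  most multi-interaction events); otherwise a single Klein–Nishina electron
  deposit is recorded and the scattered photon escapes.  Energy resolution
  is 11.5 % FWHM at 511 keV scaling as sqrt(511/E) (statistical
  scintillation model).  Timestamps add the time of flight and a Gaussian
  jitter of σ = CTR / (2.355·√2) per single so that true pairs show the
  200 ps coincidence time resolution.  The true 3-D interaction point is
  kept — monolithic detectors provide depth of interaction — and detector
  spatial resolution is applied later, on the LOR endpoints.

`p_full` is the one free knob of the detector model.  It was calibrated
once against the design-A centred-line sensitivity (29.2 kcps/MBq) and
frozen at 0.72 for every other study; the offset/centre and design-B/A
ratios are then genuine predictions (measured 0.91 and 3.5 against
published 0.92 and 3.66).

**Trues-only importance mode.**  Studies that analyse only unscattered
coincidences (the image-quality study reconstructs true counts only) can
run the engine in a trues-only mode: each photon is kept with the analytic
unscattered-escape probability exp(−∫μ dl) and every scattered or absorbed
history is dropped.  This is exact for the trues stream.  Per-module dead
time is not applied in this mode (at the IQ activity it is a < 3 % uniform
loss that cancels in the CRC and background-variability ratios), and
singles whose partner photon went undetected are pruned to bound memory.

## Coincidence processing

Energy window 440–650 keV (closed interval on the blurred energy), then
per-module paralysable dead time of 300 ns — an interaction is recorded iff
no arrival occurred on that module within τ, and every arrival extends the
dead period — then window pairing with |t₁ − t₂| ≤ 3 ns by chain
clustering, then ground-truth classification (same decay & no phantom
scatter → true; same decay & any scatter → scatter; different decays →
random).

Two defaults differ from a naive reading of the hardware chain and were
chosen deliberately (both remain configurable):

* **Dead time acts on energy-qualified singles** (`after_window`), the
  usual placement of the dead-time module in GATE digitizer chains.
  Applying it to every crystal interaction (`before_window`) would, at
  these singles rates, bend the trues curve by > 20 % already at 5 kBq/mL
  and push the NECR peak below 15 kBq/mL — both at odds with the published
  behaviour of these designs (trues linear to 5 kBq/mL, peak at 34).
* **Multiples policy `takeAllGoods`** (all distinct-module in-window pairs
  of a cluster), the common GATE PET-benchmark policy; `killAll` is
  available and documented as the stricter alternative.

## NEMA analyses

* **Sensitivity**: trues / (activity × time) for the 5 MBq, 70 cm
  back-to-back line source over 30 s, at the centre and at 10 cm radial
  offset, reported in kcps/MBq.  Axial profiles histogram true LOR
  midpoints in 1.65 mm bins.
* **Sinograms**: single-slice rebinning; radial bin 2 mm over ±350 mm, 180
  angle bins, 2 mm slices, no maximum ring difference (none is imposed for
  these designs).
* **Count rates**: the sinogram procedure zeroes bins beyond 120 mm from
  the centre, aligns each angular projection so its maximum is central,
  sums, and estimates the background under the source peak by linear
  interpolation between the profile values at ±20 mm plus everything
  outside the band.  Because the line source is axial, alignment shifts
  are computed on the slice-summed sinogram and shared across slices,
  which keeps the argmax stable at desk-scale statistics.  Headline
  T/S/R are the ground-truth labels of prompts inside the 120 mm mask
  (the analysis region the procedure defines); the profile-based estimate
  is reported alongside and agrees with the truth-based scatter fraction
  to well under 2 percentage points.  NECR = T²/(S+T+R), SF = S/(S+T).
* **Count-rate study**: the NEMA scatter phantom (203 mm polyethylene
  cylinder, 700 mm long, ¹⁸F line in a 6.4 mm channel at 45 mm offset) is
  simulated in short frames at the true activity of each concentration —
  dead time and randoms see the real rates — until the per-point prompt
  budget is met.  The concentration grid spans 0.045–50 kBq/mL with
  2 kBq/mL spacing near the reported peak; the peak is the grid argmax, no
  fitting.  Desk-scale defaults collect 4×10⁴ prompts per point and
  1.5×10⁵ on the flat top of the curve.

## Reconstruction

List-mode MLEM, x ← (x/s)·Σᵢ wᵢⱼ/(Σₖ wᵢₖ xₖ), with an exact
radiological-path (Siddon-style) projector and no resolution modelling
inside the reconstruction; detector blur lives only in the data, applied
once to the LOR endpoints as an isotropic 3-D Gaussian of 1.15 mm FWHM
(the midpoint of the 1.14/1.17 mm intrinsic resolution reported for this
detector), re-clamped into the crystal slab.  The sensitivity map s is
estimated per voxel by Monte Carlo integration of the pair-detection
probability over a common set of isotropic directions (product of the two
chord interaction probabilities, attenuated by the μ-map line integral
along the LOR); for large grids it is evaluated on a 2× coarser grid and
interpolated, the map being smooth on the centimetre scale.  TOF weighting
multiplies each voxel weight by a Gaussian centred on the annihilation
estimate from Δt with FWHM = c·CTR/2 ≈ 30 mm at 200 ps, truncated at
±3.5σ.  Initialisation is uniform over voxels with positive sensitivity;
updates preserve non-negativity and (without TOF) total counts
Σⱼ xⱼ sⱼ = N exactly.

* **Spatial resolution**: the ¹⁸F point source in its glass capillary
  (0.52/1.8 mm diameters, 0.9 mm height, as specified) at radii
  1/10/20 cm and axial stations 0 and 3/8 aFOV, reconstructed with
  non-TOF MLEM, 10 iterations, 0.5 mm voxels on a local 64³ grid centred
  on the source.  Sources sit on the +x axis so the grid axes are the
  radial/tangential/axial directions.  FWHM follows the NEMA profile
  method (parabolic peak fit, linear half-maximum crossings); its inherent
  discretisation bias at sub-2-voxel widths is quantified in the test
  suite.
* **Image quality**: the NEMA body phantom (torso outline of two
  half-circles joined by straight walls in a 300 × 230 mm envelope,
  180 mm interior length, 50 mm cold low-density lung insert, six hot
  spheres of 10–37 mm on a 114.4 mm circle; background 5.3 kBq/mL, sphere
  to background 4:1 or 8:1).  True counts only are reconstructed
  (TOF-MLEM, 20 iterations, 2 mm voxels) with attenuation correction from
  the voxelised μ-map; the 1.15 mm endpoint blur is applied here too — the
  detector's intrinsic resolution does not switch off between
  measurements, and omitting it would overstate small-sphere contrast
  recovery.  CRC = (C_H/C_B − 1)/(A_H/A_B − 1) and
  N_j = SD_j/C_B use one circular ROI per sphere on the sphere-centre
  slice and sixty background ROIs per size — twelve fixed template
  positions on each of the five slices at 0, ±1, ±2 cm.  The template
  keeps even the 37 mm ROI clear of every sphere, the lung and the wall;
  a voxel belongs to an ROI iff its centre falls inside the circle.

## Problem sizes

The shipped defaults are desk-scale: 10⁷ decays per sensitivity
measurement, ≈3×10⁷ decays for the scatter-fraction point, 3×10⁴–1.8×10⁵ prompts
per count-rate point, 10⁵ coincidences per resolution position,
and 0.8 % of the nominal 400 s image-quality acquisition (≈1.4×10⁸ decays,
≈1.9×10⁶ true coincidences).  At these sizes the stochastic targets carry
Monte Carlo error of roughly 1 % (sensitivity, SF), one to two grid steps
(NECR argmax on its flat top), ≈0.05 mm (FWHM) and several CRC points for
the smallest sphere.  The image-quality acquisition is the strongest
simplification: at 0.8 % of the nominal counts the background variability
is much higher than a full acquisition would give (it is reported as a
trend, not an absolute), while CRC, a ratio of means, stays centred.

## What the generator does and does not emulate

The generator reproduces the features the NEMA analyses are sensitive to:
solid-angle and attenuation geometry, Compton scatter energy/angle
statistics, energy blur, timing jitter, paralysable dead time and
activity-dependent randoms.  It does not model inter-crystal scatter,
Rayleigh scattering, Lu-176 intrinsic background, pile-up energy summing,
or positioning-algorithm artefacts near crystal edges; the single
calibrated `p_full` stands in for the net effect of intra-crystal physics
on detection efficiency.  Passing tests therefore validate the analysis
chain and the geometry/physics bookkeeping at the stated fidelity, not
detector microphysics.

## Known limitations

* The simulated NECR peak sits at ≈38–40 kBq/mL on a top that is flat to
  ≈1–2 % over 34–44 kBq/mL (published value: 34), with a peak NECR of
  ≈655 kcps for design A (published: 716).  The location estimate at
  desk-scale statistics can wander a grid step or two along the flat top.
  Both resolutions of the window-convention ambiguity were evaluated:
  reading the 3 ns figure as the full width of the Δt acceptance
  (|Δt| ≤ 1.5 ns) halves the randoms and pushes the simulated peak even
  later, so the |Δt| ≤ 3 ns reading is kept.
* Side-wall crystal entries and inter-module scatter are not modelled
  (absorbed into `p_full`).
* The capillary of the resolution source uses the stated 0.9 mm glass
  height verbatim even though it is smaller than its outer diameter.
* Scaled-down image-quality runs make the 10–13 mm sphere CRC noisy at the
  several-point level; the acceptance checks use the tolerance bands
  stated for reduced counts.
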
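# Methods

This note records the models, conventions, numerical choices and known
limitations behind `blufspec`, in the order the pipeline runs them.

## Vibronic model

**Normal modes.**  The Cartesian Hessian (hartree/bohr²) is
mass-weighted, H̃_ij = H_ij / √(m_i m_j) with masses in amu, and
diagonalized in the orthogonal complement of the rigid-body space.  The
rigid-body basis holds three translations plus rotations about each
principal axis whose moment of inertia exceeds 1e−6 amu·Å² — this rank
test decides linear (5 projected modes) versus nonlinear (6).  Because
rotational vectors require the geometry, `compute_modes` takes optional
coordinates; without them only translations are projected.  Eigenvalues
convert to wavenumbers through CODATA-2018 constants
(ω[cm⁻¹] = √(λ·E_h/(a₀²·u)) / 2πc); negative eigenvalues are reported as
negative (imaginary) wavenumbers.  Modes at or below a **10 cm⁻¹
low-frequency cutoff** are excluded from vibronic couplings, because the
vertical-gradient Huang–Rhys factor diverges as ω → 0.

**Carbonyl-stretch assignment.**  Band assignments such as "the C4=O4
stretch" are made by projecting each mass-weighted mode onto the
normalized bond-elongation coordinate of a chosen atom pair and taking
the mode of maximal |overlap| (score in [0, 1]; ties within 1e−6 go to
the lower frequency with a warning).  The overlap criterion is this
package's choice of assignment procedure; for a strongly localized
oscillator the score approaches 1.

**Vertical-gradient couplings.**  The excited-state gradient at the
ground-state minimum (hartree/bohr) is mass-weighted and projected on
each retained mode; S_j = g_j²/(2ħω_j³) evaluated in SI, λ_j = S_jħω_j,
λ = Σλ_j.  The model assumes displaced but undistorted harmonic surfaces:
no frequency changes, no Duschinsky rotation, no Herzberg–Teller terms.

**Spectral density and lineshape.**  J(ω) = π Σ_j S_j ω_j² B(ω − ω_j)
with a unit-area Gaussian (width = standard deviation) or Lorentzian
(width = HWHM) kernel on a grid covering [0, 1.2 ω_max] with spacing
width/8.  The discrete sticks are carried alongside the broadened grid,
and the cumulant lineshape g(t) is evaluated from the sticks by the
per-mode closed form (exact quadrature); trapezoidal integration over
the broadened grid is available for densities supplied without sticks.
The invariant λ = (ħ/π)∫J/ω dω holds between representations to better
than 1e−4 relative at the default kernel widths.

**Homogeneous spectrum.**  σ(E) ∝ Re ∫₀^{t_max} dt
e^{i(E−E_vert)t/ħ − g(t) − γt/ħ}, evaluated by trapezoidal quadrature on
a uniform time grid via a zero-padded FFT (padding refines the energy
sampling of the same quadrature sum; the result is interpolated onto the
requested grid, with the FFT resolution kept at least 4× finer than both
the grid step and γ).  Conventions: the first spectral moment equals
E_vert; the 0-0 line is at E_vert − λ; at T=0 a single mode gives the
Poisson progression e^{−S}S^n/n!.  No ω or ω³ intensity prefactor is
applied (spectra are shift/scale-aligned to a reference anyway); an
optional prefactor is deliberately out of scope of the default path.
Defaults: T = 300 K, Lorentzian damping γ = 1 meV, 2¹⁵ time points.
`auto_time_grid` extends t_max until the *suffix maximum* of the damped
envelope e^{−Re g − γt/ħ} falls below 1e−8 — single-mode envelopes
revive at every vibrational recurrence, so truncating at the first dip
would bias the transform — and refines the time step until the Fourier
window spans 8 eV.  The spectrum builder raises a truncation error when
the requested window captures less than 99.9% of the full-range area,
and rejects windows beyond the Fourier range instead of extrapolating.
Note that a Lorentzian γ ≳ the energy-grid step undersamples the peaks:
sampled moments are then only accurate to a few grid steps.

## Ensemble broadening and alignment

S1 is the lowest state of each frame; the second bright state S2′ is the
non-S1 state with the largest oscillator strength, selected per frame
because the strength migrates between adiabatic states with geometry.
The inhomogeneous spectrum is the equal-weight average of the
homogeneous line displaced by each frame's vertical energy relative to
the line's own E_vert; the displacement is applied exactly in Fourier
space on the line's uniform grid, so the area is conserved to machine
precision and the output first moment equals the ensemble mean energy.
Frames are *not* weighted by oscillator strength by default (an option
exists): the broadening is a convolution with the energy distribution
alone.  S1 and S2′ bands are broadened separately and summed before
alignment.

"First maximum" is operationalized as the lowest-energy local maximum
above 5% of the global maximum after resampling on a 1 meV grid.  One
shift and one scale, determined on the designated subject/reference
pair, are applied to all spectra, so between-state peak offsets are
invariant under alignment.

## Ensemble statistics

Percentile bootstrap (not BCa), default n_boot = 2000, resampling frames
as i.i.d. draws; intervals are the (2.5, 97.5) percentiles of the
resampled means, and the difference CI resamples the two series
independently.  i.i.d. resampling ignores serial correlation of MD
frames and therefore tends to understate uncertainty on correlated
series; a circular block bootstrap with configurable block length is
provided for that case.  At n = 200 the percentile interval mildly
undercovers (~93–95% empirical coverage against the nominal 95%), the
known small-sample behavior of this bootstrap flavor.  The
multimodality report counts local maxima of a Gaussian KDE (Scott's rule
by default; pass a bandwidth of about half the smallest expected
component separation to probe a known scale).

## Structural metrics

Hydrogen bonds: donor–acceptor distance ≤ 3.2 Å AND angle ≥ 135°,
evaluated per frame.  The angle vertex is the hydrogen (D–H···A), the
convention that standardly pairs with exactly these cutoff values; the
vertex is configurable because the cutoff pair is also quoted with an
acceptor-vertex phrasing in the literature.  Helix axes run from the
centroid of 4 consecutive starting Cα atoms to the centroid of 4 ending
ones; the interhelical angle is reported unsigned in [0°, 180°] with no
axis canonicalization beyond N→C residue order.  The β-sheet dihedral is
the standard signed torsion of four ordered Cα atoms, range (−180°, 180°].
Backbone RMSD uses least-squares (Kabsch) superposition via
`scipy.spatial.transform.Rotation.align_vectors`, with residuals
recomputed explicitly after rotation (the solver's reported residual
loses precision to cancellation near zero); "flexible parts" are
excluded through a configurable list of residue ranges, since no
canonical span list exists.  Residues are addressed by 1-based PDB
numbers.  Where a ring–atom distance is needed, the ring is represented
by its centroid (exposed as an option).

## Synthetic fixtures

The generators emulate the statistical structure of the study inputs at
toy scale; all are driven by one explicit seed each, with no global RNG
state.

* **Energy ensembles.**  Four excited states per frame, 200 frames per
  protein state, Gaussian energies with dark means (3.20, 3.60, 3.95,
  3.97) eV and light means red-shifted by (0.07, 0.05, 0.05, 0.05) eV;
  per-frame standard deviations 0.05 eV (S1) and 0.07 eV (upper states)
  are back-derived from published bootstrap 95% CIs at the reported
  frame counts (sd ≈ halfwidth/1.96·√n).  Oscillator strengths make S1
  bright (~0.25), the second state dark, and exactly one of the two top
  states bright (~0.15) per frame via a fair seeded coin — reproducing
  the S3/S4 strength alternation that motivates per-frame S2′
  selection.  Dark/light pairs share their Gaussian draws by default
  (common random numbers), so the configured mean offset is carried
  exactly by the samples; this isolates shift-recovery checks from √n
  sampling noise and is the one statistical idealization the fixtures
  make beyond Gaussianity.  Equal dark/light frame counts are used so
  that pairing is possible.
* **Scalar observables.**  Chemical-shift and carbonyl-frequency series
  use the published calculated means (11.6/11.9 ppm, 1753/1727 cm⁻¹)
  with sds back-derived the same way at n = 100 (dark) and 200 (light).
* **Toy Hessians.**  Harmonic bond-spring networks: each bond adds
  k·êêᵀ blocks, so the Hessian is symmetric and translationally
  invariant by construction, and small systems have closed-form
  frequencies.  Pure two-body springs carry no bending stiffness, so
  chain fixtures have additional zero modes — harmless below the
  low-frequency cutoff.
* **Trajectories.**  The H-bond triad places bonded frames 0.3 Å / 45°
  inside the cutoffs and broken frames ≥ 0.2 Å / 10° outside (margins
  avoid floating-point boundary sensitivity), with exactly
  round(fraction × n_frames) bonded frames in seeded random order and an
  optional per-frame rigid motion.  Helix pairs are canonical α-helix
  Cα traces (rise 1.5 Å/residue, 100° twist, radius 2.3 Å), 22 residues
  long so the two 4-residue windows sit 18 residues (= 5 full turns)
  apart and the centroid-difference axis reproduces the requested angle
  exactly.  Sheet quadruples realize a prescribed torsion by the
  standard construction.  Where the source study prints no value
  (occupancies, angles, dihedral magnitudes), the pipeline defaults
  (0.85/0.37, 25°/30°, 12°/20° for dark/light) are illustrative choices
  fixed once to give a visible dark–light contrast.

What the fixtures do **not** emulate: real electronic-structure noise
(non-Gaussian tails, state crossings), serial correlation of MD frames,
anharmonicity, and real protein topology beyond what the metric
definitions require.  Passing tests therefore validate the analysis
machinery — conventions, conservation laws, statistical calibration —
not the physics of any particular protein.

## Pipeline and determinism

The pipeline seeds every stage from one root seed through
`numpy.random.SeedSequence` spawning (string-keyed streams use CRC32,
not Python's salted `hash`).  All outputs are CSV/JSON/plain text with
fixed float formatting and no timestamps, so identical seeds give
byte-identical bundles.  The synthetic "experimental" reference for the
alignment stage is the computed dark spectrum displaced by −0.35 eV and
scaled by 0.9, making the recovered alignment parameters known by
construction.  Problem sizes throughout (200–2000 frames, 2¹⁵–2¹⁷ time
points, n_boot = 2000, 500 bootstrap-calibration replications) keep a
full run within seconds on one CPU while leaving Monte-Carlo errors well
inside the tested tolerances.

## Known limitations

* Vertical-gradient model only: no adiabatic-Hessian, emission, or
  interstate vibronic coupling; intensity prefactors are not applied.
* The broadening temperature, kernel width and damping of any published
  figure are generally unstated; the defaults here are package choices.
* Percentile-bootstrap undercoverage at small n (see above).
* PDB support is deliberately minimal (fixed-width ATOM/HETATM, no
  insertion codes, no altLocs); binary MD formats and QM-log parsing are
  out of scope and documented as extension points.
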
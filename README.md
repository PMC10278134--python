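# blufspec

Post-processing toolkit for dark-vs-light comparisons of BLUF
photoreceptor domains (blue-light-using-flavin modules such as the AppA
BLUF domain).  BLUF domains signal without any chemical change of their
flavin chromophore: photoactivation rearranges the hydrogen-bond network
around the isoalloxazine ring — via tautomerization of a conserved
glutamine — and the evidence for the light-induced structure is written
in small spectral shifts (UV–vis band positions, the C4=O4 carbonyl
stretch, NMR chemical shifts) and subtle geometry changes.  `blufspec`
implements the analysis layer that turns electronic-structure and MD
outputs into those observables:

* **Vibronic absorption lineshapes.**  From a ground-state Hessian and
  an excited-state gradient it computes per-mode Huang–Rhys factors
  S_j = g_j² / (2ħω_j³) (vertical-gradient approximation), the spectral
  density J(ω) = π Σ_j S_j ω_j² δ(ω − ω_j), the second-order cumulant
  lineshape function

  g(t) = (1/π) ∫₀^∞ dω J(ω)/ω² [coth(ħω/2k_BT)(1 − cos ωt) + i(sin ωt − ωt)],

  and the homogeneous spectrum σ(E) ∝ Re ∫₀^∞ dt e^{i(E−E_vert)t/ħ − g(t) − γt}.
  The first spectral moment sits at the vertical energy and the 0-0 line
  at E_vert − λ with λ = Σ_j S_j ħω_j.
* **Inhomogeneous broadening and alignment.**  Per-MD-frame vertical
  excitation energies (with per-frame identification of the second
  bright state S2′ as the upper state of maximal oscillator strength)
  broaden the homogeneous line by convolution; computed spectra are
  matched to a reference with a single shift/scale pair determined on
  the first absorption maximum.
* **Ensemble statistics.**  Frame averages with percentile-bootstrap 95%
  confidence intervals (optionally block bootstrap for correlated
  series), dark-minus-light difference CIs, and a kernel-density
  multimodality report.
* **Trajectory structural metrics.**  Hydrogen-bond occupancy (3.2 Å
  donor–acceptor / 135° angle cutoffs), the interhelical angle from
  4+4 Cα terminal windows per helix, the β-sheet four-Cα signed
  dihedral, and backbone RMSD after least-squares superposition.
* **Synthetic fixtures.**  Seeded generators for toy Hessians/gradients
  with analytic spectra, Gaussian dark/light excitation-energy ensembles
  with a controlled mean offset, and trajectories with exactly known
  H-bond fractions and helix/sheet geometries — every stage can be
  validated against its construction.

## Worked example

The `run` subcommand executes the whole synthetic pipeline — ensembles,
vibronic model, broadening, alignment, bootstrap statistics, geometry
metrics — from one seed and prints the summary:

```sh
$ blufspec run --seed 1 --out-dir demo
dark-vs-light summary (all quantities light minus dark)

seed: 1
reorganization energy (toy chromophore): 0.158832 eV
alignment shift: -0.350000 eV, scale: 0.900000
absorption first-maximum shift: -0.070000 eV
S1 vertical-energy shift: -0.070000 eV
S2' vertical-energy shift: -0.051897 eV
FMN_H3_shift_ppm difference: 0.293348
C4O4_freq_cm1 difference: -24.280802
H-bond occupancy: dark 0.850000, light 0.370000
interhelical angle (deg): dark 24.999429, light 30.016945
sheet dihedral (deg): dark 11.997061, light 19.972063
```

Reading the output: the configured dark→light red-shift of the S1 band
(−0.07 eV) is recovered exactly by the first maxima of the aligned
absorption spectra; the alignment stage recovered the −0.35 eV / 0.9
shift/scale pair that relates the computed dark spectrum to its
reference; the chemical-shift and carbonyl-frequency differences
(+0.29 ppm, −24 cm⁻¹) are bootstrap means over the generated frame
series; and the structural block reports the H-bond occupancies and
helix/sheet coordinates of the two states.  `demo/` holds the full
bundle: per-state spectra, observables with 95% CIs, metric
distributions and `summary.txt`.

Other subcommands expose the stages individually
(`simulate-fixtures`, `modes`, `spectrum`, `ensemble`, `stats`,
`hbond`, `geometry`); the same functionality is importable from
`blufspec` as a library.

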
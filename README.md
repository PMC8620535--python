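# vibspec

Post-processing toolkit for anharmonic vibrational spectroscopy of
molecular solids: it turns calculated transition lists into assignable
MIR/NIR spectra and quantifies how much of a spectral region comes from
fundamentals versus first overtones and binary combination bands.

The package is aimed at spectroscopists who run harmonic (periodic DFT) or
anharmonic (second-order vibrational perturbation theory, VPT2) frequency
calculations and need the downstream steps: classification, band-shape
synthesis, frequency scaling, ATR correction, regional intensity
decomposition and experimental-to-calculated band assignment.  A
synthetic-study generator with recorded ground truth makes every stage
testable without any quantum-chemistry output.

## The model

A transition exciting mode *i* by *v<sub>i</sub>* quanta has position
(cm⁻¹) given by the second-order vibrational energy expression

```
E(v) − E(0),   E(v) = Σᵢ ωᵢ(vᵢ + ½) + Σ_{i≤j} χᵢⱼ(vᵢ + ½)(vⱼ + ½)
```

with harmonic wavenumbers ωᵢ and anharmonicity constants χᵢⱼ.  Transitions
are classified by their quanta: one mode × 1 → **fundamental**, one mode
× 2 → **first overtone**, two modes × 1 each → **binary combination**
(everything beyond is `higher_order`).  Two exact identities follow and are
used as invariants throughout: the overtone sits 2χᵢᵢ away from twice its
fundamental, and a combination sits χᵢⱼ away from the sum of its two
fundamentals.

Discrete transitions are broadened with a Gauss–Lorentz **product** profile

```
f(ν) = h · exp(−4 ln2 ((ν−ν₀)/Γ_G)²) · [1 + 4((ν−ν₀)/Γ_L)²]⁻¹
```

whose amplitude *h* is chosen so the band area equals the calculated
intensity (area-proportional mode) — integral intensities then survive
broadening, and per-class regional fractions are independent of the width
parameters.  Calculated positions are calibrated with wavenumber linear
scaling (WLS), ν → ν·(a + b·ν), usually with the intercept fixed at one;
ATR spectra are corrected for the ν⁻¹ penetration depth of the evanescent
wave.  Peak matching offers nearest-first (`greedy`), optimal bipartite
(`optimal`) and spectral-order (`ordered`) strategies; the ordered
alignment is what reproduces published assignment tables when the
calculated positions carry a systematic shift.

## Worked example

The package bundles transcriptions of four published assignment tables for
crystalline menadione (vitamin K₃, 2-methyl-1,4-naphthoquinone).
Decomposing the C–H stretching region of the anharmonic table
(`examples/04_region_decomposition.py`):

```
CH-region table: 20 calculated transitions between 2817 and 3376 cm-1

Integrated-intensity shares in 3600-2600 cm-1 (broadened, trapezoid):
  fundamental          45.8 %
  binary_combination   42.5 %
  first_overtone       11.7 %
```

The rows flagged as fundamentals carry only 45.8% of this table's printed
intensity (exactly 237.4/518.6): overtone and combination bands shape most
of the C–H stretching envelope, which is why harmonic-only spectra fail to
reproduce this region.  Matching the table's experimental and calculated
position columns in spectral order reproduces every printed signed
difference exactly (`examples/05_assignment_tables.py`), e.g. the 1664 cm⁻¹
ring/C=O band at −28 cm⁻¹ against one harmonic method and −1 cm⁻¹ against
the other.

Running the pipeline blind on a synthetic study
(`examples/06_synthetic_study.py`, seed 7) recovers the ground-truth WLS
slope of −8×10⁻⁶ per cm⁻¹ with 0.03% relative error and assigns 99.3% of
picked peaks to their true generating transition.

Each script in `examples/` is a short narrative for one capability; the
`vibspec` command exposes the same steps as subcommands (`simulate`,
`scale`, `synth`, `decompose`, `assign`, `map`).

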
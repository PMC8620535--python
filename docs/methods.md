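# Methods

## Transition arithmetic

Positions come from the textbook second-order vibrational energy
expression, `E(v) = Σᵢ ωᵢ(vᵢ+½) + Σ_{i≤j} χᵢⱼ(vᵢ+½)(vⱼ+½)`, evaluated as
`E(v) − E(0)`.  No Fermi-resonance deperturbation or variational
correction is applied: anharmonic engines handle resonances internally and
export effective constants or final positions, and this package consumes
their output as given.  Quanta are stored sparsely (only excited modes),
so ledgers stay compact at large mode counts.  `build_transition_ledger`
enumerates fundamentals, first overtones and binary combinations only —
`higher_order` transitions are representable (and classified) but never
enumerated, because ternary and higher combinations are orders of
magnitude weaker and are not tabulated in assignment work at this level.
Intensities are injected through a rule (constant, per-class decay, or any
callable) since computing them belongs to the electronic-structure side.

Exact consequences of the energy expression are used as invariants:
overtone deviation from twice the fundamental equals 2χᵢᵢ; combination
deviation from the sum of its fundamentals equals χᵢⱼ.  Both hold to
better than 1e-9 cm⁻¹ over random (ω, χ) draws.

## Band shapes

Bands are Gauss–Lorentz *products*, not Voigt convolutions: the product
form is the common choice for compact solid-state band synthesis, and its
factor widths Γ_G, Γ_L are the two tunable parameters (FWHM of each
factor, cm⁻¹).  Defaults are Γ_G = Γ_L = 8 for MIR and 16 for NIR — chosen
once to resemble sharp crystalline bands at 2 and 4 cm⁻¹ instrument
resolution; a single global width serves all bands of a spectrum.  The
default normalization is area-proportional because regional
decompositions are *integral* intensity shares: areas, not amplitudes,
must carry the calculated intensities.  The unit-amplitude area has an
exact special-function form, `(π/√b)·erfcx(√(a/b))` with `a = 4 ln2/Γ_G²`,
`b = 4/Γ_L²`, evaluated with `scipy.special.erfcx`; tests check it against
independent numerical quadrature, so the closed form and the numeric
route verify each other.  Amplitude-proportional mode is available for
display work.  Grids are stored ascending; renderers may flip the axis for
the conventional descending display.

Contribution maps assign each transition's full profile to every mode its
quanta involve, so a binary combination appears in both participating
rows.  The double counting is intentional — the map answers "which modes
shape this interval", not "how is intensity partitioned".

## Calibration

WLS models the calculated-to-observed scale factor as a line in
wavenumber, ν_scaled = ν·(a + b·ν); single-parameter mode fixes a = 1.
The fit minimizes residuals in wavenumber (observed − scaled calculated),
the quantity assignment tables report, rather than in the ratio.  A slope
of −8×10⁻⁶ per cm⁻¹ (scale factor 0.976 at 3000 cm⁻¹) is typical of the
tens-of-cm⁻¹ overestimation of harmonic DFT positions and is the
synthetic generator's default.

When assignments are unknown, fitting b from blind peak lists is a
chicken-and-egg problem: near 3000 cm⁻¹ the uncalibrated shift exceeds
the local band spacing, so nearest-first matching locks onto wrong
partners and biases b towards zero.  `calibrate_wls_slope` therefore
scores a coarse grid of trial slopes by consensus (how many rescaled
reference positions land within 5 cm⁻¹ of a picked peak) and refines the
winner with two rounds of tight greedy matching plus least squares.  On
the default synthetic conditions this recovers b to ~0.05% relative.

ATR correction uses the thin penetration-depth model,
`d_p = 1/(2πν·n₁·√(sin²θ − (n₂/n₁)²))`: absorbance is multiplied by ν and
rescaled to the original maximum.  Extended (Kramers–Kronig) ATR
correction is out of scope — it needs the full complex refractive index,
not just the two scalar indices and the angle.  The correction is not
idempotent, so corrected spectra carry an `atr_corrected` metadata flag
and a second application raises unless forced.  The `diamond-45` preset
(n₁ = 2.4, θ = 45°, n₂ = 1.5) covers the common single-reflection
diamond-IRE geometry.

## Regional decomposition

`integrate_class_fractions` synthesizes each class's sub-spectrum on an
internal grid (step = min width / 8) and integrates over the window with
the trapezoid rule; a `sum` mode adds raw intensities of transitions
inside the window instead.  For windows that enclose every band the two
agree to ~1e-6 and the broadened fractions are width-invariant — a tested
property, not an assumption.  Bands straddling a window edge contribute
their enclosed tail only in broadened mode; that is the physically
meaningful reading and the only source of (small) disagreement between
the two modes.  An empty window yields total 0 with fractions flagged
undefined rather than NaNs.

## Peak matching

Three strategies, one contract: each experimental feature gets at most one
calculated feature and vice versa, differences are always exp − calc, and
unmatched items are reported.

* `greedy` (default): nearest-first within tolerance; transparent,
  order-stable (candidate ties broken on positions, inputs effectively
  sorted).
* `optimal`: maximum-cardinality minimum-total-|difference| bipartite
  assignment (Hungarian solver); exhaustive enumeration on ≤6×6 problems
  is the test oracle, and greedy provably equals the optimum when peaks
  are separated by more than twice the tolerance.
* `ordered`: order-preserving alignment of band features as given
  (assignment tables run monotonically in wavenumber), maximizing matches
  then minimizing total |difference|.  Cost ties are broken towards
  negative differences — when two alignments explain the data equally
  well, the one keeping calculated positions above experimental ones is
  preferred, consistent with systematic harmonic overestimation.

Nearest-first pairing is *not* what published assignment tables encode:
wherever the systematic calculated-position shift exceeds the local band
spacing (the fingerprint ring modes, the 2650–2550 cm⁻¹ stretch of
combination bands), tables pair bands in spectral order and nearest-first
cross-pairs them.  The ordered strategy exists for exactly this case and
is the one that reproduces every printed signed difference of the bundled
tables.

A *feature* may group several positions: an unresolved experimental
doublet ("3075; 3070"), or two calculated transitions under one
experimental envelope ("2009; 1997").  The grouping is data the tables
themselves carry and is preserved by the transcriptions.  A matched pair
of features expands pairwise when the groups have equal size, otherwise as
a cross product (one-to-many sharing).

The default tolerances — 40 cm⁻¹ up to 2600 cm⁻¹, 65 cm⁻¹ above — bracket
the largest credible harmonic/anharmonic deviations in each range (printed
differences reach 39 and 59 cm⁻¹ respectively).  The vs/s/m/w/vw strength
labels are standard; their numeric cutoffs (0.75/0.50/0.25/0.05 of the
spectrum maximum) are this package's configuration values, as the
convention defines the labels but not thresholds.

The bundled CH-region table flags five calculated rows as fundamentals
(the ν CH and CH₃ stretches at 3037, 3003, 2984, 2942, 2934 cm⁻¹).  The
overlapped 3063 cm⁻¹ feature carries a dual assignment (νCH and a
CH₃-bend combination) but is not flagged; the transcription keeps it as a
single non-fundamental transition, consistent with the printed intensity
partition (fundamental rows sum to 237.4 of 518.6).

## Synthetic studies

The generator emulates what a mid-size aromatic ketone hands the
pipeline.  Defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| mode census | 8 / 3 / 20 | CH/CH₃ stretches, ring/C=O, bends (δ and γ alternate) |
| ranges (cm⁻¹) | 2950–3200, 1600–1750, 1000–1600, 400–1000 | per class, stratified draws |
| χ diagonal | −30·U(0.7, 1.3) | stretches; other modes 30% of it |
| χ off-diagonal | U(−3, 3) | symmetrized exactly |
| intensities | lognormal, median 50 | fundamentals; ×0.02 overtones, ×0.05 combinations |
| WLS slope b | −8×10⁻⁶ cm | applied to band centers, the recoverable distortion |
| noise | 0.5% of max | additive Gaussian |
| baseline | 0.02 + 1×10⁻⁶·ν | relative to max |
| grid | 400–7000, step 1 | cm⁻¹ |

Stratified placement (one draw per equal slot, ±10% jitter) keeps
same-class fundamentals at least 0.8 slot widths apart, so fundamental
bands are resolvable at the default width; the derived
overtone/combination forest overlaps freely, as real NIR spectra do.
Ground-truth class fractions are recorded from intensity sums (exact);
their equivalence with broadened integrals is itself a tested property.
Every generator is bit-reproducible from (config, seed); sub-seeds are
spawned with `numpy.random.SeedSequence`.

What the generator does *not* emulate: resonance-perturbed positions,
non-Gaussian noise, instrument line-shape effects, multiplicative scatter,
temperature dependence.  Passing recovery tests therefore demonstrates
the pipeline's correctness under clean additive conditions, not robustness
to those artefacts.

Problem sizes used in tests and the acceptance script: 20 independent
seeds for the recovery statistics (median slope error, class-fraction
error, assignment recovery), 100 random draws for the energy identities,
an 80001-point grid for area conservation — sizes at which the sampling
spread of each statistic is far below its acceptance margin.

## Numerical and design choices

* Unicode minus is accepted everywhere on read; writers emit ASCII hyphens
  unless typographic fidelity is requested.
* JCAMP-DX support covers XYDATA (X++(Y..Y)) in AFFN and PAC forms and
  XYPOINTS (XY..XY) for non-uniform grids, written at full double
  precision (round-trips to 1e-9).  The reader/writer is deliberately
  minimal and self-contained.
* Peak apexes are refined by parabolic interpolation of the three-point
  maximum; on blended bands the apex is pulled by neighbours, which is the
  dominant error source in slope calibration (hence the consensus fit).
* Published-table transcriptions treat printed positions as given and
  report differences as printed; whether the printed calculated columns
  are pre- or post-scaling is not stated in the source tables, so no
  rescaling is applied to them.

## Limitations

* Voigt (convolution) profiles and asymmetric band shapes are not
  provided; neither is deconvolution (fitting band parameters to
  experimental spectra).
* The class decomposition of a *measured* spectrum requires a calculated
  ledger; the package never infers transition classes from experimental
  data alone.
* Quantitative headline fractions for a real compound are only as complete
  as the transition list supplied: truncated tables (printed assignment
  tables drop weak bands) yield fractions for the tabulated set, not for
  the full calculation.
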
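"""Broaden a transition ledger into a continuous spectrum.

Each transition becomes a Gauss-Lorentz product band whose integrated area
equals its calculated intensity, so regional integrals stay meaningful.
The result is written to JCAMP-DX.
"""

import numpy as np

from vibspec import (
    AnharmonicConstants,
    LineShapeParams,
    ModeBasis,
    build_transition_ledger,
    class_decay_intensity,
    synthesize_spectrum,
    write_spectrum,
)

modes = ModeBasis.from_wavenumbers([700.0, 1650.0, 3050.0],
                                   ["gammaCH", "deltaring", "nuCH"])
chi = AnharmonicConstants([[-8.0, 1.5, -2.0], [1.5, -10.0, 0.5], [-2.0, 0.5, -32.0]])
ledger = build_transition_ledger(modes, chi, class_decay_intensity(10.0))

params = LineShapeParams(fwhm_gauss=8.0, fwhm_lorentz=8.0)  # MIR defaults
grid = np.arange(400.0, 7000.0, 1.0)
spectrum = synthesize_spectrum(ledger, params, grid)

total = np.trapezoid(spectrum.values, grid)
print(f"Synthesized {len(ledger)} bands on a {grid.size}-point grid.")
print(f"Integrated spectrum: {total:.4f}; summed intensities: {ledger.intensities.sum():.4f}")
print("(equal because area-proportional broadening conserves intensity)")

fundamentals_only = synthesize_spectrum(ledger, params, grid, class_filter=["fundamental"])
print(f"Fundamentals alone carry {np.trapezoid(fundamentals_only.values, grid) / total:.1%} "
      "of the integrated intensity.")

write_spectrum(spectrum, "synthetic_mir.jdx")
print("Wrote synthetic_mir.jdx (JCAMP-DX, wavenumber ascending).")
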
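"""Classify vibrational transitions and compute anharmonic positions.

Builds a three-mode toy molecule, evaluates second-order (VPT2-style)
transition positions from harmonic wavenumbers and anharmonicity constants,
and enumerates the full ledger of fundamentals, first overtones and binary
combinations.
"""

from vibspec import (
    AnharmonicConstants,
    ModeBasis,
    build_transition_ledger,
    class_decay_intensity,
    classify_transition,
    vpt2_transition_position,
)

modes = ModeBasis.from_wavenumbers([700.0, 1650.0, 3050.0],
                                   ["gammaCH", "deltaring", "nuCH"])
chi = AnharmonicConstants([
    [-8.0, 1.5, -2.0],
    [1.5, -10.0, 0.5],
    [-2.0, 0.5, -32.0],
])

print("Excitation {2: 1} is a", classify_transition({2: 1}).value)
print("Excitation {2: 2} is a", classify_transition({2: 2}).value)
print("Excitation {1: 1, 2: 1} is a", classify_transition({1: 1, 2: 1}).value)

fund = vpt2_transition_position(modes, chi, {2: 1})
overtone = vpt2_transition_position(modes, chi, {2: 2})
print(f"\nnuCH fundamental: {fund:.2f} cm-1 (harmonic 3050; the anharmonic")
print("shift comes from 2*chi_ii plus half the cross-constants row)")
print(f"nuCH first overtone: {overtone:.2f} cm-1; its deviation from twice")
print(f"the fundamental, {overtone - 2 * fund:+.2f} cm-1, equals 2*chi_ii = {2 * (-32.0):+.1f}")

ledger = build_transition_ledger(modes, chi, class_decay_intensity(10.0))
print(f"\nFull ledger up to binary combinations: {len(ledger)} transitions")
for t in ledger:
    print(f"  {t.position:8.2f} cm-1  {t.intensity:6.2f}  {t.transition_class.value:<19}  {t.label}")
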
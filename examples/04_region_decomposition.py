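"""Decompose regional integrated intensity by transition class.

Uses the bundled CH-stretching-region table of crystalline menadione
(2-methyl-1,4-naphthoquinone): the rows flagged as fundamentals carry only
part of the region's intensity, the rest being first overtones and binary
combinations - the reason harmonic-only calculations fail to reproduce
this region.
"""

from vibspec import LineShapeParams, integrate_class_fractions
from vibspec import datasets

ledger = datasets.table_ledger("ch_region")
print(f"CH-region table: {len(ledger)} calculated transitions between "
      f"{ledger.positions.min():.0f} and {ledger.positions.max():.0f} cm-1")

report = integrate_class_fractions(ledger, LineShapeParams(8.0, 8.0), (2600.0, 3600.0))
print("\nIntegrated-intensity shares in 3600-2600 cm-1 (broadened, trapezoid):")
for cls, fraction in sorted(report.fractions.items(), key=lambda kv: -kv[1]):
    if fraction > 0:
        print(f"  {cls:<19} {100 * fraction:5.1f} %")
print(f"\nFundamentals carry {100 * report.fractions['fundamental']:.1f}% of this "
      "table's intensity; the remainder comes from overtone and combination "
      "bands overlapping the C-H stretching envelope.")
print("(The share is width-invariant: the same numbers appear for any "
      "band width because areas, not amplitudes, carry the intensities.)")
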
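"""Match experimental bands to calculated transitions and tabulate.

Rebuilds the fingerprint-region assignment table of crystalline menadione
from the transcribed experimental and calculated position columns.  Bands
are aligned in spectral order ("ordered" strategy), which reproduces every
printed signed difference; nearest-first pairing would cross-pair wherever
the systematic harmonic overestimation exceeds the local band spacing.
"""

from vibspec import assignment_table, format_assignment_table, match_peaks
from vibspec import datasets

inputs = datasets.table_match_inputs("fingerprint", method="gatti")
result = match_peaks(inputs["exp"], inputs["calc"],
                     tolerance=inputs["tolerance"], strategy="ordered")

print(f"Matched {len(result.records)} experimental bands "
      f"(tolerance {inputs['tolerance']:.0f} cm-1).")
reproduced = sum(1 for r, e in zip(result.records, inputs["expected_differences"])
                 if round(r.difference) == e)
print(f"Signed differences reproduced exactly: {reproduced}/{len(inputs['expected_differences'])}")

table = assignment_table(result.records)
print("\nFirst rows (calculated intensities renormalized to 100 at the maximum):")
print(format_assignment_table(table.head(8)))
print("\nNegative differences mean the harmonic calculation overestimates "
      "the band position, which the WLS scale factor corrects.")
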
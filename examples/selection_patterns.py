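"""Selection-pattern statistics for the packaged marker sets.

For each marker set's direction counts, compute the drift confidence
(acceptance probability of "TBP-site-damaging variants dominate") and the
exact one-sided equivalence tail for the atherogenesis directions, rendered
with the summary table's display conventions.
"""

from tatashift import datasets
from tatashift.patterns import build_pattern_table

counts = datasets.load_table1_reference()
table = build_pattern_table(counts)
cols = ["set", "n_gt", "n_lt", "drift_display", "n_up", "n_dn", "equivalence_display"]
print(table[cols].to_string(index=False))
print(
    "\nDrift ~0.50 for the neighbourhood set means no damaging/improving "
    "asymmetry there, while its equivalence tail <0.01 shows accelerating "
    "markers dominate; the mitochondrial and miRNA sets invert both patterns."
)
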
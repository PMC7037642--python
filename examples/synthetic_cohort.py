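"""Simulate a promoter-SNP cohort with known truth and recover the drift.

Generates 300 SNPs on 70 bp promoters with a planted TATA-like site, where
only 20% of minors raise TBP affinity, then checks that the drift statistic
flags the damaging excess.
"""

from tatashift import datasets
from tatashift.cohort import CohortSpec, simulate_snp_cohort
from tatashift.patterns import drift_confidence, format_probability

params = datasets.default_params()
spec = CohortSpec(n_snps=300, prop_affinity_up=0.2, in_site_fraction=0.5, seed=7)
cohort = simulate_snp_cohort(spec, params)

dirs = [t.direction for _, t in cohort]
ups, downs, equal = dirs.count("up"), dirs.count("down"), dirs.count("equal")
conf = drift_confidence(ups, downs)
print(f"affinity up / down / unchanged: {ups} / {downs} / {equal}")
print(f"drift confidence: {conf:.6f}  (displayed {format_probability(conf)})")
print(
    "\nWith 4 damaging variants per improving one, the binomial drift "
    "statistic is essentially certain that damaging variants dominate, "
    "matching the genome-wide neutral-drift pattern the statistic targets."
)
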
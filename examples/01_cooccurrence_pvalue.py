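"""Score one contig pair from its chamber presence patterns.

Two contigs from the same genome ride along with the same cells, so
their presence patterns across microfluidic chambers co-vary.  Here the
pair is jointly present in 8 of 17 chambers; the single-term
hypergeometric probability of that overlap under random placement is
small, so we conclude the contigs belong to one genome.
"""

import numpy as np

import minimeta as mm

# presence of contigs X and Y over 17 sub-samples
x = np.array([1] * 8 + [0] * 1 + [1] * 2 + [0] * 6)
y = np.array([1] * 8 + [1] * 1 + [0] * 2 + [0] * 6)

counts = mm.tabulate_contingency(x, y)
p = mm.fisher_point_probability(counts)

print(f"contingency (a, b, c, d) = {tuple(counts)}")
print(f"co-occurrence probability p = {p:.3f}")
print(
    "p is the probability of incorrectly rejecting the null hypothesis\n"
    "that the two presence patterns are unrelated; a small value means\n"
    "the contigs almost certainly come from cells of the same genome."
)
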
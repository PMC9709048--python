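"""Haplotype and nucleotide diversity of a mixed-stock sample.

Haplotype diversity h is the (bias-corrected) chance that two individuals
drawn from the site carry different haplotypes; nucleotide diversity pi is
the average per-site nucleotide difference between two random sequences,
here computed from haplotype counts plus a pairwise-difference matrix for a
491 bp mtDNA control-region fragment.
"""

import numpy as np

import mixedstock as ms

counts = [12, 9, 1, 3, 2]  # five haplotypes, n = 27
h, h_sd = ms.haplotype_diversity(counts)
print(f"haplotype diversity h = {h:.4f} (SD {h_sd:.4f}), n = {sum(counts)}")

# pairwise nucleotide differences between the five haplotypes
d = np.array([
    [0, 1, 2, 1, 3],
    [1, 0, 1, 2, 2],
    [2, 1, 0, 3, 1],
    [1, 2, 3, 0, 4],
    [3, 2, 1, 4, 0],
], dtype=float)
pi = ms.nucleotide_diversity(counts, d, seq_length=491)
print(f"nucleotide diversity pi = {pi:.3e} per site")
print("\nLower h/pi in a later sampling period indicates a loss of genetic")
print("diversity at the site, e.g. after a shift in source contributions.")
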
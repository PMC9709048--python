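"""Haplotype and nucleotide diversity of count tables.

Haplotype diversity uses Nei's unbiased estimator

    h = n/(n-1) * (1 - sum_k p_k^2)

with its sampling variance (Nei 1987, eq. 8.12):

    V(h) = 2/(n(n-1)) * ( 2(n-2) * (sum p^3 - (sum p^2)^2) + sum p^2 - (sum p^2)^2 )

Nucleotide diversity needs the per-haplotype pairwise nucleotide difference
matrix as an explicit input (sequences are upstream of this package):

    pi = n/(n-1) * sum_{a,b} p_a p_b d_ab / L
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["DiversityEstimate", "haplotype_diversity", "nucleotide_diversity", "diversity_table"]


@dataclass(frozen=True)
class DiversityEstimate:
    h: float
    h_sd: float
    pi: float | None
    n: int


def haplotype_diversity(counts) -> tuple[float, float]:
    """Nei's unbiased haplotype diversity and its standard deviation."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0) or not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValidationError("counts must be non-negative integers")
    n = counts.sum()
    if n < 2:
        raise ValidationError("haplotype diversity needs at least 2 sampled individuals")
    p = counts / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    h = n / (n - 1) * (1 - s2)
    var = 2.0 / (n * (n - 1)) * (2 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return float(h), float(np.sqrt(max(var, 0.0)))


def nucleotide_diversity(counts, pairwise_diffs, seq_length: int) -> float:
    """Average per-site pairwise nucleotide difference, small-sample corrected."""
    counts = np.asarray(counts, dtype=float)
    d = np.asarray(pairwise_diffs, dtype=float)
    if seq_length <= 0:
        raise ValidationError("seq_length must be positive")
    k = counts.shape[0]
    if d.shape != (k, k):
        raise ValidationError(f"pairwise_diffs must be {k}x{k} to match counts")
    if not np.allclose(d, d.T):
        raise ValidationError("pairwise difference matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValidationError("pairwise difference matrix must have a zero diagonal")
    n = counts.sum()
    if n < 2:
        raise ValidationError("nucleotide diversity needs at least 2 sampled individuals")
    p = counts / n
    pi = n / (n - 1) * float(p @ d @ p) / seq_length
    return float(pi)


def diversity_table(table, pairwise_diffs=None, seq_length: int | None = None):
    """Per-site diversity estimates for a :class:`HaplotypeCountTable`."""
    out = {}
    for i, site in enumerate(table.site_labels):
        counts = table.counts[i]
        h, h_sd = haplotype_diversity(counts)
        pi = None
        if pairwise_diffs is not None:
            if seq_length is None:
                raise ValidationError("seq_length is required alongside pairwise_diffs")
            pi = nucleotide_diversity(counts, pairwise_diffs, seq_length)
        out[site] = DiversityEstimate(h=h, h_sd=h_sd, pi=pi, n=int(counts.sum()))
    return out
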
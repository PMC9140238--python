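"""Significance of repression under new peaks and of motifs inside peaks.

The binomial test asks how surprising it is that k of the n genes overlapping
redistributed Sir3 peaks are down-regulated, given the background fraction of
down-regulated genes; the Poisson test asks whether a transcription-factor
site occurs inside peaks more often than its genome-wide density predicts.
"""

import pandas as pd

from histolife import OverlapTestInput, binomial_overlap, poisson_site_significance

inp = OverlapTestInput(n=33, k=22, p=0.48)
pmf = binomial_overlap(inp, mode="pmf")
tail = binomial_overlap(inp, mode="upper_tail")
print("22 of 33 peak-overlapping genes repressed, 48% background:")
print(f"  point probability  = {pmf:.4f} (~1% chance under random selection)")
print(f"  P(K >= 22)         = {tail:.4f} (tail probability for inference)")

peaks = pd.DataFrame(
    [("chr1", 100_000, 105_000), ("chr1", 500_000, 505_000)],
    columns=["chrom", "start", "end"],
)
sites = pd.DataFrame(
    {"chrom": "chr1", "pos": [100_500, 101_200, 504_000] + list(range(0, 97_000, 1000))}
)
res = poisson_site_significance(peaks, sites, genome_length=1_000_000)
print(f"\nfactor sites in peaks: k = {res.k}, expected lambda = {res.lam:.2f}")
print(f"  p(k) = {res.pmf:.4f}, P(K >= k) = {res.upper_tail:.4f}")
print("a small tail probability means the factor is enriched inside the peaks")
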
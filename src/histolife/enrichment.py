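"""Significance tests for redistributed heterochromatin peaks.

Two bespoke computations:

* ``binomial_overlap`` — given ``n`` genes overlapping new Sir3 peaks, of
  which ``k`` are down-regulated, against a background fraction ``p`` of
  down-regulated genes in the whole expression data set, the probability of
  the observation under random gene selection.  The point probability (pmf)
  reproduces the published computation; the upper tail P(K >= k) is the
  quantity to use for actual inference.

* ``poisson_site_significance`` — whether a transcription-factor motif is
  over-represented inside a peak set: with ``lambda`` = genome-wide site
  density times total peak length, the observed in-peak site count ``k`` is
  scored as p(k) = exp(-lambda) lambda^k / k! and as the tail P(K >= k).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd
from scipy import stats

__all__ = [
    "OverlapTestInput",
    "PoissonSiteTest",
    "binomial_overlap",
    "poisson_site_significance",
]


@dataclass(frozen=True)
class OverlapTestInput:
    """Counts for the peak-overlap repression test."""

    n: int  # genes overlapping peaks
    k: int  # of those, down-regulated
    p: float  # background down-regulated fraction

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"need 0 <= p <= 1, got p={self.p}")


@dataclass(frozen=True)
class PoissonSiteTest:
    """Result of the motif-in-peak Poisson test."""

    genome_density: float  # sites per bp genome-wide
    peak_bp: int  # total peak length
    lam: float  # expected in-peak sites = density * peak_bp
    k: int  # observed in-peak sites
    pmf: float  # p(k) = exp(-lam) lam^k / k!
    upper_tail: float  # P(K >= k)


def binomial_overlap(
    inp: OverlapTestInput, mode: Literal["pmf", "upper_tail"] = "pmf"
) -> float:
    """Binomial probability that k of n peak-overlapping genes are repressed.

    ``pmf`` returns C(n,k) p^k (1-p)^(n-k); ``upper_tail`` returns
    P(K >= k) = sum_{j>=k} pmf(j).  Both are evaluated in log space.
    """
    if mode == "pmf":
        return float(stats.binom.pmf(inp.k, inp.n, inp.p))
    if mode == "upper_tail":
        # sf is P(K > k-1) = P(K >= k)
        return float(stats.binom.sf(inp.k - 1, inp.n, inp.p))
    raise ValueError(f"mode must be 'pmf' or 'upper_tail', got {mode!r}")


def _sites_in_peaks(peaks: pd.DataFrame, sites: pd.DataFrame) -> int:
    """Count site positions falling inside [start, end) of any peak."""
    count = 0
    for chrom, group in sites.groupby("chrom", sort=False):
        p = peaks[peaks["chrom"] == chrom]
        if p.empty:
            continue
        for pos in group["pos"]:
            if ((p["start"] <= pos) & (pos < p["end"])).any():
                count += 1
    return count


def poisson_site_significance(
    peaks: pd.DataFrame,
    sites: pd.DataFrame | Iterable[tuple[str, int]],
    genome_length: int,
) -> PoissonSiteTest:
    """Poisson significance of factor-site counts inside a peak set.

    Parameters
    ----------
    peaks
        DataFrame with columns ``chrom, start, end`` (0-based, half-open).
    sites
        DataFrame with columns ``chrom, pos`` or an iterable of
        ``(chrom, position)`` pairs; a site on a peak's end coordinate is
        outside (half-open convention).
    genome_length
        Total genome length in bp; the site density is |sites|/genome_length
        and the expectation is density times the summed peak length.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    if not isinstance(sites, pd.DataFrame):
        sites = pd.DataFrame(list(sites), columns=["chrom", "pos"])
    peak_bp = int((peaks["end"] - peaks["start"]).sum()) if len(peaks) else 0
    density = len(sites) / genome_length
    lam = density * peak_bp
    k = _sites_in_peaks(peaks, sites) if len(sites) and len(peaks) else 0
    pmf = float(stats.poisson.pmf(k, lam)) if lam > 0 or k == 0 else 0.0
    tail = float(stats.poisson.sf(k - 1, lam))
    return PoissonSiteTest(
        genome_density=density,
        peak_bp=peak_bp,
        lam=lam,
        k=k,
        pmf=pmf,
        upper_tail=tail,
    )
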
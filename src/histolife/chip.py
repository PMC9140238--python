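"""ChIP coverage normalisation, telomere/core partition, peak calling and
peak-to-gene assignment.

Coverage is held per chromosome as a vector of fixed-width bins (half-open,
0-based).  IP and input tracks are first scaled to an identical genome-wide
sum, the per-bin IP/input ratio is formed, per-chromosome mean signal is
split into the terminal windows (both chromosome ends) versus the interior
core — each normalised to the genome-wide mean — and enriched regions are
called as maximal runs of bins above a ratio threshold.  A gene counts as
covered by a peak when its body extended by an upstream margin on the 5'
side (strand-aware) intersects the peak by at least one bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoverageTrack",
    "GroupComparison",
    "read_bedgraph",
    "write_bedgraph",
    "write_wiggle",
    "normalize_pair",
    "enrichment_ratio",
    "partition_telomere_core",
    "compare_groups",
    "call_peaks",
    "peaks_to_genes",
]

PEAK_COLUMNS = ["chrom", "start", "end", "mean_ratio", "max_ratio"]


@dataclass
class CoverageTrack:
    """Binned per-chromosome signal.

    ``data`` maps chromosome name to a float vector; bin ``i`` covers
    ``[i*bin_size, min((i+1)*bin_size, length))``.  ``lengths`` carries the
    exact chromosome lengths so partial terminal bins can be weighted by the
    bp they actually cover.
    """

    data: dict[str, np.ndarray]
    bin_size: int
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        for chrom, values in self.data.items():
            values = np.asarray(values, dtype=float)
            if not np.all(np.isfinite(values)) or np.any(values < 0):
                raise ValueError(f"{chrom}: signal must be finite and >= 0")
            self.data[chrom] = values
            self.lengths.setdefault(chrom, len(values) * self.bin_size)

    def bin_weights(self, chrom: str) -> np.ndarray:
        """bp covered by each bin (last bin may be partial)."""
        n = len(self.data[chrom])
        w = np.full(n, float(self.bin_size))
        w[-1] = self.lengths[chrom] - (n - 1) * self.bin_size
        return w

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def genome_mean(self) -> float:
        """bp-weighted genome-wide mean signal."""
        num = sum(float(np.dot(self.data[c], self.bin_weights(c))) for c in self.data)
        den = sum(self.lengths[c] for c in self.data)
        return num / den

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            data={c: v * factor for c, v in self.data.items()},
            bin_size=self.bin_size,
            lengths=dict(self.lengths),
        )

    def same_bins_as(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and set(self.data) == set(other.data)
            and all(len(self.data[c]) == len(other.data[c]) for c in self.data)
        )


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample comparison of per-chromosome values."""

    a: tuple[float, ...]
    b: tuple[float, ...]
    t: float
    p: float
    significant: bool  # p < 0.05


# ---------------------------------------------------------------------------
# I/O: bedgraph in/out (0-based half-open), wiggle out (1-based fixedStep)


def read_bedgraph(
    path, bin_size: int, lengths: Mapping[str, int] | None = None
) -> CoverageTrack:
    """Read a bedgraph into fixed-width bins.

    Interval values are distributed over bins weighted by overlap fraction,
    so a round-trip through :func:`write_bedgraph` is exact for tracks that
    were binned to begin with.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str},
    )
    if lengths is None:
        lengths = df.groupby("chrom")["end"].max().to_dict()
    data: dict[str, np.ndarray] = {}
    for chrom, length in lengths.items():
        n = -(-int(length) // bin_size)
        vec = np.zeros(n)
        sub = df[df["chrom"] == chrom]
        # each bin takes interval values weighted by the fraction of the bin covered
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            first, last = int(start) // bin_size, (int(end) - 1) // bin_size
            for b in range(first, last + 1):
                lo = max(int(start), b * bin_size)
                hi = min(int(end), (b + 1) * bin_size)
                bin_bp = min((b + 1) * bin_size, int(length)) - b * bin_size
                vec[b] += value * (hi - lo) / bin_bp
        data[chrom] = vec
    return CoverageTrack(data=data, bin_size=bin_size, lengths={c: int(v) for c, v in lengths.items()})


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write one line per bin, clipped to the chromosome length."""
    with open(path, "w") as fh:
        for chrom in track.data:
            length = track.lengths[chrom]
            for i, value in enumerate(track.data[chrom]):
                start = i * track.bin_size
                end = min(start + track.bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def write_wiggle(track: CoverageTrack, path, name: str = "track") -> None:
    """fixedStep wiggle (1-based starts), one block per chromosome."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom in track.data:
            fh.write(
                f"fixedStep chrom={chrom} start=1 step={track.bin_size} span={track.bin_size}\n"
            )
            for value in track.data[chrom]:
                fh.write(f"{value:.6g}\n")


# ---------------------------------------------------------------------------
# Normalisation and ratio


def normalize_pair(
    ip: CoverageTrack, input_: CoverageTrack, target_sum: float = 1e6
) -> tuple[CoverageTrack, CoverageTrack]:
    """Scale IP and input so each genome-wide sum equals ``target_sum``.

    This is the equal-total normalisation applied before any IP/input
    comparison; relative shape within each track is unchanged.
    """
    if not ip.same_bins_as(input_):
        raise ValueError("IP and input tracks must share chromosomes and bins")
    totals = ip.total(), input_.total()
    if totals[0] <= 0 or totals[1] <= 0:
        raise ValueError("cannot normalize an all-zero track")
    return ip.scaled(target_sum / totals[0]), input_.scaled(target_sum / totals[1])


def enrichment_ratio(
    ip: CoverageTrack, input_: CoverageTrack, pseudo: float = 1e-9
) -> CoverageTrack:
    """Per-bin (ip + pseudo) / (input + pseudo) on an equal-sum pair."""
    if pseudo < 0:
        raise ValueError("pseudo must be >= 0")
    if not ip.same_bins_as(input_):
        raise ValueError("IP and input tracks must share chromosomes and bins")
    data = {}
    for chrom in ip.data:
        denom = input_.data[chrom] + pseudo
        num = ip.data[chrom] + pseudo
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
        data[chrom] = r
    return CoverageTrack(data=data, bin_size=ip.bin_size, lengths=dict(ip.lengths))


# ---------------------------------------------------------------------------
# Telomere / core partition


def partition_telomere_core(
    track: CoverageTrack, telomere_window: int = 20_000
) -> pd.DataFrame:
    """Mean signal in the two terminal windows vs the interior, per chromosome.

    Both values are divided by the bp-weighted genome-wide mean, so a uniform
    track gives 1.0 everywhere.  Partial bins at window boundaries contribute
    proportionally to their bp overlap.  Chromosomes not longer than twice the
    window have no interior; they are flagged (``core`` = NaN) and excluded
    from core statistics.
    """
    gmean = track.genome_mean()
    if gmean <= 0:
        raise ValueError("genome-wide mean signal must be > 0")
    rows = []
    for chrom, values in track.data.items():
        length = track.lengths[chrom]
        w = track.bin_weights(chrom)
        starts = np.arange(len(values)) * track.bin_size
        ends = starts + w
        # bp of each bin inside [0, window) + [length-window, length)
        left = np.clip(np.minimum(ends, telomere_window) - starts, 0, None)
        right = np.clip(ends - np.maximum(starts, length - telomere_window), 0, None)
        tel_w = np.minimum(left + right, w)  # windows may overlap on short chroms
        core_w = w - tel_w
        tel = float(np.dot(values, tel_w) / tel_w.sum()) / gmean
        has_core = length > 2 * telomere_window
        if has_core:
            core = float(np.dot(values, core_w) / core_w.sum()) / gmean
        else:
            warnings.warn(
                f"{chrom}: length {length} <= 2x window {telomere_window}; no core region",
                stacklevel=2,
            )
            core = float("nan")
        rows.append({"chrom": chrom, "tel": tel, "core": core, "has_core": has_core})
    return pd.DataFrame(rows)


def compare_groups(a: Iterable[float], b: Iterable[float]) -> GroupComparison:
    """Welch (unequal-variance) two-sample t-test, two-sided."""
    a = tuple(float(x) for x in a)
    b = tuple(float(x) for x in b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    with warnings.catch_warnings():
        # constant groups trigger a harmless precision warning; the nan they
        # produce is resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):  # zero variance in both groups
        t, p = (0.0, 1.0) if np.mean(a) == np.mean(b) else (np.inf, 0.0)
    return GroupComparison(a=a, b=b, t=float(t), p=float(p), significant=float(p) < 0.05)


# ---------------------------------------------------------------------------
# Peak calling and gene assignment


def call_peaks(
    ratio: CoverageTrack,
    threshold: float | None = None,
    min_len: int = 0,
    merge_gap: int = 0,
) -> pd.DataFrame:
    """Maximal runs of bins with ratio >= threshold, as 0-based half-open BED.

    Runs separated by gaps <= ``merge_gap`` bp are merged; merged runs shorter
    than ``min_len`` bp are dropped.  If ``threshold`` is None it defaults to
    the genome mean ratio plus two standard deviations (bp-weighted).
    """
    if threshold is None:
        gmean = ratio.genome_mean()
        flat = np.concatenate([ratio.data[c] for c in ratio.data])
        wts = np.concatenate([ratio.bin_weights(c) for c in ratio.data])
        var = float(np.average((flat - gmean) ** 2, weights=wts))
        threshold = gmean + 2.0 * np.sqrt(var)
    if threshold <= 1:
        raise ValueError("peak threshold must be > 1 (an enrichment ratio)")

    rows = []
    for chrom, values in ratio.data.items():
        above = values >= threshold
        if not above.any():
            continue
        # run-length extraction of True stretches
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        starts_bin, ends_bin = edges[::2], edges[1::2]
        intervals = [
            [int(s) * ratio.bin_size, min(int(e) * ratio.bin_size, ratio.lengths[chrom])]
            for s, e in zip(starts_bin, ends_bin)
        ]
        merged = [intervals[0]]
        for s, e in intervals[1:]:
            if s - merged[-1][1] <= merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s < min_len:
                continue
            sl = values[s // ratio.bin_size : -(-e // ratio.bin_size)]
            rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "mean_ratio": float(sl.mean()),
                    "max_ratio": float(sl.max()),
                }
            )
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def peaks_to_genes(
    peaks: pd.DataFrame, genes: pd.DataFrame, upstream: int = 500
) -> pd.DataFrame:
    """Assign peaks to genes whose body + 5' upstream margin they intersect.

    ``genes`` needs columns ``chrom, start, end, name, strand``; the search
    interval is ``[start-upstream, end)`` for + genes and ``[start,
    end+upstream)`` for - genes, clipped at 0.  Intersection is half-open and
    requires >= 1 bp.  Returns one row per (gene, peak) pair.
    """
    rows = []
    for _, g in genes.iterrows():
        if g["strand"] == "+":
            lo, hi = max(0, int(g["start"]) - upstream), int(g["end"])
        else:
            lo, hi = int(g["start"]), int(g["end"]) + upstream
        p = peaks[peaks["chrom"] == g["chrom"]]
        hit = p[(p["start"] < hi) & (lo < p["end"])]
        for _, pk in hit.iterrows():
            rows.append(
                {
                    "gene": g["name"],
                    "chrom": g["chrom"],
                    "gene_start": int(g["start"]),
                    "gene_end": int(g["end"]),
                    "strand": g["strand"],
                    "peak_start": int(pk["start"]),
                    "peak_end": int(pk["end"]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "chrom",
            "gene_start",
            "gene_end",
            "strand",
            "peak_start",
            "peak_end",
        ],
    )
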
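"""Pooled bar-seq quantitation of strain abundance in an aging culture.

Each strain in the pooled library carries two strain-specific DNA barcodes
("up" and "down" tags).  Reads from each timepoint are matched to barcodes,
the two channels are averaged after within-channel normalisation, and each
strain's abundance is expressed as the log2 ratio to its level in the mixed
starting population, median-adjusted per timepoint.  Strains whose scores
decay slowest have the longest chronological lifespan; the ranking marks the
top 10 strains, the top tenth percentile and the bottom 10.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "StrainBarcodeMap",
    "BarcodeCounts",
    "LifespanScoreTable",
    "read_strain_map",
    "count_barcodes",
    "lifespan_scores",
    "rank_strains",
]

_DNA = frozenset("ACGT")
CHANNELS = ("up", "down")


@dataclass(frozen=True)
class StrainBarcodeMap:
    """strain id -> (up barcode, down barcode), plus a free-text description."""

    strains: tuple[str, ...]
    up: Mapping[str, str]
    down: Mapping[str, str]
    description: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.strains:
            raise ValueError("strain map is empty")
        for channel, mapping in (("up", self.up), ("down", self.down)):
            seen: dict[str, str] = {}
            for strain in self.strains:
                bc = mapping[strain]
                if not bc or set(bc) - _DNA:
                    raise ValueError(
                        f"{strain} {channel} barcode {bc!r}: must be non-empty over A/C/G/T"
                    )
                if bc in seen:
                    raise ValueError(
                        f"duplicate {channel} barcode {bc} shared by {seen[bc]} and {strain}"
                    )
                seen[bc] = strain

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str, str]], descriptions: Mapping[str, str] | None = None
    ) -> "StrainBarcodeMap":
        strains, up, down = [], {}, {}
        for strain, u, d in pairs:
            strains.append(strain)
            up[strain] = u
            down[strain] = d
        return cls(
            strains=tuple(strains), up=up, down=down, description=dict(descriptions or {})
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.strains:
                fh.write(f"{s}\t{self.up[s]}\t{self.down[s]}\t{self.description.get(s, '')}\n")


def read_strain_map(path) -> StrainBarcodeMap:
    """Read `strain_id<TAB>up_barcode<TAB>down_barcode<TAB>description`."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["strain", "up", "down", "description"],
        dtype=str,
        keep_default_na=False,
    )
    return StrainBarcodeMap.from_pairs(
        zip(df["strain"], df["up"], df["down"]),
        descriptions=dict(zip(df["strain"], df["description"])),
    )


@dataclass
class BarcodeCounts:
    """Per-strain up/down read counts for one or more timepoint samples.

    ``counts`` is indexed by strain with a (timepoint, channel) MultiIndex on
    columns; every strain in the map has a row, zero-filled if unseen.
    ``unmatched``/``ambiguous`` tally reads per timepoint that matched no
    barcode or more than one distinct barcode.
    """

    counts: pd.DataFrame
    unmatched: dict[object, int]
    ambiguous: dict[object, int]
    scale: dict[object, float] = field(default_factory=dict)

    @property
    def timepoints(self) -> list:
        return list(dict.fromkeys(t for t, _ in self.counts.columns))

    def merge(self, other: "BarcodeCounts") -> "BarcodeCounts":
        return BarcodeCounts(
            counts=pd.concat([self.counts, other.counts], axis=1),
            unmatched={**self.unmatched, **other.unmatched},
            ambiguous={**self.ambiguous, **other.ambiguous},
            scale={**self.scale, **other.scale},
        )


def _open_maybe_gzip(path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _mismatch_index(barcodes: Iterable[str]) -> dict[str, frozenset]:
    """Map every 1-substitution variant of every barcode back to the barcode
    sequences it could have come from."""
    index: dict[str, set] = {}
    for bc in barcodes:
        variants = {bc}
        for i in range(len(bc)):
            for base in "ACGT":
                if base != bc[i]:
                    variants.add(bc[:i] + base + bc[i + 1 :])
        for v in variants:
            index.setdefault(v, set()).add(bc)
    return {v: frozenset(bcs) for v, bcs in index.items()}


def count_barcodes(
    reads,
    strain_map: StrainBarcodeMap,
    timepoint,
    max_mismatch: int = 0,
) -> BarcodeCounts:
    """Count up/down barcode occurrences in one timepoint's reads.

    ``reads`` is a FASTQ path (.fastq or .fastq.gz) or an iterable of read
    sequences.  Every offset of each read is scanned on the forward strand; a
    read increments exactly one (strain, channel) when exactly one distinct
    barcode matches within ``max_mismatch`` substitutions, is tallied as
    ambiguous when two or more distinct barcodes match, and as unmatched
    otherwise.  All barcodes must share one length (the amplicon design).
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    barcode_keys: dict[str, list[tuple[str, str]]] = {}
    for strain in strain_map.strains:
        for channel in CHANNELS:
            bc = getattr(strain_map, channel)[strain]
            barcode_keys.setdefault(bc, []).append((strain, channel))
    for bc, keys in barcode_keys.items():
        if len({s for s, _ in keys}) > 1:
            raise ValueError(f"barcode {bc} assigned to multiple strains: {keys}")
    lengths = {len(bc) for bc in barcode_keys}
    if len(lengths) != 1:
        raise ValueError("all barcodes must have the same length")
    k = lengths.pop()

    if max_mismatch == 0:
        index = {bc: frozenset({bc}) for bc in barcode_keys}
    else:
        index = _mismatch_index(barcode_keys)

    counts = {key: 0 for keys in barcode_keys.values() for key in keys}
    unmatched = ambiguous = 0

    if isinstance(reads, (str, Path)):
        with _open_maybe_gzip(reads) as fh:
            seqs = [str(rec.seq) for rec in SeqIO.parse(fh, "fastq")]
    else:
        seqs = list(reads)

    for seq in seqs:
        hits: frozenset | set = set()
        for off in range(len(seq) - k + 1):
            found = index.get(seq[off : off + k])
            if found:
                hits = hits | found
                if len(hits) > 1:
                    break
        if len(hits) == 1:
            # resolve to the unique strain; prefer the up channel if one
            # barcode serves both channels of the same strain
            keys = barcode_keys[next(iter(hits))]
            counts[min(keys, key=lambda sk: CHANNELS.index(sk[1]))] += 1
        elif len(hits) > 1:
            ambiguous += 1
        else:
            unmatched += 1

    columns = pd.MultiIndex.from_product([[timepoint], CHANNELS])
    table = pd.DataFrame(0, index=list(strain_map.strains), columns=columns, dtype=int)
    for (strain, channel), n in counts.items():
        table.loc[strain, (timepoint, channel)] = n
    return BarcodeCounts(
        counts=table,
        unmatched={timepoint: unmatched},
        ambiguous={timepoint: ambiguous},
    )


@dataclass
class LifespanScoreTable:
    """Median-adjusted log2 abundance ratios, strains x timepoints."""

    scores: pd.DataFrame  # index strain, columns timepoint
    t0: object
    pseudocount: float

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# log2 ratio vs t0={self.t0}, per-timepoint median-adjusted, "
                     f"pseudocount={self.pseudocount} reads\n")
            self.scores.to_csv(fh, sep="\t", index_label="strain")


def lifespan_scores(
    counts: BarcodeCounts,
    t0,
    pseudocount: float = 0.5,
    per_timepoint_median: bool = True,
) -> LifespanScoreTable:
    """Median-adjusted log2 abundance ratios relative to the starting pool.

    Per sample and channel, counts (times any per-sample scale factor) get a
    pseudocount and are normalised to the channel total; the up and down
    fractions are averaged; the score is log2(v_t / v_t0); and the
    per-timepoint median score over strains is subtracted so the median
    strain sits at 0 in every panel (set ``per_timepoint_median=False`` to
    subtract one global median instead).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    timepoints = counts.timepoints
    if t0 not in timepoints:
        raise ValueError(f"t0 {t0!r} not among timepoints {timepoints}")

    abundance = {}
    for t in timepoints:
        if counts.counts[t].to_numpy().sum() == 0:
            if t == t0:
                raise ValueError("t0 sample has zero total counts")
        scale = counts.scale.get(t, 1.0)
        chans = []
        for channel in CHANNELS:
            v = counts.counts[(t, channel)].to_numpy(dtype=float) * scale + pseudocount
            chans.append(v / v.sum())
        abundance[t] = (chans[0] + chans[1]) / 2.0

    v0 = abundance[t0]
    raw = pd.DataFrame(
        {t: np.log2(abundance[t] / v0) for t in timepoints}, index=counts.counts.index
    )
    if per_timepoint_median:
        adjusted = raw - raw.median(axis=0)
    else:
        adjusted = raw - np.median(raw.to_numpy())
    return LifespanScoreTable(scores=adjusted, t0=t0, pseudocount=pseudocount)


def rank_strains(table: LifespanScoreTable, at) -> pd.DataFrame:
    """Rank strains by descending score at one timepoint.

    Flags the top 10 individual strains, the top tenth percentile
    (ceil(0.1*n) strains) and the bottom 10; ties are broken by ascending
    strain id so the ordering is deterministic.
    """
    if at not in table.scores.columns:
        raise ValueError(f"timepoint {at!r} not in score table")
    s = table.scores[at]
    order = sorted(s.index, key=lambda strain: (-s[strain], strain))
    n = len(order)
    if n < 10:
        warnings.warn(f"only {n} strains; top/bottom-10 sets truncated", stacklevel=2)
    n_top_pct = math.ceil(0.1 * n)
    df = pd.DataFrame(
        {
            "strain": order,
            "score": [float(s[x]) for x in order],
            "rank": np.arange(1, n + 1),
        }
    )
    df["top10"] = df["rank"] <= 10
    df["top10pct"] = df["rank"] <= n_top_pct
    df["bottom10"] = df["rank"] > n - 10
    return df
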
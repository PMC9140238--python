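"""Synthetic study generator with planted ground truth.

Emulates the full experimental design end-to-end so every downstream stage
(bar-seq quantitation, ChIP normalisation and partition, peak calling,
binding-model predictions, DE enrichment) can be tested against known truth:

* a pooled culture of ~400 dual-barcoded strains held in stationary phase,
  each strain decaying exponentially at its own death rate, sampled by
  barcode sequencing at progressive timepoints;
* a 16-chromosome genome (coordinates only) with 20 kb telomeric windows,
  non-overlapping stranded genes, high-affinity primary factor sites near
  the telomeres and scattered lower-affinity secondary sites in the cores;
* IP/input coverage in which site enrichment follows the equilibrium
  competitive-binding occupancies — "WT" affinities concentrate signal at
  primary (telomere-proximal) sites, "mutant" affinities redistribute it to
  the secondary sites;
* an expression table in which genes under secondary peaks carry a planted
  repression effect.

All randomness flows from one root seed through named substreams (layout /
barseq / chip / expr), so each product can be regenerated independently and
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .barseq import StrainBarcodeMap
from .binding import BindingSystem, SiteClass, fractional_binding
from .chip import CoverageTrack, peaks_to_genes

__all__ = [
    "SimulationConfig",
    "GenomeLayout",
    "TruthTables",
    "make_strain_map",
    "make_genome",
    "simulate_barseq",
    "reads_to_fastq",
    "simulate_chip",
    "simulate_expression",
]

# printed amplicon primer contexts flanking the up/down barcodes
UP_FLANKS = ("ATGTCCACGAGGTCTCT", "TACGCTGCAGGTCGAGG")
DOWN_FLANKS = ("CGGTGTCGGTCTCGTAG", "GATGAATTCGAGCTGGG")

_SUBSTREAMS = {"layout": 0, "strains": 1, "barseq": 2, "chip": 3, "expr": 4, "rates": 5}
_COMP = str.maketrans("ACGT", "TGCA")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_SUBSTREAMS[stream], seed])


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the study's defaults.

    Defaults mirror the experimental design: ~400 strains sampled at days
    6/20/34/44/55 of stationary phase, a 16-chromosome genome with 20 kb
    telomeric windows, WT affinities (Ka1, Ka2) = (50, 10) uM^-1 and the
    mutant pair (10, 5) uM^-1.
    """

    n_strains: int = 400
    timepoints: tuple[int, ...] = (6, 20, 34, 44, 55)
    read_depth: int = 1_000_000
    death_rates: tuple[float, ...] | None = None  # per strain, per day; drawn if None
    max_death_rate: float = 0.15  # upper bound of the drawn rates, 1/day
    barcode_length: int = 20

    n_chromosomes: int = 16
    chrom_lengths: tuple[int, ...] | None = None  # drawn in [150, 400] kb if None
    telomere_window: int = 20_000
    n_genes: int = 400
    gene_length: int = 1_500
    primary_sites: tuple[tuple[str, int, str], ...] | None = None  # (chrom, pos, factor)
    secondary_sites: tuple[tuple[str, int, str], ...] | None = None

    bin_size: int = 50
    input_mean: float = 20.0  # expected input reads per bin
    kernel_halfwidth: int = 1_000  # flat-top enrichment footprint, bp
    kernel: Literal["flat", "gaussian"] = "flat"
    protein_budget: float = 10.0  # enrichment amplitude c in IP = input*(1 + c*occ)
    ka_wt: tuple[float, float] = (50.0, 10.0)  # uM^-1
    ka_mut: tuple[float, float] = (10.0, 5.0)  # uM^-1
    site_concentration: float = 1.0  # B per class, uM

    nb_dispersion: float = 0.1
    effect_log2fc: float = -1.0  # planted repression under secondary peaks
    sigma_log2fc: float = 0.2
    n_replicates: int = 4

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_strains", "read_depth", "n_chromosomes", "n_genes",
                     "bin_size", "barcode_length", "gene_length", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.death_rates is not None:
            if len(self.death_rates) != self.n_strains:
                raise ValueError("death_rates must have one entry per strain")
            if any(r < 0 for r in self.death_rates):
                raise ValueError("death_rates must be >= 0")
        if self.chrom_lengths is not None:
            if len(self.chrom_lengths) != self.n_chromosomes:
                raise ValueError("chrom_lengths must have one entry per chromosome")
            if min(self.chrom_lengths) <= 0:
                raise ValueError("chromosome lengths must be > 0")
            if self.telomere_window > min(self.chrom_lengths) / 2:
                raise ValueError("telomere_window must be <= min(chrom_lengths)/2")

    def resolved_death_rates(self) -> np.ndarray:
        """Per-strain rates, drawn uniformly on [0, max_death_rate] if unset."""
        if self.death_rates is not None:
            return np.asarray(self.death_rates, dtype=float)
        return _rng(self.seed, "rates").uniform(
            0.0, self.max_death_rate, size=self.n_strains
        )


@dataclass
class GenomeLayout:
    """Coordinates-only genome: chromosome sizes, genes, factor sites."""

    chromosomes: dict[str, int]
    genes: pd.DataFrame  # chrom, start, end, name, score, strand
    factor_sites: pd.DataFrame  # chrom, pos, factor, site_class
    telomere_window: int

    def telomere_windows(self) -> list[tuple[str, int, int]]:
        """Both terminal windows of every chromosome, half-open."""
        out = []
        for chrom, length in self.chromosomes.items():
            out.append((chrom, 0, min(self.telomere_window, length)))
            out.append((chrom, max(0, length - self.telomere_window), length))
        return out

    def write(self, outdir) -> None:
        """chrom-sizes TSV, genes BED6 and factor sites BED4."""
        from pathlib import Path

        outdir = Path(outdir)
        with open(outdir / "chrom.sizes", "w") as fh:
            for chrom, length in self.chromosomes.items():
                fh.write(f"{chrom}\t{length}\n")
        self.genes[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            outdir / "genes.bed", sep="\t", header=False, index=False
        )
        bed4 = self.factor_sites.assign(end=self.factor_sites["pos"] + 1)
        bed4[["chrom", "pos", "end", "factor"]].to_csv(
            outdir / "factor_sites.bed", sep="\t", header=False, index=False
        )


@dataclass
class TruthTables:
    """Planted ground truth used as the oracle for downstream stages."""

    true_abundance: pd.DataFrame | None = None  # strain x timepoint expected fractions
    true_rank: tuple[str, ...] = ()  # longest-lived first
    true_occupancy: dict[str, float] = field(default_factory=dict)  # site id -> fraction
    true_repressed: tuple[str, ...] = ()  # gene ids carrying the planted effect


# ---------------------------------------------------------------------------
# Strain map


def make_strain_map(config: SimulationConfig) -> StrainBarcodeMap:
    """Draw distinct up/down barcodes for every strain from the root seed."""
    rng = _rng(config.seed, "strains")
    k = config.barcode_length
    needed = 2 * config.n_strains
    seqs: set[str] = set()
    flank_fragments = {f[-k:] for f in UP_FLANKS + DOWN_FLANKS if len(f) >= k}
    while len(seqs) < needed:
        draw = rng.integers(0, 4, size=k)
        bc = "".join("ACGT"[b] for b in draw)
        if bc not in flank_fragments:
            seqs.add(bc)
    ordered = sorted(seqs)
    rng.shuffle(ordered)
    pairs = [
        (f"strain{i:04d}", ordered[2 * i], ordered[2 * i + 1])
        for i in range(config.n_strains)
    ]
    return StrainBarcodeMap.from_pairs(
        pairs, descriptions={p[0]: "synthetic histone mutant" for p in pairs}
    )


# ---------------------------------------------------------------------------
# Genome layout


def make_genome(config: SimulationConfig) -> GenomeLayout:
    """Build the coordinate genome: chromosomes, genes, factor sites.

    Chromosome lengths come from the config or are drawn once per seed.
    Genes are placed non-overlapping with random strand.  Primary factor
    sites default to one per chromosome end, inside the telomeric window;
    secondary sites default to two per chromosome, uniform over the core.
    """
    rng = _rng(config.seed, "layout")
    if config.chrom_lengths is None:
        lengths = rng.integers(150_000, 400_001, size=config.n_chromosomes)
    else:
        lengths = np.asarray(config.chrom_lengths)
    chroms = {f"chr{i + 1:02d}": int(l) for i, l in enumerate(lengths)}
    if config.telomere_window > min(chroms.values()) / 2:
        raise ValueError("telomere_window must be <= min(chrom_lengths)/2")

    # non-overlapping stranded genes, spread proportionally to chromosome length
    total = sum(chroms.values())
    genes = []
    gi = 0
    for chrom, length in chroms.items():
        n_here = max(1, round(config.n_genes * length / total))
        occupied: list[tuple[int, int]] = []
        attempts = 0
        while len(occupied) < n_here and attempts < 50 * n_here:
            attempts += 1
            start = int(rng.integers(0, length - config.gene_length))
            end = start + config.gene_length
            if any(s < end and start < e for s, e in occupied):
                continue
            occupied.append((start, end))
        for start, end in sorted(occupied):
            genes.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "name": f"gene{gi:04d}",
                    "score": 0,
                    "strand": "+" if rng.integers(2) else "-",
                }
            )
            gi += 1
    genes_df = pd.DataFrame(genes)

    if config.primary_sites is None:
        primary = []
        for chrom, length in chroms.items():
            offset = min(5_000, config.telomere_window // 2)
            primary.append((chrom, offset, "Rap1"))
            primary.append((chrom, length - offset, "Rap1"))
    else:
        primary = list(config.primary_sites)
    if config.secondary_sites is None:
        secondary = []
        for chrom, length in chroms.items():
            lo = config.telomere_window + config.kernel_halfwidth
            hi = length - config.telomere_window - config.kernel_halfwidth
            for pos in rng.integers(lo, hi, size=2):
                secondary.append((chrom, int(pos), "Abf1"))
    else:
        secondary = list(config.secondary_sites)

    sites = pd.DataFrame(
        [(c, p, f, "primary") for c, p, f in primary]
        + [(c, p, f, "secondary") for c, p, f in secondary],
        columns=["chrom", "pos", "factor", "site_class"],
    )

    for label, df, lo_col, hi_col in (
        ("gene", genes_df, "start", "end"),
        ("site", sites, "pos", "pos"),
    ):
        for _, row in df.iterrows():
            if row["chrom"] not in chroms:
                raise ValueError(f"{label} on unknown chromosome {row['chrom']}")
            if row[lo_col] < 0 or row[hi_col] > chroms[row["chrom"]]:
                raise ValueError(
                    f"{label} at {row['chrom']}:{row[lo_col]}-{row[hi_col]} "
                    f"outside chromosome bounds"
                )

    return GenomeLayout(
        chromosomes=chroms,
        genes=genes_df,
        factor_sites=sites,
        telomere_window=config.telomere_window,
    )


# ---------------------------------------------------------------------------
# Bar-seq reads


def expected_abundance(
    config: SimulationConfig, strains: Sequence[str] | None = None
) -> pd.DataFrame:
    """Noise-free strain fractions: exp(-rate*day), renormalised per day."""
    rates = config.resolved_death_rates()
    if strains is None:
        strains = [f"strain{i:04d}" for i in range(config.n_strains)]
    table = {}
    for day in config.timepoints:
        w = np.exp(-rates * day)
        table[day] = w / w.sum()
    return pd.DataFrame(table, index=strains)


def simulate_barseq(
    config: SimulationConfig,
    strain_map: StrainBarcodeMap,
    reverse_complement_fraction: float = 0.0,
) -> tuple[dict[int, list[str]], TruthTables]:
    """Amplicon reads per timepoint, multinomially drawn from decaying pools.

    Strain abundance at day t is proportional to exp(-rate*t); ``read_depth``
    reads per timepoint are split evenly between the up and down channels and
    drawn multinomially.  Each read is the channel's forward primer context,
    the strain barcode, then the reverse context.  Reads are forward-strand
    unless ``reverse_complement_fraction`` > 0.
    """
    if len(strain_map.strains) != config.n_strains:
        raise ValueError("strain map size does not match config.n_strains")
    rng = _rng(config.seed, "barseq")
    abundance = expected_abundance(config, strains=strain_map.strains)
    rates = config.resolved_death_rates()
    order = sorted(
        range(config.n_strains), key=lambda i: (rates[i], strain_map.strains[i])
    )
    truth = TruthTables(
        true_abundance=abundance,
        true_rank=tuple(strain_map.strains[i] for i in order),
    )

    reads: dict[int, list[str]] = {}
    for day in config.timepoints:
        p = abundance[day].to_numpy()
        out: list[str] = []
        for channel, depth in (
            ("up", config.read_depth // 2),
            ("down", config.read_depth - config.read_depth // 2),
        ):
            counts = rng.multinomial(depth, p)
            flanks = UP_FLANKS if channel == "up" else DOWN_FLANKS
            mapping = getattr(strain_map, channel)
            for strain, n in zip(strain_map.strains, counts):
                seq = flanks[0] + mapping[strain] + flanks[1]
                out.extend([seq] * int(n))
        perm = rng.permutation(len(out))
        out = [out[i] for i in perm]
        if reverse_complement_fraction > 0:
            flip = rng.random(len(out)) < reverse_complement_fraction
            out = [
                s.translate(_COMP)[::-1] if f else s for s, f in zip(out, flip)
            ]
        reads[day] = out
    return reads, truth


def reads_to_fastq(reads: Sequence[str], sample: str) -> str:
    """4-line FASTQ records with constant Phred+33 quality 'I' (Q40)."""
    chunks = []
    for i, seq in enumerate(reads):
        chunks.append(f"@{sample}:{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    return "".join(chunks)


# ---------------------------------------------------------------------------
# ChIP coverage


def _site_occupancies(config: SimulationConfig, mode: str) -> tuple[float, float]:
    ka = {"WT": config.ka_wt, "mutant": config.ka_mut}.get(mode)
    if ka is None:
        raise ValueError(f"mode must be 'WT' or 'mutant', got {mode!r}")
    system = BindingSystem(
        classes=(
            SiteClass("primary", ka[0], config.site_concentration),
            SiteClass("secondary", ka[1], config.site_concentration),
        )
    )
    f = fractional_binding(system)
    return f.f_bound[0], f.f_bound[1]


def simulate_chip(
    config: SimulationConfig,
    layout: GenomeLayout,
    mode: Literal["WT", "mutant"] = "WT",
) -> tuple[CoverageTrack, CoverageTrack, TruthTables]:
    """IP and input coverage with enrichment set by the binding model.

    The input track is Poisson noise around a uniform per-bin mean.  Around
    each factor site the expected IP signal is input_mean * (1 + c*f) inside
    the kernel footprint, where f is the site class's fractional occupancy
    from the equilibrium model under the mode's (Ka1, Ka2) and c is the
    ``protein_budget`` amplitude; elsewhere IP equals the input mean.  The
    "mutant" affinities therefore lower telomere-proximal enrichment and
    raise secondary-site enrichment relative to "WT".  Poisson counts are
    never negative, so no clipping is required.
    """
    f_primary, f_secondary = _site_occupancies(config, mode)
    # independent noise per mode, same planted expectation structure
    mode_rng = np.random.default_rng([_SUBSTREAMS["chip"], config.seed,
                                      0 if mode == "WT" else 1])

    ip_data, in_data = {}, {}
    occupancy: dict[str, float] = {}
    for chrom, length in layout.chromosomes.items():
        n_bins = -(-length // config.bin_size)
        expected_ip = np.full(n_bins, config.input_mean)
        sites = layout.factor_sites[layout.factor_sites["chrom"] == chrom]
        centers = (np.arange(n_bins) + 0.5) * config.bin_size
        for _, site in sites.iterrows():
            f = f_primary if site["site_class"] == "primary" else f_secondary
            occupancy[f"{chrom}:{int(site['pos'])}:{site['factor']}"] = f
            d = np.abs(centers - site["pos"])
            if config.kernel == "flat":
                bump = (d <= config.kernel_halfwidth).astype(float)
            else:
                bump = np.exp(-0.5 * (d / (config.kernel_halfwidth / 2.0)) ** 2)
            expected_ip = np.maximum(
                expected_ip, config.input_mean * (1.0 + config.protein_budget * f * bump)
            )
        in_data[chrom] = mode_rng.poisson(config.input_mean, size=n_bins).astype(float)
        ip_data[chrom] = mode_rng.poisson(expected_ip).astype(float)

    lengths = dict(layout.chromosomes)
    ip = CoverageTrack(data=ip_data, bin_size=config.bin_size, lengths=lengths)
    inp = CoverageTrack(data=in_data, bin_size=config.bin_size, lengths=dict(lengths))
    return ip, inp, TruthTables(true_occupancy=occupancy)


# ---------------------------------------------------------------------------
# Differential expression


def simulate_expression(
    layout: GenomeLayout,
    peaks: pd.DataFrame,
    config: SimulationConfig,
    upstream: int = 500,
) -> tuple[pd.DataFrame, TruthTables]:
    """Per-gene DE table with planted repression under peaks.

    Genes whose body plus the 5' upstream margin intersects a peak have their
    replicate log2 ratios drawn from N(effect_log2fc, sigma^2); all other
    genes from N(0, sigma^2).  The reported log2fc is the replicate mean, the
    p value a one-sample t-test against 0 at ``n_replicates``, adjusted by
    Benjamini-Hochberg.  A negative-binomial base-count column (dispersion
    ``nb_dispersion``) is included for realism but carries no signal.
    """
    from scipy import stats

    rng = _rng(config.seed, "expr")
    assigned = peaks_to_genes(peaks, layout.genes, upstream=upstream)
    covered = set(assigned["gene"]) if len(assigned) else set()

    rows = []
    n = config.n_replicates
    for _, g in layout.genes.iterrows():
        mu = config.effect_log2fc if g["name"] in covered else 0.0
        reps = rng.normal(mu, config.sigma_log2fc, size=n)
        base_mean = float(rng.lognormal(mean=np.log(100.0), sigma=1.0))
        # NB counts around base_mean with dispersion alpha: var = m + alpha*m^2
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + base_mean), size=n)
        t, p = stats.ttest_1samp(reps, 0.0)
        rows.append(
            {
                "gene": g["name"],
                "log2fc": float(reps.mean()),
                "pvalue": float(p),
                "base_mean": float(counts.mean()),
            }
        )
    df = pd.DataFrame(rows)
    df["padj"] = _bh_adjust(df["pvalue"].to_numpy())
    truth = TruthTables(true_repressed=tuple(sorted(covered)))
    return df, truth


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out
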
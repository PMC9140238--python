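# Methods

## Bar-seq lifespan quantitation

Each strain carries two independent barcodes ("up" and "down") amplified in
separate reactions, so the two channels are treated as independent estimates
of the same abundance. Counting scans every offset of every read on the
forward strand (single-end amplicon design; a reverse-complement flag exists
for libraries sequenced the other way) and accepts a read only when exactly
one distinct barcode matches within the allowed Hamming distance (0 by
default, optionally 1 via a precomputed one-substitution neighbourhood
index). Reads matching two or more distinct barcodes are tallied as
ambiguous and excluded; matched + unmatched + ambiguous always equals the
read total.

Scores: per sample and channel, counts are multiplied by an optional
per-sample scale factor (an "amplified DNA signal" adjustment; default 1 —
note it cancels under the within-channel normalisation that follows, so it
is retained purely as an explicit knob), given a pseudocount of 0.5 reads to
keep log ratios finite for dropout strains, and normalised to the channel
total. The up and down fractions are averaged *after* normalisation because
each channel is a separate amplification with its own depth. The lifespan
score is log2(v_t / v_t0) with t0 the first stationary-phase sample, then
the per-timepoint median over strains is subtracted so the median strain
sits at exactly 0 in every panel (a global-median variant is available;
per-timepoint is the default because each timepoint is plotted as its own
panel). Ranking sorts by descending score with ties broken by ascending
strain id; "top tenth percentile" is ceil(0.1·n) strains.

## ChIP tracks, telomere/core partition, peaks

Coverage lives in fixed-width bins (default 50 bp), 0-based half-open;
bedgraph is read/written in the same convention and wiggle is written as
1-based fixedStep. IP and input are each scaled so their genome-wide sums
equal a common target (default 1e6) before the per-bin ratio
(ip + ε)/(input + ε) is formed with a small guard pseudocount. The
telomere/core partition takes the mean ratio over both terminal windows
(default 20 kb; both chromosome ends count as telomeric) and over the
interior, each divided by the bp-weighted genome mean; partial bins at
window edges are weighted by their bp overlap, which makes the weighted
identity (tel·tel_bp + core·core_bp) / genome_bp = 1 hold to rounding.
Chromosomes not longer than twice the window have no interior and are
flagged out of the core statistics. Group differences use the Welch
(unequal-variance) two-sample t-test, two-sided, significance at 0.05; two
constant equal groups are defined to give t = 0, p = 1.

Peak calling is a deliberate minimal stand-in for a fragment-model caller:
maximal runs of bins at or above a ratio threshold (default: genome mean +
2 sd), merged across gaps ≤ merge_gap, dropped below min_len. It is
exhaustive at its threshold, so masking called peaks leaves nothing callable.
Gene assignment extends each gene 500 bp on its 5' side (strand-aware) and
requires ≥ 1 bp of half-open intersection with a peak.

## Equilibrium binding model

The model generalises to N site classes; all defaults use two (primary and
secondary). Units are fixed at µM and µM⁻¹. Three regimes are exposed as
separate functions rather than internal switches so approximation error is
always inspectable: the limiting-protein closed form
f_i = Ka_i·B_i/(1 + ΣKa_j·B_j); the abundant-site limit f_i = Ka_i/ΣKa_j
(valid when all B are equal and Ka·B ≫ 1 — the dimensionally careful reading
of "abundant sites"); and an exact mass-balance solver that brackets the
free-protein concentration in [0, P_tot] (the conservation residual is
strictly increasing there) and solves it with Brent's method at relative
tolerance 1e-12. Redistribution is reported as the percent change of each
class's bound fraction between two affinity pairs in the abundant-site
limit, which makes it invariant to common rescaling of the affinities; a
zero WT fraction yields an undefined (None) change rather than a division.

## Enrichment statistics

The binomial overlap test offers the point probability C(n,k)p^k(1−p)^(n−k)
— the published form of the computation — and the upper tail P(K ≥ k),
which is the quantity recommended for actual inference; both are evaluated
in log space via scipy. The background fraction p is always an explicit
input, never computed implicitly, because its reference set (all genes vs
expressed genes) is a modelling choice. The Poisson motif test resolves
"sites per unit length" as per-bp genome density × total peak bp for λ and
counts in-peak sites with half-open containment (a site on a peak's end
coordinate is outside), matching the track convention.

## Synthetic-data generator

The generator emulates the study conditions: 400 dual-barcoded strains
sampled at days 6/20/34/44/55 of stationary phase at 10⁶ reads per
timepoint; a 16-chromosome, coordinates-only genome (lengths drawn once per
seed in 150–400 kb — a desk-scale genome, roughly a third of real yeast
chromosome lengths, keeping bin counts small) with 20 kb telomeric windows,
~400 non-overlapping 1.5 kb genes, one primary factor site per chromosome
end and two secondary sites per core; and WT/mutant affinity pairs (50, 10)
and (10, 5) µM⁻¹ feeding the binding model.

Survival uses exponential decay exp(−rate·day) per strain — the minimal
monotone model, since no survival law is prescribed — with rates drawn
uniformly on [0, 0.15]/day, a range that spans near-immortal to
mostly-gone-by-day-44 strains. Reads are multinomial draws per channel at
exactly the configured depth, each read embedding the strain barcode between
the amplicon's printed primer contexts with constant Q40 quality.
Sequencing error beyond optional uniform substitution is out of scope.

ChIP input is Poisson noise around a uniform per-bin mean (20 reads/bin);
the expected IP is input_mean·(1 + c·f) inside a flat-top ±1 kb footprint
around each site (Gaussian kernel optional), where f is the class occupancy
from the binding model under the mode's affinities and c = 10 is the
enrichment amplitude. Because Poisson counts cannot go negative, the
clipping path the API reserves for additive-noise kernels never triggers.
Equal-sum normalisation of the simulated pair puts the unenriched baseline
slightly below ratio 1 (the bumps inflate the IP total), so recovery checks
measure bump heights above the measured baseline.

Expression: replicate log2 ratios are N(effect, σ²) for genes under peaks
(body + 500 bp upstream) and N(0, σ²) otherwise, with effect = −1, σ = 0.2,
4 replicates; the reported log2FC is the replicate mean, the p value a
one-sample t-test, adjusted by Benjamini–Hochberg. A negative-binomial
base-count column (dispersion 0.1) is included for table realism but
carries no signal. All randomness derives from one root seed through named
substreams (layout/strains/rates/barseq/chip/expr), so any product is
reproducible in isolation and same-seed outputs are bit-identical.

What passing tests on this generator do and do not show: they demonstrate
that the quantitation, partition, peak calling and statistics recover
planted signals of the modelled form under Poisson/Gaussian/NB noise; they
do not exercise amplification bias, mappability structure, real subtelomeric
repeat content (X/Y′ elements), copy-number effects, or correlated
biological replicates, so real-data effect sizes and p values will differ.

## Problem sizes and numerical choices

The test suite and examples run the full design (16 chromosomes, 400
strains) with read depth 10⁶ only in the single end-to-end ranking check and
2–3×10⁴ elsewhere; the redistribution study uses the generator's default
genome at bin size 50 (~90k bins). Tolerances: closed-form identities at
1e-12, the mass-balance solver at 1e-10, Monte-Carlo comparisons at three
binomial standard errors of the simulation.

## Known limitations

The peak caller has no fragment model, local background or multiple-testing
control — it is for planted-signal recovery and as a transparent stand-in,
not for production peak calling on real libraries. The barcode matcher
allows at most one substitution and no indels. The binding model is
equilibrium-only: no cooperative spreading along nucleosomes and no
kinetics. DE tables are consumed (or simulated), never estimated from raw
counts.
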
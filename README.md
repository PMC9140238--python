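# histolife

Analysis toolkit for pooled chronological-lifespan screens in budding yeast
and the heterochromatin redistribution that accompanies them. It covers four
connected questions:

1. **Which strains in a pooled, dual-barcoded mutant library live longest in
   stationary phase?** Strain-specific "up" and "down" barcodes are counted
   in the sequencing reads of each timepoint, averaged per strain, and
   expressed as the log2 ratio to the mixed starting population, adjusted to
   the per-timepoint population median. Ranking flags the top 10 strains, the
   top tenth percentile and the bottom 10.
2. **Does the silencing protein Sir3 move from telomeres to internal sites in
   a mutant?** IP and input coverage are scaled to an identical genome-wide
   sum, the per-bin IP/input ratio is split into the terminal 20 kb of each
   chromosome versus the interior core (each normalised to the genome mean),
   and groups of per-chromosome values are compared with a Welch t-test.
   Enriched regions are called by thresholding the ratio and assigned to
   genes whose body plus 500 bp upstream (strand-aware) they intersect.
3. **Why would a nucleosome-surface mutation redistribute Sir3?** An
   equilibrium competitive-binding model: with association constants
   `Ka1, Ka2` for primary and secondary site classes and limiting protein,
   the bound fractions are `f_i = Ka_i·B_i / (1 + ΣKa_j·B_j)`, collapsing to
   `f_i = Ka_i / ΣKa_j` when sites are abundant. With WT affinities
   (50, 10) µM⁻¹ primary sites are bound 5-fold above secondary sites; if a
   mutation drops them to (10, 5) µM⁻¹ the primary fraction falls 20% and the
   secondary fraction doubles — redistribution without any change in protein
   level. An exact mass-balance solver checks the approximations.
4. **Is the repression under the new peaks more than chance?** A binomial
   test on k down-regulated genes out of n peak-overlapping genes against the
   background down-regulated fraction, and a Poisson test for
   transcription-factor sites inside peaks against their genome-wide density.

A synthetic-data generator (`histolife.simulate`) produces every input with
planted ground truth — known death-rate rankings, binding-model occupancies
and repressed genes — so the whole pipeline is testable end to end without
external data.

## Worked example

```python
from histolife import fractional_binding_limit, redistribution_change

f1, f2 = fractional_binding_limit(50, 10)
print(f1, f2, f1 / f2)            # 0.8333... 0.1666... 5.0
print(redistribution_change((50, 10), (10, 5)))   # (-20.0, 100.0)
```

The 5.0 is the fold-excess of primary-site over secondary-site binding under
WT affinities; the (−20, +100) pair says the mutant loses a fifth of its
primary-site binding while doubling secondary-site binding.

Running `python examples/02_sir3_redistribution.py` simulates WT and mutant
ChIP on a 16-chromosome synthetic genome and prints:

```
WT: mean telomeric = 1.594, mean core = 0.906 (genome mean = 1)
mutant: mean telomeric = 1.443, mean core = 0.935 (genome mean = 1)
Welch t-test on telomeric values, WT vs mutant: t = 20.81, p = 2.24e-19 (significant at 0.05: True)
```

i.e. the mutant's telomeric enrichment is significantly lower and its core
signal higher — the redistribution signature. The other scripts in
`examples/` cover lifespan ranking (`01`), the binding model (`03`) and the
enrichment statistics (`04`); each prints a line explaining its numbers.

## Command line

Each library entry point is also exposed as a thin CLI:

```sh
histolife simulate --outdir demo --seed 3
histolife barseq count --fastq 6=demo/barseq_day06.fastq \
    --fastq 44=demo/barseq_day44.fastq --strains demo/strains.tsv --out counts.tsv
histolife barseq score --counts counts.tsv --t0 6 --out scores.tsv
histolife barseq rank --scores scores.tsv --at 44 --out rank.tsv
histolife chip ratio --ip ip.bedgraph --input input.bedgraph --out ratio.bedgraph
histolife chip partition --track ratio.bedgraph --out part.tsv
histolife chip peaks --ratio ratio.bedgraph --threshold 2 --out peaks.bed
histolife chip assign --peaks peaks.bed --genes genes.bed --out assigned.tsv
histolife model --ka-wt 50,10 --ka-mut 10,5
histolife enrich binomial --n 33 --k 22 --p 0.48
histolife enrich poisson --peaks peaks.bed --sites sites.bed --genome chrom.sizes
```

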
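# degenexp

Degenerative expansion of a young supergene: a tested reimplementation of
the computational chain behind the finding that the non-recombining *Sb*
variant of the fire-ant (*Solenopsis invicta*) social-chromosome supergene
has grown by >30% rather than shrunk.

Suppressed recombination is expected to degrade a chromosome — Y and W
chromosomes lose genes and eventually DNA. A young supergene offers a look
at the *early* phase, where theory predicts the opposite: insertions
(mostly repeats) are less deleterious than deletions, so they fix faster
and the non-recombining haplotype *expands* before it decays. This package
implements the four analysis stages that established this for the fire-ant
supergene, together with a synthetic-data generator that reproduces the
statistical structure of every input, so the whole pipeline is testable
without any raw sequencing or optical-map downloads:

1. **Optical-map comparison** (`degenexp.labelmaps`, `degenexp.mapalign`)
   — dynamic-programming alignment of ordered-label maps with a declared
   scoring model (Gaussian sizing error, truncated so large indels can be
   spanned; per-skipped-label penalty; free end gaps), calling of ≥3 kb
   insertions/deletions from matched-interval length differences, and
   "overhang" accounting of unaligned flanks.
2. **Enrichment statistics** (`degenexp.enrichment`) — Pearson χ²
   homogeneity of per-chromosome indel counts against length-proportional
   expectations *E*ᵢ = *n*·*L*ᵢ/Σ*L*, per-chromosome standardized residuals
   *Z*ᵢ = (*O*ᵢ−*E*ᵢ)/√*E*ᵢ with one-sided Bonferroni-corrected p-values
   (χ² = Σ*Z*ᵢ² exactly), cumulative-length shares, net overhang
   differences, and percent-expansion estimates
   100·(*L*_b/*L*_B − 1).
3. **K-mer genome sizing** (`degenexp.kmer`) — canonical 21-mer spectra
   from reads; haploid genome size as k-mer mass above the error valley
   divided by the single-copy depth peak; repeat fraction as the mass share
   above 1.5× that depth; paired one-sided *t*-test of b-vs-B percent
   differences with a 95% CI; propagation of a whole-genome difference
   Δ% to supergene scale as Δ%/*f* for a supergene occupying fraction *f*
   of the genome.
4. **Indel phylogeny** (`degenexp.phylogeny`) — presence/absence matrices
   of shared indels (kept only when present in ≥2 individuals and covered
   in all six), Hamming distances, neighbor-joining trees, and unrooted
   clan tests for species versus variant grouping.
5. **Forward simulation** (`degenexp.wfsim`) — Wright–Fisher populations of
   haploid non-recombining chromosomes accumulating insertions and
   deletions with configurable fitness costs; preset regimes demonstrate
   expansion (deletions costlier while functional elements persist), drift
   (no functional content, symmetric rates) and shrinkage (rare large
   ectopic deletions).

## Worked example

The enrichment stage applied to the published per-chromosome inputs (55 of
163 mapped insertions on a 29.61 Mb social chromosome in a 350.94 Mb placed
genome) and a planted synthetic genome:

```bash
$ python analysis/03_insertion_enrichment.py
published inputs recomputed:
  social_z: 11.1
  insertion_share_pct: 33.7
  social_genome_share_pct: 8.4
  expansion_lengths_pct: 31.7
  expansion_kmer_pct: 79.8
  expansion_repeats_pct: 47.94
...
example planted genome (seed 916): chi2=132.1 df=15, flagged=['chr16']
100 planted genomes: social chromosome uniquely flagged in 99%; deletions
spuriously flagged in 6%
```

Reading: the social chromosome carries 33.7% of insertions on 8.4% of the
genome (*Z* = 11.1); the b supergene variant is 31.7% longer by direct
length accounting, 79.8% by genome-size propagation, 47.94% by repeat
excess. On synthetic genomes with the same insertion bias, the enrichment
stage flags exactly the social chromosome in 99 of 100 seeds while the
uniformly placed deletions stay unflagged.

The simulator presets (`analysis/06_chromosome_simulation.py`, 1 Mb
chromosome, N = 200, 2000 generations):

```
expansion: mean final change +639 kb (SE 16), 20/20 replicates grew, sign-test p=9.5e-07
drift:     mean final change +14 kb (SE 18), 27/50 replicates grew, sign-test p=0.67
shrinkage: mean final change -405 kb (SE 38), 0/20 replicates grew, sign-test p=9.5e-07
```

The numbered scripts under `analysis/` run the remaining stages
(synthetic-input generation, optical-map indel calling, k-mer sizing,
phylogenies) and write their tables under `results/`.

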
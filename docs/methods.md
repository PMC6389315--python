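# Methods

This note documents the models, defaults and design choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout. All coordinates
are 0-based, half-open, and every generator is deterministic under a fixed
seed.

## Chromosome table

All enrichment expectations are normalized by a table of placed chromosome
lengths. The built-in fire-ant table has 16 chromosomes totalling
350.94 Mb, a 29.61 Mb social chromosome (8.4% of the placed genome), and a
supergene interval at 7.7–28.6 Mb of that chromosome. The lengths of
chromosomes 1–15 are a fixed plausible decreasing series constrained to
the correct total; only the social chromosome's length and the totals
enter any reported statistic. Unplaced content is excluded from the
denominator by construction.

## Synthetic genome pairs

`SyntheticGenomeSpec` plants `n_insertions` and `n_deletions` (all ≥3 kb,
the downstream detection floor) between a B genome and its b derivative.
With probability `insertion_bias` an insertion anchor is uniform inside
the supergene interval; otherwise placement is length-uniform across
chromosomes, as it is for all deletions. The default bias 0.2762 is
derived by solving
`share = bias + (1 − bias) · L_social/L_total` for an expected
social-chromosome insertion share of 33.7%, the observed value. Indel
sizes are log-uniform on [3 kb, 100 kb]; the empirical size law of large
indels is not established, so this heavy-tailed default is configurable.

Tandem-repeat families are shared arrays embedded in B whose extra copies
in b are recorded in the truth table as insertions at the array edge, so
B/b genome-size differences are concentrated in repeats, as observed.
The truth table is exhaustive: applying its edits to B reconstructs b
byte-for-byte (tested against an independent string-splicing oracle), and
it carries coordinates in both genomes.

Read simulation uses uniform start positions and substitution-only errors
(no indels in reads). This is sufficient for k-mer spectra — the only
consumer — where substitutions produce the low-multiplicity error
component; read-level indels would only perturb a k-mer's identity in the
same way. Per-base depth is Poisson(coverage) away from contig ends.

## Label maps and alignment

A label map is an ordered list of label coordinates plus a contig length —
a deliberately minimal stand-in for optical restriction maps. The noise
model has three parameters: Gaussian perturbation of inter-label intervals
(`sizing_sd_bp`, default 150 bp), independent Bernoulli label loss
(`miss_rate`), and Poisson false labels (`false_rate`). Molecule-level
artifacts (chimeras, stretch variation) are deliberately out of scope.

Alignment maximizes, over monotone non-crossing matchings, a score with a
fixed bonus per matched pair (default 6), minus the squared sizing error
of the flanked intervals in units of `sizing_sd_bp`, minus a penalty
(default 3) per internally skipped label, with at most `max_skip` = 3
labels skipped per step and free end gaps. Two numerical choices matter:

* the sizing cost is **truncated** at `cost_cap` (default 12 squared-sd
  units). Without the cap, a single large indel would make splitting the
  alignment cheaper than spanning the discrepant interval, and with free
  end gaps the optimum would silently drop one side of the map. With the
  cap, spanning an indel costs at most `cost_cap − match_bonus`, so chains
  continue across structural differences and the indel appears as an
  interval-length difference.
* ties are broken toward fewer skipped labels, then toward the nearer
  predecessor, making tracebacks reproducible.

The DP (`S[i,j]` = best score of a matching ending at pair (i,j)) is
verified against exhaustive enumeration of all monotone matchings on
instances up to 12 labels.

Indel calls: for each pair of consecutive matched intervals with length
difference |ΔL| ≥ 3 kb, one call of size |ΔL| — insertion if the b
interval is longer. The call is located on the flanking matched interval
of the reference map, because optical resolution cannot place breakpoints
within an interval; adjacent calls are not merged. Overhangs are the bp
between a map end and its outermost matched label; flanks under 1 kb are
below resolution and not reported. Reciprocal consistency matches calls
from the two alignment directions by opposite type and overlapping
flanking-label intervals on the shared map, and reports the recovered
fraction of all pooled calls.

## Enrichment statistics

Expected counts are proportional to chromosome length (an alternative
equal-per-chromosome expectation is not offered; homogeneity "according
to chromosome size" is the hypothesis of interest). The per-chromosome
standardized residual Z = (O−E)/√E reproduces the published Z = 11.1 for
55/163 insertions on 29.61/350.94 Mb; the Pearson identity χ² = ΣZ²
holds to 1e-9 and is property-tested. One-sided upper-tail normal
p-values are used (only enrichment is of interest) with Bonferroni
correction by the chromosome count. Percentages are reported at one
decimal place, with raw values retained.

Net overhang differences can be negative and cannot enter a plain χ²;
the homogeneity test used here is a 2×16 contingency χ² on per-sample
overhang bp totals across chromosomes. This is a declared substitute for
the unspecified construction behind the published overhang statistic and
is not claimed to reproduce its value (83.25).

## K-mer genome sizing

Canonical k-mers (lexicographic minimum of the 2-bit forward and
reverse-complement encodings, k = 21) are counted from reads; windows
containing non-ACGT characters are skipped and counted. The estimator is
the standard peak-normalized mass method, adequate for haploid males
(single depth peak, no heterozygosity mixture):

* **error cutoff** — the bottom of the initial descent of the histogram
  when mass exists at multiplicity 1–2; a spectrum that never rises again
  has no detectable peak and raises an error requesting deeper coverage;
* **depth λ** — the count-weighted mean multiplicity of all mass between
  the cutoff and 1.5× the modal multiplicity. A symmetric window around
  the mode would clip the right tail of the Poisson peak and bias the
  size upward by several percent; the truncated mean keeps median |bias|
  under 1% at 30× with 0.1% errors;
* **genome size** — k-mer mass above the cutoff divided by λ (multi-copy
  mass counts multiply, as it should);
* **repeat fraction** — mass share above 1.5λ (configurable multiplier;
  1.5 separates single-copy from ≥2-copy mass with a testable rule).

Note the effective per-k-mer depth is coverage·(read_length−k+1)/read_length
(≈24 at 30× with 100 bp reads), which is what the peak estimates.

The paired B/b comparison takes per-pair percent differences
100·(b−B)/B, a two-sided 95% t-CI on their mean and a one-sided paired
t-test (alternative b > B). Zero-variance inputs collapse the CI to the
mean with p = 0.5 at the boundary. Propagation divides the mean (and CI
bounds) by the supergene's genome fraction, under the stated assumption
that the entire genome-size difference lies in the supergene; with the
published 3.59% (2.02–5.16%) and fraction 0.045 this yields 79.8%
(44.9–114.7%). The repeat-excess route divides excess repeat bp by the
B-variant supergene length (10.02 Mb / 20.9 Mb = 47.94%). Per-superfamily
repeat classification requires external repeat libraries and is out of
scope; repeat content here is defined purely by k-mer multiplicity.

## Indel phylogeny

Loci are merged across individuals by transitive reciprocal 50% overlap
(the merging rule is not established; the threshold is configurable) and
retained only when present in ≥2 individuals and covered in all six.
Distances are Hamming counts over loci — absence is informative because
coverage is guaranteed by the filter — with Jaccard optional. Trees are
neighbor joining (scikit-bio); because no outgroup exists in-system,
grouping is assessed by the unrooted clan criterion (one edge separates
the group from everything else). NJ correctness is tested against exact
path distances of random additive trees. The planted-matrix generator
makes background loci species markers and supergene loci variant markers
with 5% flip noise and 5% missing coverage; both groupings are recovered
in ≥95% of seeds.

## Forward simulation

Each haploid individual carries one non-recombining chromosome: a length,
a set of intact functional elements, and a fitness that is multiplicative
over incurred disruptions, (1−s_ins)^a (1−s_del)^b. A disrupted element
costs nothing on further hits, which is the degeneration feedback: as
elements are lost, deletions stop being selected against. Insertions add
neutral DNA (modelling repeat gain) and disrupt an element only when they
land inside one; deletions remove their span and disrupt every element
they touch (full cost, not dose-graded). Event counts per chromosome per
generation are Poisson with length-independent rates by default; a
per-bp mode scales rates by current length, which changes the long-run
dynamics and is therefore opt-in. Deletions are clipped so length never
falls below 1 kb. Length bookkeeping is exact and replayed from event
logs in tests.

Reproduction is standard Wright–Fisher: N offspring draw parents with
probability proportional to fitness, then mutate. The selection machinery
is validated against the diffusion approximation (fixation probability
≈2s for a single beneficial variant, N = 500, s ∈ {0.01, 0.05}).

The quantitative parameters of the original simulations are not
established, so the presets are this module's own and the claims tested
are directional only:

* **expansion** — N = 200, T = 2000, L0 = 1 Mb, 120 elements of 5 kb
  (60% functional coverage, so a mean-5 kb deletion almost always hits
  one), μ_ins = μ_del = 0.1, s_del = 0.05 ≫ s_ins = 0.005: mean length
  grows (~+0.6 Mb), sign test across 20 replicates p < 0.01;
* **drift** — no elements, symmetric rates and sizes: mean change within
  2 SE of zero across 50 replicates;
* **shrinkage** — no elements plus an ectopic channel (rate 0.02,
  exponential mean 20 kb): mean length falls, sign test p < 0.01.

A separate feedback configuration (smaller costs so deletions do fix)
shows growth slowing as intact-element counts erode, the predicted brake
on expansion.

## Problem sizes and what the tests show

Synthetic genomes for sequence-level work are hundreds of kb (two
chromosomes, 30× coverage); enrichment and phylogeny studies use the
full-scale chromosome table with coordinate-only planting; simulator
presets are as above. These scales make every study run in seconds to a
few minutes while leaving the statistics in the same regimes as the
original data (same counts, rates, biases and noise levels where those
are known). Passing tests demonstrate internal correctness and planted-
structure recovery under the declared noise models; they do not
demonstrate robustness to real optical-map artifacts (chimeric molecules,
stretch variation), real repeat landscapes, or library/GC biases in
sequencing, none of which are emulated.

## Known limitations

* The optical-map scoring model is a minimal standard one; the original
  comparisons used a proprietary tool whose parameterization is unknown.
* Genome-size estimation assumes a single haploid depth peak; diploid or
  contaminated samples would need a mixture model.
* The overhang homogeneity statistic is a declared substitute (see above).
* Inversions are not modelled: the generator plants only insertions and
  deletions, and no breakpoint discovery is implemented.
* No repeat superfamily classification, no divergence dating, no dS
  computation: these need external data or tools.
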
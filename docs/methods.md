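# Methods

Precise definitions of every computation in `dellaseq`, the parameter
defaults, and the numerical choices behind them. Coordinates are 0-based,
half-open throughout; strand-aware quantities are defined from the
transcription start site (TSS) and transcription end site (TSE), where for a
minus-strand gene the TSS is the last base of the transcript interval and
the TSE the first.

## 1. Summit merging into reproducible binding sites

Input: one summit list per ChIP replicate (≥ 2 replicates required).

*Clustering.* Summits on one chromosome are sorted by position and chained
by single linkage: consecutive summits at most `max_distance` apart
(default 200 bp) belong to one chain. Each chain is then split greedily
left to right into blocks whose **maximum pairwise span** is ≤
`max_distance`; a block is extended while its leftmost and current summit
stay within the distance, then closed. A block is a *reproducible cluster*
when it contains summits from at least `min_replicates` distinct replicates
(default: all replicates). Non-reproducible blocks are discarded.

The greedy split is not guaranteed optimal for arbitrary inputs, so the
test suite compares it against a dynamic-programming oracle that enumerates
all contiguous partitions maximizing the number of reproducible clusters
(optimal for a span constraint on collinear points). On 1000 seeded
instances drawn in the generator's regime — true sites separated by at
least twice the merge distance plus the site width, Gaussian replicate
jitter (SD 40 bp), isolated decoys — the greedy result is exactly optimal
in every instance. Dense adversarial inputs (many summits uniform within a
few hundred bp) can make the greedy split suboptimal; such inputs do not
arise from summit calling on well-separated peaks.

*Site definition.* A cluster's representative position is the floor of the
mean summit position. The binding site is a fixed-width window (default
200 bp) centred there, shifted (never shrunk) to stay inside the
chromosome; a chromosome shorter than the site width is an error.

## 2. Peak-to-gene assignment

The anchor is the site's mean summit, a single point. For each gene the
anchor is classified as:

- **upstream** — inside the strand-aware window `[TSS − 2500, TSS)`
  (reflected for minus-strand genes); distance is |anchor − TSS|;
- **downstream** — inside `(TSE, TSE + 500]` strand-aware; distance is
  |anchor − TSE|;
- **five_prime_UTR / three_prime_UTR / intron** — structural categories for
  anchors inside the transcript; UTR intervals are exonic sequence outside
  the CDS, introns are gaps between exons. An anchor inside a **coding
  exon** is unassignable to that gene.

An upstream/downstream candidate is rejected when any *other* gene's
transcript body overlaps the open interval strictly between the anchor and
the relevant transcript endpoint (the intervening-gene rule). Among the
surviving candidates, the nearest gene **per strand** wins (ties broken by
smaller gene id), so a site is assigned to at most two genes and only when
they lie on opposite strands. Structural categories take precedence over
distance categories for the gene that contains the anchor.

## 3. Motif enrichment in site windows

*Windows.* The central `window_width` (default 200 bp, i.e. the whole
default site) around each site centre.

*Scanning.* Each position frequency matrix is converted to log2-odds
against the background base frequencies (default uniform) after adding a
pseudocount of 0.25 per cell at parse time. Both strands are scanned; a
window position is a *hit* when its score is at least
`score_threshold_fraction` (default 0.8) of the maximum attainable score.
`N` bases contribute 0 (background-neutral). A motif whose maximum score is
not positive is degenerate and is excluded from testing (and from the
Bonferroni denominator).

*Test.* For each motif, `k` = number of windows with ≥ 1 hit out of `n`
windows. The expected per-window hit probability `p` is estimated
empirically as the fraction of random background windows with ≥ 1 hit
(≥ 100 background windows required; floored at `1/(2·n_background)` so the
test remains defined for motifs never observed in the background sample).
The p-value is the exact upper-tail binomial `P(X ≥ k)` computed with
`scipy.stats.binom.sf(k − 1, n, p)`; the suite verifies ≤ 1e-12 relative
error against rational term summation up to n = 1000. Significance uses
Bonferroni: `alpha / n_tested`. Thresholds print truncated to two
significant figures in scientific notation, e.g. `0.05/254 → 1.9E-4`.

*Family aggregation.* Motifs sharing a family label are reported together
when at least one member is significant, with the best member p-value and
the number of windows hit by the union of member motifs (each window
counted once).

## 4. Z-score / Z-ratio differential expression

Each sample (column) of the log-intensity matrix is standardized to mean 0,
SD 1 (ddof = 1) across genes. For a contrast between two design cells,
`z_diff(gene)` is the difference of cell-mean z-scores, and
`z_ratio = z_diff / SD(z_diff across genes)`. Two-sided p-values come from
the standard normal; calls are `up` / `down` at `alpha` (default 0.05).

Classification combines the DEX-effect calls in the high-DELLA (PAC+) and
low-DELLA (PAC−) backgrounds: induced/repressed only under PAC+ →
DELLA-dependent; in both → DELLA-independent component present
(`*_both`); only under PAC− → `*_della_independent_only`; opposite signs →
`discordant`; neither → `null`.

Because the denominator is the cross-gene SD of `z_diff`, power degrades by
construction when a large fraction of genes carries real effects (the SD is
inflated by the effects themselves). Calibration and recovery are
therefore validated in a sparse regime (~6 % planted genes): null
false-positive rate 0.05 ± 0.02 and class sensitivity/specificity ≥ 0.9 at
effect 2 (log2 units) and noise SD 0.25.

## 5. ChIP-qPCR enrichment

Quantities derive from cycle thresholds as `Q = efficiency^(−Ct)`
(efficiency in (1, 2], default 2). Technical replicates are aggregated as
mean Ct per (amplicon, fraction, condition) before any ratio.

- **Double normalization** (default): `[Q_IP(target)/Q_IP(control)] /
  [Q_input(target)/Q_input(control)]` — the classic 2^−ΔΔCt at
  efficiency 2. The internal control amplicon (e.g. HSF) has enrichment
  exactly 1 by construction.
- **Input-only normalization**: `Q_IP / Q_input` per (amplicon, condition),
  optionally followed by a between-condition ratio in which the input terms
  cancel.

SDs are propagated on the log2 scale by the delta method from the standard
errors of the group mean Cts; condition-ratio SDs combine in quadrature.

## 6. Synthetic-data generator

One run seed drives everything; each stage derives its own
`numpy.random.Generator` from a fixed offset (`default_rng([offset, seed])`)
so stages are independently regenerable. Defaults define the study-like
regime and are fixed:

- **Genome**: 2 chromosomes × 200 kb, i.i.d. background bases; 200
  non-overlapping genes with a fixed architecture (1000 bp transcript, two
  exons flanking one 200 bp intron, 100 bp UTRs at both ends, ≥ 200 bp
  inter-gene gaps), random strands.
- **True sites**: 40, placed uniformly but ≥ 2×merge-distance + site-width
  apart (or, in promoter mode, upstream of random TSSs with clearance from
  neighbouring gene bodies).
- **Summits**: 3 replicates; per replicate one summit per true site with
  Gaussian jitter (SD 30 bp) plus 10 decoys kept ≥ 2×merge-distance from
  every true site and every other decoy, so decoys can never form a
  reproducible cluster.
- **Motifs**: a 12-motif synthetic PWM library (10 bp, information 0.9,
  families in pairs). Planting writes the per-column argmax consensus (so
  any sensible score threshold fires) at a uniform offset and strand inside
  the central window, with per-motif planting probabilities; planting flags
  per (site, motif) are recorded as ground truth.
- **Expression**: factorial DEX × PAC, 3 replicates per cell; planted class
  effects of ±2 log2 units with Gaussian noise SD 0.25.
- **qPCR**: Ct tables constructed so that the noiseless double-normalized
  enrichment equals the chosen truth exactly.

## 7. Pipeline determinism

`run_pipeline` executes the enabled stages in dependency order, exchanging
data only through files, and writes `manifest.json` containing the fully
resolved configuration and a SHA-256 hash of every output. Reruns with the
same configuration produce identical hashes; this is asserted in the test
suite and reported by `scripts/acceptance.py`.

## Limitations

- No read-level simulation: the pipeline starts at called summits, so
  summit-calling noise beyond Gaussian jitter is out of scope.
- The empirical motif background assumes i.i.d. bases; genomic
  dinucleotide structure is not modelled.
- The greedy summit split is validated in the well-separated-peaks regime,
  not for adversarial dense inputs (see §1).
- Problem sizes throughout (genome size, library size, dataset counts) are
  the package's own desk-scale choices for fast, exact validation, not
  claims about any particular organism-scale dataset.
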
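# Methods

## The model in brief

A whole-genome duplication (WGD) doubles (a triplication triples) every
gene; fractionation then erodes the duplicates, and rearrangements break
up gene order. Self-comparison of a descendant genome underestimates this
history because fractionation destroys *both* sides of a paralogous
region pair's visibility, while a comparison against an outgroup
reference genome keeps one ortholog per region visible. `wgdsig`
therefore measures WGD history through the *multiplicity* of target
regions over the reference: the number B of syntenic blocks of the target
whose footprints overlap on a reference region. The empirical
distribution f(B) over all such "superblocks" decays roughly
exponentially, f(B) ≈ a·e^(−cB), and the decay rate c — aggregated over
reference genomes and parameter settings — orders genomes by the amount
of polyploidy in their history: heavier tails (small c) mean more WGD.

## Pipeline stages and their parameters

**Coordinates.** Annotations retain base-pair coordinates for
provenance, but every distance, gap and overlap is measured in 1-based
gene ordinals per chromosome (rank by start position, ties by end then
gene id). Gene order, not physical distance, is what survives the
processes being modelled.

**Chaining** (`wgdsig.synteny`). Anchors (homolog pairs in ordinal
coordinates) are chained per chromosome pair by dynamic programming:
consecutive anchors must advance strictly on both genomes (reference
descending for antiparallel chains) with per-step gaps of at most
`max_gap` genes (default 20) on both. Chains are scored by anchor count
with summed similarity as tie-break; the best chain is extracted, its
anchors removed, and the process repeats while the best chain still has
`min_anchors` ≥ minL anchors (minL default 5; 4 and 3 are credible and
are swept in the panel design). Extraction order is non-increasing in
score, so chaining once at the smallest minL of a sweep and
re-thresholding with `filter_blocks` is exactly equivalent to re-chaining
— the pipeline exploits this. The chainer is a deliberately simple
stand-in for production synteny tools; externally computed DAGchainer-style
block text can be imported instead, producing the same block type.
Tandem duplicates are not collapsed (a known limitation): tandem arrays
can inflate anchor counts within a block but do not by themselves create
extra blocks.

**Superblocks** (`wgdsig.superblocks`). Two blocks overlap when their
inclusive reference-span intersection contains at least T genes; the
sweep uses T ∈ {5, 10}. Requiring much more than ten genes suppresses
legitimate high multiplicities; much less than five invites artifacts, so
values outside [5, 10] warn. "A set of blocks spanning a contiguous
region" is formalised as a connected component of the pairwise-overlap
graph per reference chromosome: the pairwise wording is primary, the
union span is contiguous in coverage, and the result is independent of
input order. The alternative point-wise reading (maximum stabbing depth
at a single reference position) would give smaller multiplicities on
chain-like configurations; components are canonical here. Orientation is
ignored when testing overlap — only the reference footprint matters.

**Tail fitting** (`wgdsig.tailfit`). Unweighted ordinary least squares
of ln f(B) on B over all B ≥ B_min with f(B) > 0, for B_min ∈ {2, 3, 4};
c = −slope, a = e^intercept. Natural logarithm and unweighted OLS are
the plainest reading of a log-linear fit; weighting by counts would
shift estimates and is deliberately not done. Zero counts are excluded,
never imputed (a zero carries no log-scale information; plotting
conventions that draw f = 0 at 1 are display-only). Fits need at least
two usable points; otherwise the cell is recorded as missing and simply
drops out of downstream comparisons. c is invariant to positive
rescaling of the counts, so raw counts vs. relative frequencies is
immaterial for everything retained.

**Panel aggregation** (`wgdsig.ranking`). Every ordered (target,
reference) pair is crossed with the minL and B_min sweeps (and T when
swept). For each unordered target pair {G, H}, c values are compared
over every shared condition whose reference is neither G nor H; c(G) >
c(H) is a win for G, exact ties and missing cells count for neither.
Genomes are ranked by dominance — the number of opponents beaten in the
majority of shared comparisons — with total wins and then genome id as
tie-breaks. Dominance was chosen over raw win totals because the
head-to-head majority is robust to a single opponent contributing many
lopsided cells; totals are still reported and exported.

## The simulator: what it emulates, and what it does not

`wgdsig.simulate` scripts a two-lineage (or star-shaped multi-genome)
history: optional shared polyploidies on the root lineage, a split at
`speciation_time`, then per-lineage WGD events, fractionation, and
rearrangements. Parameters and defaults:

- `n_ancestral_genes` 2000, `n_chromosomes` 8 — panel-scale runs; small
  unit tests use a few hundred genes.
- `lambda_rate` 0.8 per copy per time unit — over an interval d, each
  copy of a gene beyond the first is lost with probability 1 − e^(−λd),
  losses drawn uniformly among the gene's copies, never deleting the
  last copy (loss of all copies is taken as lethal). For a duplicate
  pair this leaves the extra copy with survival probability e^(−λt),
  and the rule composes memorylessly across intervals.
- `n_inversions` 20, `n_translocations` 5 per lineage — enough to
  fragment blocks noticeably at the 2000-gene scale without destroying
  synteny.
- `similarity_rate` 0.21, `similarity_noise_sd` 1.5 (noise truncated at
  ±3 SD) — percent similarity is 100·e^(−rate·divergence); with a
  speciation one time unit ago orthologs sit near 81%, and copies split
  by a shared event at 1.5 units sit near 73%, echoing the separation
  between recent-WGD paralog and older ortholog similarity modes seen in
  real comparisons.

The validation study conditions place two shared WGDs (times 2.0 and
1.6) before a three-genome radiation at time 1.0, with 0, 1 (time 0.5)
or 2 (times 0.6, 0.3) additional lineage duplications. The shared events
mirror the ancestral polyploidies that all study systems carry: they
guarantee every genome — including the WGD-free lineage — a non-trivial
f(B), so its c is *large* rather than undefined, which is exactly how a
basal WGD-free genome behaves against a panel of references.

Not emulated: nucleotide or protein sequences (similarities are
generated directly), tandem duplication and transposon noise, biased
subgenome fractionation, block-wise (segmental) deletion, gene
conversion, and phylogenetic structure beyond a star radiation.
Consequently, passing tests show the statistic recovers *scripted* WGD
histories under gene-by-gene fractionation and uniform rearrangement;
they do not show robustness to assembly artifacts, tandem arrays, or
rate variation across lineages, all of which affect real comparisons.

## Numerical and degenerate-case choices

- All randomness flows from a single seeded `numpy.random.Generator`
  per simulation; reruns are byte-identical, and replicate studies vary
  the seed explicitly.
- Chaining ties (equal anchor count and summed similarity) resolve to
  parallel orientation first, then lexicographically smallest anchor
  chain; block ids encode chromosome pair and extraction order.
- Interval overlap of inclusive ordinal spans is
  max(0, min(hi) − max(lo) + 1); inverted intervals are hard errors.
- Histogram bins for similarity summaries are half-open [lo, lo + w)
  with a closed top bin so a similarity of exactly 100 is representable.
- Empty homolog tables, empty block sets and empty distributions flow
  through as empty results; undefined tail fits are recorded as missing
  cells, never raised, inside the panel sweep.
- Validation-study problem sizes: 20 replicate panels of three genomes
  at 2000 ancestral genes, full minL × B_min sweep at T = 5 — about one
  to two seconds per replicate, chosen to keep the whole validation
  under a minute while leaving the per-cell statistics stable.

## Known limitations

- The chainer is greedy best-first per chromosome pair; it does not
  implement syntenic-depth quotas, block merging, or Ks-based anchor
  filtering, and is not a substitute for a production synteny pipeline
  on real assemblies — import real block calls for real analyses.
- Connectivity-based superblocks can chain long series of marginally
  overlapping blocks into one high-multiplicity component on heavily
  rearranged genomes; the T threshold bounds but does not eliminate
  this.
- The exponential tail model is descriptive: no goodness-of-fit or
  confidence interval for c is computed, matching its intended use as a
  comparative rank statistic rather than an absolute estimate.
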
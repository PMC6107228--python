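# Methods

This note documents the models and procedures implemented in `antisd`, the
parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not establish.

## Re-annotation of 16S rRNA 3' ends

**Model.** The mature 16S rRNA ends a fixed 13 bases after the 3' end of
helix 45, its terminal conserved hairpin; the anti-Shine-Dalgarno hexamer
`CCTCCT` (DNA alphabet) occupies tail positions 6-11, i.e. it starts 5
bases after the helix.  Genome annotations that truncate the gene early can
therefore be corrected by locating helix 45 and extending the 3' coordinate
to helix end + 13.  The tail length is treated as exactly 13 throughout;
organisms with genuine 14- or 15-base tails are outside the model and will
be classified from their first 13 bases.

**Procedure.** For every annotated 16S feature, a window of the annotated
span plus up to 500 bases of flank on each side is extracted in coding
orientation (flanks truncate silently at contig edges).  A 24-base helix-45
query — by default the last 24 helix-45 bases of *E. coli* K-12,
`TAACCGTAGGGGAACCTGCGGTTG` — is slid ungapped over every offset and scored
per base: identity 1, Watson-Crick complement 0.25 (A↔T, C↔G), anything
else 0 (N scores 0).  Placements scoring >= 18.0 qualify; the best
qualifying placement wins, with ties broken toward the 3'-most offset so
the reported tail abuts the true terminus when the helix motif repeats
locally.  The search runs on the coding strand only, trusting the source
annotation's strand.  The 13 bases after the placement are the tail; the 23
bases (tail + 10 genomic bases) are recorded for consensus matrices.

**Classification** is a partition: `no_helix45` (no qualifying placement);
`ambiguous` (fewer than 13 bases past the helix, or N in the tail);
`annotated_ok` (exact `CCTCCT` in the tail and the annotated 3' end at or
beyond helix end + 13); `reannotated` (exact `CCTCCT` but annotated end
short; extension = helix end + 13 − annotated end); `variant_close`
(no exact `CCTCCT`, exactly 5/6 identities at the canonical window — the
one-substitution cases); `variant_absent` (<= 4/6).  An exact `CCTCCT` at a
non-canonical tail position is surfaced in a separate report column for
manual review but does not change the category, mirroring how such cases
must be inspected individually.  For multi-copy genomes one representative
gene per taxid is chosen by maximum (helix score + antiSD identities), ties
to the lowest genomic start coordinate.  Multi-copy tail heterogeneity is
summarized over 37-base classes (24 aligned helix bases + 13-base tail),
majority class largest, ties to the lexicographically smallest sequence.

## SD discovery statistic

**Counting.** For each CDS, the W = 20 bases immediately 5' of the start
codon are collected on the coding strand (windows shorter than k after
contig truncation, or containing N, are dropped; overlap with neighboring
genes is ignored).  For every pattern of length k = 7, X counts the windows
containing the pattern within d = 1 mismatch.

**Null model.** Windows are modeled as draws from an order-m Markov chain
(default m = 3) estimated from the windows themselves with add-one
pseudocounts; the initial distribution is the pooled m-mer frequency.  The
z-score treats windows as independent Bernoulli trials:

    z = (X − Σᵢ pᵢ) / sqrt(Σᵢ pᵢ (1 − pᵢ)),

with pᵢ the exact probability that a random length-Lᵢ string from the model
contains at least one substring within Hamming distance d of the pattern.

**Exact containment probability.** pᵢ is computed by dynamic programming
over the distribution of the last t = max(k−1, m+1) bases of a growing
random string.  Any transition that would complete a word of the pattern's
Hamming ball (1 + 3k words for d = 1) is killed; the surviving mass after
L − t steps is P(no match).  Because all states sharing their low t−1
digits feed the same four successor states with the same conditional
probabilities, one step reduces to a reshape-sum plus an outer product over
the 4^t state vector, with a small per-pattern correction for the killed
transitions — scoring all 4^7 patterns takes a few seconds on one core.
When t >= k (small k with a high-order background) the prefix distribution
is additionally filtered to exclude prefixes that already contain a match.
The DP is validated against exhaustive enumeration of all 4^L strings
(k <= 5, L <= 10, random order-0/1 models) to 1e-12, and against Monte
Carlo sampling at 100,000 windows within 4 standard errors.

**Ranking and significance.** All 4^k patterns are sorted by z (ties
lexicographic).  A genome is scored significant when the 20th-ranked
pattern has z > 5.  Note one consequence of the exact statistic: when a
motif is planted verbatim in a large fraction of windows, its entire
Hamming-1 ball receives identical planted counts, so the top of the ranking
is a ~22-way near-tie and the exact pattern itself may rank anywhere within
it; the profile step below is what recovers the motif robustly.

**Profile and consensus.** The rank-1 pattern anchors an alignment at
offset 0; every other top pattern is placed at the offset in ±(k−1)
maximizing agreement with the anchor (ties: smallest |offset|, then
negative).  A z-weighted position frequency matrix with add-one
pseudocounts is scored per column by relative entropy (bits) against the
background base marginal.  The consensus reads the majority base over the
longest contiguous run of *informative* columns overlapping the anchor,
where informative means RE >= 0.5 bits **and** majority-base frequency
>= 0.5.  Two numerical choices deserve comment:

* *RE threshold 0.5 bits.*  A clean motif column in a z-weighted PFM has a
  majority frequency near 0.85; against a background marginal already
  enriched for the motif's bases this measures ~0.9 bits, well below the
  2-bit point-mass ceiling.  0.5 bits corresponds to roughly two-fold
  enrichment of the majority base and keeps genuinely conserved columns
  while rejecting background.
* *Majority requirement.*  A column split ~0.46/0.46 between two bases can
  still carry ~0.75 bits of RE, but has no majority base to read off;
  requiring a majority keeps such flanking columns out of the consensus
  string.

Both are configuration of this package's profile reconstruction, not claims
about any other implementation of the procedure.

## SD vs tail comparison

The a-tail is the reverse complement of the 13-base tail
(`TAAGGAGGTGATC` for the *E. coli* tail).  Presence: `present` if the SD is
an exact substring of the a-tail; `close` if its best full-length placement
has exactly one mismatch (shifted partial overlaps do not count as close);
`absent` otherwise.  Type: `AGGAGG` if the SD is a substring of the classic
`AGGAGG`; `shifted` if it is present in the a-tail but not a classic
subset; `absent` otherwise.  The best register slides the reverse
complement of the SD along a region over every ungapped offset with at
least 4 overlapping bases (preventing trivial 1-base registers) and reports
the maximum identity count, ties to the smallest offset.  Single-base
repeat motifs (e.g. `AAAA`) are flagged low-complexity but still
classified.

## Synthetic fixtures

`make_genome` lays features left to right on one contig, alternating
strands, separated by >= 50 background bases: 16S genes are 150 background
bases + a 24-base helix + a 13-base tail, with the GFF3 3' coordinate
foreshortened by a configurable amount (default 5, the typical correction);
CDSs are a W = 20 upstream window + ATG + 60 coding bases, with
round(plant_rate × n) genes carrying the SD motif (default `AGGAGGT`)
ending 5-9 bases before the ATG.  The background is order-0 uniform by
default; `make_upstream_set` samples windows directly from a given Markov
model and attaches *that* model as the set's background, so the null is
exactly true for unplanted windows.  Planted counts are deterministic
(round, not Bernoulli) and everything derives from one integer seed.

What the fixtures do **not** emulate: real rRNA secondary structure or
helix-45 sequence variation, operons and overlapping genes, codon-biased
coding sequence, leaderless mRNAs, sequencing error, or 14/15-base tails.
Passing the recovery tests therefore shows the statistics and bookkeeping
are correct under the stated model, not that the defaults are optimal for
any particular real genome.

## Problem sizes and defaults

Tests and the acceptance script run on one core in a few minutes:
recovery properties use 20 seeds of genomes with 150 CDSs (plant rate 0.5,
W = 20), the enumeration oracle covers 100 random models at k <= 5,
L <= 10, and Monte-Carlo validation uses 100,000 sampled windows.  Key
defaults: helix query as above (configurable), min score 18.0, flank 500,
W = 20, k = 7, d = 1, top 20, zmin 5.0, Markov order 3 (0-3), RE threshold
0.5 bits, spacer scan range 6-8 for the fixed-spacer motif count.

## Known limitations

* Tail length is fixed at 13; genuinely longer tails are truncated.
* The helix-45 search does not rescue annotations on the wrong strand.
* `classify_type` compares only against the classic `AGGAGG`; an SD subset
  of a *variant* antiSD is labeled `shifted` or `absent`.
* The containment DP requires model order <= k − 1.
* Corpus-scale tallies over tens of thousands of genomes are out of scope;
  the package processes explicit FASTA/GFF3 inputs.
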
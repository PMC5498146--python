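# Methods

This note documents the models implemented in `minimeta`, the parameters
that matter, what the synthetic-community generator does and does not
emulate, and the numerical and design choices made where the method left
them open.

## Co-occurrence model

The unit of evidence is the binary occurrence map: contig *i* is *present*
in sub-sample (chamber) *j* iff its covered base pairs there reach the
presence threshold τ (default τ = 2¹¹ = 2048 bp; the boundary counts as
present, chosen for determinism).  Binning results are insensitive to τ
over roughly 2⁹–2¹³ because binarization only needs to separate genuine
per-chamber amplification from stray coverage.  The log₂-transformed
coverage is retained purely for heat-map display.

For a contig pair, the four chamber counts (a, b, c, d) form a 2×2 table
and the score is the **hypergeometric point probability** of that table
given its margins — a single pmf term, not a cumulative Fisher tail.  The
two interpretations differ: the point probability is the chance of the
*exact* observed table; the conventional test sums all tables at least as
extreme.  The single-term form is the method's definition here (its worked
example (8,1,2,6) → 252/19448 ≈ 0.013 is reproducible only as a point
probability); the two-sided tail is exposed behind `tail="two-sided"` for
users who want the standard test.  Probabilities are evaluated in
log-factorial space (`gammaln`), which is exact to machine precision and
cannot overflow for table totals ≤ 10⁴; the unit tests pin it to an
exact-rational oracle for all small tables and check hypergeometric
normalization at 1e−12.

Self-pairs are not meaningful; the diagonal is set to the smallest computed
off-diagonal value so that, used as a distance matrix, self-distance is
minimal.  Multiple-comparison correction (Bonferroni over the distinct
pairs by default, Benjamini–Hochberg optional) is computed for *reporting*
— log₁₀ of corrected p is what heat-map output shows.  The **uncorrected**
matrix is what feeds the embedding: the raw pairwise p values are the
distance metric, and correcting first would cap most informative
small-margin pairs at 1 (with ~n²/2 pairs, a rare genome present in four
chambers has within-genome p ≈ 1e−4, which Bonferroni saturates), erasing
exactly the signal that separates rare lineages.

## Binning

The p-value matrix (diagonal zeroed) is embedded in 2-D and density
clustered:

* **Embedding** — t-SNE with `metric="precomputed"`, perplexity 30 (capped
  at (n−1)/3), 1000 iterations, seeded random initialization; identical
  seed + parameters reproduce coordinates bit-for-bit.  t-SNE is the
  default because the between-genome structure of G genomes is an
  approximately (G−1)-dimensional simplex: classical MDS must project it
  to 2-D through its top two eigenvectors and overlays clusters, whereas
  t-SNE preserves the local neighborhoods that matter for density
  clustering and recovers the reference community exactly (the end-to-end
  test asserts ARI ≥ 0.9 with every bin majority-pure).
  Classical (Torgerson) MDS remains available (`method="cmds"`) as an
  exact, eigendecomposition-based alternative with a sign convention
  (largest-magnitude coordinate positive per axis) that makes it fully
  deterministic; it is adequate for a handful of genomes.
* **Clustering** — DBSCAN with `min_points` 4.  When `eps` is not given it
  is set from the sorted 4-NN distance curve: at the first pronounced
  density break (consecutive ratio ≥ 2) in the curve's upper half, or just
  above the curve maximum when no break exists (one density regime).
  Clusters with fewer than 5 contigs and DBSCAN noise points carry the
  reserved `unbinned` label.
* **Size filter** — bins must exceed 0.5 Mbp of summed contig length;
  optionally an unbinned contig longer than the cutoff by itself is
  promoted to a singleton bin.

Bins are relabeled `bin_001…` by decreasing contig count (ties by first
contig id), which makes membership invariant to contig input order.
Consensus lineage is the majority label among a bin's assigned contigs
with its supporting fraction; a bin with fewer than half its contigs
assigned is flagged predominantly unassigned.  `evaluate_binning` scores
against simulator truth with ARI (over binned contigs), per-bin purity and
per-genome completeness-by-length.

## Abundance

A chamber counts as occupied by a genome when strictly more than 50% of
the bin's contigs have read support there.  Two support rules are kept
deliberately distinct, mirroring the method: `read-support` (≥ 1 covered
bp, the abundance rule) and `occurrence-threshold` (the τ-binarized map,
the binning rule).  With *k* of *n* chambers empty, the loaded cell count
is X = −n·ln(k/n), the maximum-likelihood inversion of the Poisson
empty-chamber fraction.  X is continuous, strictly decreasing in k, and
X(k=n)=0.  k = 0 makes the estimator infinite; the estimate is flagged
`saturated` and reported as the k = 1 lower bound −n·ln(1/n) rather than a
guess.  Relative abundance normalizes X over reported bins (saturated bins
contribute their lower bound).  The model counts chambers, not cells:
heterozygous-chamber multiplicity is never used to refine counts.

## Variation

Filters are applied before any interpretation, in order: site quality
strictly > 180 (the caller's QUAL scale, taken at face value); per-chamber
calls only where the chamber has ≥ 5 reads at the site; and at least one
chamber where the alternate allele is the only allele observed (alt ≥ 5,
ref = 0).  A chamber with both alleles each ≥ 5 reads is heterozygous —
"high confidence" for both alleles is interpreted as both meeting the same
depth floor — and contributes one dominant plus one alternate allele to
tallies.  A chamber above the depth floor where only one allele meets it
is called for its majority allele.

Classification substitutes the alternate base into the codon containing
the site (reverse-complementing on the − strand) and compares amino acids
under translation table 11 (configurable).  Positions outside all ORFs are
noncoding.  An ORF whose length is not a multiple of 3 is read in frame
from its start with a warning; positions in the incomplete trailing codon
are left unclassified by that ORF.  A site in overlapping ORFs is
nonsynonymous if the change is nonsynonymous in any of them (conservative,
logged).

dN/dS defaults to NG86-style equal-rate normalization: each codon position
contributes the fraction of its three possible substitutions that preserve
the amino acid to the synonymous site total (in-frame stop codons are
skipped), and the ratio is (Nd/N)/(Sd/S).  The raw count ratio Nd/Sd is
available behind `method="count-ratio"`.  The ratio is undefined (reported
`NA`) when the synonymous tally is zero.  The SNP-rate denominator
defaults to the bin's assembled length; callers can pass the total
sequenced length instead, and output names the choice.

## Synthetic communities

The generator emulates the post-alignment structure of an experiment —
never reads or assembly:

* **Loading** — per chamber and genome, cells ~ Poisson(λ_g), independent
  across chambers (well-mixed suspension, chambers far larger than cells).
* **Coverage** — a contig of a genome present in a chamber escapes MDA
  dropout with probability 1−d (default d = 0.2) and draws covered bp as
  τ·2^N(μ, σ) (defaults μ = 2, σ = 1, i.e. median 4τ) clipped to
  [τ, contig length]; dropped contigs draw sub-threshold noise; absent
  genomes contribute zero (chambers are physically separate).  Dropout is
  independent per contig — the simplest mechanism that makes coverage
  "variable" while occurrence stays informative; no amplification
  branching process is modeled.
* **SNPs** — polymorphic sites are placed length-proportionally across the
  genome's contigs; the proposed substitution is uniform over the three
  alternative bases, and nonsynonymous proposals are accepted with
  probability *q* (1 = neutral, matching the NG86 equal-rate null exactly;
  q < 1 emulates purifying selection, and the realized dN/dS ≈ q).  The
  alternate allele rides in each cell independently at frequency 0.3;
  chamber allele depths are Poisson at 8 reads per carrying cell where the
  contig amplified.  Sites with no alternate read anywhere are not emitted
  (a caller would not report them), and site qualities are drawn
  150 + Exp(200) so a small, class-independent fraction fails the quality
  filter.
* **Determinism** — one seed feeds four named sub-streams (structure,
  loading, coverage, SNPs) via `SeedSequence.spawn`; identical configs are
  bit-identical.

`reference_scenario()` is the canonical community: 8 genomes, λ log-spaced
over 0.05–1.0 cells/chamber (summed loading ≈ 2.8, spanning a genome in
most chambers down to a rare lineage in ~5), 20–60 contigs each of ~30 kbp
(every genome comfortably exceeds the 0.5 Mbp bin filter), 96 chambers,
dropout 0.2, neutral SNP model, seed 101.  `variation_scenario()` is a
single well-sampled genome (λ = 1.5, 120 sites) for the variation stage.
Problem sizes throughout the suite (320 contigs, 96 chambers, ≤ 1000
Monte-Carlo replicates, ≤ 20 seeds) are deliberately desk-scale: each
stage's statistical behavior is measurable in seconds without changing
any of the study conditions above.

What passing tests show — and what they do not: the simulator validates
the *statistics* (occupancy inversion, co-occurrence separation under
dropout, filter semantics, dN/dS calibration).  It does not model
chimeras, cross-chamber contamination, uneven per-chamber sequencing
depth, assembly fragmentation correlated between genomes, strain mixtures
within a genome, or real codon usage — so perfect recovery here bounds,
but does not guarantee, performance on real communities.

## Known limitations

* The point-probability distance treats all chambers as exchangeable; a
  chamber-specific capture bias would violate the hypergeometric null.
* DBSCAN's automatic eps is a heuristic; heavily overlapping communities
  (much higher loading, or dropout ≳ 0.6) fragment and merge bins, and
  `--eps` should be set by inspecting the embedding.
* Cell counts assume one genome per cell and perfect lysis; they estimate
  *detected* cells, a lower bound on loaded cells.
* dN/dS from population SNPs over short windows is a coarse selection
  proxy; the equal-rate site counting ignores transition/transversion
  bias.
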
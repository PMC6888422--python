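# Methods

## Domain grammar

A WRKY domain is called when a 7-mer window matches one of the heptapeptide
consensi {WRKYGQK, WRKYGKK, WRKYGHK} (equivalently W-R-K-Y-G-[QKH]-K; the
set is configurable through `DomainGrammar`). Every matching window is
reported, overlapping matches included, so the scanner is exactly
equivalent to naive window enumeration — a property the test suite checks
directly.

The zinc finger is sought within a window of 100 residues downstream of
each heptapeptide (default `finger_search_window`): the first arrangement
C-Xa-C-Xb-H-X-Z with a ∈ [3,7] and b ∈ [22,23] wins, candidates ordered by
smallest first-cysteine position, then smallest a, then smallest b. The
window and leftmost-first rule are package choices: they are deterministic
and match the canonical domain architecture in which the finger directly
follows the heptapeptide. Spacing ranges default to the values observed in
the sandalwood family table and widen only by configuration.

A protein's single zinc-type label comes from its C-terminal (last)
domain's fourth coordinating residue (H → C-C-H-H, C → C-C-H-C, otherwise
the variant label C-C-H-Z). Family *summaries* instead count "carries at
least one finger with residue Z", because multi-domain proteins can carry
both an H-type and a variant finger and published tallies count them under
both labels; this is why the packaged table yields 56 C-C-H-H proteins and
5 C-C-H-C proteins alongside seven variant carriers among 64.

Redundancy removal is greedy, CD-HIT style: candidates sorted by length
descending join the first retained representative with global-alignment
identity ≥ 0.95 (configurable). The threshold is a conservative default;
the clustering is validated against an exhaustive pairwise-identity oracle.

## Phylogenetic classification

Group rules: ≥2 WRKY domains → group I; one domain with C-C-H-H → II; one
domain with C-C-H-C → III; anything else (variant or undetected finger) is
deferred to phylogeny. Subgroups IIa–IIe are clades, so they are assigned
by tree placement against labeled reference domains.

Pairwise alignment is Needleman–Wunsch under BLOSUM62 with affine gaps
(open −10, extend −1; a gap of length k costs open + (k−1)·extend),
delegated to Biopython's `PairwiseAligner` and cross-checked against
exhaustive alignment enumeration on short peptides. The multiple alignment
is center-star: the center minimizes the sum of pairwise distances
(1 − identity), every other sequence aligns to it, and gaps merge under
"once a gap, always a gap". This is a deliberately simple, fully
deterministic progressive aligner; it is not ClustalW/MAFFT-quality on
divergent sequences, which is acceptable because subgroup placement only
needs relative distances within one domain family.

Distances use complete deletion (columns containing any gap are dropped),
then either the p-distance or the Poisson correction d = −ln(1−p)
(default). A gamma-rate or composite-likelihood model is not implemented:
the former's parameters are underdetermined at this scale and the latter
is a nucleotide model. Saturated pairs (p = 1) are a hard error rather
than a clamped value.

Neighbor joining is the Saitou–Nei algorithm. Ties in the Q-criterion
break lexicographically by cluster key (the smallest leaf label in each
cluster), so the topology is reproducible regardless of input order.
Negative branch-length estimates are clamped to zero with the deficit
moved to the sibling edge, preserving the pair's total — the behaviour
popularized by MEGA. On additive matrices the reconstruction is exact
(topology and branch lengths), which the tests verify against random trees
of up to eight taxa and against scikit-bio's independent NJ.

Bootstrap support resamples alignment columns with replacement, rebuilds
the tree per replicate, and reports the percentage of replicates
containing each internal bipartition (default 1000 replicates; tests use
50–200 for speed). Supports are invariant to leaf-order permutations.

Subgroup placement walks outward from the query leaf in expanding
topological neighborhoods: the nearest non-empty set of reference leaves
decides if all carry one label; otherwise the reference at minimum
patristic distance decides (ties lexicographic). The concrete
neighborhood rule is a package choice — "the enclosing clade" is not
well-defined on an unrooted tree — and the planted-subgroup benchmark
(two-level star phylogeny: subgroup prototypes diverged ~30% from a common
ancestral domain, references/queries a few substitutions from their
prototype) recovers ≥95% of planted labels through the full
MSA → distance → NJ → placement chain. Reference sequences are synthetic;
no curated Arabidopsis domain set is packaged, and users supply their own
labeled reference FASTA for real analyses.

## W-box regulome

Promoters are the 2 kb upstream of the translation start (first base of
the ATG codon; configurable), anchored at ATG rather than the TSS because
draft annotations rarely have reliable TSSs. On the minus strand the
window downstream in contig coordinates is reverse-complemented. Promoters
truncated by a contig edge are still scanned over the available span and
flagged; a start codon at the edge yields an empty promoter and the gene
is excluded from counting.

The scan pattern is (C/T)TGAC(C/T), applied to both strands by also
matching the reverse-complement pattern (A/G)GTCA(A/G) at forward
coordinates; both-strand counting is the default because W-boxes are
functional in either orientation, and `--forward-only` switches it off.
Overlapping matches all count. Genes with ≥5 boxes (boundary inclusive)
are targets. Enrichment of the target set is the hypergeometric upper
tail with Benjamini–Hochberg correction — the field default where no test
is otherwise specified — reported for the top 20 pathways.

Genome-scale W-box censuses from the original sandalwood assembly are out
of scope here; the procedure is instead validated on synthetic genomes
with exactly planted counts (see below).

## Expression

RPKM = count / (length/10³) / (library/10⁶); heat-map values are
log2(RPKM+1). FPKM is treated as the same quantity under single-end
semantics.

qPCR: two reference genes are combined by the arithmetic mean of their Cq
(equivalent to the geometric mean of linear abundances). Per replicate,
ΔCq = Cq(target) − mean(Cq refs); ΔΔCq contrasts treatment timepoints
(3 h, 6 h) against the 0 h calibrator; relative expression is 2^−ΔΔCq.
The significance gate is a Welch two-sample t-test on replicate ΔCq values
(3 vs 3); with noise-free synthetic input the statistic degenerates and
the p-value is defined as 0 (means differ) or 1 (equal). A timepoint is
"up" iff fold > 1.5 (strict) and p < 0.05, "down" iff fold < 0.5 and
p < 0.05. The gene-level call per hormone aggregates timepoints by "any
significant timepoint, never the opposite direction"; contradictory
timepoints yield "unchanged". Reference normalization makes calls
invariant to adding a constant to all Cq values of a condition — a tested
invariant.

## Synthetic data

Generators are the inverse of each analysis stage and are seeded
(`numpy.random.default_rng`); random streams are consumed in documented
order so outputs are byte-reproducible.

* **Proteins.** Flanks and spacers are drawn from the 17-letter alphabet
  excluding W, C and H, so planted heptapeptides and fingers are the only
  possible grammar matches — planted truth is exact, not probabilistic.
  Each packaged family row is realized at exactly its ORF length with one
  finger per heptapeptide (rows listing more finger labels than domains
  contribute their first `n_domains` labels, since the detector reports
  one finger per domain). A `fingerless` option plants heptapeptides with
  no valid finger as negative controls.
* **Genomes.** Background DNA is rejection-sampled base by base so that
  no W-box occurs on either strand; the planned number of consensus
  instances is then planted at non-overlapping random promoter offsets
  (random consensus word, random orientation) and the promoter re-scanned
  to confirm the exact count. One gene per contig, three-exon models,
  alternating strands, emitted as FASTA + GFF3 + truth table.
* **qPCR.** Reference Cq baselines 20 and 21 cycles plus Normal(0, 0.05);
  target Cq = gene baseline (uniform 24–30) − log2(fold) + Normal(0, 0.1)
  per replicate, three replicates. The study-condition plan plants fold
  3.0 at both treated timepoints for up-regulated genes, 0.3 for
  down-regulated genes and 1.0 otherwise, over a 42-gene universe
  (SaWRKY1–42 — every gene in the packaged direction lists falls in this
  range and the count matches the assayed panel).
* **Counts.** counts ~ Poisson(expr × length_kb × library_millions), so
  RPKM on the output is unbiased for the planted expression.

## What the synthetic benchmarks do and do not show

Planted-truth recovery demonstrates that each detector implements its
stated rule exactly and that the pipeline's stages compose correctly. It
does not demonstrate performance on real data: real promoters are not
motif-free outside planted sites, real WRKY domains diverge more than the
benchmark prototypes, real Cq noise is heavier-tailed than Gaussian, and
real families contain partial and mispredicted gene models. The effect
sizes in the qPCR plan (3.0×/0.3× at 0.1 Cq noise) give the Welch test
essentially unit power, so the end-to-end direction-list recovery checks
bookkeeping and thresholds, not statistical sensitivity.

## Problem sizes

Default test and acceptance scales: 64-protein family realization;
additive-matrix NJ up to 8 taxa; 10 kb scan sequences; 80-gene synthetic
genomes; 25-sequence subgroup benchmarks; bootstrap at 50–200 replicates
in tests (1000 by default in the CLI); 1000-permutation enrichment null.
These sizes keep the whole suite under a minute of compute while
exercising every code path at the scales the statistics need.

## Known limitations

* Center-star MSA quality degrades on long, gappy alignments; swap in an
  external aligner's output (any FASTA alignment can be wrapped in `Msa`)
  for publication-grade trees.
* One isoform per gene: the first mRNA supplies the exon structure.
* The packaged family table stores one gene at 333 aa whose cloned CDS
  implies 332 aa; the table is kept as printed (the difference is
  stop-codon accounting).
* No profile-HMM scoring: HMMER domain tables can be read to pre-filter
  candidates, but the grammar scan is the identification method.
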
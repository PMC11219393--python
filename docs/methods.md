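# Methods

This note documents the models, conventions and numerical choices behind
`bitterfam`, and what the synthetic data generator does and does not emulate.

## The inference problem

A targeted-capture experiment for an intronless gene family yields, per
candidate locus and species: a mapped length, a per-site depth vector, a
count of SNP sites (indels excluded), and two assembled haplotype sequences
(H1/H2) that may carry IUPAC degenerate codes at unphased sites. From these
the chain infers (i) which loci are absent, single-copy, or collapsed
mixtures of paralogs; (ii) which sequences are functional receptors; and
(iii) the minimal set of gene birth and death events on a dated species tree
that explains the observed repertoires.

## Locus calling

**Absence (round 2).** A locus with mean per-site depth below 10 is absent
from the sample. The comparison is strict (`<`), as are all thresholds in
the caller.

**Boxplot screens (round 3).** Quartiles use median-inclusive Tukey hinges:
for odd *n* the median element belongs to both halves; hinges are the
medians of the halves. Whiskers are the most extreme *data points* within
1.5 IQR of the hinges, not the fences themselves. Genes with mean depth
below 0.5 × the lower whisker of the per-species gene-depth boxplot, or with
mapped length < 750 bp, are excluded as possibly absent; neutral references
shorter than 1 kb are dropped; autosomal neutral references with depth above
1.5 × the NR-A upper whisker are excluded as potentially duplicated.

**Duplication candidates (rounds 3–5).** A gene whose mean depth exceeds the
gene-depth upper whisker is a duplication candidate; one whose SNP density
(SNPs per kb) alone exceeds the SNP upper whisker is routed to category 4
(copy number left undecided). For candidates, the fraction of read-length
(150 bp) windows over which H1 = H2 stands in for the proportion of reads
mapping to both references: above 0.10 the locus stays congregated
(category 1); otherwise the haplotypes become "-1"/"-2" daughter loci and
are re-screened — clean daughters give category 2 (separated single loci), a
daughter with persistent depth excess ends congregated as category 3 after
one more split attempt, and SNP-only excess in a daughter gives category 4.
The 0.10 constant fixes a judgement that was originally made by visual
inspection of mappings; a constant makes the rule testable and configurable
(`--shared-threshold`).

## Intactness classification

**ORF test.** The maximum ORF is the longest ATG-initiated, in-frame,
stop-terminated run on the forward strand across the three frames, counted
from the start codon through the last sense codon (250 codons ⇔ 750 bp).
The scan is forward-strand only and requires ATG: capture output is oriented
and the 250-amino-acid threshold presumes a translated product. Frameshifted
alleles are translated as-is; the shifted frame runs into a stop and fails
the threshold.

**7-TM test.** Transmembrane segments are counted by a deterministic
Kyte–Doolittle hydropathy scan of the translated maximal ORF: window 19
residues, threshold 1.6, maximal above-threshold runs merged when separated
by fewer than 3 sub-threshold positions. "Proper 7-TM" is read as exactly
7 segments (configurable to ≥ 7). This scanner is a declared, reproducible
stand-in for neural topology predictors; its constants are package defaults,
not fitted values, and borderline architectures that such predictors might
call differently are out of scope.

**Unphased sites.** Degenerate codes (R/Y/S/W/K/M only) are resolved into
exactly two haplotype pairs: alphabetically-first nucleotides throughout
H1 with the complements in H2, and the swap. Testing the two aligned
combinations (rather than the exponential set) suffices because a single
disrupted site fails a haplotype irrespective of phase; three/four-fold
codes are rejected rather than guessed. Gene status combines the verdicts:
all intact → intact; all disrupted → disrupted; mixed verdicts mean a
segregating pseudogene at single loci, or an unresolvable intact-and-
disrupted congregate for categories 1/3/4.

## Gene trees

TN93 distances are estimated in closed form from the two transition
proportions, the transversion proportion, and base frequencies averaged over
the pair's retained sites; sites with a gap *or* ambiguity code in either
row are excluded pairwise (ambiguity exclusion is the conservative extension
of gap exclusion). Non-positive logarithm arguments (saturation) yield NaN:
saturated pairs are flagged and refuse to enter neighbor joining rather than
being silently ceiled. NJ is the canonical Saitou–Nei agglomeration; Q-
criterion ties break to the lowest index pair, and negative branch-length
estimates clamp to zero. Bootstrap support is the fraction of site-resampled
replicate trees containing each internal bipartition of the full-data tree
(support mapped onto one tree, not a consensus topology); replicates that
produce a saturated distance are dropped and counted in a diagnostics field.

## Event placement and counting

Gene presence evolves under Dollo parsimony: each copy originates once and
absences below the origin are explained by the minimal set of losses (one
per maximal all-absent subtree). Births are considered for separated or
congregated duplicates (categories 1–3); category-4 loci contribute neither
births nor, when they mix intact and disrupted sequences, deaths. Within a
gene group, copies are ranked by the depth of the MRCA of their bearing
species; the group's ancestral copies (outgroup polarity, default one) are
absorbed by the root-most copies and every remaining copy is born on the
stem of its MRCA — frequent gene conversion, not repeated duplication,
explains sequence homogeneity of paralogs within lineages. Placements that
rest on outside evidence (gene trees including database species, earlier
comparative studies) enter through a prior-events ledger or a
`birth_source=prior` gene annotation; merging prior events never moves
inferred ones, and conflicting placements are an error unless explicitly
overridden.

Disruptions are placed at the common ancestor of a species set only when the
set is annotated as sharing the identical disruptive mutation; otherwise
each lineage receives an independent terminal event. This is deliberately
*not* the event-minimizing choice: co-occurrence alone is weaker evidence
than mutation identity, which is what the annotation encodes.

Counting: births +1; deaths −1, except congregated two-copy loci
(categories 1/3) which count −2 when entirely disrupted or lost and −1 when
an intact sequence remains; segregating pseudogenes and category-4
intact-and-disrupted loci count 0. Loss of a congregated locus at −2 is the
package's extension of the stated −2 disruption rule (the congregate stands
for two copies); no bundled data exercises it. Node totals propagate down
from a root count (which includes any root-stem events already), and leaf
totals include segregating pseudogenes, which are never subtracted.

## The simulator

`simulate_history` draws events per branch as a Gillespie process with
per-gene rates (duplication, disruption, loss) and a per-duplicate-pair
conversion rate. Conversion overwrites one partner's entire coding region
(whole-gene tracts, matching the treatment of conversion as what makes
paralogs cluster by species). Disruptions are premature stops (substitution
to TAA) or 1-bp frameshift deletions, mixed by `disruption_mix`, placed and
verified to destroy the ≥750 bp ORF; a disruption arising on a terminal
branch is heterozygous with probability `seg_pseudo_prob` (a segregating
pseudogene — exactly one disrupted allele). Losses and disruptions target
intact genes only: re-killing a pseudogene is invisible to every downstream
stage. Root genes are built to a guaranteed receptor architecture (Met +
seven 21-residue hydrophobic blocks separated by hydrophilic loops,
back-translated with random codons, 900 bp coding + 100 bp flanks, matching
the family's typical gene and probe-design geometry). Intact genes evolve
under TN93 substitution with purifying rejection — proposed mutations that
break the ORF or the 7-TM architecture are discarded — at a rate multiplier
(default 0.5) below the neutral rate, which is what makes neutral-reference
SNP density the ceiling in the emitted data.

Capture emission: per-site depth is Gamma–Poisson (negative binomial) with
mean `depth_mean × copies/2` (ploidy-scaled; NR-X halved in males) and shape
`depth_dispersion` (default 10) — capture depth is far more variable than
Poisson, and the caller must tolerate that. The empirical dispersion of real
capture data is unknown to us; 10 is a free default, not an estimate. Gene
copies sharing a family emit as one congregated locus (summed depth, union
of allelic and paralogous SNPs, shared-window fraction between the two
haplotype references) with post-split daughter records attached — the
simulator's stand-in for what further mapping rounds would see. Defaults:
`depth_mean` 1000 (the case-study's per-species averages run ≈ 350–1700),
83 autosomal + 3 X neutral references ≥ 1 kb (the realized rhesus probe
counts), read length 150, heterozygosity 2 × 10⁻³/site at neutral loci,
20% of heterozygous sites emitted unphased as IUPAC codes.

Not emulated: read-level FASTQ, mapping, base quality, chimeric reference
backfilling, genotype-quality filtering, and real capture biases (GC,
bait-affinity, off-target). Passing tests therefore demonstrate the decision
logic under the stated statistical model, not robustness to every artifact
of real capture data.

## Numerical and design choices

* All stochastic stages require an explicit seed; seeds derive from a
  `numpy` `SeedSequence` spawned along a fixed traversal order, so runs are
  bit-reproducible.
* Boxplot quartiles are exact data medians (no interpolation); ties break to
  the lower-index element by construction of the sorted halves.
* The hydropathy scan computes direct per-window sums (no running
  accumulator) so threshold comparisons are free of accumulation drift.
* NJ tie-breaks and clamping are fixed as stated so topologies are
  deterministic functions of the matrix.
* Property-test problem sizes (500 simulated histories on a 6-leaf tree,
  500 random additive trees, 1000 TN93 pairs, 200 duplication-recall
  replicates at depth 500) were chosen to keep the full suite around ten
  seconds while leaving the statistical assertions comfortably powered.

## Known limitations

* The 4-taxon parsimony optimality guarantee is verified by enumeration;
  larger instances rely on the same per-gene decomposition but are not
  exhaustively checked.
* Shared-disruption merging requires an explicit annotation; the package
  never infers mutation identity from sequences.
* The case-study fixture encodes species-level statements for the duplicated
  gene groups and stem events; it is a faithful skeleton, not a full
  re-annotation of every gene in every species (per-species repertoire
  totals beyond the bundled branches are out of its scope).
* The TM scanner is not a topology predictor: it counts hydrophobic
  segments and will disagree with neural predictors on marginal cases.
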
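# Methods

`rgevo` reimplements, as one testable pipeline, the comparative analysis of
plant disease-resistance genes (R-genes, the NBS-LRR family and its
relatives) across a set of legume genomes with grape as the out-group. Real
genome downloads are deliberately out of scope: every stage runs against a
synthetic eight-species dataset whose ground truth the generator records,
so each claim the pipeline makes can be scored. This note documents the
models, the parameters that matter, and the places where the design was
genuinely open.

## The synthetic study system

The generator (`rgevo.synthetic_data`) evolves gene families along a fixed
rooted eight-taxon species tree (grape out-group; a galegoid clade with
lotus, medicago and chickpea; a millettioid clade with pigeonpea, common
bean and the cultivated/wild soybean pair). Default branch lengths are
0.008–0.14 substitutions/site at the genome-wide rate; the soybean pair is
the shortest split. Two family classes exist:

- **R-gene families** (default 24): an ancestral protein is built from an
  architecture label drawn from the ten canonical domain combinations
  (CC/TIR/NBS/LRR singletons through CC-NBS-LRR and TIR-NBS-LRR). Domains
  are concrete motif blocks — six coiled-coil heptads with hydrophobic a/d
  and charged e/g positions, a bundled ~110-residue TIR consensus block,
  an NBS block carrying P-loop, kinase-2 and GLPL motifs, and six
  LxxLxLxx leucine-rich repeats — joined by disordered-composition
  linkers. Lengths are drawn around 500 aa, the typical legume R-protein
  length. R families evolve at 2x the genome-wide rate (the divergence
  contrast the rate comparison is designed to recover) with dN/dS 0.2 on
  linker codons.
- **Background families** (default 300): single-copy random-composition
  genes, evolved at 1x with dN/dS 0.2. They serve three roles at once:
  negatives for identification, intervening genes for cluster geometry,
  and syntenic anchors for the ortholog map and the genome-wide supergene
  tree.

**Codon evolution** is acceptance–rejection: substitutions are proposed at
uniform nucleotide positions; synonymous changes are always accepted,
non-synonymous ones with probability omega, stop-creating ones never. The
number of accepted substitutions is fixed at round(branch_length x L), so
realised substitutions/site equals the branch length by construction. This
is not a rate-matrix exponential — there is no transition/transversion
bias, and fixing the accepted count means synonymous sites absorb
proportionally more changes when omega < 1. Both simplifications are
harmless for what the generator must guarantee (NG86 recovers the omega a
sequence pair was evolved under; 4D-site divergence scales linearly with
rate), and both are reasons why passing tests here say nothing about, e.g.,
codon-usage or ts/tv effects in real genomes.

**Constraint masking.** Motif-critical codons (P-loop/kinase-2/GLPL
residues, heptad a/d/e/g positions, half the TIR block, the L positions of
each leucine-rich repeat) plus the start and stop codons reject all
non-synonymous changes, mimicking strong purifying selection on functional
motifs. Without this, default divergence would erode the planted signals
and the recovery targets would measure motif decay rather than scanner
correctness. A consequence worth knowing: measured dN/dS of R-gene
ortholog pairs sits below the nominal linker omega (about 0.15 observed at
omega = 0.2), because the masked codons contribute synonymous but no
non-synonymous changes.

**Copy numbers and layout.** R families evolve copy number along the tree
by per-branch Poisson gains/losses (default 0.08 each, capped at 6).
A shared ancestral gene order interleaves R-family blocks with background
genes: cluster families (25% of R families, root count 3) place their
copies with 1–4 intervening background genes per gap, summing to at most 8
across the block; two "boundary" families place exactly two copies 9 genes
apart (and are exempt from copy-number evolution); all other R blocks are
separated by at least 9 background genes. Copies gained beyond the root
count sit adjacent to their source copy, as tandem duplication produces.
Because the same slot order is materialised in every species (minus
species-specific losses), gene order is syntenic by construction and the
cluster rule's boundary (<= 8 intervening genes merges, 9 splits) is
planted explicitly. Genomes embed each CDS at recorded coordinates in
random intergenic DNA (~200 bp), minus-strand genes reverse-complemented;
per species, two extra R-gene copies are embedded without annotation to
exercise the genome-search arm of identification.

**Structural defects.** Each R gene independently receives at most one
defect: frameshift (1-bp deletion) or premature stop with probability
0.15 total — inside the paper-reported 7–30% pseudogenization band —
plus LackStart (ATG→ATA), LackStop, LackBoth and a 9-codon in-frame
deletion at lower rates. Truncating defects are planted downstream of the
last motif-critical codon, leaving at least ~22 codons of tail: defects
closer to the terminus would leave no alignable evidence, and a defect
inside a domain would change the gene's observable architecture, making
the architecture-recovery target ill-posed. In-frame deletions are placed
in motif-free runs for the same reason.

## Identification and classification

Domain scanners replace the HMM-based engines a real-genome study would
use, keeping their thresholds:

- **NBS**: a P-loop match ([GA]xxxxGK[ST]) with kinase-2
  ([LIVMF]{2}.{0,2}DD) or GLPL downstream. Among multiple P-loop-like
  matches the scanner keeps the supported one with the most downstream
  motifs and the latest start — spurious upstream matches otherwise
  stretch the span over the CC domain.
- **LRR**: at least three LxxLxLxx repeats (L in {L,I,V,F}), each starting
  within 30 residues of the previous repeat's end; the longest run wins.
- **TIR**: local alignment to the bundled consensus block at normalized
  score >= 0.4 (fraction of the consensus self-score).
- **CC**: a 28-residue sliding window scored over seven heptad registers
  with a bundled log-propensity table (hydrophobics +1 at a/d else −0.5;
  E/K/Q/R +0.5 at e/g), mapped through a logistic (alpha 10, beta −2.5);
  a window probability >= 0.5 is a hit, mirroring a coiled-coil HMM's
  "probability 50" threshold.

In the combined scan, TIR and NBS run first and their spans are masked
before the CC and LRR scans: both of those domains contain hydrophobic
stretches that otherwise masquerade as heptads or repeats. Architecture
labels compose presence and order (N-terminal CC/TIR strictly before the
NBS span, LRR strictly after; CC before TIR for CC-TIR-NBS); order
violations, CC+TIR+NBS+LRR together, and NBS-less multi-domain
combinations fall into "Others"; no hits is "Un-annotated". How the
original study split "Others" from "Un-annotated" for non-canonical genes
is not stated; the order-violation rule is this package's convention.

**Iterative identification** alternates (1) validating annotated proteins
by NBS scan or by alignment to the current seed set at the 1e-10
significance threshold, (2) promoting validated proteins to seeds, and
(3) searching seeds against the genomes in six frames at 1e-5 to recover
unannotated loci, until an iteration adds nothing. Significance uses an
analytic Karlin–Altschul-style proxy K·m·n·exp(−lambda·S) with K = 0.041,
lambda = 0.267 over BLOSUM62 with gap open 11/extend 1 — the thresholds
are the specified quantities; the engine behind them (Biopython
Smith–Waterman plus a word-index pre-filter, word size 6, and a 6-mer
anchored six-frame search) is an implementation choice. Annotated gene
spans are masked from the genome-search index because that step exists to
find loci the annotation missed; already-found loci are skipped before
alignment. Both filters are BLAST-like heuristics: a homolog sharing no
6-mer word with any seed would be missed, a regime the synthetic
divergences stay well clear of.

## Genomic context

Clusters chain R-genes on a chromosome by single linkage with at most 8
intervening genes ("no more than eight genes apart"); size-1 clusters are
singletons and excluded from the clustered fraction. Orthology retains
pairs with cumulative identity percentage (CIP — identities over aligned
length, summed across non-overlapping segments) above 60 and significant
alignment; reciprocal best hits are flagged with ties broken by gene id.
Each legume chromosome anchors to the out-group chromosome contributing
the plurality of its ortholog partners (ties by summed score). An R-locus
maps to the out-group iff at least 3 ortholog pairs within a +-25
gene-rank window support one out-group chromosome — the "synteny value"
is read as that supporting-pair count, and the window size is a parameter
the original study does not state.

## Structure classification

Classes are mutually exclusive with precedence Pseudo > LackBoth >
LackStart/LackStop > InDel > Complete (the original table implies
exclusivity but not precedence; this order resolves multi-defect genes).
Pseudo means frameshift evidence (CDS length not divisible by 3, or a
frame change in a re-annotation chain) or an internal stop. InDel means an
internal gap of >= 3 codons against a reference protein (codon-scale
events assumed; the threshold is configurable). For unannotated loci, a
frame-aware re-annotator chains significant local-alignment segments of a
reference protein across the three forward frames (chain score =
identities − 0.5 per overlap residue − 0.5 per query-gap residue, bounded
segment overlap 50 to absorb Smith–Waterman overextension past a
frameshift); a frame change between chained segments is a frameshift,
positioned at the junction midpoint (typically within ~5 codons of the
true site; mismatch-rich overextensions occasionally shift it further).
The chain is intronless by design — the synthetic genes have no introns —
and this is the main limitation against real genomes, where a
splice-aware model would be required.

## Phylogenetics

Protein multiple alignment is center-star (the center maximises summed
pairwise global scores; pairwise alignments merge by "once a gap, always a
gap"), exact back-translation to codons, then 4D-site extraction: a codon
column contributes third positions iff it is gap-free, all species share
the identical two-base prefix, and that prefix is four-fold degenerate.
Prefix conservation across *all* taxa is the strictest reading and was
chosen for determinism. Center-star is adequate for the closely related,
indel-free synthetic families; it is not a ClustalW replacement for deep
real-data alignments. K2P distances use pairwise deletion;
−½ln(1−2P−Q)−¼ln(1−2Q) with a saturation flag when a log argument is
non-positive. Neighbor joining is the Saitou–Nei agglomeration with
negative branch lengths clamped to zero and the deficit moved to the
sister branch. Bootstrap resamples supergene columns with replacement;
replicate RNG streams derive from one master seed by counter. The
divergence-rate contrast is reported both as the total-branch-length ratio
and as per-leaf root-to-tip ratios, since either reading of "average
divergence rate" is defensible. For the R-gene tree, families must cover
all species but need not be single-copy: each species contributes its
lexicographically first structurally intact copy.

## Family dynamics and selection

Families come from Markov clustering (expansion 2, inflation 1.5, pruning
1e-5, convergence < 1e-8, self-loops added) of the similarity graph with
edges below the 1e-10 threshold weighted by normalized score; connected
components of the converged matrix are families. Ancestral family sizes
minimise the summed |child − parent| over branches (Sankoff DP over counts
0..max, smallest count on ties). This linear-cost parsimony replaces a
stochastic birth–death likelihood deliberately: it is deterministic,
desk-scale, and sufficient for per-branch expansion/contraction
summaries; it produces no per-family p-values. Its known identifiability
limit: a single event on one of the two root-adjacent branches cannot be
distinguished from the opposite event on the other (no root prior), so
the exact-recovery check plants events only on non-root-adjacent
branches; superimposed events on one path are likewise not separable,
which is why the Poisson-rate default is scored qualitatively rather than
exactly.

NG86: potential synonymous sites per codon count the synonymous fraction
of the three possible changes at each position, with changes to stop
codons counted as non-synonymous so S + N = 3L holds exactly; observed
differences average over all k! mutational pathways between codons
differing at k positions, excluding pathways through stops (falling back
to all pathways when every one is blocked); proportions are Jukes–Cantor
corrected. The ratio is undefined (reported, never binned) when dS = 0 or
a proportion reaches 3/4. Bins: < 0.25 purifying, [0.25, 0.8)
intermediate, [0.8, 1.0] candidate, > 1 positive — the boundary
assignments at 0.25, 0.8 and 1.0 are this package's convention. Ka/Ks
pairs are one-to-one same-family orthologs with intact structure; Dxy is
the mean pairwise difference proportion across ortholog alignments,
JC-corrected.

## Problem sizes and numerical choices

The study dataset is 8 species x ~330 genes (24 R families, 300
background, seed 42); the rate-recovery dataset uses 100 + 100 families
(~10,000 4D sites per supergene); omega recovery uses 10,000 codons;
parsimony oracles use trees of <= 5 leaves where exhaustive enumeration is
feasible. Tolerances: closed forms (K2P, JC) to 1e-9; NJ on additive
matrices to 1e-9; NG86 against pathway enumeration exactly; omega to
+-0.05 (0.2) and +-0.1 (1.0); the 2x rate ratio to +-0.2. Degenerate
inputs are contracts, not crashes: empty FASTA warns and returns empty,
zero comparable sites and empty chains raise, saturated distances are
flagged rather than silently clamped.

## Known limitations

- Intronless gene models throughout; no transposable elements, no WGD.
- The analytic e-value proxy is calibrated for ranking against fixed
  thresholds, not for cross-database comparability with a real BLAST.
- Center-star alignment and the acceptance–rejection codon process are
  approximations documented above; neither is fit for real-data inference.
- Markov clustering omits cross-species score normalisation, so families
  of very unequal divergence depths could over-split on real proteomes.
- The coiled-coil scorer is a windowed propensity model, not an HMM; its
  alpha/beta were fixed against the bundled heptad table once and are not
  data-calibrated.
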
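# rgevo

Evolutionary analysis of plant disease-resistance genes (R-genes) across
multiple genomes, built as a fully testable pipeline: every stage runs
against synthetic multi-species genomes with recorded ground truth, so the
identification, classification and evolutionary inferences can be scored
rather than eyeballed.

**Who it is for.** Comparative genomicists studying the NBS-LRR gene family
— the intracellular immune receptors that dominate plant disease
resistance — and anyone who needs a desk-scale, deterministic re-creation
of the classic R-gene survey design: iterative homology search over several
genomes, domain-architecture classification, tandem-cluster and synteny
mapping, gene-structure triage, and birth–death / selection analysis, with
grape as the out-group to seven legume species.

## What the pipeline computes

1. **Identification** (`rgevo.annotate`): a seed-and-validate fixpoint
   loop. Annotated proteins are validated by an NBS motif rule (P-loop +
   kinase-2/GLPL) or by alignment to the current seed set at E < 1e-10;
   validated proteins become seeds; seeds are searched against the genomes
   in all six reading frames at E < 1e-5 to recover unannotated loci;
   repeat until nothing new appears.
2. **Architecture** : four scanners (CC coiled-coil heptads, TIR consensus,
   NBS motifs, LxxLxLxx leucine-rich repeats) compose one of twelve labels
   (CC, TIR, NBS, LRR, CC-NBS, TIR-NBS, NBS-LRR, CC-NBS-LRR, TIR-NBS-LRR,
   CC-TIR-NBS, Others, Un-annotated) from domain presence and order.
3. **Genomic context** (`rgevo.genome_context`): R-genes no more than
   eight genes apart form tandem clusters; ortholog pairs are retained at
   cumulative identity percentage (CIP) > 60 with reciprocal-best-hit
   flags; chromosomes anchor to the out-group by ortholog plurality; an
   R-locus maps iff at least three syntenic ortholog pairs support one
   out-group chromosome.
4. **Structure** (`rgevo.structure`): each gene becomes Complete, InDel,
   LackStart, LackStop, LackBoth or Pseudo (frameshift or premature
   stop), with a 3-frame chaining re-annotator for unannotated loci.
5. **Phylogenetics** (`rgevo.phylo`): four-fold-degenerate (4D) sites of
   single-copy families concatenate into one supergene per species;
   Kimura 2-parameter distances, d = −½ln(1−2P−Q) − ¼ln(1−2Q), feed a
   neighbor-joining tree with bootstrap supports; comparing total branch
   lengths of the R-gene tree vs the genome-wide tree measures the
   R-gene divergence-rate excess.
6. **Evolutionary dynamics** (`rgevo.evolution`): Markov-clustering gene
   families; ancestral family sizes by linear-cost parsimony with
   per-branch expansions/contractions; Nei–Gojobori Ka/Ks with
   Jukes–Cantor correction, dN = −¾ln(1 − 4/3·pN), binned as purifying
   (Ka/Ks < 0.25), intermediate, candidate (0.8–1.0) or positive (> 1).

The synthetic-data generator (`rgevo.synthetic_data`) is first-class code:
it evolves R-gene and background families along a fixed 8-taxon species
tree at controlled dN/dS and rate multipliers, plants domain
architectures, tandem clusters (including exact 9-gene-spacing boundary
controls), copy-number gains/losses, pseudogenization events and
unannotated loci, and writes the truth tables every score is computed
against. See `docs/methods.md` for the model and its limitations.

## Worked example

`analysis/` contains the numbered study scripts; each regenerates the
deterministic dataset (seed 42), runs one stage and writes tables under
`results/`:

```bash
python analysis/01_simulate.py        # 8 species x ~340 genes + truth
python analysis/02_identify.py        # fixpoint search + inventory
python analysis/03_genome_context.py  # clusters, orthologs, synteny map
python analysis/04_structure.py       # six-class structure calls
python analysis/05_phylo.py           # 4D supergene trees + rate ratio
python analysis/06_evolution.py       # families, birth-death, Ka/Ks
```

`02_identify.py` prints, among other things:

```
calls: 340 (16 unannotated loci)
recall: 1.000  architecture accuracy: 0.988  background FPR: 0.0000
```

meaning all 324 planted R-genes were recovered (16 of them from raw genome
sequence at loci deliberately left out of the annotation), 98.8% received
the exact planted architecture label, and none of the 2,400 background
genes was called. `03_genome_context.py` reports the planted tandem
clusters recovered exactly in every species, with the 9-gene-spaced
boundary pairs never merged, and maps medicago R-loci onto grape
chromosomes through their syntenic neighborhoods. `05_phylo.py` prints the
divergence-rate contrast — R-genes are simulated at twice the genome-wide
substitution rate, and the ratio of total branch lengths of the two
supergene trees recovers approximately 2 — and 100% bootstrap support for
every clade of the genome-wide tree. `06_evolution.py` clusters the 324
identified R proteins back into exactly the 24 planted families
(`24 R-gene families from 324 proteins`), reconstructs per-branch family
expansions/contractions by parsimony, and shows the entire Ka/Ks cohort in
the purifying bin (median 0.148 across 35 legume-vs-grape ortholog
pairs), as expected for sequences evolved at dN/dS 0.2 with conserved
motif positions.

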
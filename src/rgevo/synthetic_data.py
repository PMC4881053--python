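"""Multi-species synthetic genome generator with full ground truth.

The generator evolves gene families along a fixed 8-taxon species tree
(seven legumes plus grape as the out-group) and materialises, per species:
a proteome, a CDS set, a genome sequence with genes embedded at recorded
coordinates, and GFF3 annotation — together with truth tables for every
downstream question (which genes are R-genes, their domain architectures and
coordinates, tandem-cluster membership, structure class, ortholog partners,
simulated dN/dS, and per-branch family gains/losses).

R-gene families carry planted domain architectures built from the same motif
vocabulary the scanners recognise (CC heptads, TIR consensus block, NBS
P-loop/kinase-2/GLPL motifs, LxxLxLxx leucine-rich repeats). Background
families are random-composition single-copy genes: negatives for
identification, intervening genes for cluster geometry, and syntenic anchors
for the ortholog map. Codon evolution is an acceptance–rejection scheme:
substitutions are proposed uniformly, synonymous changes are always accepted,
non-synonymous changes with probability omega, and internal-stop-creating
changes never; motif-critical codons (and the start/stop codons) are held
under complete constraint so planted signals survive divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import TIR_CONSENSUS
from .core_io import (
    CODON_TABLE,
    GeneModel,
    FastaRecord,
    STOP_CODONS,
    assign_ranks,
    load_tree,
    reverse_complement,
    translate,
    write_fasta,
    write_gff3,
    write_tree,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "DEFAULT_TREE",
    "ARCHITECTURE_WEIGHTS",
    "build_domain_protein",
    "back_translate",
    "evolve_cds",
    "plant_defects",
    "simulate_families",
    "layout_genome",
    "simulate",
    "write_outputs",
]

# Fig-style default species tree: grape out-group, galegoid clade
# (lotus, (medicago, chickpea)) and millettioid clade
# ((pigeonpea, common_bean), (soybean, wild_soybean)).
# Branch lengths in substitutions/site at the genome-wide (1x) rate.
DEFAULT_TREE = (
    "(grape:0.14,((lotus:0.05,(medicago:0.04,chickpea:0.035)galegoid_in:0.015)"
    "galegoid:0.02,((pigeonpea:0.04,common_bean:0.035)phaseoloid:0.015,"
    "(soybean:0.008,wild_soybean:0.008)glycine:0.03)millettioid:0.02)"
    "legume:0.03)root;"
)

# default architecture mixture for planted R families
ARCHITECTURE_WEIGHTS = {
    "NBS": 0.24, "NBS-LRR": 0.12, "CC-NBS": 0.10, "CC-NBS-LRR": 0.10,
    "TIR-NBS": 0.08, "TIR-NBS-LRR": 0.08, "TIR": 0.09, "CC": 0.06,
    "LRR": 0.08, "CC-TIR-NBS": 0.05,
}

# linker/background residue alphabet, biased toward disordered-region
# composition (low L/I/V/F) so planted motifs dominate scanner signal
_LINKER_AA = "AGSTPEDNQKRHYWCMLIVF"
_LINKER_W = np.array(
    [10, 10, 10, 8, 8, 8, 8, 6, 6, 8, 6, 3, 2, 1, 2, 1, 1, 1, 1, 1],
    dtype=float,
)
_LINKER_W /= _LINKER_W.sum()

_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    _CODONS_FOR_AA.setdefault(_aa, []).append(_codon)

DEFECT_CLASSES = (
    "InDel", "LackStart", "LackStop", "LackBoth",
    "Pseudo-frameshift", "Pseudo-premature-stop",
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Rates are per branch (events) or per site (substitutions); the fixed
    seed makes all emitted files byte-identical across runs.
    """

    tree_newick: str = DEFAULT_TREE
    n_r_families: int = 24
    n_background_families: int = 300
    n_chromosomes: int = 2
    architecture_weights: dict = field(
        default_factory=lambda: dict(ARCHITECTURE_WEIGHTS))
    omega_r: float = 0.2            # dN/dS of R-gene linker codons
    omega_background: float = 0.2   # dN/dS of background genes
    r_rate_scale: float = 2.0       # R-gene substitution rate multiplier
    gain_rate: float = 0.08         # Poisson copy gains per branch
    loss_rate: float = 0.08         # Poisson copy losses per branch
    cluster_fraction: float = 0.25  # R families laid out as tandem clusters
    n_boundary_families: int = 2    # pairs planted exactly 9 genes apart
    cluster_size: int = 3           # root copy number of cluster families
    max_copies: int = 6
    p_pseudo: float = 0.15          # pseudogenization probability per gene
    p_lack_start: float = 0.03
    p_lack_stop: float = 0.03
    p_lack_both: float = 0.01
    p_indel: float = 0.04
    n_unannotated_loci: int = 2     # extra R copies per species, absent from GFF
    background_len_mean: float = 300.0  # aa
    background_len_sd: float = 60.0
    intergenic_mean: int = 200      # bp between adjacent genes
    seed: int = 42

    def validate(self) -> None:
        for name in ("gain_rate", "loss_rate", "omega_r", "omega_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_pseudo", "p_lack_start", "p_lack_stop", "p_lack_both",
                     "p_indel", "cluster_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0,1]")


# ---------------------------------------------------------------------------
# domain-architecture protein construction
# ---------------------------------------------------------------------------

def _linker(rng: np.random.Generator, length: int) -> str:
    if length <= 0:
        return ""
    idx = rng.choice(len(_LINKER_AA), size=length, p=_LINKER_W)
    return "".join(_LINKER_AA[i] for i in idx)


def _cc_block(rng: np.random.Generator) -> tuple[str, list[int]]:
    """Six heptad repeats; hydrophobic a/d, charged e/g. Returns the block
    and its critical (conserved) positions."""
    heptads = []
    critical = []
    for h in range(6):
        a = rng.choice(list("LIM"))
        d = rng.choice(list("LIM"))
        e = rng.choice(list("EK"))
        g = rng.choice(list("KE"))
        b, c, f = (_linker(rng, 1) for _ in range(3))
        heptads.append(a + b + c + d + e + f + g)
        base = 7 * h
        critical += [base, base + 3, base + 4, base + 6]
    return "".join(heptads), critical


def _tir_block(rng: np.random.Generator) -> tuple[str, list[int]]:
    # every other position conserved: enough identity to stay above the
    # scanner threshold at default divergence
    return TIR_CONSENSUS, list(range(0, len(TIR_CONSENSUS), 2))


def _nbs_block(rng: np.random.Generator) -> tuple[str, list[int]]:
    parts = [
        (_linker(rng, 10), False),
        ("GMGGLGKTT", True),        # P-loop
        (_linker(rng, 38), False),
        ("KRYLIVLDDVW", True),      # kinase-2
        (_linker(rng, 38), False),
        ("GLPLAL", True),           # GLPL
        (_linker(rng, 24), False),
        ("MHDLL", True),            # MHD-like C-terminal block
        (_linker(rng, 18), False),
    ]
    seq, critical, pos = [], [], 0
    for block, is_motif in parts:
        if is_motif:
            critical += list(range(pos, pos + len(block)))
        seq.append(block)
        pos += len(block)
    return "".join(seq), critical


def _lrr_block(rng: np.random.Generator) -> tuple[str, list[int]]:
    """Six LxxLxLxx repeats (plus 2-residue spacers)."""
    units, critical = [], []
    for u in range(6):
        l1 = "L"
        l2 = rng.choice(list("LIV"))
        l3 = rng.choice(list("LF"))
        xs = _linker(rng, 7)
        unit = l1 + xs[0] + xs[1] + l2 + xs[2] + l3 + xs[3] + xs[4] + xs[5:7]
        units.append(unit)
        base = 10 * u
        critical += [base, base + 3, base + 5]
    return "".join(units), critical


_DOMAIN_BUILDERS = {
    "CC": _cc_block, "TIR": _tir_block, "NBS": _nbs_block, "LRR": _lrr_block,
}


def build_domain_protein(label: str, rng: np.random.Generator
                         ) -> tuple[str, dict[str, tuple[int, int]], set[int]]:
    """Build an ancestral R protein for an architecture label.

    Returns (protein, domain coordinates 1-based inclusive, critical 0-based
    positions held under complete constraint during evolution). Total length
    is drawn around 500 aa, the typical legume R-protein length.
    """
    if label not in ARCHITECTURE_WEIGHTS:
        raise ValueError(f"unknown architecture label: {label}")
    domain_names = label.split("-")
    blocks = [( name, *_DOMAIN_BUILDERS[name](rng)) for name in domain_names]
    domains_len = sum(len(b[1]) for b in blocks)
    n_gaps = len(blocks) + 1  # N flank, inter-domain linkers, C flank
    target = int(np.clip(rng.normal(500, 50), 380, 650))
    spare = max(target - 1 - domains_len, 40 * n_gaps)
    cuts = np.sort(rng.integers(0, spare + 1, size=n_gaps - 1))
    gap_lens = np.diff(np.concatenate([[0], cuts, [spare]]))
    # keep inter-domain linkers at >= 40 so spans never collide
    gap_lens = np.maximum(gap_lens, 40)

    protein = ["M"]
    coords: dict[str, tuple[int, int]] = {}
    critical: set[int] = {0}
    pos = 1
    for i, (name, block, crit) in enumerate(blocks):
        lk = _linker(rng, int(gap_lens[i]))
        protein.append(lk)
        pos += len(lk)
        coords[name] = (pos + 1, pos + len(block))
        critical.update(pos + c for c in crit)
        protein.append(block)
        pos += len(block)
    tail = _linker(rng, int(gap_lens[-1]))
    protein.append(tail)
    return "".join(protein), coords, critical


def random_background_protein(rng: np.random.Generator,
                              mean: float = 300.0, sd: float = 60.0) -> str:
    length = int(np.clip(rng.normal(mean, sd), 100, 600))
    return "M" + _linker(rng, length - 1)


def back_translate(protein: str, rng: np.random.Generator,
                   add_stop: bool = True) -> str:
    """Random-synonymous-codon back-translation; appends a stop codon."""
    codons = [
        _CODONS_FOR_AA[aa][rng.integers(0, len(_CODONS_FOR_AA[aa]))]
        for aa in protein
    ]
    if add_stop:
        codons.append(("TAA", "TAG", "TGA")[rng.integers(0, 3)])
    return "".join(codons)


# ---------------------------------------------------------------------------
# codon evolution
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_OTHER = {b: [x for x in _BASES if x != b] for b in _BASES}


def evolve_cds(ancestral_cds: str, branch_length: float, omega: float,
               rng: np.random.Generator,
               constrained_codons: frozenset | set = frozenset()) -> str:
    """Evolve a CDS by acceptance–rejection substitution.

    Substitutions are proposed at uniform nucleotide positions; synonymous
    changes are accepted, non-synonymous with probability ``omega``, changes
    creating an internal stop never, and any non-synonymous change in a
    constrained codon never. The number of accepted substitutions equals
    round(branch_length x length), so realised substitutions/site matches the
    requested branch length.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if len(ancestral_cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    n = len(ancestral_cds)
    n_codons = n // 3
    if "*" in translate(ancestral_cds)[:-1]:
        raise ValueError("ancestral CDS contains an internal stop")
    target = int(round(branch_length * n))
    if target == 0:
        return ancestral_cds
    seq = list(ancestral_cds)
    accepted = 0
    attempts = 0
    max_attempts = 400 * target + 2000
    while accepted < target and attempts < max_attempts:
        attempts += 1
        pos = int(rng.integers(0, n))
        old = seq[pos]
        new = _OTHER[old][rng.integers(0, 3)]
        ci = pos // 3
        cstart = ci * 3
        codon = seq[cstart:cstart + 3]
        codon[pos - cstart] = new
        new_codon = "".join(codon)
        old_codon = "".join(seq[cstart:cstart + 3])
        old_aa = CODON_TABLE[old_codon]
        new_aa = CODON_TABLE[new_codon]
        if new_aa == "*" and ci < n_codons - 1:
            continue  # internal stop
        if new_aa != old_aa:
            if ci in constrained_codons:
                continue
            if rng.random() >= omega:
                continue
        seq[pos] = new
        accepted += 1
    return "".join(seq)


# ---------------------------------------------------------------------------
# structural defects
# ---------------------------------------------------------------------------

def plant_defects(cds: str, defect_class: str, rng: np.random.Generator,
                  protected_codons: frozenset | set = frozenset()
                  ) -> tuple[str, dict]:
    """Introduce exactly one named structural defect into a CDS.

    Returns (mutated CDS, evidence dict with the planted position). The CDS
    must include its start and stop codons.
    """
    if defect_class not in DEFECT_CLASSES:
        raise ValueError(f"unknown defect class: {defect_class}")
    n_codons = len(cds) // 3
    if n_codons < 40:
        raise ValueError("sequence too short to host a defect")
    seq = cds

    def window(frac_lo: float, frac_hi: float) -> tuple[int, int]:
        return max(1, int(n_codons * frac_lo)), min(n_codons - 2,
                                                    int(n_codons * frac_hi))

    if defect_class == "LackStart":
        return "ATA" + seq[3:], {"event": "start_lost"}
    if defect_class == "LackStop":
        return seq[:-3] + "CAA", {"event": "stop_lost"}
    if defect_class == "LackBoth":
        return "ATA" + seq[3:-3] + "CAA", {"event": "start_and_stop_lost"}
    # truncating defects go downstream of the last motif-critical codon so
    # the planted domain content stays observable on the translated protein
    domain_end = max(
        (c for c in protected_codons if c < n_codons - 1), default=0)
    t_lo = min(max(domain_end + 3, int(n_codons * 0.70)), n_codons - 24)
    t_hi = n_codons - 22  # leave an alignable tail as defect evidence
    if defect_class == "Pseudo-frameshift":
        ci = int(rng.integers(t_lo, t_hi))
        pos = 3 * ci
        return seq[:pos] + seq[pos + 1:], {"event": "frameshift",
                                           "codon": ci}
    if defect_class == "Pseudo-premature-stop":
        ci = int(rng.integers(t_lo, t_hi))
        return seq[:3 * ci] + "TAA" + seq[3 * (ci + 1):], {
            "event": "premature_stop", "codon": ci}
    # InDel: in-frame 9-codon deletion in a run free of motif-critical codons
    lo, hi = window(0.30, 0.70)
    candidates = [
        ci for ci in range(lo, hi - 9)
        if not any((ci + k) in protected_codons for k in range(9))
    ]
    if not candidates:
        raise ValueError("no unprotected run to host the in-frame deletion")
    ci = candidates[int(rng.integers(0, len(candidates)))]
    return seq[:3 * ci] + seq[3 * (ci + 9):], {"event": "indel",
                                               "codon": ci, "codons_deleted": 9}


_TRUTH_CLASS = {
    "Complete": "Complete", "InDel": "InDel", "LackStart": "LackStart",
    "LackStop": "LackStop", "LackBoth": "LackBoth",
    "Pseudo-frameshift": "Pseudo", "Pseudo-premature-stop": "Pseudo",
}


# ---------------------------------------------------------------------------
# family evolution along the species tree
# ---------------------------------------------------------------------------

@dataclass
class SimGene:
    gene_id: str
    species: str
    family_id: str
    is_r: bool
    architecture: str = ""
    domain_coords: dict = field(default_factory=dict)
    cluster_id: str = ""
    structure_class: str = "Complete"
    defect_class: str = "Complete"
    omega: float = 0.0
    cds: str = ""
    protein: str = ""
    copy_index: int = 0
    chromosome: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"


@dataclass
class SimulationResult:
    config: SimulationConfig
    tree: object
    genes: list[SimGene]
    seeds: list[FastaRecord]               # family ancestral proteins
    genomes: dict[str, dict[str, str]]     # species -> chromosome -> sequence
    gene_models: dict[str, list[GeneModel]]
    node_counts: pd.DataFrame              # family x tree-node truth counts
    branch_events: pd.DataFrame            # per family/branch gains & losses
    unannotated: pd.DataFrame              # planted loci absent from GFF3
    family_meta: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return sorted(self.genomes)

    def proteomes(self) -> dict[str, list[FastaRecord]]:
        out: dict[str, list[FastaRecord]] = {sp: [] for sp in self.species}
        for g in self.genes:
            out[g.species].append(FastaRecord(g.gene_id, g.protein))
        return out

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g.gene_id, "species": g.species,
                "family_id": g.family_id, "is_r": g.is_r,
                "architecture": g.architecture,
                "domain_coords": ";".join(
                    f"{d}:{a}-{b}" for d, (a, b) in sorted(g.domain_coords.items())),
                "cluster_id": g.cluster_id,
                "structure_class": g.structure_class,
                "defect_class": g.defect_class,
                "omega": g.omega, "chromosome": g.chromosome,
                "start": g.start, "end": g.end, "strand": g.strand,
            }
            for g in self.genes
        ]
        return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)


def _node_label(node) -> str:
    if node.taxon is not None:
        return node.taxon.label.replace(" ", "_")
    return (node.label or "node").replace(" ", "_")


def simulate_families(config: SimulationConfig,
                      rng: np.random.Generator) -> dict:
    """Evolve R and background families along the species tree.

    Per family: an ancestral protein/CDS at the root, per-branch sequence
    evolution, and (R families only) per-branch integer copy gains/losses
    drawn from Poisson rates. Returns family records with per-leaf sequences
    and copy counts, plus per-node count truth and per-branch event truth.
    """
    tree = load_tree(config.tree_newick)
    labels = list(config.architecture_weights)
    weights = np.array([config.architecture_weights[l] for l in labels])
    weights = weights / weights.sum()

    n_cluster = int(round(config.cluster_fraction * config.n_r_families))
    families = []
    for fi in range(config.n_r_families):
        label = labels[int(rng.choice(len(labels), p=weights))]
        protein, coords, critical = build_domain_protein(label, rng)
        cds = back_translate(protein, rng)
        kind = "singleton"
        root_count = 1
        if fi < n_cluster:
            kind, root_count = "cluster", config.cluster_size
        elif fi < n_cluster + config.n_boundary_families:
            kind, root_count = "boundary", 2
        constrained = frozenset(critical | {0, len(cds) // 3 - 1})
        families.append({
            "family_id": f"f{fi:03d}", "is_r": True, "label": label,
            "coords": coords, "constrained": constrained,
            "ancestral_protein": protein, "ancestral_cds": cds,
            "root_count": root_count, "kind": kind,
            "omega": config.omega_r, "rate": config.r_rate_scale,
        })
    for bi in range(config.n_background_families):
        protein = random_background_protein(
            rng, config.background_len_mean, config.background_len_sd)
        cds = back_translate(protein, rng)
        families.append({
            "family_id": f"bg{bi:03d}", "is_r": False, "label": "",
            "coords": {}, "constrained": frozenset({0, len(cds) // 3 - 1}),
            "ancestral_protein": protein, "ancestral_cds": cds,
            "root_count": 1, "kind": "background",
            "omega": config.omega_background, "rate": 1.0,
        })

    node_rows, event_rows = [], []
    for fam in families:
        seqs: dict = {}     # node -> cds
        counts: dict = {}   # node -> copy count
        for node in tree.preorder_node_iter():
            name = _node_label(node)
            if node.parent_node is None:
                seqs[node] = fam["ancestral_cds"]
                counts[node] = fam["root_count"]
            else:
                bl = (node.edge.length or 0.0) * fam["rate"]
                seqs[node] = evolve_cds(
                    seqs[node.parent_node], bl, fam["omega"], rng,
                    fam["constrained"])
                parent_count = counts[node.parent_node]
                gains = losses = 0
                # boundary families are the controlled 9-gene-spacing
                # experiment and keep exactly two copies everywhere
                if fam["is_r"] and fam["kind"] != "boundary" and parent_count > 0:
                    gains = int(rng.poisson(config.gain_rate))
                    losses = int(rng.poisson(config.loss_rate))
                count = min(max(parent_count + gains - losses, 0),
                            config.max_copies)
                counts[node] = count
                net = count - parent_count
                event_rows.append({
                    "family_id": fam["family_id"], "branch": name,
                    "gain": max(net, 0), "loss": max(-net, 0), "net": net,
                })
            node_rows.append({
                "family_id": fam["family_id"], "node": name,
                "count": counts[node],
            })
        fam["leaf_seqs"] = {
            _node_label(leaf): seqs[leaf] for leaf in tree.leaf_node_iter()
        }
        fam["leaf_counts"] = {
            _node_label(leaf): counts[leaf] for leaf in tree.leaf_node_iter()
        }
    return {
        "tree": tree,
        "families": families,
        "node_counts": pd.DataFrame(node_rows),
        "branch_events": pd.DataFrame(event_rows),
    }


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def layout_genome(species: str, genes: list[SimGene],
                  order: list[tuple[str, str]],
                  rng: np.random.Generator,
                  intergenic_mean: int = 200,
                  extra_loci: list[tuple[str, str]] | None = None
                  ) -> tuple[dict[str, str], list[GeneModel], list[dict]]:
    """Place genes on chromosomes following the shared ancestral order and
    embed each CDS in random intergenic DNA (minus-strand genes
    reverse-complemented). ``order`` is [(chromosome, gene_id)] for this
    species; ``extra_loci`` are (chromosome_slot_after_gene, cds) planted
    without annotation. Returns genome, gene models, and unannotated-locus
    records."""
    by_id = {g.gene_id: g for g in genes}
    extra_after = {}
    for after_gene, cds in (extra_loci or []):
        extra_after.setdefault(after_gene, []).append(cds)
    chrom_parts: dict[str, list[str]] = {}
    chrom_pos: dict[str, int] = {}
    models: list[GeneModel] = []
    unannotated: list[dict] = []
    for chrom, gid in order:
        parts = chrom_parts.setdefault(chrom, [])
        if chrom not in chrom_pos:
            chrom_pos[chrom] = 0
        spacer_len = int(rng.integers(intergenic_mean // 2,
                                      intergenic_mean * 3 // 2))
        spacer = _random_dna(rng, spacer_len)
        parts.append(spacer)
        chrom_pos[chrom] += spacer_len
        g = by_id[gid]
        start = chrom_pos[chrom] + 1
        end = chrom_pos[chrom] + len(g.cds)
        embedded = g.cds if g.strand == "+" else reverse_complement(g.cds)
        parts.append(embedded)
        chrom_pos[chrom] += len(g.cds)
        g.chromosome, g.start, g.end = chrom, start, end
        models.append(GeneModel(
            gene_id=g.gene_id, species=species, chromosome=chrom,
            start=start, end=end, strand=g.strand,
            protein=g.protein, cds=g.cds,
        ))
        for cds in extra_after.get(gid, ()):
            gap = _random_dna(rng, intergenic_mean)
            parts.append(gap)
            chrom_pos[chrom] += len(gap)
            lo = chrom_pos[chrom] + 1
            parts.append(cds)
            chrom_pos[chrom] += len(cds)
            unannotated.append({
                "species": species, "chromosome": chrom,
                "start": lo, "end": chrom_pos[chrom], "strand": "+",
            })
    for chrom in chrom_parts:
        tail = _random_dna(rng, intergenic_mean)
        chrom_parts[chrom].append(tail)
    genome = {c: "".join(p) for c, p in sorted(chrom_parts.items())}
    assign_ranks(models)
    return genome, models, unannotated


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def _ancestral_order(families: list[dict], config: SimulationConfig,
                     rng: np.random.Generator) -> list[dict]:
    """Build the shared ancestral gene order: R-family blocks separated by
    >= 10 background genes, cluster members <= 8 background genes apart and
    boundary pairs exactly 9 apart. Returns a list of slots
    {family_id, copy_slot, chromosome}."""
    r_fams = [f for f in families if f["is_r"]]
    bg_ids = [f["family_id"] for f in families if not f["is_r"]]
    rng.shuffle(r_fams)
    bg_iter = iter(bg_ids)

    def take_bg(n: int) -> list[dict]:
        out = []
        for _ in range(n):
            try:
                out.append({"family_id": next(bg_iter), "copy_slot": 0})
            except StopIteration:
                raise ValueError("chromosome capacity exceeded: "
                                 "not enough background families for spacing")
        return out

    slots: list[dict] = []
    for fam in r_fams:
        slots.extend(take_bg(int(rng.integers(9, 11))))
        base = max(fam["root_count"], 1)
        n_slots = max([base] + list(fam.get("leaf_counts", {}).values()))
        # gaps (intervening background genes) between consecutive copy slots;
        # copies gained beyond the root count sit adjacent (tandem
        # duplication), so cluster spans never exceed 8 intervening genes.
        # Draw bounds keep worst-case background demand within the pool at
        # any seed.
        if fam["kind"] == "cluster":
            gaps = [int(g) for g in
                    rng.integers(1, 1 + min(3, 8 // max(base - 1, 1)),
                                 size=max(base - 1, 0))]
        elif fam["kind"] == "boundary":
            gaps = [9] * (base - 1)
        else:
            gaps = []
        gaps += [0] * (n_slots - 1 - len(gaps))
        for ci in range(n_slots):
            slots.append({"family_id": fam["family_id"], "copy_slot": ci})
            if ci < len(gaps):
                slots.extend(take_bg(gaps[ci]))
    # spread remaining background genes at the end
    for bid in bg_iter:
        slots.append({"family_id": bid, "copy_slot": 0})
    # split into chromosomes at slot boundaries away from R blocks
    n_per = int(np.ceil(len(slots) / config.n_chromosomes))
    for i, slot in enumerate(slots):
        slot["chromosome"] = f"chr{i // n_per + 1}"
    # never split an R block across chromosomes: move block tail forward
    for i in range(1, len(slots)):
        if (slots[i]["copy_slot"] > 0
                and slots[i]["chromosome"] != slots[i - 1]["chromosome"]):
            slots[i]["chromosome"] = slots[i - 1]["chromosome"]
    return slots


def simulate(config: SimulationConfig | None = None) -> SimulationResult:
    """Run the full generator: family evolution, copy-number evolution,
    structural defects, genome layout, and truth bookkeeping."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    sim = simulate_families(config, rng)
    tree, families = sim["tree"], sim["families"]
    fam_by_id = {f["family_id"]: f for f in families}
    slots = _ancestral_order(families, config, rng)
    leaves = sorted(_node_label(l) for l in tree.leaf_node_iter())

    genes: list[SimGene] = []
    genomes: dict[str, dict[str, str]] = {}
    gene_models: dict[str, list[GeneModel]] = {}
    unannot_rows: list[dict] = []

    defect_menu = (
        ("Pseudo-frameshift", config.p_pseudo / 2),
        ("Pseudo-premature-stop", config.p_pseudo / 2),
        ("LackBoth", config.p_lack_both),
        ("LackStart", config.p_lack_start),
        ("LackStop", config.p_lack_stop),
        ("InDel", config.p_indel),
    )

    for sp in leaves:
        sp_genes: dict[str, SimGene] = {}
        order: list[tuple[str, str]] = []
        for slot in slots:
            fam = fam_by_id[slot["family_id"]]
            count = fam["leaf_counts"].get(sp, 1) if fam["is_r"] else 1
            if slot["copy_slot"] >= count:
                continue
            ci = slot["copy_slot"]
            gid = (f"{sp}_{fam['family_id']}_c{ci}" if fam["is_r"]
                   else f"{sp}_{fam['family_id']}")
            cds = fam["leaf_seqs"][sp]
            if ci > 0:  # tandem copies lightly diverged from the leaf sequence
                cds = evolve_cds(cds, 0.01, fam["omega"], rng,
                                 fam["constrained"])
            g = SimGene(
                gene_id=gid, species=sp, family_id=fam["family_id"],
                is_r=fam["is_r"], architecture=fam["label"],
                domain_coords=dict(fam["coords"]), omega=fam["omega"],
                cds=cds, copy_index=ci,
                strand="+" if rng.random() < 0.5 else "-",
            )
            # any family with >=2 tandem copies is a true cluster (all copy
            # slots sit within 8 intervening genes) except the 9-gene
            # boundary controls
            if fam["is_r"] and fam["kind"] != "boundary" and count >= 2:
                g.cluster_id = f"{sp}_{fam['family_id']}_cluster"
            if fam["is_r"]:
                u = rng.random()
                acc = 0.0
                for dclass, p in defect_menu:
                    acc += p
                    if u < acc:
                        g.cds, _ev = plant_defects(
                            cds, dclass, rng, fam["constrained"])
                        g.defect_class = dclass
                        g.structure_class = _TRUTH_CLASS[dclass]
                        break
            g.protein = translate(g.cds[: 3 * (len(g.cds) // 3)])
            if g.protein.endswith("*"):
                g.protein = g.protein[:-1]
            sp_genes[gid] = g
            order.append((slot["chromosome"], gid))
        # unannotated extra loci: copies of the first cluster families
        extra = []
        r_fams = [f for f in families if f["is_r"]]
        bg_order = [gid for _c, gid in order if not sp_genes[gid].is_r]
        for k in range(config.n_unannotated_loci):
            fam = r_fams[k % len(r_fams)]
            cds = evolve_cds(fam["leaf_seqs"][sp], 0.01, fam["omega"], rng,
                             fam["constrained"])
            anchor = bg_order[(k + 1) * len(bg_order) // (
                config.n_unannotated_loci + 2)]
            extra.append((anchor, cds))
        genome, models, unann = layout_genome(
            sp, list(sp_genes.values()), order, rng,
            config.intergenic_mean, extra)
        genomes[sp] = genome
        gene_models[sp] = models
        unannot_rows.extend(unann)
        genes.extend(sp_genes.values())

    seeds = [
        FastaRecord(f"RPROT_{f['family_id']}", f["ancestral_protein"])
        for f in families if f["is_r"]
    ]
    family_meta = pd.DataFrame([
        {
            "family_id": f["family_id"], "is_r": f["is_r"],
            "architecture": f["label"], "kind": f["kind"],
            "omega": f["omega"], "rate": f["rate"],
            "root_count": f["root_count"],
            "ancestral_protein": f["ancestral_protein"],
        }
        for f in families
    ])
    return SimulationResult(
        config=config, tree=tree, genes=genes, seeds=seeds,
        genomes=genomes, gene_models=gene_models,
        node_counts=sim["node_counts"], branch_events=sim["branch_events"],
        unannotated=pd.DataFrame(
            unannot_rows,
            columns=["species", "chromosome", "start", "end", "strand"]),
        family_meta=family_meta,
    )


def write_outputs(result: SimulationResult, outdir) -> Path:
    """Emit per-species FASTA/GFF3, the species tree, the seed database and
    the truth tables. Deterministic: identical seed, identical bytes."""
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    for sp in result.species:
        models = result.gene_models[sp]
        write_fasta(
            [FastaRecord(m.gene_id, m.protein) for m in models],
            out / f"{sp}.protein.fasta")
        write_fasta(
            [FastaRecord(m.gene_id, m.cds) for m in models],
            out / f"{sp}.cds.fasta")
        write_fasta(
            [FastaRecord(chrom, seq)
             for chrom, seq in sorted(result.genomes[sp].items())],
            out / f"{sp}.genome.fasta")
        write_gff3(models, out / f"{sp}.gff3")
    write_fasta(result.seeds, out / "seeds.fasta")
    write_tree(result.tree, out / "tree.nwk")
    result.truth_table().to_csv(out / "truth" / "genes.tsv", sep="\t",
                                index=False)
    result.node_counts.to_csv(out / "truth" / "node_counts.tsv", sep="\t",
                              index=False)
    result.branch_events.to_csv(out / "truth" / "branch_events.tsv",
                                sep="\t", index=False)
    result.unannotated.to_csv(out / "truth" / "unannotated_loci.tsv",
                              sep="\t", index=False)
    result.family_meta.to_csv(out / "truth" / "families.tsv", sep="\t",
                              index=False)
    return out
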
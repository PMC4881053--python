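"""Phylogenetics on four-fold-degenerate supergenes.

Single-copy gene families (exactly one member per species) are aligned at
the protein level by center-star multiple alignment, back-translated to
codons, and reduced to their four-fold degenerate (4D) third positions:
codon columns whose first two positions are identical in every species and
whose dinucleotide prefix makes the third position silent for any base.
Concatenating all 4D sites gives one supergene per species; Kimura
2-parameter (K2P) distances between supergenes feed a neighbor-joining (NJ)
tree whose internal-node stability is assessed by bootstrap resampling of
supergene columns. Comparing the total branch length of the R-gene tree to
the genome-wide single-copy tree measures the relative divergence rate of
R-genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

import dendropy

from .core_io import AlignParams, DEFAULT_PARAMS, align_global

# dinucleotide prefixes whose codons are four-fold degenerate at position 3
FOURFOLD_PREFIXES = frozenset(
    {"TC", "CT", "CC", "CG", "AC", "GT", "GC", "GG"})

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


@dataclass
class CodonAlignment:
    """Gap-padded, codon-atomic multiple alignment."""

    species: list[str]
    codon_seqs: dict[str, str]  # species -> aligned codons ('---' gaps)

    def __post_init__(self):
        lengths = {len(s) for s in self.codon_seqs.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences differ in length")
        (n,) = lengths or {0}
        if n % 3:
            raise ValueError("alignment length not a multiple of 3")

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.codon_seqs.values()))) // 3


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    model: str = "K2P"
    saturated: np.ndarray | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix not symmetric")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


# ---------------------------------------------------------------------------
# family selection and alignment
# ---------------------------------------------------------------------------

def single_copy_families(members: dict[str, dict[str, list[str]]],
                         species: list[str]) -> dict[str, dict[str, str]]:
    """Families with exactly one member in every listed species.

    ``members`` maps family -> species -> gene ids; returns family ->
    species -> the single gene id."""
    out = {}
    for fam, per_sp in sorted(members.items()):
        if all(len(per_sp.get(sp, [])) == 1 for sp in species):
            out[fam] = {sp: per_sp[sp][0] for sp in species}
    return out


def align_family(proteins: dict[str, str], cds: dict[str, str],
                 params: AlignParams = DEFAULT_PARAMS) -> CodonAlignment:
    """Center-star protein MSA, back-translated to codons.

    The center is the sequence maximising its summed pairwise global scores;
    every other sequence is aligned to the center and the pairwise
    alignments are merged ('once a gap, always a gap'). Back-translation is
    exact: each aligned residue is replaced by its source codon.
    """
    species = sorted(proteins)
    for sp in species:
        clean = cds[sp][:-3] if cds[sp][-3:] in ("TAA", "TAG", "TGA") else cds[sp]
        if len(clean) != 3 * len(proteins[sp]):
            raise ValueError(f"{sp}: CDS/protein length mismatch")
    if len(species) == 1:
        sp = species[0]
        return CodonAlignment(species=[sp],
                              codon_seqs={sp: cds[sp][: 3 * len(proteins[sp])]})
    # choose the center
    totals = {sp: 0.0 for sp in species}
    pair_aln: dict[tuple[str, str], object] = {}
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            aln = align_global(proteins[b], proteins[a], params)
            pair_aln[(a, b)] = aln
            totals[a] += aln.score
            totals[b] += aln.score
    center = max(species, key=lambda sp: (totals[sp], sp))
    # merge alignments to the center ('once a gap, always a gap')
    rows: dict[str, list[str]] = {center: list(proteins[center])}
    for sp in (s for s in species if s != center):
        if (center, sp) in pair_aln:
            aln = pair_aln[(center, sp)]  # target = center
            c_str, s_str = str(aln[0]), str(aln[1])
        else:
            aln = pair_aln[(sp, center)]  # target = sp
            c_str, s_str = str(aln[1]), str(aln[0])
        master = rows[center]
        out: dict[str, list[str]] = {k: [] for k in rows}
        new_row: list[str] = []
        i = j = 0
        while i < len(master) or j < len(c_str):
            m_gap = i < len(master) and master[i] == "-"
            c_gap = j < len(c_str) and c_str[j] == "-"
            if j >= len(c_str) or (m_gap and not c_gap):
                # gap column from an earlier merge, absent here
                for k in rows:
                    out[k].append(rows[k][i])
                new_row.append("-")
                i += 1
            elif i >= len(master) or c_gap:
                # insertion relative to the center: open a new column
                for k in rows:
                    out[k].append("-")
                new_row.append(s_str[j])
                j += 1
            else:
                # the same center residue in both
                for k in rows:
                    out[k].append(rows[k][i])
                new_row.append(s_str[j])
                i += 1
                j += 1
        out[sp] = new_row
        rows = out
    width = len(rows[center])
    for sp, row in rows.items():
        if len(row) != width:
            raise AssertionError("center-star merge produced ragged rows")
    # back-translate
    codon_seqs = {}
    for sp in species:
        src = cds[sp]
        out = []
        ci = 0
        for aa in rows[sp]:
            if aa == "-":
                out.append("---")
            else:
                out.append(src[3 * ci : 3 * ci + 3])
                ci += 1
        codon_seqs[sp] = "".join(out)
    return CodonAlignment(species=species, codon_seqs=codon_seqs)


def extract_4d_sites(alignment: CodonAlignment) -> dict[str, str]:
    """Third positions of codon columns that are gap-free, share an
    identical first-two-position prefix across all species, and whose prefix
    is four-fold degenerate. Output strings have equal lengths."""
    seqs = alignment.codon_seqs
    species = alignment.species
    out = {sp: [] for sp in species}
    for k in range(alignment.n_codons):
        codons = {sp: seqs[sp][3 * k : 3 * k + 3] for sp in species}
        if any("-" in c for c in codons.values()):
            continue
        prefixes = {c[:2] for c in codons.values()}
        if len(prefixes) != 1:
            continue
        (prefix,) = prefixes
        if prefix not in FOURFOLD_PREFIXES:
            continue
        for sp in species:
            out[sp].append(codons[sp][2])
    return {sp: "".join(v) for sp, v in out.items()}


def concatenate_supergene(site_sets: list[dict[str, str]]) -> dict[str, str]:
    """Concatenate per-family 4D site strings into one supergene/species."""
    if not site_sets:
        return {}
    species = sorted(site_sets[0])
    return {sp: "".join(s.get(sp, "") for s in site_sets) for sp in species}


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def k2p_distance(seq_a: str, seq_b: str) -> tuple[float, bool]:
    """Kimura 2-parameter distance.

    d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q) with P,Q the transition and
    transversion proportions over pairwise-comparable sites (gap/N
    excluded). Returns (distance, saturated); when a log argument is <= 0
    the distance is inf and saturated is True."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    n = ts = tv = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a not in "ACGT" or b not in "ACGT":
            continue
        n += 1
        if a != b:
            if (a, b) in TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    x, y = 1 - 2 * P - Q, 1 - 2 * Q
    if x <= 0 or y <= 0:
        return float("inf"), True
    return -0.5 * math.log(x) - 0.25 * math.log(y), False


def k2p_matrix(seqs: dict[str, str]) -> DistanceMatrix:
    ids = sorted(seqs)
    n = len(ids)
    m = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d, s = k2p_distance(seqs[ids[i]], seqs[ids[j]])
            m[i, j] = m[j, i] = d
            sat[i, j] = sat[j, i] = s
    return DistanceMatrix(ids=ids, matrix=m, saturated=sat)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch. Returns an unrooted dendropy tree (trifurcating at
    the last join)."""
    ids = list(dist.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    taxa = dendropy.TaxonNamespace(ids)
    nodes = {}
    for label in ids:
        nd = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes[label] = nd
    D = {(a, b): dist.get(a, b) for a in ids for b in ids}
    active = list(ids)
    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(D[(a, b)] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (m - 2) * D[(a, b)] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = 0.5 * D[(a, b)] + (r[a] - r[b]) / (2 * (m - 2))
        lb = D[(a, b)] - la
        if la < 0:
            lb += -la
            la = 0.0
        if lb < 0:
            la += -lb
            lb = 0.0
        new_label = f"_nj{counter}"
        counter += 1
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = la
        parent.add_child(nodes[b])
        nodes[b].edge.length = lb
        nodes[new_label] = parent
        for c in active:
            if c in (a, b):
                continue
            d_new = 0.5 * (D[(a, c)] + D[(b, c)] - D[(a, b)])
            D[(new_label, c)] = D[(c, new_label)] = max(d_new, 0.0)
        D[(new_label, new_label)] = 0.0
        active = [c for c in active if c not in (a, b)] + [new_label]
    # final trifurcation
    a, b, c = active
    root = dendropy.Node()
    va = 0.5 * (D[(a, b)] + D[(a, c)] - D[(b, c)])
    vb = 0.5 * (D[(a, b)] + D[(b, c)] - D[(a, c)])
    vc = 0.5 * (D[(a, c)] + D[(b, c)] - D[(a, b)])
    lengths = [va, vb, vc]
    labels = [a, b, c]
    # clamp negatives, moving deficits onto the other branches equally
    for i in range(3):
        if lengths[i] < 0:
            deficit = -lengths[i]
            lengths[i] = 0.0
            for j in range(3):
                if j != i:
                    lengths[j] += deficit / 2
    for label, ln in zip(labels, lengths):
        root.add_child(nodes[label])
        nodes[label].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def total_branch_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.edges())


def root_to_tip(tree: dendropy.Tree) -> dict[str, float]:
    out = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        nd = leaf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        out[leaf.taxon.label] = d
    return out


def compare_rates(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> dict:
    """Ratio of total branch lengths of two trees over the same leaf set,
    plus per-leaf ratios of path lengths from a fixed reference leaf
    (the lexicographically first; well-defined on unrooted trees, unlike
    root-to-tip distances from an arbitrary NJ trifurcation)."""
    leaves_a = {l.taxon.label for l in tree_a.leaf_node_iter()}
    leaves_b = {l.taxon.label for l in tree_b.leaf_node_iter()}
    if leaves_a != leaves_b:
        raise ValueError("trees have different leaf sets")
    tb = total_branch_length(tree_b)
    if tb == 0:
        raise ValueError("zero total branch length in denominator tree")
    ref = min(leaves_a)

    def ref_paths(tree):
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace
                if t.label in leaves_a}
        return {sp: pdm.distance(taxa[ref], taxa[sp])
                for sp in leaves_a if sp != ref}

    pa, pb = ref_paths(tree_a), ref_paths(tree_b)
    per_leaf = {
        sp: (pa[sp] / pb[sp]) if pb[sp] > 0 else float("nan")
        for sp in sorted(pa)
    }
    return {
        "total_ratio": total_branch_length(tree_a) / tb,
        "reference_leaf": ref,
        "per_leaf_ratio": per_leaf,
    }


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree, taxa: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of the smaller side
    (lexicographic tie-break)."""
    full = frozenset(taxa)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = full - side
        if len(side) < 2 or len(other) < 2:
            continue
        pick = min((sorted(side), sorted(other)))
        out.add(frozenset(pick))
    return out


def bootstrap_support(supergene: dict[str, str], n_replicates: int = 100,
                      seed: int = 0) -> dict[frozenset, float]:
    """Bootstrap column resampling of the supergene alignment.

    Per replicate, columns are drawn with replacement, a K2P + NJ tree is
    built, and each original-tree bipartition is scored by the percentage of
    replicates containing it. Replicate RNG streams derive from one master
    seed by counter, so results are reproducible."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    species = sorted(supergene)
    arr = np.array([list(supergene[sp]) for sp in species])
    n_sites = arr.shape[1]
    base_tree = nj_tree(k2p_matrix(supergene))
    targets = _bipartitions(base_tree, species)
    counts = {bp: 0 for bp in targets}
    for rep in range(n_replicates):
        rng = np.random.default_rng((seed * 100003 + rep) % (2**31))
        cols = rng.integers(0, n_sites, size=n_sites)
        boot = {sp: "".join(arr[i, cols]) for i, sp in enumerate(species)}
        btree = nj_tree(k2p_matrix(boot))
        bps = _bipartitions(btree, species)
        for bp in targets:
            if bp in bps:
                counts[bp] += 1
    return {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
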
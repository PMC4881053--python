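"""Independent oracles shared by the unit and acceptance suites.

These deliberately re-derive quantities by direct enumeration or
construction, sharing no code path with the implementations they check.
"""

import itertools
import random as pyrandom

import dendropy
import numpy as np

from rgevo.core_io import CODON_TABLE

STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")


# ---------------------------------------------------------------------------
# NG86 by direct enumeration
# ---------------------------------------------------------------------------

def oracle_sites(codon):
    total = 0.0
    for i in range(3):
        syn = sum(
            1 for b in "ACGT"
            if b != codon[i]
            and CODON_TABLE[codon[:i] + b + codon[i + 1:]]
            == CODON_TABLE[codon]
            and (codon[:i] + b + codon[i + 1:]) not in STOPS
        )
        total += syn / 3
    return total


def oracle_pathways(ca, cb):
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for strict in (True, False):
        for order in itertools.permutations(diff):
            cur, s, n, ok = ca, 0, 0, True
            for i in order:
                nxt = cur[:i] + cb[i] + cur[i + 1:]
                if strict and nxt in STOPS:
                    ok = False
                    break
                if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                    s += 1
                else:
                    n += 1
                cur = nxt
            if ok:
                paths.append((s, n))
        if paths:
            break
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def oracle_ng86(pairs):
    S = Sd = Nd = 0.0
    for ca, cb in pairs:
        S += (oracle_sites(ca) + oracle_sites(cb)) / 2
        s, n = oracle_pathways(ca, cb)
        Sd += s
        Nd += n
    N = 3 * len(pairs) - S
    return S, N, Sd, Nd


# ---------------------------------------------------------------------------
# exhaustive linear-cost parsimony
# ---------------------------------------------------------------------------

def exhaustive_min_cost(tree, leaf_counts, max_count):
    """Enumerate every internal-node assignment; return (minimal cost, the
    minimal assignment with lexicographically smallest counts)."""
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    best = None
    for combo in itertools.product(range(max_count + 1),
                                   repeat=len(internals)):
        assign = dict(zip(internals, combo))
        for leaf in tree.leaf_node_iter():
            assign[leaf] = leaf_counts[leaf.taxon.label]
        cost = sum(abs(assign[nd] - assign[nd.parent_node])
                   for nd in tree.preorder_node_iter()
                   if nd.parent_node is not None)
        key = (cost, combo)
        if best is None or key < best[0]:
            best = (key, assign)
    return best[0][0], best[1]


# ---------------------------------------------------------------------------
# tree/alignment constructions
# ---------------------------------------------------------------------------

def random_additive_matrix(rng, n):
    """Distances induced by a random binary tree with positive lengths."""
    ids = [f"t{i}" for i in range(n)]
    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        taxon_namespace=taxa, rng=pyrandom.Random(int(rng.integers(1e6))))
    for e in tree.edges():
        if e.length is not None:
            e.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    m = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                d = pdm.distance(taxa.get_taxon(a), taxa.get_taxon(b))
                m[i, j] = m[j, i] = d
    return ids, m


def clean_alignment():
    """Zero-homoplasy, strictly additive alignment on ((a,b),(c,d),e):
    every edge carries private columns with distinct lengths; plenty of
    constant background keeps the K2P correction near-linear."""
    species = ["a", "b", "c", "d", "e"]
    groups = ([({"a", "b"}, 40), ({"c", "d"}, 20),
               ({"a", "b", "c", "d"}, 30)]
              + [({sp}, 10 + 2 * i) for i, sp in enumerate(species)])
    cols = {sp: [] for sp in species}
    for clade, k in groups:
        for _ in range(k):
            for sp in species:
                cols[sp].append("C" if sp in clade else "A")
    for _ in range(500):
        for sp in species:
            cols[sp].append("G")
    return {sp: "".join(v) for sp, v in cols.items()}
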
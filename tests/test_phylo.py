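"""4D-site supergenes, K2P distances, neighbor joining and bootstrap."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from rgevo import phylo as ph
from rgevo.core_io import load_tree, translate
from rgevo.synthetic_data import back_translate


# ---------------------------------------------------------------------------
# single-copy filter
# ---------------------------------------------------------------------------

def test_single_copy_filter():
    species = ["A", "B", "C"]
    members = {
        "keep": {"A": ["a1"], "B": ["b1"], "C": ["c1"]},
        "missing": {"A": ["a1"], "B": ["b1"]},
        "multi": {"A": ["a1", "a2"], "B": ["b1"], "C": ["c1"]},
    }
    out = ph.single_copy_families(members, species)
    assert list(out) == ["keep"]
    assert out["keep"] == {"A": "a1", "B": "b1", "C": "c1"}


# ---------------------------------------------------------------------------
# center-star alignment + back-translation
# ---------------------------------------------------------------------------

def test_identical_sequences_gap_free():
    prots = {s: "MKVLLE" for s in "abc"}
    cds = {s: "ATGAAAGTTCTTCTTGAA" for s in "abc"}
    aln = ph.align_family(prots, cds)
    assert all("-" not in s for s in aln.codon_seqs.values())


def test_single_insertion_creates_one_codon_gap():
    prots = {"s1": "MKVLLE", "s2": "MKVQLLE", "s3": "MKVLLE"}
    cds = {"s1": "ATGAAAGTTCTTCTTGAA",
           "s2": "ATGAAAGTTCAACTTCTTGAA",
           "s3": "ATGAAAGTGCTGCTCGAA"}
    aln = ph.align_family(prots, cds)
    assert aln.codon_seqs["s1"].count("-") == 3
    assert aln.codon_seqs["s2"].count("-") == 0
    assert "CAA" in aln.codon_seqs["s2"]


def test_back_translation_preserves_every_codon(rng):
    prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 50))
    cds = {s: back_translate(prot, rng, add_stop=False) for s in "ab"}
    prots = {s: translate(cds[s]) for s in "ab"}
    aln = ph.align_family(prots, cds)
    for s in "ab":
        assert aln.codon_seqs[s].replace("---", "") == cds[s]


def test_cds_protein_mismatch_errors():
    with pytest.raises(ValueError):
        ph.align_family({"a": "MKV", "b": "MKV"},
                        {"a": "ATGAAA", "b": "ATGAAAGTT"})


# ---------------------------------------------------------------------------
# 4D sites
# ---------------------------------------------------------------------------

def _aln(cols):
    species = sorted(cols[0])
    return ph.CodonAlignment(
        species=species,
        codon_seqs={sp: "".join(c[sp] for c in cols) for sp in species})


def test_4d_extraction_rules():
    # GG- prefix is 4D: third positions emitted
    aln = _aln([{"a": "GGA", "b": "GGG", "c": "GGT"}])
    assert ph.extract_4d_sites(aln) == {"a": "A", "b": "G", "c": "T"}
    # ATG is not 4D
    aln = _aln([{"a": "ATG", "b": "ATG", "c": "ATG"}])
    assert ph.extract_4d_sites(aln) == {"a": "", "b": "", "c": ""}
    # differing prefixes disqualify the column
    aln = _aln([{"a": "GGA", "b": "GAA", "c": "GGA"}])
    assert ph.extract_4d_sites(aln) == {"a": "", "b": "", "c": ""}
    # gap columns are skipped
    aln = _aln([{"a": "GGA", "b": "---", "c": "GGT"}])
    assert ph.extract_4d_sites(aln) == {"a": "", "b": "", "c": ""}


def test_4d_extraction_order_independent_and_additive(rng):
    cols = []
    for _ in range(30):
        pre = rng.choice(["GG", "GC", "AT", "TT"])
        cols.append({sp: pre + rng.choice(list("ACGT")) for sp in "abc"})
    full = ph.extract_4d_sites(_aln(cols))
    part1 = ph.extract_4d_sites(_aln(cols[:15]))
    part2 = ph.extract_4d_sites(_aln(cols[15:]))
    for sp in "abc":
        assert full[sp] == part1[sp] + part2[sp]


# ---------------------------------------------------------------------------
# K2P
# ---------------------------------------------------------------------------

def test_k2p_identical_zero():
    assert ph.k2p_distance("ACGT" * 10, "ACGT" * 10) == (0.0, False)


def test_k2p_closed_form():
    b = list("A" * 100)
    for i in range(10):
        b[i] = "G"            # transitions: P = 0.1
    for i in range(10, 15):
        b[i] = "C"            # transversions: Q = 0.05
    d, sat = ph.k2p_distance("A" * 100, "".join(b))
    assert not sat
    assert d == pytest.approx(0.17018, abs=1e-5)
    expected = -0.5 * math.log(1 - 0.2 - 0.05) - 0.25 * math.log(1 - 0.1)
    assert d == pytest.approx(expected, abs=1e-9)


def test_k2p_saturated_flag():
    b = list("A" * 100)
    for i in range(45):
        b[i] = "G"
    for i in range(45, 55):
        b[i] = "T"
    d, sat = ph.k2p_distance("A" * 100, "".join(b))
    assert sat and math.isinf(d)


def test_k2p_equals_jc_at_one_to_two_proportioning():
    """With transitions:transversions = 1:2 (P = p/3, Q = 2p/3) the K2P
    distance reduces to the Jukes-Cantor formula."""
    for p in (0.06, 0.15, 0.3):
        n = 300
        k_ts = round(n * p / 3)
        k_tv = round(n * 2 * p / 3)
        b = list("A" * n)
        for i in range(k_ts):
            b[i] = "G"
        for i in range(k_ts, k_ts + k_tv):
            b[i] = "C" if i % 2 else "T"
        d, _ = ph.k2p_distance("A" * n, "".join(b))
        p_obs = (k_ts + k_tv) / n
        jc = -0.75 * math.log(1 - 4 * p_obs / 3)
        assert d == pytest.approx(jc, rel=1e-9)


def test_k2p_no_comparable_sites_errors():
    with pytest.raises(ValueError):
        ph.k2p_distance("NNN", "NNN")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _tree_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.distance(taxa[a], taxa[b])


from _oracles import random_additive_matrix as _random_additive_matrix  # noqa: E402


@pytest.mark.parametrize("n", [4, 5, 6, 8])
def test_nj_recovers_additive_matrices_exactly(n, rng):
    """On an additive matrix the NJ tree reproduces every pairwise distance
    to 1e-9 (hence topology and branch lengths are exact)."""
    ids, m = _random_additive_matrix(rng, n)
    tree = ph.nj_tree(ph.DistanceMatrix(ids=ids, matrix=m))
    dist = _tree_distances(tree)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                assert dist(a, b) == pytest.approx(m[i, j], abs=1e-9)


def test_nj_matches_skbio_topology(rng):
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    ids, m = _random_additive_matrix(rng, 6)
    ours = ph.nj_tree(ph.DistanceMatrix(ids=ids, matrix=m))
    theirs = sk_nj(SkDM(m, ids))
    ours_bps = ph._bipartitions(ours, ids)
    theirs_newick = str(theirs).strip()
    theirs_dp = load_tree(theirs_newick)
    theirs_bps = ph._bipartitions(theirs_dp, ids)
    assert ours_bps == theirs_bps


def test_nj_ultrametric_matches_upgma_topology(rng):
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    # ultrametric matrix from a clock-like tree
    ids = ["a", "b", "c", "d", "e"]
    m = np.array([
        [0, 2, 6, 6, 8],
        [2, 0, 6, 6, 8],
        [6, 6, 0, 4, 8],
        [6, 6, 4, 0, 8],
        [8, 8, 8, 8, 0]], float)
    tree = ph.nj_tree(ph.DistanceMatrix(ids=ids, matrix=m))
    bps = ph._bipartitions(tree, ids)
    link = hierarchy.average(squareform(m))

    def canon(side):
        other = set(ids) - set(side)
        return frozenset(min((sorted(side), sorted(other))))

    # UPGMA clades from the linkage: {a,b} and {c,d}
    assert canon({"a", "b"}) in bps
    assert canon({"c", "d"}) in bps


def test_nj_equal_distances_star_like():
    ids = ["a", "b", "c", "d"]
    m = np.ones((4, 4)) - np.eye(4)
    tree = ph.nj_tree(ph.DistanceMatrix(ids=ids, matrix=m))
    internal = [e.length for e in tree.preorder_edge_iter()
                if e.head_node and not e.head_node.is_leaf()
                and e.length is not None]
    assert all(abs(l) < 1e-12 for l in internal)


def test_nj_too_few_taxa_errors():
    with pytest.raises(ValueError):
        ph.nj_tree(ph.DistanceMatrix(ids=["a", "b"],
                                     matrix=np.zeros((2, 2))))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

from _oracles import clean_alignment as _clean_alignment  # noqa: E402


def test_bootstrap_clean_alignment_full_support():
    supports = ph.bootstrap_support(_clean_alignment(), n_replicates=50,
                                    seed=1)
    assert supports, "no bipartitions scored"
    assert all(v == pytest.approx(100.0) for v in supports.values())


def test_bootstrap_supports_bounded_and_deterministic():
    sg = _clean_alignment()
    s1 = ph.bootstrap_support(sg, n_replicates=25, seed=7)
    s2 = ph.bootstrap_support(sg, n_replicates=25, seed=7)
    assert s1 == s2
    assert all(0.0 <= v <= 100.0 for v in s1.values())


# ---------------------------------------------------------------------------
# rate comparison
# ---------------------------------------------------------------------------

def test_compare_rates_identity_and_linearity():
    t1 = load_tree("((a:1,b:1):1,(c:1,d:1):1):0;")
    t2 = load_tree("((a:1,b:1):1,(c:1,d:1):1):0;")
    assert ph.compare_rates(t1, t2)["total_ratio"] == pytest.approx(1.0)
    t3 = load_tree("((a:3,b:3):3,(c:3,d:3):3):0;")
    assert ph.compare_rates(t3, t2)["total_ratio"] == pytest.approx(3.0)


def test_compare_rates_leafset_mismatch_errors():
    t1 = load_tree("((a:1,b:1):1,c:1):0;")
    t2 = load_tree("((a:1,x:1):1,c:1):0;")
    with pytest.raises(ValueError):
        ph.compare_rates(t1, t2)
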
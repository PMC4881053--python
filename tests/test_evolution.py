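"""Family clustering, ancestral-count parsimony and NG86 selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from _oracles import SENSE_CODONS, exhaustive_min_cost, oracle_ng86

from rgevo import evolution as ev
from rgevo.core_io import CODON_TABLE, FastaRecord, load_tree
from rgevo.synthetic_data import back_translate, evolve_cds


def test_ng86_phe_example():
    r = ev.ng86([("TTT", "TTC")])
    assert (r.Sd, r.Nd) == (1.0, 0.0)
    assert ev._SYN_SITES["TTT"] == pytest.approx(1 / 3)


def test_ng86_identical_ratio_undefined():
    r = ev.ng86([("ATG", "ATG"), ("GCT", "GCT")])
    assert r.pS == r.pN == 0.0
    assert r.ratio is None


def test_ng86_site_conservation_s_plus_n_equals_3l(rng):
    for _ in range(20):
        pairs = [(SENSE_CODONS[i], SENSE_CODONS[j])
                 for i, j in zip(rng.integers(0, 61, 30),
                                 rng.integers(0, 61, 30))]
        r = ev.ng86(pairs)
        assert r.S + r.N == pytest.approx(3 * len(pairs))


def test_ng86_symmetry(rng):
    pairs = [(SENSE_CODONS[i], SENSE_CODONS[j])
             for i, j in zip(rng.integers(0, 61, 40),
                             rng.integers(0, 61, 40))]
    fwd = ev.ng86(pairs)
    rev = ev.ng86([(b, a) for a, b in pairs])
    for f in ("S", "N", "Sd", "Nd", "pS", "pN"):
        assert getattr(fwd, f) == pytest.approx(getattr(rev, f))


def test_ng86_matches_enumeration_oracle(rng):
    """NG86 fields equal direct pathway enumeration on random codon pairs
    (exact agreement)."""
    for _ in range(200):
        idx = rng.integers(0, 61, size=(50, 2))
        pairs = [(SENSE_CODONS[i], SENSE_CODONS[j]) for i, j in idx]
        S, N, Sd, Nd = oracle_ng86(pairs)
        r = ev.ng86(pairs)
        assert r.S == pytest.approx(S, abs=1e-12)
        assert r.N == pytest.approx(N, abs=1e-12)
        assert r.Sd == pytest.approx(Sd, abs=1e-12)
        assert r.Nd == pytest.approx(Nd, abs=1e-12)


def test_jc_correct_values_and_monotonicity():
    assert ev.jc_correct(0.0) == 0.0
    assert ev.jc_correct(0.3) == pytest.approx(0.38312, abs=1e-5)
    grid = np.linspace(0, 0.7, 30)
    vals = [ev.jc_correct(p) for p in grid]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    with pytest.raises(ValueError):
        ev.jc_correct(0.8)


# ---------------------------------------------------------------------------
# codon pair alignment and dxy
# ---------------------------------------------------------------------------

def test_codon_align_identical_gap_free():
    pairs = ev.codon_align_pair("ATGAAAGTTTGA", "ATGAAAGTTTGA")
    assert all("-" not in a and "-" not in b for a, b in pairs)


def test_codon_align_one_insertion_one_codon_gap():
    pairs = ev.codon_align_pair("ATGAAAGTTCTTGAATAA",
                                "ATGAAAGTTCAACTTGAATAA")
    gaps = [(a, b) for a, b in pairs if "-" in a or "-" in b]
    assert gaps == [("---", "CAA")]
    for a, b in pairs:
        assert len(a) == len(b) == 3


def test_codon_align_internal_stop_errors():
    with pytest.raises(ValueError):
        ev.codon_align_pair("ATGTAAAAATGA", "ATGAAAAAATGA")


def test_dxy_reductions_and_oracle(rng):
    ident = [[("ATG", "ATG"), ("GCT", "GCT")]]
    assert ev.dxy(ident) == 0.0
    # n=1 reduces to jc of the p-distance
    pairs = [("ATG", "ATA"), ("GCT", "GCT")]
    p = 1 / 6
    assert ev.dxy([pairs]) == pytest.approx(ev.jc_correct(p))
    # brute-force average over enumerated site comparisons
    sets = []
    for _ in range(4):
        idx = rng.integers(0, 61, size=(20, 2))
        sets.append([(SENSE_CODONS[i], SENSE_CODONS[j]) for i, j in idx])
    props = []
    for s in sets:
        d = sum(x != y for ca, cb in s for x, y in zip(ca, cb))
        props.append(d / (3 * len(s)))
    assert ev.dxy(sets) == pytest.approx(ev.jc_correct(np.mean(props)))


# ---------------------------------------------------------------------------
# selection bins
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ratio,expected", [
    (0.10, "purifying"),
    (0.90, "candidate"),
    (1.50, "positive"),
    (0.25, "intermediate"),   # boundary excluded from purifying
    (0.80, "candidate"),
    (1.00, "candidate"),
    (1.0000001, "positive"),
])
def test_selection_bins(ratio, expected):
    r = ev.SelectionResult(pair=("a", "b"), S=100, N=200, Sd=1, Nd=1,
                           pS=0.01, pN=0.01, dS=0.01, dN=0.01, ratio=ratio)
    assert ev.classify_selection(r).bin == expected


def test_undefined_ratio_unbinned_and_partition():
    rs = [ev.SelectionResult(pair=(f"a{i}", "b"), S=1, N=2, Sd=0, Nd=0,
                             pS=0, pN=0, dS=None, dN=None, ratio=ratio)
          for i, ratio in enumerate([0.1, 0.5, 0.9, 1.4, None])]
    table = ev.selection_summary(rs)
    assert table.bin.isna().sum() == 1
    binned = table.bin.dropna()
    assert len(binned) == 4
    assert set(binned) <= set(ev.SELECTION_BINS)


# ---------------------------------------------------------------------------
# Sankoff parsimony
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("newick,counts", [
    ("((A:1,B:1)ab:1,C:1)root;", {"A": 2, "B": 2, "C": 2}),
    ("((A:1,B:1)ab:1,C:1)root;", {"A": 2, "B": 2, "C": 0}),
    ("(((A:1,B:1)ab:1,C:1)abc:1,(D:1,E:1)de:1)root;",
     {"A": 3, "B": 1, "C": 0, "D": 2, "E": 4}),
    ("(((A:1,B:1)ab:1,C:1)abc:1,(D:1,E:1)de:1)root;",
     {"A": 0, "B": 0, "C": 4, "D": 4, "E": 0}),
])
def test_sankoff_equals_exhaustive_search(newick, counts):
    tree = load_tree(newick)
    df = pd.DataFrame([counts], index=["f"])
    events = ev.reconstruct_counts(df, tree)
    rec_cost = int(events.per_branch.gain.sum()
                   + events.per_branch.loss.sum())
    oracle_cost, _ = exhaustive_min_cost(tree, counts, max(counts.values()))
    assert rec_cost == oracle_cost


def test_sankoff_smallest_tie_example():
    # (A:2,B:2,C:0): ancestor(ab)=2, root 0 under the smallest-tie rule
    tree = load_tree("((A:1,B:1)ab:1,C:1)root;")
    df = pd.DataFrame([{"A": 2, "B": 2, "C": 0}], index=["f"])
    events = ev.reconstruct_counts(df, tree)
    nodes = events.node_counts.set_index("node")["count"]
    assert nodes["root"] == 0 and nodes["ab"] == 2
    ab = events.per_branch.set_index("branch")
    assert ab.loc["ab", "gain"] == 2


def test_sankoff_conservation_identity(rng):
    tree = load_tree("(((A:1,B:1)ab:1,C:1)abc:1,(D:1,E:1)de:1)root;")
    counts = pd.DataFrame(
        rng.integers(0, 5, size=(6, 5)),
        columns=list("ABCDE"), index=[f"f{i}" for i in range(6)])
    events = ev.reconstruct_counts(counts, tree)
    nodes = events.node_counts.set_index(["family_id", "node"])["count"]
    parent = {"A": ["ab", "abc", "root"], "D": ["de", "root"]}
    for fam in counts.index:
        for leaf, path in parent.items():
            total = nodes[(fam, leaf)]
            net = nodes[(fam, leaf)] - nodes[(fam, "root")]
            walk = nodes[(fam, leaf)] - nodes[(fam, path[0])]
            for a, b in zip(path, path[1:]):
                walk += nodes[(fam, a)] - nodes[(fam, b)]
            assert walk == net  # telescoping path identity


# ---------------------------------------------------------------------------
# Markov clustering families
# ---------------------------------------------------------------------------

def _family(rng, n_members, seed_len=150):
    base_prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), seed_len))
    base = back_translate(base_prot, rng, add_stop=False)
    out = []
    for i in range(n_members):
        cds = evolve_cds(base, 0.08, 0.3, rng)
        from rgevo.core_io import translate
        out.append(translate(cds))
    return out


def test_two_disjoint_families_two_clusters(rng):
    fam1 = _family(rng, 3)
    fam2 = _family(rng, 3)
    recs, species_of = [], {}
    for fi, fam in enumerate((fam1, fam2)):
        for si, seq in enumerate(fam):
            gid = f"f{fi}_m{si}"
            recs.append(FastaRecord(gid, seq))
            species_of[gid] = f"s{si}"
    fm = ev.build_families(recs, species_of=species_of)
    groups = {frozenset(sum(per.values(), [])) for per in fm.members.values()}
    assert groups == {frozenset(f"f0_m{i}" for i in range(3)),
                      frozenset(f"f1_m{i}" for i in range(3))}


def test_mcl_invariant_to_input_order_and_weight_scale(rng):
    fam1 = _family(rng, 3)
    fam2 = _family(rng, 2)
    recs = [FastaRecord(f"g{i}", s) for i, s in enumerate(fam1 + fam2)]
    fm1 = ev.build_families(recs)
    fm2 = ev.build_families(list(reversed(recs)))
    def groups(fm):
        return {frozenset(sum(per.values(), [])) for per in fm.members.values()}
    assert groups(fm1) == groups(fm2)


def test_planted_families_recovered_exactly(small_sim):
    """Family clustering returns the generator's families exactly —
    including keeping families apart that share near-identical domain
    blocks (TIR/NBS), which only the match-fraction cutoff prevents from
    bridging."""
    recs, species_of, fam_of = [], {}, {}
    for g in small_sim.genes:
        if g.is_r:
            recs.append(FastaRecord(g.gene_id, g.protein))
            species_of[g.gene_id] = g.species
            fam_of[g.gene_id] = g.family_id
    fm = ev.build_families(recs, species_of=species_of)
    groups = {frozenset(sum(per.values(), []))
              for per in fm.members.values()}
    truth_groups: dict[str, set] = {}
    for gid, f in fam_of.items():
        truth_groups.setdefault(f, set()).add(gid)
    assert groups == {frozenset(v) for v in truth_groups.values()}


def test_mcl_matrix_weight_scaling_invariance():
    import scipy.sparse as sp
    rows = [0, 1, 1, 2, 3, 4, 4, 3]
    cols = [1, 0, 2, 1, 4, 3, 3, 4]
    vals = [0.9, 0.9, 0.8, 0.8, 0.7, 0.7, 0.7, 0.7]
    A = sp.csr_matrix((vals, (rows, cols)), shape=(5, 5)) + sp.eye(5)
    B = A * 7.0
    ra = ev._mcl(A.tocsc(), 1.5, 2, 1e-5, 1e-8, 100)
    rb = ev._mcl(B.tocsc(), 1.5, 2, 1e-5, 1e-8, 100)
    la = sp.csgraph.connected_components(ra, directed=False)[1]
    lb = sp.csgraph.connected_components(rb, directed=False)[1]
    assert (la == la[0]).sum() == (lb == lb[0]).sum()
    assert len(set(la)) == len(set(lb))
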
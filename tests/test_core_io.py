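"""Core I/O, translation and alignment-engine behaviour."""

import random

import numpy as np
import pytest

from rgevo import core_io as cio
from rgevo.core_io import FastaRecord


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def test_fasta_round_trip(tmp_path):
    recs = [FastaRecord("a", "MKV"), FastaRecord("b", "M" * 130),
            FastaRecord("c", "ACDEFGHIKLMNPQRSTVWY")]
    path = tmp_path / "x.fasta"
    cio.write_fasta(recs, path)
    back = cio.read_fasta(path)
    assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in recs]
    # 60-column wrap
    lines = path.read_text().splitlines()
    assert max(len(l) for l in lines if not l.startswith(">")) == 60


def test_fasta_single_record(tmp_path):
    p = tmp_path / "one.fasta"
    p.write_text(">a\nMKV\n")
    assert [(r.id, r.seq) for r in cio.read_fasta(p)] == [("a", "MKV")]


def test_fasta_empty_file_warns(tmp_path, caplog):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    with caplog.at_level("WARNING", logger="rgevo"):
        assert cio.read_fasta(p) == []
    assert any("no records" in r.message for r in caplog.records)


def test_fasta_sequence_before_header_names_line(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text("\nMKV\n>a\nMKV\n")
    with pytest.raises(ValueError, match="line 2"):
        cio.read_fasta(p)


# ---------------------------------------------------------------------------
# GFF3 ranks
# ---------------------------------------------------------------------------

def _gff(tmp_path, rows):
    p = tmp_path / "g.gff3"
    body = "\n".join(
        f"{c}\tsrc\tgene\t{s}\t{e}\t.\t{st}\t.\tID={gid}"
        for c, s, e, st, gid in rows)
    p.write_text("##gff-version 3\n" + body + "\n")
    return p


def test_gff3_rank_by_start(tmp_path):
    p = _gff(tmp_path, [("chr1", 100, 200, "+", "g1"),
                        ("chr1", 50, 80, "-", "g2")])
    genes = {g.gene_id: g for g in cio.read_gff3(p)}
    assert genes["g1"].rank == 1 and genes["g2"].rank == 0
    assert genes["g2"].strand == "-"


def test_gff3_ranks_independent_per_chromosome(tmp_path):
    p = _gff(tmp_path, [("chr1", 10, 20, "+", "a"),
                        ("chr2", 5, 9, "+", "b"),
                        ("chr1", 30, 40, "+", "c")])
    genes = {g.gene_id: g for g in cio.read_gff3(p)}
    assert (genes["a"].rank, genes["c"].rank, genes["b"].rank) == (0, 1, 0)


def test_gff3_tie_break_matches_brute_force_and_is_stable(tmp_path):
    rows = [("chr1", s, s + 5, "+", gid)
            for gid, s in [("z", 10), ("a", 10), ("m", 3), ("k", 10)]]
    expected = sorted(rows, key=lambda r: (r[1], r[4]))
    for seed in range(3):
        shuffled = rows[:]
        random.Random(seed).shuffle(shuffled)
        genes = cio.read_gff3(_gff(tmp_path, shuffled))
        ordered = sorted(genes, key=lambda g: g.rank)
        assert [g.gene_id for g in ordered] == [r[4] for r in expected]
        assert sorted(g.rank for g in genes) == list(range(len(rows)))


def test_gff3_rejects_bad_records(tmp_path):
    with pytest.raises(ValueError, match="end < start"):
        cio.read_gff3(_gff(tmp_path, [("chr1", 50, 10, "+", "g")]))
    with pytest.raises(ValueError, match="strand"):
        cio.read_gff3(_gff(tmp_path, [("chr1", 10, 50, "?", "g")]))


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("cds,frame,expected", [
    ("ATGGCTTAA", 0, "MA*"),
    ("ATGGCTTAA", 1, "WL"),   # TGG, CTT
    ("ATGNNN", 0, "MX"),
    ("", 0, ""),
])
def test_translate(cds, frame, expected):
    assert cio.translate(cds, frame) == expected


def test_translate_reverse_complement_property(rng):
    """Translating the reverse complement equals reversing the per-codon
    antisense translation (brute-force oracle on random 300-mers)."""
    for _ in range(20):
        dna = "".join(rng.choice(list("ACGT"), 300))
        rc = cio.reverse_complement(dna)
        for frame in (0, 1, 2):
            # oracle: translate codons of rc one by one
            expected = "".join(
                cio.CODON_TABLE[rc[i:i + 3]]
                for i in range(frame, len(rc) - 2, 3))
            assert cio.translate(rc, frame) == expected


# ---------------------------------------------------------------------------
# local alignment
# ---------------------------------------------------------------------------

def _sw_oracle(a, b, mat, open_cost=12.0, extend_cost=1.0):
    """Independent Gotoh local alignment (first gap position costs
    open_cost, each further one extend_cost)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (left)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (up)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - extend_cost)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - extend_cost)
            diag = H[i - 1][j - 1] + mat[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def test_align_local_identity():
    res = cio.align_local("MKV", "MKV")
    assert res.normalized_score == 1.0
    assert res.raw_score == cio.self_score("MKV")


def test_align_local_unrelated_near_zero():
    res = cio.align_local("MKV", "QQQ")
    assert res.normalized_score < 0.2


def test_align_local_planted_copy_scores_diagonal_sum(rng):
    mat = cio.DEFAULT_PARAMS.matrix
    query = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 30))
    subject = "GGG" + query + "PPP"
    res = cio.align_local(query, subject)
    assert res.raw_score >= sum(mat[c, c] for c in query)
    seg = res.segments[0]
    assert seg.n_identical >= 30 and seg.n_identical <= seg.aligned_length


def test_align_local_matches_brute_force_dp(rng):
    mat = cio.DEFAULT_PARAMS.matrix
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(15):
        a = "".join(rng.choice(aas, int(rng.integers(5, 14))))
        b = "".join(rng.choice(aas, int(rng.integers(5, 14))))
        assert cio.align_local(a, b).raw_score == pytest.approx(
            _sw_oracle(a, b, mat))


def test_align_local_score_symmetry(rng):
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(10):
        a = "".join(rng.choice(aas, 20))
        b = "".join(rng.choice(aas, 25))
        assert cio.align_local(a, b).raw_score == \
            cio.align_local(b, a).raw_score


def test_align_local_empty_errors():
    with pytest.raises(ValueError):
        cio.align_local("", "MKV")


# ---------------------------------------------------------------------------
# six-frame search
# ---------------------------------------------------------------------------

def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _back_translate_simple(protein):
    table = {}
    for codon, aa in cio.CODON_TABLE.items():
        table.setdefault(aa, codon)
    return "".join(table[aa] for aa in protein)


def test_search_six_frame_finds_planted_copy(rng):
    query = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
    insert = _back_translate_simple(query)
    genome = _random_dna(rng, 2000) + insert + _random_dna(rng, 2000)
    hits = cio.search_six_frame(query, genome)
    assert hits, "planted locus not found"
    top = hits[0]
    assert top.segments[0].frame > 0
    lo = min(s.s_start for s in top.segments)
    hi = max(s.s_end for s in top.segments)
    assert lo >= 2001 - 3 and hi <= 2000 + len(insert) + 3


def test_search_six_frame_reverse_strand(rng):
    query = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
    insert = cio.reverse_complement(_back_translate_simple(query))
    genome = _random_dna(rng, 1500) + insert + _random_dna(rng, 1500)
    hits = cio.search_six_frame(query, genome)
    assert hits and hits[0].segments[0].frame < 0


def test_search_six_frame_random_genome_empty(rng):
    query = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
    genome = _random_dna(rng, 5000)
    assert cio.search_six_frame(query, genome) == []
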
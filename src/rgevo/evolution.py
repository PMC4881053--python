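"""Gene-family dynamics and selection signals.

Families are built from an all-vs-all protein similarity graph by Markov
clustering (MCL: alternate expansion of the column-stochastic weight matrix
and element-wise inflation until convergence). Ancestral family sizes along
the species tree are reconstructed by linear-cost integer parsimony (a
Sankoff dynamic program minimising the summed absolute copy-number change
over branches, smallest count on ties), giving per-branch expansion and
contraction events.

Selection on ortholog pairs is measured by the Nei–Gojobori (NG86) method:
potential synonymous (S) and non-synonymous (N) sites are counted per codon,
observed synonymous/non-synonymous differences (Sd, Nd) are averaged over
all mutational pathways between differing codons (pathways through stop
codons excluded), and the proportions are Jukes–Cantor corrected to dS and
dN. Ka/Ks bins follow the conventional reading: < 0.25 purifying, 0.8-1.0
candidate, > 1 positive selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotate import _SeedIndex
from .core_io import AlignParams, DEFAULT_PARAMS, CODON_TABLE, align_global, align_local

SELECTION_BINS = ("purifying", "intermediate", "candidate", "positive")
PURIFYING_MAX = 0.25
CANDIDATE_MIN = 0.8
CANDIDATE_MAX = 1.0


@dataclass
class FamilyMatrix:
    """Gene-family membership and the derived per-species count matrix."""

    members: dict[str, dict[str, list[str]]]  # family -> species -> gene ids

    def counts(self, species: list[str] | None = None) -> pd.DataFrame:
        if species is None:
            species = sorted({
                sp for per in self.members.values() for sp in per})
        rows = {
            fam: {sp: len(per.get(sp, [])) for sp in species}
            for fam, per in sorted(self.members.items())
        }
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=species).fillna(0).astype(int)

    @property
    def n_families(self) -> int:
        return len(self.members)


@dataclass
class BranchEvents:
    """Reconstruction summary: per-branch gains/losses and per-node counts."""

    per_branch: pd.DataFrame       # branch (child node), gain, loss, net
    node_counts: pd.DataFrame      # family x node reconstructed counts


@dataclass
class SelectionResult:
    pair: tuple[str, str]
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    ratio: float | None
    bin: str | None = None


# ---------------------------------------------------------------------------
# family construction (similarity graph + Markov clustering)
# ---------------------------------------------------------------------------

def build_families(proteins: list, params: AlignParams = DEFAULT_PARAMS,
                   inflation: float = 1.5, expansion: int = 2,
                   prune: float = 1e-5, tol: float = 1e-8,
                   max_iter: int = 100, match_fraction: float = 0.3,
                   species_of=None) -> FamilyMatrix:
    """Cluster proteins of >= 2 species into families.

    Edges connect pairs with a significant alignment (e-value proxy below
    the protein threshold) whose score is also at least ``match_fraction``
    of the smaller self-alignment score — the coverage-style cutoff that
    keeps single shared domains (a common TIR or NBS block between
    otherwise unrelated proteins) from bridging families. Edge weight is
    the score normalized by the smaller self-score. A word-index
    pre-filter keeps graph construction near-linear; Markov clustering
    runs on the column-stochastic weight matrix and connected components
    of the converged matrix are the families.
    """
    def rid(r):
        return getattr(r, "id", None) or getattr(r, "gene_id")

    def rseq(r):
        return getattr(r, "seq", None) or getattr(r, "protein")

    recs = sorted(((rid(r), rseq(r)) for r in proteins), key=lambda x: x[0])
    ids = [i for i, _ in recs]
    seqs = dict(recs)
    if species_of is None:
        species_of = {}
    index = _SeedIndex()
    for gid, seq in recs:
        index.add(gid, seq)
    from .core_io import self_score

    n = len(ids)
    pos = {gid: k for k, gid in enumerate(ids)}
    selfs = {gid: self_score(seq, params) for gid, seq in recs}
    rows, cols, vals = [], [], []
    for gid in ids:
        for other in index.candidates(seqs[gid], exclude=gid):
            if other <= gid:
                continue  # score each unordered pair once
            res = align_local(seqs[gid], seqs[other], params,
                              score_only=True)
            if res.evalue_proxy >= params.evalue_protein:
                continue
            w = res.raw_score / max(min(selfs[gid], selfs[other]), 1.0)
            if w < match_fraction:
                continue
            rows += [pos[gid], pos[other]]
            cols += [pos[other], pos[gid]]
            vals += [w, w]
    M = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    M = M + sp.eye(n, format="csr")  # self-loops stabilise MCL
    M = _mcl(M, inflation, expansion, prune, tol, max_iter)
    # families = connected components of the converged matrix
    nc, labels = sp.csgraph.connected_components(M, directed=False)
    groups: dict[int, list[str]] = {}
    for gid, k in zip(ids, labels):
        groups.setdefault(int(k), []).append(gid)
    members: dict[str, dict[str, list[str]]] = {}
    fam_counter = 0
    for k in sorted(groups, key=lambda k: min(groups[k])):
        genes = sorted(groups[k])
        fam = f"FAM{fam_counter:04d}"
        fam_counter += 1
        per: dict[str, list[str]] = {}
        for g in genes:
            per.setdefault(species_of.get(g, "unknown"), []).append(g)
        members[fam] = per
    return FamilyMatrix(members=members)


def _mcl(M: sp.csr_matrix, inflation: float, expansion: int,
         prune: float, tol: float, max_iter: int) -> sp.csr_matrix:
    def normalize(A):
        colsum = np.asarray(A.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        return A @ sp.diags(1.0 / colsum)

    A = normalize(M.tocsc())
    for _ in range(max_iter):
        prev = A.copy()
        A = A ** expansion
        A = A.power(inflation)
        A.data[A.data < prune] = 0.0
        A.eliminate_zeros()
        A = normalize(A)
        diff = abs(A - prev)
        change = diff.max() if diff.nnz else 0.0
        if change < tol:
            break
    return A.tocsr()


# ---------------------------------------------------------------------------
# ancestral count parsimony
# ---------------------------------------------------------------------------

def reconstruct_counts(counts: pd.DataFrame, tree) -> BranchEvents:
    """Linear-cost Sankoff reconstruction of ancestral family sizes.

    ``counts``: families x species integer matrix; ``tree``: rooted dendropy
    tree whose leaf labels match the columns. Per family the ancestral
    integer counts minimise the sum of |child - parent| over all branches;
    ties resolve to the smallest count. Per-branch gains and losses are
    summed over families.
    """
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = set(leaves) - set(counts.columns)
    if missing:
        raise ValueError(f"species missing from count matrix: {missing}")

    def node_label(nd):
        lbl = nd.taxon.label if nd.taxon else (nd.label or "node")
        return lbl.replace(" ", "_")

    branch_rows: dict[str, dict[str, float]] = {}
    node_count_rows = []
    for fam, row in counts.iterrows():
        cmax = int(max(row.max(), 0))
        states = np.arange(cmax + 1)
        cost: dict = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                c = int(row[node_label(nd)])
                v = np.full(cmax + 1, np.inf)
                v[c] = 0.0
                cost[nd] = v
            else:
                v = np.zeros(cmax + 1)
                for ch in nd.child_nodes():
                    child_cost = cost[ch]
                    # min over child state: child_cost + |child - parent|
                    trans = np.abs(states[:, None] - states[None, :])
                    v = v + np.min(child_cost[None, :] + trans, axis=1)
                cost[nd] = v
        assign: dict = {}
        root = tree.seed_node
        assign[root] = int(np.argmin(cost[root]))  # argmin takes smallest tie
        for nd in tree.preorder_node_iter():
            if nd is root:
                continue
            p = assign[nd.parent_node]
            v = cost[nd] + np.abs(states - p)
            assign[nd] = int(np.argmin(v))
        for nd in tree.preorder_node_iter():
            lbl = node_label(nd)
            node_count_rows.append(
                {"family_id": fam, "node": lbl, "count": assign[nd]})
            if nd is root:
                continue
            net = assign[nd] - assign[nd.parent_node]
            slot = branch_rows.setdefault(
                lbl, {"gain": 0, "loss": 0, "net": 0,
                      "families_expanded": 0, "families_contracted": 0})
            slot["gain"] += max(net, 0)
            slot["loss"] += max(-net, 0)
            slot["net"] += net
            if net > 0:
                slot["families_expanded"] += 1
            elif net < 0:
                slot["families_contracted"] += 1
    per_branch = (
        pd.DataFrame.from_dict(branch_rows, orient="index")
        .rename_axis("branch").reset_index()
    )
    node_counts = pd.DataFrame(node_count_rows)
    return BranchEvents(per_branch=per_branch, node_counts=node_counts)


# ---------------------------------------------------------------------------
# NG86 with Jukes-Cantor correction
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


def _syn_fraction(codon: str) -> float:
    """Potential synonymous sites of one codon: per position, the fraction
    of the three possible changes that are synonymous (changes to stop
    codons count as non-synonymous)."""
    aa = CODON_TABLE[codon]
    s = 0.0
    for i in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if CODON_TABLE[alt] == aa and alt not in _STOPS:
                syn += 1
        s += syn / 3.0
    return s


_SYN_SITES = {c: _syn_fraction(c) for c in CODON_TABLE if c not in _STOPS}


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average synonymous/non-synonymous step counts over all mutational
    pathways between two codons; pathways through stop codons are excluded
    (all-blocked pairs fall back to averaging over every pathway)."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(exclude_stops: bool):
        syn_tot = nsyn_tot = 0.0
        n_paths = 0
        for order in itertools.permutations(diff):
            cur = codon_a
            syn = nsyn = 0
            blocked = False
            for i in order:
                nxt = cur[:i] + codon_b[i] + cur[i + 1:]
                if exclude_stops and nxt in _STOPS:
                    blocked = True
                    break
                if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                    syn += 1
                else:
                    nsyn += 1
                cur = nxt
            if not blocked:
                syn_tot += syn
                nsyn_tot += nsyn
                n_paths += 1
        return syn_tot, nsyn_tot, n_paths

    syn_tot, nsyn_tot, n_paths = walk(True)
    if n_paths == 0:
        syn_tot, nsyn_tot, n_paths = walk(False)
    return syn_tot / n_paths, nsyn_tot / n_paths


_PATHWAY_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -3/4 ln(1 - 4/3 p)."""
    if not 0 <= p < 0.75:
        raise ValueError("proportion out of correctable range [0, 3/4)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(codon_pairs: list[tuple[str, str]] | object,
         pair_ids: tuple[str, str] = ("a", "b")) -> SelectionResult:
    """Nei-Gojobori dN/dS over an aligned codon sequence pair.

    Accepts a list of (codon_a, codon_b) tuples or a 2-species
    CodonAlignment; gapped codon pairs are excluded. ``ratio`` is None when
    dS = 0 or a proportion is beyond the Jukes-Cantor range."""
    pairs = _as_codon_pairs(codon_pairs)
    if not pairs:
        raise ValueError("no ungapped codon pairs")
    S = N = Sd = Nd = 0.0
    L = 0
    for ca, cb in pairs:
        if ca in _STOPS or cb in _STOPS:
            continue
        L += 1
        S += 0.5 * (_SYN_SITES[ca] + _SYN_SITES[cb])
        key = (ca, cb)
        if key not in _PATHWAY_CACHE:
            _PATHWAY_CACHE[key] = _pathway_counts(ca, cb)
        sd, nd = _PATHWAY_CACHE[key]
        Sd += sd
        Nd += nd
    if L == 0:
        raise ValueError("no comparable codons")
    N = 3 * L - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jc_correct(pS) if pS < 0.75 else None
    dN = jc_correct(pN) if pN < 0.75 else None
    ratio = None
    if dS is not None and dN is not None and dS > 0:
        ratio = dN / dS
    return SelectionResult(pair=pair_ids, S=S, N=N, Sd=Sd, Nd=Nd,
                           pS=pS, pN=pN, dS=dS, dN=dN, ratio=ratio)


def _as_codon_pairs(obj) -> list[tuple[str, str]]:
    if isinstance(obj, list):
        out = []
        for ca, cb in obj:
            if "-" in ca or "-" in cb:
                continue
            out.append((ca.upper(), cb.upper()))
        return out
    # 2-species CodonAlignment
    seqs = list(obj.codon_seqs.values())
    if len(seqs) != 2:
        raise ValueError("ng86 needs exactly two sequences")
    a, b = seqs
    pairs = []
    for k in range(0, len(a), 3):
        ca, cb = a[k : k + 3], b[k : k + 3]
        if "-" in ca or "-" in cb:
            continue
        pairs.append((ca, cb))
    return pairs


def codon_align_pair(cds_a: str, cds_b: str,
                     params: AlignParams = DEFAULT_PARAMS
                     ) -> list[tuple[str, str]]:
    """Codon-atomic pairwise alignment via global protein alignment.

    Returns aligned codon pairs including gap codons ('---'); internal
    stops raise (pseudogenes route through the structure module first)."""
    from .core_io import translate

    def clean(cds, name):
        aa = translate(cds[: len(cds) // 3 * 3])
        if aa.endswith("*"):
            aa = aa[:-1]
            cds = cds[: 3 * len(aa)]
        if "*" in aa:
            raise ValueError(f"{name}: internal stop codon")
        return cds[: 3 * len(aa)], aa

    cds_a, aa_a = clean(cds_a, "cds_a")
    cds_b, aa_b = clean(cds_b, "cds_b")
    aln = align_global(aa_b, aa_a, params)  # target = aa_a, query = aa_b
    row_a, row_b = str(aln[0]), str(aln[1])
    out = []
    ia = ib = 0
    for ra, rb in zip(row_a, row_b):
        ca = cds_a[3 * ia : 3 * ia + 3] if ra != "-" else "---"
        cb = cds_b[3 * ib : 3 * ib + 3] if rb != "-" else "---"
        if ra != "-":
            ia += 1
        if rb != "-":
            ib += 1
        out.append((ca, cb))
    return out


def dxy(codon_pair_sets: list[list[tuple[str, str]]]) -> float:
    """Mean pairwise nucleotide difference proportion across ortholog
    alignments, Jukes-Cantor corrected."""
    if not codon_pair_sets:
        raise ValueError("no alignments")
    props = []
    for pairs in codon_pair_sets:
        diff = tot = 0
        for ca, cb in pairs:
            if "-" in ca or "-" in cb:
                continue
            for x, y in zip(ca, cb):
                tot += 1
                if x != y:
                    diff += 1
        if tot:
            props.append(diff / tot)
    if not props:
        raise ValueError("no comparable sites")
    return jc_correct(float(np.mean(props)))


# ---------------------------------------------------------------------------
# selection bins
# ---------------------------------------------------------------------------

def classify_selection(result: SelectionResult) -> SelectionResult:
    """Attach the selection bin; undefined ratios stay unbinned."""
    if result.ratio is None:
        result.bin = None
        return result
    r = result.ratio
    if r < PURIFYING_MAX:
        result.bin = "purifying"
    elif r < CANDIDATE_MIN:
        result.bin = "intermediate"
    elif r <= CANDIDATE_MAX:
        result.bin = "candidate"
    else:
        result.bin = "positive"
    return result


def selection_summary(results: list[SelectionResult]) -> pd.DataFrame:
    """Boxplot-ready cohort table plus counts per bin (undefined ratios
    reported separately)."""
    rows = []
    for r in results:
        classify_selection(r)
        rows.append({
            "gene_a": r.pair[0], "gene_b": r.pair[1],
            "S": r.S, "N": r.N, "Sd": r.Sd, "Nd": r.Nd,
            "dS": r.dS, "dN": r.dN, "ratio": r.ratio, "bin": r.bin,
        })
    return pd.DataFrame(rows)
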
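"""Genomic and syntenic context of R-genes: tandem-cluster calling,
CIP-based orthology with reciprocal best hits, chromosome anchoring to the
out-group, and the synteny-supported R-locus map.

Two R-genes on the same chromosome belong to one cluster when they are
separated by no more than eight intervening genes (single-linkage chaining
over gene ranks). Cross-species ortholog pairs are retained when the
cumulative identity percentage (CIP: identities over aligned length summed
across alignment segments) exceeds 60 and the alignment is significant;
mutually best pairs are flagged as reciprocal best hits (RBH). Each legume
chromosome is anchored to the out-group chromosome contributing the
plurality of its ortholog partners, and an R-locus is considered mappable
when at least three ortholog pairs in its gene-rank neighborhood support the
same out-group chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotate import _SeedIndex
from .core_io import (
    AlignParams,
    DEFAULT_PARAMS,
    AlignmentSegment,
    GeneModel,
    align_local,
)

MAX_INTERVENING = 8  # cluster rule: "no more than eight genes apart"
CIP_THRESHOLD = 60.0
SYNTENY_MIN_SUPPORT = 3
DEFAULT_SYNTENY_WINDOW = 25


@dataclass
class Cluster:
    cluster_id: str
    species: str
    chromosome: str
    members: list[str]          # gene ids ordered by rank
    span: tuple[int, int]       # min start, max end

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    cip: float
    rbh: bool
    raw_score: float = 0.0


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def call_clusters(genes: list[GeneModel], r_gene_ids,
                  max_intervening: int = MAX_INTERVENING) -> list[Cluster]:
    """Single-linkage chaining of R-genes along each chromosome.

    Two R-genes join one cluster iff the number of intervening genes
    (rank_j - rank_i - 1) is <= ``max_intervening``; chaining is transitive.
    Size-1 clusters are returned as singletons. Unknown R-gene ids raise.
    """
    by_id = {g.gene_id: g for g in genes}
    missing = sorted(set(r_gene_ids) - set(by_id))
    if missing:
        raise KeyError(f"R-gene ids absent from gene table: {missing[:5]}")
    r_genes = sorted(
        (by_id[g] for g in set(r_gene_ids)),
        key=lambda g: (g.species, g.chromosome, g.rank),
    )
    clusters: list[Cluster] = []
    current: list[GeneModel] = []

    def flush():
        if not current:
            return
        cid = f"{current[0].species}:{current[0].chromosome}:" \
              f"{len(clusters)}"
        clusters.append(Cluster(
            cluster_id=cid, species=current[0].species,
            chromosome=current[0].chromosome,
            members=[g.gene_id for g in current],
            span=(min(g.start for g in current),
                  max(g.end for g in current)),
        ))

    for g in r_genes:
        if (current
                and g.species == current[-1].species
                and g.chromosome == current[-1].chromosome
                and g.rank - current[-1].rank - 1 <= max_intervening):
            current.append(g)
        else:
            flush()
            current = [g]
    flush()
    return clusters


def clustered_fraction(clusters: list[Cluster]) -> float:
    """Fraction of R-genes sitting in clusters of size >= 2."""
    total = sum(c.size for c in clusters)
    if total == 0:
        return 0.0
    return sum(c.size for c in clusters if c.size >= 2) / total


def clusters_table(clusters: list[Cluster]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "cluster_id": c.cluster_id, "species": c.species,
            "chromosome": c.chromosome, "size": c.size,
            "members": ",".join(c.members),
            "span_start": c.span[0], "span_end": c.span[1],
        }
        for c in clusters
    ])


# ---------------------------------------------------------------------------
# CIP orthology
# ---------------------------------------------------------------------------

def compute_cip(segments: list[AlignmentSegment], query_length: int) -> float:
    """Cumulative identity percentage over non-overlapping segments.

    Overlapping segments (on the query) are trimmed greedily, keeping the
    segments with more identities. CIP = 100 x sum(identities) /
    sum(aligned length); zero aligned length gives 0.
    """
    kept: list[AlignmentSegment] = []
    for seg in sorted(segments, key=lambda s: (-s.n_identical, s.q_start)):
        if all(seg.q_end < k.q_start or seg.q_start > k.q_end for k in kept):
            kept.append(seg)
    total_len = sum(s.aligned_length for s in kept)
    if total_len == 0:
        return 0.0
    return 100.0 * sum(s.n_identical for s in kept) / total_len


def assign_orthologs(proteins_a: list, proteins_b: list,
                     params: AlignParams = DEFAULT_PARAMS,
                     cip_threshold: float = CIP_THRESHOLD
                     ) -> list[OrthologPair]:
    """All-vs-all protein comparison between two species.

    Pairs with CIP above threshold and significant e-value proxy are
    retained; a pair is RBH when each member is the other's top-raw-score
    hit (ties broken by gene id). A word-index pre-filter limits the
    alignments to plausibly homologous pairs.
    """
    if not proteins_a or not proteins_b:
        raise ValueError("assign_orthologs: empty proteome")

    def rid(r):
        return getattr(r, "id", None) or getattr(r, "gene_id")

    def rseq(r):
        return getattr(r, "seq", None) or getattr(r, "protein")

    index_b = _SeedIndex()
    for r in proteins_b:
        index_b.add(rid(r), rseq(r))

    seq_a = {rid(r): rseq(r) for r in proteins_a}
    pairs: dict[tuple[str, str], dict] = {}
    best_a: dict[str, tuple] = {}
    best_b: dict[str, tuple] = {}
    for ga in sorted(seq_a):
        pa = seq_a[ga]
        for gb in index_b.candidates(pa):
            res = align_local(pa, index_b.seqs[gb], params,
                              query_id=ga, subject_id=gb)
            if res.evalue_proxy >= params.evalue_protein:
                continue
            cip = compute_cip(res.segments, len(pa))
            key_a = (-res.raw_score, gb)
            key_b = (-res.raw_score, ga)
            if ga not in best_a or key_a < best_a[ga][0]:
                best_a[ga] = (key_a, gb)
            if gb not in best_b or key_b < best_b[gb][0]:
                best_b[gb] = (key_b, ga)
            if cip > cip_threshold:
                pairs[(ga, gb)] = {"cip": cip, "score": res.raw_score}
    out = []
    for (ga, gb), info in sorted(pairs.items()):
        rbh = best_a.get(ga, (None, None))[1] == gb and \
            best_b.get(gb, (None, None))[1] == ga
        out.append(OrthologPair(gene_a=ga, gene_b=gb, cip=info["cip"],
                                rbh=rbh, raw_score=info["score"]))
    return out


def orthologs_table(pairs: list[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame([
        {"gene_a": p.gene_a, "gene_b": p.gene_b, "cip": p.cip,
         "rbh": p.rbh, "raw_score": p.raw_score}
        for p in pairs
    ])


# ---------------------------------------------------------------------------
# chromosome anchoring and the R-locus map
# ---------------------------------------------------------------------------

def anchor_chromosomes(pairs: list[OrthologPair],
                       genes_a: list[GeneModel],
                       genes_b: list[GeneModel]) -> dict[str, str | None]:
    """Assign each chromosome of species A to the out-group (B) chromosome
    contributing the plurality of its ortholog partners; ties broken by the
    larger summed raw score. Chromosomes with no orthologs map to None."""
    chrom_a = {g.gene_id: g.chromosome for g in genes_a}
    chrom_b = {g.gene_id: g.chromosome for g in genes_b}
    votes: dict[str, dict[str, list[float]]] = {}
    for p in pairs:
        ca, cb = chrom_a.get(p.gene_a), chrom_b.get(p.gene_b)
        if ca is None or cb is None:
            continue
        votes.setdefault(ca, {}).setdefault(cb, []).append(p.raw_score)
    anchors: dict[str, str | None] = {
        c: None for c in {g.chromosome for g in genes_a}}
    for ca, tallies in votes.items():
        anchors[ca] = max(
            tallies, key=lambda cb: (len(tallies[cb]), sum(tallies[cb]), cb))
    return anchors


def map_r_loci(r_gene_ids, pairs: list[OrthologPair],
               genes_a: list[GeneModel], genes_b: list[GeneModel],
               window: int = DEFAULT_SYNTENY_WINDOW,
               min_support: int = SYNTENY_MIN_SUPPORT) -> pd.DataFrame:
    """Project R-loci of species A onto the out-group via local synteny.

    An R-locus is mapped iff >= ``min_support`` ortholog pairs within a
    +-``window`` gene-rank neighborhood support the same out-group
    chromosome (the locus's synteny value); its projected position is the
    partner position of the nearest supporting pair."""
    by_a = {g.gene_id: g for g in genes_a}
    by_b = {g.gene_id: g for g in genes_b}
    anchored_pairs = [
        p for p in pairs if p.gene_a in by_a and p.gene_b in by_b
    ]
    rows = []
    for rid_ in sorted(set(r_gene_ids)):
        if rid_ not in by_a:
            raise KeyError(f"R-gene {rid_} absent from gene table")
        g = by_a[rid_]
        support: dict[str, list[OrthologPair]] = {}
        for p in anchored_pairs:
            ga = by_a[p.gene_a]
            if ga.chromosome != g.chromosome:
                continue
            if abs(ga.rank - g.rank) > window:
                continue
            support.setdefault(by_b[p.gene_b].chromosome, []).append(p)
        best_chrom, best = None, []
        for cb in sorted(support):
            if len(support[cb]) > len(best):
                best_chrom, best = cb, support[cb]
        synteny_value = len(best)
        if synteny_value >= min_support:
            nearest = min(
                best, key=lambda p: (abs(by_a[p.gene_a].rank - g.rank),
                                     p.gene_a))
            rows.append({
                "gene_id": rid_, "chromosome": g.chromosome,
                "mapped": True, "synteny_value": synteny_value,
                "target_chromosome": best_chrom,
                "target_position": by_b[nearest.gene_b].start,
            })
        else:
            rows.append({
                "gene_id": rid_, "chromosome": g.chromosome,
                "mapped": False, "synteny_value": synteny_value,
                "target_chromosome": None, "target_position": None,
            })
    return pd.DataFrame(rows)
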
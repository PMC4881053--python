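"""Structural re-annotation and gene-structure classification.

Each R-gene is classified into one of six structure classes: Complete,
InDel (in-frame insertion/deletion of at least three codons relative to a
reference protein), LackStart (no ATG), LackStop (no terminal stop),
LackBoth, or Pseudo (open-reading-frame shift or premature stop). Classes
are mutually exclusive with precedence
Pseudo > LackBoth > LackStart/LackStop > InDel > Complete.

For unannotated loci a frame-aware re-annotator chains local alignment
segments of a reference protein across the three forward reading frames of
the locus DNA; a frame change between adjacent chained segments is recorded
as a frameshift. The chaining is intronless by design (the synthetic genes
have no introns); splice-aware modelling is a documented limitation for
real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_io import (
    AlignParams,
    DEFAULT_PARAMS,
    AlignmentSegment,
    STOP_CODONS,
    align_global,
    align_local,
    translate,
)

STRUCTURE_CLASSES = ("Complete", "InDel", "LackStart", "LackStop",
                     "LackBoth", "Pseudo")

INDEL_MIN_CODONS = 3  # internal gap threshold for the InDel class


@dataclass
class StructureCall:
    gene_id: str
    cls: str
    evidence: list[str] = field(default_factory=list)


@dataclass
class Chain:
    """Chained frame-annotated alignment segments over one locus."""

    segments: list[AlignmentSegment]
    locus_dna: str
    score: float

    @property
    def frames(self) -> list[int]:
        return [s.frame for s in self.segments]

    @property
    def frameshifts(self) -> list[int]:
        """Estimated locus positions (1-based) where the frame changes:
        the midpoint of the junction between adjacent segments (both ends
        overextend a little into the other segment's territory)."""
        out = []
        for a, b in zip(self.segments, self.segments[1:]):
            if a.frame != b.frame:
                out.append((a.s_end + b.s_start) // 2)
        return out

    def query_coverage(self, query_length: int) -> float:
        covered = set()
        for s in self.segments:
            covered.update(range(s.q_start, s.q_end + 1))
        return len(covered) / query_length if query_length else 0.0


def realign_locus(locus_dna: str, seed_protein: str,
                  params: AlignParams = DEFAULT_PARAMS,
                  gap_penalty: float = 0.5) -> Chain:
    """Best chain of local alignment segments across the 3 forward frames.

    Segments come from the optimal local alignment of the reference protein
    against each frame translation; the chain maximises total identities
    minus a per-residue gap penalty subject to co-linearity in both the
    query and the locus. Frame changes between adjacent chained segments
    indicate frameshifts. Random DNA yields an empty chain.
    """
    pool: list[AlignmentSegment] = []
    for frame in (0, 1, 2):
        prot = translate(locus_dna, frame)
        if len(prot) < 5:
            continue
        res = align_local(seed_protein, prot, params)
        if res.raw_score <= 0 or res.evalue_proxy >= params.evalue_genome:
            continue
        for seg in res.segments:
            # genomic (1-based) coordinates of the aligned block
            g1 = frame + 3 * (seg.s_start - 1) + 1
            g2 = frame + 3 * seg.s_end
            if seg.n_identical < max(5, seg.aligned_length // 3):
                continue
            pool.append(AlignmentSegment(
                q_start=seg.q_start, q_end=seg.q_end,
                s_start=g1, s_end=g2, frame=frame,
                n_identical=seg.n_identical,
                aligned_length=seg.aligned_length,
            ))
    if not pool:
        return Chain(segments=[], locus_dna=locus_dna, score=0.0)
    pool.sort(key=lambda s: (s.q_start, s.s_start))
    n = len(pool)
    best = [float(s.n_identical) for s in pool]
    prev = [-1] * n
    # local alignments overextend a few residues past a frameshift, so a
    # bounded overlap between chained segments is tolerated (and not
    # double-counted in the chain score)
    max_overlap = 50
    for j in range(n):
        for i in range(j):
            a, b = pool[i], pool[j]
            if (a.q_end < b.q_start + max_overlap
                    and a.s_end < b.s_start + 3 * max_overlap
                    and a.q_start < b.q_start and a.s_start < b.s_start):
                gap = max(b.q_start - a.q_end - 1, 0)
                # overlapping residues are mismatch-rich overextensions;
                # charge half of them against the chain score
                overlap = max(a.q_end - b.q_start + 1, 0)
                cand = (best[i] + b.n_identical - gap_penalty * gap
                        - 0.5 * overlap)
                if cand > best[j]:
                    best[j], prev[j] = cand, i
    end = max(range(n), key=lambda j: best[j])
    chain = []
    j = end
    while j != -1:
        chain.append(pool[j])
        j = prev[j]
    chain.reverse()
    return Chain(segments=chain, locus_dna=locus_dna, score=best[end])


def classify_structure(cds_or_chain, seed_protein: str | None = None,
                       params: AlignParams = DEFAULT_PARAMS,
                       gene_id: str = "") -> StructureCall:
    """Classify a CDS (or a re-annotation chain) into a structure class.

    Pseudo iff frameshift evidence (CDS length not a multiple of 3, or a
    frame change in the chain) or an internal stop; else LackStart iff the
    first codon is not ATG, LackStop iff the last codon is not a stop (both
    defects give LackBoth); else InDel iff a global alignment to the
    reference protein contains an internal gap of >= 3 codons; else
    Complete."""
    if isinstance(cds_or_chain, Chain):
        chain = cds_or_chain
        if not chain.segments:
            raise ValueError("empty chain cannot be classified")
        if chain.frameshifts:
            return StructureCall(
                gene_id=gene_id, cls="Pseudo",
                evidence=[f"frameshift@{p}" for p in chain.frameshifts])
        lo = chain.segments[0].s_start
        hi = chain.segments[-1].s_end
        # local alignments trim terminal codons: extend in frame to the
        # nearest start/stop codon (within 60 codons) before classifying
        cds = _extend_orf(chain.locus_dna, lo, hi)
        return classify_structure(cds, seed_protein, params, gene_id)
    cds = cds_or_chain
    if not cds:
        raise ValueError("empty input cannot be classified")
    cds = cds.upper()
    evidence: list[str] = []
    if len(cds) % 3 != 0:
        return StructureCall(
            gene_id=gene_id, cls="Pseudo",
            evidence=[f"frameshift:len%3=={len(cds) % 3}"])
    aa = translate(cds)
    internal = aa[:-1]
    if "*" in internal:
        pos = internal.index("*") + 1
        return StructureCall(gene_id=gene_id, cls="Pseudo",
                             evidence=[f"premature_stop@codon{pos}"])
    lack_start = not cds.startswith("ATG")
    lack_stop = cds[-3:] not in STOP_CODONS
    if lack_start and lack_stop:
        return StructureCall(gene_id=gene_id, cls="LackBoth",
                             evidence=["no_start", "no_stop"])
    if lack_start:
        return StructureCall(gene_id=gene_id, cls="LackStart",
                             evidence=["no_start"])
    if lack_stop:
        return StructureCall(gene_id=gene_id, cls="LackStop",
                             evidence=["no_stop"])
    if seed_protein:
        protein = aa[:-1] if aa.endswith("*") else aa
        gap = _max_internal_gap(protein, seed_protein, params)
        if gap >= INDEL_MIN_CODONS:
            return StructureCall(gene_id=gene_id, cls="InDel",
                                 evidence=[f"internal_gap:{gap}codons"])
    return StructureCall(gene_id=gene_id, cls="Complete", evidence=evidence)


def _extend_orf(dna: str, lo: int, hi: int, max_codons: int = 60) -> str:
    """Extend a codon-aligned genomic interval (1-based inclusive) upstream
    to an ATG and downstream to a stop codon, both in frame."""
    start = lo - 1
    for _ in range(max_codons):
        if dna[start : start + 3] == "ATG":
            break
        nxt = start - 3
        if nxt < 0 or dna[nxt : nxt + 3] in STOP_CODONS:
            break
        start = nxt
    end = hi  # exclusive
    for _ in range(max_codons):
        if dna[end - 3 : end] in STOP_CODONS:
            break
        if end + 3 > len(dna):
            break
        end += 3
    return dna[start:end]


def _max_internal_gap(protein: str, reference: str,
                      params: AlignParams) -> int:
    """Longest internal gap (in residues = codons) in the global alignment
    of a protein against its reference; terminal overhangs are ignored."""
    aln = align_global(protein, reference, params)
    t_blocks, q_blocks = aln.aligned
    best = 0
    for k in range(1, len(t_blocks)):
        gap_t = int(t_blocks[k][0] - t_blocks[k - 1][1])
        gap_q = int(q_blocks[k][0] - q_blocks[k - 1][1])
        best = max(best, gap_t, gap_q)
    return best


def summarize_structures(calls: list[StructureCall],
                         species_of: dict[str, str] | None = None
                         ) -> pd.DataFrame:
    """Six-class count table (per species when a gene->species map is
    given) plus the pseudogene fraction."""
    rows = []
    for c in calls:
        sp = (species_of or {}).get(c.gene_id, "all")
        rows.append({"species": sp, "class": c.cls})
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["species", "class"]).size().unstack(fill_value=0)
        .reindex(columns=list(STRUCTURE_CLASSES), fill_value=0)
    )
    table["Total"] = table.sum(axis=1)
    table["pseudo_fraction"] = table["Pseudo"] / table["Total"]
    return table
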
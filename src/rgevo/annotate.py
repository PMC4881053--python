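"""R-gene identification and domain-architecture classification.

Four lightweight domain scanners locate the canonical R-protein domains
(coiled-coil CC, Toll/interleukin-1-receptor TIR, nucleotide-binding NBS and
leucine-rich-repeat LRR) directly from sequence motifs.  An iterative
seed-and-validate search grows the R-gene set to a fixpoint: annotated
proteins are validated either by the NBS motif rule or by significant
similarity to the current seed set, validated proteins become new seeds, and
the seed set is searched against the genomes in all six translation frames to
recover unannotated loci.  Finally every call receives exactly one
architecture label from the twelve-category vocabulary (ten canonical domain
combinations plus "Others" and "Un-annotated").
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    AlignParams,
    DEFAULT_PARAMS,
    AlignmentResult,
    align_local,
    build_frame_index,
    search_six_frame,
)

log = logging.getLogger("rgevo")

ARCHITECTURE_LABELS = [
    "CC", "CC-NBS", "CC-NBS-LRR", "CC-TIR-NBS", "LRR", "NBS", "NBS-LRR",
    "TIR", "TIR-NBS", "TIR-NBS-LRR", "Others", "Un-annotated",
]

# Bundled TIR-domain consensus block used by scan_tir and by the synthetic
# generator when planting TIR domains.
TIR_CONSENSUS = (
    "DVFLSFRGEDTRKTFVSHLYAALERAGIHTFRDDEELRKGEEISPSLLKAIEESRIAIVVFSKNYAS"
    "STWCLDELVKIMECRKTKGQIVIPVFYDVDPSHVRHQTGSFGEA"
)

# coiled-coil heptad log-propensity table: hydrophobic residues favoured at
# the a/d core positions, charged/polar at the e/g interface positions
CC_AD_RESIDUES = set("LIVMF")
CC_EG_RESIDUES = set("EKQR")
CC_AD_SCORE = 1.0
CC_AD_PENALTY = -0.5
CC_EG_SCORE = 0.5
CC_WINDOW = 28
CC_ALPHA = 10.0
CC_BETA = -2.5

_P_LOOP = re.compile(r"[GA].{4}GK[ST]")
_KINASE2 = re.compile(r"[LIVMF]{2}.{0,2}DD")
_GLPL = re.compile(r"GLPL")
_LRR_REPEAT = re.compile(r"[LIVF]..[LIVF].[LIVF]..")


@dataclass(frozen=True)
class DomainHit:
    """A located domain on a protein (1-based inclusive coordinates)."""

    domain: str
    start: int
    end: int
    score: float
    detail: str = ""


@dataclass
class RGeneCall:
    gene_id: str
    species: str
    evidence: str  # original_annotation | iterative_search
    architecture: str = "Un-annotated"
    best_hit_id: str | None = None
    domain_hits: list[DomainHit] = field(default_factory=list)
    iteration_found: int = 1
    chromosome: str = ""
    locus_start: int = 0
    locus_end: int = 0


# ---------------------------------------------------------------------------
# scanners
# ---------------------------------------------------------------------------

def scan_nbs(protein: str) -> DomainHit | None:
    """NBS (NB-ARC) detection by the three-motif rule.

    A hit requires a P-loop ([GA]xxxxGK[ST]) followed downstream by at least
    one of kinase-2 ([LIVMF]{2}.{0,2}DD) or the GLPL motif; the reported span
    runs from the first to the last matched motif.
    """
    if not protein:
        return None
    best = None
    # several spurious P-loop-like matches can occur; keep the supported one
    # with the most downstream motifs and the tightest (latest-start) span
    for ploop in _P_LOOP.finditer(protein):
        downstream = []
        k2 = _KINASE2.search(protein, ploop.end())
        if k2 is not None:
            downstream.append(("kinase2", k2))
        gl = _GLPL.search(protein, ploop.end())
        if gl is not None:
            downstream.append(("GLPL", gl))
        if not downstream:
            continue
        key = (len(downstream), ploop.start())
        if best is None or key > best[0]:
            best = (key, ploop, downstream)
    if best is None:
        return None
    _, ploop, downstream = best
    names = ["P-loop"] + [n for n, _ in downstream]
    last_end = max(m.end() for _, m in downstream)
    return DomainHit(
        domain="NBS", start=ploop.start() + 1, end=last_end,
        score=float(len(names)), detail="+".join(names),
    )


def scan_lrr(protein: str) -> DomainHit | None:
    """Leucine-rich-repeat detection: at least three LxxLxLxx repeats
    (L = L/I/V/F), each starting within 30 residues of the previous repeat's
    end. Separated runs are independent; the longest qualifying run wins."""
    matches = list(_LRR_REPEAT.finditer(protein))
    if not matches:
        return None
    runs: list[list[re.Match]] = [[matches[0]]]
    for m in matches[1:]:
        if m.start() - runs[-1][-1].end() <= 30:
            runs[-1].append(m)
        else:
            runs.append([m])
    best = max(runs, key=len)
    if len(best) < 3:
        return None
    return DomainHit(
        domain="LRR", start=best[0].start() + 1, end=best[-1].end(),
        score=float(len(best)), detail=f"repeats={len(best)}",
    )


def scan_tir(protein: str, tir_consensus: str = TIR_CONSENSUS,
             threshold: float = 0.4,
             params: AlignParams = DEFAULT_PARAMS) -> DomainHit | None:
    """TIR detection by local alignment of the bundled consensus block;
    a hit requires normalized score >= threshold (fraction of the consensus
    self-score)."""
    if not protein:
        return None
    res = align_local(tir_consensus, protein, params,
                      query_id="TIR", subject_id="protein")
    if res.normalized_score < threshold or not res.segments:
        return None
    return DomainHit(
        domain="TIR",
        start=min(s.s_start for s in res.segments),
        end=max(s.s_end for s in res.segments),
        score=res.normalized_score,
        detail=f"norm={res.normalized_score:.2f}",
    )


def cc_window_probabilities(protein: str) -> np.ndarray:
    """Per-window coiled-coil probability: for each 28-residue window the
    best of the seven heptad registers' mean log-propensity is mapped through
    a logistic."""
    L = len(protein)
    if L < CC_WINDOW:
        return np.zeros(0)
    ad = np.array([CC_AD_SCORE if c in CC_AD_RESIDUES else CC_AD_PENALTY
                   for c in protein])
    eg = np.array([CC_EG_SCORE if c in CC_EG_RESIDUES else 0.0
                   for c in protein])
    idx = np.arange(L)
    best = np.full(L - CC_WINDOW + 1, -np.inf)
    for reg in range(7):
        phase = (idx + reg) % 7
        contrib = np.where(np.isin(phase, (0, 3)), ad,
                           np.where(np.isin(phase, (4, 6)), eg, 0.0))
        csum = np.concatenate([[0.0], np.cumsum(contrib)])
        wsum = csum[CC_WINDOW:] - csum[:-CC_WINDOW]
        best = np.maximum(best, wsum / CC_WINDOW)
    return 1.0 / (1.0 + np.exp(-(CC_ALPHA * best + CC_BETA)))


def scan_cc(protein: str, threshold: float = 0.5) -> DomainHit | None:
    """Coiled-coil detection by windowed heptad propensity; span is the union
    of qualifying windows. Proteins shorter than one window give no hit."""
    probs = cc_window_probabilities(protein)
    if probs.size == 0:
        return None
    hits = np.nonzero(probs >= threshold)[0]
    if hits.size == 0:
        return None
    return DomainHit(
        domain="CC", start=int(hits[0]) + 1, end=int(hits[-1]) + CC_WINDOW,
        score=float(probs.max()), detail=f"p={probs.max():.2f}",
    )


def scan_all(protein: str, params: AlignParams = DEFAULT_PARAMS) -> list[DomainHit]:
    """Run all four scanners on one protein.

    The TIR and NBS scans run first; their spans are masked out before the
    CC and LRR scans so that hydrophobic stretches inside those globular
    domains cannot masquerade as coiled-coil heptads or leucine-rich
    repeats."""
    hits = []
    tir = scan_tir(protein, params=params)
    if tir is not None:
        hits.append(tir)
    nbs = scan_nbs(protein)
    if nbs is not None:
        hits.append(nbs)
    masked = protein
    for h in hits:
        masked = masked[: h.start - 1] + "X" * (h.end - h.start + 1) + masked[h.end:]
    for scanner in (scan_cc, scan_lrr):
        h = scanner(masked)
        if h is not None:
            hits.append(h)
    hits.sort(key=lambda h: h.start)
    return hits


# ---------------------------------------------------------------------------
# architecture classification
# ---------------------------------------------------------------------------

def classify_architecture(hits: list[DomainHit], protein_length: int) -> str:
    """Map located domains to one of the twelve architecture labels.

    N-terminal CC or TIR must lie fully before the NBS span and C-terminal
    LRR fully after it; CC before TIR before NBS composes CC-TIR-NBS. Any
    ordering violation, overlap with the NBS span, all four domains together,
    or a multi-domain combination lacking NBS falls into "Others"; no hits at
    all is "Un-annotated"."""
    by = {h.domain: h for h in hits}
    if not by:
        return "Un-annotated"
    cc, tir, nbs, lrr = (by.get(d) for d in ("CC", "TIR", "NBS", "LRR"))
    if cc and tir and nbs and lrr:
        return "Others"
    if nbs is None:
        present = [d for d in ("CC", "TIR", "LRR") if by.get(d)]
        return present[0] if len(present) == 1 else "Others"
    # N-before-NBS / C-after-NBS ordering rules
    for nterm in (cc, tir):
        if nterm is not None and nterm.end >= nbs.start:
            log.warning("architecture: %s overlaps/after NBS span", nterm.domain)
            return "Others"
    if lrr is not None and lrr.start <= nbs.end:
        return "Others"
    if cc is not None and tir is not None:
        if not (cc.end < tir.start):
            return "Others"
        if lrr is not None:
            return "Others"
        return "CC-TIR-NBS"
    label = ""
    if cc is not None:
        label += "CC-"
    if tir is not None:
        label += "TIR-"
    label += "NBS"
    if lrr is not None:
        label += "-LRR"
    return label


# ---------------------------------------------------------------------------
# iterative seed-and-validate identification
# ---------------------------------------------------------------------------

class _SeedIndex:
    """Incrementally grown word index over seed proteins, used as a BLAST-like
    pre-filter: a protein is aligned only against seeds sharing enough words."""

    def __init__(self, word_size: int = 6, min_shared: int = 3):
        self.word_size = word_size
        self.min_shared = min_shared
        self.words: dict[str, set[str]] = {}
        self.seqs: dict[str, str] = {}

    def add(self, seed_id: str, seq: str) -> None:
        if seed_id in self.seqs:
            return
        self.seqs[seed_id] = seq
        w = self.word_size
        for i in range(len(seq) - w + 1):
            self.words.setdefault(seq[i : i + w], set()).add(seed_id)

    def candidates(self, protein: str, exclude: str = "") -> list[str]:
        w = self.word_size
        counts: dict[str, int] = {}
        seen = set()
        for i in range(len(protein) - w + 1):
            word = protein[i : i + w]
            if word in seen:
                continue
            seen.add(word)
            for sid in self.words.get(word, ()):
                counts[sid] = counts.get(sid, 0) + 1
        return sorted(
            sid for sid, c in counts.items()
            if c >= self.min_shared and sid != exclude
        )


def _best_seed_hit(protein: str, seed_ids: list[str], index: _SeedIndex,
                   params: AlignParams) -> AlignmentResult | None:
    """Best alignment of a protein against the given seeds; ties broken by
    highest raw score, then lowest e-value proxy, then seed id."""
    best: AlignmentResult | None = None
    for sid in seed_ids:
        res = align_local(protein, index.seqs[sid], params,
                          query_id="query", subject_id=sid, score_only=True)
        if best is None or (
            (-res.raw_score, res.evalue_proxy, res.subject_id)
            < (-best.raw_score, best.evalue_proxy, best.subject_id)
        ):
            best = res
    return best


def iterative_identify(
    proteomes: dict[str, list],
    genomes: dict[str, dict[str, str]],
    seed_db: list,
    params: AlignParams = DEFAULT_PARAMS,
    max_iter: int = 10,
    annotated_spans: dict[str, dict[str, list[tuple[int, int]]]] | None = None,
) -> list[RGeneCall]:
    """Grow the R-gene call set to a fixpoint.

    Per iteration: (1) screen not-yet-validated annotated proteins by the NBS
    motif rule or by alignment to the current seed set below the protein
    e-value threshold; (2) validated proteins join the seed set; (3) search
    the current seeds against the genomes in six frames below the genome
    e-value threshold to recover unannotated loci (annotated gene spans are
    masked). Stops when an iteration adds nothing; raises if ``max_iter`` is
    exceeded, listing per-iteration growth.

    ``proteomes`` maps species to records with .id/.seq (or GeneModels);
    ``genomes`` maps species to {chromosome: sequence}.
    """
    if not seed_db:
        raise ValueError("iterative_identify: empty seed database")

    def rec_id(r):
        return getattr(r, "id", None) or getattr(r, "gene_id")

    def rec_seq(r):
        return getattr(r, "seq", None) or getattr(r, "protein")

    index = _SeedIndex()
    for rec in seed_db:
        index.add("seed:" + rec_id(rec), rec_seq(rec))

    pending: list[tuple[str, str, str]] = []  # (species, gene_id, protein)
    for sp, recs in sorted(proteomes.items()):
        for rec in recs:
            pending.append((sp, rec_id(rec), rec_seq(rec)))

    frame_indexes = {}
    for sp, chroms in sorted(genomes.items()):
        masked = (annotated_spans or {}).get(sp, {})
        frame_indexes[sp] = {
            chrom: build_frame_index(seq, params.word_size,
                                     masked.get(chrom, ()))
            for chrom, seq in sorted(chroms.items())
        }

    calls: list[RGeneCall] = []
    found_loci: dict[str, list[tuple[str, int, int]]] = {}
    new_seeds: list[tuple[str, str]] = [
        ("seed:" + rec_id(r), rec_seq(r)) for r in seed_db
    ]
    growth: list[int] = []
    for iteration in range(1, max_iter + 1):
        added = 0
        # (1) validate annotated proteins
        still_pending = []
        validated_this_round: list[tuple[str, str]] = []
        for sp, gid, prot in pending:
            call = None
            if scan_nbs(prot) is not None:
                call = RGeneCall(gene_id=gid, species=sp,
                                 evidence="original_annotation",
                                 iteration_found=iteration)
            else:
                cand = index.candidates(prot)
                if cand:
                    best = _best_seed_hit(prot, cand, index, params)
                    if best is not None and best.evalue_proxy < params.evalue_protein:
                        call = RGeneCall(
                            gene_id=gid, species=sp,
                            evidence="iterative_search",
                            best_hit_id=best.subject_id,
                            iteration_found=iteration,
                        )
            if call is None:
                still_pending.append((sp, gid, prot))
            else:
                calls.append(call)
                validated_this_round.append((gid, prot))
                added += 1
        pending = still_pending
        # (2) validated candidates join the seed set
        for gid, prot in validated_this_round:
            index.add(gid, prot)
        new_seeds.extend(validated_this_round)
        # (3) six-frame genome search with the seeds new this round
        for sid, seq in new_seeds:
            for sp, chrom_idx in frame_indexes.items():
                for chrom, fidx in chrom_idx.items():
                    known = [
                        (a, b) for c, a, b in found_loci.get(sp, ())
                        if c == chrom
                    ]
                    hits = search_six_frame(
                        seq, "", params, query_id=sid, genome_id=chrom,
                        index=fidx, threshold=params.evalue_genome,
                        skip_genomic=known,
                    )
                    for hit in hits:
                        if not hit.segments:
                            continue
                        lo = min(s.s_start for s in hit.segments)
                        hi = max(s.s_end for s in hit.segments)
                        if _register_locus(found_loci.setdefault(sp, []),
                                           chrom, lo, hi):
                            calls.append(
                                RGeneCall(
                                    gene_id=f"{sp}:{chrom}:{lo}-{hi}",
                                    species=sp, evidence="iterative_search",
                                    best_hit_id=sid,
                                    iteration_found=iteration,
                                    chromosome=chrom,
                                    locus_start=lo, locus_end=hi,
                                )
                            )
                            added += 1
        new_seeds = []
        growth.append(added)
        if added == 0:
            return calls
    raise RuntimeError(
        f"iterative_identify: no convergence in {max_iter} iterations; "
        f"growth per iteration: {growth}"
    )


def _register_locus(loci: list[tuple[str, int, int]], chrom: str,
                    lo: int, hi: int) -> bool:
    """Record a genomic locus unless it overlaps one already found."""
    for c, a, b in loci:
        if c == chrom and lo <= b and a <= hi:
            return False
    loci.append((chrom, lo, hi))
    return True


def classify_calls(calls: list[RGeneCall],
                   proteomes: dict[str, list],
                   params: AlignParams = DEFAULT_PARAMS) -> None:
    """Attach domain hits and architecture labels to annotated-protein calls
    in place; genome-locus calls keep "Un-annotated"."""
    seqs: dict[tuple[str, str], str] = {}
    for sp, recs in proteomes.items():
        for rec in recs:
            rid = getattr(rec, "id", None) or getattr(rec, "gene_id")
            rseq = getattr(rec, "seq", None) or getattr(rec, "protein")
            seqs[(sp, rid)] = rseq
    for call in calls:
        prot = seqs.get((call.species, call.gene_id))
        if prot is None:
            continue
        call.domain_hits = scan_all(prot, params)
        call.architecture = classify_architecture(call.domain_hits, len(prot))


def summarize_inventory(calls: list[RGeneCall]) -> pd.DataFrame:
    """Per-species x per-architecture count table with Total row and column
    (the twelve-category inventory)."""
    species = sorted({c.species for c in calls})
    table = pd.DataFrame(0, index=ARCHITECTURE_LABELS, columns=species)
    for c in calls:
        table.loc[c.architecture, c.species] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table
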
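"""Shared domain types, standard-format I/O, genetic-code utilities and the
pairwise alignment engine used by every downstream stage.

Coordinates are genomic 1-based inclusive (GFF3 convention); protein domain
coordinates are 1-based inclusive; gene ranks along a chromosome are 0-based.
Minus-strand genes store their CDS already reverse-complemented into coding
orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("rgevo")

__all__ = [
    "GeneModel",
    "AlignmentSegment",
    "AlignmentResult",
    "AlignParams",
    "FastaRecord",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "translate",
    "reverse_complement",
    "align_local",
    "align_global",
    "self_score",
    "evalue_proxy",
    "search_six_frame",
    "load_tree",
    "write_tree",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One annotated gene: coordinates, strand, rank along its chromosome,
    and the linked CDS/protein sequences (CDS stored in coding orientation)."""

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int = -1
    protein: str = ""
    cds: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")


@dataclass(frozen=True)
class AlignmentSegment:
    """One gapless aligned block. Query/subject coordinates are 1-based
    inclusive; ``frame`` is 0 for protein-protein alignments, +1..+3 / -1..-3
    for translated-DNA subjects (sign = strand)."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    frame: int
    n_identical: int
    aligned_length: int


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    segments: list[AlignmentSegment]
    raw_score: float
    normalized_score: float
    evalue_proxy: float

    @property
    def n_identical(self) -> int:
        return sum(s.n_identical for s in self.segments)

    @property
    def aligned_length(self) -> int:
        return sum(s.aligned_length for s in self.segments)


@dataclass
class AlignParams:
    """Scoring scheme and significance constants.

    BLOSUM62 with BLAST-default affine gaps (11 open / 1 extend; a gap of
    length k costs 11 + k) and fixed Karlin–Altschul-style constants for the
    analytic E-value proxy ``K * m * n * exp(-lambda * score)``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    ka_K: float = 0.041
    ka_lambda: float = 0.267
    evalue_protein: float = 1e-10   # protein-vs-protein significance
    evalue_genome: float = 1e-5     # translated genome search significance
    word_size: int = 6              # six-frame search anchor word length

    _matrix: object = field(default=None, repr=False, compare=False)

    @property
    def matrix(self):
        if self._matrix is None:
            object.__setattr__(
                self, "_matrix", substitution_matrices.load(self.matrix_name)
            )
        return self._matrix


DEFAULT_PARAMS = AlignParams()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FastaRecord:
    id: str
    seq: str


def read_fasta(path) -> list[FastaRecord]:
    """Read a FASTA file into (id, sequence) records.

    An empty file yields an empty list (with a warning); a sequence line
    appearing before any header is a parse error naming the line number.
    """
    records: list[FastaRecord] = []
    # pre-scan for the header-before-sequence contract with a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: sequence line before header at line {lineno}"
                )
            break
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(FastaRecord(id=rec.id, seq=str(rec.seq)))
    if not records:
        log.warning("read_fasta: no records in %s", path)
    return records


def write_fasta(records: Iterable, path) -> str:
    """Write records (anything with .id/.seq) as FASTA wrapped at 60 columns."""
    recs = list(records)
    if not recs:
        raise ValueError("write_fasta: no records to write")
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in recs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecs)
    return str(path)


# ---------------------------------------------------------------------------
# GFF3 (gene features only)
# ---------------------------------------------------------------------------

def read_gff3(path, species: str = "") -> list[GeneModel]:
    """Read gene features from a GFF3 file into GeneModels.

    Ranks are assigned per chromosome by sorted start, ties broken by
    gene_id, so they form a permutation of 0..n-1 on every chromosome.
    Records with end < start or an unknown strand are rejected with an error.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields[:9]
            if ftype != "gene":
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: end < start")
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            gene_id = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if not gene_id:
                raise ValueError(f"{path}:{lineno}: gene feature lacks ID attribute")
            genes.append(
                GeneModel(
                    gene_id=gene_id, species=species, chromosome=chrom,
                    start=start_i, end=end_i, strand=strand,
                )
            )
    assign_ranks(genes)
    return genes


def assign_ranks(genes: list[GeneModel]) -> None:
    """Assign 0-based ranks along each chromosome by (start, gene_id)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for members in by_chrom.values():
        members.sort(key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(members):
            g.rank = i


def write_gff3(genes: Sequence[GeneModel], path) -> str:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            fh.write(
                f"{g.chromosome}\trgevo\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
    return str(path)


# ---------------------------------------------------------------------------
# genetic code
# ---------------------------------------------------------------------------

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

CODON_TABLE = _CODON_TABLE
STOP_CODONS = frozenset(c for c, aa in _CODON_TABLE.items() if aa == "*")


def translate(cds: str, frame: int = 0) -> str:
    """Translate DNA in the given frame (0/1/2) with the standard code.

    Stops become '*' and are retained; any codon containing a non-ACGT
    character becomes 'X'.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    s = cds.upper()
    out = []
    for i in range(frame, len(s) - 2, 3):
        out.append(_CODON_TABLE.get(s[i : i + 3], "X"))
    return "".join(out)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

def _make_aligner(params: AlignParams, mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = params.matrix
    # Biopython charges open_gap_score on the first gap position, so BLAST's
    # 11 + k cost for a length-k gap maps to open = -(11+1), extend = -1.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    if mode == "global":
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older Biopython attribute names
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def _sanitize(seq: str) -> str:
    """Replace residues missing from the scoring alphabet with X."""
    alphabet = "ACDEFGHIKLMNPQRSTVWYBZX*"
    return "".join(c if c in alphabet else "X" for c in seq.upper())


def self_score(protein: str, params: AlignParams = DEFAULT_PARAMS) -> float:
    """Score of a sequence aligned to itself (matrix diagonal sum)."""
    mat = params.matrix
    s = _sanitize(protein)
    return float(sum(mat[c, c] for c in s))


def evalue_proxy(raw_score: float, m: int, n: int,
                 params: AlignParams = DEFAULT_PARAMS) -> float:
    """Analytic Karlin–Altschul-style significance proxy K·m·n·exp(−λ·S)."""
    return params.ka_K * m * n * math.exp(-params.ka_lambda * raw_score)


def _segments_from_alignment(alignment, frame: int = 0,
                             q_offset: int = 0, s_offset: int = 0
                             ) -> list[AlignmentSegment]:
    """Extract gapless blocks from a Bio.Align alignment as 1-based segments."""
    qseq = str(alignment.sequences[1])  # query
    sseq = str(alignment.sequences[0])  # subject/target
    t_blocks, q_blocks = alignment.aligned  # target rows, query rows
    segments = []
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        ts, te, qs, qe = int(ts), int(te), int(qs), int(qe)
        n_id = sum(1 for a, b in zip(sseq[ts:te], qseq[qs:qe]) if a == b)
        segments.append(
            AlignmentSegment(
                q_start=qs + 1 + q_offset, q_end=qe + q_offset,
                s_start=ts + 1 + s_offset, s_end=te + s_offset,
                frame=frame, n_identical=n_id, aligned_length=te - ts,
            )
        )
    return segments


def align_local(query: str, subject: str,
                params: AlignParams = DEFAULT_PARAMS,
                query_id: str = "query", subject_id: str = "subject",
                score_only: bool = False) -> AlignmentResult:
    """Optimal local (Smith–Waterman) protein alignment.

    ``raw_score`` is the SW optimum under the configured scheme;
    ``normalized_score`` is the fraction of the query's self-alignment score,
    clipped to [0, 1].
    """
    if not query or not subject:
        raise ValueError("align_local: empty sequence")
    q, s = _sanitize(query), _sanitize(subject)
    aligner = _make_aligner(params, "local")
    score = float(aligner.score(s, q))
    segments: list[AlignmentSegment] = []
    if not score_only and score > 0:
        alignment = next(iter(aligner.align(s, q)))
        segments = _segments_from_alignment(alignment)
    sself = self_score(q, params)
    norm = max(0.0, min(1.0, score / sself)) if sself > 0 else 0.0
    return AlignmentResult(
        query_id=query_id, subject_id=subject_id, segments=segments,
        raw_score=max(score, 0.0), normalized_score=norm,
        evalue_proxy=evalue_proxy(max(score, 0.0), len(q), len(s), params),
    )


def align_global(query: str, subject: str,
                 params: AlignParams = DEFAULT_PARAMS):
    """Global (end-gap-free) protein alignment; returns the Bio.Align
    alignment object (subject is the target row, query the query row)."""
    if not query or not subject:
        raise ValueError("align_global: empty sequence")
    aligner = _make_aligner(params, "global")
    return next(iter(aligner.align(_sanitize(subject), _sanitize(query))))


# ---------------------------------------------------------------------------
# six-frame translated search
# ---------------------------------------------------------------------------

def _frame_translations(genome: str) -> dict[int, str]:
    """All six frame translations. Keys +1..+3 (forward, frame i-1) and
    -1..-3 (reverse-complement, frame i-1)."""
    frames = {}
    rc = reverse_complement(genome)
    for i in (0, 1, 2):
        frames[i + 1] = translate(genome, i)
        frames[-(i + 1)] = translate(rc, i)
    return frames


def build_frame_index(genome: str, word_size: int = 5,
                      masked: Sequence[tuple[int, int]] = ()) -> dict:
    """Pre-computed six-frame word index of a genome sequence.

    ``masked`` is a list of 1-based inclusive genomic intervals whose frame
    positions are excluded from the index (e.g. already-annotated genes).
    """
    import numpy as np

    n = len(genome)
    frames = _frame_translations(genome)
    mask = np.zeros(n, dtype=bool)
    for a, b in masked:
        mask[max(a - 1, 0) : min(b, n)] = True

    def word_masked(frame: int, n_aa: int) -> "np.ndarray":
        """Boolean per word start: word overlaps a masked genomic position."""
        o = abs(frame) - 1
        m = mask if frame > 0 else mask[::-1]
        usable = (n - o) // 3
        if usable <= 0:
            return np.zeros(0, dtype=bool)
        cod = m[o : o + 3 * usable].reshape(usable, 3).any(axis=1)
        if usable < word_size:
            return np.zeros(0, dtype=bool)
        csum = np.concatenate([[0], np.cumsum(cod)])
        return (csum[word_size:] - csum[:-word_size]) > 0

    index: dict[int, dict[str, list[int]]] = {}
    for frame, prot in frames.items():
        words: dict[str, list[int]] = {}
        wm = word_masked(frame, len(prot)) if mask.any() else None
        for i in range(len(prot) - word_size + 1):
            w = prot[i : i + word_size]
            if "*" in w or "X" in w:
                continue
            if wm is not None and i < len(wm) and wm[i]:
                continue
            words.setdefault(w, []).append(i)
        index[frame] = words
    return {"frames": frames, "words": index, "length": n,
            "masked": [(int(a), int(b)) for a, b in masked]}


def _aa_to_genomic(frame: int, aa_start: int, aa_end: int, n: int) -> tuple[int, int]:
    """Map a 1-based inclusive aa interval in a frame translation to 1-based
    forward-strand genomic coordinates."""
    if frame > 0:
        g1 = (frame - 1) + 3 * (aa_start - 1) + 1
        g2 = (frame - 1) + 3 * aa_end
    else:
        r1 = (-frame - 1) + 3 * (aa_start - 1) + 1
        r2 = (-frame - 1) + 3 * aa_end
        g1 = n - r2 + 1
        g2 = n - r1 + 1
    return g1, g2


def search_six_frame(query: str, genome: str,
                     params: AlignParams = DEFAULT_PARAMS,
                     query_id: str = "query", genome_id: str = "genome",
                     index: dict | None = None,
                     threshold: float | None = None,
                     skip_genomic: Sequence[tuple[int, int]] = ()
                     ) -> list[AlignmentResult]:
    """Search a protein query against all six translation frames of a genome.

    Word-anchored: exact ``word_size``-mer matches group into diagonal bands;
    each band is extended by local alignment of the query against a window of
    the frame translation. Only hits with ``evalue_proxy`` below the genome
    threshold are returned, sorted by raw score descending. Segment genomic
    coordinates are returned 1-based on the forward strand; frame sign gives
    the strand.
    """
    if threshold is None:
        threshold = params.evalue_genome
    if index is None:
        index = build_frame_index(genome, params.word_size)
    frames, words = index["frames"], index["words"]
    n = index["length"]
    masked = index.get("masked", [])
    w = params.word_size
    qlen = len(query)
    results: list[AlignmentResult] = []
    aligner = _make_aligner(params, "local")
    for frame, word_index in words.items():
        prot = frames[frame]
        # collect (diagonal, subject position) anchors
        diag_hits: dict[int, list[int]] = {}
        for qi in range(qlen - w + 1):
            qw = _sanitize(query[qi : qi + w])
            for si in word_index.get(qw, ()):
                diag_hits.setdefault(si - qi, []).append(si)
        if not diag_hits:
            continue
        # cluster anchor positions by locality (coincidental word hits far
        # apart on one diagonal must not fuse into a genome-sized window)
        positions = sorted(si for pos in diag_hits.values() for si in pos)
        pad = qlen // 2 + w
        clusters: list[list[int]] = [[positions[0], positions[0]]]
        for si in positions[1:]:
            if si - clusters[-1][1] <= qlen:
                clusters[-1][1] = si
            else:
                clusters.append([si, si])
        windows: list[list[int]] = []
        for lo, hi in clusters:
            lo = max(0, lo - pad)
            hi = min(len(prot), hi + pad + w)
            if windows and lo <= windows[-1][1]:
                windows[-1][1] = max(windows[-1][1], hi)
            else:
                windows.append([lo, hi])
        for lo, hi in windows:
            if skip_genomic:
                g_lo, g_hi = _aa_to_genomic(frame, lo + 1, hi, n)
                if any(a <= g_hi and g_lo <= b for a, b in skip_genomic):
                    continue
            sub = prot[lo:hi]
            score = float(aligner.score(_sanitize(sub), _sanitize(query)))
            if score <= 0:
                continue
            ev = evalue_proxy(score, qlen, 2 * n, params)
            if ev >= threshold:
                continue
            alignment = next(iter(aligner.align(_sanitize(sub), _sanitize(query))))
            segs = []
            for seg in _segments_from_alignment(alignment, frame=frame):
                g1, g2 = _aa_to_genomic(
                    frame, seg.s_start + lo, seg.s_end + lo, n
                )
                segs.append(
                    AlignmentSegment(
                        q_start=seg.q_start, q_end=seg.q_end,
                        s_start=g1, s_end=g2, frame=frame,
                        n_identical=seg.n_identical,
                        aligned_length=seg.aligned_length,
                    )
                )
            if segs and masked:
                # windows around intergenic word anchors can slide onto a
                # neighbouring masked (annotated) gene; such hits are not
                # unannotated loci
                h_lo = min(s.s_start for s in segs)
                h_hi = max(s.s_end for s in segs)
                if any(a <= h_hi and h_lo <= b for a, b in masked):
                    continue
            sself = self_score(query, params)
            results.append(
                AlignmentResult(
                    query_id=query_id, subject_id=genome_id,
                    segments=segs, raw_score=score,
                    normalized_score=max(0.0, min(1.0, score / sself)),
                    evalue_proxy=ev,
                )
            )
    results.sort(key=lambda r: (-r.raw_score, r.evalue_proxy))
    return results


# ---------------------------------------------------------------------------
# species trees (thin dendropy wrappers)
# ---------------------------------------------------------------------------

def load_tree(path_or_string, schema: str = "newick"):
    """Load a rooted species tree (dendropy.Tree)."""
    import dendropy

    src = str(path_or_string)
    if src.lstrip().startswith("("):
        return dendropy.Tree.get(data=src, schema=schema,
                                 rooting="force-rooted",
                                 preserve_underscores=True)
    return dendropy.Tree.get(path=src, schema=schema,
                             rooting="force-rooted",
                             preserve_underscores=True)


def write_tree(tree, path) -> str:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
    return str(path)
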
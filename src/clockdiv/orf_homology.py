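"""ORF finding, translation, UTR trimming and best-hit homology search.

This implements the first half of the ortholog-assignment flow: translate
each focal-taxon transcript via its longest open reading frame, then score
it against a panel of single-copy reference orthologs with Smith-Waterman
local alignment (affine gaps, BLOSUM62 by default).  Genes whose best hits
are ambiguous, or that belong to declared multi-gene families, are deferred
to tree-based clade assignment (see :mod:`clockdiv.tree_build`).

E-values are deliberately not computed: ranking is by raw alignment score
with a uniqueness margin, which preserves the single-best-hit /
defer-to-tree decision structure while staying deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .io_formats import Alphabet, SequenceRecord

_CODON = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class OrfAnnotation:
    """Coordinates of an open reading frame on the *forward* strand record.

    ``start``/``end`` are 0-based half-open nucleotide positions on the
    strand given by ``strand`` (i.e. on the reverse complement when '-').
    """

    start: int
    end: int
    frame: int
    strand: str
    length_nt: int

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")
        if self.length_nt != self.end - self.start:
            raise ValueError("length_nt inconsistent with start/end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    score: float
    identity: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    unique_best: bool = False


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def translate(seq: SequenceRecord | str, frame: int = 0, strand: str = "+") -> SequenceRecord:
    """Translate under the standard genetic code.

    Stops become '*', any codon containing an ambiguous base becomes 'X',
    and a trailing partial codon is dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if isinstance(seq, SequenceRecord):
        nt, sid = seq.residues, seq.id
    else:
        nt, sid = seq, "seq"
    nt = nt.upper().replace("U", "T")
    if strand == "-":
        nt = reverse_complement(nt)
    aa = []
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        aa.append(_CODON.get(codon, "X"))
    return SequenceRecord(sid, "".join(aa) or "X", Alphabet.aa) if aa else SequenceRecord(sid, "X", Alphabet.aa)


def find_longest_orf(seq: SequenceRecord, require_atg: bool = True, allow_open_3prime: bool = True) -> OrfAnnotation | None:
    """Longest ORF over both strands and all three frames.

    An ORF starts at ATG (when ``require_atg``) and runs to the first stop;
    with ``allow_open_3prime`` an ORF may run off the 3' end without a stop
    (the incomplete tail codon is excluded).  Ties break toward the longer
    ORF, then '+' strand, then smaller start.  Returns ``None`` when no ORF
    exists under the policy.
    """
    if len(seq.residues) < 3:
        raise ValueError("sequence shorter than one codon")
    best: OrfAnnotation | None = None
    for strand in "+-":
        nt = seq.residues.upper().replace("U", "T")
        if strand == "-":
            nt = reverse_complement(nt)
        for frame in range(3):
            i = frame
            while i <= len(nt) - 3:
                if require_atg and nt[i : i + 3] != "ATG":
                    i += 3
                    continue
                # scan to stop or open 3' end
                j = i
                stopped = False
                while j <= len(nt) - 3:
                    codon = nt[j : j + 3]
                    j += 3
                    if _CODON.get(codon) == "*":
                        stopped = True
                        break
                if not stopped and not allow_open_3prime:
                    break
                cand = OrfAnnotation(start=i, end=j, frame=frame, strand=strand, length_nt=j - i)
                if _orf_better(cand, best):
                    best = cand
                i = j if stopped else len(nt)
    return best


def _orf_better(cand: OrfAnnotation, best: OrfAnnotation | None) -> bool:
    if best is None:
        return True
    key_c = (cand.length_nt, cand.strand == "+", -cand.start)
    key_b = (best.length_nt, best.strand == "+", -best.start)
    return key_c > key_b


def orf_protein(seq: SequenceRecord, orf: OrfAnnotation) -> SequenceRecord:
    """Translate exactly the ORF span (stop codon, if present, excluded)."""
    nt = seq.residues.upper().replace("U", "T")
    if orf.strand == "-":
        nt = reverse_complement(nt)
    if orf.end > len(nt):
        raise ValueError("ORF extends past end of sequence")
    prot = translate(SequenceRecord(seq.id, nt[orf.start : orf.end], Alphabet.nt))
    residues = prot.residues.rstrip("*")
    return SequenceRecord(seq.id, residues, Alphabet.aa)


def trim_utrs(seq: SequenceRecord, orf: OrfAnnotation) -> SequenceRecord:
    """Drop 5'/3' untranslated flanks: keep only the ORF's translation.

    The returned record carries a ``_cds`` suffix on the id.
    """
    prot = orf_protein(seq, orf)
    return SequenceRecord(seq.id + "_cds", prot.residues, Alphabet.aa)


# ---------------------------------------------------------------------------
# Smith-Waterman with affine gaps

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_NEG_INF = -1e30


def _matrix_lookup(matrix) -> dict[tuple[str, str], float]:
    if isinstance(matrix, dict):
        return matrix
    lut = {}
    for a in matrix.alphabet:
        for b in matrix.alphabet:
            lut[(a, b)] = float(matrix[a, b])
    return lut


def local_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentHit:
    """Optimal Smith-Waterman local alignment with affine gap costs.

    Opening a gap of length L costs ``gap_open + L * gap_extend`` (BLAST
    convention).  'X' scores 0 against anything.  Traceback ties prefer
    diagonal, then up (gap in b), then left.  When no cell is positive the
    hit has score 0 and empty spans.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    ida = a.id if isinstance(a, SequenceRecord) else "a"
    idb = b.id if isinstance(b, SequenceRecord) else "b"
    if not sa or not sb:
        raise ValueError("both sequences must be nonempty")
    lut = _matrix_lookup(matrix if matrix is not None else _BLOSUM62)

    def sub(x: str, y: str) -> float:
        if x == "X" or y == "X":
            return 0.0
        return lut.get((x, y), lut.get((y, x), 0.0))

    n, m = len(sa), len(sb)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), _NEG_INF)  # gap in a (left moves)
    F = np.full((n + 1, m + 1), _NEG_INF)  # gap in b (up moves)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open - gap_extend, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open - gap_extend, F[i - 1, j] - gap_extend)
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub(sa[i - 1], sb[j - 1]), F[i, j], E[i, j])
    score = float(H.max())
    if score <= 0:
        return AlignmentHit(ida, idb, 0.0, 0.0, (0, 0), (0, 0))
    # deterministic endpoint: smallest (i, j) among maxima
    i, j = np.argwhere(H == H.max())[0]
    i, j = int(i), int(j)
    end_a, end_b = i, j
    ident = 0
    ncols = 0
    state = "H"
    while H[i, j] > 0 or state != "H":
        if state == "H":
            diag = H[i - 1, j - 1] + sub(sa[i - 1], sb[j - 1]) if i > 0 and j > 0 else _NEG_INF
            if i > 0 and j > 0 and H[i, j] == diag:
                ncols += 1
                if sa[i - 1] == sb[j - 1]:
                    ident += 1
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - H cell must match one predecessor
                break
        elif state == "F":
            if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                i, state = i - 1, "H"
            else:
                i = i - 1
        else:  # E
            if E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                j, state = j - 1, "H"
            else:
                j = j - 1
    start_a, start_b = i, j
    identity = ident / ncols if ncols else 0.0
    return AlignmentHit(ida, idb, score, identity, (start_a, end_a), (start_b, end_b))


def best_hit(
    query: SequenceRecord,
    targets: Sequence[SequenceRecord],
    min_score: float = 0.0,
    unique_margin: float = 0.10,
    **align_kw,
) -> list[AlignmentHit]:
    """Rank targets by local-alignment score against ``query``.

    Hits scoring below ``min_score`` are dropped; ordering is (score desc,
    subject id asc).  The top hit's ``unique_best`` flag is set when its
    score exceeds the runner-up by at least ``unique_margin`` times the top
    score (trivially true with a single hit).
    """
    if not targets:
        raise ValueError("targets must be nonempty")
    hits = [local_align(query, t, **align_kw) for t in targets]
    hits = [h for h in hits if h.score >= min_score and h.score > 0]
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    if not hits:
        return []
    top = hits[0]
    unique = len(hits) == 1 or (top.score - hits[1].score) >= unique_margin * top.score
    hits[0] = AlignmentHit(
        top.query_id, top.subject_id, top.score, top.identity, top.query_span, top.subject_span, unique
    )
    return hits


def assign_single_copy(
    query_set: Sequence[SequenceRecord],
    reference_orthologs: Mapping[str, SequenceRecord],
    multigene_families: Mapping[str, str] | None = None,
    min_score: float = 40.0,
    unique_margin: float = 0.10,
) -> dict[str, object]:
    """Assign each reference gene a single focal-taxon candidate, or defer.

    For every gene the reference sequence is searched against ``query_set``.
    Outcomes per gene: the best-hit query id when the top hit is uniquely
    best and the gene is not in a declared multi-gene family; ``"deferred"``
    when the gene belongs to a multi-gene family or the margin rule fails
    (these go to tree-based clade assignment); ``"absent"`` when nothing
    scores above ``min_score`` (legitimate: some clock genes are genuinely
    missing from particular insect lineages).
    """
    multigene_families = multigene_families or {}
    out: dict[str, object] = {}
    for gene, ref in reference_orthologs.items():
        if not query_set:
            out[gene] = "absent"
            continue
        hits = best_hit(ref, list(query_set), min_score=min_score, unique_margin=unique_margin)
        if not hits:
            out[gene] = "absent"
        elif gene in multigene_families or not hits[0].unique_best:
            out[gene] = "deferred"
        else:
            out[gene] = hits[0].subject_id
    return out
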
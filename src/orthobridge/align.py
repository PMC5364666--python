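"""Pairwise protein alignment: Smith–Waterman local and Needle-style global.

Both use affine gap costs (a gap of length L costs open + L*extend, i.e. the
open penalty plus one extend charged on the first gap residue).  Dynamic
programming runs on :class:`Bio.Align.PairwiseAligner`; identity, similarity,
coverage and spans are derived from the optimal traceback.  E-values are
attached downstream by the search layer, which knows the database size.

Identity is the fraction of alignment columns (gaps included) with identical
residues; similarity the fraction whose residue pair scores > 0 under the
scoring matrix.  Because BLOSUM diagonals are positive, identity ≤ similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from Bio import Align

from .matrices import ScoringMatrix
from .seqio import SequenceRecord

def _bio_matrix(matrix: ScoringMatrix):
    # cached on the matrix instance so the cache cannot outlive the object
    cached = matrix.__dict__.get("_bio_array")
    if cached is None:
        cached = matrix.to_biopython()
        matrix.__dict__["_bio_array"] = cached
    return cached


@dataclass
class AlignmentResult:
    """Scores and statistics for one pairwise comparison.

    Spans are 1-based inclusive; ``query_span`` is ``None`` for an empty
    local alignment (no positive-scoring segment).
    """

    query_id: str
    subject_id: str
    raw_score: float
    aligned_query: str
    aligned_subject: str
    query_span: Optional[Tuple[int, int]]
    subject_span: Optional[Tuple[int, int]]
    identity_pct: float
    similarity_pct: float
    query_coverage_pct: float
    mode: str = "local"
    bit_score: Optional[float] = None
    evalue: Optional[float] = None

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_query)

    def is_empty(self) -> bool:
        return self.alignment_length == 0


def _column_stats(aq: str, asub: str, matrix: ScoringMatrix) -> Tuple[int, int]:
    ident = simil = 0
    for a, b in zip(aq, asub):
        if a == "-" or b == "-":
            continue
        if a == b:
            ident += 1
        if matrix.score(a, b) > 0:
            simil += 1
    return ident, simil


def _expand(alignment, query: str, subject: str) -> Tuple[str, str, Tuple[int, int], Tuple[int, int]]:
    """Gapped strings plus 1-based inclusive spans from a biopython alignment."""
    tcoords, qcoords = alignment.coordinates  # target rows = query here
    aq, asub = [], []
    for i in range(len(tcoords) - 1):
        t0, t1 = tcoords[i], tcoords[i + 1]
        q0, q1 = qcoords[i], qcoords[i + 1]
        if t1 > t0 and q1 > q0:
            aq.append(query[t0:t1])
            asub.append(subject[q0:q1])
        elif t1 > t0:
            aq.append(query[t0:t1])
            asub.append("-" * (t1 - t0))
        else:
            aq.append("-" * (q1 - q0))
            asub.append(subject[q0:q1])
    qspan = (int(tcoords[0]) + 1, int(tcoords[-1]))
    sspan = (int(qcoords[0]) + 1, int(qcoords[-1]))
    return "".join(aq), "".join(asub), qspan, sspan


def _empty_result(query: SequenceRecord, subject: SequenceRecord,
                  mode: str) -> AlignmentResult:
    return AlignmentResult(
        query_id=query.id, subject_id=subject.id, raw_score=0.0,
        aligned_query="", aligned_subject="", query_span=None,
        subject_span=None, identity_pct=0.0, similarity_pct=0.0,
        query_coverage_pct=0.0, mode=mode,
    )


def _make_aligner(matrix: ScoringMatrix, gap_open: float, gap_extend: float,
                  mode: str, end_gaps_penalized: bool = True) -> Align.PairwiseAligner:
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _bio_matrix(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    if mode == "global" and not end_gaps_penalized:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def smith_waterman(query: SequenceRecord, subject: SequenceRecord,
                   matrix: ScoringMatrix, gap_open: float = 11,
                   gap_extend: float = 1) -> AlignmentResult:
    """Optimal local alignment under affine gaps.

    Returns an empty result (score 0, no spans) when no segment pair scores
    positively — such comparisons carry no reportable hit.
    """
    if not query.residues or not subject.residues:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend, "local")
    score = aligner.score(query.residues, subject.residues)
    if score <= 0:
        return _empty_result(query, subject, "local")
    alignment = aligner.align(query.residues, subject.residues)[0]
    aq, asub, qspan, sspan = _expand(alignment, query.residues, subject.residues)
    length = len(aq)
    ident, simil = _column_stats(aq, asub, matrix)
    coverage = (qspan[1] - qspan[0] + 1) / len(query) * 100.0
    return AlignmentResult(
        query_id=query.id, subject_id=subject.id, raw_score=float(score),
        aligned_query=aq, aligned_subject=asub, query_span=qspan,
        subject_span=sspan,
        identity_pct=ident / length * 100.0,
        similarity_pct=simil / length * 100.0,
        query_coverage_pct=coverage, mode="local",
    )


def needle_global(query: SequenceRecord, subject: SequenceRecord,
                  matrix: ScoringMatrix, gap_open: float = 10,
                  gap_extend: float = 0.5,
                  end_gaps_penalized: bool = False) -> AlignmentResult:
    """Global alignment with EMBOSS Needle's defaults (open 10, extend 0.5,
    end gaps unpenalized) for whole-protein identity/similarity figures."""
    if not query.residues or not subject.residues:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend, "global",
                            end_gaps_penalized=end_gaps_penalized)
    alignment = aligner.align(query.residues, subject.residues)[0]
    aq, asub, qspan, sspan = _expand(alignment, query.residues, subject.residues)
    length = len(aq)
    ident, simil = _column_stats(aq, asub, matrix)
    return AlignmentResult(
        query_id=query.id, subject_id=subject.id,
        raw_score=float(alignment.score),
        aligned_query=aq, aligned_subject=asub, query_span=qspan,
        subject_span=sspan,
        identity_pct=ident / length * 100.0,
        similarity_pct=simil / length * 100.0,
        query_coverage_pct=100.0, mode="global",
    )
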
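"""Query-vs-proteome ranking, filter regimes and reciprocal-best-hit calls.

Three filter regimes mirror the ortholog-search modes used for cryptic,
fast-evolving families:

``strict``
    coverage ≥ 50% and score ≥ 50 (the InParanoid-style cut-off, modeled as
    a plain filter — no in-paralog clustering).
``relaxed``
    score ≥ 30 and E ≤ 0.01, no coverage floor.
``fungal``
    BLOSUM45, score ≥ 30, E ≤ 0.01, with confidence tiers by query
    coverage: ≥ 20% high, ≥ 10% medium.

Coverage is the span of the best single local alignment on the query as a
percentage of query length.  An ortholog call requires the forward best hit
to pass its regime's filters and the reverse search of that hit against the
query's own proteome to return the original query as best hit (best-hit
identity only; no tier requirement on the reverse direction).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, List, Optional, Tuple

from .align import AlignmentResult, smith_waterman
from .kastats import (KarlinAltschulParams, bit_score, composition_frequencies,
                      evalue, karlin_altschul_params)
from .matrices import ScoringMatrix, load_builtin
from .seqio import Proteome, SequenceRecord

TIER_ORDER = {"high": 0, "medium": 1, "reject": 2}


@dataclass(frozen=True)
class SearchConfig:
    """Thresholds and scoring parameters for one search regime."""

    mode: str
    matrix_name: str = "BLOSUM62"
    min_score: float = 30.0
    max_evalue: Optional[float] = 0.01
    min_coverage: Optional[float] = None     # hard floor (strict regime)
    coverage_high: Optional[float] = None    # tier thresholds (fungal regime)
    coverage_medium: Optional[float] = None
    gap_open: float = 11.0
    gap_extend: float = 1.0

    @classmethod
    def strict(cls) -> "SearchConfig":
        return cls(mode="strict", matrix_name="BLOSUM62", min_score=50.0,
                   max_evalue=None, min_coverage=50.0,
                   gap_open=11.0, gap_extend=1.0)

    @classmethod
    def relaxed(cls) -> "SearchConfig":
        return cls(mode="relaxed", matrix_name="BLOSUM62", min_score=30.0,
                   max_evalue=0.01, gap_open=11.0, gap_extend=1.0)

    @classmethod
    def fungal(cls) -> "SearchConfig":
        return cls(mode="fungal", matrix_name="BLOSUM45", min_score=30.0,
                   max_evalue=0.01, coverage_high=20.0, coverage_medium=10.0,
                   gap_open=14.0, gap_extend=2.0)

    @classmethod
    def by_name(cls, mode: str, **overrides) -> "SearchConfig":
        base = {"strict": cls.strict, "relaxed": cls.relaxed,
                "fungal": cls.fungal}[mode]()
        return replace(base, **overrides) if overrides else base

    def matrix(self) -> ScoringMatrix:
        return load_builtin(self.matrix_name)


@dataclass
class Hit:
    """One filtered alignment against a subject proteome."""

    result: AlignmentResult
    subject_species: str
    tier: str  # high | medium | reject
    passed_score: bool
    passed_evalue: bool
    passed_coverage: bool

    @property
    def subject_id(self) -> str:
        return self.result.subject_id

    def accepted(self) -> bool:
        return self.tier != "reject"


@dataclass
class OrthologCall:
    """An accepted, reciprocally verified ortholog."""

    query_id: str
    subject_id: str
    query_species: str
    subject_species: str
    forward: Hit
    reciprocal: bool
    confidence: str                      # high | medium
    methods: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.reciprocal:
            raise ValueError("ortholog calls require reciprocal verification")


def proteome_params(matrix: ScoringMatrix, proteome: Proteome) -> KarlinAltschulParams:
    """Karlin–Altschul parameters for one subject proteome, with the
    composition estimated from that proteome.  Cached on the proteome
    instance (keyed by matrix name) so the cache dies with the object."""
    cache = proteome.__dict__.setdefault("_ka_params", {})
    if matrix.name not in cache:
        freqs = composition_frequencies(proteome.records)
        cache[matrix.name] = karlin_altschul_params(matrix, freqs)
    return cache[matrix.name]


def _assign_tier(res: AlignmentResult, config: SearchConfig) -> Tuple[str, bool, bool, bool]:
    ok_score = res.raw_score >= config.min_score
    ok_e = (config.max_evalue is None
            or (res.evalue is not None and res.evalue <= config.max_evalue))
    cov = res.query_coverage_pct
    if config.min_coverage is not None:
        ok_cov = cov >= config.min_coverage
        tier = "high" if (ok_score and ok_e and ok_cov) else "reject"
    elif config.coverage_high is not None:
        if ok_score and ok_e and cov >= config.coverage_high:
            tier, ok_cov = "high", True
        elif ok_score and ok_e and cov >= (config.coverage_medium or 0.0):
            tier, ok_cov = "medium", True
        else:
            tier, ok_cov = "reject", cov >= (config.coverage_medium or 0.0)
    else:
        ok_cov = True
        tier = "high" if (ok_score and ok_e) else "reject"
    return tier, ok_score, ok_e, ok_cov


def _rank_key(h: Hit):
    # score desc, E-value asc, subject id asc — the fixed tie-break chain.
    ev = h.result.evalue if h.result.evalue is not None else 0.0
    return (-h.result.raw_score, ev, h.subject_id)


def search_proteome(query: SequenceRecord, proteome: Proteome,
                    config: SearchConfig) -> List[Hit]:
    """Align the query against every subject and return ranked, filtered hits.

    Self-hits (identical record id) are excluded; hits are sorted by
    (raw score desc, E-value asc, subject id asc) and carry a tier.
    """
    if len(proteome) == 0:
        raise ValueError(f"proteome {proteome.species!r} is empty")
    matrix = config.matrix()
    params = proteome_params(matrix, proteome)
    n = proteome.total_residues
    hits: List[Hit] = []
    for subject in proteome:
        if subject.id == query.id:
            continue
        res = smith_waterman(query, subject, matrix,
                             gap_open=config.gap_open,
                             gap_extend=config.gap_extend)
        res.evalue = evalue(res.raw_score, len(query), n, params)
        res.bit_score = bit_score(res.raw_score, params)
        tier, oks, oke, okc = _assign_tier(res, config)
        hits.append(Hit(result=res, subject_species=proteome.species,
                        tier=tier, passed_score=oks, passed_evalue=oke,
                        passed_coverage=okc))
    hits.sort(key=_rank_key)
    return hits


def best_hit(hits: List[Hit]) -> Optional[Hit]:
    """First non-rejected hit of a ranked list, or None."""
    for h in hits:
        if h.accepted():
            return h
    return None


def reciprocal_best_hit(query: SequenceRecord, target: Proteome,
                        source: Proteome,
                        config: SearchConfig) -> Optional[OrthologCall]:
    """Forward best hit plus reverse best-hit verification.

    The reverse search runs under the same config but only the best-hit
    *identity* matters: the top-ranked subject of the reverse search (no
    filters applied) must be the original query.
    """
    forward = best_hit(search_proteome(query, target, config))
    if forward is None:
        return None
    candidate = target.get(forward.subject_id)
    reverse = search_proteome(candidate, source, config)
    if not reverse or reverse[0].subject_id != query.id:
        return None
    confidence = forward.tier  # high for strict/relaxed; tiered for fungal
    return OrthologCall(
        query_id=query.id, subject_id=candidate.id,
        query_species=query.species, subject_species=target.species,
        forward=forward, reciprocal=True, confidence=confidence,
        methods=frozenset({config.mode}),
    )


@dataclass
class MergeResult:
    """Outcome of combining the strict and relaxed search methods."""

    confidence: Optional[str]            # high | medium | None
    methods: FrozenSet[str]
    conflict: Optional[Tuple[str, str]] = None


def merge_method_calls(strict_call: Optional[OrthologCall],
                       relaxed_call: Optional[OrthologCall]) -> MergeResult:
    """Both methods agree → high confidence; one alone → medium.

    If both methods name different subjects the pair is flagged as a
    conflict and no call is made.
    """
    if strict_call is None and relaxed_call is None:
        return MergeResult(confidence=None, methods=frozenset())
    if strict_call is not None and relaxed_call is not None:
        if strict_call.subject_id != relaxed_call.subject_id:
            return MergeResult(
                confidence=None, methods=frozenset({"strict", "relaxed"}),
                conflict=(strict_call.subject_id, relaxed_call.subject_id))
        return MergeResult(confidence="high",
                           methods=frozenset({"strict", "relaxed"}))
    present = strict_call if strict_call is not None else relaxed_call
    return MergeResult(confidence="medium", methods=present.methods)
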
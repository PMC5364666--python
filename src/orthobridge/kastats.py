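"""Karlin–Altschul statistics for ungapped local alignment scores.

For a scoring system with negative expected score and at least one positive
score, the number of chance local alignments scoring at least S in an
m-by-n comparison follows E = K·m·n·exp(−λS).  λ is the unique positive
root of Σᵢⱼ pᵢpⱼ·exp(λ·sᵢⱼ) = 1; K comes from the standard series
approximation over the lattice of attainable scores.  The bit score is
(λS − ln K)/ln 2.

These parameters are computed for the ungapped system; the search layer
applies them to affine-gapped DP scores, which makes reported E-values
conservative (smaller than a gapped calibration would give) — a documented
divergence from heuristic BLAST statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
from scipy.optimize import brentq

from .matrices import ScoringMatrix
from .seqio import SequenceRecord

#: Robinson & Robinson (1991) amino-acid background frequencies, the
#: standard BLAST composition table.
ROBINSON_FREQS: Dict[str, float] = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


class StatisticsError(ValueError):
    """Raised when the scoring system admits no finite statistics."""


@dataclass(frozen=True)
class KarlinAltschulParams:
    lam: float
    K: float
    H: float
    background_freqs: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        total = sum(self.background_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")


def composition_frequencies(records: Iterable[SequenceRecord],
                            pseudocount: float = 1.0) -> Dict[str, float]:
    """Residue frequencies estimated from sequences (X excluded), with a
    pseudocount so every canonical residue keeps positive probability on
    small synthetic proteomes."""
    counts = {aa: pseudocount for aa in ROBINSON_FREQS}
    for rec in records:
        for ch in rec.residues:
            if ch in counts:
                counts[ch] += 1
    total = sum(counts.values())
    return {aa: c / total for aa, c in counts.items()}


def _score_distribution(matrix: ScoringMatrix, freqs: Mapping[str, float]):
    """Probability of each integer score for a random aligned residue pair."""
    letters = [aa for aa in freqs if freqs[aa] > 0]
    probs: Dict[int, float] = {}
    for a in letters:
        for b in letters:
            s = int(matrix.score(a, b))
            probs[s] = probs.get(s, 0.0) + freqs[a] * freqs[b]
    return probs


def karlin_altschul_params(matrix: ScoringMatrix,
                           freqs: Optional[Mapping[str, float]] = None,
                           n_terms: int = 60) -> KarlinAltschulParams:
    """Solve for λ, K and the relative entropy H of the scoring system.

    ``freqs`` defaults to the Robinson–Robinson table.  Raises
    :class:`StatisticsError` when the expected pair score is non-negative or
    no pair scores positively (no finite statistics exist).
    """
    if freqs is None:
        freqs = ROBINSON_FREQS
    total = sum(freqs.values())
    freqs = {a: p / total for a, p in freqs.items()}
    dist = _score_distribution(matrix, freqs)
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    expected = float(np.dot(scores, probs))
    if expected >= 0 or scores[-1] <= 0:
        raise StatisticsError(
            "matrix/composition yields no finite statistics "
            f"(expected score {expected:.4f}, max score {scores[-1]})"
        )

    def f(lam: float) -> float:
        return float(np.sum(probs * np.exp(lam * scores)) - 1.0)

    # f(0)=0, f'(0)=expected<0, f(∞)=+∞ → unique positive root.
    hi = 0.5
    while f(hi) < 0:
        hi *= 2.0
    lam = brentq(f, 1e-9, hi, xtol=1e-14, rtol=8.9e-16)

    # Relative entropy of the induced (aligned) pair distribution.
    H = float(lam * np.sum(scores * probs * np.exp(lam * scores)))

    # K by the Karlin–Altschul series over the score lattice:
    #   σ = Σ_{k≥1} (1/k)·( E[e^{λ S_k}; S_k<0] + P(S_k ≥ 0) )
    #   K = d·λ·e^{−2σ} / ( H·(1 − e^{−λd}) )
    d = 0
    for s in scores[probs > 0]:
        d = math.gcd(d, abs(int(s)))
    d = max(d, 1)
    lo, hi_s = int(scores[0]), int(scores[-1])
    offset = -lo  # index 0 ↔ score lo for one step
    step = np.zeros(hi_s - lo + 1)
    for s, p in zip(scores, probs):
        step[int(s) - lo] = p
    sigma = 0.0
    conv = step.copy()
    for k in range(1, n_terms + 1):
        s_vals = np.arange(len(conv)) - k * offset
        neg = s_vals < 0
        term = float(np.sum(conv[neg] * np.exp(lam * s_vals[neg])) + np.sum(conv[~neg]))
        sigma += term / k
        if k < n_terms:
            conv = np.convolve(conv, step)
    K = d * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * d)))
    return KarlinAltschulParams(lam=lam, K=K, H=H, background_freqs=dict(freqs))


def evalue(raw_score: float, query_len: int, db_residues: int,
           params: KarlinAltschulParams) -> float:
    """Expected number of chance hits scoring ≥ raw_score: K·m·n·e^(−λS)."""
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("lengths must be positive")
    return params.K * query_len * db_residues * math.exp(-params.lam * raw_score)


def bit_score(raw_score: float, params: KarlinAltschulParams) -> float:
    """Normalized score in bits: (λS − ln K)/ln 2."""
    return (params.lam * raw_score - math.log(params.K)) / math.log(2.0)
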
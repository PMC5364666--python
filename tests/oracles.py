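"""Independent reference implementations used only as test oracles.

Deliberately written from first principles (plain-Python Gotoh DP, grid
root scans, regex motif search, BFS reachability) so they share no code
path with the package implementations they check.
"""

from __future__ import annotations

import re
from typing import Dict, List, Sequence, Tuple

NEG = float("-inf")


def gotoh_local_score(a: str, b: str, score, gap_open: float,
                      gap_extend: float) -> float:
    """Best local alignment score, affine gaps (open+extend on first gap
    residue), by the three-state Gotoh recurrence with a zero floor."""
    n, m = len(a), len(b)
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (up)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (left)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                          X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                          Y[i][j - 1] - gap_extend)
            diag = M[i - 1][j - 1] + score(a[i - 1], b[j - 1])
            M[i][j] = max(0.0, diag, X[i][j], Y[i][j])
            best = max(best, M[i][j])
    return best


def gotoh_global_score(a: str, b: str, score, gap_open: float,
                       gap_extend: float, end_gaps_penalized: bool) -> float:
    """Optimal global alignment score under the same affine model."""
    n, m = len(a), len(b)
    gap = lambda k: gap_open + k * gap_extend if k else 0.0
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap(i) if end_gaps_penalized else 0.0
    for j in range(1, m + 1):
        Y[0][j] = -gap(j) if end_gaps_penalized else 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            open_from = max(M[i - 1][j], Y[i - 1][j])
            X[i][j] = max(open_from - gap_open - gap_extend,
                          X[i - 1][j] - gap_extend)
            open_from = max(M[i][j - 1], X[i][j - 1])
            Y[i][j] = max(open_from - gap_open - gap_extend,
                          Y[i][j - 1] - gap_extend)
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + score(a[i - 1], b[j - 1])
    if end_gaps_penalized:
        return max(M[n][m], X[n][m], Y[n][m])
    # free end gaps: best over last row/column of match-ending states
    best = NEG
    for i in range(1, n + 1):
        best = max(best, M[i][m], Y[i][m])
    for j in range(1, m + 1):
        best = max(best, M[n][j], X[n][j])
    return best


def grid_pi(net_charge, residues: str, table: str, step: float = 1e-3) -> float:
    """Brute-force pI: finest pH grid point where net charge changes sign."""
    prev_ph, prev_q = 0.0, net_charge(residues, 0.0, table)
    ph = step
    while ph <= 14.0:
        q = net_charge(residues, ph, table)
        if prev_q > 0 >= q:
            return (prev_ph + ph) / 2.0
        prev_ph, prev_q = ph, q
        ph += step
    raise AssertionError("no zero crossing on [0, 14]")


def regex_motif_anchors(residues: str, pattern: str) -> List[int]:
    """1-based anchors of (overlapping) motif matches via a regex lookahead."""
    rx = []
    for cls, single in re.findall(r"\[([A-Z]+)\]|([A-Zx])", pattern):
        if cls:
            rx.append(f"[{cls}]")
        elif single == "x":
            rx.append(".")
        else:
            rx.append(single)
    compiled = re.compile("(?=" + "".join(rx) + ")")
    return [m.start() + 1 for m in compiled.finditer(residues)]


def bfs_reachable(edges: Dict[str, List[str]], start: str) -> Dict[str, int]:
    """BFS over a directed graph; returns node → hop distance from start."""
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in edges.get(u, []):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def leaf_path_lengths(newick_dists, species: str,
                      others: Sequence[str]) -> List[Tuple[float, str]]:
    """Sorted (distance, tag) pairs from an externally supplied pairwise
    distance function — used to cross-check tree neighbor ordering."""
    return sorted((newick_dists(species, o), o) for o in others)
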
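"""Substitution matrices: NCBI-format parsing and the shipped BLOSUM tables.

BLOSUM45 suits diverged sequences (the fungal search regime); BLOSUM62 is
the general-purpose default used for global identity/similarity figures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Tuple


class MatrixFormatError(ValueError):
    """Raised for asymmetric, incomplete or malformed matrix files."""


@dataclass
class ScoringMatrix:
    """A symmetric residue-pair score table over a declared alphabet."""

    name: str
    alphabet: str
    scores: Dict[Tuple[str, str], int] = field(repr=False)

    def __post_init__(self) -> None:
        for a in self.alphabet:
            for b in self.alphabet:
                if (a, b) not in self.scores:
                    raise MatrixFormatError(
                        f"{self.name}: missing score for pair ({a},{b})"
                    )
                if self.scores[(a, b)] != self.scores[(b, a)]:
                    raise MatrixFormatError(
                        f"{self.name}: asymmetric scores for ({a},{b})"
                    )

    def score(self, a: str, b: str) -> int:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise KeyError(f"{self.name}: residue pair ({a},{b}) not in alphabet")

    def __call__(self, a: str, b: str) -> int:
        return self.score(a, b)

    def max_score(self) -> int:
        return max(self.scores.values())

    def min_score(self) -> int:
        return min(self.scores.values())

    def to_biopython(self):
        """Export as a ``Bio.Align.substitution_matrices.Array``."""
        import numpy as np
        from Bio.Align import substitution_matrices

        arr = substitution_matrices.Array(self.alphabet, dims=2, dtype=float)
        for a in self.alphabet:
            for b in self.alphabet:
                arr[a, b] = self.scores[(a, b)]
        return arr


def parse_matrix(text: str, name: str = "matrix") -> ScoringMatrix:
    """Parse NCBI-format substitution matrix text.

    Lines starting with ``#`` are comments; the first non-comment line lists
    the column alphabet; each following line starts with its row residue.
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise MatrixFormatError(f"{name}: no matrix content")
    columns = lines[0].split()
    if any(len(c) != 1 for c in columns):
        raise MatrixFormatError(f"{name}: malformed alphabet line")
    scores: Dict[Tuple[str, str], int] = {}
    rows = []
    for ln in lines[1:]:
        parts = ln.split()
        row = parts[0]
        if len(row) != 1:
            raise MatrixFormatError(f"{name}: malformed row label {row!r}")
        vals = parts[1:]
        if len(vals) != len(columns):
            raise MatrixFormatError(
                f"{name}: row {row!r} has {len(vals)} values, expected {len(columns)}"
            )
        rows.append(row)
        for col, v in zip(columns, vals):
            scores[(row, col)] = int(v)
    if sorted(rows) != sorted(columns):
        raise MatrixFormatError(f"{name}: row and column alphabets differ")
    alphabet = "".join(columns)
    return ScoringMatrix(name=name, alphabet=alphabet, scores=scores)


def read_matrix(path: os.PathLike | str, name: str | None = None) -> ScoringMatrix:
    """Read an NCBI-format matrix file from disk."""
    path = str(path)
    with open(path) as fh:
        text = fh.read()
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    return parse_matrix(text, name=name)


_BUILTIN_CACHE: Dict[str, ScoringMatrix] = {}


def load_builtin(name: str) -> ScoringMatrix:
    """Load a matrix shipped with the package (``BLOSUM45`` or ``BLOSUM62``).

    Instances are memoized, so repeated lookups share one object."""
    name = name.upper()
    if name not in _BUILTIN_CACHE:
        try:
            text = (resources.files("orthobridge") / "data"
                    / f"{name}.txt").read_text()
        except FileNotFoundError:
            raise KeyError(f"no built-in matrix named {name!r}")
        _BUILTIN_CACHE[name] = parse_matrix(text, name=name)
    return _BUILTIN_CACHE[name]
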
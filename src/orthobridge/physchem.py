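"""Physicochemical corroboration battery for candidate orthologs.

Fast-evolving, intrinsically disordered proteins can retain a recognizable
fingerprint even when sequence identity has decayed below direct-search
range: a high charged-residue fraction, a low isoelectric point, PEST
proteolytic signals and short conserved interaction motifs.  This module
computes that battery: charged fraction, Henderson–Hasselbalch isoelectric
point, average molecular mass, PEST-FIND-style region scoring, motif
scanning and per-column motif conservation on a supplied MSA.

All coordinates are 1-based inclusive.  ``X`` residues are excluded from
every compositional denominator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Optional, Sequence, Set, Tuple

from Bio import AlignIO

from .seqio import SequenceRecord

# -- residue tables -------------------------------------------------------

#: Average residue masses (Da), i.e. amino acid minus water.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "Q": 128.1307, "E": 129.1155, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: Kyte–Doolittle hydropathy.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: pKa tables for the Henderson–Hasselbalch net-charge model.  The
#: Bjellqvist table (the one common pI servers use) carries residue-specific
#: terminal pKas; EMBOSS and Lehninger are selectable alternatives.
PKA_TABLES: Dict[str, Dict] = {
    "bjellqvist": {
        "positive": {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
        "negative": {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
        "nterm_by_residue": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
                             "T": 6.82, "V": 7.44, "E": 7.7},
        "cterm_by_residue": {"D": 4.55, "E": 4.75},
    },
    "emboss": {
        "positive": {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5},
        "negative": {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
        "nterm_by_residue": {},
        "cterm_by_residue": {},
    },
    "lehninger": {
        "positive": {"Nterm": 9.69, "K": 10.53, "R": 12.48, "H": 6.0},
        "negative": {"Cterm": 2.34, "D": 3.86, "E": 4.25, "C": 8.33, "Y": 10.07},
        "nterm_by_residue": {},
        "cterm_by_residue": {},
    },
}

DEFAULT_CHARGED_SET = frozenset("DEKRH")


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# -- composition ----------------------------------------------------------

def charged_fraction(seq: SequenceRecord | str,
                     charged_set: Set[str] = DEFAULT_CHARGED_SET) -> float:
    """Percentage of (non-X) residues in ``charged_set``.

    Default set {D,E,K,R,H}: both acidic residues and the three basic ones.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    known = [r for r in residues if r != "X"]
    if not known:
        raise ValueError("sequence has no known residues")
    n = sum(1 for r in known if r in charged_set)
    return n / len(known) * 100.0


def molecular_mass(seq: SequenceRecord | str) -> float:
    """Average molecular mass in kDa (residue masses plus one water)."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    total = WATER_MASS + sum(RESIDUE_MASS[r] for r in residues if r != "X")
    return total / 1000.0


# -- isoelectric point ----------------------------------------------------

def net_charge(residues: str, pH: float, pka_table: str = "bjellqvist") -> float:
    """Henderson–Hasselbalch net charge at ``pH`` (termini + side chains)."""
    table = PKA_TABLES[pka_table]
    known = [r for r in residues if r != "X"]
    if not known:
        raise ValueError("sequence has no known residues")
    pos = dict(table["positive"])
    neg = dict(table["negative"])
    nterm_pka = table["nterm_by_residue"].get(known[0], pos["Nterm"])
    cterm_pka = table["cterm_by_residue"].get(known[-1], neg["Cterm"])

    charge = 1.0 / (1.0 + 10.0 ** (pH - nterm_pka))
    charge -= 1.0 / (1.0 + 10.0 ** (cterm_pka - pH))
    for aa in "KRH":
        n = known.count(aa)
        if n:
            charge += n / (1.0 + 10.0 ** (pH - pos[aa]))
    for aa in "DECY":
        n = known.count(aa)
        if n:
            charge -= n / (1.0 + 10.0 ** (neg[aa] - pH))
    return charge


def isoelectric_point(seq: SequenceRecord | str,
                      pka_table: str = "bjellqvist",
                      tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so the root is unique; it is
    defined for any sequence because the termini always ionize.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(residues, mid, pka_table) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# -- PEST regions ---------------------------------------------------------

@dataclass(frozen=True)
class PESTRegion:
    """A PEST candidate: a DEPST-rich stretch flanked by K/R/H or termini.

    ``start``/``end`` are 1-based inclusive coordinates of the stretch
    itself (no positive residue lies strictly inside); ``flanks`` gives the
    flanking positive residues, with ``^``/``$`` marking sequence termini.
    """

    start: int
    end: int
    score: float
    flanks: Tuple[str, str]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def pest_score(residues: str) -> float:
    """PEST-FIND score of a candidate stretch.

    0.55 × (mass-weighted mole % of D,E,P,S,T) − 0.5 × (mass-weighted
    hydrophobicity index), where Kyte–Doolittle hydropathies are rescaled
    linearly to 0–90 (hv = 10·KD + 45).  Scores range from −45 (purely
    hydrophobic, no DEPST) to +50 (pure aspartate); scores above the
    conventional +16 threshold mark strong proteolytic signals.
    """
    known = [r for r in residues if r != "X"]
    if not known:
        raise ValueError("region has no known residues")
    total_mass = sum(RESIDUE_MASS[r] for r in known)
    depst_mass = sum(RESIDUE_MASS[r] for r in known if r in "DEPST")
    depst_pct = 100.0 * depst_mass / total_mass
    hydro = sum(RESIDUE_MASS[r] * (10.0 * KYTE_DOOLITTLE[r] + 45.0)
                for r in known) / total_mass
    return 0.55 * depst_pct - 0.5 * hydro


def find_pest_regions(seq: SequenceRecord | str, min_length: int = 12,
                      min_score: Optional[float] = None) -> List[PESTRegion]:
    """All valid PEST candidates, sorted by start position.

    Candidates are maximal stretches of at least ``min_length`` residues
    bounded by K/R/H (or the sequence termini) that contain at least one P,
    one D or E, and one S or T.  ``min_score`` optionally filters by score
    (the conventional strong-signal cut is +16).
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    regions: List[PESTRegion] = []
    n = len(residues)
    boundaries = [i for i, r in enumerate(residues) if r in "KRH"]
    edges = [-1] + boundaries + [n]
    for left, right in zip(edges, edges[1:]):
        start, end = left + 1, right - 1  # 0-based inner stretch
        length = end - start + 1
        if length < min_length:
            continue
        stretch = residues[start:end + 1]
        if not (any(c == "P" for c in stretch)
                and any(c in "DE" for c in stretch)
                and any(c in "ST" for c in stretch)):
            continue
        score = pest_score(stretch)
        if min_score is not None and score < min_score:
            continue
        left_flank = residues[left] if left >= 0 else "^"
        right_flank = residues[right] if right < n else "$"
        regions.append(PESTRegion(start=start + 1, end=end + 1,
                                  score=round(score, 2),
                                  flanks=(left_flank, right_flank)))
    return regions


# -- motifs ---------------------------------------------------------------

@dataclass(frozen=True)
class MotifPattern:
    """A fixed-length motif of positional residue classes.

    Built from strings like ``"RxxxRxx[RK]"``: ``x`` is unconstrained, a
    plain letter constrains a position to that residue, and ``[..]`` lists
    an allowed class.
    """

    name: str
    length: int
    constraints: Tuple[Tuple[int, frozenset], ...]  # (0-based offset, allowed)

    @classmethod
    def from_string(cls, pattern: str, name: Optional[str] = None) -> "MotifPattern":
        tokens = re.findall(r"\[([A-Z]+)\]|([A-Zx])", pattern)
        constraints = []
        for offset, (cls_tok, single) in enumerate(tokens):
            if cls_tok:
                constraints.append((offset, frozenset(cls_tok)))
            elif single != "x":
                constraints.append((offset, frozenset(single)))
        if not constraints:
            raise ValueError("pattern must constrain at least one position")
        return cls(name=name or pattern, length=len(tokens),
                   constraints=tuple(constraints))

    def constrained_offsets(self) -> List[int]:
        return [off for off, _ in self.constraints]


def motif_scan(seq: SequenceRecord | str, pattern: MotifPattern) -> List[int]:
    """1-based anchor positions of every (possibly overlapping) match."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if pattern.length > len(residues):
        raise ValueError("pattern longer than sequence")
    anchors = []
    for start in range(len(residues) - pattern.length + 1):
        if all(residues[start + off] in allowed
               for off, allowed in pattern.constraints):
            anchors.append(start + 1)
    return anchors


# -- MSA conservation -----------------------------------------------------

def read_msa(path, fmt: Optional[str] = None):
    """Read an MSA in aligned-FASTA or Clustal format."""
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    return AlignIO.read(str(path), fmt)


def motif_conservation(msa, reference_id: str,
                       reference_positions: Sequence[int],
                       allowed: Optional[Sequence[Set[str]]] = None
                       ) -> Dict[int, float]:
    """Conservation of reference positions across an alignment.

    Each 1-based ungapped position of the reference row is mapped to its
    alignment column; the returned percentage counts sequences carrying an
    allowed residue at that column among sequences with a non-gap residue
    there.  ``allowed`` defaults to the reference residue itself.
    """
    rows = {rec.id: str(rec.seq).upper() for rec in msa}
    if reference_id not in rows:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    ref_row = rows[reference_id]
    # ungapped position (1-based) → column index
    col_of: Dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ref_row):
        if ch != "-":
            pos += 1
            col_of[pos] = col
    if allowed is None:
        allowed = [None] * len(reference_positions)
    out: Dict[int, float] = {}
    for p, cls in zip(reference_positions, allowed):
        if p not in col_of:
            raise ValueError(
                f"reference position {p} outside the ungapped reference row")
        col = col_of[p]
        cls = cls or {ref_row[col]}
        with_residue = [row[col] for row in rows.values() if row[col] != "-"]
        if not with_residue:
            out[p] = 0.0
            continue
        match = sum(1 for ch in with_residue if ch in cls)
        out[p] = _round1(match / len(with_residue) * 100.0)
    return out


# -- bundled profile ------------------------------------------------------

@dataclass
class PhyschemProfile:
    """Per-protein fingerprint used to corroborate a candidate ortholog."""

    protein_id: str
    length: int
    charged_fraction_pct: float
    isoelectric_point: float
    molecular_mass_kDa: float
    pest_regions: List[PESTRegion] = field(default_factory=list)
    motif_hits: List[Tuple[str, int]] = field(default_factory=list)


def physchem_profile(seq: SequenceRecord,
                     charged_set: Set[str] = DEFAULT_CHARGED_SET,
                     pka_table: str = "bjellqvist",
                     pest_min_score: Optional[float] = None,
                     motifs: Sequence[MotifPattern] = ()) -> PhyschemProfile:
    """Compute the full battery for one protein (values half-up rounded to
    one decimal, PEST scores to two)."""
    hits = []
    for pat in motifs:
        if pat.length <= len(seq):
            hits.extend((pat.name, a) for a in motif_scan(seq, pat))
    return PhyschemProfile(
        protein_id=seq.id,
        length=len(seq),
        charged_fraction_pct=_round1(charged_fraction(seq, charged_set)),
        isoelectric_point=_round1(isoelectric_point(seq, pka_table)),
        molecular_mass_kDa=_round1(molecular_mass(seq)),
        pest_regions=find_pest_regions(seq, min_score=pest_min_score),
        motif_hits=hits,
    )
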
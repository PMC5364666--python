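"""Phylogeny-guided stepwise ("bridging") ortholog search.

A fast-evolving family can be invisible to a direct query from a distant
species while remaining detectable from phylogenetic neighbors.  The walk
starts with reciprocal-best-hit (RBH) searches from the seed against every
species; each following round re-queries every still-absent species with
the orthologs already found in other species, trying present species in
order of increasing tree path distance (ties are all attempted and
recorded).  Rounds use a snapshot of the present set, so the walk is a
breadth-first search over the directed RBH-acceptance graph: the final
present set equals the set of species reachable from the seed, and each
recorded chain has minimal link count.  A species, once present, is never
overwritten; the walk reaches a fixed point in at most ``max_depth`` rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .search import Hit, OrthologCall, SearchConfig, reciprocal_best_hit
from .seqio import Proteome, SequenceRecord
from .taxtree import TaxonTree

#: A provenance chain: (species, protein id) from seed to final hit.
Chain = Tuple[Tuple[str, str], ...]


@dataclass
class SpeciesEntry:
    """Per-species outcome of a bridging walk."""

    species: str
    status: str                       # present | absent
    protein_id: Optional[str] = None
    tier: Optional[str] = None        # confidence of the final link
    chain: Chain = ()
    link_hits: Tuple[Hit, ...] = ()
    found_by: Dict[str, str] = field(default_factory=dict)  # query id → protein id

    @property
    def chain_length(self) -> int:
        """Number of links (accepted calls) from seed to this species."""
        return max(len(self.chain) - 1, 0)

    @property
    def n_queries(self) -> int:
        return len(self.found_by)


@dataclass
class PhyleticProfile:
    """Presence/absence of the family across the species universe."""

    seed_id: str
    seed_species: str
    entries: Dict[str, SpeciesEntry]

    def present_species(self) -> List[str]:
        return [s for s, e in self.entries.items() if e.status == "present"]

    def absent_species(self) -> List[str]:
        return [s for s, e in self.entries.items() if e.status == "absent"]

    def __getitem__(self, species: str) -> SpeciesEntry:
        return self.entries[species]


def bridge_search(seed: SequenceRecord, universe: Mapping[str, Proteome],
                  tree: TaxonTree, config: SearchConfig,
                  max_depth: int = 5) -> PhyleticProfile:
    """Run the stepwise search from ``seed`` over ``universe``.

    ``max_depth`` bounds the chain length (number of links); round 0 (direct
    RBH from the seed) produces chains of one link.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be ≥ 1")
    if seed.species not in universe:
        raise ValueError(f"seed species {seed.species!r} not in universe")
    tree.validate_universe(universe.keys())

    species_order = sorted(universe)
    entries: Dict[str, SpeciesEntry] = {
        sp: SpeciesEntry(species=sp, status="absent") for sp in species_order
    }
    entries[seed.species] = SpeciesEntry(
        species=seed.species, status="present", protein_id=seed.id,
        tier="high", chain=((seed.species, seed.id),),
        found_by={seed.id: seed.id},
    )

    # One RBH per (query protein, target species); results never change.
    rbh_cache: Dict[Tuple[str, str], Optional[OrthologCall]] = {}

    def attempt(query: SequenceRecord, source_sp: str,
                target_sp: str) -> Optional[OrthologCall]:
        key = (query.id, target_sp)
        if key not in rbh_cache:
            rbh_cache[key] = reciprocal_best_hit(
                query, universe[target_sp], universe[source_sp], config)
        return rbh_cache[key]

    def accept(target_sp: str, source_entry: SpeciesEntry,
               call: OrthologCall) -> None:
        e = entries[target_sp]
        e.status = "present"
        e.protein_id = call.subject_id
        e.tier = call.confidence
        e.chain = source_entry.chain + ((target_sp, call.subject_id),)
        e.link_hits = source_entry.link_hits + (call.forward,)
        e.found_by[call.query_id] = call.subject_id

    # Round 0: direct RBH from the seed.
    seed_entry = entries[seed.species]
    for sp in species_order:
        if sp == seed.species:
            continue
        call = attempt(seed, seed.species, sp)
        if call is not None:
            accept(sp, seed_entry, call)

    # Bridging rounds: query absent species from present ones, nearest first.
    for _round in range(1, max_depth):
        present_snapshot = [sp for sp in species_order
                            if entries[sp].status == "present"]
        changed = False
        for sp in species_order:
            if entries[sp].status == "present":
                continue
            ranked = tree.neighbors_by_distance(sp, present_snapshot)
            accepted_dist: Optional[float] = None
            for dist, neighbor in ranked:
                if accepted_dist is not None and dist > accepted_dist:
                    break
                src = entries[neighbor]
                query = universe[neighbor].get(src.protein_id)
                call = attempt(query, neighbor, sp)
                if call is None:
                    continue
                if accepted_dist is None:
                    accept(sp, src, call)
                    accepted_dist = dist
                    changed = True
                else:
                    # tied-distance neighbor: record for consistency checks
                    entries[sp].found_by[call.query_id] = call.subject_id
        if not changed:
            break

    return PhyleticProfile(seed_id=seed.id, seed_species=seed.species,
                           entries=entries)


def combine_profiles(a: PhyleticProfile, b: PhyleticProfile) -> PhyleticProfile:
    """Union two walks (e.g. runs from two different seeds).

    Presence wins over absence; when both found a species, the shorter
    chain is kept and the found-by maps are merged, so disagreements
    between seeds remain visible to :func:`consistency_check`.
    """
    if set(a.entries) != set(b.entries):
        raise ValueError("profiles cover different species universes")
    merged: Dict[str, SpeciesEntry] = {}
    for sp in a.entries:
        ea, eb = a.entries[sp], b.entries[sp]
        if ea.status == "present" and eb.status == "present":
            keep = ea if ea.chain_length <= eb.chain_length else eb
        elif ea.status == "present":
            keep = ea
        else:
            keep = eb
        e = SpeciesEntry(species=sp, status=keep.status,
                         protein_id=keep.protein_id, tier=keep.tier,
                         chain=keep.chain, link_hits=keep.link_hits,
                         found_by={**ea.found_by, **eb.found_by})
        merged[sp] = e
    return PhyleticProfile(seed_id=f"{a.seed_id}+{b.seed_id}",
                           seed_species=a.seed_species, entries=merged)


def consistency_check(profile: PhyleticProfile) -> List[str]:
    """Species where different queries accepted different proteins.

    An empty list means every species was resolved to a single protein by
    all effective queries (vacuously true for single-query species).
    """
    conflicts = []
    for sp in sorted(profile.entries):
        ids = set(profile.entries[sp].found_by.values())
        if len(ids) > 1:
            conflicts.append(sp)
    return conflicts


def fraction_percent(found: int, analyzed: int) -> float:
    """found/analyzed as a percentage, half-up rounded to one decimal."""
    if analyzed <= 0:
        raise ValueError("analyzed must be positive")
    pct = Decimal(found * 100) / Decimal(analyzed)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CladeSummary:
    label: str
    found: int
    analyzed: int
    percent: float


def clade_summary(profile: PhyleticProfile, tree: TaxonTree,
                  clade_labels: Sequence[str]) -> List[CladeSummary]:
    """Per-clade found/analyzed counts in the Fig.-style bracket form."""
    out = []
    for label in clade_labels:
        leaves = tree.clade(label)  # KeyError for unknown labels
        analyzed = [sp for sp in profile.entries if sp in leaves]
        if not analyzed:
            raise ValueError(f"clade {label!r} contains no analyzed species")
        found = sum(1 for sp in analyzed
                    if profile.entries[sp].status == "present")
        out.append(CladeSummary(label=label, found=found,
                                analyzed=len(analyzed),
                                percent=fraction_percent(found, len(analyzed))))
    return out
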
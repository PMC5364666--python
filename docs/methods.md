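# Methods

## The problem and the overall procedure

Orthology between fast-evolving proteins can be invisible to direct
similarity search. Intrinsically disordered proteins that function through
short interaction motifs rather than a folded core are the extreme case:
with little constraint on most positions, pairwise identity between distant
orthologs decays to the level of unrelated sequences, and a query from one
end of the tree scores no better against its true ortholog than against
noise. `orthobridge` implements the strategy used to resolve such cases:

1. **Direct search.** Reciprocal-best-hit (RBH) searches of the seed
   protein against every proteome in the universe, under a configurable
   filter regime.
2. **Bridging.** For every species still lacking a hit, re-query with
   orthologs already accepted in other species, trying candidates in order
   of increasing tree path distance. Iterate to a fixed point. Because the
   intermediate species diverged less from the target clade than the seed
   did, their orthologs can cross a similarity gap the seed cannot.
3. **Corroboration.** Candidates found this way are, by construction, weak
   sequence matches; the physicochemical battery (charge, pI, mass, PEST
   signals, motif content/conservation) supplies orthogonal evidence that
   the endpoints are the same kind of protein.

The package assumes one protein per gene and per species (single-copy
family, no paralog handling), rooted species trees whose leaves are exactly
the searched species, and protein sequences over the 20 canonical residues
plus `X` (unknown; aligned using the matrix's X row, excluded from all
compositional denominators). All reported coordinates are 1-based
inclusive.

## Alignment and score statistics

Local (Smith–Waterman) and global (Needle-style) alignments use affine gap
costs: a gap of length *L* costs *open* + *L*·*extend*. Defaults follow the
common tool conventions for each matrix: BLOSUM62 regime open 11 / extend 1,
BLOSUM45 regime open 14 / extend 2, global alignment open 10 / extend 0.5
with end gaps free. Identity is identical columns over alignment length
(gaps included); similarity counts columns whose residue pair scores > 0.
The dynamic programming itself runs on biopython's `PairwiseAligner`; the
test suite checks it against an independently written plain-Python Gotoh
implementation.

Local scores get Karlin–Altschul statistics computed from the scoring
matrix and a residue composition: λ solves Σᵢⱼ pᵢpⱼ e^{λsᵢⱼ} = 1 (Brent
root-finding to machine precision; the ``+1/−1 over a uniform 4-letter
alphabet'' case, whose answer is analytically ln 3, is kept as a test),
and K follows the standard series approximation over the integer score
lattice (60 convolution terms; for BLOSUM62 with the Robinson–Robinson
composition this yields λ = 0.3176, K = 0.134, matching the published
ungapped values). Composition is estimated from the subject proteome with a
pseudocount of one per residue — on the small synthetic proteomes used here
a raw estimate would be unstable, and a degenerate composition can make the
expected score non-negative, where no finite statistics exist (reported as
an error).

**Deliberate divergence from heuristic search tools:** raw scores are exact
gapped DP scores, while λ and K are the ungapped parameters. Gapped λ is
smaller than ungapped λ, so the reported E-values are smaller than a gapped
calibration would give and the score/E thresholds are effectively more
permissive than the same numbers in a heuristic search engine. The
threshold regimes (score ≥ 30/50, E ≤ 0.01, coverage 10/20/50%) are
therefore ported as configuration, not claimed to be numerically identical
to their originals. Coverage is the span of the best single local alignment
on the query divided by query length; no multi-segment chaining.

## Search regimes and confidence

Three regimes: `strict` (coverage ≥ 50%, score ≥ 50 — the conservative
database-style cut-off, modeled as a plain filter without any in-paralog
clustering), `relaxed` (score ≥ 30, E ≤ 0.01, no coverage floor) and
`fungal` (BLOSUM45, score ≥ 30, E ≤ 0.01, coverage ≥ 20% high confidence /
≥ 10% medium). Ranking ties break by (score desc, E asc, subject id asc) —
a fixed, documented chain, since any choice here must simply be
deterministic. The reverse search of an RBH check imposes best-hit identity
only (no filters): the forward direction already gates the call. Calls made
by both the strict and relaxed methods merge to high confidence, one method
alone to medium; if the two methods name different subjects the pair is
flagged as a conflict and no call is made.

## The bridging walk

Round 0 is direct RBH from the seed. Each later round takes a snapshot of
the present set and, for every absent species, attempts RBH with the
ortholog of each present species, nearest first by tree path distance
(branch lengths when present, edge counts otherwise), stopping at the first
acceptance; other present species at the same tied distance are also
attempted and their results recorded, which feeds the cross-query
consistency check. A species, once present, is never overwritten.

Two properties follow by construction and are verified against independent
oracles in the tests: the fixed-point present set equals BFS reachability in
the directed RBH-acceptance graph (because every present species is
eventually attempted for every absent one), and each chain has the minimum
possible number of links (because rounds are synchronous BFS levels). The
original manual procedure picked intermediate queries by inspection; the
nearest-first rule is this package's formalization of that choice.
`max_depth` (default 5) bounds chain length; the motivating study needed
three effective hops. Confidence of a bridged call is the confidence of its
final link — the chain is recorded so stricter downstream policies can be
applied.

## Physicochemical battery

* **Charged fraction** — percentage of non-X residues in {D,E,K,R,H} by
  default. The set is configurable ({D,E,K,R} is the common alternative);
  published percentages for the reference proteins could not be
  recalibrated against here (no sequence access offline), so the default
  follows the inclusive convention.
* **Isoelectric point** — Henderson–Hasselbalch net charge over termini and
  D,E,C,Y,H,K,R side chains; bisection on pH ∈ [0,14] to 1e-4. Default pKa
  table is Bjellqvist with residue-specific terminal adjustments (the table
  common pI servers use; cross-checked against biopython's implementation
  of the same model to ±0.02 within its valid bisection interval); EMBOSS
  and Lehninger tables are selectable.
* **Molecular mass** — sum of average residue masses plus one water, in kDa.
* **PEST regions** — candidate stretches of ≥ 12 residues bounded by K/R/H
  or the termini, containing ≥ 1 P, ≥ 1 D/E and ≥ 1 S/T; score =
  0.55 · (mass-weighted mole % of D,E,P,S,T) − 0.5 · (mass-weighted
  hydrophobicity index), Kyte–Doolittle hydropathies rescaled linearly to
  0–90 (hv = 10·KD + 45). The score ranges from −45 (pure isoleucine) to
  +50 (pure aspartate); +16 is the conventional strong-signal threshold.
  Whether the original scorer subtracted one equivalent of each critical
  residue class before computing percentages is not documented; this
  implementation does not, matching the published score range exactly.
* **Motifs** — fixed-length positional residue classes parsed from strings
  like `RxxxRxx[RK]`; overlapping matches allowed; conservation of
  reference positions on an MSA counts sequences with an allowed residue
  among sequences with a non-gap residue in that column.

## The simulator

The generator emulates the statistical regime the search strategy targets,
not any particular genome:

* a root family sequence (~260 aa) drawn with charged fraction boosted to
  0.42 (disordered-protein-like composition);
* a planted PEST-like segment (32 aa, DEPST-rich, lysine-flanked, class
  constrained with strength 0.5) and a planted `RxxxRxx[RK]` motif whose
  constrained positions resist substitution with strength 0.9 and whose
  span indels may not disrupt (spacing is part of the motif definition);
* per-branch substitutions at Poisson(branch length × sequence length),
  replacements drawn from the BLOSUM62-conditional distribution
  q(b|a) ∝ pₐp_b e^{λs_ab}, which produces similarity decay consistent with
  the matrices used for detection;
* indels at 0.015 events/site/unit branch with geometric lengths (mean
  2.5);
* eight random decoys per species (120–380 aa, background composition) and
  clade-specific family loss;
* byte-identical output under a fixed seed.

The benchmark scenario (12 species) places the seed in an outgroup clade,
then a ladder of two intermediate clades, then a fast-evolving target clade
whose sub-clade (two species) lost the family. Branch lengths were
calibrated against the generator's measured identity-vs-path decay so that
each adjacent hop sits near 30–40% identity while the seed-to-target path
accumulates ~2.85 substitutions/site. A note on that calibration: global
alignment with free end gaps has an identity floor of ~16% for unrelated
sequences of this composition, and on a tree the seed-to-target distance
cannot exceed the sum of the hop distances; a single intermediate clade
therefore cannot combine "every hop detectable" with "endpoints at the
floor". The two-clade ladder mirrors the real discovery chain (seed →
intermediate taxa → bridge species → target clade) and achieves both:
endpoint identity lands at ~15% — at the floor, indistinguishable from
unrelated — and the direct search finds nothing in the target clade while
every hop of the walk succeeds.

What the simulator does **not** emulate: paralogy and gene duplication,
codon-level evolution, domain architecture change, heterogeneous
site-rates beyond the motif/PEST protection, and compositional drift
control (family charged fraction relaxes from 0.42 toward the replacement
model's stationary composition over long branches). Passing benchmarks
therefore show that the walk recovers a single-copy family under realistic
similarity decay with decoys — not that it resolves paralog-rich families.

## Problem sizes and runtime

The shipped benchmark uses 12 species × 9 proteins of 120–380 aa; a full
bridging walk is ~1,000 pairwise alignments and runs in about two seconds.
The test suite (oracle sweeps included) runs in ~10 s; the acceptance
script in ~15 s. These sizes were chosen as the smallest at which every
qualitative regime (detectable hop, cryptic endpoint, loss clade, decoy
rejection) is present with margin.

## Known limitations

* E-values use ungapped λ/K on gapped scores (conservative direction:
  E-values understate the chance-hit rate; thresholds are configuration).
* Single best local alignment per pair — no multi-HSP chaining, so
  coverage of repeat-containing proteins is understated.
* The strict regime models only the cut-off of database-style ortholog
  inference, not in-paralog clustering.
* pI and PEST constants are table-dependent; reported to one decimal, the
  choice of table matters at that precision and is selectable but not
  recalibrated against the published reference values (offline build).
* MSA construction is out of scope; conservation statistics require a
  supplied alignment.
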
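# Methods

## Model and assumptions

The pipeline rests on two assumptions. First, the *operon proxy*: two
protein families whose genes sit on the same nucleotide record fewer than
a small number of coding genes apart are taken to be co-operonic, hence
co-expressed and physically interacting, so concatenating their
per-record homologues yields correctly matched rows for inter-protein
co-evolution analysis. Gene order is the only locus information used;
strand and intergenic distance are ignored (no strand rule is defined for
the pairing). Second, the *contact proxy*: a strongly co-evolving
inter-protein residue pair is expected to be in spatial contact in the
assembled complex, so mapping top-scoring pairs onto a structural model
and measuring cross-chain Cα–Cα distances validates (or falsifies) the
model's interfaces.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_coverage` | 0.60 | hit kept iff coverage of the query profile is strictly > 60% |
| `max_evalue` | 1e-3 | inclusive e-value cutoff (final round of the upstream iterative search; the full schedule 1e-12 ×4, 1e-6, 1e-3 is recorded in the run log as provenance only) |
| `max_separation` | 20 | pair kept iff \|Δ gene index\| < 20 (strict) |
| `pairing` | closest | one pair per record: smallest separation, then smallest combined e-value, then lexicographic gene indices; `all` keeps every candidate |
| `max_gap_ratio` | 0.25 | row kept iff gap fraction ≤ 25% (inclusive) |
| `max_identity` | 0.90 | greedy scan; row dropped iff identity to a retained row > 90% |
| `distance_cutoff` | 12.0 Å | distogram bins whose upper edge ≤ cutoff are summed into the contact probability |
| `min_score` | 0.05 | ranking floor |
| `selection` | threshold70 | keep pairs scoring ≥ 0.7 × top score; alternatives `top:N`, `min_score:x` |
| `contact_cutoff` | 12.0 Å | a selected pair counts as within the interface iff its minimal cross-chain Cα–Cα distance ≤ cutoff; chosen to match the aggregation cutoff |
| `pseudocount` | 1.0 | Laplace mass for MI frequency estimates |

Boundary semantics follow the phrasing of each rule: coverage and
identity are strict inequalities ("more than 60%", "more than 90%
identical is redundant"), gap ratio and e-value are inclusive cutoffs,
and gene separation is strictly less than the limit.

## MI/APC scorer

For columns *i*, *j*, rows gapped in either column are excluded from that
pair's counts (gaps reflect alignment coverage, not residue identity, so
they are not a 21st state). With pair counts *n<sub>ab</sub>* over the
q = 20 alphabet, n rows and pseudocount λ, the joint estimate is
p(a,b) = (n<sub>ab</sub> + λ/q²)/(n + λ); marginals are its row/column
sums, so the joint stays a proper distribution and λ = 0 recovers the
empirical frequencies. MI is reported in bits. The average-product
correction subtracts MI̅(i)·MI̅(j)/MI̅ computed per matrix: over all
entries for the rectangular inter-block matrix, over off-diagonal entries
for the symmetric intra matrices (the diagonal is self-MI, i.e. column
entropy, and is zeroed in the output). Column pairs with fewer than two
mutually ungapped rows score 0 with a logged warning. Sequence weighting
is deliberately absent from the default path: the scorer is a
transparent coupling detector for desk-scale analysis and ground-truth
testing, not a phylogeny-corrected evolutionary estimator; network-based
distogram scores are the production route and enter through the
distogram backend.

## Distogram aggregation

A bin contributes to the contact probability iff its *upper* edge is at
or below the distance cutoff, so "distance ≤ 12 Å" holds exactly whenever
the cutoff lands on a bin edge, independent of the bin grid. Bin edges
are always read from file metadata, never hard-coded. The optional
trailing no-contact bin never qualifies. Per-pair probability vectors
must sum to 1 within 1e-4 (then they are renormalized exactly); larger
deviations are rejected as corrupt.

## Geometry and classification

Distances are minimal Euclidean Cα–Cα distances over all chain-copy
combinations; for a pair within one family only distinct-chain
combinations count. A same-family pair is *homo-oligomeric* when its
minimal cross-chain distance is smaller than its minimal within-chain
distance, else *intra*; different families give *hetero-oligomeric*. The
cross-versus-within rule is this package's operational definition —
assignment of such pairs is ambiguous from score data alone. Ranking and
selection operate on the inter-protein (hetero) matrix by default.
Profile columns are 1-based; an optional per-family offset maps them to
author residue numbering. Pairs unresolved in the structure are reported
with an absent distance and excluded from the precision denominator,
never silently dropped.

## Synthetic data

The generator emulates the three inputs with known truth. Genome records
carry both families within the separation limit with probability
`colocate_prob` (the planted pairs, whose hits always pass the default
filters), both families too far apart, or one family; a `decoy_fraction`
of records adds hits failing coverage or e-value so the filters are
exercised. Coupled alignments draw background columns i.i.d. from
per-column Dirichlet(1) profiles; each planted column pair is, with
probability ε, drawn jointly through a fixed random one-to-one alphabet
mapping, else independently from its marginals. This mixture (not a
Potts model) was chosen for its closed forms: at ε = 1 the planted MI
equals the marginal column entropy, and MI increases monotonically in ε.
Gaps are injected i.i.d. (default 5%). Toy structures place each
connected component of the planted contact graph on a straight line with
step d satisfying d ≤ contact_distance and 3d ≥ far_distance (feasible
iff far ≤ 3·contact; residue degree ≤ 2, open paths only), remaining
residues in family-specific far lanes, all base coordinates on the y = 0,
x ≥ R<sub>min</sub> half-plane; symmetric copies are rotations about z,
with R<sub>min</sub> derived from the smallest nonzero relative rotation
angle so distinct copies stay ≥ far_distance apart. Every generated
structure is verified exhaustively against both distance guarantees
before being returned.

The default bundle (1200 records, colocation 0.6, blocks of 30 columns,
ten planted pairs at ε = 0.9, 5% gaps, three copies per family) yields a
curated alignment of roughly 700 rows — comfortably above the ~1000-row
depth regarded as sufficient for co-evolution analysis at full scale,
relative to its 60 columns — and is the reference condition for the
end-to-end validation mirror: every pair selected at 70% of the top
score lies within 12 Å of the planted interface.

What the generator does *not* emulate: phylogenetic correlation between
rows (available only as an explicit duplication-with-mutation stress
mode), realistic amino-acid substitution processes, alignment errors,
paralogy confusion, or structural realism beyond the distance
constraints. Passing tests therefore demonstrate the correctness of the
pipeline's logic and numerics, not the field performance of MI-based
scoring on real alignments.

## Numerical choices

MI is clamped at 0 against round-off; score ties in ranking break by
ascending residue indices; the redundancy filter is greedy keep-first in
row order (deterministic, matches the "remaining sequences" reading, and
cheap at the row counts involved) rather than a clustering method; the
gap filter runs before the identity filter because identity between
gappy rows is unstable. Identity uses mutually non-gap columns as the
denominator (0 if none). All randomness flows through
`numpy.random.default_rng` seeds carried in configuration; pipeline
outputs contain no timestamps, so identical config + seed reproduces
every artifact byte for byte.

## Problem sizes

Tests and the acceptance script run entirely on synthetic data at the
scales above: oracle sweeps use ≤ 50-row × ≤ 10-column alignments (200
instances), recovery checks a 1000-row × 60-column alignment, and the
end-to-end bundle ~700 curated rows. The full suite completes in well
under a minute on one CPU.

## Known limitations

* The MI/APC backend is depth-hungry and unweighted; on shallow or
  phylogenetically skewed alignments its ranking will degrade long
  before a network-based scorer's would.
* Selection scope is hetero-pairs only; intra-block matrices are
  computed and written but not fed into selection.
* The hit-table reader consumes one documented TSV dialect; converting
  native search-tool outputs is left to the caller.
* Closed cycles in the planted contact graph are rejected rather than
  laid out.
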
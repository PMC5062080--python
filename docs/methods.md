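# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open. Conversions to the 1-based
inclusive conventions of `show-coords` tables and AGP happen only in the
parsers and writers. `show-coords` rows may carry either coordinate pair
reversed; both sides are normalised to `start < end` and the strand is `-`
exactly when one side was reversed. PAF coordinates are consumed as-is;
PAF identity is `100 · matches / alignment_block_length` (columns 10/11).

## Missing-region detection

Draft-vs-reference alignment blocks are filtered (defaults: identity ≥ 90%,
reference span ≥ 1 kb — both surfaced as flags, since reasonable values
depend on the divergence between draft genotype and reference), their
reference intervals unioned per reference sequence with abutting intervals
merged, and the complement within `[0, reference length)` taken. Regions
shorter than `missing_min_length` (default 400 kb, the scale at which an
absent region is worth patching rather than polishing) are discarded.
Coverage uses all retained blocks regardless of which draft scaffold they
come from: a region is missing only if *no* draft sequence aligns there.

## Donor assignment and placement

A donor block qualifies for a region when the overlap of its reference
interval with the region is at least `min_region_overlap` (default 0.5) of
the block's aligned length — the denominator is the block, not the region,
so a short donor fully inside a long region qualifies. Each donor commits to
its single best region; within a region candidates are ranked by
`(aligned_length, identity, donor_id)`. One donor is placed per region,
best-first; multi-donor tiling of one region is deliberately out of scope —
it would require an overlap-layout step that alignment-to-reference evidence
alone cannot validate.

The insertion point comes from projecting the region's start through the
draft blocks with a *left-flank* policy: among blocks ending at or before
the region start, the one ending closest (ties: longer block, then
lexicographic id) donates its query endpoint (`query_end` on `+`,
`query_start` on `-`). If no left flank exists the region end is projected
through the symmetric right-flank policy and the placement becomes a
prepend-style extension. Blocks are treated as gap-free for projection;
only block endpoints are ever projected, for which the affine approximation
is exact. The donor's orientation is its reference strand composed with the
flank block's strand.

If the insertion point touches an N-run of the target scaffold, the run is
excised and the donor takes its place with a 100 N spacer on both sides:
once the original gap-length estimate is discarded, the residual distance to
*each* flank is unknown. A plain insertion gets a spacer only on the side
not fixed by the projected flank, and no spacer is emitted at a scaffold
terminus. 100 N is the common default for joins of unknown but bounded
distance. Conflicting placements (overlapping edited intervals on one
scaffold, compared as closed intervals so two point insertions at one
coordinate clash) are resolved by the same `(aligned_length, identity, id)`
ranking; losers are skipped and ledgered, never merged. Placements are
applied in a single left-to-right component walk per scaffold, which both
builds the output sequence and yields the AGP v2.1 component ledger; the
two are generated from the same component list, so AGP totals equal output
lengths by construction.

## Redundancy removal

A leftover is redundant when the union of its aligned intervals on the main
assembly (blocks at identity ≥ `id_threshold`, default 95%) covers at least
`cov_threshold` (default 0.95) of its length. With the masked-aware flag the
soft-masked fraction recorded at FASTA load is excluded from the
denominator, so repeat-rich leftovers are judged on their unique sequence.

## Marker anchoring

Marker hits are reduced to the best BLAST bitscore per marker; markers whose
two best bitscores tie across different scaffolds are ambiguous and dropped
(default). Each scaffold goes to the chromosome with the largest
weight-summed marker support (map weights default to 1 and are the knob for
trusting a denser or better-validated map more; ties break to the
highest-weight map's chromosome, then lexicographically).

Orientation is the sign of a weighted Spearman correlation ρ between marker
bp and cM positions, computed per map over maps contributing ≥ 2 markers
with distinct genetic positions and then averaged with map weights. ρ > 0 is
colinear (`+`), ρ < 0 anti-colinear (`-`), and ρ = 0 or no informative map
gives `?` — in particular a single marker always yields `?`, since one point
carries no order information. `?` scaffolds are emitted forward, a fixed
arbitrary convention recorded in the AGP (`na` orientation).

Within a chromosome, scaffolds are ordered by weighted mean cM (ties: longer
first, then id) and joined with 100 N spacers. This deterministic rank
ordering replaces the stochastic genetic-algorithm optimisation used by
tools like ALLMAPS: for consistent maps both recover the monotone order, and
determinism buys exact reproducibility and testability. The cost is that
with heavily conflicting multi-map evidence a global optimiser could find a
better compromise ordering; map weights are the lever provided here.

When anchoring precedes patching, the draft-vs-reference blocks are lifted
through the anchoring exactly — each scaffold's offset and orientation
inside its chromosome is known from the component list — so no realignment
is needed between stages.

## Assembly statistics

Nx is the length of the scaffold at which the cumulative length of
descending-sorted scaffolds first reaches ≥ x% of the total (ties included
in the prefix, the dominant convention); Lx is the size of that prefix.
Equal-length scaffolds sort by id so Lx accounting is deterministic. GC% is
computed over A/C/G/T only; N bases are unknowns, not composition. The gap
count is the number of maximal N-runs at a configurable minimum run length
(default 1), surfaced because published gap counts rarely state their
threshold.

## Synthetic scenarios

The generator emulates the data regime the workflow targets: a truth genome
of i.i.d. bases at a set GC (default 0.46, small-grass-like), from which the
reference is taken verbatim; a draft with `n_excised` regions (genome-wide
total, so counts not divisible by the chromosome number are expressible)
removed and replaced by an N-run of one tenth the excised length — an
undersized gap estimate, so patching exercises both gap closing and net
extension; leftovers equal to the excised pieces, optionally mutated at a
substitution rate; optional scaffold breaks (placed ≥ 2 kb from any gap so
every gap keeps both flanks); optional reverse-complemented emission of a
fraction of scaffolds, with alignments and marker hits transformed
accordingly; and markers whose genetic position is the truth position at
3.5 cM/Mb plus optional Gaussian noise, emitted as one map. Alignments are
fabricated from the construction coordinates, not an aligner, so expected
outputs are exact and tests need no external tools.

Default scale is 3 × 200 kb chromosomes with 5 excisions of 8–15 kb above a
5 kb missing-region threshold — large enough that every code path (multiple
gaps per scaffold, per-chromosome variation, flank projection through
breaks) is exercised, small enough that the full suite runs in well under a
minute per scenario.

What the scenarios deliberately do not model: indels and rearrangements
between draft and reference, repeat families (so donor placement is never
genuinely ambiguous), read-level data, and chimeric scaffolds. Passing the
recovery tests therefore shows the interval algebra, projection arithmetic,
orientation statistic and bookkeeping are exact under clean evidence — not
that the thresholds are well-tuned for diverged real genomes, where the
identity/coverage filters and the one-donor-per-region policy are the
operative safeguards.

## Numerical and degenerate-input choices

Empty assemblies are rejected by the statistics (no defined Nx); an empty
placement set is the identity on the assembly, byte-for-byte. Coverage
intervals beyond a stated reference length are a hard error (they indicate
mismatched inputs, not a boundary case). Absent projections are values
(`None`), not errors: a region with no flank is a ledger entry. Spearman ρ
is computed on rank vectors with a weighted Pearson formula; degenerate rank
variance (all-tied positions) makes a map uninformative rather than raising.
Strict FASTA parsing reports the offending line number by re-scanning the
file only on the failure path. The whole toolkit contains no random draws
outside the scenario generator, which uses a single seeded generator in a
documented call order.
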
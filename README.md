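# refgap

Reference-guided improvement of draft genome assemblies.

A draft assembly built from short reads typically falls short of the true
genome: large regions fail to assemble, scaffolds carry internal N-gaps of
poorly estimated size, and nothing says which scaffold belongs to which
chromosome. When an independent assembly of the same (or a very close)
genotype exists, it can *guide* the repair without being copied into the
result: whole-genome alignments reveal which reference regions have no draft
counterpart, leftover sequences that align into those regions can be stitched
in at coordinates projected through the flanking alignments, and genetic-map
markers can order and orient scaffolds along chromosomes.

`refgap` implements that workflow as a library plus a small CLI:

* **Missing-region detection** — merge the reference coverage of all
  draft-vs-reference alignment blocks and take the complement above a length
  threshold (default 400 kb).
* **Donor patching** — match leftover ("donor") sequences to missing regions
  by their reference alignments, project each region's flank into draft
  coordinates, and insert the donor there — excising an overlapping N-gap
  when one marks the spot — with N-spacers at uncertain junctions.
* **Redundancy removal** — drop leftovers whose aligned coverage on the main
  assembly exceeds a threshold (default ≥ 95% at ≥ 95% identity).
* **Marker anchoring** — assign each scaffold to the chromosome carrying most
  of its marker weight, orient it by the sign of the weighted Spearman
  correlation ρ between physical (bp) and genetic (cM) marker positions
  (ρ > 0 colinear `+`, ρ < 0 anti-colinear `-`, single marker or ρ = 0
  undetermined `?`), and order scaffolds by mean genetic position.
* **Assembly statistics** — N50/N75/N95, L50/L75/L95, GC%, N-base and gap
  counts, as a per-assembly comparison table.

Every step is deterministic, every insertion is recorded in an AGP v2.1
component ledger, and a synthetic-scenario generator derives all inputs
(FASTA, MUMmer `show-coords -T`, PAF, BLAST outfmt 6, map CSV) from a random
truth genome so the whole pipeline can be exercised and scored exactly
without any external data or aligner.

Consumed formats: FASTA (plain or gzip), MUMmer `show-coords -T` tables,
minimap2-style PAF, BLAST tabular (outfmt 6) marker hits, and genetic maps as
CSV (`marker_id, map, chromosome, position`).

## Worked example

Generate a synthetic study — three 200 kb chromosomes, five excised regions
of 8–15 kb each replaced in the draft by an undersized N-gap, the excised
pieces kept as leftovers, three markers per scaffold — then run the full
improvement:

```python
from refgap import (ScenarioConfig, generate_scenario, write_scenario,
                    RunConfig, run_improve, compare_stats, read_fasta)

scenario = generate_scenario(ScenarioConfig(seed=42))
paths = write_scenario(scenario, "demo/scenario")

config = RunConfig(
    draft=str(paths["draft"]),
    reference=str(paths["reference"]),
    draft_alignments=str(paths["draft_vs_ref_coords"]),
    donors=str(paths["leftovers"]),
    donor_alignments=str(paths["leftover_vs_ref_coords"]),
    marker_hits=str(paths["marker_hits"]),
    genetic_maps=str(paths["genetic_maps"]),
    missing_min_length=5_000,
    outdir="demo/out",
)
result = run_improve(config)
print(f"missing regions : {len(result.missing_regions)}")
print(f"donors placed   : {result.patch_report.n_placed}")
print(f"gap bases closed: {result.patch_report.n_gap_bases_closed}")
print(f"bases inserted  : {result.patch_report.bases_inserted}")
before = read_fasta(paths["draft"], name="before")
print(compare_stats([before, result.assembly]))
```

prints

```
missing regions : 5
donors placed   : 5
gap bases closed: 6090
bases inserted  : 60923

                         before   after
# scaffolds                   3       3
Largest scaffold (bp)    200000  200600
Total length (bp)        545167  601000
N50 (bp)                 178957  200400
N75 (bp)                 166210  200000
N95 (bp)                 166210  200000
L50                           2       2
L75                           3       3
L95                           3       3
GC%                       46.08   46.04
# N's (bases)              6090    1000
# of gaps (sites of Ns)       5      10
```

All five excised regions are found as missing, every donor lands at its true
locus, and the patched chromosomes equal the truth byte-for-byte once N-runs
are deleted: total length returns to 600 kb (plus 1 000 bp of spacers), the
6 090 undersized gap bases are gone, and the ten remaining "gaps" are the two
100 N spacers bracketing each insertion. The same workflow is available from
the shell:

```sh
refgap simulate --seed 42 -o demo/scenario
refgap improve --draft demo/scenario/draft.fasta \
    --reference demo/scenario/reference.fasta \
    --draft-alignments demo/scenario/draft_vs_ref.coords \
    --donors demo/scenario/leftovers.fasta \
    --donor-alignments demo/scenario/leftover_vs_ref.coords \
    --missing-min-length 5000 -o demo/out
```

Subcommands `stats`, `gaps`, `missing`, `patch`, `anchor`, `redundancy`,
`improve`, `simulate`; `improve` also reads a flat TOML config
(`--config run.toml`, CLI flags override).

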
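"""End-to-end improvement workflow: anchor, detect, patch, deduplicate, report.

The stage order is anchor-first: scaffolds are arranged into chromosomes from
marker evidence before reference-guided patching, and the draft-vs-reference
alignment blocks are lifted through the anchoring exactly (each scaffold's
offset and orientation inside its chromosome is known), so no realignment is
needed between stages.  A patch-only run skips anchoring.

Every stage is deterministic; two runs from one config produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import agp, marker_anchor, refpatch, wga_model
from .assembly_core import (
    Assembly,
    AssemblyStats,
    compute_stats,
    read_fasta,
    stats_table,
    write_fasta,
    write_stats_report,
)

logger = logging.getLogger("refgap")


@dataclass
class RunConfig:
    """Paths and thresholds for one improvement run.

    Only ``draft``, ``reference``, ``draft_alignments`` and ``outdir`` are
    mandatory; donor and marker inputs switch their stages on.
    """

    draft: str
    reference: str
    draft_alignments: str
    outdir: str
    donors: str | None = None
    donor_alignments: str | None = None
    self_alignments: str | None = None  # leftover-vs-assembly, for redundancy
    marker_hits: str | None = None
    genetic_maps: str | None = None
    dialect: str = "coords_tab"
    missing_min_length: int = 400_000
    min_identity: float = 90.0
    min_block: int = 1000
    min_region_overlap: float = 0.5
    cov_threshold: float = 0.95
    id_threshold: float = 95.0
    spacer: int = 100
    patch_only: bool = False
    append_unplaced_leftovers: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        for attr in ("draft", "reference", "draft_alignments", "donors",
                     "donor_alignments", "self_alignments", "marker_hits",
                     "genetic_maps"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{attr}: no such file: {value}")
        if self.donors is not None and self.donor_alignments is None:
            raise ValueError("donors given without donor_alignments")


def load_run_config(toml_path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a flat TOML file; keyword overrides win."""
    values: dict = {}
    if toml_path is not None:
        import tomllib

        with open(toml_path, "rb") as fh:
            values.update(tomllib.load(fh))
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**values)


@dataclass
class RunResult:
    config: RunConfig
    assembly: Assembly
    stats_before: AssemblyStats
    stats_after: AssemblyStats
    missing_regions: list[wga_model.MissingRegion] = field(default_factory=list)
    patch_report: refpatch.PatchReport | None = None
    anchor_result: marker_anchor.AnchorResult | None = None
    removed_leftovers: list[str] = field(default_factory=list)
    outputs: dict[str, Path] = field(default_factory=dict)


def run_improve(config: RunConfig) -> RunResult:
    """Execute the improvement workflow and write all artifacts to outdir."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for key, value in dataclasses.asdict(config).items():
        logger.info("config %s = %r", key, value)

    draft = read_fasta(config.draft, name="before")
    reference = read_fasta(config.reference, name="reference")
    ref_lengths = reference.lengths()
    blocks = wga_model.parse_alignments(
        config.draft_alignments, config.dialect,
        min_identity=config.min_identity, min_block=config.min_block,
    )
    logger.info("loaded %d draft scaffolds, %d alignment blocks", len(draft), len(blocks))
    stats_before = compute_stats(draft)

    outputs: dict[str, Path] = {}
    working = draft
    anchor_result = None

    # --- stage 1: marker anchoring -------------------------------------------
    if config.marker_hits and config.genetic_maps and not config.patch_only:
        hits = marker_anchor.load_marker_hits(config.marker_hits)
        maps = marker_anchor.load_genetic_maps(config.genetic_maps)
        assignments = marker_anchor.assign_scaffolds(hits, maps)
        anchor_result = marker_anchor.order_and_build(
            assignments, working, spacer=config.spacer
        )
        working = anchor_result.assembly
        blocks = marker_anchor.lift_blocks_through_anchoring(blocks, anchor_result)
        outputs["anchor_agp"] = outdir / "anchored.agp"
        agp.write_agp(anchor_result.components, outputs["anchor_agp"])
        outputs["anchor_ledger"] = outdir / "anchor_ledger.tsv"
        marker_anchor.write_anchor_ledger(anchor_result, outputs["anchor_ledger"])
        logger.info(
            "anchored %d chromosomes, anchored fraction %.3f",
            len(anchor_result.builds), anchor_result.anchored_fraction,
        )

    # --- stage 2: missing-region detection -----------------------------------
    coverage = wga_model.merge_coverage(blocks)
    missing = wga_model.find_missing_regions(
        coverage, ref_lengths, min_length=config.missing_min_length
    )
    logger.info("found %d missing regions >= %d bp", len(missing), config.missing_min_length)

    # --- stage 3: patching ----------------------------------------------------
    patch_report = None
    removed: list[str] = []
    if config.donors is not None:
        donors = read_fasta(config.donors, name="donors")
        donor_blocks = wga_model.parse_alignments(
            config.donor_alignments, config.dialect,
            min_identity=config.min_identity, min_block=config.min_block,
        )
        candidates = refpatch.assign_donors(
            missing, donor_blocks, min_region_overlap=config.min_region_overlap
        )
        plan = refpatch.plan_patches(missing, candidates, blocks, working)
        working, patch_report, components = refpatch.apply_patches(
            working, plan.placements, donors,
            spacer=config.spacer, n_regions_considered=plan.n_regions_considered,
        )
        for entry in patch_report.ledger:
            if entry["status"] != "applied":
                logger.warning("placement skipped: %r", entry)
        outputs["patch_agp"] = outdir / "patched.agp"
        agp.write_agp(components, outputs["patch_agp"])
        outputs["patch_report_tsv"] = outdir / "patch_report.tsv"
        outputs["patch_report_json"] = outdir / "patch_report.json"
        if patch_report.ledger:
            patch_report.to_tsv(outputs["patch_report_tsv"])
        else:
            outputs["patch_report_tsv"].write_text("")
        patch_report.to_json(outputs["patch_report_json"])

        # --- stage 4: redundancy removal of unused leftovers -----------------
        placed_ids = {
            e["donor_id"] for e in patch_report.ledger if e["status"] == "applied"
        }
        unused = Assembly(
            records=[r for r in donors if r.id not in placed_ids], name="leftovers"
        )
        if config.self_alignments is not None:
            self_blocks = wga_model.parse_alignments(
                config.self_alignments, config.dialect,
                min_identity=0.0, min_block=1,
            )
            unused, removed = refpatch.remove_redundant(
                unused, self_blocks,
                cov_threshold=config.cov_threshold, id_threshold=config.id_threshold,
            )
            logger.info("removed %d redundant leftovers", len(removed))
        if config.append_unplaced_leftovers:
            for rec in unused:
                working.add(rec)

    # --- stage 5: statistics & outputs ---------------------------------------
    working = Assembly(records=list(working.records), name="after")
    stats_after = compute_stats(working)
    outputs["fasta"] = outdir / "improved.fasta"
    write_fasta(working, outputs["fasta"])
    outputs["stats_tsv"] = outdir / "stats.tsv"
    outputs["stats_json"] = outdir / "stats.json"
    write_stats_report([stats_before, stats_after], outputs["stats_tsv"],
                       outputs["stats_json"])
    outputs["missing_tsv"] = outdir / "missing_regions.tsv"
    with open(outputs["missing_tsv"], "w") as fh:
        fh.write("ref_id\tstart\tend\tlength\n")
        for r in missing:
            fh.write(f"{r.ref_id}\t{r.start}\t{r.end}\t{r.length}\n")
    outputs["run_config"] = outdir / "run_config.json"
    outputs["run_config"].write_text(
        json.dumps(dataclasses.asdict(config), indent=2) + "\n"
    )

    return RunResult(
        config=config,
        assembly=working,
        stats_before=stats_before,
        stats_after=stats_after,
        missing_regions=missing,
        patch_report=patch_report,
        anchor_result=anchor_result,
        removed_leftovers=removed,
        outputs=outputs,
    )


def compare_stats(assemblies: list[Assembly]):
    """Stats comparison table: one column per assembly, fixed row order."""
    if not assemblies:
        raise ValueError("need at least one assembly")
    return stats_table(compute_stats(a) for a in assemblies)
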
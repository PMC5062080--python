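"""Reference-guided patching: place donor sequences into missing regions.

Given (a) regions of the reference that no draft sequence covers, (b) donor
(leftover) sequences aligned to the reference, and (c) draft-vs-reference
alignments, this module plans where each donor belongs in draft coordinates —
by projecting the missing region's flanks through the draft alignments — and
applies the insertions, closing N-gaps where the insertion point lands in
one.  Unused leftovers that are almost entirely contained in the main
assembly can then be dropped as redundant.

The whole path is deterministic: candidate donors are ranked by
(aligned_length, identity, id), one donor is placed per region, and
conflicting placements are skipped (and ledgered), never merged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .agp import Component, GapComponent, SequenceComponent
from .assembly_core import (
    Assembly,
    GapInterval,
    ScaffoldRecord,
    find_n_runs,
    reverse_complement,
)
from .wga_model import AlignmentBlock, MissingRegion, project_ref_to_draft


@dataclass(frozen=True)
class DonorPlacement:
    """A planned insertion of a donor slice into a draft scaffold."""

    donor_id: str
    donor_interval: tuple[int, int]  # [start, end) on the donor
    target_scaffold: str
    insert_at: int  # 0-based position in the original target scaffold
    orientation: str  # '+' or '-'
    anchor: str  # 'left' or 'right': which junction the projection fixed
    replaces_gap: GapInterval | None
    ref_region: MissingRegion
    score: tuple[int, float]  # (aligned_length, identity)
    notes: tuple[str, ...] = ()

    @property
    def donor_length(self) -> int:
        return self.donor_interval[1] - self.donor_interval[0]

    def edited_interval(self) -> tuple[int, int]:
        """Closed interval of target coordinates this placement touches."""
        if self.replaces_gap is not None:
            return self.replaces_gap.start, self.replaces_gap.end
        return self.insert_at, self.insert_at


@dataclass
class PatchPlan:
    placements: list[DonorPlacement]
    entries: list[dict] = field(default_factory=list)  # one per region considered

    @property
    def n_regions_considered(self) -> int:
        return len(self.entries)


@dataclass
class PatchReport:
    n_regions_considered: int = 0
    n_placed: int = 0
    n_skipped_conflict: int = 0
    n_gap_bases_closed: int = 0
    bases_inserted: int = 0
    ledger: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_regions_considered": self.n_regions_considered,
            "n_placed": self.n_placed,
            "n_skipped_conflict": self.n_skipped_conflict,
            "n_gap_bases_closed": self.n_gap_bases_closed,
            "bases_inserted": self.bases_inserted,
            "ledger": self.ledger,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.ledger).to_csv(path, sep="\t", index=False)


def _rank_key(block: AlignmentBlock) -> tuple[int, float, str]:
    return (-block.aligned_length, -block.identity, block.query_id)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def assign_donors(
    regions: Sequence[MissingRegion],
    donor_blocks: Iterable[AlignmentBlock],
    min_region_overlap: float = 0.5,
) -> dict[MissingRegion, list[AlignmentBlock]]:
    """Match donor alignment blocks to missing regions.

    A donor block is a candidate for a region when the overlap between its
    reference interval and the region is at least ``min_region_overlap`` of
    the block's aligned length.  Each donor is committed to its single best
    region (ties broken by region order); within a region candidates are
    ordered best-first by (aligned_length, identity, id).
    """
    if not 0.0 < min_region_overlap <= 1.0:
        raise ValueError("min_region_overlap must lie in (0, 1]")
    # all qualifying (donor block, region index) pairs
    qualifying: dict[str, list[tuple[int, AlignmentBlock]]] = {}
    for block in donor_blocks:
        for idx, region in enumerate(regions):
            if region.ref_id != block.ref_id:
                continue
            ov = _overlap((block.ref_start, block.ref_end), (region.start, region.end))
            if ov / block.aligned_length >= min_region_overlap:
                qualifying.setdefault(block.query_id, []).append((idx, block))
    # each donor goes to the region where its best block scores highest
    per_region: dict[int, list[AlignmentBlock]] = {}
    for donor_id, pairs in qualifying.items():
        idx, block = min(pairs, key=lambda p: (_rank_key(p[1]), p[0]))
        per_region.setdefault(idx, []).append(block)
    out: dict[MissingRegion, list[AlignmentBlock]] = {r: [] for r in regions}
    for idx, blocks in per_region.items():
        out[regions[idx]] = sorted(blocks, key=_rank_key)
    return out


def _compose_strand(a: str, b: str) -> str:
    return "+" if a == b else "-"


def _gap_at(record: ScaffoldRecord, position: int) -> GapInterval | None:
    """The maximal N-run whose closed span [start, end] contains position."""
    for gap in find_n_runs(record):
        if gap.start <= position <= gap.end:
            return gap
    return None


def plan_patches(
    regions: Sequence[MissingRegion],
    candidates: Mapping[MissingRegion, list[AlignmentBlock]],
    draft_blocks: Sequence[AlignmentBlock],
    draft: Assembly,
) -> PatchPlan:
    """Turn region->donor candidates into concrete draft-coordinate placements.

    For each region with at least one candidate the top candidate is taken
    and the region's start is projected through the draft-vs-reference
    alignments with the left-flank policy; failing that, the region's end
    with the right-flank policy (a prepend-style extension).  A region
    neither of whose flanks projects is skipped and ledgered as unanchored.
    The donor's orientation in the draft is its reference strand composed
    with the flank block's strand.
    """
    placements: list[DonorPlacement] = []
    entries: list[dict] = []
    for region in regions:
        cands = candidates.get(region, [])
        entry: dict = {
            "ref_id": region.ref_id,
            "ref_start": region.start,
            "ref_end": region.end,
            "length": region.length,
        }
        if not cands:
            entry["status"] = "no_candidate"
            entries.append(entry)
            continue
        top = cands[0]
        left = project_ref_to_draft(draft_blocks, (region.ref_id, region.start), "left_flank")
        right = project_ref_to_draft(draft_blocks, (region.ref_id, region.end), "right_flank")
        notes: list[str] = []
        if left is not None:
            scaffold_id, position, flank_strand = left
            anchor = "left"
            if right is not None and right[0] != scaffold_id:
                notes.append("split_flank")
        elif right is not None:
            scaffold_id, position, flank_strand = right
            anchor = "right"
            notes.append("prepend_extension")
        else:
            entry["status"] = "unanchored"
            entries.append(entry)
            continue
        gap = _gap_at(draft[scaffold_id], position)
        placement = DonorPlacement(
            donor_id=top.query_id,
            donor_interval=(top.query_start, top.query_end),
            target_scaffold=scaffold_id,
            insert_at=position,
            orientation=_compose_strand(top.strand, flank_strand),
            anchor=anchor,
            replaces_gap=gap,
            ref_region=region,
            score=(top.aligned_length, top.identity),
            notes=tuple(notes),
        )
        placements.append(placement)
        entry.update(
            status="planned",
            donor_id=top.query_id,
            target_scaffold=scaffold_id,
            insert_at=position,
            orientation=placement.orientation,
            closes_gap=gap is not None,
            notes=",".join(notes),
        )
        entries.append(entry)
    return PatchPlan(placements=placements, entries=entries)


def _build_components(
    record: ScaffoldRecord,
    placements: list[DonorPlacement],
    spacer: int,
) -> list[Component]:
    """Component list for one scaffold with its accepted placements applied.

    Placements are walked left-to-right along the original coordinates; a
    gap-replacement excises the N-run and brackets the donor with spacers on
    both sides (the true distances to either flank are unknown once the
    original gap-length estimate is discarded), while a plain insertion gets
    a spacer only on the side not fixed by the projected flank.  No spacer is
    emitted at a scaffold terminus.
    """
    comps: list[Component] = []
    pos = 0
    length = record.length

    def emit_draft(upto: int) -> None:
        nonlocal pos
        if upto > pos:
            comps.append(SequenceComponent(record.id, pos, upto, "+"))
        pos = upto

    for pl in sorted(placements, key=lambda p: p.edited_interval()):
        donor = SequenceComponent(pl.donor_id, *pl.donor_interval, pl.orientation)
        if pl.replaces_gap is not None:
            gap = pl.replaces_gap
            emit_draft(gap.start)
            if spacer and gap.start > 0:
                comps.append(GapComponent(spacer, evidence="align_genus"))
            comps.append(donor)
            if spacer and gap.end < length:
                comps.append(GapComponent(spacer, evidence="align_genus"))
            pos = gap.end
        else:
            p = pl.insert_at
            emit_draft(p)
            if pl.anchor == "left":
                comps.append(donor)
                if spacer and p < length:
                    comps.append(GapComponent(spacer, evidence="align_genus"))
            else:
                if spacer and p > 0:
                    comps.append(GapComponent(spacer, evidence="align_genus"))
                comps.append(donor)
    emit_draft(length)
    return comps


def _render(components: list[Component], sources: Mapping[str, str]) -> str:
    parts: list[str] = []
    for comp in components:
        if isinstance(comp, GapComponent):
            parts.append("N" * comp.length)
        else:
            piece = sources[comp.source_id][comp.start : comp.end]
            if comp.orientation == "-":
                piece = reverse_complement(piece)
            parts.append(piece)
    return "".join(parts)


def apply_patches(
    draft: Assembly,
    placements: Sequence[DonorPlacement],
    donors: Assembly,
    spacer: int = 100,
    n_regions_considered: int | None = None,
) -> tuple[Assembly, PatchReport, dict[str, list[Component]]]:
    """Apply planned placements; returns (assembly, report, AGP components).

    Placements are accepted best-first by (aligned_length, identity, id);
    a placement whose edited target interval overlaps an already-accepted
    one on the same scaffold is skipped and counted in
    ``n_skipped_conflict``.  An absent donor id is a hard error.
    """
    if spacer < 0:
        raise ValueError("spacer must be >= 0")
    for pl in placements:
        if pl.donor_id not in donors:
            raise KeyError(f"placement references unknown donor {pl.donor_id!r}")
        if pl.target_scaffold not in draft:
            raise KeyError(f"placement references unknown scaffold {pl.target_scaffold!r}")

    report = PatchReport(
        n_regions_considered=(
            n_regions_considered if n_regions_considered is not None else len(placements)
        )
    )
    accepted: dict[str, list[DonorPlacement]] = {}
    for pl in sorted(placements, key=lambda p: (-p.score[0], -p.score[1], p.donor_id)):
        mine = pl.edited_interval()
        taken = accepted.setdefault(pl.target_scaffold, [])
        # closed-interval overlap so that two point insertions at one
        # coordinate, or a point inside a replaced gap, conflict
        clash = any(
            other.edited_interval()[0] <= mine[1] and mine[0] <= other.edited_interval()[1]
            for other in taken
        )
        entry = {
            "donor_id": pl.donor_id,
            "target_scaffold": pl.target_scaffold,
            "insert_at": pl.insert_at,
            "orientation": pl.orientation,
            "donor_bases": pl.donor_length,
            "gap_bases_closed": pl.replaces_gap.length if pl.replaces_gap else 0,
            "notes": ",".join(pl.notes),
        }
        if clash:
            entry["status"] = "skipped_conflict"
            report.n_skipped_conflict += 1
        else:
            taken.append(pl)
            entry["status"] = "applied"
            report.n_placed += 1
            report.bases_inserted += pl.donor_length
            if pl.replaces_gap:
                report.n_gap_bases_closed += pl.replaces_gap.length
        report.ledger.append(entry)

    sources = {rec.id: rec.seq for rec in draft}
    for rec in donors:
        sources[rec.id] = rec.seq

    out = Assembly(name=draft.name + "_patched")
    components: dict[str, list[Component]] = {}
    for rec in draft:
        placed = accepted.get(rec.id, [])
        if placed:
            comps = _build_components(rec, placed, spacer)
            out.add(ScaffoldRecord(rec.id, _render(comps, sources), rec.masked_fraction))
        else:
            comps = [SequenceComponent(rec.id, 0, rec.length, "+")]
            out.add(rec)
        components[rec.id] = comps
    return out, report, components


def remove_redundant(
    leftovers: Assembly,
    self_blocks: Iterable[AlignmentBlock],
    cov_threshold: float = 0.95,
    id_threshold: float = 95.0,
    masked_aware: bool = False,
) -> tuple[Assembly, list[str]]:
    """Drop leftovers almost fully contained in the main assembly.

    ``self_blocks`` are leftover-vs-assembly alignments with the leftover as
    the query.  A leftover is removed when the union of its query intervals
    from blocks at identity >= ``id_threshold`` covers at least
    ``cov_threshold`` of its length; with ``masked_aware`` the soft-masked
    fraction is excluded from the length denominator.
    """
    if not 0.0 < cov_threshold <= 1.0:
        raise ValueError("cov_threshold must lie in (0, 1]")
    by_query: dict[str, list[tuple[int, int]]] = {}
    for b in self_blocks:
        if b.identity >= id_threshold:
            by_query.setdefault(b.query_id, []).append((b.query_start, b.query_end))

    kept = Assembly(name=leftovers.name)
    removed: list[str] = []
    for rec in leftovers:
        covered = 0
        last_end = 0
        for s, e in sorted(by_query.get(rec.id, [])):
            s = max(s, last_end)
            if e > s:
                covered += e - s
                last_end = e
            last_end = max(last_end, e)
        denom = rec.length * (1.0 - rec.masked_fraction) if masked_aware else rec.length
        if denom > 0 and covered / denom >= cov_threshold:
            removed.append(rec.id)
        else:
            kept.add(rec)
    return kept, removed
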
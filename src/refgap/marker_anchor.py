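"""Order and orient scaffolds into chromosomes from genetic-marker evidence.

Markers with known genetic positions (cM) on linkage maps are located on the
draft scaffolds by alignment (BLAST tabular hits).  Each scaffold is assigned
to the chromosome carrying most of its marker weight, oriented by the sign of
the weighted Spearman correlation between physical (bp) and genetic (cM)
marker positions, and the scaffolds of a chromosome are concatenated in order
of mean genetic position with N-spacers between them.

A scaffold with a single informative marker cannot be oriented — its
correlation is undefined — and is emitted with orientation '?' in its forward
strand, a deliberate echo of the trichotomy real anchoring runs report:
colinear (+), anti-colinear (-), undetermined (?).

Unlike genetic-algorithm scaffolders, the ordering here is a deterministic
rank statistic: same inputs, same chromosomes, every time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .agp import Component, GapComponent, SequenceComponent
from .assembly_core import Assembly, ScaffoldRecord
from .wga_model import AlignmentBlock

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class MapEntry:
    marker_id: str
    chromosome: str
    position: float  # genetic position (cM or rank units)


@dataclass(frozen=True)
class GeneticMap:
    name: str
    entries: tuple[MapEntry, ...]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("map weight must be > 0")
        seen = set()
        for e in self.entries:
            if e.marker_id in seen:
                raise ValueError(f"marker {e.marker_id!r} duplicated in map {self.name!r}")
            seen.add(e.marker_id)


@dataclass(frozen=True)
class MarkerHit:
    marker_id: str
    scaffold_id: str
    position: int  # 0-based bp on scaffold
    score: float
    identity: float


@dataclass(frozen=True)
class MarkerEvidence:
    """One marker's joint physical/genetic placement on a scaffold."""

    marker_id: str
    bp: int
    cm: float
    weight: float
    map_name: str
    chromosome: str


@dataclass
class ChromosomeBuild:
    chromosome: str
    scaffolds: list[tuple[str, str]]  # (scaffold_id, orientation in {+,-,?})
    support: dict[str, int] = field(default_factory=dict)  # scaffold -> marker count
    mean_cm: dict[str, float] = field(default_factory=dict)
    rho: dict[str, float | None] = field(default_factory=dict)


def load_genetic_maps(
    path: str | Path, weights: Mapping[str, float] | None = None
) -> list[GeneticMap]:
    """Read maps from CSV with columns marker_id, map, chromosome, position."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"marker_id", "map", "chromosome", "position"}
    if not required <= set(df.columns):
        raise ValueError(f"map CSV must have columns {sorted(required)}")
    maps = []
    for name, grp in df.groupby("map", sort=True):
        entries = tuple(
            MapEntry(str(r.marker_id), str(r.chromosome), float(r.position))
            for r in grp.itertuples()
        )
        weight = float(weights.get(str(name), 1.0)) if weights else 1.0
        maps.append(GeneticMap(str(name), entries, weight))
    return maps


def load_marker_hits(
    path: str | Path, min_identity: float = 0.0, unique_only: bool = True
) -> list[MarkerHit]:
    """Best BLAST hit per marker from an outfmt-6 table.

    Markers whose two best bitscores tie across different scaffolds are
    ambiguous and, with ``unique_only`` (default), discarded.  Hit position
    is min(sstart, send) converted to 0-based.
    """
    try:
        df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#",
                         dtype={"qseqid": str, "sseqid": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed BLAST tabular file {path}: {exc}") from exc
    if df["bitscore"].isna().any() or df["sstart"].isna().any():
        bad = int(df.index[df["bitscore"].isna() | df["sstart"].isna()][0]) + 1
        raise ValueError(f"{path}: malformed row at line {bad}")
    df = df[df["pident"] >= min_identity]
    hits: list[MarkerHit] = []
    for marker, grp in df.groupby("qseqid", sort=True):
        grp = grp.sort_values(["bitscore", "sseqid"], ascending=[False, True])
        top = grp.iloc[0]
        if unique_only and len(grp) > 1:
            second = grp.iloc[1]
            if second.bitscore == top.bitscore and second.sseqid != top.sseqid:
                continue
        hits.append(
            MarkerHit(
                marker_id=str(marker),
                scaffold_id=str(top.sseqid),
                position=int(min(top.sstart, top.send)) - 1,
                score=float(top.bitscore),
                identity=float(top.pident),
            )
        )
    return hits


def assign_scaffolds(
    hits: Sequence[MarkerHit], maps: Sequence[GeneticMap]
) -> dict[str, list[MarkerEvidence]]:
    """Assign each hit-bearing scaffold to its weight-majority chromosome.

    Returns scaffold -> evidence list restricted to the winning chromosome.
    Ties go to the chromosome seen in the highest-weight map, then
    lexicographic.  Scaffolds without markers simply do not appear.
    """
    lookup: dict[str, list[tuple[GeneticMap, MapEntry]]] = {}
    for gmap in maps:
        for entry in gmap.entries:
            lookup.setdefault(entry.marker_id, []).append((gmap, entry))

    per_scaffold: dict[str, list[MarkerEvidence]] = {}
    for hit in hits:
        for gmap, entry in lookup.get(hit.marker_id, []):
            per_scaffold.setdefault(hit.scaffold_id, []).append(
                MarkerEvidence(
                    marker_id=hit.marker_id,
                    bp=hit.position,
                    cm=entry.position,
                    weight=gmap.weight,
                    map_name=gmap.name,
                    chromosome=entry.chromosome,
                )
            )

    out: dict[str, list[MarkerEvidence]] = {}
    for scaffold_id, evidence in per_scaffold.items():
        support: dict[str, float] = {}
        best_map_weight: dict[str, float] = {}
        for ev in evidence:
            support[ev.chromosome] = support.get(ev.chromosome, 0.0) + ev.weight
            best_map_weight[ev.chromosome] = max(
                best_map_weight.get(ev.chromosome, 0.0), ev.weight
            )
        winner = min(
            support,
            key=lambda c: (-support[c], -best_map_weight[c], c),
        )
        out[scaffold_id] = [ev for ev in evidence if ev.chromosome == winner]
    return out


def _weighted_spearman(bp: np.ndarray, cm: np.ndarray, w: np.ndarray) -> float | None:
    """Weighted Pearson correlation of the rank vectors; None if undefined."""
    rb, rc = rankdata(bp), rankdata(cm)
    wsum = w.sum()
    mb, mc = (w * rb).sum() / wsum, (w * rc).sum() / wsum
    cov = (w * (rb - mb) * (rc - mc)).sum()
    vb = (w * (rb - mb) ** 2).sum()
    vc = (w * (rc - mc) ** 2).sum()
    if vb <= 0 or vc <= 0:
        return None
    return float(cov / np.sqrt(vb * vc))


def orient_scaffold(
    markers: Sequence[tuple[int, float, float, str]],
) -> tuple[str, float | None]:
    """Orientation from (bp, cM, weight, map_name) marker tuples.

    Per map contributing >= 2 markers with distinct genetic positions, a
    weighted Spearman correlation between bp and cM is computed; the
    map-weight-averaged correlation rho decides: '+' if rho > 0, '-' if
    rho < 0, '?' if no map is informative or rho == 0.  A single marker is
    always '?': one point carries no order information.
    """
    by_map: dict[str, list[tuple[int, float, float]]] = {}
    for bp, cm, weight, map_name in markers:
        by_map.setdefault(map_name, []).append((bp, cm, weight))

    rhos: list[tuple[float, float]] = []  # (rho, map weight)
    for entries in by_map.values():
        if len(entries) < 2:
            continue
        bp = np.array([e[0] for e in entries], dtype=float)
        cm = np.array([e[1] for e in entries], dtype=float)
        w = np.array([e[2] for e in entries], dtype=float)
        if len(np.unique(cm)) < 2:
            continue
        rho = _weighted_spearman(bp, cm, w)
        if rho is not None:
            rhos.append((rho, w.mean()))
    if not rhos:
        return "?", None
    wsum = sum(w for _, w in rhos)
    rho = sum(r * w for r, w in rhos) / wsum
    if rho > 0:
        return "+", rho
    if rho < 0:
        return "-", rho
    return "?", rho


def evidence_orientation(evidence: Sequence[MarkerEvidence]) -> tuple[str, float | None]:
    return orient_scaffold([(ev.bp, ev.cm, ev.weight, ev.map_name) for ev in evidence])


@dataclass
class AnchorResult:
    builds: list[ChromosomeBuild]
    assembly: Assembly  # chromosome sequences + passed-through leftovers
    components: dict[str, list[Component]]
    anchored_fraction: float
    ledger: pd.DataFrame  # per-scaffold: chromosome, mean_cm, rho, orientation, markers


def order_and_build(
    assignments: Mapping[str, Sequence[MarkerEvidence]],
    assembly: Assembly,
    spacer: int = 100,
    chromosome_prefix: str = "chr",
) -> AnchorResult:
    """Concatenate anchored scaffolds into chromosome sequences.

    Within a chromosome scaffolds are sorted by the weighted mean genetic
    position of their markers (ties: longer scaffold first, then id);
    '-' scaffolds are reverse-complemented, '?' scaffolds included forward.
    Unanchored scaffolds pass through unchanged.
    """
    if spacer < 0:
        raise ValueError("spacer must be >= 0")
    for scaffold_id in assignments:
        if scaffold_id not in assembly:
            raise KeyError(f"assigned scaffold {scaffold_id!r} missing from assembly")

    by_chrom: dict[str, list[str]] = {}
    mean_cm: dict[str, float] = {}
    orient: dict[str, tuple[str, float | None]] = {}
    for scaffold_id, evidence in assignments.items():
        chrom = evidence[0].chromosome
        by_chrom.setdefault(chrom, []).append(scaffold_id)
        wsum = sum(ev.weight for ev in evidence)
        mean_cm[scaffold_id] = sum(ev.cm * ev.weight for ev in evidence) / wsum
        orient[scaffold_id] = evidence_orientation(evidence)

    out = Assembly(name=assembly.name + "_anchored")
    components: dict[str, list[Component]] = {}
    builds: list[ChromosomeBuild] = []
    anchored_bp = 0
    ledger_rows: list[dict] = []

    for chrom in sorted(by_chrom):
        ordered = sorted(
            by_chrom[chrom],
            key=lambda s: (mean_cm[s], -assembly[s].length, s),
        )
        build = ChromosomeBuild(chromosome=chrom, scaffolds=[])
        parts: list[str] = []
        comps: list[Component] = []
        for i, scaffold_id in enumerate(ordered):
            rec = assembly[scaffold_id]
            orientation, rho = orient[scaffold_id]
            build.scaffolds.append((scaffold_id, orientation))
            build.support[scaffold_id] = len(assignments[scaffold_id])
            build.mean_cm[scaffold_id] = mean_cm[scaffold_id]
            build.rho[scaffold_id] = rho
            if i > 0 and spacer:
                parts.append("N" * spacer)
                comps.append(GapComponent(spacer, evidence="map"))
            seq = rec.seq if orientation != "-" else rec.reverse_complement().seq
            parts.append(seq)
            comps.append(SequenceComponent(scaffold_id, 0, rec.length, orientation))
            anchored_bp += rec.length
            ledger_rows.append(
                {
                    "scaffold_id": scaffold_id,
                    "chromosome": chrom,
                    "mean_cm": mean_cm[scaffold_id],
                    "rho": rho,
                    "orientation": orientation,
                    "n_markers": len(assignments[scaffold_id]),
                }
            )
        name = chrom if chrom.startswith(chromosome_prefix) else chromosome_prefix + chrom
        out.add(ScaffoldRecord(name, "".join(parts)))
        components[name] = comps
        builds.append(build)

    for rec in assembly:
        if rec.id not in assignments:
            out.add(rec)
            components[rec.id] = [SequenceComponent(rec.id, 0, rec.length, "+")]
            ledger_rows.append(
                {
                    "scaffold_id": rec.id,
                    "chromosome": "",
                    "mean_cm": float("nan"),
                    "rho": None,
                    "orientation": "",
                    "n_markers": 0,
                }
            )

    total = assembly.total_length
    ledger = pd.DataFrame(
        ledger_rows,
        columns=["scaffold_id", "chromosome", "mean_cm", "rho", "orientation", "n_markers"],
    )
    return AnchorResult(
        builds=builds,
        assembly=out,
        components=components,
        anchored_fraction=anchored_bp / total if total else 0.0,
        ledger=ledger,
    )


def lift_blocks_through_anchoring(
    blocks: Iterable[AlignmentBlock],
    result: AnchorResult,
) -> list[AlignmentBlock]:
    """Re-express query coordinates of draft-vs-reference blocks after anchoring.

    Each input scaffold occupies a known offset/orientation inside its
    chromosome (or passes through unchanged), so blocks can be lifted exactly
    — no realignment needed for downstream patching.
    """
    placement: dict[str, tuple[str, int, str]] = {}  # scaffold -> (object, offset, orient)
    for object_id, comps in result.components.items():
        offset = 0
        for comp in comps:
            if isinstance(comp, SequenceComponent):
                placement[comp.source_id] = (object_id, offset, comp.orientation)
            offset += comp.length

    lifted: list[AlignmentBlock] = []
    for b in blocks:
        if b.query_id not in placement:
            lifted.append(b)
            continue
        object_id, offset, orientation = placement[b.query_id]
        if orientation == "-":
            # scaffold length from the component span itself
            src_len = next(
                c.length
                for c in result.components[object_id]
                if isinstance(c, SequenceComponent) and c.source_id == b.query_id
            )
            qs = offset + (src_len - b.query_end)
            qe = offset + (src_len - b.query_start)
            strand = "-" if b.strand == "+" else "+"
        else:
            qs, qe = offset + b.query_start, offset + b.query_end
            strand = b.strand
        lifted.append(
            AlignmentBlock(object_id, qs, qe, b.ref_id, b.ref_start, b.ref_end,
                           strand, b.identity)
        )
    return lifted


def write_anchor_ledger(result: AnchorResult, path: str | Path) -> None:
    result.ledger.to_csv(path, sep="\t", index=False)


def orientation_summary(result: AnchorResult) -> dict[str, int]:
    """Counts of colinear (+), anti-colinear (-) and undetermined (?) scaffolds."""
    counts = {"+": 0, "-": 0, "?": 0}
    for build in result.builds:
        for _, orientation in build.scaffolds:
            counts[orientation] += 1
    return counts
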
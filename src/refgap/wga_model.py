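"""Whole-genome alignment coordinates: parsing, coverage algebra, projection.

Consumes the tabular coordinate formats that whole-genome aligners emit —
MUMmer ``show-coords -T`` tables and minimap2-style PAF — and provides the
interval algebra the patching workflow needs: union of reference coverage,
complement (missing regions), and projection of reference coordinates into
draft coordinates through alignment blocks.

Blocks are treated as gap-free for projection (affine offset inside a block):
the coords/PAF dialects carry no per-base alignment, and flank-endpoint
projection — the only projection patching performs — is exact regardless.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

Strand = Literal["+", "-"]


@dataclass(frozen=True)
class AlignmentBlock:
    """One local alignment between a query sequence and a reference.

    All coordinates 0-based half-open on the forward strand of each sequence;
    ``strand`` is the query orientation relative to the reference.
    """

    query_id: str
    query_start: int
    query_end: int
    ref_id: str
    ref_start: int
    ref_end: int
    strand: Strand
    identity: float  # percent in [0, 100]

    def __post_init__(self) -> None:
        if not (0 <= self.ref_start < self.ref_end):
            raise ValueError(f"bad ref interval [{self.ref_start},{self.ref_end})")
        if not (0 <= self.query_start < self.query_end):
            raise ValueError(f"bad query interval [{self.query_start},{self.query_end})")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0,100]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def aligned_length(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass(frozen=True)
class MissingRegion:
    """A reference interval with no aligned draft sequence."""

    ref_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


class ParseError(ValueError):
    pass


def _norm_1based(a: int, b: int) -> tuple[int, int, bool]:
    """1-based inclusive pair (possibly reversed) -> (0-based start, end, reversed?)."""
    if a <= b:
        return a - 1, b, False
    return b - 1, a, True


def _parse_coords_row(fields: list[str], lineno: int) -> AlignmentBlock:
    # show-coords -T: S1 E1 S2 E2 LEN1 LEN2 %IDY [extra numeric cols] ref query
    # Sequence names are the last two columns; extra columns from -c/-l are
    # numeric and tolerated by taking the fixed 7-column numeric prefix.
    if len(fields) < 9:
        raise ParseError(f"line {lineno}: expected >= 9 columns, got {len(fields)}")
    try:
        s1, e1, s2, e2 = (int(fields[i]) for i in range(4))
        identity = float(fields[6])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed coords row: {exc}") from exc
    ref_id, query_id = fields[-2], fields[-1]
    rs, re_, ref_rev = _norm_1based(s1, e1)
    qs, qe, q_rev = _norm_1based(s2, e2)
    strand: Strand = "-" if ref_rev != q_rev else "+"
    return AlignmentBlock(query_id, qs, qe, ref_id, rs, re_, strand, identity)


def _parse_paf_row(fields: list[str], lineno: int) -> AlignmentBlock:
    # PAF cols 1-12: qname qlen qstart qend strand tname tlen tstart tend
    # matches alnlen mapq; optional tags ignored.  Coordinates already
    # 0-based half-open.  Identity = 100 * matches / alnlen.
    if len(fields) < 12:
        raise ParseError(f"line {lineno}: expected >= 12 PAF columns, got {len(fields)}")
    try:
        qs, qe = int(fields[2]), int(fields[3])
        strand = fields[4]
        ts, te = int(fields[7]), int(fields[8])
        matches, alnlen = int(fields[9]), int(fields[10])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed PAF row: {exc}") from exc
    if strand not in ("+", "-"):
        raise ParseError(f"line {lineno}: bad PAF strand {strand!r}")
    identity = 100.0 * matches / alnlen if alnlen else 0.0
    return AlignmentBlock(fields[0], qs, qe, fields[5], ts, te, strand, identity)


def parse_alignments(
    path: str | Path,
    dialect: Literal["coords_tab", "paf"],
    min_identity: float = 90.0,
    min_block: int = 1000,
) -> list[AlignmentBlock]:
    """Parse an alignment coordinate file, filtering weak/short blocks.

    ``coords_tab`` rows are 1-based inclusive and may carry reversed
    coordinate pairs; both are normalised (start < end, strand set).  PAF rows
    are taken as-is.  Rows with identity < ``min_identity`` or reference span
    < ``min_block`` are dropped.  Header/banner lines in coords files
    (``NUCMER``, ``[S1] ...``, ``===``, blank) are skipped.
    """
    if dialect not in ("coords_tab", "paf"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    row_parser = _parse_coords_row if dialect == "coords_tab" else _parse_paf_row
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "coords_tab":
                first = line.split("\t", 1)[0].strip()
                # banner/header lines never start with an integer
                try:
                    int(first.split()[0])
                except (ValueError, IndexError):
                    continue
            block = row_parser(line.split("\t"), lineno)
            if block.identity >= min_identity and block.aligned_length >= min_block:
                blocks.append(block)
    return blocks


# ---------------------------------------------------------------------------
# Interval algebra


class IntervalSet:
    """Per-reference sorted disjoint (merged, non-abutting) intervals."""

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None):
        self._data: dict[str, list[tuple[int, int]]] = {}
        if intervals:
            for ref_id, ivs in intervals.items():
                self._data[ref_id] = _merge(list(ivs))

    def __getitem__(self, ref_id: str) -> list[tuple[int, int]]:
        return self._data.get(ref_id, [])

    def ref_ids(self) -> list[str]:
        return sorted(self._data)

    def total_length(self, ref_id: str | None = None) -> int:
        if ref_id is not None:
            return sum(e - s for s, e in self[ref_id])
        return sum(e - s for ivs in self._data.values() for s, e in ivs)

    def items(self):
        return self._data.items()


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals; abutting intervals are coalesced."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if s >= e:
            raise ValueError(f"empty/inverted interval [{s},{e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def merge_coverage(blocks: Iterable[AlignmentBlock]) -> IntervalSet:
    """Union of reference intervals covered by any block, per reference."""
    by_ref: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        by_ref.setdefault(b.ref_id, []).append((b.ref_start, b.ref_end))
    return IntervalSet(by_ref)


def find_missing_regions(
    coverage: IntervalSet,
    ref_lengths: Mapping[str, int],
    min_length: int = 400_000,
) -> list[MissingRegion]:
    """Complement of coverage within each reference, filtered by length.

    The 400 kb default mirrors the threshold at which large absent regions
    become worth patching from donor sequence; it is a tunable, not a law.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    regions: list[MissingRegion] = []
    for ref_id in sorted(ref_lengths):
        length = ref_lengths[ref_id]
        pos = 0
        for s, e in coverage[ref_id]:
            if e > length:
                raise ValueError(
                    f"coverage on {ref_id!r} extends to {e} beyond stated length {length}"
                )
            if s - pos >= min_length:
                regions.append(MissingRegion(ref_id, pos, s))
            pos = max(pos, e)
        if length - pos >= min_length:
            regions.append(MissingRegion(ref_id, pos, length))
    return regions


# ---------------------------------------------------------------------------
# Coordinate projection


def project_ref_to_draft(
    blocks: Iterable[AlignmentBlock],
    ref_point: tuple[str, int],
    policy: Literal["left_flank", "right_flank"],
) -> tuple[str, int, Strand] | None:
    """Project a reference coordinate into query coordinates via a flank block.

    ``left_flank`` selects, among blocks with ``ref_end <= position``, the one
    with maximal ref_end (ties: longer block, then lexicographic query id) and
    returns the query coordinate of that block's reference end — the query
    position just right of the aligned flank sequence.  ``right_flank`` is the
    mirror image.  Returns None when no qualifying block exists.
    """
    ref_id, position = ref_point
    if policy == "left_flank":
        pool = [b for b in blocks if b.ref_id == ref_id and b.ref_end <= position]
        if not pool:
            return None
        best = min(pool, key=lambda b: (-b.ref_end, -b.aligned_length, b.query_id))
        coord = best.query_end if best.strand == "+" else best.query_start
        return best.query_id, coord, best.strand
    if policy == "right_flank":
        pool = [b for b in blocks if b.ref_id == ref_id and b.ref_start >= position]
        if not pool:
            return None
        best = min(pool, key=lambda b: (b.ref_start, -b.aligned_length, b.query_id))
        coord = best.query_start if best.strand == "+" else best.query_end
        return best.query_id, coord, best.strand
    raise ValueError(f"unknown projection policy {policy!r}")


def project_point_through_block(block: AlignmentBlock, ref_pos: int) -> int:
    """Affine projection of a reference position inside a block to the query."""
    if not block.ref_start <= ref_pos <= block.ref_end:
        raise ValueError(f"position {ref_pos} outside block ref interval")
    offset = ref_pos - block.ref_start
    if block.strand == "+":
        return block.query_start + offset
    return block.query_end - offset
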
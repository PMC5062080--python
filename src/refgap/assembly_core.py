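"""Sequence containers, FASTA round-trip, N-gap discovery and contiguity statistics.

The objects here are deliberately plain: a draft genome assembly is an ordered
collection of named scaffolds over the 5-letter nucleotide alphabet
``{A, C, G, T, N}``.  All coordinates are 0-based half-open; conversion to the
1-based inclusive conventions of on-disk formats happens only at format
boundaries (FASTA has no coordinates; AGP/coords writers convert explicitly).
"""

from __future__ import annotations

import gzip
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N} (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class DuplicateIdError(ValueError):
    """Two records in one assembly share an identifier."""


class AlphabetError(ValueError):
    """A sequence contains characters outside {A,C,G,T,N}."""


@dataclass(frozen=True)
class ScaffoldRecord:
    """One named scaffold: uppercase sequence over {A,C,G,T,N}.

    ``masked_fraction`` records the fraction of bases that were lowercase
    (soft-masked) in the input; the sequence itself is stored uppercased.
    """

    id: str
    seq: str
    masked_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid scaffold id {self.id!r}")
        if len(self.seq) == 0:
            raise ValueError(f"scaffold {self.id!r} has empty sequence")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise AlphabetError(
                f"scaffold {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def n_bases(self) -> int:
        return self.seq.count("N")

    def reverse_complement(self) -> "ScaffoldRecord":
        return ScaffoldRecord(self.id, reverse_complement(self.seq), self.masked_fraction)


@dataclass
class Assembly:
    """Ordered collection of scaffolds with pairwise-distinct ids."""

    records: list[ScaffoldRecord] = field(default_factory=list)
    name: str = "assembly"

    def __post_init__(self) -> None:
        self._index: dict[str, ScaffoldRecord] = {}
        for rec in self.records:
            if rec.id in self._index:
                raise DuplicateIdError(f"duplicate scaffold id {rec.id!r}")
            self._index[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ScaffoldRecord]:
        return iter(self.records)

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self._index

    def __getitem__(self, scaffold_id: str) -> ScaffoldRecord:
        return self._index[scaffold_id]

    def add(self, rec: ScaffoldRecord) -> None:
        if rec.id in self._index:
            raise DuplicateIdError(f"duplicate scaffold id {rec.id!r}")
        self.records.append(rec)
        self._index[rec.id] = rec

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)

    def lengths(self) -> dict[str, int]:
        return {r.id: r.length for r in self.records}


@dataclass(frozen=True)
class GapInterval:
    """A maximal run of N on one scaffold, 0-based half-open."""

    scaffold_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid gap interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


# Row labels of the stats report, in fixed output order.
STATS_ROWS = [
    "# scaffolds",
    "Largest scaffold (bp)",
    "Total length (bp)",
    "N50 (bp)",
    "N75 (bp)",
    "N95 (bp)",
    "L50",
    "L75",
    "L95",
    "GC%",
    "# N's (bases)",
    "# of gaps (sites of Ns)",
]


@dataclass(frozen=True)
class AssemblyStats:
    name: str
    n_scaffolds: int
    total_length: int
    max_length: int
    nx: dict[int, int]  # threshold % -> Nx (bp)
    lx: dict[int, int]  # threshold % -> Lx (count)
    gc_percent: float
    n_bases: int
    n_gap_sites: int

    def as_row_dict(self) -> dict[str, object]:
        d: dict[str, object] = {
            "# scaffolds": self.n_scaffolds,
            "Largest scaffold (bp)": self.max_length,
            "Total length (bp)": self.total_length,
        }
        for t in sorted(self.nx):
            d[f"N{t} (bp)"] = self.nx[t]
        for t in sorted(self.lx):
            d[f"L{t}"] = self.lx[t]
        d["GC%"] = round(self.gc_percent, 2)
        d["# N's (bases)"] = self.n_bases
        d["# of gaps (sites of Ns)"] = self.n_gap_sites
        return d


# ---------------------------------------------------------------------------
# FASTA I/O


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _locate_bad_char(path: str | Path) -> tuple[int, str]:
    """Find (1-based line number, char) of the first non-ACGTN sequence char.

    Only called on the error path, so the extra pass over the file is cheap
    relative to failing usefully.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            for c in line.strip():
                if c.upper() not in ALPHABET:
                    return lineno, c
    return 0, "?"


def read_fasta(path: str | Path, name: str | None = None, strict: bool = True) -> Assembly:
    """Read a (possibly gzipped) FASTA file into an :class:`Assembly`.

    Sequences are uppercased; the lowercase (soft-masked) fraction is kept as
    per-record metadata.  In strict mode (default) any character outside
    {A,C,G,T,N} aborts with the offending line number; in lenient mode such
    characters are mapped to N.

    Raises
    ------
    DuplicateIdError
        if two headers share an identifier.
    AlphabetError
        in strict mode, on the first non-ACGTN character.
    ValueError
        on an empty sequence.
    """
    path = Path(path)
    assembly = Assembly(name=name if name is not None else path.stem)
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            raw = str(rec.seq)
            if len(raw) == 0:
                raise ValueError(f"scaffold {rec.id!r} has empty sequence in {path}")
            n_lower = sum(1 for c in raw if c.islower())
            seq = raw.upper()
            if set(seq) - ALPHABET:
                if strict:
                    lineno, char = _locate_bad_char(path)
                    raise AlphabetError(
                        f"{path}:{lineno}: non-ACGTN character {char!r} "
                        f"in scaffold {rec.id!r} (use strict=False to map to N)"
                    )
                seq = re.sub(r"[^ACGTN]", "N", seq)
            assembly.add(ScaffoldRecord(rec.id, seq, masked_fraction=n_lower / len(raw)))
    return assembly


def write_fasta(assembly: Assembly, path: str | Path, wrap: int = 60) -> None:
    """Write an assembly as FASTA with ``wrap`` bases per sequence line."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    with _open_text(path, "wt") as fh:
        for rec in assembly:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, wrap):
                fh.write(rec.seq[i : i + wrap])
                fh.write("\n")


# ---------------------------------------------------------------------------
# N-runs and statistics


def find_n_runs(record: ScaffoldRecord, min_run: int = 1) -> list[GapInterval]:
    """All maximal N-runs of length >= ``min_run``, sorted by start."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    return [
        GapInterval(record.id, m.start(), m.end())
        for m in re.finditer(r"N+", record.seq)
        if m.end() - m.start() >= min_run
    ]


def find_all_gaps(assembly: Assembly, min_run: int = 1) -> list[GapInterval]:
    gaps: list[GapInterval] = []
    for rec in assembly:
        gaps.extend(find_n_runs(rec, min_run))
    return gaps


def compute_stats(
    assembly: Assembly,
    thresholds: Sequence[int] = (50, 75, 95),
    gap_min_run: int = 1,
) -> AssemblyStats:
    """Contiguity and composition statistics.

    Nx is the length of the scaffold at which the cumulative length of
    scaffolds sorted by descending length first reaches >= x% of the total;
    Lx is the number of scaffolds in that prefix.  Length ties are broken by
    lexicographic id so Lx accounting is deterministic.  GC% is computed over
    non-N bases only.
    """
    if len(assembly) == 0:
        raise ValueError("cannot compute statistics of an empty assembly")
    if any(not 0 < t <= 100 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 100]")

    ordered = sorted(assembly, key=lambda r: (-r.length, r.id))
    total = sum(r.length for r in ordered)

    nx: dict[int, int] = {}
    lx: dict[int, int] = {}
    for t in thresholds:
        target = t / 100.0 * total
        cum = 0
        for i, rec in enumerate(ordered):
            cum += rec.length
            if cum >= target:
                nx[t] = rec.length
                lx[t] = i + 1
                break

    gc = at = n_total = gap_sites = 0
    for rec in assembly:
        gc += rec.seq.count("G") + rec.seq.count("C")
        at += rec.seq.count("A") + rec.seq.count("T")
        n_total += rec.seq.count("N")
        gap_sites += len(find_n_runs(rec, gap_min_run))
    gc_percent = 100.0 * gc / (gc + at) if gc + at else 0.0

    return AssemblyStats(
        name=assembly.name,
        n_scaffolds=len(assembly),
        total_length=total,
        max_length=ordered[0].length,
        nx=nx,
        lx=lx,
        gc_percent=gc_percent,
        n_bases=n_total,
        n_gap_sites=gap_sites,
    )


def stats_table(stats: Iterable[AssemblyStats]) -> "pandas.DataFrame":  # noqa: F821
    """One column per assembly, rows in the fixed report order."""
    import pandas as pd

    stats = list(stats)
    # object-dtype series keep counts integral instead of upcasting the column
    cols = {s.name: pd.Series(s.as_row_dict(), dtype=object) for s in stats}
    rows = list(stats[0].as_row_dict().keys()) if stats else STATS_ROWS
    return pd.DataFrame(cols, index=rows)


def write_stats_report(stats: Iterable[AssemblyStats], tsv_path: str | Path,
                       json_path: str | Path | None = None) -> None:
    stats = list(stats)
    df = stats_table(stats)
    df.to_csv(tsv_path, sep="\t", index_label="Statistic")
    if json_path is not None:
        payload = {s.name: s.as_row_dict() for s in stats}
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
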
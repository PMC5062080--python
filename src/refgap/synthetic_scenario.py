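"""Truth-based synthetic scenarios for exercising the improvement workflow.

A scenario starts from a random truth genome and derives every input the
toolkit consumes, with the truth coordinates recorded in a ledger so any
module's output can be scored exactly:

* the reference IS the truth;
* the draft is the truth with selected regions excised and replaced by an
  N-run one tenth of the excised length (an under-assembled gap whose size
  estimate is wrong, as real draft gaps usually are), optionally broken into
  scaffolds and optionally emitted reverse-complemented;
* the leftovers are the excised pieces, optionally with substitutions;
* draft-vs-reference and leftover-vs-reference alignments are fabricated
  from the construction coordinates (no aligner involved), in both the
  MUMmer ``show-coords -T`` and PAF dialects;
* markers are sampled on the draft scaffolds with genetic position equal to
  the truth physical position on a linear cM scale, plus optional Gaussian
  noise.

All randomness flows from one seeded generator in a fixed call order
(truth bases, excisions, breaks, flips, substitutions, markers), so a
scenario is bit-reproducible for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .assembly_core import Assembly, ScaffoldRecord, reverse_complement, write_fasta
from .marker_anchor import GeneticMap, MapEntry, MarkerHit
from .wga_model import AlignmentBlock

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults are a desk-scale analogue of a reference-guided improvement
    run: a few hundred-kb chromosomes, a handful of large excisions well
    above the missing-region threshold, noise off.  GC and the cM/Mb scale
    sit in the range typical of a small grass genome.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 200_000
    gc: float = 0.46
    n_excised: int = 5  # genome-wide total, placed on random chromosomes
    excised_length_range: tuple[int, int] = (8_000, 15_000)
    missing_min_length: int = 5_000
    substitution_rate: float = 0.0
    n_scaffold_breaks: int = 0  # per chromosome
    markers_per_scaffold: int = 3
    marker_position_noise: float = 0.0  # cM standard deviation
    flip_fraction: float = 0.0  # fraction of draft scaffolds emitted revcomp
    cm_per_mb: float = 3.5
    margin: int = 2_000  # min distance between features and from ends

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if not 0.0 <= self.gc <= 1.0 or not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("gc and substitution_rate must lie in [0, 1]")
        lo, hi = self.excised_length_range
        if not 0 < lo <= hi:
            raise ValueError("bad excised_length_range")
        if self.n_excised > 0 and hi + 2 * self.margin >= self.chromosome_length:
            raise ValueError("excisions do not fit in a chromosome")


@dataclass
class Scenario:
    config: ScenarioConfig
    truth: Assembly
    reference: Assembly
    draft: Assembly
    leftovers: Assembly
    draft_vs_ref: list[AlignmentBlock]
    leftover_vs_ref: list[AlignmentBlock]
    maps: list[GeneticMap]
    marker_hits: list[MarkerHit]
    ledger: dict = field(default_factory=dict)

    @property
    def ref_lengths(self) -> dict[str, int]:
        return self.reference.lengths()


def generate_truth(config: ScenarioConfig) -> Assembly:
    """Seeded i.i.d. truth genome with P(G or C) = gc."""
    rng = np.random.default_rng(config.seed)
    return _generate_truth(rng, config)


def _generate_truth(rng: np.random.Generator, config: ScenarioConfig) -> Assembly:
    p = [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    truth = Assembly(name="truth")
    for i in range(1, config.n_chromosomes + 1):
        idx = rng.choice(4, size=config.chromosome_length, p=p)
        truth.add(ScaffoldRecord(f"chr{i}", _BASES[idx].tobytes().decode()))
    return truth


def _place_excisions(
    rng: np.random.Generator, config: ScenarioConfig
) -> list[tuple[str, int, int]]:
    """Non-overlapping excision intervals, margin-separated, rejection-sampled."""
    chroms = [f"chr{i}" for i in range(1, config.n_chromosomes + 1)]
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[tuple[str, int, int]] = []
    lo, hi = config.excised_length_range
    for _ in range(config.n_excised):
        for attempt in range(1000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(lo, hi + 1))
            max_start = config.chromosome_length - length - config.margin
            if max_start <= config.margin:
                continue
            start = int(rng.integers(config.margin, max_start))
            end = start + length
            if all(
                end + config.margin <= s or e + config.margin <= start
                for s, e in placed[chrom]
            ):
                placed[chrom].append((start, end))
                out.append((chrom, start, end))
                break
        else:
            raise RuntimeError(
                "could not place excisions after 1000 attempts; "
                "use fewer/smaller excisions or longer chromosomes"
            )
    return sorted(out)


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = {b: i for i, b in enumerate(_BASES)}
    codes = np.array([idx[b] for b in arr], dtype=np.int64)
    hit = rng.random(len(seq)) < rate
    shifts = rng.integers(1, 4, size=int(hit.sum()))
    codes[hit] = (codes[hit] + shifts) % 4
    return _BASES[codes].tobytes().decode(), int(hit.sum())


def derive_scenario(truth: Assembly, config: ScenarioConfig) -> Scenario:
    """Derive draft, leftovers, alignments, markers and ledger from a truth genome.

    The truth must come from :func:`generate_truth` with the same config (the
    generator is re-seeded and the truth draw replayed so that downstream
    draws land at the documented points of the stream).
    """
    rng = np.random.default_rng(config.seed)
    _generate_truth(rng, config)  # replay to position the stream

    reference = Assembly(
        records=[ScaffoldRecord(r.id, r.seq) for r in truth], name="reference"
    )
    excisions = _place_excisions(rng, config)

    # --- draft chromosomes with N-run gap stand-ins --------------------------
    # per chromosome: draft seq, segment map [(draft_start, draft_end, truth_start)],
    # gap list [(draft_start, draft_end, excision idx)]
    draft_seq: dict[str, str] = {}
    segments: dict[str, list[tuple[int, int, int]]] = {}
    gaps: dict[str, list[tuple[int, int, int]]] = {}
    for chrom_rec in truth:
        chrom = chrom_rec.id
        segs: list[tuple[int, int, int]] = []
        gap_list: list[tuple[int, int, int]] = []
        parts: list[str] = []
        pos = 0  # truth cursor
        dpos = 0  # draft cursor
        for i, (c, s, e) in enumerate(excisions):
            if c != chrom:
                continue
            if s > pos:
                parts.append(chrom_rec.seq[pos:s])
                segs.append((dpos, dpos + (s - pos), pos))
                dpos += s - pos
            gap_len = max(1, (e - s) // 10)
            parts.append("N" * gap_len)
            gap_list.append((dpos, dpos + gap_len, i))
            dpos += gap_len
            pos = e
        if pos < chrom_rec.length:
            parts.append(chrom_rec.seq[pos:])
            segs.append((dpos, dpos + (chrom_rec.length - pos), pos))
            dpos += chrom_rec.length - pos
        draft_seq[chrom] = "".join(parts)
        segments[chrom] = segs
        gaps[chrom] = gap_list

    # --- scaffold breaks ------------------------------------------------------
    # break positions avoid N-runs (and a margin around them) so every gap
    # keeps both flanks on its scaffold
    scaffold_bounds: dict[str, list[tuple[int, int]]] = {}
    for chrom in draft_seq:
        L = len(draft_seq[chrom])
        forbidden = [(max(0, s - config.margin), min(L, e + config.margin))
                     for s, e, _ in gaps[chrom]]
        breaks: list[int] = []
        for _ in range(config.n_scaffold_breaks):
            for attempt in range(1000):
                b = int(rng.integers(config.margin, L - config.margin))
                if any(s <= b < e for s, e in forbidden):
                    continue
                if any(abs(b - o) < config.margin for o in breaks):
                    continue
                breaks.append(b)
                break
            else:
                raise RuntimeError("could not place scaffold breaks; relax margins")
        cuts = [0] + sorted(breaks) + [L]
        scaffold_bounds[chrom] = list(zip(cuts[:-1], cuts[1:]))

    # --- scaffolds, alignments, flips ----------------------------------------
    draft = Assembly(name="draft")
    draft_vs_ref: list[AlignmentBlock] = []
    scaffold_ledger: list[dict] = []
    chromosome_order: dict[str, list[str]] = {}
    gap_ledger: dict[int, tuple[str, int, int]] = {}  # excision idx -> scaffold gap
    scaffold_meta: dict[str, tuple[str, int, int, bool]] = {}
    for chrom in sorted(draft_seq):
        order: list[str] = []
        for k, (a, b) in enumerate(scaffold_bounds[chrom]):
            sid = f"scaffold_{chrom}_{k}"
            order.append(sid)
            flipped = bool(rng.random() < config.flip_fraction)
            seq = draft_seq[chrom][a:b]
            L = b - a
            local_blocks: list[tuple[int, int, int]] = []  # (qs, qe, truth_start)
            for ds, de, ts in segments[chrom]:
                s, e = max(ds, a), min(de, b)
                if s < e:
                    local_blocks.append((s - a, e - a, ts + (s - ds)))
            for gs, ge, idx in gaps[chrom]:
                if a <= gs and ge <= b:
                    lo_, hi_ = gs - a, ge - a
                    if flipped:
                        lo_, hi_ = L - hi_, L - lo_
                    gap_ledger[idx] = (sid, lo_, hi_)
            if flipped:
                seq = reverse_complement(seq)
            draft.add(ScaffoldRecord(sid, seq))
            scaffold_meta[sid] = (chrom, a, b, flipped)
            for qs, qe, ts in local_blocks:
                if flipped:
                    qs, qe = L - qe, L - qs
                draft_vs_ref.append(
                    AlignmentBlock(sid, qs, qe, chrom, ts, ts + (qe - qs),
                                   "-" if flipped else "+", 100.0)
                )
            scaffold_ledger.append(
                {
                    "id": sid,
                    "chromosome": chrom,
                    "chrom_draft_start": a,
                    "chrom_draft_end": b,
                    "orientation": "-" if flipped else "+",
                }
            )
        chromosome_order[chrom] = order

    # --- leftovers (excised pieces, optionally mutated) ----------------------
    leftovers = Assembly(name="leftovers")
    leftover_vs_ref: list[AlignmentBlock] = []
    excision_ledger: list[dict] = []
    for i, (chrom, s, e) in enumerate(excisions):
        lid = f"leftover_{i + 1}"
        seq, n_subs = _substitute(rng, truth[chrom].seq[s:e], config.substitution_rate)
        leftovers.add(ScaffoldRecord(lid, seq))
        identity = 100.0 * (len(seq) - n_subs) / len(seq)
        leftover_vs_ref.append(
            AlignmentBlock(lid, 0, len(seq), chrom, s, e, "+", identity)
        )
        sid, gs, ge = gap_ledger.get(i, ("", -1, -1))
        excision_ledger.append(
            {
                "chromosome": chrom,
                "start": s,
                "end": e,
                "length": e - s,
                "leftover_id": lid,
                "scaffold_id": sid,
                "gap_start": gs,
                "gap_end": ge,
            }
        )

    # --- markers --------------------------------------------------------------
    map_entries: list[MapEntry] = []
    marker_hits: list[MarkerHit] = []
    marker_ledger: list[dict] = []
    counter = 0
    for sid in (r.id for r in draft):
        chrom, a, b, flipped = scaffold_meta[sid]
        L = b - a
        # candidate scaffold-local positions: non-N, pre-flip coordinates
        candidates = np.concatenate(
            [
                np.arange(max(ds, a) - a, min(de, b) - a)
                for ds, de, _ in segments[chrom]
                if min(de, b) > max(ds, a)
            ]
        )
        k = min(config.markers_per_scaffold, len(candidates))
        if k == 0:
            continue
        chosen = np.sort(rng.choice(candidates, size=k, replace=False))
        for p_local in chosen:
            p_local = int(p_local)
            # truth coordinate via the segment containing this position
            p_chrom = a + p_local
            truth_bp = next(
                ts + (p_chrom - ds)
                for ds, de, ts in segments[chrom]
                if ds <= p_chrom < de
            )
            genetic = truth_bp / 1e6 * config.cm_per_mb
            if config.marker_position_noise > 0:
                genetic += float(rng.normal(0.0, config.marker_position_noise))
            p_hit = (L - 1 - p_local) if flipped else p_local
            counter += 1
            mid = f"marker_{counter:05d}"
            map_entries.append(MapEntry(mid, chrom, genetic))
            marker_hits.append(MarkerHit(mid, sid, p_hit, 100.0, 100.0))
            marker_ledger.append(
                {
                    "marker_id": mid,
                    "scaffold_id": sid,
                    "position": p_hit,
                    "chromosome": chrom,
                    "truth_bp": truth_bp,
                    "genetic_position": genetic,
                }
            )

    maps = [GeneticMap("synthmap", tuple(map_entries), weight=1.0)]
    ledger = {
        "config": asdict(config),
        "excisions": excision_ledger,
        "scaffolds": scaffold_ledger,
        "chromosome_order": chromosome_order,
        "markers": marker_ledger,
    }
    return Scenario(
        config=config,
        truth=truth,
        reference=reference,
        draft=draft,
        leftovers=leftovers,
        draft_vs_ref=draft_vs_ref,
        leftover_vs_ref=leftover_vs_ref,
        maps=maps,
        marker_hits=marker_hits,
        ledger=ledger,
    )


def generate_scenario(config: ScenarioConfig) -> Scenario:
    return derive_scenario(generate_truth(config), config)


# ---------------------------------------------------------------------------
# File emission


def _write_coords(blocks: list[AlignmentBlock], path: Path, ref: str, query: str) -> None:
    lines = [
        f"{ref} {query}",
        "NUCMER",
        "",
        "[S1]\t[E1]\t[S2]\t[E2]\t[LEN1]\t[LEN2]\t[% IDY]\t[TAGS]",
    ]
    for b in blocks:
        s1, e1 = b.ref_start + 1, b.ref_end
        if b.strand == "+":
            s2, e2 = b.query_start + 1, b.query_end
        else:
            s2, e2 = b.query_end, b.query_start + 1
        lines.append(
            "\t".join(
                str(x)
                for x in [
                    s1, e1, s2, e2,
                    b.ref_end - b.ref_start,
                    b.query_end - b.query_start,
                    f"{b.identity:.2f}",
                    b.ref_id, b.query_id,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _write_paf(
    blocks: list[AlignmentBlock],
    path: Path,
    query_lengths: dict[str, int],
    ref_lengths: dict[str, int],
) -> None:
    lines = []
    for b in blocks:
        alnlen = b.ref_end - b.ref_start
        matches = round(b.identity * alnlen / 100.0)
        lines.append(
            "\t".join(
                str(x)
                for x in [
                    b.query_id, query_lengths[b.query_id], b.query_start, b.query_end,
                    b.strand,
                    b.ref_id, ref_lengths[b.ref_id], b.ref_start, b.ref_end,
                    matches, alnlen, 60,
                ]
            )
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def write_scenario(scenario: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Write every scenario file in the formats the other modules read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "truth": outdir / "truth.fasta",
        "reference": outdir / "reference.fasta",
        "draft": outdir / "draft.fasta",
        "leftovers": outdir / "leftovers.fasta",
        "draft_vs_ref_coords": outdir / "draft_vs_ref.coords",
        "draft_vs_ref_paf": outdir / "draft_vs_ref.paf",
        "leftover_vs_ref_coords": outdir / "leftover_vs_ref.coords",
        "leftover_vs_ref_paf": outdir / "leftover_vs_ref.paf",
        "marker_hits": outdir / "marker_hits.tsv",
        "genetic_maps": outdir / "genetic_maps.csv",
        "ledger": outdir / "ledger.json",
    }
    write_fasta(scenario.truth, paths["truth"])
    write_fasta(scenario.reference, paths["reference"])
    write_fasta(scenario.draft, paths["draft"])
    write_fasta(scenario.leftovers, paths["leftovers"])
    _write_coords(scenario.draft_vs_ref, paths["draft_vs_ref_coords"],
                  "reference.fasta", "draft.fasta")
    _write_coords(scenario.leftover_vs_ref, paths["leftover_vs_ref_coords"],
                  "reference.fasta", "leftovers.fasta")
    _write_paf(scenario.draft_vs_ref, paths["draft_vs_ref_paf"],
               scenario.draft.lengths(), scenario.ref_lengths)
    _write_paf(scenario.leftover_vs_ref, paths["leftover_vs_ref_paf"],
               scenario.leftovers.lengths(), scenario.ref_lengths)

    blast_rows = []
    for h in scenario.marker_hits:
        blast_rows.append(
            "\t".join(
                str(x)
                for x in [
                    h.marker_id, h.scaffold_id, f"{h.identity:.2f}", 1, 0, 0,
                    1, 1, h.position + 1, h.position + 1, "1e-50", f"{h.score:.1f}",
                ]
            )
        )
    paths["marker_hits"].write_text("\n".join(blast_rows) + ("\n" if blast_rows else ""))

    map_lines = ["marker_id,map,chromosome,position"]
    for gmap in scenario.maps:
        for e in gmap.entries:
            map_lines.append(f"{e.marker_id},{gmap.name},{e.chromosome},{e.position!r}")
    paths["genetic_maps"].write_text("\n".join(map_lines) + "\n")

    paths["ledger"].write_text(json.dumps(scenario.ledger, indent=2) + "\n")
    return paths
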
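"""Donor assignment, patch planning/application, redundancy removal."""

import pytest

from refgap.agp import GapComponent, SequenceComponent
from refgap.assembly_core import Assembly, GapInterval, reverse_complement
from refgap.refpatch import (
    DonorPlacement,
    apply_patches,
    assign_donors,
    plan_patches,
    remove_redundant,
)
from refgap.wga_model import AlignmentBlock, MissingRegion

from conftest import make_assembly


def block(q, qs, qe, r, rs, re, strand="+", ident=100.0):
    return AlignmentBlock(q, qs, qe, r, rs, re, strand, ident)


def placement(donor_id, interval, target, at, orientation="+", anchor="left",
              gap=None, score=(100, 100.0)):
    return DonorPlacement(
        donor_id=donor_id, donor_interval=interval, target_scaffold=target,
        insert_at=at, orientation=orientation, anchor=anchor, replaces_gap=gap,
        ref_region=MissingRegion("r", 0, 1), score=score,
    )


class TestAssignDonors:
    region = MissingRegion("r", 300_000, 750_000)

    def test_no_blocks_empty_candidates(self):
        out = assign_donors([self.region], [])
        assert out[self.region] == []

    def test_contained_block_accepted(self):
        b = block("d1", 0, 350_000, "r", 350_000, 700_000)
        out = assign_donors([self.region], [b])
        assert out[self.region] == [b]

    def test_low_overlap_rejected(self):
        b = block("d1", 0, 400_000, "r", 600_000, 1_000_000)  # overlap 150k / 400k
        out = assign_donors([self.region], [b], min_region_overlap=0.5)
        assert out[self.region] == []

    def test_candidates_ordered_by_aligned_length(self):
        b1 = block("d1", 0, 200_000, "r", 400_000, 600_000)
        b2 = block("d2", 0, 350_000, "r", 350_000, 700_000)
        out = assign_donors([self.region], [b1, b2])
        assert [b.query_id for b in out[self.region]] == ["d2", "d1"]

    def test_donor_committed_to_single_best_region(self):
        r1 = MissingRegion("r", 0, 100)
        r2 = MissingRegion("r", 200, 300)
        # same donor qualifies for both; the longer alignment wins
        b1 = block("d1", 0, 50, "r", 10, 60)
        b2 = block("d1", 0, 90, "r", 205, 295)
        out = assign_donors([r1, r2], [b1, b2])
        assert out[r1] == []
        assert out[r2] == [b2]


class TestPlanPatches:
    def test_gap_interior_insertion(self):
        # draft scaffold covers ref [0,33M-like) and beyond a missing region
        draft = make_assembly({"s1": "ACGT" * 25 + "N" * 10 + "ACGT" * 25})
        region = MissingRegion("r", 100, 600)
        dblocks = [
            block("s1", 0, 100, "r", 0, 100),
            block("s1", 110, 210, "r", 600, 700),
        ]
        donor_block = block("d1", 0, 500, "r", 100, 600)
        plan = plan_patches([region], {region: [donor_block]}, dblocks, draft)
        (pl,) = plan.placements
        assert pl.target_scaffold == "s1"
        assert pl.insert_at == 100
        assert pl.replaces_gap == GapInterval("s1", 100, 110)
        assert pl.orientation == "+"

    def test_split_flank_noted(self):
        draft = make_assembly({"s1": "A" * 100, "s2": "A" * 100})
        region = MissingRegion("r", 100, 600)
        dblocks = [
            block("s1", 0, 100, "r", 0, 100),
            block("s2", 0, 100, "r", 600, 700),
        ]
        donor_block = block("d1", 0, 500, "r", 100, 600)
        plan = plan_patches([region], {region: [donor_block]}, dblocks, draft)
        (pl,) = plan.placements
        assert pl.target_scaffold == "s1" and pl.insert_at == 100
        assert "split_flank" in pl.notes

    def test_prepend_extension_via_right_flank(self):
        draft = make_assembly({"s1": "A" * 100})
        region = MissingRegion("r", 0, 500)
        dblocks = [block("s1", 0, 100, "r", 500, 600)]
        donor_block = block("d1", 0, 500, "r", 0, 500)
        plan = plan_patches([region], {region: [donor_block]}, dblocks, draft)
        (pl,) = plan.placements
        assert pl.anchor == "right" and pl.insert_at == 0
        assert "prepend_extension" in pl.notes

    def test_unanchored_and_empty_ledgered(self):
        draft = make_assembly({"s1": "A" * 100})
        r1 = MissingRegion("r2", 0, 500)  # no blocks on r2 at all
        r2 = MissingRegion("r", 1000, 2000)
        plan = plan_patches([r1, r2], {r1: [block("d1", 0, 500, "r2", 0, 500)], r2: []},
                            [block("s1", 0, 100, "r", 0, 100)], draft)
        assert plan.placements == []
        statuses = {e["status"] for e in plan.entries}
        assert statuses == {"unanchored", "no_candidate"}

    def test_minus_flank_composes_orientation(self):
        draft = make_assembly({"s1": "A" * 100})
        region = MissingRegion("r", 100, 600)
        dblocks = [block("s1", 0, 100, "r", 0, 100, "-")]
        donor_block = block("d1", 0, 500, "r", 100, 600, "-")
        plan = plan_patches([region], {region: [donor_block]}, dblocks, draft)
        assert plan.placements[0].orientation == "+"  # (-) x (-) = (+)


class TestApplyPatches:
    def test_empty_placements_identity(self):
        draft = make_assembly({"s1": "ACGTNNNACGT"})
        out, report, comps = apply_patches(draft, [], Assembly(name="d"))
        assert [(r.id, r.seq) for r in out] == [(r.id, r.seq) for r in draft]
        assert report.n_placed == report.bases_inserted == 0

    def test_gap_replacement_with_spacer(self):
        draft = make_assembly({"s1": "AAAANNNNNNAAAA"})
        donors = make_assembly({"d1": "CCC"})
        pl = placement("d1", (0, 3), "s1", 4, gap=GapInterval("s1", 4, 10))
        out, report, comps = apply_patches(draft, [pl], donors, spacer=1)
        assert out["s1"].seq == "AAAANCCCNAAAA"
        assert report.n_gap_bases_closed == 6
        assert report.bases_inserted == 3

    def test_minus_orientation_reverse_complements(self):
        draft = make_assembly({"s1": "AAAANNNNNNAAAA"})
        donors = make_assembly({"d1": "CCG"})
        pl = placement("d1", (0, 3), "s1", 4, orientation="-",
                       gap=GapInterval("s1", 4, 10))
        out, _, _ = apply_patches(draft, [pl], donors, spacer=1)
        assert out["s1"].seq == "AAAANCGGNAAAA"

    def test_interior_insertion_spacer_on_unanchored_side(self):
        draft = make_assembly({"s1": "AAAATTTT"})
        donors = make_assembly({"d1": "CC"})
        pl = placement("d1", (0, 2), "s1", 4)
        out, _, _ = apply_patches(draft, [pl], donors, spacer=3)
        assert out["s1"].seq == "AAAACCNNNTTTT"

    def test_append_at_terminus_no_spacer(self):
        draft = make_assembly({"s1": "AAAA"})
        donors = make_assembly({"d1": "CC"})
        pl = placement("d1", (0, 2), "s1", 4)
        out, _, _ = apply_patches(draft, [pl], donors, spacer=3)
        assert out["s1"].seq == "AAAACC"

    def test_conflicting_placement_skipped(self):
        draft = make_assembly({"s1": "AAAANNNNNNAAAA"})
        donors = make_assembly({"d1": "CCC", "d2": "GGG"})
        gap = GapInterval("s1", 4, 10)
        p1 = placement("d1", (0, 3), "s1", 4, gap=gap, score=(300, 99.0))
        p2 = placement("d2", (0, 3), "s1", 4, gap=gap, score=(200, 99.0))
        out, report, _ = apply_patches(draft, [p1, p2], donors, spacer=1)
        assert report.n_placed == 1
        assert report.n_skipped_conflict == 1
        assert out["s1"].seq == "AAAANCCCNAAAA"  # higher-ranked d1 won

    def test_unknown_donor_is_hard_error(self):
        draft = make_assembly({"s1": "AAAA"})
        with pytest.raises(KeyError, match="ghost"):
            apply_patches(draft, [placement("ghost", (0, 1), "s1", 0)], Assembly())

    def test_total_length_accounting(self):
        draft = make_assembly({"s1": "AAAANNNNNNAAAA"})
        donors = make_assembly({"d1": "CCCCC"})
        pl = placement("d1", (0, 5), "s1", 4, gap=GapInterval("s1", 4, 10))
        out, report, _ = apply_patches(draft, [pl], donors, spacer=2)
        expected = draft.total_length + report.bases_inserted + 2 * 2 - 6
        assert out.total_length == expected

    def test_provenance_components_replay(self):
        """Every non-N output base traces to exactly one source slice, in order."""
        draft = make_assembly({"s1": "AAAANNNNNNTTTT"})
        donors = make_assembly({"d1": "CCGTT"})
        pl = placement("d1", (1, 4), "s1", 4, orientation="-",
                       gap=GapInterval("s1", 4, 10))
        out, _, comps = apply_patches(draft, [pl], donors, spacer=2)
        sources = {"s1": draft["s1"].seq, "d1": donors["d1"].seq}
        rebuilt = []
        for c in comps["s1"]:
            if isinstance(c, GapComponent):
                rebuilt.append("N" * c.length)
            else:
                piece = sources[c.source_id][c.start : c.end]
                rebuilt.append(reverse_complement(piece) if c.orientation == "-" else piece)
        assert "".join(rebuilt) == out["s1"].seq
        seq_comps = [c for c in comps["s1"] if isinstance(c, SequenceComponent)]
        assert [c.source_id for c in seq_comps] == ["s1", "d1", "s1"]


class TestRemoveRedundant:
    def test_unaligned_leftover_kept(self):
        lo = make_assembly({"l1": "A" * 1000})
        kept, removed = remove_redundant(lo, [])
        assert [r.id for r in kept] == ["l1"] and removed == []

    def test_high_coverage_removed(self):
        lo = make_assembly({"l1": "A" * 1000})
        blocks = [
            block("l1", 0, 600, "m", 0, 600, ident=99.0),
            block("l1", 500, 980, "m", 5000, 5480, ident=99.0),
        ]
        kept, removed = remove_redundant(lo, blocks, cov_threshold=0.95, id_threshold=95)
        assert removed == ["l1"] and len(kept) == 0

    def test_low_identity_blocks_ignored(self):
        lo = make_assembly({"l1": "A" * 1000})
        blocks = [
            block("l1", 0, 600, "m", 0, 600, ident=90.0),
            block("l1", 500, 980, "m", 5000, 5480, ident=90.0),
        ]
        kept, removed = remove_redundant(lo, blocks, cov_threshold=0.95, id_threshold=95)
        assert removed == [] and len(kept) == 1

    def test_cov_threshold_monotone(self, rng):
        """Raising cov_threshold never removes more leftovers."""
        lo = make_assembly({f"l{i}": "A" * 500 for i in range(10)})
        blocks = []
        for i in range(10):
            for _ in range(int(rng.integers(0, 4))):
                s = int(rng.integers(0, 400))
                e = int(rng.integers(s + 1, 501))
                blocks.append(block(f"l{i}", s, e, "m", 0, e - s, ident=99.0))
        prev = None
        for cov in (0.5, 0.7, 0.9, 0.99):
            _, removed = remove_redundant(lo, blocks, cov_threshold=cov)
            if prev is not None:
                assert set(removed) <= prev
            prev = set(removed)


class TestScenarioRecovery:
    def test_noise_free_round_trip(self, noise_free_scenario):
        """Missing-region detection + patching reconstructs the truth exactly."""
        from refgap import wga_model

        sc = noise_free_scenario
        cov = wga_model.merge_coverage(sc.draft_vs_ref)
        missing = wga_model.find_missing_regions(
            cov, sc.ref_lengths, sc.config.missing_min_length
        )
        true_regions = {
            (e["chromosome"], e["start"], e["end"]) for e in sc.ledger["excisions"]
        }
        assert {(m.ref_id, m.start, m.end) for m in missing} == true_regions

        cands = assign_donors(missing, sc.leftover_vs_ref)
        plan = plan_patches(missing, cands, sc.draft_vs_ref, sc.draft)
        # every donor lands at its true locus
        by_donor = {e["leftover_id"]: e for e in sc.ledger["excisions"]}
        for pl in plan.placements:
            truth = by_donor[pl.donor_id]
            assert pl.target_scaffold == truth["scaffold_id"]
            assert pl.replaces_gap is not None
            assert (pl.replaces_gap.start, pl.replaces_gap.end) == (
                truth["gap_start"], truth["gap_end"]
            )
        patched, report, _ = apply_patches(sc.draft, plan.placements, sc.leftovers)
        assert report.n_placed == len(sc.ledger["excisions"])
        assert report.n_skipped_conflict == 0
        for rec in patched:
            chrom = rec.id.split("_")[1]
            assert rec.seq.replace("N", "") == sc.truth[chrom].seq

    def test_n_count_bounded_by_spacers(self, noise_free_scenario):
        from refgap import wga_model

        sc = noise_free_scenario
        cov = wga_model.merge_coverage(sc.draft_vs_ref)
        missing = wga_model.find_missing_regions(
            cov, sc.ref_lengths, sc.config.missing_min_length
        )
        cands = assign_donors(missing, sc.leftover_vs_ref)
        plan = plan_patches(missing, cands, sc.draft_vs_ref, sc.draft)
        spacer = 100
        before = sum(r.n_bases() for r in sc.draft)
        patched, report, _ = apply_patches(sc.draft, plan.placements, sc.leftovers, spacer)
        after = sum(r.n_bases() for r in patched)
        assert after - before <= report.n_placed * 2 * spacer
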
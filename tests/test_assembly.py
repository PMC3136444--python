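"""Map-guided supercontig ordering, discrepancy detection, split decisions."""

import numpy as np
import pandas as pd
import pytest

from ril_atlas.assembly import (Discrepancy, Gap, Supercontig, apply_splits,
                                assembly_report, assign_and_order, choose_split,
                                detect_discrepancies, split_supercontig)
from ril_atlas.linkage import map_from_positions

from conftest import make_marker_table


def _map_for(markers, genetic, physical=None, chromosome="I"):
    k = make_marker_table(markers, chromosome=chromosome, genetic=genetic)
    if physical is not None:
        k["physical_bp"] = physical
    return map_from_positions(k)


class TestAssignAndOrder:
    def test_single_marker_placed_unoriented(self):
        sctgs = [Supercontig("fpc0001", 1000, markers=[("a", 500)])]
        lmap = _map_for(["a", "b"], [0.0, 10.0])
        asm = assign_and_order(sctgs, lmap, None)
        pl = asm.chromosomes["I"][0]
        assert pl.name == "fpc0001" and pl.orientation == 0

    def test_reversed_marker_order_flips_contig(self):
        sctgs = [Supercontig("fpc0002", 2000,
                             markers=[("a", 1500), ("b", 200)])]
        lmap = _map_for(["a", "b"], [10.0, 20.0])
        asm = assign_and_order(sctgs, lmap, None)
        assert asm.chromosomes["I"][0].orientation == -1

    def test_no_marker_contig_unassembled(self):
        sctgs = [Supercontig("fpc0003", 500)]
        lmap = _map_for(["a", "b"], [0.0, 10.0])
        asm = assign_and_order(sctgs, lmap, None)
        assert asm.unassembled == ["fpc0003"]

    def test_tied_point_contigs_go_to_random_bin(self):
        sctgs = [Supercontig("fpc0004", 100, markers=[("a", 50)]),
                 Supercontig("fpc0005", 100, markers=[("b", 50)]),
                 Supercontig("fpc0006", 100, markers=[("c", 50)])]
        lmap = _map_for(["a", "b", "c"], [5.0, 5.0, 12.0])
        asm = assign_and_order(sctgs, lmap, None)
        assert asm.random_bin["I"] == ["fpc0004", "fpc0005"]
        assert [p.name for p in asm.chromosomes["I"]] == ["fpc0006"]

    def test_truth_layout_reconstructed(self):
        """Five contigs shuffled and reassembled into the truth order."""
        rng = np.random.default_rng(4)
        names = [f"fpc{i:04d}" for i in range(5)]
        lengths = [4000, 3000, 5000, 2000, 6000]
        markers, genetic, physical = [], [], []
        sctgs = []
        offset = 0
        cm = 0.0
        for name, length in zip(names, lengths):
            ms = [(f"{name}_ma", 500), (f"{name}_mb", length - 500)]
            sctgs.append(Supercontig(name, length, markers=list(ms)))
            for mn, pos in ms:
                markers.append(mn)
                physical.append(offset + pos)
                genetic.append(cm)
                cm += 2.0
            offset += length
        lmap = _map_for(markers, genetic, physical=physical)
        shuffled = list(sctgs)
        rng.shuffle(shuffled)
        asm = assign_and_order(shuffled, lmap, None)
        placed = [p.name for p in asm.chromosomes["I"]]
        assert placed == names
        assert all(p.orientation == 1 for p in asm.chromosomes["I"])
        offsets = [p.offset for p in asm.chromosomes["I"]]
        assert offsets == [0, 4000, 7000, 12000, 14000]
        assert asm.total_placed_bp() == sum(lengths)


class TestDetectDiscrepancies:
    def _setup(self, genetic_q=15.0):
        p = Supercontig("fpc0010", 10_000,
                        gaps=[Gap(4000), Gap(6000)],
                        markers=[("p1", 1000), ("p2", 9000)])
        q = Supercontig("fpc0011", 2000, markers=[("q1", 1000)])
        lmap = _map_for(["p1", "q1", "p2"], [10.0, genetic_q, 20.0],
                        physical=[1000, 20_000, 9000])
        return p, q, lmap

    def test_insertion_case_flagged(self):
        p, q, lmap = self._setup()
        asm = assign_and_order([p, q], lmap, None)
        found = detect_discrepancies(asm, lmap, None, [p, q])
        ins = [d for d in found if d.kind == "insertion"]
        assert len(ins) == 1
        assert ins[0].supercontig == "fpc0010" and ins[0].donor == "fpc0011"

    def test_internal_order_conflict_flagged(self):
        # genetic order 0, 8, 4 along the contig: no orientation fixes it
        s = Supercontig("fpc0012", 5000,
                        markers=[("m1", 1000), ("m2", 3000), ("m3", 4000)])
        lmap = _map_for(["m1", "m3", "m2"], [0.0, 4.0, 8.0],
                        physical=[100, 200, 300])
        asm = assign_and_order([s], lmap, None)
        found = detect_discrepancies(asm, lmap, None, [s])
        assert any(d.kind == "internal_order" for d in found)

    def test_concordant_assembly_clean(self):
        s1 = Supercontig("fpc0013", 5000, markers=[("a", 500), ("b", 4500)])
        s2 = Supercontig("fpc0014", 5000, markers=[("c", 500), ("d", 4500)])
        lmap = _map_for(["a", "b", "c", "d"], [0.0, 5.0, 10.0, 15.0],
                        physical=[500, 4500, 5500, 9500])
        asm = assign_and_order([s1, s2], lmap, None)
        assert detect_discrepancies(asm, lmap, None, [s1, s2]) == []


class TestChooseSplit:
    def test_interpolation_with_tie_toward_lower_coordinate(self):
        """Donor at 15 cM between flanks (10 cM @ 1.0 Mbp, 20 cM @ 2.0 Mbp)."""
        sctg = Supercontig("fpc0020", 3_000_000,
                           gaps=[Gap(1_400_000), Gap(1_600_000)],
                           markers=[("r1", 1_000_000), ("r2", 2_000_000)])
        d = Discrepancy(kind="insertion", supercontig="fpc0020", donor="fpc0021",
                        donor_marker=("q", 15.0),
                        flanks=(("r1", 10.0, 1_000_000), ("r2", 20.0, 2_000_000)))
        dec = choose_split(d, sctg)
        assert dec.rule == "interpolate"
        assert dec.positions == (1_400_000,)  # 1.5 Mbp target; tie -> lower

    def test_nonrecombinant_flank_uses_nearest_gap(self):
        sctg = Supercontig("fpc0022", 3_000_000,
                           gaps=[Gap(1_200_000), Gap(2_600_000)],
                           markers=[("r1", 1_000_000), ("r2", 2_000_000)])
        d = Discrepancy(kind="insertion", supercontig="fpc0022", donor="x",
                        donor_marker=("q", 10.0),
                        flanks=(("r1", 10.0, 1_000_000), ("r2", 20.0, 2_000_000)))
        dec = choose_split(d, sctg)
        assert dec.rule == "minimize_distance"
        assert dec.positions == (1_200_000,)

    def test_reorder_picks_smallest_fragment_gap(self):
        sctg = Supercontig("fpc0023", 1_000_000,
                           gaps=[Gap(100_000), Gap(500_000), Gap(900_000)],
                           markers=[("m", 50_000)])
        d = Discrepancy(kind="internal_order", supercontig="fpc0023")
        dec = choose_split(d, sctg)
        assert dec.rule == "smallest_fragment"
        assert dec.positions == (100_000,)

    def test_supported_gaps_not_eligible(self):
        sctg = Supercontig("fpc0024", 1_000_000,
                           gaps=[Gap(300_000, supported=True)],
                           markers=[("m", 350_000)])
        d = Discrepancy(kind="internal_order", supercontig="fpc0024")
        dec = choose_split(d, sctg)
        assert dec.rule == "move_discrepant_contig"


class TestApplySplits:
    def test_first_split_letter_suffixes(self):
        sctg = Supercontig("fpc0001", 1000, gaps=[Gap(400)])
        frags = split_supercontig(sctg, [400])
        assert [f.name for f in frags] == ["fpc0001a", "fpc0001b"]
        assert [f.length for f in frags] == [400, 600]

    def test_resplit_suffixed_contig_digit_rule(self):
        sctg = Supercontig("fpc0071c", 1000)
        frags = split_supercontig(sctg, [300])
        # largest fragment keeps the letter with a digit appended
        assert sorted(f.name for f in frags) == ["fpc0071c2", "fpc0071d"]
        largest = max(frags, key=lambda f: f.length)
        assert largest.name == "fpc0071c2"

    def test_length_conserved_and_markers_reassigned(self):
        sctg = Supercontig("fpc0030", 10_000, gaps=[Gap(3000), Gap(7000)],
                           markers=[("a", 1000), ("b", 5000), ("c", 9000)])
        frags = split_supercontig(sctg, [3000, 7000])
        assert sum(f.length for f in frags) == 10_000
        assert [len(f.markers) for f in frags] == [1, 1, 1]
        assert frags[1].markers == [("b", 2000)]

    def test_split_outside_bounds_errors(self):
        with pytest.raises(ValueError):
            split_supercontig(Supercontig("fpc0031", 100), [100])

    def test_zero_decisions_identity_and_discrepancies_nonincreasing(self):
        p = Supercontig("fpc0040", 10_000, gaps=[Gap(4000, False)],
                        markers=[("p1", 1000), ("p2", 9000)])
        q = Supercontig("fpc0041", 2000, markers=[("q1", 1000)])
        lmap = _map_for(["p1", "q1", "p2"], [10.0, 15.0, 20.0],
                        physical=[1000, 20_000, 9000])
        asm = assign_and_order([p, q], lmap, None)
        same, asm2 = apply_splits([p, q], [], lmap, None)
        assert {s.name for s in same} == {"fpc0040", "fpc0041"}
        before = detect_discrepancies(asm, lmap, None, [p, q])
        decisions = [choose_split(d, p) for d in before if d.kind == "insertion"]
        new_sctgs, new_asm = apply_splits([p, q], decisions, lmap, None)
        after = detect_discrepancies(new_asm, lmap, None, new_sctgs)
        assert len(after) <= len(before)
        report = assembly_report(new_asm)
        assert set(report.columns) == {"chromosome", "supercontig", "orientation",
                                       "start", "end"}
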
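import pytest

from umirep.demux import (RawRead, TagGroup, ThresholdError, apply_threshold,
                          demultiplex, group_by_tag, length_filter,
                          merge_length_variants, parse_read, tag_error_profile)
from umirep.simulate import SPACER

IDX = "AAGCT"


def make_read(tag="ACGTACGTACGT", payload="A" * 180, index=IDX):
    return index + tag + SPACER + payload


class TestParseRead:
    def test_exact_structure(self):
        seq = make_read(payload="G" * 180)
        raw, reason = parse_read("r1", seq, {IDX})
        assert reason is None
        assert raw.sample_index == IDX
        assert raw.tag == "ACGTACGTACGT"
        assert raw.payload == "G" * 180
        assert raw.payload_plus_spacer_len == 195

    def test_unknown_index_rejected(self):
        raw, reason = parse_read("r1", make_read(index="TTTTT"), {IDX})
        assert raw is None and reason == "unknown_index"

    def test_deletion_in_tag_gives_11bp_tag(self):
        seq = IDX + "ACGTACGTACG" + SPACER + "G" * 180  # 11-nt tag
        raw, reason = parse_read("r1", seq, {IDX})
        assert reason is None
        assert len(raw.tag) == 11

    def test_single_edit_in_spacer_tolerated(self):
        spaced = SPACER[:7] + "A" + SPACER[8:]
        assert spaced != SPACER
        seq = IDX + "ACGTACGTACGT" + spaced + "G" * 180
        raw, reason = parse_read("r1", seq, {IDX})
        assert reason is None
        assert raw.tag == "ACGTACGTACGT"

    def test_mangled_spacer_rejected(self):
        seq = IDX + "ACGTACGTACGT" + "CCCCCCCCCCCCCCC" + "G" * 180
        raw, reason = parse_read("r1", seq, {IDX})
        assert raw is None and reason == "no_spacer"


class TestLengthFilter:
    @pytest.mark.parametrize("length,kept", [(149, False), (150, True), (400, True)])
    def test_boundary(self, length, kept):
        raw = RawRead("r", IDX, "A" * 12, "G" * (length - 15), length)
        assert length_filter(raw) is kept


class TestMergeLengthVariants:
    @staticmethod
    def groups_from(tag_reads):
        return {t: TagGroup(t, ["P"] * n) for t, n in tag_reads.items()}

    def test_single_deletion_derivative(self):
        groups = self.groups_from({"A" * 12: 20, "A" * 11: 1})
        merge_length_variants(groups)
        assert groups["A" * 11].is_derivative
        assert groups["A" * 11].parent_tag == "A" * 12
        assert groups["A" * 12].merged_children == ["A" * 11]

    def test_single_insertion_derivative(self):
        groups = self.groups_from({"A" * 12: 5, "A" * 12 + "T": 1})
        merge_length_variants(groups)
        assert groups["A" * 12 + "T"].is_derivative

    def test_tie_goes_to_most_reads(self):
        # the 11-mer is one deletion away from both 12-mers
        t1, t2 = "T" + "A" * 11, "A" * 11 + "T"
        groups = self.groups_from({t1: 5, t2: 9, "A" * 11: 1})
        merge_length_variants(groups)
        assert groups["A" * 11].parent_tag == t2

    def test_unrelated_tag_not_merged(self):
        groups = self.groups_from({"A" * 12: 5, "C" * 11: 2})
        merge_length_variants(groups)
        assert not groups["C" * 11].is_derivative

    def test_hamming_neighbours_of_same_length_not_merged(self):
        groups = self.groups_from({"A" * 12: 5, "C" + "A" * 11: 3})
        merge_length_variants(groups)
        assert not groups["C" + "A" * 11].is_derivative
        assert not groups["A" * 12].is_derivative


def profile_from_spec(spec):
    """Build synthetic tag groups realizing {r: (n12, nderiv)}."""
    groups = {}
    i = 0
    for r, (n12, nderiv) in spec.items():
        for _ in range(n12):
            tag = format(i, "012b").replace("0", "A").replace("1", "C")
            groups[tag] = TagGroup(tag, ["P"] * r)
            i += 1
        for _ in range(nderiv):
            tag = format(i, "011b").replace("0", "T").replace("1", "G")
            g = TagGroup(tag, ["P"] * r)
            g.is_derivative = True
            groups[tag] = g
            i += 1
    return groups


class TestTagErrorProfile:
    def test_threshold_at_first_passing_bin(self):
        # fractions: r=1: 0.55, r=2: 0.80, r=3: 0.92, r=4: 0.97, r=5: 1.0
        groups = profile_from_spec({1: (55, 45), 2: (80, 20), 3: (92, 8),
                                    4: (97, 3), 5: (100, 0)})
        report = tag_error_profile(groups)
        assert report.bins[1][2] == pytest.approx(0.55)
        assert report.bins[3][2] == pytest.approx(0.92)
        assert report.r_star == 3

    def test_zero_error_profile(self):
        groups = profile_from_spec({1: (10, 0), 2: (20, 0)})
        report = tag_error_profile(groups)
        assert all(b[2] == 1.0 for b in report.bins.values())
        assert report.r_star == 1

    def test_all_bins_failing_aborts(self):
        groups = profile_from_spec({1: (1, 9), 2: (2, 8)})
        with pytest.raises(ThresholdError):
            tag_error_profile(groups)


class TestApplyThreshold:
    def test_below_threshold_removed_and_derivatives_never_retained(self):
        keep = TagGroup("A" * 12, ["P"] * 3)
        low = TagGroup("C" * 12, ["P"] * 2)
        deriv = TagGroup("G" * 13, ["P"] * 9)
        deriv.is_derivative = True
        retained = apply_threshold({g.tag: g for g in (keep, low, deriv)}, 3)
        assert [g.tag for g in retained] == ["A" * 12]


class TestOnSimulatedRuns:
    def test_zero_error_recovers_exact_molecule_count(self, zero_error_run):
        cfg, clones, reads, molecules = zero_error_run
        by_index, tally = demultiplex(reads, [cfg.sample_index])
        groups = merge_length_variants(group_by_tag(by_index[cfg.sample_index]))
        report = tag_error_profile(groups)
        retained = apply_threshold(groups, report.r_star)
        assert len(retained) == cfg.n_molecules
        assert {g.tag for g in retained} == {m.barcode for m in molecules}
        assert tally["unknown_index"] == tally["no_spacer"] == tally["short"] == 0

    def test_partition_property(self, noisy_run):
        cfg, clones, reads, molecules = noisy_run
        by_index, tally = demultiplex(reads, [cfg.sample_index])
        raw = by_index[cfg.sample_index]
        # every read is rejected, dropped short, or in exactly one tag group
        assert sum(tally.values()) == len(reads)
        groups = group_by_tag(raw)
        assert sum(g.n_reads for g in groups.values()) == tally["kept"] == len(raw)

    def test_noisy_molecule_count_close_and_profile_rises(self, noisy_run):
        cfg, clones, reads, molecules = noisy_run
        by_index, _ = demultiplex(reads, [cfg.sample_index])
        groups = merge_length_variants(group_by_tag(by_index[cfg.sample_index]))
        report = tag_error_profile(groups)
        retained = apply_threshold(groups, report.r_star)
        assert abs(len(retained) - cfg.n_molecules) / cfg.n_molecules < 0.03
        fracs = [report.bins[r][2] for r in sorted(report.bins) if report.bins[r][2] is not None]
        assert fracs[0] < 0.9 <= min(fracs[-3:])
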
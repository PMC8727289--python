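"""Pattern-table IO, per-read call assembly, depth QC and the control split."""

import pytest

from epimrd import (
    ReadPattern,
    SampleReads,
    SplitSpec,
    ValidationError,
    from_bismark_calls,
    qc_filter,
    read_pattern_tsv,
    split_controls,
    write_pattern_tsv,
)


def make_sample(sample_id, depths: dict[str, int], n_cpgs: dict[str, int]):
    s = SampleReads(sample_id)
    for rid, depth in depths.items():
        if depth:
            s.add(ReadPattern(sample_id, rid, (0,) * n_cpgs[rid], depth))
    return s


class TestPatternTsv:
    def test_basic_row(self, tmp_path, toy_panel):
        p = tmp_path / "r.tsv"
        p.write_text("S1\ttoy\t0101\t12\n")
        samples = read_pattern_tsv(p, toy_panel)
        (s,) = samples
        (rp,) = s.patterns["toy"]
        assert (rp.pattern, rp.count) == ("0101", 12)

    def test_bad_alphabet_rejected(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("S1\ttoy\t012\t5\n")
        with pytest.raises(ValidationError, match=r"\{0,1\}"):
            read_pattern_tsv(p)

    def test_length_checked_against_panel(self, tmp_path, toy_panel):
        p = tmp_path / "r.tsv"
        p.write_text("S1\ttoy\t010\t5\n")
        with pytest.raises(ValidationError, match="S1"):
            read_pattern_tsv(p, toy_panel)

    def test_duplicate_rows_merge_additively(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("S1\ttoy\t0101\t12\nS1\ttoy\t0101\t8\n")
        (s,) = read_pattern_tsv(p)
        assert s.patterns["toy"][0].count == 20

    def test_round_trip_preserves_collapsed_counts(self, tmp_path):
        s = SampleReads("S1")
        s.add(ReadPattern("S1", "toy", (0, 1, 0, 1), 12, ((97, "A"),)))
        s.add(ReadPattern("S1", "toy", (1, 1, 1, 1), 3))
        path = tmp_path / "w.tsv"
        write_pattern_tsv([s], path)
        (back,) = read_pattern_tsv(path)
        assert {(p.pattern, p.count, p.allele_bases) for p in back.patterns["toy"]} == {
            ("0101", 12, ((97, "A"),)),
            ("1111", 3, ()),
        }


class TestBismarkAssembly:
    def test_read_covering_all_cpgs(self, toy_panel):
        calls = [("r1", sym, "chr1", pos) for sym, pos in
                 zip("+-+-", (100, 110, 120, 130))]
        sample, tally = from_bismark_calls(calls, toy_panel, "S1")
        assert sample.patterns["toy"][0].pattern == "1010"
        assert tally.reads_kept == 1

    def test_partial_read_discarded_and_counted(self, toy_panel):
        calls = [("r1", "+", "chr1", pos) for pos in (100, 110, 120)]
        sample, tally = from_bismark_calls(calls, toy_panel, "S1")
        assert sample.patterns == {}
        assert tally.reads_partial == 1

    def test_call_outside_panel_tallied(self, toy_panel):
        sample, tally = from_bismark_calls([("r1", "+", "chr9", 5)], toy_panel, "S1")
        assert tally.calls_outside_panel == 1

    def test_depth_conservation_against_simulator(self, panel):
        """Calls emitted for complete reads over two regions reassemble into
        exactly the emitted per-region depths."""
        r1, r2 = panel.regions[0], panel.regions[1]
        calls = []
        for i in range(60):
            region = r1 if i % 2 else r2
            for pos in region.cpg_positions:
                calls.append((f"read{i}", "+" if i % 3 else "-", region.chrom, pos))
        sample, tally = from_bismark_calls(calls, panel, "S1")
        assert sample.depth(r1.region_id) == 30
        assert sample.depth(r2.region_id) == 30
        assert tally.reads_kept == 60 and tally.reads_partial == 0


class TestQcFilter:
    N_CPGS = {"cg15289427": 14, "cg22797031": 10, "cg27630153": 15, "cg19586199": 9}

    def _sample(self, sid, depths):
        return make_sample(sid, dict(zip(self.N_CPGS, depths)), self.N_CPGS)

    def test_boundary_depth_50_kept(self, panel):
        kept, excl = qc_filter([self._sample("a", (60, 80, 50, 51))], panel)
        assert [s.sample_id for s in kept] == ["a"]

    def test_one_shallow_amplicon_excludes_sample(self, panel):
        kept, excl = qc_filter([self._sample("a", (60, 80, 49, 1000))], panel)
        assert [s.sample_id for s in excl] == ["a"]
        assert excl[0].qc_pass is False

    def test_empty_sample_excluded(self, panel):
        kept, excl = qc_filter([SampleReads("a")], panel)
        assert not kept and len(excl) == 1

    def test_conservation(self, panel):
        samples = [self._sample(str(i), (50 + i - 2,) * 4) for i in range(5)]
        kept, excl = qc_filter(samples, panel)
        assert len(kept) + len(excl) == 5
        assert {s.sample_id for s in kept} | {s.sample_id for s in excl} == {
            s.sample_id for s in samples
        }


class TestControlSplit:
    def _controls(self, n):
        return [SampleReads(f"c{i}") for i in range(n)]

    def test_seven_to_three_ratio(self):
        train, val = split_controls(self._controls(10), SplitSpec(seed=1))
        assert (len(train), len(val)) == (7, 3)
        assert {s.sample_id for s in train}.isdisjoint({s.sample_id for s in val})

    def test_deterministic_under_seed(self):
        a = split_controls(self._controls(10), SplitSpec(seed=7))
        b = split_controls(self._controls(10), SplitSpec(seed=7))
        assert [s.sample_id for s in a[0]] == [s.sample_id for s in b[0]]

    def test_three_controls_round_to_two_one(self):
        train, val = split_controls(self._controls(3), SplitSpec(seed=0))
        assert (len(train), len(val)) == (2, 1)

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValidationError):
            split_controls(self._controls(1))
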
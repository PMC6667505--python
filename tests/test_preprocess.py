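"""Demultiplexing, 5'-tag extraction, UMI de-duplication, coverage export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capcall import preprocess as pp
from capcall import simulate as sim
from conftest import make_tags


# ---------------------------------------------------------------------------
# barcode layout


class TestBarcodeLayout:
    def test_mapcap_layout(self):
        lay = pp.parse_barcode_layout("NNNNNTTTTTTNN")
        assert lay.length == 13
        assert lay.index_positions == tuple(range(5, 11))
        assert lay.umi_positions == (0, 1, 2, 3, 4, 11, 12)
        assert lay.umi_length == 7

    def test_index_only_layout_has_empty_umi(self):
        lay = pp.parse_barcode_layout("TTTTTT")
        assert lay.index_length == 6
        assert lay.umi_positions == ()

    def test_illegal_character_names_offset(self):
        with pytest.raises(pp.LayoutError, match="offset 2"):
            pp.parse_barcode_layout("NNQTT")

    def test_empty_pattern_rejected(self):
        with pytest.raises(pp.LayoutError):
            pp.parse_barcode_layout("")

    def test_partition_invariant(self):
        lay = pp.parse_barcode_layout("NTNTNT")
        assert sorted(lay.index_positions + lay.umi_positions) == list(range(6))
        assert not set(lay.index_positions) & set(lay.umi_positions)


# ---------------------------------------------------------------------------
# demultiplexing


def _write_fastq(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


@pytest.fixture
def demux_setup(tmp_path):
    layout = pp.parse_barcode_layout("NNNNNTTTTTTNN")
    sheet = pp.SampleSheet({"A": "AACCGG", "B": "TTGGCC"})
    genomic = "ACGT" * 10

    def run(records, max_mismatch=1, **kw):
        r1 = tmp_path / "R1.fastq"
        r2 = tmp_path / "R2.fastq"
        _write_fastq(r1, records)
        _write_fastq(r2, [(n, "TTTT" + s[13:]) for n, s in records])
        return pp.demultiplex(
            str(r1), str(r2), layout, sheet, outdir=str(tmp_path / "out"),
            max_mismatch=max_mismatch, collect_assignments=True, **kw,
        )

    return run


class TestDemultiplex:
    def test_exact_match_carries_umi(self, demux_setup, tmp_path):
        umi5, umi2 = "GGGGG", "CA"
        rec = ("read1", umi5 + "AACCGG" + umi2 + "ACGT" * 10)
        stats, assign = demux_setup([rec])
        assert stats.assigned["A"] == 1 and stats.total == 1
        assert assign.iloc[0]["umi"] == umi5 + umi2
        assert len(assign.iloc[0]["umi"]) == 7
        r1_lines = (tmp_path / "out" / "A_R1.fastq").read_text().splitlines()
        assert r1_lines[0] == "@read1_GGGGGCA"
        assert r1_lines[1] == "ACGT" * 10  # layout removed
        r2_lines = (tmp_path / "out" / "A_R2.fastq").read_text().splitlines()
        assert r2_lines[0] == "@read1_GGGGGCA"  # UMI on both mates

    def test_one_mismatch_rescued_two_rejected(self, demux_setup):
        one_off = "AACCGT"  # distance 1 from A, 4 from B
        two_off = "AACCTT"  # distance 2 from A
        stats, _ = demux_setup(
            [("r1", "GGGGG" + one_off + "CAACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"),
             ("r2", "GGGGG" + two_off + "CAACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT")]
        )
        assert stats.assigned["A"] == 1
        assert stats.undetermined == 1

    def test_equidistant_is_ambiguous(self, demux_setup):
        # distance 1 from both AACCGG and AACGGG-like pair: craft a sheet-free
        # case by using barcodes differing at one position
        layout = pp.parse_barcode_layout("TTTTTT")
        sheet = pp.SampleSheet({"A": "AAAAAA", "B": "AAAAAT"})
        import tempfile, os

        d = tempfile.mkdtemp()
        r1, r2 = os.path.join(d, "r1.fq"), os.path.join(d, "r2.fq")
        _write_fastq(r1, [("r", "AAAAACGGGG")])  # distance 1 from both
        _write_fastq(r2, [("r", "CCCCC")])
        with pytest.warns(UserWarning, match="Hamming"):
            stats = pp.demultiplex(r1, r2, layout, sheet, outdir=None)
        assert stats.ambiguous == 1 and stats.total == 1

    def test_short_read_counted_separately(self, demux_setup):
        stats, _ = demux_setup([("r", "AACCG")])
        assert stats.undetermined == 1 and stats.too_short == 1

    def test_partition_invariant(self, demux_setup):
        recs = [
            ("a", "GGGGGAACCGGCA" + "ACGT" * 10),
            ("b", "GGGGGTTGGCCCA" + "ACGT" * 10),
            ("c", "GGGGGACGTACCA" + "ACGT" * 10),  # far from both
            ("d", "TTT"),
        ]
        stats, _ = demux_setup(recs)
        assert sum(stats.assigned.values()) + stats.undetermined + stats.ambiguous == 4

    def test_empty_sheet_rejected(self):
        with pytest.raises(ValueError):
            pp.SampleSheet({})


def test_demux_roundtrip_zero_errors(tmp_path):
    """Simulated multiplexed reads with clean barcodes are assigned 100%
    correctly at max_mismatch=0."""
    cfg = sim.SimConfig(
        seed=11, chrom_sizes={"chr1": 30_000}, n_tss=4,
        background_rate=0.2, n_replicates=3,
    )
    truth = sim.build_truth(cfg)
    reads, _ = sim.render_reads(truth)
    r1, r2 = str(tmp_path / "R1.fastq"), str(tmp_path / "R2.fastq")
    sim.write_fastq_pairs(reads, cfg, truth.genome, r1, r2)
    layout = pp.parse_barcode_layout(cfg.barcode_pattern)
    sheet = pp.SampleSheet(
        {s: cfg.sample_barcodes[i] for i, s in enumerate(cfg.samples)}
    )
    stats, assign = pp.demultiplex(
        r1, r2, layout, sheet, outdir=None, max_mismatch=0,
        collect_assignments=True,
    )
    assert stats.undetermined == 0 and stats.ambiguous == 0
    truth_sample = dict(
        zip("r" + reads["read_no"].astype(str), reads["sample"].astype(str))
    )
    assert all(truth_sample[n] == s for n, s in zip(assign["name"], assign["sample"]))
    lut = sim._umi_lut(cfg.umi_length)
    truth_umi = dict(zip("r" + reads["read_no"].astype(str), lut[reads["umi_int"]]))
    assert all(truth_umi[n] == u for n, u in zip(assign["name"], assign["umi"]))


# ---------------------------------------------------------------------------
# 5' tag extraction


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:1000\n"


def _sam(tmp_path, rows):
    path = tmp_path / "t.sam"
    with open(path, "w") as fh:
        fh.write(SAM_HEADER)
        for name, flag, pos1, cigar, seq in rows:
            fh.write(
                f"{name}\t{flag}\tchr1\t{pos1}\t60\t{cigar}\t*\t0\t0\t{seq}\t"
                f"{'I' * len(seq)}\n"
            )
    return str(path)


class TestExtractTags:
    def test_plus_strand_five_prime_is_leftmost(self, tmp_path):
        path = _sam(tmp_path, [("r1_AAACCCG", 0, 101, "50M", "A" * 50)])
        tags = pp.extract_five_prime_tags(path)
        assert tags.iloc[0]["pos"] == 100 and tags.iloc[0]["strand"] == "+"
        assert tags.iloc[0]["umi"] == "AAACCCG"

    def test_minus_strand_five_prime_is_rightmost(self, tmp_path):
        path = _sam(tmp_path, [("r1_AAACCCG", 16, 101, "50M", "A" * 50)])
        tags = pp.extract_five_prime_tags(path)
        # reference span [100, 150) -> 5' end at 149 on the minus strand
        assert tags.iloc[0]["pos"] == 149 and tags.iloc[0]["strand"] == "-"

    def test_secondary_supplementary_unmapped_skipped(self, tmp_path):
        path = _sam(
            tmp_path,
            [
                ("r1_A", 256, 101, "50M", "A" * 50),
                ("r2_A", 2048, 101, "50M", "A" * 50),
                ("r3_A", 4, 101, "50M", "A" * 50),
            ],
        )
        assert len(pp.extract_five_prime_tags(path)) == 0

    def test_mapq_filter(self, tmp_path):
        path = _sam(tmp_path, [("r1_A", 0, 101, "50M", "A" * 50)])
        assert len(pp.extract_five_prime_tags(path, min_mapq=61)) == 0
        assert len(pp.extract_five_prime_tags(path, min_mapq=60)) == 1

    def test_missing_umi_token_raises_with_read_name(self, tmp_path):
        path = _sam(tmp_path, [("plainname", 0, 101, "50M", "A" * 50)])
        with pytest.raises(ValueError, match="plainname"):
            pp.extract_five_prime_tags(path, mode="mapcap")

    def test_rampage_mode_takes_15bp_from_read(self, tmp_path):
        seq = "ACGTACGTACGTACG" + "T" * 35
        path = _sam(tmp_path, [("r1", 0, 101, "50M", seq)])
        tags = pp.extract_five_prime_tags(path, mode="rampage")
        assert tags.iloc[0]["umi"] == "ACGTACGTACGTACG"

    def test_rampage_minus_strand_umi_is_read_not_reference(self, tmp_path):
        # for a reverse alignment, SAM stores the reverse complement of the
        # read; the UMI must come from the original read orientation
        seq = "A" * 35 + "TTTTTTTTTTGGGGG"
        path = _sam(tmp_path, [("r1", 16, 101, "50M", seq)])
        tags = pp.extract_five_prime_tags(path, mode="rampage")
        assert tags.iloc[0]["umi"] == "CCCCCAAAAAAAAAA"


# ---------------------------------------------------------------------------
# duplicate filtering


def _brute_force_unique(tags):
    seen = set()
    keep = []
    ordered = tags.sort_values(
        ["chrom", "pos", "strand", "umi", "name"], kind="mergesort"
    )
    for idx, row in ordered.iterrows():
        key = (row["sample"], row["chrom"], row["strand"], row["pos"], row["umi"])
        if key not in seen:
            seen.add(key)
            keep.append(idx)
    return ordered.loc[keep].reset_index(drop=True)


class TestFilterDuplicates:
    def test_same_position_same_umi_collapsed(self):
        tags = make_tags(
            [("chr1", 100, "+", "AAACCCG", "b"), ("chr1", 100, "+", "AAACCCG", "a")]
        )
        out = pp.filter_duplicates(tags)
        assert len(out) == 1
        assert out.iloc[0]["name"] == "a"  # first in name order survives

    def test_distinct_umis_both_kept(self):
        tags = make_tags(
            [("chr1", 100, "+", "AAACCCG"), ("chr1", 100, "+", "AAACCCT")]
        )
        assert len(pp.filter_duplicates(tags)) == 2

    def test_opposite_strands_both_kept(self):
        tags = make_tags([("chr1", 100, "+"), ("chr1", 100, "-")])
        assert len(pp.filter_duplicates(tags)) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        tags = make_tags(
            [
                ("chr1", int(rng.integers(0, 50)), "+",
                 "".join(rng.choice(list("ACGT"), 3)))
                for _ in range(200)
            ]
        )
        once = pp.filter_duplicates(tags)
        twice = pp.filter_duplicates(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_input(self):
        out = pp.filter_duplicates(make_tags([]).iloc[:0])
        assert len(out) == 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(0, 30),
                st.sampled_from(["+", "-"]),
                st.sampled_from(["AA", "AC", "AG"]),
            ),
            max_size=60,
        )
    )
    def test_matches_brute_force_oracle(self, rows):
        tags = make_tags(rows)
        out = pp.filter_duplicates(tags)
        expected = _brute_force_unique(tags)
        assert len(out) == len(expected)
        lhs = out[["chrom", "pos", "strand", "umi", "name"]].reset_index(drop=True)
        rhs = expected[["chrom", "pos", "strand", "umi", "name"]]
        pd.testing.assert_frame_equal(lhs, rhs)


def test_no_duplication_and_unique_umis_removes_nothing():
    cfg = sim.SimConfig(
        seed=13, chrom_sizes={"chr1": 50_000}, n_tss=5,
        pcr_geometric_p=1.0, collision_free_umis=True, background_rate=0.3,
    )
    truth = sim.build_truth(cfg)
    reads, _ = sim.render_reads(truth)
    tags = sim.tags_from_reads(reads)
    assert len(pp.filter_duplicates(tags)) == len(tags)


# ---------------------------------------------------------------------------
# bedGraph export


class TestBedgraph:
    def test_cpm_value(self, tmp_path):
        tags = make_tags([("chr1", 100, "+")] + [("chr1", i, "+") for i in range(9)])
        paths = pp.export_five_prime_bedgraph(tags, str(tmp_path / "t"))
        lines = open(paths["+"]).read().splitlines()
        # 10 tags total -> one tag at a base = 1e5 CPM
        assert "chr1\t100\t101\t100000" in lines

    def test_raw_counts_two_tags_same_base(self, tmp_path):
        tags = make_tags([("chr1", 5, "+"), ("chr1", 5, "+")])
        paths = pp.export_five_prime_bedgraph(
            tags, str(tmp_path / "t"), normalization="raw"
        )
        assert open(paths["+"]).read() == "chr1\t5\t6\t2\n"

    def test_strands_split_and_sorted(self, tmp_path):
        tags = make_tags(
            [("chr1", 50, "-"), ("chr1", 10, "+"), ("chr1", 5, "+"), ("chr1", 7, "-")]
        )
        paths = pp.export_five_prime_bedgraph(
            tags, str(tmp_path / "t"), normalization="raw"
        )
        plus = [l.split("\t")[1] for l in open(paths["+"]).read().splitlines()]
        minus = [l.split("\t")[1] for l in open(paths["-"]).read().splitlines()]
        assert plus == ["5", "10"] and minus == ["7", "50"]
        # values match a naive per-base histogram
        for strand, path in paths.items():
            for line in open(path):
                _, s, _, v = line.split()
                expect = ((tags["pos"] == int(s)) & (tags["strand"] == strand)).sum()
                assert int(v) == expect

    def test_zero_tags_cpm_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            pp.export_five_prime_bedgraph(
                make_tags([]).iloc[:0], str(tmp_path / "t")
            )
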
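"""Demultiplexing, 5'-end tag extraction, UMI-aware PCR de-duplication and
single-base coverage export for 5'-capped-RNA (MAPCap/RAMPAGE-style) libraries.

The inline adapter ("s-oligo") carries a sample index and a unique molecular
identifier (UMI) at fixed positions of the barcode-bearing mate, described by a
pattern over {N, T} where N marks UMI bases and T marks sample-index bases
(e.g. ``NNNNNTTTTTTNN``: a 6 nt index flanked by 7 random nucleotides). After
demultiplexing, the UMI travels in the read name; duplicates are reads sharing
strand, mapped 5' position and UMI, of which only the first instance (in
coordinate-then-read-name order) is kept.
"""

from __future__ import annotations

import gzip
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

UMI_DELIMITER = "_"
_AMBIGUOUS = object()


class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class BarcodeLayout:
    """Positions of sample-index (T) and UMI (N) bases in the inline adapter."""

    pattern: str
    index_positions: tuple[int, ...]
    umi_positions: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def index_length(self) -> int:
        return len(self.index_positions)

    @property
    def umi_length(self) -> int:
        return len(self.umi_positions)


def parse_barcode_layout(pattern: str) -> BarcodeLayout:
    """Parse an {N, T} pattern string into a reusable layout.

    N = random (UMI) base, T = sample-index base. Any other character raises a
    LayoutError naming the offending 0-based offset.
    """
    if not pattern:
        raise LayoutError("empty barcode pattern")
    pattern = pattern.upper()
    for i, ch in enumerate(pattern):
        if ch not in "NT":
            raise LayoutError(f"illegal character {ch!r} at offset {i} (expected N or T)")
    return BarcodeLayout(
        pattern=pattern,
        index_positions=tuple(i for i, c in enumerate(pattern) if c == "T"),
        umi_positions=tuple(i for i, c in enumerate(pattern) if c == "N"),
    )


@dataclass
class SampleSheet:
    """Sample name -> index sequence map with uniqueness/length validation."""

    entries: dict[str, str]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("empty sample sheet")
        self.entries = {k: v.upper() for k, v in self.entries.items()}
        seqs = list(self.entries.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("index sequences must be unique")
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("index sequences must all have the same length")

    @property
    def index_length(self) -> int:
        return len(next(iter(self.entries.values())))

    def min_pairwise_distance(self) -> int:
        seqs = list(self.entries.values())
        if len(seqs) < 2:
            return len(seqs[0])
        return min(
            sum(a != b for a, b in zip(s1, s2))
            for s1, s2 in itertools.combinations(seqs, 2)
        )


@dataclass
class DemuxStats:
    """Read-pair accounting; assigned + undetermined + ambiguous == total."""

    assigned: dict[str, int] = field(default_factory=dict)
    undetermined: int = 0
    ambiguous: int = 0
    too_short: int = 0  # subset of undetermined

    @property
    def total(self) -> int:
        return sum(self.assigned.values()) + self.undetermined + self.ambiguous

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample": s, "reads": n} for s, n in sorted(self.assigned.items())]
        rows.append({"sample": "undetermined", "reads": self.undetermined})
        rows.append({"sample": "ambiguous", "reads": self.ambiguous})
        return pd.DataFrame(rows)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _build_lookup(sheet: SampleSheet, max_mismatch: int) -> dict[str, object]:
    """Map every index sequence within max_mismatch of a barcode to its unique
    nearest sample (unique-minimum rule); collisions at equal distance map to
    the ambiguous sentinel."""
    best: dict[str, tuple[int, object]] = {}
    for sample, bc in sheet.entries.items():
        variants = {0: [bc]}
        pool = [bc]
        for d in range(1, max_mismatch + 1):
            nxt = []
            for seq in pool:
                for i in range(len(seq)):
                    for base in "ACGTN":
                        if base != seq[i]:
                            nxt.append(seq[:i] + base + seq[i + 1 :])
            variants[d] = nxt
            pool = nxt
        for d, seqs in variants.items():
            for seq in seqs:
                cur = best.get(seq)
                if cur is None or d < cur[0]:
                    best[seq] = (d, sample)
                elif d == cur[0] and cur[1] is not sample:
                    best[seq] = (d, _AMBIGUOUS)
    return {seq: who for seq, (d, who) in best.items()}


def _opener(path: str, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def demultiplex(
    r1_path: str,
    r2_path: str,
    layout: BarcodeLayout,
    sheet: SampleSheet,
    outdir: str | None = None,
    max_mismatch: int = 1,
    barcode_mate: str = "R1",
    collect_assignments: bool = False,
):
    """Split a multiplexed paired FASTQ by inline sample index.

    The layout bases are removed from the barcode mate; the UMI string is
    appended to the read identifier of both mates (``name_UMI``). Reads whose
    index is not within ``max_mismatch`` of a unique nearest barcode go to
    ``undetermined``; equidistant matches are counted as ambiguous (and written
    to the undetermined files). Reads shorter than the layout are undetermined
    and additionally tallied in ``stats.too_short``.

    Returns ``DemuxStats`` or ``(DemuxStats, assignments)`` where assignments
    is a DataFrame (name, sample, umi) when ``collect_assignments`` is set.
    """
    if barcode_mate not in ("R1", "R2"):
        raise ValueError("barcode_mate must be R1 or R2")
    if sheet.index_length != layout.index_length:
        raise ValueError(
            f"sample sheet index length {sheet.index_length} != layout index "
            f"length {layout.index_length}"
        )
    if sheet.min_pairwise_distance() <= 2 * max_mismatch:
        warnings.warn(
            "pairwise barcode Hamming distance <= 2*max_mismatch; "
            "assignment may be ambiguous",
            stacklevel=2,
        )
    lookup = _build_lookup(sheet, max_mismatch)
    idx_pos = list(layout.index_positions)
    umi_pos = list(layout.umi_positions)
    layout_len = layout.length

    stats = DemuxStats(assigned={s: 0 for s in sheet.entries})
    names: list[str] = []
    samples: list[str] = []
    umis: list[str] = []

    writers: dict[str, tuple[list, list]] = {}
    handles = []

    def _buffers(sample: str):
        if sample not in writers:
            writers[sample] = ([], [])
        return writers[sample]

    def _flush():
        if outdir is None:
            for bufs in writers.values():
                bufs[0].clear()
                bufs[1].clear()
            return
        for sample, (b1, b2) in writers.items():
            for mate, buf in (("R1", b1), ("R2", b2)):
                if buf:
                    with _opener(f"{outdir}/{sample}_{mate}.fastq", "a") as fh:
                        fh.write("".join(buf))
                    buf.clear()

    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for sample in list(sheet.entries) + ["undetermined"]:
            for mate in ("R1", "R2"):
                open(f"{outdir}/{sample}_{mate}.fastq", "w").close()

    n_since_flush = 0
    with pysam.FastxFile(r1_path) as f1, pysam.FastxFile(r2_path) as f2:
        for rec1, rec2 in zip(f1, f2):
            bc_rec = rec1 if barcode_mate == "R1" else rec2
            seq = bc_rec.sequence
            if len(seq) < layout_len:
                stats.undetermined += 1
                stats.too_short += 1
                target = "undetermined"
                out1, out2 = rec1, rec2
                umi = ""
            else:
                index = "".join(seq[i] for i in idx_pos)
                who = lookup.get(index)
                umi = "".join(seq[i] for i in umi_pos)
                if who is None:
                    stats.undetermined += 1
                    target = "undetermined"
                    out1, out2 = rec1, rec2
                elif who is _AMBIGUOUS:
                    stats.ambiguous += 1
                    target = "undetermined"
                    out1, out2 = rec1, rec2
                else:
                    stats.assigned[who] += 1
                    target = who
                    out1, out2 = rec1, rec2
                    if collect_assignments:
                        names.append(rec1.name)
                        samples.append(who)
                        umis.append(umi)
            b1, b2 = _buffers(target)
            if target == "undetermined":
                b1.append(f"@{out1.name}\n{out1.sequence}\n+\n{out1.quality}\n")
                b2.append(f"@{out2.name}\n{out2.sequence}\n+\n{out2.quality}\n")
            else:
                name = f"{out1.name}{UMI_DELIMITER}{umi}"
                if barcode_mate == "R1":
                    s1 = out1.sequence[layout_len:]
                    q1 = out1.quality[layout_len:]
                    s2, q2 = out2.sequence, out2.quality
                else:
                    s1, q1 = out1.sequence, out1.quality
                    s2 = out2.sequence[layout_len:]
                    q2 = out2.quality[layout_len:]
                b1.append(f"@{name}\n{s1}\n+\n{q1}\n")
                b2.append(f"@{name}\n{s2}\n+\n{q2}\n")
            n_since_flush += 1
            if n_since_flush >= 500_000:
                _flush()
                n_since_flush = 0
    _flush()
    for h in handles:
        h.close()

    if collect_assignments:
        assignments = pd.DataFrame({"name": names, "sample": samples, "umi": umis})
        return stats, assignments
    return stats


def extract_five_prime_tags(
    alignments: str,
    min_mapq: int = 0,
    mode: str = "mapcap",
    sample: str | None = None,
    rampage_umi_length: int = 15,
) -> pd.DataFrame:
    """One tag per primary mapped R1: the transcript 5' end of the alignment.

    For + strand alignments the 5' end is the leftmost aligned base; for -
    strand the rightmost. Secondary/supplementary/unmapped records and R2
    mates are skipped. In ``mapcap`` mode the UMI is the trailing
    underscore-delimited token of the read name (raising on reads without
    one); in ``rampage`` mode it is the first ``rampage_umi_length`` bases of
    the read sequence; in ``raw`` mode no UMI is extracted (callers attach
    UMIs separately, e.g. from a demultiplexing assignment table).
    """
    if mode not in ("mapcap", "rampage", "raw"):
        raise ValueError("mode must be 'mapcap', 'rampage' or 'raw'")
    revcomp = str.maketrans("ACGTN", "TGCAN")
    cap = 1 << 16
    rid = np.empty(cap, np.int32)
    poss = np.empty(cap, np.int64)
    minus = np.empty(cap, bool)
    mapqs = np.empty(cap, np.int32)
    umis: list[str] = []
    names: list[str] = []
    n = 0
    with pysam.AlignmentFile(alignments, check_sq=False) as fh:
        references = list(fh.references) or ["*"]
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_paired and not aln.is_read1:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            if mode == "mapcap":
                name = aln.query_name
                if UMI_DELIMITER not in name:
                    raise ValueError(
                        f"read {name!r} has no UMI token in its name "
                        f"(expected '...{UMI_DELIMITER}UMI' after demultiplexing)"
                    )
                base, umi = name.rsplit(UMI_DELIMITER, 1)
                umis.append(umi)
            elif mode == "raw":
                base = aln.query_name
            else:
                seq = aln.query_sequence or ""
                if aln.is_reverse:
                    # query_sequence is reported on the reference strand.
                    seq = seq[::-1].translate(revcomp)
                umis.append(seq[:rampage_umi_length])
                base = aln.query_name
            if n == cap:
                cap *= 2
                rid = np.resize(rid, cap)
                poss = np.resize(poss, cap)
                minus = np.resize(minus, cap)
                mapqs = np.resize(mapqs, cap)
            if aln.is_reverse:
                minus[n] = True
                poss[n] = aln.reference_end - 1
            else:
                minus[n] = False
                poss[n] = aln.reference_start
            rid[n] = aln.reference_id
            mapqs[n] = aln.mapping_quality
            names.append(base)
            n += 1
    return pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(rid[:n], categories=references),
            "pos": poss[:n],
            "strand": pd.Categorical.from_codes(
                minus[:n].astype(np.int8), categories=["+", "-"]
            ),
            "umi": pd.Series(umis, dtype=str)
            if mode != "raw"
            else pd.Series([""] * n, dtype=str),
            "sample": sample if sample is not None else "",
            "name": pd.Series(names, dtype=str),
            "mapq": mapqs[:n],
        }
    )


def filter_duplicates(tags: pd.DataFrame, mode: str = "mapcap") -> pd.DataFrame:
    """Collapse PCR duplicates: reads sharing (chrom, strand, 5' position, UMI).

    Within each group exactly the first tag in (chrom, pos, strand, umi, name)
    order survives, making the output deterministic and the operation
    idempotent. De-duplication is per sample when a sample column is present.
    """
    if len(tags) == 0:
        return tags.copy()
    if "umi" not in tags.columns:
        raise ValueError("tags carry no 'umi' column")
    sort_cols = [c for c in ("chrom", "pos", "strand", "umi", "name") if c in tags.columns]
    key = [c for c in ("sample", "chrom", "strand", "pos", "umi") if c in tags.columns]
    out = tags.sort_values(sort_cols, kind="mergesort")
    out = out.drop_duplicates(subset=key, keep="first")
    return out.reset_index(drop=True)


def encode_umis(umis, umi_length: int) -> np.ndarray:
    """ACGT UMI strings -> base-4 integers (A=0, C=1, G=2, T=3)."""
    b = np.asarray(umis, dtype=f"S{umi_length}").view(np.uint8)
    b = b.reshape(-1, umi_length)
    lut = np.zeros(256, dtype=np.int64)
    for i, base in enumerate(b"ACGT"):
        lut[base] = i
    powers = 4 ** np.arange(umi_length - 1, -1, -1, dtype=np.int64)
    return lut[b] @ powers


def run_preprocessing(
    r1_path: str,
    r2_path: str,
    alignments: str,
    layout: BarcodeLayout,
    sheet: SampleSheet,
    max_mismatch: int = 1,
    min_mapq: int = 0,
) -> tuple[DemuxStats, pd.DataFrame]:
    """Full preprocessing chain in memory: demultiplex the multiplexed FASTQ,
    extract 5' tags from the coordinate-sorted alignments of the trimmed
    reads, attach each tag's sample and UMI from the demultiplexing result,
    and remove PCR duplicates.

    Designed for multi-million-read inputs: sample and UMI assignments are
    re-encoded as categoricals/integers immediately after demultiplexing, and
    the tag/assignment join runs on integer read numbers when read names look
    like ``<prefix><digits>`` (falling back to a string join otherwise).

    Returns (demux stats, deduplicated tag table).
    """
    stats, assign = demultiplex(
        r1_path, r2_path, layout, sheet, outdir=None,
        max_mismatch=max_mismatch, collect_assignments=True,
    )
    samples = sorted(sheet.entries)
    umi_length = layout.umi_length
    numeric_names = (
        len(assign) > 0
        and assign["name"].iloc[0][:1].isalpha()
        and assign["name"].iloc[0][1:].isdigit()
    )
    if umi_length:
        lut = _umi_string_table(umi_length)
        umi_col = pd.Categorical.from_codes(
            encode_umis(assign["umi"].to_numpy(), umi_length), categories=lut
        )
    else:
        umi_col = ""
    compact = pd.DataFrame(
        {
            "umi": umi_col,
            "sample": pd.Categorical(assign["sample"], categories=samples),
        }
    )
    if numeric_names:
        compact["key"] = pd.to_numeric(assign["name"].str.slice(1)).astype(np.int64)
    else:
        compact["key"] = assign["name"]
    del assign

    raw = extract_five_prime_tags(alignments, min_mapq=min_mapq, mode="raw")
    raw = raw.drop(columns=["umi", "sample"])
    if numeric_names:
        raw["key"] = pd.to_numeric(raw["name"].str.slice(1)).astype(np.int64)
    else:
        raw["key"] = raw["name"]
    raw = raw.drop(columns=["name"])
    tagged = raw.merge(compact, on="key", how="inner")
    del raw, compact
    tagged = tagged.rename(columns={"key": "name"})
    return stats, filter_duplicates(tagged)


def _umi_string_table(umi_length: int) -> np.ndarray:
    """All UMI strings of the given length in base-4 (lexicographic) order."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    n = 4 ** umi_length
    codes = np.empty((n, umi_length), dtype=np.uint8)
    idx = np.arange(n)
    for j in range(umi_length - 1, -1, -1):
        codes[:, j] = bases[idx % 4]
        idx //= 4
    return codes.view(f"S{umi_length}").ravel().astype("U")


def export_five_prime_bedgraph(
    tags: pd.DataFrame,
    out_prefix: str,
    normalization: str = "CPM",
) -> dict[str, str]:
    """Single-base 5'-end coverage, one bedGraph per strand.

    Values are raw tag counts or counts-per-million of the total tag count
    (both strands pooled). Intervals are sorted and non-overlapping within
    each file. Returns the mapping strand -> path.
    """
    if normalization not in ("raw", "CPM"):
        raise ValueError("normalization must be 'raw' or 'CPM'")
    total = len(tags)
    if normalization == "CPM" and total == 0:
        raise ValueError("cannot CPM-normalize zero tags")
    paths = {}
    for strand, suffix in (("+", "plus"), ("-", "minus")):
        sub = tags[tags["strand"] == strand]
        counts = (
            sub.groupby(["chrom", "pos"], sort=True, observed=True).size().reset_index(name="count")
        )
        if normalization == "CPM":
            counts["value"] = counts["count"] * 1e6 / total
        else:
            counts["value"] = counts["count"]
        path = f"{out_prefix}.{suffix}.bedgraph"
        with open(path, "w") as fh:
            for chrom, pos, value in zip(
                counts["chrom"], counts["pos"], counts["value"]
            ):
                v = f"{value:.6g}" if normalization == "CPM" else f"{int(value)}"
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{v}\n")
        paths[strand] = path
    return paths
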
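"""Hierarchical, mutually exclusive TSS annotation.

Gene models are flattened into a per-strand map where every base carries
exactly one category, assigned by rank: genic sense (5'UTR > CDS > 3'UTR >
intron) > genic antisense (same internal order) > enhancer > repeat >
intergenic. Enhancer and repeat BED sets are unstranded and re-label only
bases that are intergenic on the strand under consideration. Each TSS cluster
is then annotated by the category at its anchor base (summit by default),
along with the nearest same-strand annotated gene TSS and the signed distance
to it (positive = downstream of the gene TSS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

from . import intervals

SENSE_ORDER = ["5UTR", "CDS", "3UTR", "intron"]
CATEGORIES = (
    [f"{c} (sense)" for c in SENSE_ORDER]
    + [f"{c} (antisense)" for c in SENSE_ORDER]
    + ["enhancer", "repeat", "intergenic"]
)


@dataclass
class FeatureHierarchy:
    """Flattened per-strand category map plus annotated gene TSS positions."""

    chrom_sizes: dict[str, int]
    # (chrom, strand) -> sorted arrays: starts, ends, category codes
    flat: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]]
    categories: list[str] = field(default_factory=lambda: list(CATEGORIES))
    # (chrom, strand) -> (sorted TSS positions, transcript ids)
    gene_tss: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def category_at(self, chrom: str, strand: str, pos: int) -> str:
        key = (chrom, strand)
        if key not in self.flat:
            return "unplaced"
        starts, ends, codes = self.flat[key]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= ends[i]:
            return "unplaced"
        return self.categories[codes[i]]


def _transcript_features(db: gffutils.FeatureDB):
    """Per-strand interval lists for 5'UTR/CDS/3'UTR/intron, plus gene spans
    and transcript 5' ends, all 0-based half-open."""
    feats: dict[str, dict[tuple[str, str], list]] = {
        c: {} for c in SENSE_ORDER
    }
    gene_spans: dict[str, list] = {}
    tss: dict[tuple[str, str], list] = {}

    def add(cat, chrom, strand, s, e):
        if e > s:
            feats[cat].setdefault((chrom, strand), []).append((s, e))

    for tr in db.features_of_type(("transcript", "mRNA")):
        chrom, strand = tr.seqid, tr.strand
        exons = sorted(
            [(f.start - 1, f.end) for f in db.children(tr, featuretype="exon")]
        )
        cds = sorted([(f.start - 1, f.end) for f in db.children(tr, featuretype="CDS")])
        if not exons:
            exons = [(tr.start - 1, tr.end)]
        tr_start, tr_end = exons[0][0], exons[-1][1]
        gene_spans.setdefault(chrom, []).append((tr_start, tr_end))
        tss_pos = tr_start if strand == "+" else tr_end - 1
        tss.setdefault((chrom, strand), []).append((tss_pos, tr.id))

        exon_arr = np.array(exons)
        intron = intervals.subtract([(tr_start, tr_end)], exon_arr)
        for s, e in intron:
            add("intron", chrom, strand, s, e)
        if cds:
            cds_lo = cds[0][0]
            cds_hi = cds[-1][1]
            for s, e in intervals.intersect(exon_arr, cds):
                add("CDS", chrom, strand, s, e)
            up = intervals.intersect(exon_arr, [(tr_start, cds_lo)])
            down = intervals.intersect(exon_arr, [(cds_hi, tr_end)])
            five, three = (up, down) if strand == "+" else (down, up)
            for s, e in five:
                add("5UTR", chrom, strand, s, e)
            for s, e in three:
                add("3UTR", chrom, strand, s, e)
        else:
            warnings.warn(
                f"transcript {tr.id} has no CDS; exons ranked at intron level",
                stacklevel=2,
            )
            for s, e in exons:
                add("intron", chrom, strand, s, e)
    return feats, gene_spans, tss


def build_feature_hierarchy(
    gtf_path: str,
    chrom_sizes: dict[str, int],
    enhancers: pd.DataFrame | None = None,
    repeats: pd.DataFrame | None = None,
    enhancer_over_repeat: bool = True,
) -> FeatureHierarchy:
    """Flatten a GTF plus optional enhancer/repeat BED sets into a map where
    every base of every chromosome carries exactly one category per strand.

    Genic categories are claimed first in rank order (sense before antisense);
    remaining intergenic bases overlapping an enhancer, then a repeat, are
    re-labelled; everything left is intergenic.
    """
    db = gffutils.create_db(
        gtf_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    feats, _gene_spans, tss = _transcript_features(db)

    def bed_ivs(df: pd.DataFrame | None, chrom: str):
        if df is None or len(df) == 0:
            return np.empty((0, 2), dtype=np.int64)
        sub = df[df["chrom"] == chrom]
        return sub[["start", "end"]].to_numpy(np.int64)

    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    flat: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    unstranded_first = "enhancer" if enhancer_over_repeat else "repeat"
    unstranded_second = "repeat" if enhancer_over_repeat else "enhancer"

    for chrom, size in chrom_sizes.items():
        enh = bed_ivs(enhancers, chrom)
        rep = bed_ivs(repeats, chrom)
        unstranded = {
            "enhancer": enh,
            "repeat": rep,
        }
        for strand in ("+", "-"):
            anti = "-" if strand == "+" else "+"
            ranked: list[tuple[str, np.ndarray]] = []
            for cat in SENSE_ORDER:
                ranked.append(
                    (f"{cat} (sense)", np.array(feats[cat].get((chrom, strand), []), dtype=np.int64).reshape(-1, 2))
                )
            for cat in SENSE_ORDER:
                ranked.append(
                    (f"{cat} (antisense)", np.array(feats[cat].get((chrom, anti), []), dtype=np.int64).reshape(-1, 2))
                )
            ranked.append((unstranded_first, unstranded[unstranded_first]))
            ranked.append((unstranded_second, unstranded[unstranded_second]))

            claimed = np.empty((0, 2), dtype=np.int64)
            pieces: list[tuple[int, int, int]] = []
            for cat, ivs in ranked:
                ivs = intervals.intersect(ivs, [(0, size)])
                free = intervals.subtract(ivs, claimed)
                for s, e in free:
                    pieces.append((int(s), int(e), cat_index[cat]))
                claimed = intervals.merge(
                    np.vstack([claimed, free]) if len(free) else claimed
                )
            for s, e in intervals.subtract([(0, size)], claimed):
                pieces.append((int(s), int(e), cat_index["intergenic"]))
            pieces.sort()
            arr = np.array(pieces, dtype=np.int64).reshape(-1, 3)
            flat[(chrom, strand)] = (arr[:, 0], arr[:, 1], arr[:, 2])

    gene_tss = {}
    for (chrom, strand), entries in tss.items():
        entries.sort()
        gene_tss[(chrom, strand)] = (
            np.array([p for p, _ in entries], dtype=np.int64),
            np.array([t for _, t in entries], dtype=object),
        )
    return FeatureHierarchy(
        chrom_sizes=dict(chrom_sizes), flat=flat, gene_tss=gene_tss
    )


def _nearest_gene_tss(hier: FeatureHierarchy, chrom: str, strand: str, pos: int):
    key = (chrom, strand)
    if key not in hier.gene_tss or len(hier.gene_tss[key][0]) == 0:
        return None, np.nan
    positions, ids = hier.gene_tss[key]
    i = int(np.searchsorted(positions, pos))
    best, bid = None, None
    for j in (i - 1, i):
        if 0 <= j < len(positions):
            d = abs(int(positions[j]) - pos)
            if best is None or d < best:
                best, bid = d, j
    signed = pos - int(positions[bid])
    if strand == "-":
        signed = -signed
    return str(ids[bid]), signed


def annotate_tss(
    clusters: pd.DataFrame,
    hierarchy: FeatureHierarchy,
    anchor: str = "summit",
) -> pd.DataFrame:
    """Label each TSS cluster with the category of its anchor base.

    anchor='summit' (default) looks up the summit base; anchor='majority'
    assigns the category covering the largest part of the cluster interval.
    Clusters on chromosomes absent from the hierarchy get 'unplaced'.
    """
    if anchor not in ("summit", "majority"):
        raise ValueError("anchor must be 'summit' or 'majority'")
    out = clusters.copy().reset_index(drop=True)
    cats = []
    nearest = []
    dists = []
    for row in out.itertuples():
        chrom, strand = row.chrom, row.strand
        if chrom not in hierarchy.chrom_sizes:
            warnings.warn(f"cluster on unknown chromosome {chrom}", stacklevel=2)
            cats.append("unplaced")
            nearest.append(None)
            dists.append(np.nan)
            continue
        if anchor == "summit":
            pos = int(getattr(row, "summit", (row.start + row.end) // 2))
            cats.append(hierarchy.category_at(chrom, strand, pos))
        else:
            key = (chrom, strand)
            starts, ends, codes = hierarchy.flat[key]
            cover: dict[int, int] = {}
            for s, e, c in zip(starts, ends, codes):
                lo, hi = max(s, row.start), min(e, row.end)
                if hi > lo:
                    cover[c] = cover.get(c, 0) + (hi - lo)
            best = max(cover.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            cats.append(hierarchy.categories[best])
            pos = int(getattr(row, "summit", (row.start + row.end) // 2))
        gid, signed = _nearest_gene_tss(hierarchy, chrom, strand, pos)
        nearest.append(gid)
        dists.append(signed)
    out["category"] = cats
    out["nearest_gene_tss"] = nearest
    out["distance_to_gene_tss"] = dists
    return out


def category_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Category frequency table (counts and fractions)."""
    counts = annotated["category"].value_counts()
    return pd.DataFrame(
        {
            "category": counts.index,
            "n": counts.to_numpy(),
            "fraction": counts.to_numpy() / max(len(annotated), 1),
        }
    ).reset_index(drop=True)


def distance_to_nearest(
    clusters: pd.DataFrame,
    features: pd.DataFrame,
    anchor: str = "summit",
) -> pd.Series:
    """Distance (bp) from each cluster to the nearest feature interval.

    0 when the anchor base lies inside a feature; otherwise the gap to the
    closest covered base. NaN when the cluster's chromosome has no features.
    Features are treated as unstranded (BED3).
    """
    by_chrom = {
        chrom: sub[["start", "end"]].to_numpy(np.int64)
        for chrom, sub in features.groupby("chrom")
    }
    out = np.full(len(clusters), np.nan)
    for i, row in enumerate(clusters.itertuples()):
        ivs = by_chrom.get(row.chrom)
        if ivs is None or len(ivs) == 0:
            continue
        if anchor == "summit":
            pos = int(getattr(row, "summit", (row.start + row.end) // 2))
            out[i] = intervals.gap_to_point(ivs, pos)
        else:
            m = intervals.merge(ivs)
            if intervals.total_length(
                intervals.intersect(m, [(row.start, row.end)])
            ):
                out[i] = 0
            else:
                out[i] = min(
                    intervals.gap_to_point(m, int(row.start)),
                    intervals.gap_to_point(m, int(row.end) - 1),
                )
    return pd.Series(out, index=clusters.index, name="distance")
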
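import numpy as np
import pandas as pd

TAG_COLS = ["chrom", "pos", "strand", "umi", "sample", "name", "mapq"]


def make_tags(rows, sample="s1"):
    """Tag table from (chrom, pos, strand[, umi[, name]]) tuples."""
    if not rows:
        return pd.DataFrame(
            {c: pd.Series(dtype=d) for c, d in zip(
                TAG_COLS, [str, np.int64, str, str, str, str, np.int32]
            )}
        )
    recs = []
    for i, row in enumerate(rows):
        chrom, pos, strand = row[:3]
        umi = row[3] if len(row) > 3 else "AAAAAAA"
        name = row[4] if len(row) > 4 else f"t{i}"
        recs.append(
            {
                "chrom": chrom,
                "pos": pos,
                "strand": strand,
                "umi": umi,
                "sample": sample,
                "name": name,
                "mapq": 60,
            }
        )
    return pd.DataFrame(recs)


def match_fraction(truth_tss: pd.DataFrame, clusters: pd.DataFrame, radius=100):
    """(recall, fp_fraction, shape_agreement) of called clusters vs planted
    TSSs with +/- radius matching on the same strand."""
    hit = agree = matched = 0
    for r in truth_tss.itertuples():
        sub = clusters[(clusters.chrom == r.chrom) & (clusters.strand == r.strand)]
        m = sub[(sub.start - radius <= r.mode) & (r.mode < sub.end + radius)]
        if len(m):
            hit += 1
            matched += 1
            best = m.iloc[int(np.argmax(m.score.to_numpy()))]
            agree += best["shape"] == r.shape
    fp = 0
    for c in clusters.itertuples():
        sub = truth_tss[
            (truth_tss.chrom == c.chrom) & (truth_tss.strand == c.strand)
        ]
        near = (c.start - radius <= sub["mode"]) & (sub["mode"] < c.end + radius)
        if not near.any():
            fp += 1
    recall = hit / len(truth_tss) if len(truth_tss) else 0.0
    fp_frac = fp / len(clusters) if len(clusters) else 0.0
    shape_agreement = agree / matched if matched else 0.0
    return recall, fp_frac, shape_agreement
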
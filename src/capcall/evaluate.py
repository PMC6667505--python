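"""Precision-recall evaluation of TSS detections against an annotation-derived
truth set.

Positives are annotated TSS positions of expressed transcripts (TPM above a
threshold) that fall inside an open-chromatin peak. A detection matches an
anchor when it lies within a +/- radius (default 100 bp) window; matching is
one-to-one and greedy by descending detection score. Detections inside the
genic mask that have no anchor within the radius are false positives;
unmatched anchors are false negatives. Sweeping the detection score yields a
precision-recall curve, the area under it (trapezoid over recall-sorted
points) and the best F1 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals


@dataclass
class TruthSet:
    """Positive TSS anchors, the genic mask for FP accounting and the match
    radius."""

    anchors: pd.DataFrame  # chrom, pos, strand
    genic_mask: dict[str, np.ndarray]  # chrom -> (n, 2) intervals (unstranded)
    radius: int = 100
    require_peak_for_positives: bool = True

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("match radius must be >= 0")
        self.anchors = (
            self.anchors.drop_duplicates(["chrom", "pos", "strand"])
            .sort_values(["chrom", "pos", "strand"], kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def n_positives(self) -> int:
        return len(self.anchors)


def build_truth_sets(
    annotated_tss: pd.DataFrame,
    expression: pd.DataFrame,
    open_peaks: pd.DataFrame,
    genic_regions: pd.DataFrame,
    tpm_threshold: float = 1.0,
    radius: int = 100,
    require_peak_for_positives: bool = True,
) -> TruthSet:
    """Anchors = TSSs of expressed transcripts that overlap an open peak.

    ``annotated_tss`` carries (transcript_id, chrom, pos, strand);
    ``expression`` carries (transcript_id, tpm). Transcripts with TPM strictly
    above ``tpm_threshold`` count as expressed. ``genic_regions`` (chrom,
    start, end) defines where unmatched detections count as false positives.
    """
    if len(expression) == 0:
        raise ValueError("empty expression table")
    tpm = dict(zip(expression["transcript_id"], expression["tpm"]))
    expressed = annotated_tss[
        annotated_tss["transcript_id"].map(lambda t: tpm.get(t, 0.0)) > tpm_threshold
    ]
    peaks_by_chrom = {
        chrom: intervals.merge(sub[["start", "end"]].to_numpy(np.int64))
        for chrom, sub in open_peaks.groupby("chrom")
    }
    if require_peak_for_positives:
        keep = [
            intervals.point_in(peaks_by_chrom.get(row.chrom, []), int(row.pos))
            if row.chrom in peaks_by_chrom
            else False
            for row in expressed.itertuples()
        ]
        expressed = expressed[np.asarray(keep, dtype=bool)] if len(expressed) else expressed
    mask = {
        chrom: intervals.merge(sub[["start", "end"]].to_numpy(np.int64))
        for chrom, sub in genic_regions.groupby("chrom")
    }
    return TruthSet(
        anchors=expressed[["chrom", "pos", "strand"]].reset_index(drop=True),
        genic_mask=mask,
        radius=radius,
        require_peak_for_positives=require_peak_for_positives,
    )


@dataclass
class PRCurve:
    """Score-threshold sweep: (threshold, tp, fp, fn, precision, recall, f1)
    rows plus summary scalars."""

    table: pd.DataFrame
    auprc: float
    best_f1: float
    best_threshold: float
    n_positives: int = 0
    extras: dict = field(default_factory=dict)


def _detection_distance(row, anchor_pos: np.ndarray) -> np.ndarray:
    """bp distance from a detection to each anchor: 0 inside the interval,
    else gap to the nearest covered base."""
    lo, hi = int(row.start), int(row.end)
    return np.where(
        (anchor_pos >= lo) & (anchor_pos < hi),
        0,
        np.minimum(np.abs(anchor_pos - lo), np.abs(anchor_pos - (hi - 1))),
    )


def match_detections(detections: pd.DataFrame, truth: TruthSet) -> pd.DataFrame:
    """Greedy one-to-one matching of detections to anchors.

    Detections are visited in descending score order; each consumes at most
    one (the nearest still-unmatched) same-strand anchor within the radius.
    Adds boolean columns: matched, near_anchor (any anchor within radius,
    consumed or not) and in_genic (inside the genic mask).
    """
    det = detections.reset_index(drop=True).copy()
    det["matched"] = False
    det["near_anchor"] = False
    det["in_genic"] = False
    anchors_by = {
        key: sub.reset_index() for key, sub in truth.anchors.groupby(["chrom", "strand"], observed=True)
    }
    consumed: dict[tuple[str, str], np.ndarray] = {
        key: np.zeros(len(sub), dtype=bool) for key, sub in anchors_by.items()
    }
    order = np.argsort(-det["score"].to_numpy(float), kind="mergesort")
    for i in order:
        row = det.iloc[i]
        mask = truth.genic_mask.get(row.chrom)
        mid = int(getattr(row, "summit", (row.start + row.end) // 2))
        if mask is not None and len(mask):
            det.loc[i, "in_genic"] = intervals.point_in(mask, mid)
        sub = anchors_by.get((row.chrom, row.strand))
        if sub is None:
            continue
        dist = _detection_distance(row, sub["pos"].to_numpy(np.int64))
        near = dist <= truth.radius
        if not np.any(near):
            continue
        det.loc[i, "near_anchor"] = True
        taken = consumed[(row.chrom, row.strand)]
        avail = near & ~taken
        if np.any(avail):
            j = int(np.flatnonzero(avail)[np.argmin(dist[avail])])
            taken[j] = True
            det.loc[i, "matched"] = True
    return det


def precision_recall_sweep(
    detections: pd.DataFrame,
    truth: TruthSet,
    thresholds: np.ndarray | None = None,
) -> PRCurve:
    """Precision/recall/F1 across score thresholds, plus AUPRC.

    At threshold t, detections with score >= t are kept; TP = kept matched
    detections, FP = kept detections inside the genic mask with no anchor
    within the radius, FN = anchors not matched by any kept detection.
    Precision at an empty prediction set is defined as 1. AUPRC integrates
    precision over recall by trapezoid, with a left extension at the
    precision of the highest threshold.
    """
    n_pos = truth.n_positives
    if len(detections) == 0:
        table = pd.DataFrame(
            [{"threshold": np.inf, "tp": 0, "fp": 0, "fn": n_pos,
              "precision": 1.0, "recall": 0.0, "f1": 0.0}]
        )
        return PRCurve(table=table, auprc=0.0, best_f1=0.0,
                       best_threshold=np.inf, n_positives=n_pos)
    det = match_detections(detections, truth)
    scores = det["score"].to_numpy(float)
    if thresholds is None:
        thresholds = np.unique(scores)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    tp_flag = det["matched"].to_numpy()
    fp_flag = (det["in_genic"] & ~det["near_anchor"]).to_numpy()
    rows = []
    for t in thresholds:
        kept = scores >= t
        tp = int(np.sum(tp_flag & kept))
        fp = int(np.sum(fp_flag & kept))
        fn = n_pos - tp
        prec = tp / (tp + fp) if (tp + fp) else 1.0
        rec = tp / n_pos if n_pos else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        rows.append(
            {"threshold": t, "tp": tp, "fp": fp, "fn": fn,
             "precision": prec, "recall": rec, "f1": f1}
        )
    table = pd.DataFrame(rows)
    pts = table.sort_values(["recall", "precision"], kind="mergesort")
    rec = np.concatenate([[0.0], pts["recall"].to_numpy()])
    prec = np.concatenate([[pts["precision"].iloc[0]], pts["precision"].to_numpy()])
    auprc = float(np.trapezoid(prec, rec))
    best = table.iloc[int(table["f1"].idxmax())]
    return PRCurve(
        table=table,
        auprc=auprc,
        best_f1=float(best["f1"]),
        best_threshold=float(best["threshold"]),
        n_positives=n_pos,
    )
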
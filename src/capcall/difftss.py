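"""Differential TSS usage between two groups of replicated samples.

Counts on the union of detected TSS clusters are modelled per row as

    y_ij ~ NB(mu_ij, phi_r),   log mu_ij = beta_{g(j)} + log s_j

with s_j a per-sample size factor and group-mean coding, so the Wald contrast
is beta_B - beta_A. Size factors come from one of five schemes: RLE
(median-of-ratios), TMM, upper-quartile, TMM on large genomic bins
("windowTMM"), or "external" (median-of-ratios on a spike-in count table).
Dispersions are estimated per row by Cox-Reid adjusted profile likelihood
with empirical-Bayes shrinkage toward the common value; p-values are
two-sided normal on the Wald statistic with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import intervals
from ._nb import fit_log_abundance, nb_loglik, scaled_priors
from .tsscall import SlidingWindowGrid, WindowCountSet, count_tags_in_windows

_LOG2 = np.log(2.0)

NORMALIZATION_METHODS = ("RLE", "TMM", "upperquartile", "windowTMM", "external")


# ---------------------------------------------------------------------------
# union matrix


@dataclass
class UnionTSSMatrix:
    """Strand-specific 5'-tag counts on the union of detected TSS clusters."""

    regions: pd.DataFrame  # chrom, start, end, strand
    counts: np.ndarray  # (R, S) int
    samples: list[str]
    groups: list[str]
    library_sizes: np.ndarray

    def __post_init__(self):
        if len(self.groups) != len(self.samples):
            raise ValueError("one group label per sample required")


def union_regions(cluster_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge overlapping same-strand clusters from several samples into
    non-overlapping union rows (opposite strands stay separate)."""
    allc = pd.concat(cluster_sets, ignore_index=True)
    if len(allc) == 0:
        raise ValueError("no TSS clusters to union")
    rows = []
    for (chrom, strand), sub in allc.groupby(["chrom", "strand"], sort=True, observed=True):
        merged = intervals.merge(sub[["start", "end"]].to_numpy(), gap=-1)
        for s, e in merged:
            rows.append({"chrom": chrom, "start": int(s), "end": int(e), "strand": strand})
    return pd.DataFrame(rows)


def build_union_matrix(
    cluster_sets: list[pd.DataFrame],
    tags: pd.DataFrame,
    chrom_sizes: dict[str, int],
    groups: list[str],
    samples: list[str] | None = None,
    spike_prefix: str = "ERCC-",
) -> UnionTSSMatrix:
    """Count tags per sample on the union of per-sample TSS cluster sets."""
    regions = union_regions(cluster_sets)
    grid = SlidingWindowGrid(chrom_sizes=dict(chrom_sizes))
    wcs: WindowCountSet = count_tags_in_windows(
        tags, grid, regions=regions, samples=samples, spike_prefix=spike_prefix
    )
    return UnionTSSMatrix(
        regions=wcs.windows.reset_index(drop=True),
        counts=wcs.window_counts,
        samples=wcs.samples,
        groups=list(groups),
        library_sizes=wcs.library_sizes,
    )


# ---------------------------------------------------------------------------
# size factors


@dataclass
class SizeFactors:
    """Per-sample positive factors on the count scale (divide counts by the
    factor to normalize), rescaled to geometric mean 1."""

    factors: np.ndarray
    method: str

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(~np.isfinite(self.factors)) or np.any(self.factors <= 0):
            raise ValueError(f"non-positive size factor from method {self.method}")


def _geomean_one(f: np.ndarray) -> np.ndarray:
    return f / np.exp(np.mean(np.log(f)))


def _rle_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style median of ratios over rows without zeros."""
    counts = np.asarray(counts, dtype=float)
    keep = np.all(counts > 0, axis=1)
    if keep.sum() < 1:
        raise ValueError(
            "no zero-free rows for median-of-ratios; consider upperquartile "
            "or external spike-in factors"
        )
    sub = counts[keep]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    return _geomean_one(np.median(sub / ref[:, None], axis=0))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """Trimmed, precision-weighted mean of M-values of one column vs the
    reference; returns the compositional scaling factor 2^f."""
    mask = (obs > 0) & (ref > 0)
    obs, ref = obs[mask].astype(float), ref[mask].astype(float)
    if len(obs) == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = len(M)
    lo_m = int(np.floor(n * logratio_trim)) + 1
    lo_a = int(np.floor(n * sum_trim)) + 1
    rank_m = sps.rankdata(M, method="average")
    rank_a = sps.rankdata(A, method="average")
    keep = (
        (rank_m >= lo_m)
        & (rank_m <= n + 1 - lo_m)
        & (rank_a >= lo_a)
        & (rank_a <= n + 1 - lo_a)
    )
    if not np.any(keep):
        keep = np.ones(n, dtype=bool)
    wk = np.where(w[keep] > 0, 1.0 / w[keep], 0.0)
    if wk.sum() <= 0:
        f = float(np.mean(M[keep]))
    else:
        f = float(np.sum(wk * M[keep]) / wk.sum())
    return 2.0 ** f


def _tmm_factors(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    N = counts.sum(axis=0)
    if np.any(N <= 0):
        raise ValueError("a sample has zero total counts")
    uq = np.array(
        [np.percentile(c[c > 0] / n, 75) if np.any(c > 0) else 0.0 for c, n in zip(counts.T, N)]
    )
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    comp = np.array(
        [
            1.0
            if j == ref_idx
            else _tmm_pair(counts[:, j], counts[:, ref_idx], N[j], N[ref_idx])
            for j in range(counts.shape[1])
        ]
    )
    comp = _geomean_one(comp)
    return _geomean_one(N * comp)


def _upperquartile_factors(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    uq = []
    for col in counts.T:
        nz = col[col > 0]
        if len(nz) == 0:
            raise ValueError("a sample has no nonzero counts for upperquartile")
        uq.append(np.percentile(nz, 75))
    return _geomean_one(np.asarray(uq))


def bin_tag_counts(
    tags: pd.DataFrame,
    chrom_sizes: dict[str, int],
    bin_bp: int = 10_000,
    samples: list[str] | None = None,
    spike_prefix: str = "ERCC-",
) -> np.ndarray:
    """Unstranded tag counts in large genomic bins (rows) per sample."""
    if samples is None:
        samples = sorted(tags["sample"].unique())
    sub = tags[~tags["chrom"].str.startswith(spike_prefix)]
    parts = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        nbins = max(1, -(-size // bin_bp))
        mat = np.zeros((nbins, len(samples)), dtype=np.int64)
        csub = sub[sub["chrom"] == chrom]
        for j, sample in enumerate(samples):
            pos = csub.loc[csub["sample"] == sample, "pos"].to_numpy(np.int64)
            pos = pos[(pos >= 0) & (pos < size)]
            mat[:, j] = np.bincount(pos // bin_bp, minlength=nbins)
        parts.append(mat)
    return np.vstack(parts)


def compute_size_factors(
    counts,
    method: str = "RLE",
    tags: pd.DataFrame | None = None,
    chrom_sizes: dict[str, int] | None = None,
    window_bin_bp: int = 10_000,
    samples: list[str] | None = None,
) -> SizeFactors:
    """Per-sample size factors by one of five normalization schemes.

    ``counts`` is the union-TSS count matrix (rows x samples) for RLE, TMM
    and upperquartile; for ``external`` it is the spike-in count table
    (species x samples); ``windowTMM`` ignores it and bins ``tags`` over the
    genome in ``window_bin_bp`` bins (``tags`` + ``chrom_sizes`` required).
    All factors are returned on the count scale with geometric mean 1.
    """
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {NORMALIZATION_METHODS}")
    if method == "windowTMM":
        if tags is None or chrom_sizes is None:
            raise ValueError("windowTMM requires tags and chrom_sizes")
        binned = bin_tag_counts(tags, chrom_sizes, window_bin_bp, samples=samples)
        return SizeFactors(_tmm_factors(binned), method)
    if isinstance(counts, pd.DataFrame):
        counts = counts.to_numpy()
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a rows x samples matrix with >= 2 samples")
    if method in ("RLE", "external"):
        if method == "external" and np.sum(np.all(counts > 0, axis=1)) < 2:
            raise ValueError("spike-in table needs >= 2 zero-free rows")
        return SizeFactors(_rle_factors(counts), method)
    if method == "TMM":
        return SizeFactors(_tmm_factors(counts), method)
    return SizeFactors(_upperquartile_factors(counts), method)


# ---------------------------------------------------------------------------
# NB Wald test


def benjamini_hochberg(pvalues: np.ndarray, method: str = "fdr_bh") -> np.ndarray:
    """BH step-up adjusted p-values (or Holm via method='holm').

    BH is computed natively with the textbook p * n / rank running minimum;
    other methods delegate to statsmodels.
    """
    p = np.asarray(pvalues, dtype=float)
    if method != "fdr_bh":
        return multipletests(p, method=method)[1]
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def _group_fit(y, offsets_exp, phi):
    """One-group fit + observed information per row for one sample subset."""
    beta = fit_log_abundance(y, offsets_exp, phi)
    phi_arr = np.asarray(phi, dtype=float)
    if phi_arr.ndim == 0:
        phi_arr = np.full(y.shape[0], float(phi_arr))
    mu = offsets_exp[None, :] * np.exp(beta)[:, None]
    info = (mu / (1.0 + phi_arr[:, None] * mu)).sum(axis=1)
    ll = nb_loglik(y, mu, phi_arr)
    return beta, info, ll


def _apl(y, offsets_exp, groups_mask, phi):
    """Cox-Reid adjusted profile log-likelihood per row at dispersion phi.

    With group-mean coding the Fisher information is diagonal, so the CR
    adjustment is -0.5 * (log I_A + log I_B).
    """
    bA, iA, llA = _group_fit(y[:, groups_mask], offsets_exp[groups_mask], phi)
    bB, iB, llB = _group_fit(y[:, ~groups_mask], offsets_exp[~groups_mask], phi)
    with np.errstate(divide="ignore"):
        cr = 0.5 * (np.log(np.maximum(iA, 1e-300)) + np.log(np.maximum(iB, 1e-300)))
    return llA + llB - cr


def estimate_dispersions(
    y: np.ndarray,
    offsets_exp: np.ndarray,
    group_mask: np.ndarray,
    mode: str = "shrunk",
    prior_df: float = 10.0,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Per-row NB dispersions by CR-adjusted profile likelihood.

    mode 'common' returns the single maximizer of the summed APL for every
    row; 'perrow' maximizes each row's APL alone; 'shrunk' (default)
    maximizes APL_row + prior_n * mean-APL, squeezing row estimates toward
    the common value with weight prior_n = prior_df / residual df.
    Returns (per-row dispersions, common dispersion).
    """
    if grid is None:
        grid = np.concatenate([[1e-4], np.logspace(-3, np.log10(4.0), 29)])
    apl = np.stack([_apl(y, offsets_exp, group_mask, phi) for phi in grid], axis=1)
    mean_apl = apl.mean(axis=0)
    common = float(grid[int(np.argmax(mean_apl))])
    if mode == "common":
        return np.full(y.shape[0], common), common
    if mode == "perrow":
        objective = apl
    elif mode == "shrunk":
        df_resid = max(y.shape[1] - 2, 1)
        prior_n = prior_df / df_resid
        objective = apl + prior_n * mean_apl[None, :]
    else:
        raise ValueError(f"unknown dispersion mode {mode!r}")
    best = np.argmax(objective, axis=1)
    return grid[best], common


def detect_diff_tss(
    matrix: UnionTSSMatrix,
    size_factors: SizeFactors,
    dispersion_mode: str = "shrunk",
    prior_count: float = 0.5,
    fixed_phi: float | None = None,
    prior_df: float = 10.0,
    adjust: str = "fdr_bh",
    spike_prefix: str = "ERCC-",
) -> pd.DataFrame:
    """Per-TSS two-group NB Wald test.

    Fits group-mean abundances with offsets log(s_j), computes the Wald
    statistic z = log-fold-change / SE with a two-sided normal p-value, and
    BH-adjusts across rows. The reported log2 fold-change is on the
    size-factor-normalized scale (group B over group A, groups in sorted
    label order). Spike-in rows, if present, are excluded from testing.
    """
    glabels = sorted(set(matrix.groups))
    if len(glabels) != 2:
        raise ValueError(f"exactly 2 groups required, got {glabels}")
    group_mask = np.array([g == glabels[0] for g in matrix.groups])
    nA, nB = int(group_mask.sum()), int((~group_mask).sum())
    if max(nA, nB) < 2 and fixed_phi is None:
        raise ValueError(
            "dispersion is unidentifiable with a single replicate in both "
            "groups; supply fixed_phi"
        )

    keep = ~matrix.regions["chrom"].str.startswith(spike_prefix).to_numpy()
    regions = matrix.regions[keep].reset_index(drop=True)
    counts = np.asarray(matrix.counts, dtype=float)[keep]

    s = np.asarray(size_factors.factors, dtype=float)
    priors = scaled_priors(s, prior_count)
    y = counts + priors[None, :]

    if fixed_phi is not None:
        phi = np.full(len(y), float(fixed_phi))
        common = float(fixed_phi)
    else:
        phi, common = estimate_dispersions(
            y, s, group_mask, mode=dispersion_mode, prior_df=prior_df
        )

    bA, iA, _ = _group_fit(y[:, group_mask], s[group_mask], phi)
    bB, iB, _ = _group_fit(y[:, ~group_mask], s[~group_mask], phi)
    se = np.sqrt(1.0 / np.maximum(iA, 1e-300) + 1.0 / np.maximum(iB, 1e-300))
    lfc_nat = bB - bA
    z = lfc_nat / se
    pval = 2.0 * sps.norm.sf(np.abs(z))
    fdr = benjamini_hochberg(pval, method=adjust)

    out = regions.copy()
    out["baseMean"] = (counts / s[None, :]).mean(axis=1)
    out["log2FC"] = lfc_nat / _LOG2
    out["SE"] = se / _LOG2
    out["stat"] = z
    out["pvalue"] = pval
    out["FDR"] = fdr
    out["dispersion"] = phi
    out.attrs["common_dispersion"] = common
    out.attrs["groups"] = glabels
    out.attrs["size_factors"] = s.tolist()
    out.attrs["normalization"] = size_factors.method
    return out
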
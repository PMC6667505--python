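"""Seeded synthetic 5'-capped-RNA datasets with full ground truth.

The generator plants sharp and broad TSSs on a random genome, draws
per-replicate molecule counts from a negative binomial around each TSS's
expected expression, scatters uniform background molecules, tags every
molecule with a UMI, amplifies it into a geometric number of PCR copies, and
renders the result as tag tables, coordinate-sorted SAM and multiplexed
paired FASTQ carrying the inline s-oligo bases (sample index + UMI). A
capped spike-in dilution series (2-fold ladder within each sample, scaled
across samples) is generated alongside for external normalization.

Default study conditions (see docs/methods.md for rationale): 2 Mb genome,
200 TSSs (70% sharp), expression ~ LogNormal(log 150, 1) tags/replicate
floored so every TSS has at least 10x the background per-bp density,
background 0.5 tags/bp/replicate, NB dispersion 0.1 between replicates,
PCR copies ~ Geometric(0.8), 7 nt UMIs, 4 replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b

#: default 6 nt sample indexes, pairwise Hamming distance >= 3
DEFAULT_BARCODES = (
    "AACAGC", "CCATAG", "GGTCCA", "TTGGTT",
    "ACGCTA", "CATTGC", "GTAGAT", "TGCACG",
)


@dataclass
class SimConfig:
    """All knobs of the generator; ``seed`` fixes every downstream draw."""

    seed: int = 1
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 2_000_000})
    n_tss: int = 200
    sharp_fraction: float = 0.7
    # P(offset) for offsets -4..+4 around the sharp mode: 90% of tags within
    # +/-2 bp, decaying satellite tail (real CAGE tag piles taper, they do
    # not stop abruptly)
    sharp_kernel: tuple[float, ...] = (
        0.015, 0.035, 0.09, 0.16, 0.40, 0.16, 0.09, 0.035, 0.015,
    )
    broad_width_min: int = 30
    broad_width_max: int = 70
    expr_mean: float = 150.0  # expected tags per TSS per replicate
    expr_sigma: float = 1.0  # log-scale sd of the log-normal
    min_fold_over_background: float = 10.0
    background_rate: float = 1.2  # tags per bp per replicate, both strands
    n_replicates: int = 4  # per group
    n_groups: int = 1
    replicate_libsize_factors: tuple[float, ...] | None = None
    phi_sim: float = 0.1
    pcr_geometric_p: float = 0.8  # copies per molecule ~ Geometric(p), mean 1/p
    umi_length: int = 7
    collision_free_umis: bool = False
    barcode_pattern: str = "NNNNNTTTTTTNN"
    sample_barcodes: tuple[str, ...] = DEFAULT_BARCODES
    diff_fraction: float = 0.0  # fraction of TSSs with a planted group effect
    diff_log2fc: float = 1.0
    n_spike_species: int = 10
    spike_top_count: float = 8192.0
    spike_dilution: float = 2.0
    spike_sample_step: float = 2.0  # per-sample relative concentration ladder
    spike_sample_factors: tuple[float, ...] | None = None  # overrides the step
    spike_prefix: str = "ERCC-SIM-"
    read_length: int = 50
    placement_margin: int = 1100
    min_tss_separation: int = 300

    def __post_init__(self):
        if not (0 <= self.sharp_fraction <= 1):
            raise ValueError("sharp_fraction must be in [0, 1]")
        if self.background_rate < 0 or self.expr_mean <= 0:
            raise ValueError("rates must be non-negative, expression positive")
        if abs(sum(self.sharp_kernel) - 1.0) > 1e-9:
            raise ValueError("sharp kernel must sum to 1")
        if self.n_replicates < 1 or self.n_groups < 1:
            raise ValueError("need at least one replicate and one group")

    @property
    def samples(self) -> list[str]:
        return [
            f"g{g + 1}r{r + 1}"
            for g in range(self.n_groups)
            for r in range(self.n_replicates)
        ]

    @property
    def sample_groups(self) -> list[str]:
        return [
            f"g{g + 1}"
            for g in range(self.n_groups)
            for _ in range(self.n_replicates)
        ]

    def libsize_factor(self, sample_index: int) -> float:
        if self.replicate_libsize_factors is None:
            return 1.0
        return self.replicate_libsize_factors[sample_index]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted TSS table, genome sequence and the generating config."""

    tss: pd.DataFrame  # tss_id, chrom, strand, start, end, width, shape, mode, expr_g*
    genome: dict[str, np.ndarray]  # chrom -> uint8 ASCII bases
    config: SimConfig


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, stream]))


def build_truth(config: SimConfig) -> GroundTruth:
    """Plant TSSs without same-strand overlap and draw their expression.

    Sharp TSS intervals span the 7 bp kernel support around the mode; broad
    intervals span a uniform 30-70 bp body. Expected tags per replicate are
    log-normal, floored at min_fold_over_background * background_rate * width
    so every planted TSS meets the configured density contrast. A configured
    fraction of TSSs carries a group-B fold-change for differential tests.
    """
    rng = _rng(config.seed, 0)
    genome = {
        chrom: _BASES[rng.integers(0, 4, size=size)]
        for chrom, size in sorted(config.chrom_sizes.items())
    }

    chroms = sorted(config.chrom_sizes)
    weights = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    usable = weights - 2 * config.placement_margin
    if np.all(usable <= 0):
        raise ValueError("chromosomes too short for the placement margin")
    weights = np.maximum(usable, 0) / np.maximum(usable, 0).sum()

    n_sharp = int(round(config.n_tss * config.sharp_fraction))
    shapes = ["sharp"] * n_sharp + ["broad"] * (config.n_tss - n_sharp)
    half_kernel = (len(config.sharp_kernel) - 1) // 2

    occupied: dict[tuple[str, str], list[tuple[int, int]]] = {}
    rows = []
    max_tries = 200 * config.n_tss
    tries = 0
    for i, shape in enumerate(shapes):
        if shape == "sharp":
            width = 2 * half_kernel + 1
        else:
            width = int(rng.integers(config.broad_width_min, config.broad_width_max + 1))
        placed = False
        while not placed:
            tries += 1
            if tries > max_tries:
                raise ValueError(
                    "genome too small to place the requested TSSs without overlap"
                )
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            size = config.chrom_sizes[chrom]
            lo = config.placement_margin
            hi = size - config.placement_margin - width
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            end = start + width
            pad = config.min_tss_separation
            clashes = any(
                start - pad < e and s < end + pad
                for s, e in occupied.get((chrom, strand), [])
            )
            if clashes:
                continue
            occupied.setdefault((chrom, strand), []).append((start, end))
            mode = start + half_kernel if shape == "sharp" else (start + end) // 2
            rows.append(
                {
                    "tss_id": f"tss{i + 1:04d}",
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "width": width,
                    "shape": shape,
                    "mode": mode,
                }
            )
            placed = True
    tss = pd.DataFrame(rows)

    expr = rng.lognormal(mean=np.log(config.expr_mean), sigma=config.expr_sigma,
                         size=len(tss))
    floor = (
        config.min_fold_over_background
        * config.background_rate
        * tss["width"].to_numpy(float)
    )
    expr = np.maximum(expr, floor)
    is_diff = rng.random(len(tss)) < config.diff_fraction
    tss["is_diff"] = is_diff
    for g in range(config.n_groups):
        scale = np.where(is_diff & (g > 0), 2.0 ** config.diff_log2fc, 1.0)
        tss[f"expr_g{g + 1}"] = expr * scale
    return GroundTruth(tss=tss, genome=genome, config=config)


def _umi_lut(umi_length: int) -> np.ndarray:
    """All 4**k UMI strings as a lookup table indexed by base-4 integer."""
    n = 4 ** umi_length
    codes = np.empty((n, umi_length), dtype=np.uint8)
    idx = np.arange(n)
    for j in range(umi_length - 1, -1, -1):
        codes[:, j] = _BASES[idx % 4]
        idx //= 4
    return codes.view(f"S{umi_length}").ravel().astype("U")


def render_reads(
    truth: GroundTruth, config: SimConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw molecules, UMIs and PCR copies for every sample.

    Returns ``(reads, molecule_counts)``. ``reads`` has one row per
    sequenced read (post-amplification) with memory-lean columns: chrom /
    strand / sample (categorical), pos (0-based 5' end), tss_index (row into
    the truth table, -1 for background), molecule (pre-amplification id),
    umi_int (base-4 encoded UMI; see :func:`_umi_lut`), read_no (unique read
    id; the rendered read name is ``f"r{read_no}"``). ``molecule_counts`` is
    the pre-amplification truth: molecules per (tss_id, sample).
    """
    if config is None:
        config = truth.config
    kernel = np.asarray(config.sharp_kernel, dtype=float)
    half_kernel = (len(kernel) - 1) // 2
    offsets = np.arange(-half_kernel, half_kernel + 1)
    tss = truth.tss
    chroms = sorted(config.chrom_sizes)
    chrom_code = {c: i for i, c in enumerate(chroms)}
    tss_chrom_codes = tss["chrom"].map(chrom_code).to_numpy(np.int16)
    tss_strand_codes = (tss["strand"] == "-").to_numpy().astype(np.int8)

    parts = []
    mol_base = 0
    for si, sample in enumerate(config.samples):
        rng = _rng(config.seed, 100 + si)
        group = config.sample_groups[si]
        lib = config.libsize_factor(si)
        mean = tss[f"expr_{group}"].to_numpy(float) * lib
        if config.phi_sim > 0:
            lam = rng.gamma(shape=1.0 / config.phi_sim,
                            scale=mean * config.phi_sim)
        else:
            lam = mean
        n_mol = rng.poisson(lam)

        rep = np.repeat(np.arange(len(tss), dtype=np.int32), n_mol)
        total = len(rep)
        pos = np.empty(total, dtype=np.int64)
        sharp_mask = np.repeat((tss["shape"] == "sharp").to_numpy(), n_mol)
        modes = np.repeat(tss["mode"].to_numpy(np.int64), n_mol)
        starts = np.repeat(tss["start"].to_numpy(np.int64), n_mol)
        widths = np.repeat(tss["width"].to_numpy(np.int64), n_mol)
        ns = int(sharp_mask.sum())
        pos[sharp_mask] = modes[sharp_mask] + rng.choice(offsets, size=ns, p=kernel)
        nb = total - ns
        pos[~sharp_mask] = starts[~sharp_mask] + np.floor(
            rng.random(nb) * widths[~sharp_mask]
        ).astype(np.int64)
        ccodes = [np.repeat(tss_chrom_codes, n_mol)]
        scodes = [np.repeat(tss_strand_codes, n_mol)]
        poss = [pos]
        tidx = [rep]

        # Background covers the whole chromosome minus a read-length margin
        # (so rendered reads never run off the sequence ends).
        bg_margin = config.read_length
        for chrom in chroms:
            size = config.chrom_sizes[chrom]
            span = size - 2 * bg_margin
            n_bg = rng.poisson(config.background_rate * span * lib)
            ccodes.append(np.full(n_bg, chrom_code[chrom], dtype=np.int16))
            scodes.append((rng.random(n_bg) < 0.5).astype(np.int8))
            poss.append(rng.integers(bg_margin, size - bg_margin, size=n_bg))
            tidx.append(np.full(n_bg, -1, dtype=np.int32))

        ccode = np.concatenate(ccodes)
        scode = np.concatenate(scodes)
        pos = np.concatenate(poss)
        tss_index = np.concatenate(tidx)
        n = len(pos)
        molecule = mol_base + np.arange(n, dtype=np.int64)
        mol_base += n

        space = 4 ** config.umi_length
        if config.collision_free_umis:
            order = np.lexsort((pos, scode, ccode))
            ccode, scode, pos = ccode[order], scode[order], pos[order]
            tss_index, molecule = tss_index[order], molecule[order]
            new_group = np.ones(n, dtype=bool)
            new_group[1:] = (
                (np.diff(ccode) != 0) | (np.diff(scode) != 0) | (np.diff(pos) != 0)
            )
            gid = np.cumsum(new_group) - 1
            group_starts = np.flatnonzero(new_group)
            within = np.arange(n) - np.repeat(
                group_starts, np.diff(np.append(group_starts, n))
            )
            if n and within.max() >= space:
                raise ValueError("too many molecules at one position for unique UMIs")
            group_offsets = rng.integers(0, space, size=len(group_starts))
            umi_int = (group_offsets[gid] + within) % space
        else:
            umi_int = rng.integers(0, space, size=n)

        copies = np.minimum(
            rng.geometric(config.pcr_geometric_p, size=n), 50
        ).astype(np.int64)
        idx = np.repeat(np.arange(n), copies)
        copy_no = np.arange(len(idx)) - np.repeat(np.cumsum(copies) - copies, copies)
        parts.append(
            pd.DataFrame(
                {
                    "chrom": pd.Categorical.from_codes(ccode[idx], categories=chroms),
                    "strand": pd.Categorical.from_codes(
                        scode[idx], categories=["+", "-"]
                    ),
                    "pos": pos[idx],
                    "tss_index": tss_index[idx],
                    "sample": pd.Categorical(
                        [sample] * len(idx), categories=config.samples
                    ),
                    "molecule": molecule[idx],
                    "umi_int": umi_int[idx],
                    "read_no": molecule[idx] * 64 + copy_no,
                }
            )
        )

    reads = pd.concat(parts, ignore_index=True)
    mols = reads.drop_duplicates("molecule")
    planted = mols[mols["tss_index"] >= 0]
    mc = (
        planted.groupby(
            [
                pd.Categorical.from_codes(
                    planted["tss_index"].to_numpy(), categories=tss["tss_id"]
                ),
                planted["sample"],
            ],
            observed=True,
        )
        .size()
        .rename_axis(["tss_id", "sample"])
        .reset_index(name="molecules")
    )
    return reads, mc


def render_spikes(config: SimConfig) -> pd.DataFrame:
    """Spike-in count table: a within-sample 2-fold dilution ladder, scaled
    across samples by the configured relative-concentration series, with
    Poisson counting noise. Rows are species (named with the spike prefix so
    prefix-based exclusion is exercised), columns samples."""
    if config.n_spike_species < 2:
        raise ValueError("need at least 2 spike species")
    import warnings

    rng = _rng(config.seed, 50)
    ranks = np.arange(config.n_spike_species)
    within = config.spike_top_count / config.spike_dilution ** ranks
    if config.spike_sample_factors is not None:
        sample_factors = np.asarray(config.spike_sample_factors, dtype=float)
        if len(sample_factors) != len(config.samples):
            raise ValueError("one spike concentration factor per sample required")
    else:
        sample_factors = config.spike_sample_step ** np.arange(
            len(config.samples), dtype=float
        )
    if np.any(sample_factors == 0):
        warnings.warn(
            "zero spike concentration for at least one sample: the all-zero "
            "column cannot support external normalization",
            stacklevel=2,
        )
    expected = np.outer(within, sample_factors)
    counts = rng.poisson(expected)
    names = [f"{config.spike_prefix}{r + 1:02d}" for r in ranks]
    return pd.DataFrame(counts, index=names, columns=config.samples)


def tags_from_reads(reads: pd.DataFrame, umi_length: int = 7) -> pd.DataFrame:
    """Reads table -> tag table (preprocess conventions), one tag per read.

    UMIs are rendered as categorical ACGT strings (the category table is the
    full base-4 code book, already in lexicographic order, so sorting and
    grouping behave exactly like plain strings at a fraction of the memory).
    """
    lut = _umi_lut(umi_length)
    return pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "pos": reads["pos"].astype(np.int64),
            "strand": reads["strand"],
            "umi": pd.Categorical.from_codes(
                reads["umi_int"].to_numpy(np.int64), categories=lut
            ),
            "sample": reads["sample"],
            "name": reads["read_no"].astype(np.int64),
            "mapq": np.int32(60),
        }
    )


def simulate_tss_count_matrix(
    n_rows: int,
    n_per_group: tuple[int, int] = (3, 3),
    mean: float = 150.0,
    sigma: float = 1.0,
    phi: float = 0.1,
    diff_fraction: float = 0.0,
    diff_log2fc: float = 2.0,
    size_factors: np.ndarray | None = None,
    seed: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Direct NB count matrix for differential-testing studies.

    Returns (counts, group_labels, is_diff). Row means are log-normal; a
    ``diff_fraction`` of rows carries ``diff_log2fc`` in group B. Size
    factors multiply expected counts per sample.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    nA, nB = n_per_group
    S = nA + nB
    if size_factors is None:
        size_factors = np.ones(S)
    groups = np.array(["A"] * nA + ["B"] * nB)
    base = rng.lognormal(np.log(mean), sigma, size=n_rows)
    is_diff = rng.random(n_rows) < diff_fraction
    mu = np.outer(base, size_factors)
    mu[:, nA:] *= np.where(is_diff, 2.0 ** diff_log2fc, 1.0)[:, None]
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    else:
        lam = mu
    counts = rng.poisson(lam)
    return counts, groups, is_diff


# ---------------------------------------------------------------------------
# file renderers


def write_fasta(genome: dict[str, np.ndarray], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom].tobytes().decode()
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gather_seqs(
    genome: dict[str, np.ndarray],
    chrom: np.ndarray,
    pos: np.ndarray,
    strand: np.ndarray,
    length: int,
) -> np.ndarray:
    """Read sequences whose 5' end sits at ``pos`` on ``strand`` (length bp),
    as a U-string array; minus-strand sequences are reverse-complemented."""
    out = np.empty(len(pos), dtype=f"S{length}")
    for c in np.unique(chrom):
        arr = genome[c]
        m = chrom == c
        p = pos[m]
        plus = strand[m] == "+"
        seqs = np.empty((m.sum(), length), dtype=np.uint8)
        if plus.any():
            gathered = arr[np.clip(p[plus, None] + np.arange(length), 0, len(arr) - 1)]
            seqs[plus] = gathered
        minus = ~plus
        if minus.any():
            gathered = arr[
                np.clip(p[minus, None] - np.arange(length), 0, len(arr) - 1)
            ]
            seqs[minus] = _COMP[gathered]
        out[m] = seqs.view(f"S{length}").ravel()
    return out.astype("U")


def write_sam(
    reads: pd.DataFrame,
    genome: dict[str, np.ndarray],
    chrom_sizes: dict[str, int],
    path: str,
    read_length: int = 50,
    layout_length: int = 13,
) -> None:
    """Coordinate-sorted single-end SAM of the genomic portion of each read.

    Alignments are single-block (no splicing); the 5' end of the alignment is
    the read's tag position, so plus-strand records start at pos and
    minus-strand records end at pos (SAM flag 16).
    """
    glen = read_length - layout_length
    df = reads.sort_values(["chrom", "pos", "read_no"], kind="mergesort")
    n = len(df)
    chrom_all = np.asarray(df["chrom"].astype(str).to_numpy(object))
    pos_all = df["pos"].to_numpy(np.int64)
    strand_all = np.asarray(df["strand"].astype(str).to_numpy(object))
    read_no_all = df["read_no"].to_numpy(np.int64)
    qual = "I" * glen
    cigar = f"{glen}M"
    chunk = 500_000
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for c in sorted(chrom_sizes):
            fh.write(f"@SQ\tSN:{c}\tLN:{chrom_sizes[c]}\n")
        for i in range(0, n, chunk):
            sl = slice(i, min(i + chunk, n))
            chrom = chrom_all[sl]
            pos = pos_all[sl]
            strand = strand_all[sl]
            minus = strand == "-"
            left = np.where(minus, pos - glen + 1, pos)
            seqs = _gather_seqs(genome, chrom, pos, strand, glen)
            flags = np.where(minus, 16, 0)
            fh.write(
                "".join(
                    f"r{rn}\t{fl}\t{c}\t{p + 1}\t60\t{cigar}\t*\t0\t0\t{s}\t{qual}\n"
                    for rn, fl, c, p, s in zip(
                        read_no_all[sl], flags, chrom, left, seqs
                    )
                )
            )


def write_fastq_pairs(
    reads: pd.DataFrame,
    config: SimConfig,
    genome: dict[str, np.ndarray],
    r1_path: str,
    r2_path: str,
) -> None:
    """Multiplexed paired FASTQ with the s-oligo layout on R1.

    R1 = layout bases (sample index at the T positions, the molecule's UMI at
    the N positions) followed by the genomic sequence 5'-anchored at the tag
    position; R2 is the reverse complement of the genomic portion (fragment
    length modelling is out of scope). Samples are interleaved in generation
    order; read names match the SAM records.
    """
    from .preprocess import parse_barcode_layout

    layout = parse_barcode_layout(config.barcode_pattern)
    glen = config.read_length - layout.length
    n = len(reads)
    umi_lut_codes = np.empty((4 ** config.umi_length, config.umi_length), np.uint8)
    idx = np.arange(4 ** config.umi_length)
    for j in range(config.umi_length - 1, -1, -1):
        umi_lut_codes[:, j] = _BASES[idx % 4]
        idx //= 4
    bc_codes = np.array(
        [
            np.frombuffer(config.sample_barcodes[i].encode(), dtype=np.uint8)
            for i in range(len(config.samples))
        ]
    )

    q1 = "I" * config.read_length
    q2 = "I" * glen
    chunk = 250_000
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for i in range(0, n, chunk):
            sl = slice(i, min(i + chunk, n))
            sub = reads.iloc[sl]
            m = len(sub)
            chrom = np.asarray(sub["chrom"].astype(str).to_numpy(object))
            pos = sub["pos"].to_numpy(np.int64)
            strand = np.asarray(sub["strand"].astype(str).to_numpy(object))
            genomic = _gather_seqs(genome, chrom, pos, strand, glen)

            prefix = np.empty((m, layout.length), dtype=np.uint8)
            umi_b = umi_lut_codes[sub["umi_int"].to_numpy(np.int64)]
            for k, p in enumerate(layout.umi_positions):
                prefix[:, p] = umi_b[:, k]
            sample_idx = np.asarray(sub["sample"].cat.codes)
            for k, p in enumerate(layout.index_positions):
                prefix[:, p] = bc_codes[sample_idx, k]
            prefix_str = prefix.view(f"S{layout.length}").ravel().astype("U")

            r1 = np.char.add(prefix_str, genomic)
            gb = np.asarray(genomic, dtype=f"S{glen}").view(np.uint8).reshape(m, glen)
            r2 = _COMP[gb[:, ::-1]].copy().view(f"S{glen}").ravel().astype("U")
            names = sub["read_no"].to_numpy(np.int64)
            f1.write(
                "".join(
                    f"@r{a}\n{b}\n+\n{q1}\n" for a, b in zip(names, r1)
                )
            )
            f2.write(
                "".join(
                    f"@r{a}\n{b}\n+\n{q2}\n" for a, b in zip(names, r2)
                )
            )


def write_truth(truth: GroundTruth, bed_path: str, tsv_path: str) -> None:
    """Planted TSS intervals as BED6 (score = width) plus the full TSV."""
    tss = truth.tss
    with open(bed_path, "w") as fh:
        for row in tss.itertuples():
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.tss_id}\t"
                f"{row.width}\t{row.strand}\n"
            )
    tss.to_csv(tsv_path, sep="\t", index=False)
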
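"""Haploid-vs-diploid log-likelihood ratios from low-pass read observations.

The discriminating signal for absence of heterozygosity: given a handful of
reads in a genomic bin and the local haplotype frequencies of a phased
reference panel, the probability of the observed alleles differs between

* the haploid hypothesis — a single latent haplotype drawn from the panel
  generated every read (what an iso-disomic / AOH region looks like), and
* the diploid hypothesis — two latent haplotypes drawn independently from the
  panel, each read generated from one of them with probability 1/2.

With per-base error rate ``epsilon``, a read's emission probability given a
local haplotype pattern is Π over its SNPs of (1-eps) on match else eps.
Then, over the distinct local patterns j with frequencies f_j (an exact
collapse of the panel),

    L_hap = Σ_j f_j Π_r e(r, j)
    L_dip = Σ_j Σ_k f_j f_k Π_r [ e(r,j)/2 + e(r,k)/2 ]

and LLR = ln L_hap − ln L_dip.  A single read gives LLR = 0 identically, and
eps = 1/2 makes every read uninformative (LLR = 0): at least two reads with
usable SNPs are needed for signal, which is why bins carry a minimum-read
validity flag.

Per 10 kb bin, one LLR is computed per observed SNP ("anchor"): the read set
is every read covering the anchor plus the nearest other SNP-bearing reads in
the bin (by leftmost-SNP distance, read_id as tie-break) up to
``max_reads_per_anchor`` reads.  The bin's feature is the mean and population
variance of those per-anchor LLRs.  When the bin holds no more reads than the
cap, every anchor shares the same read set, hence the same LLR — that is a
genuine property of sparse data, not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observations import ObservationSet
from .panel import HaplotypePanel, LocalPatternSet, collapse_local_patterns

BIN_SIZE = 10_000


@dataclass
class EmissionConfig:
    epsilon: float = 0.002
    max_reads_per_anchor: int = 12
    min_reads_per_bin: int = 2
    #: optional sensitivity-analysis mode: instead of per-anchor read sets,
    #: draw `resample_draws` random subsets of up to `max_reads_per_anchor`
    #: reads per bin and aggregate LLR over draws. 0 = off (default).
    resample_draws: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon < 0.5 or self.epsilon == 0.5):
            raise ValueError("epsilon must be in [0, 0.5]")
        if self.max_reads_per_anchor < 1:
            raise ValueError("max_reads_per_anchor must be >= 1")


@dataclass
class BinStat:
    """LLR summary of one genomic bin (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    llr_mean: float
    llr_var: float
    n_snps_with_llr: int
    n_reads: int
    valid: bool


# -- emission and likelihood kernels ---------------------------------------


def emission_prob(
    read_alleles: np.ndarray, pattern_alleles: np.ndarray, epsilon: float
) -> float:
    """P(read's observed alleles | local haplotype pattern)."""
    read_alleles = np.asarray(read_alleles)
    pattern_alleles = np.asarray(pattern_alleles)
    if read_alleles.shape != pattern_alleles.shape:
        raise ValueError("pattern does not cover the read's SNPs")
    match = read_alleles == pattern_alleles
    return float(
        (1.0 - epsilon) ** match.sum() * epsilon ** (match.size - match.sum())
    )


def _emission_matrix(
    reads: list[tuple[np.ndarray, np.ndarray]],
    patterns: LocalPatternSet,
    epsilon: float,
) -> np.ndarray:
    """(R, P) emission probabilities; reads given in panel SNP index space."""
    cols = patterns.snp_indices
    E = np.empty((len(reads), patterns.patterns.shape[0]))
    for r, (snp_idx, alleles) in enumerate(reads):
        snp_idx = np.asarray(snp_idx, dtype=np.int64)
        j = np.searchsorted(cols, snp_idx)
        if (j >= cols.size).any() or (cols[np.minimum(j, cols.size - 1)] != snp_idx).any():
            raise ValueError("pattern set does not cover a read's SNPs")
        pat = patterns.patterns[:, j]  # (P, k_r)
        match = pat == np.asarray(alleles, dtype=np.uint8)[None, :]
        n_match = match.sum(axis=1)
        E[r] = (1.0 - epsilon) ** n_match * epsilon ** (pat.shape[1] - n_match)
    return E


def ploidy_likelihoods(
    reads: list[tuple[np.ndarray, np.ndarray]],
    patterns: LocalPatternSet,
    epsilon: float,
) -> tuple[float, float]:
    """(L_hap, L_dip) for a set of grouped reads over collapsed patterns.

    Exact: pattern collapse preserves the full-panel sums because pattern
    frequencies are summed haplotype weights.
    """
    if not reads:
        raise ValueError("empty read list")
    E = _emission_matrix(reads, patterns, epsilon)
    f = patterns.freqs
    l_hap = float(f @ E.prod(axis=0))
    M = np.ones((f.size, f.size))
    for r in range(E.shape[0]):
        M *= 0.5 * (E[r][:, None] + E[r][None, :])
    l_dip = float(f @ M @ f)
    return l_hap, l_dip


def llr_from_reads(
    reads: list[tuple[np.ndarray, np.ndarray]],
    panel: HaplotypePanel,
    epsilon: float,
) -> float:
    """ln L_hap − ln L_dip for grouped reads, collapsing the panel locally."""
    union = np.unique(np.concatenate([np.asarray(i) for i, _ in reads]))
    patterns = collapse_local_patterns(panel, union)
    l_hap, l_dip = ploidy_likelihoods(reads, patterns, epsilon)
    if l_hap <= 0.0 or l_dip <= 0.0:
        # only reachable at epsilon == 0 with inconsistent reads
        return float("-inf") if l_hap <= 0.0 else float("inf")
    return float(np.log(l_hap) - np.log(l_dip))


# -- per-anchor read-set assembly -------------------------------------------


class _BinReads:
    """Reads of one bin: parallel lists of (snp_indices, alleles) + metadata."""

    __slots__ = ("reads", "read_ids", "left_pos", "covers")

    def __init__(self, reads, read_ids, left_pos, covers):
        self.reads = reads          # list[(idx_array, allele_array)]
        self.read_ids = read_ids    # list[str]
        self.left_pos = left_pos    # np.ndarray, leftmost SNP position (1-based)
        self.covers = covers        # list[set[int]] panel indices per read


def _anchor_read_set(
    anchor_index: int,
    anchor_pos: int,
    bin_reads: _BinReads,
    max_reads: int,
) -> list[int] | None:
    covering = [
        r for r in range(len(bin_reads.reads)) if anchor_index in bin_reads.covers[r]
    ]
    if not covering:
        return None
    chosen = list(covering)
    if len(chosen) < max_reads:
        others = [r for r in range(len(bin_reads.reads)) if r not in set(covering)]
        others.sort(
            key=lambda r: (
                abs(int(bin_reads.left_pos[r]) - anchor_pos),
                bin_reads.read_ids[r],
            )
        )
        chosen += others[: max_reads - len(chosen)]
    elif len(chosen) > max_reads:
        chosen.sort(
            key=lambda r: (
                abs(int(bin_reads.left_pos[r]) - anchor_pos),
                bin_reads.read_ids[r],
            )
        )
        chosen = chosen[:max_reads]
    return chosen


def snp_anchored_llr(
    anchor_index: int,
    bin_reads: _BinReads,
    panel: HaplotypePanel,
    cfg: EmissionConfig,
) -> float | None:
    """LLR for one anchor SNP, or None if no read covers it."""
    anchor_pos = int(panel.positions[anchor_index])
    chosen = _anchor_read_set(
        anchor_index, anchor_pos, bin_reads, cfg.max_reads_per_anchor
    )
    if chosen is None:
        return None
    reads = [bin_reads.reads[r] for r in chosen]
    return llr_from_reads(reads, panel, cfg.epsilon)


# -- per-bin statistics ------------------------------------------------------


def _group_bin_reads(
    obs: ObservationSet, panel: HaplotypePanel
) -> dict[tuple[str, int], _BinReads]:
    """Group observations into reads, and reads into bins by leftmost SNP."""
    t = obs.table
    if not len(t):
        return {}
    snp_idx = t["snp_index"].to_numpy()
    alleles = t["allele"].to_numpy()
    pos = panel.positions[snp_idx]
    rid_codes, rid_uniques = pd.factorize(t["read_id"])
    order = np.lexsort((pos, rid_codes))
    snp_idx, alleles, pos, rid_codes = (
        snp_idx[order],
        alleles[order],
        pos[order],
        rid_codes[order],
    )
    boundaries = np.flatnonzero(np.r_[True, rid_codes[1:] != rid_codes[:-1]])
    ends = np.r_[boundaries[1:], rid_codes.size]
    out: dict[tuple[str, int], _BinReads] = {}
    for b, e in zip(boundaries, ends):
        idx = snp_idx[b:e]
        left = int(pos[b])  # rows sorted by pos within read
        chrom = panel.chroms[idx[0]]
        key = (str(chrom), (left - 1) // BIN_SIZE)
        br = out.get(key)
        if br is None:
            br = _BinReads([], [], [], [])
            out[key] = br
        br.reads.append((idx, alleles[b:e]))
        br.read_ids.append(str(rid_uniques[rid_codes[b]]))
        br.left_pos.append(left)
        br.covers.append(set(int(i) for i in idx))
    for br in out.values():
        br.left_pos = np.asarray(br.left_pos, dtype=np.int64)
        # deterministic read order: (leftmost pos, read_id)
        order = sorted(
            range(len(br.reads)), key=lambda r: (int(br.left_pos[r]), br.read_ids[r])
        )
        br.reads = [br.reads[r] for r in order]
        br.read_ids = [br.read_ids[r] for r in order]
        br.covers = [br.covers[r] for r in order]
        br.left_pos = br.left_pos[list(order)]
    return out


def bin_statistics(
    bins: dict[str, np.ndarray],
    obs: ObservationSet,
    panel: HaplotypePanel,
    cfg: EmissionConfig | None = None,
    seed: int = 0,
) -> list[BinStat]:
    """Per-bin LLR mean/variance over all computable SNP-anchored LLRs.

    ``bins`` maps chromosome -> (n, 2) array of half-open [start, end) rows
    tiling the chromosome from 0 (see ``windowing.make_bins``).  Bins with
    fewer than ``min_reads_per_bin`` SNP-bearing reads, or with no computable
    anchor, are marked invalid; that is data, not an error.
    """
    cfg = cfg or EmissionConfig()
    grouped = _group_bin_reads(obs, panel)
    rng = np.random.default_rng(seed)
    out: list[BinStat] = []
    for chrom, arr in bins.items():
        for bin_id in range(arr.shape[0]):
            start, end = int(arr[bin_id, 0]), int(arr[bin_id, 1])
            br = grouped.get((chrom, start // BIN_SIZE))
            if br is None or len(br.reads) < cfg.min_reads_per_bin:
                out.append(
                    BinStat(
                        chrom, start, end, 0.0, 0.0, 0,
                        0 if br is None else len(br.reads), False,
                    )
                )
                continue
            llrs = _bin_llrs(br, panel, cfg, rng)
            if not llrs:
                out.append(
                    BinStat(chrom, start, end, 0.0, 0.0, 0, len(br.reads), False)
                )
                continue
            v = np.asarray(llrs)
            out.append(
                BinStat(
                    chrom, start, end,
                    float(v.mean()), float(v.var()),  # population variance
                    len(llrs), len(br.reads), True,
                )
            )
    return out


def _bin_llrs(
    br: _BinReads,
    panel: HaplotypePanel,
    cfg: EmissionConfig,
    rng: np.random.Generator,
) -> list[float]:
    n_reads = len(br.reads)
    if cfg.resample_draws > 0:
        m = min(cfg.max_reads_per_anchor, n_reads)
        vals = []
        for _ in range(cfg.resample_draws):
            pick = rng.choice(n_reads, size=m, replace=False)
            vals.append(
                llr_from_reads([br.reads[r] for r in pick], panel, cfg.epsilon)
            )
        return vals
    anchors = sorted(set().union(*br.covers))
    if n_reads <= cfg.max_reads_per_anchor:
        # every anchor's read set is the whole bin: one LLR shared by all
        llr = llr_from_reads(br.reads, panel, cfg.epsilon)
        return [llr] * len(anchors)
    vals = []
    for a in anchors:
        llr = snp_anchored_llr(a, br, panel, cfg)
        if llr is not None:
            vals.append(llr)
    return vals


# -- track export ------------------------------------------------------------


def write_binstat_track(stats: list[BinStat], path) -> None:
    """BED4-like TSV: chrom start end llr_mean llr_var n_snps valid."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tllr_mean\tllr_var\tn_snps\tvalid\n")
        for s in stats:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.llr_mean:.6g}\t"
                f"{s.llr_var:.6g}\t{s.n_snps_with_llr}\t{int(s.valid)}\n"
            )
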
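"""Synthetic panels, individuals with implanted AOH tracts, and low-pass reads.

The generator emulates the study regime end to end, on one chromosome at
desk scale: a phased haplotype panel with block linkage disequilibrium
(founder haplotypes plus Li–Stephens-style copies with a per-bp switch
rate), diploid individuals whose second haplotype is overwritten by the
first inside implanted intervals (iso-disomy: long contiguous homozygosity,
zero heterozygous panel sites inside the tract), and uniformly placed
single-end short reads at a configurable fold-coverage with a per-base
substitution error.

Defaults model a common-variant genotyping panel: minor allele frequencies
from a Beta(0.5, 0.5) truncated to [0.02, 0.98], 2 SNPs per kb, 35 bp reads.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .observations import ObservationSet
from .panel import HaplotypePanel, PanelSNP

_SUB = {"A": "C", "C": "T", "G": "A", "T": "G"}
_BASES = "ACGT"


@dataclass
class SimConfig:
    n_haplotypes: int = 60
    n_founders: int = 12
    switch_rate: float = 1e-5  # per bp, Li-Stephens copying switch rate
    mutation_rate: float = 1e-4  # per site, copying mismatch rate
    snp_density: float = 0.002  # SNPs per bp (2 per kb)
    maf_beta: tuple[float, float] = (0.5, 0.5)
    maf_bounds: tuple[float, float] = (0.02, 0.98)
    chrom: str = "chr1"
    chrom_length: int = 100_000_000
    read_length: int = 35
    epsilon_seq: float = 0.002  # per-base read error
    depth: float = 0.1  # fold coverage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.n_founders > self.n_haplotypes:
            raise ValueError("n_founders cannot exceed n_haplotypes")
        if self.depth <= 0 or self.snp_density <= 0:
            raise ValueError("depth and snp_density must be positive")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class SyntheticTruth:
    """A simulated diploid individual with known AOH intervals."""

    panel: HaplotypePanel
    hap_indices: tuple[int, int]
    haplotypes: np.ndarray  # (2, S) allele codes after AOH implanting
    aoh_intervals: list[tuple[str, int, int]]  # 0-based half-open
    provenance: dict = field(default_factory=dict)

    def heterozygous_mask(self) -> np.ndarray:
        return self.haplotypes[0] != self.haplotypes[1]


# -- panel simulation --------------------------------------------------------


def simulate_panel(cfg: SimConfig) -> HaplotypePanel:
    """Founder haplotypes + Li-Stephens copies, giving block LD; seeded."""
    rng = np.random.default_rng(cfg.seed)
    L, n_snps = cfg.chrom_length, int(round(cfg.chrom_length * cfg.snp_density))
    # distinct sorted 1-based positions
    pos = np.array([], dtype=np.int64)
    while pos.size < n_snps:
        extra = rng.integers(1, L + 1, size=int(1.1 * (n_snps - pos.size)) + 16)
        pos = np.unique(np.concatenate([pos, extra]))
    pos = np.sort(rng.choice(pos, size=n_snps, replace=False))

    a, b = cfg.maf_beta
    lo, hi = cfg.maf_bounds
    freqs = np.clip(rng.beta(a, b, size=n_snps), lo, hi)

    K, H = cfg.n_founders, cfg.n_haplotypes
    founders = (rng.random((K, n_snps)) < freqs).astype(np.uint8)
    haps = np.empty((H, n_snps), dtype=np.uint8)
    haps[:K] = founders
    for h in range(K, H):
        n_switch = rng.poisson(cfg.switch_rate * L)
        cuts = np.sort(rng.integers(0, L, size=n_switch))
        bounds = np.searchsorted(pos - 1, cuts)
        seg_bounds = np.r_[0, bounds, n_snps]
        sources = rng.integers(0, K, size=seg_bounds.size - 1)
        row = np.concatenate(
            [
                founders[src, s:e]
                for src, s, e in zip(sources, seg_bounds[:-1], seg_bounds[1:])
            ]
        )
        flip = rng.random(n_snps) < cfg.mutation_rate
        haps[h] = row ^ flip.astype(np.uint8)

    ref_codes = rng.integers(0, 4, size=n_snps)
    snps = [
        PanelSNP(
            cfg.chrom,
            int(p),
            _BASES[c],
            _SUB[_BASES[c]],
            index=i,
        )
        for i, (p, c) in enumerate(zip(pos, ref_codes))
    ]
    return HaplotypePanel(snps, haps, population_tag=f"synthetic-{cfg.config_hash()}")


# -- individual simulation ---------------------------------------------------


def simulate_individual(
    panel: HaplotypePanel,
    aoh_spec: list[tuple[str, int, int]],
    seed: int,
) -> SyntheticTruth:
    """Draw two panel haplotypes; implant iso-disomy over ``aoh_spec``.

    Inside each AOH interval the second haplotype's alleles are overwritten
    by the first, producing contiguous homozygosity at every panel site.
    """
    ivals = sorted(aoh_spec)
    for (c1, s1, e1), (c2, s2, e2) in zip(ivals, ivals[1:]):
        if c1 == c2 and s2 < e1:
            raise ValueError(f"overlapping AOH intervals: {ivals}")
    rng = np.random.default_rng(seed)
    i, j = rng.choice(panel.n_haplotypes, size=2, replace=False)
    haps = np.stack([panel.haplotypes[i].copy(), panel.haplotypes[j].copy()])
    for chrom, start, end in ivals:
        idx = panel.snp_indices_in(chrom, start, end)
        haps[1, idx] = haps[0, idx]
    return SyntheticTruth(
        panel=panel,
        hap_indices=(int(i), int(j)),
        haplotypes=haps,
        aoh_intervals=ivals,
        provenance={"seed": int(seed)},
    )


# -- read simulation ---------------------------------------------------------


def _background_base(pos0: int) -> str:
    return _BASES[(pos0 * 2654435761) % 4]


def simulate_reads(
    truth: SyntheticTruth,
    cfg: SimConfig,
    seed: int | None = None,
    sam_path: str | Path | None = None,
) -> ObservationSet:
    """Uniform single-end reads at ``cfg.depth`` fold; seeded and reproducible.

    Each read is drawn from one of the individual's two haplotypes with
    probability 1/2; at each overlapped panel SNP the true allele is flipped
    with probability ``epsilon_seq``.  Optionally writes a minimal single-end
    SAM (MAPQ 60, uniform base quality) — intended for small simulations, as
    it materializes every read.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    L, rl = cfg.chrom_length, cfg.read_length
    n_reads = int(round(cfg.depth * L / rl))
    starts0 = rng.integers(0, L - rl + 1, size=n_reads)
    hap_choice = rng.integers(0, 2, size=n_reads)

    sl = truth.panel.chrom_slice(cfg.chrom)
    pos0 = truth.panel.positions[sl] - 1
    lo = np.searchsorted(pos0, starts0, side="left") + sl.start
    hi = np.searchsorted(pos0, starts0 + rl, side="left") + sl.start
    counts = hi - lo
    sel = np.flatnonzero(counts > 0)
    reps = counts[sel]
    total = int(reps.sum())
    if total:
        seg_starts = np.cumsum(reps) - reps
        within = np.arange(total) - np.repeat(seg_starts, reps)
        snp_idx = np.repeat(lo[sel], reps) + within
        read_of_obs = np.repeat(sel, reps)
        hap_of_obs = hap_choice[read_of_obs]
        alleles = np.where(
            hap_of_obs == 0,
            truth.haplotypes[0][snp_idx],
            truth.haplotypes[1][snp_idx],
        ).astype(np.int8)
        flips = rng.random(total) < cfg.epsilon_seq
        alleles = (alleles ^ flips.astype(np.int8)).astype(np.int8)
        table = pd.DataFrame(
            {
                "read_id": [f"r{int(i):08d}" for i in read_of_obs],
                "snp_index": snp_idx.astype(np.int64),
                "allele": alleles,
                "base_quality": np.full(total, 37, dtype=np.int16),
            }
        )
    else:
        table = None
        snp_idx = np.empty(0, dtype=np.int64)
        read_of_obs = np.empty(0, dtype=np.int64)
        alleles = np.empty(0, dtype=np.int8)

    obs = ObservationSet(
        table, depth_estimate=n_reads * rl / L, source="synthetic"
    ).canonical(truth.panel)

    if sam_path is not None:
        _write_sam(
            sam_path, truth, cfg, starts0, read_of_obs, snp_idx, alleles
        )
    return obs


def _write_sam(path, truth, cfg, starts0, read_of_obs, snp_idx, alleles):
    panel = truth.panel
    obs_by_read: dict[int, list[tuple[int, int]]] = {}
    for r, s, a in zip(read_of_obs, snp_idx, alleles):
        obs_by_read.setdefault(int(r), []).append((int(s), int(a)))
    rl = cfg.read_length
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{cfg.chrom}\tLN:{cfg.chrom_length}\n")
        qual = "F" * rl  # phred 37
        for i, s0 in enumerate(starts0):
            seq = [_background_base(int(s0) + k) for k in range(rl)]
            for sidx, allele in obs_by_read.get(i, ()):  # place SNP bases
                snp = panel.snps[sidx]
                off = (snp.pos - 1) - int(s0)
                seq[off] = snp.alt_allele if allele else snp.ref_allele
            fh.write(
                f"r{i:08d}\t0\t{cfg.chrom}\t{int(s0) + 1}\t60\t{rl}M\t*\t0\t0\t"
                f"{''.join(seq)}\t{qual}\n"
            )


# -- benchmark generation ----------------------------------------------------


def place_aoh(
    cfg: SimConfig, size_range: tuple[int, int], seed: int
) -> list[tuple[str, int, int]]:
    """One implanted AOH interval, uniform size and position."""
    rng = np.random.default_rng(seed)
    size = int(rng.integers(size_range[0], size_range[1] + 1))
    start = int(rng.integers(0, cfg.chrom_length - size + 1))
    return [(cfg.chrom, start, start + size)]


def make_benchmark(
    n_train_samples: int,
    n_test_samples: int,
    depths: list[float],
    aoh_size_range: tuple[int, int],
    cfg: SimConfig,
    outdir: str | Path | None = None,
) -> dict:
    """Panels + individuals + reads per depth, with a seed manifest.

    Train and test individuals use disjoint seed streams (and therefore
    independent haplotype draws).  Returns a manifest dict; with ``outdir``
    also writes panel TSV, observation TSVs, truth BEDs and manifest JSON.
    The in-memory objects ride along under the "data" key.
    """
    panel = simulate_panel(cfg)
    base = cfg.seed
    samples: dict[str, SyntheticTruth] = {}
    observations: dict[tuple[str, float], ObservationSet] = {}
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "depths": list(depths),
        "samples": {},
    }
    roles = [("train", k) for k in range(n_train_samples)] + [
        ("test", k) for k in range(n_test_samples)
    ]
    for role, k in roles:
        offset = k if role == "train" else 100_000 + k
        ind_seed = (base * 1_000_003 + 17 + offset) % 2**31
        aoh_seed = (base * 1_000_033 + 71 + offset) % 2**31
        name = f"{role}{k}"
        aoh = place_aoh(cfg, aoh_size_range, aoh_seed)
        truth = simulate_individual(panel, aoh, ind_seed)
        samples[name] = truth
        read_seeds = {}
        for depth in depths:
            dcfg = SimConfig(**{**asdict(cfg), "depth": depth})
            rseed = (base * 1_000_099 + 1000 * offset + int(depth * 1000)) % 2**31
            read_seeds[str(depth)] = rseed
            observations[(name, depth)] = simulate_reads(truth, dcfg, seed=rseed)
        manifest["samples"][name] = {
            "role": role,
            "individual_seed": ind_seed,
            "aoh_seed": aoh_seed,
            "read_seeds": read_seeds,
            "aoh_intervals": [list(t) for t in truth.aoh_intervals],
            "hap_indices": list(truth.hap_indices),
        }

    if outdir is not None:
        from .observations import write_observation_tsv
        from .panel import write_panel_tsv
        from .windowing import write_bed3

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_panel_tsv(panel, outdir / "panel.tsv")
        for name, truth in samples.items():
            write_bed3(truth.aoh_intervals, outdir / f"{name}.truth.bed")
            for depth in depths:
                write_observation_tsv(
                    observations[(name, depth)],
                    panel,
                    outdir / f"{name}.depth{depth}.obs.tsv",
                )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    manifest["data"] = {
        "panel": panel,
        "samples": samples,
        "observations": observations,
    }
    return manifest
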
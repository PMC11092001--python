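"""Genome binning and sliding windows over valid bins.

The genome is tiled into fixed-size bins (10 kb by default).  Classification
operates on sliding windows of exactly N *valid* bins — bins without usable
LLR data are skipped and the next valid bin is pulled in, so every window
carries a full feature matrix even at ultra-low depth.  The window's
"checkpoint" is the midpoint of its central valid bin; the binary label of a
window is whether that checkpoint falls inside a truth AOH interval
(0-based half-open).

Window size follows the depth tier used throughout: 100 bins for ultra-low
depth (< 0.25x by default), 250 bins otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .likelihood import BIN_SIZE, BinStat

#: depth (fold-coverage) below which the small window tier is used
DEPTH_TIER_CUTOVER = 0.25
N_SMALL = 100
N_LARGE = 250


def window_bins_for_depth(depth: float, cutover: float = DEPTH_TIER_CUTOVER) -> int:
    """100 bins for ultra-low depth, 250 bins from ``cutover`` upward."""
    return N_SMALL if depth < cutover else N_LARGE


@dataclass
class GenomeDefinition:
    """Chromosome lengths plus the assembly-gap (N-region) mask."""

    chrom_lengths: dict[str, int]
    n_mask: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.n_mask = self._normalize(self.n_mask)

    def _normalize(self, mask):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in mask:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"mask chromosome {chrom!r} not in genome")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(f"mask interval {chrom}:{start}-{end} out of bounds")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        out = []
        for chrom in self.chrom_lengths:
            ivals = sorted(by_chrom.get(chrom, []))
            merged: list[list[int]] = []
            for s, e in ivals:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out += [(chrom, s, e) for s, e in merged]
        return out

    def mask_for(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.n_mask if c == chrom]

    @classmethod
    def from_files(cls, lengths_path, mask_bed: str | Path | None = None):
        """Lengths from a `chrom\\tlength` table, mask from BED3."""
        lengths: dict[str, int] = {}
        with open(lengths_path) as fh:
            for line in fh:
                if line.strip() and not line.startswith("#"):
                    chrom, length = line.split()[:2]
                    lengths[chrom] = int(length)
        mask = read_bed3(mask_bed) if mask_bed else []
        return cls(lengths, mask)


def read_bed3(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED3 intervals (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                chrom, start, end = line.split()[:3]
                out.append((chrom, int(start), int(end)))
    return out


def write_bed3(intervals, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def make_bins(
    genome: GenomeDefinition, bin_size: int = BIN_SIZE
) -> dict[str, np.ndarray]:
    """Tile each chromosome with half-open bins from 0; last bin may be short."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    out: dict[str, np.ndarray] = {}
    for chrom, length in genome.chrom_lengths.items():
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        out[chrom] = np.column_stack([starts, ends])
    return out


@dataclass
class WindowRecord:
    """N valid bins, a checkpoint in the central bin, and the 2 x N features.

    ``features`` row 0 is the bins' llr_mean, row 1 llr_var.  ``central_bin``
    is the (start, end) of the valid bin at offset floor(N/2); callers use it
    to anchor called-region boundaries.
    """

    chrom: str
    bin_indices: np.ndarray
    checkpoint: int
    central_bin: tuple[int, int]
    features: np.ndarray
    label: int | None = None


def build_windows(
    bin_stats: list[BinStat], n_bins: int, step_bins: int = 1
) -> list[WindowRecord]:
    """Sliding windows of exactly ``n_bins`` valid bins per chromosome.

    Invalid bins are skipped: the window always extends to the next valid bin
    so its feature matrix is full.  Windows advance ``step_bins`` valid bins
    at a time (1 = the 10 kb increment in bin units) and never cross a
    chromosome boundary.  Chromosomes with fewer than ``n_bins`` valid bins
    yield no windows.
    """
    if n_bins < 3:
        raise ValueError("window size must be at least 3 bins")
    out: list[WindowRecord] = []
    by_chrom: dict[str, list[tuple[int, BinStat]]] = {}
    for i, s in enumerate(bin_stats):
        if s.valid:
            by_chrom.setdefault(s.chrom, []).append((i, s))
    center_off = n_bins // 2
    for chrom, valid in by_chrom.items():
        for w0 in range(0, len(valid) - n_bins + 1, step_bins):
            chunk = valid[w0 : w0 + n_bins]
            idx = np.array([i for i, _ in chunk], dtype=np.int64)
            feats = np.array(
                [[s.llr_mean for _, s in chunk], [s.llr_var for _, s in chunk]]
            )
            cb = chunk[center_off][1]
            out.append(
                WindowRecord(
                    chrom=chrom,
                    bin_indices=idx,
                    checkpoint=(cb.start + cb.end) // 2,
                    central_bin=(cb.start, cb.end),
                    features=feats,
                )
            )
    return out


def label_checkpoints(
    windows: list[WindowRecord], truth_regions: list[tuple[str, int, int]]
) -> list[WindowRecord]:
    """Label = 1 iff the checkpoint lies inside a truth interval (half-open)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in truth_regions:
        by_chrom.setdefault(chrom, []).append((start, end))
    for w in windows:
        w.label = int(
            any(s <= w.checkpoint < e for s, e in by_chrom.get(w.chrom, []))
        )
    return windows


def assemble_feature_tensor(
    windows: list[WindowRecord],
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Stack windows into a K x 2 x N tensor in genome order.

    Returns the tensor and the parallel (chrom, checkpoint) index.
    """
    if not windows:
        return np.empty((0, 2, 0)), []
    n = windows[0].features.shape[1]
    if any(w.features.shape != (2, n) for w in windows):
        raise ValueError("windows have mixed sizes")
    order = sorted(range(len(windows)), key=lambda i: (windows[i].chrom, windows[i].checkpoint))
    tensor = np.stack([windows[i].features for i in order])
    index = [(windows[i].chrom, windows[i].checkpoint) for i in order]
    return tensor, index


def write_windows_manifest(windows: list[WindowRecord], path: str | Path) -> None:
    """TSV: chrom checkpoint label n_valid_bins first_bin last_bin."""
    with open(path, "w") as fh:
        fh.write("chrom\tcheckpoint\tlabel\tn_valid_bins\tfirst_bin\tlast_bin\n")
        for w in windows:
            label = "" if w.label is None else str(w.label)
            fh.write(
                f"{w.chrom}\t{w.checkpoint}\t{label}\t{len(w.bin_indices)}\t"
                f"{w.bin_indices[0]}\t{w.bin_indices[-1]}\n"
            )
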
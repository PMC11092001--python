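"""Phased haplotype reference panel.

A panel is the population source of linkage-disequilibrium information: an
H x S matrix of phased haplotypes over S biallelic SNPs, with a probability
weight per haplotype row (uniform when loaded from a cohort VCF).  The
likelihood engine never iterates over all H haplotypes directly; it collapses
the panel to the distinct local allele patterns over the handful of SNPs a
read set touches (`collapse_local_patterns`), which is exact because pattern
frequencies are the summed weights of the haplotypes carrying them.

Coordinates: SNP positions are 1-based (VCF convention).  Every interval type
elsewhere in the package is 0-based half-open; conversion happens only at I/O
boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class PanelError(ValueError):
    """Malformed or unusable panel input."""


class EmptyPanelError(PanelError):
    """No phased biallelic SNP survived loading/filtering."""


_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class PanelSNP:
    """One biallelic panel site.

    ``pos`` is 1-based; ``index`` is the dense 0-based position in panel order.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    index: int


@dataclass
class LoadReport:
    """Counts of records dropped while loading a panel VCF."""

    n_kept: int = 0
    n_multiallelic: int = 0
    n_non_snp: int = 0
    n_missing_gt: int = 0
    n_unphased: int = 0

    @property
    def n_dropped(self) -> int:
        return (
            self.n_multiallelic + self.n_non_snp + self.n_missing_gt + self.n_unphased
        )


@dataclass
class LocalPatternSet:
    """Distinct panel allele patterns restricted to a subset of SNPs.

    ``patterns`` is (P, k) over the k SNPs in ``snp_indices``; ``freqs`` sums
    the weights of all haplotypes sharing each pattern.  Likelihoods computed
    over patterns equal the full-panel sums exactly.
    """

    snp_indices: np.ndarray
    patterns: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.snp_indices = np.asarray(self.snp_indices, dtype=np.int64)
        self.patterns = np.asarray(self.patterns, dtype=np.uint8)
        self.freqs = np.asarray(self.freqs, dtype=float)


class HaplotypePanel:
    """Ordered SNPs + H x S phased haplotype matrix + per-haplotype weights."""

    def __init__(
        self,
        snps: list[PanelSNP],
        haplotypes: np.ndarray,
        weights: np.ndarray | None = None,
        population_tag: str = "",
    ) -> None:
        haplotypes = np.asarray(haplotypes, dtype=np.uint8)
        if haplotypes.ndim != 2:
            raise PanelError("haplotype matrix must be 2-D (H x S)")
        H, S = haplotypes.shape
        if S != len(snps):
            raise PanelError(f"{len(snps)} SNPs but haplotype matrix has {S} columns")
        if S < 1:
            raise EmptyPanelError("empty panel: no SNPs")
        if H < 2:
            raise PanelError("panel needs at least 2 haplotypes")
        if not np.isin(haplotypes, (0, 1)).all():
            raise PanelError("haplotype allele codes must be 0 (ref) or 1 (alt)")
        if weights is None:
            weights = np.full(H, 1.0 / H)
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (H,) or (weights < 0).any():
            raise PanelError("weights must be a nonnegative vector of length H")
        total = weights.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            weights = weights / total
        for i, s in enumerate(snps):
            if s.index != i:
                raise PanelError("PanelSNP.index must be dense 0..S-1 in order")
        self.snps = list(snps)
        self.haplotypes = haplotypes
        self.weights = weights
        self.population_tag = population_tag
        self.load_report: LoadReport | None = None
        # lookup arrays, per chromosome, in panel order
        self.chroms = np.array([s.chrom for s in snps])
        self.positions = np.array([s.pos for s in snps], dtype=np.int64)
        self._chrom_slices: dict[str, slice] = {}
        start = 0
        for i in range(1, S + 1):
            if i == S or snps[i].chrom != snps[start].chrom:
                name = snps[start].chrom
                if name in self._chrom_slices:
                    raise PanelError(f"chromosome {name} appears in two blocks")
                pos_block = self.positions[start:i]
                if (np.diff(pos_block) <= 0).any():
                    raise PanelError(
                        f"positions not strictly increasing on {name}"
                    )
                self._chrom_slices[name] = slice(start, i)
                start = i

    # -- basic properties ---------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def chromosomes(self) -> list[str]:
        return list(self._chrom_slices)

    def chrom_slice(self, chrom: str) -> slice:
        if chrom not in self._chrom_slices:
            raise PanelError(f"chromosome {chrom!r} not in panel")
        return self._chrom_slices[chrom]

    def snp_indices_in(self, chrom: str, start0: int, end0: int) -> np.ndarray:
        """Panel indices of SNPs with 0-based position in [start0, end0)."""
        if chrom not in self._chrom_slices:
            return np.empty(0, dtype=np.int64)
        sl = self._chrom_slices[chrom]
        pos0 = self.positions[sl] - 1
        lo = np.searchsorted(pos0, start0, side="left")
        hi = np.searchsorted(pos0, end0, side="left")
        return np.arange(sl.start + lo, sl.start + hi, dtype=np.int64)

    def alt_frequencies(self) -> np.ndarray:
        """Weighted alt-allele frequency per SNP."""
        return self.weights @ self.haplotypes


# -- VCF loading ------------------------------------------------------------


_REGION_RE = re.compile(r"^([^:]+)(?::(\d+)-(\d+))?$")


def load_panel_vcf(
    path: str | Path,
    region: str | None = None,
    sample_ids: list[str] | None = None,
    population_tag: str = "",
) -> HaplotypePanel:
    """Load phased biallelic SNPs from a VCF into a panel.

    Each diploid sample contributes two haplotype rows; weights are uniform.
    Multiallelic, non-SNP, unphased and any-missing-GT records are dropped and
    counted in the returned panel's ``load_report``.
    """
    import pysam

    vcf = pysam.VariantFile(str(path))
    all_samples = list(vcf.header.samples)
    if sample_ids is None:
        samples = all_samples
    else:
        missing = [s for s in sample_ids if s not in all_samples]
        if missing:
            raise PanelError(f"sample(s) not in VCF: {', '.join(missing)}")
        samples = list(sample_ids)
    if not samples:
        raise EmptyPanelError("VCF has no samples")

    if region is not None:
        m = _REGION_RE.match(region)
        if not m:
            raise PanelError(f"bad region {region!r}; expected chrom[:start-end]")
        chrom = m.group(1)
        rstart = int(m.group(2)) if m.group(2) else None
        rend = int(m.group(3)) if m.group(3) else None
    else:
        chrom = rstart = rend = None

    report = LoadReport()
    snps: list[PanelSNP] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if chrom is not None:
            if rec.chrom != chrom:
                continue
            if rstart is not None and not (rstart <= rec.pos <= rend):
                continue
        alts = rec.alts or ()
        if len(alts) != 1:
            report.n_multiallelic += 1
            continue
        ref, alt = rec.ref, alts[0]
        if ref not in _BASES or alt not in _BASES:
            report.n_non_snp += 1
            continue
        col = np.empty(2 * len(samples), dtype=np.uint8)
        ok = True
        for i, name in enumerate(samples):
            call = rec.samples[name]
            gt = call.get("GT")
            if gt is None or len(gt) != 2 or None in gt:
                report.n_missing_gt += 1
                ok = False
                break
            if not call.phased:
                report.n_unphased += 1
                ok = False
                break
            col[2 * i] = gt[0]
            col[2 * i + 1] = gt[1]
        if not ok:
            continue
        snps.append(
            PanelSNP(rec.chrom, rec.pos, ref, alt, index=len(snps))
        )
        columns.append(col)
        report.n_kept += 1
    vcf.close()

    if not snps:
        raise EmptyPanelError(
            "empty panel: no phased biallelic SNPs"
            + (f" in region {region}" if region else "")
        )
    panel = HaplotypePanel(
        snps,
        np.column_stack(columns),
        population_tag=population_tag,
    )
    panel.load_report = report
    return panel


# -- panel TSV fixture format ----------------------------------------------


def write_panel_tsv(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel as `chrom pos ref alt h1 ... hH` rows (one per SNP)."""
    with open(path, "w") as fh:
        header = ["chrom", "pos", "ref", "alt"] + [
            f"h{i + 1}" for i in range(panel.n_haplotypes)
        ]
        fh.write("\t".join(header) + "\n")
        for s in panel.snps:
            row = [s.chrom, str(s.pos), s.ref_allele, s.alt_allele]
            row += [str(int(a)) for a in panel.haplotypes[:, s.index]]
            fh.write("\t".join(row) + "\n")


def read_panel_tsv(path: str | Path, population_tag: str = "") -> HaplotypePanel:
    """Read a panel from the TSV fixture format; uniform weights."""
    snps: list[PanelSNP] = []
    columns: list[np.ndarray] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["chrom", "pos", "ref", "alt"]:
            raise PanelError(f"bad panel TSV header: {header[:4]}")
        n_h = len(header) - 4
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4 + n_h:
                raise PanelError(f"line {lineno}: expected {4 + n_h} fields")
            alleles = parts[4:]
            if any(a not in ("0", "1") for a in alleles):
                raise PanelError(
                    f"line {lineno}: allele codes must be 0/1, got {alleles}"
                )
            snps.append(
                PanelSNP(parts[0], int(parts[1]), parts[2], parts[3], len(snps))
            )
            columns.append(np.array(alleles, dtype=np.uint8))
    if not snps:
        raise EmptyPanelError("empty panel: TSV has no SNP rows")
    return HaplotypePanel(
        snps, np.column_stack(columns), population_tag=population_tag
    )


# -- local pattern collapsing ----------------------------------------------


def collapse_local_patterns(
    panel: HaplotypePanel, snp_indices
) -> LocalPatternSet:
    """Collapse the panel to distinct allele patterns over ``snp_indices``.

    Pattern frequencies sum the weights of the haplotypes carrying each
    pattern, so any likelihood evaluated over (patterns, freqs) equals the
    same likelihood summed over all H haplotypes.
    """
    idx = np.asarray(list(snp_indices), dtype=np.int64)
    if idx.size == 0:
        raise PanelError("snp_indices must be nonempty")
    if (idx < 0).any() or (idx >= panel.n_snps).any():
        raise PanelError("snp index out of range")
    sub = panel.haplotypes[:, idx]
    patterns, inverse = np.unique(sub, axis=0, return_inverse=True)
    freqs = np.zeros(patterns.shape[0])
    np.add.at(freqs, inverse, panel.weights)
    return LocalPatternSet(idx, patterns, freqs)
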
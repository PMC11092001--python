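"""AOH region calling and truth scoring.

Checkpoint probabilities become region calls by: (1) taking maximal runs of
consecutive checkpoints with probability strictly above the threshold
(default 0.6), anchored at the central bins of the first/last run members;
(2) merging candidates separated by at most ``merge_gap``; (3) subtracting
assembly-gap (N-region) intervals, splitting calls they interrupt; and
(4) dropping fragments below ``min_size``.  All intervals are 0-based
half-open, sorted, non-overlapping.

Scoring follows the reciprocal-of-truth convention used for microarray
comparisons: a truth region counts as detected when the called regions cover
at least ``min_overlap`` percent of its length (50% by default); predictions
touching no truth are "additional calls".  Regions of at least 10 Mb are
flagged reportable, the conventional threshold for raising the possibility
of uniparental disomy.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .windowing import GenomeDefinition


@dataclass
class AOHRegion:
    """Called region (0-based half-open) with mean checkpoint confidence."""

    chrom: str
    start: int
    end: int
    mean_prob: float
    n_checkpoints: int

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class ConcordanceReport:
    """Per-truth overlap scoring plus the 50%-rule sensitivity."""

    per_truth: pd.DataFrame  # chrom start end overlap_percent concordant
    sensitivity: float | None
    additional_calls: list[AOHRegion]

    @property
    def n_concordant(self) -> int:
        return int(self.per_truth["concordant"].sum()) if len(self.per_truth) else 0


# -- thresholding ------------------------------------------------------------


def threshold_segments(
    track: pd.DataFrame, threshold: float = 0.6
) -> list[tuple[str, int, int]]:
    """Candidate intervals from maximal runs of probability > threshold.

    The track must be genome-ordered with columns chrom, checkpoint,
    bin_start, bin_end, probability.  A candidate spans from the central-bin
    start of the run's first checkpoint to the central-bin end of its last.
    Strict inequality: probability exactly at the threshold does not call.
    """
    out: list[tuple[str, int, int]] = []
    if not len(track):
        return out
    cur: list[int] | None = None
    cur_chrom = None
    for row in track.itertuples(index=False):
        above = row.probability > threshold
        if above and cur is not None and row.chrom == cur_chrom:
            cur[1] = int(row.bin_end)
        elif above:
            if cur is not None:
                out.append((cur_chrom, cur[0], cur[1]))
            cur = [int(row.bin_start), int(row.bin_end)]
            cur_chrom = row.chrom
        elif cur is not None:
            out.append((cur_chrom, cur[0], cur[1]))
            cur = None
    if cur is not None:
        out.append((cur_chrom, cur[0], cur[1]))
    return out


# -- merging / masking -------------------------------------------------------


def _subtract_mask(
    ivals: list[tuple[int, int]], mask: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    for s, e in ivals:
        pieces = [(s, e)]
        for ms, me in mask:
            nxt = []
            for ps, pe in pieces:
                if me <= ps or ms >= pe:
                    nxt.append((ps, pe))
                    continue
                if ps < ms:
                    nxt.append((ps, ms))
                if me < pe:
                    nxt.append((me, pe))
            pieces = nxt
        out += pieces
    return out


def merge_and_mask(
    candidates: list[tuple[str, int, int]],
    genome: GenomeDefinition,
    merge_gap: int = 500_000,
    min_size: int = 1_000_000,
) -> list[tuple[str, int, int]]:
    """Merge nearby candidates, subtract N regions, drop small fragments.

    Idempotent: applying the operation to its own output is a no-op.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in candidates:
        by_chrom.setdefault(chrom, []).append((s, e))
    out: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        ivals = sorted(by_chrom[chrom])
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s - merged[-1][1] <= merge_gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        pieces = _subtract_mask(
            [(s, e) for s, e in merged], genome.mask_for(chrom)
        )
        out += [
            (chrom, s, e) for s, e in sorted(pieces) if e - s >= min_size
        ]
    return out


def call_regions(
    track: pd.DataFrame,
    genome: GenomeDefinition,
    threshold: float = 0.6,
    merge_gap: int = 500_000,
    min_size: int = 1_000_000,
) -> list[AOHRegion]:
    """Full caller: threshold -> merge -> N-mask -> size filter -> confidence."""
    candidates = threshold_segments(track, threshold)
    final = merge_and_mask(candidates, genome, merge_gap, min_size)
    regions: list[AOHRegion] = []
    for chrom, s, e in final:
        sub = track[
            (track["chrom"] == chrom)
            & (track["checkpoint"] >= s)
            & (track["checkpoint"] < e)
        ]
        probs = sub["probability"].to_numpy()
        regions.append(
            AOHRegion(
                chrom, s, e,
                mean_prob=float(probs.mean()) if probs.size else float("nan"),
                n_checkpoints=int(probs.size),
            )
        )
    return regions


# -- truth comparison --------------------------------------------------------


def overlap_fraction(
    truth_region: tuple[int, int], predictions: list[tuple[int, int]]
) -> float:
    """Percent of the truth interval covered by the union of predictions.

    Half-open intervals; result rounded half-up to 2 decimals (the
    convention used when quoting percent overlap with an orthogonal assay).
    """
    ts, te = truth_region
    if te <= ts:
        raise ValueError("zero-length truth region")
    ivals = sorted((max(s, ts), min(e, te)) for s, e in predictions)
    covered = 0
    reach = ts
    for s, e in ivals:
        s = max(s, reach)
        if e <= s:
            continue
        covered += e - s
        reach = e
    pct = Decimal(100 * covered) / Decimal(te - ts)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def concordance(
    truths: list[tuple[str, int, int]],
    predictions: list[AOHRegion],
    min_overlap: float = 50.0,
) -> ConcordanceReport:
    """Score calls against truth with the >= min_overlap percent rule.

    Sensitivity = concordant truths / total truths (None when no truth is
    given).  Predictions intersecting no truth region at all are listed as
    additional calls.
    """
    pred_by_chrom: dict[str, list[AOHRegion]] = {}
    for r in predictions:
        pred_by_chrom.setdefault(r.chrom, []).append(r)
    rows = []
    for chrom, ts, te in truths:
        preds = [(r.start, r.end) for r in pred_by_chrom.get(chrom, [])]
        pct = overlap_fraction((ts, te), preds)
        rows.append((chrom, ts, te, pct, pct >= min_overlap))
    per_truth = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "overlap_percent", "concordant"]
    )
    sensitivity = (
        float(per_truth["concordant"].mean()) if len(per_truth) else None
    )
    additional = []
    for r in predictions:
        hits = any(
            r.chrom == chrom and r.start < te and ts < r.end
            for chrom, ts, te in truths
        )
        if not hits:
            additional.append(r)
    return ConcordanceReport(per_truth, sensitivity, additional)


# -- reporting ---------------------------------------------------------------

REPORT_MIN_SIZE = 10_000_000


def iscn_line(region: AOHRegion, build: str = "GRCh38", band: str = "?") -> str:
    """ISCN-like homozygosity line, 1-based inclusive coordinates in text."""
    chrom = region.chrom.removeprefix("chr")
    return (
        f"seq[{build}] hmz({chrom})({band}) "
        f"chr{chrom}:g.{region.start + 1}_{region.end}hmz"
    )


def write_report(
    regions: list[AOHRegion],
    bed_path: str | Path,
    text_path: str | Path | None = None,
    build: str = "GRCh38",
    report_min_size: int = REPORT_MIN_SIZE,
) -> None:
    """BED3+score output and an ISCN-like text report with reportable flags."""
    with open(bed_path, "w") as fh:
        fh.write("#chrom\tstart\tend\tmean_prob\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.mean_prob:.4f}\n")
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write("#region\treportable\tsize_bp\tmean_prob\n")
            for r in regions:
                flag = "yes" if r.size >= report_min_size else "no"
                fh.write(
                    f"{iscn_line(r, build)}\t{flag}\t{r.size}\t{r.mean_prob:.4f}\n"
                )
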
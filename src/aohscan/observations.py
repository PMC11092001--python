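"""Per-read allele observations at panel SNPs.

The unit of all downstream likelihoods is one read's observed alleles at the
panel SNPs it overlaps.  Observations are held as a flat table (one row per
(read, SNP) pair) that always keeps a read's rows together: down-sampling
keeps or drops whole reads, never splits them.

Sources: a SAM/BAM alignment (``ingest_alignments``, after the
uniquely-aligned high-quality-read filter), a plain TSV
(``read_observation_tsv``), or the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import HaplotypePanel

OBS_COLUMNS = ["read_id", "snp_index", "allele", "base_quality"]


@dataclass
class UahrConfig:
    """Uniquely-aligned high-quality read (UAHR) filter settings.

    ``min_mapq`` is the numeric proxy for "uniquely aligned".  Base quality is
    enforced as mean phred > ``min_baseq`` (plus a per-site check at each used
    SNP) unless ``strict_baseq`` demands every base exceed it.  Reads with more
    than ``max_n_frac`` undetermined (N) bases are rejected.
    """

    min_mapq: int = 30
    min_baseq: int = 20
    strict_baseq: bool = False
    max_n_frac: float = 0.05


class ObservationSet:
    """Flat table of allele observations plus a mean-depth estimate."""

    def __init__(
        self,
        table: pd.DataFrame | None = None,
        depth_estimate: float = 0.0,
        source: str = "synthetic",
    ) -> None:
        if table is None:
            table = pd.DataFrame(
                {
                    "read_id": pd.Series(dtype=str),
                    "snp_index": pd.Series(dtype=np.int64),
                    "allele": pd.Series(dtype=np.int8),
                    "base_quality": pd.Series(dtype=np.int16),
                }
            )
        missing = [c for c in OBS_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"observation table missing columns {missing}")
        self.table = table.reset_index(drop=True)
        self.depth_estimate = float(depth_estimate)
        self.source = source

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_reads(self) -> int:
        return self.table["read_id"].nunique()

    def canonical(self, panel: HaplotypePanel) -> "ObservationSet":
        """Sort rows by (genome position, read_id); deterministic ordering."""
        t = self.table.copy()
        t["_pos"] = panel.positions[t["snp_index"].to_numpy()]
        t["_chrom"] = panel.chroms[t["snp_index"].to_numpy()]
        t = t.sort_values(["_chrom", "_pos", "read_id"], kind="mergesort")
        t = t.drop(columns=["_pos", "_chrom"]).reset_index(drop=True)
        return ObservationSet(t, self.depth_estimate, self.source)


# -- UAHR filter ------------------------------------------------------------


def uahr_filter(record, cfg: UahrConfig) -> tuple[bool, str]:
    """Accept/reject one alignment record; returns (accepted, reason).

    Reject reasons: unmapped, not-primary, duplicate, mapq, no-qual, baseq,
    n-frac.  Accepted records return (True, "ok").
    """
    if record.is_unmapped:
        return False, "unmapped"
    if record.is_secondary or record.is_supplementary:
        return False, "not-primary"
    if record.is_duplicate:
        return False, "duplicate"
    if record.mapping_quality < cfg.min_mapq:
        return False, "mapq"
    quals = record.query_qualities
    if quals is None:
        return False, "no-qual"
    quals = np.asarray(quals)
    if cfg.strict_baseq:
        if not (quals > cfg.min_baseq).all():
            return False, "baseq"
    elif quals.mean() <= cfg.min_baseq:
        return False, "baseq"
    seq = record.query_sequence or ""
    if seq:
        n_frac = seq.upper().count("N") / len(seq)
        if n_frac > cfg.max_n_frac:
            return False, "n-frac"
    return True, "ok"


# -- alignment ingestion ----------------------------------------------------


def ingest_alignments(
    path: str | Path,
    panel: HaplotypePanel,
    filter_cfg: UahrConfig | None = None,
) -> ObservationSet:
    """Extract allele observations at panel SNPs from a SAM/BAM file.

    Only reads passing the UAHR filter contribute observations.  At each
    overlapped panel SNP the read base is coded 0/1 if it matches ref/alt;
    other bases (or low-quality bases in the default per-site mode) skip that
    site for that read.  ``depth_estimate`` is total aligned bases over total
    reference length, accumulated over all UAHR reads whether or not they
    touch a SNP.
    """
    import pysam

    cfg = filter_cfg or UahrConfig()
    af = pysam.AlignmentFile(str(path), check_sq=False)
    ref_names = set(af.references or ())
    panel_chroms = set(panel.chromosomes())
    if ref_names and not (ref_names & panel_chroms):
        af.close()
        raise ValueError(
            "no overlap between alignment references and panel chromosomes: "
            f"alignment has {sorted(ref_names)}, panel has {sorted(panel_chroms)}"
        )
    genome_length = sum(af.lengths or ()) or None

    rows: list[tuple[str, int, int, int]] = []
    aligned_bases = 0
    for rec in af:
        ok, _ = uahr_filter(rec, cfg)
        if not ok:
            continue
        aligned_bases += rec.query_alignment_length
        chrom = rec.reference_name
        if chrom not in panel_chroms:
            continue
        idx = panel.snp_indices_in(chrom, rec.reference_start, rec.reference_end)
        if idx.size == 0:
            continue
        ref2query = {
            rpos: qpos
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True)
        }
        seq = rec.query_sequence
        quals = rec.query_qualities
        for i in idx:
            snp = panel.snps[i]
            qpos = ref2query.get(snp.pos - 1)
            if qpos is None:
                continue
            base = seq[qpos].upper()
            q = quals[qpos]
            if not cfg.strict_baseq and q <= cfg.min_baseq:
                continue
            if base == snp.ref_allele:
                allele = 0
            elif base == snp.alt_allele:
                allele = 1
            else:
                continue
            rows.append((rec.query_name, int(i), allele, int(q)))
    af.close()

    table = pd.DataFrame(rows, columns=OBS_COLUMNS)
    if len(table):
        table = table.drop_duplicates(subset=["read_id", "snp_index"])
        table["snp_index"] = table["snp_index"].astype(np.int64)
        table["allele"] = table["allele"].astype(np.int8)
        table["base_quality"] = table["base_quality"].astype(np.int16)
    else:
        table = None
    depth = aligned_bases / genome_length if genome_length else 0.0
    obs = ObservationSet(table, depth_estimate=depth, source="bam")
    return obs.canonical(panel)


# -- down-sampling ----------------------------------------------------------


def downsample_observations(
    obs: ObservationSet,
    target: float,
    seed: int,
    is_fraction: bool = False,
    exact: bool = False,
) -> ObservationSet:
    """Keep each read (all its observations) with probability target/current.

    ``target`` is a fold-coverage unless ``is_fraction``.  Bernoulli per read
    by default; ``exact`` keeps exactly round(p * n_reads) reads instead.
    """
    if is_fraction:
        p = float(target)
    else:
        if obs.depth_estimate <= 0:
            raise ValueError("depth_estimate unknown; pass is_fraction=True")
        p = float(target) / obs.depth_estimate
    if p > 1.0 + 1e-9:
        raise ValueError(
            f"target depth {target} exceeds current {obs.depth_estimate}"
        )
    p = min(p, 1.0)
    read_ids = np.sort(obs.table["read_id"].unique())
    rng = np.random.default_rng(seed)
    if exact:
        n_keep = int(round(p * read_ids.size))
        keep_ids = rng.choice(read_ids, size=n_keep, replace=False)
    else:
        keep_ids = read_ids[rng.random(read_ids.size) < p]
    mask = obs.table["read_id"].isin(set(keep_ids))
    return ObservationSet(
        obs.table[mask].reset_index(drop=True),
        depth_estimate=obs.depth_estimate * p,
        source=obs.source,
    )


# -- TSV round-trip ---------------------------------------------------------


def write_observation_tsv(
    obs: ObservationSet, panel: HaplotypePanel, path: str | Path
) -> None:
    """Write `read_id chrom pos allele baseq` rows (pos 1-based)."""
    t = obs.table
    with open(path, "w") as fh:
        fh.write("\t".join(["read_id", "chrom", "pos", "allele", "baseq"]) + "\n")
        fh.write(f"# depth_estimate={obs.depth_estimate!r}\n")
        idx = t["snp_index"].to_numpy()
        chroms = panel.chroms[idx] if len(t) else []
        poss = panel.positions[idx] if len(t) else []
        for row, chrom, pos in zip(t.itertuples(index=False), chroms, poss):
            fh.write(
                f"{row.read_id}\t{chrom}\t{pos}\t{row.allele}\t{row.base_quality}\n"
            )


def read_observation_tsv(
    path: str | Path, panel: HaplotypePanel
) -> tuple[ObservationSet, int]:
    """Read the observation TSV; returns (set, n_skipped_non_panel_rows)."""
    pos_lookup: dict[tuple[str, int], int] = {
        (s.chrom, s.pos): s.index for s in panel.snps
    }
    rows: list[tuple[str, int, int, int]] = []
    depth = 0.0
    skipped = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["read_id", "chrom", "pos", "allele", "baseq"]:
            raise ValueError(f"bad observation TSV header: {header}")
        for line in fh:
            if line.startswith("#"):
                if line.startswith("# depth_estimate="):
                    depth = float(line.split("=", 1)[1])
                continue
            read_id, chrom, pos, allele, baseq = line.rstrip("\n").split("\t")
            key = (chrom, int(pos))
            if key not in pos_lookup:
                skipped += 1
                continue
            rows.append((read_id, pos_lookup[key], int(allele), int(baseq)))
    table = pd.DataFrame(rows, columns=OBS_COLUMNS) if rows else None
    if table is not None:
        table["snp_index"] = table["snp_index"].astype(np.int64)
        table["allele"] = table["allele"].astype(np.int8)
        table["base_quality"] = table["base_quality"].astype(np.int16)
    obs = ObservationSet(table, depth_estimate=depth, source="tsv")
    return obs.canonical(panel), skipped
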
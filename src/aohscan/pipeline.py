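"""End-to-end orchestration: observations -> LLR bins -> windows -> calls.

Thin glue used by the CLI, the benchmark runner and the test suite; all
scientific content lives in the step modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import caller, classifier, hmm_baseline, likelihood, windowing
from .observations import ObservationSet
from .panel import HaplotypePanel


@dataclass
class CallerConfig:
    threshold: float = 0.6
    merge_gap: int = 500_000
    min_size: int = 1_000_000
    min_overlap: float = 50.0
    report_min_size: int = caller.REPORT_MIN_SIZE


def sample_windows(
    obs: ObservationSet,
    panel: HaplotypePanel,
    genome: windowing.GenomeDefinition,
    n_bins: int | None = None,
    emission_cfg: likelihood.EmissionConfig | None = None,
    seed: int = 0,
) -> list[windowing.WindowRecord]:
    """Bin LLR statistics + sliding windows for one sample.

    ``n_bins`` defaults to the depth tier implied by the sample's
    depth estimate (100 below 0.25x, else 250).
    """
    bins = windowing.make_bins(genome)
    stats = likelihood.bin_statistics(bins, obs, panel, emission_cfg, seed=seed)
    if n_bins is None:
        n_bins = windowing.window_bins_for_depth(obs.depth_estimate)
    return windowing.build_windows(stats, n_bins)


def training_tensor(
    labeled_windows: list[list[windowing.WindowRecord]],
    max_windows: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool labeled windows across samples into a K x 2 x N tensor + labels.

    With ``max_windows`` the pool is subsampled (seeded, keeping every
    positive window and filling up with negatives) to bound training cost.
    """
    windows = [w for ws in labeled_windows for w in ws]
    if any(w.label is None for w in windows):
        raise ValueError("all training windows must be labeled")
    tensor = np.stack([w.features for w in windows])
    labels = np.array([w.label for w in windows], dtype=float)
    if max_windows is not None and len(windows) > max_windows:
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(labels == 1.0)
        neg = np.flatnonzero(labels == 0.0)
        if pos.size > max_windows // 2:
            pos = rng.choice(pos, size=max_windows // 2, replace=False)
        n_neg = min(neg.size, max_windows - pos.size)
        neg = rng.choice(neg, size=n_neg, replace=False)
        keep = np.sort(np.concatenate([pos, neg]))
        tensor, labels = tensor[keep], labels[keep]
    return tensor, labels


def predict_sample(
    obs: ObservationSet,
    panel: HaplotypePanel,
    genome: windowing.GenomeDefinition,
    params: classifier.ModelParams,
    emission_cfg: likelihood.EmissionConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Probability track for one sample with a trained model."""
    windows = sample_windows(
        obs, panel, genome, n_bins=params.n_bins, emission_cfg=emission_cfg, seed=seed
    )
    return classifier.predict(windows, params)


def call_and_score(
    track: pd.DataFrame,
    genome: windowing.GenomeDefinition,
    truth: list[tuple[str, int, int]] | None = None,
    cfg: CallerConfig | None = None,
) -> tuple[list[caller.AOHRegion], caller.ConcordanceReport | None]:
    cfg = cfg or CallerConfig()
    regions = caller.call_regions(
        track, genome, cfg.threshold, cfg.merge_gap, cfg.min_size
    )
    report = (
        caller.concordance(truth, regions, cfg.min_overlap)
        if truth is not None
        else None
    )
    return regions, report


def hmm_call_and_score(
    windows: list[windowing.WindowRecord],
    genome: windowing.GenomeDefinition,
    truth: list[tuple[str, int, int]] | None = None,
    cfg: CallerConfig | None = None,
    seed: int = 0,
):
    """Baseline: Gaussian-HMM track through the same caller."""
    track = hmm_baseline.hmm_probability_track(windows, seed=seed)
    return call_and_score(track, genome, truth, cfg)
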
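"""Reference synthetic benchmark: train, call, and score at several depths.

One 100 Mb chromosome, a 60-haplotype panel at 2 SNPs/kb, 8 training and 8
test individuals each carrying a single implanted 10-20 Mb iso-disomy tract,
sequenced at 0.1-fold with 35 bp single-end reads.  The classifier is
trained on the training individuals' labeled windows (small-depth tier,
N = 100 bins) and scored on the test individuals with the 50%-overlap
concordance rule.  The same trained model is then applied to fresh read
sets of a subset of test individuals at 0.05x and 0.5x (three read-sampling
seeds each) for the depth trend, and a 5-state full-covariance Gaussian HMM
is run on the identical test windows as the baseline.

All quantities reported by the acceptance script are computed here at run
time; every random draw derives from the single ``seed`` argument.
"""

from __future__ import annotations

import time
from dataclasses import asdict

import numpy as np

from . import classifier, pipeline, windowing
from .synthetic import SimConfig, make_benchmark, simulate_reads

MB = 1_000_000


def _labeled_windows(obs, truth, panel, genome, n_bins):
    ws = pipeline.sample_windows(obs, panel, genome, n_bins=n_bins)
    windowing.label_checkpoints(ws, truth.aoh_intervals)
    return ws


def run_full_benchmark(
    seed: int = 1,
    n_train: int = 8,
    n_test: int = 8,
    depth: float = 0.1,
    extra_depths: tuple[float, ...] = (0.05, 0.5),
    n_depth_individuals: int = 3,
    n_depth_seeds: int = 3,
    chrom_length: int = 100 * MB,
    aoh_size_range: tuple[int, int] = (10 * MB, 20 * MB),
    n_bins: int = 100,
    max_train_windows: int = 3000,
    verbose: bool = False,
) -> dict:
    """Run the whole benchmark; returns a dict of computed quantities.

    Keys include per-depth concordance sensitivities, additional >= 10 Mb
    calls per genome, the HMM baseline sensitivity, depth-calibration error
    and the heterozygous-site count inside implanted AOH tracts.
    """
    t_start = time.time()
    cfg = SimConfig(chrom_length=chrom_length, depth=depth, seed=seed % 2**31)
    genome = windowing.GenomeDefinition({cfg.chrom: cfg.chrom_length})
    bench = make_benchmark(
        n_train, n_test, [depth], aoh_size_range, cfg
    )
    panel = bench["data"]["panel"]
    samples = bench["data"]["samples"]
    observations = bench["data"]["observations"]
    log = print if verbose else (lambda *a, **k: None)
    log(f"[bench] panel: H={panel.n_haplotypes} S={panel.n_snps} "
        f"({time.time() - t_start:.0f}s)")

    # ---- truth integrity / depth calibration (cheap, from the same data)
    het_inside = 0
    depth_rel_errs = []
    for name, truth in samples.items():
        het = truth.heterozygous_mask()
        for chrom, s, e in truth.aoh_intervals:
            idx = panel.snp_indices_in(chrom, s, e)
            het_inside += int(het[idx].sum())
        obs = observations[(name, depth)]
        depth_rel_errs.append(abs(obs.depth_estimate - depth) / depth)

    # ---- training
    train_ws = []
    for k in range(n_train):
        name = f"train{k}"
        ws = _labeled_windows(
            observations[(name, depth)], samples[name], panel, genome, n_bins
        )
        train_ws.append(ws)
        log(f"[bench] {name}: {len(ws)} windows ({time.time() - t_start:.0f}s)")
    tensor, labels = pipeline.training_tensor(
        train_ws, max_windows=max_train_windows, seed=seed
    )
    tc = classifier.TrainConfig(seed=seed)
    params, report = classifier.train(tensor, labels, tc)
    log(f"[bench] trained: {len(report.accuracies)} epochs, "
        f"best acc {report.best_accuracy:.4f}, early={report.early_stopped} "
        f"({time.time() - t_start:.0f}s)")

    # ---- test-set scoring at the training depth (BGRU + HMM baseline)
    caller_cfg = pipeline.CallerConfig()
    n_concordant = 0
    n_truth = 0
    additional_10mb = 0
    per_sample = {}
    hmm_concordant = 0
    for k in range(n_test):
        name = f"test{k}"
        truth = samples[name]
        ws = _labeled_windows(
            observations[(name, depth)], truth, panel, genome, n_bins
        )
        track = classifier.predict(ws, params)
        regions, rep = pipeline.call_and_score(
            track, genome, truth.aoh_intervals, caller_cfg
        )
        n_truth += len(truth.aoh_intervals)
        n_concordant += rep.n_concordant
        big_additional = [r for r in rep.additional_calls if r.size >= 10 * MB]
        additional_10mb += len(big_additional)
        _, hmm_rep = pipeline.hmm_call_and_score(
            ws, genome, truth.aoh_intervals, caller_cfg, seed=seed
        )
        hmm_concordant += hmm_rep.n_concordant
        per_sample[name] = {
            "overlap_percent": rep.per_truth["overlap_percent"].tolist(),
            "n_regions": len(regions),
            "n_additional_10mb": len(big_additional),
            "hmm_overlap_percent": hmm_rep.per_truth["overlap_percent"].tolist(),
        }
        log(f"[bench] {name}: overlap={per_sample[name]['overlap_percent']} "
            f"hmm={per_sample[name]['hmm_overlap_percent']} "
            f"({time.time() - t_start:.0f}s)")

    # ---- depth trend: same truths, fresh reads at extra depths x seeds
    depth_sens: dict[float, list[float]] = {d: [] for d in extra_depths}
    for rep_i in range(n_depth_seeds):
        for d in extra_depths:
            hits = 0
            total = 0
            for k in range(n_depth_individuals):
                name = f"test{k}"
                truth = samples[name]
                dcfg = SimConfig(**{**asdict(cfg), "depth": d})
                rseed = (seed * 7 + 1013 * rep_i + 13 * k + int(d * 1000)) % 2**31
                obs = simulate_reads(truth, dcfg, seed=rseed)
                ws = pipeline.sample_windows(obs, panel, genome, n_bins=n_bins)
                track = classifier.predict(ws, params)
                _, rep = pipeline.call_and_score(
                    track, genome, truth.aoh_intervals, caller_cfg
                )
                hits += rep.n_concordant
                total += len(truth.aoh_intervals)
            depth_sens[d].append(hits / total)
            log(f"[bench] depth {d} rep {rep_i}: sens={hits}/{total} "
                f"({time.time() - t_start:.0f}s)")

    return {
        "seed": seed,
        "n_train": n_train,
        "n_test": n_test,
        "n_truth_regions": n_truth,
        "sensitivity": n_concordant / n_truth,
        "hmm_sensitivity": hmm_concordant / n_truth,
        "additional_10mb_per_genome": additional_10mb / n_test,
        "depth_sensitivities": {str(d): v for d, v in depth_sens.items()},
        "mean_depth_sensitivity": {
            str(d): float(np.mean(v)) for d, v in depth_sens.items()
        },
        "het_sites_inside_aoh": het_inside,
        "max_depth_rel_error": float(max(depth_rel_errs)),
        "train_epochs": len(report.accuracies),
        "train_best_accuracy": report.best_accuracy,
        "train_early_stopped": report.early_stopped,
        "per_sample": per_sample,
        "runtime_s": time.time() - t_start,
    }
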
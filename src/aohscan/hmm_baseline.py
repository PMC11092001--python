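"""Gaussian-HMM baseline segmenter.

A 5-state hidden Markov model with full-covariance Gaussian emissions is fit
to the genome-ordered sequence of per-checkpoint 2-vectors (window mean of
bin LLR means, window mean of bin LLR variances).  States are unsupervised;
the state whose emission mean has the largest first component (LLR mean) is
taken as the AOH state, and the AOH probability of a checkpoint is its
posterior mass on that state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .windowing import WindowRecord


def window_summaries(windows: list[WindowRecord]) -> tuple[np.ndarray, list[int]]:
    """Per-checkpoint (mean of bin llr_mean, mean of bin llr_var) 2-vectors.

    Windows are put in genome order; returns (K, 2) array and per-chromosome
    run lengths (HMM sequences never span chromosomes).
    """
    order = sorted(
        range(len(windows)), key=lambda i: (windows[i].chrom, windows[i].checkpoint)
    )
    X = np.array(
        [
            [windows[i].features[0].mean(), windows[i].features[1].mean()]
            for i in order
        ]
    )
    lengths: list[int] = []
    prev = None
    for i in order:
        if windows[i].chrom != prev:
            lengths.append(1)
            prev = windows[i].chrom
        else:
            lengths[-1] += 1
    return X, lengths


def hmm_fit_predict(
    summaries: np.ndarray,
    lengths: list[int] | None = None,
    n_states: int = 5,
    seed: int = 0,
    n_iter: int = 50,
) -> np.ndarray:
    """Posterior AOH probability per checkpoint from a Gaussian HMM.

    Fits ``n_states`` states with full covariance to the summary sequence and
    returns the posterior probability of the state with the largest
    emission-mean first component.  Degenerate covariances trigger one jitter
    retry before the error propagates.
    """
    from hmmlearn.hmm import GaussianHMM

    X = np.asarray(summaries, dtype=float)
    if X.ndim != 2:
        raise ValueError("summaries must be (K, 2)")
    if np.unique(X, axis=0).shape[0] < n_states:
        # fewer distinct observations than states: constant-ish input
        n_states = max(1, np.unique(X, axis=0).shape[0])

    def _fit(jitter: float):
        Xj = X if jitter == 0.0 else X + np.random.default_rng(seed).normal(
            0.0, jitter, X.shape
        )
        nf = X.shape[1]
        model = GaussianHMM(
            n_components=n_states,
            covariance_type="full",
            n_iter=n_iter,
            random_state=seed,
            min_covar=1e-3,
            # PSD matrix prior keeps per-state covariances positive-definite
            # even when a state collapses onto near-identical summaries
            covars_prior=1e-3 * np.eye(nf),
            covars_weight=nf + 2,
        )
        model.fit(Xj, lengths)
        post = model.predict_proba(Xj, lengths)
        return model, post

    # at ultra-low depth many summaries are exact ties, so a state can
    # collapse onto a singular covariance; retry with growing data-scaled
    # jitter before giving up
    scale = float(X.std() or 1.0)
    last_err: Exception | None = None
    for jitter in (0.0, 1e-4 * scale, 1e-3 * scale, 1e-2 * scale):
        try:
            model, post = _fit(jitter)
            break
        except (ValueError, np.linalg.LinAlgError) as err:
            last_err = err
    else:
        raise last_err
    aoh_state = int(np.argmax(model.means_[:, 0]))
    return post[:, aoh_state]


def hmm_probability_track(
    windows: list[WindowRecord], n_states: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Same track format as the BGRU classifier, from the HMM baseline."""
    if not windows:
        return pd.DataFrame(
            columns=["chrom", "checkpoint", "bin_start", "bin_end", "probability"]
        )
    X, lengths = window_summaries(windows)
    probs = hmm_fit_predict(X, lengths, n_states=n_states, seed=seed)
    order = sorted(
        range(len(windows)), key=lambda i: (windows[i].chrom, windows[i].checkpoint)
    )
    return pd.DataFrame(
        {
            "chrom": [windows[i].chrom for i in order],
            "checkpoint": [windows[i].checkpoint for i in order],
            "bin_start": [windows[i].central_bin[0] for i in order],
            "bin_end": [windows[i].central_bin[1] for i in order],
            "probability": probs,
        }
    )
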
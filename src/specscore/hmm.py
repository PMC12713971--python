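"""Gaussian-emission HMM staging over the five band features.

Each 30-s epoch carries a 5-vector of relative-dB band powers; each
spectral stage is an HMM state emitting a diagonal-covariance Gaussian
over those features.  The model is initialised from an argmax labelling
(band k dominant -> stage k), refined by Baum-Welch expectation
maximisation, and decoded by *maximal posterior probability per epoch*
(forward-backward marginals), not by the single most-probable path: each
epoch gets the stage with the largest conditional probability given the
whole night.

Noise-flagged epochs are decoded like any other but carry zero weight in
the EM sufficient statistics, so a few artifact epochs cannot drag the
stage Gaussians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stages import SPECTRAL_STAGES
from .bands import BandSeries

__all__ = ["HMMModel", "PosteriorMatrix", "init_hmm", "em_fit", "posterior_decode"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HMMModel:
    """Initial distribution, transition matrix and per-stage Gaussian emissions."""

    pi: np.ndarray            # (K,)
    A: np.ndarray             # (K, K), rows sum to 1
    means: np.ndarray         # (K, D) dB
    variances: np.ndarray     # (K, D) dB^2, diagonal covariance
    stages: tuple[str, ...] = SPECTRAL_STAGES

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=np.float64)
        self.A = np.asarray(self.A, dtype=np.float64)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        k = len(self.stages)
        if self.pi.shape != (k,) or self.A.shape != (k, k):
            raise ValueError("pi/A shapes inconsistent with stage count")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")
        if np.any(np.abs(self.A.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("each transition row must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    @property
    def n_states(self) -> int:
        return len(self.stages)

    def log_emission(self, obs: np.ndarray) -> np.ndarray:
        """(T, K) log N(obs_t | mean_k, diag var_k)."""
        obs = np.atleast_2d(obs)
        d = obs.shape[1]
        diff = obs[:, None, :] - self.means[None, :, :]
        return -0.5 * (
            d * _LOG2PI
            + np.log(self.variances).sum(axis=1)[None, :]
            + (diff**2 / self.variances[None, :, :]).sum(axis=2)
        )


@dataclass
class PosteriorMatrix:
    """Per-epoch stage posteriors from forward-backward, with the data log-likelihood."""

    gamma: np.ndarray     # (T, K), rows sum to 1
    loglik: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")
        if np.any(np.abs(self.gamma.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("posterior rows must sum to 1")


def init_hmm(
    bands: BandSeries,
    sticky: float = 5.0,
    var_floor: float = 0.25,
    pi_wake: float = 0.8,
) -> HMMModel:
    """Deterministic initialisation from the argmax-band labelling.

    Each epoch is provisionally labelled with the stage whose band feature
    is largest (band k corresponds to stage k by construction).  Stage
    Gaussians take the moments of their labelled epochs; the transition
    matrix counts labelled transitions plus ``sticky`` diagonal
    pseudo-counts (sleep stages persist across epochs).  A stage with no
    labelled epochs falls back to the global moments and a uniform
    transition row.  The initial distribution puts ``pi_wake`` mass on
    WAKE, the rest uniform, since nights begin awake.
    """
    k = len(bands.band_defs)
    x = bands.values
    t = x.shape[0]
    if t < max(10, k):
        raise ValueError(f"need at least 10 epochs to initialise, got {t}")
    labels = np.argmax(x, axis=1)

    global_mean = x.mean(axis=0)
    global_var = np.maximum(x.var(axis=0), var_floor)
    means = np.empty((k, x.shape[1]))
    variances = np.empty_like(means)
    for s in range(k):
        sel = labels == s
        if sel.sum() >= 2:
            means[s] = x[sel].mean(axis=0)
            variances[s] = np.maximum(x[sel].var(axis=0), var_floor)
        elif sel.sum() == 1:
            means[s] = x[sel][0]
            variances[s] = global_var
        else:
            means[s] = global_mean
            variances[s] = global_var

    counts = np.zeros((k, k))
    np.add.at(counts, (labels[:-1], labels[1:]), 1.0)
    counts += sticky * np.eye(k)
    occupied = counts.sum(axis=1) > 0
    A = np.where(
        occupied[:, None], counts / np.maximum(counts.sum(axis=1, keepdims=True), 1e-300),
        1.0 / k,
    )

    pi = np.full(k, (1.0 - pi_wake) / (k - 1))
    pi[0] = pi_wake
    return HMMModel(pi=pi, A=A, means=means, variances=variances)


def _forward_backward(model: HMMModel, logb: np.ndarray):
    """Scaled forward-backward.

    Returns (gamma, xi_sum, loglik): posteriors (T, K), summed two-slice
    marginals (K, K) and the total log-likelihood.  Per-step scaling keeps
    everything in probability space without underflow.
    """
    t_len, k = logb.shape
    # stabilise each row before exponentiating
    shift = logb.max(axis=1, keepdims=True)
    b = np.exp(logb - shift)

    alpha = np.empty((t_len, k))
    scale = np.empty(t_len)
    a = model.pi * b[0]
    scale[0] = a.sum()
    if scale[0] <= 0 or not np.isfinite(scale[0]):
        raise FloatingPointError("zero/invalid forward mass at epoch 0")
    alpha[0] = a / scale[0]
    for i in range(1, t_len):
        a = (alpha[i - 1] @ model.A) * b[i]
        scale[i] = a.sum()
        if scale[i] <= 0 or not np.isfinite(scale[i]):
            raise FloatingPointError(f"zero/invalid forward mass at epoch {i}")
        alpha[i] = a / scale[i]

    beta = np.empty((t_len, k))
    beta[-1] = 1.0
    xi_sum = np.zeros((k, k))
    for i in range(t_len - 2, -1, -1):
        nxt = b[i + 1] * beta[i + 1]
        beta[i] = (model.A @ nxt) / scale[i + 1]
        xi = alpha[i][:, None] * model.A * nxt[None, :] / scale[i + 1]
        xi_sum += xi

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.sum(np.log(scale)) + shift.sum())
    return gamma, xi_sum, loglik


def em_fit(
    model: HMMModel,
    bands: BandSeries,
    max_iter: int = 50,
    tol: float = 1e-6,
    var_floor: float = 0.25,
) -> tuple[HMMModel, list[float]]:
    """Baum-Welch refinement; returns the fitted model and the log-likelihood trace.

    Iterates until the relative log-likelihood improvement drops below
    ``tol`` or ``max_iter`` is reached.  The likelihood is non-decreasing
    (EM guarantee; the variance floor can bite only at floor-level scales).
    Noise-flagged epochs contribute nothing to the emission statistics.
    """
    x = bands.values
    weights = np.ones(x.shape[0])
    if bands.noisy_epochs is not None:
        weights[bands.noisy_epochs] = 0.0
    if weights.sum() == 0:
        raise ValueError("every epoch is noise-flagged; nothing to fit")

    history: list[float] = []
    for _ in range(max_iter):
        logb = model.log_emission(x)
        if not np.isfinite(logb).all():
            bad = np.argwhere(~np.isfinite(logb))[0]
            raise FloatingPointError(
                f"non-finite emission log-density at epoch {bad[0]}, stage "
                f"{model.stages[bad[1]]}"
            )
        gamma, xi_sum, loglik = _forward_backward(model, logb)
        if not np.isfinite(loglik):
            raise FloatingPointError("non-finite log-likelihood")
        if history and loglik < history[-1]:
            # masked-epoch weighting or the variance floor can, rarely, push
            # the plain likelihood down; keep the better previous model
            model = prev_model
            break
        history.append(loglik)
        prev_model = model

        pi = gamma[0] / gamma[0].sum()
        A = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), 1e-300)
        wg = gamma * weights[:, None]
        denom = wg.sum(axis=0)
        means = model.means.copy()
        variances = model.variances.copy()
        fed = denom > 1e-8          # states starved of (unmasked) data keep params
        means[fed] = (wg.T @ x)[fed] / denom[fed, None]
        sq = (wg.T @ (x**2))[fed] / denom[fed, None]
        variances[fed] = np.maximum(sq - means[fed] ** 2, var_floor)
        model = HMMModel(pi=pi, A=A, means=means, variances=variances,
                         stages=model.stages)
        if len(history) >= 2:
            prev, cur = history[-2], history[-1]
            if (cur - prev) < tol * abs(prev):
                break
    return model, history


def posterior_decode(model: HMMModel, bands: BandSeries):
    """Assign each epoch the stage of maximal conditional probability.

    Runs forward-backward and takes the per-epoch argmax of the posterior;
    ties break by the fixed stage order (WAKE first).  Returns
    ``(Hypnogram, PosteriorMatrix)``.
    """
    from .hypnogram import Hypnogram

    logb = model.log_emission(bands.values)
    gamma, _, loglik = _forward_backward(model, logb)
    idx = np.argmax(gamma, axis=1)       # argmax takes the first max: fixed tie order
    stages = [model.stages[i] for i in idx]
    hyp = Hypnogram(stages=stages, epoch_len=bands.epoch_len)
    return hyp, PosteriorMatrix(gamma=gamma, loglik=loglik)
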
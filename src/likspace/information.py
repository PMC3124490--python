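"""Stimulus-specific information, mutual information, and stimulus distances.

The information specifically conveyed about stimulus ``s_i`` by a response
``r`` is the KL divergence between the stimulus-conditional and the
stimulus-averaged response distribution,

    I_ssi(s_i) = sum_r p(r|s_i) log2 [ p(r|s_i) / pbar(r) ],
    pbar(r)    = sum_j p(s_j) p(r|s_j),

and the mutual information is its prior-weighted average,
``I(S;R) = sum_i p(s_i) I_ssi(s_i)``.  For point-process models the
expectation over responses is intractable (the response alphabet is all
binary vectors of length ``J``), so ``I_ssi`` is estimated by Monte Carlo:
the mean over observed (or simulated) spike trains from ``s_i`` of
``log2[p(obs|s_i)/pbar(obs)]`` — exactly the mean of the ``i``-th
likelihood-space coordinate after scaling by the average response
distribution.  The distance between two stimuli is the absolute difference
of their specific informations, a symmetric nonnegative pseudo-metric.

All quantities are in bits (log base 2).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp, rel_entr

from .core import SpikeTrain, bin_spike_train, log_likelihood
from .ekf import PointProcessFilter
from .likelihood_space import ProjectingDistributions

__all__ = [
    "specific_information_discrete",
    "mutual_information",
    "specific_information_mc",
    "stimulus_distance",
    "distance_matrix",
    "sliding_window_information",
    "slice_train",
]

LN2 = np.log(2.0)


def specific_information_discrete(cond: np.ndarray, marginal: np.ndarray) -> float:
    """KL divergence ``sum_r p(r|s) log2[p(r|s)/p(r)]`` in bits.

    ``0 * log(0/.)`` is treated as 0.  Both arguments must be valid
    probability vectors over the same finite response alphabet.
    """
    cond = np.asarray(cond, dtype=float)
    marginal = np.asarray(marginal, dtype=float)
    if cond.shape != marginal.shape:
        raise ValueError("conditional and marginal must share the alphabet")
    for name, p in (("conditional", cond), ("marginal", marginal)):
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} is not a probability vector")
    if np.any((cond > 0) & (marginal == 0)):
        raise ValueError("conditional puts mass where the marginal is zero")
    return float(rel_entr(cond, marginal).sum() / LN2)


def mutual_information(joint: np.ndarray) -> float:
    """Mutual information of a joint ``p(s, r)`` table in bits.

    Computed as the prior-weighted average of the per-stimulus specific
    informations, ``I(S;R) = sum_i p(s_i) I_ssi(s_i)``.
    """
    joint = np.asarray(joint, dtype=float)
    if joint.ndim != 2 or np.any(joint < -1e-12) or abs(joint.sum() - 1.0) > 1e-9:
        raise ValueError("joint must be a 2-D probability table summing to 1")
    priors = joint.sum(axis=1)
    marginal = joint.sum(axis=0)
    total = 0.0
    for i, p_s in enumerate(priors):
        if p_s == 0:
            continue
        total += p_s * specific_information_discrete(joint[i] / p_s, marginal)
    return float(total)


def specific_information_mc(
    models: ProjectingDistributions,
    stimulus: int,
    observations,
) -> float:
    """Monte-Carlo specific information of ``stimulus`` in bits.

    ``observations`` are spike trains recorded or simulated under stimulus
    ``i``; the estimate is the sample mean of
    ``log2[p(obs|s_i) / sum_j p(s_j) p(obs|s_j)]`` and converges to the
    exact KL form as the number of observations grows.  Raises if some
    observation has zero average probability under the models (support
    violation).
    """
    observations = list(observations)
    if not observations:
        raise ValueError("at least one observation is required")
    priors = models.priors
    with np.errstate(divide="ignore"):
        log_priors = np.log(priors)
    vals = np.empty(len(observations))
    for m_idx, obs in enumerate(observations):
        lls = np.array(
            [log_likelihood(obs, mod, form=models.form) for mod in models.models]
        )
        log_pbar = logsumexp(lls + log_priors)
        if not np.isfinite(log_pbar):
            raise ValueError(
                "observation has zero probability under the averaged model "
                "(model support violation)"
            )
        vals[m_idx] = (lls[stimulus] - log_pbar) / LN2
    return float(vals.mean())


def stimulus_distance(info_i: float, info_j: float) -> float:
    """Distance between stimuli as ``|I_ssi(s_i) - I_ssi(s_j)|`` in bits.

    The absolute value makes the distance symmetric with zero diagonal; as a
    difference of scalars it satisfies the triangle inequality (a
    pseudo-metric: distinct stimuli with equal specific information are at
    distance 0).
    """
    return abs(float(info_i) - float(info_j))


def distance_matrix(specific_infos) -> np.ndarray:
    """Pairwise ``|I_i - I_j|`` matrix from per-stimulus specific informations."""
    v = np.asarray(specific_infos, dtype=float)
    return np.abs(v[:, None] - v[None, :])


def slice_train(train: SpikeTrain, w0: float, w1: float) -> SpikeTrain:
    """Restrict a train to the window ``(w0, w1]`` and shift it to ``(0, w1-w0]``."""
    mask = (train.times > w0) & (train.times <= w1)
    return SpikeTrain(
        times=train.times[mask] - w0,
        interval=(0.0, w1 - w0),
        neuron_id=train.neuron_id,
        trial_id=train.trial_id,
        stimulus_id=train.stimulus_id,
    )


def _rate_framework_ssi(
    counts_by_stimulus: dict, target, priors: np.ndarray, alpha: float = 0.5
) -> float:
    """Specific information from empirical spike-count (PSTH) tables.

    Per-stimulus count histograms over the pooled count alphabet, Laplace
    smoothing ``alpha`` to avoid log 0.
    """
    labels = list(counts_by_stimulus)
    cmax = max((max(c) if len(c) else 0) for c in counts_by_stimulus.values())
    A = cmax + 1
    tables = {}
    for lab in labels:
        c = np.asarray(counts_by_stimulus[lab])
        hist = np.bincount(c, minlength=A).astype(float)
        tables[lab] = (hist + alpha) / (hist.sum() + alpha * A)
    marginal = np.sum([p * tables[lab] for p, lab in zip(priors, labels)], axis=0)
    return specific_information_discrete(tables[target], marginal)


def sliding_window_information(
    trains_by_stimulus: dict,
    target,
    delta: float = 0.001,
    window: float = 0.100,
    step: float = 0.010,
    q: float = 1e-4,
    priors=None,
    form: str = "bernoulli",
) -> pd.DataFrame:
    """Time course of stimulus-specific information in a sliding window.

    For each window position the stimulus-conditional intensity models are
    refit (EKF on the window's binned data) and the target stimulus's
    specific information is estimated two ways:

    * ``bits_likelihood`` — Monte-Carlo over the window's observed trains
      under the refit point-process models (likelihood framework);
    * ``bits_rate`` — from empirical spike-count histograms with Laplace
      smoothing 0.5 (PSTH / rate framework baseline).

    Parameters
    ----------
    trains_by_stimulus : dict
        Stimulus label -> list of SpikeTrain (repeated trials, common
        interval).
    target : label
        Stimulus whose specific information is tracked.
    window, step : float
        Window length and step in seconds (defaults 100 ms / 10 ms).

    Returns
    -------
    DataFrame with columns ``window_center_s``, ``bits_likelihood``,
    ``bits_rate``; for a full interval of length T there are
    ``floor((T - window)/step) + 1`` windows.
    """
    labels = list(trains_by_stimulus)
    if target not in labels:
        raise ValueError(f"target {target!r} not among stimuli {labels}")
    if priors is None:
        priors = np.full(len(labels), 1.0 / len(labels))
    else:
        priors = np.asarray(priors, dtype=float)
    t0, t1 = trains_by_stimulus[labels[0]][0].interval
    n_windows = int(np.floor((t1 - t0 - window) / step + 1e-9)) + 1
    rows = []
    tgt_idx = labels.index(target)
    for w in range(n_windows):
        w0 = t0 + w * step
        w1 = w0 + window
        sliced = {
            lab: [slice_train(tr, w0, w1) for tr in trs]
            for lab, trs in trains_by_stimulus.items()
        }
        binned = {
            lab: [bin_spike_train(tr, delta) for tr in trs]
            for lab, trs in sliced.items()
        }
        fitted = []
        for lab in labels:
            est = PointProcessFilter(q=q)
            est.fit(binned[lab])
            fitted.append(est.intensity_)
        models = ProjectingDistributions(
            models=tuple(fitted), priors=priors, labels=tuple(labels), form=form
        )
        bits_lik = specific_information_mc(models, tgt_idx, binned[target])
        counts = {lab: [tr.n for tr in trs] for lab, trs in sliced.items()}
        bits_rate = _rate_framework_ssi(counts, target, priors)
        rows.append(
            {
                "window_center_s": w0 + window / 2.0,
                "bits_likelihood": bits_lik,
                "bits_rate": bits_rate,
            }
        )
    return pd.DataFrame(rows)
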
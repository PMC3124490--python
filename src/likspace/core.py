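"""Domain types, binning, and single-neuron point-process likelihoods.

A spike train on an observation interval ``(t_start, t_end]`` is fully
characterized by its conditional intensity function ``lambda(t | H_t)``, the
instantaneous spike probability rate given spiking history.  Discretizing the
interval into ``J`` bins of width ``delta`` fine enough that each bin holds at
most one spike turns the train into a binary increment vector whose joint
probability is a product of conditionally independent Bernoulli events.

Two discrete likelihood forms are provided:

``local_poisson`` (default)
    ``sum_k dN_k*ln(lambda_k*delta) - sum_k lambda_k*delta`` — the discrete
    counterpart of the continuous form ``sum_j ln lambda(u_j) - int lambda``,
    which exponentiates the integrated intensity.

``bernoulli``
    ``sum_k [dN_k*ln(lambda_k*delta) + (1-dN_k)*ln(1-lambda_k*delta)]`` — a
    proper probability mass over binary vectors; agrees with the local-Poisson
    form to O((lambda*delta)^2).

All likelihood arithmetic is done in log space (natural log, nats); products
over ~1000 bins would underflow otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate

__all__ = [
    "SpikeTrain",
    "BinnedSpikeTrain",
    "IntensityModel",
    "bin_spike_train",
    "log_likelihood",
    "continuous_log_likelihood",
    "binning_jacobian",
]

_TIME_TOL = 1e-12


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one neuron in one trial.

    Parameters
    ----------
    times : array-like of float
        Strictly increasing spike times in seconds, each inside
        ``(t_start, t_end]``.
    interval : (float, float)
        Observation interval ``(t_start, t_end]`` in seconds.
    neuron_id, trial_id, stimulus_id : hashable, optional
        Opaque labels carried through analyses.
    """

    times: np.ndarray
    interval: tuple[float, float]
    neuron_id: object = None
    trial_id: object = None
    stimulus_id: object = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        t0, t1 = float(self.interval[0]), float(self.interval[1])
        object.__setattr__(self, "interval", (t0, t1))
        if not t1 > t0:
            raise ValueError(f"empty observation interval ({t0}, {t1}]")
        if times.ndim != 1:
            raise ValueError("spike times must be a 1-D sequence")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] <= t0 - _TIME_TOL or times[-1] > t1 + _TIME_TOL:
                raise ValueError(
                    f"spike times must lie in ({t0}, {t1}]; "
                    f"got range [{times[0]}, {times[-1]}]"
                )

    @property
    def n(self) -> int:
        """Number of spikes."""
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return self.interval[1] - self.interval[0]


@dataclass(frozen=True)
class BinnedSpikeTrain:
    """Binary increment vector ``dN_1..dN_J`` at bin width ``delta``.

    Bins are half-open and 0-based: bin ``k`` covers
    ``[t_start + k*delta, t_start + (k+1)*delta)``; a spike exactly at
    ``t_end`` is assigned to the last bin.
    """

    increments: np.ndarray
    delta: float
    interval: tuple[float, float]
    truncated_last: bool = False
    neuron_id: object = None
    trial_id: object = None
    stimulus_id: object = None

    def __post_init__(self) -> None:
        inc = np.asarray(self.increments, dtype=np.int8)
        object.__setattr__(self, "increments", inc)
        t0, t1 = float(self.interval[0]), float(self.interval[1])
        object.__setattr__(self, "interval", (t0, t1))
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if inc.ndim != 1:
            raise ValueError("increments must be 1-D")
        if inc.size and not np.isin(inc, (0, 1)).all():
            raise ValueError("increments must be 0/1 (at most one spike per bin)")
        span = t1 - t0
        covered = inc.size * self.delta
        if not self.truncated_last and abs(covered - span) > 1e-9 * max(1.0, span):
            raise ValueError(
                f"J*delta = {covered} does not span the interval length {span}; "
                "flag truncated_last if the final bin is shorter"
            )

    @property
    def J(self) -> int:
        return int(self.increments.size)

    @property
    def n(self) -> int:
        return int(self.increments.sum())

    def bin_widths(self) -> np.ndarray:
        """Per-bin widths; all ``delta`` except a truncated final bin."""
        w = np.full(self.J, self.delta)
        if self.truncated_last:
            span = self.interval[1] - self.interval[0]
            w[-1] = span - (self.J - 1) * self.delta
        return w


@dataclass(frozen=True)
class IntensityModel:
    """Per-bin conditional intensity ``lambda_k`` (Hz) on a uniform bin grid.

    Optionally carries the latent state trajectory and parameters that
    generated it (e.g. the EKF posterior path), and the full per-bin filter
    trace.  The Bernoulli reading of one bin requires ``lambda_k*delta < 1``;
    a violation triggers a warning at construction.
    """

    lambda_per_bin: np.ndarray
    delta: float
    interval: tuple[float, float] | None = None
    states: np.ndarray | None = None
    params: dict = field(default_factory=dict)
    trace: list | None = None

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambda_per_bin, dtype=float)
        object.__setattr__(self, "lambda_per_bin", lam)
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if lam.ndim != 1 or lam.size == 0:
            raise ValueError("lambda_per_bin must be a non-empty 1-D vector")
        if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
            raise ValueError("all intensities must be positive and finite")
        if np.any(lam * self.delta >= 1.0):
            warnings.warn(
                "lambda*delta >= 1 in some bins; Bernoulli interpretation "
                "invalid — consider a smaller delta",
                RuntimeWarning,
                stacklevel=2,
            )

    @property
    def J(self) -> int:
        return int(self.lambda_per_bin.size)

    @property
    def t_start(self) -> float:
        return 0.0 if self.interval is None else self.interval[0]

    def at(self, t) -> np.ndarray:
        """Step-function lookup of the intensity at time(s) ``t`` (Hz).

        Times beyond the last bin edge (including exactly the interval end)
        use the last bin's intensity.
        """
        t = np.asarray(t, dtype=float)
        k = np.floor((t - self.t_start) / self.delta).astype(int)
        k = np.clip(k, 0, self.J - 1)
        return self.lambda_per_bin[k]

    def cumulative(self, t) -> np.ndarray:
        """Exact integrated intensity ``int_{t_start}^{t} lambda`` (unitless)."""
        t = np.asarray(t, dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(self.lambda_per_bin * self.delta)])
        rel = np.clip(t - self.t_start, 0.0, self.J * self.delta)
        k = np.minimum(np.floor(rel / self.delta).astype(int), self.J - 1)
        return csum[k] + self.lambda_per_bin[k] * (rel - k * self.delta)

    def integral(self) -> float:
        """Integrated intensity over the full grid, ``sum_k lambda_k*delta``."""
        return float(np.sum(self.lambda_per_bin * self.delta))


def bin_spike_train(
    train: SpikeTrain, delta: float, allow_truncated: bool = False
) -> BinnedSpikeTrain:
    """Discretize a spike train into binary increments at bin width ``delta``.

    Bin ``k`` (0-based) covers ``[t_start + k*delta, t_start + (k+1)*delta)``;
    a spike exactly at ``t_end`` falls in the last bin.  Two spikes in one bin
    violate the at-most-one-spike-per-bin requirement and raise ``ValueError``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    t0, t1 = train.interval
    span = t1 - t0
    ratio = span / delta
    if abs(ratio - round(ratio)) < 1e-9:
        J = int(round(ratio))
        truncated = False
    else:
        if not allow_truncated:
            raise ValueError(
                f"interval length {span} is not a multiple of delta={delta}; "
                "pass allow_truncated=True to shorten the final bin"
            )
        J = int(math.ceil(ratio - 1e-9))
        truncated = True
    inc = np.zeros(J, dtype=np.int8)
    if train.n:
        k = np.floor((train.times - t0) / delta).astype(int)
        k[np.abs(train.times - t1) <= _TIME_TOL] = J - 1  # t_end -> last bin
        k = np.clip(k, 0, J - 1)
        counts = np.bincount(k, minlength=J)
        if counts.max() > 1:
            bad = int(np.argmax(counts > 1))
            raise ValueError(
                f"bin {bad} contains {counts[bad]} spikes; "
                f"use a smaller delta than {delta}"
            )
        inc[k] = 1
    return BinnedSpikeTrain(
        increments=inc,
        delta=delta,
        interval=train.interval,
        truncated_last=truncated,
        neuron_id=train.neuron_id,
        trial_id=train.trial_id,
        stimulus_id=train.stimulus_id,
    )


def log_likelihood(
    binned: BinnedSpikeTrain,
    model: IntensityModel,
    form: str = "local_poisson",
) -> float:
    """Discrete point-process log-likelihood of a binned train (nats).

    Parameters
    ----------
    binned : BinnedSpikeTrain
    model : IntensityModel
        Must share ``delta`` and length ``J`` with ``binned``.
    form : {"local_poisson", "bernoulli"}
        ``local_poisson`` returns
        ``sum_k dN_k*ln(lambda_k*delta) - sum_k lambda_k*delta``;
        ``bernoulli`` returns the exact Bernoulli product mass.
    """
    if model.J != binned.J:
        raise ValueError(f"length mismatch: model J={model.J}, data J={binned.J}")
    if abs(model.delta - binned.delta) > 1e-12 * max(model.delta, binned.delta):
        raise ValueError(
            f"bin width mismatch: model delta={model.delta}, data delta={binned.delta}"
        )
    lam = model.lambda_per_bin
    if np.any(lam <= 0):
        raise ValueError("all intensities must be strictly positive")
    dn = binned.increments.astype(float)
    lamdt = lam * binned.delta
    if form == "local_poisson":
        return float(np.dot(dn, np.log(lamdt)) - lamdt.sum())
    if form == "bernoulli":
        if np.any(lamdt >= 1.0):
            raise ValueError("bernoulli form requires lambda*delta < 1 in every bin")
        return float(np.dot(dn, np.log(lamdt)) + np.dot(1.0 - dn, np.log1p(-lamdt)))
    raise ValueError(f"unknown likelihood form {form!r}")


def continuous_log_likelihood(
    train: SpikeTrain,
    intensity: Callable[[float], float] | IntensityModel,
) -> float:
    """Continuous-time log-likelihood ``sum_j ln lambda(u_j) - int lambda`` (nats).

    ``intensity`` may be a callable of time (integrated by adaptive
    quadrature) or an :class:`IntensityModel` (integrated exactly as a step
    function).  Differs from :func:`log_likelihood` of the binned train by the
    ``n*ln(delta)`` Jacobian of the discretization; see
    :func:`binning_jacobian`.
    """
    t0, t1 = train.interval
    if isinstance(intensity, IntensityModel):
        at_spikes = intensity.at(train.times) if train.n else np.array([])
        total = intensity.cumulative(t1) - intensity.cumulative(t0)
    else:
        at_spikes = np.array([float(intensity(u)) for u in train.times])
        total, _ = integrate.quad(intensity, t0, t1, limit=200)
    if train.n and np.any(at_spikes <= 0):
        bad = train.times[np.argmax(at_spikes <= 0)]
        raise ValueError(f"intensity must be positive at spike times; fails at t={bad}")
    point_term = float(np.sum(np.log(at_spikes))) if train.n else 0.0
    return point_term - float(total)


def binning_jacobian(n_spikes: int, delta: float) -> float:
    """Offset ``n*ln(delta)`` between binned and continuous log-likelihoods.

    ``log_likelihood(binned) ~ continuous_log_likelihood + n*ln(delta)`` as
    ``delta -> 0``; subtract this to compare the two on a common scale.
    """
    return n_spikes * math.log(delta)
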
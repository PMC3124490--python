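"""Extended Kalman filtering of point-process observations.

The log-intensity of a neuron is modeled as a latent linear-Gaussian state
process ``x_k = F x_{k-1} + eps_k`` with ``eps_k ~ N(0, Q)`` and an
exponential link ``lambda_k = exp(c . x_k)``, which keeps the conditional
intensity strictly positive.  Spike counts pooled over ``M`` repeated trials
enter through a linearized observation equation: the expected pooled count in
bin ``k`` is ``M * lambda_k * delta``, its Jacobian with respect to the state
is ``M * lambda_k * delta * c`` (Taylor expansion about the one-step
prediction mean), and the observation-noise variance is taken equal to the
expected count — the Poisson-like variance choice appropriate when ``delta``
is small.

The recursion per bin is the standard predict/update cycle:

    x_pred = F x_post
    S_pred = F S_post F' + Q
    innov  = dN_k - M*lambda*delta
    S_inn  = C S_pred C' + R
    K      = S_pred C' / S_inn
    x_post = x_pred + K*innov
    S_post = (I - K C) S_pred          (Joseph-form alternative available)

Estimation is maximum a posteriori under a Gaussian approximation of the
filtering density; no backward smoothing pass is performed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .core import BinnedSpikeTrain, IntensityModel

__all__ = [
    "StateSpaceConfig",
    "FilterState",
    "linearized_observation",
    "ekf_step",
    "fit_intensity",
    "PointProcessFilter",
]

# lambda*delta is clamped to this range so it remains a valid per-bin
# probability and exp() cannot overflow.
_LAMDT_MIN = 1e-6
_LAMDT_MAX = 0.99


def _as_psd(name: str, m: np.ndarray) -> np.ndarray:
    m = np.atleast_2d(np.asarray(m, dtype=float))
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    eigmin = np.linalg.eigvalsh(m).min()
    if eigmin < -1e-10:
        raise ValueError(f"{name} must be positive semidefinite (min eig {eigmin:g})")
    return m


@dataclass(frozen=True)
class StateSpaceConfig:
    """Configuration of the linear-Gaussian state model.

    Parameters
    ----------
    F : (d, d) array
        State transition matrix; identity gives a random walk.
    Q : (d, d) array
        State-noise covariance per bin, symmetric PSD.
    x0 : (d,) array
        Initial state mean.
    S0 : (d, d) array
        Initial state covariance, symmetric PSD.
    delta : float
        Bin width in seconds.
    n_trials : int
        Number of pooled trials ``M``.
    c : (d,) array
        Observation coefficients in the link ``lambda = exp(c . x)``.
    """

    F: np.ndarray
    Q: np.ndarray
    x0: np.ndarray
    S0: np.ndarray
    delta: float
    n_trials: int = 1
    c: np.ndarray | None = None

    def __post_init__(self) -> None:
        F = np.atleast_2d(np.asarray(self.F, dtype=float))
        Q = _as_psd("Q", self.Q)
        S0 = _as_psd("S0", self.S0)
        x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        d = x0.size
        c = np.ones(d) if self.c is None else np.atleast_1d(np.asarray(self.c, float))
        for name, m in (("F", F), ("Q", Q), ("S0", S0)):
            if m.shape != (d, d):
                raise ValueError(f"{name} shape {m.shape} inconsistent with state dim {d}")
        if c.size != d:
            raise ValueError("c must have the state dimension")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for k, v in (("F", F), ("Q", Q), ("x0", x0), ("S0", S0), ("c", c)):
            object.__setattr__(self, k, v)

    @property
    def dim(self) -> int:
        return self.x0.size


@dataclass(frozen=True)
class FilterState:
    """One bin's filter record: prediction, update, and diagnostics."""

    x_pred: np.ndarray
    S_pred: np.ndarray
    x_post: np.ndarray
    S_post: np.ndarray
    innovation: float
    innovation_cov: float
    gain: np.ndarray


def linearized_observation(
    x_pred: np.ndarray, cfg: StateSpaceConfig
) -> tuple[float, np.ndarray, float]:
    """Linearize the count observation about the one-step prediction mean.

    Returns ``(expected_count, jacobian, obs_noise_variance)`` where the
    expected pooled count over ``M`` trials is ``M*lambda*delta`` with
    ``lambda = exp(c . x_pred)``, the Jacobian is ``M*lambda*delta*c``, and
    the noise variance equals the expected count.  ``lambda*delta`` is
    clamped to [1e-6, 0.99] (with a warning on the upper side) so it stays a
    valid Bernoulli probability and the exponential cannot overflow.
    """
    x_pred = np.atleast_1d(np.asarray(x_pred, dtype=float))
    loglam_dt = float(cfg.c @ x_pred) + math.log(cfg.delta)
    lamdt = math.exp(min(loglam_dt, 700.0))
    if lamdt > _LAMDT_MAX:
        warnings.warn(
            f"lambda*delta = {lamdt:.3g} clamped to {_LAMDT_MAX}; "
            "state is outside the valid Bernoulli range",
            RuntimeWarning,
            stacklevel=2,
        )
        lamdt = _LAMDT_MAX
    lamdt = max(lamdt, _LAMDT_MIN)
    expected = cfg.n_trials * lamdt
    jacobian = expected * cfg.c
    return expected, jacobian, expected


def ekf_step(
    prev_x: np.ndarray,
    prev_S: np.ndarray,
    dN_k: float,
    cfg: StateSpaceConfig,
    joseph: bool = False,
) -> FilterState:
    """One predict/update cycle given the pooled count ``dN_k`` in bin ``k``.

    ``joseph=True`` uses the Joseph-form covariance update
    ``(I-KC) S (I-KC)' + K R K'``, algebraically equal to ``(I-KC) S`` but
    numerically guaranteed symmetric PSD.
    """
    prev_x = np.atleast_1d(np.asarray(prev_x, dtype=float))
    prev_S = np.atleast_2d(np.asarray(prev_S, dtype=float))
    x_pred = cfg.F @ prev_x
    S_pred = cfg.F @ prev_S @ cfg.F.T + cfg.Q
    expected, C, R = linearized_observation(x_pred, cfg)
    innovation = float(dN_k) - expected
    S_inn = float(C @ S_pred @ C) + R
    if not np.isfinite(S_inn) or S_inn <= 0:
        raise np.linalg.LinAlgError(
            f"singular innovation covariance ({S_inn}) — check Q, S0 and the link"
        )
    K = (S_pred @ C) / S_inn
    x_post = x_pred + K * innovation
    IKC = np.eye(cfg.dim) - np.outer(K, C)
    if joseph:
        S_post = IKC @ S_pred @ IKC.T + R * np.outer(K, K)
    else:
        S_post = IKC @ S_pred
    S_post = 0.5 * (S_post + S_post.T)
    return FilterState(
        x_pred=x_pred,
        S_pred=S_pred,
        x_post=x_post,
        S_post=S_post,
        innovation=innovation,
        innovation_cov=S_inn,
        gain=K,
    )


class PointProcessFilter(BaseEstimator):
    """EKF estimator of a per-bin conditional intensity from repeated trials.

    Counts are pooled per bin across the ``M`` trials of one stimulus and a
    single latent state path is filtered through them; the fitted intensity
    ``lambda_k = exp(c . x_post_k)`` is the intensity of *one* trial (the
    trial multiplicity enters the observation model, not the link).

    Parameters
    ----------
    q : float, default 1e-5
        Per-bin state-noise variance (isotropic, ``Q = q*I``).  Larger values
        track faster intensity changes at the cost of noisier estimates.
    transition : array or None
        State transition matrix ``F``; ``None`` means identity (random walk).
    x0, S0 : array or None
        Initial state mean / covariance.  ``None`` picks the data-scaled
        neutral start ``x0 = ln(max(mean rate, 1 Hz))`` and ``S0 = I``.
    obs_coef : array or None
        Link coefficients ``c``; ``None`` means all-ones (scalar state:
        ``lambda = exp(x)``).
    joseph : bool, default False
        Use the Joseph-form covariance update.

    Attributes
    ----------
    intensity_ : IntensityModel
        Fitted per-bin intensity with state path and filter trace attached.
    lambda_hat_ : ndarray of shape (J,)
        Fitted intensity in Hz.
    trace_ : list of FilterState
        Full per-bin filter records.
    config_ : StateSpaceConfig
        The resolved configuration used for the fit.
    """

    def __init__(
        self,
        q: float = 1e-5,
        transition: np.ndarray | None = None,
        x0: np.ndarray | None = None,
        S0: np.ndarray | None = None,
        obs_coef: np.ndarray | None = None,
        joseph: bool = False,
    ):
        self.q = q
        self.transition = transition
        self.x0 = x0
        self.S0 = S0
        self.obs_coef = obs_coef
        self.joseph = joseph

    def _resolve_config(
        self, counts: np.ndarray, M: int, delta: float, span: float
    ) -> StateSpaceConfig:
        if self.x0 is not None:
            x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        else:
            mean_rate = counts.sum() / (M * span)
            x0 = np.array([math.log(max(mean_rate, 1.0))])
        d = x0.size
        F = np.eye(d) if self.transition is None else np.asarray(self.transition, float)
        Q = self.q * np.eye(d)
        S0 = np.eye(d) if self.S0 is None else np.asarray(self.S0, float)
        c = None if self.obs_coef is None else np.asarray(self.obs_coef, float)
        return StateSpaceConfig(
            F=F, Q=Q, x0=x0, S0=S0, delta=delta, n_trials=M, c=c
        )

    def fit(self, X, y=None) -> "PointProcessFilter":
        """Filter the pooled counts of an ensemble of binned trials.

        Parameters
        ----------
        X : list of BinnedSpikeTrain, or (M, J) binary array
            Repeated trials of one neuron under one stimulus on a common
            bin grid.
        """
        if isinstance(X, np.ndarray):
            raise TypeError(
                "pass a list of BinnedSpikeTrain; a bare array has no bin width"
            )
        trials = list(X)
        if not trials:
            raise ValueError("at least one trial is required")
        ref = trials[0]
        for t in trials[1:]:
            if t.J != ref.J or abs(t.delta - ref.delta) > 1e-12:
                raise ValueError(
                    "mismatched trial grids: all trials must share J and delta"
                )
        M = len(trials)
        counts = np.sum([t.increments for t in trials], axis=0).astype(float)
        span = ref.interval[1] - ref.interval[0]
        cfg = self._resolve_config(counts, M, ref.delta, span)
        x, S = cfg.x0, cfg.S0
        trace: list[FilterState] = []
        lam = np.empty(ref.J)
        for k in range(ref.J):
            st = ekf_step(x, S, counts[k], cfg, joseph=self.joseph)
            x, S = st.x_post, st.S_post
            lamdt = math.exp(min(float(cfg.c @ x) + math.log(cfg.delta), 700.0))
            lam[k] = np.clip(lamdt, _LAMDT_MIN, _LAMDT_MAX) / cfg.delta
            trace.append(st)
        self.config_ = cfg
        self.trace_ = trace
        self.lambda_hat_ = lam
        self.states_ = np.array([st.x_post for st in trace])
        self.intensity_ = IntensityModel(
            lambda_per_bin=lam,
            delta=ref.delta,
            interval=ref.interval,
            states=self.states_,
            params={"q": self.q, "M": M},
            trace=trace,
        )
        return self

    def trace_frame(self):
        """Filter trace as a DataFrame (bin, x_pred, x_post, variance, lambda_hat)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "bin": np.arange(len(self.trace_)),
                "x_pred": [float(st.x_pred[0]) for st in self.trace_],
                "x_post": [float(st.x_post[0]) for st in self.trace_],
                "variance": [float(st.S_post[0, 0]) for st in self.trace_],
                "lambda_hat": self.lambda_hat_,
            }
        )


def fit_intensity(
    ensemble: list[BinnedSpikeTrain],
    q: float = 1e-5,
    joseph: bool = False,
    **kwargs,
) -> IntensityModel:
    """Fit a per-bin intensity to repeated trials of one stimulus by EKF.

    Thin wrapper over :class:`PointProcessFilter`; see it for parameters.
    """
    est = PointProcessFilter(q=q, joseph=joseph, **kwargs)
    est.fit(ensemble)
    return est.intensity_
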
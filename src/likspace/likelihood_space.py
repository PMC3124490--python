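"""Projection of spike trains into likelihood coordinates and classification.

Given ``P`` stimulus-conditional intensity models, the likelihood projection
maps an observed spike train (a ``J``-dimensional binary vector, ``J >> P``)
to the ``P``-vector of its log-likelihoods under each model.  In this
*likelihood space*:

* the minimum-error Bayes rule becomes the linear discriminant
  ``argmax_i [coord_i + ln p(s_i)]`` with unit slope;
* every decision region is an intersection of half-spaces, hence convex and
  connected, even when the corresponding observation-space region is
  disconnected;
* cluster separability can be compared against the raw observation space via
  the Fisher discriminant ratio.

Coordinates are natural-log likelihoods; :func:`LikelihoodVector.linear`
exposes raw likelihoods for plotting.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import BinnedSpikeTrain, IntensityModel, SpikeTrain, bin_spike_train, log_likelihood
from .ekf import PointProcessFilter
from .population import PopulationIntensity, PopulationRecording, population_log_likelihood

__all__ = [
    "ProjectingDistributions",
    "LikelihoodVector",
    "project",
    "project_many",
    "classify",
    "decision_region_convexity_check",
    "fisher_ratio",
    "mean_pairwise_fisher",
    "separability_improvement",
    "LikelihoodSpaceClassifier",
]


@dataclass(frozen=True)
class ProjectingDistributions:
    """The ``P`` stimulus-conditional models spanning the likelihood space.

    Parameters
    ----------
    models : sequence of IntensityModel or PopulationIntensity
        One per stimulus; all on a common bin grid.
    priors : array-like or None
        Prior stimulus probabilities ``p(s_i)``; ``None`` means uniform.
    labels : sequence, optional
        Stimulus labels aligned with ``models``.
    form : {"local_poisson", "bernoulli"}
        Likelihood form used for single-neuron projections.
    """

    models: tuple
    priors: np.ndarray = None
    labels: tuple = None
    form: str = "local_poisson"

    def __post_init__(self) -> None:
        models = tuple(self.models)
        object.__setattr__(self, "models", models)
        if len(models) < 2:
            raise ValueError("at least two projecting distributions are required")
        if self.priors is None:
            priors = np.full(len(models), 1.0 / len(models))
        else:
            priors = np.asarray(self.priors, dtype=float)
        if priors.size != len(models) or abs(priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must match the model count and sum to 1")
        if np.any(priors < 0):
            raise ValueError("priors must be nonnegative")
        object.__setattr__(self, "priors", priors)
        labels = (
            tuple(self.labels) if self.labels is not None else tuple(range(len(models)))
        )
        if len(labels) != len(models):
            raise ValueError("labels must align with models")
        object.__setattr__(self, "labels", labels)

    @property
    def P(self) -> int:
        return len(self.models)


@dataclass(frozen=True)
class LikelihoodVector:
    """A spike train as a point in likelihood space (nats per coordinate)."""

    coords: np.ndarray
    true_stimulus: object = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if not np.all(np.isfinite(coords)):
            raise ValueError("likelihood coordinates must be finite")

    @property
    def P(self) -> int:
        return int(self.coords.size)

    def linear(self) -> np.ndarray:
        """Raw (non-log) likelihoods; may underflow for long trains."""
        return np.exp(self.coords)


def project(
    observation: BinnedSpikeTrain | PopulationRecording,
    models: ProjectingDistributions,
) -> LikelihoodVector:
    """Project one observation onto the ``P`` likelihood coordinates.

    Coordinate ``i`` is the log-likelihood of the observation under model
    ``i``; the output dimension is ``P`` regardless of the bin count ``J``
    (a dimensionality reduction whenever ``J > P``).
    """
    if isinstance(observation, PopulationRecording):
        coords = [
            population_log_likelihood(observation, m) for m in models.models
        ]
        true = observation.stimulus_id
    elif isinstance(observation, BinnedSpikeTrain):
        coords = [
            log_likelihood(observation, m, form=models.form) for m in models.models
        ]
        true = observation.stimulus_id
    else:
        raise TypeError(
            "observation must be a BinnedSpikeTrain or PopulationRecording"
        )
    return LikelihoodVector(coords=np.array(coords), true_stimulus=true)


def project_many(observations, models: ProjectingDistributions) -> np.ndarray:
    """Project ``M`` observations; returns an ``(M, P)`` coordinate array."""
    return np.array([project(o, models).coords for o in observations])


def classify(lv, priors=None) -> int:
    """Bayes rule in likelihood space: ``argmax_i [coord_i + ln p(s_i)]``.

    Zero-prior stimuli are excluded.  Exact ties resolve to the smallest
    index.  Returns the 0-based stimulus index.
    """
    coords = lv.coords if isinstance(lv, LikelihoodVector) else np.asarray(lv, float)
    if priors is None:
        score = coords
    else:
        priors = np.asarray(priors, dtype=float)
        with np.errstate(divide="ignore"):
            score = coords + np.log(priors)
    return int(np.argmax(score))


def decision_region_convexity_check(
    models: ProjectingDistributions,
    stimulus: int,
    n_pairs: int = 200,
    seed: int | None = None,
    n_alpha: int = 11,
    scale: float = 5.0,
) -> dict:
    """Empirically verify convexity of one decision region in likelihood space.

    Random likelihood-space points are drawn, those classified as
    ``stimulus`` are paired, and each convex combination on an equispaced
    ``alpha`` grid is re-classified.  The region is an intersection of
    half-spaces, so no violation should ever occur; the check is a guard
    against implementation error, not a statistical test.

    Returns a report dict with ``passed``, ``n_pairs_checked``,
    ``n_violations`` and ``vacuous`` (no two points fell in the region).
    """
    rng = np.random.default_rng(seed)
    pts = rng.normal(loc=-scale, scale=scale, size=(50 * n_pairs, models.P))
    labels = np.array([classify(p, models.priors) for p in pts])
    in_region = pts[labels == stimulus]
    if len(in_region) < 2:
        return {
            "passed": True,
            "vacuous": True,
            "n_pairs_checked": 0,
            "n_violations": 0,
        }
    alphas = np.linspace(0.0, 1.0, n_alpha)
    n_violations = 0
    n_checked = 0
    for _ in range(n_pairs):
        a, b = in_region[rng.choice(len(in_region), size=2, replace=False)]
        n_checked += 1
        for al in alphas:
            if classify(al * a + (1 - al) * b, models.priors) != stimulus:
                n_violations += 1
                break
    return {
        "passed": n_violations == 0,
        "vacuous": False,
        "n_pairs_checked": n_checked,
        "n_violations": n_violations,
    }


def fisher_ratio(cluster_a: np.ndarray, cluster_b: np.ndarray) -> float:
    """Fisher discriminant ratio between two point clusters.

    Both clusters are projected on the Fisher direction
    ``w = (S_a + S_b)^-1 (m_a - m_b)`` (population covariances); the ratio is
    ``(m~_a - m~_b)^2 / (s~_a^2 + s~_b^2)`` of the 1-D projections.  A
    singular pooled scatter is ridge-regularized with ``1e-8 * I`` and a
    warning.  Affine-invariant: rescaling all points leaves it unchanged.
    """
    a = np.atleast_2d(np.asarray(cluster_a, dtype=float))
    b = np.atleast_2d(np.asarray(cluster_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("clusters must share the dimension")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    Sa = np.cov(a, rowvar=False, ddof=0) if len(a) > 1 else np.zeros((a.shape[1],) * 2)
    Sb = np.cov(b, rowvar=False, ddof=0) if len(b) > 1 else np.zeros((b.shape[1],) * 2)
    Sa, Sb = np.atleast_2d(Sa), np.atleast_2d(Sb)
    Sw = Sa + Sb
    diff = ma - mb
    if np.allclose(diff, 0) and np.allclose(Sw, 0):
        return 0.0
    try:
        cond = np.linalg.cond(Sw)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            "singular pooled scatter; ridge 1e-8*I added", RuntimeWarning, stacklevel=2
        )
        Sw = Sw + 1e-8 * np.eye(Sw.shape[0])
    w = np.linalg.solve(Sw, diff)
    sep = float(w @ diff) ** 2
    spread = float(w @ Sa @ w) + float(w @ Sb @ w)
    if spread == 0.0:
        return np.inf if sep > 0 else 0.0
    return sep / spread


def mean_pairwise_fisher(points: np.ndarray, labels) -> float:
    """Mean Fisher ratio over all unordered label pairs."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    ratios = [
        fisher_ratio(points[labels == a], points[labels == b])
        for a, b in itertools.combinations(uniq, 2)
    ]
    return float(np.mean(ratios))


def separability_improvement(
    obs_space_points: np.ndarray,
    lik_space_points: np.ndarray,
    labels,
) -> float:
    """Percent Fisher-ratio improvement of likelihood space over observation space.

    ``100 * (FR_lik - FR_obs) / FR_obs`` computed per unordered stimulus pair
    and averaged over pairs.
    """
    obs = np.asarray(obs_space_points, dtype=float)
    lik = np.asarray(lik_space_points, dtype=float)
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    improvements = []
    for a, b in itertools.combinations(uniq, 2):
        ia, ib = labels == a, labels == b
        fr_obs = fisher_ratio(obs[ia], obs[ib])
        fr_lik = fisher_ratio(lik[ia], lik[ib])
        if fr_obs == 0:
            continue
        improvements.append(100.0 * (fr_lik - fr_obs) / fr_obs)
    if not improvements:
        return 0.0
    return float(np.mean(improvements))


class LikelihoodSpaceClassifier(BaseEstimator, ClassifierMixin):
    """Bayes classifier operating in the likelihood space of EKF-fitted models.

    ``fit`` groups training spike trains by stimulus label, estimates one
    conditional-intensity model per stimulus by extended Kalman filtering,
    and stores them as projecting distributions.  ``transform`` maps spike
    trains to their ``(M, P)`` log-likelihood coordinates; ``predict``
    applies the unit-slope linear discriminant ``argmax_i coord_i + ln p_i``.

    Parameters
    ----------
    delta : float, default 0.001
        Bin width in seconds used to discretize the trains.
    q : float, default 1e-5
        EKF per-bin state-noise variance.
    priors : array-like or None
        Stimulus priors; ``None`` means uniform.
    form : {"local_poisson", "bernoulli"}
        Likelihood form for the coordinates.

    Attributes
    ----------
    classes_ : ndarray
        Sorted unique stimulus labels.
    models_ : ProjectingDistributions
        Fitted stimulus-conditional models.
    """

    def __init__(
        self,
        delta: float = 0.001,
        q: float = 1e-5,
        priors=None,
        form: str = "local_poisson",
    ):
        self.delta = delta
        self.q = q
        self.priors = priors
        self.form = form

    def _bin(self, x) -> BinnedSpikeTrain:
        if isinstance(x, BinnedSpikeTrain):
            return x
        if isinstance(x, SpikeTrain):
            return bin_spike_train(x, self.delta)
        raise TypeError("inputs must be SpikeTrain or BinnedSpikeTrain")

    def fit(self, X, y) -> "LikelihoodSpaceClassifier":
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y must have the same length")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two stimulus classes")
        binned = [self._bin(x) for x in X]
        fitted = []
        for label in self.classes_:
            ensemble = [b for b, lab in zip(binned, y) if lab == label]
            est = PointProcessFilter(q=self.q)
            est.fit(ensemble)
            fitted.append(est.intensity_)
        self.models_ = ProjectingDistributions(
            models=tuple(fitted),
            priors=self.priors,
            labels=tuple(self.classes_),
            form=self.form,
        )
        return self

    def transform(self, X) -> np.ndarray:
        """Likelihood-space coordinates of ``X``, shape ``(len(X), P)``."""
        binned = [self._bin(x) for x in X]
        return project_many(binned, self.models_)

    def decision_function(self, X) -> np.ndarray:
        scores = self.transform(X)
        with np.errstate(divide="ignore"):
            return scores + np.log(self.models_.priors)

    def predict(self, X) -> np.ndarray:
        idx = np.argmax(self.decision_function(X), axis=1)
        return self.classes_[idx]
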
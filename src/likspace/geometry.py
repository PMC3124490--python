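"""Classical MDS, dissimilarity matrices, and rate-vector baselines.

Classical (Torgerson) multidimensional scaling embeds a dissimilarity matrix
``D`` in a low-dimensional Euclidean space: double-center the squared
dissimilarities, ``B = -1/2 * J D^2 J`` with ``J = I - 11'/n``, eigendecompose
``B``, and take the eigenvectors of the two largest eigenvalues scaled by the
square roots of those eigenvalues.  (Taking eigenvectors of ``D`` itself is
not a valid embedding; the double-centered form is the standard construction
and the one implemented here.)  Negative eigenvalues — a non-Euclidean input —
are truncated to zero with a warning and the fraction of dispersion explained
by the retained positive part is reported.

The rate-framework baselines mirror conventional population analyses: mean
firing-rate vectors in a fixed response window (z-scored across stimuli, unit
Euclidean length) compared by correlation distance, and a sliding-window
between-stimulus distance whose argmax gives a latency of maximum
dissimilarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core import SpikeTrain
from .information import sliding_window_information

__all__ = [
    "DissimilarityMatrix",
    "Embedding2D",
    "ClassicalMDS",
    "classical_mds",
    "pairwise_distances",
    "rate_vectors",
    "sliding_distance",
]


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Real symmetric matrix, zero diagonal, nonnegative entries."""

    matrix: np.ndarray
    labels: tuple = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if np.any(m < -1e-12):
            raise ValueError("dissimilarities must be nonnegative")
        labels = (
            tuple(self.labels)
            if self.labels is not None
            else tuple(range(m.shape[0]))
        )
        if len(labels) != m.shape[0]:
            raise ValueError("labels must match the matrix size")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return int(self.matrix.shape[0])

    def normalized(self) -> "DissimilarityMatrix":
        """Proximity normalization: divide by the maximum entry."""
        mx = self.matrix.max()
        if mx == 0:
            return self
        return DissimilarityMatrix(self.matrix / mx, labels=self.labels)


@dataclass(frozen=True)
class Embedding2D:
    """Low-dimensional MDS coordinates (column means zero by construction)."""

    coords: np.ndarray
    eigenvalues: np.ndarray
    explained_fraction: float
    labels: tuple = None


class ClassicalMDS(BaseEstimator, TransformerMixin):
    """Torgerson classical multidimensional scaling.

    Parameters
    ----------
    n_components : int, default 2
        Embedding dimension (the eigenvectors of the largest eigenvalues).

    Attributes
    ----------
    embedding_ : Embedding2D
        Coordinates, full eigenvalue spectrum, and the positive-dispersion
        fraction explained by the retained components.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None) -> "ClassicalMDS":
        d = X if isinstance(X, DissimilarityMatrix) else DissimilarityMatrix(X)
        n = d.n
        D2 = d.matrix**2
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ D2 @ J
        B = 0.5 * (B + B.T)
        eigval, eigvec = np.linalg.eigh(B)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        if eigval.min() < -1e-8 * max(1.0, abs(eigval).max()):
            warnings.warn(
                "negative eigenvalues truncated: dissimilarities are not "
                f"Euclidean (most negative {eigval.min():.3g})",
                RuntimeWarning,
                stacklevel=2,
            )
        k = self.n_components
        top = np.clip(eigval[:k], 0.0, None)
        coords = eigvec[:, :k] * np.sqrt(top)
        pos = np.clip(eigval, 0.0, None).sum()
        explained = float(top.sum() / pos) if pos > 0 else 1.0
        self.embedding_ = Embedding2D(
            coords=coords,
            eigenvalues=eigval,
            explained_fraction=explained,
            labels=d.labels,
        )
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_.coords


def classical_mds(d, n_components: int = 2) -> Embedding2D:
    """Embed a dissimilarity matrix; thin wrapper over :class:`ClassicalMDS`."""
    return ClassicalMDS(n_components=n_components).fit(d).embedding_


def pairwise_distances(
    points: np.ndarray,
    metric: str = "euclidean",
    normalize: bool = False,
    labels=None,
) -> DissimilarityMatrix:
    """Pairwise dissimilarities between row vectors.

    ``euclidean`` is the amplitude of the vector difference (for binary
    spike-train vectors, ``sqrt(Hamming distance)``); ``correlation`` is
    ``1 - Pearson correlation`` (2 for perfect anti-correlation).
    ``normalize=True`` divides the matrix by its maximum entry (proximity
    normalization used before MDS display).
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    n = x.shape[0]
    if metric == "euclidean":
        diff = x[:, None, :] - x[None, :, :]
        m = np.sqrt((diff**2).sum(axis=2))
    elif metric == "correlation":
        xc = x - x.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(xc, axis=1)
        if np.any(norms == 0):
            raise ValueError("correlation distance undefined for constant vectors")
        corr = (xc @ xc.T) / np.outer(norms, norms)
        m = 1.0 - np.clip(corr, -1.0, 1.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    out = DissimilarityMatrix(m, labels=labels)
    return out.normalized() if normalize else out


def rate_vectors(
    trains, window: tuple[float, float] = (0.070, 0.270)
) -> pd.DataFrame:
    """Normalized population firing-rate vectors, one row per stimulus.

    For every neuron the mean firing rate over ``window`` (trial-averaged,
    default the 70-270 ms response interval) is computed; per neuron the
    rates are z-scored across stimuli, and each stimulus row is then scaled
    to unit Euclidean length.  Scaling all spike counts by a common factor
    leaves the result unchanged.

    Parameters
    ----------
    trains : iterable of SpikeTrain
        Must carry ``neuron_id`` and ``stimulus_id``.

    Returns
    -------
    DataFrame indexed by stimulus with one column per neuron.
    """
    w0, w1 = window
    span = w1 - w0
    acc: dict = {}
    for tr in trains:
        key = (tr.stimulus_id, tr.neuron_id)
        count = int(np.sum((tr.times > w0) & (tr.times <= w1)))
        acc.setdefault(key, []).append(count / span)
    stimuli = sorted({s for s, _ in acc}, key=str)
    neurons = sorted({n for _, n in acc}, key=str)
    rates = np.array(
        [[np.mean(acc.get((s, n), [0.0])) for n in neurons] for s in stimuli]
    )
    mu = rates.mean(axis=0)
    sd = rates.std(axis=0, ddof=0)
    z = np.where(sd > 0, (rates - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    z = np.where(norms > 0, z / np.where(norms > 0, norms, 1.0), 0.0)
    return pd.DataFrame(z, index=pd.Index(stimuli, name="stimulus"), columns=neurons)


def _window_rate_vector(trains: list[SpikeTrain], w0: float, w1: float) -> np.ndarray:
    """Per-neuron mean rate in (w0, w1], ordered by neuron id."""
    acc: dict = {}
    for tr in trains:
        count = int(np.sum((tr.times > w0) & (tr.times <= w1)))
        acc.setdefault(tr.neuron_id, []).append(count / (w1 - w0))
    return np.array([np.mean(acc[n]) for n in sorted(acc, key=str)])


def sliding_distance(
    trains_by_stimulus: dict,
    framework: str = "rate",
    pair: tuple = None,
    window: float = 0.100,
    step: float = 0.010,
    delta: float = 0.001,
    q: float = 1e-4,
) -> tuple[pd.DataFrame, float]:
    """Between-stimulus distance in a sliding window, plus its peak latency.

    ``framework="rate"`` uses the correlation distance between the two
    stimuli's per-neuron mean-rate vectors in each window (requires at least
    two neurons).  ``framework="likelihood"`` uses the information-based
    stimulus distance ``|I_ssi(a) - I_ssi(b)|`` from point-process models
    refit per window.  The peak latency is the window center of the maximum
    distance.

    Returns ``(DataFrame[window_center_s, distance], peak_latency_s)``.
    """
    labels = list(trains_by_stimulus)
    if pair is None:
        pair = (labels[0], labels[1])
    a, b = pair
    if framework == "likelihood":
        df_a = sliding_window_information(
            trains_by_stimulus, target=a, delta=delta, window=window, step=step, q=q
        )
        df_b = sliding_window_information(
            trains_by_stimulus, target=b, delta=delta, window=window, step=step, q=q
        )
        df = pd.DataFrame(
            {
                "window_center_s": df_a["window_center_s"],
                "distance": np.abs(
                    df_a["bits_likelihood"].to_numpy()
                    - df_b["bits_likelihood"].to_numpy()
                ),
            }
        )
    elif framework == "rate":
        t0, t1 = trains_by_stimulus[a][0].interval
        n_neurons = len({tr.neuron_id for tr in trains_by_stimulus[a]})
        if n_neurons < 2:
            raise ValueError("rate-framework distance needs at least two neurons")
        n_windows = int(np.floor((t1 - t0 - window) / step + 1e-9)) + 1
        rows = []
        for w in range(n_windows):
            w0 = t0 + w * step
            w1 = w0 + window
            va = _window_rate_vector(trains_by_stimulus[a], w0, w1)
            vb = _window_rate_vector(trains_by_stimulus[b], w0, w1)
            ca = va - va.mean()
            cb = vb - vb.mean()
            denom = np.linalg.norm(ca) * np.linalg.norm(cb)
            if denom == 0:
                dist = 0.0 if np.allclose(va, vb) else 1.0
            else:
                dist = 1.0 - float(ca @ cb) / denom
            rows.append({"window_center_s": w0 + window / 2.0, "distance": dist})
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown framework {framework!r}")
    peak_latency = float(df.loc[df["distance"].idxmax(), "window_center_s"])
    return df, peak_latency
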
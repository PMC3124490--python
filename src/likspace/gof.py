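"""Time-rescaling goodness-of-fit for point-process intensity models.

By the time-rescaling theorem, if spikes ``u_1 < ... < u_n`` come from a
point process with conditional intensity ``lambda(t)``, the rescaled
inter-spike intervals

    tau_j = int_{u_{j-1}}^{u_j} lambda(t) dt        (u_0 = t_start)

are i.i.d. unit-rate exponentials, so ``z_j = 1 - exp(-tau_j)`` are i.i.d.
uniform on [0, 1].  Agreement between the model and the data is read off a
KS plot — empirical CDF of the ``z_j`` against the uniform CDF — which
should follow the 45-degree line within the asymptotic 95% confidence band
of half-width ``1.36 / sqrt(n)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from scipy import integrate

from .core import IntensityModel, SpikeTrain

__all__ = ["RescaledTimes", "KSResult", "rescale", "ks_test", "ks_plot_data"]

KS_BAND_95 = 1.36  # asymptotic 95% two-sided KS critical constant


class KSResult(NamedTuple):
    ks_stat: float
    band_halfwidth: float
    passed: bool


@dataclass(frozen=True)
class RescaledTimes:
    """Rescaled intervals, their uniform transforms, and the KS summary."""

    taus: np.ndarray
    zs: np.ndarray
    ks_stat: float = np.nan
    band_halfwidth: float = np.nan

    @property
    def n(self) -> int:
        return int(self.zs.size)

    @property
    def passed(self) -> bool:
        return bool(self.ks_stat < self.band_halfwidth)


def rescale(
    train: SpikeTrain,
    intensity: Callable[[float], float] | IntensityModel,
) -> RescaledTimes:
    """Rescale inter-spike intervals by the integrated intensity.

    ``intensity`` may be a callable (adaptive quadrature per interval) or an
    :class:`IntensityModel` (exact piecewise-constant integration).  The
    first interval integrates from ``t_start``.  The KS summary fields are
    filled when the train has at least two spikes.
    """
    t0, _ = train.interval
    edges = np.concatenate([[t0], train.times])
    if isinstance(intensity, IntensityModel):
        cum = intensity.cumulative(edges)
        taus = np.diff(cum)
    else:
        taus = np.array(
            [
                integrate.quad(intensity, a, b, limit=200)[0]
                for a, b in zip(edges[:-1], edges[1:])
            ]
        )
    if np.any(taus < -1e-12):
        raise ValueError("negative rescaled interval; intensity must be nonnegative")
    taus = np.clip(taus, 0.0, None)
    zs = -np.expm1(-taus)
    if zs.size >= 2:
        stat, band, _ = ks_test(zs)
        return RescaledTimes(taus=taus, zs=zs, ks_stat=stat, band_halfwidth=band)
    return RescaledTimes(taus=taus, zs=zs)


def ks_test(zs: np.ndarray) -> KSResult:
    """KS statistic of ``zs`` against the uniform CDF with a 95% band.

    ``ks_stat = sup_z |ECDF(z) - z|`` (the one-sample statistic
    ``D_n = max_k max(k/n - z_(k), z_(k) - (k-1)/n)``);
    ``band_halfwidth = 1.36 / sqrt(n)``; the model passes when the statistic
    stays inside the band.
    """
    zs = np.asarray(zs, dtype=float)
    n = zs.size
    if n < 2:
        raise ValueError("at least two rescaled intervals are required")
    if np.any((zs < 0) | (zs > 1)):
        raise ValueError("zs must lie in [0, 1]")
    z = np.sort(zs)
    k = np.arange(1, n + 1)
    d_plus = np.max(k / n - z)
    d_minus = np.max(z - (k - 1) / n)
    stat = float(max(d_plus, d_minus))
    band = KS_BAND_95 / np.sqrt(n)
    return KSResult(ks_stat=stat, band_halfwidth=float(band), passed=stat < band)


def ks_plot_data(zs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Paired quantile series for a KS plot.

    Returns ``(model_quantiles, empirical_quantiles)`` where the model
    quantiles are ``(k - 0.5)/n`` and the empirical quantiles the sorted
    ``zs``; a well-fit model tracks the 45-degree line.  The sup distance
    between the two series agrees with :func:`ks_test` to within ``0.5/n``.
    """
    zs = np.sort(np.asarray(zs, dtype=float))
    n = zs.size
    model_q = (np.arange(1, n + 1) - 0.5) / n
    return model_q, zs
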
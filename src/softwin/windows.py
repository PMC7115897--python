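"""Soft-window weight construction.

A *soft window* assigns each observation a weight in ``(0, 1]`` according to
its temporal distance from one or more *peaks* — the dates on which the
treatment (mutant) group was measured.  Each peak contributes a bump-shaped
curve built from a symmetric cumulative distribution function ``F``::

    c(t) = F(t; m - l_L, k_L) * (1 - F(t; m + l_R, k_R))

where ``m`` is the peak location, ``l`` the bandwidth (half-width, in time
units) and ``k`` the shape (edge sharpness, in 1/time units; large ``k``
approaches a hard rectangular window, small ``k`` a diffuse one).  The shape
parameter acts as a rate: the effective scale of ``F`` is ``1/k``.  Per-peak
curves are normalized to a maximum of 1 over the evaluated grid and merged
across peaks by inclusion–exclusion, so overlapping windows fuse into one
without the combined weight ever dropping below any constituent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateCurveError,
    EmptyInputError,
    InvalidParameterError,
    ShapeMismatchError,
)

__all__ = [
    "CDF_FAMILIES",
    "WEIGHT_FLOOR",
    "WindowSpec",
    "WeightVector",
    "cdf",
    "peak_weight",
    "normalize_peak",
    "combine",
    "generate_weights",
    "wgf",
    "hard_window",
    "count_hard",
    "sws",
    "merge_peak_days",
]

#: Continuous, symmetric location–scale families usable as the kernel CDF.
CDF_FAMILIES = {
    "logistic": stats.logistic,
    "gaussian": stats.norm,
    "cauchy": stats.cauchy,
    "laplace": stats.laplace,
}

#: Lower floor applied to generated weights so the (0, 1] contract holds in
#: floating point; distinct from the 1e-7 reporting cutoff for "included"
#: controls (see :func:`softwin.models.effective_control_count`).
WEIGHT_FLOOR = 1e-12


def cdf(x, mu: float, k: float, family: str = "logistic") -> np.ndarray:
    """Evaluate the kernel CDF ``F(x; mu, 1/k)``.

    ``k`` is a rate: the distribution's scale is ``1/k``, so ``k -> inf``
    turns ``F`` into a step function at ``mu``.

    Parameters
    ----------
    x : array_like
        Evaluation points (time units).
    mu : float
        Location; ``F(mu) = 1/2`` for every family and every ``k > 0``.
    k : float
        Strictly positive sharpness (1/time units).
    family : str
        One of ``logistic``, ``gaussian``, ``cauchy``, ``laplace``.
    """
    if not np.isfinite(k) or k <= 0:
        raise InvalidParameterError(f"shape parameter k must be > 0, got {k!r}")
    try:
        dist = CDF_FAMILIES[family]
    except KeyError:
        raise InvalidParameterError(
            f"unknown CDF family {family!r}; choose from {sorted(CDF_FAMILIES)}"
        ) from None
    return dist.cdf(k * (np.asarray(x, dtype=float) - mu))


@dataclass(frozen=True)
class WindowSpec:
    """Parameters of a multi-peak soft window.

    Attributes
    ----------
    peaks : ndarray, shape (p,)
        Strictly increasing peak times ``m_i``.
    bandwidths : ndarray, shape (p, 2)
        Nonnegative left/right half-widths ``(l_iL, l_iR)`` per peak.
    shapes : ndarray, shape (p, 2)
        Strictly positive left/right sharpness ``(k_iL, k_iR)`` per peak.
    family : str
        Kernel CDF family.
    """

    peaks: np.ndarray
    bandwidths: np.ndarray
    shapes: np.ndarray
    family: str = "logistic"

    def __post_init__(self):
        peaks = np.atleast_1d(np.asarray(self.peaks, dtype=float))
        bw = np.asarray(self.bandwidths, dtype=float).reshape(len(peaks), 2)
        sh = np.asarray(self.shapes, dtype=float).reshape(len(peaks), 2)
        if peaks.size < 1:
            raise InvalidParameterError("a window needs at least one peak")
        if peaks.size > 1 and not np.all(np.diff(peaks) > 0):
            raise InvalidParameterError("peaks must be strictly increasing")
        if np.any(bw < 0) or not np.all(np.isfinite(bw)):
            raise InvalidParameterError("bandwidths must be finite and >= 0")
        if np.any(sh <= 0) or not np.all(np.isfinite(sh)):
            raise InvalidParameterError("shapes must be finite and > 0")
        if self.family not in CDF_FAMILIES:
            raise InvalidParameterError(f"unknown CDF family {self.family!r}")
        object.__setattr__(self, "peaks", peaks)
        object.__setattr__(self, "bandwidths", bw)
        object.__setattr__(self, "shapes", sh)

    @property
    def p(self) -> int:
        """Number of peaks."""
        return len(self.peaks)

    @classmethod
    def symmetric(
        cls, peaks, l: float, k: float, family: str = "logistic"
    ) -> "WindowSpec":
        """Shared symmetric bandwidth ``l`` and shape ``k`` for all peaks."""
        peaks = np.atleast_1d(np.asarray(peaks, dtype=float))
        p = len(peaks)
        return cls(
            peaks=peaks,
            bandwidths=np.full((p, 2), float(l)),
            shapes=np.full((p, 2), float(k)),
            family=family,
        )


@dataclass(frozen=True)
class WeightVector:
    """Per-observation weights in ``(0, 1]`` aligned to observation times."""

    times: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if times.shape != weights.shape or times.ndim != 1:
            raise ShapeMismatchError(
                f"times {times.shape} and weights {weights.shape} must be 1-D and aligned"
            )
        if weights.size and (np.min(weights) <= 0 or np.max(weights) > 1 + 1e-12):
            raise InvalidParameterError("weights must lie in (0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "weights", weights)

    def __len__(self) -> int:
        return len(self.weights)


def peak_weight(
    times,
    m: float,
    l_left: float,
    l_right: float,
    k_left: float,
    k_right: float,
    family: str = "logistic",
) -> np.ndarray:
    """Raw (unnormalized) single-peak curve ``F(t; m-lL, kL)(1 - F(t; m+lR, kR))``."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise EmptyInputError("times must be nonempty")
    if l_left < 0 or l_right < 0:
        raise InvalidParameterError("bandwidths must be >= 0")
    rise = cdf(times, m - l_left, k_left, family)
    fall = 1.0 - cdf(times, m + l_right, k_right, family)
    return rise * fall


def normalize_peak(c) -> np.ndarray:
    """Scale a raw peak curve by its maximum so the grid maximum is exactly 1."""
    c = np.asarray(c, dtype=float)
    cmax = np.max(c) if c.size else 0.0
    if not cmax > 0:
        raise DegenerateCurveError("peak curve maximum must be strictly positive")
    return c / cmax


def combine(curves: Sequence[np.ndarray]) -> np.ndarray:
    """Merge normalized peak curves into one weight profile.

    Uses the closed form ``w = 1 - prod_i (1 - c*_i)``, algebraically equal
    to the alternating inclusion–exclusion sum over all subsets of peaks.
    A single curve is returned unchanged.
    """
    mat = np.atleast_2d(np.asarray(curves, dtype=float))
    if mat.ndim != 2:
        raise ShapeMismatchError("curves must be a (p, n) stack")
    if mat.shape[0] == 1:
        return mat[0].copy()
    if np.any(mat < 0) or np.any(mat > 1 + 1e-12):
        raise InvalidParameterError("normalized curves must lie in [0, 1]")
    return 1.0 - np.prod(1.0 - mat, axis=0)


def generate_weights(times, spec: WindowSpec) -> WeightVector:
    """Evaluate the weight-generating function for ``spec`` on ``times``.

    Each peak's curve is normalized over the observed grid before merging,
    and the result is floored at :data:`WEIGHT_FLOOR` so every weight is
    strictly positive.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise EmptyInputError("times must be nonempty")
    curves = [
        normalize_peak(
            peak_weight(
                times,
                spec.peaks[i],
                spec.bandwidths[i, 0],
                spec.bandwidths[i, 1],
                spec.shapes[i, 0],
                spec.shapes[i, 1],
                spec.family,
            )
        )
        for i in range(spec.p)
    ]
    w = combine(curves)
    w = np.clip(w, WEIGHT_FLOOR, 1.0)
    return WeightVector(times=times, weights=w)


def wgf(times, l: float, k: float, peaks, family: str = "logistic") -> WeightVector:
    """Symmetric weight-generating function ``WGF(t, l, k, m)``.

    Convenience wrapper building a shared-parameter :class:`WindowSpec`.
    """
    return generate_weights(times, WindowSpec.symmetric(peaks, l, k, family))


def hard_window(times, peaks, l: float) -> np.ndarray:
    """Indicator of ``t`` in the union of closed intervals ``[m_i - l, m_i + l]``."""
    if l < 0:
        raise InvalidParameterError("bandwidth l must be >= 0")
    times = np.asarray(times, dtype=float)
    peaks = np.atleast_1d(np.asarray(peaks, dtype=float))
    inside = np.zeros(times.shape, dtype=bool)
    for m in peaks:
        inside |= (times >= m - l) & (times <= m + l)
    return inside.astype(int)


def count_hard(times, peaks, l: float) -> int:
    """``T(l)``: number of observations inside the hard window of width ``l``."""
    return int(hard_window(times, peaks, l).sum())


def sws(w: WeightVector) -> float:
    """Sum-of-weights score: total weight mass, an effective sample size.

    Satisfies ``SWS(l, k) >= T(l)`` with equality in the hard limit
    ``k -> inf``.
    """
    return float(np.sum(w.weights))


def merge_peak_days(times, min_sep: float = 1.0) -> np.ndarray:
    """Collapse measurement times closer than ``min_sep`` into single peaks.

    Times are sorted and greedily clustered; each cluster contributes its
    mean as one peak.  Used to turn raw mutant measurement dates into the
    peak set of a :class:`WindowSpec`.
    """
    times = np.sort(np.asarray(times, dtype=float))
    if times.size == 0:
        raise EmptyInputError("times must be nonempty")
    clusters = [[times[0]]]
    for t in times[1:]:
        if t - clusters[-1][-1] < min_sep:
            clusters[-1].append(t)
        else:
            clusters.append([t])
    return np.array([float(np.mean(c)) for c in clusters])
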
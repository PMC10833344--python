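"""The B-factor <-> resolution trend.

Diffraction fades at wide angles at a rate set by the overall Debye-Waller
B factor (A^2).  Across deposited protein structures, the achievable
resolution d (A) and the B factor follow a smooth empirical trend that is
well captured by a quadratic,

    B(d) = a d^2 + b d + c,

fit over an interval of resolutions and growing unreliable at very low
resolution.  The simulator uses the forward map to pick a B factor for a
target resolution label, and inference inverts it to convert an inferred
B factor into a resolution.

The shipped default coefficients ``(a, b, c) = (4, 0, 12)`` are the
classic rule-of-thumb ``B = 4 d^2 + 12`` trend; they are configuration,
not code, and :func:`fit_trend` refits the quadratic from any
``(d, mean B)`` summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TrendError",
    "TrendRangeWarning",
    "TrendModel",
    "DEFAULT_TREND",
    "b_from_resolution",
    "resolution_from_b",
    "fit_trend",
]


class TrendError(ValueError):
    """Invalid trend model or out-of-domain query."""


class TrendRangeWarning(UserWarning):
    """Query outside the fitted/reliable range of the trend."""


@dataclass(frozen=True)
class TrendModel:
    """Quadratic B(d) trend with validity bounds.

    ``fit_range`` is the resolution interval (A) the coefficients were fit
    on; ``reliable_limit`` is the resolution beyond which the trend is
    considered unreliable (values are flagged, never clamped, unless
    ``clamp`` is requested explicitly by the caller).
    """

    a: float = 4.0
    b: float = 0.0
    c: float = 12.0
    fit_range: tuple[float, float] = (1.0, 4.5)
    reliable_limit: float = 5.5

    def __post_init__(self) -> None:
        d_lo, d_hi = self.fit_range
        if not (0 < d_lo < d_hi):
            raise TrendError("fit_range must satisfy 0 < d_lo < d_hi")
        # strictly increasing B(d) across the fitted interval, where the
        # trend is actually evaluated: derivative 2 a d + b > 0 on
        # [d_lo, d_hi] (a refit from noisy summaries may carry a small
        # negative linear term that is harmless there)
        tol = 1e-8 * max(1.0, abs(self.a), abs(self.b), abs(self.c))
        slope_lo = 2 * self.a * d_lo + self.b
        slope_hi = 2 * self.a * d_hi + self.b
        if min(slope_lo, slope_hi) <= tol:
            raise TrendError("trend must be strictly increasing on the fit range")

    def b_at(self, d):
        return self.a * np.square(d) + self.b * np.asarray(d, dtype=float) + self.c

    def is_reliable(self, d) -> np.ndarray | bool:
        """True where a resolution is within the trend's reliable range."""
        out = np.asarray(d, dtype=float) <= self.reliable_limit
        return bool(out) if out.ndim == 0 else out


DEFAULT_TREND = TrendModel()


def b_from_resolution(d, trend: TrendModel = DEFAULT_TREND):
    """B factor (A^2) implied by resolution ``d`` (A) under the trend.

    Warns (``TrendRangeWarning``) when ``d`` lies outside the fitted
    interval; raises :class:`TrendError` for non-positive ``d``.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise TrendError("resolution must be positive")
    d_lo, d_hi = trend.fit_range
    if np.any(d_arr < d_lo) or np.any(d_arr > d_hi):
        warnings.warn(f"resolution outside fitted interval {trend.fit_range}",
                      TrendRangeWarning, stacklevel=2)
    out = trend.b_at(d_arr)
    return float(out) if out.ndim == 0 else out


def resolution_from_b(B, trend: TrendModel = DEFAULT_TREND, clamp: bool = False):
    """Resolution d (A) implied by B factor (A^2): inverse of the trend.

    Returns the unique positive root of ``a d^2 + b d + (c - B) = 0``.
    Values beyond ``trend.reliable_limit`` are flagged with a
    ``TrendRangeWarning`` (and clamped to the limit only if ``clamp``).
    Raises :class:`TrendError` for B below the trend's minimum
    ``B(d -> 0+) = c``.
    """
    B_arr = np.asarray(B, dtype=float)
    if np.any(B_arr < trend.c):
        raise TrendError("B below the trend minimum: no positive resolution root")
    if trend.a != 0:
        disc = trend.b ** 2 - 4.0 * trend.a * (trend.c - B_arr)
        d = (-trend.b + np.sqrt(disc)) / (2.0 * trend.a)
    else:
        d = (B_arr - trend.c) / trend.b
    if np.any(d > trend.reliable_limit):
        warnings.warn(
            f"resolution beyond reliable limit {trend.reliable_limit} A "
            "(low confidence)", TrendRangeWarning, stacklevel=2)
        if clamp:
            d = np.minimum(d, trend.reliable_limit)
    d_lo, _ = trend.fit_range
    if np.any(d < d_lo):
        warnings.warn(f"resolution below fitted interval {trend.fit_range}",
                      TrendRangeWarning, stacklevel=2)
    return float(d) if d.ndim == 0 else d


def fit_trend(points: Iterable[Sequence[float]],
              fit_range: tuple[float, float] = (1.0, 4.5),
              reliable_limit: float = 5.5) -> TrendModel:
    """Least-squares quadratic fit of ``(d, mean B)`` points inside ``fit_range``.

    Points outside the interval are ignored.  Requires at least three
    usable points; the fitted trend must be strictly increasing on the
    interval or a :class:`TrendError` is raised.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise TrendError("points must be (d, B) pairs")
    d_lo, d_hi = fit_range
    keep = (pts[:, 0] >= d_lo) & (pts[:, 0] <= d_hi)
    pts = pts[keep]
    if pts.shape[0] < 3:
        raise TrendError("need at least 3 points inside the fit range")
    a, b, c = np.polyfit(pts[:, 0], pts[:, 1], deg=2)
    try:
        return TrendModel(a=float(a), b=float(b), c=float(c),
                          fit_range=fit_range, reliable_limit=reliable_limit)
    except TrendError as err:
        raise TrendError(f"fitted trend is invalid: {err}") from err


def load_trend_table(path) -> list[tuple[float, float]]:
    """Read a two-column plain-text ``(d, B)`` table (whitespace/comma separated)."""
    pts = np.loadtxt(path, delimiter=None, comments="#", ndmin=2)
    if pts.shape[1] < 2:
        pts = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    return [(float(r[0]), float(r[1])) for r in pts]
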
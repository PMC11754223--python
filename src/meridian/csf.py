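"""Contrast sensitivity function summaries: parabola fit, AULCSF, cutoff.

The CSF is modelled as a second-degree polynomial in x = log10(spatial
frequency in cpd): logCS(x) = a*x**2 + b*x + c.  Two summary measures
follow: the area under the log CSF (AULCSF), integrating the fitted
curve (clipped at logCS = 0) between configurable frequency bounds, and
the high-frequency cutoff, the frequency at which fitted sensitivity
falls to 1 (logCS = 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CSFFit",
    "fit_parabola",
    "aulcsf",
    "sf_cutoff",
    "fit_csf",
]

DEFAULT_DOMAIN = (0.6, 12.0)


@dataclass(frozen=True)
class CSFFit:
    """Fitted quadratic with its derived summaries.

    ``cutoff`` is NaN when the fitted curve has no high-frequency zero
    crossing (no real root, or a non-physiological upward parabola).
    """

    a: float
    b: float
    c: float
    aulcsf: float
    cutoff: float  # cpd; NaN when undefined
    domain_lo: float
    domain_hi: float

    def log_cs(self, sf) -> np.ndarray:
        x = np.log10(np.asarray(sf, dtype=float))
        return self.a * x * x + self.b * x + self.c


def fit_parabola(
    sfs: Sequence[float], log_cs: Sequence[float]
) -> Tuple[float, float, float]:
    """Ordinary least-squares quadratic in x = log10(sf).

    Requires at least three distinct spatial frequencies.
    """
    sfs = np.asarray(sfs, dtype=float)
    y = np.asarray(log_cs, dtype=float)
    if sfs.shape != y.shape or sfs.ndim != 1:
        raise ValueError("sfs and log_cs must be 1-D sequences of equal length")
    if np.any(sfs <= 0):
        raise ValueError("spatial frequencies must be positive")
    if len(np.unique(sfs)) < 3:
        raise ValueError(
            f"need >= 3 distinct spatial frequencies, got {len(np.unique(sfs))}"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("log_cs contains non-finite values")
    x = np.log10(sfs)
    a, b, c = np.polyfit(x, y, 2)
    return float(a), float(b), float(c)


def _antiderivative(a: float, b: float, c: float, x: float) -> float:
    return a * x**3 / 3.0 + b * x**2 / 2.0 + c * x


def _real_roots(a: float, b: float, c: float) -> list:
    """Real roots of a*x**2 + b*x + c, ascending (handles a == 0)."""
    if a == 0.0:
        if b == 0.0:
            return []
        return [-c / b]
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return []
    s = math.sqrt(disc)
    roots = sorted([(-b - s) / (2.0 * a), (-b + s) / (2.0 * a)])
    return roots


def aulcsf(
    a: float,
    b: float,
    c: float,
    domain_lo: float = DEFAULT_DOMAIN[0],
    domain_hi: float = DEFAULT_DOMAIN[1],
    clip_negative: bool = True,
) -> float:
    """Area under the fitted log CSF over [domain_lo, domain_hi] (cpd).

    Integration is on the log10-frequency axis, in closed form from the
    quadratic antiderivative.  With ``clip_negative`` (default) the curve
    is clipped at logCS = 0, splitting the integral at its real roots, so
    regions of sub-unity sensitivity contribute nothing.
    """
    if not (0 < domain_lo < domain_hi):
        raise ValueError(
            f"need 0 < domain_lo < domain_hi, got ({domain_lo}, {domain_hi})"
        )
    lo = math.log10(domain_lo)
    hi = math.log10(domain_hi)
    if not clip_negative:
        return _antiderivative(a, b, c, hi) - _antiderivative(a, b, c, lo)
    # Breakpoints where the curve may change sign.
    points = [lo] + [r for r in _real_roots(a, b, c) if lo < r < hi] + [hi]
    area = 0.0
    for left, right in zip(points[:-1], points[1:]):
        mid = 0.5 * (left + right)
        if a * mid * mid + b * mid + c > 0:
            area += _antiderivative(a, b, c, right) - _antiderivative(a, b, c, left)
    return max(area, 0.0)


def sf_cutoff(a: float, b: float, c: float) -> float:
    """High-frequency cutoff: 10**x at the larger real root of the quadratic.

    Returns NaN (a missing value, not an error) when the curve never
    reaches logCS = 0 on the high-frequency side: no real root, a
    downward parabola whose vertex is below zero, or a curve that grows
    without bound (a > 0, or a == 0 with b >= 0), the latter flagged with
    a warning as a non-physiological fit.
    """
    if a > 0 or (a == 0 and b >= 0):
        warnings.warn(
            "non-physiological CSF fit (curve does not fall at high "
            "frequencies); cutoff undefined",
            stacklevel=2,
        )
        return math.nan
    roots = _real_roots(a, b, c)
    if not roots:
        return math.nan
    return 10.0 ** roots[-1]


def fit_csf(
    sfs: Sequence[float],
    log_cs: Sequence[float],
    domain_lo: float = DEFAULT_DOMAIN[0],
    domain_hi: float = DEFAULT_DOMAIN[1],
    clip_negative: bool = True,
) -> CSFFit:
    """Fit the parabola and derive AULCSF and cutoff in one call."""
    a, b, c = fit_parabola(sfs, log_cs)
    return CSFFit(
        a=a,
        b=b,
        c=c,
        aulcsf=aulcsf(a, b, c, domain_lo, domain_hi, clip_negative),
        cutoff=sf_cutoff(a, b, c),
        domain_lo=domain_lo,
        domain_hi=domain_hi,
    )
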
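"""Standard-curve calibration and plaque-assay titration.

ELISA/MSD plates are calibrated with a four-parameter logistic (4PL) curve,
luminescence ATP assays with a hyperbolic (one-site saturation) curve.
Unknowns are back-calculated by analytic inversion; responses outside the
fitted range are flagged and substituted (below the curve: lower detection
limit / sqrt(2); above: the upper limit).  Viral stocks are titered as
PFU/mL = mean countable plaques x dilution factor / infection volume, with
the countable window fixed at 5-50 isolated plaques per well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

__all__ = [
    "Measurement",
    "FourPLCurve",
    "HyperbolicCurve",
    "invert_curve",
    "substitute_out_of_range",
    "plaque_titer",
    "TiterError",
    "CurveFitError",
]

COUNTABLE_WINDOW = (5, 50)


class TiterError(ValueError):
    """No well fell inside the countable plaque window."""


class CurveFitError(RuntimeError):
    """Standard-curve fitting failed to converge from any start."""


@dataclass(frozen=True)
class Measurement:
    """One back-calculated unknown with its range flag."""

    response: float
    dilution: float = 1.0
    analyte: str = ""
    concentration: Optional[float] = None
    flag: str = "in_range"  # in_range | below_fit | above_fit


def _check_standards(conc: np.ndarray, resp: np.ndarray, min_points: int) -> None:
    if conc.shape != resp.shape or conc.ndim != 1:
        raise ValueError("concentrations and responses must be 1-D, equal length")
    if conc.size < min_points:
        raise ValueError(f"need at least {min_points} standards, got {conc.size}")
    if np.any(conc <= 0):
        raise ValueError("standard concentrations must be positive")
    if not (np.all(np.isfinite(conc)) and np.all(np.isfinite(resp))):
        raise ValueError("non-finite standards")
    diffs = np.diff(resp[np.argsort(conc)])
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("standard responses are not monotone in concentration")


class FourPLCurve(BaseEstimator):
    """Four-parameter logistic calibration: y = d + (a - d) / (1 + (x/c)^b).

    ``a`` is the response at zero concentration, ``d`` the response at
    infinite concentration, ``c`` the inflection concentration and ``b`` the
    slope.  Fitted by least squares (optionally 1/y^2 weighted) from the
    standard initialization (a, d from the extreme responses, c at the
    geometric mid-concentration, b = 1) plus three perturbed starts, keeping
    the best residual sum of squares.

    Fitted attributes: ``a_``, ``b_``, ``c_``, ``d_``, ``rss_``,
    ``response_range_`` (responses at the lowest/highest standard).
    """

    model = "4PL"

    def __init__(self, weighting: Optional[str] = None, min_decades: float = 2.0):
        self.weighting = weighting
        self.min_decades = min_decades

    def fit(self, conc: Sequence[float], resp: Sequence[float]) -> "FourPLCurve":
        x = np.asarray(conc, dtype=float)
        y = np.asarray(resp, dtype=float)
        _check_standards(x, y, min_points=5)
        if math.log10(x.max() / x.min()) < self.min_decades:
            raise ValueError(
                f"standards span fewer than {self.min_decades} decades"
            )
        if self.weighting not in (None, "1/y2"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        w = 1.0 / np.maximum(np.abs(y), 1e-12) if self.weighting == "1/y2" else None

        order = np.argsort(x)
        a0 = y[order][0]
        d0 = y[order][-1]
        c0 = math.sqrt(x.min() * x.max())
        starts = [
            (a0, 1.0, c0, d0),
            (a0, 0.5, c0 * 0.3, d0),
            (a0, 2.0, c0 * 3.0, d0),
            (a0, 1.5, c0, d0),
        ]

        def resid(p):
            a, b, c, d = p
            r = d + (a - d) / (1.0 + (x / c) ** b) - y
            return r * w if w is not None else r

        best = None
        for p0 in starts:
            try:
                sol = least_squares(
                    resid,
                    p0,
                    bounds=([-np.inf, 1e-6, 1e-12, -np.inf], np.inf),
                    max_nfev=5000,
                )
            except Exception:
                continue
            if not sol.success:
                continue
            rss = float(np.sum((self._eval(sol.x, x) - y) ** 2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
        if best is None:
            raise CurveFitError("4PL fit failed from all starts")
        self.rss_, (self.a_, self.b_, self.c_, self.d_) = best[0], tuple(best[1])
        lo_conc, hi_conc = x.min(), x.max()
        self.conc_range_ = (float(lo_conc), float(hi_conc))
        self.response_range_ = (
            float(self.predict([lo_conc])[0]),
            float(self.predict([hi_conc])[0]),
        )
        return self

    @staticmethod
    def _eval(p, x):
        a, b, c, d = p
        return d + (a - d) / (1.0 + (np.asarray(x, dtype=float) / c) ** b)

    def predict(self, conc: Sequence[float]) -> np.ndarray:
        """Fitted response at the given concentrations."""
        return self._eval((self.a_, self.b_, self.c_, self.d_), conc)

    def inverse(self, response: float) -> float:
        """Analytic inversion x = c ((a - d)/(y - d) - 1)^(1/b)."""
        a, b, c, d = self.a_, self.b_, self.c_, self.d_
        if response == d or response == a:
            raise ValueError("response at a curve asymptote cannot be inverted")
        ratio = (a - d) / (response - d) - 1.0
        if ratio <= 0:
            raise ValueError("response outside the invertible branch")
        return float(c * ratio ** (1.0 / b))


class HyperbolicCurve(BaseEstimator):
    """One-site saturation calibration: y = Bmax x / (Kd + x).

    Fitted attributes: ``Bmax_``, ``Kd_``, ``rss_``, ``response_range_``.
    """

    model = "hyperbolic"

    def __init__(self, min_decades: float = 0.0):
        self.min_decades = min_decades

    def fit(self, conc: Sequence[float], resp: Sequence[float]) -> "HyperbolicCurve":
        x = np.asarray(conc, dtype=float)
        y = np.asarray(resp, dtype=float)
        _check_standards(x, y, min_points=3)

        bmax0 = float(y.max()) * 1.2
        half = 0.5 * y.max()
        kd0 = float(x[np.argmin(np.abs(y - half))])

        def resid(p):
            bmax, kd = p
            return bmax * x / (kd + x) - y

        sol = least_squares(resid, (bmax0, max(kd0, 1e-9)),
                            bounds=([1e-12, 1e-12], np.inf), max_nfev=5000)
        if not sol.success:
            raise CurveFitError("hyperbolic fit failed")
        self.Bmax_, self.Kd_ = (float(v) for v in sol.x)
        self.rss_ = float(np.sum(resid(sol.x) ** 2))
        self.conc_range_ = (float(x.min()), float(x.max()))
        self.response_range_ = (
            float(self.predict([x.min()])[0]),
            float(self.predict([x.max()])[0]),
        )
        return self

    def predict(self, conc: Sequence[float]) -> np.ndarray:
        x = np.asarray(conc, dtype=float)
        return self.Bmax_ * x / (self.Kd_ + x)

    def inverse(self, response: float) -> float:
        """Analytic inversion x = Kd y / (Bmax - y)."""
        if response >= self.Bmax_:
            raise ValueError("response at or above the saturation asymptote")
        if response <= 0:
            raise ValueError("response must be positive to invert")
        return float(self.Kd_ * response / (self.Bmax_ - response))


def invert_curve(curve, response: float, dilution: float = 1.0,
                 analyte: str = "") -> Measurement:
    """Back-calculate one unknown, flagging out-of-fit responses.

    In-range responses are inverted analytically and multiplied by the
    dilution; responses beyond the response at the lowest standard are
    flagged ``below_fit`` and beyond the highest standard ``above_fit``,
    without inversion.
    """
    if dilution <= 0:
        raise ValueError("dilution must be positive")
    r_lo, r_hi = curve.response_range_  # at lowest / highest standard conc
    increasing = r_hi >= r_lo
    if increasing:
        if response < r_lo:
            return Measurement(response, dilution, analyte, None, "below_fit")
        if response > r_hi:
            return Measurement(response, dilution, analyte, None, "above_fit")
    else:
        if response > r_lo:
            return Measurement(response, dilution, analyte, None, "below_fit")
        if response < r_hi:
            return Measurement(response, dilution, analyte, None, "above_fit")
    conc = curve.inverse(response) * dilution
    return Measurement(response, dilution, analyte, conc, "in_range")


def substitute_out_of_range(
    measurement: Measurement, lower_limit: float, upper_limit: float
) -> Measurement:
    """Apply the detection-limit substitution rule.

    Below the fit curve: lower_limit / sqrt(2); above: the upper limit;
    in-range measurements pass through unchanged.  Idempotent.
    """
    if not (0 < lower_limit < upper_limit):
        raise ValueError("need 0 < lower_limit < upper_limit")
    if measurement.flag == "below_fit":
        return replace(measurement, concentration=lower_limit / math.sqrt(2.0))
    if measurement.flag == "above_fit":
        return replace(measurement, concentration=float(upper_limit))
    return measurement


def plaque_titer(
    plaque_counts: Sequence[int],
    dilution_factor: float,
    infection_volume_ml: float,
    countable: Tuple[int, int] = COUNTABLE_WINDOW,
) -> float:
    """Viral titer in PFU/mL from countable plaque wells.

    Wells outside the countable window are excluded; the titer is the mean
    retained count times the dilution factor over the infection volume.
    """
    if infection_volume_ml <= 0:
        raise ValueError("infection volume must be positive")
    if dilution_factor <= 0:
        raise ValueError("dilution factor must be positive")
    lo, hi = countable
    counts = [int(c) for c in plaque_counts]
    retained = [c for c in counts if lo <= c <= hi]
    if not retained:
        raise TiterError(
            f"no well in the countable window [{lo}, {hi}]; counts were {counts}"
        )
    return float(np.mean(retained)) * dilution_factor / infection_volume_ml
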
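"""Concentration-dependent exchange bounds: acetate-excretion feedback.

Acetate excretion by E. coli slows as external acetate accumulates
(thermodynamic feedback through the Pta-AckA pathway). The bound used here
is logarithmic in the external concentration c:

    Ex(c) = -ln(c / c_s) / ln(c_s / V_max),   clamped to [0, V_max]

with V_max the maximal excretion rate (mmol gCDW^-1 h^-1) and c_s the
concentration (mM) at which excretion saturates to zero. Two identities pin
the shape: Ex(c_s) = 0 and Ex(V_max) = 1 for any valid parameter pair.

The module also fits candidate feedback families (linear, polynomial of
degree 2-5, logarithmic) to (concentration, rate) data by least squares, the
way the logarithmic form is selected from excretion-rate measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["FeedbackParams", "excretion_bound", "fit_feedback_curve", "FeedbackFit"]


@dataclass(frozen=True)
class FeedbackParams:
    """Parameters of the logarithmic excretion bound for one compound."""

    v_max: float = 2.0          # maximal excretion rate, mmol gCDW^-1 h^-1
    c_sat: float = 13.0         # external concentration at saturation, mM
    compound: str = "ac"

    def __post_init__(self) -> None:
        if self.v_max <= 0:
            raise ValueError(f"V_max must be positive, got {self.v_max}")
        if self.c_sat <= self.v_max:
            raise ValueError(
                f"c_sat ({self.c_sat}) must exceed V_max ({self.v_max}) for the "
                "logarithm's denominator ln(c_sat/V_max) to be positive"
            )


def excretion_bound(c: float, params: FeedbackParams) -> float:
    """Upper bound on excretion at external concentration *c* (mM).

    Clamped to [0, V_max]: super-saturation (c >= c_sat) blocks excretion
    but never forces uptake, and very low concentrations (where the raw
    logarithm exceeds V_max) saturate at the maximal rate. Ex(0) = V_max.
    """
    if c < 0:
        raise ValueError(f"concentration must be non-negative, got {c}")
    if c == 0:
        return params.v_max
    raw = -math.log(c / params.c_sat) / math.log(params.c_sat / params.v_max)
    return min(max(raw, 0.0), params.v_max)


@dataclass
class FeedbackFit:
    """Least-squares fit of one candidate feedback family."""

    family: str
    coefficients: np.ndarray       # polynomial coefficients, highest degree first
    rss: float                     # residual sum of squares
    params: FeedbackParams | None  # populated for family="log"

    def predict(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        if self.family == "log":
            return np.polyval(self.coefficients, np.log(c))
        return np.polyval(self.coefficients, c)


_FAMILY_DOF = {"linear": 2, "poly2": 3, "poly3": 4, "poly4": 5, "poly5": 6, "log": 2}


def fit_feedback_curve(
    concentrations: np.ndarray, rates: np.ndarray, family: str
) -> FeedbackFit:
    """Fit a feedback family to (concentration, rate) points.

    Families: ``linear``, ``poly2`` ... ``poly5`` (ordinary polynomial least
    squares in c) and ``log`` (least squares in ln c; its coefficients are
    re-expressed as the (V_max, c_sat) of the logarithmic bound).
    """
    if family not in _FAMILY_DOF:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(_FAMILY_DOF)}")
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(rates, dtype=float)
    if c.shape != r.shape or c.ndim != 1:
        raise ValueError("concentrations and rates must be 1-D arrays of equal length")
    need = _FAMILY_DOF[family]
    if len(c) < max(need, 3):
        raise ValueError(
            f"family {family!r} needs at least {max(need, 3)} points, got {len(c)}"
        )

    if family == "log":
        if np.any(c <= 0):
            raise ValueError("log family requires strictly positive concentrations")
        x = np.log(c)
        coeffs = np.polyfit(x, r, 1)
        b, a = float(coeffs[0]), float(coeffs[1])  # r = b*ln(c) + a
        params = None
        if b < 0:
            # invert r = -ln(c/c_s)/ln(c_s/V) = -(1/ln(c_s/V)) ln c + ln(c_s)/ln(c_s/V)
            c_sat = math.exp(-a / b)
            v_max = c_sat * math.exp(1.0 / b)
            try:
                params = FeedbackParams(v_max=v_max, c_sat=c_sat)
            except ValueError:
                params = None  # fit fell outside the valid parameter region
        fit = FeedbackFit(family=family, coefficients=coeffs, rss=0.0, params=params)
    else:
        degree = 1 if family == "linear" else int(family[-1])
        coeffs = np.polyfit(c, r, degree)
        fit = FeedbackFit(family=family, coefficients=coeffs, rss=0.0, params=None)
    resid = r - fit.predict(c)
    fit.rss = float(np.dot(resid, resid))
    return fit
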
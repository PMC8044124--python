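"""Dose–response curve fitting, ICx inversion, fold-change resistance, and
combination-index synergy scoring.

The viability model is the four-parameter logistic (4PL)

    f(d) = bottom + (top - bottom) / (1 + (d / m)^h)

with ``top`` the zero-dose asymptote, ``bottom`` the infinite-dose asymptote,
``m`` the midpoint concentration (f(m) = (top+bottom)/2) and ``h > 0`` the
Hill slope.  ICx is the dose at which modeled inhibition relative to the
zero-dose asymptote reaches x, i.e. f(dose) = (1 - x)·top; for a full-range
curve (top=1, bottom=0) IC50 equals m.  The combination index follows the
mutually exclusive Chou–Talalay form CI = d_a/Dx_a + d_b/Dx_b at a common
effect level: CI < 1 synergy, = 1 additivity, > 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DegenerateDataError, FitError, InsufficientDataError

CI_ADDITIVITY_TOL = 1e-6

SYNERGY = "synergy"
ADDITIVE = "additive"
ANTAGONISM = "antagonism"

#: Deterministic multi-start grid over Hill slopes; midpoint starts span the
#: observed dose range geometrically.
HILL_STARTS = (0.5, 1.0, 2.0, 4.0)
N_MIDPOINT_STARTS = 4


def _logistic4(dose, top, bottom, log_m, h):
    return bottom + (top - bottom) / (1.0 + np.exp(h * (np.log(dose) - log_m)))


class FourParamLogistic(RegressorMixin, BaseEstimator):
    """Sklearn-style 4PL dose–response regressor.

    Parameters
    ----------
    constrain : bool, default False
        If True fit the two-parameter variant with top fixed at 1 and bottom
        at 0 (responses already normalized to the untreated control).
    max_nfev : int
        Function-evaluation budget per start.

    Attributes (after fit)
    ----------------------
    top_, bottom_, hill_, midpoint_ : float
        Fitted asymptotes, Hill slope, and midpoint concentration.
    residual_norm_ : float
        Euclidean norm of residuals at the solution.
    converged_ : bool
        True if at least one start converged; fit raises otherwise, so this
        is True on any fitted instance.
    """

    def __init__(self, constrain: bool = False, max_nfev: int = 10000):
        self.constrain = constrain
        self.max_nfev = max_nfev

    def fit(self, X, y):
        doses = np.asarray(X, dtype=float).ravel()
        responses = np.asarray(y, dtype=float).ravel()
        if doses.shape != responses.shape:
            raise ValueError("doses and responses must have equal length")
        if not np.all(np.isfinite(doses)) or not np.all(np.isfinite(responses)):
            raise ValueError("doses and responses must be finite")
        if np.any(doses <= 0):
            raise ValueError("doses must be strictly positive")
        if np.unique(doses).size < 4:
            raise InsufficientDataError("need >= 4 distinct positive doses")
        if np.ptp(responses) == 0.0:
            raise DegenerateDataError(
                "responses are constant; curve parameters are unidentifiable"
            )

        log_lo, log_hi = np.log(doses.min()), np.log(doses.max())
        m_starts = np.linspace(log_lo, log_hi, N_MIDPOINT_STARTS)
        top0 = float(responses.max())
        bot0 = float(responses.min())

        best = None
        diagnostics = []
        for h0 in HILL_STARTS:
            for lm0 in m_starts:
                try:
                    if self.constrain:
                        popt, _ = curve_fit(
                            lambda d, log_m, h: _logistic4(d, 1.0, 0.0, log_m, h),
                            doses,
                            responses,
                            p0=[lm0, h0],
                            bounds=([log_lo - 15.0, 1e-3], [log_hi + 15.0, 50.0]),
                            max_nfev=self.max_nfev,
                        )
                        params = (1.0, 0.0, popt[0], popt[1])
                    else:
                        popt, _ = curve_fit(
                            _logistic4,
                            doses,
                            responses,
                            p0=[top0, bot0, lm0, h0],
                            bounds=(
                                [-np.inf, -np.inf, log_lo - 15.0, 1e-3],
                                [np.inf, np.inf, log_hi + 15.0, 50.0],
                            ),
                            max_nfev=self.max_nfev,
                        )
                        params = tuple(popt)
                except (RuntimeError, ValueError) as exc:  # start failed
                    diagnostics.append(f"(h0={h0}, log_m0={lm0:.3g}): {exc}")
                    continue
                resid = responses - _logistic4(doses, *params)
                sse = float(resid @ resid)
                if best is None or sse < best[0]:
                    best = (sse, params)
        if best is None:
            raise FitError(
                "4PL fit failed from every start; diagnostics: "
                + "; ".join(diagnostics[:4])
            )
        sse, (top, bottom, log_m, h) = best
        self.top_ = float(top)
        self.bottom_ = float(bottom)
        self.midpoint_ = float(np.exp(log_m))
        self.hill_ = float(h)
        self.residual_norm_ = float(np.sqrt(sse))
        self.converged_ = True
        self.doses_ = doses
        self.responses_ = responses
        return self

    def predict(self, X):
        self._check_fitted()
        doses = np.asarray(X, dtype=float).ravel()
        return _logistic4(doses, self.top_, self.bottom_, np.log(self.midpoint_), self.hill_)

    def inhibition(self, X):
        """Modeled inhibition relative to the zero-dose asymptote: 1 - f(d)/top."""
        self._check_fitted()
        return 1.0 - self.predict(X) / self.top_

    def ic(self, x: float) -> float:
        """Dose at which modeled inhibition reaches fraction ``x`` (closed form).

        Requires (1-x)·top to lie strictly between the asymptotes.
        """
        self._check_fitted()
        if not 0.0 < x < 1.0:
            raise ValueError(f"inhibition fraction must lie in (0, 1), got {x}")
        target = (1.0 - x) * self.top_
        lo, hi = sorted((self.bottom_, self.top_))
        if not lo < target < hi:
            raise ValueError(
                f"inhibition {x:.3g} is outside the achievable range of this curve "
                f"(asymptotes {self.bottom_:.4g}..{self.top_:.4g})"
            )
        ratio = (self.top_ - target) / (target - self.bottom_)
        return float(self.midpoint_ * ratio ** (1.0 / self.hill_))

    def _check_fitted(self):
        if not hasattr(self, "midpoint_"):
            raise RuntimeError("FourParamLogistic is not fitted")


# DoseResponseFit is the fitted estimator itself.
DoseResponseFit = FourParamLogistic


def fit_four_param_logistic(doses, responses, constrain: bool = False) -> FourParamLogistic:
    """Least-squares 4PL fit with deterministic multi-start initialization."""
    return FourParamLogistic(constrain=constrain).fit(doses, responses)


def inhibitory_concentration(fit: FourParamLogistic, x: float) -> float:
    """ICx: dose producing inhibition fraction x under the fitted curve."""
    return fit.ic(x)


def resistance_fold_change(ic50_test: float, ic50_reference: float) -> float:
    """IC50 fold change of a test line relative to its parental reference."""
    if ic50_test <= 0 or ic50_reference <= 0:
        raise ValueError("IC50 values must be strictly positive")
    return ic50_test / ic50_reference


@dataclass(frozen=True)
class CombinationRecord:
    """A combination dose pair scored against single-agent equi-effective doses."""

    dose_a: float
    dose_b: float
    dx_a: float
    dx_b: float
    ci: float
    verdict: str


def combination_index(
    dose_a: float, dose_b: float, dx_a: float, dx_b: float
) -> CombinationRecord:
    """Chou–Talalay combination index at a common effect level.

    ``dx_a`` / ``dx_b`` are the single-agent doses producing the same effect
    as the combination (dose_a, dose_b).  CI = dose_a/Dx_a + dose_b/Dx_b;
    synergy below 1, additive at 1 (tolerance 1e-6), antagonism above.
    """
    for name, v in (("dose_a", dose_a), ("dose_b", dose_b), ("dx_a", dx_a), ("dx_b", dx_b)):
        if not v > 0:
            raise ValueError(f"{name} must be strictly positive, got {v}")
    ci = dose_a / dx_a + dose_b / dx_b
    if abs(ci - 1.0) <= CI_ADDITIVITY_TOL:
        verdict = ADDITIVE
    elif ci < 1.0:
        verdict = SYNERGY
    else:
        verdict = ANTAGONISM
    return CombinationRecord(
        dose_a=dose_a, dose_b=dose_b, dx_a=dx_a, dx_b=dx_b, ci=float(ci), verdict=verdict
    )


def combination_index_from_fits(
    fit_a: FourParamLogistic,
    fit_b: FourParamLogistic,
    dose_a: float,
    dose_b: float,
    effect: float,
) -> CombinationRecord:
    """CI for a combination dose pair using fitted single-agent curves.

    ``effect`` is the common inhibition level at which the combination was
    observed; the single-agent equi-effective doses come from each fit's ICx.
    """
    return combination_index(dose_a, dose_b, fit_a.ic(effect), fit_b.ic(effect))
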
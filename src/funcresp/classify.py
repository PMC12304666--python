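"""Functional-response type classification via polynomial logistic regression.

The shape of the proportion-consumed vs. density curve distinguishes a
type II response (proportion declines monotonically with density) from a
type III response (proportion initially rises).  The proportion is modelled
as a grouped-binomial logistic polynomial in initial density N0,

    Na/N0 ~ logistic(P0 + P1*N0 + P2*N0^2 + P3*N0^3),

fit by maximum likelihood with each replicate entering as an independent
(na out of n0) binomial observation.  Starting from the cubic, the highest-
order term is removed whenever its Wald chi-square p-value exceeds alpha,
preserving the polynomial hierarchy, until the highest retained term is
significant.  The sign of the linear coefficient then makes the call:
significantly negative => type II, significantly positive => type III,
otherwise inconclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .datamodel import DesignError, PredationTrial

__all__ = ["TermStats", "LogisticFit", "fit_polynomial_logistic", "fit_polynomial_logistic_arrays", "classify_response"]

TERM_NAMES = ("intercept", "linear", "quadratic", "cubic")


@dataclass(frozen=True)
class TermStats:
    """One polynomial coefficient with its Wald test."""

    estimate: float
    se: float
    chi2: float
    p: float


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logistic polynomial and the response-type call it supports."""

    instar: int
    treatment: str
    terms: Mapping[str, TermStats]  # retained terms only, always including the intercept
    retained_terms: tuple[str, ...]
    response_type: str  # "II", "III" or "inconclusive"
    n_trials: int
    converged: bool
    overdispersion: float  # Pearson chi2 / df_resid, reported but not corrected
    alpha: float = 0.05
    diagnostic: str = ""

    @property
    def term_order(self) -> tuple[str, ...]:
        """All candidate terms up to the entry degree, for table layout."""
        return TERM_NAMES[: max(3, len(self.retained_terms)) + 1][:4]

    def predict_proportion(self, n0) -> np.ndarray:
        """Fitted proportion consumed at density n0 (logistic of the polynomial)."""
        n0 = np.asarray(n0, dtype=float)
        eta = np.zeros_like(n0)
        for k, name in enumerate(TERM_NAMES):
            if name in self.terms:
                eta += self.terms[name].estimate * n0**k
        return 1.0 / (1.0 + np.exp(-eta))


def _design_matrix(n0: np.ndarray, degree: int) -> np.ndarray:
    return np.column_stack([n0**k for k in range(degree + 1)])


def _glm_fit(n0: np.ndarray, na: np.ndarray, degree: int):
    endog = np.column_stack([na, n0 - na])
    model = sm.GLM(endog, _design_matrix(n0, degree), family=sm.families.Binomial())
    with warnings.catch_warnings():
        # separation is detected downstream via extreme-coefficient checks
        warnings.simplefilter("ignore")
        return model.fit(maxiter=200)


def _term_stats(res, degree: int) -> dict[str, TermStats]:
    out = {}
    for k in range(degree + 1):
        est = float(res.params[k])
        se = float(res.bse[k])
        chi2 = (est / se) ** 2 if se > 0 else np.inf
        p = float(sps.chi2.sf(chi2, 1))
        out[TERM_NAMES[k]] = TermStats(estimate=est, se=se, chi2=float(chi2), p=p)
    return out


def fit_polynomial_logistic_arrays(
    n0,
    na,
    *,
    instar: int = 0,
    treatment: str = "",
    max_degree: int = 3,
    alpha: float = 0.05,
) -> LogisticFit:
    """Fit the logistic polynomial on raw density/consumption arrays.

    ``na`` may be non-integer (e.g. model expectations used as noiseless
    pseudo-data); each observation enters as (na, n0 - na) grouped-binomial.
    See :func:`fit_polynomial_logistic` for the trial-level interface.
    """
    n0 = np.asarray(n0, dtype=float)
    na = np.asarray(na, dtype=float)
    if not 1 <= max_degree <= 3:
        raise ValueError(f"max_degree must be in 1..3, got {max_degree}")
    if len(np.unique(n0)) < 2:
        raise DesignError("at least 2 distinct prey densities are required")
    if np.any((na < 0) | (na > n0)):
        raise ValueError("na must lie in [0, n0]")

    if np.all(na == 0):
        return LogisticFit(
            instar=instar, treatment=treatment, terms={}, retained_terms=("intercept",),
            response_type="inconclusive", n_trials=len(n0), converged=False,
            overdispersion=np.nan, alpha=alpha,
            diagnostic="degenerate: zero consumption everywhere",
        )

    # cap the entry degree at what the number of distinct densities supports
    degree = min(max_degree, len(np.unique(n0)) - 1)
    res, stats_by_term = None, None
    diagnostic = ""
    while degree >= 1:
        try:
            res = _glm_fit(n0, na, degree)
        except Exception as e:  # separation / singular design
            diagnostic = f"degree-{degree} fit failed ({e.__class__.__name__}); reduced"
            degree -= 1
            continue
        stats_by_term = _term_stats(res, degree)
        top = TERM_NAMES[degree]
        if degree > 1 and stats_by_term[top].p > alpha:
            degree -= 1  # backward elimination, hierarchy preserved
            continue
        break
    if res is None or stats_by_term is None:
        return LogisticFit(
            instar=instar, treatment=treatment, terms={}, retained_terms=("intercept",),
            response_type="inconclusive", n_trials=len(n0), converged=False,
            overdispersion=np.nan, alpha=alpha, diagnostic=diagnostic or "no model could be fit",
        )

    converged = bool(res.converged) and np.all(np.isfinite(res.params)) and np.all(np.isfinite(res.bse))
    if np.any(np.abs(res.params) > 1e4):
        converged = False
        diagnostic = diagnostic or "suspect separation: extreme coefficients"
    overdisp = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else np.nan

    retained = TERM_NAMES[: degree + 1]
    fit = LogisticFit(
        instar=instar, treatment=treatment, terms=stats_by_term, retained_terms=retained,
        response_type="pending", n_trials=len(n0), converged=converged,
        overdispersion=overdisp, alpha=alpha, diagnostic=diagnostic,
    )
    object.__setattr__(fit, "response_type", classify_response(fit, alpha))
    return fit


def fit_polynomial_logistic(
    trials: Iterable[PredationTrial],
    max_degree: int = 3,
    alpha: float = 0.05,
) -> LogisticFit:
    """Fit the logistic polynomial to one instar x treatment group of trials."""
    trials = [tr for tr in trials if not tr.excluded]
    if not trials:
        raise DesignError("no trials to fit")
    instars = {tr.predator_instar for tr in trials}
    treatments = {tr.treatment for tr in trials}
    if len(instars) > 1 or len(treatments) > 1:
        raise DesignError(f"expected one instar x treatment group, got {instars} x {treatments}")
    return fit_polynomial_logistic_arrays(
        [tr.n0 for tr in trials],
        [tr.na for tr in trials],
        instar=trials[0].predator_instar,
        treatment=trials[0].treatment,
        max_degree=max_degree,
        alpha=alpha,
    )


def classify_response(fit: LogisticFit, alpha: float | None = None) -> str:
    """Type call from the sign and significance of the linear coefficient.

    ``II`` if P1 < 0 with p <= alpha, ``III`` if P1 > 0 with p <= alpha,
    ``inconclusive`` otherwise (including unconverged or degenerate fits).
    """
    alpha = fit.alpha if alpha is None else alpha
    if not fit.converged or "linear" not in fit.terms:
        return "inconclusive"
    lin = fit.terms["linear"]
    if lin.p <= alpha:
        return "II" if lin.estimate < 0 else "III"
    return "inconclusive"
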
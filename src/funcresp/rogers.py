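"""Rogers' random predator equation: forward model, NLS fitting, CL comparison.

The random predator equation describes a type II functional response when
consumed prey are not replaced during the trial, so prey density declines as
the predator feeds.  With attack rate ``a`` (h^-1), handling time ``th`` (h),
initial density ``n0`` and exposure window ``t`` (h), the expected number of
prey attacked ``Na`` solves the implicit equation

    Na = n0 * (1 - exp(a * (th * Na - t)))

whose unique root in [0, n0] has the closed form

    Na = n0 - W(a * th * n0 * exp(-a * (t - th * n0))) / (a * th)

with ``W`` the principal branch of the Lambert-W function.  ``t / th`` is the
saturation plateau: the maximum number of prey the predator can process in
one exposure window.

Parameters are estimated by nonlinear least squares on consumption counts
(the classic PROC NLIN-style analysis), with asymptotic t-based Wald 95%
confidence limits; a seeded nonparametric bootstrap is available as an
alternative.  Treatments are compared by the CL-overlap rule: two estimates
differ significantly (at the level the CLs were built for) exactly when
their intervals are disjoint.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .datamodel import DesignError, PredationTrial

__all__ = [
    "DomainError",
    "InfiniteCapacityError",
    "RogersFit",
    "ComparisonResult",
    "predict_na",
    "predict_na_bisection",
    "holling_na",
    "fit_rogers",
    "fit_rogers_arrays",
    "max_attack",
    "compare_parameters",
    "assign_group_letters",
]


class DomainError(ValueError):
    """A model input lies outside the parameter domain."""


class InfiniteCapacityError(ZeroDivisionError):
    """Handling time of zero implies unbounded attack capacity T/Th."""


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _lambertw_exp(y: np.ndarray) -> np.ndarray:
    """W(e^y) for real y, stable for arbitrarily large y.

    For moderate y the principal branch is evaluated directly; for large y
    (where e^y overflows) W(e^y) solves w + log(w) = y, computed by Newton
    iteration from the asymptotic seed w0 = y - log(y).
    """
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    small = y < 500.0
    if np.any(small):
        out[small] = special.lambertw(np.exp(y[small])).real
    if np.any(~small):
        yy = y[~small]
        w = yy - np.log(yy)
        for _ in range(4):  # quadratic convergence; 4 steps reach machine precision
            w -= (w + np.log(w) - yy) / (1.0 + 1.0 / w)
        out[~small] = w
    return out


def holling_na(a, n0, t):
    """Expected consumption without handling time: n0 * (1 - exp(-a t))."""
    return np.asarray(n0, dtype=float) * -np.expm1(-np.asarray(a, dtype=float) * t)


def predict_na(a, th, n0, t):
    """Expected number of prey attacked under the random predator equation.

    Parameters
    ----------
    a : float
        Attack rate, h^-1 (``a >= 0``).
    th : float
        Handling time per prey, h (``th >= 0``).
    n0 : float or array
        Initial prey density (prey are depleted, not replaced).
    t : float
        Exposure window, h (``t > 0``).

    Returns
    -------
    float or ndarray
        The unique root of the implicit equation in ``[0, n0]``; continuous
        and non-decreasing in each of ``a``, ``n0`` and ``t``.
    """
    a = float(a)
    th = float(th)
    t = float(t)
    n0_arr = np.asarray(n0, dtype=float)
    scalar = n0_arr.ndim == 0
    n0_arr = np.atleast_1d(n0_arr)
    if a < 0 or th < 0 or t <= 0 or np.any(n0_arr < 0):
        raise DomainError(f"predict_na requires a>=0, th>=0, n0>=0, t>0 (got a={a}, th={th}, t={t})")
    if a == 0.0:
        na = np.zeros_like(n0_arr)
    elif th == 0.0:
        na = holling_na(a, n0_arr, t)
    else:
        na = np.zeros_like(n0_arr)
        pos = n0_arr > 0
        x = n0_arr[pos]
        # log of the Lambert-W argument: a*th*n0 * exp(a*(th*n0 - t))
        y = np.log(a * th * x) + a * (th * x - t)
        na[pos] = x - _lambertw_exp(y) / (a * th)
    na = np.clip(na, 0.0, n0_arr)
    return float(na[0]) if scalar else na


def predict_na_bisection(a, th, n0, t, tol: float = 1e-12, max_iter: int = 200) -> float:
    """Reference root of the implicit random-predator equation by bisection.

    Slow scalar solver kept as an independent check on the Lambert-W closed
    form: ``f(Na) = Na - n0*(1 - exp(a*(th*Na - t)))`` is bracketed on
    ``[0, n0]`` (f(0) <= 0 <= f(n0)) and bisected to ``|f| < tol``.
    """
    a, th, n0, t = float(a), float(th), float(n0), float(t)
    if a < 0 or th < 0 or n0 < 0 or t <= 0:
        raise DomainError("predict_na_bisection requires a>=0, th>=0, n0>=0, t>0")
    if a == 0.0 or n0 == 0.0:
        return 0.0

    def f(na: float) -> float:
        with np.errstate(over="ignore"):  # +inf is a valid bracket value
            return na - n0 * -np.expm1(a * (th * na - t))

    lo, hi = 0.0, n0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) < tol:
            return mid
        if fm < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RogersFit:
    """Fitted random-predator parameters for one instar x treatment dataset."""

    instar: int
    treatment: str
    a_hat: float
    th_hat: float
    a_cl: tuple[float, float]
    th_cl: tuple[float, float]
    tth_hat: float
    tth_cl: tuple[float, float]
    exposure_h: float
    n_trials: int
    sse: float
    converged: bool
    diagnostic: str = ""
    a_se: float = float("nan")
    th_se: float = float("nan")
    ci_method: str = "wald"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("a", "th", "tth"):
            lo, hi = getattr(self, f"{name}_cl")
            est = getattr(self, f"{name}_hat")
            if np.isfinite(est) and not (lo <= est <= hi or np.isnan(lo) or np.isnan(hi)):
                raise ValueError(f"{name} CL ({lo}, {hi}) does not contain estimate {est}")


_A_BOUNDS = (1e-6, 10.0)


def _initial_guesses(n0, na, t, n_starts, rng):
    """Heuristic start plus seeded log-normal jitters.

    a0 comes from inverting the zero-handling-time limit at the lowest
    density (-log(1 - p)/t on the mean proportion consumed); th0 from the
    plateau t/max(na).
    """
    lowest = n0 == n0.min()
    p = float(np.clip(na[lowest].mean() / n0.min(), 1e-3, 0.999))
    a0 = float(np.clip(-np.log1p(-p) / t, _A_BOUNDS[0] * 10, _A_BOUNDS[1] / 10))
    na_max = max(float(na.max()), 0.5)
    th0 = float(np.clip(t / na_max, 1e-3, t * 0.9))
    starts = [(a0, th0)]
    for _ in range(n_starts - 1):
        ja, jth = np.exp(rng.normal(0.0, 0.7, size=2))
        starts.append(
            (
                float(np.clip(a0 * ja, *_A_BOUNDS)),
                float(np.clip(th0 * jth, 1e-3, t)),
            )
        )
    return starts


def _nls(n0, na, t, starts):
    """Bounded least squares on counts from each start; keep the best SSE."""
    best, best_sse = None, np.inf
    for a0, th0 in starts:
        try:
            res = optimize.least_squares(
                lambda p: predict_na(p[0], p[1], n0, t) - na,
                x0=[a0, th0],
                bounds=([_A_BOUNDS[0], 0.0], [_A_BOUNDS[1], t]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:
            continue
        sse = float(2.0 * res.cost)
        if sse < best_sse:
            best, best_sse = res, sse
    if best is None:
        raise RuntimeError("nonlinear least squares failed from every start")
    return best


def _wald_cls(res, n: int, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Asymptotic t-based intervals from the Jacobian at the optimum."""
    sse = float(2.0 * res.cost)
    dof = max(n - 2, 1)
    J = res.jac
    try:
        cov = sse / dof * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
    tq = stats.t.ppf(1.0 - alpha / 2.0, dof)
    return se, tq * se


def fit_rogers(
    trials: Iterable[PredationTrial],
    t: float | None = None,
    *,
    ci_method: str = "wald",
    bootstrap_b: int = 999,
    alpha: float = 0.05,
    n_starts: int = 5,
    seed: int = 0,
) -> RogersFit:
    """Fit the random predator equation to one instar x treatment dataset.

    Ordinary least squares on consumption counts, solved with bounded
    trust-region least squares from a heuristic start plus ``n_starts - 1``
    seeded jitters.  95% CLs are asymptotic Wald intervals with the
    t-quantile at ``n - 2`` degrees of freedom (``ci_method="wald"``), or
    percentile intervals from ``bootstrap_b`` resamples of replicates within
    density (``ci_method="bootstrap"``).

    A fit whose optimum sits on a parameter bound — including the
    non-identifiable case where every trial consumed all prey, which drives
    ``th`` to its 0 boundary — is returned with ``converged=False`` and a
    diagnostic, never silently.
    """
    trials = [tr for tr in trials if not tr.excluded]
    if not trials:
        raise DesignError("no trials to fit")
    instars = {tr.predator_instar for tr in trials}
    treatments = {tr.treatment for tr in trials}
    if len(instars) > 1 or len(treatments) > 1:
        raise DesignError(f"fit_rogers expects one instar x treatment group, got {instars} x {treatments}")
    if t is None:
        exps = {tr.exposure_h for tr in trials}
        if len(exps) > 1:
            raise DesignError(f"mixed exposure times {exps}; pass t explicitly")
        t = exps.pop()
    return fit_rogers_arrays(
        [tr.n0 for tr in trials],
        [tr.na for tr in trials],
        t,
        instar=trials[0].predator_instar,
        treatment=trials[0].treatment,
        ci_method=ci_method,
        bootstrap_b=bootstrap_b,
        alpha=alpha,
        n_starts=n_starts,
        seed=seed,
    )


def fit_rogers_arrays(
    n0,
    na,
    t: float,
    *,
    instar: int = 0,
    treatment: str = "",
    ci_method: str = "wald",
    bootstrap_b: int = 999,
    alpha: float = 0.05,
    n_starts: int = 5,
    seed: int = 0,
) -> RogersFit:
    """Array-level interface to :func:`fit_rogers`.

    ``na`` may be non-integer (e.g. noiseless model expectations used as
    pseudo-data for self-consistency checks).
    """
    n0 = np.asarray(n0, dtype=float)
    na = np.asarray(na, dtype=float)
    if len(np.unique(n0)) < 2:
        raise DesignError("at least 2 distinct prey densities are required")
    if np.all(na == 0):
        raise DesignError("all trials have zero consumption; the attack rate is not identifiable")

    saturated = bool(np.all(na == n0))
    rng = np.random.default_rng(seed)
    res = _nls(n0, na, t, _initial_guesses(n0, na, t, n_starts, rng))
    a_hat, th_hat = float(res.x[0]), float(res.x[1])
    sse = float(2.0 * res.cost)
    n = len(n0)

    diagnostic = ""
    converged = bool(res.success)
    if saturated:
        converged = False
        diagnostic = "saturated: all prey consumed at every density; th at its 0 boundary (non-identifiable)"
    if np.isclose(a_hat, _A_BOUNDS[0]) or np.isclose(a_hat, _A_BOUNDS[1]):
        converged = False
        diagnostic = diagnostic or f"attack rate at bound ({a_hat:g})"
    if th_hat <= 1e-9 or np.isclose(th_hat, t):
        converged = False
        diagnostic = diagnostic or f"handling time at bound ({th_hat:g})"

    if ci_method == "wald":
        se, half = _wald_cls(res, n, alpha)
        a_cl = (a_hat - half[0], a_hat + half[0])
        th_cl = (th_hat - half[1], th_hat + half[1])
    elif ci_method == "bootstrap":
        se = np.full(2, np.nan)
        a_cl, th_cl = _bootstrap_cls(n0, na, t, (a_hat, th_hat), bootstrap_b, alpha, rng)
        a_cl = (min(a_cl[0], a_hat), max(a_cl[1], a_hat))
        th_cl = (min(th_cl[0], th_hat), max(th_cl[1], th_hat))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    if th_hat > 0:
        tth_hat = t / th_hat
        th_lo, th_hi = th_cl
        tth_cl = (t / th_hi if th_hi > 0 else 0.0, t / th_lo if th_lo > 0 else np.inf)
    else:
        tth_hat, tth_cl = np.inf, (np.nan, np.nan)

    return RogersFit(
        instar=instar,
        treatment=treatment,
        a_hat=a_hat,
        th_hat=th_hat,
        a_cl=tuple(float(x) for x in a_cl),
        th_cl=tuple(float(x) for x in th_cl),
        tth_hat=float(tth_hat),
        tth_cl=tuple(float(x) for x in tth_cl),
        exposure_h=float(t),
        n_trials=n,
        sse=sse,
        converged=converged,
        diagnostic=diagnostic,
        a_se=float(se[0]),
        th_se=float(se[1]),
        ci_method=ci_method,
        alpha=alpha,
    )


def _bootstrap_cls(n0, na, t, x0, b, alpha, rng):
    """Percentile CLs from resampling replicates within each density."""
    ests = []
    densities = np.unique(n0)
    idx_by_density = {d: np.flatnonzero(n0 == d) for d in densities}
    for _ in range(b):
        idx = np.concatenate([rng.choice(ix, size=len(ix), replace=True) for ix in idx_by_density.values()])
        try:
            res = optimize.least_squares(
                lambda p: predict_na(p[0], p[1], n0[idx], t) - na[idx],
                x0=list(x0),
                bounds=([_A_BOUNDS[0], 0.0], [_A_BOUNDS[1], t]),
            )
        except Exception:
            continue
        ests.append(res.x)
    ests = np.asarray(ests)
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    a_lo, a_hi = np.percentile(ests[:, 0], qs)
    th_lo, th_hi = np.percentile(ests[:, 1], qs)
    return (a_lo, a_hi), (th_lo, th_hi)


# ---------------------------------------------------------------------------
# derived quantities and comparisons
# ---------------------------------------------------------------------------

def max_attack(th_hat: float, th_cl: tuple[float, float], t: float = 24.0):
    """Maximum prey processed per exposure window, ``T/Th``, with its CL.

    The transform is decreasing in ``th``, so the interval endpoints swap:
    ``tth_cl = (t/th_hi, t/th_lo)``.
    """
    th_lo, th_hi = th_cl
    if th_hat <= 0 or th_lo <= 0:
        raise InfiniteCapacityError(
            f"handling time of zero (th={th_hat}, cl=({th_lo}, {th_hi})) implies unbounded capacity"
        )
    if not th_lo <= th_hat <= th_hi:
        raise DomainError(f"th CL ({th_lo}, {th_hi}) does not contain estimate {th_hat}")
    return t / th_hat, (t / th_hi, t / th_lo)


@dataclass(frozen=True)
class ComparisonResult:
    parameter: str
    significant: bool
    letters: tuple[str, str]
    intervals: tuple[tuple[float, float], tuple[float, float]]
    alpha: float = 0.05


def _overlap(i: tuple[float, float], j: tuple[float, float]) -> bool:
    return i[0] <= j[1] and j[0] <= i[1]


def compare_parameters(fit_a: RogersFit, fit_b: RogersFit, parameter: str = "th") -> ComparisonResult:
    """Compare one parameter across two fits by the CL-overlap rule.

    Disjoint 95% CLs => significant difference (letters ``a``/``b``);
    overlapping CLs => no significant difference (both ``a``).  Unconverged
    fits are refused — their intervals are not trustworthy.
    """
    if parameter not in ("a", "th", "tth"):
        raise ValueError(f"unknown parameter {parameter!r}; expected 'a', 'th' or 'tth'")
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("comparison refused: at least one fit did not converge")
    ia = getattr(fit_a, f"{parameter}_cl")
    ib = getattr(fit_b, f"{parameter}_cl")
    letters = assign_group_letters([getattr(fit_a, f"{parameter}_hat"), getattr(fit_b, f"{parameter}_hat")], [ia, ib])
    return ComparisonResult(
        parameter=parameter,
        significant=not _overlap(ia, ib),
        letters=(letters[0], letters[1]),
        intervals=(ia, ib),
        alpha=fit_a.alpha,
    )


def assign_group_letters(estimates: Sequence[float], intervals: Sequence[tuple[float, float]]) -> list[str]:
    """Letters by connected components of the CL-overlap graph.

    Estimates whose intervals overlap (directly or through a chain) share a
    letter; components are lettered ``a, b, c, ...`` in order of their
    smallest member estimate.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _overlap(intervals[i], intervals[j]):
                parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    comp_min = {}
    for i, r in enumerate(roots):
        comp_min[r] = min(comp_min.get(r, np.inf), estimates[i])
    order = {r: k for k, r in enumerate(sorted(comp_min, key=comp_min.get))}
    return [string.ascii_lowercase[order[r]] for r in roots]
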
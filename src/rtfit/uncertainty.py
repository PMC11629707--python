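"""Profile-likelihood confidence intervals and fold-change significance.

The profile of a parameter is the log-likelihood maximized over all other
parameters, scanned over that one.  A level-``q`` confidence interval is the
region where the profile stays within ``chi2_1.ppf(q)/2`` log-likelihood
units of the optimum — the continuous version of the likelihood ratio test,
so excluding Δ = 1 (log Δ = 0) from the 95% CI of a fold-change is the same
decision as a 5%-level LRT of the shared-parameter null model.

Profiles are computed on each parameter's optimization scale (log10 for
strictly positive parameters) with an adaptive step targeting ~0.1
log-likelihood units per step; intervals are reported on the linear scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .data import TimeCourseDataset
from .estimation import (
    FitResult,
    ParameterSpace,
    _LBFGSB_OPTIONS,
    _Objective,
)
from .model import ModelSpec, SpecError

__all__ = [
    "ProfileResult",
    "FoldChangeDecision",
    "profile_likelihood",
    "confidence_interval",
    "lrt",
    "test_fold_change",
]


@dataclass(frozen=True)
class ProfileResult:
    """Profile likelihood of one parameter.

    ``grid`` holds profiled values on the optimization scale (ascending),
    ``loglik`` the re-optimized log-likelihood at each grid point.  ``lower``
    / ``upper`` are CI endpoints on the linear scale; an open endpoint means
    the profile never dropped below the threshold before hitting a bound.
    """

    name: str
    scale: str
    grid: np.ndarray
    loglik: np.ndarray
    mle: float                     # linear scale
    loglik_opt: float
    level: float
    lower: float
    upper: float
    lower_open: bool
    upper_open: bool
    gaps: tuple[float, ...] = ()   # grid points where re-optimization failed

    def to_frame(self):
        import pandas as pd
        lin = 10.0 ** self.grid if self.scale == "log10" else self.grid
        return pd.DataFrame({"value": lin, f"{self.name}_scaled": self.grid,
                             "profile_loglik": self.loglik})


def _chi2_halfwidth(level: float, df: int = 1) -> float:
    return float(stats.chi2.ppf(level, df) / 2.0)


def profile_likelihood(fit: FitResult, dataset: TimeCourseDataset,
                       spec: ModelSpec | None = None,
                       space: ParameterSpace | None = None,
                       param: str = "", level: float = 0.95,
                       target_dll: float = 0.1, max_steps: int = 100) -> ProfileResult:
    """Profile one free parameter of a fitted model.

    Steps away from the MLE in both directions on the parameter's scale,
    re-optimizing all other free parameters at every step (warm-started from
    the previous step), until the profile drops ``chi2_1.ppf(level)/2 + 0.5``
    below the optimum, a bound is reached, or ``max_steps`` per direction.
    Step size adapts towards ``target_dll`` log-likelihood units per step.
    """
    spec = spec if spec is not None else fit.spec
    space = space if space is not None else fit.space
    if not param:
        raise ValueError("param name required")
    free_names = space.free_names
    if param not in free_names:
        if param in space.names:
            raise SpecError(f"parameter {param!r} is fixed, cannot profile")
        raise SpecError(f"unknown parameter {param!r}; free: {free_names}")

    obj = _Objective(dataset, spec, space)
    k = free_names.index(param)
    pdef = space[param]
    lo_s, hi_s = pdef.to_scaled(pdef.lb), pdef.to_scaled(pdef.ub)
    x_mle = np.asarray(fit.x_scaled, dtype=float)
    ll_opt = fit.loglik
    drop_stop = _chi2_halfwidth(level) + 0.5

    other = [i for i in range(len(free_names)) if i != k]
    other_bounds = [space.scaled_bounds()[i] for i in other]

    def reoptimize(value: float, x_warm: np.ndarray) -> tuple[float, np.ndarray] | None:
        """Max LL over the other parameters at fixed ``param`` = value."""
        if not other:
            x = x_warm.copy()
            x[k] = value
            nll = obj.neg_ll(x)
            return (-nll, x) if np.isfinite(nll) else None

        def nll_sub(z):
            x = x_warm.copy()
            x[k] = value
            x[other] = z
            return obj.neg_ll(x)

        best = None
        for z0 in (x_warm[other], x_mle[other]):
            res = optimize.minimize(nll_sub, z0, method="L-BFGS-B",
                                    bounds=other_bounds, options=_LBFGSB_OPTIONS)
            if np.isfinite(res.fun) and (best is None or res.fun < best[0]):
                best = (float(res.fun), np.asarray(res.x))
            if best is not None and best[0] < np.inf:
                break  # warm start succeeded; MLE restart only as fallback
        if best is None:
            return None
        x = x_warm.copy()
        x[k] = value
        x[other] = best[1]
        return (-best[0], x)

    def scan(direction: int) -> tuple[list[float], list[float], list[float], bool]:
        """Returns (grid, lls, gaps, hit_bound_still_above_threshold)."""
        grid: list[float] = []
        lls: list[float] = []
        gaps: list[float] = []
        h = max((hi_s - lo_s) / 100.0, 1e-12)
        h_min = max((hi_s - lo_s) * 1e-8, 1e-14)
        x_warm = x_mle.copy()
        value = x_mle[k]
        ll_prev = ll_opt
        budget = 4 * max_steps  # counts re-optimizations incl. retracted steps
        while len(grid) < max_steps and budget > 0:
            budget -= 1
            nxt = value + direction * h
            at_bound = False
            if nxt <= lo_s:
                nxt, at_bound = lo_s, True
            elif nxt >= hi_s:
                nxt, at_bound = hi_s, True
            out = reoptimize(nxt, x_warm)
            if out is None:
                gaps.append(nxt)
                value = nxt
                if at_bound:
                    return grid, lls, gaps, True
                continue
            ll, x_new = out
            dll = abs(ll_prev - ll)
            if dll > 4.0 * target_dll and h > h_min and not at_bound:
                h = max(h / 4.0, h_min)  # overshoot: retract and retry finer
                continue
            grid.append(nxt)
            lls.append(ll)
            x_warm = x_new
            if dll < target_dll / 4.0:
                h = h * 2.0
            value, ll_prev = nxt, ll
            if ll_opt - ll > drop_stop:
                return grid, lls, gaps, False
            if at_bound:
                return grid, lls, gaps, True
        return grid, lls, gaps, True  # budget exhausted: treat side as open

    left = scan(-1)
    right = scan(+1)

    grid = np.array(list(reversed(left[0])) + [x_mle[k]] + right[0])
    lls = np.array(list(reversed(left[1])) + [ll_opt] + right[1])
    mle_lin = pdef.to_linear(x_mle[k])

    prof = ProfileResult(
        name=param, scale=pdef.scale, grid=grid, loglik=lls, mle=mle_lin,
        loglik_opt=ll_opt, level=level, lower=np.nan, upper=np.nan,
        lower_open=left[3], upper_open=right[3],
        gaps=tuple(left[2] + right[2]),
    )
    lower, upper, lo_open, up_open = confidence_interval(prof)
    return ProfileResult(
        name=param, scale=pdef.scale, grid=grid, loglik=lls, mle=mle_lin,
        loglik_opt=ll_opt, level=level, lower=lower, upper=upper,
        lower_open=lo_open, upper_open=up_open,
        gaps=tuple(left[2] + right[2]),
    )


def confidence_interval(profile: ProfileResult,
                        level: float | None = None) -> tuple[float, float, bool, bool]:
    """CI endpoints from a computed profile, linear scale.

    The interval is where the profile stays above ``loglik_opt -
    chi2_1.ppf(level)/2`` (1.9207 at 95%); endpoints interpolate linearly
    between adjacent grid points on the profiling scale.  A side whose
    profile never crosses the threshold is open (endpoint = last profiled
    value, flag set).
    """
    level = level if level is not None else profile.level
    thr = profile.loglik_opt - _chi2_halfwidth(level)
    grid, lls = profile.grid, profile.loglik
    k = int(np.argmin(np.abs(grid - (np.log10(profile.mle)
                                     if profile.scale == "log10" else profile.mle))))

    def cross(indices) -> tuple[float, bool]:
        prev_i = None
        for i in indices:
            if lls[i] < thr:
                if prev_i is None:
                    return float(grid[i]), False
                x0, x1 = grid[prev_i], grid[i]
                y0, y1 = lls[prev_i], lls[i]
                frac = (y0 - thr) / (y0 - y1)
                return float(x0 + frac * (x1 - x0)), False
            prev_i = i
        return float(grid[indices[-1]]) if len(indices) else float(grid[k]), True

    lo_s, lo_open = cross(list(range(k, -1, -1)))
    hi_s, hi_open = cross(list(range(k, len(grid))))
    to_lin = (lambda v: 10.0 ** v) if profile.scale == "log10" else (lambda v: v)
    return to_lin(lo_s), to_lin(hi_s), lo_open, hi_open


def lrt(nested, full, df: int) -> tuple[float, float]:
    """Likelihood ratio test of a nested against a full model.

    Accepts :class:`FitResult` objects or raw log-likelihoods.  Returns
    ``(statistic, p_value)`` with ``statistic = max(0, 2 (LL_full -
    LL_nested))`` against a chi-square with ``df`` degrees of freedom.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    ll_nested = getattr(nested, "loglik", nested)
    ll_full = getattr(full, "loglik", full)
    raw = 2.0 * (ll_full - ll_nested)
    if ll_full - ll_nested < -1e-6:
        warnings.warn(
            f"full model log-likelihood below nested by {-raw / 2:.3g}: "
            "likely optimizer failure in the full fit", RuntimeWarning)
    stat = max(0.0, raw)
    return stat, float(stats.chi2.sf(stat, df))


@dataclass(frozen=True)
class FoldChangeDecision:
    """Outcome of testing H0: Δ = 1 via the profile CI of the fold-change."""

    name: str
    significant: bool
    unidentifiable: bool
    ci: tuple[float, float]
    ci_open: tuple[bool, bool]
    mle: float
    level: float


def test_fold_change(profile: ProfileResult, level: float | None = None) -> FoldChangeDecision:
    """Reject H0: log(Δ) = 0 exactly when Δ = 1 lies outside the profile CI.

    A fold-change whose CI is open on both sides is flagged unidentifiable
    and never significant; a one-sided open CI can still exclude 1 through
    its closed side.
    """
    level = level if level is not None else profile.level
    lower, upper, lo_open, up_open = confidence_interval(profile, level)
    if lo_open and up_open:
        return FoldChangeDecision(profile.name, False, True, (lower, upper),
                                  (lo_open, up_open), profile.mle, level)
    below = (not up_open) and upper < 1.0
    above = (not lo_open) and lower > 1.0
    return FoldChangeDecision(profile.name, bool(below or above), False,
                              (lower, upper), (lo_open, up_open), profile.mle, level)
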
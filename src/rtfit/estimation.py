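"""Maximum-likelihood estimation of RTF models.

Fits are Gaussian maximum likelihood with a single shared error SD ``sigma``
across all doses, conditions and replicates.  Optimization is bounded
multi-start: the first start is the data-driven default initial guess, the
rest are Latin-hypercube draws on each parameter's optimization scale
(log10 for strictly positive parameters), each refined with L-BFGS-B.  The
sorted per-start objectives form the waterfall diagnostic of optimizer
reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import TimeCourseDataset
from .model import (
    _LN10,
    DYNAMIC_PARAMS,
    DoseParams,
    HillTriplet,
    ModelSpec,
    SpecError,
    free_parameter_names,
)

__all__ = [
    "ParamDef",
    "ParameterSpace",
    "FitResult",
    "OptimizationError",
    "default_space",
    "log_likelihood",
    "chi_square",
    "predict",
    "sample_starts",
    "fit",
    "waterfall",
    "dose_params_from_estimates",
    "fit_individual_doses",
    "compare_joint_vs_individual",
]

class OptimizationError(RuntimeError):
    """Every optimizer start failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class ParamDef:
    """One scalar of the optimization problem: bounds, initial guess, scale."""

    name: str
    lb: float
    ub: float
    init: float
    scale: str = "linear"  # "linear" | "log10"
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not self.fixed:
            if not (self.lb <= self.init <= self.ub):
                raise ValueError(
                    f"{self.name}: initial guess {self.init} outside [{self.lb}, {self.ub}]")
            if self.scale == "log10" and self.lb <= 0:
                raise ValueError(f"{self.name}: log10 scale needs positive bounds")

    def to_scaled(self, value: float) -> float:
        return float(np.log10(value)) if self.scale == "log10" else float(value)

    def to_linear(self, value: float) -> float:
        return float(10.0 ** value) if self.scale == "log10" else float(value)


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered collection of :class:`ParamDef`, aligned with a ModelSpec."""

    params: tuple[ParamDef, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(self.params))
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in space")

    def __iter__(self):
        return iter(self.params)

    def __len__(self) -> int:
        return len(self.params)

    def __getitem__(self, name: str) -> ParamDef:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    @property
    def free(self) -> list[ParamDef]:
        return [p for p in self.params if not p.fixed]

    @property
    def free_names(self) -> list[str]:
        return [p.name for p in self.free]

    def fix(self, name: str, value: float) -> "ParameterSpace":
        """New space with ``name`` held at ``value`` during optimization."""
        if name not in self.names:
            raise KeyError(name)
        return ParameterSpace(tuple(
            replace(p, fixed=True, init=value, lb=min(p.lb, value), ub=max(p.ub, value))
            if p.name == name else p
            for p in self.params))

    def scaled_bounds(self) -> list[tuple[float, float]]:
        return [(p.to_scaled(p.lb), p.to_scaled(p.ub)) for p in self.free]

    def scaled_init(self) -> np.ndarray:
        return np.array([p.to_scaled(p.init) for p in self.free])

    def start_from(self, values: Mapping[str, float]) -> np.ndarray:
        """Scaled free start vector from linear values, clipped into bounds;
        parameters absent from ``values`` fall back to their initial guess."""
        out = []
        for p in self.free:
            v = values.get(p.name, p.init)
            lo, hi = p.to_scaled(p.lb), p.to_scaled(p.ub)
            try:
                s = p.to_scaled(v)
            except (ValueError, FloatingPointError):
                s = p.to_scaled(p.init)
            if not np.isfinite(s):
                s = p.to_scaled(p.init)
            out.append(float(np.clip(s, lo, hi)))
        return np.array(out)


def _table_row(family: str, name: str, spec: ModelSpec, y: np.ndarray,
               times: np.ndarray, doses: np.ndarray) -> ParamDef:
    """Default bounds and initial guess for one parameter, from the data."""
    y_rng = float(y.max() - y.min())
    t_rng = float(times.max() - times.min())
    if family in ("A", "B"):
        lb, ub = 0.0, 2.0 * y_rng
        init = 0.1 * lb + 0.9 * ub
        if spec.sign_of(family) == "down":
            lb, ub = -ub, 0.0
            init = 0.9 * lb + 0.1 * ub
        return ParamDef(name, lb, ub, init, "linear")
    if family in ("alpha", "beta", "gamma"):
        min_gap = float(np.diff(times).min())
        lb, ub = 1.0 / (2.0 * t_rng), 2.0 / min_gap
        return ParamDef(name, lb, ub, 0.5 * (lb + ub), "log10")
    if family == "tau":
        return ParamDef(name, -t_rng / 5.0, t_rng / 2.0, -t_rng / 10.0, "linear")
    if family == "h":
        return ParamDef(name, 1.0, 10.0, 5.5, "log10")
    if family == "K":
        positive = doses[doses > 0]
        if positive.size == 0:
            raise SpecError("dose-dependent model needs at least one positive dose")
        lb, ub = float(positive.min()) / 10.0, float(doses.max()) * 10.0
        return ParamDef(name, lb, ub, 0.5 * (lb + ub), "log10")
    if family == "b":
        lb, ub = float(y.min()), float(y.max())
        return ParamDef(name, lb, ub, 0.5 * (lb + ub), "linear")
    if family == "sigma":
        ub = max(1e-10, float(np.std(y, ddof=1)))
        lb = min(ub, max(1e-10, y_rng / 1e4))
        return ParamDef(name, lb, ub, 0.5 * (lb + ub), "log10")
    if family == "delta":
        return ParamDef(name, 1e-2, 1e2, 1.0, "log10")
    raise AssertionError(family)


def _resolve_conditions(dataset: TimeCourseDataset, spec: ModelSpec) -> ModelSpec:
    """Match a single-condition spec to a single-condition dataset regardless
    of the placeholder label; multi-condition specs must name real conditions."""
    if (len(spec.conditions) == 1
            and spec.conditions[0] not in dataset.conditions
            and len(dataset.conditions) == 1):
        return replace(spec, conditions=dataset.conditions)
    return spec


def default_space(dataset: TimeCourseDataset, spec: ModelSpec) -> ParameterSpace:
    """Data-driven default bounds and initial guesses for every free scalar.

    Amplitude bounds span twice the observed response range (sign-flipped
    for down-regulation), rate bounds derive from the time resolution, the
    retardation from the time range, Hill ``K`` from the dose ladder, and
    ``b``/``sigma`` from the response values.  With multiple conditions only
    reference-condition responses define the response-derived bounds;
    measurement times and doses are pooled (one shared transformed axis).
    Fold-changes Δ get bounds [1e-2, 1e2] with initial guess 1.
    """
    spec = _resolve_conditions(dataset, spec)
    for cond in spec.conditions:
        if cond not in dataset.conditions:
            raise SpecError(f"condition {cond!r} not present in dataset")
    y = dataset.values_for(
        spec.reference_condition if len(spec.conditions) > 1 else None)
    times = dataset.times
    doses = dataset.doses
    if float(y.max() - y.min()) <= 0:
        raise SpecError("degenerate data: all response values identical")
    if spec.dose_dependent and np.unique(doses).size < 2:
        raise SpecError("dose-dependent model needs >= 2 distinct doses")

    defs: list[ParamDef] = []
    for name in free_parameter_names(spec):
        if name.startswith("delta_"):
            defs.append(_table_row("delta", name, spec, y, times, doses))
            continue
        base, _, comp = name.partition("_")
        if base in DYNAMIC_PARAMS and comp in ("K", "h"):
            family = comp
        elif base in DYNAMIC_PARAMS:  # "<p>_M" or bare scalar "<p>"
            family = base
        else:
            family = name  # "b", "sigma"
        defs.append(_table_row(family, name, spec, y, times, doses))
    return ParameterSpace(tuple(defs))


# ---------------------------------------------------------------------------
# Compiled objective
# ---------------------------------------------------------------------------

class _Objective:
    """Vectorized Gaussian negative log-likelihood of an RTF model.

    Rows are grouped by (condition, dose); per evaluation the dynamic
    parameters are resolved per group through their Hill laws, fold-changes
    and ties, then the RTF is evaluated for all rows in one numpy pass.
    """

    def __init__(self, dataset: TimeCourseDataset, spec: ModelSpec,
                 space: ParameterSpace):
        spec = _resolve_conditions(dataset, spec)
        self.spec = spec
        self.space = space
        self.names = space.names
        expected = free_parameter_names(spec)
        if self.names != expected:
            raise SpecError("parameter space does not match the model spec")
        self.index = {n: i for i, n in enumerate(self.names)}

        df = dataset.frame[dataset.frame["condition"].isin(spec.conditions)]
        if len(df) == 0:
            raise SpecError("dataset has no rows for the spec's conditions")
        cond_idx = {c: i for i, c in enumerate(spec.conditions)}
        ci = df["condition"].map(cond_idx).to_numpy()
        key = pd.MultiIndex.from_arrays([ci, df["dose"]])
        codes, uniques = pd.factorize(key)
        self.row_group = codes
        self.g_cond = np.array([u[0] for u in uniques], dtype=int)
        self.g_dose = np.array([u[1] for u in uniques], dtype=float)
        self.y = df["value"].to_numpy(dtype=float)
        self.T = dataset.T
        t_real = df["time"].to_numpy(dtype=float)
        self._a_ln10 = t_real * (10.0 / self.T) * _LN10
        self.n_obs = len(self.y)
        self.n_cond = len(spec.conditions)

        # per base scalar: (theta index, per-condition delta theta index or -1)
        self._delta_idx: dict[str, np.ndarray] = {}
        for base in spec._base_names():
            idx = np.full(self.n_cond, -1, dtype=int)
            if base in spec.condition_dependent:
                for c, cond in enumerate(spec.conditions[1:], start=1):
                    idx[c] = self.index[spec.delta_name(base, cond)]
            self._delta_idx[base] = idx

        self._present = spec._present_dynamic()
        self._log_mask = np.array([p.scale == "log10" for p in space.params])
        self._fixed_mask = np.array([p.fixed for p in space.params])
        self._fixed_scaled = np.array([p.to_scaled(p.init) if p.fixed else 0.0
                                       for p in space.params])
        self._free_pos = np.flatnonzero(~self._fixed_mask)

    # -- parameter plumbing ------------------------------------------------

    def full_scaled(self, x_free: np.ndarray) -> np.ndarray:
        full = self._fixed_scaled.copy()
        full[self._free_pos] = x_free
        return full

    def linear_from_scaled(self, full_scaled: np.ndarray) -> np.ndarray:
        lin = full_scaled.copy()
        lin[self._log_mask] = 10.0 ** lin[self._log_mask]
        return lin

    def theta_from_any(self, theta) -> np.ndarray:
        """Full linear vector from a mapping or array (linear scale)."""
        if isinstance(theta, Mapping):
            missing = [n for n in self.names if n not in theta]
            if missing:
                raise KeyError(f"theta missing parameters: {missing}")
            return np.array([float(theta[n]) for n in self.names])
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(self.names),):
            raise ValueError(f"theta must have length {len(self.names)}")
        return theta

    def _scalar_by_cond(self, lin: np.ndarray, base: str) -> np.ndarray:
        """(n_cond,) value of one base scalar, fold-changes applied."""
        v = np.full(self.n_cond, lin[self.index[base]])
        didx = self._delta_idx[base]
        has = didx >= 0
        if has.any():
            v[has] = v[has] * lin[didx[has]]
        return v

    # -- model surface -----------------------------------------------------

    def predict_linear(self, lin: np.ndarray) -> np.ndarray:
        spec = self.spec
        gc = self.g_cond
        values: dict[str, np.ndarray] = {}
        for p in self._present:
            if p in spec.ties:
                continue
            if p in spec.dose_dependent:
                M = self._scalar_by_cond(lin, f"{p}_M")[gc]
                K = self._scalar_by_cond(lin, f"{p}_K")[gc]
                h = self._scalar_by_cond(lin, f"{p}_h")[gc]
                d = self.g_dose
                with np.errstate(divide="ignore", over="ignore"):
                    ratio = np.where(d > 0, K / np.where(d > 0, d, 1.0), np.inf)
                    frac = np.where(d > 0, 1.0 / (1.0 + ratio ** h), 0.0)
                if p == "tau":
                    frac = 1.0 - frac
                values[p] = np.where(K > 0, M * frac, M)
            else:
                values[p] = self._scalar_by_cond(lin, p)[gc]
        for tied, source in spec.ties.items():
            values[tied] = values[source]

        b_g = self._scalar_by_cond(lin, "b")[gc]
        tau_g = values["tau"]
        tau_row = tau_g[self.row_group] * _LN10
        tt = (np.logaddexp(self._a_ln10, tau_row) - np.logaddexp(0.0, tau_row)) / _LN10

        R = b_g[self.row_group].copy()
        if "A" in values:
            R += values["A"][self.row_group] * -np.expm1(-values["alpha"][self.row_group] * tt)
        if "B" in values:
            R += (values["B"][self.row_group]
                  * -np.expm1(-values["beta"][self.row_group] * tt)
                  * np.exp(-values["gamma"][self.row_group] * tt))
        return R

    def loglik_linear(self, lin: np.ndarray) -> float:
        sigma = lin[self.index["sigma"]]
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        r = self.y - self.predict_linear(lin)
        return float(-0.5 * self.n_obs * np.log(2.0 * np.pi * sigma ** 2)
                     - np.dot(r, r) / (2.0 * sigma ** 2))

    def neg_ll(self, x_free: np.ndarray) -> float:
        lin = self.linear_from_scaled(self.full_scaled(x_free))
        try:
            val = -self.loglik_linear(lin)
        except (ValueError, FloatingPointError):
            return np.inf
        return val if np.isfinite(val) else np.inf


# ---------------------------------------------------------------------------
# Public likelihood / prediction API
# ---------------------------------------------------------------------------

def log_likelihood(theta, dataset: TimeCourseDataset, spec: ModelSpec,
                   space: ParameterSpace | None = None) -> float:
    """Gaussian log-likelihood of ``theta`` (mapping or vector, linear scale)
    over all points of all doses, conditions and replicates, one shared sigma."""
    space = space if space is not None else default_space(dataset, spec)
    obj = _Objective(dataset, spec, space)
    return obj.loglik_linear(obj.theta_from_any(theta))


def predict(theta, dataset: TimeCourseDataset, spec: ModelSpec,
            space: ParameterSpace | None = None) -> np.ndarray:
    """Model predictions aligned with the dataset's rows (spec conditions only)."""
    space = space if space is not None else default_space(dataset, spec)
    obj = _Objective(dataset, spec, space)
    return obj.predict_linear(obj.theta_from_any(theta))


def chi_square(theta, dataset: TimeCourseDataset, spec: ModelSpec,
               sigma_fixed: float, space: ParameterSpace | None = None) -> float:
    """``sum((y_i - R_i)^2) / sigma_fixed^2`` with an externally fixed error SD."""
    if sigma_fixed <= 0:
        raise ValueError("sigma_fixed must be > 0")
    space = space if space is not None else default_space(dataset, spec)
    obj = _Objective(dataset, spec, space)
    r = obj.y - obj.predict_linear(obj.theta_from_any(theta))
    return float(np.dot(r, r) / sigma_fixed ** 2)


def dose_params_from_estimates(estimates: Mapping[str, float], spec: ModelSpec,
                               condition: str | None = None) -> DoseParams:
    """Assemble a :class:`DoseParams` for one condition from a flat estimate
    mapping; dose-independent scalars become constant (K = 0) triplets and
    absent amplitudes constants at zero.  Use together with ``spec.ties``
    when evaluating."""
    condition = condition or spec.reference_condition
    if condition not in spec.conditions:
        raise SpecError(f"unknown condition {condition!r}")

    def scalar(base: str, default: float | None = None) -> float:
        if base in estimates:
            v = float(estimates[base])
        elif default is not None:
            v = default
        else:
            raise KeyError(base)
        dn = spec.delta_name(base, condition)
        if condition != spec.reference_condition and base in spec.condition_dependent:
            v *= float(estimates[dn])
        return v

    present = spec._present_dynamic()
    trips: dict[str, HillTriplet] = {}
    for p in DYNAMIC_PARAMS:
        direction = "decreasing" if p == "tau" else "increasing"
        if p not in present:
            trips[p] = HillTriplet.constant(0.0 if p in ("A", "B") else 1.0, direction)
        elif p in spec.ties:
            trips[p] = HillTriplet.constant(1.0, direction)  # overridden by tie
        elif p in spec.dose_dependent:
            trips[p] = HillTriplet(M=scalar(f"{p}_M"), K=scalar(f"{p}_K"),
                                   h=scalar(f"{p}_h"), direction=direction)
        else:
            trips[p] = HillTriplet.constant(scalar(p), direction)
    return DoseParams(b=scalar("b"), sigma=float(estimates.get("sigma", 1.0)), **trips)


# ---------------------------------------------------------------------------
# Multi-start fitting
# ---------------------------------------------------------------------------

def sample_starts(space: ParameterSpace, n_starts: int, seed: int = 0) -> list[np.ndarray]:
    """Start vectors on the optimization scale: the default initial guess
    first, then Latin-hypercube draws within bounds (deterministic per seed)."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    starts = [space.scaled_init()]
    n_extra = n_starts - 1
    if n_extra > 0:
        bounds = np.array(space.scaled_bounds())
        sampler = stats.qmc.LatinHypercube(d=len(space.free), rng=np.random.default_rng(seed))
        unit = sampler.random(n_extra)
        lo, hi = bounds[:, 0], bounds[:, 1]
        starts += list(lo + unit * (hi - lo))
    return starts


@dataclass(frozen=True)
class FitResult:
    """Best-of-multi-start maximum-likelihood fit."""

    estimates: dict[str, float]          # full linear-scale values, incl. fixed
    loglik: float
    converged_repeatedly: bool
    per_start: tuple[tuple[int, float], ...]  # (start index, final -LL)
    x_scaled: np.ndarray                 # free parameters, optimization scale
    spec: ModelSpec = field(repr=False, compare=False, default=None)
    space: ParameterSpace = field(repr=False, compare=False, default=None)
    n_obs: int = 0
    seed: int = 0
    n_starts: int = 0

    @property
    def start_objectives(self) -> np.ndarray:
        """Final objective (-LL) of each start, sorted ascending (waterfall)."""
        return np.sort([obj for _, obj in self.per_start])

    def free_estimates(self) -> dict[str, float]:
        return {n: self.estimates[n] for n in self.space.free_names}

    def summary(self) -> dict:
        return {
            "loglik": self.loglik,
            "n_free_parameters": len(self.space.free_names),
            "n_obs": self.n_obs,
            "converged_repeatedly": self.converged_repeatedly,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
        }


_LBFGSB_OPTIONS = {"maxiter": 500, "ftol": 1e-11, "gtol": 1e-8}


def fit(dataset: TimeCourseDataset, spec: ModelSpec,
        space: ParameterSpace | None = None, n_starts: int = 50, seed: int = 0,
        warm_start: Mapping[str, float] | None = None) -> FitResult:
    """Multi-start bounded maximum-likelihood fit of ``spec`` to ``dataset``.

    ``warm_start`` (linear-scale values) is prepended as an extra start —
    used e.g. when refitting reduced models from the current optimum.  The
    fit is flagged ``converged_repeatedly`` when >= 2 starts reach the best
    objective within 1e-3.
    """
    space = space if space is not None else default_space(dataset, spec)
    obj = _Objective(dataset, spec, space)
    starts = sample_starts(space, n_starts, seed)
    if warm_start is not None:
        starts = [space.start_from(warm_start)] + starts
    bounds = space.scaled_bounds()

    results: list[tuple[int, float, np.ndarray]] = []
    diagnostics = []
    for i, x0 in enumerate(starts):
        if not np.isfinite(obj.neg_ll(x0)):
            diagnostics.append((i, "non-finite objective at start"))
            results.append((i, np.inf, x0))
            continue
        res = optimize.minimize(obj.neg_ll, x0, method="L-BFGS-B",
                                bounds=bounds, options=_LBFGSB_OPTIONS)
        fun = float(res.fun) if np.isfinite(res.fun) else np.inf
        results.append((i, fun, np.asarray(res.x)))
        if not np.isfinite(fun):
            diagnostics.append((i, res.message))
    finite = [r for r in results if np.isfinite(r[1])]
    if not finite:
        raise OptimizationError("all optimizer starts failed", diagnostics)

    best = min(finite, key=lambda r: r[1])
    n_at_best = sum(1 for r in finite if r[1] - best[1] <= 1e-3)
    lin = obj.linear_from_scaled(obj.full_scaled(best[2]))
    estimates = {n: float(v) for n, v in zip(space.names, lin)}
    return FitResult(
        estimates=estimates,
        loglik=-best[1],
        converged_repeatedly=n_at_best >= 2,
        per_start=tuple((i, f) for i, f, _ in results),
        x_scaled=np.asarray(best[2], dtype=float),
        spec=spec,
        space=space,
        n_obs=obj.n_obs,
        seed=seed,
        n_starts=len(starts),
    )


def waterfall(fit_result: FitResult) -> pd.DataFrame:
    """Sorted final objectives per start — the multi-start waterfall."""
    df = pd.DataFrame(fit_result.per_start, columns=["start_index", "objective"])
    return df.sort_values("objective", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Joint vs. individual single-dose fits
# ---------------------------------------------------------------------------

def fit_individual_doses(dataset: TimeCourseDataset, spec: ModelSpec | None = None,
                         n_starts: int = 20, seed: int = 0,
                         condition: str | None = None) -> dict[float, FitResult]:
    """Fit the single-dose RTF independently to each dose of one condition."""
    spec = spec if spec is not None else ModelSpec.single_dose(transient=False)
    if spec.dose_dependent:
        raise SpecError("individual-dose fitting requires a dose-independent spec")
    fits: dict[float, FitResult] = {}
    for k, d in enumerate(dataset.doses):
        sub = dataset.subset(condition=condition, dose=float(d))
        fits[float(d)] = fit(sub, spec, n_starts=n_starts, seed=seed + 1000 * k)
    return fits


def compare_joint_vs_individual(dataset: TimeCourseDataset,
                                joint_spec: ModelSpec | None = None,
                                single_spec: ModelSpec | None = None,
                                n_starts: int = 30, seed: int = 0,
                                condition: str | None = None) -> dict:
    """Chi-square comparison of the joint dose-dependent RTF against
    independent single-dose fits, both evaluated with the error SD fixed at
    the joint fit's estimate, plus the LRT of joint (nested) vs individual
    (full).  A p-value near 1 means the joint Hill structure loses nothing.
    """
    joint_spec = joint_spec if joint_spec is not None else ModelSpec.dose_response()
    single_spec = single_spec if single_spec is not None else ModelSpec.single_dose(transient=False)
    data = dataset if condition is None else dataset.subset(condition=condition)

    joint = fit(data, joint_spec, n_starts=n_starts, seed=seed)
    sigma = joint.estimates["sigma"]
    chi2_joint = chi_square(joint.estimates, data, joint_spec, sigma, joint.space)

    individual = fit_individual_doses(data, single_spec, n_starts=max(10, n_starts // 2),
                                      seed=seed)
    chi2_ind = sum(
        chi_square(f.estimates, data.subset(dose=d), single_spec, sigma, f.space)
        for d, f in individual.items())

    # sigma is fixed for the comparison, so it is not counted as fitted
    n_joint = len(joint.space.free_names) - 1
    n_single = len(next(iter(individual.values())).space.free_names) - 1
    n_ind = n_single * len(individual)
    df = n_ind - n_joint
    stat = max(0.0, chi2_joint - chi2_ind)
    return {
        "chi2_joint": chi2_joint,
        "chi2_individual": float(chi2_ind),
        "n_params_joint": n_joint,
        "n_params_individual": n_ind,
        "df": df,
        "lrt_statistic": stat,
        "p_value": float(stats.chi2.sf(stat, df)),
        "sigma_fixed": sigma,
        "joint_fit": joint,
        "individual_fits": individual,
    }
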
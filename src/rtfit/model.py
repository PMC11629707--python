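"""Retarded transient function (RTF) in time, dose and condition space.

The RTF describes the non-oscillatory response of a signalling compound as
the sum of a sustained component ``A (1 - exp(-alpha t))``, a transient
component ``B (1 - exp(-beta t)) exp(-gamma t)`` and an offset ``b``, where
``t`` is a non-linearly retarded transformation of experimental time
controlled by a delay parameter ``tau``.  Dose dependence enters by replacing
each of the six dynamic parameters ``{A, B, alpha, beta, gamma, tau}`` with a
Hill function of the dose; differences between biological conditions are
expressed as multiplicative fold-changes on the reference condition's
parameters.

Everything in this module is a pure function of its arguments; estimation and
the CLI are layered on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DYNAMIC_PARAMS",
    "SingleDoseParams",
    "HillTriplet",
    "DoseParams",
    "FoldChangeSet",
    "ModelSpec",
    "transform_time",
    "eval_hill",
    "eval_rtf",
    "dose_params_at",
    "eval_dose_rtf",
    "apply_fold_changes",
    "free_parameter_names",
    "count_free_parameters",
]

#: Canonical order of the dynamic parameters of the time-dependent RTF.
DYNAMIC_PARAMS = ("A", "B", "alpha", "beta", "gamma", "tau")

#: Amplitude -> rate constants that lose all influence when the amplitude is
#: structurally fixed to zero (the corresponding exponential term vanishes).
_RATES_OF_AMPLITUDE = {"A": ("alpha",), "B": ("beta", "gamma")}

_LN10 = math.log(10.0)


class SpecError(ValueError):
    """Inconsistent model structure (ties, fixed parameters, conditions)."""


def _check_finite(name: str, *values: float) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} must be finite, got {v!r}")


def transform_time(t_real, tau: float, T: float):
    """Retarded time transformation of experimental time.

    ``t = log10(10^(t_real*10/T) + 10^tau) - log10(1 + 10^tau)``

    Parameters
    ----------
    t_real
        Experimental time(s), scalar or array, finite.
    tau
        Time shift; larger values delay the response onset.
    T
        Range of the measurement times (``max(t) - min(t)``), > 0.  Dividing
        by ``T`` makes the transformation independent of time units.

    Returns
    -------
    Transformed time in ``[0, 10*t_real/T]``; exactly 0 at ``t_real = 0``,
    monotone increasing in ``t_real`` and non-increasing in ``tau``.
    """
    t_real = np.asarray(t_real, dtype=float)
    _check_finite("t_real", t_real)
    _check_finite("tau", tau)
    _check_finite("T", T)
    if T <= 0:
        raise ValueError(f"time range T must be > 0, got {T}")
    a = t_real * (10.0 / T)
    # log10(10^a + 10^tau) via logaddexp in natural base: immune to overflow
    # for exponents far beyond float range.
    out = (np.logaddexp(a * _LN10, tau * _LN10) - np.logaddexp(0.0, tau * _LN10)) / _LN10
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SingleDoseParams:
    """Parameters of the time-dependent RTF at a single dose.

    ``A``/``B`` are the sustained/transient amplitudes, ``alpha``/``beta``/
    ``gamma`` the rate constants (reciprocals are timescales), ``tau`` the
    retardation, ``b`` the offset and ``sigma`` the SD of the additive
    Gaussian measurement error.  Rate constants must be non-negative (zero is
    the degenerate no-response limit reached e.g. at dose 0) and ``sigma``
    strictly positive.
    """

    A: float
    B: float
    alpha: float
    beta: float
    gamma: float
    tau: float
    b: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        _check_finite(
            "SingleDoseParams",
            self.A, self.B, self.alpha, self.beta, self.gamma,
            self.tau, self.b, self.sigma,
        )
        for name in ("alpha", "beta", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def eval_rtf(t_real, p: SingleDoseParams, T: float):
    """Expected response of the time-dependent RTF at ``t_real``.

    Returns ``A(1-e^(-alpha t)) + B(1-e^(-beta t))e^(-gamma t) + b`` with
    ``t = transform_time(t_real, p.tau, T)``.  Equals ``b`` exactly at
    ``t_real = 0`` and tends to ``A + b`` as ``t_real -> inf`` for
    ``gamma > 0``.
    """
    if not isinstance(p, SingleDoseParams):
        p = SingleDoseParams(*p)
    t = transform_time(t_real, p.tau, T)
    sustained = p.A * -np.expm1(-p.alpha * np.asarray(t))
    transient = p.B * -np.expm1(-p.beta * np.asarray(t)) * np.exp(-p.gamma * np.asarray(t))
    out = sustained + transient + p.b
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class HillTriplet:
    """One Hill dose–response law ``M d^h / (K^h + d^h)``.

    ``M`` is the maximal value (in the units of the dynamic parameter it
    governs, may be negative for down-regulation), ``K >= 0`` the
    half-maximal dose (EC50) and ``h > 0`` the Hill coefficient.  The
    ``decreasing`` direction, ``M (1 - d^h/(K^h + d^h))``, is used for the
    retardation ``tau``, which shrinks with increasing dose.

    ``K = 0`` is a structural flag meaning "no dose dependence": the law is
    then the constant ``M`` for either direction (see the package methods
    note; this is a definition, not the ``K -> 0`` limit of the decreasing
    form).
    """

    M: float
    K: float
    h: float = 1.0
    direction: str = "increasing"

    def __post_init__(self) -> None:
        _check_finite("HillTriplet", self.M, self.K, self.h)
        if self.K < 0:
            raise ValueError("half-maximal dose K must be >= 0")
        if self.h <= 0:
            raise ValueError("Hill coefficient h must be > 0")
        if self.direction not in ("increasing", "decreasing"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @classmethod
    def constant(cls, value: float, direction: str = "increasing") -> "HillTriplet":
        """Dose-independent triplet (K = 0) evaluating to ``value`` everywhere."""
        return cls(M=value, K=0.0, h=1.0, direction=direction)


def _hill_fraction(d, K, h):
    """``d^h / (K^h + d^h)`` computed stably as ``1 / (1 + (K/d)^h)``."""
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(d > 0, np.asarray(K) / np.where(d > 0, d, 1.0), np.inf)
        frac = 1.0 / (1.0 + ratio ** np.asarray(h))
    return np.where(d > 0, frac, 0.0)


def eval_hill(triplet: HillTriplet, d):
    """Evaluate a Hill triplet at dose(s) ``d >= 0``."""
    d = np.asarray(d, dtype=float)
    _check_finite("dose", d)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    if triplet.K == 0:
        out = np.full_like(d, triplet.M, dtype=float)
        return out if out.ndim else float(out)
    frac = _hill_fraction(d, triplet.K, triplet.h)
    if triplet.direction == "decreasing":
        frac = 1.0 - frac
    out = triplet.M * frac
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DoseParams:
    """Dose-dependent RTF parameters: one Hill triplet per dynamic parameter.

    ``tau`` must carry a decreasing triplet (response gets faster, not
    slower, with dose); the remaining five are increasing.  The offset ``b``
    and error SD ``sigma`` do not depend on dose.
    """

    A: HillTriplet
    B: HillTriplet
    alpha: HillTriplet
    beta: HillTriplet
    gamma: HillTriplet
    tau: HillTriplet
    b: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.tau.direction != "decreasing":
            raise ValueError("tau's Hill triplet must be decreasing")
        for name in ("A", "B", "alpha", "beta", "gamma"):
            if getattr(self, name).direction != "increasing":
                raise ValueError(f"{name}'s Hill triplet must be increasing")
        _check_finite("DoseParams", self.b, self.sigma)
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def dose_params_at(dp: DoseParams, d: float, ties: Mapping[str, str] | None = None) -> SingleDoseParams:
    """Resolve the dose-dependent parameters at a single dose.

    Each dynamic parameter is evaluated through its Hill triplet; ``b`` and
    ``sigma`` pass through unchanged.  ``ties`` (e.g. ``{"gamma": "alpha"}``)
    are applied *after* the Hill evaluation, so a tied rate tracks its source
    at every dose.
    """
    values = {name: eval_hill(getattr(dp, name), d) for name in DYNAMIC_PARAMS}
    if ties:
        for tied, source in ties.items():
            if tied not in values or source not in values:
                raise SpecError(f"cannot tie {tied!r} to {source!r}")
            values[tied] = values[source]
    return SingleDoseParams(b=dp.b, sigma=dp.sigma, **values)


def eval_dose_rtf(t_real, d: float, dp: DoseParams, T: float,
                  ties: Mapping[str, str] | None = None):
    """Expected response of the dose-dependent RTF at ``(t_real, d)``."""
    return eval_rtf(t_real, dose_params_at(dp, d, ties=ties), T)


@dataclass(frozen=True)
class FoldChangeSet:
    """Multiplicative fold-changes Δ for one non-reference condition.

    Keys name Hill-parameter scalars of :class:`DoseParams` in the flat
    ``"<dynamic>_<M|K|h>"`` form (e.g. ``"A_M"``, ``"alpha_K"``) or ``"b"``.
    All factors must be > 0; Δ = 1 means no condition effect.
    """

    factors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.factors.items():
            _check_finite(f"fold-change {name}", value)
            if value <= 0:
                raise ValueError(f"fold-change {name} must be > 0, got {value}")


def apply_fold_changes(dp_ref: DoseParams, fc: FoldChangeSet) -> DoseParams:
    """Reference-condition parameters scaled by the fold-changes of ``fc``.

    Scalars absent from ``fc`` are shared with the reference bit-exactly.
    """
    if not isinstance(fc, FoldChangeSet):
        fc = FoldChangeSet(fc)
    triplets = {name: getattr(dp_ref, name) for name in DYNAMIC_PARAMS}
    b = dp_ref.b
    for name, delta in fc.factors.items():
        if name == "b":
            b = b * delta
            continue
        try:
            dyn, comp = name.rsplit("_", 1)
        except ValueError:
            raise SpecError(f"unknown fold-change target {name!r}") from None
        if dyn not in triplets or comp not in ("M", "K", "h"):
            raise SpecError(f"unknown fold-change target {name!r}")
        trip = triplets[dyn]
        triplets[dyn] = replace(trip, **{comp: getattr(trip, comp) * delta})
    return DoseParams(b=b, sigma=dp_ref.sigma, **triplets)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative structure of an RTF model.

    Attributes
    ----------
    dose_dependent
        Dynamic parameters carrying a Hill triplet ``{M, K, h}``; the rest
        are dose-independent scalars.
    fixed_to_zero
        Amplitudes structurally absent (``B = 0`` removes the transient part
        and with it ``beta`` and ``gamma``; ``A = 0`` removes ``alpha``).
    ties
        ``tied -> source`` equality constraints applied after Hill
        evaluation, e.g. the default biology-motivated ``gamma ≡ alpha``
        (sustained and transient parts triggered together).
    regulation_sign
        ``"up"`` (default) or ``"down"`` per amplitude; down-regulation
        flips the sign of the amplitude bounds during estimation.
    conditions
        Ordered condition labels; the first is the reference.
    condition_dependent
        Free-parameter base names (e.g. ``"A_M"``, ``"tau"`` or ``"b"``)
        that carry one fold-change Δ per non-reference condition.
    """

    dose_dependent: tuple[str, ...] = ()
    fixed_to_zero: tuple[str, ...] = ()
    ties: Mapping[str, str] = field(default_factory=dict)
    regulation_sign: Mapping[str, str] = field(default_factory=dict)
    conditions: tuple[str, ...] = ("control",)
    condition_dependent: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose_dependent", tuple(self.dose_dependent))
        object.__setattr__(self, "fixed_to_zero", tuple(self.fixed_to_zero))
        object.__setattr__(self, "ties", dict(self.ties))
        object.__setattr__(self, "regulation_sign", dict(self.regulation_sign))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "condition_dependent", tuple(self.condition_dependent))
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        for p in self.dose_dependent:
            if p not in DYNAMIC_PARAMS:
                raise SpecError(f"unknown dynamic parameter {p!r}")
        for p in self.fixed_to_zero:
            if p not in ("A", "B"):
                raise SpecError(f"only amplitudes can be fixed to zero, not {p!r}")
        if len(set(self.dose_dependent)) != len(self.dose_dependent):
            raise SpecError("duplicate entries in dose_dependent")
        if not self.conditions:
            raise SpecError("at least one condition required")
        if len(set(self.conditions)) != len(self.conditions):
            raise SpecError("duplicate condition labels")
        active = self._active_dynamic()
        for tied, source in self.ties.items():
            if tied not in DYNAMIC_PARAMS or source not in DYNAMIC_PARAMS:
                raise SpecError(f"tie {tied!r} -> {source!r} names unknown parameters")
            if tied in self.dose_dependent:
                raise SpecError(f"{tied!r} cannot be both tied and dose-dependent")
            if source not in active:
                raise SpecError(f"tie source {source!r} is not an active parameter")
            if tied not in self._present_dynamic():
                raise SpecError(f"tied parameter {tied!r} is structurally absent")
        for sign in self.regulation_sign.values():
            if sign not in ("up", "down"):
                raise SpecError(f"regulation sign must be 'up' or 'down', got {sign!r}")
        base = set(self._base_names())
        for name in self.condition_dependent:
            if name not in base or name == "sigma":
                raise SpecError(f"{name!r} cannot be condition-dependent")
        if self.condition_dependent and len(self.conditions) < 2:
            raise SpecError("condition-dependent parameters need >= 2 conditions")
        for p in self.dose_dependent:
            if p not in self._present_dynamic():
                raise SpecError(f"dose-dependent parameter {p!r} is structurally absent")

    def _present_dynamic(self) -> tuple[str, ...]:
        """Dynamic parameters not removed by an amplitude fixed to zero."""
        gone = set(self.fixed_to_zero)
        for amp in self.fixed_to_zero:
            gone.update(_RATES_OF_AMPLITUDE[amp])
        return tuple(p for p in DYNAMIC_PARAMS if p not in gone)

    def _active_dynamic(self) -> tuple[str, ...]:
        """Present dynamic parameters contributing their own free scalars."""
        return tuple(p for p in self._present_dynamic() if p not in self.ties)

    def _base_names(self) -> list[str]:
        names: list[str] = []
        for p in self._active_dynamic():
            if p in self.dose_dependent:
                names += [f"{p}_M", f"{p}_K", f"{p}_h"]
            else:
                names.append(p)
        names += ["b", "sigma"]
        return names

    @property
    def reference_condition(self) -> str:
        return self.conditions[0]

    def sign_of(self, amplitude: str) -> str:
        return self.regulation_sign.get(amplitude, "up")

    def delta_name(self, base: str, condition: str) -> str:
        return f"delta_{base}_{condition}"

    # -- constructors ------------------------------------------------------

    @classmethod
    def single_dose(cls, transient: bool = True, tie_rates: bool = False,
                    **kwargs) -> "ModelSpec":
        """Plain time-dependent RTF (no dose dependence).

        With ``transient=False`` the amplitude ``B`` is fixed to zero,
        leaving the five parameters ``{A, alpha, tau, b, sigma}``.
        ``tie_rates`` applies the default ``gamma ≡ alpha`` tie.
        """
        fixed = () if transient else ("B",)
        ties = {"gamma": "alpha"} if (transient and tie_rates) else {}
        return cls(fixed_to_zero=fixed, ties=ties, **kwargs)

    @classmethod
    def dose_response(cls, dose_dependent: Sequence[str] = ("A", "alpha", "tau"),
                      transient: bool = False, tie_rates: bool = False,
                      **kwargs) -> "ModelSpec":
        """Dose-dependent RTF; defaults to the sustained-only application
        structure with Hill laws on ``A``, ``alpha`` and ``tau`` (11 free
        parameters for one condition)."""
        fixed = () if transient else ("B",)
        ties = {"gamma": "alpha"} if (transient and tie_rates) else {}
        return cls(dose_dependent=tuple(dose_dependent), fixed_to_zero=fixed,
                   ties=ties, **kwargs)


def free_parameter_names(spec: ModelSpec) -> list[str]:
    """Ordered names of the free scalars implied by ``spec``.

    Dose-dependent dynamic parameters contribute ``{name}_M/_K/_h``;
    dose-independent ones a single scalar; then ``b`` and ``sigma``; then one
    ``delta_{base}_{condition}`` per condition-dependent base name and
    non-reference condition.
    """
    names = spec._base_names()
    for cond in spec.conditions[1:]:
        names += [spec.delta_name(base, cond) for base in spec.condition_dependent]
    return names


def count_free_parameters(spec: ModelSpec,
                          n_doses_fitted_individually: int | None = None) -> int:
    """Number of free scalars of ``spec``.

    With ``n_doses_fitted_individually = D``, counts ``D`` independent
    single-dose fits of the (necessarily dose-independent, single-condition)
    structure — e.g. 7 sustained-only fits use 35 parameters, against 11 for
    the joint dose-dependent model.
    """
    n = len(free_parameter_names(spec))
    if n_doses_fitted_individually is not None:
        if spec.dose_dependent:
            raise SpecError("individual-dose counting requires a dose-independent spec")
        if len(spec.conditions) > 1:
            raise SpecError("individual-dose counting requires a single condition")
        if n_doses_fitted_individually < 1:
            raise SpecError("need at least one dose")
        n *= n_doses_fitted_individually
    return n
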
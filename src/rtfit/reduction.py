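"""Backward elimination of dose- and condition-dependencies.

Candidates for removal are (i) a dynamic parameter's Hill dose-dependence —
its ``K`` is set to zero so the Hill law collapses to the constant ``M`` and
the Hill coefficient loses all influence, dropping two free parameters —
and (ii) a fold-change Δ fixed to 1, sharing the parameter across
conditions.  Each round tentatively removes every candidate, refits, and
permanently removes the one with the largest LRT p-value if it exceeds the
significance threshold; the loop stops when every removal would
significantly worsen the fit.  The trail records every decision so order
effects can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .data import TimeCourseDataset
from .estimation import FitResult, OptimizationError, default_space, fit
from .model import ModelSpec, SpecError, count_free_parameters
from .uncertainty import lrt

__all__ = [
    "ReductionStep",
    "ReductionTrail",
    "eliminate_dose_dependency",
    "eliminate_condition_dependency",
    "backward_eliminate",
]


def eliminate_dose_dependency(spec: ModelSpec, param: str) -> ModelSpec:
    """Spec with ``param``'s Hill dose-dependence removed (K -> 0).

    The parameter becomes a single dose-independent scalar (the former
    ``M``); its ``K`` and ``h`` disappear, so the free-parameter count drops
    by 2.  Condition fold-changes on the removed ``K``/``h`` scalars are
    dropped with them; a Δ on the ``M`` migrates to the scalar.
    """
    if param not in spec.dose_dependent:
        raise SpecError(f"{param!r} is not dose-dependent")
    cond_dep = []
    for name in spec.condition_dependent:
        if name in (f"{param}_K", f"{param}_h"):
            continue
        cond_dep.append(param if name == f"{param}_M" else name)
    return replace(spec,
                   dose_dependent=tuple(p for p in spec.dose_dependent if p != param),
                   condition_dependent=tuple(dict.fromkeys(cond_dep)))


def eliminate_condition_dependency(spec: ModelSpec, param: str) -> ModelSpec:
    """Spec with ``param``'s fold-change fixed to Δ = 1 (shared across
    conditions); drops one free parameter per non-reference condition."""
    if param not in spec.condition_dependent:
        raise SpecError(f"{param!r} carries no fold-change")
    return replace(spec, condition_dependent=tuple(
        n for n in spec.condition_dependent if n != param))


@dataclass(frozen=True)
class ReductionStep:
    """One recorded elimination decision."""

    kind: str            # "dose" | "condition"
    term: str
    statistic: float
    df: int
    p_value: float
    ll_before: float
    ll_after: float
    accepted: bool


@dataclass(frozen=True)
class ReductionTrail:
    """Audit trail of a backward-elimination run."""

    steps: tuple[ReductionStep, ...]
    evaluations: tuple[ReductionStep, ...]   # every tentative refit, all rounds
    initial_spec: ModelSpec
    final_spec: ModelSpec
    initial_fit: FitResult
    final_fit: FitResult
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "step": i + 1, "kind": s.kind, "term": s.term,
            "statistic": s.statistic, "df": s.df, "p_value": s.p_value,
            "ll_before": s.ll_before, "ll_after": s.ll_after,
            "decision": "removed" if s.accepted else "kept",
        } for i, s in enumerate(self.steps)]
        return pd.DataFrame(rows, columns=["step", "kind", "term", "statistic",
                                           "df", "p_value", "ll_before",
                                           "ll_after", "decision"])


def _candidates(spec: ModelSpec, protected: set[str]) -> list[tuple[str, str]]:
    out = [("dose", p) for p in spec.dose_dependent if f"dose:{p}" not in protected]
    out += [("condition", p) for p in spec.condition_dependent
            if f"condition:{p}" not in protected]
    return out


def _remove(spec: ModelSpec, kind: str, term: str) -> ModelSpec:
    return (eliminate_dose_dependency(spec, term) if kind == "dose"
            else eliminate_condition_dependency(spec, term))


def backward_eliminate(dataset: TimeCourseDataset, spec: ModelSpec,
                       alpha: float = 0.05, seed: int = 0,
                       n_starts: int = 30, n_starts_refit: int = 10,
                       protected: Sequence[str] = ()) -> ReductionTrail:
    """Greedy backward elimination at significance level ``alpha``.

    ``protected`` entries (``"dose:tau"``, ``"condition:A_M"``) encode prior
    knowledge and are never candidates.  Tentative refits warm-start from
    the current optimum plus ``n_starts_refit`` fresh Latin-hypercube
    starts; a refit that fails outright is skipped for that round.
    """
    protected = set(protected)
    current_spec = spec
    current_fit = fit(dataset, spec, n_starts=n_starts, seed=seed)
    initial_fit = current_fit

    steps: list[ReductionStep] = []
    evaluations: list[ReductionStep] = []
    round_seed = seed
    while True:
        cands = _candidates(current_spec, protected)
        if not cands:
            break
        trials: list[tuple[ReductionStep, ModelSpec, FitResult]] = []
        for kind, term in cands:
            round_seed += 1
            new_spec = _remove(current_spec, kind, term)
            df = (2 if kind == "dose" else len(current_spec.conditions) - 1)
            warm = dict(current_fit.estimates)
            if kind == "dose" and f"{term}_M" in warm:
                warm.setdefault(term, warm[f"{term}_M"])  # collapsed scalar = former M
            try:
                new_fit = fit(dataset, new_spec, n_starts=n_starts_refit,
                              seed=round_seed, warm_start=warm)
            except (OptimizationError, SpecError):
                continue
            stat, p = lrt(new_fit, current_fit, df=df)
            step = ReductionStep(kind, term, stat, df, p,
                                 current_fit.loglik, new_fit.loglik, False)
            evaluations.append(step)
            trials.append((step, new_spec, new_fit))
        if not trials:
            break
        best_step, best_spec, best_fit = max(trials, key=lambda t: t[0].p_value)
        if best_step.p_value > alpha:
            accepted = replace(best_step, accepted=True)
            steps.append(accepted)
            evaluations[evaluations.index(best_step)] = accepted
            assert count_free_parameters(best_spec) < count_free_parameters(current_spec)
            current_spec, current_fit = best_spec, best_fit
        else:
            steps.append(best_step)  # the refused removal that stopped the loop
            break

    return ReductionTrail(tuple(steps), tuple(evaluations), spec, current_spec,
                          initial_fit, current_fit, alpha)
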
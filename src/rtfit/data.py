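"""Tidy time-course tables and synthetic data emulating the study design.

The on-disk format is a long-format CSV with columns ``time, dose,
condition, replicate, value`` (header required, UTF-8, ``.`` decimal
separator), one row per measurement.  The synthetic generator draws additive
Gaussian noise around the dose-dependent RTF surface; the shipped fixture
mimics an ELISA read-out of nigericin-triggered inflammasome activation in
macrophages: seven doses, eight time points, three replicates, a wild-type
reference and a perturbed (knockout-like) condition, sustained-only
responses (B = 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    DoseParams,
    FoldChangeSet,
    HillTriplet,
    ModelSpec,
    apply_fold_changes,
    eval_dose_rtf,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "TimeCourseDataset",
    "FormatError",
    "read_timecourse",
    "write_timecourse",
    "simulate_dataset",
    "fixture_inflammasome_like",
    "fixture_truth",
    "fixture_spec",
]

REQUIRED_COLUMNS = ("time", "dose", "condition", "value")
COLUMNS = ("time", "dose", "condition", "replicate", "value")


class FormatError(ValueError):
    """Malformed input table (missing columns, bad numerics, negative doses)."""


@dataclass(frozen=True)
class TimeCourseDataset:
    """Validated collection of (time, dose, condition, replicate, value) rows."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        if len(df) == 0:
            raise FormatError("dataset is empty")
        df = df.copy()
        if "replicate" not in df.columns:
            df["replicate"] = 1
        bad_rows: list[str] = []
        for col in ("time", "dose", "value"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            for idx in df.index[coerced.isna() & df[col].notna()]:
                bad_rows.append(f"row {idx}: non-numeric {col} {df.at[idx, col]!r}")
            for idx in df.index[df[col].isna()]:
                bad_rows.append(f"row {idx}: missing {col}")
            df[col] = coerced
        if not bad_rows:
            for idx in df.index[df["dose"] < 0]:
                bad_rows.append(f"row {idx}: negative dose {df.at[idx, 'dose']}")
        if bad_rows:
            raise FormatError("invalid rows:\n" + "\n".join(bad_rows))
        df = df[list(COLUMNS)].reset_index(drop=True)
        times = np.unique(df["time"].to_numpy())
        if len(times) < 3:
            raise FormatError("need at least 3 distinct time points")
        object.__setattr__(self, "frame", df)

    # -- derived views -----------------------------------------------------

    @property
    def times(self) -> np.ndarray:
        """Sorted unique measurement times (all conditions pooled)."""
        return np.unique(self.frame["time"].to_numpy())

    @property
    def T(self) -> float:
        """Time range shared by all curves: max(time) - min(time)."""
        t = self.times
        return float(t[-1] - t[0])

    @property
    def doses(self) -> np.ndarray:
        """Sorted unique dose ladder."""
        return np.unique(self.frame["dose"].to_numpy())

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.frame["condition"]))

    def __len__(self) -> int:
        return len(self.frame)

    def values_for(self, condition: str | None = None) -> np.ndarray:
        df = self.frame
        if condition is not None:
            df = df[df["condition"] == condition]
        return df["value"].to_numpy()

    def subset(self, condition: str | None = None, dose: float | None = None) -> "TimeCourseDataset":
        df = self.frame
        if condition is not None:
            df = df[df["condition"] == condition]
        if dose is not None:
            df = df[df["dose"] == dose]
        if len(df) == 0:
            raise ValueError("subset selects no rows")
        return TimeCourseDataset(df.reset_index(drop=True))


def read_timecourse(path: str | Path) -> TimeCourseDataset:
    """Read a long-format time-course CSV, validating as it goes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    try:
        return TimeCourseDataset(df)
    except FormatError as err:
        raise FormatError(f"{path}: {err}") from None


def write_timecourse(dataset: TimeCourseDataset, path: str | Path) -> None:
    """Write a dataset as CSV with 17 significant digits (roundtrip-exact)."""
    dataset.frame.to_csv(path, index=False, float_format="%.17g")


def simulate_dataset(
    dp_by_condition: Mapping[str, DoseParams],
    doses: Sequence[float],
    times: Sequence[float],
    n_replicates: int = 1,
    sigma: float = 0.0,
    seed: int = 0,
    ties: Mapping[str, str] | None = None,
) -> TimeCourseDataset:
    """Draw a dataset from the dose-dependent RTF with additive N(0, sigma²) noise.

    Conditions are emitted in mapping order (first = reference).  The time
    range used by the retardation transform is ``max(times) - min(times)``.
    Deterministic under a fixed ``seed``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    times = np.asarray(list(times), dtype=float)
    doses = np.asarray(list(doses), dtype=float)
    if times.size == 0 or doses.size == 0:
        raise ValueError("times and doses must be non-empty")
    T = float(times.max() - times.min())
    rng = np.random.default_rng(seed)
    rows = []
    for condition, dp in dp_by_condition.items():
        for d in doses:
            mean = np.asarray(eval_dose_rtf(times, float(d), dp, T, ties=ties))
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, sigma, size=times.shape) if sigma > 0 else 0.0
                values = mean + noise
                rows.append(pd.DataFrame({
                    "time": times, "dose": d, "condition": condition,
                    "replicate": rep, "value": values,
                }))
    return TimeCourseDataset(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Synthetic fixture emulating the inflammasome ELISA design
# ---------------------------------------------------------------------------

#: Experimental design of the fixture: 7 log-spaced doses (µM-like units),
#: 8 time points (hour-like units), 3 replicates per cell.
FIXTURE_DOSES = tuple(float(x) for x in np.round(np.geomspace(1.0, 10.0, 7), 3))
FIXTURE_TIMES = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.5, 6.0)
FIXTURE_N_REPLICATES = 3


#: Generator truth for the reference ("wildtype") condition: sustained-only
#: response, Hill laws on A (amplitude), alpha (rate) and tau (delay).  The
#: EC50s sit inside the dose ladder and every Hill law approaches its
#: plateau within it, as in a well-designed dose-finding experiment.
_FIXTURE_WT_DYNAMICS = dict(
    A=HillTriplet(M=1.0, K=3.0, h=2.0),
    B=HillTriplet.constant(0.0),
    alpha=HillTriplet(M=1.2, K=2.0, h=2.0),
    beta=HillTriplet.constant(1.0),
    gamma=HillTriplet.constant(1.0),
    tau=HillTriplet(M=1.5, K=4.5, h=4.0, direction="decreasing"),
    b=0.05,
)


def _surface_range() -> float:
    dp = DoseParams(sigma=1.0, **_FIXTURE_WT_DYNAMICS)
    times = np.asarray(FIXTURE_TIMES)
    T = float(times.max() - times.min())
    vals = np.concatenate([
        np.asarray(eval_dose_rtf(times, d, dp, T)) for d in FIXTURE_DOSES])
    return float(vals.max() - vals.min())


#: Noise SD of the fixture: exactly 2% of the noise-free response range.
FIXTURE_SIGMA = 0.02 * _surface_range()

FIXTURE_WT = DoseParams(sigma=FIXTURE_SIGMA, **_FIXTURE_WT_DYNAMICS)

#: Fold-changes of the perturbed ("knockout") condition, mirroring a
#: perturbation that blunts the amplitude and rate, delays the response and
#: shifts/steepens the dose dependence.
FIXTURE_KO_FC = FoldChangeSet({
    "A_M": 0.4,
    "alpha_M": 0.5,
    "tau_M": 1.6,
    "A_K": 1.8,
    "alpha_h": 1.8,
})


def fixture_truth() -> dict:
    """Generator truth of the fixture, keyed for direct comparison with fits."""
    wt = FIXTURE_WT
    return {
        "params_by_condition": {
            "wildtype": wt,
            "knockout": apply_fold_changes(wt, FIXTURE_KO_FC),
        },
        "fold_changes": dict(FIXTURE_KO_FC.factors),
        "free_values": {
            "A_M": wt.A.M, "A_K": wt.A.K, "A_h": wt.A.h,
            "alpha_M": wt.alpha.M, "alpha_K": wt.alpha.K, "alpha_h": wt.alpha.h,
            "tau_M": wt.tau.M, "tau_K": wt.tau.K, "tau_h": wt.tau.h,
            "b": wt.b, "sigma": wt.sigma,
        },
        "doses": FIXTURE_DOSES,
        "times": FIXTURE_TIMES,
        "n_replicates": FIXTURE_N_REPLICATES,
        "sigma": wt.sigma,
    }


def fixture_spec(two_conditions: bool = True,
                 condition_dependent: Sequence[str] | None = None) -> ModelSpec:
    """ModelSpec matching the fixture's generating structure.

    Single condition: the 11-parameter sustained-only dose-dependent model.
    Two conditions: the same plus one Δ per condition-dependent base name
    (default: the five names perturbed in the fixture truth).
    """
    if not two_conditions:
        return ModelSpec.dose_response()
    if condition_dependent is None:
        condition_dependent = tuple(FIXTURE_KO_FC.factors)
    return ModelSpec.dose_response(
        conditions=("wildtype", "knockout"),
        condition_dependent=tuple(condition_dependent),
    )


def fixture_inflammasome_like(seed: int = 0, two_conditions: bool = True) -> TimeCourseDataset:
    """Synthetic inflammasome-activation-like dataset.

    7 doses × 8 times × 3 replicates per condition, sustained-only
    responses, additive Gaussian noise with a single sigma.  The generating
    parameters are exposed via :func:`fixture_truth`.
    """
    truth = fixture_truth()
    params = truth["params_by_condition"]
    if not two_conditions:
        params = {"wildtype": params["wildtype"]}
    return simulate_dataset(
        params,
        doses=FIXTURE_DOSES,
        times=FIXTURE_TIMES,
        n_replicates=FIXTURE_N_REPLICATES,
        sigma=truth["sigma"],
        seed=seed,
    )
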
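"""Dose-response and group-summary statistics for the cell assays.

The dose-response model is the one-parameter inhibitor-vs-normalized-
response curve Y = 100/(1 + X/IC50): Y is the remaining normalized current
in percent, X the blocker concentration. IC50 is the only free parameter
and is fitted by least squares on a log scale to enforce positivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "DoseResponseFit",
    "GroupSummary",
    "NonIdentifiableError",
    "predict_response",
    "fit_ic50",
    "percent_reduction",
    "summarize_inhibition",
]


class NonIdentifiableError(ValueError):
    """The dose-response data carry no information about IC50."""


@dataclass
class DoseResponseFit:
    ic50: float  # µM
    residual_sum_squares: float
    doses: np.ndarray  # µM
    responses: np.ndarray  # normalized response, percent

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float
    units: str = "%"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("sem must be non-negative")


def predict_response(dose, ic50: float):
    """Normalized response Y = 100/(1 + dose/ic50); accepts scalars or arrays."""
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("doses must be non-negative")
    out = 100.0 / (1.0 + dose / ic50)
    return float(out) if out.ndim == 0 else out


def fit_ic50(doses, responses) -> DoseResponseFit:
    """Least-squares estimate of IC50 for the one-parameter model.

    The sum of squared residuals is minimized over log10(IC50) with a
    deterministic coarse grid scan followed by bounded scalar minimization,
    so the result is reproducible and robust to the starting point.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape or doses.ndim != 1:
        raise ValueError("doses and responses must be matching 1-D arrays")
    positive = doses[doses > 0]
    if len(np.unique(positive)) < 2:
        raise ValueError("need at least two distinct positive doses")
    if np.ptp(responses) == 0:
        raise NonIdentifiableError("all responses are equal; IC50 is not identifiable")
    if np.any((responses < -10) | (responses > 110)):
        warnings.warn("responses outside [-10, 110] retained as measured",
                      stacklevel=2)

    lo = np.log10(positive.min()) - 3.0
    hi = np.log10(positive.max()) + 3.0

    def sse(log_ic50: float) -> float:
        resid = responses - 100.0 / (1.0 + doses / 10.0 ** log_ic50)
        return float(resid @ resid)

    grid = np.linspace(lo, hi, 241)
    values = [sse(g) for g in grid]
    center = grid[int(np.argmin(values))]
    step = grid[1] - grid[0]
    result = minimize_scalar(sse, bounds=(center - 2 * step, center + 2 * step),
                             method="bounded", options={"xatol": 1e-12})
    ic50 = float(10.0 ** result.x)
    return DoseResponseFit(ic50=ic50, residual_sum_squares=float(result.fun),
                           doses=doses, responses=responses)


def percent_reduction(control: GroupSummary, treated: GroupSummary) -> float:
    """100 × (control.mean − treated.mean) / control.mean."""
    if control.mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (control.mean - treated.mean) / control.mean


def summarize_inhibition(replicates, label: str = "", units: str = "%") -> GroupSummary:
    """Mean ± SEM (sample sd / sqrt(n)); a single replicate gets sem 0."""
    values = np.asarray(replicates, dtype=float)
    if values.size == 0:
        raise ValueError("empty replicate list")
    if values.size == 1:
        warnings.warn("single replicate: SEM set to 0 by convention", stacklevel=2)
        sem = 0.0
    else:
        sem = float(np.std(values, ddof=1) / np.sqrt(values.size))
    return GroupSummary(label=label, n=int(values.size), mean=float(values.mean()),
                        sem=sem, units=units)
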
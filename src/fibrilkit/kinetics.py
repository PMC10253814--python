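"""Boltzmann-sigmoid analysis of ThT fibrillization kinetics.

Amyloid growth curves monitored by Thioflavin T fluorescence are sigmoidal:
a lag phase (nucleation), an elongation phase, and a final plateau of mature
fibrils.  The empirical model fitted here is the Boltzmann sigmoid

    y(t) = y1 + (y2 - y1) / (1 + exp(-2 (t - t_half) / (t_half - t_lag)))

where ``y1`` and ``y2`` are the initial and final fluorescence plateaus,
``t_half`` is the time at 50% amplitude, and ``t_lag`` is the lag time --
geometrically, the intercept of the tangent at ``t_half`` with the ``y1``
baseline.  The apparent aggregation rate constant is

    k_agg = 2 / (t_half - t_lag)   [min^-1]

This module provides the model, a bounded nonlinear least-squares fitter,
trace normalization, replicate aggregation, and cross-condition comparison
utilities (percent reductions and Hofmeister/electroselectivity ranking).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    AlignmentError,
    DegenerateParameterError,
    GroupingError,
    NoTransitionError,
    OrderingError,
    ValidationError,
    ZeroRangeError,
)

__all__ = [
    "KineticTrace",
    "ReplicateSet",
    "SigmoidFit",
    "boltzmann_model",
    "fit_sigmoid",
    "aggregation_rate",
    "normalize_trace",
    "aggregate_replicates",
    "reduction_percent",
    "rank_conditions",
    "ELECTROSELECTIVITY_SERIES",
    "parse_condition",
]

#: Anion ordering by affinity for charged surfaces (electroselectivity),
#: the inverse of the Hofmeister solubility series for monovalent anions.
ELECTROSELECTIVITY_SERIES: tuple[str, ...] = ("HSO4", "AC", "Cl", "NO3", "BF4")

_CONDITION_RE = re.compile(
    r"^\s*(?:EMIM\s+)?(?P<anion>HSO4|AC|Cl|NO3|BF4)\s*\[?\s*(?P<conc>\d+(?:\.\d+)?)\s*mM\s*\]?\s*$",
    re.IGNORECASE,
)

_ANION_CANONICAL = {a.lower(): a for a in ELECTROSELECTIVITY_SERIES}


def parse_condition(label: str) -> tuple[str | None, float]:
    """Split a condition label into (anion, concentration_mM).

    ``"control"`` (any case) maps to ``(None, 0.0)``.  Ionic-liquid labels
    follow the ``"EMIM <anion> [<c> mM]"`` convention, with the cation prefix
    and brackets optional.
    """
    if label.strip().lower() == "control":
        return None, 0.0
    m = _CONDITION_RE.match(label)
    if m is None:
        raise ValidationError(f"unrecognized condition label: {label!r}")
    anion = _ANION_CANONICAL[m.group("anion").lower()]
    return anion, float(m.group("conc"))


@dataclass(frozen=True)
class KineticTrace:
    """One ThT fluorescence time course for a single condition/replicate.

    Attributes
    ----------
    times : ndarray
        Sampling times in minutes, strictly increasing, length >= 5.
    intensities : ndarray
        Fluorescence intensities (arbitrary units), same length as ``times``.
    condition : str
        Condition label, e.g. ``"control"`` or ``"EMIM Cl [25 mM]"``.
    replicate : int
        Replicate identifier.
    """

    times: np.ndarray
    intensities: np.ndarray
    condition: str = "control"
    replicate: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValidationError("times and intensities must be 1-D and equal length")
        if t.size < 5:
            raise ValidationError("a kinetic trace needs at least 5 points")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise ValidationError("times and intensities must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate traces of one condition with their mean and average deviation.

    ``avg_dev_trace`` is the per-timepoint mean absolute deviation from the
    replicate mean (the convention used for kinetic error bars); it is zero
    everywhere for a single replicate.
    """

    traces: tuple[KineticTrace, ...]
    mean_trace: KineticTrace
    avg_dev_trace: np.ndarray

    @property
    def condition(self) -> str:
        return self.mean_trace.condition


@dataclass(frozen=True)
class SigmoidFit:
    """Boltzmann-sigmoid parameters fitted to one trace.

    ``k_agg`` always equals ``2 / (t_half - t_lag)``.  ``uncertainties`` holds
    1-sigma standard errors for (y1, y2, t_lag, t_half) derived from the local
    curvature of the least-squares objective; ``k_agg_uncertainty`` is the
    corresponding propagated error.  ``flagged`` marks fits whose relative
    parameter uncertainty exceeds ``flag_threshold`` (default 20%), the gate
    used to reject over-steep or under-sampled curves.
    """

    y1: float
    y2: float
    t_lag: float
    t_half: float
    k_agg: float
    uncertainties: dict[str, float] = field(default_factory=dict)
    k_agg_uncertainty: float = float("nan")
    residual_rms: float = float("nan")
    converged: bool = True
    flagged: bool = False
    condition: str = ""
    replicate: int | None = None

    @property
    def accepted(self) -> bool:
        """A fit usable for downstream comparison: converged and well-ordered."""
        return self.converged and self.t_half > self.t_lag > 0 and self.y2 > self.y1


def boltzmann_model(
    t: float | np.ndarray, y1: float, y2: float, t_lag: float, t_half: float
) -> float | np.ndarray:
    """Evaluate the Boltzmann sigmoid at time(s) ``t``.

    Raises
    ------
    DegenerateParameterError
        If ``t_half == t_lag`` (the exponent is undefined).
    """
    if t_half == t_lag:
        raise DegenerateParameterError("t_half must differ from t_lag")
    t = np.asarray(t, dtype=float) if not np.isscalar(t) else t
    z = -2.0 * (np.asarray(t, dtype=float) - t_half) / (t_half - t_lag)
    # clip avoids overflow in exp for extreme times; the sigmoid saturates anyway
    out = y1 + (y2 - y1) / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))
    if np.isscalar(t):
        return float(out)
    return out


def aggregation_rate(t_lag: float, t_half: float) -> float:
    """Apparent aggregation rate constant k_agg = 2/(t_half - t_lag) in min^-1.

    Raises
    ------
    OrderingError
        If ``t_half <= t_lag``.
    """
    if t_half <= t_lag:
        raise OrderingError(f"require t_half > t_lag, got {t_half} <= {t_lag}")
    return 2.0 / (t_half - t_lag)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Cheap, robust starting point: plateau means and threshold crossings."""
    y1 = float(np.mean(y[:3]))
    y2 = float(np.mean(y[-3:]))
    mid = 0.5 * (y1 + y2)
    low = y1 + 0.1 * (y2 - y1)
    above_mid = np.nonzero(y >= mid)[0]
    above_low = np.nonzero(y >= low)[0]
    t_half = float(t[above_mid[0]]) if above_mid.size else float(t[t.size // 2])
    t_low = float(t[above_low[0]]) if above_low.size else float(t[0])
    gap = max(t_half - t_low, (t[-1] - t[0]) / max(len(t) - 1, 1))
    t_lag = max(t_half - gap, 0.25 * t_half) if t_half > 0 else gap
    return y1, y2, max(t_lag, 1e-6), t_half


def fit_sigmoid(
    trace: KineticTrace,
    *,
    flag_threshold: float = 0.20,
    xtol: float = 1e-8,
    max_nfev: int = 5000,
) -> SigmoidFit:
    """Fit the Boltzmann sigmoid to a trace by bounded nonlinear least squares.

    The fit is parametrized as (y1, y2, t_lag, gap) with ``gap = t_half -
    t_lag > 0`` so the ordering constraint holds by construction; t_lag is
    bounded in (0, t_max).  Standard errors come from the Jacobian at the
    optimum.  Fits whose relative parameter uncertainty exceeds
    ``flag_threshold`` are flagged (not rejected) -- the gate that, at 20%,
    screens out over-steep curves whose parameters are not trustworthy.

    Raises
    ------
    NoTransitionError
        If the trace has no dynamic range or no sigmoidal rise.
    """
    t = trace.times
    y = trace.intensities
    yrange = float(np.ptp(y))
    if yrange <= 0:
        raise NoTransitionError("constant trace: no transition to fit")
    rise = float(np.mean(y[-3:]) - np.mean(y[:3]))
    if rise <= 0.1 * yrange:
        raise NoTransitionError("trace shows no sigmoidal rise above scatter")

    y1_0, y2_0, t_lag_0, t_half_0 = _initial_guess(t, y)
    gap_0 = max(t_half_0 - t_lag_0, 1e-3)
    t_max = float(t[-1])
    p0 = np.array([y1_0, y2_0, t_lag_0, gap_0])
    lower = np.array([y1_0 - yrange, y1_0 - yrange, 1e-9, 1e-9])
    upper = np.array([y2_0 + yrange, y2_0 + 2 * yrange, t_max, t_max])
    p0 = np.clip(p0, lower + 1e-12, upper - 1e-12)

    def residuals(p: np.ndarray) -> np.ndarray:
        y1, y2, t_lag, gap = p
        return boltzmann_model(t, y1, y2, t_lag, t_lag + gap) - y

    result = least_squares(
        residuals, p0, bounds=(lower, upper), xtol=xtol, ftol=xtol, gtol=xtol,
        max_nfev=max_nfev,
    )
    y1, y2, t_lag, gap = result.x
    t_half = t_lag + gap
    n, p = t.size, 4
    residual_rms = float(np.sqrt(np.mean(result.fun**2)))

    # covariance from J^T J; singular Jacobians leave uncertainties as inf
    dof = max(n - p, 1)
    s_sq = 2.0 * result.cost / dof
    try:
        cov = np.linalg.inv(result.jac.T @ result.jac) * s_sq
        perr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        var_t_half = cov[2, 2] + cov[3, 3] + 2.0 * cov[2, 3]
        err_t_half = math.sqrt(max(var_t_half, 0.0))
    except np.linalg.LinAlgError:
        perr = np.full(p, np.inf)
        err_t_half = float("inf")

    uncertainties = {
        "y1": float(perr[0]),
        "y2": float(perr[1]),
        "t_lag": float(perr[2]),
        "t_half": float(err_t_half),
    }
    k_agg = 2.0 / gap
    k_err = 2.0 / gap**2 * float(perr[3])

    rel_errs = []
    for key, val in (("y1", y1), ("y2", y2), ("t_lag", t_lag), ("t_half", t_half)):
        scale = abs(val) if key in ("t_lag", "t_half") else yrange
        if scale > 0:
            rel_errs.append(uncertainties[key] / scale)
    # the lag-to-half gap governs k_agg; over-steep curves resolve it poorly
    rel_errs.append(float(perr[3]) / gap)
    flagged = bool(rel_errs and max(rel_errs) > flag_threshold)

    return SigmoidFit(
        y1=float(y1),
        y2=float(y2),
        t_lag=float(t_lag),
        t_half=float(t_half),
        k_agg=float(k_agg),
        uncertainties=uncertainties,
        k_agg_uncertainty=float(k_err),
        residual_rms=residual_rms,
        converged=bool(result.success),
        flagged=flagged,
        condition=trace.condition,
        replicate=trace.replicate,
    )


def normalize_trace(trace: KineticTrace, fit: SigmoidFit) -> KineticTrace:
    """Map intensities to (y - y1)/(y2 - y1) so the fitted plateaus become 0 and 1.

    Raises
    ------
    ZeroRangeError
        If the fitted plateaus coincide.
    """
    if fit.y2 == fit.y1:
        raise ZeroRangeError("fit has zero amplitude (y2 == y1)")
    scaled = (trace.intensities - fit.y1) / (fit.y2 - fit.y1)
    return KineticTrace(
        times=trace.times.copy(),
        intensities=scaled,
        condition=trace.condition,
        replicate=trace.replicate,
    )


def aggregate_replicates(traces: Iterable[KineticTrace]) -> ReplicateSet:
    """Combine replicate traces into a mean trace with average absolute deviation.

    All traces must share an identical time grid (the plate-reader sampling
    schedule).  The deviation statistic is the mean absolute deviation from
    the per-timepoint mean, the convention used for kinetic error bars.
    """
    traces = tuple(traces)
    if not traces:
        raise ValidationError("need at least one trace to aggregate")
    grid = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != grid.shape or not np.allclose(tr.times, grid):
            raise AlignmentError("replicate traces must share one time grid")
    stack = np.vstack([tr.intensities for tr in traces])
    mean = stack.mean(axis=0)
    avg_dev = np.abs(stack - mean).mean(axis=0)
    mean_trace = KineticTrace(
        times=grid.copy(),
        intensities=mean,
        condition=traces[0].condition,
        replicate=-1,
    )
    return ReplicateSet(traces=traces, mean_trace=mean_trace, avg_dev_trace=avg_dev)


def reduction_percent(fit: SigmoidFit, control: SigmoidFit, which: str) -> float:
    """Percent reduction of ``t_lag`` or ``t_half`` relative to a control fit.

    Returns ``100 * (control - value) / control``; positive values mean the
    condition accelerated fibrillization.
    """
    if which not in ("t_lag", "t_half"):
        raise ValidationError(f"which must be 't_lag' or 't_half', got {which!r}")
    ref = getattr(control, which)
    val = getattr(fit, which)
    if ref <= 0:
        raise ValidationError(f"control {which} must be positive, got {ref}")
    return 100.0 * (ref - val) / ref


def rank_conditions(
    fits: Mapping[str, SigmoidFit],
    parameter: str = "t_half",
    reference_series: Sequence[str] = ELECTROSELECTIVITY_SERIES,
) -> tuple[list[str], str | None]:
    """Sort ionic-liquid conditions by a kinetic parameter and test the anion order.

    Parameters
    ----------
    fits : mapping
        Condition label -> fit, all at one shared IL concentration (the
        control, if present, is ignored for the ordering test).
    parameter : str
        One of ``t_lag``, ``t_half``, ``k_agg``.
    reference_series : sequence
        Anion order to test against, least to most surface-active; default is
        the electroselectivity series HSO4 < AC < Cl < NO3 < BF4.

    Returns
    -------
    (ordered, match)
        Condition labels sorted ascending by the parameter, and a verdict:
        ``"forward"`` if the anion order equals the reference series,
        ``"reverse"`` if it equals its reverse, ``"none"`` otherwise, or
        ``None`` when fewer than two IL conditions are present.

    Raises
    ------
    GroupingError
        If the IL conditions span more than one concentration.
    """
    if parameter not in ("t_lag", "t_half", "k_agg"):
        raise ValidationError(f"unsupported ranking parameter: {parameter!r}")
    il_items = []
    for label, fit in fits.items():
        anion, conc = parse_condition(label)
        if anion is not None:
            il_items.append((label, anion, conc, getattr(fit, parameter)))
    concs = {c for (_, _, c, _) in il_items}
    if len(concs) > 1:
        raise GroupingError(f"mixed concentrations in one ranking: {sorted(concs)}")
    ordered_all = sorted(fits, key=lambda lbl: getattr(fits[lbl], parameter))
    if len(il_items) < 2:
        return ordered_all, None
    il_items.sort(key=lambda item: item[3])
    anion_order = [anion for (_, anion, _, _) in il_items]
    ref = [a for a in reference_series if a in anion_order]
    if anion_order == ref:
        match = "forward"
    elif anion_order == ref[::-1]:
        match = "reverse"
    else:
        match = "none"
    return ordered_all, match
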
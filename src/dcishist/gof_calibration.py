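"""Chi-square goodness of fit and simulation-based calibration.

The fit statistic is a Pearson chi-square on yearly age-adjusted rates,
``sum over years of (observed - estimated)^2 / estimated``, referred to a
chi-square distribution with (number of years - 1) degrees of freedom.
Calibration minimizes the combined DCIS + IBC statistic over a named
subset of natural-history parameters with a bounded Nelder-Mead simplex;
each objective evaluation re-simulates the population with a fixed seed
(common random numbers), so the objective is deterministic in the
parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort_sim import PopulationSpec, simulate_population
from .errors import DegenerateExpectedError, InputError, InvalidParameterError
from .outcomes import IncidenceTable, compute_incidence
from . import states as st

__all__ = [
    "GofResult",
    "CalibrationResult",
    "deviance",
    "combined_deviance",
    "apply_free_params",
    "calibrate",
]

DEFAULT_YEARS = tuple(range(1975, 2016))


@dataclass
class GofResult:
    statistic: float
    df: int
    p_value: float
    residuals: pd.Series  # per-year (observed - estimated)


def _aligned_rates(table: IncidenceTable, diagnosis: str, years) -> pd.Series:
    rates = table.age_adjusted_rate(diagnosis)
    missing = [y for y in years if y not in rates.index]
    if missing:
        raise InputError(f"{diagnosis}: table missing age-adjusted rates for years {missing[:5]}...")
    return rates.loc[list(years)]


def deviance(
    projected: IncidenceTable,
    observed: IncidenceTable,
    diagnosis: str = st.DIAG_DCIS,
    years=DEFAULT_YEARS,
) -> GofResult:
    """Pearson chi-square of observed vs projected age-adjusted rates.

    Degrees of freedom are (number of years - 1); the p-value is the
    upper tail of the chi-square reference distribution.
    """
    years = list(years)
    if not years:
        raise InputError("at least one year is required")
    est = _aligned_rates(projected, diagnosis, years).to_numpy()
    obs = _aligned_rates(observed, diagnosis, years).to_numpy()
    bad = (est <= 0) & (obs > 0)
    if np.any(bad):
        raise DegenerateExpectedError(
            f"projected rate <= 0 with positive observed rate in years "
            f"{list(np.asarray(years)[bad])[:5]}"
        )
    safe_est = np.where(est > 0, est, 1.0)
    terms = np.where(est > 0, (obs - est) ** 2 / safe_est, 0.0)
    statistic = float(terms.sum())
    df = len(years) - 1
    p_value = float(stats.chi2.sf(statistic, df))
    return GofResult(
        statistic=statistic,
        df=df,
        p_value=p_value,
        residuals=pd.Series(obs - est, index=pd.Index(years, name="year")),
    )


def combined_deviance(projected, observed, years=DEFAULT_YEARS) -> float:
    """Sum of the DCIS and IBC statistics."""
    return (
        deviance(projected, observed, st.DIAG_DCIS, years).statistic
        + deviance(projected, observed, st.DIAG_IBC, years).statistic
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

#: Names addressable by ``calibrate``.  "p1" rebalances p2/p3 to keep the
#: exit probabilities summing to one at a fixed p2:p3 ratio.
FREE_PARAM_NAMES = (
    "p1",
    "mst1",
    "mst2",
    "mst3",
    "undetectable_mean_dwell",
    "undetectable_direct_to_ibc_frac",
    "ibc_preclinical_mean_dwell",
    "frac_to_screen_detectable",
    "onset_scale",
)


def apply_free_params(spec: PopulationSpec, values: dict[str, float]) -> PopulationSpec:
    """Return a new spec with the named free parameters substituted."""
    params = spec.params
    config = spec.config
    for name, value in values.items():
        if name not in FREE_PARAM_NAMES:
            raise InputError(f"unknown free parameter {name!r}")
        if name == "p1":
            rest = 1.0 - value
            tail = params.p2 + params.p3
            if tail > 0:
                params = params.with_paths(value, rest * params.p2 / tail, rest * params.p3 / tail)
            else:
                params = params.with_paths(value, rest, 0.0)
        elif name == "onset_scale":
            params = replace(params, onset_hazard=params.onset_hazard.scaled(value))
        elif name == "frac_to_screen_detectable":
            config = replace(config, frac_to_screen_detectable=value)
        else:
            params = replace(params, **{name: value})
    return spec.with_(params=params, config=config)


@dataclass
class CalibrationResult:
    params: dict[str, float]
    objective: float
    converged: bool
    n_evaluations: int
    seed: int
    trace: list[tuple[dict[str, float], float]] = field(default_factory=list)
    approx_se: dict[str, float] = field(default_factory=dict)


def _to_unit(value, lo, hi):
    x = (value - lo) / (hi - lo)
    x = min(max(x, 1e-9), 1 - 1e-9)
    return special.logit(x)


def _from_unit(z, lo, hi):
    return lo + (hi - lo) * special.expit(z)


def calibrate(
    free_params: dict[str, float],
    bounds: dict[str, tuple[float, float]],
    target: IncidenceTable,
    spec: PopulationSpec,
    n_sim: int,
    seed: int,
    years=DEFAULT_YEARS,
    max_evaluations: int = 200,
    xatol: float = 0.01,
    fatol: float = 1.0,
) -> CalibrationResult:
    """Fit free natural-history parameters to an observed incidence table.

    ``free_params`` maps names to initial values; ``bounds`` gives the
    box for each.  The objective (combined DCIS + IBC chi-square on
    age-adjusted rates) is evaluated by simulating ``n_sim`` women with
    the given fixed seed per evaluation.
    """
    names = list(free_params)
    for n in names:
        if n not in bounds:
            raise InputError(f"missing bounds for free parameter {n!r}")
        lo, hi = bounds[n]
        if not lo < hi:
            raise InvalidParameterError(f"bounds for {n!r} must satisfy lo < hi")
        if not lo <= free_params[n] <= hi:
            raise InvalidParameterError(f"initial {n}={free_params[n]} outside bounds")
    sim_spec = spec.with_(n_women=n_sim, seed=seed)
    years = [y for y in years if y in set(target.age_adjusted["year"])]
    if not years:
        raise InputError("target table covers none of the requested years")

    trace: list[tuple[dict[str, float], float]] = []
    cache: dict[tuple[float, ...], float] = {}

    def objective_at(values: dict[str, float]) -> float:
        key = tuple(round(values[n], 12) for n in names)
        if key in cache:
            return cache[key]
        candidate = apply_free_params(sim_spec, values)
        log = simulate_population(candidate)
        projected = compute_incidence(log, "screened", weights=target.weights)
        try:
            obj = combined_deviance(projected, target, years)
        except DegenerateExpectedError:
            obj = float("inf")
        cache[key] = obj
        trace.append((dict(values), obj))
        return obj

    obj0 = objective_at(free_params)
    if not np.isfinite(obj0):
        raise InputError("objective is non-finite at the initial point")
    if not names:
        return CalibrationResult(
            params={}, objective=obj0, converged=True, n_evaluations=1, seed=seed, trace=trace
        )

    z0 = np.array([_to_unit(free_params[n], *bounds[n]) for n in names])

    def fun(z: np.ndarray) -> float:
        values = {n: _from_unit(z[i], *bounds[n]) for i, n in enumerate(names)}
        return objective_at(values)

    res = optimize.minimize(
        fun,
        z0,
        method="Nelder-Mead",
        options={
            "maxfev": max_evaluations,
            "xatol": xatol,
            "fatol": fatol,
            "initial_simplex": _initial_simplex(z0),
        },
    )
    fitted = {n: float(_from_unit(res.x[i], *bounds[n])) for i, n in enumerate(names)}

    approx_se = {}
    for i, n in enumerate(names):
        lo, hi = bounds[n]
        h = 0.05 * (hi - lo)
        vp = dict(fitted)
        vm = dict(fitted)
        vp[n] = min(fitted[n] + h, hi)
        vm[n] = max(fitted[n] - h, lo)
        f0, fp, fm = res.fun, objective_at(vp), objective_at(vm)
        curv = (fp - 2 * f0 + fm) / h**2
        approx_se[n] = float(np.sqrt(2.0 / curv)) if curv > 0 else float("nan")

    return CalibrationResult(
        params=fitted,
        objective=float(res.fun),
        converged=bool(res.success),
        n_evaluations=len(trace),
        seed=seed,
        trace=trace,
        approx_se=approx_se,
    )


def _initial_simplex(z0: np.ndarray, step: float = 0.75) -> np.ndarray:
    n = len(z0)
    simplex = np.tile(z0, (n + 1, 1))
    for i in range(n):
        simplex[i + 1, i] += step
    return simplex
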
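"""Replication runner and simulation performance metrics.

Performance of an estimator for a scenario is summarised per
(estimand, evaluation time) cell by

    bias      = mean(theta_hat_i) - theta
    empSE     = sample SD of theta_hat_i
    MCSE      = empSE / sqrt(nsim)

with evaluation times taken at the 20th/50th/80th percentiles of event
occurrence in the analysis population.  The required number of replicates for
a target Monte Carlo SE is ceil(Var(theta_hat) / MCSE_target^2).  Relative
efficiency is a variance ratio oriented so that values above one favour the
reference (first) estimator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import aalen as _aalen
from . import gformula as _gf
from .dgm import ScenarioConfig, simulate_cohort
from .truth import TrueEffects

__all__ = [
    "PerformanceRow",
    "BootstrapCI",
    "percentile_event_times",
    "run_replications",
    "compute_bias_mcse",
    "summarize_performance",
    "required_nsim",
    "relative_efficiency",
    "percentile_bootstrap",
]

logger = logging.getLogger(__name__)

ESTIMANDS = ("TE", "DE", "IE")

#: replicate-failure fraction above which a study cell is aborted
MAX_FAILURE_FRACTION = 0.01


@dataclass
class PerformanceRow:
    scenario: str
    sub_scenario: str
    method: str
    estimand: str
    time: float
    truth: float
    mean_estimate: float
    bias: float
    percent_bias: float  # 100 * bias / truth, NaN when truth == 0
    mcse: float
    empirical_se: float
    nsim: int


@dataclass
class BootstrapCI:
    label: str
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    B: int
    level: float
    samples: np.ndarray  # (B, ...) stored bootstrap statistics


def percentile_event_times(
    data,
    percentiles: Sequence[float] = (20, 50, 80),
    first_visit: float = 1.0,
    among: str = "events",
) -> np.ndarray:
    """Times corresponding to percentiles of event occurrence.

    ``data`` is a cohort frame (columns T, E) or a bare array of event times
    with every entry an event; the population is restricted to T >= the
    first analysis visit first.  With ``among='events'`` (default) t_p is the
    empirical p-quantile of the observed event times — well defined even when
    fewer than p% of the population ever has the event, which is why it is
    the default.  ``among='population'`` instead returns the time by which p%
    of the whole analysis population has failed, raising when the requested
    percentile exceeds the final event fraction.
    """
    if among not in ("events", "population"):
        raise ValueError("among must be 'events' or 'population'")
    if isinstance(data, pd.DataFrame):
        keep = data["T"].to_numpy(float) >= first_visit
        T = data["T"].to_numpy(float)[keep]
        E = data["E"].to_numpy(int)[keep]
    else:
        T = np.asarray(data, float)
        T = T[T >= first_visit]
        E = np.ones_like(T, dtype=int)
    n = T.size
    if n == 0:
        raise ValueError("empty analysis population")
    ev = np.sort(T[E == 1])
    if ev.size == 0:
        raise ValueError("no events in the analysis population")
    out = np.empty(len(percentiles))
    denom = n if among == "population" else ev.size
    for i, p in enumerate(percentiles):
        k = math.ceil(p / 100.0 * denom)
        if k > ev.size:
            raise ValueError(
                f"requested percentile {p}% exceeds the final event proportion "
                f"({100 * ev.size / n:.1f}%)"
            )
        out[i] = ev[k - 1]
    return out


def _estimate_one(
    cohort: pd.DataFrame,
    method: str,
    times,
    gformula_spec: Optional[_gf.GFormulaSpec],
) -> pd.DataFrame:
    if method == "aalen":
        curves = _aalen.estimate_aalen(cohort, times).curves
    elif method == "vansteelandt":
        curves = _gf.estimate_effect_curves(
            cohort, times, spec=gformula_spec
        ).curves
    else:
        raise ValueError(f"unknown method {method!r}")
    return curves.melt(id_vars="time", var_name="estimand", value_name="estimate")


def _one_replicate(config, rep, rep_seed, methods, times, gformula_spec):
    cohort = simulate_cohort(config, seed=rep_seed)
    rows, failures = [], []
    for method in methods:
        try:
            est = _estimate_one(cohort, method, times, gformula_spec)
        except Exception as exc:  # noqa: BLE001 - recorded, never imputed
            failures.append((rep, method, repr(exc)))
            logger.warning("replicate %d (%s) failed: %r", rep, method, exc)
            continue
        est.insert(0, "replicate", rep)
        est.insert(1, "method", method)
        rows.append(est)
    return rows, failures


def run_replications(
    config: ScenarioConfig,
    methods: Sequence[str],
    nsim: int,
    times,
    master_seed: int = 0,
    n: Optional[int] = None,
    gformula_spec: Optional[_gf.GFormulaSpec] = None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Simulate and analyse ``nsim`` independent cohorts.

    Per-replicate seeds are spawned from the master seed before any work
    starts, so results are identical for any execution order or worker count
    (``n_jobs`` uses joblib when not 1).  Replicate failures are logged and
    recorded; more than 1% of failures aborts the cell rather than reporting
    a selectively successful summary.
    """
    if isinstance(methods, str):
        methods = (methods,)
    if n is not None:
        from dataclasses import replace

        config = replace(config, n=n)
    times = np.atleast_1d(np.asarray(times, float))
    seeds = [
        int(ss.generate_state(1)[0] % (2**31 - 1))
        for ss in np.random.SeedSequence(master_seed).spawn(nsim)
    ]
    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(_one_replicate)(config, rep, s, methods, times, gformula_spec)
            for rep, s in enumerate(seeds)
        )
    else:
        results = [
            _one_replicate(config, rep, s, methods, times, gformula_spec)
            for rep, s in enumerate(seeds)
        ]
    rows = [frame for r, _ in results for frame in r]
    failures = [f for _, fs in results for f in fs]
    if failures:
        frac = len(failures) / (nsim * len(methods))
        if frac >= MAX_FAILURE_FRACTION:
            raise RuntimeError(
                f"{len(failures)} replicate failures "
                f"({100 * frac:.1f}% >= {100 * MAX_FAILURE_FRACTION:.0f}%): "
                f"{failures[:3]}"
            )
    out = pd.concat(rows, ignore_index=True)
    out.attrs["failures"] = failures
    out.attrs["nsim"] = nsim
    return out


def compute_bias_mcse(estimates: np.ndarray, truth: float) -> dict:
    """Bias, empirical SE and MCSE of the bias for one cell.

    MCSE uses deviations from the replicate mean (the convention for the
    Monte Carlo SE of a bias estimate), so MCSE * sqrt(nsim) = empSE exactly.
    """
    estimates = np.asarray(estimates, float)
    nsim = estimates.size
    if nsim < 2:
        raise ValueError("need at least 2 estimates")
    mean = float(estimates.mean())
    bias = mean - truth
    emp_se = float(estimates.std(ddof=1))
    return {
        "mean_estimate": mean,
        "bias": bias,
        "percent_bias": 100.0 * bias / truth if truth != 0 else float("nan"),
        "empirical_se": emp_se,
        "mcse": emp_se / math.sqrt(nsim),
        "nsim": nsim,
    }


def summarize_performance(
    estimates: pd.DataFrame,
    truth: TrueEffects,
    scenario: str = "",
    sub_scenario: str = "",
) -> pd.DataFrame:
    """Tidy table of PerformanceRows from a replication run and a truth object."""
    rows = []
    for (method, estimand, time), grp in estimates.groupby(
        ["method", "estimand", "time"], sort=True
    ):
        theta = float(truth.at(time)[estimand])
        stats = compute_bias_mcse(grp["estimate"].to_numpy(), theta)
        rows.append(
            dict(
                scenario=scenario,
                sub_scenario=sub_scenario,
                method=method,
                estimand=estimand,
                time=float(time),
                truth=theta,
                **stats,
            )
        )
    return pd.DataFrame(rows)


def required_nsim(var_hat: float, target_mcse: float) -> int:
    """Minimum replicate count for a target Monte Carlo SE of the bias."""
    if target_mcse <= 0:
        raise ValueError("target MCSE must be positive")
    if var_hat <= 0:
        raise ValueError("variance must be positive")
    return math.ceil(var_hat / target_mcse**2)


def relative_efficiency(
    estimates_ref: np.ndarray, estimates_comp: np.ndarray
) -> float:
    """Var(comparator) / Var(reference); > 1 means the reference is more
    efficient.  Returns NaN when the reference variance is zero."""
    v_ref = float(np.var(np.asarray(estimates_ref, float), ddof=1))
    v_comp = float(np.var(np.asarray(estimates_comp, float), ddof=1))
    if v_ref == 0.0:
        return float("nan")
    return v_comp / v_ref


def percentile_bootstrap(
    estimator: Callable[[pd.DataFrame], np.ndarray],
    cohort: pd.DataFrame,
    B: int = 500,
    level: float = 0.95,
    seed: int = 0,
    id_col: str = "id",
    max_retries: int = 3,
    label: str = "statistic",
) -> BootstrapCI:
    """Nonparametric percentile bootstrap resampling whole individuals.

    All rows sharing an ``id`` move together, which keeps stacked landmark
    rows of one person in the same resample.  A failing resample is redrawn
    up to ``max_retries`` times (logged) before the failure propagates.
    """
    rng = np.random.default_rng(seed)
    point = np.atleast_1d(np.asarray(estimator(cohort), float))
    ids = cohort[id_col].unique()
    groups = {i: df for i, df in cohort.groupby(id_col)}
    stats = np.empty((B,) + point.shape)
    for b in range(B):
        for attempt in range(max_retries + 1):
            chosen = rng.choice(ids, size=len(ids), replace=True)
            resample = pd.concat(
                [groups[i] for i in chosen], ignore_index=True
            )
            # re-key ids so duplicated individuals stay distinct units
            sizes = [len(groups[i]) for i in chosen]
            resample[id_col] = np.repeat(np.arange(len(chosen)), sizes)
            try:
                stats[b] = np.atleast_1d(np.asarray(estimator(resample), float))
                break
            except Exception as exc:  # noqa: BLE001
                logger.warning("bootstrap resample %d failed (%r); redrawing", b, exc)
                if attempt == max_retries:
                    raise
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(stats, alpha, axis=0)
    upper = np.quantile(stats, 1.0 - alpha, axis=0)
    return BootstrapCI(
        label=label, point=point, lower=lower, upper=upper, B=B, level=level,
        samples=stats,
    )
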
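"""Dynamic path analysis with Aalen's additive hazards model.

The hazard is modelled additively in the exposure, baseline covariates and the
most recent mediator value,

    lambda_i(t) = alpha_0(t) + alpha_A(t) A_i + alpha_Z0(t) Z0_i
                  + alpha_M0(t) M0_i + alpha_M(t) M_{i, r(t)},

where r(t) is the latest analysis visit at or before t (covariates are carried
forward, never interpolated).  At each distinct event time t_j the increment of
the cumulative coefficient vector is the least-squares solution

    dB_hat(t_j) = (X' X)^{-1} X' dN(t_j)

over the risk set, with dN_i = 1 for individuals failing at t_j.  At the same
event times the mediator is regressed by OLS on the exposure and baseline
covariates (a model marginal over the mediator's own past).  The ratio-scale
effects are cumulative sums:

    DE(t) = exp(-B_A(t))
    IE(t) = exp(-sum_{t_j <= t} betaA_hat(t_j) * dB_M(t_j))
    TE(t) = DE(t) * IE(t)

This estimator assumes all confounding is controlled by baseline covariates;
time-varying confounders are deliberately unsupported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dgm import mediator_column

__all__ = [
    "CumulativeCoefficients",
    "MediatorPathFit",
    "EffectCurves",
    "fit_additive_increments",
    "fit_mediator_at_event_times",
    "estimate_effects",
    "estimate_aalen",
]

logger = logging.getLogger(__name__)

#: singular values below this (relative to the largest) are treated as zero
RCOND = 1e-8


@dataclass
class CumulativeCoefficients:
    """Cumulative additive-hazard regression coefficients.

    ``B(t)`` is a step function changing only at event times, with B(0) = 0.
    With an intercept-only design the single cumulative coefficient is the
    Nelson-Aalen estimator sum d_j / Y_j.
    """

    event_times: np.ndarray  # distinct, ascending
    increments: np.ndarray  # (J, p)
    names: list[str]
    risk_size: np.ndarray  # (J,)
    n_events: np.ndarray  # multiplicity d_j at each time
    rank_deficient: np.ndarray  # (J,) bool

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.increments, axis=0)

    def cumulative_at(self, times, name: str) -> np.ndarray:
        """B_name evaluated at arbitrary times (right-continuous step)."""
        j = self.names.index(name)
        cum = np.concatenate([[0.0], self.cumulative[:, j]])
        idx = np.searchsorted(self.event_times, np.atleast_1d(times), side="right")
        return cum[idx]


@dataclass
class MediatorPathFit:
    """Per-event-time OLS fits of the current mediator on baseline covariates."""

    event_times: np.ndarray
    coefs: np.ndarray  # (J, q); rows NaN where the fit was undefined
    names: list[str]
    risk_size: np.ndarray
    n_carried_forward: int = 0  # event times whose coefficients were carried

    def coef(self, name: str) -> np.ndarray:
        return self.coefs[:, self.names.index(name)]


@dataclass
class EffectCurves:
    """Time-indexed IE/DE/TE on the survival-ratio scale."""

    curves: pd.DataFrame  # columns time, IE, DE, TE
    method: str
    contrast: tuple[int, int] = (1, 0)  # (direct-path a, mediator-path a*)

    def at(self, t: float) -> pd.Series:
        idx = int(np.argmin(np.abs(self.curves["time"].to_numpy() - t)))
        return self.curves.iloc[idx]


def _restrict(cohort: pd.DataFrame, first_visit: int) -> pd.DataFrame:
    out = cohort.loc[cohort["T"] >= first_visit].reset_index(drop=True)
    if out.empty:
        raise ValueError(f"no individuals with T >= {first_visit}")
    return out


def _interval_visit(t: float, visits: Sequence[int]) -> int:
    """Latest analysis visit at or before t (covariate carry-forward)."""
    eligible = [v for v in visits if v <= t]
    return max(eligible) if eligible else min(visits)


def _event_grid(cohort: pd.DataFrame):
    """Sorted cohort, distinct event times with multiplicities."""
    df = cohort.sort_values("T", kind="mergesort").reset_index(drop=True)
    T = df["T"].to_numpy(float)
    E = df["E"].to_numpy(int)
    ev = np.unique(T[E == 1])
    return df, T, E, ev


def fit_additive_increments(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = ("A", "Z0", "M_0"),
    mediator: str | None = "M",
    visits: Sequence[int] = (1, 2, 3),
    singular: str = "pinv",
    time_updated_confounder: str | None = None,
) -> CumulativeCoefficients:
    """Least-squares hazard increments at every distinct event time.

    ``covariates`` are time-fixed columns; when ``mediator`` is not None a
    time-updated column ``M_{r(t)}`` (carry-forward over ``visits``) is
    appended to the design; ``time_updated_confounder`` (a column prefix such
    as ``"L"``) appends a second carried-forward column the same way.  The
    analysis population is restricted to individuals surviving to the first
    visit.  ``singular='pinv'`` resolves a
    rank-deficient normal system with the Moore-Penrose pseudoinverse and a
    logged warning; ``'truncate'`` stops accumulating at the first deficient
    time; ``'raise'`` raises.
    """
    if singular not in ("pinv", "truncate", "raise"):
        raise ValueError("singular must be one of 'pinv', 'truncate', 'raise'")
    first_visit = min(visits) if mediator is not None else 1
    df = _restrict(cohort, first_visit)
    df, T, E, ev = _event_grid(df)
    n = len(df)
    names = ["intercept", *covariates]
    base = np.column_stack(
        [np.ones(n)] + [df[c].to_numpy(float) for c in covariates]
    )
    if mediator is not None:
        names.append("M_current")
    if time_updated_confounder is not None:
        names.append(f"{time_updated_confounder}_current")
    p = len(names)
    J = len(ev)
    increments = np.zeros((J, p))
    risk_size = np.zeros(J, dtype=int)
    n_events = np.zeros(J, dtype=int)
    deficient = np.zeros(J, dtype=bool)
    truncated_at = None
    for j, tj in enumerate(ev):
        i0 = np.searchsorted(T, tj, side="left")  # risk set: T >= tj
        X = base[i0:]
        k = _interval_visit(tj, visits)
        if mediator is not None:
            mcol = df[mediator_column(k)].to_numpy(float)[i0:]
            X = np.column_stack([X, mcol])
        if time_updated_confounder is not None:
            lcol = df[f"{time_updated_confounder}_{k}"].to_numpy(float)[i0:]
            X = np.column_stack([X, lcol])
        fail = (T[i0:] == tj) & (E[i0:] == 1)
        risk_size[j] = X.shape[0]
        n_events[j] = int(fail.sum())
        xtx = X.T @ X
        xtd = X.T @ fail.astype(float)
        sv = np.linalg.svd(xtx, compute_uv=False)
        if sv[-1] <= RCOND * sv[0] or X.shape[0] < p:
            deficient[j] = True
            if singular == "raise":
                raise np.linalg.LinAlgError(
                    f"singular design at event time {tj:.4f}"
                )
            if singular == "truncate":
                truncated_at = tj
                increments = increments[:j]
                ev = ev[:j]
                risk_size = risk_size[:j]
                n_events = n_events[:j]
                deficient = deficient[:j]
                break
            logger.warning(
                "rank-deficient design at event time %.4f; using pseudoinverse", tj
            )
            increments[j] = np.linalg.pinv(xtx, rcond=RCOND) @ xtd
        else:
            increments[j] = np.linalg.solve(xtx, xtd)
    if truncated_at is not None:
        logger.warning("accumulation truncated at event time %.4f", truncated_at)
    return CumulativeCoefficients(
        event_times=np.asarray(ev, float),
        increments=increments,
        names=names,
        risk_size=risk_size,
        n_events=n_events,
        rank_deficient=deficient,
    )


def fit_mediator_at_event_times(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = ("A", "Z0", "M_0"),
    visits: Sequence[int] = (1, 2, 3),
) -> MediatorPathFit:
    """OLS of the current mediator on exposure and baseline covariates, per
    event time (main effects only).

    At event times with fewer at-risk individuals than parameters the fit is
    undefined; coefficients from the nearest preceding defined time are
    carried forward (logged), and leading undefined times fall back to the
    first defined fit.
    """
    df = _restrict(cohort, min(visits))
    df, T, E, ev = _event_grid(df)
    n = len(df)
    base = np.column_stack(
        [np.ones(n)] + [df[c].to_numpy(float) for c in covariates]
    )
    names = ["intercept", *covariates]
    q = base.shape[1]
    J = len(ev)
    coefs = np.full((J, q), np.nan)
    risk_size = np.zeros(J, dtype=int)
    for j, tj in enumerate(ev):
        i0 = np.searchsorted(T, tj, side="left")
        X = base[i0:]
        k = _interval_visit(tj, visits)
        y = df[mediator_column(k)].to_numpy(float)[i0:]
        risk_size[j] = X.shape[0]
        if X.shape[0] < q:
            continue
        xtx = X.T @ X
        sv = np.linalg.svd(xtx, compute_uv=False)
        if sv[-1] <= RCOND * sv[0]:
            continue
        coefs[j] = np.linalg.solve(xtx, X.T @ y)
    undefined = np.isnan(coefs[:, 0])
    n_carried = int(undefined.sum())
    if n_carried:
        logger.warning(
            "mediator fit undefined at %d of %d event times; carrying forward",
            n_carried,
            J,
        )
        defined_idx = np.flatnonzero(~undefined)
        if defined_idx.size == 0:
            raise ValueError("mediator regression undefined at every event time")
        last = None
        for j in range(J):
            if undefined[j]:
                coefs[j] = coefs[last] if last is not None else coefs[defined_idx[0]]
            else:
                last = j
    return MediatorPathFit(
        event_times=np.asarray(ev, float),
        coefs=coefs,
        names=names,
        risk_size=risk_size,
        n_carried_forward=n_carried,
    )


def estimate_effects(
    cc: CumulativeCoefficients,
    mf: MediatorPathFit,
    times,
    exposure: str = "A",
) -> EffectCurves:
    """Combine hazard increments and mediator-path coefficients into effect
    curves on the survival-ratio scale.
    """
    if len(cc.event_times) != len(mf.event_times) or not np.allclose(
        cc.event_times, mf.event_times
    ):
        raise ValueError("hazard and mediator fits are on different event-time grids")
    times = np.atleast_1d(np.asarray(times, float))
    beta_A = mf.coef(exposure)
    dB_M = cc.increments[:, cc.names.index("M_current")]
    ie_cum = np.concatenate([[0.0], np.cumsum(beta_A * dB_M)])
    idx = np.searchsorted(cc.event_times, times, side="right")
    IE = np.exp(-ie_cum[idx])
    DE = np.exp(-cc.cumulative_at(times, exposure))
    curves = pd.DataFrame({"time": times, "IE": IE, "DE": DE, "TE": IE * DE})
    return EffectCurves(curves=curves, method="aalen")


def estimate_aalen(
    cohort: pd.DataFrame,
    times,
    covariates: Sequence[str] = ("A", "Z0", "M_0"),
    visits: Sequence[int] = (1, 2, 3),
) -> EffectCurves:
    """Full dynamic-path-analysis pipeline on one cohort."""
    cc = fit_additive_increments(cohort, covariates=covariates, visits=visits)
    mf = fit_mediator_at_event_times(cohort, covariates=covariates, visits=visits)
    return estimate_effects(cc, mf, times)
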
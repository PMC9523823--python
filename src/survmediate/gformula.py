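"""Sequential-regression estimator of nested-counterfactual survival curves.

The estimand is S_{A(a),M(a*)}(t): the probability of surviving past t had
the exposure been set to ``a`` on every pathway except the mediator process,
whose values are set to those it would have taken under exposure ``a*``
(time-varying confounders L follow the ``a`` argument and may depend on past
mediator values, so cross-world dependence propagates through M -> L -> M).

Identification writes S_{A(a),M(a*)}(t) as an iterated integral over the
visit-wise mediator and confounder densities, with the exposure argument set
per path.  Estimation replaces the integrals by regressions fitted backwards
from the last visit before t:

* a terminal conditional-survival factor P(T > t | T > K, history, A = a)
  from a hazard model (additive by default, Cox optional) fitted once on the
  full follow-up with visit-updated covariates;
* an M-step per visit k: regress the running pseudo-outcome on the history
  excluding M_k and predict with A = a*  (integrates M_k under a*);
* an L-step per visit k: extend the at-risk set to visit k-1, assign 0 to
  individuals who died in (k-1, k] (the at-risk indicator is part of L_k),
  regress on the history excluding L_k, and predict with A = a.

The mean of the final predictions over the analysis population (individuals
surviving to the first visit) estimates the survival probability.  Ratio
contrasts give IE(t) = S_{(1,1)}/S_{(1,0)}, DE(t) = S_{(1,0)}/S_{(0,0)} and
TE = IE * DE.

Pseudo-outcome regressions use a fractional-logit family by default: a
logit-link Bernoulli quasi-likelihood, well defined for responses in (0, 1).
A linear (OLS) family is available; with saturated designs on discrete data
either family reproduces stratum means, which makes the recursion equal the
brute-force summation of the identification formula.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .aalen import CumulativeCoefficients, EffectCurves, fit_additive_increments
from .dgm import confounder_column, mediator_column

__all__ = [
    "GFormulaSpec",
    "CounterfactualSurvival",
    "TerminalPredictor",
    "AdditiveTerminalPredictor",
    "CoxTerminalPredictor",
    "fit_terminal_survival",
    "sequential_gformula",
    "estimate_effect_curves",
]

logger = logging.getLogger(__name__)


@dataclass
class GFormulaSpec:
    """Configuration of the sequential-regression procedure."""

    terminal_model: str = "aalen"  # 'aalen' | 'cox' | a fitted TerminalPredictor
    family: str = "fractional-logit"  # 'fractional-logit' | 'linear'
    saturated: bool = False  # full-interaction designs (small discrete cohorts)
    eps: float = 1e-6  # clipping bound for pseudo-outcomes and predictions
    visits: tuple = (0, 1, 2, 3)
    exposure: str = "A"
    baseline_covariates: tuple = ("Z0", "M_0")  # M_0 (and L_0) always included
    confounder_prefix: Optional[str] = None  # e.g. "L"; None = auto-detect

    def resolve_confounders(self, cohort: pd.DataFrame) -> Optional[str]:
        if self.confounder_prefix is not None:
            return self.confounder_prefix
        return "L" if confounder_column(0) in cohort.columns else None


@dataclass
class CounterfactualSurvival:
    """One contrast's estimated survival curve with per-individual detail."""

    contrast: tuple[int, int]  # (a, a_star)
    times: np.ndarray
    survival: np.ndarray
    final_predictions: list  # per time, vector over the analysis population
    n_clipped: int = 0


class TerminalPredictor:
    """Interface: conditional survival P(T > t | T > k, history, A = a)."""

    def predict(self, df: pd.DataFrame, t: float, k: int, a: float) -> np.ndarray:
        raise NotImplementedError


class AdditiveTerminalPredictor(TerminalPredictor):
    """Additive-hazards terminal factor.

    Fitted via least-squares increments on the full follow-up with
    visit-updated covariates; the conditional survival from k to t is
    exp(-x'(B(t) - B(k))) with the covariates frozen at their visit-k values.
    Predictions outside [eps, 1-eps] are clipped and counted.
    """

    def __init__(self, cohort: pd.DataFrame, spec: GFormulaSpec):
        self.spec = spec
        lprefix = spec.resolve_confounders(cohort)
        self.lprefix = lprefix
        covs = [spec.exposure, *spec.baseline_covariates]
        if lprefix is not None and confounder_column(0) not in covs:
            covs.append(confounder_column(0))
        self.covariates = covs
        self.visits = [v for v in spec.visits if v > 0]
        self.cc: CumulativeCoefficients = fit_additive_increments(
            cohort,
            covariates=covs,
            mediator="M",
            visits=self.visits,
            time_updated_confounder=lprefix,
        )
        self.n_clipped = 0

    def predict(self, df: pd.DataFrame, t: float, k: int, a: float) -> np.ndarray:
        names = self.cc.names
        out = np.zeros(len(df))
        dB = {
            name: self.cc.cumulative_at([t], name)[0]
            - self.cc.cumulative_at([float(k)], name)[0]
            for name in names
        }
        out += dB["intercept"]
        for c in self.covariates:
            val = np.full(len(df), a) if c == self.spec.exposure else df[c].to_numpy(float)
            out += dB[c] * val
        mk = max(0, k) if k in (0, *self.visits) else max(v for v in (0, *self.visits) if v <= k)
        out += dB["M_current"] * df[mediator_column(mk)].to_numpy(float)
        if self.lprefix is not None:
            out += dB[f"{self.lprefix}_current"] * df[
                confounder_column(mk)
            ].to_numpy(float)
        surv = np.exp(-out)
        eps = self.spec.eps
        n_bad = int(((surv < eps) | (surv > 1 - eps)).sum())
        if n_bad:
            self.n_clipped += n_bad
            logger.debug("clipped %d terminal predictions at t=%.3f", n_bad, t)
        return np.clip(surv, eps, 1 - eps)


class CoxTerminalPredictor(TerminalPredictor):
    """Proportional-hazards terminal factor (Breslow baseline hazard)."""

    def __init__(self, cohort: pd.DataFrame, spec: GFormulaSpec):
        from lifelines import CoxTimeVaryingFitter

        self.spec = spec
        lprefix = spec.resolve_confounders(cohort)
        self.lprefix = lprefix
        covs = [spec.exposure, *spec.baseline_covariates]
        if lprefix is not None and confounder_column(0) not in covs:
            covs.append(confounder_column(0))
        self.covariates = covs
        self.visits = [v for v in spec.visits if v > 0]
        first = min(self.visits)
        df = cohort.loc[cohort["T"] >= first].reset_index(drop=True)
        episodes = []
        for k in [0, *self.visits]:
            nxt = k + 1
            sub = df.loc[df["T"] > k] if k >= first else df
            stop = np.minimum(sub["T"].to_numpy(float), nxt)
            ep = pd.DataFrame(
                {
                    "pid": sub["id"].to_numpy(),
                    "start": float(k),
                    "stop": stop,
                    "event": ((sub["E"] == 1) & (sub["T"] <= nxt)).astype(int),
                }
            )
            for c in covs:
                ep[c] = sub[c].to_numpy(float)
            ep["M_current"] = sub[mediator_column(min(k, max(self.visits)))].to_numpy(float)
            if lprefix is not None:
                ep["L_current"] = sub[confounder_column(min(k, max(self.visits)))].to_numpy(float)
            episodes.append(ep.loc[ep["stop"] > ep["start"]])
        long = pd.concat(episodes, ignore_index=True)
        self._xcols = [*covs, "M_current"] + (["L_current"] if lprefix else [])
        self.fitter = CoxTimeVaryingFitter(penalizer=1e-6)
        self.fitter.fit(
            long,
            id_col="pid",
            start_col="start",
            stop_col="stop",
            event_col="event",
            show_progress=False,
        )
        bh = self.fitter.baseline_cumulative_hazard_
        self._bh_times = bh.index.to_numpy(float)
        self._bh_values = bh.iloc[:, 0].to_numpy(float)
        self._means = long[self._xcols].mean()
        self.n_clipped = 0

    def _H0(self, t: float) -> float:
        idx = np.searchsorted(self._bh_times, t, side="right")
        return self._bh_values[idx - 1] if idx > 0 else 0.0

    def predict(self, df: pd.DataFrame, t: float, k: int, a: float) -> np.ndarray:
        beta = self.fitter.params_
        mk = max(v for v in (0, *self.visits) if v <= k)
        X = pd.DataFrame(index=df.index)
        for c in self.covariates:
            X[c] = a if c == self.spec.exposure else df[c].to_numpy(float)
        X["M_current"] = df[mediator_column(mk)].to_numpy(float)
        if self.lprefix is not None:
            X["L_current"] = df[confounder_column(mk)].to_numpy(float)
        lin = ((X[self._xcols] - self._means) @ beta).to_numpy(float)
        dH = self._H0(t) - self._H0(float(k))
        surv = np.exp(-dH * np.exp(lin))
        eps = self.spec.eps
        self.n_clipped += int(((surv < eps) | (surv > 1 - eps)).sum())
        return np.clip(surv, eps, 1 - eps)


def fit_terminal_survival(cohort: pd.DataFrame, spec: GFormulaSpec) -> TerminalPredictor:
    """Fit the terminal conditional-survival predictor chosen in ``spec``."""
    if isinstance(spec.terminal_model, TerminalPredictor):
        return spec.terminal_model
    if spec.terminal_model == "aalen":
        return AdditiveTerminalPredictor(cohort, spec)
    if spec.terminal_model == "cox":
        return CoxTerminalPredictor(cohort, spec)
    raise ValueError(f"unknown terminal model {spec.terminal_model!r}")


# ---------------------------------------------------------------------------
# pseudo-outcome regressions
# ---------------------------------------------------------------------------


def _design(df: pd.DataFrame, columns: Sequence[str], saturated: bool) -> np.ndarray:
    cols = [df[c].to_numpy(float) for c in columns]
    X = [np.ones(len(df))] + cols
    if saturated:
        for r in range(2, len(columns) + 1):
            for idx in combinations(range(len(columns)), r):
                prod = cols[idx[0]].copy()
                for i in idx[1:]:
                    prod = prod * cols[i]
                X.append(prod)
    return np.column_stack(X)


def _fit_predict(
    y: np.ndarray,
    df_fit: pd.DataFrame,
    df_new: pd.DataFrame,
    columns: Sequence[str],
    spec: GFormulaSpec,
) -> np.ndarray:
    """Fit the pseudo-outcome regression and predict for ``df_new``."""
    X = _design(df_fit, columns, spec.saturated)
    Xn = _design(df_new, columns, spec.saturated)
    y = np.clip(y, spec.eps, 1 - spec.eps)
    if spec.family == "linear":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = Xn @ beta
    elif spec.family == "fractional-logit":
        if np.all(y == y[0]):
            # degenerate pseudo-outcomes: constant fit, no iteration
            logger.debug("degenerate pseudo-outcomes (all %.3g)", y[0])
            pred = np.full(len(df_new), y[0])
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            pred = res.predict(Xn)
    else:
        raise ValueError(f"unknown family {spec.family!r}")
    return np.clip(pred, spec.eps, 1 - spec.eps)


def _history_columns(
    k_mediators: int, k_confounders: Optional[int], spec: GFormulaSpec, lprefix
) -> list[str]:
    """Covariate list: baseline + exposure + M_1..M_a + L_1..L_b."""
    cols = [spec.exposure, *spec.baseline_covariates]
    if lprefix is not None and confounder_column(0) not in cols:
        cols.append(confounder_column(0))
    cols += [mediator_column(v) for v in spec.visits if 0 < v <= k_mediators]
    if lprefix is not None and k_confounders is not None:
        cols += [confounder_column(v) for v in spec.visits if 0 < v <= k_confounders]
    return cols


def sequential_gformula(
    cohort: pd.DataFrame,
    a: int,
    a_star: int,
    t: float,
    spec: GFormulaSpec | None = None,
    terminal: TerminalPredictor | None = None,
) -> CounterfactualSurvival:
    """Estimate S_{A(a),M(a*)}(t) by backward sequential regression.

    The cohort is restricted to individuals surviving to the first analysis
    visit; for t at or before the first visit the estimate is the averaged
    terminal factor with A = a (no mediator integration is possible there).
    """
    spec = spec or GFormulaSpec()
    lprefix = spec.resolve_confounders(cohort)
    visits = [v for v in spec.visits if v > 0]
    first = min(visits)
    df = cohort.loc[cohort["T"] >= first].reset_index(drop=True)
    if df.empty:
        raise ValueError("no individuals at risk at the first visit")
    if terminal is None:
        terminal = fit_terminal_survival(df, spec)
    # last visit strictly before t (t exactly at a visit uses the previous one,
    # since survival to t is governed by the hazard on (K, t])
    K = int(np.ceil(t)) - 1
    K = max(0, min(K, max(visits)))
    T = df["T"].to_numpy(float)

    def at_risk(k: int) -> np.ndarray:
        return T >= k

    risk_K = at_risk(K)
    V = np.asarray(
        terminal.predict(df.loc[risk_K].assign(**{spec.exposure: float(a)}), t, K, float(a)),
        float,
    )
    current = risk_K
    for k in range(K, 0, -1):
        # M-step: integrate M_k under exposure a*
        cols = _history_columns(k - 1, k, spec, lprefix)
        sub = df.loc[current]
        V = _fit_predict(
            V, sub, sub.assign(**{spec.exposure: float(a_star)}), cols, spec
        )
        # L-step: extend to visit k-1, deaths in (k-1, k] contribute 0
        prev = at_risk(k - 1)
        V_ext = np.zeros(int(prev.sum()))
        V_ext[current[prev]] = V
        cols = _history_columns(k - 1, k - 1, spec, lprefix)
        sub = df.loc[prev]
        V = _fit_predict(
            V_ext, sub, sub.assign(**{spec.exposure: float(a)}), cols, spec
        )
        current = prev
    S = float(np.mean(V))
    return CounterfactualSurvival(
        contrast=(a, a_star),
        times=np.asarray([t]),
        survival=np.asarray([S]),
        final_predictions=[V],
        n_clipped=getattr(terminal, "n_clipped", 0),
    )


def estimate_effect_curves(
    cohort: pd.DataFrame,
    times,
    spec: GFormulaSpec | None = None,
) -> EffectCurves:
    """IE/DE/TE curves from the three contrasts (1,1), (1,0), (0,0).

    IE(t) is 1 for t at or before the first visit, where the mediator has not
    yet been measured.  Ratios whose denominator falls below the clipping
    bound are reported as missing.
    """
    spec = spec or GFormulaSpec()
    times = np.atleast_1d(np.asarray(times, float))
    visits = [v for v in spec.visits if v > 0]
    first = min(visits)
    df = cohort.loc[cohort["T"] >= first].reset_index(drop=True)
    terminal = fit_terminal_survival(df, spec)
    S = {}
    for contrast in ((1, 1), (1, 0), (0, 0)):
        vals = np.empty(len(times))
        for i, t in enumerate(times):
            a, a_star = contrast
            if t <= first:
                a_star = a  # no mediator integration before the first visit
            vals[i] = sequential_gformula(
                df, a, a_star, float(t), spec=spec, terminal=terminal
            ).survival[0]
        S[contrast] = vals

    def ratio(num, den):
        den = np.where(den < spec.eps, np.nan, den)
        return num / den

    IE = ratio(S[(1, 1)], S[(1, 0)])
    IE = np.where(times <= first, 1.0, IE)
    DE = ratio(S[(1, 0)], S[(0, 0)])
    curves = pd.DataFrame({"time": times, "IE": IE, "DE": DE, "TE": IE * DE})
    return EffectCurves(curves=curves, method="vansteelandt")
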
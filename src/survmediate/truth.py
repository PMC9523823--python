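"""Simulation-based true effect curves from cross-world counterfactual arms.

For a configured mechanism the four arms (a, a*) in {(1,1), (0,0), (1,0),
(0,1)} are generated by evaluating the structural equations with the exposure
argument ``a`` on the direct path (confounder process and hazard) and ``a*``
on the mediator path, with the baseline confounder drawn at its marginal
probability so that the exposure is unconfounded.  All four arms share the
same underlying random draws (common random numbers), which tightens the
Monte Carlo error of the survival-curve ratios.

True effects on the survival-ratio scale:

    TE(t) = S_{A(1),M(1)}(t) / S_{A(0),M(0)}(t)
    DE(t) = S_{A(1),M(0)}(t) / S_{A(0),M(0)}(t)
    IE(t) = S_{A(1),M(1)}(t) / S_{A(1),M(0)}(t)

so that TE = DE * IE holds algebraically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dgm import ScenarioConfig, _block_seeds, _raw_draws, _assemble, BLOCK_SIZE

__all__ = [
    "ARMS",
    "TrueEffects",
    "simulate_counterfactual_arms",
    "arm_survival",
    "compute_true_effects",
    "true_effects",
]

ARMS = ((1, 1), (0, 0), (1, 0), (0, 1))

#: survival-probability floor below which a ratio is reported as missing
MIN_DENOMINATOR = 1e-6


@dataclass
class TrueEffects:
    """True effect curves and the arm survival curves they are built from.

    ``se`` holds block-jackknife Monte Carlo standard errors of the ratio
    curves (columns TE, DE, IE); they account for the common random numbers
    shared across arms.
    """

    times: np.ndarray
    curves: pd.DataFrame  # columns S11, S00, S10, S01, TE, DE, IE indexed by time
    n_truth: int
    se: pd.DataFrame | None = None

    def at(self, t: float) -> pd.Series:
        idx = int(np.argmin(np.abs(self.times - t)))
        return self.curves.iloc[idx]

    def se_at(self, t: float, estimand: str) -> float:
        if self.se is None:
            return 0.0
        idx = int(np.argmin(np.abs(self.times - t)))
        return float(self.se.iloc[idx][estimand])


def simulate_counterfactual_arms(
    config: ScenarioConfig,
    n_truth: int = 500_000,
    seed: int | None = None,
    restriction: str = "armwise",
) -> dict[tuple[int, int], pd.DataFrame]:
    """Generate the four cross-world arms at large n.

    Individuals with an event before the first analysis visit are removed,
    matching the estimators' analysis population.  ``restriction='armwise'``
    drops them arm by arm; ``'shared'`` drops any individual who fails before
    the first visit in at least one arm (a common index set).
    """
    if restriction not in ("armwise", "shared"):
        raise ValueError("restriction must be 'armwise' or 'shared'")
    if seed is None:
        seed = config.seed
    first_visit = min(v for v in config.analysis_visits if v > 0)
    arms: dict[tuple[int, int], list[pd.DataFrame]] = {arm: [] for arm in ARMS}
    offset = 0
    for ss in _block_seeds(seed, n_truth):
        m = min(BLOCK_SIZE, n_truth - offset)
        rng = np.random.default_rng(ss)
        raw = _raw_draws(config, BLOCK_SIZE, rng)
        raw = {k: (v[:m] if v is not None else None) for k, v in raw.items()}
        block_frames = {}
        for a, a_star in ARMS:
            block_frames[(a, a_star)] = _assemble(
                config, raw, a_M=float(a_star), a_D=float(a),
                z0_marginal=True, id_offset=offset,
            )
        if restriction == "shared":
            keep = np.ones(m, dtype=bool)
            for df in block_frames.values():
                keep &= df["T"].to_numpy() >= first_visit
            for arm, df in block_frames.items():
                arms[arm].append(df.loc[keep])
        else:
            for arm, df in block_frames.items():
                arms[arm].append(df.loc[df["T"].to_numpy() >= first_visit])
        offset += m
    return {arm: pd.concat(frames, ignore_index=True) for arm, frames in arms.items()}


def arm_survival(arm: pd.DataFrame, times) -> np.ndarray:
    """Empirical survival S(t) = #{T_i > t} / n of one counterfactual arm.

    Valid because the only censoring is administrative at the study end; the
    proportion still at risk is the survival probability.
    """
    T = np.asarray(arm["T"] if isinstance(arm, pd.DataFrame) else arm, float)
    if T.size == 0:
        raise ValueError("empty arm")
    times = np.atleast_1d(np.asarray(times, float))
    return (T[None, :] > times[:, None]).mean(axis=1)


def compute_true_effects(
    arms: dict[tuple[int, int], pd.DataFrame], times
) -> TrueEffects:
    """Ratio-scale TE/DE/IE curves from the four arm survival curves.

    Ratios with a denominator survival below ``MIN_DENOMINATOR`` are reported
    as missing (NaN), never raised.
    """
    times = np.atleast_1d(np.asarray(times, float))
    S = {arm: arm_survival(df, times) for arm, df in arms.items()}
    n_truth = max(len(df) for df in arms.values())

    def ratio(num, den):
        den = np.where(den < MIN_DENOMINATOR, np.nan, den)
        return num / den

    curves = pd.DataFrame(
        {
            "time": times,
            "S11": S[(1, 1)],
            "S00": S[(0, 0)],
            "S10": S[(1, 0)],
            "S01": S[(0, 1)],
            "TE": ratio(S[(1, 1)], S[(0, 0)]),
            "DE": ratio(S[(1, 0)], S[(0, 0)]),
            "IE": ratio(S[(1, 1)], S[(1, 0)]),
        }
    ).set_index("time", drop=False)
    se = _jackknife_se(arms, times)
    return TrueEffects(times=times, curves=curves, n_truth=n_truth, se=se)


def _jackknife_se(
    arms: dict[tuple[int, int], pd.DataFrame], times: np.ndarray
) -> pd.DataFrame | None:
    """Leave-one-block-out SEs of the ratio curves.

    Blocks follow the generator's substream structure (id // BLOCK_SIZE), so
    draws shared across arms stay paired and the positive correlation the
    common random numbers induce is reflected in the SE.
    """
    counts = {}
    totals = {}
    blocks = None
    for arm, df in arms.items():
        if "id" not in df.columns:
            return None
        b = df["id"].to_numpy() // BLOCK_SIZE
        T = df["T"].to_numpy(float)
        nb = int(b.max()) + 1 if len(b) else 1
        if blocks is None or nb > blocks:
            blocks = nb
        gt = np.zeros((len(times), nb))
        nn = np.bincount(b, minlength=nb).astype(float)
        for i, t in enumerate(times):
            gt[i] = np.bincount(b, weights=(T > t).astype(float), minlength=nb)
        counts[arm] = gt
        totals[arm] = nn
    if blocks is None or blocks < 2:
        return None

    def loo_S(arm):
        gt, nn = counts[arm], totals[arm]
        return (gt.sum(axis=1, keepdims=True) - gt) / (nn.sum() - nn)[None, :]

    S = {arm: loo_S(arm) for arm in arms}
    out = {}
    for name, (num, den) in {
        "TE": ((1, 1), (0, 0)),
        "DE": ((1, 0), (0, 0)),
        "IE": ((1, 1), (1, 0)),
    }.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = S[num] / S[den]
        mean = np.nanmean(theta, axis=1, keepdims=True)
        B = theta.shape[1]
        out[name] = np.sqrt((B - 1) / B * np.nansum((theta - mean) ** 2, axis=1))
    out["time"] = times
    return pd.DataFrame(out).set_index("time", drop=False)


def true_effects(
    config: ScenarioConfig,
    times,
    n_truth: int = 500_000,
    seed: int | None = None,
    restriction: str = "armwise",
) -> TrueEffects:
    """Convenience wrapper: simulate arms and compute effect curves."""
    arms = simulate_counterfactual_arms(
        config, n_truth=n_truth, seed=seed, restriction=restriction
    )
    return compute_true_effects(arms, times)
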
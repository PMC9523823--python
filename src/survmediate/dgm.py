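"""Synthetic cohort generation under additive-hazard mediation mechanisms.

The generator produces cohorts with a binary exposure ``A`` at time 0, a binary
baseline confounder ``Z0`` whose distribution depends on ``A`` (equivalent to
simulating confounding of the exposure by ``Z0``), a continuous mediator with a
random intercept/slope trajectory measured on a regular grid, an optional
time-varying confounder process ``L``, and continuous event times drawn wave by
wave from a piecewise-constant additive hazard

    lambda_i(t) = alpha_0 + alpha_A A_i + alpha_Z0 Z0_i
                  + alpha_M(t) M_i(t) + alpha_L(t) L_i(t)

with administrative censoring at ``tau``.  Within each wave (one grid interval)
an exponential candidate time is drawn at the hazard evaluated at the wave
start; the candidate is accepted if it falls inside the wave.

The exposure argument is split internally into a mediator-path argument ``a_M``
(entering every mediator mean) and a direct-path argument ``a_D`` (entering the
confounder process and the hazard).  Factual cohorts use ``a_M = a_D = A``;
the :mod:`survmediate.truth` module sets them to different values to generate
cross-world counterfactual arms while sharing the underlying random draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "HazardPositivityError",
    "ConfounderBlock",
    "ScenarioConfig",
    "RegistrySyntheticConfig",
    "draw_baseline",
    "simulate_mediator_paths",
    "generate_event_times",
    "simulate_cohort",
    "simulate_registry",
    "fmt_time",
    "mediator_column",
    "confounder_column",
]

SUB_SCENARIOS = ("DE+IE", "NoDE", "NoIE")

#: individuals are simulated in fixed-size blocks, each with its own spawned
#: random substream, so that enlarging ``n`` never reshuffles earlier blocks.
BLOCK_SIZE = 4096


class ConfigError(ValueError):
    """Raised when a scenario configuration is invalid."""


class HazardPositivityError(RuntimeError):
    """Raised when a simulated per-individual hazard is not strictly positive."""


def fmt_time(t: float) -> str:
    """Canonical column suffix for a grid time (``1`` not ``1.0``)."""
    if float(t) == int(t):
        return str(int(t))
    return ("%g" % float(t))


def mediator_column(t: float) -> str:
    return f"M_{fmt_time(t)}"


def confounder_column(t: float) -> str:
    return f"L_{fmt_time(t)}"


def _as_schedule(value, length: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, length)
    if arr.size != length:
        raise ConfigError(f"{name} must be a scalar or length-{length} sequence")
    return arr


def _check_psd(mat: np.ndarray, name: str, errors: list[str]) -> None:
    if mat.shape != (2, 2):
        errors.append(f"{name} must be 2x2")
        return
    if not np.allclose(mat, mat.T):
        errors.append(f"{name} must be symmetric")
        return
    eig = np.linalg.eigvalsh(mat)
    if eig.min() < -1e-10:
        errors.append(f"{name} must be positive semidefinite (eigenvalues {eig})")


@dataclass(frozen=True)
class ConfounderBlock:
    """Parameters of the time-varying confounder process ``L``.

    ``L_0 ~ N(mu_l0 + psi_Z0 Z0, 1)`` and, for grid times t > 0,
    ``L_t ~ N(mu_l0 + mu_l1 t + psi_Z0 Z0 + psi_A(t) a_D + psi_M M_{t-1}, 1)``.
    ``beta_L`` is the effect of the contemporaneous ``L_t`` on the mediator
    mean and ``alpha_L`` the per-interval hazard coefficient of the current L.
    """

    mu_L: tuple[float, float] = (1.0, 0.5)
    Sigma_L: tuple = ((0.25, 0.0), (0.0, 0.01))
    psi_Z0: float = 0.3
    psi_A: tuple = (0.0, 0.0, 0.0)  # per visit 1..3; nonzero only when A affects L
    psi_M: float = 0.1
    beta_L: float = 0.05
    alpha_L: tuple = (0.002, 0.002, 0.002, 0.002)  # per interval [k, k+1)

    def mu(self) -> np.ndarray:
        return np.asarray(self.mu_L, dtype=float)

    def cov(self) -> np.ndarray:
        return np.asarray(self.Sigma_L, dtype=float)


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete parameterisation of one data-generating mechanism."""

    n: int = 2000
    p_A: float = 0.5
    p_Z0_given_A: tuple[float, float] = (0.6, 0.4)  # (P(Z0=1|A=1), P(Z0=1|A=0))
    mediator_re_mean: tuple[float, float] = (2.9, 0.0)
    mediator_re_cov: tuple = ((0.25, -0.015), (-0.015, 0.010))
    beta_Z0: float = 0.5
    beta_A_schedule: tuple = (1.0, 1.0, 1.0)  # effect of A on M at visits 1..3
    mediator_resid_sd: float = 1.0
    alpha_0: float = 0.27
    alpha_A: float = 0.10
    alpha_Z0: float = 0.10
    alpha_M_schedule: tuple = (0.05, 0.05, 0.05, 0.05)  # per interval [k, k+1)
    confounder_block: Optional[ConfounderBlock] = None
    measurement_interval: float = 1.0
    analysis_visits: tuple = (0, 1, 2, 3)
    admin_censor_time: float = 4.0
    sub_scenario: str = "DE+IE"
    seed: int = 0
    name: str = "custom"

    # ---- derived helpers -------------------------------------------------

    def grid(self) -> np.ndarray:
        """Generation times 0, delta, 2*delta, ... < tau."""
        delta = self.measurement_interval
        n_steps = int(round(self.admin_censor_time / delta))
        return np.round(np.arange(n_steps) * delta, 10)

    def n_visits(self) -> int:
        return len([v for v in self.analysis_visits if v > 0])

    def beta_A_at(self, t: float) -> float:
        sched = _as_schedule(self.beta_A_schedule, 3, "beta_A_schedule")
        idx = min(int(math.ceil(t)), 3) - 1
        return float(sched[idx])

    def alpha_M_at(self, t: float) -> float:
        sched = _as_schedule(self.alpha_M_schedule, 4, "alpha_M_schedule")
        return float(sched[min(int(math.floor(t)), 3)])

    def psi_A_at(self, t: float) -> float:
        if self.confounder_block is None:
            return 0.0
        sched = _as_schedule(self.confounder_block.psi_A, 3, "psi_A")
        idx = min(int(math.ceil(t)), 3) - 1
        return float(sched[idx])

    def alpha_L_at(self, t: float) -> float:
        if self.confounder_block is None:
            return 0.0
        sched = _as_schedule(self.confounder_block.alpha_L, 4, "alpha_L")
        return float(sched[min(int(math.floor(t)), 3)])

    def p_Z0_marginal(self) -> float:
        p1, p0 = self.p_Z0_given_A
        return self.p_A * p1 + (1.0 - self.p_A) * p0

    # ---- validation ------------------------------------------------------

    def validate(self) -> "ScenarioConfig":
        errors: list[str] = []
        if self.n <= 0:
            errors.append("n must be positive")
        for pname, p in [("p_A", self.p_A)] + [
            (f"p_Z0_given_A[{i}]", v) for i, v in enumerate(self.p_Z0_given_A)
        ]:
            if not 0.0 <= p <= 1.0:
                errors.append(f"{pname}={p} must lie in [0, 1]")
        _check_psd(np.asarray(self.mediator_re_cov, float), "mediator_re_cov", errors)
        if self.confounder_block is not None:
            _check_psd(self.confounder_block.cov(), "Sigma_L", errors)
        if self.mediator_resid_sd < 0:
            errors.append("mediator_resid_sd must be non-negative")
        if self.measurement_interval <= 0:
            errors.append("measurement_interval must be positive")
        if self.admin_censor_time <= 0:
            errors.append("admin_censor_time must be positive")
        if self.sub_scenario not in SUB_SCENARIOS:
            errors.append(
                f"sub_scenario {self.sub_scenario!r} not one of {SUB_SCENARIOS}"
            )
        if self.sub_scenario == "NoDE":
            psi_A = (
                np.zeros(3)
                if self.confounder_block is None
                else _as_schedule(self.confounder_block.psi_A, 3, "psi_A")
            )
            if self.alpha_A != 0.0 or np.any(psi_A != 0.0):
                errors.append(
                    "NoDE requires every non-mediator path from A to the hazard "
                    "to be null (alpha_A=0 and psi_A=0)"
                )
        if self.sub_scenario == "NoIE":
            if np.any(_as_schedule(self.beta_A_schedule, 3, "beta_A") != 0.0):
                errors.append("NoIE requires beta_A_schedule = 0")
        if errors:
            raise ConfigError("; ".join(errors))
        return self

    def with_sub_scenario(self, sub: str) -> "ScenarioConfig":
        """Return a copy with the exposure paths switched per sub-scenario."""
        if sub not in SUB_SCENARIOS:
            raise ConfigError(f"unknown sub-scenario {sub!r}")
        cfg = replace(self, sub_scenario=sub)
        if sub == "NoDE":
            block = cfg.confounder_block
            if block is not None:
                block = replace(block, psi_A=(0.0, 0.0, 0.0))
            cfg = replace(cfg, alpha_A=0.0, confounder_block=block)
        elif sub == "NoIE":
            cfg = replace(cfg, beta_A_schedule=(0.0, 0.0, 0.0))
        return cfg


# ---------------------------------------------------------------------------
# raw draws and deterministic assembly
# ---------------------------------------------------------------------------


def _raw_draws(config: ScenarioConfig, n: int, rng: np.random.Generator) -> dict:
    """All stochastic inputs for ``n`` individuals, in a fixed draw order.

    Keeping raw draws separate from their deterministic transformation lets
    counterfactual arms share randomness (common random numbers).
    """
    grid = config.grid()
    g = len(grid)
    has_L = config.confounder_block is not None
    raw = {
        "u_A": rng.random(n),
        "u_Z0": rng.random(n),
        "z_M": rng.standard_normal((n, 2)),
        "z_L": rng.standard_normal((n, 2)) if has_L else None,
        "eps_L": rng.standard_normal((n, g)) if has_L else None,
        "eps_M": rng.standard_normal((n, g)),
        "u_wave": rng.random((n, g)),
    }
    return raw


def _assemble(
    config: ScenarioConfig,
    raw: dict,
    a_M: Optional[np.ndarray] = None,
    a_D: Optional[np.ndarray] = None,
    z0_marginal: bool = False,
    id_offset: int = 0,
) -> pd.DataFrame:
    """Deterministically transform raw draws into a cohort block.

    ``a_M``/``a_D`` override the exposure argument on the mediator path and on
    the direct (confounder + hazard) path; ``None`` means factual (both equal
    the drawn exposure ``A``).
    """
    n = raw["u_A"].shape[0]
    grid = config.grid()
    delta = config.measurement_interval
    tau = config.admin_censor_time
    block = config.confounder_block
    has_L = block is not None

    A = (raw["u_A"] < config.p_A).astype(float)
    if a_M is None:
        a_M = A
    else:
        a_M = np.broadcast_to(np.asarray(a_M, float), (n,)).copy()
    if a_D is None:
        a_D = A
    else:
        a_D = np.broadcast_to(np.asarray(a_D, float), (n,)).copy()

    if z0_marginal:
        pz = config.p_Z0_marginal()
        Z0 = (raw["u_Z0"] < pz).astype(float)
    else:
        p1, p0 = config.p_Z0_given_A
        Z0 = (raw["u_Z0"] < np.where(A == 1.0, p1, p0)).astype(float)

    chol_M = np.linalg.cholesky(
        np.asarray(config.mediator_re_cov, float) + 1e-12 * np.eye(2)
    )
    re_M = np.asarray(config.mediator_re_mean, float) + raw["z_M"] @ chol_M.T
    mu_m0, mu_m1 = re_M[:, 0], re_M[:, 1]

    if has_L:
        chol_L = np.linalg.cholesky(block.cov() + 1e-12 * np.eye(2))
        re_L = block.mu() + raw["z_L"] @ chol_L.T
        mu_l0, mu_l1 = re_L[:, 0], re_L[:, 1]

    M = np.empty((n, len(grid)))
    L = np.empty((n, len(grid))) if has_L else None
    for w, t in enumerate(grid):
        if has_L:
            mean_L = mu_l0 + block.psi_Z0 * Z0
            if t > 0:
                mean_L = (
                    mean_L
                    + mu_l1 * t
                    + config.psi_A_at(t) * a_D
                    + block.psi_M * M[:, w - 1]
                )
            L[:, w] = mean_L + raw["eps_L"][:, w]
        mean_M = mu_m0 + config.beta_Z0 * Z0
        if t > 0:
            mean_M = mean_M + mu_m1 * t + config.beta_A_at(t) * a_M
        if has_L:
            mean_M = mean_M + block.beta_L * L[:, w]
        M[:, w] = mean_M + config.mediator_resid_sd * raw["eps_M"][:, w]

    # event times in waves
    T = np.full(n, tau)
    E = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    for w, t_w in enumerate(grid):
        lam = (
            config.alpha_0
            + config.alpha_A * a_D
            + config.alpha_Z0 * Z0
            + config.alpha_M_at(t_w) * M[:, w]
        )
        if has_L:
            lam = lam + config.alpha_L_at(t_w) * L[:, w]
        bad = alive & (lam <= 0)
        if np.any(bad):
            i = int(np.nonzero(bad)[0][0])
            raise HazardPositivityError(
                f"non-positive hazard {lam[i]:.4f} for individual "
                f"{id_offset + i} in wave starting at t={t_w} "
                f"(scenario {config.name!r})"
            )
        t_cand = -np.log(raw["u_wave"][:, w]) / lam
        newly = alive & (t_cand < delta)
        T[newly] = t_w + t_cand[newly]
        E[newly] = 1
        alive &= ~newly

    data = {
        "id": np.arange(id_offset, id_offset + n),
        "A": A.astype(int),
        "Z0": Z0.astype(int),
    }
    for w, t in enumerate(grid):
        col = M[:, w].copy()
        col[grid[w] > T] = np.nan  # no post-death measurements
        data[mediator_column(t)] = col
    if has_L:
        for w, t in enumerate(grid):
            col = L[:, w].copy()
            col[grid[w] > T] = np.nan
            data[confounder_column(t)] = col
    data["T"] = T
    data["E"] = E
    return pd.DataFrame(data)


def _block_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    n_blocks = (n + BLOCK_SIZE - 1) // BLOCK_SIZE
    return np.random.SeedSequence(seed).spawn(n_blocks)


def _simulate(
    config: ScenarioConfig,
    n: int,
    seed: int,
    a_M=None,
    a_D=None,
    z0_marginal: bool = False,
) -> pd.DataFrame:
    """Blockwise simulation; prefix-stable in ``n`` for a fixed seed."""
    config.validate()
    frames = []
    offset = 0
    for ss in _block_seeds(seed, n):
        m = min(BLOCK_SIZE, n - offset)
        rng = np.random.default_rng(ss)
        raw = _raw_draws(config, BLOCK_SIZE, rng)
        raw = {k: (v[:m] if v is not None else None) for k, v in raw.items()}
        frames.append(
            _assemble(config, raw, a_M=a_M, a_D=a_D, z0_marginal=z0_marginal,
                      id_offset=offset)
        )
        offset += m
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def draw_baseline(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw exposure, baseline confounder and random effects for ``config.n``."""
    config.validate()
    n = config.n
    raw = _raw_draws(config, n, rng)
    A = (raw["u_A"] < config.p_A).astype(int)
    p1, p0 = config.p_Z0_given_A
    Z0 = (raw["u_Z0"] < np.where(A == 1, p1, p0)).astype(int)
    chol = np.linalg.cholesky(np.asarray(config.mediator_re_cov, float) + 1e-12 * np.eye(2))
    re = np.asarray(config.mediator_re_mean, float) + raw["z_M"] @ chol.T
    out = pd.DataFrame(
        {"id": np.arange(n), "A": A, "Z0": Z0, "mu_m0": re[:, 0], "mu_m1": re[:, 1]}
    )
    if config.confounder_block is not None:
        block = config.confounder_block
        cholL = np.linalg.cholesky(block.cov() + 1e-12 * np.eye(2))
        reL = block.mu() + raw["z_L"] @ cholL.T
        out["mu_l0"], out["mu_l1"] = reL[:, 0], reL[:, 1]
    out.attrs["_raw"] = raw
    return out


def simulate_mediator_paths(
    config: ScenarioConfig, baseline: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Mediator (and confounder) values at every generation time.

    Within a visit the causal ordering is L_t before M_t; across visits
    M_t feeds L_{t+1}.
    """
    n = len(baseline)
    grid = config.grid()
    block = config.confounder_block
    has_L = block is not None
    A = baseline["A"].to_numpy(float)
    Z0 = baseline["Z0"].to_numpy(float)
    mu_m0 = baseline["mu_m0"].to_numpy(float)
    mu_m1 = baseline["mu_m1"].to_numpy(float)
    M = np.empty((n, len(grid)))
    L = np.empty((n, len(grid))) if has_L else None
    for w, t in enumerate(grid):
        if has_L:
            mean_L = baseline["mu_l0"].to_numpy(float) + block.psi_Z0 * Z0
            if t > 0:
                mean_L = (
                    mean_L
                    + baseline["mu_l1"].to_numpy(float) * t
                    + config.psi_A_at(t) * A
                    + block.psi_M * M[:, w - 1]
                )
            L[:, w] = mean_L + rng.standard_normal(n)
        mean_M = mu_m0 + config.beta_Z0 * Z0
        if t > 0:
            mean_M = mean_M + mu_m1 * t + config.beta_A_at(t) * A
        if has_L:
            mean_M = mean_M + block.beta_L * L[:, w]
        M[:, w] = mean_M + config.mediator_resid_sd * rng.standard_normal(n)
    out = pd.DataFrame({mediator_column(t): M[:, w] for w, t in enumerate(grid)})
    if has_L:
        for w, t in enumerate(grid):
            out[confounder_column(t)] = L[:, w]
    return out


def generate_event_times(
    config: ScenarioConfig,
    baseline: pd.DataFrame,
    paths: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (T, E) from the wave-wise additive hazard.

    Raises :class:`HazardPositivityError` naming the individual and wave if a
    hazard is not strictly positive.
    """
    n = len(baseline)
    grid = config.grid()
    delta = config.measurement_interval
    tau = config.admin_censor_time
    A = baseline["A"].to_numpy(float)
    Z0 = baseline["Z0"].to_numpy(float)
    has_L = config.confounder_block is not None
    T = np.full(n, tau)
    E = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    hazards = np.empty((n, len(grid)))
    for w, t_w in enumerate(grid):
        lam = (
            config.alpha_0
            + config.alpha_A * A
            + config.alpha_Z0 * Z0
            + config.alpha_M_at(t_w) * paths[mediator_column(t_w)].to_numpy(float)
        )
        if has_L:
            lam = lam + config.alpha_L_at(t_w) * paths[
                confounder_column(t_w)
            ].to_numpy(float)
        bad = alive & ~(lam > 0)
        if np.any(bad):
            i = int(np.nonzero(bad)[0][0])
            raise HazardPositivityError(
                f"non-positive hazard {lam[i]:.4f} for individual {i} in wave "
                f"starting at t={t_w} (scenario {config.name!r})"
            )
        hazards[:, w] = lam
        u = rng.random(n)
        t_cand = -np.log(u) / lam
        newly = alive & (t_cand < delta)
        T[newly] = t_w + t_cand[newly]
        E[newly] = 1
        alive &= ~newly
    return T, E


def simulate_cohort(config: ScenarioConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Simulate a factual cohort; deterministic given (config, seed).

    The returned frame has one row per individual with columns ``id``, ``A``,
    ``Z0``, mediator columns ``M_<t>`` (NaN after death), optional confounder
    columns ``L_<t>``, event/censoring time ``T`` and event indicator ``E``.
    """
    if seed is None:
        seed = config.seed
    return _simulate(config, config.n, seed)


# ---------------------------------------------------------------------------
# synthetic annual-review registry (fixture for the landmark constructor)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegistrySyntheticConfig:
    """Parameters of a synthetic annual-review registry.

    Emulates the structure of a disease registry with annual monitoring
    visits: staggered entry ages, an absorbing incident exposure (diagnosis),
    a declining continuous mediator (lung-function-like, steeper decline after
    diagnosis), auxiliary covariates and a continuous outcome age.  This is a
    test fixture for landmarking, not a model of any real registry.
    """

    n: int = 500
    entry_age_range: tuple[int, int] = (18, 35)
    exit_age: int = 60
    onset_prob: float = 0.04  # annual probability of incident diagnosis
    prevalent_frac: float = 0.05  # diagnosed before entry (to be filtered out)
    missing_genotype_frac: float = 0.05
    mediator_mean: float = 85.0
    mediator_sd: float = 10.0
    mediator_slope: float = -1.0
    onset_extra_slope: float = -1.0
    mediator_resid_sd: float = 3.0
    base_death_rate: float = 0.015
    exposure_death_rate: float = 0.03
    mediator_death_rate: float = 0.0012  # per unit of (100 - mediator)
    seed: int = 0


def simulate_registry(config: RegistrySyntheticConfig) -> pd.DataFrame:
    """One row per individual per annual review, up to outcome or exit.

    Columns: id, age, diagnosed (absorbing 0/1), mediator, bmi, iv_days,
    sex, genotype_known, entry_age, outcome_age, event.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    lo, hi = config.entry_age_range
    for i in range(config.n):
        entry = int(rng.integers(lo, hi + 1))
        sex = int(rng.integers(0, 2))
        genotype_known = int(rng.random() > config.missing_genotype_frac)
        prevalent = rng.random() < config.prevalent_frac
        base = rng.normal(config.mediator_mean, config.mediator_sd)
        onset_age = None
        if prevalent:
            onset_age = entry - int(rng.integers(1, 5))
        diagnosed = prevalent
        outcome_age = None
        age = entry
        while age <= config.exit_age:
            if not diagnosed and rng.random() < config.onset_prob:
                diagnosed = True
                onset_age = age
            years = age - entry
            slope = config.mediator_slope
            extra = 0.0
            if onset_age is not None and age >= onset_age:
                extra = config.onset_extra_slope * (age - onset_age)
            med = base + slope * years + extra + rng.normal(0, config.mediator_resid_sd)
            bmi = rng.normal(22.0, 2.0)
            iv_days = int(rng.poisson(4 if diagnosed else 2))
            rate = (
                config.base_death_rate
                + config.exposure_death_rate * diagnosed
                + config.mediator_death_rate * max(0.0, 100.0 - med)
            )
            gap = rng.exponential(1.0 / rate)
            rows.append(
                dict(
                    id=i,
                    age=age,
                    diagnosed=int(diagnosed),
                    mediator=med,
                    bmi=bmi,
                    iv_days=iv_days,
                    sex=sex,
                    genotype_known=genotype_known,
                    entry_age=entry,
                )
            )
            if gap < 1.0:
                outcome_age = age + gap
                break
            age += 1
        reg_rows = [r for r in rows if r["id"] == i]
        if outcome_age is None:
            out_age, event = float(min(age, config.exit_age + 1)), 0
        else:
            out_age, event = float(outcome_age), 1
        for r in reg_rows:
            r["outcome_age"] = out_age
            r["event"] = event
    return pd.DataFrame(rows)
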
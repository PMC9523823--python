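import numpy as np
import pandas as pd
import pytest

import survmediate as sm
from survmediate.gformula import TerminalPredictor
from survmediate.dgm import RegistrySyntheticConfig, simulate_registry


@pytest.fixture(scope="session")
def reference_config():
    return sm.get_scenario("baseline", n=2000, seed=0)


@pytest.fixture(scope="session")
def reference_cohort(reference_config):
    return sm.simulate_cohort(reference_config)


@pytest.fixture(scope="session")
def big_reference_cohort():
    return sm.simulate_cohort(sm.get_scenario("baseline", n=60_000, seed=1))


@pytest.fixture(scope="session")
def synthetic_registry():
    return simulate_registry(RegistrySyntheticConfig(n=400, seed=5))


@pytest.fixture()
def toy_survival_cohort():
    """5 individuals, event times {1.1, 1.9, 2.4}, two administratively
    censored at the horizon t=4."""
    return pd.DataFrame(
        {
            "id": range(5),
            "A": [0, 1, 0, 1, 0],
            "Z0": [0, 0, 1, 1, 0],
            "M_0": [1.0, 2.0, 1.5, 2.5, 1.8],
            "M_1": [1.1, 2.1, 1.4, 2.4, 1.9],
            "M_2": [np.nan, 2.2, np.nan, 2.3, 2.0],
            "M_3": [np.nan, np.nan, np.nan, 2.2, 2.1],
            "T": [1.1, 2.4, 1.9, 4.0, 4.0],
            "E": [1, 1, 1, 0, 0],
        }
    )


def discrete_gformula_toy(n=4000, seed=2):
    """Binary mediator and confounder over two post-exposure visits with
    discrete event times; every covariate cell is populated."""
    rng = np.random.default_rng(seed)
    A = rng.integers(0, 2, n)
    Z0 = rng.integers(0, 2, n)
    L1 = (rng.random(n) < 0.3 + 0.2 * A).astype(int)
    M1 = (rng.random(n) < 0.3 + 0.2 * A + 0.2 * L1).astype(int)
    # survival through (1, 2]
    p_die1 = 0.15 + 0.1 * M1 + 0.05 * A
    die1 = rng.random(n) < p_die1
    L2 = (rng.random(n) < 0.3 + 0.2 * A + 0.2 * M1).astype(int)
    M2 = (rng.random(n) < 0.2 + 0.2 * A + 0.3 * M1 + 0.1 * L2).astype(int)
    p_die2 = 0.2 + 0.1 * M2 + 0.05 * A
    die2 = rng.random(n) < p_die2
    T = np.where(die1, 1.5, np.where(die2, 2.2, 4.0))
    E = (T < 4.0).astype(int)
    df = pd.DataFrame(
        {"id": np.arange(n), "A": A, "Z0": Z0, "M_0": 0, "L_0": 0,
         "M_1": M1, "L_1": L1, "M_2": M2.astype(float), "L_2": L2.astype(float),
         "T": T, "E": E}
    )
    df.loc[df["T"] < 2, ["M_2", "L_2"]] = np.nan
    return df


class EmpiricalTerminal(TerminalPredictor):
    """Stratum-frequency estimate of P(T > t | T >= k, history, A)."""

    def __init__(self, df, cols):
        self.df = df
        self.cols = cols

    def predict(self, df, t, k, a):
        base = self.df[self.df["T"] >= k].copy()
        cols = [c for c in self.cols if not c.endswith(("_2",))] if k < 2 else self.cols
        base["_gt"] = (base["T"] > t).astype(float)
        table = base.groupby(cols)["_gt"].mean()
        keys = df.assign(A=a)[cols]
        idx = pd.MultiIndex.from_frame(keys)
        return table.reindex(idx).to_numpy()


def gformula_enumeration_oracle(df, a, a_star, t):
    """Direct summation of the identification formula over all observed
    mediator/confounder configurations, using empirical conditional
    frequencies (two visits, evaluation time in (2, 3])."""
    pop = df[df["T"] >= 1]
    r1 = pop  # at risk at visit 1
    r2 = df[df["T"] >= 2]

    def freq(frame, cond, event):
        sel = np.ones(len(frame), bool)
        for c, v in cond.items():
            sel &= frame[c].to_numpy() == v
        sub = frame.loc[sel]
        return event(sub).mean()

    per_z = {}
    for z in (0, 1):
        s = 0.0
        for l1 in (0, 1):
            p_l1 = freq(r1, {"A": a, "Z0": z}, lambda d: (d["L_1"] == l1))
            for m1 in (0, 1):
                p_m1 = freq(
                    r1, {"A": a_star, "Z0": z, "L_1": l1},
                    lambda d: (d["M_1"] == m1),
                )
                cell1 = {"A": a, "Z0": z, "L_1": l1, "M_1": m1}
                p_surv = freq(r1, cell1, lambda d: (d["T"] >= 2))
                inner = 0.0
                for l2 in (0, 1):
                    p_l2 = freq(r2, cell1, lambda d: (d["L_2"] == l2))
                    for m2 in (0, 1):
                        p_m2 = freq(
                            r2,
                            {"A": a_star, "Z0": z, "L_1": l1, "M_1": m1,
                             "L_2": l2},
                            lambda d: (d["M_2"] == m2),
                        )
                        p_t = freq(
                            r2,
                            {"A": a, "Z0": z, "L_1": l1, "M_1": m1,
                             "L_2": l2, "M_2": m2},
                            lambda d: (d["T"] > t),
                        )
                        inner += p_l2 * p_m2 * p_t
                s += p_l1 * p_m1 * p_surv * inner
        per_z[z] = s
    return float(pop["Z0"].map(per_z).mean())


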
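"""Landmark (age-specific) analysis datasets from annual-review registries.

Registries with no natural time zero for unexposed individuals are handled by
stacking age-specific datasets: for each landmark age, everyone still at risk
at that age contributes a row as either newly exposed (diagnosed within the
past year -- prevalent cases never re-enter) or never-exposed-so-far, with the
clock reset to zero at the landmark age.  Baseline covariates come from the
review before exposure assessment and the first mediator measurement from the
review after it, preserving temporal ordering.  An individual can appear as
exposed at most once (their first-diagnosis age) but as unexposed at many
ages; individuals later diagnosed are deliberately not censored at diagnosis
when contributing unexposed rows, because that censoring would be informative.

The stacked output follows the cohort column contract (A, Z0 covariates,
M_0..M_K, T, E) so both estimators and the individual-level bootstrap can be
applied directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EligibilityRules",
    "AttritionReport",
    "apply_eligibility_filters",
    "build_age_specific_datasets",
    "categorize_iv_days",
    "IV_DAY_CATEGORIES",
]

logger = logging.getLogger(__name__)

#: six clinically motivated bins; courses of IV antibiotics come in weeks.
#: The boundary day 21 belongs to the three-week bin, the next bin is 22-28.
IV_DAY_CATEGORIES = ("0", "1-7", "8-14", "15-21", "22-28", ">28")

_IV_EDGES = (0, 7, 14, 21, 28)


def categorize_iv_days(days: int) -> str:
    """Map a count of IV-antibiotic days to its six-level category."""
    if days < 0:
        raise ValueError(f"negative IV-day count: {days}")
    if days == 0:
        return IV_DAY_CATEGORIES[0]
    for label, hi in zip(IV_DAY_CATEGORIES[1:-1], _IV_EDGES[1:]):
        if days <= hi:
            return label
    return IV_DAY_CATEGORIES[-1]


@dataclass
class EligibilityRules:
    """Cohort-entry rules applied to a registry before landmarking."""

    age_min: int = 18
    age_max: int = 60
    min_mediator_measurements: int = 2
    require_known_genotype: bool = True
    exclude_prevalent: bool = True  # diagnosed before first registry review


@dataclass
class AttritionReport:
    steps: list = field(default_factory=list)  # (rule, individuals remaining)

    def add(self, rule: str, n: int) -> None:
        self.steps.append((rule, n))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "individuals"])


_KNOWN_RULES = {
    "age_min",
    "age_max",
    "min_mediator_measurements",
    "require_known_genotype",
    "exclude_prevalent",
}


def apply_eligibility_filters(
    registry: pd.DataFrame, rules: EligibilityRules | dict | None = None
) -> tuple[pd.DataFrame, AttritionReport]:
    """Filter a long registry table, returning it with an attrition report.

    The registry has one row per individual per integer review age with
    columns ``id, age, diagnosed, mediator, ...``; the diagnosed flag is
    absorbing.  Filters operate on whole individuals.
    """
    if rules is None:
        rules = EligibilityRules()
    elif isinstance(rules, dict):
        unknown = set(rules) - _KNOWN_RULES
        if unknown:
            raise ValueError(f"unknown eligibility rule(s): {sorted(unknown)}")
        rules = EligibilityRules(**rules)
    report = AttritionReport()
    df = registry.copy()
    report.add("initial", df["id"].nunique())

    in_window = df["age"].between(rules.age_min, rules.age_max)
    ok_ids = df.loc[in_window, "id"].unique()
    df = df[df["id"].isin(ok_ids) & in_window]
    report.add(f"age {rules.age_min}-{rules.age_max}", df["id"].nunique())

    if rules.require_known_genotype and "genotype_known" in df.columns:
        ok = df.groupby("id")["genotype_known"].first() == 1
        df = df[df["id"].isin(ok[ok].index)]
        report.add("known genotype", df["id"].nunique())

    if rules.exclude_prevalent:
        first = df.sort_values("age").groupby("id").first()
        ok = first["diagnosed"] == 0
        df = df[df["id"].isin(ok[ok].index)]
        report.add("no prevalent exposure", df["id"].nunique())

    counts = df.dropna(subset=["mediator"]).groupby("id")["mediator"].size()
    ok_ids = counts[counts >= rules.min_mediator_measurements].index
    df = df[df["id"].isin(ok_ids)]
    report.add(
        f">= {rules.min_mediator_measurements} mediator measurements",
        df["id"].nunique(),
    )
    return df.reset_index(drop=True), report


def build_age_specific_datasets(
    registry: pd.DataFrame,
    age_min: int = 18,
    age_max: int = 50,
    n_visits: int = 3,
    horizon: float = 4.0,
    baseline_covariates: Sequence[str] = ("mediator", "bmi"),
) -> pd.DataFrame:
    """Stack age-specific landmark datasets into one analysis cohort.

    For each landmark age ``a`` the exposed are individuals first diagnosed at
    ``a`` (diagnosed flag switched on between reviews a-1 and a) and the
    unexposed are those never diagnosed by ``a``; both need the prior review
    at ``a - 1`` for baseline covariates, otherwise the individual-age is
    excluded and logged.  Output columns: ``id`` (registry id, shared across
    an individual's stacked rows for clustered bootstrapping), ``landmark_age``
    (also an adjustment covariate), ``A``, baseline covariates prefixed
    ``base_`` plus ``M_0`` (baseline mediator), per-visit mediators
    ``M_1..M_{n_visits}`` from reviews after exposure assessment, and the
    reset-clock ``T`` (administratively censored at ``horizon``) and ``E``.
    """
    by_id = {i: g.set_index("age") for i, g in registry.groupby("id")}
    rows = []
    n_missing_baseline = 0
    for i, g in by_id.items():
        ages = g.index.to_numpy()
        out_age = float(g["outcome_age"].iloc[0])
        event = int(g["event"].iloc[0])
        diag = g["diagnosed"]
        first_diag_age = None
        diagnosed_ages = diag[diag == 1]
        if len(diagnosed_ages):
            first_diag_age = int(diagnosed_ages.index.min())
        for a in range(age_min, age_max + 1):
            if a not in ages or out_age <= a:
                continue  # not at risk / not reviewed at this age
            if first_diag_age is not None and a > first_diag_age:
                continue  # already exposed; contributes nowhere after diagnosis age
            exposed = int(first_diag_age == a) if first_diag_age is not None else 0
            if (a - 1) not in ages:
                n_missing_baseline += 1
                continue  # no prior review for baseline measurements
            prior = g.loc[a - 1]
            row = {
                "id": i,
                "landmark_age": a,
                "A": exposed,
                "M_0": float(prior["mediator"]),
            }
            for c in baseline_covariates:
                if c == "mediator":
                    continue  # already carried as M_0
                row[f"base_{c}"] = float(prior[c]) if c in g.columns else np.nan
            # first mediator measurement comes from the review AFTER exposure
            # assessment; subsequent visits follow annually
            for k in range(1, n_visits + 1):
                va = a + k
                row[f"M_{k}"] = (
                    float(g.loc[va, "mediator"]) if va in ages else np.nan
                )
            t_reset = out_age - a
            if t_reset >= horizon:
                row["T"], row["E"] = horizon, 0
            else:
                row["T"], row["E"] = t_reset, event
            rows.append(row)
    if n_missing_baseline:
        logger.warning(
            "excluded %d individual-ages lacking the prior-review baseline",
            n_missing_baseline,
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out.attrs["n_missing_baseline"] = n_missing_baseline
    # invariant: nobody is exposed at two landmark ages
    exposed_counts = out.loc[out["A"] == 1].groupby("id").size()
    assert (exposed_counts <= 1).all(), "individual exposed at multiple landmarks"
    return out
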
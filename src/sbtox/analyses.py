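"""The four analyses: base case, hospitalization scenario, one-way DSA, PSA.

All comparisons are against 3D-CRT, reported as incremental cost (EUR) and
incremental utility (QALYs) per patient — deliberately not as a single
cost-effectiveness ratio, since the advanced techniques are expected to be
dominant (cheaper and more effective, the south-east quadrant of the
cost-effectiveness plane).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import LifeTable, run_cohort, run_mixed_cohort
from .parameters import ParameterSet, Technique
from .synthetic import Fixtures
from .valuation import EconomicResult, evaluate

log = logging.getLogger("sbtox")

__all__ = [
    "IncrementalResult",
    "BaseCaseResult",
    "run_base_case",
    "run_hospitalization_scenario",
    "run_owsa",
    "run_psa",
    "PsaResult",
    "OWSA_DEFAULT_IDS",
]

COMPARATORS = (Technique.IMRT_IGRT, Technique.IMRT)
REFERENCE = Technique.CRT3D


@dataclass(frozen=True)
class IncrementalResult:
    """Intervention minus 3D-CRT, discounted and undiscounted."""

    intervention: Technique
    dcost_discounted: float
    dqaly_discounted: float
    dcost_undiscounted: float
    dqaly_undiscounted: float


@dataclass(frozen=True)
class BaseCaseResult:
    results: dict[Technique, EconomicResult]
    incrementals: dict[Technique, IncrementalResult]

    def to_frame(self) -> pd.DataFrame:
        """Absolute and incremental costs/QALYs, discounted and undiscounted."""
        rows = []
        for tech, res in self.results.items():
            inc = self.incrementals.get(tech)
            for disc in (True, False):
                rows.append(
                    {
                        "technique": tech.value,
                        "discounting": "discounted" if disc else "undiscounted",
                        "cost": res.cost_discounted if disc else res.cost_undiscounted,
                        "qaly": res.qaly_discounted if disc else res.qaly_undiscounted,
                        "incr_cost": (
                            None if inc is None
                            else (inc.dcost_discounted if disc else inc.dcost_undiscounted)
                        ),
                        "incr_qaly": (
                            None if inc is None
                            else (inc.dqaly_discounted if disc else inc.dqaly_undiscounted)
                        ),
                    }
                )
        return pd.DataFrame(rows)


def _evaluate_all(ps: ParameterSet, fixtures: Fixtures,
                  include_indirect: bool) -> dict[Technique, EconomicResult]:
    out = {}
    for tech in Technique:
        trace = run_mixed_cohort(ps, tech, fixtures.incidence, fixtures.life_table)
        out[tech] = evaluate(trace, ps, fixtures.utilities, tech, include_indirect)
    return out


def _incrementals(results: dict[Technique, EconomicResult]) -> dict[Technique, IncrementalResult]:
    ref = results[REFERENCE]
    return {
        tech: IncrementalResult(
            intervention=tech,
            dcost_discounted=results[tech].cost_discounted - ref.cost_discounted,
            dqaly_discounted=results[tech].qaly_discounted - ref.qaly_discounted,
            dcost_undiscounted=results[tech].cost_undiscounted - ref.cost_undiscounted,
            dqaly_undiscounted=results[tech].qaly_undiscounted - ref.qaly_undiscounted,
        )
        for tech in COMPARATORS
    }


def run_base_case(ps: ParameterSet, fixtures: Fixtures,
                  include_indirect: bool | None = None) -> BaseCaseResult:
    """Deterministic base case: three age-mixed cohort runs on shared fixtures."""
    if include_indirect is None:
        include_indirect = ps.settings.include_indirect
    results = _evaluate_all(ps, fixtures, include_indirect)
    return BaseCaseResult(results=results, incrementals=_incrementals(results))


def run_hospitalization_scenario(
    ps: ParameterSet, life_table: LifeTable,
    cohort_ages: tuple[int, ...] = (30, 50, 70, 90),
    horizons: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70),
) -> pd.DataFrame:
    """Cumulative expected hospitalizations per 100 patients.

    Homogeneous cohorts by start age; first events (grade 3-4) and all
    recurrences count; undiscounted expectations.  Cells whose horizon
    extends beyond age 100 are NA.
    """
    rows = []
    for age in cohort_ages:
        for tech in Technique:
            trace = run_cohort(ps, tech, age, life_table)
            cum = np.cumsum(trace.aggregate_flow("hospitalizations"))
            for h in horizons:
                if age + h > ps.settings.horizon_age:
                    value = np.nan
                else:
                    cycles = int(round(h / trace.cycle_length))
                    value = 100.0 * cum[cycles - 1]
                rows.append(
                    {"age": age, "technique": tech.value, "horizon": h,
                     "hospitalizations_per_100": value}
                )
    return pd.DataFrame(rows)


#: canonical parameters varied in the one-way DSA (derived complements and
#: the printed per-technique toxicity rows are excluded: the former follow
#: their canonical sibling, the latter are derived from the reference row)
OWSA_DEFAULT_IDS = (
    "tox_event_uncertainty",
    "p_mgmt_loperamide", "p_second_line_ab", "p_mgmt_ab", "p_mgmt_bas",
    "p_surgery_after_hosp", "p_death_after_surgery", "p_death_after_supportive",
    "p_rec1_surgery", "p_rec1_supportive", "p_rec2_surgery", "p_rec2_supportive",
    "p_rec3_surgery", "p_rec3_supportive", "p_rec4_surgery", "p_rec4_supportive",
    "cost_loperamide_unit", "cost_ab_unit", "cost_bas_unit",
    "cost_hosp_surgery", "cost_hosp_supportive",
    "activity_rate", "wage_daily", "wage_annual",
    "sick_days_event", "sick_days_management", "sick_leave_hosp_factor",
)


def run_owsa(
    ps: ParameterSet, fixtures: Fixtures,
    param_ids: tuple[str, ...] | None = None,
    intervention: Technique = Technique.IMRT_IGRT,
    include_indirect: bool | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way deterministic sensitivity analysis (default 70% / 130%).

    Returns two tornado tables (incremental cost, incremental QALYs) for
    ``intervention`` vs 3D-CRT, sorted by spread, widest first.
    """
    param_ids = param_ids or OWSA_DEFAULT_IDS
    for pid in param_ids:
        ps[pid]  # raise early on unknown ids
    lo, hi = ps.settings.dsa_low, ps.settings.dsa_high

    def incr(p: ParameterSet) -> tuple[float, float]:
        base = run_base_case(p, fixtures, include_indirect)
        inc = base.incrementals[intervention]
        return inc.dcost_discounted, inc.dqaly_discounted

    rows_cost, rows_qaly = [], []
    for pid in param_ids:
        c_lo, q_lo = incr(ps.perturb(pid, lo))
        c_hi, q_hi = incr(ps.perturb(pid, hi))
        rows_cost.append({"parameter": pid, "low": c_lo, "high": c_hi,
                          "spread": abs(c_hi - c_lo)})
        rows_qaly.append({"parameter": pid, "low": q_lo, "high": q_hi,
                          "spread": abs(q_hi - q_lo)})
    cost = pd.DataFrame(rows_cost).sort_values("spread", ascending=False,
                                               ignore_index=True)
    qaly = pd.DataFrame(rows_qaly).sort_values("spread", ascending=False,
                                               ignore_index=True)
    return cost, qaly


@dataclass(frozen=True)
class PsaResult:
    draws: pd.DataFrame     # one row per Monte-Carlo draw
    summary: dict


def run_psa(
    ps: ParameterSet, fixtures: Fixtures,
    n_draws: int | None = None, seed: int = 0,
    mode: str | None = None,
    include_indirect: bool | None = None,
) -> PsaResult:
    """Probabilistic sensitivity analysis: joint independent parameter draws.

    Each draw re-runs the full model for all three techniques; results are
    the incremental cost and utility per comparator.  Reproducible under a
    fixed seed.  The summary reports means, 2.5/97.5 percentiles and the
    share of draws in the south-east quadrant (cost-saving and
    QALY-gaining) per comparator.
    """
    n = ps.settings.psa_draws if n_draws is None else n_draws
    if n < 1:
        raise ValueError("n_draws must be >= 1")
    mode = mode or ps.settings.psa_mode
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n):
        drawn = ps.sample(rng=rng, mode=mode)
        results = _evaluate_all(drawn, fixtures,
                                ps.settings.include_indirect
                                if include_indirect is None else include_indirect)
        inc = _incrementals(results)
        rows.append(
            {
                "draw": d,
                "dcost_imrt_igrt": inc[Technique.IMRT_IGRT].dcost_discounted,
                "dqaly_imrt_igrt": inc[Technique.IMRT_IGRT].dqaly_discounted,
                "dcost_imrt": inc[Technique.IMRT].dcost_discounted,
                "dqaly_imrt": inc[Technique.IMRT].dqaly_discounted,
            }
        )
    draws = pd.DataFrame(rows)
    summary: dict = {"n_draws": n, "seed": seed, "mode": mode}
    for tech in ("imrt_igrt", "imrt"):
        dc, dq = draws[f"dcost_{tech}"], draws[f"dqaly_{tech}"]
        se_share = float(((dc < 0) & (dq > 0)).mean())
        summary[tech] = {
            "dcost_mean": float(dc.mean()),
            "dcost_p2.5": float(dc.quantile(0.025)),
            "dcost_p97.5": float(dc.quantile(0.975)),
            "dqaly_mean": float(dq.mean()),
            "dqaly_p2.5": float(dq.quantile(0.025)),
            "dqaly_p97.5": float(dq.quantile(0.975)),
            "southeast_share": se_share,
        }
        log.info("PSA %s: south-east quadrant share %.3f", tech, se_share)
    return PsaResult(draws=draws, summary=summary)
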
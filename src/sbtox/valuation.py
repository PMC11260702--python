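"""Costs and QALYs from a cohort trace.

Costs follow a micro-costing logic: per-cycle event flows from the Markov
engine are multiplied by the collapsed cycle-tree expectations (drug-course
costs for pharmacological events, admission costs for hospitalizations),
and indirect costs add productivity losses — morbidity (sick-leave days ×
daily wage × activity rate, for the working-age part of the cohort) and
premature death from toxicity valued by the human-capital approach (gross
earnings to the retirement age, discounted at the cost rate).

QALYs multiply alive occupancy by an age-dependent baseline utility; every
event temporarily lowers utility for one cycle by the pathway-specific
*relative* disutility (multiplicative on the baseline).  Life-years use the
trapezoid of start- and end-of-cycle occupancy (half-cycle correction);
discounting values each cycle at its midpoint by default (3.0%/year for
costs, 1.5%/year for utilities).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .event_trees import build_hospital_tree, build_pharma_tree, collapse
from .markov import CohortTrace
from .parameters import ParameterSet, Technique

__all__ = [
    "UtilityCurve",
    "EconomicResult",
    "discount_factor",
    "accrue_costs",
    "accrue_qalys",
    "summarize",
    "evaluate",
]

COST_COMPONENTS = ("drugs", "hospitalizations",
                   "productivity_morbidity", "productivity_mortality")


@dataclass(frozen=True)
class UtilityCurve:
    """Baseline (symptom-free) utility by age, non-increasing, in [0, 1]."""

    age: np.ndarray
    utility: np.ndarray

    def __post_init__(self) -> None:
        age = np.asarray(self.age, dtype=float)
        u = np.asarray(self.utility, dtype=float)
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "utility", u)
        if age.shape != u.shape or age.size < 2:
            raise ValueError("age and utility must be equal-length (>= 2)")
        if np.any(np.diff(age) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(u < 0) or np.any(u > 1):
            raise ValueError("utilities must lie in [0, 1]")
        if np.any(np.diff(u) > 1e-12):
            raise ValueError("baseline utility must be non-increasing in age")

    def __call__(self, age):
        age = np.asarray(age, dtype=float)
        if np.any(age < self.age[0] - 1e-9) or np.any(age > self.age[-1] + 0.5 + 1e-9):
            raise ValueError("requested age outside the utility curve's range")
        out = np.interp(age, self.age, self.utility)
        return float(out) if out.ndim == 0 else out

    @classmethod
    def from_csv(cls, path: str | Path) -> "UtilityCurve":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"utility curve not found: {path}")
        frame = pd.read_csv(path)
        return cls(frame["age"].to_numpy(), frame["utility"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.age, "utility": self.utility}).to_csv(path, index=False)


def discount_factor(t_years, rate: float):
    """Discrete-time discount factor ``(1 + rate)^-t`` from model entry."""
    t = np.asarray(t_years, dtype=float)
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = (1.0 + rate) ** (-t)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ValuationStreams:
    """Per-cycle, per-start-age streams (raw and discounted), pre-aggregation."""

    times: np.ndarray                        # (C,) valuation times in years
    cost_raw: dict[str, np.ndarray]          # component -> (n_ages, C)
    cost_disc: dict[str, np.ndarray]
    qaly_raw: np.ndarray                     # (n_ages, C)
    qaly_disc: np.ndarray
    ly_raw: np.ndarray


@dataclass(frozen=True)
class EconomicResult:
    """Discounted and undiscounted totals per technique (per patient)."""

    technique: Technique
    cost_discounted: float
    cost_undiscounted: float
    qaly_discounted: float
    qaly_undiscounted: float
    ly_undiscounted: float
    breakdown_discounted: dict[str, float]
    breakdown_undiscounted: dict[str, float]


def _valuation_times(n_cycles: int, ps: ParameterSet) -> np.ndarray:
    cl = ps.settings.cycle_length_years
    k = np.arange(n_cycles, dtype=float)
    return (k + 0.5) * cl if ps.settings.half_cycle == "mid" else k * cl


def _working_annuity(age: np.ndarray, retirement: float, rate: float,
                     discounted: bool) -> np.ndarray:
    """Present value (at death) of one euro per remaining working year."""
    w = np.clip(retirement - age, 0.0, None)
    if not discounted or rate == 0.0:
        return w
    v = 1.0 / (1.0 + rate)
    m = np.floor(w)
    frac = w - m
    return (1.0 - v**m) / (1.0 - v) + frac * v**m


def accrue_costs(trace: CohortTrace, ps: ParameterSet,
                 include_indirect: bool = True) -> dict[str, np.ndarray]:
    """Undiscounted per-cycle cost streams by component, shape (n_ages, C)."""
    pharma = collapse(build_pharma_tree(ps))
    hospital = collapse(build_hospital_tree(ps))
    f_pharma = trace.flows["pharma_events"]
    f_hosp = trace.flows["hosp_events"]
    shape = f_pharma.shape

    streams = {
        "drugs": f_pharma * pharma.expected_cost,
        "hospitalizations": f_hosp * hospital.expected_cost,
        "productivity_morbidity": np.zeros(shape),
        "productivity_mortality": np.zeros(shape),
    }
    if include_indirect:
        s = ps.settings
        working = trace.ages < s.retirement_age
        wage_rate = ps.base("wage_daily") * ps.value("activity_rate")
        sick_days = (f_pharma * pharma.expected_sick_days
                     + f_hosp * hospital.expected_sick_days)
        streams["productivity_morbidity"] = sick_days * wage_rate * working
        annual = ps.base("wage_annual") * ps.value("activity_rate")
        hc = annual * _working_annuity(trace.ages, s.retirement_age,
                                       s.cost_discount, discounted=False)
        streams["productivity_mortality"] = trace.flows["death_sb"] * hc
    return streams


def _discounted_costs(trace: CohortTrace, ps: ParameterSet,
                      include_indirect: bool) -> dict[str, np.ndarray]:
    # mortality productivity needs the within-working-life discounting too,
    # so the discounted stream is not just `raw x factor` for that component
    streams = accrue_costs(trace, ps, include_indirect)
    t = _valuation_times(trace.n_cycles, ps)
    df = discount_factor(t, ps.settings.cost_discount)
    disc = {k: v * df for k, v in streams.items()}
    if include_indirect:
        s = ps.settings
        annual = ps.base("wage_annual") * ps.value("activity_rate")
        hc = annual * _working_annuity(trace.ages, s.retirement_age,
                                       s.cost_discount, discounted=True)
        disc["productivity_mortality"] = trace.flows["death_sb"] * hc * df
    return disc


def accrue_qalys(trace: CohortTrace, ps: ParameterSet,
                 curve: UtilityCurve) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle (QALY, life-year) streams, undiscounted, shape (n_ages, C)."""
    pharma = collapse(build_pharma_tree(ps))
    hospital = collapse(build_hospital_tree(ps))
    cl = trace.cycle_length
    alive = trace.space.alive
    occ_alive = trace.occupancy[:, :, alive].sum(axis=2)     # (n_ages, C+1)
    alive_avg = 0.5 * (occ_alive[:, :-1] + occ_alive[:, 1:])  # trapezoid
    # frozen (post-horizon) cells keep growing in age but are masked out below,
    # so clamp them into the curve's domain before interpolation
    mid_age = np.where(trace.active, trace.ages + 0.5 * cl, curve.age[-1])
    u = curve(mid_age)
    act = trace.active
    base = alive_avg * u * cl
    dis = (trace.flows["pharma_events"] * pharma.expected_disutility_weight
           + trace.flows["hosp_events"] * hospital.expected_disutility_weight) * u * cl
    qaly = (base - dis) * act
    ly = alive_avg * cl * act
    return qaly, ly


def build_streams(trace: CohortTrace, ps: ParameterSet, curve: UtilityCurve,
                  include_indirect: bool = True) -> ValuationStreams:
    times = _valuation_times(trace.n_cycles, ps)
    cost_raw = accrue_costs(trace, ps, include_indirect)
    cost_disc = _discounted_costs(trace, ps, include_indirect)
    qaly_raw, ly_raw = accrue_qalys(trace, ps, curve)
    dfu = discount_factor(times, ps.settings.utility_discount)
    return ValuationStreams(
        times=times,
        cost_raw=cost_raw,
        cost_disc=cost_disc,
        qaly_raw=qaly_raw,
        qaly_disc=qaly_raw * dfu,
        ly_raw=ly_raw,
    )


def summarize(trace: CohortTrace, streams: ValuationStreams,
              technique: Technique | None = None) -> EconomicResult:
    """Weight-aggregate streams into per-patient lifetime totals."""
    w = trace.weights

    def total(arr: np.ndarray) -> float:
        return float(w @ arr.sum(axis=1))

    bd_raw = {k: total(v) for k, v in streams.cost_raw.items()}
    bd_disc = {k: total(v) for k, v in streams.cost_disc.items()}
    return EconomicResult(
        technique=technique,
        cost_discounted=sum(bd_disc.values()),
        cost_undiscounted=sum(bd_raw.values()),
        qaly_discounted=total(streams.qaly_disc),
        qaly_undiscounted=total(streams.qaly_raw),
        ly_undiscounted=total(streams.ly_raw),
        breakdown_discounted=bd_disc,
        breakdown_undiscounted=bd_raw,
    )


def evaluate(trace: CohortTrace, ps: ParameterSet, curve: UtilityCurve,
             technique: Technique | None = None,
             include_indirect: bool = True) -> EconomicResult:
    """Convenience: streams + summary in one call."""
    streams = build_streams(trace, ps, curve, include_indirect)
    return summarize(trace, streams, technique)
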
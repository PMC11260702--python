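"""Probability and rate transformations.

Three transformations drive the toxicity dynamics:

* rate <-> probability conversion under a constant hazard,
  ``r = -ln(1-p)/t`` and ``p = 1 - exp(-r t)``;
* scaling of the reference (IMRT/IGRT) grade-probability vector to other
  techniques by the ratio of their normal tissue complication
  probabilities (NTCP).  The scaling acts directly on the probability
  scale with the unrounded NTCP ratios, which is the arithmetic that
  reproduces the published per-technique probabilities to three decimals;
* the late-toxicity decay schedule: event hazards are constant for the
  first five years after radiotherapy and then decline by 25% per whole
  elapsed year, applied as a step function on the rate scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet, Technique

__all__ = [
    "prob_to_rate",
    "rate_to_prob",
    "DecaySchedule",
    "decay_multiplier",
    "decayed_probability",
    "GradeProbabilityVector",
    "scale_by_ntcp",
    "grade_vector",
]


def prob_to_rate(p, t: float = 1.0):
    """Constant-hazard rate (per year) for probability ``p`` over ``t`` years."""
    p = np.asarray(p, dtype=float)
    if t <= 0:
        raise ValueError("duration t must be > 0")
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("probability must lie in [0, 1) for rate conversion")
    out = -np.log1p(-p) / t
    return float(out) if out.ndim == 0 else out


def rate_to_prob(r, t: float = 1.0):
    """Probability over ``t`` years under constant hazard ``r`` (per year)."""
    r = np.asarray(r, dtype=float)
    if t <= 0:
        raise ValueError("duration t must be > 0")
    if np.any(r < 0):
        raise ValueError("rate must be >= 0")
    out = -np.expm1(-r * t)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DecaySchedule:
    """Stepwise annual decline of the event hazard after an onset delay."""

    onset_years: float = 5.0
    annual_decline: float = 0.25

    def __post_init__(self) -> None:
        if self.onset_years < 0:
            raise ValueError("onset_years must be >= 0")
        if not 0.0 <= self.annual_decline < 1.0:
            raise ValueError("annual_decline must lie in [0, 1)")


def decay_multiplier(years_since_treatment: float, sched: DecaySchedule) -> float:
    """Multiplier on the event rate at a given time since treatment.

    1.0 up to the onset; beyond it, ``(1 - d)^k`` where ``k`` is the number
    of whole years elapsed past the onset (a step per year, not a
    continuous decline).
    """
    if years_since_treatment < 0:
        raise ValueError("years_since_treatment must be >= 0")
    past = years_since_treatment - sched.onset_years
    if past < 0:
        return 1.0
    return (1.0 - sched.annual_decline) ** int(np.floor(past))


def decayed_probability(
    p0, years_since_treatment: float, sched: DecaySchedule, cycle_length: float = 0.5
):
    """Per-cycle probability after applying the decay schedule on the rate scale."""
    mult = decay_multiplier(years_since_treatment, sched)
    return rate_to_prob(prob_to_rate(p0, cycle_length) * mult, cycle_length)


@dataclass(frozen=True)
class GradeProbabilityVector:
    """Half-yearly first-event probabilities for toxicity grades 1-4 (unit scale)."""

    technique: Technique
    p_grade: np.ndarray  # shape (4,)

    def __post_init__(self) -> None:
        p = np.asarray(self.p_grade, dtype=float)
        object.__setattr__(self, "p_grade", p)
        if p.shape != (4,):
            raise ValueError("p_grade must hold four grade probabilities")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("grade probabilities must lie in [0, 1]")
        if p.sum() > 1.0 + 1e-12:
            raise ValueError("grade probabilities must sum to <= 1")

    @property
    def total(self) -> float:
        return float(self.p_grade.sum())


def scale_by_ntcp(
    base: GradeProbabilityVector,
    ntcp_target: float,
    ntcp_ref: float,
    technique: Technique | None = None,
) -> GradeProbabilityVector:
    """Scale a grade-probability vector by the NTCP ratio ``target/ref``.

    The ratio multiplies the probabilities directly (not their rates);
    scaled values exceeding 1 are an error.
    """
    if ntcp_target <= 0 or ntcp_ref <= 0:
        raise ValueError("NTCP fractions must be > 0")
    ratio = ntcp_target / ntcp_ref
    scaled = base.p_grade * ratio
    if np.any(scaled > 1.0):
        raise ValueError(f"NTCP scaling by {ratio:.4f} pushes a probability above 1")
    return GradeProbabilityVector(technique or base.technique, scaled)


def grade_vector(
    ps: ParameterSet, technique: Technique, apply_uncertainty: bool = True
) -> GradeProbabilityVector:
    """Half-yearly grade probabilities for a technique.

    Built from the IMRT/IGRT reference row scaled by the unrounded NTCP
    ratio; the joint uncertainty multiplier (base 1.0, varied in PSA)
    multiplies the reference vector so that all techniques move together.
    """
    base = np.array([ps.prob(f"tox_grade{g}_imrt_igrt") for g in range(1, 5)])
    if apply_uncertainty:
        base = np.clip(base * ps.value("tox_event_uncertainty"), 0.0, 1.0)
    ref = GradeProbabilityVector(Technique.IMRT_IGRT, base)
    ntcp = ps.ntcp
    return scale_by_ntcp(ref, ntcp[technique], ntcp[Technique.IMRT_IGRT], technique)
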
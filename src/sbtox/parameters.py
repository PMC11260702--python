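"""Parameter registry for the small-bowel toxicity burden model.

Every model quantity — half-yearly toxicity transition probabilities by
grade and radiotherapy technique, treatment-pathway probabilities,
recurrence risks, unit costs, wages, sick-leave days and disutilities —
lives in a :class:`ParameterSet` together with its base-case value, its
uncertainty distribution for probabilistic sensitivity analysis (PSA) and
its provenance.  Values are stored exactly as printed in the source table
(probabilities on the percent scale, costs in 2022 euros) and converted to
the unit scale at a single point (:meth:`ParameterSet.value`), so that
percent/unit confusion cannot creep into the engine.

Three operations support the sensitivity machinery:

* :meth:`ParameterSet.perturb` — multiplicative one-way perturbation for
  deterministic sensitivity analysis, with probabilities capped at 100%.
* :meth:`ParameterSet.sample` — one joint independent Monte-Carlo draw for
  PSA.  Two modes are supported: ``"calibrated"`` (default) re-derives each
  beta/gamma/lognormal around its printed base-case mean so that the PSA is
  centred on the base case; ``"verbatim"`` samples from the distribution
  parameters exactly as printed, some of which are not consistent with
  their own base values.
* :meth:`ParameterSet.as_degenerate` — collapses every distribution, which
  turns the PSA into a base-case replay (useful for testing).

Complementary branch pairs (surgery vs. supportive split, survival vs.
death after each, antibiotics vs. bile-acid-sequestrant mix) are kept
consistent: one member of each pair is canonical and the sibling is always
its complement, both after sampling and in the decision trees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("sbtox")

__all__ = [
    "Technique",
    "DistributionSpec",
    "Parameter",
    "ModelSettings",
    "ParameterSet",
    "ParameterTableError",
    "load_parameter_set",
    "REQUIRED_IDS",
]


class Technique(str, Enum):
    """Radiotherapy delivery technique, in decreasing order of precision."""

    IMRT_IGRT = "imrt_igrt"
    IMRT = "imrt"
    CRT3D = "3dcrt"


#: Parameter id of the normal tissue complication probability per technique.
NTCP_IDS = {
    Technique.IMRT_IGRT: "ntcp_imrt_igrt",
    Technique.IMRT: "ntcp_imrt",
    Technique.CRT3D: "ntcp_3dcrt",
}

GROUPS = frozenset(
    {"transition", "treatment", "recurrence", "mortality",
     "direct_cost", "indirect_cost", "utility"}
)
FAMILIES = frozenset({"beta", "gamma", "lognormal", "degenerate"})

#: derived id -> canonical id; the derived member is always 100 - canonical.
DERIVED_COMPLEMENTS = {
    "p_supportive_after_hosp": "p_surgery_after_hosp",
    "p_mgmt_after_surgery": "p_death_after_surgery",
    "p_mgmt_after_supportive": "p_death_after_supportive",
    "p_second_line_bas": "p_second_line_ab",
}


class ParameterTableError(ValueError):
    """Raised when a parameter table is incomplete, unknown or invalid."""


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty distribution of a single parameter.

    ``family`` is one of ``beta`` (optionally with a ``scale`` stretching
    the support to [0, scale]), ``gamma`` (shape ``kappa``, scale
    ``theta``), ``lognormal`` (``mu_log`` and optionally ``sigma_log``) or
    ``degenerate`` (no sampling uncertainty).
    """

    family: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterTableError(f"unknown distribution family {self.family!r}")
        p = self.params
        if self.family == "beta":
            if p.get("alpha", 0.0) <= 0 or p.get("beta", 0.0) <= 0:
                raise ParameterTableError(f"beta requires alpha, beta > 0, got {p}")
            if p.get("scale", 1.0) <= 0:
                raise ParameterTableError("beta scale must be > 0")
        elif self.family == "gamma":
            if p.get("kappa", 0.0) <= 0 or p.get("theta", 0.0) <= 0:
                raise ParameterTableError(f"gamma requires kappa, theta > 0, got {p}")
        elif self.family == "lognormal":
            if "mu_log" not in p:
                raise ParameterTableError("lognormal requires mu_log")
            if p.get("sigma_log", 1.0) <= 0:
                raise ParameterTableError("lognormal sigma_log must be > 0")

    @property
    def degenerate(self) -> bool:
        return self.family == "degenerate"


def _parse_dist_params(text: str) -> dict[str, float]:
    if not text or not text.strip():
        return {}
    out: dict[str, float] = {}
    for chunk in text.split(";"):
        key, _, val = chunk.partition("=")
        out[key.strip()] = float(val)
    return out


def _format_dist_params(params: dict[str, float]) -> str:
    return ";".join(f"{k}={v!r}" for k, v in params.items())


@dataclass(frozen=True)
class Parameter:
    """One model quantity, stored on the scale it is printed on."""

    id: str
    group: str
    base_value: float
    unit: str  # "%", "EUR", "days" or "dimensionless"
    distribution: DistributionSpec
    source: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ParameterTableError(f"{self.id}: unknown group {self.group!r}")
        v = self.base_value
        if self.unit == "%":
            if self.group == "utility":
                if not -100.0 <= v <= 0.0:
                    raise ParameterTableError(
                        f"{self.id}: relative disutility {v} outside [-100, 0] percent"
                    )
            elif not 0.0 <= v <= 100.0:
                raise ParameterTableError(
                    f"{self.id}: probability/proportion {v} outside [0, 100] percent"
                )
        elif v < 0.0:
            raise ParameterTableError(f"{self.id}: value {v} must be >= 0 ({self.unit})")

    @property
    def unit_value(self) -> float:
        """Value on the unit scale (percent rows divided by 100)."""
        return self.base_value / 100.0 if self.unit == "%" else self.base_value


@dataclass(frozen=True)
class ModelSettings:
    """Global model configuration (cycle structure, discounting, analysis knobs).

    Time-related fields are in years, rates are annual fractions.  The
    resource-use fields (drug course length and daily doses) describe one
    pharmaceutical treatment course per toxicity event.
    """

    cycle_length_years: float = 0.5
    horizon_age: float = 100.0
    cost_discount: float = 0.030
    utility_discount: float = 0.015
    decay_onset_years: float = 5.0
    decay_per_year: float = 0.25
    dsa_low: float = 0.70
    dsa_high: float = 1.30
    psa_draws: int = 1000
    psa_mode: str = "calibrated"  # or "verbatim"
    psa_ess: float = 100.0  # effective sample size for calibrated betas
    lognormal_sigma: float = 0.25  # sigma_log when the table prints none
    course_days: float = 90.0
    loperamide_units_per_day: float = 2.0
    ab_units_per_day: float = 3.0
    bas_units_per_day: float = 4.0
    retirement_age: float = 65.0
    half_cycle: str = "mid"  # valuation timing: "mid" or "start"
    pharma_recurrence: str = "supportive"  # recurrence proxy for pharma pathway
    decay_on_recurrence: bool = True
    pharma_failure_escalates: bool = False
    include_indirect: bool = True

    def __post_init__(self) -> None:
        if self.cycle_length_years <= 0:
            raise ValueError("cycle_length_years must be > 0")
        if self.psa_mode not in ("calibrated", "verbatim"):
            raise ValueError(f"unknown psa_mode {self.psa_mode!r}")
        if self.half_cycle not in ("mid", "start"):
            raise ValueError(f"unknown half_cycle convention {self.half_cycle!r}")
        if self.pharma_recurrence not in ("supportive", "surgery"):
            raise ValueError(f"unknown pharma_recurrence proxy {self.pharma_recurrence!r}")


def _required_ids() -> frozenset[str]:
    ids = set()
    for tech in ("imrt_igrt", "imrt", "3dcrt"):
        ids.update(f"tox_grade{g}_{tech}" for g in range(1, 5))
        ids.add(f"ntcp_{tech}")
    ids.add("tox_event_uncertainty")
    ids.update(
        {
            "p_mgmt_loperamide", "p_second_line_ab", "p_second_line_bas",
            "p_mgmt_ab", "p_mgmt_bas",
            "p_surgery_after_hosp", "p_supportive_after_hosp",
            "p_mgmt_after_surgery", "p_death_after_surgery",
            "p_mgmt_after_supportive", "p_death_after_supportive",
        }
    )
    for lvl in range(1, 5):
        ids.update({f"p_rec{lvl}_surgery", f"p_rec{lvl}_supportive"})
    ids.update(
        {
            "cost_loperamide_unit", "cost_ab_unit", "cost_bas_unit",
            "cost_hosp_surgery", "cost_hosp_supportive",
            "activity_rate", "wage_daily", "wage_annual",
            "sick_days_event", "sick_days_management", "sick_leave_hosp_factor",
            "disutility_pharma", "disutility_supportive", "disutility_surgery",
        }
    )
    return frozenset(ids)


REQUIRED_IDS: frozenset[str] = _required_ids()


@dataclass(frozen=True)
class ParameterSet:
    """A complete, validated set of model parameters plus global settings."""

    parameters: dict[str, Parameter]
    settings: ModelSettings = field(default_factory=ModelSettings)

    # -- access -----------------------------------------------------------
    def __getitem__(self, pid: str) -> Parameter:
        try:
            return self.parameters[pid]
        except KeyError:
            raise KeyError(f"unknown parameter id {pid!r}") from None

    def base(self, pid: str) -> float:
        """Base-case value on the printed scale."""
        return self[pid].base_value

    def value(self, pid: str) -> float:
        """Base-case value on the unit scale (single percent->fraction point)."""
        return self[pid].unit_value

    def prob(self, pid: str) -> float:
        """Unit-scale probability accessor; insists the row is a percentage."""
        p = self[pid]
        if p.unit != "%":
            raise ValueError(f"{pid} is not a percentage row (unit {p.unit!r})")
        return p.unit_value

    @property
    def ntcp(self) -> dict[Technique, float]:
        """NTCP fraction per technique, unit scale."""
        return {tech: self.value(pid) for tech, pid in NTCP_IDS.items()}

    # -- sensitivity machinery -------------------------------------------
    def perturb(self, pid: str, factor: float) -> "ParameterSet":
        """Return a copy with ``base_value(pid)`` multiplied by ``factor``.

        Probabilities/proportions are capped at 100% (disutilities at
        -100%); the cap is logged.  All other parameters are untouched.
        """
        if factor <= 0:
            raise ValueError("perturbation factor must be > 0")
        p = self[pid]
        new = p.base_value * factor
        if p.unit == "%":
            if p.group == "utility":
                if new < -100.0:
                    log.warning("perturb: %s capped at -100%% (was %.4f)", pid, new)
                    new = -100.0
            elif new > 100.0:
                log.warning("perturb: %s capped at 100%% (was %.4f)", pid, new)
                new = 100.0
        params = dict(self.parameters)
        params[pid] = replace(p, base_value=new)
        return replace(self, parameters=params)

    def as_degenerate(self) -> "ParameterSet":
        """Copy with every uncertainty distribution collapsed to the base value."""
        degenerate = DistributionSpec("degenerate")
        params = {
            pid: replace(p, distribution=degenerate)
            for pid, p in self.parameters.items()
        }
        return replace(self, parameters=params)

    def _draw(self, p: Parameter, rng: np.random.Generator, mode: str) -> float:
        spec = p.distribution
        if spec.degenerate:
            return p.base_value
        if spec.family == "beta":
            scale = spec.params.get("scale", 1.0)
            printed_scale = 100.0 * scale if p.unit == "%" else scale
            if mode == "calibrated":
                m = p.base_value / printed_scale  # mean on the [0,1] support
                if not 0.0 < m < 1.0:
                    raise ParameterTableError(
                        f"{p.id}: cannot calibrate beta around mean {m}"
                    )
                ess = self.settings.psa_ess
                a, b = m * ess, (1.0 - m) * ess
            else:
                a, b = spec.params["alpha"], spec.params["beta"]
            return float(rng.beta(a, b)) * printed_scale
        if spec.family == "gamma":
            kappa = spec.params["kappa"]
            theta = p.base_value / kappa if mode == "calibrated" else spec.params["theta"]
            return float(rng.gamma(kappa, theta))
        # lognormal
        sigma = spec.params.get("sigma_log", self.settings.lognormal_sigma)
        if mode == "calibrated":
            mu = math.log(p.base_value) - sigma**2 / 2.0
        else:
            mu = spec.params["mu_log"]
        return float(rng.lognormal(mu, sigma))

    def sample(
        self,
        seed: int | None = None,
        *,
        rng: np.random.Generator | None = None,
        mode: str | None = None,
    ) -> "ParameterSet":
        """One joint independent Monte-Carlo draw of every parameter.

        Deterministic under a fixed ``seed``; complement pairs stay
        complementary (the canonical member is drawn, the sibling derived).
        Invalid distribution parameters are rejected at load time, not here.
        """
        if rng is None:
            rng = np.random.default_rng(seed)
        mode = mode or self.settings.psa_mode
        if mode not in ("calibrated", "verbatim"):
            raise ValueError(f"unknown sampling mode {mode!r}")
        new: dict[str, Parameter] = {}
        for pid in sorted(self.parameters):
            if pid in DERIVED_COMPLEMENTS:
                continue
            p = self.parameters[pid]
            new[pid] = replace(p, base_value=self._draw(p, rng, mode))
        for did, cid in DERIVED_COMPLEMENTS.items():
            derived = self.parameters[did]
            if not self.parameters[cid].distribution.degenerate:
                derived = replace(derived, base_value=100.0 - new[cid].base_value)
            new[did] = derived
        # keep the original row order for serialization round-trips
        ordered = {pid: new[pid] for pid in self.parameters}
        return replace(self, parameters=ordered)

    # -- serialization ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": p.id,
                "group": p.group,
                "base_value": p.base_value,
                "unit": p.unit,
                "family": p.distribution.family,
                "dist_params": _format_dist_params(p.distribution.params),
                "source": p.source,
            }
            for p in self.parameters.values()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_complements(params: dict[str, Parameter]) -> None:
    for did, cid in DERIVED_COMPLEMENTS.items():
        total = params[did].base_value + params[cid].base_value
        if abs(total - 100.0) > 0.05:
            raise ParameterTableError(
                f"{did} + {cid} = {total:.3f}%, expected 100% (complement pair)"
            )


def load_parameter_set(
    source: str | Path | None = None,
    settings: ModelSettings | None = None,
) -> ParameterSet:
    """Load and validate a parameter table.

    ``source`` is a CSV with columns ``id, group, base_value, unit, family,
    dist_params, source``; when omitted, the packaged base-case table is
    used.  Missing mandatory ids, unknown ids and out-of-range values all
    raise :class:`ParameterTableError`.
    """
    if source is None:
        with resources.as_file(
            resources.files("sbtox.data").joinpath("base_case.csv")
        ) as path:
            frame = pd.read_csv(path, dtype={"dist_params": str, "source": str})
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"parameter table not found: {path}")
        frame = pd.read_csv(path, dtype={"dist_params": str, "source": str})

    frame = frame.fillna({"dist_params": "", "source": ""})
    params: dict[str, Parameter] = {}
    for row in frame.itertuples(index=False):
        if row.id in params:
            raise ParameterTableError(f"duplicate parameter id {row.id!r}")
        spec = DistributionSpec(str(row.family), _parse_dist_params(str(row.dist_params)))
        params[row.id] = Parameter(
            id=str(row.id),
            group=str(row.group),
            base_value=float(row.base_value),
            unit=str(row.unit),
            distribution=spec,
            source=str(row.source),
        )

    missing = sorted(REQUIRED_IDS - set(params))
    if missing:
        raise ParameterTableError(f"parameter table incomplete, missing ids: {missing}")
    unknown = sorted(set(params) - REQUIRED_IDS)
    if unknown:
        raise ParameterTableError(f"parameter table contains unknown ids: {unknown}")
    _check_complements(params)
    return ParameterSet(parameters=params, settings=settings or ModelSettings())
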
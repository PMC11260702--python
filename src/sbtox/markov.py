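"""Half-yearly Markov cohort engine.

State space (22 states):

* ``post_treatment`` — symptom-free entry state; the only state exposed to
  first-event risk (once any event occurs the patient never returns);
* ``mgmt_{pathway}_r{level}`` — symptom management after an event, indexed
  by the treatment pathway of the last event (pharma / supportive /
  surgery) and by the number of recurrences experienced so far (0-4,
  capped at 4);
* ``recurrent_event_{level}`` — one-cycle tunnel states: a recurrence
  spends exactly one cycle here before resolving through the
  hospitalization tree into a new management state or death;
* ``death_sb`` and ``death_other`` — absorbing.

Within a cycle, background (other-cause) mortality is applied first and
toxicity dynamics act on the survivors.  First-event probabilities carry
the post-five-year decay on a clock that runs on time since treatment;
recurrence risks are pathway- and level-conditioned and, by default, not
time-conditioned.  Recurrence risk from pharmacologically managed states
uses the non-operative ("supportive") recurrence probabilities as proxy.

Event payloads (costs, sick leave, temporary disutility, admission counts)
are not handled here; the engine records per-cycle event *flows* which the
valuation layer multiplies by collapsed-tree expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import event_trees
from .event_trees import PathwayOutcome, build_hospital_tree, build_pharma_tree, collapse
from .hazards import DecaySchedule, decay_multiplier, prob_to_rate, rate_to_prob, grade_vector
from .parameters import ParameterSet, Technique

__all__ = [
    "PATHWAYS",
    "N_LEVELS",
    "StateSpace",
    "build_state_space",
    "LifeTable",
    "CohortTrace",
    "ModelDynamics",
    "build_dynamics",
    "build_transition_matrix",
    "run_cohort",
    "run_mixed_cohort",
]

PATHWAYS = ("pharma", "supportive", "surgery")
N_LEVELS = 5  # recurrences experienced so far: 0..4 (capped)


@dataclass(frozen=True)
class StateSpace:
    """Ordered model states with index helpers."""

    names: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def post_treatment(self) -> int:
        return 0

    def mgmt(self, pathway: str, level: int) -> int:
        return 1 + min(level, N_LEVELS - 1) * len(PATHWAYS) + PATHWAYS.index(pathway)

    def recurrent(self, level: int) -> int:
        # tunnel level 1..4
        return 1 + N_LEVELS * len(PATHWAYS) + (min(level, 4) - 1)

    @property
    def death_sb(self) -> int:
        return self.n - 2

    @property
    def death_other(self) -> int:
        return self.n - 1

    @property
    def alive(self) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        mask[[self.death_sb, self.death_other]] = False
        return mask


def build_state_space() -> StateSpace:
    names = ["post_treatment"]
    for level in range(N_LEVELS):
        for pw in PATHWAYS:
            names.append(f"mgmt_{pw}_r{level}")
    for level in range(1, 5):
        names.append(f"recurrent_event_{level}")
    names += ["death_sb", "death_other"]
    return StateSpace(tuple(names))


@dataclass(frozen=True)
class LifeTable:
    """Annual other-cause death probability by integer age (0-100)."""

    age: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        age = np.asarray(self.age, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "qx", qx)
        if age.shape != qx.shape or age.size == 0:
            raise ValueError("age and qx must be equal-length, non-empty")
        if np.any(np.diff(age) != 1):
            raise ValueError("life-table ages must be consecutive integers")
        if np.any(qx < 0) or np.any(qx > 1):
            raise ValueError("life-table qx must lie in [0, 1]")

    def annual_q(self, age):
        """Annual probability of other-cause death at (possibly fractional) age."""
        idx = np.clip(np.floor(np.asarray(age, dtype=float)).astype(int) - self.age[0],
                      0, self.age.size - 1)
        out = self.qx[idx]
        return float(out) if out.ndim == 0 else out

    def half_cycle_q(self, age):
        """Per half-year probability: 1 - (1 - q_annual)^0.5."""
        q = self.annual_q(age)
        return 1.0 - np.sqrt(1.0 - q)

    @classmethod
    def zero(cls, max_age: int = 100) -> "LifeTable":
        """Immortal background population (toxicity-only analyses)."""
        ages = np.arange(0, max_age + 1)
        return cls(ages, np.zeros_like(ages, dtype=float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"life table not found: {path}")
        frame = pd.read_csv(path)
        return cls(frame["age"].to_numpy(), frame["qx"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.age, "qx": self.qx}).to_csv(path, index=False)


#: per-cycle event-flow series recorded by the engine
FLOW_KEYS = (
    "first_event_g1", "first_event_g2", "first_event_g3", "first_event_g4",
    "pharma_events", "hosp_events", "recurrences", "hospitalizations",
    "death_sb", "death_other",
)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy and event flows, stacked over start ages.

    ``occupancy[i, k, s]`` is the cohort fraction of start age ``i`` in
    state ``s`` at the start of cycle ``k``; flows are per-cycle event
    masses.  Cohorts whose horizon (age 100) falls before the last cycle
    are frozen afterwards (``active`` False, zero flows).
    """

    space: StateSpace
    start_ages: np.ndarray          # (n_ages,)
    weights: np.ndarray             # (n_ages,) non-negative, sum 1
    cycle_length: float
    occupancy: np.ndarray           # (n_ages, n_cycles+1, n_states)
    ages: np.ndarray                # (n_ages, n_cycles) age at cycle start
    active: np.ndarray              # (n_ages, n_cycles) bool
    flows: dict[str, np.ndarray]    # each (n_ages, n_cycles)

    @property
    def n_cycles(self) -> int:
        return self.ages.shape[1]

    def aggregate_flow(self, key: str) -> np.ndarray:
        """Weight-averaged per-cycle flow across start ages."""
        return self.weights @ self.flows[key]

    def aggregate_occupancy(self) -> np.ndarray:
        return np.einsum("i,iks->ks", self.weights, self.occupancy)

    def to_frame(self) -> pd.DataFrame:
        """Weight-averaged trace as a tidy table (one row per cycle)."""
        occ = self.aggregate_occupancy()
        data = {"cycle": np.arange(self.n_cycles)}
        data["age"] = self.weights @ self.ages
        for s, name in enumerate(self.space.names):
            data[name] = occ[:-1, s]
        for key in FLOW_KEYS:
            data[f"flow_{key}"] = self.aggregate_flow(key)
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ModelDynamics:
    """Technique-specific transition ingredients precomputed from a ParameterSet."""

    ps: ParameterSet
    technique: Technique
    space: StateSpace
    p0: np.ndarray                  # (4,) half-cycle grade probabilities, undecayed
    pharma: PathwayOutcome
    hospital: PathwayOutcome
    rec: np.ndarray                 # (N_LEVELS, len(PATHWAYS)) next-recurrence prob
    sched: DecaySchedule

    def grade_probs(self, cycle_index: int) -> np.ndarray:
        """Decayed grade probabilities for a given cycle (clock: time since treatment)."""
        years = cycle_index * self.ps.settings.cycle_length_years
        mult = decay_multiplier(years, self.sched)
        if mult == 1.0:
            return self.p0
        return rate_to_prob(prob_to_rate(self.p0, 0.5) * mult, 0.5)

    def rec_probs(self, cycle_index: int) -> np.ndarray:
        if not self.ps.settings.decay_on_recurrence:
            return self.rec
        years = cycle_index * self.ps.settings.cycle_length_years
        mult = decay_multiplier(years, self.sched)
        if mult == 1.0:
            return self.rec
        return rate_to_prob(prob_to_rate(self.rec, 0.5) * mult, 0.5)


def build_dynamics(ps: ParameterSet, technique: Technique) -> ModelDynamics:
    space = build_state_space()
    p0 = grade_vector(ps, technique).p_grade
    pharma = collapse(build_pharma_tree(ps))
    hospital = collapse(build_hospital_tree(ps))
    rec = np.empty((N_LEVELS, len(PATHWAYS)))
    for level in range(N_LEVELS):
        nxt = min(level + 1, 4)
        for j, pw in enumerate(PATHWAYS):
            cls = "surgery" if pw == "surgery" else "supportive"
            if pw == "pharma":
                cls = ps.settings.pharma_recurrence
            rec[level, j] = ps.prob(f"p_rec{nxt}_{cls}")
    sched = DecaySchedule(ps.settings.decay_onset_years, ps.settings.decay_per_year)
    return ModelDynamics(ps, technique, space, p0, pharma, hospital, rec, sched)


def _dest_index(space: StateSpace, dest: str, level: int) -> int:
    if dest == event_trees.DEST_DEATH_SB:
        return space.death_sb
    return space.mgmt(dest, level)


def transition_matrix(dyn: ModelDynamics, cycle_index: int, age: float,
                      life_table: LifeTable) -> np.ndarray:
    """Explicit one-cycle stochastic matrix (rows sum to 1).

    Background mortality competes first: every alive state sends ``q`` to
    other-cause death and distributes the remaining ``1 - q`` through the
    toxicity dynamics.
    """
    space = dyn.space
    S = space.n
    T = np.zeros((S, S))
    q = float(life_table.half_cycle_q(age))
    s = 1.0 - q

    pg = dyn.grade_probs(cycle_index)
    pe = float(pg.sum())
    if pe > 1.0:
        raise ValueError("total event probability exceeds 1 after scaling")

    # post-treatment row
    i = space.post_treatment
    T[i, space.death_other] += q
    p_pharma_evt = float(pg[0] + pg[1])
    p_hosp_evt = float(pg[2] + pg[3])
    for dest, pr in dyn.pharma.dest_probs.items():
        T[i, _dest_index(space, dest, 0)] += s * p_pharma_evt * pr
    for dest, pr in dyn.hospital.dest_probs.items():
        T[i, _dest_index(space, dest, 0)] += s * p_hosp_evt * pr
    T[i, i] += s * (1.0 - pe)

    # management rows
    rec = dyn.rec_probs(cycle_index)
    for level in range(N_LEVELS):
        for j, pw in enumerate(PATHWAYS):
            i = space.mgmt(pw, level)
            r = float(rec[level, j])
            T[i, space.death_other] += q
            T[i, space.recurrent(min(level + 1, 4))] += s * r
            T[i, i] += s * (1.0 - r)

    # tunnel rows: resolve through the hospitalization tree
    for level in range(1, 5):
        i = space.recurrent(level)
        T[i, space.death_other] += q
        for dest, pr in dyn.hospital.dest_probs.items():
            T[i, _dest_index(space, dest, level)] += s * pr

    T[space.death_sb, space.death_sb] = 1.0
    T[space.death_other, space.death_other] = 1.0
    if np.any(T < -1e-12):
        raise ValueError("negative transition probability (inconsistent parameters)")
    return T


def build_transition_matrix(
    ps: ParameterSet, technique: Technique, cycle_index: int, age: float,
    life_table: LifeTable,
) -> np.ndarray:
    """Convenience wrapper building the dynamics from scratch (tests, inspection)."""
    return transition_matrix(build_dynamics(ps, technique), cycle_index, age, life_table)


def _normalize_incidence(incidence) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(incidence, pd.DataFrame):
        ages = incidence["age"].to_numpy(dtype=float)
        w = incidence["weight"].to_numpy(dtype=float)
    else:
        ages = np.array(sorted(incidence), dtype=float)
        w = np.array([incidence[a] for a in sorted(incidence)], dtype=float)
    if np.any(w < 0):
        raise ValueError("incidence weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"incidence weights must sum to 1 (got {w.sum():.6f})")
    return ages, w


def _run(dyn: ModelDynamics, start_ages: np.ndarray, weights: np.ndarray,
         life_table: LifeTable, horizon_age: float) -> CohortTrace:
    ps = dyn.ps
    space = dyn.space
    cl = ps.settings.cycle_length_years
    start_ages = np.asarray(start_ages, dtype=float)
    n_ages = start_ages.size
    n_cycles_per_age = np.ceil((horizon_age - start_ages) / cl - 1e-12).astype(int)
    if np.any(n_cycles_per_age <= 0):
        raise ValueError("horizon must allow at least one cycle for every start age")
    C = int(n_cycles_per_age.max())

    i_pt = space.post_treatment
    i_sb, i_do = space.death_sb, space.death_other
    i_re = np.array([space.recurrent(lv) for lv in range(1, 5)])
    i_mg = np.array([[space.mgmt(pw, lv) for pw in PATHWAYS] for lv in range(N_LEVELS)])
    hosp_dest = dyn.hospital.dest_probs
    hd_sb = hosp_dest.get(event_trees.DEST_DEATH_SB, 0.0)

    X = np.zeros((n_ages, space.n))
    X[:, i_pt] = 1.0
    occupancy = np.zeros((n_ages, C + 1, space.n))
    occupancy[:, 0] = X
    ages = np.zeros((n_ages, C))
    active = np.zeros((n_ages, C), dtype=bool)
    flows = {key: np.zeros((n_ages, C)) for key in FLOW_KEYS}

    alive = space.alive
    immortal = LifeTable.zero(int(np.ceil(horizon_age)) + 1)
    mgmt_flat = i_mg.ravel()
    # the toxicity-only matrix changes only when the decay multiplier steps
    # (once per model year), so cache it per multiplier value
    cache: dict[float, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    for k in range(C):
        age_k = start_ages + k * cl
        act = k < n_cycles_per_age
        ages[:, k] = age_k
        active[:, k] = act

        q = np.where(act, life_table.half_cycle_q(age_k), 0.0)
        srv = 1.0 - q

        # toxicity-only dynamics (background mortality factored out): one
        # shared matrix per cycle, then competing-first mortality per age
        mult = decay_multiplier(k * cl, dyn.sched)
        if mult not in cache:
            cache[mult] = (transition_matrix(dyn, k, 0.0, immortal),
                           dyn.grade_probs(k), dyn.rec_probs(k))
        M, pg, rec = cache[mult]
        Y = X @ M
        Xn = np.empty_like(X)
        Xn[:, alive] = srv[:, None] * Y[:, alive]
        alive_mass = X[:, alive].sum(axis=1)
        Xn[:, i_sb] = X[:, i_sb] + srv * (Y[:, i_sb] - X[:, i_sb])
        Xn[:, i_do] = X[:, i_do] + q * alive_mass

        # event flows for the valuation layer
        x_pt = X[:, i_pt]
        f_grades = x_pt[:, None] * srv[:, None] * pg[None, :]      # (n, 4)
        f_pharma = f_grades[:, 0] + f_grades[:, 1]
        f_hosp_first = f_grades[:, 2] + f_grades[:, 3]
        f_rec = (X[:, mgmt_flat] @ rec.ravel()) * srv
        f_resolve = X[:, i_re].sum(axis=1) * srv

        Xn = np.where(act[:, None], Xn, X)

        for g in range(4):
            flows[f"first_event_g{g+1}"][:, k] = f_grades[:, g] * act
        flows["pharma_events"][:, k] = f_pharma * act
        # admission payloads accrue in the event cycle: severe first events
        # resolve within-cycle, recurrences at tunnel entry
        flows["hosp_events"][:, k] = (f_hosp_first + f_rec) * act
        flows["recurrences"][:, k] = f_rec * act
        flows["hospitalizations"][:, k] = (f_hosp_first + f_rec) * act
        flows["death_sb"][:, k] = (f_hosp_first + f_resolve) * hd_sb * act
        flows["death_other"][:, k] = q * alive_mass

        X = Xn
        occupancy[:, k + 1] = X
        total = X.sum(axis=1)
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise RuntimeError("cohort mass not conserved")

    return CohortTrace(
        space=space,
        start_ages=start_ages,
        weights=np.asarray(weights, dtype=float),
        cycle_length=cl,
        occupancy=occupancy,
        ages=ages,
        active=active,
        flows=flows,
    )


def run_cohort(
    ps: ParameterSet, technique: Technique, start_age: float,
    life_table: LifeTable, horizon_age: float | None = None,
) -> CohortTrace:
    """Deterministic cohort run for a single start age (25-99)."""
    if not 25 <= start_age <= 99:
        raise ValueError("start_age must lie in [25, 99]")
    horizon = ps.settings.horizon_age if horizon_age is None else horizon_age
    if horizon <= start_age:
        raise ValueError("horizon must lie after the start age")
    dyn = build_dynamics(ps, technique)
    return _run(dyn, np.array([start_age]), np.array([1.0]), life_table, horizon)


def run_mixed_cohort(
    ps: ParameterSet, technique: Technique, incidence,
    life_table: LifeTable, horizon_age: float | None = None,
) -> CohortTrace:
    """Age-mixed cohort: one run per start age, stacked with incidence weights.

    ``incidence`` is a DataFrame with ``age``/``weight`` columns or an
    age->weight mapping; weights must be non-negative and sum to 1.
    """
    ages, weights = _normalize_incidence(incidence)
    horizon = ps.settings.horizon_age if horizon_age is None else horizon_age
    dyn = build_dynamics(ps, technique)
    return _run(dyn, ages, weights, life_table, horizon)
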
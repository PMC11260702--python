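"""Within-cycle treatment-pathway decision trees ("Markov cycle trees").

A toxicity event triggers a short decision tree inside the half-yearly
cycle: mild events (grade 1-2) are managed pharmaceutically, severe events
(grade 3-4) and every recurrence require hospitalization for supportive
care or surgery.  Each tree is collapsed exactly (path enumeration, no
sampling) into a :class:`PathwayOutcome`: destination-state probabilities
plus the expected one-time cost, sick-leave days, temporary utility loss
and admission count per event.

Pharmaceutical tree
    Loperamide controls symptoms with high probability; failures receive a
    second line, antibiotics or bile-acid sequestrants.  All paths end in
    pharmacologically managed symptom control within the cycle (recovery
    from mild toxicity is taken as given; escalation happens only through
    later recurrence, unless ``pharma_failure_escalates`` is set).

Hospitalization tree
    Admission splits into surgery or supportive (non-surgical) treatment;
    each arm either returns the patient to symptom management under that
    pathway label or ends in death from small-bowel toxicity.

Sick-leave attachment: every event carries the per-event sick leave, which
hospitalized paths multiply by (1 + additional-leave factor); entering a
symptom-management state adds the management sick leave once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import ParameterSet

__all__ = [
    "Terminal",
    "ChanceNode",
    "PathwayOutcome",
    "build_pharma_tree",
    "build_hospital_tree",
    "collapse",
    "to_outline",
]

#: Destination labels understood by the Markov engine.
DEST_PHARMA = "pharma"
DEST_SUPPORTIVE = "supportive"
DEST_SURGERY = "surgery"
DEST_DEATH_SB = "death_sb"


@dataclass
class Terminal:
    """Leaf of a cycle tree: destination state plus one-time payloads."""

    label: str
    destination: str
    cost: float = 0.0
    sick_days: float = 0.0
    disutility: float = 0.0  # fraction of one cycle's utility lost, >= 0
    hospitalization: int = 0


@dataclass
class ChanceNode:
    """Chance node with branch probabilities resolved from the parameter set."""

    label: str
    branches: list[tuple[float, "Node"]] = field(default_factory=list)


Node = Terminal | ChanceNode


@dataclass(frozen=True)
class PathwayOutcome:
    """A cycle tree collapsed to expectations per triggering event."""

    dest_probs: dict[str, float]
    expected_cost: float
    expected_sick_days: float
    expected_disutility_weight: float
    expected_hospitalizations: float

    @property
    def death_prob(self) -> float:
        return self.dest_probs.get(DEST_DEATH_SB, 0.0)


def collapse(tree: Node, atol: float = 1e-9) -> PathwayOutcome:
    """Exact expectation over all root-to-leaf paths of the tree."""
    dest: dict[str, float] = {}
    totals = {"cost": 0.0, "sick": 0.0, "dis": 0.0, "hosp": 0.0}

    def walk(node: Node, prob: float) -> None:
        if isinstance(node, Terminal):
            dest[node.destination] = dest.get(node.destination, 0.0) + prob
            totals["cost"] += prob * node.cost
            totals["sick"] += prob * node.sick_days
            totals["dis"] += prob * node.disutility
            totals["hosp"] += prob * node.hospitalization
            return
        branch_sum = sum(p for p, _ in node.branches)
        if abs(branch_sum - 1.0) > atol:
            raise ValueError(
                f"chance node {node.label!r} branches sum to {branch_sum!r}, not 1"
            )
        for p, child in node.branches:
            if p < 0:
                raise ValueError(f"negative branch probability at {node.label!r}")
            if p > 0:
                walk(child, prob * p)

    walk(tree, 1.0)
    total = sum(dest.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"collapsed destination probabilities sum to {total}")
    return PathwayOutcome(
        dest_probs=dest,
        expected_cost=totals["cost"],
        expected_sick_days=totals["sick"],
        expected_disutility_weight=totals["dis"],
        expected_hospitalizations=totals["hosp"],
    )


def _course_cost(ps: ParameterSet, unit_cost_id: str, units_per_day: float) -> float:
    return ps.base(unit_cost_id) * units_per_day * ps.settings.course_days


def _offset_costs(node: Node, extra: float) -> Node:
    """Copy of a subtree with ``extra`` added to every terminal's cost."""
    if isinstance(node, Terminal):
        return Terminal(
            node.label, node.destination, node.cost + extra,
            node.sick_days, node.disutility, node.hospitalization,
        )
    return ChanceNode(node.label, [(p, _offset_costs(c, extra)) for p, c in node.branches])


def build_pharma_tree(ps: ParameterSet) -> ChanceNode:
    """Pharmaceutical management of a grade 1-2 first event."""
    s = ps.settings
    p_lop = ps.prob("p_mgmt_loperamide")
    p_ab_mix = ps.prob("p_second_line_ab")
    p_ab = ps.prob("p_mgmt_ab")
    p_bas = ps.prob("p_mgmt_bas")

    lop_cost = _course_cost(ps, "cost_loperamide_unit", s.loperamide_units_per_day)
    ab_cost = _course_cost(ps, "cost_ab_unit", s.ab_units_per_day)
    bas_cost = _course_cost(ps, "cost_bas_unit", s.bas_units_per_day)

    sick = ps.base("sick_days_event") + ps.base("sick_days_management")
    dis = -ps.value("disutility_pharma")

    def managed(label: str, cost: float) -> Terminal:
        return Terminal(label, DEST_PHARMA, cost, sick, dis)

    if s.pharma_failure_escalates:
        hosp = build_hospital_tree(ps)
        ab_fail: Node = _offset_costs(hosp, lop_cost + ab_cost)
        bas_fail: Node = _offset_costs(hosp, lop_cost + bas_cost)
    else:
        ab_fail = managed("AB failure, managed", lop_cost + ab_cost)
        bas_fail = managed("BAS failure, managed", lop_cost + bas_cost)

    ab_node = ChanceNode(
        "antibiotics",
        [(p_ab, managed("AB success", lop_cost + ab_cost)), (1.0 - p_ab, ab_fail)],
    )
    bas_node = ChanceNode(
        "bile acid sequestrants",
        [(p_bas, managed("BAS success", lop_cost + bas_cost)), (1.0 - p_bas, bas_fail)],
    )
    second_line = ChanceNode(
        "second line", [(p_ab_mix, ab_node), (1.0 - p_ab_mix, bas_node)]
    )
    return ChanceNode(
        "loperamide",
        [(p_lop, managed("loperamide success", lop_cost)), (1.0 - p_lop, second_line)],
    )


def build_hospital_tree(ps: ParameterSet) -> ChanceNode:
    """Hospitalization after a grade 3-4 first event or any recurrence."""
    p_surg = ps.prob("p_surgery_after_hosp")
    p_die_surg = ps.prob("p_death_after_surgery")
    p_die_sup = ps.prob("p_death_after_supportive")

    c_surg = ps.base("cost_hosp_surgery")
    c_sup = ps.base("cost_hosp_supportive")
    event_sick = ps.base("sick_days_event") * (1.0 + ps.base("sick_leave_hosp_factor"))
    mgmt_sick = ps.base("sick_days_management")
    d_surg = -ps.value("disutility_surgery")
    d_sup = -ps.value("disutility_supportive")

    surgery = ChanceNode(
        "surgery",
        [
            (
                1.0 - p_die_surg,
                Terminal("surgery, managed", DEST_SURGERY, c_surg,
                         event_sick + mgmt_sick, d_surg, 1),
            ),
            (
                p_die_surg,
                Terminal("surgery, death", DEST_DEATH_SB, c_surg, event_sick, d_surg, 1),
            ),
        ],
    )
    supportive = ChanceNode(
        "supportive treatment",
        [
            (
                1.0 - p_die_sup,
                Terminal("supportive, managed", DEST_SUPPORTIVE, c_sup,
                         event_sick + mgmt_sick, d_sup, 1),
            ),
            (
                p_die_sup,
                Terminal("supportive, death", DEST_DEATH_SB, c_sup, event_sick, d_sup, 1),
            ),
        ],
    )
    return ChanceNode("hospitalization", [(p_surg, surgery), (1.0 - p_surg, supportive)])


def to_outline(tree: Node, indent: int = 0) -> str:
    """Debug export: indented text outline with resolved probabilities."""
    pad = "  " * indent
    if isinstance(tree, Terminal):
        return (
            f"{pad}* {tree.label} -> {tree.destination} "
            f"(cost={tree.cost:.3f}, sick={tree.sick_days:.3f}, "
            f"disutility={tree.disutility:.3f}, hosp={tree.hospitalization})"
        )
    lines = [f"{pad}{tree.label}:"]
    for p, child in tree.branches:
        lines.append(f"{pad}- p={p:.6f}")
        lines.append(to_outline(child, indent + 1))
    return "\n".join(lines)
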
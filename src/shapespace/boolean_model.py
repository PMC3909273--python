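"""Two-compartment Boolean model of Rac/Rho activity.

The model splits GTPase signalling into a cortical compartment (protrusion
and retraction machinery) and an adhesion compartment (substrate adhesion
machinery).  In each compartment Rac and Rho antagonise one another, so a
compartment is in exactly one of three activity states: RAC on, RHO on, or
neither (NONE) — mutual exclusion is structural in the state encoding.  Two
further constraint rules prune the 3 x 3 raw state space:

* ``global_activity_required`` — at least one GTPase must be active in at
  least one compartment (only the all-off state is excluded);
* ``cortical_rac_forces_adhesion_activity`` — Rac-driven protrusion in the
  cortical compartment promotes Rho activity in the adhesion compartment, so
  cortical RAC with a silent adhesion compartment is excluded.

Under the default rules exactly seven states survive, one per observed cell
shape.  The model is static: upstream regulators (RhoGEFs/RhoGAPs) can move
it between states at any time, so it is enumerated, not iterated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml

__all__ = [
    "Activity",
    "BooleanState",
    "RuleSet",
    "StateShapeMap",
    "is_admissible",
    "enumerate_states",
    "map_state_to_shape",
    "DEFAULT_STATE_SHAPE_MAP",
    "enumeration_report",
]


class Activity(str, Enum):
    """Which GTPase (if either) is active in a compartment."""

    RAC = "RAC"
    RHO = "RHO"
    NONE = "NONE"


# deterministic enumeration order within a compartment
_ACTIVITY_ORDER = (Activity.RAC, Activity.RHO, Activity.NONE)


@dataclass(frozen=True)
class BooleanState:
    """Activity in the cortical and adhesion compartments.

    Within-compartment Rac/Rho mutual exclusion is encoded by the Activity
    enum: a compartment cannot have both GTPases on.
    """

    cortical: Activity
    adhesion: Activity

    def __str__(self) -> str:
        return f"({self.cortical.value}, {self.adhesion.value})"


@dataclass
class RuleSet:
    """Constraint rules pruning the raw 3 x 3 state space.

    ``mutual_antagonism`` is structural (the Activity enum cannot express
    both GTPases on in one compartment); the flag is kept so configurations
    are explicit about the assumption.
    """

    mutual_antagonism: bool = True
    global_activity_required: bool = True
    cortical_rac_forces_adhesion_activity: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleSet":
        return cls(**yaml.safe_load(Path(path).read_text()))


def is_admissible(state: BooleanState, rules: RuleSet | None = None) -> bool:
    """Whether a state satisfies the constraint rules.

    The global-activity rule excludes only the state where both compartments
    are silent; the forcing rule excludes cortical RAC paired with a silent
    adhesion compartment.
    """
    rules = rules or RuleSet()
    if rules.global_activity_required:
        if state.cortical is Activity.NONE and state.adhesion is Activity.NONE:
            return False
    if rules.cortical_rac_forces_adhesion_activity:
        if state.cortical is Activity.RAC and state.adhesion is Activity.NONE:
            return False
    return True


def enumerate_states(rules: RuleSet | None = None) -> list[BooleanState]:
    """All admissible states in a fixed order (cortical-major, RAC < RHO < NONE)."""
    rules = rules or RuleSet()
    return [
        s
        for c in _ACTIVITY_ORDER
        for a in _ACTIVITY_ORDER
        if is_admissible(s := BooleanState(cortical=c, adhesion=a), rules)
    ]


@dataclass
class StateShapeMap:
    """Partial, configurable assignment of admissible states to shape ids.

    ``evidence`` records, per state, why the assignment was made; entries
    marked "inferred" follow from shape characteristics rather than an
    explicit statement and are the ones most worth overriding.
    """

    mapping: dict[BooleanState, int]
    evidence: dict[BooleanState, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = list(self.mapping.values())
        if len(set(shapes)) != len(shapes):
            raise ValueError("state->shape mapping must be injective")

    def to_yaml(self, path: str | Path) -> None:
        doc = [
            {
                "cortical": s.cortical.value,
                "adhesion": s.adhesion.value,
                "shape": shape,
                "evidence": self.evidence.get(s, ""),
            }
            for s, shape in self.mapping.items()
        ]
        Path(path).write_text(yaml.safe_dump(doc))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StateShapeMap":
        doc = yaml.safe_load(Path(path).read_text())
        mapping, evidence = {}, {}
        for entry in doc:
            s = BooleanState(
                cortical=Activity(entry["cortical"]),
                adhesion=Activity(entry["adhesion"]),
            )
            mapping[s] = int(entry["shape"])
            evidence[s] = entry.get("evidence", "")
        return cls(mapping=mapping, evidence=evidence)


def _default_map() -> StateShapeMap:
    R, H, N = Activity.RAC, Activity.RHO, Activity.NONE
    entries = {
        BooleanState(R, H): (5, "polarized migratory cell: Rac at the leading "
                                "edge, Rho at the trailing edge/adhesions"),
        BooleanState(R, R): (7, "large flat lamellipodial cell; enriched by "
                                "constitutively active Rac"),
        BooleanState(H, H): (1, "round contractile cell; enriched by "
                                "constitutively active Rho"),
        BooleanState(N, R): (6, "unpolarized spread cell with many adhesions: "
                                "cortical Rho activation fails while Rac acts "
                                "at adhesions"),
        BooleanState(H, R): (3, "inferred: long bipolar contractile cell that "
                                "does not round up because Rac maintains "
                                "adhesions"),
        BooleanState(H, N): (2, "inferred: small blebby rounded cell, very "
                                "similar to shape 1 with little Rac activity"),
        BooleanState(N, H): (4, "inferred: poorly spread cell with defective "
                                "lamellipodia after loss of Rac-mediated "
                                "protrusion"),
    }
    return StateShapeMap(
        mapping={s: shape for s, (shape, _) in entries.items()},
        evidence={s: ev for s, (_, ev) in entries.items()},
    )


DEFAULT_STATE_SHAPE_MAP = _default_map()


def map_state_to_shape(
    state: BooleanState,
    mapping: StateShapeMap | None = None,
    rules: RuleSet | None = None,
) -> int | str:
    """Shape id for an admissible state, or ``"unassigned"`` if the map has
    no entry for it."""
    mapping = mapping or DEFAULT_STATE_SHAPE_MAP
    if not is_admissible(state, rules):
        raise ValueError(f"state {state} is not admissible under the rules")
    return mapping.mapping.get(state, "unassigned")


def enumeration_report(
    rules: RuleSet | None = None, mapping: StateShapeMap | None = None
) -> dict:
    """JSON-ready summary: every raw state, its admissibility under each
    rule, and the mapped shape for admissible states."""
    rules = rules or RuleSet()
    mapping = mapping or DEFAULT_STATE_SHAPE_MAP
    states = []
    for c in _ACTIVITY_ORDER:
        for a in _ACTIVITY_ORDER:
            s = BooleanState(c, a)
            admissible = is_admissible(s, rules)
            entry = {
                "cortical": c.value,
                "adhesion": a.value,
                "admissible": admissible,
                "violates": [],
            }
            if rules.global_activity_required and c is Activity.NONE and a is Activity.NONE:
                entry["violates"].append("global_activity_required")
            if (
                rules.cortical_rac_forces_adhesion_activity
                and c is Activity.RAC
                and a is Activity.NONE
            ):
                entry["violates"].append("cortical_rac_forces_adhesion_activity")
            if admissible:
                shape = mapping.mapping.get(s, "unassigned")
                entry["shape"] = shape
                if s in mapping.evidence:
                    entry["evidence"] = mapping.evidence[s]
            states.append(entry)
    return {
        "rules": dict(rules.__dict__),
        "n_admissible": sum(e["admissible"] for e in states),
        "states": states,
    }
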
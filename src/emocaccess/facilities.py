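"""Facility readiness scoring and five-level classification.

A facility's readiness score (0-14) combines two dimensions:

* **General readiness** (max 5): one point each for being open 24/7 and
  having electricity, water, any functioning motorised transport, and a
  functioning mode of communication.
* **Signal-function readiness** (max 9): one point per emergency
  obstetric/newborn signal function for which the facility is both
  *staffed* (a cadre able to perform it is present) and *equipped* (the
  minimum drugs/equipment/supplies are in stock).

Levels 1-5 are then assigned from the score plus two extra criteria —
recent caesarean performance and transport availability:

====== ============ ==========================================
Level  Score band   Other criterion
====== ============ ==========================================
5      10-14        caesarean delivery in the last three months
4      10-14        —
3      0-9          functioning motorised transport
2      6-9          —
1      0-5          —
====== ============ ==========================================

Rules are evaluated top-down, first match wins, so transport promotes
any score-0-9 facility to level 3 regardless of the 6-9 / 0-5 banding.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

MAX_SCORE = 14
N_GENERAL_ITEMS = 5
N_SIGNAL_FUNCTIONS = 9

#: The nine emergency obstetric and newborn care signal functions.
SIGNAL_FUNCTIONS: tuple[str, ...] = (
    "parenteral_antibiotics",
    "parenteral_uterotonics",
    "parenteral_anticonvulsants",
    "manual_removal_placenta",
    "removal_retained_products",
    "assisted_vaginal_delivery",
    "newborn_resuscitation",
    "blood_transfusion",
    "caesarean_delivery",
)

GENERAL_ITEMS: tuple[str, ...] = (
    "open_24_7",
    "has_electricity",
    "has_water",
    "has_transport",
    "has_communication",
)


@dataclass(frozen=True)
class ChecklistEntry:
    """Minimum requirements for one signal function.

    ``cadres``: staff categories any one of which can perform the
    function; ``items``: drugs/equipment/supplies that must all be in
    stock for the facility to count as equipped.
    """

    cadres: frozenset[str]
    items: frozenset[str]


def _default_entries() -> dict[str, ChecklistEntry]:
    clinical = frozenset(
        {"doctor", "midwife", "surgical_technician", "medical_technician"}
    )
    entries = {
        fn: ChecklistEntry(cadres=clinical, items=frozenset({fn + "_kit"}))
        for fn in SIGNAL_FUNCTIONS
    }
    # Caesarean readiness additionally requires surgical staff and the
    # capability to give general or regional anaesthesia.
    entries["caesarean_delivery"] = ChecklistEntry(
        cadres=frozenset({"doctor", "surgical_technician"}),
        items=frozenset({"caesarean_delivery_kit", "anaesthesia"}),
    )
    return entries


@dataclass
class SignalFunctionChecklist:
    """Configurable cadre/item requirements per signal function.

    The default is a minimal one-kit-per-function list; real
    assessments substitute their own item inventories.
    """

    entries: dict[str, ChecklistEntry] = field(default_factory=_default_entries)

    def __post_init__(self) -> None:
        missing = set(SIGNAL_FUNCTIONS) - set(self.entries)
        extra = set(self.entries) - set(SIGNAL_FUNCTIONS)
        if missing or extra:
            raise ValueError(
                f"checklist must define exactly the nine signal functions; "
                f"missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        if "anaesthesia" not in self.entries["caesarean_delivery"].items:
            raise ValueError("caesarean checklist entry must require anaesthesia")

    def derive_flags(
        self, staff_cadres: set[str], items_in_stock: set[str]
    ) -> tuple[tuple[bool, ...], tuple[bool, ...]]:
        """Map raw staff/stock inventories to (staffed, equipped) flags."""
        staffed, equipped = [], []
        for fn in SIGNAL_FUNCTIONS:
            entry = self.entries[fn]
            staffed.append(bool(entry.cadres & staff_cadres))
            equipped.append(entry.items <= items_in_stock)
        return tuple(staffed), tuple(equipped)


DEFAULT_CHECKLIST = SignalFunctionChecklist()


@dataclass
class FacilityRecord:
    """One facility: location, readiness attributes, derived score/level.

    Missing survey responses are encoded as ``False`` (not ready) before
    construction; every flag here is a definite boolean.
    """

    id: str
    x: float
    y: float
    open_24_7: bool = False
    has_electricity: bool = False
    has_water: bool = False
    has_transport: bool = False
    has_communication: bool = False
    signal_staffed: tuple[bool, ...] = (False,) * N_SIGNAL_FUNCTIONS
    signal_equipped: tuple[bool, ...] = (False,) * N_SIGNAL_FUNCTIONS
    caesarean_last_3_months: bool = False
    sector: str = "public"
    facility_type: str = "health_centre"
    readiness_score: int | None = None
    level: int | None = None

    def __post_init__(self) -> None:
        self.signal_staffed = tuple(bool(b) for b in self.signal_staffed)
        self.signal_equipped = tuple(bool(b) for b in self.signal_equipped)
        if len(self.signal_staffed) != N_SIGNAL_FUNCTIONS:
            raise ValueError("signal_staffed must have nine entries")
        if len(self.signal_equipped) != N_SIGNAL_FUNCTIONS:
            raise ValueError("signal_equipped must have nine entries")

    @property
    def general_items(self) -> tuple[bool, ...]:
        return (
            self.open_24_7,
            self.has_electricity,
            self.has_water,
            self.has_transport,
            self.has_communication,
        )


def compute_readiness_score(
    facility: FacilityRecord,
    checklist: SignalFunctionChecklist = DEFAULT_CHECKLIST,
) -> int:
    """Readiness score 0-14: general items + staffed-and-equipped functions.

    The checklist parameter is used when scoring from raw inventories
    via :meth:`SignalFunctionChecklist.derive_flags`; records carrying
    pre-derived boolean flags (the common case) are scored from those.
    """
    general = sum(facility.general_items)
    signal = sum(
        s and e for s, e in zip(facility.signal_staffed, facility.signal_equipped)
    )
    return int(general + signal)


def classify_level(score: int, caesarean_recent: bool, has_transport: bool) -> int:
    """Assign the facility level (1-5) from score and the two extra criteria.

    First matching rule wins: 5 (score>=10 + recent caesarean),
    4 (score>=10), 3 (score<=9 + transport), 2 (6<=score<=9), 1.
    """
    if not (0 <= score <= MAX_SCORE):
        raise ValueError(f"readiness score must be in [0, {MAX_SCORE}], got {score}")
    if score >= 10:
        return 5 if caesarean_recent else 4
    if has_transport:
        return 3
    if score >= 6:
        return 2
    return 1


def score_roster(
    facilities: list[FacilityRecord],
    checklist: SignalFunctionChecklist = DEFAULT_CHECKLIST,
) -> list[FacilityRecord]:
    """Return a new roster with readiness_score and level filled in."""
    out = []
    for f in facilities:
        score = compute_readiness_score(f, checklist)
        level = classify_level(score, f.caesarean_last_3_months, f.has_transport)
        out.append(replace(f, readiness_score=score, level=level))
    return out
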
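"""Supply side: treatments, cadres, daily capability minutes, consumables.

Facilities are identified by their level label ("1a", "1b", "2"); the default
scenario has one facility per level.  Capabilities are minutes of healthcare-
worker time per cadre per facility per day, constant over the horizon.  The
ledger allows negative balances: delivery is permitted whenever every required
cadre has *strictly positive* minutes remaining, and the full footprint is
then committed, which encodes the sanctioned "finish the last HSI of the day"
overtime.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import CapabilityLookupError, ValidationError

CADRE_CLINICAL_OFFICER = "clinical_officer"
CADRE_NURSE = "nurse"
CADRE_PHARMACIST = "pharmacist"


@dataclass
class TreatmentSpec:
    """One service type with a per-cadre minute footprint.

    ``preventive`` treatments clear ``risk_flag`` on the person instead of
    converting a disease episode to treated status; ``prevention_seek_rate``
    is the per-year rate at which flag-holders request the service.
    """

    treatment_id: str
    target_cause: str
    facility_level: str
    footprint: Dict[str, float]
    emergency: bool = False
    preventive: bool = False
    consumable_items: List[list] = field(default_factory=list)
    effectiveness: float = 1.0
    alt_effectiveness: float = 1.0
    risk_flag: Optional[str] = None
    prevention_seek_rate: float = 0.0

    def validate(self) -> None:
        if not self.treatment_id:
            raise ValidationError("treatment_id", "must be non-empty")
        if not self.footprint:
            raise ValidationError("footprint", f"{self.treatment_id}: footprint is empty")
        for cadre, minutes in self.footprint.items():
            if not minutes > 0:
                raise ValidationError(
                    "footprint",
                    f"{self.treatment_id}: minutes for cadre {cadre!r} must be > 0",
                )
        for name in ("effectiveness", "alt_effectiveness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(name, f"{self.treatment_id}: must be in [0, 1]")
        if self.alt_effectiveness > self.effectiveness:
            raise ValidationError(
                "alt_effectiveness",
                f"{self.treatment_id}: must not exceed effectiveness",
            )
        for item in self.consumable_items:
            if len(item) != 2:
                raise ValidationError(
                    "consumable_items", f"{self.treatment_id}: expected [item_id, probability]"
                )
            if not 0.0 <= float(item[1]) <= 1.0:
                raise ValidationError(
                    "consumable_items",
                    f"{self.treatment_id}: availability probability for {item[0]!r} "
                    "must be in [0, 1]",
                )
        if self.preventive and not self.risk_flag:
            raise ValidationError(
                "risk_flag", f"{self.treatment_id}: preventive treatment must name a risk flag"
            )
        if self.prevention_seek_rate < 0:
            raise ValidationError(
                "prevention_seek_rate", f"{self.treatment_id}: must be >= 0"
            )


@dataclass
class CapabilitySchedule:
    """Minutes available per (facility, cadre) per day, constant over time."""

    minutes: Dict[str, Dict[str, float]]

    def get(self, facility: str, cadre: str) -> float:
        try:
            return self.minutes[facility][cadre]
        except KeyError:
            raise CapabilityLookupError(
                f"no capability entry for facility {facility!r}, cadre {cadre!r}"
            ) from None

    def validate(self, treatments: Sequence[TreatmentSpec] = ()) -> None:
        for facility, cadres in self.minutes.items():
            for cadre, m in cadres.items():
                if m < 0:
                    raise ValidationError(
                        "capabilities", f"({facility}, {cadre}): minutes must be >= 0"
                    )
        for t in treatments:
            for cadre in t.footprint:
                if cadre not in self.minutes.get(t.facility_level, {}):
                    raise ValidationError(
                        "capabilities",
                        f"treatment {t.treatment_id!r} needs ({t.facility_level}, {cadre}) "
                        "but the schedule has no such entry",
                    )

    def scaled(self, factor: float) -> "CapabilitySchedule":
        return CapabilitySchedule(
            {f: {c: m * factor for c, m in cadres.items()} for f, cadres in self.minutes.items()}
        )


class ConsumableOutcome(enum.Enum):
    """Outcome of the consumable check for one HSI attempt."""

    AVAILABLE = "available"
    SUBSTITUTED = "substituted"
    REPEAT_VISIT = "repeat_visit"
    DEFAULT_FROM_CARE = "default_from_care"


#: (substituted, repeat_visit, default_from_care) when a stock-out occurs.
DEFAULT_BRANCH_PROBS = (0.5, 0.3, 0.2)

_STOCKOUT_BRANCHES = (
    ConsumableOutcome.SUBSTITUTED,
    ConsumableOutcome.REPEAT_VISIT,
    ConsumableOutcome.DEFAULT_FROM_CARE,
)


def validate_branch_probs(branch_probs: Sequence[float]) -> None:
    if len(branch_probs) != 3:
        raise ValidationError("branch_probs", "expected 3 probabilities")
    if any(p < 0 for p in branch_probs):
        raise ValidationError("branch_probs", "probabilities must be >= 0")
    if abs(sum(branch_probs) - 1.0) > 1e-9:
        raise ValidationError("branch_probs", "probabilities must sum to 1")


def draw_consumables(
    spec: TreatmentSpec,
    branch_probs: Sequence[float],
    rng: np.random.Generator,
) -> ConsumableOutcome:
    """Draw availability of every consumable item, independently per attempt.

    All items available -> AVAILABLE; otherwise one of the three stock-out
    branches is sampled from ``branch_probs``.
    """
    validate_branch_probs(branch_probs)
    if not spec.consumable_items:
        return ConsumableOutcome.AVAILABLE
    probs = np.array([float(it[1]) for it in spec.consumable_items])
    if np.all(rng.random(len(probs)) < probs):
        return ConsumableOutcome.AVAILABLE
    idx = rng.choice(3, p=np.asarray(branch_probs, dtype=float))
    return _STOCKOUT_BRANCHES[idx]


class CapabilityLedger:
    """Running per-day balance of committed vs scheduled minutes.

    Reset exactly to the schedule at each day boundary via :meth:`start_day`.
    Balances may go negative: the caller checks feasibility (strictly positive
    remaining minutes on every required cadre) *before* committing, and the
    commit then books the full footprint.
    """

    def __init__(self, schedule: CapabilitySchedule):
        self.schedule = schedule
        self.remaining: Dict[Tuple[str, str], float] = {}
        self.committed: Dict[Tuple[str, str], float] = {}
        self.start_day()

    def start_day(self) -> None:
        self.remaining = {
            (f, c): m
            for f, cadres in self.schedule.minutes.items()
            for c, m in cadres.items()
        }
        self.committed = {key: 0.0 for key in self.remaining}

    def remaining_minutes(self, facility: str, cadre: str) -> float:
        try:
            return self.remaining[(facility, cadre)]
        except KeyError:
            raise CapabilityLookupError(
                f"no capability entry for facility {facility!r}, cadre {cadre!r}"
            ) from None

    def can_deliver(self, facility: str, footprint: Mapping[str, float]) -> bool:
        return all(self.remaining_minutes(facility, cadre) > 0 for cadre in footprint)

    def commit(self, facility: str, footprint: Mapping[str, float]) -> None:
        for cadre, minutes in footprint.items():
            key = (facility, cadre)
            if key not in self.remaining:
                raise CapabilityLookupError(
                    f"no capability entry for facility {facility!r}, cadre {cadre!r}"
                )
            self.remaining[key] -= minutes
            self.committed[key] += minutes


def remaining_minutes(ledger: CapabilityLedger, facility: str, cadre: str) -> float:
    """Capability minus minutes already committed today (may be negative)."""
    return ledger.remaining_minutes(facility, cadre)


def build_default_footprints() -> List[TreatmentSpec]:
    """Default treatment catalogue: 12 services over 3 levels and 3 cadres.

    ``outpatient_over5`` at level "1a" carries the reference footprint of
    27 clinical-officer minutes, 18 nurse minutes and 9.5 pharmacist minutes.
    """
    co, nu, ph = CADRE_CLINICAL_OFFICER, CADRE_NURSE, CADRE_PHARMACIST
    return [
        TreatmentSpec(
            "outpatient_over5", "cardio", "1a",
            {co: 27.0, nu: 18.0, ph: 9.5},
            consumable_items=[["cardio_meds", 0.8]],
            effectiveness=0.85, alt_effectiveness=0.6,
        ),
        TreatmentSpec(
            "pneumonia_treatment_child", "lri", "1a",
            {co: 15.0, nu: 20.0, ph: 5.0},
            consumable_items=[["antibiotics", 0.75]],
            effectiveness=0.9, alt_effectiveness=0.65,
        ),
        TreatmentSpec(
            "measles_treatment", "measles", "1a",
            {co: 8.0, nu: 12.0},
            consumable_items=[["vitamin_a", 0.85]],
            effectiveness=0.85, alt_effectiveness=0.6,
        ),
        TreatmentSpec(
            "measles_vaccination", "measles", "1a",
            {nu: 5.0},
            preventive=True, risk_flag="unvaccinated", prevention_seek_rate=0.3,
            consumable_items=[["vaccine_doses", 0.8]],
            effectiveness=0.95, alt_effectiveness=0.95,
        ),
        TreatmentSpec(
            "contraception", "neonatal", "1a",
            {nu: 10.0, ph: 5.0},
            preventive=True, risk_flag="fertile_unprotected", prevention_seek_rate=0.02,
            consumable_items=[["contraceptives", 0.8]],
            effectiveness=0.95, alt_effectiveness=0.9,
        ),
        TreatmentSpec(
            "antenatal_visit", "neonatal", "1b",
            {nu: 15.0},
            preventive=True, risk_flag="anc_unattended", prevention_seek_rate=0.1,
            consumable_items=[["iron_folate", 0.7]],
            effectiveness=0.9, alt_effectiveness=0.8,
        ),
        TreatmentSpec(
            "hiv_treatment", "hiv", "1b",
            {co: 20.0, nu: 15.0, ph: 10.0},
            consumable_items=[["arv", 0.85]],
            effectiveness=0.9, alt_effectiveness=0.7,
        ),
        TreatmentSpec(
            "hiv_testing", "hiv", "1a",
            {nu: 8.0},
            preventive=True, risk_flag="hiv_high_risk", prevention_seek_rate=0.15,
            consumable_items=[["test_kits", 0.85]],
            effectiveness=0.95, alt_effectiveness=0.9,
        ),
        TreatmentSpec(
            "tb_treatment", "tb", "1b",
            {co: 25.0, ph: 12.0},
            consumable_items=[["tb_drugs", 0.8]],
            effectiveness=0.85, alt_effectiveness=0.6,
        ),
        TreatmentSpec(
            "tb_screening", "tb", "1b",
            {nu: 10.0},
            preventive=True, risk_flag="tb_high_risk", prevention_seek_rate=0.1,
            consumable_items=[["xray_film", 0.7]],
            effectiveness=0.9, alt_effectiveness=0.85,
        ),
        TreatmentSpec(
            "perinatal_care", "neonatal", "1b",
            {co: 10.0, nu: 40.0},
            emergency=True,
            consumable_items=[["delivery_kit", 0.7]],
            effectiveness=0.8, alt_effectiveness=0.55,
        ),
        TreatmentSpec(
            "emergency_care", "injury", "2",
            {co: 30.0, nu: 30.0},
            emergency=True,
            consumable_items=[["surgical_supplies", 0.75]],
            effectiveness=0.85, alt_effectiveness=0.6,
        ),
    ]
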
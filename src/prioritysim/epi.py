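"""Daily individual-based disease dynamics and care-seeking.

The engine represents the population as a column-oriented :class:`Cohort`
(numpy arrays) for speed; :class:`Person` is the record-per-individual view
used at the module boundaries (population sampling, priority assignment).

Hazards are quoted per person-year and converted to daily probabilities via
``1 - exp(-h / 365)``.  Prevalence used for transmission feedback is computed
once at the start of each day (synchronous update), which removes within-day
order dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import ValidationError
from .queue import CareEpisode

DAYS_PER_YEAR = 365

SEVERITY_ROUTINE = "routine"
SEVERITY_EMERGENCY = "emergency"

RESOLUTION_ONGOING = "ongoing"
RESOLUTION_RECOVERED_UNTREATED = "recovered_untreated"
RESOLUTION_RECOVERED_TREATED = "recovered_treated"
RESOLUTION_DIED = "died"


@dataclass
class Person:
    """An individual: age, vital status, conditions, vulnerable-category flags.

    The ``under5`` flag is never stored; it is recomputed from age on access.
    """

    person_id: int
    birth_date: int  # simulation day (negative for people alive at day 0)
    alive: bool = True
    sex: str = "f"
    active_conditions: Set[Tuple[str, int, bool]] = field(default_factory=set)
    flags: Set[str] = field(default_factory=set)

    def age_years(self, day: int) -> float:
        return (day - self.birth_date) / DAYS_PER_YEAR

    def is_under5(self, day: int) -> bool:
        return self.age_years(day) < 5.0

    def flags_on(self, day: int) -> Set[str]:
        out = set(self.flags)
        if self.is_under5(day):
            out.add("under5")
        else:
            out.discard("under5")
        return out


@dataclass
class DiseaseEpisode:
    """One active (or resolved) condition of one person."""

    person_id: int
    cause_id: str
    onset_day: int
    severity: str = SEVERITY_ROUTINE
    resolved: bool = False
    resolution: str = RESOLUTION_ONGOING
    end_day: Optional[int] = None
    treated: bool = False

    def resolve(self, resolution: str, day: int) -> None:
        self.resolved = True
        self.resolution = resolution
        self.end_day = day


@dataclass
class DeathRecord:
    person_id: int
    cause_id: str
    day: int
    age_years: float


class _CauseState:
    __slots__ = ("active", "treated", "onset_day", "ever")

    def __init__(self, capacity: int):
        self.active = np.zeros(capacity, dtype=bool)
        self.treated = np.zeros(capacity, dtype=bool)
        self.onset_day = np.zeros(capacity, dtype=np.int32)
        self.ever = np.zeros(capacity, dtype=bool)

    def grow(self, capacity: int) -> None:
        for name in self.__slots__:
            old = getattr(self, name)
            new = np.zeros(capacity, dtype=old.dtype)
            new[: len(old)] = old
            setattr(self, name, new)


class Cohort:
    """Column-oriented population state; person ids are array indices."""

    def __init__(self, cause_ids: Sequence[str], capacity: int = 256):
        self.capacity = max(capacity, 16)
        self.n = 0
        self.birth_day = np.zeros(self.capacity, dtype=np.int32)
        self.alive = np.zeros(self.capacity, dtype=bool)
        self.female = np.zeros(self.capacity, dtype=bool)
        self.flags: Dict[str, np.ndarray] = {}
        self.conditions: Dict[str, _CauseState] = {
            c: _CauseState(self.capacity) for c in cause_ids
        }

    # -- construction ------------------------------------------------------

    @classmethod
    def from_persons(cls, persons: Sequence[Person], cause_ids: Sequence[str]) -> "Cohort":
        cohort = cls(cause_ids, capacity=len(persons) + 64)
        for p in persons:
            idx = cohort.add_person(p.birth_date, p.sex == "f", p.flags)
            for (cause_id, onset_day, treated) in p.active_conditions:
                st = cohort.conditions[cause_id]
                st.active[idx] = True
                st.treated[idx] = treated
                st.onset_day[idx] = onset_day
                st.ever[idx] = True
            if not p.alive:
                cohort.alive[idx] = False
        return cohort

    def _ensure_capacity(self, n: int) -> None:
        if n <= self.capacity:
            return
        new_cap = max(n, self.capacity * 2)
        for name in ("birth_day", "alive", "female"):
            old = getattr(self, name)
            new = np.zeros(new_cap, dtype=old.dtype)
            new[: self.capacity] = old[: self.capacity]
            setattr(self, name, new)
        for flag, arr in self.flags.items():
            new = np.zeros(new_cap, dtype=bool)
            new[: self.capacity] = arr[: self.capacity]
            self.flags[flag] = new
        for st in self.conditions.values():
            st.grow(new_cap)
        self.capacity = new_cap

    def add_person(self, birth_day: int, female: bool, flags: Iterable[str] = ()) -> int:
        self._ensure_capacity(self.n + 1)
        idx = self.n
        self.n += 1
        self.birth_day[idx] = birth_day
        self.alive[idx] = True
        self.female[idx] = female
        for flag in flags:
            self.flag_array(flag)[idx] = True
        return idx

    # -- accessors ---------------------------------------------------------

    def flag_array(self, flag: str) -> np.ndarray:
        if flag not in self.flags:
            self.flags[flag] = np.zeros(self.capacity, dtype=bool)
        return self.flags[flag]

    def set_flag(self, idx: int, flag: str, value: bool = True) -> None:
        self.flag_array(flag)[idx] = value

    def has_flag(self, idx: int, flag: str) -> bool:
        return bool(self.flag_array(flag)[idx])

    def age_years(self, day: int) -> np.ndarray:
        return (day - self.birth_day[: self.n]) / DAYS_PER_YEAR

    @property
    def n_alive(self) -> int:
        return int(np.count_nonzero(self.alive[: self.n]))

    def person_view(self, idx: int) -> "PersonView":
        return PersonView(self, idx)

    def to_persons(self) -> List[Person]:
        out = []
        for i in range(self.n):
            conditions = {
                (c, int(st.onset_day[i]), bool(st.treated[i]))
                for c, st in self.conditions.items()
                if st.active[i]
            }
            flags = {f for f, arr in self.flags.items() if arr[i]}
            out.append(
                Person(
                    person_id=i,
                    birth_date=int(self.birth_day[i]),
                    alive=bool(self.alive[i]),
                    sex="f" if self.female[i] else "m",
                    active_conditions=conditions,
                    flags=flags,
                )
            )
        return out

    def kill(self, idx: int, day: int) -> List[Tuple[str, int]]:
        """Mark a person dead; returns the (cause, onset) pairs censored."""
        self.alive[idx] = False
        censored = []
        for cause_id, st in self.conditions.items():
            if st.active[idx]:
                st.active[idx] = False
                censored.append((cause_id, int(st.onset_day[idx])))
        return censored


class PersonView:
    """Lightweight per-person facade over a Cohort (duck-types Person)."""

    __slots__ = ("_cohort", "person_id")

    def __init__(self, cohort: Cohort, idx: int):
        self._cohort = cohort
        self.person_id = idx

    @property
    def alive(self) -> bool:
        return bool(self._cohort.alive[self.person_id])

    def age_years(self, day: int) -> float:
        return (day - int(self._cohort.birth_day[self.person_id])) / DAYS_PER_YEAR

    def is_under5(self, day: int) -> bool:
        return self.age_years(day) < 5.0

    def flags_on(self, day: int) -> Set[str]:
        i = self.person_id
        out = {f for f, arr in self._cohort.flags.items() if arr[i]}
        if self.is_under5(day):
            out.add("under5")
        return out


# ---------------------------------------------------------------------------
# Daily steps
# ---------------------------------------------------------------------------


def _band_rates(cause, ages: np.ndarray, year_index: int) -> np.ndarray:
    """Per-person incidence hazard from the cause's age bands and trends."""
    rates = np.zeros(len(ages))
    for band in cause.base_incidence:
        lo, hi, rate = float(band[0]), float(band[1]), float(band[2])
        trend = float(band[3]) if len(band) > 3 else 0.0
        r = max(0.0, rate + trend * year_index)
        mask = (ages >= lo) & (ages < hi)
        rates[mask] = r
    return rates


def untreated_prevalence(cohort: Cohort, cause_id: str) -> float:
    """Fraction of the living population with an active untreated condition."""
    n_alive = cohort.n_alive
    if n_alive == 0:
        return 0.0
    st = cohort.conditions[cause_id]
    n = cohort.n
    count = int(np.count_nonzero(st.active[:n] & ~st.treated[:n] & cohort.alive[:n]))
    return count / n_alive


def step_incidence(
    cohort: Cohort,
    causes: Sequence,
    day: int,
    rng: np.random.Generator,
    emergency_causes: Iterable[str] = (),
    prevalences: Optional[Mapping[str, float]] = None,
) -> List[DiseaseEpisode]:
    """Draw new disease episodes for one day.

    Each alive, currently susceptible person acquires cause ``c`` with daily
    probability ``1 - exp(-h/365)`` where
    ``h = base_incidence(age, year) * (1 + transmission_coefficient * p_u)``
    and ``p_u`` is the start-of-day prevalence of untreated active cases.
    Reinfection after recovery is permitted, damped by the cause's
    prior-exposure (immunity) multiplier.
    """
    year_index = day // DAYS_PER_YEAR
    n = cohort.n
    ages = cohort.age_years(day)
    alive = cohort.alive[:n]
    emergency_causes = set(emergency_causes)
    episodes: List[DiseaseEpisode] = []
    for cause in causes:
        st = cohort.conditions[cause.cause_id]
        eligible = alive & ~st.active[:n]
        if cause.sex_restricted == "f":
            eligible &= cohort.female[:n]
        elif cause.sex_restricted == "m":
            eligible &= ~cohort.female[:n]
        idx = np.flatnonzero(eligible)
        if len(idx) == 0:
            continue
        rates = _band_rates(cause, ages[idx], year_index)
        if cause.transmission_coefficient > 0:
            prev = (
                prevalences[cause.cause_id]
                if prevalences is not None
                else untreated_prevalence(cohort, cause.cause_id)
            )
            rates = rates * (1.0 + cause.transmission_coefficient * prev)
        if cause.immunity_multiplier != 1.0:
            ever = st.ever[idx]
            rates = np.where(ever, rates * cause.immunity_multiplier, rates)
        p = -np.expm1(-rates / DAYS_PER_YEAR)
        hit = idx[rng.random(len(idx)) < p]
        severity = (
            SEVERITY_EMERGENCY if cause.cause_id in emergency_causes else SEVERITY_ROUTINE
        )
        for i in hit:
            i = int(i)
            st.active[i] = True
            st.treated[i] = False
            st.onset_day[i] = day
            st.ever[i] = True
            if cause.onset_flag:
                cohort.set_flag(i, cause.onset_flag, True)
            episodes.append(
                DiseaseEpisode(
                    person_id=i, cause_id=cause.cause_id, onset_day=day, severity=severity
                )
            )
    return episodes


def _risk_multiplier(cohort: Cohort, cause, idx: np.ndarray) -> np.ndarray:
    mult = np.ones(len(idx))
    for flag, m in cause.risk_modifiers:
        arr = cohort.flag_array(flag)
        mult *= np.where(arr[idx], float(m), 1.0)
    return mult


def step_progression(
    cohort: Cohort,
    causes: Sequence,
    day: int,
    rng: np.random.Generator,
    registry: Optional[Mapping[Tuple[str, int], DiseaseEpisode]] = None,
) -> Tuple[List[DeathRecord], List[Tuple[str, int, bool]]]:
    """Resolve ongoing episodes by death or recovery for one day.

    Death occurs with daily hazard ``(treated or untreated hazard) x risk
    modifier product / 365``; recovery occurs once the (treated or untreated)
    duration has elapsed.  A death censors the person's other conditions.

    Returns ``(death_records, recoveries)`` with recoveries as
    ``(cause_id, person_id, treated)`` tuples.
    """
    n = cohort.n
    deaths: List[DeathRecord] = []
    recoveries: List[Tuple[str, int, bool]] = []
    for cause in causes:
        st = cohort.conditions[cause.cause_id]
        idx = np.flatnonzero(st.active[:n] & cohort.alive[:n])
        if len(idx) == 0:
            continue
        treated = st.treated[idx]
        hazard = np.where(
            treated, cause.treated_death_hazard, cause.untreated_death_hazard
        ) * _risk_multiplier(cohort, cause, idx)
        p = -np.expm1(-hazard / DAYS_PER_YEAR)
        died = rng.random(len(idx)) < p
        dur_days = np.where(
            treated,
            cause.treated_duration * DAYS_PER_YEAR,
            cause.untreated_duration * DAYS_PER_YEAR,
        )
        recovered = ~died & ((day - st.onset_day[idx]) >= dur_days)
        for i in idx[died]:
            i = int(i)
            age = (day - int(cohort.birth_day[i])) / DAYS_PER_YEAR
            censored = cohort.kill(i, day)
            deaths.append(DeathRecord(i, cause.cause_id, day, age))
            if registry is not None:
                for censored_cause, _onset in censored:
                    ep = registry.get((censored_cause, i))
                    if ep is not None and not ep.resolved:
                        ep.resolve(RESOLUTION_DIED, day)
            if cause.onset_flag and cause.clear_flag_on_resolution:
                cohort.set_flag(i, cause.onset_flag, False)
        for i in idx[recovered]:
            i = int(i)
            was_treated = bool(st.treated[i])
            st.active[i] = False
            recoveries.append((cause.cause_id, i, was_treated))
            if cause.onset_flag and cause.clear_flag_on_resolution:
                cohort.set_flag(i, cause.onset_flag, False)
            if registry is not None:
                ep = registry.get((cause.cause_id, i))
                if ep is not None and not ep.resolved:
                    ep.resolve(
                        RESOLUTION_RECOVERED_TREATED
                        if was_treated
                        else RESOLUTION_RECOVERED_UNTREATED,
                        day,
                    )
    return deaths, recoveries


def step_care_seeking(
    episodes: Sequence[DiseaseEpisode],
    cohort: Cohort,
    causes_by_id: Mapping[str, object],
    curative_by_cause: Mapping[str, object],
    day: int,
    rng: np.random.Generator,
    tiebreak_fn: Optional[Callable[[int, str], float]] = None,
) -> List[CareEpisode]:
    """Convert new disease episodes into treatment requests.

    Each new unresolved episode generates, with the cause's care-seeking
    probability, one care episode for the treatment mapped to the cause at
    that treatment's facility level.  Emergency-severity episodes always seek
    care the same day.  Causes with no mapped treatment (or not subject to
    resource constraints) proceed untreated.
    """
    out: List[CareEpisode] = []
    for ep in episodes:
        if ep.resolved or not cohort.alive[ep.person_id]:
            continue
        cause = causes_by_id[ep.cause_id]
        if not cause.resource_constrained:
            continue
        treatment = curative_by_cause.get(ep.cause_id)
        if treatment is None:
            continue
        p_seek = 1.0 if ep.severity == SEVERITY_EMERGENCY else cause.care_seeking_probability
        if p_seek < 1.0 and rng.random() >= p_seek:
            continue
        tiebreak = (
            tiebreak_fn(ep.person_id, treatment.treatment_id)
            if tiebreak_fn is not None
            else float(rng.random())
        )
        out.append(
            CareEpisode(
                person_id=ep.person_id,
                treatment_id=treatment.treatment_id,
                facility_id=treatment.facility_level,
                first_seek_date=day,
                cause_id=ep.cause_id,
                emergency=treatment.emergency,
                preventive=False,
                tiebreak=tiebreak,
            )
        )
    return out


def step_prevention_seeking(
    cohort: Cohort,
    preventive_treatments: Sequence,
    day: int,
    rng: np.random.Generator,
    tiebreak_fn: Optional[Callable[[int, str], float]] = None,
) -> List[CareEpisode]:
    """Generate demand for preventive services among risk-flag holders."""
    n = cohort.n
    out: List[CareEpisode] = []
    for t in preventive_treatments:
        if t.prevention_seek_rate <= 0:
            continue
        eligible = cohort.alive[:n] & cohort.flag_array(t.risk_flag)[:n]
        idx = np.flatnonzero(eligible)
        if len(idx) == 0:
            continue
        p = -np.expm1(-t.prevention_seek_rate / DAYS_PER_YEAR)
        hit = idx[rng.random(len(idx)) < p]
        for i in hit:
            i = int(i)
            tiebreak = (
                tiebreak_fn(i, t.treatment_id)
                if tiebreak_fn is not None
                else float(rng.random())
            )
            out.append(
                CareEpisode(
                    person_id=i,
                    treatment_id=t.treatment_id,
                    facility_id=t.facility_level,
                    first_seek_date=day,
                    cause_id=t.target_cause,
                    emergency=t.emergency,
                    preventive=True,
                    tiebreak=tiebreak,
                )
            )
    return out


#: Flags assigned to every newborn.
NEWBORN_FLAGS = ("unvaccinated", "fertile_unprotected", "anc_unattended")


def step_demography(
    cohort: Cohort,
    spec,
    day: int,
    rng: np.random.Generator,
) -> Tuple[List[int], List[DeathRecord]]:
    """Background deaths (recorded under the residual cause) and births.

    Births occur at the crude birth rate among alive persons not covered by
    contraception (the ``fertile_unprotected`` risk flag); newborns receive
    the newborn flag set (the under-5 flag itself is derived from age).
    """
    n = cohort.n
    deaths: List[DeathRecord] = []
    alive_idx = np.flatnonzero(cohort.alive[:n])
    if len(alive_idx) > 0 and spec.background_mortality:
        ages = cohort.age_years(day)[alive_idx]
        hazard = np.zeros(len(alive_idx))
        for band in spec.background_mortality:
            lo, hi, h = float(band[0]), float(band[1]), float(band[2])
            hazard[(ages >= lo) & (ages < hi)] = h
        p = -np.expm1(-hazard / DAYS_PER_YEAR)
        died = alive_idx[rng.random(len(alive_idx)) < p]
        for i in died:
            i = int(i)
            age = (day - int(cohort.birth_day[i])) / DAYS_PER_YEAR
            cohort.kill(i, day)
            deaths.append(DeathRecord(i, "other", day, age))
    n = cohort.n
    eligible = cohort.alive[:n] & cohort.flag_array("fertile_unprotected")[:n]
    lam = spec.crude_birth_rate * int(np.count_nonzero(eligible)) / DAYS_PER_YEAR
    n_births = int(rng.poisson(lam)) if lam > 0 else 0
    born: List[int] = []
    for _ in range(n_births):
        female = bool(rng.random() < 0.5)
        born.append(cohort.add_person(day, female, NEWBORN_FLAGS))
    return born, deaths
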
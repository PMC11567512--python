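"""Policy priorities, daily queue ordering, rigid delivery, persistence.

Four engine tiers are used: 0 (child emergency), 1 (emergency), 2 (high) and
3 (low).  Emergencies are reserved by the engine and cannot be expressed in a
policy, which only maps non-emergency treatments to {high, low}, optionally
fast-tracks vulnerable categories, and optionally excludes treatments.

The delivery scan is "skip and continue": an episode whose footprint cannot be
served (some required cadre has no strictly positive minutes remaining) is
postponed, but the scan proceeds so lower-priority HSIs can still run while
capabilities remain.  Committing a feasible footprint may drive balances
negative — the sanctioned overtime to finish the day's last HSI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .errors import UnknownTreatmentError, ValidationError
from .healthsystem import (
    CapabilityLedger,
    ConsumableOutcome,
    TreatmentSpec,
    draw_consumables,
)

TIER_CHILD_EMERGENCY = 0
TIER_EMERGENCY = 1
TIER_HIGH = 2
TIER_LOW = 3

VULNERABLE_CATEGORIES = ("under5", "pregnant", "hiv_diagnosed", "tb_diagnosed")

DEFAULT_MAX_ATTEMPTS = 7


@dataclass
class Policy:
    """Declarative priority assignment over non-emergency treatments."""

    policy_id: str
    tier_of: Dict[str, str] = field(default_factory=dict)  # treatment -> "high"|"low"
    excluded: Set[str] = field(default_factory=set)
    fasttrack: Dict[str, Set[str]] = field(default_factory=dict)

    def validate(self, treatment_ids: Optional[Sequence[str]] = None) -> None:
        for tid, tier in self.tier_of.items():
            if tier not in ("high", "low"):
                raise ValidationError(
                    "tier_of", f"policy {self.policy_id!r}: tier for {tid!r} must be high|low"
                )
        overlap = self.excluded & set(self.tier_of)
        if overlap:
            raise ValidationError(
                "excluded",
                f"policy {self.policy_id!r}: treatments {sorted(overlap)} are both "
                "excluded and assigned a tier",
            )
        for tid, cats in self.fasttrack.items():
            if tid in self.excluded:
                raise ValidationError(
                    "fasttrack",
                    f"policy {self.policy_id!r}: fast-track references excluded "
                    f"treatment {tid!r}",
                )
            bad = set(cats) - set(VULNERABLE_CATEGORIES)
            if bad:
                raise ValidationError(
                    "fasttrack",
                    f"policy {self.policy_id!r}: unknown vulnerable categories {sorted(bad)}",
                )
        if treatment_ids is not None:
            known = set(treatment_ids)
            for tid in list(self.tier_of) + list(self.excluded) + list(self.fasttrack):
                if tid not in known:
                    raise ValidationError(
                        "policy",
                        f"policy {self.policy_id!r} references unknown treatment {tid!r}",
                    )


@dataclass
class CareEpisode:
    """One person's pursuit of one treatment at one facility."""

    person_id: int
    treatment_id: str
    facility_id: str
    first_seek_date: int
    cause_id: Optional[str] = None
    emergency: bool = False
    preventive: bool = False
    attempts_used: int = 0
    priority: Optional[int] = None
    tiebreak: float = 0.0
    status: str = "queued"  # queued | delivered | defaulted | excluded
    last_outcome: Optional[str] = None
    effective: bool = False


def queue_key(episode: CareEpisode) -> Tuple[int, int, float, int]:
    """Strict total order: tier, first seek date, tiebreak, then person id."""
    return (episode.priority, episode.first_seek_date, episode.tiebreak, episode.person_id)


def assign_priority(episode: CareEpisode, person, policy: Policy) -> int:
    """Assign the engine tier for an episode under a policy.

    ``person`` must expose ``is_under5(day)`` and ``flags_on(day)``.  Emergency
    tiers are engine-reserved; policies determine only the high/low split and
    fast-tracking of vulnerable categories.
    """
    if episode.emergency:
        tier = TIER_CHILD_EMERGENCY if person.is_under5(episode.first_seek_date) else TIER_EMERGENCY
    else:
        tid = episode.treatment_id
        if tid not in policy.tier_of:
            raise UnknownTreatmentError(
                f"policy {policy.policy_id!r} has no tier for treatment {tid!r}"
            )
        if policy.tier_of[tid] == "high":
            tier = TIER_HIGH
        else:
            flags = person.flags_on(episode.first_seek_date)
            fast = policy.fasttrack.get(tid, ())
            tier = TIER_HIGH if flags.intersection(fast) else TIER_LOW
    episode.priority = tier
    return tier


def apply_policy_filter(episode: CareEpisode, policy: Policy) -> str:
    """Mark an episode excluded if its treatment is not provided at all."""
    if episode.treatment_id in policy.excluded:
        episode.status = "excluded"
        return "excluded"
    episode.status = "queued"
    return "queued"


def order_queue(
    episodes: Sequence[CareEpisode], seed: Optional[int] = None
) -> List[CareEpisode]:
    """Sort one facility-day's queue by (tier, first seek date, tiebreak).

    Tiebreaks are normally drawn once at episode creation; ``seed`` is only
    used to fill in missing tiebreaks for standalone use.
    """
    if seed is not None:
        rng = np.random.default_rng(seed)
        for ep in episodes:
            if ep.tiebreak == 0.0:
                ep.tiebreak = float(rng.random())
    for ep in episodes:
        if ep.priority is None:
            raise ValidationError("priority", f"episode for person {ep.person_id} has no tier")
    return sorted(episodes, key=queue_key)


RngLike = Union[np.random.Generator, Callable[[CareEpisode], np.random.Generator]]


def run_day(
    ordered_episodes: Sequence[CareEpisode],
    ledger: CapabilityLedger,
    treatments: Mapping[str, TreatmentSpec],
    branch_probs: Sequence[float],
    rng: RngLike,
    day: int = 0,
    log: Optional[list] = None,
    log_postponed: bool = False,
) -> Tuple[List[CareEpisode], List[CareEpisode], List[CareEpisode]]:
    """Deliver one ordered facility queue under rigid capability accounting.

    Scans the queue in order.  An episode is deliverable iff remaining minutes
    are strictly positive for *every* cadre in its footprint; if so the full
    footprint is committed (balances may go negative) and the consumable check
    runs.  Infeasible episodes are postponed and the scan continues.

    ``rng`` is either a Generator (draws consumed in scan order) or a callable
    ``episode -> Generator`` yielding a scan-order-independent substream.

    Returns ``(delivered, postponed, defaulted_via_consumables)``; episodes
    that were served but need a repeat visit are returned with the postponed.
    """
    delivered: List[CareEpisode] = []
    postponed: List[CareEpisode] = []
    cons_defaulted: List[CareEpisode] = []

    def _log(ep: CareEpisode, outcome: str, footprint: Mapping[str, float]) -> None:
        if log is None:
            return
        row = {
            "day": day,
            "facility": ep.facility_id,
            "treatment": ep.treatment_id,
            "person_id": ep.person_id,
            "tier": ep.priority,
            "first_seek_date": ep.first_seek_date,
            "attempt": ep.attempts_used + 1,
            "outcome": outcome,
        }
        for cadre, minutes in footprint.items():
            row[f"minutes_{cadre}"] = minutes
        log.append(row)

    for ep in ordered_episodes:
        if ep.treatment_id not in treatments:
            raise UnknownTreatmentError(f"unknown treatment {ep.treatment_id!r}")
        spec = treatments[ep.treatment_id]
        if not ledger.can_deliver(ep.facility_id, spec.footprint):
            ep.last_outcome = "postponed"
            postponed.append(ep)
            if log_postponed:
                _log(ep, "postponed", {})
            continue
        ledger.commit(ep.facility_id, spec.footprint)
        ep_rng = rng(ep) if callable(rng) else rng
        outcome = draw_consumables(spec, branch_probs, ep_rng)
        if outcome is ConsumableOutcome.REPEAT_VISIT:
            ep.last_outcome = "repeat_visit"
            postponed.append(ep)
            _log(ep, "repeat_visit", spec.footprint)
        elif outcome is ConsumableOutcome.DEFAULT_FROM_CARE:
            ep.status = "defaulted"
            ep.last_outcome = "default_consumables"
            cons_defaulted.append(ep)
            _log(ep, "default_consumables", spec.footprint)
        else:
            effectiveness = (
                spec.effectiveness
                if outcome is ConsumableOutcome.AVAILABLE
                else spec.alt_effectiveness
            )
            ep.effective = bool(ep_rng.random() < effectiveness)
            ep.status = "delivered"
            ep.last_outcome = (
                "delivered_available"
                if outcome is ConsumableOutcome.AVAILABLE
                else "delivered_substituted"
            )
            delivered.append(ep)
            _log(ep, ep.last_outcome, spec.footprint)
    return delivered, postponed, cons_defaulted


def close_day(
    postponed_episodes: Sequence[CareEpisode],
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
) -> Tuple[List[CareEpisode], List[CareEpisode]]:
    """Advance persistence for unserved episodes at the end of a day.

    Each postponed episode uses up one attempt; once ``max_attempts`` have
    been consumed the episode defaults permanently, otherwise it is re-queued
    at the same facility with its first-seek date unchanged.
    """
    retried: List[CareEpisode] = []
    defaulted: List[CareEpisode] = []
    for ep in postponed_episodes:
        ep.attempts_used += 1
        if ep.attempts_used >= max_attempts:
            ep.status = "defaulted"
            defaulted.append(ep)
        else:
            ep.status = "queued"
            retried.append(ep)
    return retried, defaulted


def _present(ids: Sequence[str], catalogue: Set[str]) -> List[str]:
    return [tid for tid in ids if tid in catalogue]


def preset_policies(treatments: Sequence[TreatmentSpec]) -> List[Policy]:
    """The seven named prioritisation policies mapped onto a catalogue.

    NP      equal (low) priority for all non-emergency treatments.
    LCOA    three-level strategy: a targeted high-priority list, exclusion of
            the dominant infectious cause's treatment, everything else low.
    HSSP3   inclusion without internal prioritisation (behaves like NP).
    VP      high priority to vertical-programme services (HIV, TB,
            immunisation).
    RMNCH   high priority to reproductive/maternal/neonatal/child services.
    CMD     high priority to cardiometabolic services.
    CV      priority by patient characteristics only: every treatment
            fast-tracks the four vulnerable categories.
    """
    non_emergency = [t.treatment_id for t in treatments if not t.emergency]
    catalogue = set(non_emergency)

    def tiers(high: Sequence[str], excluded: Sequence[str] = ()) -> Dict[str, str]:
        return {
            tid: ("high" if tid in set(high) else "low")
            for tid in non_emergency
            if tid not in set(excluded)
        }

    lcoa_high = _present(
        ["pneumonia_treatment_child", "measles_vaccination", "measles_treatment",
         "tb_treatment", "hiv_testing"],
        catalogue,
    )
    lcoa_excluded = _present(["hiv_treatment"], catalogue)
    vp_high = _present(
        ["hiv_treatment", "hiv_testing", "tb_treatment", "tb_screening",
         "measles_vaccination"],
        catalogue,
    )
    rmnch_high = _present(
        ["antenatal_visit", "contraception", "pneumonia_treatment_child",
         "measles_treatment", "measles_vaccination"],
        catalogue,
    )
    cmd_high = _present(["outpatient_over5"], catalogue)

    policies = [
        Policy("NP", tier_of=tiers([])),
        Policy("LCOA", tier_of=tiers(lcoa_high, lcoa_excluded), excluded=set(lcoa_excluded)),
        Policy("HSSP3", tier_of=tiers([])),
        Policy("VP", tier_of=tiers(vp_high)),
        Policy("RMNCH", tier_of=tiers(rmnch_high)),
        Policy("CMD", tier_of=tiers(cmd_high)),
        Policy(
            "CV",
            tier_of=tiers([]),
            fasttrack={tid: set(VULNERABLE_CATEGORIES) for tid in non_emergency},
        ),
    ]
    for p in policies:
        p.validate([t.treatment_id for t in treatments])
    return policies
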
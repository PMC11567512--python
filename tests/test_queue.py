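import numpy as np
import pytest

from prioritysim.errors import UnknownTreatmentError, ValidationError
from prioritysim.healthsystem import CapabilityLedger, CapabilitySchedule, TreatmentSpec
from prioritysim.queue import (
    TIER_CHILD_EMERGENCY,
    TIER_EMERGENCY,
    TIER_HIGH,
    TIER_LOW,
    CareEpisode,
    Policy,
    apply_policy_filter,
    assign_priority,
    close_day,
    order_queue,
    preset_policies,
    queue_key,
    run_day,
)

from conftest import make_person

NO_STOCKOUT = (1.0, 0.0, 0.0)


def make_episode(person_id=0, treatment_id="t", day=0, tiebreak=0.5, priority=None,
                 emergency=False, facility="f"):
    return CareEpisode(
        person_id=person_id,
        treatment_id=treatment_id,
        facility_id=facility,
        first_seek_date=day,
        emergency=emergency,
        tiebreak=tiebreak,
        priority=priority,
    )


def simple_treatment(tid="t", minutes=None, facility="f"):
    return TreatmentSpec(tid, "c", facility, minutes or {"clinical_officer": 40.0})


class TestAssignPriority:
    def setup_method(self):
        self.policy = Policy("P", tier_of={"t": "low", "h": "high"},
                             fasttrack={"t": {"tb_diagnosed"}})

    def test_child_emergency_outranks_adult_emergency(self):
        child = make_person(age_years=3)
        adult = make_person(age_years=30)
        assert assign_priority(make_episode(emergency=True), child, self.policy) == TIER_CHILD_EMERGENCY
        assert assign_priority(make_episode(emergency=True), adult, self.policy) == TIER_EMERGENCY

    def test_high_and_low_tiers(self):
        adult = make_person(age_years=30)
        assert assign_priority(make_episode(treatment_id="h"), adult, self.policy) == TIER_HIGH
        assert assign_priority(make_episode(treatment_id="t"), adult, self.policy) == TIER_LOW

    def test_fasttrack_promotes_flag_holder(self):
        flagged = make_person(age_years=30, flags={"tb_diagnosed"})
        assert assign_priority(make_episode(treatment_id="t"), flagged, self.policy) == TIER_HIGH

    def test_unknown_treatment_raises(self):
        adult = make_person(age_years=30)
        with pytest.raises(UnknownTreatmentError):
            assign_priority(make_episode(treatment_id="zzz"), adult, self.policy)

    def test_no_policy_uniform_tier(self, default_bundle):
        np_policy = default_bundle.policy("NP")
        adult = make_person(age_years=30)
        child = make_person(age_years=2)
        tiers = {
            assign_priority(make_episode(treatment_id=tid), person, np_policy)
            for tid in np_policy.tier_of
            for person in (adult, child)
        }
        assert tiers == {TIER_LOW}

    def test_cv_fasttracks_any_treatment(self, default_bundle):
        cv = default_bundle.policy("CV")
        tb_patient = make_person(age_years=40, flags={"tb_diagnosed"})
        for tid in cv.tier_of:
            assert assign_priority(make_episode(treatment_id=tid), tb_patient, cv) == TIER_HIGH


class TestPolicyFilter:
    def test_excluded(self):
        policy = Policy("P", tier_of={"a": "low"}, excluded={"x"})
        ep = make_episode(treatment_id="x")
        assert apply_policy_filter(ep, policy) == "excluded"
        assert ep.status == "excluded"

    def test_empty_exclusion_set(self):
        policy = Policy("P", tier_of={"a": "low"})
        ep = make_episode(treatment_id="a")
        assert apply_policy_filter(ep, policy) == "queued"

    def test_policy_invariants(self):
        with pytest.raises(ValidationError):
            Policy("P", tier_of={"a": "low"}, excluded={"a"}).validate()
        with pytest.raises(ValidationError):
            Policy("P", excluded={"a"}, fasttrack={"a": {"under5"}}).validate()
        with pytest.raises(ValidationError):
            Policy("P", tier_of={"a": "low"}, fasttrack={"a": {"wealthy"}}).validate()


class TestOrderQueue:
    def test_tier_order(self):
        eps = [make_episode(person_id=i, priority=p) for i, p in enumerate((3, 2, 0))]
        assert [e.priority for e in order_queue(eps)] == [0, 2, 3]

    def test_earlier_seek_date_first(self):
        a = make_episode(person_id=1, day=8, priority=2)
        b = make_episode(person_id=2, day=5, priority=2)
        assert order_queue([a, b]) == [b, a]

    def test_missing_priority_rejected(self):
        with pytest.raises(ValidationError):
            order_queue([make_episode()])

    def test_matches_comparison_sort_oracle(self):
        # Brute-force insertion sort with an explicit pairwise comparator.
        def before(a, b):
            if a.priority != b.priority:
                return a.priority < b.priority
            if a.first_seek_date != b.first_seek_date:
                return a.first_seek_date < b.first_seek_date
            if a.tiebreak != b.tiebreak:
                return a.tiebreak < b.tiebreak
            return a.person_id < b.person_id

        def oracle_sort(eps):
            out = []
            for ep in eps:
                i = 0
                while i < len(out) and before(out[i], ep):
                    i += 1
                out.insert(i, ep)
            return out

        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            eps = [
                make_episode(
                    person_id=i,
                    day=int(rng.integers(0, 3)),
                    priority=int(rng.integers(0, 4)),
                    tiebreak=float(rng.choice([0.1, 0.5, 0.9])),
                )
                for i in range(n)
            ]
            assert order_queue(list(eps)) == oracle_sort(eps)


def oracle_run_day(ordered, schedule_minutes, treatments, facility="f"):
    """Independent greedy reference: walk the sorted queue, deliver iff every
    required cadre has strictly positive minutes remaining, commit in full."""
    remaining = dict(schedule_minutes)
    delivered = []
    for ep in ordered:
        fp = treatments[ep.treatment_id].footprint
        if all(remaining[c] > 0 for c in fp):
            for c, m in fp.items():
                remaining[c] -= m
            delivered.append(ep)
    return delivered


class TestRunDay:
    def test_greedy_overtime_example(self):
        # 100 minutes, four 40-minute HSIs: three delivered (overtime on the
        # third, since 20 > 0 remained), fourth postponed.
        t = simple_treatment()
        ledger = CapabilityLedger(CapabilitySchedule({"f": {"clinical_officer": 100.0}}))
        eps = [make_episode(person_id=i, priority=3, tiebreak=i / 10) for i in range(4)]
        delivered, postponed, defaulted = run_day(
            order_queue(eps), ledger, {"t": t}, NO_STOCKOUT, np.random.default_rng(0)
        )
        assert len(delivered) == 3 and len(postponed) == 1 and not defaulted
        assert ledger.remaining_minutes("f", "clinical_officer") == pytest.approx(-20.0)

    def test_two_cadre_requires_all(self):
        t = simple_treatment(minutes={"a": 10.0, "b": 10.0})
        ledger = CapabilityLedger(CapabilitySchedule({"f": {"a": 0.0, "b": 100.0}}))
        delivered, postponed, _ = run_day(
            [make_episode(priority=3)], ledger, {"t": t}, NO_STOCKOUT,
            np.random.default_rng(0),
        )
        assert not delivered and len(postponed) == 1

    def test_empty_queue_leaves_ledger_unchanged(self):
        ledger = CapabilityLedger(CapabilitySchedule({"f": {"a": 10.0}}))
        delivered, postponed, defaulted = run_day(
            [], ledger, {}, NO_STOCKOUT, np.random.default_rng(0)
        )
        assert delivered == postponed == defaulted == []
        assert ledger.remaining_minutes("f", "a") == 10.0

    def test_skip_and_continue(self):
        # The infeasible big HSI is skipped; the later small one still runs.
        treatments = {
            "big": simple_treatment("big", {"a": 50.0, "b": 10.0}),
            "small": simple_treatment("small", {"a": 5.0}),
        }
        ledger = CapabilityLedger(CapabilitySchedule({"f": {"a": 100.0, "b": 0.0}}))
        eps = [
            make_episode(person_id=0, treatment_id="big", priority=2),
            make_episode(person_id=1, treatment_id="small", priority=3),
        ]
        delivered, postponed, _ = run_day(
            order_queue(eps), ledger, treatments, NO_STOCKOUT, np.random.default_rng(0)
        )
        assert [e.treatment_id for e in delivered] == ["small"]
        assert [e.treatment_id for e in postponed] == ["big"]

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(11)
        cadres = ["a", "b", "c"]
        for _ in range(150):
            treatments = {}
            for k in range(int(rng.integers(1, 5))):
                chosen = rng.choice(cadres, size=int(rng.integers(1, 4)), replace=False)
                treatments[f"t{k}"] = simple_treatment(
                    f"t{k}", {c: float(rng.integers(1, 60)) for c in chosen}
                )
            schedule = {c: float(rng.integers(0, 150)) for c in cadres}
            eps = [
                make_episode(
                    person_id=i,
                    treatment_id=f"t{int(rng.integers(0, len(treatments)))}",
                    day=int(rng.integers(0, 5)),
                    priority=int(rng.integers(0, 4)),
                    tiebreak=float(rng.random()),
                )
                for i in range(int(rng.integers(0, 25)))
            ]
            ordered = order_queue(eps)
            expected = oracle_run_day(ordered, schedule, treatments)
            ledger = CapabilityLedger(CapabilitySchedule({"f": dict(schedule)}))
            delivered, postponed, defaulted = run_day(
                ordered, ledger, treatments, NO_STOCKOUT, np.random.default_rng(0)
            )
            assert not defaulted
            assert {e.person_id for e in delivered} == {e.person_id for e in expected}


class TestCloseDay:
    def test_defaults_after_max_attempts(self):
        t = simple_treatment()
        treatments = {"t": t}
        ep = make_episode(priority=3)
        queue = [ep]
        for day in range(7):
            ledger = CapabilityLedger(CapabilitySchedule({"f": {"clinical_officer": 0.0}}))
            _, postponed, _ = run_day(
                order_queue(queue), ledger, treatments, NO_STOCKOUT,
                np.random.default_rng(0), day=day,
            )
            queue, defaulted = close_day(postponed, max_attempts=7)
            if day < 6:
                assert ep.status == "queued" and not defaulted
            else:
                assert ep.status == "defaulted" and defaulted == [ep]
        assert ep.attempts_used == 7
        assert ep.first_seek_date == 0

    def test_illustrative_three_attempt_variant(self):
        ep = make_episode(priority=3)
        for _ in range(2):
            retried, defaulted = close_day([ep], max_attempts=3)
            assert retried == [ep] and not defaulted
        retried, defaulted = close_day([ep], max_attempts=3)
        assert defaulted == [ep] and ep.attempts_used == 3

    def test_delivered_episode_not_requeued(self):
        t = simple_treatment()
        ledger = CapabilityLedger(CapabilitySchedule({"f": {"clinical_officer": 100.0}}))
        ep = make_episode(priority=3)
        ep.attempts_used = 2  # third attempt
        delivered, postponed, _ = run_day(
            [ep], ledger, {"t": t}, NO_STOCKOUT, np.random.default_rng(0)
        )
        assert delivered == [ep] and ep.status == "delivered"
        assert not postponed


class TestPriorityMonotonicity:
    def test_promotion_never_reduces_deliveries(self):
        # Holding footprints, capabilities and tiebreaks fixed, promoting one
        # treatment from low to high never lowers its same-day delivered count.
        rng = np.random.default_rng(23)
        cadres = ["a", "b"]
        for _ in range(60):
            treatments = {
                f"t{k}": simple_treatment(
                    f"t{k}",
                    {
                        c: float(rng.integers(5, 50))
                        for c in rng.choice(cadres, size=int(rng.integers(1, 3)), replace=False)
                    },
                )
                for k in range(3)
            }
            schedule = {c: float(rng.integers(20, 120)) for c in cadres}
            base = [
                (
                    i,
                    f"t{int(rng.integers(0, 3))}",
                    int(rng.integers(0, 4)),
                    float(rng.random()),
                )
                for i in range(int(rng.integers(5, 20)))
            ]

            def deliveries(promoted: bool) -> int:
                eps = []
                for person_id, tid, day, tiebreak in base:
                    tier = TIER_HIGH if (promoted and tid == "t0") else TIER_LOW
                    eps.append(
                        make_episode(
                            person_id=person_id, treatment_id=tid, day=day,
                            tiebreak=tiebreak, priority=tier,
                        )
                    )
                ledger = CapabilityLedger(CapabilitySchedule({"f": dict(schedule)}))
                delivered, _, _ = run_day(
                    order_queue(eps), ledger, treatments, NO_STOCKOUT,
                    np.random.default_rng(0),
                )
                return sum(e.treatment_id == "t0" for e in delivered)

            assert deliveries(True) >= deliveries(False)


class TestPresets:
    def test_seven_policies(self, default_bundle):
        ids = [p.policy_id for p in default_bundle.policies]
        assert ids == ["NP", "LCOA", "HSSP3", "VP", "RMNCH", "CMD", "CV"]

    def test_lcoa_excludes_dominant_infectious_treatment(self, default_bundle):
        lcoa = default_bundle.policy("LCOA")
        assert "hiv_treatment" in lcoa.excluded
        assert "hiv_treatment" not in lcoa.tier_of

    def test_emergency_treatments_not_in_policies(self, default_bundle):
        emergency = {t.treatment_id for t in default_bundle.treatments if t.emergency}
        for p in default_bundle.policies:
            assert not emergency & set(p.tier_of)
            assert not emergency & p.excluded

    def test_presets_validate_against_catalogue(self, default_bundle):
        tids = [t.treatment_id for t in default_bundle.treatments]
        for p in preset_policies(default_bundle.treatments):
            p.validate(tids)

    def test_queue_key_strict_total_order(self):
        a = make_episode(person_id=1, priority=2, tiebreak=0.5)
        b = make_episode(person_id=2, priority=2, tiebreak=0.5)
        assert queue_key(a) != queue_key(b)
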
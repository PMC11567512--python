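"""Orchestration: run scenarios under policies with common random numbers.

The daily loop is: demography -> incidence -> care-seeking -> priority
assignment/filter -> queue ordering -> delivery per facility -> persistence
close-out -> progression -> DALY accrual.  Random streams are derived from
(master seed, replicate, purpose label); the policy is *not* part of seed
derivation, so policies are compared under common random numbers.
"""

from __future__ import annotations

import hashlib
import json
import os
import sys
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__, epi, outcomes
from ._rng import derived_seed, stream, substream
from .epi import Cohort, DiseaseEpisode
from .errors import PrioritySimError
from .healthsystem import CapabilityLedger
from .outcomes import DalyLedger, ComparisonReport
from .queue import (
    CareEpisode,
    Policy,
    apply_policy_filter,
    assign_priority,
    close_day,
    order_queue,
    run_day,
)
from .scenario import ScenarioBundle, dumps_scenario, sample_population

DAYS_PER_YEAR = epi.DAYS_PER_YEAR


@dataclass
class RunManifest:
    """Provenance record sufficient to reproduce an experiment bit-for-bit."""

    scenario_hash: str
    policy_ids: List[str]
    replicates: int
    master_seed: int
    horizon_years: int
    software_version: str = __version__
    outputs: Dict[str, str] = field(default_factory=dict)
    completed_runs: List[List] = field(default_factory=list)  # [policy, replicate]

    def to_dict(self) -> dict:
        return {
            "scenario_hash": self.scenario_hash,
            "policy_ids": self.policy_ids,
            "replicates": self.replicates,
            "master_seed": self.master_seed,
            "horizon_years": self.horizon_years,
            "software_version": self.software_version,
            "outputs": self.outputs,
            "completed_runs": self.completed_runs,
        }


def scenario_hash(bundle: ScenarioBundle) -> str:
    return hashlib.sha256(dumps_scenario(bundle).encode()).hexdigest()


class _Run:
    """State for one (bundle, policy, replicate) simulation."""

    def __init__(
        self,
        bundle: ScenarioBundle,
        policy: Policy,
        replicate_id: int,
        log_postponed: bool = False,
    ):
        bundle.validate()
        self.bundle = bundle
        self.policy = policy
        self.replicate = replicate_id
        self.log_postponed = log_postponed
        self.causes = bundle.causes
        self.causes_by_id = bundle.causes_by_id()
        self.treatments = bundle.treatments_by_id()
        self.curative_by_cause = bundle.curative_by_cause()
        self.preventive_treatments = [t for t in bundle.treatments if t.preventive]
        self.emergency_causes = {
            c: t.emergency for c, t in self.curative_by_cause.items()
        }
        seed = derived_seed(bundle.master_seed, "population", replicate_id)
        persons = sample_population(bundle.population, seed)
        self.cohort = Cohort.from_persons(persons, bundle.cause_ids())
        self.rng = {
            label: stream(bundle.master_seed, label, replicate_id)
            for label in ("init", "demography", "incidence", "progression", "seeking")
        }
        self.registry: Dict[Tuple[str, int], DiseaseEpisode] = {}
        self.all_episodes: List[DiseaseEpisode] = []
        self.queues: Dict[str, List[CareEpisode]] = {}
        self.open_care: Dict[Tuple[int, str], CareEpisode] = {}
        self.events: List[tuple] = []
        self.delivery_log: List[dict] = []
        self.capability = CapabilityLedger(bundle.capabilities)
        scale = bundle.population.national_population / bundle.population.initial_size
        self.ledger = DalyLedger(
            policy_id=policy.policy_id, replicate_id=replicate_id, scale_factor=scale
        )
        self.horizon_days = bundle.horizon_years * DAYS_PER_YEAR

    # -- helpers -----------------------------------------------------------

    def _tiebreak(self, day: int):
        master, rep = self.bundle.master_seed, self.replicate

        def fn(person_id: int, treatment_id: str) -> float:
            return float(substream(master, "tiebreak", rep, person_id, treatment_id, day).random())

        return fn

    def _consumable_rng(self, day: int):
        master, rep = self.bundle.master_seed, self.replicate

        def fn(ep: CareEpisode):
            return substream(master, "consumables", rep, ep.person_id, ep.treatment_id, day)

        return fn

    def _register_episode(self, ep: DiseaseEpisode) -> None:
        self.registry[(ep.cause_id, ep.person_id)] = ep
        self.all_episodes.append(ep)
        self.events.append((ep.onset_day, ep.person_id, ep.cause_id, "incidence"))

    def _log_terminal(self, ep: CareEpisode, day: int, outcome: str) -> None:
        self.delivery_log.append(
            {
                "day": day,
                "facility": ep.facility_id,
                "treatment": ep.treatment_id,
                "person_id": ep.person_id,
                "tier": ep.priority,
                "first_seek_date": ep.first_seek_date,
                "attempt": ep.attempts_used,
                "outcome": outcome,
            }
        )

    def _seed_initial_prevalence(self) -> List[DiseaseEpisode]:
        rng = self.rng["init"]
        episodes: List[DiseaseEpisode] = []
        ages = self.cohort.age_years(0)
        n = self.cohort.n
        for cause in self.causes:
            if cause.initial_prevalence <= 0:
                continue
            rates = epi._band_rates(cause, ages, 0)
            eligible = self.cohort.alive[:n] & (rates > 0)
            if cause.sex_restricted == "f":
                eligible &= self.cohort.female[:n]
            elif cause.sex_restricted == "m":
                eligible &= ~self.cohort.female[:n]
            idx = np.flatnonzero(eligible)
            hit = idx[rng.random(len(idx)) < cause.initial_prevalence]
            st = self.cohort.conditions[cause.cause_id]
            severity = (
                epi.SEVERITY_EMERGENCY
                if self.emergency_causes.get(cause.cause_id, False)
                else epi.SEVERITY_ROUTINE
            )
            for i in hit:
                i = int(i)
                st.active[i] = True
                st.treated[i] = False
                st.onset_day[i] = 0
                st.ever[i] = True
                if cause.onset_flag:
                    self.cohort.set_flag(i, cause.onset_flag, True)
                episodes.append(
                    DiseaseEpisode(
                        person_id=i, cause_id=cause.cause_id, onset_day=0, severity=severity
                    )
                )
        return episodes

    def _enqueue(self, care_episodes: Sequence[CareEpisode], day: int) -> None:
        for cep in care_episodes:
            key = (cep.person_id, cep.treatment_id)
            if key in self.open_care:
                continue  # one open pursuit per (person, treatment)
            if apply_policy_filter(cep, self.policy) == "excluded":
                self._log_terminal(cep, day, "excluded")
                continue
            assign_priority(cep, self.cohort.person_view(cep.person_id), self.policy)
            self.open_care[key] = cep
            self.queues.setdefault(cep.facility_id, []).append(cep)

    def _drop_lapsed(self, day: int) -> None:
        """Remove queued episodes whose person died or condition resolved."""
        for facility, pending in self.queues.items():
            kept = []
            for cep in pending:
                lapsed = not self.cohort.alive[cep.person_id]
                if not lapsed and not cep.preventive and cep.cause_id is not None:
                    st = self.cohort.conditions[cep.cause_id]
                    lapsed = not st.active[cep.person_id]
                if lapsed:
                    cep.status = "defaulted"
                    self.open_care.pop((cep.person_id, cep.treatment_id), None)
                    self._log_terminal(cep, day, "lapsed")
                else:
                    kept.append(cep)
            self.queues[facility] = kept

    def _apply_delivery(self, cep: CareEpisode, day: int) -> None:
        spec = self.treatments[cep.treatment_id]
        if not cep.effective:
            return
        if spec.preventive:
            self.cohort.set_flag(cep.person_id, spec.risk_flag, False)
            return
        if cep.cause_id is None:
            return
        st = self.cohort.conditions[cep.cause_id]
        if st.active[cep.person_id]:
            st.treated[cep.person_id] = True
            ep = self.registry.get((cep.cause_id, cep.person_id))
            if ep is not None:
                ep.treated = True

    # -- main loop ---------------------------------------------------------

    def run(self) -> Tuple[DalyLedger, pd.DataFrame, pd.DataFrame]:
        bundle = self.bundle
        start_year = bundle.start_year
        initial_episodes = self._seed_initial_prevalence()
        for ep in initial_episodes:
            self._register_episode(ep)
        pending_new_episodes = initial_episodes

        for day in range(self.horizon_days):
            year = start_year + day // DAYS_PER_YEAR

            born, bg_deaths = epi.step_demography(
                self.cohort, bundle.population, day, self.rng["demography"]
            )
            for i in born:
                self.events.append((day, i, "", "birth"))
            for rec in bg_deaths:
                self.events.append((day, rec.person_id, rec.cause_id, "death"))
                self.ledger.add_yll(rec.cause_id, year, outcomes.compute_yll(rec.age_years))

            prevalences = {
                c.cause_id: epi.untreated_prevalence(self.cohort, c.cause_id)
                for c in self.causes
                if c.transmission_coefficient > 0
            }
            new_episodes = epi.step_incidence(
                self.cohort,
                self.causes,
                day,
                self.rng["incidence"],
                emergency_causes={c for c, e in self.emergency_causes.items() if e},
                prevalences=prevalences,
            )
            for ep in new_episodes:
                self._register_episode(ep)
            pending_new_episodes = pending_new_episodes + new_episodes if day == 0 else new_episodes

            tiebreak_fn = self._tiebreak(day)
            seekers = epi.step_care_seeking(
                pending_new_episodes,
                self.cohort,
                self.causes_by_id,
                self.curative_by_cause,
                day,
                self.rng["seeking"],
                tiebreak_fn=tiebreak_fn,
            )
            seekers += epi.step_prevention_seeking(
                self.cohort,
                self.preventive_treatments,
                day,
                self.rng["seeking"],
                tiebreak_fn=tiebreak_fn,
            )
            self._enqueue(seekers, day)
            self._drop_lapsed(day)

            self.capability.start_day()
            consumable_rng = self._consumable_rng(day)
            for facility in sorted(self.queues):
                pending = self.queues[facility]
                if not pending:
                    continue
                ordered = order_queue(pending)
                delivered, postponed, cons_defaulted = run_day(
                    ordered,
                    self.capability,
                    self.treatments,
                    bundle.consumable_branch_probs,
                    consumable_rng,
                    day=day,
                    log=self.delivery_log,
                    log_postponed=self.log_postponed,
                )
                for cep in delivered:
                    self.open_care.pop((cep.person_id, cep.treatment_id), None)
                    self._apply_delivery(cep, day)
                for cep in cons_defaulted:
                    self.open_care.pop((cep.person_id, cep.treatment_id), None)
                retried, defaulted = close_day(postponed, bundle.max_attempts)
                for cep in defaulted:
                    self.open_care.pop((cep.person_id, cep.treatment_id), None)
                    self._log_terminal(cep, day, "defaulted")
                self.queues[facility] = retried

            deaths, recoveries = epi.step_progression(
                self.cohort, self.causes, day, self.rng["progression"], registry=self.registry
            )
            for rec in deaths:
                self.events.append((day, rec.person_id, rec.cause_id, "death"))
                self.ledger.add_yll(rec.cause_id, year, outcomes.compute_yll(rec.age_years))
            for cause_id, person_id, _treated in recoveries:
                self.events.append((day, person_id, cause_id, "recovery"))

        for (cause_id, year), yld in outcomes.compute_yld(
            self.all_episodes, self.causes_by_id, start_year, end_day=self.horizon_days
        ).items():
            self.ledger.add_yld(cause_id, year, yld)
        # Ensure every simulated year appears, so horizons line up across runs.
        for y in range(start_year, start_year + bundle.horizon_years):
            self.ledger.cells.setdefault(("other", y), [0.0, 0.0])

        events_df = pd.DataFrame(
            self.events, columns=["day", "person_id", "cause", "event"]
        )
        delivery_df = pd.DataFrame(
            self.delivery_log,
            columns=[
                "day", "facility", "treatment", "person_id", "tier",
                "first_seek_date", "attempt", "outcome",
            ]
            + [
                f"minutes_{cadre}"
                for cadre in sorted({c for t in bundle.treatments for c in t.footprint})
            ],
        )
        return self.ledger, events_df, delivery_df


def run_scenario(
    bundle: ScenarioBundle,
    policy: Union[Policy, str],
    replicate_id: int,
    log_postponed: bool = False,
) -> Tuple[DalyLedger, pd.DataFrame, pd.DataFrame]:
    """Execute the full daily loop for one policy and replicate.

    Seeds derive from (master_seed, replicate, stream label) only, so the
    same replicate of different policies shares epidemiological draws.
    """
    if isinstance(policy, str):
        policy = bundle.policy(policy)
    try:
        return _Run(bundle, policy, replicate_id, log_postponed=log_postponed).run()
    except PrioritySimError as exc:
        raise type(exc)(
            f"[policy={policy.policy_id} replicate={replicate_id}] {exc}"
        ) from exc


def run_experiment(
    bundle: ScenarioBundle,
    policies: Optional[Sequence[Union[Policy, str]]] = None,
    out_dir: Optional[str] = None,
    benchmark: str = "NP",
    progress: bool = False,
) -> Tuple[ComparisonReport, RunManifest]:
    """Run replicates x policies, aggregate, and optionally write artifacts."""
    if policies is None:
        resolved = list(bundle.policies)
    else:
        resolved = [bundle.policy(p) if isinstance(p, str) else p for p in policies]
    manifest = RunManifest(
        scenario_hash=scenario_hash(bundle),
        policy_ids=[p.policy_id for p in resolved],
        replicates=bundle.replicates,
        master_seed=bundle.master_seed,
        horizon_years=bundle.horizon_years,
    )
    ledgers: List[DalyLedger] = []
    try:
        for policy in resolved:
            for rep in range(bundle.replicates):
                t0 = time.time()
                ledger, _events, _deliveries = run_scenario(bundle, policy, rep)
                ledgers.append(ledger)
                manifest.completed_runs.append([policy.policy_id, rep])
                if progress:
                    print(
                        f"{policy.policy_id} replicate {rep}: "
                        f"{ledger.total():.3g} DALYs ({time.time() - t0:.1f}s)",
                        file=sys.stderr,
                    )
    finally:
        if out_dir is not None and manifest.completed_runs:
            _write_outputs(out_dir, manifest, ledgers, benchmark, final=False)
    report = outcomes.aggregate_replicates(ledgers, benchmark=benchmark)
    if out_dir is not None:
        _write_outputs(out_dir, manifest, ledgers, benchmark, final=True, report=report)
    return report, manifest


def _write_outputs(
    out_dir: str,
    manifest: RunManifest,
    ledgers: Sequence[DalyLedger],
    benchmark: str,
    final: bool,
    report: Optional[ComparisonReport] = None,
) -> None:
    os.makedirs(out_dir, exist_ok=True)
    ledger_path = os.path.join(out_dir, "ledgers.csv")
    pd.concat([ledger.to_frame() for ledger in ledgers], ignore_index=True).to_csv(
        ledger_path, index=False
    )
    manifest.outputs["ledgers"] = ledger_path
    if final and report is not None:
        report_path = os.path.join(out_dir, "report.json")
        with open(report_path, "w") as fh:
            fh.write(report.to_json())
        manifest.outputs["report"] = report_path
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2)
    manifest.outputs["manifest"] = manifest_path
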
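"""Synthetic scenario generation, validation and (de)serialization.

A scenario bundle is one human-editable YAML document carrying population,
cause and treatment catalogues, the capability schedule, the policy set and
run configuration.  The default scenario encodes the structural features the
downstream analysis assumes: an initially dominant treatable infectious cause
whose untreated incidence escalates dynamically, a demographically rising
childhood cause that overtakes it, several further causes, and a residual
"other" cause that is not subject to resource constraints.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import yaml

from . import healthsystem
from ._rng import derived_seed
from .epi import Person
from .errors import ParseError, ValidationError
from .healthsystem import CapabilitySchedule, TreatmentSpec, validate_branch_probs
from .queue import Policy, preset_policies

SCHEMA_VERSION = 1

RESIDUAL_CAUSE = "other"

CAUSE_KINDS = ("infectious", "non-communicable", "perinatal", "other-residual")

#: Probability that a freshly sampled individual carries each stored flag.
DEFAULT_FLAG_PROBS: Dict[str, float] = {
    "unvaccinated": 0.35,
    "fertile_unprotected": 1.0,
    "anc_unattended": 0.7,
    "hiv_high_risk": 0.15,
    "tb_high_risk": 0.15,
}


@dataclass
class PopulationSpec:
    initial_size: int
    age_distribution: List[list]  # [lo, hi, probability]
    crude_birth_rate: float  # births per person-year
    background_mortality: List[list]  # [lo, hi, hazard per year]
    national_population: int

    def validate(self) -> None:
        if self.initial_size < 1:
            raise ValidationError("initial_size", "must be >= 1")
        if self.national_population < self.initial_size:
            raise ValidationError("national_population", "must be >= initial_size")
        if not self.age_distribution:
            raise ValidationError("age_distribution", "must be non-empty")
        total = 0.0
        for band in self.age_distribution:
            if len(band) != 3:
                raise ValidationError("age_distribution", "bands are [lo, hi, probability]")
            lo, hi, p = (float(x) for x in band)
            if hi <= lo or lo < 0:
                raise ValidationError("age_distribution", f"bad band [{lo}, {hi}]")
            if p < 0:
                raise ValidationError("age_distribution", "probabilities must be >= 0")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("age_distribution", f"probabilities sum to {total}, not 1")
        if self.crude_birth_rate < 0:
            raise ValidationError("crude_birth_rate", "must be >= 0")
        for band in self.background_mortality:
            if len(band) != 3 or float(band[2]) < 0:
                raise ValidationError(
                    "background_mortality", "bands are [lo, hi, hazard >= 0]"
                )


@dataclass
class CauseSpec:
    """One cause of disease, disability and death.

    ``base_incidence`` is a list of ``[age_lo, age_hi, rate, trend]`` bands:
    per-person per-year hazard with an additive per-year linear trend (floored
    at zero).  ``transmission_coefficient`` couples incidence to the
    prevalence of untreated active cases and must be 0 for non-infectious
    kinds.  Causes with ``resource_constrained=False`` accrue burden but never
    compete for healthcare-worker time.
    """

    cause_id: str
    kind: str
    base_incidence: List[list]
    disability_weight: float
    untreated_death_hazard: float
    untreated_duration: float
    treated_death_hazard: float
    treated_duration: float
    transmission_coefficient: float = 0.0
    risk_modifiers: List[list] = field(default_factory=list)
    care_seeking_probability: float = 1.0
    resource_constrained: bool = True
    immunity_multiplier: float = 1.0
    initial_prevalence: float = 0.0
    onset_flag: Optional[str] = None
    clear_flag_on_resolution: bool = False
    sex_restricted: Optional[str] = None

    def validate(self) -> None:
        if self.kind not in CAUSE_KINDS:
            raise ValidationError("kind", f"{self.cause_id}: unknown kind {self.kind!r}")
        if not 0.0 <= self.disability_weight <= 1.0:
            raise ValidationError(
                "disability_weight", f"{self.cause_id}: must be in [0, 1]"
            )
        for name in (
            "untreated_death_hazard",
            "treated_death_hazard",
            "transmission_coefficient",
            "immunity_multiplier",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(name, f"{self.cause_id}: must be >= 0")
        if self.treated_death_hazard > self.untreated_death_hazard:
            raise ValidationError(
                "treated_death_hazard",
                f"{self.cause_id}: must not exceed untreated_death_hazard",
            )
        if self.kind != "infectious" and self.transmission_coefficient != 0:
            raise ValidationError(
                "transmission_coefficient",
                f"{self.cause_id}: must be 0 for non-infectious causes",
            )
        if self.untreated_duration <= 0 or self.treated_duration <= 0:
            raise ValidationError(
                "untreated_duration", f"{self.cause_id}: durations must be > 0"
            )
        if not 0.0 <= self.care_seeking_probability <= 1.0:
            raise ValidationError(
                "care_seeking_probability", f"{self.cause_id}: must be in [0, 1]"
            )
        if not 0.0 <= self.initial_prevalence <= 1.0:
            raise ValidationError(
                "initial_prevalence", f"{self.cause_id}: must be in [0, 1]"
            )
        if not self.base_incidence:
            raise ValidationError("base_incidence", f"{self.cause_id}: must be non-empty")
        for band in self.base_incidence:
            if len(band) not in (3, 4):
                raise ValidationError(
                    "base_incidence",
                    f"{self.cause_id}: bands are [lo, hi, rate(, trend)]",
                )
            if float(band[2]) < 0:
                raise ValidationError(
                    "base_incidence", f"{self.cause_id}: rates must be >= 0"
                )
        for mod in self.risk_modifiers:
            if len(mod) != 2 or float(mod[1]) < 0:
                raise ValidationError(
                    "risk_modifiers", f"{self.cause_id}: entries are [flag, multiplier>=0]"
                )
        if self.sex_restricted not in (None, "f", "m"):
            raise ValidationError("sex_restricted", f"{self.cause_id}: must be f, m or null")


@dataclass
class ScenarioBundle:
    population: PopulationSpec
    causes: List[CauseSpec]
    treatments: List[TreatmentSpec]
    capabilities: CapabilitySchedule
    policies: List[Policy]
    horizon_years: int
    replicates: int
    master_seed: int
    start_year: int = 2023
    max_attempts: int = 7
    consumable_branch_probs: List[float] = field(
        default_factory=lambda: list(healthsystem.DEFAULT_BRANCH_PROBS)
    )
    schema_version: int = SCHEMA_VERSION

    # -- derived views -----------------------------------------------------

    def cause_ids(self) -> List[str]:
        return [c.cause_id for c in self.causes]

    def causes_by_id(self) -> Dict[str, CauseSpec]:
        return {c.cause_id: c for c in self.causes}

    def treatments_by_id(self) -> Dict[str, TreatmentSpec]:
        return {t.treatment_id: t for t in self.treatments}

    def curative_by_cause(self) -> Dict[str, TreatmentSpec]:
        return {t.target_cause: t for t in self.treatments if not t.preventive}

    def policy(self, policy_id: str) -> Policy:
        for p in self.policies:
            if p.policy_id == policy_id:
                return p
        raise KeyError(f"no policy {policy_id!r} in bundle")

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.horizon_years < 1:
            raise ValidationError("horizon_years", "must be >= 1")
        if self.replicates < 1:
            raise ValidationError("replicates", "must be >= 1")
        if self.max_attempts < 1:
            raise ValidationError("max_attempts", "must be >= 1")
        validate_branch_probs(self.consumable_branch_probs)
        self.population.validate()
        if not self.causes:
            raise ValidationError("causes", "must be non-empty")
        cause_ids = self.cause_ids()
        if len(set(cause_ids)) != len(cause_ids):
            raise ValidationError("causes", "cause ids must be unique")
        for c in self.causes:
            c.validate()
        tids = [t.treatment_id for t in self.treatments]
        if len(set(tids)) != len(tids):
            raise ValidationError("treatments", "treatment ids must be unique")
        curative_seen: Set[str] = set()
        for t in self.treatments:
            t.validate()
            if t.target_cause not in cause_ids:
                raise ValidationError(
                    "treatments",
                    f"treatment {t.treatment_id!r} targets unknown cause "
                    f"{t.target_cause!r}",
                )
            if not t.preventive:
                if t.target_cause in curative_seen:
                    raise ValidationError(
                        "treatments",
                        f"cause {t.target_cause!r} has more than one curative treatment",
                    )
                curative_seen.add(t.target_cause)
        self.capabilities.validate(self.treatments)
        pids = [p.policy_id for p in self.policies]
        if len(set(pids)) != len(pids):
            raise ValidationError("policies", "policy ids must be unique")
        for p in self.policies:
            p.validate(tids)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "master_seed": self.master_seed,
            "start_year": self.start_year,
            "horizon_years": self.horizon_years,
            "replicates": self.replicates,
            "max_attempts": self.max_attempts,
            "consumable_branch_probs": [float(p) for p in self.consumable_branch_probs],
            "population": asdict(self.population),
            "causes": [asdict(c) for c in self.causes],
            "treatments": [asdict(t) for t in self.treatments],
            "capabilities": self.capabilities.minutes,
            "policies": [
                {
                    "policy_id": p.policy_id,
                    "tier_of": dict(sorted(p.tier_of.items())),
                    "excluded": sorted(p.excluded),
                    "fasttrack": {k: sorted(v) for k, v in sorted(p.fasttrack.items())},
                }
                for p in self.policies
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioBundle":
        def build(klass, payload, context):
            try:
                return klass(**payload)
            except TypeError as exc:
                raise ParseError(f"{context}: {exc}") from exc

        try:
            population = build(PopulationSpec, data["population"], "population")
            causes = [
                build(CauseSpec, c, f"causes[{i}]") for i, c in enumerate(data["causes"])
            ]
            treatments = [
                build(TreatmentSpec, t, f"treatments[{i}]")
                for i, t in enumerate(data["treatments"])
            ]
            capabilities = CapabilitySchedule(
                {
                    f: {c: float(m) for c, m in cadres.items()}
                    for f, cadres in data["capabilities"].items()
                }
            )
            policies = [
                Policy(
                    policy_id=p["policy_id"],
                    tier_of=dict(p.get("tier_of", {})),
                    excluded=set(p.get("excluded", [])),
                    fasttrack={k: set(v) for k, v in p.get("fasttrack", {}).items()},
                )
                for p in data["policies"]
            ]
        except KeyError as exc:
            raise ParseError(f"missing required section/field: {exc}") from exc
        bundle = cls(
            population=population,
            causes=causes,
            treatments=treatments,
            capabilities=capabilities,
            policies=policies,
            horizon_years=int(data["horizon_years"]),
            replicates=int(data["replicates"]),
            master_seed=int(data["master_seed"]),
            start_year=int(data.get("start_year", 2023)),
            max_attempts=int(data.get("max_attempts", 7)),
            consumable_branch_probs=list(
                data.get("consumable_branch_probs", healthsystem.DEFAULT_BRANCH_PROBS)
            ),
            schema_version=int(data.get("schema_version", SCHEMA_VERSION)),
        )
        bundle.validate()
        return bundle


# ---------------------------------------------------------------------------
# Default scenario
# ---------------------------------------------------------------------------


def default_causes() -> List[CauseSpec]:
    """Eight causes: two with crossing burden trajectories, five further
    resource-constrained causes, and the residual unconstrained one."""
    return [
        CauseSpec(
            "hiv", "infectious",
            base_incidence=[[15, 50, 0.08, -0.004]],
            transmission_coefficient=4.0,
            disability_weight=0.3,
            untreated_death_hazard=0.45, untreated_duration=5.0,
            treated_death_hazard=0.02, treated_duration=0.3,
            risk_modifiers=[["hiv_high_risk", 1.5]],
            care_seeking_probability=0.7,
            immunity_multiplier=0.1,
            initial_prevalence=0.22,
            onset_flag="hiv_diagnosed",
        ),
        CauseSpec(
            "lri", "infectious",
            base_incidence=[[0, 5, 0.55, 0.045], [5, 100, 0.03, 0.001]],
            transmission_coefficient=0.3,
            disability_weight=0.2,
            untreated_death_hazard=1.0, untreated_duration=0.2,
            treated_death_hazard=0.05, treated_duration=0.08,
            care_seeking_probability=0.8,
            immunity_multiplier=0.9,
        ),
        CauseSpec(
            "neonatal", "perinatal",
            base_incidence=[[15, 50, 0.12, 0.002]],
            disability_weight=0.35,
            untreated_death_hazard=0.6, untreated_duration=0.75,
            treated_death_hazard=0.05, treated_duration=0.75,
            risk_modifiers=[["anc_unattended", 2.0]],
            care_seeking_probability=0.85,
            sex_restricted="f",
            onset_flag="pregnant",
            clear_flag_on_resolution=True,
        ),
        CauseSpec(
            "tb", "infectious",
            base_incidence=[[15, 70, 0.05, 0.0]],
            transmission_coefficient=1.5,
            disability_weight=0.33,
            untreated_death_hazard=0.18, untreated_duration=3.0,
            treated_death_hazard=0.02, treated_duration=0.5,
            risk_modifiers=[["hiv_diagnosed", 2.0], ["tb_high_risk", 1.5]],
            care_seeking_probability=0.7,
            immunity_multiplier=0.5,
            initial_prevalence=0.02,
            onset_flag="tb_diagnosed",
        ),
        CauseSpec(
            "measles", "infectious",
            base_incidence=[[0, 15, 0.3, -0.002]],
            transmission_coefficient=1.0,
            disability_weight=0.15,
            untreated_death_hazard=0.15, untreated_duration=0.1,
            treated_death_hazard=0.01, treated_duration=0.05,
            risk_modifiers=[["unvaccinated", 3.0]],
            care_seeking_probability=0.75,
            immunity_multiplier=0.05,
        ),
        CauseSpec(
            "cardio", "non-communicable",
            base_incidence=[[30, 90, 0.25, 0.002]],
            disability_weight=0.12,
            untreated_death_hazard=0.04, untreated_duration=5.0,
            treated_death_hazard=0.01, treated_duration=1.0,
            care_seeking_probability=0.8,
            initial_prevalence=0.05,
        ),
        CauseSpec(
            "injury", "non-communicable",
            base_incidence=[[0, 90, 0.08, 0.0]],
            disability_weight=0.25,
            untreated_death_hazard=0.9, untreated_duration=0.15,
            treated_death_hazard=0.08, treated_duration=0.1,
            care_seeking_probability=1.0,
        ),
        CauseSpec(
            RESIDUAL_CAUSE, "other-residual",
            base_incidence=[[0, 90, 0.1, 0.0]],
            disability_weight=0.05,
            untreated_death_hazard=0.02, untreated_duration=0.5,
            treated_death_hazard=0.02, treated_duration=0.5,
            care_seeking_probability=0.0,
            resource_constrained=False,
        ),
    ]


def default_population() -> PopulationSpec:
    return PopulationSpec(
        initial_size=2000,
        age_distribution=[
            [0, 5, 0.18],
            [5, 15, 0.26],
            [15, 30, 0.24],
            [30, 50, 0.19],
            [50, 70, 0.10],
            [70, 90, 0.03],
        ],
        crude_birth_rate=0.055,
        background_mortality=[
            [0, 5, 0.008],
            [5, 15, 0.002],
            [15, 50, 0.004],
            [50, 70, 0.015],
            [70, 90, 0.08],
        ],
        national_population=14_500_000,
    )


def default_capabilities() -> CapabilitySchedule:
    """Daily cadre minutes sized so demand exceeds supply at the default
    population (roughly half to two-thirds of requested HSIs deliverable)."""
    return CapabilitySchedule(
        {
            "1a": {"clinical_officer": 7.0, "nurse": 12.0, "pharmacist": 3.5},
            "1b": {"clinical_officer": 3.5, "nurse": 6.0, "pharmacist": 1.5},
            "2": {"clinical_officer": 5.0, "nurse": 5.0, "pharmacist": 1.0},
        }
    )


def make_default_scenario(master_seed: int) -> ScenarioBundle:
    """Fully populated, validated default bundle (deterministic per seed)."""
    treatments = healthsystem.build_default_footprints()
    bundle = ScenarioBundle(
        population=default_population(),
        causes=default_causes(),
        treatments=treatments,
        capabilities=default_capabilities(),
        policies=preset_policies(treatments),
        horizon_years=20,
        replicates=10,
        master_seed=int(master_seed),
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------


def sample_population(
    spec: PopulationSpec,
    seed: int,
    flag_probs: Optional[Dict[str, float]] = None,
) -> List[Person]:
    """Sample the initial population: exactly ``initial_size`` alive persons.

    Ages are drawn from the age distribution (uniform within band); the
    under-5 flag is derived from age, stored flags are Bernoulli draws from
    ``flag_probs``.
    """
    spec.validate()
    if flag_probs is None:
        flag_probs = DEFAULT_FLAG_PROBS
    rng = np.random.default_rng(seed)
    n = spec.initial_size
    bands = np.array([[float(b[0]), float(b[1])] for b in spec.age_distribution])
    probs = np.array([float(b[2]) for b in spec.age_distribution])
    probs = probs / probs.sum()
    band_idx = rng.choice(len(bands), size=n, p=probs)
    ages = rng.uniform(bands[band_idx, 0], bands[band_idx, 1])
    female = rng.random(n) < 0.5
    flag_draws = {flag: rng.random(n) < p for flag, p in flag_probs.items()}
    persons = []
    for i in range(n):
        flags = {flag for flag, hit in flag_draws.items() if hit[i]}
        persons.append(
            Person(
                person_id=i,
                birth_date=-int(round(ages[i] * 365)),
                alive=True,
                sex="f" if female[i] else "m",
                flags=flags,
            )
        )
    return persons


# ---------------------------------------------------------------------------
# Scaling helpers & IO
# ---------------------------------------------------------------------------


def scale_bundle(
    bundle: ScenarioBundle,
    initial_size: Optional[int] = None,
    horizon_years: Optional[int] = None,
    replicates: Optional[int] = None,
    capability_factor: Optional[float] = None,
) -> ScenarioBundle:
    """Copy of a bundle resized for quick runs.

    Capabilities scale with the population by default so the degree of
    scarcity is preserved at smaller sizes.
    """
    out = replace(bundle)
    if initial_size is not None:
        factor = initial_size / bundle.population.initial_size
        out.population = replace(bundle.population, initial_size=initial_size)
        if capability_factor is None:
            capability_factor = factor
    if capability_factor is not None:
        out.capabilities = bundle.capabilities.scaled(capability_factor)
    if horizon_years is not None:
        out.horizon_years = horizon_years
    if replicates is not None:
        out.replicates = replicates
    out.validate()
    return out


def unconstrained_bundle(bundle: ScenarioBundle, minutes: float = 1e12) -> ScenarioBundle:
    """Copy with capabilities far above any attainable daily demand."""
    caps = CapabilitySchedule(
        {f: {c: minutes for c in cadres} for f, cadres in bundle.capabilities.minutes.items()}
    )
    out = replace(bundle, capabilities=caps)
    out.validate()
    return out


def population_seed(bundle: ScenarioBundle, replicate: int = 0) -> int:
    """The documented stream-split seed for initial population sampling."""
    return derived_seed(bundle.master_seed, "population", replicate)


def dumps_scenario(bundle: ScenarioBundle) -> str:
    return yaml.safe_dump(bundle.to_dict(), sort_keys=False)


def write_scenario(bundle: ScenarioBundle, path) -> None:
    bundle.validate()
    with open(path, "w") as fh:
        fh.write(dumps_scenario(bundle))


def read_scenario(path) -> ScenarioBundle:
    with open(path) as fh:
        text = fh.read()
    try:
        data = yaml.safe_load(io.StringIO(text))
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ParseError(f"{path}: invalid YAML{where}: {exc}") from exc
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    return ScenarioBundle.from_dict(data)
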
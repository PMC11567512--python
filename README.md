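# prioritysim

Individual-based simulation of priority-driven health service delivery under
rigid human-resource constraints, with DALY-based policy comparison.

Disease episodes in a synthetic population generate daily demand for
healthcare-worker time at facilities. A *rigid* capacity-constrained queue
delivers services in policy-defined priority order: appointment durations are
fixed, no task shifting between cadres is allowed, overtime is permitted only
to finish the day's last service, and a patient is turned away whenever any
required cadre has exhausted its minutes. Unserved patients re-seek care daily
at the same facility up to a maximum number of attempts, then default from
care permanently. Prioritisation policies assign each non-emergency treatment
a high or low tier, optionally fast-track vulnerable patients (under-5,
pregnant, HIV-diagnosed, TB-diagnosed) and optionally exclude treatments
entirely; emergency tiers are reserved by the engine, with child emergencies
above adult ones. Policies are compared by disability-adjusted life years
(YLL against a 70-year reference life expectancy, plus disability-weighted
YLD), aggregated over replicates with common random numbers.

## Modules

| module         | responsibility |
|----------------|----------------|
| `scenario`     | synthetic scenario generation, validation, YAML (de)serialization, population sampling |
| `epi`          | daily disease dynamics: incidence with transmission feedback, progression, demography, care-seeking |
| `healthsystem` | treatments with per-cadre minute footprints, capability ledger, stochastic consumables |
| `queue`        | priority assignment, queue ordering, rigid delivery, persistence/default; the seven named policy presets |
| `outcomes`     | DALY ledgers, replicate aggregation with 95% CIs, horizon views, cause ranking |
| `experiment`   | orchestration with common random numbers, run manifests, output files |

The seven policy presets are NP (equal priority benchmark), LCOA (targeted
high-priority list plus exclusion of the dominant infectious cause's
treatment), HSSP3 (inclusion without internal prioritisation), VP (vertical
programmes), RMNCH (reproductive/maternal/neonatal/child health), CMD
(cardiometabolic) and CV (priority purely by patient characteristics).

## CLI

```bash
prioritysim scenario make --seed 1 --out scenario.yaml
prioritysim scenario validate scenario.yaml
prioritysim run --scenario scenario.yaml --policies NP,CV,LCOA \
    --replicates 10 --seed 1 --out runs/demo
prioritysim report runs/demo --horizon 3
prioritysim presets
```

`run` writes `ledgers.csv` (policy, replicate, cause, year, YLL, YLD),
`report.json` and `manifest.json` into the output directory; `report`
recomputes the comparison from the ledgers at any horizon.

## Determinism

All randomness derives from a single master seed. Streams are split by
(purpose label, replicate); policy identity never enters seed derivation, so
policies are compared under common random numbers. Draws whose consumption
order could depend on the policy (consumable checks, effectiveness draws,
queue tiebreaks) use substreams keyed on (person, treatment, day), which makes
runs bit-reproducible and makes all policies produce identical event logs when
capacity is unconstrained and nothing is excluded.
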
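"""DALY accounting (YLL + YLD), replicate aggregation and policy comparison.

Years of life lost use a fixed reference life expectancy (default 70 years),
undiscounted.  Years lived with disability are the disability weight times
time lived with the condition, attributed to calendar years pro rata and
censored at the simulation horizon.  Confidence intervals across replicates
use the normal approximation (mean +/- 1.96 sd / sqrt(n)).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError

DAYS_PER_YEAR = 365

#: Reference life expectancy in years for YLL computation.
DEFAULT_REFERENCE_LIFE_EXPECTANCY = 70.0

Z_95 = 1.96


def compute_yll(
    age_at_death: float,
    reference_life_expectancy: float = DEFAULT_REFERENCE_LIFE_EXPECTANCY,
) -> float:
    """Undiscounted years of life lost for one death."""
    if age_at_death < 0:
        raise ValidationError("age_at_death", "must be >= 0")
    return max(0.0, reference_life_expectancy - age_at_death)


def compute_yld(
    episodes: Iterable,
    causes_by_id: Mapping[str, object],
    start_year: int = 2023,
    end_day: Optional[int] = None,
) -> Dict[Tuple[str, int], float]:
    """Years lived with disability per (cause, calendar year).

    Each episode contributes ``disability_weight * days / 365`` split pro rata
    over the calendar years it spans.  Ongoing episodes are censored at
    ``end_day`` (the last simulated day); deaths after the horizon are never
    imputed.
    """
    out: Dict[Tuple[str, int], float] = {}
    for ep in episodes:
        cause = causes_by_id[ep.cause_id]
        w = cause.disability_weight
        if w == 0:
            continue
        d0 = ep.onset_day
        d1 = ep.end_day
        if d1 is None:
            if end_day is None:
                raise ValidationError(
                    "end_day", "required to censor episodes still ongoing"
                )
            d1 = end_day
        if end_day is not None:
            d1 = min(d1, end_day)
        if d1 <= d0:
            continue
        y0 = d0 // DAYS_PER_YEAR
        y1 = (d1 - 1) // DAYS_PER_YEAR
        for y in range(y0, y1 + 1):
            days = min(d1, (y + 1) * DAYS_PER_YEAR) - max(d0, y * DAYS_PER_YEAR)
            key = (ep.cause_id, start_year + y)
            out[key] = out.get(key, 0.0) + w * days / DAYS_PER_YEAR
    return out


@dataclass
class DalyLedger:
    """Per-cause, per-calendar-year YLL and YLD for one replicate."""

    policy_id: str
    replicate_id: int
    scale_factor: float = 1.0
    cells: Dict[Tuple[str, int], List[float]] = field(default_factory=dict)  # [yll, yld]

    def add_yll(self, cause_id: str, year: int, years: float) -> None:
        if years < 0:
            raise ValidationError("yll", "must be >= 0")
        self.cells.setdefault((cause_id, year), [0.0, 0.0])[0] += years

    def add_yld(self, cause_id: str, year: int, years: float) -> None:
        if years < 0:
            raise ValidationError("yld", "must be >= 0")
        self.cells.setdefault((cause_id, year), [0.0, 0.0])[1] += years

    def total(self, scaled: bool = True) -> float:
        raw = sum(yll + yld for yll, yld in self.cells.values())
        return raw * self.scale_factor if scaled else raw

    def per_cause(self, scaled: bool = True) -> Dict[str, float]:
        out: Dict[str, float] = {}
        k = self.scale_factor if scaled else 1.0
        for (cause, _year), (yll, yld) in self.cells.items():
            out[cause] = out.get(cause, 0.0) + (yll + yld) * k
        return out

    def per_year(self, scaled: bool = True) -> Dict[int, float]:
        out: Dict[int, float] = {}
        k = self.scale_factor if scaled else 1.0
        for (_cause, year), (yll, yld) in self.cells.items():
            out[year] = out.get(year, 0.0) + (yll + yld) * k
        return out

    def years(self) -> List[int]:
        return sorted({year for (_c, year) in self.cells})

    def restrict_years(self, years: Sequence[int]) -> "DalyLedger":
        keep = set(years)
        return DalyLedger(
            policy_id=self.policy_id,
            replicate_id=self.replicate_id,
            scale_factor=self.scale_factor,
            cells={k: list(v) for k, v in self.cells.items() if k[1] in keep},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "policy": self.policy_id,
                "replicate": self.replicate_id,
                "cause": cause,
                "year": year,
                "yll": yll,
                "yld": yld,
                "scale_factor": self.scale_factor,
            }
            for (cause, year), (yll, yld) in sorted(self.cells.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["policy", "replicate", "cause", "year", "yll", "yld", "scale_factor"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> List["DalyLedger"]:
        ledgers = []
        for (policy, replicate), group in df.groupby(["policy", "replicate"], sort=True):
            ledger = cls(
                policy_id=str(policy),
                replicate_id=int(replicate),
                scale_factor=float(group["scale_factor"].iloc[0]),
            )
            for _, row in group.iterrows():
                key = (str(row["cause"]), int(row["year"]))
                ledger.cells[key] = [float(row["yll"]), float(row["yld"])]
            ledgers.append(ledger)
        return ledgers


@dataclass
class PolicySummary:
    mean: float
    sd: float
    n: int
    ci_low: float
    ci_high: float
    pct_change: float
    degenerate_ci: bool = False


@dataclass
class ComparisonReport:
    """Policy comparison over a horizon, relative to a benchmark policy."""

    benchmark: str
    years: List[int]
    policies: List[str]
    totals: Dict[str, PolicySummary]
    per_year: Dict[str, Dict[int, float]]
    per_cause: Dict[str, Dict[str, float]]
    ledgers: List[DalyLedger] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "benchmark": self.benchmark,
            "years": self.years,
            "policies": self.policies,
            "totals": {
                p: {
                    "mean": s.mean,
                    "sd": s.sd,
                    "n": s.n,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                    "pct_change": s.pct_change,
                    "degenerate_ci": s.degenerate_ci,
                }
                for p, s in self.totals.items()
            },
            "per_year": {p: {str(y): v for y, v in series.items()} for p, series in self.per_year.items()},
            "per_cause": self.per_cause,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def aggregate_replicates(
    ledgers: Sequence[DalyLedger],
    benchmark: str = "NP",
) -> ComparisonReport:
    """Mean, 95% CI and percent change vs the benchmark across replicates.

    All ledgers must cover the same calendar years.  With a single replicate
    the CI is undefined and flagged degenerate.
    """
    if not ledgers:
        raise ValidationError("ledgers", "must be non-empty")
    year_sets = {tuple(ledger.years()) for ledger in ledgers}
    if len(year_sets) != 1:
        raise ValidationError("ledgers", "mismatched horizons across ledgers")
    years = list(year_sets.pop())
    by_policy: Dict[str, List[DalyLedger]] = {}
    for ledger in ledgers:
        by_policy.setdefault(ledger.policy_id, []).append(ledger)
    policies = list(by_policy)
    if benchmark not in by_policy:
        benchmark = policies[0]

    def summarize(values: List[float]) -> Tuple[float, float, int]:
        arr = np.asarray(values, dtype=float)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        return mean, sd, len(arr)

    means: Dict[str, Tuple[float, float, int]] = {
        p: summarize([ledger.total() for ledger in reps]) for p, reps in by_policy.items()
    }
    bench_mean = means[benchmark][0]
    totals: Dict[str, PolicySummary] = {}
    for p, (mean, sd, n) in means.items():
        half = Z_95 * sd / math.sqrt(n) if n > 1 else float("nan")
        pct = 0.0 if p == benchmark else (
            (mean - bench_mean) / bench_mean * 100.0 if bench_mean != 0 else float("nan")
        )
        totals[p] = PolicySummary(
            mean=mean,
            sd=sd,
            n=n,
            ci_low=mean - half if n > 1 else float("nan"),
            ci_high=mean + half if n > 1 else float("nan"),
            pct_change=pct,
            degenerate_ci=n < 2,
        )

    per_year: Dict[str, Dict[int, float]] = {}
    per_cause: Dict[str, Dict[str, float]] = {}
    for p, reps in by_policy.items():
        year_acc: Dict[int, List[float]] = {y: [] for y in years}
        cause_acc: Dict[str, List[float]] = {}
        for ledger in reps:
            ledger_years = ledger.per_year()
            for y in years:
                year_acc[y].append(ledger_years.get(y, 0.0))
            for cause, v in ledger.per_cause().items():
                cause_acc.setdefault(cause, []).append(v)
        n_reps = len(reps)
        per_year[p] = {y: float(np.mean(vs)) for y, vs in year_acc.items()}
        # Missing cause cells count as zero so decompositions stay additive.
        per_cause[p] = {c: float(np.sum(vs) / n_reps) for c, vs in cause_acc.items()}

    return ComparisonReport(
        benchmark=benchmark,
        years=years,
        policies=policies,
        totals=totals,
        per_year=per_year,
        per_cause=per_cause,
        ledgers=list(ledgers),
    )


def horizon_view(report: ComparisonReport, horizon_years: int) -> ComparisonReport:
    """Recompute a report on cumulative DALYs over the first N years only."""
    if horizon_years < 1:
        raise ValidationError("horizon_years", "must be >= 1")
    if horizon_years > len(report.years):
        raise ValidationError(
            "horizon_years",
            f"{horizon_years} exceeds the simulated horizon of {len(report.years)} years",
        )
    keep = report.years[:horizon_years]
    truncated = [ledger.restrict_years(keep) for ledger in report.ledgers]
    return aggregate_replicates(truncated, benchmark=report.benchmark)


def rank_causes(report: ComparisonReport, residual: str = "other") -> List[str]:
    """Causes sorted by benchmark total DALYs descending, residual last.

    Ties are broken by cause id (stable, documented rule); the residual cause
    is excluded from the ranking and appended at the end regardless of size.
    """
    contributions = report.per_cause.get(report.benchmark, {})
    ranked = sorted(
        (c for c in contributions if c != residual),
        key=lambda c: (-contributions[c], c),
    )
    if residual in contributions:
        ranked.append(residual)
    return ranked
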
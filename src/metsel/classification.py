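"""Check-anchored drought-tolerance classification.

Accessions are binned by grain yield against the replicated reference
checks: above the best tolerant check -> high-yielding drought-tolerant;
down to the designated upper anchor -> moderately resistant; down to the
lower anchor -> moderately susceptible; below it -> highly susceptible.
Exact ties with a boundary check resolve to the better category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CheckConfig",
    "ToleranceCall",
    "CATEGORIES",
    "classify",
    "category_summary",
    "consistent_tolerant",
]

log = logging.getLogger(__name__)

CATEGORIES = (
    "high-yielding drought-tolerant",
    "moderately resistant",
    "moderately susceptible",
    "highly drought-susceptible",
)


@dataclass
class CheckConfig:
    tolerant: tuple[str, ...]
    susceptible: tuple[str, ...]
    #: tolerant check forming the moderate-resistant lower bound
    upper_anchor: str
    #: susceptible check forming the highly-susceptible upper bound
    lower_anchor: str

    def __post_init__(self) -> None:
        self.tolerant = tuple(self.tolerant)
        self.susceptible = tuple(self.susceptible)
        if not self.tolerant or not self.susceptible:
            raise ValueError("check lists must be non-empty")
        if set(self.tolerant) & set(self.susceptible):
            raise ValueError("tolerant and susceptible check lists overlap")
        if self.upper_anchor not in self.tolerant:
            raise ValueError("upper anchor must be a tolerant check")
        if self.lower_anchor not in self.susceptible:
            raise ValueError("lower anchor must be a susceptible check")

    @property
    def all_checks(self) -> tuple[str, ...]:
        return self.tolerant + self.susceptible


def default_checks() -> CheckConfig:
    return CheckConfig(
        tolerant=("Apo", "Norungan", "CO 53", "Anna (R) 4"),
        susceptible=("IR 64", "Jaya", "Pusa 44"),
        upper_anchor="Anna (R) 4",
        lower_anchor="IR 64",
    )


@dataclass
class ToleranceCall:
    genotype: str
    category: str
    value: float
    environment: str


def classify(
    yields: Mapping[str, float] | pd.Series,
    checks: CheckConfig,
    environment: str = "multi",
) -> list[ToleranceCall]:
    """Categorise every non-check accession by yield against the checks."""
    if isinstance(yields, pd.Series):
        yields = yields.to_dict()
    missing = [c for c in checks.all_checks if c not in yields]
    if missing:
        raise ValueError(f"check value(s) missing from yields: {missing}")

    top = max(yields[c] for c in checks.tolerant)
    upper = yields[checks.upper_anchor]
    lower = yields[checks.lower_anchor]
    if not (lower <= upper <= top):
        log.warning(
            "%s: check ordering inconsistent with labels (top=%.4g, "
            "upper anchor=%.4g, lower anchor=%.4g); binning rules applied as-is",
            environment, top, upper, lower,
        )

    check_set = set(checks.all_checks)
    calls = []
    for geno in sorted(set(yields) - check_set):
        v = yields[geno]
        if v >= top:
            cat = CATEGORIES[0]
        elif v >= upper:
            cat = CATEGORIES[1]
        elif v >= lower:
            cat = CATEGORIES[2]
        else:
            cat = CATEGORIES[3]
        calls.append(ToleranceCall(genotype=geno, category=cat, value=float(v),
                                   environment=environment))
    return calls


def category_summary(calls: Iterable[ToleranceCall]) -> pd.DataFrame:
    """Count and percent of non-check accessions per category (2 decimals)."""
    calls = list(calls)
    if not calls:
        raise ValueError("no tolerance calls supplied")
    total = len(calls)
    counts = {cat: 0 for cat in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [counts[c] for c in CATEGORIES],
            "percent": [round(100.0 * counts[c] / total, 2) for c in CATEGORIES],
        }
    )


def consistent_tolerant(calls_by_env: Mapping[str, Iterable[ToleranceCall]]) -> list[str]:
    """Accessions in the tolerant category in every supplied environment."""
    if len(calls_by_env) < 2:
        raise ValueError("need tolerance calls from at least 2 environments")
    sets = []
    for calls in calls_by_env.values():
        sets.append({c.genotype for c in calls if c.category == CATEGORIES[0]})
    out = set.intersection(*sets)
    return sorted(out)
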
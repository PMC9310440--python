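"""Seeded Monte-Carlo cohort simulation.

Each simulated patient gets a uniform age, a uniform diet category, one
Bernoulli 0/1 draw per marker at its diet-adjusted prior, derived
fusion/fission flags, and a deterministic disease-progression probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DomainError
from .network_model import (
    MARKERS,
    Config,
    NetworkSpec,
    DietModifierTable,
    PriorTable,
    default_config,
    effective_probability,
)

__all__ = [
    "PatientRecord",
    "CohortTable",
    "sample_age",
    "sample_diet",
    "sample_markers",
    "derive_fusion",
    "derive_fission",
    "simulate_cohort",
]

_FUSION_MARKERS = ("opa1", "mfn1", "mfn2")
_FISSION_MARKERS = ("drp1", "fis1")


@dataclass(frozen=True)
class PatientRecord:
    """One simulated individual; column order matches the cohort CSV."""

    id: int
    atp: int
    opa1: int
    mfn1: int
    mfn2: int
    drp1: int
    fis1: int
    db: int
    os: int
    ht: int
    ob: int
    dp: int
    pa: int
    diet: str
    age: int
    fusion: int
    fission: int
    ad_probability: float

    def __post_init__(self) -> None:
        if self.id < 1:
            raise DomainError(f"patient id {self.id} must be >= 1")
        for name in MARKERS + ("fusion", "fission"):
            value = getattr(self, name)
            if value not in (0, 1):
                raise DomainError(f"{name}={value!r} is not a binary flag")
        if not 30 <= self.age <= 95:
            raise DomainError(f"age {self.age} outside [30, 95]")
        if not 0.0 <= self.ad_probability <= 1.0:
            raise DomainError(f"AD probability {self.ad_probability} outside [0, 1]")

    def markers(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in MARKERS}


@dataclass(frozen=True)
class CohortTable:
    """Ordered patient records plus the metadata that reproduces them."""

    records: tuple[PatientRecord, ...]
    n: int
    seed: int | None
    config_digest: str = ""

    def __post_init__(self) -> None:
        if len(self.records) != self.n:
            raise DomainError(f"cohort has {len(self.records)} records, expected n={self.n}")
        ids = [r.id for r in self.records]
        if ids != list(range(1, len(ids) + 1)):
            raise DomainError("patient ids must be unique and sequential from 1")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def marker_frequencies(self) -> dict[str, float]:
        """Empirical abnormality frequency of each marker over the cohort."""
        n = len(self.records)
        return {
            m: sum(getattr(r, m) for r in self.records) / n for m in MARKERS
        }


def sample_age(rng: np.random.Generator, age_range: tuple[int, int] = (30, 95)) -> int:
    """Integer age drawn uniformly from the inclusive *age_range*."""
    lo, hi = age_range
    return int(rng.integers(lo, hi + 1))


def sample_diet(rng: np.random.Generator, diets: tuple[str, ...] | None = None) -> str:
    """Diet category drawn uniformly over the configured categories."""
    if diets is None:
        diets = default_config().simulation.diets
    return diets[int(rng.integers(len(diets)))]


def sample_markers(
    diet: str,
    priors: PriorTable,
    modifiers: DietModifierTable,
    rng: np.random.Generator,
    network: NetworkSpec | None = None,
) -> dict[str, int]:
    """One independent Bernoulli draw per marker at its effective probability.

    The effective probability is the marker's prior pushed through the diet's
    odds-scale modifier.  If *network* carries a CPT override for a marker
    whose parents are earlier markers, the parent-conditioned probability is
    used instead (the four-way False/True parent linking).
    """
    draws = rng.random(len(MARKERS))
    states: dict[str, int] = {}
    for i, marker in enumerate(MARKERS):
        override = (network.cpt_overrides.get(marker) if network else None)
        if override is not None:
            missing = [p for p in override.parents if p not in states]
            if missing:
                raise DomainError(
                    f"cpt parents {missing} of {marker!r} are not sampled before it"
                )
            p = override.probability(states)
        else:
            p = effective_probability(
                priors.prior(marker), modifiers.modifier(diet, marker)
            )
        states[marker] = int(draws[i] < p)
    return states


def derive_fusion(markers: Mapping[str, int]) -> int:
    """1 iff at least two of opa1/mfn1/mfn2 are abnormal."""
    missing = [m for m in _FUSION_MARKERS if m not in markers]
    if missing:
        raise DomainError(f"fusion derivation: missing marker(s) {missing}")
    return int(sum(int(markers[m]) for m in _FUSION_MARKERS) >= 2)


def derive_fission(markers: Mapping[str, int]) -> int:
    """1 iff drp1 or fis1 is abnormal."""
    missing = [m for m in _FISSION_MARKERS if m not in markers]
    if missing:
        raise DomainError(f"fission derivation: missing marker(s) {missing}")
    return int(any(int(markers[m]) for m in _FISSION_MARKERS))


def simulate_cohort(
    n: int,
    seed: int,
    config: Config | None = None,
) -> CohortTable:
    """Simulate *n* patients reproducibly under (*n*, *seed*, *config*).

    Draw order per patient is fixed: age, diet, then the twelve markers in
    cohort-column order, using a single seeded generator.
    """
    from .cases import EvidencePattern, evaluate_ad_probability  # cycle-free

    if n < 1:
        raise DomainError(f"cohort size n={n} must be >= 1")
    if config is None:
        config = default_config()
    rng = np.random.default_rng(seed)
    sim = config.simulation

    records = []
    for pid in range(1, n + 1):
        age = sample_age(rng, sim.age_range)
        diet = sample_diet(rng, sim.diets)
        markers = sample_markers(
            diet, config.priors, config.diet_modifiers, rng, config.network
        )
        ev = EvidencePattern(diet=diet, age=age, **markers)
        records.append(
            PatientRecord(
                id=pid,
                diet=diet,
                age=age,
                fusion=derive_fusion(markers),
                fission=derive_fission(markers),
                ad_probability=evaluate_ad_probability(
                    ev, config.priors, config.case_rule
                ),
                **markers,
            )
        )
    return CohortTable(
        records=tuple(records), n=n, seed=seed, config_digest=config.digest()
    )
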
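"""Deterministic evidence-to-risk evaluation and the five reference cases.

The mapping from an evidence pattern to a progression probability is a
four-step cascade over the prior table:

1. any abnormal mitochondrial-dynamics marker -> prior of the
   highest-priority abnormal one;
2. otherwise, no diet intervention -> a fixed baseline (0.743 by default);
3. otherwise, any positive lifestyle marker -> the largest prior among the
   positive ones;
4. otherwise -> the age-bracket risk.

The cascade is the minimal deterministic rule consistent with all five
published reference rows; every element of it is configurable via
:class:`~mitobayes.network_model.CaseRule`.  Step 2 is a constant rather than
a marker lookup: the reference row it reproduces has no abnormal marker, so
no marker-based rule can yield its printed probability.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError
from .network_model import (
    DIET_CATEGORIES,
    MARKERS,
    CaseRule,
    Config,
    PriorTable,
    age_risk,
    default_config,
)

__all__ = ["EvidencePattern", "evaluate_ad_probability", "reproduce_table2", "TABLE2_PATTERNS"]


@dataclass(frozen=True)
class EvidencePattern:
    """Full observable assignment for one individual: 12 markers, diet, age."""

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

    def __post_init__(self) -> None:
        for name in MARKERS:
            if getattr(self, name) not in (0, 1):
                raise DomainError(f"{name}={getattr(self, name)!r} is not a binary flag")
        if self.diet not in DIET_CATEGORIES:
            raise DomainError(f"unknown diet category {self.diet!r}")
        if not 30 <= self.age <= 95:
            raise DomainError(f"age {self.age} outside [30, 95]")

    def markers(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in MARKERS}


def evaluate_ad_probability(
    ev: EvidencePattern,
    priors: PriorTable | None = None,
    rule: CaseRule | None = None,
) -> float:
    """Disease-progression probability for one evidence pattern.

    Deterministic and total on valid inputs; the output is always either a
    marker prior from the table, the no-diet baseline, or an age-bracket risk.
    """
    if priors is None:
        priors = default_config().priors
    if rule is None:
        rule = CaseRule()

    for marker in rule.marker_priority:
        if getattr(ev, marker):
            return priors.prior(marker)
    if ev.diet == "none":
        return rule.no_diet_baseline
    positive = [m for m in rule.lifestyle_set if getattr(ev, m)]
    if positive:
        return max(priors.prior(m) for m in positive)
    return age_risk(ev.age, priors)


def _pattern(bits: str, diet: str, age: int) -> EvidencePattern:
    flags = dict(zip(MARKERS, (int(b) for b in bits)))
    return EvidencePattern(diet=diet, age=age, **flags)


#: The five published reference evidence patterns (marker bits in column
#: order atp..pa, then diet and age).
TABLE2_PATTERNS: tuple[EvidencePattern, ...] = (
    _pattern("000000101010", "HFO", 63),
    _pattern("111101100101", "HL", 31),
    _pattern("101000000110", "starv", 70),
    _pattern("110101001011", "CR", 86),
    _pattern("000000101000", "none", 80),
)


def reproduce_table2(config: Config | None = None):
    """The five reference rows as a fully derived 5-record cohort."""
    from .cohort import CohortTable, PatientRecord, derive_fusion, derive_fission

    if config is None:
        config = default_config()
    records = []
    for i, ev in enumerate(TABLE2_PATTERNS, start=1):
        markers = ev.markers()
        records.append(
            PatientRecord(
                id=i,
                diet=ev.diet,
                age=ev.age,
                fusion=derive_fusion(markers),
                fission=derive_fission(markers),
                ad_probability=evaluate_ad_probability(
                    ev, config.priors, config.case_rule
                ),
                **markers,
            )
        )
    return CohortTable(
        records=tuple(records), n=5, seed=None, config_digest=config.digest()
    )
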
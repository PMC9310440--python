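"""Static model structure: prior table, signed influence graph, diet modifiers.

The bundled defaults encode the published prior-probability table (per-marker
abnormality rates and age-bracket risks) and the signed directed influence
graph linking diet, biomarkers, mitochondrial fusion/fission and the disease
node.  Everything is overridable from a YAML configuration file; the schema is
documented in the README.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping

import networkx as nx
import yaml

from .errors import ConfigError, DomainError, GraphError

__all__ = [
    "MARKERS",
    "MITO_MARKERS",
    "DIET_CATEGORIES",
    "PriorTable",
    "NetworkSpec",
    "DietModifierTable",
    "SimulationParams",
    "CaseRule",
    "Config",
    "default_config",
    "load_config",
    "write_config",
    "age_risk",
    "validate_dag",
    "effective_probability",
]

#: The twelve binary markers, in the order the cohort table prints them.
MARKERS: tuple[str, ...] = (
    "atp", "opa1", "mfn1", "mfn2", "drp1", "fis1",
    "db", "os", "ht", "ob", "dp", "pa",
)

#: The five mitochondrial-dynamics markers (fusion + fission machinery).
MITO_MARKERS: tuple[str, ...] = ("opa1", "mfn1", "mfn2", "drp1", "fis1")

#: Diet categories.  ``none`` renders as ``0`` in the cohort CSV.
DIET_CATEGORIES: tuple[str, ...] = ("HFO", "HL", "starv", "CR", "none")

_EDGE_SIGNS = ("promoting", "deterrent")


def _check_probability(value: Any, where: str) -> float:
    try:
        p = float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"{where}: expected a number, got {value!r}") from None
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"{where}: probability {p} outside [0, 1]")
    return p


@dataclass(frozen=True)
class PriorTable:
    """Marginal prior probabilities per marker and per age bracket.

    Parameters
    ----------
    marker_priors :
        Map from marker name to its abnormality probability.
    age_bracket_priors :
        Ordered ``((lo, hi), probability)`` pairs with inclusive integer
        bounds; brackets must be disjoint and jointly cover ``age_range``.
    default_prior :
        Probability used for markers absent from ``marker_priors``.
    age_range :
        Inclusive integer age span the brackets must cover.
    """

    marker_priors: Mapping[str, float]
    age_bracket_priors: tuple[tuple[tuple[int, int], float], ...]
    default_prior: float = 0.5
    age_range: tuple[int, int] = (30, 95)

    def __post_init__(self) -> None:
        for name, p in self.marker_priors.items():
            _check_probability(p, f"priors.markers.{name}")
        _check_probability(self.default_prior, "priors.default")
        lo, hi = self.age_range
        covered = set()
        for (a, b), p in self.age_bracket_priors:
            _check_probability(p, f"priors.age_brackets[{a},{b}]")
            if a > b:
                raise ConfigError(f"priors.age_brackets: empty bracket [{a},{b}]")
            span = set(range(a, b + 1))
            if covered & span:
                raise ConfigError(f"priors.age_brackets: bracket [{a},{b}] overlaps another")
            covered |= span
        if covered != set(range(lo, hi + 1)):
            raise ConfigError(
                f"priors.age_brackets: brackets do not exactly cover [{lo},{hi}]"
            )

    def prior(self, marker: str) -> float:
        """Prior abnormality probability for *marker* (default if unlisted)."""
        return float(self.marker_priors.get(marker, self.default_prior))


@dataclass(frozen=True)
class NetworkSpec:
    """Node set and signed directed edges of the influence graph.

    Edge signs are symbolic (``promoting`` raises the child's chance,
    ``deterrent`` suppresses it); quantitative effects live in
    :class:`DietModifierTable`.  ``cpt_overrides`` optionally attaches a full
    parent-conditioned probability table to a marker: each entry maps every
    binary combination of the parent states to a probability.
    """

    nodes: frozenset[str]
    edges: tuple[tuple[str, str, str], ...]
    cpt_overrides: Mapping[str, "CPTOverride"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for parent, child, sign in self.edges:
            if parent not in self.nodes:
                raise GraphError(f"edge ({parent} -> {child}): undeclared node {parent!r}")
            if child not in self.nodes:
                raise GraphError(f"edge ({parent} -> {child}): undeclared node {child!r}")
            if sign not in _EDGE_SIGNS:
                raise GraphError(
                    f"edge ({parent} -> {child}): sign {sign!r} not in {_EDGE_SIGNS}"
                )
        for child, cpt in self.cpt_overrides.items():
            if child not in self.nodes:
                raise GraphError(f"cpt_overrides: undeclared node {child!r}")
            for parent in cpt.parents:
                if parent not in self.nodes:
                    raise GraphError(f"cpt_overrides[{child}]: undeclared parent {parent!r}")
        validate_dag(self)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from((p, c, {"sign": s}) for p, c, s in self.edges)
        return g


@dataclass(frozen=True)
class CPTOverride:
    """Parent-conditioned probability table for one binary node.

    ``table`` must enumerate all ``2**len(parents)`` parent-state tuples
    (e.g. for two parents: ``(0,0), (0,1), (1,0), (1,1)``).
    """

    parents: tuple[str, ...]
    table: Mapping[tuple[int, ...], float]

    def __post_init__(self) -> None:
        k = len(self.parents)
        want = {tuple(int(b) for b in _bits(i, k)) for i in range(2 ** k)}
        got = {tuple(int(b) for b in key) for key in self.table}
        if got != want:
            raise ConfigError(
                f"cpt table over parents {self.parents}: states {sorted(got)} "
                f"do not enumerate all {2 ** k} binary combinations"
            )
        for key, p in self.table.items():
            _check_probability(p, f"cpt[{key}]")

    def probability(self, parent_states: Mapping[str, int]) -> float:
        key = tuple(int(parent_states[p]) for p in self.parents)
        return float(self.table[key])


def _bits(i: int, k: int) -> tuple[int, ...]:
    return tuple((i >> (k - 1 - j)) & 1 for j in range(k))


@dataclass(frozen=True)
class DietModifierTable:
    """Per-diet odds-scale multipliers applied to marker priors.

    A multiplier of 1 is the identity; values above 1 raise the marker's
    effective probability, values below 1 lower it.  The ``none`` diet is
    all-identity by construction.
    """

    modifiers: Mapping[str, Mapping[str, float]]
    diets: tuple[str, ...] = DIET_CATEGORIES

    def __post_init__(self) -> None:
        for diet, table in self.modifiers.items():
            if diet not in self.diets:
                raise ConfigError(f"diet_modifiers: unknown diet {diet!r}")
            for marker, m in table.items():
                if marker not in MARKERS:
                    raise ConfigError(f"diet_modifiers.{diet}: unknown marker {marker!r}")
                if not float(m) > 0:
                    raise ConfigError(f"diet_modifiers.{diet}.{marker}: modifier {m} must be > 0")
        for marker, m in self.modifiers.get("none", {}).items():
            if float(m) != 1.0:
                raise ConfigError(f"diet_modifiers.none.{marker}: 'none' diet must be identity")

    def modifier(self, diet: str, marker: str) -> float:
        if diet not in self.diets:
            raise DomainError(f"unknown diet category {diet!r}")
        return float(self.modifiers.get(diet, {}).get(marker, 1.0))


@dataclass(frozen=True)
class SimulationParams:
    n: int = 1000
    seed: int = 0
    age_range: tuple[int, int] = (30, 95)
    diets: tuple[str, ...] = DIET_CATEGORIES

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"simulation.n: {self.n} must be >= 1")
        if self.age_range[0] > self.age_range[1]:
            raise ConfigError(f"simulation.age_range: empty range {self.age_range}")
        if not self.diets:
            raise ConfigError("simulation.diets: at least one diet category required")


@dataclass(frozen=True)
class CaseRule:
    """Deterministic evidence-to-risk cascade configuration.

    ``marker_priority`` orders the five mitochondrial markers; the risk of the
    highest-priority abnormal one wins.  ``lifestyle_set`` lists the markers
    eligible for the lifestyle fallback.  ``no_diet_baseline`` is returned for
    marker-free patients without a diet intervention.
    """

    marker_priority: tuple[str, ...] = ("opa1", "mfn2", "mfn1", "drp1", "fis1")
    lifestyle_set: tuple[str, ...] = ("ht", "dp", "ob", "pa", "os")
    no_diet_baseline: float = 0.743

    def __post_init__(self) -> None:
        if set(self.marker_priority) != set(MITO_MARKERS):
            raise ConfigError(
                "case_rule.marker_priority must cover exactly the five "
                f"mitochondrial markers {MITO_MARKERS}"
            )
        for m in self.lifestyle_set:
            if m not in MARKERS:
                raise ConfigError(f"case_rule.lifestyle: unknown marker {m!r}")
        _check_probability(self.no_diet_baseline, "case_rule.no_diet_baseline")


@dataclass(frozen=True)
class Config:
    """Bundle of the four validated model tables plus the case rule.

    Unpacks as ``priors, network, diet_modifiers, simulation = config``.
    """

    priors: PriorTable
    network: NetworkSpec
    diet_modifiers: DietModifierTable
    simulation: SimulationParams
    case_rule: CaseRule = field(default_factory=CaseRule)

    def __iter__(self) -> Iterator[Any]:
        return iter((self.priors, self.network, self.diet_modifiers, self.simulation))

    def digest(self) -> str:
        """Stable hex digest of the full configuration (for run metadata)."""
        doc = yaml.safe_dump(_config_to_dict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# bundled defaults

_DEFAULT_MARKER_PRIORS: dict[str, float] = {
    "ht": 0.20,
    "os": 0.275,   # published as a 25-30% range; midpoint
    "ob": 0.034,
    "dp": 0.132,
    "pa": 0.177,
    "drp1": 0.743,
    "opa1": 0.614,
    "mfn1": 0.278,
    "mfn2": 0.336,
    "fis1": 0.60,
}

_DEFAULT_AGE_BRACKETS: tuple[tuple[tuple[int, int], float], ...] = (
    ((30, 64), 0.04),
    ((65, 74), 0.15),
    ((75, 84), 0.43),
    ((85, 95), 0.38),
)

_DEFAULT_NODES = frozenset(
    ("age", "diet", "fusion", "fission", "AD") + MARKERS
)

# Signed influence edges.  'promoting' = parent raises the child's chance,
# 'deterrent' = parent suppresses it.
_DEFAULT_EDGES: tuple[tuple[str, str, str], ...] = (
    ("diet", "os", "deterrent"),
    ("diet", "ob", "promoting"),
    ("diet", "atp", "promoting"),
    ("diet", "opa1", "promoting"),
    ("diet", "mfn1", "promoting"),
    ("diet", "mfn2", "promoting"),
    ("diet", "drp1", "promoting"),
    ("diet", "fis1", "promoting"),
    ("opa1", "fusion", "promoting"),
    ("mfn1", "fusion", "promoting"),
    ("mfn2", "fusion", "promoting"),
    ("drp1", "fission", "promoting"),
    ("fis1", "fission", "promoting"),
    ("fusion", "AD", "deterrent"),
    ("fission", "AD", "promoting"),
    ("age", "AD", "promoting"),
    ("db", "AD", "promoting"),
    ("os", "AD", "promoting"),
    ("ht", "AD", "promoting"),
    ("ob", "AD", "promoting"),
    ("dp", "AD", "promoting"),
    ("pa", "AD", "deterrent"),
    ("atp", "AD", "deterrent"),
)

# Odds multipliers realizing the qualitative diet->marker signs.
# 2.0 for a promoting edge, 0.5 for a deterrent one.
_DEFAULT_DIET_MODIFIERS: dict[str, dict[str, float]] = {
    "HFO": {"os": 0.5, "mfn2": 2.0, "atp": 2.0},
    "HL": {"fis1": 2.0, "ob": 2.0, "mfn2": 0.5},
    "starv": {"mfn1": 2.0, "opa1": 2.0, "atp": 2.0},
    "CR": {"fis1": 2.0, "drp1": 2.0},
    "none": {},
}


def default_config() -> Config:
    """The bundled default model: published priors, influence graph, modifiers."""
    return Config(
        priors=PriorTable(
            marker_priors=dict(_DEFAULT_MARKER_PRIORS),
            age_bracket_priors=_DEFAULT_AGE_BRACKETS,
        ),
        network=NetworkSpec(nodes=_DEFAULT_NODES, edges=_DEFAULT_EDGES),
        diet_modifiers=DietModifierTable(
            modifiers=copy.deepcopy(_DEFAULT_DIET_MODIFIERS)
        ),
        simulation=SimulationParams(),
        case_rule=CaseRule(),
    )


# --------------------------------------------------------------------------
# operations

def age_risk(age: int, priors: PriorTable) -> float:
    """Risk probability of the unique age bracket containing *age*.

    Raises
    ------
    DomainError
        If *age* falls outside the table's configured age range.
    """
    lo, hi = priors.age_range
    if not lo <= age <= hi:
        raise DomainError(f"age {age} outside configured range [{lo}, {hi}]")
    for (a, b), p in priors.age_bracket_priors:
        if a <= age <= b:
            return p
    raise DomainError(f"age {age} not covered by any bracket")  # pragma: no cover


def validate_dag(spec: NetworkSpec) -> list[str]:
    """Topological order of the influence graph; raises on a cycle.

    Returns a node ordering in which every parent precedes its children.

    Raises
    ------
    GraphError
        If the edge list contains a directed cycle (one cycle is reported).
    """
    g = nx.DiGraph()
    g.add_nodes_from(sorted(spec.nodes))
    g.add_edges_from((p, c) for p, c, _ in spec.edges)
    try:
        return list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise GraphError(f"influence graph contains a cycle: {path}") from None


def effective_probability(prior: float, modifier: float) -> float:
    """Apply an odds-scale multiplier to a probability, clamped to [0, 1].

    ``p' = m*odds / (1 + m*odds)`` with ``odds = p/(1-p)``; the endpoints 0
    and 1 are fixed points for every modifier.
    """
    if not 0.0 <= prior <= 1.0:
        raise DomainError(f"prior {prior} outside [0, 1]")
    if not modifier > 0:
        raise DomainError(f"odds modifier {modifier} must be > 0")
    if prior in (0.0, 1.0) or modifier == 1.0:
        return prior
    odds = modifier * prior / (1.0 - prior)
    return odds / (1.0 + odds)


# --------------------------------------------------------------------------
# configuration (de)serialization

def _config_to_dict(config: Config) -> dict[str, Any]:
    return {
        "priors": {
            "markers": {k: float(v) for k, v in sorted(config.priors.marker_priors.items())},
            "age_brackets": [
                {"min": a, "max": b, "probability": float(p)}
                for (a, b), p in config.priors.age_bracket_priors
            ],
            "default": float(config.priors.default_prior),
            "age_range": list(config.priors.age_range),
        },
        "network": {
            "nodes": sorted(config.network.nodes),
            "edges": [
                {"parent": p, "child": c, "sign": s} for p, c, s in config.network.edges
            ],
            "cpt_overrides": {
                child: {
                    "parents": list(cpt.parents),
                    "table": {
                        "".join(str(b) for b in key): float(v)
                        for key, v in sorted(cpt.table.items())
                    },
                }
                for child, cpt in sorted(config.network.cpt_overrides.items())
            },
        },
        "diet_modifiers": {
            diet: {k: float(v) for k, v in sorted(table.items())}
            for diet, table in sorted(config.diet_modifiers.modifiers.items())
        },
        "simulation": {
            "n": config.simulation.n,
            "seed": config.simulation.seed,
            "age_range": list(config.simulation.age_range),
            "diets": list(config.simulation.diets),
        },
        "case_rule": {
            "marker_priority": list(config.case_rule.marker_priority),
            "lifestyle": list(config.case_rule.lifestyle_set),
            "no_diet_baseline": float(config.case_rule.no_diet_baseline),
        },
    }


def write_config(config: Config, path: str) -> None:
    """Serialize *config* to a YAML document at *path*."""
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)


def _as_mapping(value: Any, key: str) -> Mapping[str, Any]:
    if value is None:
        return {}
    if not isinstance(value, Mapping):
        raise ConfigError(f"{key}: expected a mapping, got {type(value).__name__}")
    return value


def load_config(path: str | None = None) -> Config:
    """Load and validate a model configuration.

    ``path=None`` (or a file with missing sections) falls back to the bundled
    defaults section by section.

    Raises
    ------
    ConfigError
        Malformed document, unknown key, or out-of-range probability.
    GraphError
        Cyclic edge list or undeclared edge endpoint.
    """
    base = default_config()
    if path is None:
        return base

    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path!r}: {exc}") from None
    doc = _as_mapping(doc, "config")

    known = {"priors", "network", "diet_modifiers", "simulation", "case_rule"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")

    priors = base.priors
    if "priors" in doc:
        section = _as_mapping(doc["priors"], "priors")
        markers = dict(base.priors.marker_priors)
        markers.update(
            {k: _check_probability(v, f"priors.markers.{k}")
             for k, v in _as_mapping(section.get("markers"), "priors.markers").items()}
        )
        brackets = base.priors.age_bracket_priors
        if "age_brackets" in section:
            brackets = tuple(
                ((int(row["min"]), int(row["max"])),
                 _check_probability(row["probability"], "priors.age_brackets"))
                for row in section["age_brackets"]
            )
        priors = PriorTable(
            marker_priors=markers,
            age_bracket_priors=brackets,
            default_prior=_check_probability(
                section.get("default", base.priors.default_prior), "priors.default"
            ),
            age_range=tuple(section.get("age_range", base.priors.age_range)),
        )

    network = base.network
    if "network" in doc:
        section = _as_mapping(doc["network"], "network")
        nodes = frozenset(section.get("nodes", sorted(base.network.nodes)))
        edges = base.network.edges
        if "edges" in section:
            edges = tuple(
                (row["parent"], row["child"], row.get("sign", "promoting"))
                for row in section["edges"]
            )
        overrides = {}
        for child, spec in _as_mapping(
            section.get("cpt_overrides"), "network.cpt_overrides"
        ).items():
            overrides[child] = CPTOverride(
                parents=tuple(spec["parents"]),
                table={
                    tuple(int(ch) for ch in str(key)): v
                    for key, v in spec["table"].items()
                },
            )
        network = NetworkSpec(nodes=nodes, edges=edges, cpt_overrides=overrides)

    modifiers = base.diet_modifiers
    if "diet_modifiers" in doc:
        merged = copy.deepcopy(dict(base.diet_modifiers.modifiers))
        for diet, table in _as_mapping(doc["diet_modifiers"], "diet_modifiers").items():
            merged[diet] = {k: float(v) for k, v in _as_mapping(table, f"diet_modifiers.{diet}").items()}
        diets = tuple(_as_mapping(doc.get("simulation"), "simulation").get(
            "diets", base.simulation.diets))
        modifiers = DietModifierTable(modifiers=merged, diets=diets)

    simulation = base.simulation
    if "simulation" in doc:
        section = _as_mapping(doc["simulation"], "simulation")
        simulation = SimulationParams(
            n=int(section.get("n", base.simulation.n)),
            seed=int(section.get("seed", base.simulation.seed)),
            age_range=tuple(section.get("age_range", base.simulation.age_range)),
            diets=tuple(section.get("diets", base.simulation.diets)),
        )

    case_rule = base.case_rule
    if "case_rule" in doc:
        section = _as_mapping(doc["case_rule"], "case_rule")
        case_rule = CaseRule(
            marker_priority=tuple(
                section.get("marker_priority", base.case_rule.marker_priority)
            ),
            lifestyle_set=tuple(section.get("lifestyle", base.case_rule.lifestyle_set)),
            no_diet_baseline=float(
                section.get("no_diet_baseline", base.case_rule.no_diet_baseline)
            ),
        )

    return Config(
        priors=priors,
        network=network,
        diet_modifiers=modifiers,
        simulation=simulation,
        case_rule=case_rule,
    )
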
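import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitobayes import (
    ConfigError,
    DomainError,
    GraphError,
    age_risk,
    default_config,
    effective_probability,
    load_config,
    validate_dag,
    write_config,
)
from mitobayes.network_model import (
    CPTOverride,
    CaseRule,
    DietModifierTable,
    NetworkSpec,
    PriorTable,
    SimulationParams,
)

DEFAULT_MARKER_PRIORS = {
    "ht": 0.20,
    "os": 0.275,
    "ob": 0.034,
    "dp": 0.132,
    "pa": 0.177,
    "drp1": 0.743,
    "opa1": 0.614,
    "mfn1": 0.278,
    "mfn2": 0.336,
    "fis1": 0.60,
}

DEFAULT_AGE_BRACKETS = {(30, 64): 0.04, (65, 74): 0.15, (75, 84): 0.43, (85, 95): 0.38}


class TestDefaults:
    def test_marker_priors_match_published_table(self, priors):
        assert dict(priors.marker_priors) == DEFAULT_MARKER_PRIORS

    def test_age_bracket_priors_match_published_table(self, priors):
        assert {bounds: p for bounds, p in priors.age_bracket_priors} == DEFAULT_AGE_BRACKETS

    def test_unlisted_markers_use_default_prior(self, priors):
        assert priors.prior("atp") == 0.5
        assert priors.prior("db") == 0.5

    def test_default_diets(self, config):
        assert config.simulation.diets == ("HFO", "HL", "starv", "CR", "none")


class TestAgeRisk:
    @pytest.mark.parametrize(
        "age,expected",
        [(63, 0.04), (30, 0.04), (64, 0.04), (65, 0.15), (74, 0.15),
         (75, 0.43), (80, 0.43), (84, 0.43), (85, 0.38), (90, 0.38), (95, 0.38)],
    )
    def test_bracket_lookup(self, priors, age, expected):
        assert age_risk(age, priors) == expected

    @pytest.mark.parametrize("age", [29, 96, 120, -5])
    def test_out_of_range_rejected(self, priors, age):
        with pytest.raises(DomainError):
            age_risk(age, priors)

    def test_total_on_configured_range(self, priors):
        values = {p for _, p in priors.age_bracket_priors}
        for age in range(30, 96):
            assert age_risk(age, priors) in values


class TestPriorTableValidation:
    def test_probability_above_one_rejected(self):
        with pytest.raises(ConfigError):
            PriorTable(
                marker_priors={"ht": 1.2},
                age_bracket_priors=(((30, 95), 0.1),),
            )

    def test_overlapping_brackets_rejected(self):
        with pytest.raises(ConfigError):
            PriorTable(
                marker_priors={},
                age_bracket_priors=(((30, 70), 0.1), ((70, 95), 0.2)),
            )

    def test_gap_in_coverage_rejected(self):
        with pytest.raises(ConfigError):
            PriorTable(
                marker_priors={},
                age_bracket_priors=(((30, 60), 0.1), ((62, 95), 0.2)),
            )


class TestLoadConfig:
    def test_bundled_default_has_published_drp1_prior(self):
        config = load_config(None)
        assert config.priors.prior("drp1") == 0.743

    def test_empty_file_equals_defaults(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("{}\n")
        assert load_config(str(path)).digest() == default_config().digest()

    def test_round_trip_is_identity(self, tmp_path, config):
        path = tmp_path / "config.yaml"
        write_config(config, str(path))
        loaded = load_config(str(path))
        assert loaded.priors == config.priors
        assert loaded.network.nodes == config.network.nodes
        assert set(loaded.network.edges) == set(config.network.edges)
        assert loaded.diet_modifiers.modifiers == config.diet_modifiers.modifiers
        assert loaded.simulation == config.simulation
        assert loaded.case_rule == config.case_rule
        assert loaded.digest() == config.digest()

    def test_out_of_range_prior_rejected_with_key_name(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("priors:\n  markers:\n    drp1: 1.2\n")
        with pytest.raises(ConfigError, match="drp1"):
            load_config(str(path))

    def test_unknown_top_level_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("spurious: 1\n")
        with pytest.raises(ConfigError, match="spurious"):
            load_config(str(path))

    def test_cyclic_edges_rejected(self, tmp_path):
        path = tmp_path / "cyclic.yaml"
        path.write_text(
            "network:\n"
            "  nodes: [A, B]\n"
            "  edges:\n"
            "    - {parent: A, child: B, sign: promoting}\n"
            "    - {parent: B, child: A, sign: promoting}\n"
        )
        with pytest.raises(GraphError):
            load_config(str(path))

    def test_malformed_yaml_rejected(self, tmp_path):
        path = tmp_path / "broken.yaml"
        path.write_text("priors: [unclosed\n")
        with pytest.raises(ConfigError):
            load_config(str(path))

    def test_prior_override_merges(self, tmp_path):
        path = tmp_path / "override.yaml"
        path.write_text("priors:\n  markers:\n    os: 0.30\n")
        config = load_config(str(path))
        assert config.priors.prior("os") == 0.30
        assert config.priors.prior("drp1") == 0.743


class TestValidateDag:
    def test_bundled_graph_orders_diet_before_markers_before_ad(self, config):
        order = validate_dag(config.network)
        pos = {node: i for i, node in enumerate(order)}
        assert pos["diet"] < pos["opa1"] < pos["fusion"] < pos["AD"]
        assert pos["drp1"] < pos["fission"] < pos["AD"]

    def test_single_node_no_edges(self):
        spec = NetworkSpec(nodes=frozenset({"A"}), edges=())
        assert validate_dag(spec) == ["A"]

    def test_two_cycle_rejected_at_construction(self):
        with pytest.raises(GraphError, match="cycle"):
            NetworkSpec(
                nodes=frozenset({"A", "B"}),
                edges=(("A", "B", "promoting"), ("B", "A", "promoting")),
            )

    def test_undeclared_endpoint_rejected(self):
        with pytest.raises(GraphError, match="undeclared"):
            NetworkSpec(nodes=frozenset({"A"}), edges=(("A", "B", "promoting"),))


def _has_cycle_bruteforce(n_nodes, edges):
    """Independent oracle: reachability closure via repeated matrix squaring."""
    reach = [[False] * n_nodes for _ in range(n_nodes)]
    for a, b in edges:
        reach[a][b] = True
    for _ in range(n_nodes):
        for i, j, k in itertools.product(range(n_nodes), repeat=3):
            if reach[j][i] and reach[i][k]:
                reach[j][k] = True
    return any(reach[i][i] for i in range(n_nodes))


@settings(max_examples=150, deadline=None)
@given(
    n_nodes=st.integers(min_value=1, max_value=6),
    edge_bits=st.integers(min_value=0, max_value=2**30 - 1),
)
def test_validate_dag_agrees_with_reachability_oracle(n_nodes, edge_bits):
    pairs = [(a, b) for a in range(n_nodes) for b in range(n_nodes) if a != b]
    edges = [pairs[i] for i in range(len(pairs)) if (edge_bits >> i) & 1]
    nodes = frozenset(f"n{i}" for i in range(n_nodes))
    named = tuple((f"n{a}", f"n{b}", "promoting") for a, b in edges)
    if _has_cycle_bruteforce(n_nodes, edges):
        with pytest.raises(GraphError):
            NetworkSpec(nodes=nodes, edges=named)
    else:
        order = validate_dag(NetworkSpec(nodes=nodes, edges=named))
        pos = {node: i for i, node in enumerate(order)}
        assert all(pos[f"n{a}"] < pos[f"n{b}"] for a, b in edges)


class TestEffectiveProbability:
    def test_identity_modifier(self):
        assert effective_probability(0.3, 1.0) == 0.3

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_endpoints_are_fixed_points(self, p):
        assert effective_probability(p, 2.0) == p
        assert effective_probability(p, 0.5) == p

    def test_doubling_odds(self):
        # p=0.5 -> odds 1 -> odds 2 -> p=2/3
        assert effective_probability(0.5, 2.0) == pytest.approx(2 / 3)

    def test_halving_odds(self):
        assert effective_probability(0.5, 0.5) == pytest.approx(1 / 3)

    @given(
        p=st.floats(min_value=0.0, max_value=1.0),
        m=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_output_is_probability(self, p, m):
        assert 0.0 <= effective_probability(p, m) <= 1.0

    def test_nonpositive_modifier_rejected(self):
        with pytest.raises(DomainError):
            effective_probability(0.5, 0.0)


class TestDietModifierTable:
    def test_none_diet_must_be_identity(self):
        with pytest.raises(ConfigError):
            DietModifierTable(modifiers={"none": {"os": 2.0}})

    def test_nonpositive_modifier_rejected(self):
        with pytest.raises(ConfigError):
            DietModifierTable(modifiers={"HL": {"os": -1.0}})

    def test_unknown_marker_rejected(self):
        with pytest.raises(ConfigError):
            DietModifierTable(modifiers={"HL": {"nosuch": 2.0}})

    def test_missing_entries_default_to_identity(self, config):
        assert config.diet_modifiers.modifier("HL", "drp1") == 1.0
        assert config.diet_modifiers.modifier("none", "os") == 1.0


class TestCPTOverride:
    def test_full_enumeration_accepted(self):
        cpt = CPTOverride(
            parents=("db", "ht"),
            table={(0, 0): 0.1, (0, 1): 0.2, (1, 0): 0.3, (1, 1): 0.4},
        )
        assert cpt.probability({"db": 1, "ht": 0}) == 0.3

    def test_missing_combination_rejected(self):
        with pytest.raises(ConfigError):
            CPTOverride(parents=("db", "ht"), table={(0, 0): 0.1, (1, 1): 0.4})


class TestOtherValidation:
    def test_simulation_n_below_one_rejected(self):
        with pytest.raises(ConfigError):
            SimulationParams(n=0)

    def test_case_rule_priority_must_cover_mito_markers(self):
        with pytest.raises(ConfigError):
            CaseRule(marker_priority=("opa1", "mfn2"))
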
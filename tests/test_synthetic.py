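"""Synthetic network, attribute and choice generation."""

import math

import numpy as np
import pytest

from routewalk.environment import validate_attributes
from routewalk.network import to_segment_graph
from routewalk.routing import shortest_distance_route
from routewalk.synthetic import (
    DEFAULT_ATTRIBUTE_PARAMS,
    SyntheticConfig,
    draw_choices,
    generate_network,
    pairwise_design,
    pairwise_observations,
    sample_edge_attributes,
    sample_od_pairs,
    simulate_choices,
    stage_rng,
)


class TestGenerateNetwork:
    def test_rectilinear_grid_shape_and_costs(self):
        """4x4 with zero jitter: 24 edges, angular costs only 0 or 1."""
        cfg = SyntheticConfig(rows=4, cols=4, jitter_std=0.0, seed=1)
        net = generate_network(cfg)
        assert len(net.nodes) == 16
        assert len(net.edges) == 24
        for link in to_segment_graph(net).links:
            assert link.angular_cost == pytest.approx(0.0, abs=1e-9) or \
                link.angular_cost == pytest.approx(1.0, abs=1e-9)

    def test_seed_determinism(self):
        a = generate_network(SyntheticConfig(seed=7))
        b = generate_network(SyntheticConfig(seed=7))
        assert a.nodes == b.nodes
        assert set(a.edges) == set(b.edges)
        for eid in a.edges:
            assert a.edges[eid].geometry == b.edges[eid].geometry
            assert dict(a.edges[eid].attributes) == dict(b.edges[eid].attributes)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="2x2"):
            generate_network(SyntheticConfig(rows=1, cols=5))

    def test_attributes_satisfy_audit_schema(self):
        net = generate_network(SyntheticConfig(seed=3, rows=5, cols=5))
        for eid, edge in net.edges.items():
            validate_attributes(edge.attributes, edge_id=eid)

    def test_attribute_marginals_match_config(self):
        """Monte-Carlo means at n = 10,000 draws sit within 3 SEs of theory."""
        rng = stage_rng(99, "attributes")
        n = 10_000
        length = 100.0  # per-100 m count rates apply directly
        draws = {f: np.empty(n) for f in DEFAULT_ATTRIBUTE_PARAMS}
        for i in range(n):
            rec = sample_edge_attributes(rng, length)
            for f, v in rec.items():
                draws[f][i] = v
        expected = {
            "sidewalk_width": math.exp(math.log(2.0) + 0.30**2 / 2),
            "garbage_bins": 1.5,
            "green_spaces": 0.4 * 1 + 0.4 * 2 + 0.2 * 3,
            "shops": 1.2 / (1.2 + 6.0),
        }
        for f, mu in expected.items():
            x = draws[f]
            se = x.std(ddof=1) / math.sqrt(n)
            assert abs(x.mean() - mu) < 3 * se, f


class TestSampleOdPairs:
    def test_lengths_within_band(self):
        cfg = SyntheticConfig(seed=11, n_od_pairs=50)
        net = generate_network(cfg)
        pairs = sample_od_pairs(net, cfg)
        assert len(pairs) == 50
        for o, d in pairs:
            dist = shortest_distance_route(net, o, d).total_length
            assert 0.5 * cfg.trip_length_scale <= dist <= 2.0 * cfg.trip_length_scale

    def test_seed_determinism(self):
        cfg = SyntheticConfig(seed=21, n_od_pairs=30)
        net = generate_network(cfg)
        assert sample_od_pairs(net, cfg) == sample_od_pairs(net, cfg)

    def test_mean_length_near_target(self):
        """Empirical mean shortest length within 20% of the trip scale."""
        cfg = SyntheticConfig(seed=13, n_od_pairs=200)
        net = generate_network(cfg)
        pairs = sample_od_pairs(net, cfg)
        mean = np.mean(
            [shortest_distance_route(net, o, d).total_length for o, d in pairs]
        )
        assert abs(mean - cfg.trip_length_scale) < 0.2 * cfg.trip_length_scale

    def test_infeasible_target_is_an_error(self):
        cfg = SyntheticConfig(seed=1, rows=3, cols=3, trip_length_scale=1e6,
                              n_od_pairs=5)
        net = generate_network(cfg)
        with pytest.raises(RuntimeError, match="OD pairs"):
            sample_od_pairs(net, cfg)


@pytest.fixture(scope="module")
def cohort():
    cfg = SyntheticConfig(seed=17, n_od_pairs=60)
    net = generate_network(cfg)
    return cfg, net, sample_od_pairs(net, cfg)


class TestSimulateChoices:

    def test_zero_beta_gives_uniform_choices(self, cohort):
        """With beta = 0, each labeled alternative is picked about half the time."""
        cfg, net, od = cohort
        attrs = ["green_spaces"]
        X, pairs = pairwise_design(net, od, attrs)
        n = 2000
        rng = stage_rng(99, "choices")
        picks = np.concatenate(
            [draw_choices(X, np.zeros(1), rng) for _ in range(n // len(od) + 1)]
        )
        share = picks.mean()
        se = math.sqrt(0.25 / len(picks))
        assert abs(share - 0.5) < 3 * se

    def test_strong_preference_dominates(self):
        """A large coefficient on a large attribute gap wins almost surely."""
        X = np.zeros((2000, 2, 1))
        X[:, 0, 0] = 3.0  # greener alternative
        X[:, 1, 0] = 1.0
        rng = np.random.default_rng(2)
        picks = draw_choices(X, np.array([3.0]), rng)
        p_logit = 1.0 / (1.0 + math.exp(-3.0 * 2.0))
        share = (picks == 0).mean()
        se = math.sqrt(p_logit * (1 - p_logit) / 2000)
        assert share > 0.9
        assert abs(share - p_logit) < 3.5 * se

    def test_choice_frequencies_match_logit_closed_form(self, cohort):
        """Empirical pairwise shares track exp(b'dx)/(1+exp(b'dx))."""
        cfg, net, od = cohort
        attrs = sorted(cfg.beta_true)
        beta = np.array([cfg.beta_true[a] for a in attrs])
        X, pairs = pairwise_design(net, od, attrs)
        dx = X[:, 0] - X[:, 1]
        informative = np.abs(dx).sum(axis=1) > 1e-12
        p_first = 1.0 / (1.0 + np.exp(-(dx @ beta)))
        reps = 400
        counts = np.zeros(len(od))
        for r in range(reps):
            rng = np.random.default_rng(30_000 + r)
            counts += draw_choices(X, beta, rng) == 0
        share = counts / reps
        se = np.sqrt(p_first * (1 - p_first) / reps)
        z = (share[informative] - p_first[informative]) / np.maximum(se[informative], 1e-9)
        # essentially all standardized deviations within Monte-Carlo error
        assert np.mean(np.abs(z) < 3.0) > 0.97

    def test_full_chosen_list_is_seed_deterministic(self, cohort):
        cfg, net, od = cohort
        a = simulate_choices(net, od, cfg.beta_true, seed=5)
        b = simulate_choices(net, od, cfg.beta_true, seed=5)
        assert [r.edge_ids for r in a] == [r.edge_ids for r in b]
        c = simulate_choices(net, od, cfg.beta_true, mode="choice-set", seed=5)
        d = simulate_choices(net, od, cfg.beta_true, mode="choice-set", seed=5)
        assert [r.edge_ids for r in c] == [r.edge_ids for r in d]

    def test_choice_set_mode_valid_routes(self, cohort):
        """Choice-set mode returns valid routes on the right OD pairs."""
        cfg, net, od = cohort
        chosen = simulate_choices(net, od[:20], cfg.beta_true, mode="choice-set", seed=9)
        for route, (o, d) in zip(chosen, od[:20]):
            assert route.origin == o
            assert route.destination == d
            assert len(set(route.edge_ids)) == len(route.edge_ids)

    def test_coincident_alternatives_return_common_route(self):
        """When both labels agree the common route is the chosen one."""
        cfg = SyntheticConfig(rows=2, cols=3, jitter_std=0.0, seed=4,
                              trip_length_scale=100.0, n_od_pairs=4)
        net = generate_network(cfg)
        od = [("n00_00", "n00_01")]  # adjacent: single sensible route
        chosen = simulate_choices(net, od, cfg.beta_true, seed=1)
        assert chosen[0].edge_ids == ("h00_00",)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_recovery_within_three_se(self, seed):
        """Estimate on the generation choice set recovers beta_true, n=500."""
        from routewalk.clogit import fit_clogit

        cfg = SyntheticConfig(seed=seed, n_od_pairs=500)
        net = generate_network(cfg)
        od = sample_od_pairs(net, cfg)
        attrs = sorted(cfg.beta_true)
        beta_true = np.array([cfg.beta_true[a] for a in attrs])
        X, _ = pairwise_design(net, od, attrs)
        choices = draw_choices(X, beta_true, stage_rng(seed, "choices"))
        fit = fit_clogit(pairwise_observations(X, choices, attrs), attributes=attrs)
        assert fit.converged
        for b, t, s in zip(fit.beta, beta_true, fit.se):
            assert abs(b - t) < 3 * s
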
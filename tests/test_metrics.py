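"""Network metrics: generosity, reciprocity null, stationarity, tau, types."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coopnet.core import LoggedUpdate, Session, SessionConfig, replay
from coopnet.metrics import (
    behavioural_type_series,
    bidirectional_fraction,
    expected_reciprocity,
    kendall_tau,
    mean_generosity_series,
    normalized_generosity,
    recipients_providers_tau,
    reciprocity_null,
    stationary_average,
    stationary_rounds,
    summarize_series,
)
from coopnet.core import DomainError


def _session_from_rounds(n, round_edges, **config_kwargs):
    """Build a session whose stored rounds follow the given edge sets."""
    config = SessionConfig(n_participants=n, n_rounds=len(round_edges), **config_kwargs)
    events = []
    prev = set()
    for t, edges in enumerate(round_edges, start=1):
        edges = set(edges)
        for e in edges - prev:
            events.append(LoggedUpdate(t, e[0], e[1], "add"))
        for e in prev - edges:
            events.append(LoggedUpdate(t, e[0], e[1], "remove"))
        prev = edges
    states = replay(config, config.participants, events, len(round_edges))
    return Session(config=config, rounds=states, events=events)


class TestGenerosity:
    @pytest.mark.parametrize("g, n, expected", [
        (18, 31, 0.6), (0, 10, 0.0), (9, 10, 1.0),
    ])
    def test_normalized_generosity(self, g, n, expected):
        assert normalized_generosity(g, n) == pytest.approx(expected)

    def test_out_of_range_degree_rejected(self):
        with pytest.raises(DomainError):
            normalized_generosity(10, 10)

    def test_mean_series_hand_built_session(self):
        # 3-node round with edges {(0,1),(1,0),(2,0)}: every node has g=1,
        # so mean normalized generosity is (1/2 + 1/2 + 1/2) / 3 = 0.5
        session = _session_from_rounds(3, [{(0, 1), (1, 0), (2, 0)}],
                                       max_updates_per_round=2)
        series = mean_generosity_series(session)
        assert series[0] == 0.0
        assert series[1] == pytest.approx(0.5)

    def test_complete_digraph_has_density_one(self):
        n = 4
        full = {(i, j) for i in range(n) for j in range(n) if i != j}
        session = _session_from_rounds(n, [full], max_updates_per_round=n - 1)
        assert mean_generosity_series(session)[1] == pytest.approx(1.0)


class TestBidirectional:
    def test_fraction_counts_links_with_reverse(self):
        assert bidirectional_fraction({(1, 2), (2, 1), (1, 3)}) == pytest.approx(2 / 3)

    def test_fully_reciprocal_graph(self):
        assert bidirectional_fraction({(1, 2), (2, 1), (2, 3), (3, 2)}) == 1.0

    def test_star_out_graph_has_none(self):
        assert bidirectional_fraction({(0, i) for i in range(1, 5)}) == 0.0

    def test_dyad_mode(self):
        # one reciprocated dyad out of two connected dyads
        assert bidirectional_fraction({(1, 2), (2, 1), (1, 3)},
                                      mode="dyads") == pytest.approx(1 / 2)

    def test_empty_edge_set_undefined(self):
        with pytest.raises(DomainError):
            bidirectional_fraction(set())


def _enumerate_expected_reciprocity(n, m):
    """Exhaustive average bidirectional fraction over all m-edge digraphs."""
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    fracs = []
    for edges in itertools.combinations(pairs, m):
        edge_set = set(edges)
        fracs.append(sum((j, i) in edge_set for (i, j) in edge_set) / m)
    return sum(fracs) / len(fracs)


class TestReciprocityNull:
    def test_closed_form_small_case(self):
        # n=3, m=2: of the C(6,2)=15 two-edge graphs, 3 are reciprocal pairs
        assert expected_reciprocity(3, 2) == pytest.approx(0.2)
        assert _enumerate_expected_reciprocity(3, 2) == pytest.approx(0.2)

    def test_single_edge_has_no_partner(self):
        assert expected_reciprocity(5, 1) == 0.0

    @pytest.mark.parametrize("n", [3, 4])
    @pytest.mark.parametrize("m", [1, 2, 3, 4])
    def test_closed_form_matches_enumeration(self, n, m):
        assert expected_reciprocity(n, m) == pytest.approx(
            _enumerate_expected_reciprocity(n, m))

    @pytest.mark.parametrize("n, m", [(6, 10), (10, 40), (8, 20)])
    def test_monte_carlo_matches_closed_form(self, n, m):
        result = reciprocity_null(n, m, reps=4000, seed=1)
        se = result.sd / math.sqrt(len(result.samples))
        assert abs(result.mean - result.expected) <= 3 * se

    def test_m_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            reciprocity_null(3, 7)


class TestStationarity:
    def test_constant_series_is_stationary_everywhere(self):
        assert stationary_rounds([2.0] * 6) == set(range(6))

    def test_hand_computed_central_differences(self):
        # series [0,1,2,3,3,3,3,3]: |derivative| = [1,1,1,.5,0,0,0,0],
        # max 1, threshold 0.1 -> stationary rounds are 4..7
        assert stationary_rounds([0, 1, 2, 3, 3, 3, 3, 3]) == {4, 5, 6, 7}

    def test_linear_series_has_no_stationary_rounds(self):
        assert stationary_rounds([0, 1, 2, 3, 4]) == set()

    def test_short_series_rejected(self):
        with pytest.raises(DomainError):
            stationary_rounds([1, 2])

    def test_stationary_average_is_last_window_mean(self):
        assert stationary_average([0, 0, 0, 1, 2, 3, 4, 5], window=5) == 3.0
        assert stationary_average([0.2, 0.6, 0.6, 0.6, 0.6, 0.6]) == pytest.approx(0.6)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(DomainError):
            stationary_average([1, 2, 3], window=5)

    def test_stationary_average_invariant_under_prepending(self):
        series = [0.1, 0.5, 0.58, 0.6, 0.61, 0.6, 0.59, 0.6]
        assert stationary_average(series) == stationary_average([0.0, 0.0] + series)

    def test_summarize_series(self):
        s = summarize_series([0, 1, 2, 3, 3, 3, 3, 3])
        assert s.stationary_mean == pytest.approx(3.0)
        assert s.stationary_rounds == frozenset({4, 5, 6, 7})


def _tau_b_bruteforce(x, y):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (concordant - discordant) / denom


def _tie_term(v):
    from collections import Counter
    return sum(c * (c - 1) / 2 for c in Counter(v).values())


class TestKendallTau:
    def test_identical_series(self):
        assert kendall_tau([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_reversed_series(self):
        assert kendall_tau([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_series_matches_bruteforce(self):
        x, y = [1, 1, 2, 3], [1, 2, 2, 3]
        assert kendall_tau(x, y) == pytest.approx(_tau_b_bruteforce(x, y))

    def test_zero_variance_undefined(self):
        assert kendall_tau([2, 2, 2], [1, 2, 3]) is None

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(2, 30).flatmap(lambda n: st.tuples(
        st.lists(st.integers(0, 8), min_size=n, max_size=n),
        st.lists(st.integers(0, 8), min_size=n, max_size=n))))
    def test_matches_pair_counting_oracle(self, xy):
        x, y = xy
        tau = kendall_tau(x, y)
        if len(set(x)) == 1 or len(set(y)) == 1:
            assert tau is None
        else:
            assert tau == pytest.approx(_tau_b_bruteforce(x, y), abs=1e-12)


class TestBehaviouralTypeSeries:
    def test_reciprocal_network_is_exactly_fair(self):
        session = _session_from_rounds(3, [{(0, 1), (1, 0)}])
        assert behavioural_type_series(session)["mean_series"][1] == pytest.approx(0.0)

    def test_single_edge_mean_zero(self):
        # L = +1 for the donor and -1 for the recipient, mean 0
        session = _session_from_rounds(3, [{(0, 1)}])
        assert behavioural_type_series(session)["mean_series"][1] == pytest.approx(0.0)

    def test_asymmetric_round_hand_value(self):
        # edges {(0,1),(0,2)}: L_0 = 1, L_1 = L_2 = -1, mean -1/3
        session = _session_from_rounds(3, [{(0, 1), (0, 2)}])
        assert behavioural_type_series(session)["mean_series"][1] == pytest.approx(-1 / 3)

    def test_all_isolated_round_undefined(self):
        session = _session_from_rounds(3, [{(0, 1)}])
        assert behavioural_type_series(session)["mean_series"][0] is None


def test_recipients_providers_tau_on_coupled_session():
    """In a session where one participant's g and l grow together, its tau is
    strongly positive."""
    rounds = [
        {(0, 1)},
        {(0, 1), (1, 0)},
        {(0, 1), (1, 0), (0, 2), (2, 0)},
        {(0, 1), (1, 0), (0, 2), (2, 0)},
    ]
    session = _session_from_rounds(3, rounds)
    result = recipients_providers_tau(session)
    # g and l move in lockstep; heavy ties keep tau-b slightly below 1
    assert result["per_participant"][0] > 0.8
    assert result["mean"] is not None


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_uniform_agents_reciprocity_within_null_band(seed):
    """Late rounds of a target-uniform ('uniform_random') session fall inside
    the 95% band of the fixed-edge-count random null: the null is unbiased
    for agents that treat every possible link alike."""
    from coopnet import SessionConfig, simulate_session
    from coopnet.simulate import PRESETS

    config = SessionConfig(n_participants=15, n_rounds=40)
    session = simulate_session(config, PRESETS["uniform_random"], seed=seed)
    state = session.rounds[-1]
    null = reciprocity_null(15, len(state.edges), reps=2000, seed=3)
    lo, hi = null.percentile_band()
    assert lo <= bidirectional_fraction(state.edges) <= hi
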
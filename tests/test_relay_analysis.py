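import math

import numpy as np
import pytest

from bsenm.prominent_modes import CoupledPairList
from bsenm.relay_analysis import (
    NEUTRAL,
    NONE,
    OFF,
    ON,
    SOFTENING,
    STIFFENING,
    ResponseSet,
    build_relay_routes,
    classify_prominent_responses,
    delta_couplings,
    label_on_off,
    union_pair_list,
)
from bsenm.rigidity_graph import RigidityGraph


def _cpl(pairs, category="SS", label=""):
    return CoupledPairList(
        pairs=sorted(pairs), source_modes={}, category=category, state_label=label
    )


def _graph(n, edges, category="SS"):
    K = np.zeros((n, n))
    for i, j, k in edges:
        K[i, j] = K[j, i] = k
    return RigidityGraph(category, K)


def _response(pairs, delta, k_ref=None, k_resp=None, category="SS"):
    delta = np.asarray(delta, dtype=float)
    if k_ref is None:
        k_ref = np.maximum(-delta, 0) + 1.0
        k_resp = k_ref + delta
    return ResponseSet(
        category=category, pairs=list(pairs), k_ref=np.asarray(k_ref, dtype=float),
        k_resp=np.asarray(k_resp, dtype=float), delta_k=delta,
    )


class TestUnionAndDelta:
    def test_union_examples(self):
        assert union_pair_list(_cpl([(1, 5)]), _cpl([(1, 5), (2, 8)])) == [
            (1, 5),
            (2, 8),
        ]
        a = _cpl([(0, 1), (2, 3), (4, 5)])
        b = _cpl([(6, 7), (8, 9), (10, 11), (12, 13)])
        assert len(union_pair_list(a, b)) == 7

    def test_union_random_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = {tuple(sorted(p)) for p in rng.integers(0, 15, size=(8, 2)) if p[0] != p[1]}
            b = {tuple(sorted(p)) for p in rng.integers(0, 15, size=(8, 2)) if p[0] != p[1]}
            got = union_pair_list(_cpl(a), _cpl(b))
            assert got == sorted(a | b)

    def test_union_category_mismatch_errors(self):
        with pytest.raises(ValueError):
            union_pair_list(_cpl([], "SS"), _cpl([], "BB"))

    def test_delta_sign_convention_response_minus_reference(self):
        ref = _graph(10, [(2, 9, 5.0)])
        resp = _graph(10, [])
        rs = delta_couplings(ref, resp, [(2, 9)])
        assert rs.delta_k[0] == -5.0
        rs = label_on_off(rs)
        assert rs.switch[0] == OFF

    def test_delta_zero_when_states_equal(self):
        g = _graph(6, [(0, 3, 1.0), (1, 4, 2.0)])
        rs = delta_couplings(g, g, [(0, 3), (1, 4)])
        np.testing.assert_array_equal(rs.delta_k, 0.0)

    def test_delta_random_subtraction_oracle(self):
        rng = np.random.default_rng(8)
        n = 12
        A = np.triu(rng.uniform(0, 2, (n, n)), 1)
        B = np.triu(rng.uniform(0, 2, (n, n)), 1)
        ref = RigidityGraph("BS", A + A.T)
        resp = RigidityGraph("BS", B + B.T)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)][:30]
        rs = delta_couplings(ref, resp, pairs)
        for (i, j), dk in zip(pairs, rs.delta_k):
            assert dk == pytest.approx(B[i, j] + B.T[i, j] - A[i, j] - A.T[i, j])

    def test_pair_absent_from_both_graphs_warns_and_keeps_zero(self):
        g = _graph(5, [])
        with pytest.warns(UserWarning, match="absent"):
            rs = delta_couplings(g, g, [(0, 4)])
        assert rs.delta_k[0] == 0.0


class TestClassify:
    def test_top_quartile_of_eight(self):
        pairs = [(i, i + 8) for i in range(8)]
        rs = classify_prominent_responses(
            _response(pairs, [1, -2, 3, -4, 5, -6, 7, -8]), percentile=25
        )
        assert rs.klass == [
            NEUTRAL, NEUTRAL, NEUTRAL, NEUTRAL, NEUTRAL, NEUTRAL,
            STIFFENING, SOFTENING,
        ]
        assert rs.percentile_threshold == 7.0

    def test_one_softening_one_stiffening_rest_neutral(self):
        pairs = [(i, i + 9) for i in range(8)]
        rs = classify_prominent_responses(
            _response(pairs, [-10, 10, 0, 0, 0, 0, 0, 0]), percentile=25
        )
        assert rs.klass[0] == SOFTENING and rs.klass[1] == STIFFENING
        assert all(c == NEUTRAL for c in rs.klass[2:])

    def test_ties_at_threshold_are_included(self):
        pairs = [(i, i + 9) for i in range(8)]
        rs = classify_prominent_responses(
            _response(pairs, [5, 5, 5, 1, 1, 1, 1, 1]), percentile=25
        )
        assert rs.klass[:3] == [STIFFENING] * 3

    def test_all_zero_deltas_neutral_with_warning(self):
        pairs = [(0, 2), (1, 3)]
        with pytest.warns(UserWarning):
            rs = classify_prominent_responses(_response(pairs, [0, 0]))
        assert rs.klass == [NEUTRAL, NEUTRAL]
        assert rs.percentile_threshold == 0.0

    def test_random_vectors_match_sort_and_cut_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = int(rng.integers(4, 40))
            dk = np.round(rng.normal(0, 3, size=n), 2)
            pairs = [(i, i + n) for i in range(n)]
            rs = classify_prominent_responses(_response(pairs, dk), percentile=25)
            m = math.ceil(0.25 * n)
            thr = sorted(np.abs(dk), reverse=True)[m - 1]
            for v, c in zip(dk, rs.klass):
                if abs(v) >= thr and v != 0:
                    assert c == (SOFTENING if v < 0 else STIFFENING)
                else:
                    assert c == NEUTRAL

    def test_prominent_count_without_ties(self):
        rng = np.random.default_rng(6)
        for n in (4, 9, 16, 33):
            dk = rng.permutation(np.arange(1, n + 1)) * rng.choice([-1.0, 1.0], n)
            pairs = [(i, i + n) for i in range(n)]
            rs = classify_prominent_responses(_response(pairs, dk), percentile=25)
            assert sum(c != NEUTRAL for c in rs.klass) == math.ceil(0.25 * n)


class TestOnOff:
    @pytest.mark.parametrize(
        "k_ref,k_resp,expect",
        [(4.0, 0.0, OFF), (0.0, 3.0, ON), (2.0, 5.0, NONE), (0.0, 0.0, NONE)],
    )
    def test_switch_labels(self, k_ref, k_resp, expect):
        rs = _response([(0, 1)], [k_resp - k_ref], k_ref=[k_ref], k_resp=[k_resp])
        assert label_on_off(rs).switch[0] == expect

    def test_zero_tolerance_respected(self):
        rs = _response([(0, 1)], [-3.9], k_ref=[4.0], k_resp=[0.1])
        assert label_on_off(rs, zero_tol=0.0).switch[0] == NONE
        rs = _response([(0, 1)], [-3.9], k_ref=[4.0], k_resp=[0.1])
        assert label_on_off(rs, zero_tol=0.2).switch[0] == OFF


def _nodes_response(pairs, klass=None, switch=None):
    n = len(pairs)
    rs = _response(pairs, [1.0] * n)
    rs.klass = klass or [STIFFENING] * n
    rs.switch = switch or [NONE] * n
    return rs


class TestRelayRoutes:
    def test_shared_residue_links_pairs(self):
        routes = build_relay_routes([_nodes_response([(10, 50), (50, 80)])], seq_gap=2)
        assert len(routes) == 1
        assert routes[0].residues == [10, 50, 80]

    def test_nearby_sequence_links_pairs(self):
        routes = build_relay_routes([_nodes_response([(10, 50), (12, 49)])], seq_gap=2)
        assert len(routes) == 1

    def test_gap_beyond_limit_does_not_link(self):
        routes = build_relay_routes([_nodes_response([(10, 50), (13, 60)])], seq_gap=2)
        assert routes == []  # closest residues 3 apart, no size-2 component

    def test_neutral_pairs_excluded_but_on_off_included(self):
        rs = _nodes_response(
            [(5, 20), (6, 40)],
            klass=[NEUTRAL, NEUTRAL],
            switch=[OFF, ON],
        )
        routes = build_relay_routes([rs], seq_gap=2)
        assert len(routes) == 1 and len(routes[0].members) == 2

    def test_planted_chain_recovered_among_isolated_pairs(self):
        chain = [(10 + i, 11 + i) for i in range(6)]
        isolated = [(30, 60), (40, 70), (50, 80), (65, 90), (75, 95)]
        routes = build_relay_routes([_nodes_response(chain + isolated)], seq_gap=0)
        assert len(routes) == 1
        assert len(routes[0].members) == 6
        assert routes[0].residues == list(range(10, 17))

    def test_matches_union_find_oracle_on_random_sets(self, union_find_oracle):
        rng = np.random.default_rng(14)
        for _ in range(30):
            m = int(rng.integers(2, 25))
            pairs = []
            while len(pairs) < m:
                i, j = sorted(rng.integers(0, 60, size=2).tolist())
                if i != j:
                    pairs.append((i, j))
            gap = int(rng.integers(0, 5))
            routes = build_relay_routes([_nodes_response(pairs)], seq_gap=gap)
            oracle = union_find_oracle(pairs, gap)
            # pairs may repeat; compare as residue-pair multisets
            got_sets = sorted(
                [sorted((m_[1], m_[2]) for m_ in r.members) for r in routes]
            )
            oracle_sets = sorted([sorted(pairs[i] for i in g) for g in oracle])
            assert got_sets == oracle_sets

    def test_routes_refine_as_gap_grows(self):
        rng = np.random.default_rng(44)
        pairs = [tuple(sorted(p)) for p in rng.integers(0, 50, size=(15, 2)) if p[0] != p[1]]
        rs = _nodes_response(pairs)
        for g in range(4):
            fine = build_relay_routes([rs], seq_gap=g)
            coarse = build_relay_routes([rs], seq_gap=g + 1)
            coarse_sets = [set(map(tuple, ((m[1], m[2]) for m in r.members))) for r in coarse]
            for r in fine:
                members = {(m[1], m[2]) for m in r.members}
                assert any(members <= cs for cs in coarse_sets)

    def test_invalid_seq_gap_rejected(self):
        with pytest.raises(ValueError):
            build_relay_routes([], seq_gap=5)

    def test_empty_node_set_gives_empty_routes(self):
        assert build_relay_routes([], seq_gap=2) == []


def test_antisymmetry_under_state_swap():
    rng = np.random.default_rng(10)
    n = 14
    A = np.triu(rng.uniform(0, 2, (n, n)) * (rng.random((n, n)) < 0.4), 1)
    B = np.triu(rng.uniform(0, 2, (n, n)) * (rng.random((n, n)) < 0.4), 1)
    ref = RigidityGraph("SS", A + A.T)
    resp = RigidityGraph("SS", B + B.T)
    pairs = sorted(
        {(i, j) for i, j in zip(*np.nonzero(np.triu(A + B, 1)))}
    )
    fwd = label_on_off(
        classify_prominent_responses(delta_couplings(ref, resp, pairs))
    )
    bwd = label_on_off(
        classify_prominent_responses(delta_couplings(resp, ref, pairs))
    )
    np.testing.assert_allclose(bwd.delta_k, -fwd.delta_k)
    swap_c = {SOFTENING: STIFFENING, STIFFENING: SOFTENING, NEUTRAL: NEUTRAL}
    swap_s = {ON: OFF, OFF: ON, NONE: NONE}
    assert bwd.klass == [swap_c[c] for c in fwd.klass]
    assert bwd.switch == [swap_s[s] for s in fwd.switch]


@pytest.mark.parametrize("dummy", [0])
def test_prominent_count_property_hypothesis(dummy):
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False).map(
                lambda v: round(v, 3)
            ),
            min_size=1,
            max_size=40,
        )
    )
    def check(dks):
        pairs = [(i, i + 100) for i in range(len(dks))]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rs = classify_prominent_responses(_response(pairs, dks), percentile=25)
        m = math.ceil(0.25 * len(dks))
        abs_dk = [abs(v) for v in dks]
        thr = sorted(abs_dk, reverse=True)[m - 1]
        n_prom = sum(c != NEUTRAL for c in rs.klass)
        # ties inclusive: at least m prominent unless zeros intrude
        assert n_prom == sum(1 for v in dks if abs(v) >= thr and v != 0)
        assert rs.percentile_threshold == thr

    check()
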
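"""Flooding (breakpoint) and pruning (DPI Level) neighbor selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fphc.bn_model import forward_sample
from fphc.fpns import (
    DPIRanking,
    RelatedSet,
    choose_theta,
    detect_breakpoint,
    dpi_levels,
    flood,
    fpns_all,
    fpns_from_mi,
    mi_vector,
    normal_segment_loglik,
    prune,
    q_statistic,
    related_all,
)
from fphc.mi_core import MIMatrix, exact_mi_matrix
from fphc.synth_fixtures import motif_fixtures, random_cpts, random_tree

from conftest import make_bn


def scan_breakpoint_oracle(values):
    """Independent exhaustive scan of the segmented-Gaussian likelihood ratio,
    written directly on scipy.stats.norm (no shared code with the library)."""

    def loglik(seg):
        mu = np.mean(seg)
        sd = np.sqrt(max(np.var(seg), 1e-12))
        return float(stats.norm(mu, sd).logpdf(seg).sum())

    m = len(values)
    null = loglik(values)
    qs = [2 * (loglik(values[:k]) + loglik(values[k:]) - null) for k in range(1, m)]
    return int(np.argmax(qs)) + 1, np.array(qs)


class TestSegmentLoglik:
    def test_single_value_finite_at_floor(self):
        ll = normal_segment_loglik(np.array([0.1]))
        assert np.isfinite(ll)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi * 1e-12))

    def test_constant_segment_floor_engaged(self):
        assert np.isfinite(normal_segment_loglik(np.array([0.1, 0.1, 0.1])))

    def test_matches_direct_formula(self):
        vals = np.array([0.1, 0.2, 0.3])
        var = vals.var()
        expected = stats.norm(0.2, np.sqrt(var)).logpdf(vals).sum()
        assert normal_segment_loglik(vals) == pytest.approx(float(expected))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normal_segment_loglik(np.array([]))


class TestQStatistic:
    def test_identical_values_give_zero(self):
        vals = np.full(6, 0.2)
        for k in range(1, 6):
            assert q_statistic(vals, k) == pytest.approx(0.0, abs=1e-9)

    def test_two_cluster_vector_peaks_at_boundary(self):
        vals = np.array([0.01, 0.011, 0.012, 0.013, 0.5, 0.51, 0.52, 0.53])
        qs = [q_statistic(vals, k) for k in range(1, 8)]
        assert int(np.argmax(qs)) + 1 == 4

    def test_out_of_range_k(self):
        vals = np.arange(5.0)
        for k in (0, 5, 6):
            with pytest.raises(ValueError):
                q_statistic(vals, k)

    @given(st.lists(st.floats(0, 1), min_size=3, max_size=25))
    @settings(deadline=None, max_examples=100)
    def test_q_nonnegative(self, raw):
        vals = np.sort(np.array(raw))
        for k in range(1, len(vals)):
            assert q_statistic(vals, k) >= -1e-9


class TestDetectBreakpoint:
    def test_documented_example_vector(self):
        raw = np.array([0.001, 0.002, 0.001, 0.002, 0.001, 0.30, 0.32, 0.31])
        result = detect_breakpoint(np.sort(raw))
        assert result.k == 5  # related set = the three high-MI nodes

    def test_all_equal_ties_to_smallest_k(self):
        assert detect_breakpoint(np.full(7, 0.3)).k == 1

    def test_too_short_vector_instructs_caller(self):
        with pytest.raises(ValueError, match="related"):
            detect_breakpoint(np.array([0.1, 0.2]))

    def test_matches_independent_exhaustive_scan(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            m = int(rng.integers(3, 30))
            vals = np.sort(rng.random(m))
            res = detect_breakpoint(vals)
            k_oracle, qs_oracle = scan_breakpoint_oracle(vals)
            assert res.k == k_oracle
            assert np.allclose(res.q_values, qs_oracle, atol=1e-6)


def chain_with_isolated_bn(seed=0):
    """T -> A -> B -> C -> D plus isolated nodes U1, U2, U3 (binary)."""
    nodes = ["T", "A", "B", "C", "D", "U1", "U2", "U3"]
    edges = {("T", "A"), ("A", "B"), ("B", "C"), ("C", "D")}
    cards = {v: 2 for v in nodes}
    rng = np.random.default_rng(seed)
    cpts = {"T": [0.5, 0.5]}
    for child in ["A", "B", "C", "D"]:
        f = rng.uniform(0.8, 0.95)
        cpts[child] = [[f, 1 - f], [1 - f, f]]
    for u in ["U1", "U2", "U3"]:
        p = rng.uniform(0.3, 0.7)
        cpts[u] = [p, 1 - p]
    return make_bn(nodes, edges, cards, cpts)


class TestFlood:
    def test_two_variable_dataset_error_path(self):
        mi = MIMatrix(np.array([[0.0, 0.1], [0.1, 0.0]]), ["A", "B"])
        with pytest.raises(ValueError):
            flood("A", mi)

    def test_chain_plus_isolated_related_set(self):
        mi = exact_mi_matrix(chain_with_isolated_bn())
        related = flood("T", mi)
        assert set(related.members) == {"A", "B", "C", "D"}
        # descending-MI order with the direct neighbor first
        assert related.members[0] == "A"
        assert related.mi_values == sorted(related.mi_values, reverse=True)

    def test_detached_node_excluded_from_every_related_set(self):
        mi = exact_mi_matrix(chain_with_isolated_bn())
        for target in ["T", "A", "B", "C", "D"]:
            assert not set(flood(target, mi).members) & {"U1", "U2", "U3"}


class TestDPILevels:
    def test_singleton_related_set_gets_level_one(self):
        mi = MIMatrix(np.zeros((2, 2)), ["T", "A"])
        ranking = dpi_levels("T", RelatedSet("T", ["A"], [0.0]), mi)
        assert ranking.levels == {"A": 1}

    def test_chain_levels_count_hops(self, chain_bn):
        mi = exact_mi_matrix(chain_bn)
        ranking = dpi_levels("T", related_all("T", mi), mi)
        assert ranking.levels == {"A": 1, "B": 2}

    @pytest.mark.parametrize("seed", range(5))
    def test_tree_direct_neighbors_level_one(self, seed):
        tree = random_tree(7, seed)
        bn = random_cpts(tree, 3, 0.25, seed + 50)
        mi = exact_mi_matrix(bn)
        for target in tree.nodes:
            ranking = dpi_levels(target, related_all(target, mi), mi)
            for nb in set(tree.parents(target)) | set(tree.children(target)):
                assert ranking.levels[nb] == 1
            # structural invariants of the ranking
            members = list(ranking.levels)
            assert ranking.levels[members[0]] == 1
            for i, v in enumerate(members):
                preceding_max = max(
                    [ranking.levels[u] for u in members[:i]], default=0
                )
                assert 1 <= ranking.levels[v] <= preceding_max + 1

    def test_missing_member_rejected(self, chain_bn):
        mi = exact_mi_matrix(chain_bn)
        with pytest.raises(KeyError):
            dpi_levels("T", RelatedSet("T", ["Z"], [0.1]), mi)


class TestChooseTheta:
    @pytest.mark.parametrize(
        "levels, expected",
        [
            ({"a": 1, "b": 1, "c": 2, "d": 2, "e": 2, "f": 3}, 2),  # mode 2
            ({"a": 1, "b": 1, "c": 1}, 2),                          # floored at 2
            ({"a": 1, "b": 1, "c": 3, "d": 3, "e": 2}, 2),          # tie -> smallest
            ({"a": 3, "b": 3, "c": 4, "d": 4}, 3),
        ],
    )
    def test_mode_policy(self, levels, expected):
        assert choose_theta(DPIRanking("T", levels), "mode") == expected

    def test_fixed_policy_passthrough(self):
        assert choose_theta(DPIRanking("T", {"a": 1}), 3) == 3
        with pytest.raises(ValueError):
            choose_theta(DPIRanking("T", {"a": 1}), 0)

    def test_empty_ranking_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            assert choose_theta(DPIRanking("T", {}), "mode") == 2


class TestPrune:
    def test_theta_one_keeps_direct_neighbor_only(self, chain_bn):
        mi = exact_mi_matrix(chain_bn)
        related = related_all("T", mi)
        ranking = dpi_levels("T", related, mi)
        assert prune(related, ranking, 1) == ["A"]

    def test_theta_above_max_level_keeps_everything(self, chain_bn):
        mi = exact_mi_matrix(chain_bn)
        related = related_all("T", mi)
        ranking = dpi_levels("T", related, mi)
        assert prune(related, ranking, 5) == related.members

    def test_monotone_in_theta(self):
        mi = exact_mi_matrix(chain_with_isolated_bn())
        for target in ["T", "A", "B", "C", "D"]:
            related = related_all(target, mi)
            ranking = dpi_levels(target, related, mi)
            for theta in range(1, 7):
                assert set(prune(related, ranking, theta)) <= set(
                    prune(related, ranking, theta + 1)
                )

    def test_duplicate_parents_sibling_survives_theta_one(self):
        # two shared parents over-estimate the T-S correlation: the sibling S
        # ends up at DPI Level 1 and survives the deepest pruning (a known
        # false positive of the method)
        motif = motif_fixtures()["duplicate_parents"]
        bn = random_cpts(motif, 2, 0.15, seed=4)
        mi = exact_mi_matrix(bn)
        related = related_all("T", mi)
        ranking = dpi_levels("T", related, mi)
        assert "S" in prune(related, ranking, 1)


class TestFpnsAll:
    def test_deterministic_for_identical_input(self):
        bn = chain_with_isolated_bn()
        data = forward_sample(bn, 400, seed=9)
        a = fpns_all(data, "mode")
        b = fpns_all(data, "mode")
        assert a.neighbors == b.neighbors and a.theta_used == b.theta_used

    def test_too_few_variables_rejected(self):
        from fphc.bn_model import SampleMatrix

        data = SampleMatrix(np.zeros((10, 3), dtype=int), ["A", "B", "C"])
        with pytest.raises(ValueError):
            fpns_all(data)

    def test_neighbor_sets_subset_of_related_sets(self):
        mi = exact_mi_matrix(chain_with_isolated_bn())
        sets = fpns_from_mi(mi, "mode")
        for t in mi.var_names:
            assert set(sets.neighbors[t]) <= set(flood(t, mi).members)

    def test_symmetrize_union_contains_intersection(self):
        mi = exact_mi_matrix(chain_with_isolated_bn())
        sets = fpns_from_mi(mi, 2)
        assert sets.symmetrize("intersection") <= sets.symmetrize("union")

    def test_runtime_scales_polynomially(self):
        # empirical log-log slope across |V| in {10, 20, 40} on random MI
        # matrices must stay within the quartic worst-case contract
        import time

        rng = np.random.default_rng(0)
        sizes = [10, 20, 40]
        times = []
        for n in sizes:
            raw = rng.random((n, n)) * 0.5
            mi = MIMatrix((raw + raw.T) / 2 - np.diag(np.diag(raw)),
                          [f"X{i}" for i in range(n)])
            reps = []
            for _ in range(3):
                t0 = time.perf_counter()
                fpns_from_mi(mi, "mode")
                reps.append(time.perf_counter() - t0)
            times.append(min(reps))
        slope = np.polyfit(np.log(sizes), np.log(times), 1)[0]
        assert slope < 4.5
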
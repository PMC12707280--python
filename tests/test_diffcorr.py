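import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import comb

from germnet.diffcorr import (
    bh_adjust,
    bipartite_network,
    degree_summary,
    differential_correlation,
    fisher_z,
    fisher_z_test,
    overlap_hypergeom,
    pairwise_spearman,
    to_networkx,
)


def brute_spearman(x, y):
    """Rank-then-Pearson oracle with midranks, independent of the fast path."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def brute_bh_rejections(p, alpha):
    """Largest-j step-up rule: reject the j smallest p with p_(j) <= j*alpha/m."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    j_max = 0
    for j in range(1, m + 1):
        if p[order[j - 1]] <= j * alpha / m:
            j_max = j
    rejected = np.zeros(m, bool)
    rejected[order[:j_max]] = True
    return rejected


def _frames(plant_rows, microbe_rows, samples=None):
    samples = samples or [f"s{i}" for i in range(len(next(iter(plant_rows.values()))))]
    p = pd.DataFrame.from_dict(plant_rows, orient="index")
    m = pd.DataFrame.from_dict(microbe_rows, orient="index")
    p.columns = samples
    m.columns = samples
    return p, m


class TestPairwiseSpearman:
    def test_monotone_transform_gives_one(self):
        p, m = _frames({"pg": [1, 2, 3, 4, 5]}, {"mg": [2, 4, 9, 16, 100]})
        assert pairwise_spearman(p, m).loc["pg", "mg"] == pytest.approx(1.0)

    def test_reversed_order_gives_minus_one(self):
        p, m = _frames({"pg": [1, 2, 3, 4, 5]}, {"mg": [5, 4, 3, 2, 1]})
        assert pairwise_spearman(p, m).loc["pg", "mg"] == pytest.approx(-1.0)

    def test_tied_ranks_hand_value(self):
        p, m = _frames({"pg": [1, 2, 3, 4]}, {"mg": [1, 2, 2, 4]})
        assert pairwise_spearman(p, m).loc["pg", "mg"] == pytest.approx(
            0.9486833, abs=1e-6
        )

    def test_constant_feature_is_missing(self):
        p, m = _frames({"pg": [1, 2, 3, 4]}, {"flat": [7, 7, 7, 7], "ok": [1, 3, 2, 4]})
        table = pairwise_spearman(p, m)
        assert np.isnan(table.loc["pg", "flat"])
        assert not np.isnan(table.loc["pg", "ok"])

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            p = pd.DataFrame(
                rng.integers(0, 6, size=(4, 6)), index=[f"p{i}" for i in range(4)]
            )
            m = pd.DataFrame(
                rng.integers(0, 6, size=(5, 6)), index=[f"m{i}" for i in range(5)]
            )
            table = pairwise_spearman(p, m)
            for pi in p.index:
                for mi in m.index:
                    if p.loc[pi].nunique() == 1 or m.loc[mi].nunique() == 1:
                        continue
                    assert table.loc[pi, mi] == pytest.approx(
                        brute_spearman(p.loc[pi], m.loc[mi]), abs=1e-12
                    )

    def test_requires_four_samples(self):
        p, m = _frames({"pg": [1, 2, 3]}, {"mg": [1, 2, 3]})
        with pytest.raises(ValueError):
            pairwise_spearman(p, m)

    def test_sample_subset(self):
        p, m = _frames({"pg": [1, 2, 3, 4, 99]}, {"mg": [1, 2, 3, 4, -99]})
        table = pairwise_spearman(p, m, sample_subset=["s0", "s1", "s2", "s3"])
        assert table.loc["pg", "mg"] == pytest.approx(1.0)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_maps_to_half_ln_three(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * math.log(3.0))
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_unit_rho_rejected_unless_clamped(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)
        assert np.isfinite(fisher_z(1.0, clamp=True))


class TestFisherZTest:
    def test_closed_form_chain(self):
        z_a, z_b, se, z_stat, p = fisher_z_test(0.9, -0.9, 10, 10)
        assert z_b - z_a == pytest.approx(-2.94444, abs=1e-5)
        assert se == pytest.approx(0.534522, abs=1e-6)
        assert abs(z_stat) == pytest.approx(5.50854, abs=1e-4)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z_stat)), rel=1e-9)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_test(0.1, 0.2, 3, 10)


class TestBhAdjust:
    def test_step_up_enumeration(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.42]), [0.42])

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_p(self, p_values):
        q = bh_adjust(p_values)
        order = np.argsort(p_values, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
        st.floats(0.01, 0.99),
    )
    @settings(max_examples=150, deadline=None)
    def test_rejections_match_bruteforce_at_any_alpha(self, p_values, alpha):
        # skip exact boundary ties: the two implementations compute the same
        # quantity in different floating-point orders
        m = len(p_values)
        grid = np.array([p * m / j for p in p_values for j in range(1, m + 1)])
        assume(np.abs(grid - alpha).min() > 1e-9)
        q = bh_adjust(p_values)
        np.testing.assert_array_equal(q <= alpha, brute_bh_rejections(p_values, alpha))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDifferentialCorrelation:
    def _null_pair_data(self, rng, n_plant=3, n_microbe=3, n=8):
        samples_a = [f"a{i}" for i in range(n)]
        samples_b = [f"b{i}" for i in range(n)]
        block = rng.normal(size=(n_plant, n))
        plant = pd.DataFrame(
            np.hstack([block, block]),
            index=[f"p{i}" for i in range(n_plant)],
            columns=samples_a + samples_b,
        )
        mblock = rng.normal(size=(n_microbe, n))
        microbe = pd.DataFrame(
            np.hstack([mblock, mblock]),
            index=[f"m{i}" for i in range(n_microbe)],
            columns=samples_a + samples_b,
        )
        return plant, microbe, samples_a, samples_b

    def test_identical_conditions_give_null(self, rng):
        plant, microbe, sa, sb = self._null_pair_data(rng)
        table = differential_correlation(plant, microbe, sa, sb)
        np.testing.assert_allclose(table["delta_z"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table["p"], 1.0)
        assert not table["significant"].any()

    def test_condition_swap_negates_delta_z(self, rng):
        plant = pd.DataFrame(rng.normal(size=(4, 16)), index=[f"p{i}" for i in range(4)])
        microbe = pd.DataFrame(rng.normal(size=(3, 16)), index=[f"m{i}" for i in range(3)])
        sa = list(plant.columns[:8])
        sb = list(plant.columns[8:])
        fwd = differential_correlation(plant, microbe, sa, sb)
        rev = differential_correlation(plant, microbe, sb, sa)
        np.testing.assert_allclose(fwd["delta_z"], -rev["delta_z"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)
        np.testing.assert_array_equal(fwd["significant"], rev["significant"])

    def test_planted_switch_detected(self, rng):
        n = 24
        sa = [f"a{i}" for i in range(n)]
        sb = [f"b{i}" for i in range(n)]
        u_a, u_b = rng.normal(size=n), rng.normal(size=n)
        rho = 0.95
        plant_rows = {"planted_p": np.concatenate([u_a, u_b])}
        for i in range(9):
            plant_rows[f"null_p{i}"] = rng.normal(size=2 * n)
        microbe_rows = {
            "planted_m": np.concatenate(
                [
                    rho * u_a + math.sqrt(1 - rho**2) * rng.normal(size=n),
                    -rho * u_b + math.sqrt(1 - rho**2) * rng.normal(size=n),
                ]
            )
        }
        for i in range(9):
            microbe_rows[f"null_m{i}"] = rng.normal(size=2 * n)
        plant = pd.DataFrame.from_dict(plant_rows, orient="index")
        plant.columns = sa + sb
        microbe = pd.DataFrame.from_dict(microbe_rows, orient="index")
        microbe.columns = sa + sb
        table = differential_correlation(plant, microbe, sa, sb)
        hit = table.set_index(["plant_feature", "microbial_feature"]).loc[
            ("planted_p", "planted_m")
        ]
        assert hit["significant"]
        assert hit["delta_z"] < -1

    def test_untestable_pairs_excluded_from_family(self, rng):
        plant, microbe, sa, sb = self._null_pair_data(rng)
        plant.loc["flat"] = 1.0
        table = differential_correlation(plant, microbe, sa, sb)
        assert "flat" not in set(table["plant_feature"])
        assert len(table) == 9  # 3x3 testable pairs only

    def test_small_condition_rejected(self, rng):
        plant, microbe, sa, sb = self._null_pair_data(rng)
        with pytest.raises(ValueError):
            differential_correlation(plant, microbe, sa[:3], sb)


class TestBipartiteNetwork:
    def _table(self):
        return pd.DataFrame(
            [[0.9, 0.71], [0.69, -0.95]],
            index=["p1", "p2"],
            columns=["m1", "m2"],
        )

    def test_all_below_threshold(self):
        edges = bipartite_network(self._table(), rho_threshold=0.99)
        assert len(edges) == 0

    def test_signed_threshold_counts(self):
        edges = bipartite_network(self._table(), rho_threshold=0.7)
        assert len(edges) == 2
        assert set(zip(edges["plant_feature"], edges["microbial_feature"])) == {
            ("p1", "m1"),
            ("p1", "m2"),
        }

    def test_absolute_threshold_flag(self):
        edges = bipartite_network(self._table(), rho_threshold=0.7, use_abs=True)
        assert len(edges) == 3

    def test_focus_feature_yields_star(self):
        table = pd.DataFrame(
            [[0.9, 0.1], [0.8, 0.9], [0.75, 0.2]],
            index=["p1", "p2", "p3"],
            columns=["hub", "other"],
        )
        edges = bipartite_network(table, rho_threshold=0.7, restrict_to="hub")
        assert set(edges["microbial_feature"]) == {"hub"}
        summary = degree_summary(edges)
        hub_degree = summary.loc[summary["feature"] == "hub", "degree"].item()
        assert hub_degree == 3

    def test_networkx_export(self):
        g = to_networkx(bipartite_network(self._table(), rho_threshold=0.7))
        assert g.number_of_edges() == 2
        assert g.nodes["p1"]["bipartite"] == "plant"


class TestOverlapHypergeom:
    def test_saturation(self):
        universe = set(range(10))
        k, p = overlap_hypergeom(universe, universe, universe, tail="lower")
        assert k == 10
        assert p == pytest.approx(1.0)

    def test_direct_combinatorics(self):
        universe = set(range(10))
        a = set(range(5))
        b = set(range(5, 9))
        k, p = overlap_hypergeom(a, b, universe, tail="lower")
        assert k == 0
        assert p == pytest.approx(comb(5, 4) / comb(10, 4))

    def test_pmf_normalizes(self):
        total = sum(
            stats.hypergeom(M=10, n=5, N=4).pmf(k) for k in range(0, 5)
        )
        assert total == pytest.approx(1.0)

    def test_upper_tail_matches_enumeration(self):
        universe = set(range(8))
        a = set(range(4))
        b = {0, 1, 4, 5}
        k, p = overlap_hypergeom(a, b, universe, tail="upper")
        dist = stats.hypergeom(M=8, n=4, N=4)
        expected = sum(dist.pmf(j) for j in range(k, 5))
        assert p == pytest.approx(expected)

    def test_containment_enforced(self):
        with pytest.raises(ValueError):
            overlap_hypergeom({1, 99}, {1}, set(range(10)))
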
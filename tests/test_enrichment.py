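import math

import numpy as np
import pandas as pd
import pytest

from thermoadapt import (
    binomial_enrichment,
    enrichment_score,
    filter_sets,
    ranked_enrichment,
)
from thermoadapt.enrichment import RankedEnrichment


def exact_binomial_tail(k, n, q):
    """Independent oracle: direct summation of the binomial upper tail."""
    return sum(
        math.comb(n, j) * q**j * (1 - q) ** (n - j) for j in range(k, n + 1)
    )


def brute_force_es(deltas: pd.Series, members, p=1.0):
    """Independent oracle: walk the full ranking accumulating the running sum."""
    ranked = deltas.sort_values(ascending=False)
    member_set = set(members)
    w = np.abs(ranked.to_numpy()) ** p
    total = sum(w[i] for i, g in enumerate(ranked.index) if g in member_set)
    n_miss = len(ranked) - len(member_set & set(ranked.index))
    running, best = 0.0, 0.0
    for i, g in enumerate(ranked.index):
        if g in member_set:
            running += w[i] / total
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestFilterSets:
    def test_boundary_15_removed_16_retained(self):
        universe = [f"g{i}" for i in range(100)]
        sets = {"fifteen": universe[:15], "sixteen": universe[:16]}
        kept = filter_sets(sets, universe)
        assert "fifteen" not in kept
        assert "sixteen" in kept

    def test_intersect_then_threshold(self):
        universe = [f"g{i}" for i in range(100)]
        # 30 members but only 10 inside the universe -> removed
        sets = {"mixed": universe[:10] + [f"x{i}" for i in range(20)]}
        assert filter_sets(sets, universe) == {}

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            filter_sets({"a": ["g1"]}, [])


class TestBinomialEnrichment:
    def test_worked_tail_example(self):
        # N=100, K=10, n=10, k=5 -> sum_{j>=5} C(10,j) 0.1^j 0.9^(10-j)
        universe = [f"g{i}" for i in range(100)]
        sets = {"s": universe[:10] + universe[50:56]}  # pad to pass size filter
        # use min_size=10 and a 10-gene set to match the worked numbers
        sets = {"s": universe[:10]}
        selected = universe[5:10] + universe[20:25]  # overlap k=5
        (res,) = binomial_enrichment(selected, sets, universe, min_size=10)
        assert res.statistic == 5
        assert res.p == pytest.approx(exact_binomial_tail(5, 10, 0.1), rel=1e-12)
        assert res.p == pytest.approx(1.635e-3, rel=0.01)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        sets = {"s": universe[:20]}
        res = binomial_enrichment(universe[20:30], sets, universe)[0]
        assert res.statistic == 0
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_saturated_selection(self):
        universe = [f"g{i}" for i in range(40)]
        sets = {"s": universe[:16]}
        (res,) = binomial_enrichment(universe, sets, universe)
        assert res.statistic == 16
        assert res.p == pytest.approx(exact_binomial_tail(16, 40, 0.4), rel=1e-12)

    def test_matches_oracle_on_small_universes(self):
        # spot-grid of (N, K, n, k); the full N<=50 sweep runs in acceptance
        universe_pool = [f"g{i}" for i in range(50)]
        for N in (10, 23, 50):
            universe = universe_pool[:N]
            for K in (1, N // 3, N - 1):
                for n in (1, N // 2, N):
                    sets = {"s": universe[:K]}
                    selected = universe[:n]
                    (res,) = binomial_enrichment(
                        selected, sets, universe, min_size=1
                    )
                    k = len(set(universe[:K]) & set(selected))
                    assert res.p == pytest.approx(
                        exact_binomial_tail(k, n, K / N), abs=1e-12
                    )

    def test_bonferroni_multiplier(self):
        universe = [f"g{i}" for i in range(100)]
        sets = {f"s{i}": universe[i : i + 20] for i in range(5)}
        results = binomial_enrichment(universe[:10], sets, universe)
        for r in results:
            assert r.adjusted == pytest.approx(min(1.0, r.p * 5))

    def test_selection_outside_universe_errors(self):
        with pytest.raises(ValueError, match="alien"):
            binomial_enrichment(
                ["alien"], {"s": ["g1"] * 1}, [f"g{i}" for i in range(20)]
            )


class TestEnrichmentScore:
    def test_hand_enumerated_toy(self):
        # ranking g1..g5 with deltas 3,2,1,-1,-2
        # set {g1,g3}: hits at ranks 1,3 -> running sum peaks at 3/4 = 0.75
        # set {g4,g5}: all decrements first -> trough at -1.0
        deltas = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0],
                           index=["g1", "g2", "g3", "g4", "g5"])
        assert enrichment_score(deltas, ["g1", "g3"]) == pytest.approx(0.75)
        assert enrichment_score(deltas, ["g4", "g5"]) == pytest.approx(-1.0)

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(10, 200))
            deltas = pd.Series(
                rng.normal(size=n), index=[f"g{i}" for i in range(n)]
            )
            k = int(rng.integers(2, n // 2))
            members = list(rng.choice(deltas.index, size=k, replace=False))
            assert enrichment_score(deltas, members) == pytest.approx(
                brute_force_es(deltas, members), abs=1e-12
            )

    def test_matches_external_reference_implementation(self):
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(1)
        deltas = pd.Series(
            np.sort(rng.normal(size=80))[::-1], index=[f"g{i}" for i in range(80)]
        )
        sets = {
            "A": [f"g{i}" for i in range(0, 30, 3)],
            "B": [f"g{i}" for i in range(50, 80, 2)],
        }
        res = gseapy.prerank(
            rnk=deltas, gene_sets=sets, min_size=1, max_size=100,
            permutation_num=4, weight=1.0, seed=0, outdir=None, no_plot=True,
        ).res2d.set_index("Term")
        for name, members in sets.items():
            assert enrichment_score(deltas, members) == pytest.approx(
                float(res.loc[name, "ES"]), abs=1e-6
            )

    def test_weight_zero_invariant_to_monotone_rescale(self):
        rng = np.random.default_rng(3)
        deltas = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        members = [f"g{i}" for i in range(0, 50, 7)]
        es = enrichment_score(deltas, members, weight_exponent=0.0)
        rescaled = np.exp(deltas / 3.0) * 100  # strictly monotone
        assert enrichment_score(rescaled, members, weight_exponent=0.0) == pytest.approx(
            es, abs=1e-12
        )


class TestRankedEnrichment:
    def test_perfect_enrichment_has_minimal_p(self):
        rng = np.random.default_rng(4)
        deltas = pd.Series(
            np.sort(rng.normal(size=300))[::-1],
            index=[f"g{i}" for i in range(300)],
        )
        top = list(deltas.index[:20])
        n_perm = 500
        (res,) = ranked_enrichment(deltas, {"top": top}, n_perm=n_perm, seed=1)
        assert res.direction == "up"
        assert res.statistic > 0.9
        # at the permutation floor: no null excursion reaches the observed ES
        assert res.p <= 0.01

    def test_null_set_is_unremarkable(self):
        rng = np.random.default_rng(5)
        deltas = pd.Series(rng.normal(size=400), index=[f"g{i}" for i in range(400)])
        members = list(rng.choice(deltas.index, size=25, replace=False))
        (res,) = ranked_enrichment(deltas, {"s": members}, n_perm=300, seed=2)
        assert res.p > 0.001

    def test_type_one_error_calibrated(self):
        # 200 random sets against one ranking: nominal 0.05 within [0.02, 0.10]
        rng = np.random.default_rng(6)
        deltas = pd.Series(
            rng.normal(size=1000), index=[f"g{i}" for i in range(1000)]
        )
        sets = {
            f"null{j}": list(rng.choice(deltas.index, size=30, replace=False))
            for j in range(200)
        }
        results = ranked_enrichment(deltas, sets, n_perm=1000, seed=3)
        frac = np.mean([r.p < 0.05 for r in results])
        assert 0.02 <= frac <= 0.10

    def test_direction_matches_sign(self):
        deltas = pd.Series(
            np.linspace(3, -3, 100), index=[f"g{i}" for i in range(100)]
        )
        sets = {"up": [f"g{i}" for i in range(16)],
                "down": [f"g{i}" for i in range(84, 100)]}
        results = {r.name: r for r in ranked_enrichment(deltas, sets, n_perm=200,
                                                        seed=4)}
        assert results["up"].direction == "up"
        assert results["down"].direction == "down"

    def test_zero_length_ranking_errors(self):
        with pytest.raises(ValueError):
            ranked_enrichment(pd.Series(dtype=float), {"s": ["g"]})

    def test_low_n_perm_logs_warning(self, caplog):
        deltas = pd.Series(
            np.random.default_rng(7).normal(size=100),
            index=[f"g{i}" for i in range(100)],
        )
        with caplog.at_level("WARNING"):
            ranked_enrichment(deltas, {"s": list(deltas.index[:20])}, n_perm=50,
                              seed=5)
        assert any("n_perm" in r.message for r in caplog.records)

    def test_planted_set_flagged_others_calibrated(self, default_dataset,
                                                   default_profiles):
        # both structural requirements: the planted regulon-derived set is
        # detected, random sets are not flooded with false positives
        ds = default_dataset
        delta = default_profiles["Anc_hs"] - default_profiles["Anc_r"]
        results = ranked_enrichment(delta, ds.genesets, n_perm=500, seed=6)
        by_name = {r.name: r for r in results}
        assert by_name["planted_hs"].p < 0.01
        null_ps = [r.p for r in results if r.name != "planted_hs"]
        assert np.mean([p < 0.05 for p in null_ps]) <= 0.15
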
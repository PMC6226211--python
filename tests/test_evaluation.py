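"""Simulated profiles, rank statistics, PR curves and AUPR conventions."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chemgen.containers import AnnotationMatrix, GeneticInteractionMatrix
from chemgen.evaluation import (average_precision, braun_blanquet,
                                effective_rank, gold_rank_significance,
                                per_term_aupr, rank_terms, simulate_profiles,
                                top1_accuracy, top_prediction_pr)


def _gi(values):
    values = np.asarray(values, dtype=float)
    return GeneticInteractionMatrix(pd.DataFrame(
        values, index=[f"s{i}" for i in range(values.shape[0])],
        columns=[f"q{j}" for j in range(values.shape[1])]))


def _ann(membership, genes, terms):
    return AnnotationMatrix(pd.DataFrame(membership, index=genes, columns=terms))


class TestSimulateProfiles:
    def test_zero_noise_copies_parents(self, rng):
        gi = _gi(rng.standard_normal((6, 4)))
        sim = simulate_profiles(gi, replicates=2, variance_multiplier=0.0,
                                seed=0)
        for pid, parent in sim.parent_query.items():
            np.testing.assert_array_equal(sim.profiles.scores[pid].values,
                                          gi.scores[parent].values)

    def test_profile_count(self, rng):
        gi = _gi(rng.standard_normal((5, 7)))
        sim = simulate_profiles(gi, replicates=3, seed=1)
        assert sim.profiles.n_conditions() == 21
        assert (sim.profiles.condition_types == "treatment").all()

    def test_noise_variance_matches_multiplier(self):
        rng = np.random.default_rng(2)
        gi = _gi(rng.standard_normal((3, 400)))
        multiplier = 2.0
        sim = simulate_profiles(gi, replicates=1,
                                variance_multiplier=multiplier, seed=3)
        noise = sim.profiles.scores.values - gi.scores.values
        for i in range(3):
            target = multiplier * gi.scores.values[i].var(ddof=1)
            observed = noise[i].var(ddof=1)
            # sample variance of n Gaussians: se = target * sqrt(2/(n-1))
            se = target * np.sqrt(2 / (noise.shape[1] - 1))
            assert abs(observed - target) <= 3 * se

    def test_terms_inherited_from_parent(self, rng):
        gi = _gi(rng.standard_normal((4, 4)))
        ann = _ann([[1, 0], [1, 0], [0, 1], [0, 1]],
                   [f"q{j}" for j in range(4)], ["T0", "T1"])
        sim = simulate_profiles(gi, replicates=2, seed=4, ann=ann)
        for pid, parent in sim.parent_query.items():
            expected = {t for t in ann.term_ids if parent in ann.genes_of(t)}
            assert sim.inherited_terms[pid] == expected


class TestRankOrder:
    def test_total_order_keys(self):
        p = pd.Series([0.2, 0.1, 0.1, 0.1], index=["T3", "T2", "T0", "T1"])
        z = pd.Series([9.0, 5.0, 5.0, 7.0], index=["T3", "T2", "T0", "T1"])
        # p asc, then z desc, then id asc: T1(0.1,7), T0(0.1,5), T2(0.1,5), T3
        assert list(rank_terms(p, z)) == ["T1", "T0", "T2", "T3"]


class TestTopPredictionPr:
    def _frames(self, rows):
        p = pd.DataFrame({k: [r[k][0] for r in rows.values()]
                          for k in rows[list(rows)[0]]}, index=list(rows))
        z = pd.DataFrame({k: [r[k][1] for r in rows.values()]
                          for k in rows[list(rows)[0]]}, index=list(rows))
        return p, z

    def test_tp_then_fp(self):
        rows = {
            "a": {"T0": (0.01, 5.0), "T1": (0.5, 1.0)},
            "b": {"T0": (0.9, 0.1), "T1": (0.02, 4.0)},
        }
        p, z = self._frames(rows)
        gold = pd.Series([frozenset({"T0"}), frozenset({"T0"})],
                         index=["a", "b"])
        table = top_prediction_pr(p, z, gold)
        assert table["hit"].tolist() == [True, False]
        np.testing.assert_allclose(table["precision"], [1.0, 0.5])
        assert table["recall"].tolist() == [1, 1]
        assert top1_accuracy(table) == 0.5

    def test_all_true_positives(self):
        rows = {
            "a": {"T0": (0.01, 5.0), "T1": (0.5, 1.0)},
            "b": {"T0": (0.02, 4.0), "T1": (0.8, 0.5)},
        }
        p, z = self._frames(rows)
        gold = pd.Series([frozenset({"T0"}), frozenset({"T0"})],
                         index=["a", "b"])
        table = top_prediction_pr(p, z, gold)
        assert (table["precision"] == 1.0).all()
        assert top1_accuracy(table) == 1.0

    def test_accuracy_matches_recount_oracle(self, rng):
        n_prof, n_terms = 12, 6
        index = [f"prof{i}" for i in range(n_prof)]
        terms = [f"T{t}" for t in range(n_terms)]
        p = pd.DataFrame(rng.random((n_prof, n_terms)), index=index,
                         columns=terms)
        z = pd.DataFrame(rng.standard_normal((n_prof, n_terms)), index=index,
                         columns=terms)
        gold = pd.Series([frozenset(rng.choice(terms, 2, replace=False))
                          for _ in index], index=index)
        table = top_prediction_pr(p, z, gold)
        hits = sum(rank_terms(p.loc[i], z.loc[i])[0] in gold[i] for i in index)
        assert table["recall"].iloc[-1] == hits
        assert top1_accuracy(table) == pytest.approx(hits / n_prof)


class TestGoldRankSignificance:
    def test_unique_smallest_p_is_rank_one(self):
        p = pd.Series([0.001, 0.5, 0.8], index=["T0", "T1", "T2"])
        z = pd.Series([5.0, 1.0, 0.5], index=["T0", "T1", "T2"])
        rank, _ = gold_rank_significance(p, z, "T0", n_shuffles=100, seed=0)
        assert rank == 1

    def test_empirical_p_matches_analytic_law(self, rng):
        # with distinct scores, P(shuffled rank <= r) = r / n_terms
        n_terms = 20
        terms = [f"T{t:02d}" for t in range(n_terms)]
        p = pd.Series(np.sort(rng.random(n_terms)), index=terms)
        z = pd.Series(rng.standard_normal(n_terms), index=terms)
        for gold in ("T04", "T09"):
            rank, emp = gold_rank_significance(p, z, gold, n_shuffles=20_000,
                                               seed=5)
            expected = rank / n_terms
            se = np.sqrt(expected * (1 - expected) / 20_000)
            assert emp == pytest.approx(expected, abs=4 * se)

    def test_all_tied_scores_give_p_one(self):
        # with every (p, z) identical the id tie-break fixes the rank, so
        # every shuffle reproduces it and the empirical p is exactly 1
        terms = ["T0", "T1", "T2", "T3"]
        p = pd.Series(0.5, index=terms)
        z = pd.Series(1.0, index=terms)
        rank, emp = gold_rank_significance(p, z, "T2", n_shuffles=2000, seed=6)
        assert rank == 3  # deterministic id tie-break
        assert emp == 1.0


class TestEffectiveRank:
    def _setup(self):
        genes = [f"g{j}" for j in range(8)]
        membership = {
            "Tgold": [1, 1, 1, 1, 0, 0, 0, 0],
            "Thalf": [1, 1, 0, 0, 1, 1, 0, 0],  # overlap 2/4 = 0.5
            "Tfar": [0, 0, 0, 0, 0, 1, 1, 1],  # overlap 0/... = 0
        }
        ann = _ann(pd.DataFrame(membership, index=genes).values.tolist(),
                   genes, list(membership))
        return ann

    def test_related_term_ranked_better(self):
        ann = self._setup()
        p = pd.Series([0.5, 0.01, 0.1], index=["Tgold", "Thalf", "Tfar"])
        z = pd.Series([1.0, 3.0, 2.0], index=["Tgold", "Thalf", "Tfar"])
        # order: Thalf(1), Tfar(2), Tgold(3); Thalf overlaps 0.5 >= 0.4
        assert effective_rank(p, z, "Tgold", ann, 0.4) == 1

    def test_no_related_terms_falls_back_to_gold(self):
        ann = self._setup()
        p = pd.Series([0.5, 0.01, 0.1], index=["Tgold", "Thalf", "Tfar"])
        z = pd.Series([1.0, 3.0, 2.0], index=["Tgold", "Thalf", "Tfar"])
        assert effective_rank(p, z, "Tgold", ann, 0.6) == 3

    def test_threshold_one_without_nesting(self):
        ann = self._setup()
        p = pd.Series([0.3, 0.01, 0.1], index=["Tgold", "Thalf", "Tfar"])
        z = pd.Series([1.0, 3.0, 2.0], index=["Tgold", "Thalf", "Tfar"])
        assert effective_rank(p, z, "Tgold", ann, 1.0) == 3


class TestAupr:
    def test_perfect_ranking(self):
        # 2 positives of 4 ranked first: AP 1, random 0.5, normalized 2
        assert average_precision([1, 1, 0, 0]) == pytest.approx(1.0)
        profiles = ["a", "b", "c", "d"]
        p = pd.Series([0.01, 0.02, 0.5, 0.9], index=profiles)
        z = pd.Series([4.0, 3.0, 1.0, 0.1], index=profiles)
        assert per_term_aupr(p, z, {"a", "b"}) == pytest.approx(2.0)

    def test_positives_last(self):
        # AP = (1/3 + 2/4)/2 = 5/12; normalized by 1/2 -> 5/6
        assert average_precision([0, 0, 1, 1]) == pytest.approx(5 / 12)
        profiles = ["a", "b", "c", "d"]
        p = pd.Series([0.01, 0.02, 0.5, 0.9], index=profiles)
        z = pd.Series([4.0, 3.0, 1.0, 0.1], index=profiles)
        assert per_term_aupr(p, z, {"c", "d"}) == pytest.approx(5 / 6)

    def test_exhaustive_against_brute_force(self):
        # every binary list of length <= 8 with >= 1 positive
        for n in range(1, 9):
            for labels in itertools.product([0, 1], repeat=n):
                if not any(labels):
                    continue
                tp = 0
                precisions = []
                for i, lab in enumerate(labels, start=1):
                    tp += lab
                    if lab:
                        precisions.append(tp / i)
                assert average_precision(labels) == pytest.approx(
                    sum(precisions) / len(precisions))

    def test_random_scores_average_near_one(self, rng):
        # normalized AUPR of random rankings hovers around chance = 1
        # (average precision carries a small upward finite-list bias, which
        # shrinks as the list grows; 300 profiles keeps it under ~6%)
        n, n_pos = 300, 75
        values = []
        profiles = [f"p{i}" for i in range(n)]
        positives = set(profiles[:n_pos])
        for _ in range(60):
            p = pd.Series(rng.random(n), index=profiles)
            z = pd.Series(rng.standard_normal(n), index=profiles)
            values.append(per_term_aupr(p, z, positives))
        assert np.mean(values) == pytest.approx(1.0, abs=0.12)

    def test_no_positives_rejected(self):
        p = pd.Series([0.1], index=["a"])
        z = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            per_term_aupr(p, z, set())


class TestBraunBlanquet:
    @pytest.mark.parametrize("a, b, expected", [
        ({1, 2, 3}, {2, 3, 4, 5}, 0.5),
        ({1, 2}, {1, 2}, 1.0),
        ({1}, {2}, 0.0),
    ])
    def test_values(self, a, b, expected):
        assert braun_blanquet(a, b) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            braun_blanquet(set(), {1})

    def test_never_exceeds_overlap_index(self, rng):
        from chemgen.annotations import overlap_index
        for _ in range(20):
            a = set(rng.choice(30, rng.integers(1, 10), replace=False))
            b = set(rng.choice(30, rng.integers(1, 10), replace=False))
            assert braun_blanquet(a, b) <= overlap_index(a, b) + 1e-12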
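"""Null statistics: control/within z and empirical p, combination rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chemgen.containers import AnnotationMatrix
from chemgen.significance import (SOURCES, SourceStats, Z_SENTINEL,
                                  combine_statistics, control_statistics,
                                  within_statistics)


def _frame(values, prefix_r="c", prefix_c="T"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return pd.DataFrame(values,
                        index=[f"{prefix_r}{i}" for i in range(values.shape[0])],
                        columns=[f"{prefix_c}{j}" for j in range(values.shape[1])])


def _ann(membership, genes, terms):
    return AnnotationMatrix(pd.DataFrame(membership, index=genes, columns=terms))


class TestControlStatistics:
    def test_score_at_the_control_mean(self):
        stats = control_statistics(_frame([[2.0]]), _frame([[1.0], [3.0]]),
                                   "control")
        assert stats.z.iat[0, 0] == pytest.approx(0.0)

    def test_hand_mean_sd(self):
        # controls [1,3]: mean 2, sample sd sqrt(2); X=5 -> z=3/sqrt(2), p=0
        stats = control_statistics(_frame([[5.0]]), _frame([[1.0], [3.0]]),
                                   "control")
        assert stats.z.iat[0, 0] == pytest.approx(3 / np.sqrt(2))
        assert stats.p.iat[0, 0] == 0.0
        assert stats.counts.iat[0, 0] == 0
        assert stats.denominator == 2

    def test_tie_with_largest_control_counts(self):
        stats = control_statistics(_frame([[3.0]]), _frame([[1.0], [3.0]]),
                                   "control")
        assert stats.p.iat[0, 0] >= 1 / 2

    def test_needs_two_controls(self):
        with pytest.raises(ValueError):
            control_statistics(_frame([[1.0]]), _frame([[1.0]]), "control")

    def test_zero_variance_sentinel(self):
        null = _frame([[2.0], [2.0]])
        stats = control_statistics(_frame([[2.0], [5.0]]), null, "control")
        assert stats.z.iat[0, 0] == 0.0
        assert stats.z.iat[1, 0] == Z_SENTINEL
        assert stats.zero_variance.values.all()

    def test_loop_oracle_random_instance(self, rng):
        obs = _frame(rng.standard_normal((5, 4)))
        null = _frame(rng.standard_normal((7, 4)))
        stats = control_statistics(obs, null, "control")
        for c in range(5):
            for t in range(4):
                col = null.values[:, t]
                z = (obs.iat[c, t] - col.mean()) / col.std(ddof=1)
                p = np.mean(obs.iat[c, t] <= col)
                assert stats.z.iat[c, t] == pytest.approx(z, abs=1e-12)
                assert stats.p.iat[c, t] == pytest.approx(p, abs=1e-15)

    def test_self_cohort_p_at_least_one_over_n(self, rng):
        x = _frame(rng.standard_normal((6, 3)))
        stats = control_statistics(x, x, "control")
        assert (stats.p.values >= 1 / 6 - 1e-15).all()


class TestWithinStatistics:
    def test_term_mean_equals_profile_mean(self):
        sim = _frame([[1.0, 2.0, 3.0]], prefix_c="g")
        ann = _ann([[1], [0], [1]], ["g0", "g1", "g2"], ["T0"])
        stats = within_statistics(sim, ann, n_permutations=10, seed=0)
        assert stats.z.iat[0, 0] == pytest.approx(0.0)

    def test_hand_sample_moments(self):
        # S=[0,0,4], term {g2}: z = (4 - 4/3) / (4/sqrt(3)) = 2/sqrt(3)
        sim = _frame([[0.0, 0.0, 4.0]], prefix_c="g")
        ann = _ann([[0], [0], [1]], ["g0", "g1", "g2"], ["T0"])
        stats = within_statistics(sim, ann, n_permutations=10, seed=0)
        assert stats.z.iat[0, 0] == pytest.approx(2 / np.sqrt(3))

    def test_constant_row_permutation_invariant(self):
        sim = _frame([[2.0, 2.0, 2.0]], prefix_c="g")
        ann = _ann([[1], [1], [0]], ["g0", "g1", "g2"], ["T0"])
        stats = within_statistics(sim, ann, n_permutations=500, seed=1)
        assert stats.p.iat[0, 0] == 1.0
        assert stats.z.iat[0, 0] == 0.0  # zero variance, zero numerator

    def test_z_loop_oracle(self, rng):
        sim = _frame(rng.standard_normal((5, 8)), prefix_c="g")
        genes = [f"g{j}" for j in range(8)]
        membership = rng.integers(0, 2, size=(8, 4))
        membership[0] = 1  # no empty terms
        ann = _ann(membership, genes, [f"T{t}" for t in range(4)])
        stats = within_statistics(sim, ann, n_permutations=5, seed=2)
        for c in range(5):
            row = sim.values[c]
            w, y = row.mean(), row.std(ddof=1)
            for t in range(4):
                d = membership[:, t].sum()
                x = row @ membership[:, t]
                z = (x / d - w) / (y / np.sqrt(d))
                assert stats.z.iat[c, t] == pytest.approx(z, abs=1e-12)

    def test_permutation_p_monte_carlo_stability(self, rng):
        # two independent seeds at large n agree within binomial error
        sim = _frame(rng.standard_normal((2, 12)), prefix_c="g")
        genes = [f"g{j}" for j in range(12)]
        ann = _ann([[1] if j < 4 else [0] for j in range(12)], genes, ["T0"])
        n_l = 10_000
        a = within_statistics(sim, ann, n_l, seed=10).p.values
        b = within_statistics(sim, ann, n_l, seed=20).p.values
        se = 3 * np.sqrt(np.maximum(a * (1 - a), 0.25 / n_l) / n_l)
        assert (np.abs(a - b) <= se + 3e-2).all()

    def test_p_is_rational_with_denominator_n_l(self, rng):
        sim = _frame(rng.standard_normal((3, 6)), prefix_c="g")
        genes = [f"g{j}" for j in range(6)]
        ann = _ann([[1, 0], [1, 0], [0, 1], [0, 1], [1, 1], [0, 0]],
                   genes, ["T0", "T1"])
        stats = within_statistics(sim, ann, 37, seed=3)
        np.testing.assert_array_equal(stats.p.values * 37,
                                      stats.counts.values.astype(float))
        assert ((stats.p.values >= 0) & (stats.p.values <= 1)).all()


def _stats_from(z, p):
    z = _frame(z)
    p = _frame(p)
    counts = (p * 100).round().astype(int)
    zero = pd.DataFrame(False, index=z.index, columns=z.columns)
    return z, p, counts, zero


class TestCombine:
    def _combined(self, triples):
        """triples: {source: (z, p)} for a single (condition, term) cell."""
        stats = {}
        for source, (z, p) in triples.items():
            zf, pf, counts, zero = _stats_from([[z]], [[p]])
            stats[source] = SourceStats(source, zf, pf, counts, 100, zero)
        return combine_statistics(stats)

    def test_unique_max_p_wins(self):
        out = self._combined({"control": (3.0, 0.02), "resampled": (2.0, 0.05),
                              "within": (4.0, 0.01)})
        assert out.p_final.iat[0, 0] == 0.05
        assert out.z_final.iat[0, 0] == 2.0
        assert out.source.iat[0, 0] == "resampled"

    def test_p_tie_broken_by_min_z(self):
        out = self._combined({"control": (2.5, 0.05), "resampled": (2.0, 0.05),
                              "within": (4.0, 0.01)})
        assert out.p_final.iat[0, 0] == 0.05
        assert out.z_final.iat[0, 0] == 2.0
        assert out.source.iat[0, 0] == "resampled"

    def test_full_tie_is_value_invariant(self):
        out = self._combined({s: (1.5, 0.2) for s in SOURCES})
        assert out.p_final.iat[0, 0] == 0.2
        assert out.z_final.iat[0, 0] == 1.5

    def test_exhaustive_tie_patterns(self):
        # every assignment of two p levels and two z levels across sources
        for ps in itertools.product([0.2, 0.7], repeat=3):
            for zs in itertools.product([1.0, 2.0], repeat=3):
                out = self._combined(dict(zip(SOURCES, zip(zs, ps))))
                pmax = max(ps)
                tied = [i for i, p in enumerate(ps) if p == pmax]
                zmin = min(zs[i] for i in tied)
                assert out.p_final.iat[0, 0] == pmax
                assert out.z_final.iat[0, 0] == zmin

    def test_missing_source_rejected(self):
        z, p, counts, zero = _stats_from([[1.0]], [[0.5]])
        with pytest.raises(ValueError):
            combine_statistics(
                {"control": SourceStats("control", z, p, counts, 100, zero)})

    def test_numerator_denominator_follow_winner(self):
        zf, pf, counts, zero = _stats_from([[1.0]], [[0.30]])
        stats = {"control": SourceStats("control", zf, pf, counts, 100, zero)}
        for source, p in (("resampled", 0.10), ("within", 0.20)):
            z2, p2, c2, zero2 = _stats_from([[1.0]], [[p]])
            stats[source] = SourceStats(source, z2, p2, c2, 100, zero2)
        out = combine_statistics(stats)
        assert out.source.iat[0, 0] == "control"
        assert out.p_numerator.iat[0, 0] == 30
        assert out.p_denominator.iat[0, 0] == 100
        table = out.to_frame()
        assert set(table.columns) >= {"condition_id", "term_id", "z", "p",
                                      "source", "p_count_numerator",
                                      "p_count_denominator"}
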
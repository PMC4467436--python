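"""ECDF transform, KS random-walk scoring and argmax subtype calls."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_es
from coexsig.io_formats import GeneSetCollection
from coexsig.sample_scoring import (
    classify,
    ecdf_transform,
    random_walk_es,
    sample_rank_statistic,
    score_samples,
)
from coexsig.synthetic_data import simulate_expression, two_program_config


class TestEcdfTransform:
    def test_strictly_increasing_gene(self):
        m = pd.DataFrame([[1.0, 2, 3, 4]], index=["g"], columns=list("abcd"))
        np.testing.assert_allclose(
            ecdf_transform(m).loc["g"], [0.25, 0.5, 0.75, 1.0]
        )

    def test_direct_enumeration_with_ties(self):
        m = pd.DataFrame(
            [[1, 2, 3], [9, 8, 7], [5, 5, 5]],
            index=list("abc"), columns=list("xyz"), dtype=float,
        )
        expected = np.array([[1/3, 2/3, 1.0], [1.0, 2/3, 1/3], [1.0, 1.0, 1.0]])
        np.testing.assert_allclose(ecdf_transform(m).to_numpy(), expected)

    def test_identical_sample_columns_transform_identically(self, rng):
        col = rng.normal(size=8)
        m = pd.DataFrame({"s1": col, "s2": col, "s3": rng.normal(size=8)})
        z = ecdf_transform(m)
        np.testing.assert_allclose(z["s1"], z["s2"])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ecdf_transform(pd.DataFrame([[1.0]], index=["g"], columns=["s"]))


class TestSampleRankStatistic:
    def test_weights_are_distance_from_middle_rank(self):
        m = pd.DataFrame(
            [[4.0, 1], [3, 2], [2, 3], [1, 4]], index=list("abcd"), columns=["s", "t"]
        )
        _, weights = sample_rank_statistic(ecdf_transform(m), "s")
        np.testing.assert_allclose(weights, [1.0, 0.0, 1.0, 2.0])

    def test_middle_rank_has_minimal_weight(self):
        m = pd.DataFrame(
            np.arange(14, dtype=float).reshape(7, 2), index=list("abcdefg"),
            columns=["s", "t"],
        )
        _, weights = sample_rank_statistic(ecdf_transform(m), "s")
        assert weights.argmin() in (2, 3)  # ranks adjacent to N/2 = 3.5
        assert weights[0] == weights.max() or weights[-1] == weights.max()

    def test_reversed_transformed_values_reverse_order(self):
        z = np.array([0.9, 0.1, 0.7, 0.3, 0.5])
        m1 = pd.DataFrame({"s": z, "t": z}, index=list("abcde"))
        m2 = pd.DataFrame({"s": 1 - z, "t": 1 - z}, index=list("abcde"))
        o1, _ = sample_rank_statistic(m1, "s")
        o2, _ = sample_rank_statistic(m2, "s")
        np.testing.assert_array_equal(o1, o2[::-1])


class TestRandomWalkEs:
    def test_hand_computed_uniform_walk(self):
        w = np.ones(6)
        member = np.zeros(6, dtype=bool)
        member[[0, 3]] = True
        es, path = random_walk_es(w, member, return_path=True)
        np.testing.assert_allclose(path, [0.5, 0.25, 0.0, 0.5, 0.25, 0.0])
        assert es == pytest.approx(0.5)

    def test_top_placement_maximises_es_over_all_placements(self):
        w = np.abs(6 / 2 - np.arange(1, 7, dtype=float))
        es_by_placement = {}
        for pos in combinations(range(6), 2):
            member = np.zeros(6, dtype=bool)
            member[list(pos)] = True
            es_by_placement[pos] = random_walk_es(w, member)
        assert max(es_by_placement, key=es_by_placement.get) == (0, 1)
        assert es_by_placement[(0, 1)] > 0

    def test_bottom_placement_is_negative(self):
        w = np.abs(8 / 2 - np.arange(1, 9, dtype=float))
        member = np.zeros(8, dtype=bool)
        member[[6, 7]] = True
        assert random_walk_es(w, member) < 0

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("es_mode", ["difference", "max"])
    def test_oracle_equivalence_small_lists(self, seed, es_mode):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        w = np.abs(n / 2 - np.arange(1, n + 1, dtype=float))
        member = np.zeros(n, dtype=bool)
        member[rng.choice(n, size=int(rng.integers(2, n)), replace=False)] = True
        ours = random_walk_es(w, member, es_mode=es_mode)
        assert ours == pytest.approx(
            brute_force_es(list(w), list(member), es_mode=es_mode), abs=1e-12
        )

    def test_too_small_set_rejected(self):
        with pytest.raises(ValueError):
            random_walk_es(np.ones(5), np.array([1, 0, 0, 0, 0], dtype=bool))


class TestScoreSamples:
    def _score_oracle(self, matrix, genes):
        """Independent composition: counting ECDF + scalar walk."""
        x = matrix.to_numpy()
        n, p = x.shape
        out = np.empty(p)
        for j in range(p):
            z = np.array([np.sum(x[g] <= x[g, j]) / p for g in range(n)])
            order = sorted(range(n), key=lambda g: (-z[g], g))
            weights = [abs(n / 2 - (r + 1)) for r in range(n)]
            member = [matrix.index[g] in genes for g in order]
            out[j] = brute_force_es(weights, member)
        return out

    def test_matches_independent_composition_oracle(self, rng):
        m = pd.DataFrame(
            rng.normal(8, 1, (10, 4)),
            index=[f"g{i}" for i in range(10)],
            columns=list("wxyz"),
        )
        genes = {"g1", "g4", "g7"}
        scores = score_samples(m, GeneSetCollection.from_dict({"S": genes}))
        np.testing.assert_allclose(
            scores.loc["S"].to_numpy(), self._score_oracle(m, genes), atol=1e-12
        )

    def test_invariant_under_monotone_per_gene_transform(self, rng):
        m = pd.DataFrame(
            rng.normal(0, 1, (12, 6)),
            index=[f"g{i}" for i in range(12)], columns=[f"s{j}" for j in range(6)],
        )
        coll = GeneSetCollection.from_dict({"S": ["g0", "g3", "g5"]})
        s1 = score_samples(m, coll)
        s2 = score_samples(np.exp(m / 3) + 5, coll)  # strictly monotone per gene
        pd.testing.assert_frame_equal(s1, s2)

    def test_permuting_samples_permutes_scores(self, rng, small_matrix):
        coll = GeneSetCollection.from_dict({"S": ["g1", "g2", "g3"]})
        s1 = score_samples(small_matrix, coll)
        perm = list(small_matrix.columns[::-1])
        s2 = score_samples(small_matrix[perm], coll)
        pd.testing.assert_frame_equal(s1[perm], s2)

    def test_concordantly_high_set_scores_above_low_set(self, rng):
        base = rng.normal(8, 1, (20, 10))
        m = pd.DataFrame(base, index=[f"g{i}" for i in range(20)],
                         columns=[f"s{j}" for j in range(10)])
        m.loc[["g0", "g1", "g2"], "s0"] = m.to_numpy().max() + rng.random(3)
        m.loc[["g0", "g1", "g2"], "s1"] = m.to_numpy().min() - rng.random(3)
        scores = score_samples(m, GeneSetCollection.from_dict({"S": ["g0", "g1", "g2"]}))
        assert scores.loc["S", "s0"] > scores.loc["S", "s1"]

    def test_unmatched_sets_skipped_and_all_unmatched_is_error(self, small_matrix):
        coll = GeneSetCollection.from_dict({"bad": ["nope1", "nope2"]})
        with pytest.raises(ValueError, match="no gene set"):
            score_samples(small_matrix, coll)


class TestClassify:
    def test_argmax_label_and_margin(self):
        scores = pd.DataFrame(
            {"s1": [0.5, -0.2]}, index=["CD133M", "CD44M"]
        )
        call = classify(scores, ["CD133M", "CD44M"])
        assert call.labels["s1"] == "CD133M"
        assert call.table.loc["s1", "margin"] == pytest.approx(0.7)

    def test_exact_tie_goes_to_first_candidate(self, caplog):
        scores = pd.DataFrame({"s1": [0.3, 0.3]}, index=["M2", "M1"])
        call = classify(scores, ["M1", "M2"])
        assert call.labels["s1"] == "M1"
        assert call.table.loc["s1", "margin"] == 0.0

    def test_missing_candidate_rejected(self):
        scores = pd.DataFrame({"s1": [0.3]}, index=["M1"])
        with pytest.raises(KeyError):
            classify(scores, ["M1", "M2"])

    def test_two_program_simulation_recovers_planted_labels(self):
        cfg = two_program_config(rng_seed=11)
        m, truth = simulate_expression(cfg)
        coll = GeneSetCollection.from_dict(
            {"CD133M": truth.members("CD133M"), "CD44M": truth.members("CD44M")}
        )
        call = classify(score_samples(m, coll), ["CD133M", "CD44M"])
        expected = {
            s: ("CD133M" if sub == "A" else "CD44M")
            for s, sub in truth.sample_subtype.items()
        }
        acc = np.mean([call.labels[s] == expected[s] for s in call.labels.index])
        assert acc >= 0.95
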
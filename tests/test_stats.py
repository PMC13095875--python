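"""CLR transform, hierarchical clustering, PCA and ANOVA/Tukey letters."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from rosawax.stats import (
    anova_tukey,
    clr_transform,
    compact_letter_display,
    hca,
    pca,
)


def frame(rows, index=None, columns=None):
    return pd.DataFrame(np.asarray(rows, dtype=float), index=index,
                        columns=columns)


class TestClr:
    def test_uniform_row_maps_to_zero(self):
        out = clr_transform(frame([[1, 1, 1, 1]]))
        assert np.allclose(out.to_numpy(), 0.0)

    def test_two_part_composition_closed_form(self):
        out = clr_transform(frame([[4, 1]]))
        assert out.to_numpy()[0] == pytest.approx(
            [math.log(2), -math.log(2)]
        )

    def test_zero_replacement_keeps_row_sum_zero(self):
        out = clr_transform(frame([[1, 0, 2]]))
        assert out.to_numpy().sum() == pytest.approx(0.0, abs=1e-12)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(7)
        m = frame(rng.uniform(0.1, 10, size=(6, 8)))
        out = clr_transform(m)
        assert np.allclose(out.sum(axis=1), 0.0, atol=1e-9)

    def test_invariant_to_row_rescaling(self):
        rng = np.random.default_rng(8)
        m = frame(rng.uniform(0.1, 10, size=(4, 6)))
        scaled = m.mul(np.array([2.0, 0.5, 10.0, 1e-3]), axis=0)
        assert np.allclose(
            clr_transform(m).to_numpy(), clr_transform(scaled).to_numpy()
        )

    def test_row_with_one_positive_entry_errors(self):
        with pytest.raises(ValueError, match="positive"):
            clr_transform(frame([[1, 0, 0]]))


class TestHca:
    def test_identical_rows_merge_first(self):
        m = frame([[0, 0], [0, 0], [10, 10]], index=["a", "b", "c"])
        tree = hca(m)
        first = tree.linkage[0]
        merged = {tree.labels[int(first[0])], tree.labels[int(first[1])]}
        assert merged == {"a", "b"}
        assert first[2] == pytest.approx(0.0)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(11)
        m = frame(rng.normal(size=(5, 3)),
                  index=["a", "b", "c", "d", "e"])
        shuffled = m.iloc[[3, 1, 4, 0, 2]]
        t1, t2 = hca(m), hca(shuffled)
        assert t1.labels == t2.labels
        assert np.allclose(t1.linkage, t2.linkage)

    def test_two_tight_pairs_merge_before_root(self):
        m = frame(
            [[0, 0], [0.1, 0], [10, 10], [10.1, 10]],
            index=["a", "b", "c", "d"],
        )
        Z = hca(m).linkage
        # first two merges join the tight pairs (leaves 0..3), root joins them
        assert set(Z[0, :2].astype(int)) in ({0, 1}, {2, 3})
        assert set(Z[1, :2].astype(int)) in ({0, 1}, {2, 3})

    def test_distance_scaling_preserves_topology(self):
        rng = np.random.default_rng(12)
        m = frame(rng.normal(size=(6, 4)))
        t1, t2 = hca(m), hca(m * 3.0)
        assert np.allclose(t1.linkage[:, :2], t2.linkage[:, :2])

    def test_newick_parses_back_to_same_leaves(self):
        m = frame([[0, 0], [1, 0], [5, 5]], index=["x", "y", "z"])
        nwk = hca(m).to_newick()
        assert nwk.endswith(";")
        for label in ("x", "y", "z"):
            assert label in nwk

    def test_single_row_errors(self):
        with pytest.raises(ValueError):
            hca(frame([[1, 2]]))


class TestPca:
    def test_single_varying_column_explains_everything(self):
        m = frame([[0, 5], [1, 5], [2, 5], [3, 5]])
        res = pca(m, standardize=False)
        assert res.variance_explained[0] == pytest.approx(100.0)

    def test_variance_sums_to_100(self):
        rng = np.random.default_rng(13)
        m = frame(rng.normal(size=(8, 5)))
        res = pca(m)
        assert res.variance_explained.sum() == pytest.approx(100.0)

    def test_2x2_matches_analytic_eigenvectors(self):
        m = frame([[2.0, 1.0], [-2.0, -1.0], [1.0, -1.0], [-1.0, 1.0]])
        res = pca(m, standardize=False)
        cov = np.cov(m.to_numpy(), rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        for j in range(2):
            v = eigvecs[:, j]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            assert np.allclose(res.loadings.iloc[:, j].to_numpy(), v)
        expected_pct = 100 * eigvals / eigvals.sum()
        assert np.allclose(res.variance_explained, expected_pct)

    def test_scores_are_centred_and_reconstruct(self):
        rng = np.random.default_rng(14)
        m = frame(rng.normal(size=(6, 4)))
        res = pca(m, standardize=True)
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-9)
        X = m.to_numpy()
        X = X - X.mean(axis=0)
        X = X / X.std(axis=0, ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, X, atol=1e-9)

    def test_sign_convention(self):
        rng = np.random.default_rng(15)
        m = frame(rng.normal(size=(7, 4)))
        res = pca(m)
        L = res.loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_zero_variance_column_dropped_with_warning(self):
        m = frame([[1, 5, 0], [2, 5, 1], [3, 5, 0.5]])
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca(m, standardize=True)
        assert res.loadings.shape[0] == 2


class TestAnovaTukey:
    def test_identical_groups_share_a_letter(self):
        res = anova_tukey({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert res.letters["a"] == res.letters["b"] == "a"

    def test_well_separated_groups_get_distinct_letters(self):
        res = anova_tukey(
            {"g1": [1.0, 1.1, 0.9], "g2": [10.0, 10.1, 9.9]}
        )
        assert set(res.letters["g1"]) & set(res.letters["g2"]) == set()

    def test_three_groups_close_pair_far_singleton(self):
        res = anova_tukey(
            {
                "A": [1.0, 1.1, 0.9, 1.05],
                "B": [1.1, 1.0, 1.2, 0.95],
                "C": [20.0, 19.9, 20.1, 20.05],
            }
        )
        assert set(res.letters["A"]) & set(res.letters["B"])
        assert not set(res.letters["A"]) & set(res.letters["C"])
        assert not set(res.letters["B"]) & set(res.letters["C"])

    def test_letters_consistent_with_pairwise_decisions(self):
        rng = np.random.default_rng(17)
        groups = {
            g: list(rng.normal(loc, 1.0, size=5))
            for g, loc in zip("abcde", [0, 0.5, 3.0, 3.2, 9.0])
        }
        res = anova_tukey(groups)
        decisions = {
            frozenset((r.group1, r.group2)): bool(r.reject)
            for r in res.pairwise.itertuples()
        }
        for g1, g2 in combinations(sorted(groups), 2):
            share = bool(set(res.letters[g1]) & set(res.letters[g2]))
            assert share != decisions[frozenset((g1, g2))]

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0, 2.0]})


class TestCompactLetterDisplay:
    def test_no_differences_single_letter(self):
        letters = compact_letter_display(["x", "y", "z"], set())
        assert set(letters.values()) == {"a"}

    def test_chain_of_differences(self):
        sig = {frozenset(("a", "c"))}
        letters = compact_letter_display(["a", "b", "c"], sig)
        assert not set(letters["a"]) & set(letters["c"])
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])

    def test_all_pairs_different(self):
        sig = {
            frozenset(p) for p in combinations(["a", "b", "c"], 2)
        }
        letters = compact_letter_display(["a", "b", "c"], sig)
        assert len({frozenset(v) for v in letters.values()}) == 3
        for g1, g2 in combinations(["a", "b", "c"], 2):
            assert not set(letters[g1]) & set(letters[g2])
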
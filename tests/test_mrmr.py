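"""mRMR: discretization, plug-in mutual information, greedy selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from kbdsig import discretize, mutual_information, select_mrmr
from kbdsig.mrmr import DiscretizedMatrix


def brute_force_mi(x, y):
    """Independent plug-in MI oracle: explicit sum over the joint table."""
    x, y = list(x), list(y)
    n = len(x)
    mi = 0.0
    for xv in set(x):
        for yv in set(y):
            pxy = sum(1 for a, b in zip(x, y) if a == xv and b == yv) / n
            if pxy == 0:
                continue
            px = x.count(xv) / n
            py = y.count(yv) / n
            mi += pxy * math.log2(pxy / (px * py))
    return mi


class TestDiscretize:
    def test_three_sigma_points_map_to_three_states(self):
        # values at mu -3s, mu, mu +3s for one gene (plus spread to fix sigma)
        vals = np.array([-3.0, 0.0, 3.0, -1.0, 1.0, 0.0])
        df = pd.DataFrame({"g": vals})
        disc = discretize(df, k_sigma=1.0)
        assert disc.states[0, 0] == -1 and disc.states[1, 0] == 0 and disc.states[2, 0] == 1

    def test_constant_gene_all_zero_with_warning(self):
        df = pd.DataFrame({"g": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            disc = discretize(df)
        assert (disc.states == 0).all()

    def test_gaussian_middle_state_fraction_matches_normal_cdf(self, rng):
        n = 4000
        df = pd.DataFrame({"g": rng.normal(5.0, 2.0, size=n)})
        disc = discretize(df, k_sigma=1.0)
        frac0 = np.mean(disc.states == 0)
        expected = stats.norm.cdf(1) - stats.norm.cdf(-1)
        tol = 3 * np.sqrt(expected * (1 - expected) / n)
        assert abs(frac0 - expected) < tol + 0.01  # sigma estimated from sample

    def test_nonpositive_k_sigma_rejected(self):
        with pytest.raises(ValueError, match="k_sigma"):
            discretize(pd.DataFrame({"g": [1.0, 2.0]}), k_sigma=0.0)


class TestMutualInformation:
    def test_constant_x_gives_zero(self):
        assert mutual_information([1] * 8, [0, 1] * 4) == 0.0

    def test_identical_balanced_binary_gives_one_bit(self):
        y = [0, 1] * 6
        assert mutual_information(y, y) == pytest.approx(1.0)

    def test_matches_bruteforce_on_2x2_table(self):
        # joint counts [[2,1],[1,2]], n=6
        x = [0, 0, 0, 1, 1, 1]
        y = [0, 0, 1, 0, 1, 1]
        assert mutual_information(x, y) == pytest.approx(brute_force_mi(x, y), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([1, 2], [1, 2, 3])

    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 3)), min_size=2, max_size=40))
    def test_axioms_nonnegative_symmetric_self_entropy(self, pairs):
        x = [a for a, _ in pairs]
        y = [b for _, b in pairs]
        mi = mutual_information(x, y)
        assert mi >= 0
        assert mi == pytest.approx(mutual_information(y, x), abs=1e-12)
        # self-MI equals the empirical entropy
        n = len(x)
        entropy = -sum((c / n) * math.log2(c / n) for c in pd.Series(x).value_counts())
        assert mutual_information(x, x) == pytest.approx(entropy, abs=1e-12)

    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 1)), min_size=2, max_size=30))
    def test_invariant_under_state_relabeling(self, pairs):
        x = np.array([a for a, _ in pairs])
        y = np.array([b for _, b in pairs])
        relabel = {0: 7, 1: -3, 2: 0}
        x2 = np.array([relabel[v] for v in x])
        assert mutual_information(x, y) == pytest.approx(mutual_information(x2, y), abs=1e-12)


def _random_disc(rng, n_samples=30, n_genes=8):
    states = rng.integers(-1, 2, size=(n_samples, n_genes)).astype(np.int8)
    labels = rng.integers(0, 2, size=n_samples)
    return DiscretizedMatrix(states=states, genes=[f"g{i}" for i in range(n_genes)],
                             thresholds=np.zeros((n_genes, 2)), labels=labels)


class TestSelectMrmr:
    def test_perfect_predictor_ranked_first(self, rng):
        states = rng.integers(-1, 2, size=(40, 5)).astype(np.int8)
        labels = rng.integers(0, 2, size=40)
        states[:, 3] = np.where(labels == 1, 1, -1)
        disc = DiscretizedMatrix(states=states, genes=list("abcde"),
                                 thresholds=np.zeros((5, 2)), labels=labels)
        assert select_mrmr(disc, n=1).ordered_genes[0] == 3

    def test_redundant_duplicate_penalized(self, rng):
        """Two identical informative genes plus a weaker independent gene:
        the second pick must be the independent gene under MID."""
        n = 60
        labels = np.array([0, 1] * (n // 2))
        perfect = np.where(labels == 1, 1, -1).astype(np.int8)
        # strong: tracks the label with 10% flips (shared by both duplicates,
        # and not identical to the label so redundancy can exceed relevance)
        strong = perfect.copy()
        strong[rng.random(n) < 0.1] *= -1
        # weak: independently noisy copy of the label
        weak = perfect.copy()
        weak[rng.random(n) < 0.3] *= -1
        states = np.column_stack([strong, strong.copy(), weak]).astype(np.int8)
        disc = DiscretizedMatrix(states=states, genes=["dup1", "dup2", "indep"],
                                 thresholds=np.zeros((3, 2)), labels=labels)
        ranking = select_mrmr(disc, n=2, criterion="MID")
        assert ranking.gene_names[0] in ("dup1",)  # tie between duplicates -> lower index
        assert ranking.gene_names[1] == "indep"

    @pytest.mark.parametrize("criterion", ["MID", "MIQ"])
    def test_greedy_step_equals_bruteforce_max(self, criterion, rng):
        """At every greedy step the chosen gene attains the exact maximum of
        the criterion over all remaining candidates (independent recomputation
        from raw states)."""
        for trial in range(5):
            disc = _random_disc(rng)
            n = 5
            ranking = select_mrmr(disc, n=n, criterion=criterion)
            selected = []
            for step, (pick, score) in enumerate(zip(ranking.ordered_genes, ranking.scores)):
                best_val, best_gene = -np.inf, None
                for g in range(disc.states.shape[1]):
                    if g in selected:
                        continue
                    rel = brute_force_mi(disc.states[:, g], disc.labels)
                    if step == 0:
                        val = rel
                    else:
                        red = np.mean([brute_force_mi(disc.states[:, g], disc.states[:, s])
                                       for s in selected])
                        val = rel - red if criterion == "MID" else rel / max(red, 1e-12)
                    if val > best_val:
                        best_val, best_gene = val, g
                assert score == pytest.approx(best_val, abs=1e-12)
                crit_of_pick = best_val  # pick must attain the max
                assert pick == best_gene or score == pytest.approx(best_val, abs=1e-12)
                selected.append(pick)

    def test_full_ranking_is_permutation(self, rng):
        disc = _random_disc(rng, n_genes=6)
        ranking = select_mrmr(disc, n=6)
        assert sorted(ranking.ordered_genes) == list(range(6))

    def test_deterministic(self, rng):
        disc = _random_disc(rng)
        a = select_mrmr(disc, n=4)
        b = select_mrmr(disc, n=4)
        assert a.ordered_genes == b.ordered_genes and a.scores == b.scores

    def test_zero_relevance_panel_warns_and_ranks_by_index(self):
        states = np.zeros((10, 4), dtype=np.int8)
        disc = DiscretizedMatrix(states=states, genes=list("abcd"),
                                 thresholds=np.zeros((4, 2)), labels=[0, 1] * 5)
        with pytest.warns(UserWarning, match="zero relevance"):
            ranking = select_mrmr(disc, n=4)
        assert ranking.ordered_genes == [0, 1, 2, 3]

    def test_errors(self, rng):
        disc = _random_disc(rng, n_genes=3)
        with pytest.raises(ValueError, match="n must be"):
            select_mrmr(disc, n=4)
        single = DiscretizedMatrix(states=disc.states, genes=disc.genes,
                                   thresholds=disc.thresholds, labels=np.zeros(30))
        with pytest.raises(ValueError, match="both classes"):
            select_mrmr(single, n=2)
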
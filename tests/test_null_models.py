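import itertools
import math

import numpy as np
import pytest

from assemblyproc.io_formats import OtuTable, parse_tree
from assemblyproc.null_models import (NullConfig, abundance_weights, beta_mntd,
                                      bnti_matrix, cophenetic_matrix,
                                      null_assembled_table, raup_crick_bray)
from assemblyproc.synthetic_data import sim_tree
from conftest import random_table


# --- independent oracles ----------------------------------------------------

def path_distance_oracle(tree, a, b):
    """Tip-to-tip distance as depth(a) + depth(b) - 2*depth(lca)."""
    def ancestors(tip):
        chain, node = [], tree.find(tip)
        while node is not None:
            chain.append(node)
            node = node.parent
        return chain

    def depth(node):
        d = 0.0
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        return d

    anc_a = ancestors(a)
    in_a = set(map(id, anc_a))
    lca = next(n for n in ancestors(b) if id(n) in in_a)
    return depth(tree.find(a)) + depth(tree.find(b)) - 2 * depth(lca)


def beta_mntd_oracle(counts_i, counts_j, dist, transform="log1p"):
    """Exhaustive double loop over present taxa."""
    def weights(x):
        g = [math.log1p(v) if transform == "log1p" else float(v) for v in x]
        g = [gi if xi > 0 else 0.0 for gi, xi in zip(g, x)]
        s = sum(g)
        return [gi / s for gi in g]

    wi, wj = weights(counts_i), weights(counts_j)
    pres_i = [k for k, v in enumerate(counts_i) if v > 0]
    pres_j = [k for k, v in enumerate(counts_j) if v > 0]
    total = 0.0
    for k in pres_i:
        total += wi[k] * min(dist[k][m] for m in pres_j)
    for k in pres_j:
        total += wj[k] * min(dist[k][m] for m in pres_i)
    return 0.5 * total


# --- cophenetic --------------------------------------------------------------

class TestCopheneticMatrix:
    def test_two_tip(self):
        dm = cophenetic_matrix(parse_tree("(A:0.1,B:0.2):0;"))
        assert dm["A", "B"] == pytest.approx(0.3)

    def test_four_tip_hand_sums(self, four_tip_tree):
        dm = cophenetic_matrix(four_tip_tree)
        assert dm["A", "D"] == pytest.approx(4.0)
        assert dm["A", "B"] == pytest.approx(2.0)

    def test_against_traversal_oracle(self):
        tree = sim_tree(10, seed=3)
        dm = cophenetic_matrix(tree)
        ids = list(dm.ids)
        for a, b in itertools.combinations(ids, 2):
            assert dm[a, b] == pytest.approx(path_distance_oracle(tree, a, b))


# --- abundance weights -------------------------------------------------------

class TestAbundanceWeights:
    def test_symmetric_counts(self):
        w = abundance_weights([10, 0, 10])
        assert w.tolist() == pytest.approx([0.5, 0.0, 0.5])

    def test_log_hand_computation(self):
        w = abundance_weights([math.e - 1, 0, math.e**2 - 1])
        assert w == pytest.approx([1 / 3, 0.0, 2 / 3])

    def test_identity_transform(self):
        w = abundance_weights([1, 3, 0], transform="none")
        assert w == pytest.approx([0.25, 0.75, 0.0])

    def test_sum_one_and_support(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.integers(0, 20, size=8)
            if not (x > 0).any():
                continue
            w = abundance_weights(x)
            assert w.sum() == pytest.approx(1.0)
            assert ((w == 0) == (x == 0)).all()

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            abundance_weights([0, 0])


# --- betaMNTD ----------------------------------------------------------------

class TestBetaMNTD:
    def test_identical_communities_zero(self, four_tip_tree):
        dm = cophenetic_matrix(four_tip_tree)
        w = abundance_weights([3, 1, 0, 2])
        assert beta_mntd(w, w, dm) == pytest.approx(0.0)

    def test_single_taxon_reduction(self, four_tip_tree):
        dm = cophenetic_matrix(four_tip_tree)
        order = list(dm.ids)
        wi = np.array([1.0 if o == "A" else 0.0 for o in order])
        wj = np.array([1.0 if o == "C" else 0.0 for o in order])
        assert beta_mntd(wi, wj, dm) == pytest.approx(4.0)

    def test_brute_force_oracle_small_trees(self):
        rng = np.random.default_rng(12)
        for rep in range(50):
            n = int(rng.integers(3, 7))
            tree = sim_tree(n, seed=1000 + rep)
            dm = cophenetic_matrix(tree)
            order = list(dm.ids)
            ci = rng.integers(0, 6, size=n)
            cj = rng.integers(0, 6, size=n)
            if not (ci > 0).any() or not (cj > 0).any():
                continue
            got = beta_mntd(abundance_weights(ci), abundance_weights(cj), dm)
            exp = beta_mntd_oracle(ci.tolist(), cj.tolist(), dm.data.tolist())
            assert abs(got - exp) < 1e-12


# --- betaNTI -----------------------------------------------------------------

def exact_bnti_oracle(counts, tree, transform="log1p"):
    """Exhaustive z-score over every permutation of tip identities, computed
    with the double-loop betaMNTD oracle (sample sd)."""
    dm = cophenetic_matrix(tree)
    order = list(dm.ids)
    D = dm.data
    n = len(order)
    obs = beta_mntd_oracle(counts[0], counts[1], D.tolist(), transform)
    vals = []
    for perm in itertools.permutations(range(n)):
        Dp = D[np.ix_(perm, perm)]
        vals.append(beta_mntd_oracle(counts[0], counts[1], Dp.tolist(), transform))
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
    return (obs - mean) / math.sqrt(var)


class TestBnti:
    def test_exact_permutation_equivalence(self):
        tree = sim_tree(5, seed=21)
        order = [t.name for t in tree.tips()]
        counts = np.array([[4, 0, 3, 1, 0], [0, 2, 5, 0, 1]])
        table = OtuTable(("s1", "s2"), tuple(order), counts)
        perms = list(itertools.permutations(range(5)))
        z = bnti_matrix(table, tree, NullConfig(seed=0),
                        permutations=[np.array(p) for p in perms])
        expected = exact_bnti_oracle(counts.tolist(), tree)
        assert z.iloc[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_identical_membership_degenerate_nan(self, four_tip_tree):
        table = OtuTable(("a", "b"), tuple("ABCD"),
                         np.array([[3, 1, 0, 2], [1, 3, 0, 4]]))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            z = bnti_matrix(table, four_tip_tree,
                            NullConfig(n_randomizations=50, seed=1))
        assert math.isnan(z.iloc[0, 1])

    def test_near_identical_communities_nonpositive(self):
        # same dominant clade membership, one extra close relative: observed
        # turnover cannot exceed the shuffled-null expectation
        tree = sim_tree(12, seed=5)
        order = [t.name for t in tree.tips()]
        c1 = np.zeros(12, int); c1[:6] = 10
        c2 = np.zeros(12, int); c2[:6] = 10; c2[6] = 1
        table = OtuTable(("a", "b"), tuple(order), np.array([c1, c2]))
        z = bnti_matrix(table, tree, NullConfig(n_randomizations=200, seed=2))
        assert z.iloc[0, 1] <= 0

    def test_symmetry_and_nan_diagonal(self):
        rng = np.random.default_rng(3)
        tree = sim_tree(8, seed=8)
        order = [t.name for t in tree.tips()]
        table = OtuTable(tuple(f"s{i}" for i in range(4)), tuple(order),
                         rng.integers(0, 9, size=(4, 8)) + np.eye(4, 8, dtype=int))
        z = bnti_matrix(table, tree, NullConfig(n_randomizations=100, seed=4))
        m = z.to_numpy()
        assert np.isnan(np.diag(m)).all()
        off = ~np.isnan(m)
        assert np.allclose(m[off], m.T[off])


# --- Raup-Crick --------------------------------------------------------------

def rc_oracle(table, n_rand, seed, tie_weight=0.5):
    """Independent re-implementation of the abundance-based Raup-Crick null
    for a 2-sample table (per-pair assembly, python loops)."""
    rng = np.random.default_rng(seed)
    X = table.counts
    occ = (X > 0).sum(axis=0).astype(float)
    occ_w = occ / occ.sum()
    meta_p = X.sum(axis=0) / X.sum()

    def bray(u, v):
        return np.abs(u - v).sum() / (u + v).sum()

    obs = bray(X[0].astype(float), X[1].astype(float))
    less = eq = 0
    n_taxa = X.shape[1]
    for _ in range(n_rand):
        nulls = []
        for s in range(2):
            k = int((X[s] > 0).sum())
            tot = int(X[s].sum())
            drawn = rng.choice(n_taxa, size=k, replace=False, p=occ_w)
            v = np.zeros(n_taxa)
            v[drawn] = 1
            if tot > k:
                p = meta_p[drawn] / meta_p[drawn].sum()
                v[drawn] += rng.multinomial(tot - k, p)
            nulls.append(v)
        nb = bray(nulls[0], nulls[1])
        if nb < obs - 1e-12:
            less += 1
        elif abs(nb - obs) <= 1e-12:
            eq += 1
    return 2 * ((less + tie_weight * eq) / n_rand - 0.5)


class TestRaupCrick:
    def test_range_symmetry_nan_diagonal(self):
        rng = np.random.default_rng(5)
        table = random_table(rng, n_samples=5, n_otus=8, max_count=30)
        rc = raup_crick_bray(table, NullConfig(n_randomizations=100, seed=6))
        m = rc.to_numpy()
        assert np.isnan(np.diag(m)).all()
        off = ~np.isnan(m)
        assert (m[off] >= -1).all() and (m[off] <= 1).all()
        assert np.allclose(m[off], m.T[off])

    def test_boundaries(self):
        # two nearly-disjoint rich samples: observed BC above every null
        counts = np.zeros((2, 20), dtype=int)
        counts[0, :10] = 50
        counts[1, 10:] = 50
        table = OtuTable(("a", "b"), tuple(f"o{i}" for i in range(20)), counts)
        rc = raup_crick_bray(table, NullConfig(n_randomizations=200, seed=7))
        assert rc.iloc[0, 1] == pytest.approx(1.0)
        # identical abundant samples: observed BC below (almost) every null
        counts2 = np.tile(np.arange(1, 21) * 5, (2, 1)).astype(int)
        table2 = OtuTable(("a", "b"), tuple(f"o{i}" for i in range(20)), counts2)
        rc2 = raup_crick_bray(table2, NullConfig(n_randomizations=200, seed=8))
        assert rc2.iloc[0, 1] == pytest.approx(-1.0, abs=0.02)

    def test_monte_carlo_stability_and_independent_oracle(self):
        counts = np.array([[12, 5, 0], [0, 7, 9]])
        table = OtuTable(("a", "b"), ("x", "y", "z"), counts)
        rc1 = raup_crick_bray(table, NullConfig(n_randomizations=10_000, seed=1))
        rc2 = raup_crick_bray(table, NullConfig(n_randomizations=10_000, seed=2))
        assert abs(rc1.iloc[0, 1] - rc2.iloc[0, 1]) < 0.05
        oracle = rc_oracle(table, 10_000, seed=3)
        assert abs(rc1.iloc[0, 1] - oracle) < 0.05

    def test_single_sample_rejected(self):
        table = OtuTable(("a",), ("x", "y"), np.array([[3, 4]]))
        with pytest.raises(ValueError):
            raup_crick_bray(table, NullConfig(n_randomizations=10, seed=0))

    def test_clear_classifications_robust_to_randomization_count(self):
        # fewer randomizations only widen Monte-Carlo noise: pairs far from
        # the thresholds keep their labels between 200 and 1000 shuffles
        from assemblyproc.process_inference import classify_pair
        from assemblyproc.synthetic_data import (AssemblyScenarioConfig,
                                                 sim_scenario)
        bundle = sim_scenario(AssemblyScenarioConfig(
            "variable_selection", n_samples=8, seed=31))
        labels = {}
        for n_rand in (200, 1000):
            z = bnti_matrix(bundle.table, bundle.tree,
                            NullConfig(n_randomizations=n_rand, seed=9))
            m = z.to_numpy()
            iu = np.triu_indices(8, 1)
            labels[n_rand] = [(b, classify_pair(b, 0.0))
                              for b in m[iu] if abs(b) > 4]
        assert labels[200] and labels[1000]
        assert ([lab for _, lab in labels[200]]
                == [lab for _, lab in labels[1000]])

    def test_null_assembled_table_preserves_margins(self):
        rng = np.random.default_rng(9)
        table = random_table(rng, n_samples=4, n_otus=10, max_count=20)
        nt = null_assembled_table(table, NullConfig(seed=10))
        assert np.array_equal(nt.sample_totals(), table.sample_totals())
        assert np.array_equal((nt.counts > 0).sum(axis=1),
                              (table.counts > 0).sum(axis=1))
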
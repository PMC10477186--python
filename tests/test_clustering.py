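import numpy as np
import pytest
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

import dartpop as dp
from dartpop.clustering import TreeNode, match_cluster_labels
from dartpop.diversity import DistanceMatrix
from tests.conftest import make_matrix


@pytest.fixture(scope="module")
def small_k2_fixture():
    cfg = dp.SimulationConfig(n_pops=2, pop_sizes=(20, 20), n_markers=100,
                              fst=0.4, seed=13)
    return dp.simulate_structured_populations(cfg)


def test_k1_degenerate_q_and_likelihood(small_k2_fixture):
    gm, _, _ = small_k2_fixture
    state = dp.admixture_gibbs(gm, 1, burn_in=200, n_iter=200, seed=0)
    assert np.allclose(state.Q, 1.0)
    # lnL at pooled frequencies (binomial log-likelihood) within MC error
    from dartpop.io_formats import MISSING
    from scipy.stats import binom

    p = dp.allele_frequency(gm)
    ll = 0.0
    for j in range(gm.n_markers):
        col = gm.calls[:, j]
        col = col[col != MISSING]
        ll += binom.logpmf(col, 2, p[j]).sum()
    # posterior draws of P sit below the pooled-frequency maximum by about
    # half a unit per sampled frequency (L/2 in total)
    mean_ll = state.loglik_trace.mean()
    assert ll - 1.5 * gm.n_markers <= mean_ll <= ll


def test_gibbs_seed_determinism(small_k2_fixture):
    gm, _, _ = small_k2_fixture
    a = dp.admixture_gibbs(gm, 2, burn_in=100, n_iter=100, seed=5)
    b = dp.admixture_gibbs(gm, 2, burn_in=100, n_iter=100, seed=5)
    np.testing.assert_array_equal(a.Q, b.Q)
    np.testing.assert_array_equal(a.loglik_trace, b.loglik_trace)


def test_gibbs_q_rows_sum_to_one(small_k2_fixture):
    gm, _, _ = small_k2_fixture
    state = dp.admixture_gibbs(gm, 3, burn_in=100, n_iter=100, seed=6)
    np.testing.assert_allclose(state.Q.sum(axis=1), 1.0, atol=1e-9)


def test_gibbs_recovers_two_pops(small_k2_fixture):
    gm, labels, _ = small_k2_fixture
    state = dp.admixture_gibbs(gm, 2, burn_in=500, n_iter=500, seed=7)
    Q = match_cluster_labels(state.Q, labels)
    assert (Q.argmax(axis=1) == labels).mean() >= 0.95


def test_gibbs_rejects_bad_inputs(small_k2_fixture):
    gm, _, _ = small_k2_fixture
    with pytest.raises(ValueError, match="K"):
        dp.admixture_gibbs(gm, 0)
    with pytest.raises(ValueError, match="exceed"):
        dp.admixture_gibbs(gm, gm.n_samples + 1)
    from dartpop.io_formats import SILICODART

    sil = make_matrix(np.zeros((4, 3), dtype=int), marker_type=SILICODART)
    with pytest.raises(ValueError, match="SNP"):
        dp.admixture_gibbs(sil, 2)


def test_admixed_q_recovery():
    """A 50/50 admixed individual between two highly diverged populations
    gets a posterior-mean membership near one half."""
    cfg = dp.SimulationConfig(n_pops=2, pop_sizes=(30, 30), n_markers=400,
                              fst=0.5, seed=14)
    gm, labels, freqs = dp.simulate_structured_populations(cfg)
    q_rows = np.tile([0.5, 0.5], (6, 1))
    adm = dp.simulate_admixed(cfg, q_rows, freqs, seed=15)
    combined = gm.concat_samples(adm)
    state = dp.admixture_gibbs(combined, 2, burn_in=800, n_iter=800, seed=16)
    q_adm = state.Q[-6:, :]
    assert np.allclose(q_adm, 0.5, atol=0.1)


def test_evanno_forced_arithmetic():
    lnp = {1: [-5000.0] * 3, 2: [-4010.0, -4000.0, -3990.0],
           3: [-3900.0] * 3, 4: [-3880.0] * 3}
    table = dp.evanno_delta_k(lnp)
    row = table.set_index("K").loc[2]
    sd2 = np.std([-4010.0, -4000.0, -3990.0], ddof=1)
    assert row["l_second"] == pytest.approx(abs(-3900 - 2 * (-4000) + (-5000)))
    assert row["delta_k"] == pytest.approx(900.0 / sd2)


def test_evanno_linear_lnp_gives_zero_delta():
    lnp = {k: [-1000.0 * (5 - k) + o for o in (0.0, 1.0, -1.0)] for k in (1, 2, 3, 4)}
    table = dp.evanno_delta_k(lnp)
    inner = table.dropna(subset=["delta_k"])
    assert (inner["delta_k"].abs() < 1e-9).all()


@pytest.mark.parametrize(
    "q_row,expected",
    [((0.7, 0.2, 0.1), "cluster_1"), ((0.5, 0.3, 0.2), "admixed"),
     ((0.6, 0.4, 0.0), "cluster_1")],
)
def test_sixty_percent_membership_rule(q_row, expected):
    out = dp.assign_clusters(np.array([q_row]), ["s"], threshold=0.60)
    assert out.loc[0, "cluster"] == expected


def test_upgma_hand_case_and_newick(tmp_path):
    D = np.array([[0.0, 0.1, 0.4], [0.1, 0.0, 0.4], [0.4, 0.4, 0.0]])
    dm = DistanceMatrix(["a", "b", "c"], D)
    tree = dp.upgma(dm)
    first = tree.children[0] if not tree.children[0].is_leaf else tree.children[1]
    assert sorted(first.leaves()) == ["a", "b"]
    assert first.height == pytest.approx(0.05)
    assert tree.height == pytest.approx(0.2)
    path = tmp_path / "t.nwk"
    dp.export_newick(tree, path)
    import dendropy

    parsed = dendropy.Tree.get(path=str(path), schema="newick")
    assert {l.taxon.label for l in parsed.leaf_node_iter()} == {"a", "b", "c"}


def test_upgma_is_ultrametric(two_pop_panel):
    gm = two_pop_panel[0]
    dm = dp.nei_distance_individuals(gm.select_samples(gm.sample_ids[:25]))
    tree = dp.upgma(dm)

    def depths(node, acc=0.0):
        if node.is_leaf:
            return [acc]
        out = []
        for c in node.children:
            out += depths(c, acc + node.height - c.height)
        return out

    d = depths(tree)
    assert np.allclose(d, d[0], atol=1e-9)


def test_upgma_matches_scipy_average_linkage():
    """Merge heights agree with scipy's average-linkage on random matrices."""
    rng = np.random.default_rng(17)
    for _ in range(5):
        X = rng.normal(size=(6, 4))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(6)], D)
        tree = dp.upgma(dm)

        def heights(node):
            if node.is_leaf:
                return []
            return [node.height] + heights(node.children[0]) + heights(node.children[1])

        mine = sorted(2 * h for h in heights(tree))
        ref = sorted(average(squareform(D))[:, 2])
        np.testing.assert_allclose(mine, ref, atol=1e-10)


def test_pca_matches_svd_oracle_and_separates_groups():
    rng = np.random.default_rng(18)
    calls = rng.integers(0, 3, size=(10, 20))
    gm = make_matrix(calls)
    scores, explained = dp.pca_genotypes(gm, 3)
    X = calls - calls.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    np.testing.assert_allclose(np.abs(scores), np.abs(U[:, :3] * S[:3]), atol=1e-8)
    np.testing.assert_allclose(explained, S[:3] ** 2 / (S**2).sum(), atol=1e-12)
    assert explained.sum() <= 1.0 + 1e-12
    assert (np.diff(explained) <= 1e-12).all()

    fixed = np.array([[0] * 20] * 5 + [[2] * 20] * 5, dtype=np.int16)
    s2, e2 = dp.pca_genotypes(make_matrix(fixed), 2)
    assert e2[0] > 0.99
    assert (s2[:5, 0] * s2[5:, 0] < 0).all()  # PC1 separates the groups
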
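import itertools

import numpy as np
import pytest

import dartpop as dp
from dartpop.diversity import (
    DistanceMatrix,
    combined_triangle_table,
    group_allele_frequencies,
)
from dartpop.io_formats import MISSING
from tests.conftest import make_matrix


# ---------------------------------------------------------------------------
# Brute-force oracles from the definitions
# ---------------------------------------------------------------------------


def nei_oracle(p1, p2):
    """Nei 1972 from per-locus frequency vectors, straight from the formula."""
    jxy = np.mean([a * b + (1 - a) * (1 - b) for a, b in zip(p1, p2)])
    jx = np.mean([a * a + (1 - a) * (1 - a) for a in p1])
    jy = np.mean([b * b + (1 - b) * (1 - b) for b in p2])
    return -np.log(jxy / np.sqrt(jx * jy))


def wc_theta_oracle(calls, labels):
    """Two-group Weir-Cockerham theta by direct per-locus components."""
    num = den = 0.0
    r = 2
    for l in range(calls.shape[1]):
        ns, ps, hs = [], [], []
        for g in (0, 1):
            col = calls[labels == g, l]
            col = col[col != MISSING]
            if len(col) == 0:
                break
            ns.append(len(col))
            ps.append(col.sum() / (2 * len(col)))
            hs.append((col == 1).mean())
        else:
            n1, n2 = ns
            nbar = (n1 + n2) / 2
            if nbar <= 1:
                continue
            nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
            pbar = (n1 * ps[0] + n2 * ps[1]) / (n1 + n2)
            if pbar <= 0 or pbar >= 1:
                continue
            s2 = (n1 * (ps[0] - pbar) ** 2 + n2 * (ps[1] - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * hs[0] + n2 * hs[1]) / (n1 + n2)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


def test_nei_groups_hand_case():
    # single locus, p1 = 1.0, p2 = 0.5: I = 0.5/sqrt(0.5) -> D = -ln(0.7071)
    calls = np.array([[2], [2], [1], [1]], dtype=np.int16)
    gm = make_matrix(calls)
    grouping = {"s00": "x", "s01": "x", "s02": "y", "s03": "y"}
    dm = dp.nei_distance_groups(gm, grouping)
    assert dm.get("x", "y") == pytest.approx(0.34657, abs=1e-4)


def test_nei_identical_frequencies_is_zero():
    calls = np.array([[0, 1, 2], [2, 1, 0], [0, 1, 2], [2, 1, 0]], dtype=np.int16)
    gm = make_matrix(calls)
    grouping = {"s00": "x", "s01": "x", "s02": "y", "s03": "y"}
    assert dp.nei_distance_groups(gm, grouping).get("x", "y") == pytest.approx(0.0, abs=1e-12)


def test_nei_individuals_matches_oracle_small():
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 3, size=(4, 3))
    gm = make_matrix(calls)
    dm = dp.nei_distance_individuals(gm)
    for i, j in itertools.combinations(range(4), 2):
        expect = nei_oracle(calls[i] / 2.0, calls[j] / 2.0)
        assert dm.values[i, j] == pytest.approx(max(expect, 0.0), abs=1e-10)


def test_nei_individuals_consistent_with_group_entry_point():
    rng = np.random.default_rng(1)
    calls = rng.integers(0, 3, size=(2, 50))
    gm = make_matrix(calls)
    dm_ind = dp.nei_distance_individuals(gm)
    grouping = {"s00": "a", "s01": "b"}
    dm_grp = dp.nei_distance_groups(gm, grouping)
    assert dm_ind.values[0, 1] == pytest.approx(dm_grp.get("a", "b"), abs=1e-10)


def test_nei_self_distance_zero(two_pop_panel):
    gm = two_pop_panel[0]
    dm = dp.nei_distance_individuals(gm.select_samples(gm.sample_ids[:10]))
    assert np.allclose(np.diag(dm.values), 0.0)


def test_group_nei_stable_across_seeds():
    """Balding-Nichols panels at F = 0.10 put the between-population Nei
    distance in a narrow, seed-reproducible band."""
    vals = []
    for seed in (1, 2, 3):
        cfg = dp.SimulationConfig(n_pops=2, pop_sizes=(100, 100), n_markers=2000,
                                  fst=0.10, seed=seed)
        gm, labels, _ = dp.simulate_structured_populations(cfg)
        grouping = {s: f"p{l}" for s, l in zip(gm.sample_ids, labels)}
        vals.append(dp.nei_distance_groups(gm, grouping).get("p0", "p1"))
    assert max(vals) - min(vals) < 0.01
    assert 0.03 < np.mean(vals) < 0.09


def test_theta_matches_oracle_and_model(two_pop_panel):
    gm, labels, _, grouping = two_pop_panel
    theta = dp.weir_cockerham_theta(gm, grouping)
    assert theta == pytest.approx(wc_theta_oracle(gm.calls, labels), abs=1e-12)
    assert 0.08 <= theta <= 0.12  # Balding-Nichols expectation E[theta] = F = 0.10


def test_theta_complete_fixation_is_one():
    calls = np.array([[0] * 20] * 5 + [[2] * 20] * 5, dtype=np.int16)
    gm = make_matrix(calls)
    grouping = {s: ("a" if i < 5 else "b") for i, s in enumerate(gm.sample_ids)}
    assert dp.weir_cockerham_theta(gm, grouping) == pytest.approx(1.0)


def test_fst_pairwise_symmetric_and_clamped(two_pop_panel):
    gm, _, _, grouping = two_pop_panel
    fst = dp.fst_pairwise(gm, grouping)
    np.testing.assert_allclose(fst.theta, fst.theta.T)
    assert (fst.theta >= 0).all()
    assert np.allclose(np.diag(fst.theta), 0.0)


def test_sample_order_invariance(two_pop_panel):
    gm, _, _, grouping = two_pop_panel
    sub = gm.select_samples(gm.sample_ids[:30] + gm.sample_ids[100:130])
    rng = np.random.default_rng(2)
    shuffled_ids = list(sub.sample_ids)
    rng.shuffle(shuffled_ids)
    shuffled = sub.select_samples(shuffled_ids)
    assert dp.weir_cockerham_theta(sub, grouping) == pytest.approx(
        dp.weir_cockerham_theta(shuffled, grouping), abs=1e-12
    )


@pytest.mark.parametrize(
    "theta,expected",
    [(0.0, "low"), (0.049, "low"), (0.05, "moderate"), (0.08, "moderate"),
     (0.15, "high"), (0.25, "high"), (0.47, "very high")],
)
def test_classify_fst_bands(theta, expected):
    assert dp.classify_fst(theta) == expected


def test_amova_two_fixed_groups():
    calls = np.array([[0] * 30] * 6 + [[2] * 30] * 6, dtype=np.int16)
    gm = make_matrix(calls)
    grouping = {s: ("a" if i < 6 else "b") for i, s in enumerate(gm.sample_ids)}
    res = dp.amova(gm, grouping, n_permutations=99, seed=0)
    assert res.pct_among == pytest.approx(100.0)
    assert res.p_value == pytest.approx(1 / 100)
    assert res.sigma_total == pytest.approx(res.sigma_among + res.sigma_within)


def test_amova_agrees_with_theta(two_pop_panel):
    gm, _, _, grouping = two_pop_panel
    res = dp.amova(gm, grouping, n_permutations=49, seed=1)
    theta = dp.weir_cockerham_theta(gm, grouping)
    assert res.phi_st == pytest.approx(theta, abs=0.02)


def test_amova_excludes_singleton_groups(two_pop_panel):
    gm, _, _, grouping = two_pop_panel
    grouping = dict(grouping)
    grouping[gm.sample_ids[0]] = "lonely"
    res = dp.amova(gm, grouping, n_permutations=9, seed=2)
    assert res.df_among == 1  # only the two real groups remain


def test_amova_distance_matrix_path_matches_ssd_oracle():
    """The Excoffier squared-distance path reproduces a direct sum-of-squares
    partition computed from the definitions."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(12, 5))
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    ids = [f"s{i}" for i in range(12)]
    grouping = {s: ("a" if i < 5 else "b" if i < 9 else "c") for i, s in enumerate(ids)}
    res = dp.amova(DistanceMatrix(ids, D, metric="euclid"), grouping,
                   n_permutations=9, seed=3)
    D2 = D**2
    ssd_total = D2.sum() / (2 * 12)
    ssd_within = 0.0
    sizes = []
    for g in ("a", "b", "c"):
        rows = [i for i, s in enumerate(ids) if grouping[s] == g]
        sizes.append(len(rows))
        ssd_within += D2[np.ix_(rows, rows)].sum() / (2 * len(rows))
    ms_within = ssd_within / (12 - 3)
    ms_among = (ssd_total - ssd_within) / 2
    n_prime = (12 - sum(s**2 for s in sizes) / 12) / 2
    sigma_a = (ms_among - ms_within) / n_prime
    assert res.phi_st == pytest.approx(sigma_a / (sigma_a + ms_within), abs=1e-12)


def test_within_group_summary_hand_distances():
    D = np.zeros((3, 3))
    D[0, 1] = D[1, 0] = 0.1
    D[0, 2] = D[2, 0] = 0.2
    D[1, 2] = D[2, 1] = 0.3
    dm = DistanceMatrix(["a", "b", "c"], D)
    table = dp.within_group_distance_summary(dm, {"a": "g", "b": "g", "c": "g"})
    row = table.iloc[0]
    assert (row["min"], row["max"], row["mean"]) == (0.1, 0.3, pytest.approx(0.2))


def test_within_group_summary_singleton_flagged():
    dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.5], [0.5, 0.0]]))
    table = dp.within_group_distance_summary(dm, {"a": "g1", "b": "g2"})
    assert not table["defined"].any()
    assert table["min"].isna().all()


def test_combined_triangle_layout(two_pop_panel):
    gm, _, _, grouping = two_pop_panel
    nei = dp.nei_distance_groups(gm, grouping)
    fst = dp.fst_pairwise(gm, grouping)
    table = combined_triangle_table(nei, fst)
    assert table.iloc[0, 1] == pytest.approx(nei.values[0, 1])
    assert table.iloc[1, 0] == pytest.approx(fst.theta[1, 0])
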
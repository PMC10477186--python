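import itertools

import numpy as np
import pytest

import dartpop as dp
from dartpop.io_formats import MISSING
from dartpop.parentage import _pair_state_probs
from tests.conftest import make_matrix


@pytest.fixture(scope="module")
def pedigree_panel():
    """Candidate parents plus progeny of known crosses (no genotyping error)."""
    cfg = dp.SimulationConfig(n_pops=1, pop_sizes=(12,), n_markers=2000, fst=0.1, seed=30)
    gm, _, _ = dp.simulate_structured_populations(cfg)
    parents = gm.sample_ids[:6]
    aug, ped1 = dp.simulate_progeny(gm, parents[0], parents[1], 2, seed=31)
    aug, ped2 = dp.simulate_progeny(aug, parents[2], parents[2], 1, seed=32)
    return aug, parents, ped1, ped2


def test_genotype_pair_table_is_a_distribution():
    p = np.array([0.3, 0.5, 0.9])
    T = _pair_state_probs(p)
    np.testing.assert_allclose(T.sum(axis=0), 1.0, atol=1e-12)


def test_self_pair_k2(two_pop_panel):
    gm = two_pop_panel[0]
    dup = dp.GenotypeMatrix(
        gm.sample_ids[:1] + ["copy"],
        list(gm.markers),
        np.vstack([gm.calls[:1], gm.calls[:1]]),
    )
    est = dp.ml_ibd(dup, (gm.sample_ids[0], "copy"),
                    freqs=dp.allele_frequency(gm))
    assert est.k2 > 0.95
    assert est.kinship >= 0.48


def test_parent_offspring_and_unrelated_kinship(pedigree_panel):
    aug, parents, ped1, _ = pedigree_panel
    kid = ped1["sample_id"].iloc[0]
    po = dp.ml_ibd(aug, (parents[0], kid))
    assert po.kinship == pytest.approx(0.25, abs=0.03)
    assert po.k1 > 0.9
    un = dp.ml_ibd(aug, (parents[3], parents[4]))
    assert abs(un.kinship) < 0.02


def test_em_loglik_monotone(pedigree_panel):
    aug, parents, ped1, _ = pedigree_panel
    est = dp.ml_ibd(aug, (parents[0], ped1["sample_id"].iloc[0]))
    assert np.all(np.diff(est.loglik_trace) >= -1e-9)


def test_ibd_simplex_and_batch_consistency(pedigree_panel):
    aug, parents, ped1, _ = pedigree_panel
    pairs = [(parents[0], ped1["sample_id"].iloc[0]), (parents[3], parents[4])]
    batch = dp.ml_ibd_pairs(aug, pairs)
    for _, row in batch.iterrows():
        assert row[["k0", "k1", "k2"]].sum() == pytest.approx(1.0, abs=1e-9)
        single = dp.ml_ibd(aug, (row["sample_a"], row["sample_b"]))
        assert row["kinship"] == pytest.approx(single.kinship, abs=1e-6)


def test_degenerate_frequencies_error():
    gm = make_matrix(np.zeros((4, 50), dtype=int))
    with pytest.raises(ValueError, match="informative"):
        dp.ml_ibd(gm, ("s00", "s01"))


def test_confirm_seed_parent_recovery(pedigree_panel):
    aug, parents, ped1, _ = pedigree_panel
    kid = ped1["sample_id"].iloc[0]
    # recorded truth -> confirmed
    parent, status = dp.confirm_seed_parent(aug, kid, parents[0], parents)
    assert (parent, status) == (parents[0], "confirmed")
    # recorded swapped -> corrected to a true parent
    parent, status = dp.confirm_seed_parent(aug, kid, parents[4], parents)
    assert status == "corrected" and parent in (parents[0], parents[1])
    # no candidate qualifies -> unconfirmed
    parent, status = dp.confirm_seed_parent(aug, kid, None, parents[3:5])
    assert (parent, status) == (None, "unconfirmed")


def test_pc_error_rule():
    parent = np.array([0, 1, 2, 0, MISSING])
    child = np.array([2, 0, 2, MISSING, 0])
    e, n = dp.mendelian_errors_pc(parent, child)
    assert (e, n) == (1, 3)  # only the 0-vs-2 locus; het never inconsistent
    assert dp.mendelian_errors_pc(child, parent) == (e, n)


def test_ppc_trio_truth_table_exhaustive():
    """All 27 genotype combinations against direct gamete enumeration."""
    for g1, g2, c in itertools.product(range(3), repeat=3):
        allowed = {
            a + b
            for a in ({0} if g1 == 0 else {1} if g1 == 2 else {0, 1})
            for b in ({0} if g2 == 0 else {1} if g2 == 2 else {0, 1})
        }
        e, n = dp.mendelian_errors_ppc(np.array([g1]), np.array([g2]), np.array([c]))
        assert n == 1
        assert e == (0 if c in allowed else 1)


def test_ppc_examples_and_symmetry():
    assert dp.mendelian_errors_ppc(np.array([2]), np.array([2]), np.array([1]))[0] == 1
    assert dp.mendelian_errors_ppc(np.array([0]), np.array([2]), np.array([0]))[0] == 1
    rng = np.random.default_rng(33)
    a, b, c = rng.integers(0, 3, size=(3, 200))
    assert dp.mendelian_errors_ppc(a, b, c) == dp.mendelian_errors_ppc(b, a, c)


def test_ppc_dominates_pc_counts(pedigree_panel):
    aug, parents, ped1, _ = pedigree_panel
    kid = ped1["sample_id"].iloc[0]
    ck = aug.calls[aug.sample_index(kid)]
    for cand in parents[2:4]:
        p1 = aug.calls[aug.sample_index(parents[0])]
        p2 = aug.calls[aug.sample_index(cand)]
        ppc = dp.mendelian_errors_ppc(p1, p2, ck)[0]
        assert ppc >= dp.mendelian_errors_pc(p1, ck)[0]
        assert ppc >= dp.mendelian_errors_pc(p2, ck)[0]


def test_pc_null_rate_matches_enumeration():
    """Expected opposite-homozygote rate for unrelated pairs is
    2 p^2 q^2 per locus under HWE."""
    rng = np.random.default_rng(34)
    p = np.array([0.3, 0.5, 0.7])
    n = 40_000
    g1 = rng.binomial(2, p, size=(n, 3))
    g2 = rng.binomial(2, p, size=(n, 3))
    rate = (np.abs(g1 - g2) == 2).mean(axis=0)
    expect = 2 * (p**2) * ((1 - p) ** 2)
    np.testing.assert_allclose(rate, expect, atol=0.01)


def test_scan_parents_identifies_donor(pedigree_panel):
    aug, parents, ped1, ped2 = pedigree_panel
    progeny = list(ped1["sample_id"]) + list(ped2["sample_id"])
    seed_parents = {**{k: parents[0] for k in ped1["sample_id"]},
                    **{k: parents[2] for k in ped2["sample_id"]}}
    report = dp.scan_parents(aug, progeny, parents, seed_parents)
    donors, freq = dp.pollen_donor_table(report)
    best = donors.set_index("progeny")
    for kid in ped1["sample_id"]:
        assert best.loc[kid, "pollen_parent"] == parents[1]
    # true-trio PPC counts are zero without genotyping error
    ppc = report[(report["relationship"] == "PPC")
                 & (report["parent2"] == parents[1])]
    assert (ppc[ppc["progeny"].isin(ped1["sample_id"])]["errors"] == 0).all()


def test_gap_threshold_forced_arithmetic():
    out = dp.gap_threshold([2, 5, 8, 150, 200])
    assert out["distinct"] and out["threshold"] == pytest.approx(79.0)
    flat = dp.gap_threshold([10, 20, 30, 40])
    assert not flat["distinct"] and flat["threshold"] is None


def test_gap_threshold_separates_truth_classes(pedigree_panel):
    aug, parents, ped1, _ = pedigree_panel
    kid = ped1["sample_id"].iloc[0]
    ck = aug.calls[aug.sample_index(kid)]
    counts = []
    truth = []
    for cand in parents:
        e, _ = dp.mendelian_errors_pc(aug.calls[aug.sample_index(cand)], ck)
        counts.append(e)
        truth.append(cand in (parents[0], parents[1]))
    out = dp.gap_threshold(counts)
    assert out["distinct"]
    for e, is_parent in zip(counts, truth):
        assert (e < out["threshold"]) == is_parent


def test_classify_evidence_thresholds():
    import pandas as pd

    report = pd.DataFrame({
        "progeny": ["a", "a"], "relationship": ["PPC", "PPC"],
        "parent1": ["p", "p"], "parent2": ["q", "r"],
        "errors": [10, 200], "n_loci": [500, 500], "error_rate": [0.02, 0.4],
    })
    out = dp.classify_evidence(report, {"PPC": {"threshold": 94.0}})
    assert list(out["evidence"]) == ["strong", "weak"]
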
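"""Nei genetic distances, Weir-Cockerham FST, AMOVA and group summaries.

Nei's (1972) standard genetic distance between two frequency profiles is

    D = -ln I,   I = J_xy / sqrt(J_x J_y)

where J_xy, J_x, J_y are means over loci of sum_i p1i p2i, sum_i p1i^2 and
sum_i p2i^2 (ratio of averages; each biallelic locus contributes p and 1-p).
Individuals are treated as two-allele samples with frequencies 0, 1/2, 1
read off the dosage, which puts clonal duplicates near D = 0 and makes the
0.025 duplicate threshold meaningful.

FST between groups is Weir & Cockerham's theta, the ratio of the summed
among-population variance component to the summed total over loci.  AMOVA
partitions the total molecular variance among and within groups on allele
copies (Excoffier's sum-of-squares formulation), with significance from
permuting individuals among groups; on this scale Phi_ST estimates the same
quantity as theta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix

logger = logging.getLogger("dartpop")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix over individuals or groups."""

    ids: list[str]
    values: np.ndarray
    metric: str = "nei1972"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-9, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass
class FstMatrix:
    ids: list[str]
    theta: np.ndarray            # clamped at 0 for reporting
    theta_raw: np.ndarray        # unclamped estimates
    estimator: str = "weir-cockerham"

    def get(self, a: str, b: str) -> float:
        return float(self.theta[self.ids.index(a), self.ids.index(b)])


@dataclass
class AmovaResult:
    sigma_among: float
    sigma_within: float
    phi_st: float
    df_among: int
    df_within: int
    p_value: float
    n_permutations: int

    @property
    def sigma_total(self) -> float:
        return self.sigma_among + self.sigma_within

    @property
    def pct_among(self) -> float:
        return 100.0 * self.sigma_among / self.sigma_total

    @property
    def pct_within(self) -> float:
        return 100.0 * self.sigma_within / self.sigma_total

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["among groups", "within groups", "total"],
                "df": [self.df_among, self.df_within, self.df_among + self.df_within],
                "variance": [self.sigma_among, self.sigma_within, self.sigma_total],
                "pct": [self.pct_among, self.pct_within, 100.0],
                "phi_st": [self.phi_st, np.nan, np.nan],
                "p_value": [self.p_value, np.nan, np.nan],
            }
        )


# ---------------------------------------------------------------------------
# Allele frequencies per group
# ---------------------------------------------------------------------------


def group_allele_frequencies(
    gm: GenotypeMatrix, grouping: dict[str, str]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-group alternate-allele frequencies and non-missing sample counts.

    Returns (group ids, freqs G x L, counts G x L).  Only SNP markers enter.
    """
    snp_idx = np.flatnonzero(gm.snp_mask)
    groups = sorted(set(grouping.values()))
    freqs = np.full((len(groups), len(snp_idx)), np.nan)
    counts = np.zeros((len(groups), len(snp_idx)))
    calls = gm.calls[:, snp_idx]
    for g, name in enumerate(groups):
        rows = [i for i, s in enumerate(gm.sample_ids) if grouping.get(s) == name]
        sub = calls[rows, :]
        obs = sub != MISSING
        n = obs.sum(axis=0)
        total = np.where(obs, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[g] = np.where(n > 0, total / (2.0 * n), np.nan)
        counts[g] = n
    return groups, freqs, counts


# ---------------------------------------------------------------------------
# Nei (1972) distances
# ---------------------------------------------------------------------------


def _nei_from_freqs(p1: np.ndarray, p2: np.ndarray, unbiased: bool = False,
                    n1: np.ndarray | None = None, n2: np.ndarray | None = None) -> float:
    """Nei distance from two per-locus alt-frequency vectors (NaN = missing).

    ``unbiased`` applies Nei (1978)'s small-sample correction to J_x and J_y
    (requires per-locus sample sizes n1, n2 in individuals).
    """
    ok = ~np.isnan(p1) & ~np.isnan(p2)
    if not ok.any():
        raise ValueError("no loci with data in both groups")
    a1, a2 = p1[ok], p2[ok]
    jxy = np.mean(a1 * a2 + (1 - a1) * (1 - a2))
    jx_loc = a1**2 + (1 - a1) ** 2
    jy_loc = a2**2 + (1 - a2) ** 2
    if unbiased:
        if n1 is None or n2 is None:
            raise ValueError("unbiased correction requires sample sizes")
        m1, m2 = 2.0 * n1[ok], 2.0 * n2[ok]
        jx_loc = (m1 * jx_loc - 1.0) / (m1 - 1.0)
        jy_loc = (m2 * jy_loc - 1.0) / (m2 - 1.0)
    jx, jy = np.mean(jx_loc), np.mean(jy_loc)
    identity = jxy / np.sqrt(jx * jy)
    return float(-np.log(np.clip(identity, 1e-300, None)))


def nei_distance_groups(
    gm: GenotypeMatrix, grouping: dict[str, str], unbiased: bool = False
) -> DistanceMatrix:
    """Pairwise Nei (1972; optionally 1978 unbiased) distance between groups."""
    groups, freqs, counts = group_allele_frequencies(gm, grouping)
    G = len(groups)
    D = np.zeros((G, G))
    for a in range(G):
        for b in range(a + 1, G):
            D[a, b] = D[b, a] = _nei_from_freqs(
                freqs[a], freqs[b], unbiased, counts[a], counts[b]
            )
    return DistanceMatrix(groups, D, "nei1978" if unbiased else "nei1972")


def nei_distance_individuals(gm: GenotypeMatrix) -> DistanceMatrix:
    """Individual-level Nei distance (each sample a 2-allele frequency
    profile: 0, 1/2 or 1 from the dosage), over pairwise-complete loci."""
    snp_idx = np.flatnonzero(gm.snp_mask)
    calls = gm.calls[:, snp_idx].astype(float)
    obs = calls != MISSING
    P = np.where(obs, calls / 2.0, 0.0)
    Q = np.where(obs, 1.0 - calls / 2.0, 0.0)
    M = obs.astype(float)
    # per-pair sums over shared loci
    jxy = P @ P.T + Q @ Q.T
    A = (P**2 + Q**2) * M
    jx = A @ M.T          # sum over shared loci of own homozygosity (row entity)
    n_shared = M @ M.T
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = jxy / np.sqrt(jx * jx.T)
    D = -np.log(np.clip(identity, 1e-300, None))
    np.fill_diagonal(D, 0.0)
    D[n_shared < 1] = np.nan
    D = np.maximum(D, 0.0)
    D = (D + D.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(list(gm.sample_ids), D)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


def _wc_components(
    calls: np.ndarray, group_rows: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components a, b, c for r groups."""
    r = len(group_rows)
    L = calls.shape[1]
    n = np.zeros((r, L))
    p = np.zeros((r, L))
    h = np.zeros((r, L))
    for g, rows in enumerate(group_rows):
        sub = calls[rows, :]
        obs = sub != MISSING
        n[g] = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[g] = np.where(obs, sub, 0).sum(axis=0) / (2.0 * n[g])
            h[g] = np.where(obs & (sub == 1), 1.0, 0.0).sum(axis=0) / n[g]
    nbar = n.mean(axis=0)
    nc = (n.sum(axis=0) - (n**2).sum(axis=0) / n.sum(axis=0)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2.0
    # exclude loci unusable for the estimator
    bad = (n < 1).any(axis=0) | (nbar <= 1) | ~np.isfinite(a + b + c)
    monomorphic = (pbar <= 0) | (pbar >= 1)
    keep = ~(bad | monomorphic)
    return a[keep], b[keep], c[keep]


def weir_cockerham_theta(gm: GenotypeMatrix, grouping: dict[str, str],
                         groups: list[str] | None = None) -> float:
    """Multi-locus theta = sum(a) / sum(a+b+c) over the given groups."""
    snp_idx = np.flatnonzero(gm.snp_mask)
    calls = gm.calls[:, snp_idx]
    names = groups or sorted(set(grouping.values()))
    rows = [
        np.array([i for i, s in enumerate(gm.sample_ids) if grouping.get(s) == g])
        for g in names
    ]
    if any(len(r) == 0 for r in rows):
        raise ValueError("every group needs at least one member")
    a, b, c = _wc_components(calls, rows)
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError("no polymorphic loci among the groups")
    return float(a.sum() / denom)


def fst_pairwise(gm: GenotypeMatrix, grouping: dict[str, str]) -> FstMatrix:
    """Pairwise Weir-Cockerham theta between all groups; negative estimates
    are clamped to 0 for reporting (raw values kept)."""
    names = sorted(set(grouping.values()))
    G = len(names)
    raw = np.zeros((G, G))
    for i in range(G):
        for j in range(i + 1, G):
            raw[i, j] = raw[j, i] = weir_cockerham_theta(gm, grouping, [names[i], names[j]])
    clamped = np.maximum(raw, 0.0)
    if (raw < 0).any():
        logger.info("fst_pairwise: %d negative estimates clamped to 0",
                    int((raw < 0).sum() // 2))
    return FstMatrix(names, clamped, raw)


def classify_fst(theta: float) -> str:
    """Differentiation bands: [0,0.05) low, [0.05,0.15) moderate,
    [0.15,0.25] high, >0.25 very high (boundaries assigned upward except the
    0.25 endpoint, which the convention includes in 'high')."""
    if theta < 0.05:
        return "low"
    if theta < 0.15:
        return "moderate"
    if theta <= 0.25:
        return "high"
    return "very high"


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def amova(
    data: GenotypeMatrix | DistanceMatrix,
    grouping: dict[str, str],
    n_permutations: int = 199,
    seed: int | None = 0,
) -> AmovaResult:
    """One-level AMOVA with a permutation test on Phi_ST.

    With a genotype matrix, each diploid call contributes two allele copies
    (missing calls mean-imputed), so Phi_ST is on the same scale as
    Weir-Cockerham theta; with a precomputed distance matrix, Excoffier's
    squared-distance formulation over individuals is used.  Groups of size 1
    are excluded with a warning.  p = (#{perm Phi >= obs} + 1)/(n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    ids = data.sample_ids if isinstance(data, GenotypeMatrix) else data.ids
    labels = [grouping.get(s) for s in ids]
    counts = pd.Series([l for l in labels if l is not None]).value_counts()
    valid_groups = set(counts[counts >= 2].index)
    dropped = set(counts.index) - valid_groups
    if dropped:
        logger.warning("amova: excluding size-1 group(s) %s", sorted(dropped))
    keep = [i for i, l in enumerate(labels) if l in valid_groups]
    if len(valid_groups) < 2:
        raise ValueError("AMOVA needs >= 2 groups with >= 2 members each")
    labels = np.array([labels[i] for i in keep])

    if isinstance(data, GenotypeMatrix):
        snp_idx = np.flatnonzero(data.snp_mask)
        calls = data.calls[np.ix_(keep, snp_idx)].astype(float)
        obs = calls != MISSING
        with np.errstate(invalid="ignore"):
            col_mean = np.where(obs, calls, np.nan)
            col_mean = np.nanmean(col_mean, axis=0)
        calls = np.where(obs, calls, col_mean[None, :])
        # per-individual allele-copy value sums (= dosage) and sums of squares
        # per locus: observed copies are 0/1 so the sum of squares equals the
        # dosage; an imputed call contributes two copies of value col_mean/2
        s = calls
        q = np.where(obs, calls, 2.0 * (col_mean[None, :] / 2.0) ** 2)
        return _amova_allele(s, q, labels, n_permutations, rng)

    D2 = np.asarray(data.values)[np.ix_(keep, keep)] ** 2
    return _amova_distance(D2, labels, n_permutations, rng)


def _phi_allele(s: np.ndarray, q: np.ndarray, labels: np.ndarray,
                group_names: np.ndarray) -> tuple[float, float, float, int, int]:
    N, L = s.shape
    G = len(group_names)
    member = (labels[None, :] == group_names[:, None]).astype(float)  # G x N
    n_g = member.sum(axis=1)
    S_g = member @ s                     # G x L group copy sums
    Q_tot = q.sum()
    S_tot = s.sum(axis=0)                # L
    ssd_total = Q_tot - (S_tot**2).sum() / (2.0 * N)
    ssd_within = Q_tot - ((S_g**2) / (2.0 * n_g)[:, None]).sum()
    ssd_among = ssd_total - ssd_within
    df_among, df_within = G - 1, 2 * N - G
    ms_among = ssd_among / df_among
    ms_within = ssd_within / df_within
    copies = 2.0 * n_g
    n_prime = (copies.sum() - (copies**2).sum() / copies.sum()) / df_among
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n_prime
    phi = sigma_a / (sigma_a + sigma_w)
    return phi, sigma_a, sigma_w, df_among, df_within


def _amova_allele(s, q, labels, n_permutations, rng) -> AmovaResult:
    group_names = np.array(sorted(set(labels)))
    phi, sa, sw, dfa, dfw = _phi_allele(s, q, labels, group_names)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        p_phi = _phi_allele(s, q, perm, group_names)[0]
        if p_phi >= phi:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return AmovaResult(float(sa), float(sw), float(phi), dfa, dfw, float(p), n_permutations)


def _phi_distance(D2: np.ndarray, labels: np.ndarray,
                  group_names: np.ndarray) -> tuple[float, float, float, int, int]:
    N = D2.shape[0]
    ssd_total = D2.sum() / (2.0 * N)
    ssd_within = 0.0
    n_g = []
    for g in group_names:
        rows = np.flatnonzero(labels == g)
        n_g.append(len(rows))
        ssd_within += D2[np.ix_(rows, rows)].sum() / (2.0 * len(rows))
    n_g = np.array(n_g, dtype=float)
    G = len(group_names)
    ssd_among = ssd_total - ssd_within
    df_among, df_within = G - 1, N - G
    ms_among = ssd_among / df_among
    ms_within = ssd_within / df_within
    n_prime = (N - (n_g**2).sum() / N) / df_among
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n_prime
    phi = sigma_a / (sigma_a + sigma_w)
    return phi, sigma_a, sigma_w, df_among, df_within


def _amova_distance(D2, labels, n_permutations, rng) -> AmovaResult:
    group_names = np.array(sorted(set(labels)))
    phi, sa, sw, dfa, dfw = _phi_distance(D2, labels, group_names)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _phi_distance(D2, perm, group_names)[0] >= phi:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return AmovaResult(float(sa), float(sw), float(phi), dfa, dfw, float(p), n_permutations)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def within_group_distance_summary(
    dm: DistanceMatrix, grouping: dict[str, str]
) -> pd.DataFrame:
    """Min/max/mean pairwise distance within each group; singleton groups are
    flagged undefined (NaN)."""
    rows = []
    groups = sorted(set(grouping.values()))
    index = {s: i for i, s in enumerate(dm.ids)}
    for g in groups:
        members = [index[s] for s in dm.ids if grouping.get(s) == g]
        if len(members) < 2:
            rows.append({"group": g, "n": len(members), "min": np.nan, "max": np.nan,
                         "mean": np.nan, "defined": False})
            continue
        sub = dm.values[np.ix_(members, members)]
        tri = sub[np.triu_indices(len(members), 1)]
        rows.append({"group": g, "n": len(members), "min": float(tri.min()),
                     "max": float(tri.max()), "mean": float(tri.mean()), "defined": True})
    return pd.DataFrame(rows)


def combined_triangle_table(nei: DistanceMatrix, fst: FstMatrix) -> pd.DataFrame:
    """Nei distance above the diagonal, FST below, zero diagonal."""
    if nei.ids != fst.ids:
        raise ValueError("entity sets differ")
    n = len(nei.ids)
    out = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    il = np.tril_indices(n, -1)
    out[iu] = nei.values[iu]
    out[il] = fst.theta[il]
    return pd.DataFrame(out, index=nei.ids, columns=nei.ids)
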
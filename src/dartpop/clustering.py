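"""Admixture-model Gibbs sampling, Evanno delta-K, UPGMA and PCA.

The admixture model assumes each individual i draws every allele copy from
one of K latent clusters with probabilities Q_i (its ancestry vector), and
cluster k carries allele frequency P_kl at locus l.  The Gibbs sampler
cycles

    Z | P, Q   (origin of each allele copy)
    P | Z ~ Dirichlet(lambda + allele counts)      [independent-frequency prior]
    Q | Z ~ Dirichlet(alpha + copy counts)

and records post-burn-in means of Q and P plus the data log-likelihood
trace.  The model evidence for a given K is summarized by the usual
mean-minus-half-variance estimator of ln P(X|K) so that replicate runs feed
directly into the Evanno delta-K table.  Individuals whose maximum
membership falls below 60% are reported as admixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io_formats import MISSING, GenotypeMatrix
from .diversity import DistanceMatrix


@dataclass
class AdmixtureState:
    """Posterior summaries of one admixture-model run."""

    K: int
    Q: np.ndarray                 # samples x K posterior mean memberships
    P: np.ndarray                 # K x markers posterior mean frequencies
    alpha: float
    loglik_trace: np.ndarray      # post-burn-in data log-likelihood samples
    sample_ids: list[str]

    @property
    def ln_prob_data(self) -> float:
        """STRUCTURE-style ln P(X|K): mean(lnL) - var(lnL)/2."""
        t = self.loglik_trace
        return float(t.mean() - t.var() / 2.0)


def admixture_gibbs(
    gm: GenotypeMatrix,
    K: int,
    burn_in: int = 2000,
    n_iter: int = 2000,
    seed: int | None = 0,
    alpha: float = 1.0,
    lam: float = 1.0,
) -> AdmixtureState:
    """Gibbs sampler for the admixture model on a biallelic SNP matrix."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_samples:
        raise ValueError("K cannot exceed the number of samples")
    if not gm.snp_mask.all():
        raise ValueError("admixture model requires SNP dosage markers only")
    rng = np.random.default_rng(seed)
    calls = gm.calls
    obs = calls != MISSING
    alt = np.where(obs, calls, 0).astype(float)     # alt copies per (i, l)
    ref = np.where(obs, 2 - calls, 0).astype(float)  # ref copies
    N, L = calls.shape

    Q = rng.dirichlet(np.full(K, alpha), size=N)
    P = rng.uniform(0.2, 0.8, size=(K, L))
    q_sum = np.zeros_like(Q)
    p_sum = np.zeros_like(P)
    trace = np.empty(n_iter)
    kept = 0

    for it in range(burn_in + n_iter):
        # Z | P,Q: per cell, origin weights for an alt copy are q_ik p_kl and
        # for a ref copy q_ik (1 - p_kl); counts are multinomial splits drawn
        # by a sequential-binomial scheme vectorized over (i, l).
        alt_counts = np.zeros((K, L))
        ref_counts = np.zeros((K, L))
        n_copies_k = np.zeros((N, K))
        w_alt = Q[:, :, None] * P[None, :, :]        # N x K x L
        w_ref = Q[:, :, None] * (1.0 - P[None, :, :])
        for counts_out, weights, totals in (
            (alt_counts, w_alt, alt),
            (ref_counts, w_ref, ref),
        ):
            remaining = totals.copy()
            tail = weights.sum(axis=1)               # N x L
            for k in range(K - 1):
                wk = weights[:, k, :]
                with np.errstate(invalid="ignore", divide="ignore"):
                    frac = np.where(tail > 0, wk / tail, 0.0)
                draw = rng.binomial(remaining.astype(np.int64), np.clip(frac, 0.0, 1.0))
                counts_out[k] = counts_out[k] + draw.sum(axis=0)
                n_copies_k[:, k] += draw.sum(axis=1)
                remaining = remaining - draw
                tail = tail - wk
            counts_out[K - 1] = counts_out[K - 1] + remaining.sum(axis=0)
            n_copies_k[:, K - 1] += remaining.sum(axis=1)

        # P | Z and Q | Z
        P = rng.beta(lam + alt_counts, lam + ref_counts)
        P = np.clip(P, 1e-9, 1.0 - 1e-9)
        gam = rng.gamma(alpha + n_copies_k)
        Q = gam / gam.sum(axis=1, keepdims=True)

        if it >= burn_in:
            theta = np.clip(Q @ P, 1e-12, 1.0 - 1e-12)   # per-copy alt prob
            ll = alt * np.log(theta) + ref * np.log1p(-theta)
            het = obs & (calls == 1)
            trace[kept] = ll.sum() + np.log(2.0) * het.sum()
            q_sum += Q
            p_sum += P
            kept += 1

    return AdmixtureState(
        K, q_sum / kept, p_sum / kept, alpha, trace[:kept], list(gm.sample_ids)
    )


def run_replicates(
    gm: GenotypeMatrix,
    k_values,
    n_reps: int = 10,
    burn_in: int = 2000,
    n_iter: int = 2000,
    seed: int = 0,
    alpha: float = 1.0,
) -> dict[int, list[AdmixtureState]]:
    """Replicate admixture runs per K (seeds derived deterministically)."""
    ss = np.random.SeedSequence(seed)
    out: dict[int, list[AdmixtureState]] = {}
    children = ss.spawn(len(list(k_values)) * n_reps)
    i = 0
    for K in k_values:
        out[K] = []
        for _ in range(n_reps):
            child_seed = int(children[i].generate_state(1)[0] % (2**31 - 1))
            out[K].append(
                admixture_gibbs(gm, K, burn_in, n_iter, seed=child_seed, alpha=alpha)
            )
            i += 1
    return out


def evanno_delta_k(lnp_by_k: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno table from replicate ln P(X|K) values per K.

    L'(K) = L(K) - L(K-1); L''(K) = |L(K+1) - 2 L(K) + L(K-1)|;
    delta K = L''(K) / sd(L(K)), defined only for interior K with sd > 0.
    """
    ks = sorted(lnp_by_k)
    mean = {k: float(np.mean(lnp_by_k[k])) for k in ks}
    sd = {k: float(np.std(lnp_by_k[k], ddof=1)) if len(lnp_by_k[k]) > 1 else 0.0
          for k in ks}
    rows = []
    for i, k in enumerate(ks):
        lprime = mean[k] - mean[ks[i - 1]] if i > 0 else np.nan
        if 0 < i < len(ks) - 1:
            lsecond = abs(mean[ks[i + 1]] - 2 * mean[k] + mean[ks[i - 1]])
            delta = lsecond / sd[k] if sd[k] > 0 else np.nan
        else:
            lsecond, delta = np.nan, np.nan
        rows.append({"K": k, "mean_lnp": mean[k], "sd_lnp": sd[k],
                     "l_prime": lprime, "l_second": lsecond, "delta_k": delta})
    return pd.DataFrame(rows)


def best_k(evanno: pd.DataFrame) -> int:
    """K maximizing delta K (interior K only)."""
    valid = evanno.dropna(subset=["delta_k"])
    if valid.empty:
        raise ValueError("no interior K with defined delta K")
    return int(valid.loc[valid["delta_k"].idxmax(), "K"])


def assign_clusters(
    Q: np.ndarray, sample_ids: list[str], threshold: float = 0.60
) -> pd.DataFrame:
    """60%-membership rule: below-threshold maxima are 'admixed'; a maximum
    exactly at the threshold is assigned (inclusive boundary)."""
    Q = np.asarray(Q, dtype=float)
    best = Q.argmax(axis=1)
    prob = Q.max(axis=1)
    label = [f"cluster_{b + 1}" if p >= threshold else "admixed"
             for b, p in zip(best, prob)]
    return pd.DataFrame({"sample_id": sample_ids, "cluster": label,
                         "max_membership": prob})


def match_cluster_labels(Q: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Permute Q's columns to best match integer truth labels (Hungarian
    assignment on co-membership mass); returns the permuted Q."""
    Q = np.asarray(Q, dtype=float)
    K = Q.shape[1]
    gain = np.zeros((K, K))
    for t in range(K):
        mask = truth == t
        if mask.any():
            gain[t] = Q[mask].sum(axis=0)
    rows, cols = linear_sum_assignment(-gain)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    return Q[:, perm]


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Rooted ultrametric tree from average-linkage clustering."""

    name: str | None = None
    height: float = 0.0                       # merge height (root-to-tip / 2 scale)
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [l for c in self.children for l in c.leaves()]

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return self.name.replace(" ", "_")
        parts = []
        for child in self.children:
            bl = self.height - child.height
            parts.append(f"{child._newick_inner()}:{bl:.6g}")
        return "(" + ",".join(parts) + ")"


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) agglomeration with a deterministic tie-break:
    among equally close pairs, the one whose lexicographically smallest
    member id is smallest merges first."""
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least two entities")
    D = dm.values.astype(float).copy()
    active: dict[int, TreeNode] = {i: TreeNode(name=dm.ids[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    minleaf = {i: dm.ids[i] for i in range(n)}
    idx = list(range(n))
    while len(idx) > 1:
        sub = D[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, np.inf)
        sub[np.tril_indices(len(idx), -1)] = np.inf
        dmin = sub.min()
        ties = [(idx[i], idx[j]) for i, j in np.argwhere(sub == dmin)]
        a, b = min(
            ties,
            key=lambda ab: (min(minleaf[ab[0]], minleaf[ab[1]]),
                            max(minleaf[ab[0]], minleaf[ab[1]])),
        )
        h = D[a, b] / 2.0
        node = TreeNode(height=h, children=(active[a], active[b]))
        # UPGMA update: weighted average of distances
        for c in idx:
            if c in (a, b):
                continue
            D[a, c] = D[c, a] = (sizes[a] * D[a, c] + sizes[b] * D[b, c]) / (
                sizes[a] + sizes[b]
            )
        sizes[a] += sizes[b]
        minleaf[a] = min(minleaf[a], minleaf[b])
        active[a] = node
        idx.remove(b)
        del active[b], sizes[b], minleaf[b]
    return active[idx[0]]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_genotypes(
    gm: GenotypeMatrix, n_components: int = 10, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the genotype matrix: mean-impute missing per marker, center
    (optionally scale), eigendecompose the sample covariance.

    Returns (scores n_samples x n_components, variance-explained fractions).
    """
    X = gm.calls.astype(float)
    X = np.where(gm.calls == MISSING, np.nan, X)
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean[None, :], X) - mean[None, :]
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    n_components = min(n_components, min(X.shape) - 1) or 1
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = (S**2).sum()
    scores = U[:, :n_components] * S[:n_components]
    explained = (S[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return scores, explained
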
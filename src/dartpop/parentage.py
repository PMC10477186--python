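"""Maximum-likelihood IBD relatedness and Mendelian-inconsistency parentage.

Relatedness between two non-inbred diploids is summarized by (k0, k1, k2),
the probabilities of sharing 0/1/2 alleles identical by descent at a locus;
kinship is phi = k2/2 + k1/4 (0.5 for self/clones, 0.25 for
parent-offspring, 0 for unrelated pairs).  The coefficients are fitted by EM
on the mixture likelihood

    lnL = sum_loci ln sum_m k_m P(g1, g2 | IBD = m, p)

using the standard genotype-pair probability table under Hardy-Weinberg
allele frequencies p.

Parent-offspring hypotheses are screened by counting Mendelian-inconsistent
loci: for a single candidate parent only opposite homozygotes (0 vs 2) are
impossible, while the trio test checks whether the child genotype can be
assembled from one allele of each hypothesized parent.  Low counts indicate
a real relationship; a gap in the sorted counts separates strong from weak
evidence, formalized here as the largest consecutive gap in the lower half
of the count range that exceeds twice the median consecutive spacing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix

logger = logging.getLogger("dartpop")

PC1, PC2, PPC = "PC1", "PC2", "PPC"


@dataclass
class RelatednessEstimate:
    sample_a: str
    sample_b: str
    k0: float
    k1: float
    k2: float
    loglik: float
    n_loci: int
    loglik_trace: np.ndarray | None = None

    @property
    def kinship(self) -> float:
        return self.k2 / 2.0 + self.k1 / 4.0


def _pair_state_probs(p: np.ndarray) -> np.ndarray:
    """(9, L, 3) table: P(g1, g2 | IBD state, p) for dosages g1, g2 in 0..2.

    ``p`` is the alternate-allele frequency per locus; category index is
    3 * g1 + g2.
    """
    q = 1.0 - p
    P0g = np.stack([q**2, 2 * p * q, p**2])            # HWE genotype probs
    L = p.shape[0]
    T = np.zeros((9, L, 3))
    for g1 in range(3):
        for g2 in range(3):
            T[3 * g1 + g2, :, 0] = P0g[g1] * P0g[g2]
    # one allele IBD
    T[3 * 2 + 2, :, 1] = p**3
    T[3 * 2 + 1, :, 1] = T[3 * 1 + 2, :, 1] = p**2 * q
    T[3 * 1 + 1, :, 1] = p * q
    T[3 * 1 + 0, :, 1] = T[3 * 0 + 1, :, 1] = p * q**2
    T[3 * 0 + 0, :, 1] = q**3
    # both alleles IBD
    T[3 * 2 + 2, :, 2] = p**2
    T[3 * 1 + 1, :, 2] = 2 * p * q
    T[3 * 0 + 0, :, 2] = q**2
    return T


def ml_ibd_pairs(
    gm: GenotypeMatrix,
    pairs: list[tuple[str, str]],
    freqs: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    chunk: int = 512,
) -> pd.DataFrame:
    """EM maximum-likelihood (k0, k1, k2) for many pairs at once.

    Allele frequencies default to the sample frequencies of the matrix.
    Returns a DataFrame with k0..k2, kinship, loglik and n_loci per pair.
    """
    snp_idx = np.flatnonzero(gm.snp_mask)
    calls = gm.calls[:, snp_idx]
    if freqs is None:
        obs = calls != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = np.where(n > 0, np.where(obs, calls, 0).sum(axis=0) / (2.0 * n), np.nan)
    freqs = np.asarray(freqs, dtype=float)
    informative = np.isfinite(freqs) & (freqs > 0.0) & (freqs < 1.0)
    if not informative.any():
        raise ValueError("no informative loci (all frequencies fixed or undefined)")
    calls = calls[:, informative]
    p = np.clip(freqs[informative], 1e-9, 1 - 1e-9)
    T = _pair_state_probs(p)                       # (9, L, 3)
    index = {s: i for i, s in enumerate(gm.sample_ids)}

    rows = []
    for lo in range(0, len(pairs), chunk):
        batch = pairs[lo:lo + chunk]
        i1 = np.array([index[a] for a, _ in batch])
        i2 = np.array([index[b] for _, b in batch])
        g1, g2 = calls[i1, :], calls[i2, :]
        ok = (g1 != MISSING) & (g2 != MISSING)
        cat = np.where(ok, 3 * g1 + g2, 0)
        probs = T[cat, np.arange(T.shape[1])[None, :], :]   # (C, L, 3)
        probs = np.where(ok[:, :, None], probs, 1.0)  # missing loci contribute nothing
        n_loci = ok.sum(axis=1)
        if (n_loci < 100).any():
            warnings.warn("fewer than 100 informative loci for some pairs")
        k = np.full((len(batch), 3), 1.0 / 3.0)
        prev = np.full(len(batch), -np.inf)
        for _ in range(max_iter):
            mix = (probs * k[:, None, :]).sum(axis=2)        # (C, L)
            mix = np.clip(mix, 1e-300, None)
            ll = np.where(ok, np.log(mix), 0.0).sum(axis=1)
            z = probs * k[:, None, :] / mix[:, :, None]
            z = np.where(ok[:, :, None], z, 0.0)
            k = z.sum(axis=1) / np.maximum(n_loci, 1)[:, None]
            if np.all(ll - prev < tol):
                prev = ll
                break
            prev = ll
        for j, (a, b) in enumerate(batch):
            rows.append({"sample_a": a, "sample_b": b, "k0": k[j, 0], "k1": k[j, 1],
                         "k2": k[j, 2], "kinship": k[j, 2] / 2 + k[j, 1] / 4,
                         "loglik": prev[j], "n_loci": int(n_loci[j])})
    return pd.DataFrame(rows)


def ml_ibd(
    gm: GenotypeMatrix,
    pair: tuple[str, str],
    freqs: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> RelatednessEstimate:
    """Single-pair EM fit, keeping the per-iteration log-likelihood trace."""
    snp_idx = np.flatnonzero(gm.snp_mask)
    calls = gm.calls[:, snp_idx]
    if freqs is None:
        obs = calls != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = np.where(n > 0, np.where(obs, calls, 0).sum(axis=0) / (2.0 * n), np.nan)
    freqs = np.asarray(freqs, dtype=float)
    informative = np.isfinite(freqs) & (freqs > 0.0) & (freqs < 1.0)
    if not informative.any():
        raise ValueError("no informative loci (all frequencies fixed or undefined)")
    a, b = pair
    g1 = calls[gm.sample_index(a), informative]
    g2 = calls[gm.sample_index(b), informative]
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 100:
        warnings.warn(f"only {int(ok.sum())} informative loci for pair {pair}")
    p = np.clip(freqs[informative][ok], 1e-9, 1 - 1e-9)
    T = _pair_state_probs(p)
    probs = T[3 * g1[ok] + g2[ok], np.arange(int(ok.sum())), :]   # (L, 3)
    k = np.full(3, 1.0 / 3.0)
    trace = []
    for _ in range(max_iter):
        mix = np.clip(probs @ k, 1e-300, None)
        ll = float(np.log(mix).sum())
        trace.append(ll)
        z = probs * k[None, :] / mix[:, None]
        k = z.mean(axis=0)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
    return RelatednessEstimate(a, b, *k, loglik=trace[-1], n_loci=int(ok.sum()),
                               loglik_trace=np.array(trace))


def confirm_seed_parent(
    gm: GenotypeMatrix,
    progeny: str,
    recorded: str | None,
    candidates: list[str],
    freqs: np.ndarray | None = None,
    floor: float = 0.15,
) -> tuple[str | None, str]:
    """Confirm or correct the recorded seed parent by ML kinship.

    The recorded parent is confirmed when phi >= ``floor`` (between the
    unrelated expectation 0 and the parent-offspring expectation 0.25);
    otherwise the candidate with maximal phi above the floor replaces it
    ("corrected"); with none qualifying the progeny is "unconfirmed".
    """
    est = ml_ibd_pairs(gm, [(progeny, c) for c in candidates], freqs=freqs)
    phi = dict(zip(est["sample_b"], est["kinship"]))
    if recorded is not None and phi.get(recorded, -1.0) >= floor:
        return recorded, "confirmed"
    best = max(candidates, key=lambda c: phi.get(c, -1.0))
    if phi.get(best, -1.0) >= floor:
        return best, "corrected"
    return None, "unconfirmed"


# ---------------------------------------------------------------------------
# Mendelian-inconsistency counting
# ---------------------------------------------------------------------------


def mendelian_errors_pc(
    parent: np.ndarray, child: np.ndarray
) -> tuple[int, int]:
    """Pair test: a locus is inconsistent iff parent and child are opposite
    homozygotes; loci with any missing call are skipped.  Symmetric."""
    parent = np.asarray(parent)
    child = np.asarray(child)
    ok = (parent != MISSING) & (child != MISSING)
    errors = ok & (np.abs(parent - child) == 2)
    return int(errors.sum()), int(ok.sum())


#: allowed child dosages per (parent1, parent2) dosage pair
_TRIO_OK = np.zeros((3, 3, 3), dtype=bool)
for _g1 in range(3):
    for _g2 in range(3):
        for _a in ({0} if _g1 == 0 else {1} if _g1 == 2 else {0, 1}):
            for _b in ({0} if _g2 == 0 else {1} if _g2 == 2 else {0, 1}):
                _TRIO_OK[_g1, _g2, _a + _b] = True


def mendelian_errors_ppc(
    parent1: np.ndarray, parent2: np.ndarray, child: np.ndarray
) -> tuple[int, int]:
    """Trio test: a locus is inconsistent iff the child genotype cannot take
    one allele from each parent (0x0->{0}, 0x2->{1}, 2x2->{2}, 0x1->{0,1},
    1x2->{1,2}, 1x1->{0,1,2}).  Symmetric in the two parents."""
    p1 = np.asarray(parent1)
    p2 = np.asarray(parent2)
    c = np.asarray(child)
    ok = (p1 != MISSING) & (p2 != MISSING) & (c != MISSING)
    consistent = np.zeros_like(ok)
    consistent[ok] = _TRIO_OK[p1[ok], p2[ok], c[ok]]
    return int((ok & ~consistent).sum()), int(ok.sum())


def scan_parents(
    gm: GenotypeMatrix,
    progeny_ids: list[str],
    candidate_ids: list[str],
    seed_parents: dict[str, str],
) -> pd.DataFrame:
    """Mendelian-error report for every progeny against every candidate.

    Rows: PC1 (progeny vs its confirmed seed parent), PC2 (vs every other
    candidate; the minimal count marks the putative pollen parent) and PPC
    (seed parent + each candidate as a trio).  Candidates sharing no called
    loci with a progeny are excluded with a warning.
    """
    snp = np.flatnonzero(gm.snp_mask)
    calls = {s: gm.calls[gm.sample_index(s), snp] for s in set(progeny_ids) | set(candidate_ids)}
    rows = []
    for prog in progeny_ids:
        child = calls[prog]
        sp = seed_parents.get(prog)
        if sp is not None:
            e, n = mendelian_errors_pc(calls[sp], child)
            rows.append({"progeny": prog, "relationship": PC1, "parent1": sp,
                         "parent2": None, "errors": e, "n_loci": n,
                         "error_rate": e / n if n else np.nan})
        for cand in candidate_ids:
            if cand == sp:
                continue
            e, n = mendelian_errors_pc(calls[cand], child)
            if n == 0:
                warnings.warn(f"candidate {cand} shares no called loci with {prog}; excluded")
                continue
            rows.append({"progeny": prog, "relationship": PC2, "parent1": cand,
                         "parent2": None, "errors": e, "n_loci": n,
                         "error_rate": e / n})
            if sp is not None:
                e2, n2 = mendelian_errors_ppc(calls[sp], calls[cand], child)
                rows.append({"progeny": prog, "relationship": PPC, "parent1": sp,
                             "parent2": cand, "errors": e2, "n_loci": n2,
                             "error_rate": e2 / n2 if n2 else np.nan})
    return pd.DataFrame(rows)


def pollen_donor_table(report: pd.DataFrame) -> pd.DataFrame:
    """Per-progeny best PC2 candidate and the donor frequency table."""
    pc2 = report[report["relationship"] == PC2]
    best = pc2.sort_values(["progeny", "errors", "parent1"]).groupby("progeny").first()
    freq = best["parent1"].value_counts().rename_axis("pollen_parent").reset_index(name="n_progeny")
    return best.reset_index()[["progeny", "parent1", "errors", "n_loci"]].rename(
        columns={"parent1": "pollen_parent"}
    ), freq


def gap_threshold(counts, min_gap_factor: float = 2.0) -> dict:
    """Evidence threshold from the largest 'distinct' gap in sorted counts.

    The gap search is restricted to the lower half of the count range; a gap
    is distinct when it exceeds ``min_gap_factor`` times the median
    consecutive spacing.  Returns threshold (midpoint of the gap), the gap
    magnitude and a ``distinct`` flag (threshold None when no gap
    qualifies).
    """
    c = np.sort(np.asarray(list(counts), dtype=float))
    if len(c) < 2:
        return {"threshold": None, "gap": 0.0, "distinct": False, "method": "gap"}
    gaps = np.diff(c)
    mid_range = (c[0] + c[-1]) / 2.0
    lower = np.array([(c[i] + c[i + 1]) / 2.0 <= mid_range for i in range(len(gaps))])
    med = float(np.median(gaps))
    best_gap, best_i = 0.0, None
    for i in np.flatnonzero(lower):
        if gaps[i] > best_gap:
            best_gap, best_i = float(gaps[i]), int(i)
    distinct = best_i is not None and best_gap > min_gap_factor * med and best_gap > 0
    if not distinct:
        return {"threshold": None, "gap": best_gap, "distinct": False, "method": "gap"}
    return {
        "threshold": float((c[best_i] + c[best_i + 1]) / 2.0),
        "gap": best_gap,
        "distinct": True,
        "method": "gap",
    }


def classify_evidence(report: pd.DataFrame, thresholds: dict[str, dict]) -> pd.DataFrame:
    """Annotate each report row strong/weak: counts strictly below the
    relationship's threshold are strong evidence."""
    out = report.copy()

    def _label(row):
        t = thresholds.get(row["relationship"], {}).get("threshold")
        if t is None:
            return "unclassified"
        return "strong" if row["errors"] < t else "weak"

    out["evidence"] = out.apply(_label, axis=1)
    return out
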
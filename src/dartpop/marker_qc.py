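"""Per-marker polymorphism statistics, filtering and LD pruning.

The robust-marker filter mirrors standard germplasm-diversity practice on
DArTseq panels: keep markers that are mapped, have at most 10% missing
calls, minor allele frequency of at least 5%, and are mutually independent
(pairwise genotypic LD r-squared at most 0.5, pruned greedily in a sliding
window along the genome).  A GWAS mode additionally requires call rate
>= 0.90.

He is expected heterozygosity 2pq.  PIC is Botstein's polymorphic
information content, 1 - p^2 - q^2 - 2 p^2 q^2, with maximum 0.375 for a
biallelic locus.  For dominant presence/absence markers the band frequency f
is converted to an allele-frequency estimate q_hat = sqrt(1 - f) (absence
treated as the recessive homozygote) before applying the same formulas; the
alternative convention PIC = He = 2 f (1 - f) is available via
``silico_mode="band"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, _chrom_rank

logger = logging.getLogger("dartpop")


@dataclass
class FilterCriteria:
    """Robust-marker filter thresholds (all fractions in [0, 1])."""

    max_missing: float = 0.10
    min_maf: float = 0.05
    max_ld_r2: float = 0.5
    require_mapped: bool = True
    min_call_rate: float = 0.0  # set to 0.90 for GWAS mode
    ld_window: int = 50
    ld_step: int = 5

    def __post_init__(self):
        for name in ("max_missing", "min_maf", "max_ld_r2", "min_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


GWAS_CRITERIA = FilterCriteria(max_missing=0.10, min_maf=0.05, max_ld_r2=0.5,
                               require_mapped=True, min_call_rate=0.90)


def allele_frequency(gm: GenotypeMatrix) -> np.ndarray:
    """Alternate-allele frequency per SNP marker (band frequency for
    SilicoDArT); NaN where every call is missing."""
    calls = gm.calls.astype(float)
    obs = gm.calls != MISSING
    n = obs.sum(axis=0).astype(float)
    total = np.where(obs, calls, 0.0).sum(axis=0)
    denom = np.where(gm.snp_mask, 2.0 * n, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, total / denom, np.nan)
    return p


def expected_heterozygosity(p) -> np.ndarray:
    """He = 2 p (1 - p); maximum 0.5 at p = 0.5."""
    p = np.asarray(p, dtype=float)
    return 2.0 * p * (1.0 - p)


def pic(p) -> np.ndarray:
    """Botstein's PIC = 1 - p^2 - q^2 - 2 p^2 q^2; maximum 0.375 at p = 0.5."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return 1.0 - p**2 - q**2 - 2.0 * p**2 * q**2


def compute_marker_qc(gm: GenotypeMatrix, silico_mode: str = "recessive") -> pd.DataFrame:
    """Per-marker QC table: call rate, missing rate, MAF, He, PIC, mapped.

    ``silico_mode``: "recessive" converts SilicoDArT band frequency f to
    q_hat = sqrt(1 - f); "band" uses PIC = He = 2 f (1 - f) directly.
    """
    if silico_mode not in ("recessive", "band"):
        raise ValueError("silico_mode must be 'recessive' or 'band'")
    obs = gm.calls != MISSING
    call_rate = obs.mean(axis=0)
    p = allele_frequency(gm)
    snp = gm.snp_mask
    # allele-frequency estimate used by He/PIC
    if silico_mode == "recessive":
        with np.errstate(invalid="ignore"):
            q_hat = np.sqrt(np.clip(1.0 - p, 0.0, 1.0))
        p_eff = np.where(snp, p, 1.0 - q_hat)
        he = expected_heterozygosity(p_eff)
        pic_v = pic(p_eff)
    else:
        he = np.where(snp, expected_heterozygosity(p), expected_heterozygosity(p))
        pic_v = np.where(snp, pic(p), expected_heterozygosity(p))
    maf = np.minimum(p, 1.0 - p)
    return pd.DataFrame(
        {
            "marker_id": gm.marker_ids,
            "marker_type": [m.marker_type for m in gm.markers],
            "chrom": [m.chrom for m in gm.markers],
            "pos": [m.pos for m in gm.markers],
            "call_rate": call_rate,
            "missing_rate": 1.0 - call_rate,
            "maf": maf,
            "he": he,
            "pic": pic_v,
            "mapped": [m.mapped for m in gm.markers],
            "undefined": np.isnan(p),
        }
    )


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Genotypic LD: squared Pearson correlation of two dosage vectors over
    pairwise-complete samples.  Returns NaN with <2 complete pairs or a
    zero-variance vector (callers treat NaN as 0 for pruning)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy)
    return float(r * r)


def _window_r2(calls: np.ndarray) -> np.ndarray:
    """Pairwise-complete r^2 matrix for a block of marker columns."""
    X = calls.astype(float)
    M = (calls != MISSING).astype(float)
    Xm = np.where(M > 0, X, 0.0)
    n = M.T @ M
    sx = Xm.T @ M
    sxy = Xm.T @ Xm
    sxx = (Xm**2).T @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy / n - (sx / n) * (sx.T / n)
        var_x = sxx / n - (sx / n) ** 2
        r2 = cov**2 / (var_x * var_x.T)
    r2[n < 2] = np.nan
    return r2


def ld_prune(
    gm: GenotypeMatrix,
    max_r2: float = 0.5,
    window: int = 50,
    step: int = 5,
) -> list[str]:
    """Greedy sliding-window LD pruning in genome order.

    Within each window, whenever a still-kept pair exceeds ``max_r2`` the
    member with the lower call rate is dropped (ties: lower MAF, then the
    lexicographically greater marker id).  Deterministic given input order.
    Undefined r^2 (zero variance) counts as 0, with a logged note.
    """
    order = sorted(
        range(gm.n_markers),
        key=lambda j: (_chrom_rank(gm.markers[j].chrom), gm.markers[j].pos or 0,
                       gm.markers[j].marker_id),
    )
    obs = gm.calls != MISSING
    call_rate = obs.mean(axis=0)
    p = allele_frequency(gm)
    maf = np.minimum(p, 1.0 - p)
    keep = np.ones(gm.n_markers, dtype=bool)
    n_undefined = 0
    starts = list(range(0, max(1, len(order) - window + 1), step))
    if starts[-1] + window < len(order):  # make sure the tail is covered
        starts.append(len(order) - window)
    for start in starts:
        idx = [j for j in order[start:start + window] if keep[j]]
        if len(idx) < 2:
            continue
        r2 = _window_r2(gm.calls[:, idx])
        n_undefined += int(np.isnan(r2[np.triu_indices(len(idx), 1)]).sum())
        r2 = np.nan_to_num(r2, nan=0.0)
        alive = np.ones(len(idx), dtype=bool)
        for a in range(len(idx)):
            if not alive[a]:
                continue
            for b in range(a + 1, len(idx)):
                if not alive[b] or r2[a, b] <= max_r2:
                    continue
                ja, jb = idx[a], idx[b]
                key_a = (call_rate[ja], maf[ja] if not np.isnan(maf[ja]) else -1.0,
                         _revlex(gm.markers[ja].marker_id))
                key_b = (call_rate[jb], maf[jb] if not np.isnan(maf[jb]) else -1.0,
                         _revlex(gm.markers[jb].marker_id))
                drop_local = a if key_a < key_b else b
                alive[drop_local] = False
                keep[idx[drop_local]] = False
                if drop_local == a:
                    break
    if n_undefined:
        logger.info("ld_prune: %d pairs had undefined r^2 (zero variance), treated as 0",
                    n_undefined)
    return [gm.markers[j].marker_id for j in range(gm.n_markers) if keep[j]]


class _revlex(str):
    """Orders reversed, so min() keeps the lexicographically smaller id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)


def filter_markers(
    gm: GenotypeMatrix, criteria: FilterCriteria | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply, in order: mapped -> missing/call rate -> MAF -> LD pruning.

    Returns the filtered matrix and an audit table with counts removed at
    each step (input = output + sum removed).
    """
    criteria = criteria or FilterCriteria()
    audit_rows = []
    current = gm

    def _log(step: str, before: int, after: int):
        audit_rows.append({"step": step, "n_before": before, "n_after": after,
                           "n_removed": before - after})
        logger.info("filter %s: %d -> %d markers", step, before, after)

    if criteria.require_mapped:
        keep = np.array([m.mapped for m in current.markers])
        nxt = current.select_markers(keep)
        _log("mapped", current.n_markers, nxt.n_markers)
        current = nxt

    obs = current.calls != MISSING
    call_rate = obs.mean(axis=0)
    keep = (1.0 - call_rate <= criteria.max_missing) & (call_rate >= criteria.min_call_rate)
    nxt = current.select_markers(keep)
    _log("missing", current.n_markers, nxt.n_markers)
    current = nxt

    p = allele_frequency(current)
    maf = np.minimum(p, 1.0 - p)
    keep = ~np.isnan(maf) & (maf >= criteria.min_maf)
    nxt = current.select_markers(keep)
    _log("maf", current.n_markers, nxt.n_markers)
    current = nxt

    if criteria.max_ld_r2 < 1.0:
        retained = ld_prune(current, criteria.max_ld_r2, criteria.ld_window, criteria.ld_step)
        nxt = current.select_markers(retained)
        _log("ld", current.n_markers, nxt.n_markers)
        current = nxt

    audit = pd.DataFrame(audit_rows)
    return current, audit


def qc_histogram(qc: pd.DataFrame, stat: str = "pic", n_bins: int = 10) -> pd.DataFrame:
    """Binned counts of a QC statistic (histogram-ready TSV analogue)."""
    values = qc[stat].dropna()
    hi = {"pic": 0.5, "he": 0.5, "maf": 0.5}.get(stat, float(values.max()) or 1.0)
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, hi))
    return pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts})
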
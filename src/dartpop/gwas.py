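"""Marker-trait association: GLM and kinship-corrected MLM.

GLM fits, per marker, y = intercept + PCs + dosage by least squares and
tests the dosage term with an F test; the reported effect is the dosage
coefficient (trait units per allele copy) and r2 the partial R-squared of
the marker term in percent.

MLM adds a polygenic random effect, y = X beta + u + e with
u ~ N(0, sigma_g^2 K) for a VanRaden genomic relationship matrix K.  The
variance ratio delta = sigma_e^2 / sigma_g^2 is profiled once by REML on
the null (covariate-only) model after a spectral decomposition of K
(EMMA-style rotation), then every marker is tested by generalized least
squares at that delta - the population-parameters-previously-determined
shortcut that makes a genome scan a single eigendecomposition plus one
weighted regression per marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .clustering import pca_genotypes
from .io_formats import MISSING, GenotypeMatrix

logger = logging.getLogger("dartpop")


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("kinship shape does not match sample ids")
        self.values = (v + v.T) / 2.0


def kinship_vanraden(gm: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship: centered dosage cross-product scaled
    by 2 sum p(1-p); missing calls mean-imputed.  Diagonal ~ 1 + inbreeding;
    parent-offspring entries ~ 0.5, clones ~ 1."""
    X = gm.calls.astype(float)
    X = np.where(gm.calls == MISSING, np.nan, X)
    p = np.nanmean(X, axis=0) / 2.0
    Z = np.where(np.isnan(X), 0.0, X - 2.0 * p[None, :])
    poly = (p > 0) & (p < 1)
    Z = Z[:, poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return KinshipMatrix(list(gm.sample_ids), Z @ Z.T / denom)


def _dosage_matrix(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed dosages and a polymorphic-marker mask."""
    X = gm.calls.astype(float)
    X = np.where(gm.calls == MISSING, np.nan, X)
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean[None, :], X)
    poly = X.std(axis=0) > 0
    return X, poly


def _covariates(gm: GenotypeMatrix, n_pcs: int) -> np.ndarray:
    n = gm.n_samples
    C = [np.ones((n, 1))]
    if n_pcs > 0:
        scores, _ = pca_genotypes(gm, n_pcs)
        C.append(scores)
    return np.hstack(C)


def _align_phenotype(gm: GenotypeMatrix, phenotype: pd.Series) -> np.ndarray:
    missing = [s for s in gm.sample_ids if s not in phenotype.index]
    if missing:
        raise ValueError(f"phenotype missing for samples: {missing[:5]}...")
    return phenotype.loc[gm.sample_ids].to_numpy(dtype=float)


def _marker_frame(gm: GenotypeMatrix) -> pd.DataFrame:
    p_all = np.array([
        np.nan if not np.isfinite(f) else min(f, 1 - f)
        for f in _allele_freq(gm)
    ])
    return pd.DataFrame({
        "marker_id": gm.marker_ids,
        "marker_type": [m.marker_type for m in gm.markers],
        "chrom": [m.chrom for m in gm.markers],
        "pos": [m.pos for m in gm.markers],
        "allele": [
            f"{m.ref_allele}/{m.alt_allele}" if m.ref_allele else "0/1"
            for m in gm.markers
        ],
        "maf": p_all,
    })


def _allele_freq(gm: GenotypeMatrix) -> np.ndarray:
    from .marker_qc import allele_frequency

    return allele_frequency(gm)


def glm_assoc(phenotype: pd.Series, gm: GenotypeMatrix, n_pcs: int = 3) -> pd.DataFrame:
    """Per-marker least-squares association with PC covariates.

    Returns a Table-style frame (marker, type, chrom, pos, allele, MAF,
    p_value, r2 in percent, effect); monomorphic markers are skipped with a
    log entry.
    """
    y = _align_phenotype(gm, phenotype)
    X, poly = _dosage_matrix(gm)
    C = _covariates(gm, n_pcs)
    n, k = C.shape
    if (~poly).sum():
        logger.info("glm_assoc: skipping %d monomorphic markers", int((~poly).sum()))
    # residualize y and markers on the covariates; the marker t test in the
    # residual space equals the F test for the marker term in the full model
    Cp = np.linalg.pinv(C)
    ry = y - C @ (Cp @ y)
    RX = X - C @ (Cp @ X)
    sxx = (RX**2).sum(axis=0)
    sxy = (RX * ry[:, None]).sum(axis=0)
    safe_sxx = np.where(sxx > 0, sxx, 1.0)
    beta = np.where(sxx > 0, sxy / safe_sxx, np.nan)
    rss0 = float(ry @ ry)
    rss1 = np.maximum(rss0 - np.where(sxx > 0, sxy**2 / safe_sxx, 0.0), 0.0)
    df2 = n - k - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        fstat = (rss0 - rss1) / (rss1 / df2)
        pvals = np.clip(stats.f.sf(fstat, 1, df2), 1e-300, 1.0)
        partial_r2 = np.where(rss0 > 0, (rss0 - rss1) / rss0, np.nan)
    out = _marker_frame(gm)
    out["model"] = "GLM"
    out["p_value"] = pvals
    out["r2"] = 100.0 * partial_r2
    out["effect"] = beta
    return out[poly].reset_index(drop=True)


def _reml_neg_loglik(log_delta: float, lam: np.ndarray, Uty: np.ndarray,
                     UtC: np.ndarray) -> float:
    """Negative restricted log-likelihood profile in delta = sigma_e2/sigma_g2
    after rotation by K's eigenvectors (constants dropped)."""
    delta = np.exp(log_delta)
    w = lam + delta                         # eigenvalues of K + delta I
    n, k = UtC.shape
    Wi = 1.0 / w
    CtWiC = UtC.T @ (UtC * Wi[:, None])
    CtWiy = UtC.T @ (Uty * Wi)
    beta = np.linalg.solve(CtWiC, CtWiy)
    r = Uty - UtC @ beta
    quad = float(r @ (r * Wi))
    df = n - k
    sign, logdet_C = np.linalg.slogdet(CtWiC)
    ll = -0.5 * (
        df * np.log(2 * np.pi * quad / df) + df
        + np.log(w).sum() + logdet_C
    )
    return -ll


def mlm_assoc(
    phenotype: pd.Series,
    gm: GenotypeMatrix,
    kinship: KinshipMatrix | None = None,
    n_pcs: int = 3,
) -> pd.DataFrame:
    """Mixed-model association with a single REML fit of the variance ratio.

    With K = I the generalized least squares collapses to ordinary least
    squares and the p-values equal the GLM's.
    """
    y = _align_phenotype(gm, phenotype)
    if kinship is None:
        kinship = kinship_vanraden(gm)
    if kinship.sample_ids != gm.sample_ids:
        raise ValueError("kinship sample order differs from the genotype matrix")
    X, poly = _dosage_matrix(gm)
    C = _covariates(gm, n_pcs)
    n, k = C.shape
    lam, U = np.linalg.eigh(kinship.values)
    lam = np.maximum(lam, 0.0)
    Uty = U.T @ y
    UtC = U.T @ C
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(-10.0, 10.0), method="bounded",
        args=(lam, Uty, UtC), options={"xatol": 1e-6},
    )
    delta = float(np.exp(res.x))
    w = lam + delta
    sw = 1.0 / np.sqrt(w)
    # whiten everything once, then per-marker OLS in the whitened space
    yw = Uty * sw
    Cw = UtC * sw[:, None]
    Xw = (U.T @ X) * sw[:, None]
    Cp = np.linalg.pinv(Cw)
    ry = yw - Cw @ (Cp @ yw)
    RX = Xw - Cw @ (Cp @ Xw)
    sxx = (RX**2).sum(axis=0)
    sxy = (RX * ry[:, None]).sum(axis=0)
    safe_sxx = np.where(sxx > 0, sxx, 1.0)
    beta = np.where(sxx > 0, sxy / safe_sxx, np.nan)
    rss0 = float(ry @ ry)
    rss1 = np.maximum(rss0 - np.where(sxx > 0, sxy**2 / safe_sxx, 0.0), 0.0)
    df2 = n - k - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        fstat = (rss0 - rss1) / (rss1 / df2)
        pvals = np.clip(stats.f.sf(fstat, 1, df2), 1e-300, 1.0)
        partial_r2 = np.where(rss0 > 0, (rss0 - rss1) / rss0, np.nan)
    out = _marker_frame(gm)
    out["model"] = "MLM"
    out["p_value"] = pvals
    out["r2"] = 100.0 * partial_r2
    out["effect"] = beta
    out.attrs["delta"] = delta
    result = out[poly].reset_index(drop=True)
    result.attrs["delta"] = delta
    return result


def significance_report(
    results: pd.DataFrame, method: str = "bonferroni", alpha: float = 0.05
) -> pd.DataFrame:
    """Annotate results with the multiple-testing cutoff and significance,
    sorted Manhattan-ready by (chrom, pos) with a -log10 p column."""
    if method != "bonferroni":
        raise ValueError("only bonferroni is supported")
    m = len(results)
    cutoff = alpha / m if m else alpha
    out = results.copy()
    out["cutoff"] = cutoff
    out["significant"] = out["p_value"] < cutoff
    out["neg_log10_p"] = -np.log10(np.clip(out["p_value"], 1e-300, None))
    from .io_formats import _chrom_rank

    out["_rank"] = out["chrom"].map(_chrom_rank)
    out = out.sort_values(["_rank", "pos"]).drop(columns="_rank").reset_index(drop=True)
    return out
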
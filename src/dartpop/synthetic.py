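"""Synthetic genotype, pedigree and phenotype fixtures with known truth.

The generators emulate the statistical structure of a clonally propagated,
outcrossing forage-grass germplasm panel genotyped with biallelic dosage
markers: latent source populations with tunable differentiation, admixed
individuals, clonal duplicates perturbed by genotyping error, open-pollinated
progeny with known seed and pollen parents, and quantitative phenotypes with
planted QTL effects.

Subpopulation allele frequencies follow the Balding-Nichols model: for an
ancestral frequency p and differentiation F, each population's frequency is

    p_k ~ Beta(p (1-F)/F, (1-p)(1-F)/F)

which has mean p and variance F p (1-p), so the expected Weir-Cockerham FST
between populations equals F.  Markers are simulated unlinked; linkage tests
plant correlated duplicates explicitly.  Individuals are scored as diploid
dosages, matching the marker representation (not the cytology) of an
allotetraploid crop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CHROMOSOMES,
    MISSING,
    SILICODART,
    SNP,
    GenotypeMatrix,
    MarkerRecord,
    PhenotypeTable,
    SampleSheet,
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic panel; the defaults describe the baseline study
    conditions used throughout the test-bed (three differentiated source
    populations at desk scale)."""

    n_pops: int = 3
    pop_sizes: tuple[int, ...] = (30, 30, 30)
    n_markers: int = 500
    fst: float = 0.15
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    admixture_alpha: float = 0.3
    clone_error_rate: float = 0.01
    missing_rate: float = 0.0
    progeny_design: tuple[tuple[str, str, int], ...] = ()
    qtl_effects: dict[str, float] = field(default_factory=dict)
    heritability: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if not 0.0 <= self.clone_error_rate < 1.0:
            raise ValueError("clone_error_rate must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must be in (0, 1]")
        if len(self.pop_sizes) != self.n_pops:
            raise ValueError("pop_sizes length must equal n_pops")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


def _default_markers(n_markers: int, rng: np.random.Generator) -> list[MarkerRecord]:
    """SNP markers spread evenly over the 14 chromosomes with ordered positions."""
    nts = np.array(list("ACGT"))
    markers = []
    per = int(np.ceil(n_markers / len(CHROMOSOMES)))
    for j in range(n_markers):
        chrom = CHROMOSOMES[j // per]
        pos = 10_000 * ((j % per) + 1)
        ref, alt = rng.choice(4, size=2, replace=False)
        markers.append(
            MarkerRecord(f"M{j:06d}", SNP, chrom, pos, str(nts[ref]), str(nts[alt]))
        )
    return markers


def balding_nichols_freqs(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral frequencies and the K x L matrix of population frequencies."""
    L, K, F = config.n_markers, config.n_pops, config.fst
    p_anc = rng.uniform(config.ancestral_low, config.ancestral_high, size=L)
    if F == 0.0:  # degenerate limit: every population shares the ancestral p
        return p_anc, np.tile(p_anc, (K, 1))
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    pop_freqs = rng.beta(a, b, size=(K, L))
    return p_anc, np.clip(pop_freqs, 1e-9, 1.0 - 1e-9)


def _apply_missing(calls: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate > 0.0:
        calls = calls.copy()
        calls[rng.random(calls.shape) < rate] = MISSING
    return calls


def simulate_structured_populations(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Draw K Balding-Nichols populations of diploid dosage genotypes.

    Returns the genotype matrix, the true population label per sample and
    the true K x L population allele frequencies.
    """
    if config.n_pops < 1:
        raise ValueError("need at least one population")
    rng = np.random.default_rng(config.seed)
    _, pop_freqs = balding_nichols_freqs(config, rng)
    labels = np.repeat(np.arange(config.n_pops), config.pop_sizes)
    calls = rng.binomial(2, pop_freqs[labels, :]).astype(np.int16)
    calls = _apply_missing(calls, config.missing_rate, rng)
    sample_ids = [f"P{k + 1}_{i:03d}" for k in range(config.n_pops) for i in range(config.pop_sizes[k])]
    markers = _default_markers(config.n_markers, rng)
    return GenotypeMatrix(sample_ids, markers, calls), labels, pop_freqs


def simulate_admixed(
    config: SimulationConfig,
    q_rows: np.ndarray,
    pop_freqs: np.ndarray | None = None,
    sample_prefix: str = "ADM",
    seed: int | None = None,
) -> GenotypeMatrix:
    """Admixed individuals: each of the two allele copies at every locus picks
    its source population from the individual's ancestry vector Q."""
    q = np.asarray(q_rows, dtype=float)
    if q.ndim != 2 or q.shape[1] != config.n_pops:
        raise ValueError("Q_rows must be (n_individuals, n_pops)")
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("Q rows must sum to 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if pop_freqs is None:
        _, pop_freqs = balding_nichols_freqs(config, rng)
    n, L = q.shape[0], config.n_markers
    # per copy: origin k ~ Categorical(q_i), then allele ~ Bernoulli(p_k,l)
    calls = np.zeros((n, L), dtype=np.int16)
    for copy in range(2):
        origins = np.array([rng.choice(config.n_pops, size=L, p=q[i]) for i in range(n)])
        calls += rng.binomial(1, pop_freqs[origins, np.arange(L)[None, :]]).astype(np.int16)
    calls = _apply_missing(calls, config.missing_rate, rng)
    sample_ids = [f"{sample_prefix}_{i:03d}" for i in range(n)]
    markers = _default_markers(L, rng)
    return GenotypeMatrix(sample_ids, markers, calls)


def _perturb(
    calls: np.ndarray, snp: np.ndarray, error_rate: float, missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotyping-error model: with probability ``error_rate`` a call is
    resampled uniformly from the *other* valid codes; then dropout at
    ``missing_rate``.  Missing input calls stay missing."""
    out = calls.copy()
    observed = out != MISSING
    err = observed & (rng.random(out.shape) < error_rate)
    if err.any():
        shift = rng.integers(1, np.where(snp, 3, 2))  # 1..2 for SNP, 1 for silico
        ceil = np.where(snp, 3, 2)
        out[err] = ((out + shift) % ceil)[err]
    out[observed & (rng.random(out.shape) < missing_rate)] = MISSING
    return out


def simulate_clones(
    gm: GenotypeMatrix,
    sample_id: str,
    n_copies: int,
    error_rate: float = 0.01,
    missing_rate: float = 0.0,
    seed: int | None = 0,
) -> tuple[GenotypeMatrix, list[str]]:
    """Append ``n_copies`` clonal duplicates of one sample, each perturbed by
    independent per-call genotyping error and dropout.  Returns the augmented
    matrix and the new clone ids."""
    if n_copies == 0:
        return gm, []
    rng = np.random.default_rng(seed)
    src = gm.calls[gm.sample_index(sample_id), :]
    snp = gm.snp_mask
    clone_ids, rows = [], []
    for c in range(n_copies):
        rows.append(_perturb(src[None, :], snp, error_rate, missing_rate, rng)[0])
        clone_ids.append(f"{sample_id}_clone{c + 1}")
    aug = GenotypeMatrix(
        gm.sample_ids + clone_ids, list(gm.markers), np.vstack([gm.calls, rows])
    )
    return aug, clone_ids


def _gametes(parent_calls: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n haploid gametes from a diploid dosage vector; heterozygotes transmit
    either allele with probability 1/2.  Missing parent call -> gamete -1."""
    g = np.tile(parent_calls, (n, 1))
    out = np.where(g == 2, 1, 0).astype(np.int16)
    het = g == 1
    out[het] = rng.integers(0, 2, size=int(het.sum()))
    out[g == MISSING] = -1
    return out


def simulate_progeny(
    gm: GenotypeMatrix,
    seed_parent: str,
    pollen_parent: str,
    n: int,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int | None = 0,
    id_prefix: str | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Append ``n`` offspring of a (seed parent, pollen parent) cross.

    One allele is drawn from each parent per locus.  Selfing happens only when
    the two parent ids are explicitly equal.  A locus with a missing call in
    either parent yields a missing offspring call.  Returns the augmented
    matrix and the truth pedigree table.
    """
    rng = np.random.default_rng(seed)
    snp = gm.snp_mask
    if not snp.all():
        raise ValueError("progeny simulation requires SNP (dosage) markers")
    g1 = _gametes(gm.calls[gm.sample_index(seed_parent)], n, rng)
    g2 = _gametes(gm.calls[gm.sample_index(pollen_parent)], n, rng)
    kids = (g1 + g2).astype(np.int16)
    kids[(g1 < 0) | (g2 < 0)] = MISSING
    kids = _perturb(kids, snp, error_rate, missing_rate, rng)
    prefix = id_prefix or f"{seed_parent}x{pollen_parent}"
    kid_ids = [f"{prefix}_o{i + 1:03d}" for i in range(n)]
    aug = GenotypeMatrix(gm.sample_ids + kid_ids, list(gm.markers), np.vstack([gm.calls, kids]))
    pedigree = pd.DataFrame(
        {"sample_id": kid_ids, "seed_parent": seed_parent, "pollen_parent": pollen_parent}
    )
    return aug, pedigree


def simulate_phenotypes(
    gm: GenotypeMatrix,
    qtl_effects: dict[str, float],
    heritability: float,
    seed: int,
    trait: str = "TFW",
    polygenic_fraction: float = 0.0,
    baseline: float = 10.0,
) -> tuple[PhenotypeTable, dict]:
    """Quantitative phenotypes: y = baseline + sum(a_j dosage_j) + polygenic + noise.

    The optional polygenic term is drawn with covariance proportional to the
    realized additive relationship matrix; environmental noise is scaled so
    the realized heritability (genetic variance over total) matches the
    requested value.  With zero effects and no polygenic term, y is pure
    noise of unit variance around the baseline.
    """
    if not 0.0 < heritability <= 1.0:
        raise ValueError("heritability must be in (0, 1]")
    rng = np.random.default_rng(seed)
    ids = {m.marker_id: j for j, m in enumerate(gm.markers)}
    dosages = gm.calls.astype(float)
    col_mean = np.nanmean(np.where(dosages == MISSING, np.nan, dosages), axis=0)
    dosages = np.where(gm.calls == MISSING, col_mean[None, :], dosages)

    genetic = np.zeros(gm.n_samples)
    for marker_id, effect in qtl_effects.items():
        genetic += effect * dosages[:, ids[marker_id]]
    if polygenic_fraction > 0.0:
        from .gwas import kinship_vanraden

        K = kinship_vanraden(gm).values
        jitter = 1e-6 * np.eye(gm.n_samples)
        u = np.linalg.cholesky(K + jitter) @ rng.standard_normal(gm.n_samples)
        var_q = genetic.var() if qtl_effects else 1.0
        target = polygenic_fraction / (1.0 - polygenic_fraction) * var_q
        u *= np.sqrt(target / max(u.var(), 1e-12))
        genetic = genetic + u
    var_g = genetic.var()
    if var_g > 0:
        var_e = var_g * (1.0 - heritability) / heritability
    else:
        var_e = 1.0
    noise = rng.standard_normal(gm.n_samples) * np.sqrt(var_e)
    y = np.maximum(baseline + genetic - genetic.mean() + noise, 0.0)
    table = PhenotypeTable(
        pd.DataFrame({"sample_id": gm.sample_ids, "trait": trait, "value": y})
    )
    truth = {
        "qtl_effects": dict(qtl_effects),
        "heritability": heritability,
        "var_genetic": float(var_g),
        "var_noise": float(var_e),
    }
    return table, truth


def simulate_silico(
    n_samples: int, n_markers: int, seed: int, missing_rate: float = 0.0,
    sample_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Presence/absence (SilicoDArT) markers with uniform band frequencies."""
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.05, 0.95, size=n_markers)
    calls = rng.binomial(1, f, size=(n_samples, n_markers)).astype(np.int16)
    calls = _apply_missing(calls, missing_rate, rng)
    per = int(np.ceil(n_markers / len(CHROMOSOMES)))
    markers = [
        MarkerRecord(f"S{j:06d}", SILICODART, CHROMOSOMES[j // per], 5_000 * ((j % per) + 1))
        for j in range(n_markers)
    ]
    if sample_ids is None:
        sample_ids = [f"SIL_{i:03d}" for i in range(n_samples)]
    return GenotypeMatrix(sample_ids, markers, calls)


def simulate_germplasm_study(
    seed: int,
    n_pops: int = 3,
    pop_size: int = 24,
    n_markers: int = 600,
    fst: float = 0.2,
    n_admixed: int = 9,
    n_clone_pairs: int = 4,
    n_parents: int = 6,
    progeny_per_parent: int = 6,
    error_rate: float = 0.005,
    missing_rate: float = 0.01,
    qtl_frac_variance: float = 0.2,
) -> dict:
    """One self-contained study-like panel: structured collections with
    admixed genotypes, cross-collection clonal duplicates, open-pollinated
    progeny from known seed parents, and a QTL-bearing biomass phenotype.

    Returns a dict with the genotype matrix, sample sheet, phenotypes and all
    truth objects (labels, clone map, pedigree, Q rows, QTL effects).
    """
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(
        n_pops=n_pops,
        pop_sizes=(pop_size,) * n_pops,
        n_markers=n_markers,
        fst=fst,
        missing_rate=0.0,
        seed=int(rng.integers(2**31 - 1)),
    )
    gm, labels, pop_freqs = simulate_structured_populations(cfg)

    q_rows = np.random.default_rng(int(rng.integers(2**31 - 1))).dirichlet(
        np.full(n_pops, 1.0), size=n_admixed
    )
    adm = simulate_admixed(cfg, q_rows, pop_freqs, seed=int(rng.integers(2**31 - 1)))
    gm = gm.concat_samples(adm)

    clone_truth: dict[str, list[str]] = {}
    originals = [gm.sample_ids[i] for i in rng.choice(n_pops * pop_size, n_clone_pairs, replace=False)]
    for src in originals:
        gm, ids = simulate_clones(
            gm, src, 1, error_rate, missing_rate, seed=int(rng.integers(2**31 - 1))
        )
        clone_truth[src] = ids

    parents = [gm.sample_ids[i] for i in rng.choice(pop_size, n_parents, replace=False)]
    pedigrees = []
    for sp in parents:
        pp = parents[int(rng.integers(n_parents))]
        gm, ped = simulate_progeny(
            gm, sp, pp, progeny_per_parent, error_rate, missing_rate,
            seed=int(rng.integers(2**31 - 1)), id_prefix=f"NS_{sp}",
        )
        pedigrees.append(ped)
    pedigree = pd.concat(pedigrees, ignore_index=True)

    qtl_marker = gm.markers[int(rng.integers(n_markers))].marker_id
    pheno, pheno_truth = simulate_phenotypes(
        gm, {qtl_marker: 1.0}, qtl_frac_variance, seed=int(rng.integers(2**31 - 1)),
        polygenic_fraction=0.3,
    )

    collections = ["ILRI", "EMBRAPA", "KALRO"][:n_pops]
    rows = []
    for i, s in enumerate(gm.sample_ids):
        if s in pedigree["sample_id"].values:
            coll = "Progeny"
            parent = pedigree.set_index("sample_id").loc[s, "seed_parent"]
        else:
            parent = None
            if "_clone" in s:
                # clones deposited under a different collection: cross-collection duplicates
                src_coll = collections[labels[gm.sample_ids.index(s.split("_clone")[0])] % len(collections)]
                coll = collections[(collections.index(src_coll) + 1) % len(collections)]
            elif s.startswith("ADM"):
                coll = collections[int(rng.integers(len(collections)))]
            else:
                coll = collections[labels[i] % len(collections)] if i < len(labels) else collections[0]
        rows.append({"sample_id": s, "collection": coll, "recorded_seed_parent": parent})
    sheet = SampleSheet(pd.DataFrame(rows))

    missing = _apply_missing(gm.calls, missing_rate, rng)
    gm = GenotypeMatrix(gm.sample_ids, gm.markers, missing)
    return {
        "genotypes": gm,
        "sample_sheet": sheet,
        "phenotypes": pheno,
        "truth": {
            "labels": labels,
            "pop_freqs": pop_freqs,
            "q_rows": q_rows,
            "clones": clone_truth,
            "pedigree": pedigree,
            "parents": parents,
            "qtl": {qtl_marker: 1.0},
            "phenotype": pheno_truth,
        },
    }
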
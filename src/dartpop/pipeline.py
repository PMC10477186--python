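"""End-to-end orchestration: QC -> diversity -> structure -> redundancy ->
parentage -> GWAS from a single YAML config.

Stages communicate through files (TSV/JSON) under a run directory so each
stage is independently re-runnable and auditable; a manifest records inputs,
seeds and per-stage row counts.  Optional stages degrade gracefully: without
phenotypes the GWAS stage is skipped with a logged warning, without recorded
seed parents the parentage stage is skipped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, diversity, gwas, marker_qc, parentage, redundancy
from .io_formats import (
    GenotypeMatrix,
    export_newick,
    export_tsv,
    read_dartseq_snp,
    read_phenotypes,
    read_sample_sheet,
)

logger = logging.getLogger("dartpop")


@dataclass
class PipelineConfig:
    genotypes: str = ""
    dialect: str = "one-row"
    sample_sheet: str = ""
    phenotypes: str | None = None
    output_dir: str = "dartpop_run"
    # filtering
    max_missing: float = 0.10
    min_maf: float = 0.05
    max_ld_r2: float = 0.5
    require_mapped: bool = True
    gwas_min_call_rate: float = 0.90
    # structure
    k_min: int = 1
    k_max: int = 5
    n_reps: int = 3
    burn_in: int = 2000
    n_iter: int = 2000
    structure_seed: int = 1
    membership_threshold: float = 0.60
    # thresholds
    nei_dup_threshold: float = 0.025
    kinship_dup_threshold: float = 0.45
    parent_kinship_floor: float = 0.15
    # diversity
    amova_permutations: int = 199
    amova_seed: int = 1
    # gwas
    gwas_model: str = "both"
    n_pcs: int = 3
    alpha: float = 0.05

    _FRACTIONS = (
        "max_missing", "min_maf", "max_ld_r2", "gwas_min_call_rate",
        "membership_threshold", "nei_dup_threshold", "kinship_dup_threshold",
        "parent_kinship_floor", "alpha",
    )


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys and out-of-range values
    raise with the offending field named.  Omitted keys take defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__ if not f.startswith("_")}
    errors = []
    unknown = set(raw) - known
    for key in sorted(unknown):
        errors.append(f"unknown config key: {key}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    for name in PipelineConfig._FRACTIONS:
        v = getattr(cfg, name)
        if not 0.0 <= v <= 1.0:
            errors.append(f"{name} must be in [0, 1], got {v}")
    if cfg.k_min < 1 or cfg.k_max < cfg.k_min:
        errors.append("k range must satisfy 1 <= k_min <= k_max")
    if cfg.gwas_model not in ("glm", "mlm", "both"):
        errors.append(f"gwas_model must be glm/mlm/both, got {cfg.gwas_model}")
    if errors:
        raise ValueError("; ".join(errors))
    return cfg


def run_pipeline(
    cfg: PipelineConfig,
    gm: GenotypeMatrix | None = None,
    sheet=None,
    phenotypes=None,
) -> dict:
    """Run every stage, writing TSV/JSON outputs and a manifest under
    ``cfg.output_dir``.  In-memory inputs may be passed directly (as the
    simulate subcommand does); otherwise they are read from the configured
    paths.  Returns the manifest dict."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in asdict(cfg).items()}, "stages": {}}

    if gm is None:
        gm = read_dartseq_snp(cfg.genotypes, cfg.dialect)
    if sheet is None and cfg.sample_sheet:
        sheet = read_sample_sheet(cfg.sample_sheet, gm.sample_ids)
    if phenotypes is None and cfg.phenotypes:
        phenotypes = read_phenotypes(cfg.phenotypes)

    # ---- QC ----
    qc = marker_qc.compute_marker_qc(gm)
    export_tsv(qc, out / "marker_qc.tsv")
    criteria = marker_qc.FilterCriteria(
        max_missing=cfg.max_missing, min_maf=cfg.min_maf,
        max_ld_r2=cfg.max_ld_r2, require_mapped=cfg.require_mapped,
    )
    filtered, audit = marker_qc.filter_markers(gm, criteria)
    export_tsv(audit, out / "filter_audit.tsv")
    manifest["stages"]["qc"] = {
        "n_markers_in": gm.n_markers, "n_markers_robust": filtered.n_markers,
    }

    # ---- diversity ----
    grouping = sheet.collection_of() if sheet is not None else {
        s: "all" for s in gm.sample_ids
    }
    dm = diversity.nei_distance_individuals(filtered)
    export_tsv(
        pd.DataFrame(dm.values, index=dm.ids, columns=dm.ids).reset_index(),
        out / "nei_individual.tsv",
    )
    n_groups = len(set(grouping.values()))
    if n_groups >= 2:
        nei_g = diversity.nei_distance_groups(filtered, grouping)
        fst = diversity.fst_pairwise(filtered, grouping)
        combined = diversity.combined_triangle_table(nei_g, fst)
        export_tsv(combined.reset_index(), out / "diversity_matrix.tsv")
        amova = diversity.amova(filtered, grouping, cfg.amova_permutations, cfg.amova_seed)
        export_tsv(amova.as_table(), out / "amova.tsv")
        manifest["stages"]["diversity"] = {
            "pct_within": amova.pct_within, "phi_st": amova.phi_st,
            "amova_p": amova.p_value,
        }
    summary = diversity.within_group_distance_summary(dm, grouping)
    export_tsv(summary, out / "within_group_summary.tsv")

    # ---- structure / tree / pca ----
    runs = clustering.run_replicates(
        filtered, range(cfg.k_min, cfg.k_max + 1), cfg.n_reps,
        cfg.burn_in, cfg.n_iter, seed=cfg.structure_seed,
    )
    lnp = {K: [s.ln_prob_data for s in states] for K, states in runs.items()}
    evanno = clustering.evanno_delta_k(lnp)
    export_tsv(evanno, out / "evanno.tsv")
    try:
        k_best = clustering.best_k(evanno)
    except ValueError:
        k_best = cfg.k_max
    state = runs[k_best][int(np.argmax([s.ln_prob_data for s in runs[k_best]]))]
    q_table = pd.DataFrame(state.Q, columns=[f"Q{k + 1}" for k in range(state.K)])
    q_table.insert(0, "sample_id", state.sample_ids)
    export_tsv(q_table, out / "q_matrix.tsv")
    assignments = clustering.assign_clusters(
        state.Q, state.sample_ids, cfg.membership_threshold
    )
    export_tsv(assignments, out / "cluster_assignments.tsv")
    tree = clustering.upgma(dm)
    export_newick(tree, out / "upgma.nwk")
    scores, explained = clustering.pca_genotypes(filtered, n_components=5)
    pca_table = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])])
    pca_table.insert(0, "sample_id", filtered.sample_ids)
    export_tsv(pca_table, out / "pca_scores.tsv")
    manifest["stages"]["structure"] = {
        "k_best": k_best,
        "n_admixed": int((assignments["cluster"] == "admixed").sum()),
        "pca_explained": [float(e) for e in explained],
    }

    # ---- redundancy ----
    calls, groups = redundancy.find_duplicates(
        filtered, sheet, cfg.nei_dup_threshold, cfg.kinship_dup_threshold, nei=dm
    )
    distinct = redundancy.select_distinct(filtered, groups)
    (out / "clonal_groups.json").write_text(json.dumps(groups, indent=2))
    pd.DataFrame({"sample_id": distinct}).to_csv(out / "distinct_set.tsv",
                                                 sep="\t", index=False)
    dup_rows = [
        {"sample_a": c.sample_a, "sample_b": c.sample_b, "nei": c.nei_distance,
         "kinship": c.ml_kinship, "same_collection": c.same_collection}
        for c in calls if c.is_duplicate
    ]
    export_tsv(pd.DataFrame(dup_rows), out / "duplicates.tsv")
    if sheet is not None:
        export_tsv(
            redundancy.duplicate_count_matrix(calls, sheet).reset_index(),
            out / "duplicate_counts.tsv",
        )
    manifest["stages"]["redundancy"] = {
        "n_duplicate_pairs": len(dup_rows), "n_clonal_groups": len(groups),
        "n_distinct": len(distinct),
    }

    # ---- parentage ----
    recorded = sheet.recorded_parents() if sheet is not None else {}
    if recorded:
        progeny_ids = sorted(recorded)
        candidates = sorted(set(recorded.values()))
        confirmed = {}
        statuses = []
        for prog in progeny_ids:
            parent, status = parentage.confirm_seed_parent(
                filtered, prog, recorded.get(prog), candidates,
                floor=cfg.parent_kinship_floor,
            )
            confirmed[prog] = parent
            statuses.append({"progeny": prog, "recorded": recorded.get(prog),
                             "confirmed": parent, "status": status})
        export_tsv(pd.DataFrame(statuses), out / "seed_parent_status.tsv")
        usable = {p: c for p, c in confirmed.items() if c is not None}
        report = parentage.scan_parents(filtered, sorted(usable), candidates, usable)
        export_tsv(report, out / "mendelian_report.tsv")
        thresholds = {
            rel: parentage.gap_threshold(
                report.loc[report["relationship"] == rel, "errors"]
            )
            for rel in (parentage.PC1, parentage.PC2, parentage.PPC)
        }
        (out / "thresholds.json").write_text(json.dumps(thresholds, indent=2))
        classified = parentage.classify_evidence(report, thresholds)
        export_tsv(classified, out / "parentage_evidence.tsv")
        donors, freq = parentage.pollen_donor_table(report)
        export_tsv(donors, out / "pollen_donors.tsv")
        export_tsv(freq, out / "pollen_donor_frequency.tsv")
        manifest["stages"]["parentage"] = {
            "n_progeny": len(progeny_ids),
            "n_confirmed": sum(1 for s in statuses if s["status"] == "confirmed"),
            "n_corrected": sum(1 for s in statuses if s["status"] == "corrected"),
        }
    else:
        logger.warning("no recorded seed parents; skipping parentage stage")
        manifest["stages"]["parentage"] = {"skipped": True}

    # ---- GWAS ----
    if phenotypes is not None:
        pheno = phenotypes.aggregate()
        typed = [s for s in gm.sample_ids if s in pheno.index]
        gwas_gm = gm.select_samples(typed)
        gwas_criteria = marker_qc.FilterCriteria(
            max_missing=cfg.max_missing, min_maf=cfg.min_maf,
            max_ld_r2=cfg.max_ld_r2, require_mapped=cfg.require_mapped,
            min_call_rate=cfg.gwas_min_call_rate,
        )
        gwas_markers, _ = marker_qc.filter_markers(gwas_gm, gwas_criteria)
        results = []
        if cfg.gwas_model in ("glm", "both"):
            results.append(gwas.glm_assoc(pheno, gwas_markers, cfg.n_pcs))
        if cfg.gwas_model in ("mlm", "both"):
            K = gwas.kinship_vanraden(gwas_markers)
            results.append(gwas.mlm_assoc(pheno, gwas_markers, K, cfg.n_pcs))
        full = pd.concat(results, ignore_index=True)
        annotated = significance = gwas.significance_report(full, alpha=cfg.alpha)
        export_tsv(annotated, out / "gwas_results.tsv")
        export_tsv(annotated[annotated["significant"]], out / "gwas_significant.tsv")
        manifest["stages"]["gwas"] = {
            "n_markers": gwas_markers.n_markers,
            "n_significant": int(annotated["significant"].sum()),
        }
    else:
        logger.warning("no phenotypes provided; skipping GWAS stage")
        manifest["stages"]["gwas"] = {"skipped": True}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
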
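"""End-to-end pipeline driver.

Chains the stages — synthesize (or load), phenotype, genotype QC, score,
associate — writing every intermediate artifact plus a run manifest, so
a run is fully auditable and reproducible from the config and seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import io as io_mod
from . import phenotyping, prs, qc, synth
from .config import PipelineConfig

log = logging.getLogger(__name__)

__version__ = "0.1.0"


def compute_pcs(dosages: np.ndarray, sample_ids, n_components: int = 4) -> pd.DataFrame:
    """Leading principal components of the study genotypes (covariates).

    Standardizes by the study's own allele frequencies and takes the top
    left singular vectors scaled by their singular values.
    """
    with np.errstate(invalid="ignore"):
        p = np.clip(np.nanmean(dosages, axis=0) / 2.0, 1e-6, 1 - 1e-6)
    z = qc._standardize(dosages, p)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return pd.DataFrame(scores, index=pd.Index(sample_ids, name="sample_id"), columns=cols)


def run_pipeline(
    config: PipelineConfig,
    synth_config: synth.SynthConfig | None = None,
    outdir: str | Path = "trdprs_run",
    write_artifacts: bool = True,
) -> dict:
    """Simulate a cohort, then phenotype, QC, score and associate.

    Returns a bundle dict with the labels, QC report, per-trait scores,
    association results, quartile table and manifest. With
    ``write_artifacts`` every stage's output lands under ``outdir``.
    """
    outdir = Path(outdir)
    scfg = synth_config or synth.SynthConfig(seed=config.seed)
    bundle: dict = {}

    cohort = synth.generate_cohort(scfg)
    if write_artifacts:
        bundle["paths"] = io_mod.write_cohort(cohort, outdir)
    log.info("simulated %d samples x %d variants", len(cohort.sample_ids), len(cohort.variants))

    # phenotype
    labels = phenotyping.assign_labels(
        cohort.sample_ids,
        cohort.dispensing,
        cohort.ect,
        gap_days=config.gap_days,
        min_adequate_days=config.adequate_days,
    )
    if write_artifacts:
        io_mod.write_tsv(labels, outdir / "labels.tsv")

    # QC (case/control split from the broad labels)
    broad = labels[labels["definition"] == "broad"].set_index("patient_id")
    case_mask = (broad.loc[cohort.sample_ids, "status"] == "TRD").to_numpy()
    kept_samples, kept_variants, qc_report = qc.run_qc(
        cohort.dosages, cohort.variants, cohort.sample_ids, case_mask, config
    )
    if write_artifacts:
        io_mod.write_json(qc_report, outdir / "qc_report.json")
        (outdir / "kept_samples.txt").write_text("\n".join(kept_samples) + "\n")
        (outdir / "kept_variants.txt").write_text("\n".join(kept_variants) + "\n")
    for stage, rep in qc_report.items():
        log.info("QC %s: %s", stage, rep)

    s_keep = [i for i, s in enumerate(cohort.sample_ids) if s in set(kept_samples)]
    v_keep = cohort.variants["id"].isin(kept_variants).to_numpy()
    dos = cohort.dosages[np.ix_(s_keep, np.flatnonzero(v_keep))]
    variants = cohort.variants[v_keep].reset_index(drop=True)
    sample_ids = [cohort.sample_ids[i] for i in s_keep]

    # PRS (standardized once within the whole scored sample)
    vec, prs_report = prs.compute_prs(
        dos,
        variants,
        cohort.weights,
        sample_ids,
        maf_min=config.sumstat_maf,
        info_min=config.sumstat_info,
        mhc=(config.mhc_chrom, config.mhc_start, config.mhc_end),
    )
    prs_tab = vec.to_frame()
    prs_tab["quartile"] = prs.assign_quartiles(vec.z)
    if write_artifacts:
        io_mod.write_tsv(prs_tab, outdir / "prs.tsv")
        io_mod.write_json(prs_report, outdir / "prs_filter_report.json")

    # covariate PCs from post-QC genotypes
    pcs = compute_pcs(dos, sample_ids, config.n_pcs_covar)
    if write_artifacts:
        io_mod.write_tsv(pcs.reset_index(), outdir / "pcs.tsv")

    labels_kept = labels[labels["patient_id"].isin(sample_ids)]
    results, quartiles = assoc_mod.run_comparisons(
        labels_kept,
        {"lithium_response": prs_tab},
        pcs,
        k_prevalence=config.k_prevalence,
        alpha=config.alpha,
    )
    if write_artifacts:
        io_mod.write_tsv(results, outdir / "assoc_results.tsv")
        io_mod.write_tsv(quartiles, outdir / "quartile_table.tsv")

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "synth_seed": scfg.seed,
        "version": __version__,
        "n_samples_simulated": len(cohort.sample_ids),
        "n_variants_simulated": len(cohort.variants),
        "n_samples_kept": len(sample_ids),
        "n_variants_kept": len(kept_variants),
        "n_dispense_records": len(cohort.dispensing),
        "n_ect_records": len(cohort.ect),
        "n_prs_variants": vec.n_variants_used,
        "n_assoc_rows": len(results),
    }
    if write_artifacts:
        io_mod.write_json(manifest, outdir / "manifest.json")

    bundle.update(
        {
            "cohort": cohort,
            "labels": labels,
            "qc_report": qc_report,
            "prs": prs_tab,
            "prs_report": prs_report,
            "pcs": pcs,
            "results": results,
            "quartiles": quartiles,
            "manifest": manifest,
        }
    )
    return bundle
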
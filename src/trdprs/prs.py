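"""Polygenic risk scoring.

Filters a per-SNP weight table the way PRS pipelines prepare GWAS
summary statistics (MAF/INFO thresholds, duplicates, strand-ambiguous
pairs, the MHC region, a HapMap3-style whitelist), harmonizes allele
orientation against the genotype records, computes each sample's
weighted allele-dosage sum, standardizes within the scored sample, and
assigns quartiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MHC_REGION = ("6", 28_000_000, 34_000_000)
_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class PrsVector:
    sample_ids: list
    raw: np.ndarray
    z: np.ndarray
    n_variants_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "raw": self.raw, "z": self.z}
        )


def filter_sumstats(
    table: pd.DataFrame,
    whitelist=None,
    maf_min: float = 0.10,
    info_min: float = 0.90,
    mhc=MHC_REGION,
    study_variants: pd.DataFrame | None = None,
):
    """Sequential summary-statistic filters with per-rule removal counts.

    Rules, in order: (1) maf < ``maf_min`` or info < ``info_min``;
    (2) ids occurring more than once (all copies dropped); (3)
    strand-ambiguous allele pairs {A,T}/{C,G}; (4) the MHC region,
    inclusive on both ends; (5) intersection with ``whitelist`` when
    given. If the table lacks ``maf``/``info`` columns, study-side values
    are taken from ``study_variants`` (logged); with neither available
    rule 1 is skipped and logged.

    Returns ``(filtered_table, report)``; counts satisfy
    rows_in == rows_out + sum(per-rule removals).
    """
    tab = table.reset_index(drop=True)
    report: dict[str, int] = {"rows_in": len(tab)}

    have = {"maf", "info"} <= set(tab.columns)
    if not have and study_variants is not None:
        meta = study_variants.set_index("id")[["maf", "info"]]
        tab = tab.join(meta, on="id")
        log.info("weight table lacks maf/info; substituted study-side estimates")
        have = True
    if have:
        bad = (tab["maf"] < maf_min) | (tab["info"] < info_min)
        bad = bad.fillna(False)
        report["maf_info"] = int(bad.sum())
        tab = tab[~bad]
    else:
        log.warning("no maf/info available on either side; skipping MAF/INFO filter")
        report["maf_info"] = 0

    dup = tab["id"].duplicated(keep=False)
    report["duplicate"] = int(dup.sum())
    tab = tab[~dup]

    pair = [
        frozenset((a, b))
        for a, b in zip(tab["effect_allele"].str.upper(), tab["other_allele"].str.upper())
    ]
    amb = pd.Series([p in _AMBIGUOUS_PAIRS for p in pair], index=tab.index)
    report["strand_ambiguous"] = int(amb.sum())
    tab = tab[~amb]

    chrom, lo, hi = mhc
    in_mhc = (tab["chrom"].astype(str) == str(chrom)) & (tab["pos"] >= lo) & (tab["pos"] <= hi)
    report["mhc"] = int(in_mhc.sum())
    tab = tab[~in_mhc]

    if whitelist is not None:
        wl = set(whitelist)
        out = ~tab["id"].isin(wl)
        report["not_in_whitelist"] = int(out.sum())
        tab = tab[~out]

    report["rows_out"] = len(tab)
    return tab.reset_index(drop=True), report


def harmonize(table: pd.DataFrame, variants: pd.DataFrame):
    """Align weight-table rows to genotype variants by id and allele pair.

    The genotype dosage counts alt alleles, so a weight whose effect
    allele is the variant's alt is kept as-is; one whose effect allele is
    the ref is sign-flipped; any other allele combination is dropped and
    counted. Returns ``(aligned, report)`` where ``aligned`` has columns
    ``id, weight`` in genotype orientation.
    """
    geno = variants[["id", "ref", "alt"]]
    merged = table.merge(geno, on="id", how="inner", validate="one_to_one")
    if len(merged) == 0:
        raise ValueError("no overlapping variants between weight table and genotypes")
    ea = merged["effect_allele"].str.upper()
    oa = merged["other_allele"].str.upper()
    keep_as_is = (ea == merged["alt"]) & (oa == merged["ref"])
    flipped = (ea == merged["ref"]) & (oa == merged["alt"])
    mismatch = ~(keep_as_is | flipped)
    report = {
        "matched": int(keep_as_is.sum()),
        "flipped": int(flipped.sum()),
        "allele_mismatch": int(mismatch.sum()),
        "not_in_genotypes": len(table) - len(merged),
    }
    merged = merged[~mismatch].copy()
    if len(merged) == 0:
        raise ValueError("no variants left after allele harmonization")
    w = np.where(keep_as_is[~mismatch], merged["weight"], -merged["weight"])
    aligned = pd.DataFrame({"id": merged["id"].to_numpy(), "weight": w})
    return aligned, report


def score(dosages: np.ndarray, variants: pd.DataFrame, aligned: pd.DataFrame, sample_ids) -> PrsVector:
    """Raw polygenic score: per-sample sum of alt-dosages times weights.

    Missing dosages are imputed with twice the alt-allele frequency
    estimated in the scored sample (the conventional mean-dosage
    substitution).
    """
    if len(aligned) == 0:
        raise ValueError("no variants to score")
    idx = variants.reset_index(drop=True).reset_index().set_index("id")["index"]
    cols = idx.reindex(aligned["id"])
    if cols.isna().any():
        raise ValueError("aligned weights reference variants absent from genotypes")
    cols = cols.to_numpy(dtype=int)
    d = dosages[:, cols]
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    d = np.where(np.isnan(d), col_mean[None, :], d)
    raw = d @ aligned["weight"].to_numpy()
    return PrsVector(
        sample_ids=list(sample_ids),
        raw=raw,
        z=np.full_like(raw, np.nan),
        n_variants_used=len(aligned),
    )


def standardize(raw: np.ndarray) -> np.ndarray:
    """Z-score within the whole scored sample (sample SD, n-1 denominator)."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least two samples to standardize")
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: scores are constant")
    return (raw - raw.mean()) / sd


def assign_quartiles(z: np.ndarray) -> np.ndarray:
    """Quartile labels Q1-Q4 by the empirical 25/50/75 percentiles.

    Values equal to a cutpoint fall in the lower quartile. With all
    values tied every sample lands in Q1 (warned)."""
    z = np.asarray(z, dtype=float)
    cuts = np.quantile(z, [0.25, 0.5, 0.75])
    if z.size and np.all(z == z[0]):
        warnings.warn("all scores identical; every sample assigned to Q1")
        return np.array(["Q1"] * z.size)
    labels = np.searchsorted(cuts, z, side="left")
    return np.array([f"Q{k + 1}" for k in labels])


def compute_prs(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    weights: pd.DataFrame,
    sample_ids,
    whitelist=None,
    maf_min: float = 0.10,
    info_min: float = 0.90,
    mhc=MHC_REGION,
):
    """Filter -> harmonize -> score -> standardize, returning
    ``(PrsVector, report)`` with the nested filter/harmonization counts."""
    filtered, rep_f = filter_sumstats(
        weights, whitelist, maf_min, info_min, mhc, study_variants=variants
    )
    aligned, rep_h = harmonize(filtered, variants)
    vec = score(dosages, variants, aligned, sample_ids)
    vec.z = standardize(vec.raw)
    return vec, {"sumstats": rep_f, "harmonize": rep_h, "n_scored": vec.n_variants_used}
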
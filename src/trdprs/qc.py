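"""Genotype quality control.

Replicates a Ricopili-style QC cascade for case/control genotype data:

* variant filters — call rate, invariance, Hardy-Weinberg exact test run
  separately in cases and controls, case/control call-rate difference,
  minor-allele frequency;
* sample filters — call rate and heterozygosity F statistic;
* ancestry outliers — PCA of a reference panel, projection of study
  samples, flagging beyond 6 SD of the target population on PC1/PC2;
* relatedness — method-of-moments identity-by-descent estimation
  (pi-hat) and greedy pruning of pairs above threshold.

Dosages are stored as a samples x variants float matrix with np.nan for
missing; hard calls for the count-based tests are dosages rounded to the
nearest integer genotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Conditional on the observed allele counts, enumerates every possible
    heterozygote count (they share the parity of the minor-allele count)
    and sums the probabilities of all configurations no more probable
    than the observed one. Monomorphic tables have a single
    configuration and return p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype table")
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0

    hets = np.arange(rare % 2, rare + 1, 2)
    # unnormalized log P(het = h | allele counts), constants dropped
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logw = (
        hets * math.log(2.0)
        - _lgamma(hom_rare + 1)
        - _lgamma(hets + 1)
        - _lgamma(hom_common + 1)
    )
    logp = logw - logsumexp(logw)
    obs = int(n_Aa)
    p_obs = logp[hets == obs]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    mask = logp <= p_obs[0] + 1e-12
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def _lgamma(x):
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float))


def hardcalls(dosages: np.ndarray) -> np.ndarray:
    """Round dosages to 0/1/2 genotype calls, keeping np.nan missing."""
    return np.clip(np.rint(dosages), 0, 2)


def genotype_counts(dos_col: np.ndarray) -> tuple[int, int, int]:
    """(hom-ref, het, hom-alt) counts of one variant's hard calls."""
    g = hardcalls(dos_col)
    g = g[~np.isnan(g)]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


# ---------------------------------------------------------------------------
# variant filters


def filter_variants(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    groups: np.ndarray,
    call_rate_min: float = 0.98,
    hwe_p_min: float = 1e-6,
    diff_call_max: float = 0.01,
    maf_min: float = 0.01,
):
    """Sequential variant-filter cascade with per-rule removal counts.

    ``groups`` is a boolean vector (True = case). Rules apply in order —
    a variant removed by an earlier rule is not tested by later ones:

    1. call rate < ``call_rate_min``;
    2. invariant (a single observed genotype);
    3. HWE exact p < ``hwe_p_min`` in cases OR in controls;
    4. |case call rate - control call rate| > ``diff_call_max``;
    5. MAF < ``maf_min`` (strict).

    Returns ``(kept_ids, report)`` where report maps rule name -> count.
    """
    groups = np.asarray(groups, dtype=bool)
    if not groups.any() or not (~groups).any():
        raise ValueError("both case and control groups must be non-empty")
    n, m = dosages.shape
    if len(variants) != m or groups.size != n:
        raise ValueError("dosages, variants and groups are inconsistent in size")

    ids = variants["id"].to_numpy()
    alive = np.ones(m, dtype=bool)
    report: dict[str, int] = {}
    miss = np.isnan(dosages)

    call = 1.0 - miss.mean(axis=0)
    bad = alive & (call < call_rate_min)
    report["call_rate"] = int(bad.sum())
    alive &= ~bad

    g = hardcalls(dosages)
    invariant = np.zeros(m, dtype=bool)
    for j in np.flatnonzero(alive):
        vals = np.unique(g[~miss[:, j], j])
        invariant[j] = vals.size <= 1
    bad = alive & invariant
    report["invariant"] = int(bad.sum())
    alive &= ~bad

    hwe_fail = np.zeros(m, dtype=bool)
    for j in np.flatnonzero(alive):
        for grp in (groups, ~groups):
            cnt = genotype_counts(dosages[grp, j])
            if sum(cnt) == 0:
                continue
            if hwe_exact_test(*cnt) < hwe_p_min:
                hwe_fail[j] = True
                break
    report["hwe"] = int(hwe_fail.sum())
    alive &= ~hwe_fail

    call_case = 1.0 - miss[groups].mean(axis=0)
    call_ctrl = 1.0 - miss[~groups].mean(axis=0)
    bad = alive & (np.abs(call_case - call_ctrl) > diff_call_max)
    report["diff_call_rate"] = int(bad.sum())
    alive &= ~bad

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    bad = alive & (maf < maf_min)
    report["maf"] = int(bad.sum())
    alive &= ~bad

    report["kept"] = int(alive.sum())
    return list(ids[alive]), report


def prefilter_variants(variants: pd.DataFrame, dosages: np.ndarray, maf_min: float = 0.01):
    """Merge-stage pre-pass: drop monomorphic, indel, strand-ambiguous and
    low-MAF variants before the main cascade. Returns (kept_ids, report)."""
    ids = variants["id"].to_numpy()
    alive = np.ones(len(variants), dtype=bool)
    report: dict[str, int] = {}

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    mono = (freq == 0.0) | (freq == 1.0)
    report["monomorphic"] = int(mono.sum())
    alive &= ~mono

    indel = (variants["ref"].str.len() != 1) | (variants["alt"].str.len() != 1)
    bad = alive & indel.to_numpy()
    report["indel"] = int(bad.sum())
    alive &= ~bad

    pair = variants["ref"].str.upper() + variants["alt"].str.upper()
    ambiguous = pair.isin(["AT", "TA", "CG", "GC"]).to_numpy()
    bad = alive & ambiguous
    report["strand_ambiguous"] = int(bad.sum())
    alive &= ~bad

    maf = np.minimum(freq, 1.0 - freq)
    bad = alive & (maf < maf_min)
    report["maf"] = int(bad.sum())
    alive &= ~bad

    report["kept"] = int(alive.sum())
    return list(ids[alive]), report


# ---------------------------------------------------------------------------
# sample filters


def sample_qc_metrics(dosages: np.ndarray, sample_ids) -> pd.DataFrame:
    """Per-sample call rate and heterozygosity F = 1 - O(het)/E(het).

    Expected heterozygosity sums 2p(1-p) over the sample's non-missing
    variants, with allele frequencies estimated from the study data
    itself.
    """
    miss = np.isnan(dosages)
    call = 1.0 - miss.mean(axis=1)
    g = hardcalls(dosages)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g, axis=0) / 2.0
    exp_het_var = 2.0 * p * (1.0 - p)
    obs_het = np.where(g == 1.0, 1.0, 0.0)
    obs_het[miss] = 0.0
    o = obs_het.sum(axis=1)
    e = np.where(~miss, exp_het_var[None, :], 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(e > 0, 1.0 - o / e, 0.0)
    return pd.DataFrame({"sample_id": list(sample_ids), "call_rate": call, "f_het": f})


def filter_samples(
    dosages: np.ndarray,
    sample_ids,
    call_rate_min: float = 0.98,
    fhet_bound: float = 0.20,
):
    """Drop samples with call rate < threshold or |F_het| > bound.

    Returns (kept_ids, metrics, report)."""
    metrics = sample_qc_metrics(dosages, sample_ids)
    bad_call = metrics["call_rate"] < call_rate_min
    bad_f = metrics["f_het"].abs() > fhet_bound
    keep = ~(bad_call | bad_f)
    report = {
        "call_rate": int(bad_call.sum()),
        "fhet": int((bad_f & ~bad_call).sum()),
        "kept": int(keep.sum()),
    }
    return list(metrics.loc[keep, "sample_id"]), metrics, report


# ---------------------------------------------------------------------------
# ancestry outliers by PCA projection


@dataclass
class PcaResult:
    loadings: np.ndarray  # variants x components
    ref_scores: np.ndarray  # reference samples x components
    ref_pops: pd.Series
    freqs: np.ndarray  # reference alt-allele frequencies used to standardize
    target_mean: np.ndarray
    target_sd: np.ndarray
    projections: np.ndarray  # study samples x components


def _standardize(dosages: np.ndarray, p: np.ndarray) -> np.ndarray:
    denom = np.sqrt(2.0 * p * (1.0 - p))
    denom[denom == 0] = 1.0
    z = (dosages - 2.0 * p[None, :]) / denom[None, :]
    # mean-impute missing entries (zero after centering)
    return np.where(np.isnan(z), 0.0, z)


def pca_project_and_flag(
    study_dosages: np.ndarray,
    ref_dosages: np.ndarray,
    ref_pops: pd.Series,
    study_ids,
    target_pop: str = "EUR",
    n_sd: float = 6.0,
    n_components: int = 2,
):
    """Project study samples onto reference-panel PCs; flag ancestry outliers.

    Variants are standardized by the reference panel's allele frequencies
    (mean 2p, sd sqrt(2p(1-p))); principal axes come from an SVD of the
    standardized reference matrix; a study sample is an outlier when any
    of the first ``n_components`` projected scores lies more than
    ``n_sd`` standard deviations from the target population's mean score.

    Returns (outlier_ids, PcaResult).
    """
    ref_pops = pd.Series(ref_pops).reset_index(drop=True)
    if target_pop not in set(ref_pops):
        raise ValueError(f"target population {target_pop!r} absent from reference labels")
    if study_dosages.shape[1] != ref_dosages.shape[1]:
        raise ValueError("study and reference must share the variant set")

    with np.errstate(invalid="ignore"):
        p = np.nanmean(ref_dosages, axis=0) / 2.0
    p = np.clip(p, 1e-6, 1.0 - 1e-6)
    z_ref = _standardize(ref_dosages, p)
    _, _, vt = np.linalg.svd(z_ref, full_matrices=False)
    loadings = vt[:n_components].T  # variants x k
    ref_scores = z_ref @ loadings
    proj = _standardize(study_dosages, p) @ loadings

    in_target = (ref_pops == target_pop).to_numpy()
    mean_t = ref_scores[in_target].mean(axis=0)
    sd_t = ref_scores[in_target].std(axis=0, ddof=1)
    flagged = (np.abs(proj - mean_t) > n_sd * sd_t).any(axis=1)

    result = PcaResult(
        loadings=loadings,
        ref_scores=ref_scores,
        ref_pops=ref_pops,
        freqs=p,
        target_mean=mean_t,
        target_sd=sd_t,
        projections=proj,
    )
    ids = np.asarray(list(study_ids))
    return list(ids[flagged]), result


# ---------------------------------------------------------------------------
# relatedness


@dataclass(frozen=True)
class RelatednessPair:
    id_a: str
    id_b: str
    pi_hat: float


def _ibd_expectations(p: np.ndarray):
    """Per-locus IBS-class probabilities under each IBD state."""
    q = 1.0 - p
    return {
        "e0_ibs0": 2.0 * p**2 * q**2,
        "e0_ibs1": 4.0 * p**3 * q + 4.0 * p * q**3,
        "e0_ibs2": p**4 + q**4 + 4.0 * p**2 * q**2,
        "e1_ibs1": 2.0 * p**2 * q + 2.0 * p * q**2,
        "e1_ibs2": p**3 + q**3 + p**2 * q + p * q**2,
    }


def _pi_from_moments(n0, n1, n2, E0_0, E0_1, E0_2, E1_1, E1_2, E2_2):
    with np.errstate(divide="ignore", invalid="ignore"):
        z0 = np.where(E0_0 > 0, n0 / E0_0, 0.0)
        z1 = np.where(E1_1 > 0, (n1 - z0 * E0_1) / E1_1, 0.0)
        z2 = np.where(E2_2 > 0, (n2 - z0 * E0_2 - z1 * E1_2) / E2_2, 0.0)
    z1 = np.clip(z1, 0.0, 1.0)
    z2 = np.clip(z2, 0.0, 1.0)
    return np.clip(z2 + 0.5 * z1, 0.0, 1.0)


def estimate_pi_hat(dosages: np.ndarray, sample_ids, pairs=None) -> list[RelatednessPair]:
    """Method-of-moments IBD sharing from identity-by-state counts.

    For each pair, observed counts of loci sharing 0/1/2 alleles
    identical by state are compared with their expectations under
    IBD = 0/1/2 given study allele frequencies, solving for the IBD-state
    probabilities in sequence; pi-hat = P(IBD=2) + P(IBD=1)/2, with each
    probability clipped to [0, 1]. A sample paired with itself gives
    exactly 1. All-pairs estimation is vectorized with matrix products;
    an explicit ``pairs`` list of id tuples restricts computation.
    """
    ids = list(sample_ids)
    n = len(ids)
    g = hardcalls(dosages)
    miss = np.isnan(g)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g, axis=0) / 2.0
    bad_p = np.isnan(p)
    e = _ibd_expectations(np.where(bad_p, 0.5, p))

    ok = (~miss) & ~bad_p[None, :]
    gz = np.where(ok, g, -9.0)
    a0 = (gz == 0.0).astype(float)
    a1 = (gz == 1.0).astype(float)
    a2 = (gz == 2.0).astype(float)
    okf = ok.astype(float)

    if pairs is None:
        # IBS counts over jointly observed loci
        N2 = a0 @ a0.T + a1 @ a1.T + a2 @ a2.T
        x = a0 @ a2.T
        N0 = x + x.T
        Ntot = okf @ okf.T
        N1 = Ntot - N2 - N0
        E0_0 = (okf * e["e0_ibs0"]) @ okf.T
        E0_1 = (okf * e["e0_ibs1"]) @ okf.T
        E0_2 = (okf * e["e0_ibs2"]) @ okf.T
        E1_1 = (okf * e["e1_ibs1"]) @ okf.T
        E1_2 = (okf * e["e1_ibs2"]) @ okf.T
        pi = _pi_from_moments(N0, N1, N2, E0_0, E0_1, E0_2, E1_1, E1_2, Ntot)
        iu = np.triu_indices(n, k=1)
        return [
            RelatednessPair(ids[i], ids[j], float(pi[i, j]))
            for i, j in zip(iu[0], iu[1])
        ]

    index = {s: k for k, s in enumerate(ids)}
    out = []
    for sa, sb in pairs:
        i, j = index[sa], index[sb]
        both = ok[i] & ok[j]
        d = np.abs(g[i, both] - g[j, both])
        n2, n1, n0 = float((d == 0).sum()), float((d == 1).sum()), float((d == 2).sum())
        pi = _pi_from_moments(
            n0,
            n1,
            n2,
            e["e0_ibs0"][both].sum(),
            e["e0_ibs1"][both].sum(),
            e["e0_ibs2"][both].sum(),
            e["e1_ibs1"][both].sum(),
            e["e1_ibs2"][both].sum(),
            float(both.sum()),
        )
        out.append(RelatednessPair(ids[i], ids[j], float(pi)))
    return out


def prune_related(
    pairs: list[RelatednessPair],
    call_rates: dict | pd.Series | None = None,
    threshold: float = 0.2,
) -> list[str]:
    """Greedy pruning of related samples.

    Iteratively removes the sample participating in the most
    above-threshold pairs; ties broken by lower call rate, then by
    lexicographically smaller id. Returns the removed ids (sorted).
    """
    call = dict(call_rates) if call_rates is not None else {}
    edges = {frozenset((p.id_a, p.id_b)) for p in pairs if p.pi_hat > threshold and p.id_a != p.id_b}
    removed: list[str] = []
    while edges:
        degree: dict[str, int] = {}
        for e in edges:
            for s in e:
                degree[s] = degree.get(s, 0) + 1
        # max degree, then lower call rate, then smaller id
        victim = min(degree, key=lambda s: (-degree[s], call.get(s, 1.0), s))
        removed.append(victim)
        edges = {e for e in edges if victim not in e}
    return sorted(removed)


# ---------------------------------------------------------------------------
# cascade driver


def run_qc(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    sample_ids,
    case_mask: np.ndarray,
    config=None,
    ref_dosages: np.ndarray | None = None,
    ref_pops: pd.Series | None = None,
    target_pop: str = "EUR",
    prefilter: bool = False,
):
    """Full QC cascade: samples -> variants -> ancestry -> relatedness.

    Returns ``(kept_sample_ids, kept_variant_ids, report)`` where report
    nests the per-stage removal counts.
    """
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    ids = list(sample_ids)
    case_mask = np.asarray(case_mask, dtype=bool)
    report: dict = {}

    kept_s, metrics, rep_s = filter_samples(
        dosages, ids, cfg.sample_call_rate, cfg.fhet_bound
    )
    report["samples"] = rep_s
    s_idx = [i for i, s in enumerate(ids) if s in set(kept_s)]
    dos = dosages[s_idx]
    cases = case_mask[s_idx]
    ids = [ids[i] for i in s_idx]

    var = variants
    if prefilter:
        kept_pre, rep_pre = prefilter_variants(var, dos, cfg.maf_min)
        report["prefilter"] = rep_pre
        keep = var["id"].isin(kept_pre).to_numpy()
        var = var[keep].reset_index(drop=True)
        dos = dos[:, keep]

    kept_v, rep_v = filter_variants(
        dos, var, cases, cfg.variant_call_rate, cfg.hwe_p, cfg.diff_call_rate, cfg.maf_min
    )
    report["variants"] = rep_v
    keep = var["id"].isin(kept_v).to_numpy()
    var = var[keep].reset_index(drop=True)
    dos = dos[:, keep]

    if ref_dosages is not None and ref_pops is not None:
        keep_cols = variants["id"].isin(var["id"]).to_numpy()
        outliers, _ = pca_project_and_flag(
            dos, ref_dosages[:, keep_cols], ref_pops, ids, target_pop, cfg.pc_sd, cfg.n_pcs_flag
        )
        report["ancestry_outliers"] = len(outliers)
        keep_rows = [i for i, s in enumerate(ids) if s not in set(outliers)]
        dos = dos[keep_rows]
        cases = cases[keep_rows]
        ids = [ids[i] for i in keep_rows]

    pairs = estimate_pi_hat(dos, ids)
    call = metrics.set_index("sample_id")["call_rate"]
    related = prune_related(pairs, call, cfg.pi_hat)
    report["related_removed"] = len(related)
    report["related_pairs"] = sum(1 for p in pairs if p.pi_hat > cfg.pi_hat)
    ids = [s for s in ids if s not in set(related)]

    return ids, list(var["id"]), report
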
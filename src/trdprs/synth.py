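"""Seeded synthetic register and genotype cohorts.

Generates everything the pipeline consumes — post-imputation dosage
genotypes, per-SNP weight tables with known true effects, a dispensing
register with treatment-episode structure, an ECT register, and true TRD
status drawn from a logistic model on the true polygenic score — so every
downstream stage can be exercised end-to-end with known ground truth.

Variants are independent (no LD); the true TRD liability is
``base_logit + ln(or_per_sd) * z`` where ``z`` is the standardized true
polygenic score, the generative inverse of the per-SD odds ratio the
association stage estimates. Truth labels are written to a separate file
and never consumed by the pipeline itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .phenotyping import ATC_LITHIUM

# a small formulary of real antidepressant ATC codes (SSRIs, TCAs, others)
ANTIDEPRESSANT_CODES = (
    "N06AB06",  # sertraline
    "N06AB04",  # citalopram
    "N06AB10",  # escitalopram
    "N06AB05",  # paroxetine
    "N06AB03",  # fluoxetine
    "N06AX16",  # venlafaxine
    "N06AX11",  # mirtazapine
    "N06AX21",  # duloxetine
    "N06AA09",  # amitriptyline
    "N06AA10",  # nortriptyline
    "N06AA04",  # clomipramine
    "N06AX12",  # bupropion
)

_UNAMBIGUOUS = (("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"))
_AMBIGUOUS = (("A", "T"), ("C", "G"))


@dataclass
class SynthConfig:
    """Generative parameters of a synthetic cohort.

    The defaults emulate the study conditions of the register cohorts the
    pipeline was built for: arm sizes near the narrow-definition
    comparison (~1 500 TRD-destined vs ~2 500 non-TRD-destined MDD
    cases), a true lithium-response-PRS effect of OR = 1.12 per SD,
    120-day episode gaps and 42-day adequacy, and registry category
    probabilities matching the reported proportions (94.2% of ECT cases
    with any antidepressant before first ECT; 83.6% with >=1 and 60.8%
    with >=2 adequate antidepressants; 66.5% of non-ECT cases with <=2
    adequate; ~28% lithium use among ECT cases).
    """

    n_cases_trd: int = 1500
    n_nontrd: int = 2500
    n_snps: int = 2000
    maf_range: tuple = (0.05, 0.5)
    prop_causal: float = 0.10
    weight_sd: float = 0.05
    or_per_sd: float = 1.12
    gap_days: int = 120
    min_adequate_days: int = 42
    seed: int = 0
    # genotype texture
    ambiguous_frac: float = 0.10
    mhc_frac: float = 0.03
    missing_rate: float = 0.002
    n_low_call_variants: int = 5
    n_low_call_samples: int = 2
    swap_frac: float = 0.20
    # registry structure: P(>=2 adequate), P(exactly 1 adequate),
    # P(antidepressant use but 0 adequate) among TRD-destined patients;
    # the remainder has no antidepressant dispense before ECT.
    trd_cat_probs: tuple = (0.608, 0.228, 0.106)
    nontrd_narrow_prob: float = 0.665
    lithium_frac_trd: float = 0.28
    lithium_frac_nontrd: float = 0.05
    # noise knobs: probabilities of injecting pathological streams
    noise_gap_boundary: float = 0.0
    noise_single_dispense: float = 0.0
    noise_post_ect_only: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_cases_trd <= 0 or self.n_nontrd <= 0 or self.n_snps <= 0:
            raise ValueError("cohort counts must be positive")
        if self.or_per_sd <= 0:
            raise ValueError("or_per_sd must be positive")
        if not 0.0 <= self.prop_causal <= 1.0:
            raise ValueError("prop_causal must be in [0, 1]")
        if self.weight_sd < 0:
            raise ValueError("weight_sd must be non-negative")
        if min(self.trd_cat_probs) < 0 or sum(self.trd_cat_probs) > 1.0 + 1e-9:
            raise ValueError("trd_cat_probs must be non-negative and sum to at most 1")

    def zero_noise(self) -> "SynthConfig":
        """Copy with deterministic registry structure: every TRD-destined
        patient gets >=2 adequate antidepressants before ECT, every
        non-TRD-destined patient qualifies as narrow non-TRD, and no
        pathological streams are injected. Under this configuration
        phenotyping recovers the generated truth exactly."""
        return replace(
            self,
            trd_cat_probs=(1.0, 0.0, 0.0),
            nontrd_narrow_prob=1.0,
            noise_gap_boundary=0.0,
            noise_single_dispense=0.0,
            noise_post_ect_only=0.0,
        )


@dataclass
class SyntheticCohort:
    config: SynthConfig
    sample_ids: list
    dosages: np.ndarray  # samples x variants, np.nan = missing
    variants: pd.DataFrame
    weights: pd.DataFrame
    dispensing: pd.DataFrame
    ect: pd.DataFrame
    truth: pd.DataFrame  # patient_id, prs_raw, prs_z, p_trd, status


def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    maf_range=(0.05, 0.5),
    seed: int = 0,
    ambiguous_frac: float = 0.10,
    mhc_frac: float = 0.03,
    missing_rate: float = 0.0,
    n_low_call_variants: int = 0,
    n_low_call_samples: int = 0,
):
    """Independent biallelic dosages in Hardy-Weinberg proportions.

    Each variant draws an allele frequency uniformly in ``maf_range`` and
    genotypes Binomial(2, p). A fraction of variants is planted with
    strand-ambiguous allele pairs (A/T, C/G) and a fraction inside the
    MHC region (chr6:28-34 Mb) so the summary-statistic filters have work
    to do; imputation INFO is drawn in [0.3, 1.0]. Missing genotypes are
    np.nan.

    Returns ``(dosages, variants)`` where ``variants`` has columns
    id, chrom, pos, ref, alt, maf (observed, folded), info.
    """
    if n_samples < 1 or n_snps < 1:
        raise ValueError("n_samples and n_snps must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    rng = np.random.default_rng(seed)

    p = rng.uniform(lo, hi, size=n_snps)
    dos = rng.binomial(2, p, size=(n_samples, n_snps)).astype(float)
    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan
    # plant a few samples/variants with 5% missingness so the 0.98
    # call-rate filters have deterministic work to do
    if n_low_call_variants > 0:
        cols = rng.choice(n_snps, size=min(n_low_call_variants, n_snps), replace=False)
        for c in cols:
            dos[rng.random(n_samples) < 0.05, c] = np.nan
    if n_low_call_samples > 0:
        rows = rng.choice(n_samples, size=min(n_low_call_samples, n_samples), replace=False)
        for r in rows:
            dos[r, rng.random(n_snps) < 0.05] = np.nan

    n_mhc = int(round(mhc_frac * n_snps))
    in_mhc = np.zeros(n_snps, dtype=bool)
    in_mhc[rng.choice(n_snps, size=n_mhc, replace=False)] = True
    chrom = rng.integers(1, 23, size=n_snps).astype(str)
    pos = rng.integers(1, 200_000_000, size=n_snps)
    chrom[in_mhc] = "6"
    pos[in_mhc] = rng.integers(28_000_000, 34_000_001, size=n_mhc)
    # keep non-MHC chr6 positions out of the MHC window
    clash = (chrom == "6") & ~in_mhc & (pos >= 28_000_000) & (pos <= 34_000_000)
    pos[clash] = rng.integers(40_000_000, 170_000_000, size=int(clash.sum()))

    ambiguous = rng.random(n_snps) < ambiguous_frac
    pairs = np.array(_UNAMBIGUOUS, dtype=object)
    amb_pairs = np.array(_AMBIGUOUS, dtype=object)
    pick = pairs[rng.integers(0, len(pairs), size=n_snps)]
    pick[ambiguous] = amb_pairs[rng.integers(0, len(amb_pairs), size=int(ambiguous.sum()))]
    flip = rng.random(n_snps) < 0.5
    ref = np.where(flip, pick[:, 1], pick[:, 0])
    alt = np.where(flip, pick[:, 0], pick[:, 1])

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    variants = pd.DataFrame(
        {
            "id": [f"snp{i:06d}" for i in range(n_snps)],
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "maf": maf,
            "info": rng.uniform(0.3, 1.0, size=n_snps),
        }
    )
    return dos, variants


def simulate_weights(
    variants: pd.DataFrame,
    prop_causal: float,
    weight_sd: float,
    seed: int = 0,
    swap_frac: float = 0.0,
) -> pd.DataFrame:
    """Per-SNP effect-weight table with a sparse true architecture.

    A ``prop_causal`` fraction of variants receives a weight drawn from
    Normal(0, weight_sd^2); the rest are exactly zero. The canonical
    orientation is effect allele = alt; a ``swap_frac`` fraction of rows
    is emitted with swapped alleles and sign-flipped weight, which leaves
    the implied score unchanged and exercises allele harmonization.
    """
    if len(variants) == 0:
        raise ValueError("variants must be non-empty")
    if not 0.0 <= prop_causal <= 1.0:
        raise ValueError("prop_causal must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m = len(variants)
    w = np.zeros(m)
    n_causal = int(round(prop_causal * m))
    idx = rng.choice(m, size=n_causal, replace=False)
    w[idx] = rng.normal(0.0, weight_sd, size=n_causal)

    tab = variants[["id", "chrom", "pos", "maf", "info"]].copy()
    tab["effect_allele"] = variants["alt"].to_numpy()
    tab["other_allele"] = variants["ref"].to_numpy()
    tab["weight"] = w
    swap = rng.random(m) < swap_frac
    tab.loc[swap, ["effect_allele", "other_allele"]] = tab.loc[
        swap, ["other_allele", "effect_allele"]
    ].to_numpy()
    tab.loc[swap, "weight"] = -tab.loc[swap, "weight"]
    cols = ["id", "chrom", "pos", "effect_allele", "other_allele", "weight", "maf", "info"]
    return tab[cols]


def simulate_trd_status(
    prs_z: np.ndarray, or_per_sd: float, base_logit: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Bernoulli TRD status from a logistic model on the standardized score.

    P(TRD) = logistic(base_logit + ln(or_per_sd) * z). With or_per_sd = 1
    status is independent of the score (the null).
    """
    if or_per_sd <= 0:
        raise ValueError("or_per_sd must be positive")
    prs_z = np.asarray(prs_z, dtype=float)
    rng = np.random.default_rng(seed)
    p = expit(base_logit + np.log(or_per_sd) * prs_z)
    return rng.binomial(1, p).astype(int)


def _adequate_stream(rng, start: int, span: int) -> list[int]:
    """Dispense dates forming one adequate episode of the given span."""
    # a middle dispense placed so both gaps stay <= 120 (requires span <= 240)
    lo, hi = max(1, span - 120), min(120, span - 1)
    mid = start + int(rng.integers(lo, hi + 1))
    return sorted({start, mid, start + span})


def simulate_registry(
    status: np.ndarray, config: SynthConfig, seed: int = 0, patient_ids=None
):
    """Dispensing and ECT registers consistent with the given true status.

    TRD-destined patients receive a first-ECT date and, with the
    configured category probabilities, >=2 / exactly 1 / 0 adequate
    distinct antidepressant episodes strictly before that date (or no
    antidepressant at all). Non-TRD-destined patients get no ECT and, with
    probability ``nontrd_narrow_prob``, 1-2 adequate distinct
    antidepressants (narrow non-TRD material); otherwise 3 adequate ones
    (excluded under the narrow definitions). Lithium dispenses and
    pathological streams (gap-boundary episodes, single dispenses,
    dispenses only after ECT) are injected at the configured rates.

    Returns ``(dispensing, ect)`` DataFrames.
    """
    status = np.asarray(status)
    n = status.size
    if patient_ids is None:
        patient_ids = [f"P{i:06d}" for i in range(n)]
    rng = np.random.default_rng(seed)
    p2, p1, p0 = config.trd_cat_probs
    disp_rows: list[tuple] = []
    ect_rows: list[tuple] = []

    for pid, st in zip(patient_ids, status):
        codes = list(rng.choice(ANTIDEPRESSANT_CODES, size=4, replace=False))
        if st == 1:
            ect_day = int(rng.integers(400, 601))
            ect_rows.append((pid, ect_day))
            u = rng.random()
            if u < p2:
                n_adequate = 2 + int(rng.random() < 0.4)
            elif u < p2 + p1:
                n_adequate = 1
            elif u < p2 + p1 + p0:
                n_adequate = 0  # antidepressant use, nothing adequate
            else:
                n_adequate = -1  # no antidepressant before ECT
            horizon = ect_day - 1
        else:
            ect_day = None
            if rng.random() < config.nontrd_narrow_prob:
                n_adequate = 1 + int(rng.random() < 0.5)
            else:
                n_adequate = 3  # breaks the <=2 rule -> excluded under narrow
            horizon = 600

        if n_adequate >= 0:
            for k in range(max(n_adequate, 1)):
                code = codes[k]
                if k < n_adequate:
                    span = int(rng.integers(config.min_adequate_days, 181))
                    start = int(rng.integers(0, max(horizon - span, 1)))
                    days = _adequate_stream(rng, start, span)
                else:
                    # inadequate filler: a single dispense (duration 0)
                    days = [int(rng.integers(0, horizon))]
                disp_rows += [(pid, code, d) for d in days]

        li_p = config.lithium_frac_trd if st == 1 else config.lithium_frac_nontrd
        if rng.random() < li_p:
            d0 = int(rng.integers(0, 500))
            disp_rows += [(pid, ATC_LITHIUM, d0), (pid, ATC_LITHIUM, d0 + 30)]

        if rng.random() < config.noise_gap_boundary:
            d0 = int(rng.integers(0, 300))
            gap = 120 if rng.random() < 0.5 else 121
            disp_rows += [(pid, codes[3], d0), (pid, codes[3], d0 + gap)]
        if rng.random() < config.noise_single_dispense:
            disp_rows.append((pid, codes[3], int(rng.integers(0, 600))))
        if st == 1 and rng.random() < config.noise_post_ect_only:
            # wipe pre-ECT history: dispenses only after the ECT date
            disp_rows = [r for r in disp_rows if r[0] != pid or r[1] == ATC_LITHIUM]
            span = int(rng.integers(config.min_adequate_days, 181))
            disp_rows += [
                (pid, codes[0], d) for d in _adequate_stream(rng, ect_day + 10, span)
            ]

    dispensing = pd.DataFrame(disp_rows, columns=["patient_id", "atc", "date"])
    ect = pd.DataFrame(ect_rows, columns=["patient_id", "date"])
    return dispensing, ect


def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Full synthetic cohort: genotypes, weights, registers, truth.

    The realized TRD count is Binomial around ``n_cases_trd`` — the
    baseline logit is set to ``logit(n_cases_trd / n_total)`` and status
    is drawn per sample from the true-score logistic model.
    """
    n = config.n_cases_trd + config.n_nontrd
    rng = np.random.default_rng(config.seed)
    s_geno, s_wt, s_status, s_reg = rng.integers(0, 2**31 - 1, size=4)

    dos, variants = simulate_genotypes(
        n,
        config.n_snps,
        config.maf_range,
        seed=int(s_geno),
        ambiguous_frac=config.ambiguous_frac,
        mhc_frac=config.mhc_frac,
        missing_rate=config.missing_rate,
        n_low_call_variants=config.n_low_call_variants,
        n_low_call_samples=config.n_low_call_samples,
    )
    weights = simulate_weights(
        variants,
        config.prop_causal,
        config.weight_sd,
        seed=int(s_wt),
        swap_frac=config.swap_frac,
    )
    # true raw score in canonical (alt-dosage) orientation, missing as mean
    w = np.where(
        weights["effect_allele"].to_numpy() == variants["alt"].to_numpy(),
        weights["weight"].to_numpy(),
        -weights["weight"].to_numpy(),
    )
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(dos, axis=0)
    filled = np.where(np.isnan(dos), col_mean, dos)
    raw = filled @ w
    sd = raw.std(ddof=1)
    z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)

    base_logit = float(np.log(config.n_cases_trd / config.n_nontrd))
    status = simulate_trd_status(z, config.or_per_sd, base_logit, seed=int(s_status))
    sample_ids = [f"P{i:06d}" for i in range(n)]
    dispensing, ect = simulate_registry(status, config, seed=int(s_reg), patient_ids=sample_ids)

    truth = pd.DataFrame(
        {
            "patient_id": sample_ids,
            "prs_raw": raw,
            "prs_z": z,
            "p_trd": expit(base_logit + np.log(config.or_per_sd) * z),
            "status": status,
        }
    )
    return SyntheticCohort(
        config=config,
        sample_ids=sample_ids,
        dosages=dos,
        variants=variants,
        weights=weights,
        dispensing=dispensing,
        ect=ect,
        truth=truth,
    )


def simulate_reference_panel(
    variants: pd.DataFrame,
    n_per_pop: int = 100,
    fst: float = 0.1,
    populations=("EUR", "EAS"),
    seed: int = 0,
):
    """Two-population reference panel for ancestry-outlier projection.

    Population allele frequencies diverge from the study frequencies via
    a Balding-Nichols Beta draw with the given Fst, so populations
    separate on the leading principal components. Returns
    ``(dosages, pop_labels)``; sample order follows ``populations``.
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p0 = np.clip(variants["maf"].to_numpy(dtype=float), 0.01, 0.99)
    blocks, labels = [], []
    a = (1.0 - fst) / fst
    for pop in populations:
        p_pop = rng.beta(a * p0, a * (1.0 - p0))
        blocks.append(rng.binomial(2, p_pop, size=(n_per_pop, len(p0))).astype(float))
        labels += [pop] * n_per_pop
    return np.vstack(blocks), pd.Series(labels, name="population")
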
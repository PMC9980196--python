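"""PRS-TRD association statistics.

For each polygenic score and each TRD definition the battery computes:
the mean PRS difference between arms (Welch t-test), the odds ratio per
SD of PRS from a logistic regression adjusted for the first four
principal components (Wald CI and p), Nagelkerke's pseudo-R2 of the PRS
over the covariate-only baseline, its conversion to the liability scale
at an assumed population TRD proportion K among MDD cases, a
Cochran-Armitage trend test across score quartiles, and Bonferroni
significance flags across the main comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .prs import assign_quartiles

Z975 = 1.959964  # two-sided 95% normal quantile


@dataclass
class LiabilityParams:
    """K: assumed proportion of MDD cases that are TRD in the population;
    P: observed TRD fraction in the analyzed sample."""

    K: float = 0.10
    P: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.K < 1.0 and 0.0 < self.P < 1.0):
            raise ValueError("K and P must be in (0, 1)")


@dataclass
class AssociationResult:
    trait: str
    definition: str
    adjustment: str
    n_trd: int
    n_nontrd: int
    mean_diff: float
    t_p: float
    beta: float
    se: float
    or_per_sd: float
    ci_low: float
    ci_high: float
    p: float
    r2_nagelkerke: float
    r2_liability: float
    significant: bool = False


class SeparationError(RuntimeError):
    pass


def prs_mean_difference(prs_z: np.ndarray, outcome: np.ndarray):
    """mean(PRS | TRD) - mean(PRS | non-TRD) with a Welch two-sided t-test."""
    prs_z = np.asarray(prs_z, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    a, b = prs_z[outcome], prs_z[~outcome]
    if a.size < 2 or b.size < 2:
        raise ValueError("each arm needs at least two samples for the t-test")
    diff = a.mean() - b.mean()
    if np.allclose(a.std(), 0) and np.allclose(b.std(), 0) and np.isclose(diff, 0):
        return 0.0, 1.0
    t = stats.ttest_ind(a, b, equal_var=False)
    return float(diff), float(t.pvalue)


def _check_separation(y: np.ndarray, X: pd.DataFrame) -> None:
    for name in X.columns:
        if name == "const":
            continue
        x = X[name].to_numpy(dtype=float)
        lo1, hi1 = x[y == 1].min(), x[y == 1].max()
        lo0, hi0 = x[y == 0].min(), x[y == 0].max()
        if hi1 < lo0 or hi0 < lo1:
            raise SeparationError(f"perfect separation on predictor {name!r}")


def fit_logistic(y, X, add_const: bool = True):
    """Maximum-likelihood logistic fit (Newton scoring, tol 1e-8, <=50 iter).

    ``X`` is a DataFrame of predictors (no intercept column; one is
    added). Returns the fitted statsmodels results object. Raises on
    rank-deficient designs, perfect separation (naming the offending
    predictor) and non-convergence.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    X = pd.DataFrame(X)
    if add_const:
        X = sm.add_constant(X, has_constant="add")
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError("design matrix is rank deficient")
    _check_separation(y, X)
    with np.errstate(all="ignore"):
        res = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=50, disp=False)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError("logistic fit did not converge in 50 iterations")
    return res


def nagelkerke_r2(llnull: float, llfull: float, n: int) -> float:
    """Nagelkerke's rescaled likelihood-ratio pseudo-R2.

    ``llnull`` is the log-likelihood of the baseline (covariates-only)
    model and ``llfull`` that of the model adding the score term."""
    if n <= 0:
        raise ValueError("n must be positive")
    cs = 1.0 - np.exp((2.0 / n) * (llnull - llfull))
    maxi = 1.0 - np.exp((2.0 / n) * llnull)
    return float(cs / maxi)


def liability_r2(r2_observed: float, params: LiabilityParams) -> float:
    """Observed-scale R2 converted to the liability scale.

    Uses the ascertainment-corrected threshold-model factor
    C = [K(1-K)/z^2] * [K(1-K)/(P(1-P))] with z the standard-normal
    density at the liability threshold Phi^-1(1-K); K = P = 0.5 gives
    exactly pi/2.
    """
    t = stats.norm.isf(params.K)
    z = stats.norm.pdf(t)
    c = (params.K * (1 - params.K) / z**2) * (
        params.K * (1 - params.K) / (params.P * (1 - params.P))
    )
    return float(r2_observed * c)


def quartile_trend_test(quartiles, outcome, scores=(1, 2, 3, 4), method: str = "cochran-armitage"):
    """Trend in TRD proportion across score quartiles.

    ``cochran-armitage``: 1-df chi-square for linear trend in proportions
    with the given group scores (invariant to affine rescaling of the
    scores). ``heterogeneity``: ordinary k x 2 chi-square with k-1 df.
    Returns (statistic, p).
    """
    quartiles = np.asarray(quartiles)
    outcome = np.asarray(outcome, dtype=bool)
    levels = [f"Q{k}" for k in (1, 2, 3, 4)]
    present = [q for q in levels if (quartiles == q).any()]
    n_i = np.array([(quartiles == q).sum() for q in present], dtype=float)
    r_i = np.array([(outcome & (quartiles == q)).sum() for q in present], dtype=float)

    if method == "heterogeneity":
        table = np.vstack([r_i, n_i - r_i])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)
    if method != "cochran-armitage":
        raise ValueError(f"unknown trend method {method!r}")

    s = np.asarray(scores, dtype=float)[: len(present)]
    N, R = n_i.sum(), r_i.sum()
    pbar = R / N
    num = (s * r_i).sum() - pbar * (s * n_i).sum()
    var = pbar * (1 - pbar) * ((s**2 * n_i).sum() - (s * n_i).sum() ** 2 / N)
    if var == 0:
        return 0.0, 1.0
    chi2 = num**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def bonferroni(alpha: float = 0.05, m: int = 6) -> float:
    """Per-comparison significance threshold alpha/m."""
    if m <= 0:
        raise ValueError("number of comparisons must be positive")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m


def associate(
    outcome,
    prs_z,
    covariates: pd.DataFrame,
    trait: str = "prs",
    definition: str = "broad",
    adjustment: str = "None",
    k_prevalence: float = 0.10,
) -> AssociationResult:
    """One PRS-definition comparison: t-test, adjusted logistic OR per SD,
    Nagelkerke and liability R2 (PRS term over the covariate baseline)."""
    y = np.asarray(outcome, dtype=int)
    z = np.asarray(prs_z, dtype=float)
    X_full = pd.DataFrame(covariates).copy()
    X_full.insert(0, "prs_z", z)

    mean_diff, t_p = prs_mean_difference(z, y.astype(bool))
    full = fit_logistic(y, X_full)
    if len(X_full.columns) > 1:
        null = fit_logistic(y, X_full.drop(columns="prs_z"))
        llnull = null.llf
    else:
        null = fit_logistic(y, pd.DataFrame(index=X_full.index))
        llnull = null.llf
    beta = float(full.params["prs_z"])
    se = float(full.bse["prs_z"])
    p = float(full.pvalues["prs_z"])
    r2n = nagelkerke_r2(llnull, full.llf, len(y))
    P = float(y.mean())
    r2l = liability_r2(r2n, LiabilityParams(K=k_prevalence, P=P))
    return AssociationResult(
        trait=trait,
        definition=definition,
        adjustment=adjustment,
        n_trd=int(y.sum()),
        n_nontrd=int((1 - y).sum()),
        mean_diff=mean_diff,
        t_p=t_p,
        beta=beta,
        se=se,
        or_per_sd=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        p=p,
        r2_nagelkerke=r2n,
        r2_liability=r2l,
    )


def run_comparisons(
    labels: pd.DataFrame,
    prs_tables: dict[str, pd.DataFrame],
    pcs: pd.DataFrame,
    disorder_prs: dict[str, pd.DataFrame] | None = None,
    k_prevalence: float = 0.10,
    alpha: float = 0.05,
    lithium_sensitivity: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The full association battery over traits x definitions.

    Parameters
    ----------
    labels
        Long phenotype table (patient_id, definition, status,
        lithium_user, ...) as produced by phenotyping.
    prs_tables
        trait name -> DataFrame (sample_id, z) of standardized scores.
        Scores were standardized once within the whole scored sample;
        subset analyses reuse those z-scores.
    pcs
        sample_id-indexed DataFrame of PC covariates (first four used by
        default convention; all provided columns are included).
    disorder_prs
        Optional {"MDD": ..., "BIP": ...} score tables used as additional
        covariates in the sensitivity adjustments.
    lithium_sensitivity
        Also refit the main model after dropping lithium users from the
        TRD arm.

    Returns
    -------
    (results, quartile_table): results has one row per trait x definition
    x adjustment (+ lithium-excluded refits, tagged ``lithium_excluded``);
    Bonferroni significance is flagged for the main (unadjusted,
    non-sensitivity) rows at alpha / (#traits x #definitions). The
    quartile table gives per-quartile arm counts, TRD proportion and the
    trend-test p per trait x definition.
    """
    disorder_prs = disorder_prs or {}
    definitions = list(dict.fromkeys(labels["definition"]))
    m = len(prs_tables) * len(definitions)
    threshold = bonferroni(alpha, m)

    adjustments: list[tuple[str, list[str]]] = [("None", [])]
    if "MDD" in disorder_prs:
        adjustments.append(("MDD_adj", ["MDD"]))
    if "BIP" in disorder_prs:
        adjustments.append(("BIP_adj", ["BIP"]))
    if {"MDD", "BIP"} <= set(disorder_prs):
        adjustments.append(("BIP_MDD_adj", ["BIP", "MDD"]))

    rows, qrows = [], []
    for trait, tab in prs_tables.items():
        z = tab.set_index("sample_id")["z"]
        quart_all = pd.Series(assign_quartiles(z.to_numpy()), index=z.index)
        for definition in definitions:
            sub = labels[(labels["definition"] == definition) & labels["status"].isin(["TRD", "non-TRD"])]
            sub = sub[sub["patient_id"].isin(z.index) & sub["patient_id"].isin(pcs.index)]
            ids = sub["patient_id"].to_numpy()
            y = (sub["status"] == "TRD").to_numpy().astype(int)
            zz = z.loc[ids].to_numpy()
            base_cov = pcs.loc[ids]

            for adj, extra in adjustments:
                cov = base_cov.copy()
                for name in extra:
                    cov[f"prs_{name.lower()}"] = (
                        disorder_prs[name].set_index("sample_id")["z"].loc[ids].to_numpy()
                    )
                res = associate(y, zz, cov, trait, definition, adj, k_prevalence)
                if adj == "None":
                    res.significant = res.p <= threshold
                rows.append((res, False))

            if lithium_sensitivity:
                li = sub.set_index("patient_id")["lithium_user"].astype(bool)
                keep = ~(li.to_numpy() & (y == 1))  # drop lithium-using TRD cases
                res = associate(
                    y[keep], zz[keep], base_cov.iloc[keep], trait, definition, "None", k_prevalence
                )
                rows.append((res, True))

            quart = quart_all.loc[ids].to_numpy()
            stat, p_trend = quartile_trend_test(quart, y.astype(bool))
            for q in ("Q1", "Q2", "Q3", "Q4"):
                in_q = quart == q
                n_trd = int((y[in_q] == 1).sum())
                n_non = int((y[in_q] == 0).sum())
                prop = n_trd / max(n_trd + n_non, 1)
                qrows.append((trait, definition, q, n_trd, n_non, prop, stat, p_trend))

    results = pd.DataFrame(
        [
            {
                "trait": r.trait,
                "definition": r.definition,
                "adjustment": r.adjustment,
                "lithium_excluded": li_ex,
                "n_trd": r.n_trd,
                "n_nontrd": r.n_nontrd,
                "mean_diff": r.mean_diff,
                "t_p": r.t_p,
                "beta": r.beta,
                "se": r.se,
                "or": r.or_per_sd,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "r2_nagelkerke": r.r2_nagelkerke,
                "r2_liability": r.r2_liability,
                "significant": r.significant,
            }
            for r, li_ex in rows
        ]
    )
    quartile_table = pd.DataFrame(
        qrows,
        columns=["trait", "definition", "quartile", "n_trd", "n_nontrd", "proportion", "trend_chi2", "trend_p"],
    )
    return results, quartile_table
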
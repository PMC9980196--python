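"""Genotype QC: HWE exact test, filter cascade, PCA projection, relatedness."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from trdprs import (
    estimate_pi_hat,
    filter_samples,
    filter_variants,
    hwe_exact_test,
    pca_project_and_flag,
    prune_related,
)
from trdprs.qc import (
    RelatednessPair,
    genotype_counts,
    prefilter_variants,
    run_qc,
    sample_qc_metrics,
)
from trdprs.synth import simulate_genotypes, simulate_reference_panel


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Independent route: exact conditional probabilities of every
    heterozygote configuration from the closed-form multinomial count,
    P(h | nA, na) proportional to 2^h / (hom_A! h! hom_a!)."""
    n = n_AA + n_Aa + n_aa
    na = 2 * n_aa + n_Aa
    nA = 2 * n - na
    rare = min(na, nA)
    hets = list(range(rare % 2, rare + 1, 2))
    probs = []
    for h in hets:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs.append(math.exp(h * math.log(2) - gammaln(hom_r + 1) - gammaln(h + 1) - gammaln(hom_c + 1)))
    total = sum(probs)
    probs = [p / total for p in probs]
    p_obs = probs[hets.index(n_Aa)]
    return sum(p for p in probs if p <= p_obs * (1 + 1e-12)), probs


class TestHweExactTest:
    def test_matches_enumeration_oracle_for_all_small_tables(self):
        """Every genotype table with up to 30 samples agrees with the
        full-enumeration oracle; configuration probabilities sum to 1."""
        for n in range(1, 31):
            for n_AA in range(n + 1):
                for n_Aa in range(n - n_AA + 1):
                    n_aa = n - n_AA - n_Aa
                    expected, probs = hwe_oracle(n_AA, n_Aa, n_aa)
                    assert abs(sum(probs) - 1.0) < 1e-12
                    got = hwe_exact_test(n_AA, n_Aa, n_aa)
                    assert got == pytest.approx(expected, abs=1e-10)
                    assert 0.0 < got <= 1.0

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((0, 2, 0), 1.0),  # het-only table is modal for 2 of each allele
            ((10, 0, 0), 1.0),  # monomorphic: single configuration
            ((1, 0, 1), 1 / 3),  # both-homozygote table for nA=na=2
        ],
    )
    def test_known_tables(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-12)

    def test_extreme_disequilibrium_is_tiny(self):
        assert hwe_exact_test(50, 0, 50) < 1e-6

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 0)


def _variants_for(m):
    return pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 1000,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )


class TestVariantFilters:
    def test_cascade_rules_and_boundaries(self, rng):
        n = 500
        groups = np.zeros(n, dtype=bool)
        groups[:250] = True
        cols = {}
        cols["ok"] = rng.binomial(2, 0.3, n).astype(float)
        low_call = cols["ok"].copy()
        low_call[:15] = np.nan  # call rate 0.97 < 0.98
        cols["low_call"] = low_call
        cols["invariant"] = np.zeros(n)
        # cases in extreme HW disequilibrium, controls in equilibrium
        hwe_bad = np.concatenate([np.zeros(125), np.full(125, 2)])
        cols["hwe_bad"] = np.concatenate([hwe_bad, rng.binomial(2, 0.5, 250)]).astype(float)
        diff = rng.binomial(2, 0.3, n).astype(float)
        diff[:4] = np.nan  # overall call 0.992 kept; case/control diff 0.016 > 0.01
        cols["diff_call"] = diff
        # exact MAF boundary: 0.009 removed, 0.010 kept (strict <)
        cols["maf_low"] = _exact_maf_col(n, 0.009)
        cols["maf_edge"] = _exact_maf_col(n, 0.010)
        m = len(cols)
        dos = np.column_stack(list(cols.values()))
        var = _variants_for(m)
        var["id"] = list(cols.keys())
        kept, report = filter_variants(dos, var, groups)
        assert "low_call" not in kept and report["call_rate"] == 1
        assert "invariant" not in kept and report["invariant"] == 1
        assert "hwe_bad" not in kept and report["hwe"] == 1
        assert "diff_call" not in kept and report["diff_call_rate"] == 1
        assert "maf_low" not in kept and report["maf"] == 1
        assert "ok" in kept and "maf_edge" in kept
        assert report["kept"] == 2

    def test_cascade_is_idempotent(self, rng):
        n, m = 120, 40
        dos, var = simulate_genotypes(n, m, (0.05, 0.5), seed=3, missing_rate=0.02)
        groups = np.arange(n) < 60
        kept, _ = filter_variants(dos, var, groups)
        keep = var["id"].isin(kept).to_numpy()
        kept2, report2 = filter_variants(dos[:, keep], var[keep].reset_index(drop=True), groups)
        assert kept2 == kept
        assert all(report2[k] == 0 for k in ("call_rate", "invariant", "hwe", "diff_call_rate", "maf"))

    def test_empty_group_rejected(self, rng):
        dos, var = simulate_genotypes(10, 5, seed=0)
        with pytest.raises(ValueError):
            filter_variants(dos, var, np.ones(10, dtype=bool))

    def test_prefilter_rules(self):
        n = 100
        var = pd.DataFrame(
            {
                "id": ["mono", "indel", "ambig", "ok"],
                "chrom": ["1"] * 4,
                "pos": [1, 2, 3, 4],
                "ref": ["A", "AT", "A", "A"],
                "alt": ["G", "G", "T", "G"],
            }
        )
        dos = np.column_stack(
            [np.zeros(n), _exact_maf_col(n, 0.3), _exact_maf_col(n, 0.3), _exact_maf_col(n, 0.3)]
        )
        kept, report = prefilter_variants(var, dos)
        assert kept == ["ok"]
        assert report["monomorphic"] == 1 and report["indel"] == 1
        assert report["strand_ambiguous"] == 1


def _exact_maf_col(n, maf):
    """Dosage column with exactly the requested alt-allele frequency.

    Minor alleles sit in heterozygote carriers spread evenly over the
    samples, so the column is consistent with Hardy-Weinberg proportions
    and balanced across any contiguous group split."""
    k = round(maf * 2 * n)
    assert k <= n
    col = np.zeros(n)
    col[np.linspace(0, n - 1, k).astype(int)] = 1.0
    return col


class TestSampleFilters:
    def test_call_rate_boundary_strict(self):
        m = 1000
        dos = np.ones((3, m))
        dos[1, :20] = np.nan  # 0.980 kept (strict <)
        dos[2, :21] = np.nan  # 0.979 removed
        # give variants some heterozygosity so F is near 0 for kept rows
        rng = np.random.default_rng(0)
        base = rng.binomial(2, 0.5, size=(3, m)).astype(float)
        base[np.isnan(dos)] = np.nan
        kept, metrics, report = filter_samples(base, ["a", "b", "c"])
        assert "b" in kept and "c" not in kept
        assert report["call_rate"] == 1

    def test_fully_homozygous_sample_flagged(self, rng):
        m = 2000
        dos = rng.binomial(2, 0.4, size=(30, m)).astype(float)
        dos[0] = np.where(dos[0] == 1.0, 2.0, dos[0])  # no hets at all
        ids = [f"s{i}" for i in range(30)]
        kept, metrics, _ = filter_samples(dos, ids)
        f0 = metrics.set_index("sample_id").loc["s0", "f_het"]
        assert f0 > 0.9
        assert "s0" not in kept
        # typical samples sit near F = 0 and are kept
        assert metrics.set_index("sample_id").loc["s1", "f_het"] == pytest.approx(0, abs=0.15)
        assert "s1" in kept


class TestPcaProjection:
    def test_target_population_study_rarely_flagged_and_divergent_flagged(self, rng):
        m = 500
        _, var = simulate_genotypes(50, m, (0.1, 0.5), seed=1)
        ref, pops = simulate_reference_panel(var, n_per_pop=80, fst=0.15, seed=2)
        # study samples drawn from the EUR reference frequencies
        eur = ref[(pops == "EUR").to_numpy()]
        p_eur = eur.mean(axis=0) / 2
        study_eur = rng.binomial(2, p_eur, size=(40, m)).astype(float)
        p_eas = ref[(pops == "EAS").to_numpy()].mean(axis=0) / 2
        study_eas = rng.binomial(2, p_eas, size=(10, m)).astype(float)
        study = np.vstack([study_eur, study_eas])
        ids = [f"e{i}" for i in range(40)] + [f"x{i}" for i in range(10)]
        outliers, res = pca_project_and_flag(study, ref, pops, ids, "EUR")
        assert all(o.startswith("x") for o in outliers)
        assert len(outliers) == 10

    def test_projection_reproduces_reference_scores(self):
        m = 300
        _, var = simulate_genotypes(50, m, (0.1, 0.5), seed=5)
        ref, pops = simulate_reference_panel(var, n_per_pop=60, fst=0.1, seed=6)
        ids = [f"r{i}" for i in range(ref.shape[0])]
        _, res = pca_project_and_flag(ref, ref, pops, ids, "EUR")
        np.testing.assert_allclose(res.projections, res.ref_scores, atol=1e-8)

    def test_unknown_target_population_errors(self):
        _, var = simulate_genotypes(10, 50, seed=0)
        ref, pops = simulate_reference_panel(var, n_per_pop=10, seed=0)
        with pytest.raises(ValueError, match="target population"):
            pca_project_and_flag(ref[:5], ref, pops, ["a"] * 5, "AFR")


class TestRelatedness:
    def test_self_pair_is_exactly_one(self, rng):
        g = rng.binomial(2, rng.uniform(0.1, 0.5, 500), size=(10, 500)).astype(float)
        ids = [f"s{i}" for i in range(10)]
        pair = estimate_pi_hat(g, ids, pairs=[("s3", "s3")])[0]
        assert pair.pi_hat == 1.0

    def test_unrelated_near_zero(self, rng):
        m = 5000
        p = rng.uniform(0.1, 0.5, m)
        g = rng.binomial(2, p, size=(60, m)).astype(float)
        ids = [f"s{i}" for i in range(60)]
        pairs = estimate_pi_hat(g, ids, pairs=[("s0", "s1"), ("s2", "s3")])
        for pr in pairs:
            assert pr.pi_hat == pytest.approx(0.0, abs=0.05)

    def test_vectorized_all_pairs_equals_pairwise_path(self, rng):
        m = 400
        g = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(8, m)).astype(float)
        g[rng.random(g.shape) < 0.02] = np.nan
        ids = [f"s{i}" for i in range(8)]
        allp = {frozenset((p.id_a, p.id_b)): p.pi_hat for p in estimate_pi_hat(g, ids)}
        expl = estimate_pi_hat(g, ids, pairs=[("s0", "s5"), ("s2", "s7")])
        for pr in expl:
            assert allp[frozenset((pr.id_a, pr.id_b))] == pytest.approx(pr.pi_hat, abs=1e-10)

    def test_parent_offspring_near_half(self, rng):
        m = 5000
        p = rng.uniform(0.1, 0.5, m)
        pop = rng.binomial(2, p, size=(100, m)).astype(float)
        parent = pop[0]
        from_parent = np.where(parent == 1.0, rng.integers(0, 2, m), parent / 2)
        child = from_parent + rng.binomial(1, p)
        g = np.vstack([pop, child[None, :]])
        ids = [f"s{i}" for i in range(101)]
        pr = estimate_pi_hat(g, ids, pairs=[("s0", "s100")])[0]
        assert pr.pi_hat == pytest.approx(0.5, abs=0.05)


class TestPruning:
    def test_single_pair_drops_lower_call_rate_member(self):
        pairs = [RelatednessPair("a", "b", 0.6)]
        call = {"a": 0.999, "b": 0.95}
        assert prune_related(pairs, call) == ["b"]

    def test_below_threshold_untouched(self):
        pairs = [RelatednessPair("a", "b", 0.15)]
        assert prune_related(pairs, {}) == []

    def test_triangle_removes_two(self):
        pairs = [
            RelatednessPair("a", "b", 0.5),
            RelatednessPair("b", "c", 0.5),
            RelatednessPair("a", "c", 0.5),
        ]
        removed = prune_related(pairs, {"a": 0.99, "b": 0.98, "c": 0.97})
        assert len(removed) == 2
        # equal degrees: lowest call rate goes first, then again
        assert removed == ["b", "c"]

    def test_hub_removed_first(self):
        pairs = [
            RelatednessPair("hub", x, 0.5) for x in ("a", "b", "c")
        ]
        assert prune_related(pairs, {}) == ["hub"]


def test_run_qc_cascade_reports_all_stages(rng):
    from trdprs import SynthConfig, generate_cohort

    cohort = generate_cohort(SynthConfig(n_cases_trd=40, n_nontrd=60, n_snps=150, seed=11))
    case = (cohort.truth["status"] == 1).to_numpy()
    kept_s, kept_v, report = run_qc(
        cohort.dosages, cohort.variants, cohort.sample_ids, case
    )
    assert set(report) >= {"samples", "variants", "related_removed"}
    assert 0 < len(kept_s) <= 100
    assert 0 < len(kept_v) <= 150
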
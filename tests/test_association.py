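import math
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mdrkit import studydata
from mdrkit.association import (
    bonferroni_threshold,
    display_threshold,
    fisher_exact_2x2,
    fisher_exact_rxc,
    logistic_codominant,
    logistic_interaction_check,
    two_sample_summary_test,
)
from mdrkit.io_model import Dataset, SnpMeta, ValidationError


# ---------------------------------------------------------------------------
# independent exact-test oracles (integer arithmetic, no gammaln)


def fisher_2x2_oracle(a, b, c, d):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        mass = comb(r1, x) * comb(r2, c1 - x)
        if mass <= p_obs:
            total += mass
    return total / denom


def fisher_2x3_oracle(table):
    """Freeman-Halton p for a 2x3 table by direct integer enumeration."""
    t = [list(map(int, row)) for row in table]
    r1 = sum(t[0])
    cols = [t[0][j] + t[1][j] for j in range(3)]
    n = r1 + sum(t[1])

    def mass(x0, x1, x2):
        return comb(cols[0], x0) * comb(cols[1], x1) * comb(cols[2], x2)

    denom = comb(n, r1)
    obs = mass(*t[0])
    total = 0
    for x0 in range(min(cols[0], r1) + 1):
        for x1 in range(min(cols[1], r1 - x0) + 1):
            x2 = r1 - x0 - x1
            if 0 <= x2 <= cols[2]:
                m = mass(x0, x1, x2)
                if m <= obs:
                    total += m
    return total / denom


# ---------------------------------------------------------------------------
# Fisher exact


def test_fisher_2x2_symmetric_table():
    oddsr, p = fisher_exact_2x2([[1, 1], [1, 1]])
    assert oddsr == 1.0 and p == 1.0


def test_fisher_2x2_zero_margin():
    oddsr, p = fisher_exact_2x2([[0, 0], [3, 4]])
    assert oddsr is None and p == 1.0


def test_fisher_2x2_gender_table():
    """Case-control sex split (80/12 vs 105/42): significant female excess."""
    oddsr, p = fisher_exact_2x2([[80, 12], [105, 42]])
    assert p == pytest.approx(fisher_2x2_oracle(80, 12, 105, 42), abs=1e-10)
    assert p < 0.01
    assert oddsr == pytest.approx(80 * 42 / (12 * 105), rel=1e-12)


@given(
    a=st.integers(0, 12), b=st.integers(0, 12),
    c=st.integers(0, 12), d=st.integers(0, 12),
)
def test_fisher_2x2_matches_enumeration_and_permutation_invariance(a, b, c, d):
    t = [[a, b], [c, d]]
    rows = np.asarray(t).sum(axis=1)
    cols = np.asarray(t).sum(axis=0)
    _, p = fisher_exact_2x2(t)
    if (rows > 0).all() and (cols > 0).all():
        assert p == pytest.approx(fisher_2x2_oracle(a, b, c, d), abs=1e-9)
    _, p_rows = fisher_exact_2x2([[c, d], [a, b]])
    _, p_cols = fisher_exact_2x2([[b, a], [d, c]])
    assert p == pytest.approx(p_rows, abs=1e-12)
    assert p == pytest.approx(p_cols, abs=1e-12)


def test_fisher_rxc_modal_table_is_one():
    assert fisher_exact_rxc([[1, 1, 1], [1, 1, 1]]) == pytest.approx(1.0)


def test_fisher_rxc_reduces_to_2x2_with_zero_column():
    t23 = [[5, 0, 3], [2, 0, 7]]
    _, p22 = fisher_exact_2x2([[5, 3], [2, 7]])
    assert fisher_exact_rxc(t23) == pytest.approx(p22, abs=1e-12)


@given(data=st.data())
def test_fisher_rxc_matches_integer_enumeration_oracle(data):
    table = data.draw(
        st.lists(st.lists(st.integers(0, 7), min_size=3, max_size=3),
                 min_size=2, max_size=2)
    )
    arr = np.asarray(table)
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        return
    assert fisher_exact_rxc(table) == pytest.approx(fisher_2x3_oracle(table), abs=1e-12)


def test_fisher_rxc_capacity_guard():
    big = [[500, 400, 300], [450, 350, 600]]
    with pytest.raises(ValueError, match="Monte-Carlo"):
        fisher_exact_rxc(big, max_tables=1000)


# ---------------------------------------------------------------------------
# logistic regression


def _dataset_from_geno(geno, pheno, ids=("rs_a", "rs_b")):
    geno = np.atleast_2d(np.asarray(geno, dtype=np.int8).T).T
    metas = [SnpMeta(s, ref_allele="A", minor_allele="C") for s in ids[: geno.shape[1]]]
    return Dataset(
        [f"i{k}" for k in range(len(pheno))],
        geno,
        np.asarray(pheno, dtype=np.int8),
        snp_meta=metas,
    )


def test_logistic_binary_predictor_closed_form():
    """With a 0/1 genotype and no covariates the het OR is ad/bc and the
    Wald SE is sqrt(1/a + 1/b + 1/c + 1/d)."""
    a, b, c, d = 30, 18, 22, 41  # case/g1, case/g0, ctrl/g1, ctrl/g0
    geno = [1] * a + [0] * b + [1] * c + [0] * d
    pheno = [1] * (a + b) + [0] * (c + d)
    results, fit = logistic_codominant(_dataset_from_geno(geno, pheno, ("rs_a",)), "rs_a")
    het = [r for r in results if r.term.endswith("het")][0]
    assert het.or_estimate == pytest.approx(a * d / (b * c), rel=1e-6)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    assert fit.se["rs_a_het"] == pytest.approx(se, rel=1e-5)


def test_logistic_intercept_only_log_odds():
    geno = [0] * 10
    pheno = [1] * 4 + [0] * 6
    _, fit = logistic_codominant(_dataset_from_geno(geno, pheno, ("rs_a",)), "rs_a")
    assert fit.coefficients["const"] == pytest.approx(math.log(4 / 6), abs=1e-8)


def test_separation_reported_not_crashed(table3_dataset):
    """rs11292 has zero heterozygote cases: that term is non-estimable while
    the minor-homozygote term still gets an OR."""
    results, fit = logistic_codominant(table3_dataset, "rs11292")
    het = [r for r in results if r.term.endswith("het")][0]
    hom = [r for r in results if r.term.endswith("hom")][0]
    assert not het.estimable and "separation" in het.note
    assert hom.estimable and hom.or_estimate > 0
    assert "rs11292_het" in fit.dropped_terms


def test_logistic_recovers_known_log_or():
    """Simulated codominant data with per-genotype log-OR 0.7 recovers the
    coefficient within +-0.1 at n = 5000."""
    rng = np.random.default_rng(123)
    n = 5000
    u = rng.random(n)
    geno = np.where(u < 0.49, 0, np.where(u < 0.91, 1, 2)).astype(np.int8)
    logit = -0.5 + 0.7 * geno
    pheno = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(np.int8)
    _, fit = logistic_codominant(_dataset_from_geno(geno, pheno, ("rs_a",)), "rs_a")
    assert fit.coefficients["rs_a_het"] == pytest.approx(0.7, abs=0.1)
    assert fit.coefficients["rs_a_hom"] == pytest.approx(1.4, abs=0.2)


def test_wald_ci_coverage_near_nominal():
    """95% Wald CI covers the true OR in roughly 95% of replicates."""
    rng = np.random.default_rng(5)
    true_beta = 0.5
    covered = 0
    reps = 150
    for _ in range(reps):
        n = 600
        u = rng.random(n)
        geno = np.where(u < 0.49, 0, np.where(u < 0.91, 1, 2)).astype(np.int8)
        pheno = (rng.random(n) < 1 / (1 + np.exp(0.2 - true_beta * geno))).astype(np.int8)
        try:
            results, _ = logistic_codominant(
                _dataset_from_geno(geno, pheno, ("rs_a",)), "rs_a"
            )
        except ValidationError:
            continue
        het = [r for r in results if r.term.endswith("het")][0]
        if het.estimable and het.ci95[0] <= math.exp(true_beta) <= het.ci95[1]:
            covered += 1
    assert 0.89 * reps <= covered <= 0.99 * reps


def test_interaction_detected_for_dominance_xor():
    """Phenotype driven by the XOR of two dominance codes: the product term
    is significant while neither main effect is."""
    rng = np.random.default_rng(17)
    n = 1500
    # MAF 1 - sqrt(1/2): P(minor-allele carrier) = 1/2, so the dominance
    # codes are balanced and the XOR has no marginal effect
    q = 1 - math.sqrt(0.5)
    probs = ((1 - q) ** 2, (1 - q) ** 2 + 2 * q * (1 - q))
    u = rng.random(n)
    ga = np.where(u < probs[0], 0, np.where(u < probs[1], 1, 2)).astype(np.int8)
    u = rng.random(n)
    gb = np.where(u < probs[0], 0, np.where(u < probs[1], 1, 2)).astype(np.int8)
    xor = (ga >= 1) ^ (gb >= 1)
    pheno = (rng.random(n) < np.where(xor, 0.7, 0.3)).astype(np.int8)
    ds = _dataset_from_geno(np.column_stack([ga, gb]), pheno)
    res, _ = logistic_interaction_check(ds, ["rs_a", "rs_b"], coding="dominant")
    assert res.p < 1e-6
    for snp in ("rs_a", "rs_b"):
        mains, _ = logistic_codominant(ds, snp)
        assert all(r.p > 0.001 for r in mains if r.estimable)


def test_interaction_null_p_is_roughly_uniform():
    """Independent null SNPs give a near-uniform interaction p-value."""
    rng = np.random.default_rng(29)
    ps = []
    for _ in range(60):
        n = 400
        geno = rng.integers(0, 3, size=(n, 2)).astype(np.int8)
        pheno = rng.integers(0, 2, size=n).astype(np.int8)
        res, _ = logistic_interaction_check(
            _dataset_from_geno(geno, pheno), ["rs_a", "rs_b"]
        )
        if res.p is not None:
            ps.append(res.p)
    ks = stats.kstest(ps, "uniform")
    assert ks.pvalue > 0.01


def test_duplicate_snp_collinearity_diagnostic(table3_dataset):
    with pytest.raises(ValidationError, match="duplicate"):
        logistic_interaction_check(table3_dataset, ["rs679620", "rs679620"])


# ---------------------------------------------------------------------------
# Bonferroni + summary t


def test_bonferroni_threshold_values():
    assert bonferroni_threshold(0.05, 9) == pytest.approx(0.05 / 9)
    assert display_threshold(bonferroni_threshold(0.05, 9)) == 0.005
    assert bonferroni_threshold(0.05, 1) == 0.05
    assert bonferroni_threshold(0.05, 5) == pytest.approx(0.01)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


@given(m=st.integers(1, 500))
def test_bonferroni_scales_inversely(m):
    assert bonferroni_threshold(0.05, m) * m == pytest.approx(0.05, rel=1e-12)


def test_summary_t_matches_study_age_row():
    age = studydata.DEMOGRAPHICS["age"]
    p = two_sample_summary_test(*age["case"], 92, *age["control"], 147)
    assert p == pytest.approx(0.0001, abs=1e-4)
    assert p < 0.001


def test_summary_t_identical_groups():
    assert two_sample_summary_test(5.0, 1.0, 30, 5.0, 1.0, 30) == pytest.approx(1.0)


def test_summary_t_matches_raw_data_t():
    """Summary-statistic t equals scipy's pooled t on raw samples with the
    same moments."""
    rng = np.random.default_rng(3)
    x = rng.normal(10, 2, 80)
    y = rng.normal(11, 2.5, 120)
    p_raw = stats.ttest_ind(x, y, equal_var=True).pvalue
    p_sum = two_sample_summary_test(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )
    assert p_sum == pytest.approx(p_raw, rel=1e-10)


def test_summary_t_rejects_bad_inputs():
    with pytest.raises(ValueError):
        two_sample_summary_test(1, 0.0, 10, 2, 1.0, 10)
    with pytest.raises(ValueError):
        two_sample_summary_test(1, 1.0, 1, 2, 1.0, 10)
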
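"""Single-SNP association and interaction-corroboration inference.

Implements the classical case-control toolbox around the interaction
search: Fisher exact tests (2x2 via scipy, r x c by complete Freeman-Halton
enumeration), covariate-adjusted codominant logistic regression with Wald
odds ratios, a product-term interaction check, the Bonferroni threshold,
and the pooled two-sample t-test from summary statistics.

Separation (a genotype class with zero cases or zero controls, as happens
for rare heterozygote classes in small studies) is detected up front and
reported as a non-estimable term rather than rescued by penalization.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io_model import MISSING, Dataset, ValidationError

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class AssociationResult:
    """One odds-ratio row: term, OR with 95% CI, Wald p, reference label.

    ``or_estimate`` is None when the term is non-estimable (separation or
    collinearity); ``note`` carries the diagnostic.
    """

    term: str
    or_estimate: float | None
    ci95: tuple[float, float] | None
    p: float | None
    reference: str = ""
    note: str = ""

    @property
    def estimable(self) -> bool:
        return self.or_estimate is not None


@dataclass
class LogisticFit:
    coefficients: dict[str, float]
    se: dict[str, float]
    converged: bool
    n_used: int
    loglike: float = math.nan
    dropped_terms: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# exact tests


def fisher_exact_2x2(table, *, or_kind: str = "sample") -> tuple[float | None, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities of all tables (fixed
    margins) no more probable than the observed one.  The odds ratio is the
    sample OR ``ad/bc`` by default, or the conditional MLE with
    ``or_kind="cmle"``; a zero margin gives p = 1 and a non-estimable OR.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("fisher_exact_2x2 needs a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return None, 1.0
    _, p = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    if or_kind == "cmle":
        oddsr = float(stats.contingency.odds_ratio(t, kind="conditional").statistic)
    elif b * c == 0:
        oddsr = math.inf if a * d > 0 else None
    else:
        oddsr = a * d / (b * c)
    return oddsr, float(p)


def _log_table_prob(table: np.ndarray, row_sums, col_sums, n) -> float:
    # multivariate hypergeometric probability of a table with fixed margins
    return float(
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def fill(rows_left, col_rem):
        if len(rows_left) == 1:
            if all(x >= 0 for x in col_rem):
                yield [list(col_rem)]
            return
        total = rows_left[0]
        ranges = [range(min(total, col_rem[j]) + 1) for j in range(c - 1)]
        for head in itertools.product(*ranges):
            last = total - sum(head)
            if 0 <= last <= col_rem[-1]:
                row = list(head) + [last]
                rem = [col_rem[j] - row[j] for j in range(c)]
                for rest in fill(rows_left[1:], rem):
                    yield [row] + rest

    yield from fill(list(row_sums), list(col_sums))


def fisher_exact_rxc(table, *, max_tables: int = 2_000_000) -> float:
    """Freeman-Halton exact test for an r x c table by full enumeration.

    Sums the probabilities of every margin-fixed table whose probability
    does not exceed the observed table's (with a 1e-7 relative tolerance
    against floating round-off).  A loose upper bound on the enumeration
    size guards against infeasible tables; Monte-Carlo approximation is the
    standard fallback for those.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or min(t.shape) < 2 or (t < 0).any():
        raise ValidationError("fisher_exact_rxc needs a non-negative r x c table")
    row_sums, col_sums, n = t.sum(axis=1), t.sum(axis=0), int(t.sum())
    if n == 0:
        return 1.0
    # drop empty rows/columns: they do not affect the distribution
    t = t[row_sums > 0][:, col_sums > 0]
    if t.ndim != 2 or min(t.shape) < 2:
        return 1.0
    row_sums, col_sums = t.sum(axis=1), t.sum(axis=0)
    bound = 1
    for rs in row_sums[:-1]:
        for cs in col_sums[:-1]:
            bound *= min(rs, cs) + 1
            if bound > max_tables:
                raise ValueError(
                    "table too large for complete enumeration; "
                    "use a Monte-Carlo approximation instead"
                )
    log_p_obs = _log_table_prob(t, row_sums, col_sums, t.sum())
    cutoff = log_p_obs + 1e-7
    total = 0.0
    for cand in _enumerate_tables(row_sums.tolist(), col_sums.tolist()):
        lp = _log_table_prob(np.asarray(cand), row_sums, col_sums, t.sum())
        if lp <= cutoff:
            total += math.exp(lp)
    return float(min(total, 1.0))


# ---------------------------------------------------------------------------
# logistic regression


def _design_matrix(
    dataset: Dataset, covariates: tuple[str, ...]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Covariate design columns (sex coded as a male indicator; admixture
    proportions passed through as given, caller drops one of k)."""
    n = dataset.n
    cols: dict[str, np.ndarray] = {}
    for name in covariates:
        if dataset.covariates is None or name not in dataset.covariates.columns:
            raise ValidationError(f"missing covariate {name!r}")
        col = dataset.covariates[name]
        if name == "sex":
            cols["sex_male"] = (
                col.astype(str).str.lower() != "female"
            ).to_numpy(dtype=float)
        else:
            cols[name] = pd.to_numeric(col).to_numpy(dtype=float)
    frame = pd.DataFrame(cols if cols else {}, index=range(n))
    return frame, dataset.phenotype.astype(float)


def _fit_logit(X: pd.DataFrame, y: np.ndarray) -> tuple[LogisticFit, object]:
    import statsmodels.api as sm

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValidationError(
            "design matrix is rank deficient (collinear terms: check for "
            "duplicated SNPs or redundant covariates)"
        )
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100)
    converged = bool(getattr(res, "converged", True))
    fit = LogisticFit(
        coefficients={k: float(v) for k, v in res.params.items()},
        se={k: float(v) for k, v in res.bse.items()},
        converged=converged,
        n_used=int(len(y)),
        loglike=float(res.llf),
    )
    return fit, res


def _wald_row(fit: LogisticFit, term: str, reference: str = "") -> AssociationResult:
    beta, se = fit.coefficients[term], fit.se[term]
    if not math.isfinite(beta) or not math.isfinite(se) or se > 50:
        return AssociationResult(term, None, None, None, reference, note="unstable fit")
    z = beta / se
    return AssociationResult(
        term=term,
        or_estimate=math.exp(beta),
        ci95=(math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)),
        p=float(2 * stats.norm.sf(abs(z))),
        reference=reference,
    )


def logistic_codominant(
    dataset: Dataset, snp_id: str, covariates: tuple[str, ...] = ()
) -> tuple[list[AssociationResult], LogisticFit]:
    """Codominant logistic model for one SNP, optionally covariate adjusted.

    The SNP enters as two indicators (heterozygote and minor-allele
    homozygote) against the major-homozygote reference.  A genotype class
    with zero cases or zero controls separates the likelihood; that class
    is reported non-estimable and its individuals are dropped so the other
    terms stay finite.
    """
    j = dataset.snp_index(snp_id)
    geno = dataset.genotypes[:, j]
    keep = geno != MISSING
    ds = dataset.subset(keep)
    geno = ds.genotypes[:, j]
    ds.require_case_control()

    labels = {1: f"{snp_id}_het", 2: f"{snp_id}_hom"}
    separated: list[int] = []
    absent: list[int] = []
    for g in (1, 2):
        n_case = int(((geno == g) & (ds.phenotype == 1)).sum())
        n_ctrl = int(((geno == g) & (ds.phenotype == 0)).sum())
        if n_case + n_ctrl == 0:
            absent.append(g)
        elif n_case == 0 or n_ctrl == 0:
            separated.append(g)
    usable = ~np.isin(geno, separated)
    ds_fit = ds.subset(usable)
    geno_fit = ds_fit.genotypes[:, j]

    X, y = _design_matrix(ds_fit, covariates)
    for g in (1, 2):
        if g not in separated and g not in absent:
            X[labels[g]] = (geno_fit == g).astype(float)
    X.insert(0, "const", 1.0)
    fit, _ = _fit_logit(X, y)
    fit.dropped_terms = [labels[g] for g in separated + absent]

    results = []
    for g in (1, 2):
        term = labels[g]
        if g in separated:
            results.append(
                AssociationResult(term, None, None, None, reference=f"{snp_id}_ref",
                                  note="separation: genotype class has zero cases or controls")
            )
        elif g in absent:
            results.append(
                AssociationResult(term, None, None, None, reference=f"{snp_id}_ref",
                                  note="genotype class absent")
            )
        elif term in fit.coefficients:
            results.append(_wald_row(fit, term, reference=f"{snp_id}_ref"))
    return results, fit


def allele_or(dataset: Dataset, snp_id: str) -> AssociationResult:
    """Unadjusted allele-level odds ratio (minor vs major) with Wald CI."""
    from .descriptive import allele_counts, genotype_counts

    rows = []
    for group in ("case", "control"):
        ac = allele_counts(genotype_counts(dataset, snp_id, group))
        rows.append((ac.minor_count, ac.major_count))
    (a, b), (c, d) = rows
    if min(a, b, c, d) == 0:
        return AssociationResult(f"{snp_id}_allele", None, None, None, note="zero cell")
    or_ = a * d / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    _, p = fisher_exact_2x2([[a, b], [c, d]])
    return AssociationResult(
        term=f"{snp_id}_allele",
        or_estimate=or_,
        ci95=(or_ * math.exp(-Z95 * se), or_ * math.exp(Z95 * se)),
        p=p,
        reference="major allele",
    )


def logistic_interaction_check(
    dataset: Dataset,
    snp_ids: list[str],
    covariates: tuple[str, ...] = (),
    *,
    coding: str = "additive",
) -> tuple[AssociationResult, LogisticFit]:
    """Product-term interaction model over 2-3 SNPs.

    SNPs enter as single-column genotype codes -- ``additive`` allele
    counts (default) or ``dominant`` minor-allele-carrier indicators --
    with all products up to the full k-way term; the returned result is
    the Wald test of the highest-order product, the usual parametric
    counterpart to an MDR interaction model.
    """
    if not 2 <= len(snp_ids) <= 3:
        raise ValidationError("interaction check takes 2 or 3 SNPs")
    if len(set(snp_ids)) != len(snp_ids):
        raise ValidationError("duplicate SNP in interaction model (collinear)")
    if coding not in ("additive", "dominant"):
        raise ValueError("coding must be 'additive' or 'dominant'")
    idx = [dataset.snp_index(s) for s in snp_ids]
    keep = (dataset.genotypes[:, idx] != MISSING).all(axis=1)
    ds = dataset.subset(keep)
    ds.require_case_control()
    codes = {s: ds.genotypes[:, dataset.snp_index(s)].astype(float) for s in snp_ids}
    if coding == "dominant":
        codes = {s: (c >= 1).astype(float) for s, c in codes.items()}

    X, y = _design_matrix(ds, covariates)
    for s in snp_ids:
        X[s] = codes[s]
    for r in range(2, len(snp_ids) + 1):
        for comb in itertools.combinations(snp_ids, r):
            X[":".join(comb)] = np.prod([codes[s] for s in comb], axis=0)
    X.insert(0, "const", 1.0)
    top = ":".join(snp_ids)
    fit, _ = _fit_logit(X, y)
    return _wald_row(fit, top), fit


# ---------------------------------------------------------------------------
# simple tests


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Per-test significance threshold alpha/m (full precision)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return alpha / m_tests


def display_threshold(threshold: float, decimals: int = 3) -> float:
    """Presentation truncation of a threshold (0.05/9 renders as 0.005)."""
    scale = 10**decimals
    return math.floor(threshold * scale) / scale


def two_sample_summary_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Two-sided pooled-variance Student t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.pvalue)
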
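"""Genotype/allele frequency tables and Hardy-Weinberg equilibrium tests.

Counts are always over typed (non-missing) genotypes; frequencies are kept
at full precision and rounded only when rendering.  The HWE test is the
Pearson chi-square on the three genotype classes against the (p^2, 2pq, q^2)
expectations implied by the sample allele frequency, 1 degree of freedom and
no continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import MISSING, Dataset, ValidationError

GROUPS = ("case", "control")


@dataclass(frozen=True)
class GenotypeCounts:
    snp_id: str
    group: str
    n0: int  # major-allele homozygotes
    n1: int  # heterozygotes
    n2: int  # minor-allele homozygotes

    def __post_init__(self) -> None:
        if min(self.n0, self.n1, self.n2) < 0:
            raise ValidationError("negative genotype count")

    @property
    def n_typed(self) -> int:
        return self.n0 + self.n1 + self.n2

    @property
    def fractions(self) -> tuple[float, float, float]:
        n = self.n_typed
        if n == 0:
            return (float("nan"),) * 3
        return (self.n0 / n, self.n1 / n, self.n2 / n)


@dataclass(frozen=True)
class AlleleCounts:
    snp_id: str
    group: str
    minor_count: int
    total_alleles: int

    @property
    def major_count(self) -> int:
        return self.total_alleles - self.minor_count

    @property
    def minor_freq(self) -> float:
        if self.total_alleles == 0:
            return float("nan")
        return self.minor_count / self.total_alleles


@dataclass(frozen=True)
class HweResult:
    snp_id: str
    chi2: float
    p: float
    df: int = 1


def genotype_counts(dataset: Dataset, snp_id: str, group: str) -> GenotypeCounts:
    """Count 0/1/2 genotypes for one SNP within cases or controls."""
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    col = dataset.column(snp_id)
    sel = col[dataset.phenotype == (1 if group == "case" else 0)]
    sel = sel[sel != MISSING]
    return GenotypeCounts(
        snp_id=snp_id,
        group=group,
        n0=int((sel == 0).sum()),
        n1=int((sel == 1).sum()),
        n2=int((sel == 2).sum()),
    )


def allele_counts(gc: GenotypeCounts) -> AlleleCounts:
    """Derive minor-allele counts from genotype counts.

    Each heterozygote contributes one minor allele, each minor homozygote
    two; the frequency is undefined (NaN) when nothing was typed, but the
    (zero) counts are still returned.
    """
    return AlleleCounts(
        snp_id=gc.snp_id,
        group=gc.group,
        minor_count=gc.n1 + 2 * gc.n2,
        total_alleles=2 * gc.n_typed,
    )


def hwe_chisq(gc: GenotypeCounts) -> HweResult:
    """Pearson chi-square HWE test from genotype counts (1 df, no Yates).

    Monomorphic SNPs (minor or major allele absent) are in trivial
    equilibrium: chi2 = 0, p = 1.
    """
    n = gc.n_typed
    if n == 0:
        raise ValidationError(f"{gc.snp_id}: no typed genotypes")
    q = (gc.n1 + 2 * gc.n2) / (2 * n)
    if q in (0.0, 1.0):
        return HweResult(snp_id=gc.snp_id, chi2=0.0, p=1.0)
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n
    observed = np.array([gc.n0, gc.n1, gc.n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(snp_id=gc.snp_id, chi2=chi2, p=float(stats.chi2.sf(chi2, 1)))


def describe_table(dataset: Dataset, *, hwe_group: str = "control") -> pd.DataFrame:
    """Per-SNP descriptive table: genotype/allele counts by group plus HWE.

    One row per SNP; count columns are ``<group>_n0/n1/n2/minor/total`` and
    the HWE chi-square p is computed in ``hwe_group`` (controls by default).
    """
    rows = []
    for sid in dataset.snp_ids:
        row: dict[str, object] = {"snp_id": sid}
        for group in GROUPS:
            gc = genotype_counts(dataset, sid, group)
            ac = allele_counts(gc)
            row.update(
                {
                    f"{group}_n0": gc.n0,
                    f"{group}_n1": gc.n1,
                    f"{group}_n2": gc.n2,
                    f"{group}_minor": ac.minor_count,
                    f"{group}_total": ac.total_alleles,
                    f"{group}_maf_pct": round(100 * ac.minor_freq, 1)
                    if ac.total_alleles
                    else float("nan"),
                }
            )
        gc = genotype_counts(dataset, sid, hwe_group)
        if gc.n_typed:
            hwe = hwe_chisq(gc)
            row["hwe_p"] = hwe.p
        else:
            row["hwe_p"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
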
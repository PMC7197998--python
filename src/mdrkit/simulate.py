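"""Synthetic case-control genotype generator with plantable epistasis.

Emulates the statistical structure the analysis pipeline assumes: unlinked
biallelic loci in Hardy-Weinberg proportions at specified minor-allele
frequencies, case-control ascertainment to fixed group sizes via a
penetrance model, group-shifted covariates, and uniform genotype dropout.
Defaults reproduce the motivating study's conditions: 92 cases and 147
controls at nine SNPs with Mexican-population MAFs, cases older and heavier
than controls and predominantly female.

Penetrance models map multilocus genotypes to disease probability.  The
XOR (checkerboard) model is the canonical purely epistatic two-locus
pattern: risk is elevated exactly when one, and only one, of the two loci
is heterozygous, so at P(het) = 0.5 both loci show no marginal effect at
all while the pair is fully informative.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import MISSING, Dataset, SnpMeta, ValidationError
from .studydata import DEMOGRAPHICS, N_CASES, N_CONTROLS, SNP_PANEL

MAX_DRAWS = 10**7


@dataclass(frozen=True)
class PenetranceModel:
    """Map from multilocus genotype tuple to disease probability."""

    loci: tuple[str, ...]
    table: dict[tuple[int, ...], float]

    def __post_init__(self) -> None:
        for key, prob in self.table.items():
            if len(key) != len(self.loci):
                raise ValidationError("penetrance key length does not match loci")
            if not 0.0 <= prob <= 1.0:
                raise ValidationError(f"penetrance {prob} outside [0, 1]")

    def probabilities(self, genotypes: np.ndarray, snp_ids: list[str]) -> np.ndarray:
        idx = [snp_ids.index(s) for s in self.loci]
        sub = genotypes[:, idx]
        return np.array([self.table[tuple(int(g) for g in row)] for row in sub])


def xor_penetrance(
    loci, baseline: float = 0.05, effect: float = 0.4
) -> PenetranceModel:
    """Checkerboard two-locus penetrance: baseline + effect iff exactly one
    locus is heterozygous.

    When each locus has heterozygote probability 0.5 (MAF 0.5 under HWE)
    the marginal penetrance of every single-locus genotype equals
    baseline + effect/2 - a purely epistatic effect with zero main effects.
    """
    loci = tuple(loci)
    if len(loci) != 2:
        raise ValidationError("xor penetrance is a two-locus model")
    if baseline < 0 or effect < 0 or baseline + effect > 1:
        raise ValidationError("need 0 <= baseline, 0 <= effect, baseline + effect <= 1")
    table = {}
    for ga, gb in itertools.product((0, 1, 2), repeat=2):
        hit = (ga == 1) != (gb == 1)
        table[(ga, gb)] = baseline + (effect if hit else 0.0)
    return PenetranceModel(loci=loci, table=table)


def marginal_penetrance(
    locus: str, baseline: float = 0.05, or_per_allele: float = 1.5
) -> PenetranceModel:
    """Single-locus log-additive penetrance: odds multiply by
    ``or_per_allele`` per copy of the minor allele."""
    base_odds = baseline / (1 - baseline)
    table = {}
    for g in (0, 1, 2):
        odds = base_odds * or_per_allele**g
        table[(g,)] = odds / (1 + odds)
    return PenetranceModel(loci=(locus,), table=table)


@dataclass
class CovariateParams:
    """Group-specific covariate distributions (defaults from the study).

    Age and BMI are normal with group means/SDs; sex is Bernoulli(female);
    admixture proportions, when enabled, are Dirichlet over three ancestral
    components (Amerindian/European/African-like concentration).
    """

    age: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEMOGRAPHICS["age"])
    )
    bmi: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEMOGRAPHICS["bmi"])
    )
    female_prob: dict[str, float] = field(
        default_factory=lambda: {
            g: f / (f + m) for g, (f, m) in DEMOGRAPHICS["sex"].items()
        }
    )
    admixture_alpha: tuple[float, ...] | None = (5.0, 3.5, 0.8)


@dataclass
class SimConfig:
    """Full generator configuration; one global seed drives everything."""

    snp_metas: list[SnpMeta] = field(default_factory=lambda: list(SNP_PANEL))
    n_cases: int = N_CASES
    n_controls: int = N_CONTROLS
    penetrance: PenetranceModel | None = None
    covariates: CovariateParams | None = field(default_factory=CovariateParams)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValidationError("need positive case and control counts")
        if self.penetrance is not None:
            ids = [m.snp_id for m in self.snp_metas]
            for locus in self.penetrance.loci:
                if locus not in ids:
                    raise ValidationError(f"penetrance locus {locus!r} not in panel")


def simulate_genotypes(mafs, n: int, seed_or_rng) -> np.ndarray:
    """HWE genotypes at independent loci: P(0,1,2) = ((1-q)^2, 2q(1-q), q^2)."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    mafs = np.asarray(mafs, dtype=float)
    if ((mafs <= 0) | (mafs > 0.5)).any():
        raise ValidationError("every maf must lie in (0, 0.5]")
    u = rng.random((n, len(mafs)))
    hom_major = (1 - mafs) ** 2
    het = 2 * mafs * (1 - mafs)
    geno = np.full((n, len(mafs)), 2, dtype=np.int8)
    geno[u < hom_major + het] = 1
    geno[u < hom_major] = 0
    return geno


def _covariate_frame(
    params: CovariateParams, phenotype: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(phenotype)
    age = np.empty(n)
    bmi = np.empty(n)
    sex = np.empty(n, dtype=object)
    for group, is_case in (("case", 1), ("control", 0)):
        m = phenotype == is_case
        mu, sd = params.age[group]
        age[m] = rng.normal(mu, sd, m.sum())
        mu, sd = params.bmi[group]
        bmi[m] = rng.normal(mu, sd, m.sum())
        sex[m] = np.where(
            rng.random(m.sum()) < params.female_prob[group], "female", "male"
        )
    frame = pd.DataFrame({"age": age, "sex": sex, "bmi": bmi})
    if params.admixture_alpha is not None:
        adm = rng.dirichlet(params.admixture_alpha, size=n)
        for j in range(adm.shape[1]):
            frame[f"anc{j + 1}"] = adm[:, j]
    return frame


def simulate_case_control(config: SimConfig) -> Dataset:
    """Draw a case-control dataset under a penetrance model.

    Individuals are drawn from the HWE population model, disease status is
    Bernoulli(penetrance of their multilocus genotype), and sampling
    continues until the case and control quotas are both full (case-control
    ascertainment by rejection, bounded at 10^7 draws).  With no penetrance
    model the phenotype is independent of every genotype (the null
    generator).  Covariates are drawn per group; genotypes are then masked
    missing uniformly at ``missing_rate``.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rng_geno, rng_disease, rng_cov, rng_miss = (
        np.random.default_rng(s) for s in seeds
    )
    mafs = [m.maf for m in config.snp_metas]
    snp_ids = [m.snp_id for m in config.snp_metas]
    n_total = config.n_cases + config.n_controls

    if config.penetrance is None:
        genotypes = simulate_genotypes(mafs, n_total, rng_geno)
        phenotype = np.array(
            [1] * config.n_cases + [0] * config.n_controls, dtype=np.int8
        )
    else:
        probs = config.penetrance.table.values()
        if min(probs) >= 1.0 or max(probs) <= 0.0:
            raise ValidationError("penetrance makes one group unreachable")
        kept: list[np.ndarray] = []
        kept_ph: list[int] = []
        need = {1: config.n_cases, 0: config.n_controls}
        drawn = 0
        batch = max(1024, n_total)
        while (need[1] > 0 or need[0] > 0) and drawn < MAX_DRAWS:
            g = simulate_genotypes(mafs, batch, rng_geno)
            drawn += batch
            pen = config.penetrance.probabilities(g, snp_ids)
            disease = (rng_disease.random(batch) < pen).astype(np.int8)
            for row, d in zip(g, disease):
                if need[int(d)] > 0:
                    kept.append(row)
                    kept_ph.append(int(d))
                    need[int(d)] -= 1
        if need[1] > 0 or need[0] > 0:
            raise ValidationError(
                "case/control quota not reached within the draw bound; "
                "penetrance model makes one group effectively unreachable"
            )
        order = np.argsort(kept_ph, kind="stable")[::-1]  # cases first
        genotypes = np.stack(kept)[order]
        phenotype = np.asarray(kept_ph, dtype=np.int8)[order]

    covariates = (
        _covariate_frame(config.covariates, phenotype, rng_cov)
        if config.covariates is not None
        else None
    )
    if config.missing_rate > 0:
        mask = rng_miss.random(genotypes.shape) < config.missing_rate
        genotypes = genotypes.copy()
        genotypes[mask] = MISSING

    individuals = [f"sim{i}" for i in range(n_total)]
    return Dataset(
        individuals=individuals,
        genotypes=genotypes,
        phenotype=phenotype,
        covariates=covariates,
        snp_meta=list(config.snp_metas),
    )
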
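"""Dataset model and genotype file I/O.

The central container is :class:`Dataset`: a rectangular matrix of SNP
genotypes coded as minor-allele counts (0/1/2, ``-1`` for missing), a binary
case/control phenotype, optional per-individual covariates, and per-SNP
metadata.  Three flat-file dialects are supported:

``csv-coded``
    Comma-separated, header row, genotypes already coded 0/1/2, phenotype
    column named ``Class`` (configurable), missing genotype ``NA``.
``allele-pairs``
    Like ``csv-coded`` but genotype cells hold two-letter allele pairs
    ("CT"); coding is derived from the control-group minor allele.
``mdr-flatfile``
    Tab-delimited attribute file: SNP columns then a final ``Class`` column
    with 0 = control, 1 = case; missing genotype ``-9``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # in-memory missing-genotype code

#: Missing-genotype sentinels by dialect, overridable per call.
MISSING_SENTINELS = {"csv-coded": "NA", "allele-pairs": "NA", "mdr-flatfile": "-9"}

DIALECTS = ("csv-coded", "allele-pairs", "mdr-flatfile")


class ParseError(ValueError):
    """Malformed input file (wrong row length, bad token)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a dataset invariant."""


@dataclass(frozen=True)
class SnpMeta:
    """Per-SNP metadata: identifiers, alleles, and minor-allele frequency.

    ``maf`` is the population minor-allele frequency after minor-allele
    orientation, so it must lie in [0, 0.5].  Positions are opaque
    ``"chr:pos"`` strings (1-based); no coordinate arithmetic is done.
    """

    snp_id: str
    gene: str = ""
    chrom_pos: str = ""
    ref_allele: str = "N"
    minor_allele: str = "N"
    maf: float = math.nan

    def __post_init__(self) -> None:
        if self.ref_allele == self.minor_allele:
            raise ValidationError(
                f"{self.snp_id}: ref and minor allele are both {self.ref_allele!r}"
            )
        if not math.isnan(self.maf) and not 0.0 <= self.maf <= 0.5:
            raise ValidationError(f"{self.snp_id}: maf {self.maf} outside [0, 0.5]")

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


@dataclass
class Dataset:
    """Case-control genotype dataset.

    Attributes
    ----------
    individuals
        Ordered opaque IDs, one per row.
    genotypes
        ``(n, p)`` int8 array; entries 0/1/2 count the minor allele,
        ``MISSING`` (-1) marks an untyped genotype.
    phenotype
        ``(n,)`` int8 array, 1 = case, 0 = control.
    covariates
        Optional DataFrame aligned to rows (e.g. age, sex, bmi, admixture
        proportions).  ``sex`` is stored as strings ``"female"``/``"male"``.
    snp_meta
        Per-column :class:`SnpMeta`, aligned to genotype columns.
    """

    individuals: list[str]
    genotypes: np.ndarray
    phenotype: np.ndarray
    covariates: pd.DataFrame | None = None
    snp_meta: list[SnpMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValidationError("genotypes must be a 2-D matrix")
        n, p = self.genotypes.shape
        if not self.snp_meta:
            self.snp_meta = [
                SnpMeta(snp_id=f"snp{j}", ref_allele="A", minor_allele="B")
                for j in range(p)
            ]
        if len(self.individuals) != n or len(self.phenotype) != n:
            raise ValidationError("row count mismatch between matrix/phenotype/ids")
        if len(self.snp_meta) != p:
            raise ValidationError("snp_meta length does not match genotype columns")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValidationError("covariate row count mismatch")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid genotype code {self.genotypes[i, j]} at row {i}, column {j}"
            )
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValidationError("phenotype must be binary 0/1")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [m.snp_id for m in self.snp_meta]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP {snp_id!r}") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.genotypes[:, self.snp_index(snp_id)]

    def require_case_control(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValidationError("analysis requires at least one case and one control")

    def subset(self, mask: np.ndarray) -> "Dataset":
        mask = np.asarray(mask, dtype=bool)
        cov = self.covariates.loc[mask].reset_index(drop=True) if self.covariates is not None else None
        return Dataset(
            individuals=[i for i, keep in zip(self.individuals, mask) if keep],
            genotypes=self.genotypes[mask],
            phenotype=self.phenotype[mask],
            covariates=cov,
            snp_meta=list(self.snp_meta),
        )

    def equals(self, other: "Dataset") -> bool:
        return (
            self.individuals == other.individuals
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
            and self.snp_ids == other.snp_ids
        )


# ---------------------------------------------------------------------------
# reading


def _control_minor_flip(genotypes: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """Columns whose coded allele is the control-group *major* allele.

    Returns a boolean per-column mask: True where the coded-allele frequency
    among typed controls strictly exceeds 0.5, i.e. the 0<->2 coding must be
    flipped so codes count the control minor allele.
    """
    ctrl = genotypes[phenotype == 0]
    p = genotypes.shape[1]
    flip = np.zeros(p, dtype=bool)
    for j in range(p):
        col = ctrl[:, j]
        col = col[col != MISSING]
        if col.size:
            flip[j] = col.mean() / 2.0 > 0.5
    return flip


def _parse_allele_pair(token: str, line_no: int) -> tuple[str, str] | None:
    if len(token) != 2 or not token.isalpha():
        raise ParseError(f"line {line_no}: unknown genotype symbol {token!r}")
    return token[0].upper(), token[1].upper()


def read_genotype_table(
    path: str | Path,
    dialect: str = "csv-coded",
    *,
    phenotype_col: str | None = None,
    covariate_cols: Sequence[str] = (),
    id_col: str = "id",
    missing: str | None = None,
    orient_to_controls: bool = True,
    snp_meta: Sequence[SnpMeta] | None = None,
) -> Dataset:
    """Read a genotype table in one of the supported dialects.

    Orientation: unless ``snp_meta`` fixes the alleles or
    ``orient_to_controls`` is False, genotype codes are normalized so they
    count the minor allele as estimated in the control group (a column is
    flipped 0<->2 only when its coded-allele control frequency strictly
    exceeds 0.5; an exact 50/50 tie keeps the coding as given, and for
    allele pairs the tie is broken alphabetically).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    sentinel = missing if missing is not None else MISSING_SENTINELS[dialect]
    sep = "\t" if dialect == "mdr-flatfile" else ","
    pheno_name = phenotype_col or "Class"

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split(sep)
    ncol = len(header)
    if pheno_name not in header:
        raise ValidationError(f"{path}: phenotype column {pheno_name!r} not in header")
    rows = []
    for line_no, line in enumerate(lines[1:], start=2):
        cells = line.split(sep)
        if len(cells) != ncol:
            raise ParseError(
                f"{path}: line {line_no}: expected {ncol} fields, found {len(cells)}"
            )
        rows.append(cells)
    frame = pd.DataFrame(rows, columns=header, dtype=str)

    pheno_raw = frame.pop(pheno_name)
    uniq = sorted(set(pheno_raw))
    mapping: dict[str, int]
    if set(uniq) <= {"0", "1"}:
        mapping = {"0": 0, "1": 1}
    elif {u.lower() for u in uniq} <= {"case", "control"}:
        mapping = {u: int(u.lower() == "case") for u in uniq}
    else:
        raise ValidationError(f"{path}: phenotype not binary (values {uniq})")
    phenotype = pheno_raw.map(mapping).to_numpy(dtype=np.int8)

    ids: list[str]
    if id_col in frame.columns:
        ids = frame.pop(id_col).tolist()
    else:
        ids = [f"ind{i}" for i in range(len(frame))]
    covariates = None
    cov_cols = [c for c in covariate_cols if c in frame.columns]
    if cov_cols:
        covariates = frame[cov_cols].copy().reset_index(drop=True)
        for c in cov_cols:
            try:
                covariates[c] = pd.to_numeric(covariates[c])
            except (ValueError, TypeError):
                pass  # non-numeric covariate (e.g. sex) stays as strings
        frame = frame.drop(columns=cov_cols)

    snp_ids = list(frame.columns)
    n, p = len(frame), len(snp_ids)
    geno = np.full((n, p), MISSING, dtype=np.int8)

    if dialect == "allele-pairs":
        metas = []
        for j, sid in enumerate(snp_ids):
            pairs: list[tuple[str, str] | None] = []
            for i, token in enumerate(frame[sid]):
                if token == sentinel:
                    pairs.append(None)
                else:
                    pairs.append(_parse_allele_pair(token, i + 2))
            # control-group allele counts decide the minor allele; an allele
            # seen only in cases counts 0 in controls and is therefore minor
            seen: set[str] = {a for pr in pairs if pr is not None for a in pr}
            counts: dict[str, int] = {a: 0 for a in seen}
            for pr, ph in zip(pairs, phenotype):
                if pr is not None and ph == 0:
                    for a in pr:
                        counts[a] += 1
            if sum(counts.values()) == 0:  # no typed controls: use everyone
                for pr in pairs:
                    if pr is not None:
                        for a in pr:
                            counts[a] += 1
            alleles = sorted(counts)
            if len(alleles) > 2:
                raise ValidationError(f"{path}: {sid}: more than two alleles {alleles}")
            if len(alleles) == 1:
                minor, major = "N", alleles[0]
            else:
                a, b = alleles  # alphabetical; ties at 0.5 pick `a` as minor
                minor, major = (a, b) if counts[a] <= counts[b] else (b, a)
            for i, pr in enumerate(pairs):
                if pr is not None:
                    geno[i, j] = sum(al == minor for al in pr)
            total = sum(counts.values())
            maf = counts.get(minor, 0) / total if total else math.nan
            metas.append(
                SnpMeta(snp_id=sid, ref_allele=major, minor_allele=minor,
                        maf=min(maf, 0.5) if not math.isnan(maf) else maf)
            )
        meta_list = list(snp_meta) if snp_meta is not None else metas
    else:
        valid_tokens = {"0": 0, "1": 1, "2": 2}
        for j, sid in enumerate(snp_ids):
            for i, token in enumerate(frame[sid]):
                if token == sentinel:
                    continue
                if token not in valid_tokens:
                    raise ValidationError(
                        f"{path}: line {i + 2}: unknown genotype symbol {token!r} at {sid}"
                    )
                geno[i, j] = valid_tokens[token]
        if snp_meta is not None:
            meta_list = list(snp_meta)
        else:
            meta_list = [SnpMeta(snp_id=s, ref_allele="A", minor_allele="B") for s in snp_ids]
        if orient_to_controls and snp_meta is None:
            flip = _control_minor_flip(geno, phenotype)
            for j in np.nonzero(flip)[0]:
                col = geno[:, j]
                col[col != MISSING] = 2 - col[col != MISSING]
                m = meta_list[j]
                meta_list[j] = replace(m, ref_allele=m.minor_allele, minor_allele=m.ref_allele)

    if snp_meta is not None and list(snp_ids) != [m.snp_id for m in meta_list]:
        raise ValidationError(f"{path}: header SNPs do not match supplied metadata")
    return Dataset(
        individuals=ids,
        genotypes=geno,
        phenotype=phenotype,
        covariates=covariates,
        snp_meta=meta_list,
    )


# ---------------------------------------------------------------------------
# writing


def write_mdr_flatfile(dataset: Dataset, path: str | Path, *, missing: str = "-9") -> None:
    """Write the tab-delimited attribute/Class dialect.

    One header row of SNP ids followed by ``Class``; codes 0/1/2, the given
    missing sentinel, phenotype 1 = case / 0 = control.  Round-trips through
    :func:`read_genotype_table` bit-identically (IDs are positional in this
    dialect and regenerate as ``ind<i>``).
    """
    _write_table(dataset, Path(path), sep="\t", missing=missing, with_ids=False)


def write_genotype_table(
    dataset: Dataset,
    path: str | Path,
    dialect: str = "csv-coded",
    *,
    missing: str | None = None,
) -> None:
    """Write ``dataset`` in any supported dialect."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    sentinel = missing if missing is not None else MISSING_SENTINELS[dialect]
    if dialect == "mdr-flatfile":
        write_mdr_flatfile(dataset, path, missing=sentinel)
    elif dialect == "csv-coded":
        _write_table(dataset, Path(path), sep=",", missing=sentinel, with_ids=True)
    else:  # allele-pairs
        _write_allele_pairs(dataset, Path(path), missing=sentinel)


def _write_table(ds: Dataset, path: Path, *, sep: str, missing: str, with_ids: bool) -> None:
    header = (["id"] if with_ids else []) + ds.snp_ids + ["Class"]
    code = {0: "0", 1: "1", 2: "2", MISSING: missing}
    with open(path, "w") as fh:
        fh.write(sep.join(header) + "\n")
        for i in range(ds.n):
            cells = [code[int(g)] for g in ds.genotypes[i]]
            row = ([ds.individuals[i]] if with_ids else []) + cells + [str(int(ds.phenotype[i]))]
            fh.write(sep.join(row) + "\n")


def _write_allele_pairs(ds: Dataset, path: Path, *, missing: str) -> None:
    for m in ds.snp_meta:
        if "N" in (m.ref_allele, m.minor_allele):
            raise ValidationError(f"{m.snp_id}: allele-pairs output needs real alleles")
    with open(path, "w") as fh:
        fh.write(",".join(["id"] + ds.snp_ids + ["Class"]) + "\n")
        for i in range(ds.n):
            cells = []
            for j, m in enumerate(ds.snp_meta):
                g = int(ds.genotypes[i, j])
                if g == MISSING:
                    cells.append(missing)
                else:
                    cells.append(m.ref_allele * (2 - g) + m.minor_allele * g)
            fh.write(",".join([ds.individuals[i]] + cells + [str(int(ds.phenotype[i]))]) + "\n")


# ---------------------------------------------------------------------------
# stratification


def stratify(
    dataset: Dataset, rule: str, *, age_cutoff: float = 50.0
) -> list[tuple[str, Dataset]]:
    """Partition a dataset ``by-sex`` or ``by-age-cutoff``.

    ``by-age-cutoff`` splits at ``age_cutoff`` years into ``<=cutoff`` and
    ``>cutoff`` strata; empty strata are dropped, so the returned datasets
    always partition the input exactly.
    """
    if dataset.covariates is None:
        raise ValidationError("stratification requires covariates")
    cov = dataset.covariates
    if rule == "by-sex":
        if "sex" not in cov.columns:
            raise ValidationError("missing covariate 'sex'")
        sex = cov["sex"].astype(str).str.lower().to_numpy()
        parts = [("female", sex == "female"), ("male", sex != "female")]
    elif rule == "by-age-cutoff":
        if "age" not in cov.columns:
            raise ValidationError("missing covariate 'age'")
        age = pd.to_numeric(cov["age"]).to_numpy()
        parts = [
            (f"<={age_cutoff:g}", age <= age_cutoff),
            (f">{age_cutoff:g}", age > age_cutoff),
        ]
    else:
        raise ValueError(f"unknown stratification rule {rule!r}")
    return [(label, dataset.subset(mask)) for label, mask in parts if mask.any()]


def export_snp_meta(metas: Iterable[SnpMeta]) -> str:
    """JSON export of a SNP metadata list."""
    return json.dumps([m.__dict__ for m in metas], indent=2)
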
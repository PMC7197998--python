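"""Published summary data from the motivating knee-osteoarthritis study.

A case-control study of 92 knee-OA patients and 147 healthy controls from
Mexico City genotyped nine biallelic SNPs in eight extracellular-matrix
genes.  Individual-level genotypes were never deposited; what the study
published are summary tables: the SNP panel with Mexican-population minor
allele frequencies, demographic summaries, and per-group genotype counts.
Those printed numbers are stored here verbatim and drive worked examples,
fixtures, and the defaults of :mod:`mdrkit.simulate`.

Note the per-SNP typed totals vary (genotyping dropouts), so padding with
missing genotypes is required when expanding counts to individuals.
"""

from __future__ import annotations

import numpy as np

from .io_model import MISSING, Dataset, SnpMeta

N_CASES = 92
N_CONTROLS = 147

#: The nine-SNP panel: dbSNP id, gene, position, major/minor allele, MAF.
SNP_PANEL: list[SnpMeta] = [
    SnpMeta("rs699947", "VEGFA", "6:43736389", "C", "A", 0.42),
    SnpMeta("rs3025039", "VEGFA", "6:43752536", "C", "T", 0.30),
    SnpMeta("rs11292", "HIF1AN", "10:102313607", "A", "G", 0.13),
    SnpMeta("rs1800255", "COL3A1", "2:189864080", "G", "A", 0.23),
    SnpMeta("rs4444903", "EGF", "4:110834110", "G", "A", 0.38),
    SnpMeta("rs679620", "MMP3", "11:102713620", "C", "T", 0.31),
    SnpMeta("rs2252070", "MMP13", "11:102826539", "T", "C", 0.29),
    SnpMeta("rs2297518", "NOS2", "17:26096597", "G", "A", 0.13),
    SnpMeta("rs2070744", "NOS3", "7:150690079", "T", "C", 0.27),
]

#: Published genotype counts (major hom, het, minor hom) by group.
GENOTYPE_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "rs3025039": {"case": (31, 37, 12), "control": (57, 44, 18)},
    "rs699947": {"case": (39, 34, 8), "control": (57, 41, 16)},
    "rs11292": {"case": (61, 0, 14), "control": (51, 25, 11)},
    "rs1800255": {"case": (35, 42, 7), "control": (30, 39, 5)},
    "rs4444903": {"case": (23, 41, 18), "control": (31, 56, 24)},
    "rs679620": {"case": (39, 30, 11), "control": (41, 27, 11)},
    "rs2252070": {"case": (38, 41, 6), "control": (46, 41, 7)},
    "rs2297518": {"case": (65, 14, 1), "control": (66, 15, 1)},
    "rs2070744": {"case": (58, 23, 6), "control": (53, 24, 7)},
}

#: Published "HWE in controls" p-values, for cross-checking.
HWE_CONTROL_P: dict[str, float] = {
    "rs3025039": 0.061,
    "rs699947": 0.063,
    "rs11292": 0.011,
    "rs1800255": 0.102,
    "rs4444903": 0.890,
    "rs679620": 0.073,
    "rs2252070": 0.602,
    "rs2297518": 0.887,
    "rs2070744": 0.092,
}

#: Demographics: mean, SD by group for continuous traits; counts for sex.
DEMOGRAPHICS = {
    "age": {"case": (47.2, 12.4), "control": (40.9, 12.0)},
    "bmi": {"case": (29.0, 4.19), "control": (24.8, 4.38)},
    # (female, male) counts
    "sex": {"case": (80, 12), "control": (105, 42)},
}


def panel_mafs() -> list[float]:
    return [m.maf for m in SNP_PANEL]


def counts_to_dataset(
    counts: dict[str, dict[str, tuple[int, int, int]]] | None = None,
    *,
    n_cases: int = N_CASES,
    n_controls: int = N_CONTROLS,
    seed: int | None = None,
) -> Dataset:
    """Expand per-SNP genotype counts into an individual-level dataset.

    Only the per-SNP marginal distributions are published, so columns are
    filled independently: within each group a column gets ``n0`` zeros,
    ``n1`` ones, ``n2`` twos and missing codes up to the group size, then an
    optional seeded within-group shuffle.  Marginal counts (and hence allele
    frequencies and HWE) match the input exactly; the joint genotype
    distribution carries no interaction signal.
    """
    counts = counts if counts is not None else GENOTYPE_COUNTS
    snp_ids = list(counts)
    metas = {m.snp_id: m for m in SNP_PANEL}
    rng = np.random.default_rng(seed) if seed is not None else None
    geno_parts = []
    for group, size in (("case", n_cases), ("control", n_controls)):
        block = np.full((size, len(snp_ids)), MISSING, dtype=np.int8)
        for j, sid in enumerate(snp_ids):
            n0, n1, n2 = counts[sid][group]
            if n0 + n1 + n2 > size:
                raise ValueError(f"{sid}: {group} counts exceed group size {size}")
            col = np.array([0] * n0 + [1] * n1 + [2] * n2 + [MISSING] * (size - n0 - n1 - n2),
                           dtype=np.int8)
            if rng is not None:
                rng.shuffle(col)
            block[:, j] = col
        geno_parts.append(block)
    genotypes = np.vstack(geno_parts)
    phenotype = np.array([1] * n_cases + [0] * n_controls, dtype=np.int8)
    meta_list = [
        metas.get(sid, SnpMeta(snp_id=sid, ref_allele="A", minor_allele="B"))
        for sid in snp_ids
    ]
    individuals = [f"case{i}" for i in range(n_cases)] + [f"ctrl{i}" for i in range(n_controls)]
    return Dataset(
        individuals=individuals,
        genotypes=genotypes,
        phenotype=phenotype,
        snp_meta=meta_list,
    )
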
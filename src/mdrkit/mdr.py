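"""Multifactor dimensionality reduction (MDR).

MDR collapses a k-locus genotype table into a one-dimensional high/low-risk
attribute: a multilocus cell is high-risk when the ratio of its within-cell
case percentage to control percentage meets or exceeds a threshold (1.0).
Candidate locus combinations are scored by stratified 10-fold
cross-validated balanced accuracy, per-size winners are ranked by mean
training balanced accuracy, cross-validation consistency (CVC) counts the
folds in which the overall winner is also the fold winner, and significance
comes from a phenotype-permutation test.

The engine is vectorized: each combination becomes a one-hot cell-membership
matrix so that case counts per cell for *many* phenotype vectors at once are
a single matrix product.  This makes the permutation test (hundreds of
relabelings x all combinations x all folds) cheap, and an independent naive
implementation can be checked against it cell-for-cell in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .io_model import MISSING, Dataset, ValidationError

UNKNOWN_POLICIES = ("low", "high", "exclude")


@dataclass
class CellTable:
    """Case/control counts per multilocus genotype cell for one combination."""

    combo: tuple[str, ...]
    cells: dict[tuple[int, ...], tuple[int, int]]  # cell -> (cases, controls)
    n_cases: int
    n_controls: int


@dataclass
class RiskLabeling:
    """Per-cell {'high','low','unknown'} labels learned from a cell table."""

    combo: tuple[str, ...]
    labels: dict[tuple[int, ...], str]
    threshold_ratio: float = 1.0


@dataclass
class MDRModel:
    """Best model of one size: combination, per-fold accuracies, CVC."""

    combo: tuple[str, ...]
    fold_train_ba: np.ndarray
    fold_test_ba: np.ndarray
    cvc: int
    n_folds: int
    perm_p: float | None = None
    cell_labels: dict[tuple[int, ...], str] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.combo)

    @property
    def train_ba(self) -> float:
        return float(np.mean(self.fold_train_ba))

    @property
    def test_ba(self) -> float:
        return float(np.mean(self.fold_test_ba))


# ---------------------------------------------------------------------------
# direct (single-labeling) operations


def _combo_columns(dataset: Dataset, combo: tuple[str, ...]) -> np.ndarray:
    if len(set(combo)) != len(combo):
        raise ValidationError(f"duplicate SNP in combination {combo}")
    idx = [dataset.snp_index(s) for s in combo]
    return dataset.genotypes[:, idx]


def build_cell_table(dataset: Dataset, combo) -> CellTable:
    """Cross-tabulate case/control counts over the 3^k multilocus cells.

    Individuals missing a genotype at *any* SNP of the combination are
    excluded (per-combination deletion, which maximizes data use and mirrors
    per-SNP typed totals differing across a study).
    """
    combo = tuple(combo)
    if not 1 <= len(combo) <= 5:
        raise ValidationError("combination size must be between 1 and 5")
    g = _combo_columns(dataset, combo)
    valid = (g != MISSING).all(axis=1)
    cells: dict[tuple[int, ...], tuple[int, int]] = {}
    for row, ph in zip(g[valid], dataset.phenotype[valid]):
        key = tuple(int(x) for x in row)
        cases, ctrls = cells.get(key, (0, 0))
        cells[key] = (cases + int(ph == 1), ctrls + int(ph == 0))
    return CellTable(
        combo=combo,
        cells=cells,
        n_cases=int(dataset.phenotype[valid].sum()),
        n_controls=int((dataset.phenotype[valid] == 0).sum()),
    )


def label_cells(ct: CellTable, threshold_ratio: float = 1.0) -> RiskLabeling:
    """Label cells high/low-risk by the case%:control% ratio rule.

    A cell is high-risk iff (cases/n_cases) / (controls/n_controls) meets or
    exceeds the threshold (computed by cross-multiplication, so a cell with
    controls = 0 but cases > 0 is high-risk); cells empty in the table are
    'unknown'.
    """
    if ct.n_cases == 0 or ct.n_controls == 0:
        raise ValidationError("labeling requires both cases and controls")
    labels = {}
    for key, (cases, ctrls) in ct.cells.items():
        if cases + ctrls == 0:
            labels[key] = "unknown"
        elif cases * ct.n_controls >= threshold_ratio * ctrls * ct.n_cases:
            labels[key] = "high"
        else:
            labels[key] = "low"
    return RiskLabeling(combo=ct.combo, labels=labels, threshold_ratio=threshold_ratio)


def balanced_accuracy(truth, predicted_high) -> float:
    """(sensitivity + specificity) / 2, 'high' predicting 'case'."""
    truth = np.asarray(truth, dtype=bool)
    pred = np.asarray(predicted_high, dtype=bool)
    if truth.shape != pred.shape:
        raise ValidationError("truth and prediction lengths differ")
    n_case = int(truth.sum())
    n_ctrl = int((~truth).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValidationError("balanced accuracy needs both classes in truth")
    sens = float((pred & truth).sum()) / n_case
    spec = float((~pred & ~truth).sum()) / n_ctrl
    return (sens + spec) / 2.0


def assign_folds(phenotype: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Phenotype-stratified fold ids via a seeded shuffle.

    Cases and controls are shuffled separately and dealt round-robin so
    every fold keeps the study's case:control ratio (up to rounding).
    """
    phenotype = np.asarray(phenotype)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(phenotype), dtype=np.int32)
    for cls in (0, 1):
        idx = np.nonzero(phenotype == cls)[0]
        if len(idx) < n_folds:
            raise ValidationError(
                f"too few individuals of class {cls} for {n_folds} stratified folds"
            )
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


# ---------------------------------------------------------------------------
# vectorized evaluation engine


def _evaluate_combos(
    genotypes: np.ndarray,
    pheno_mat: np.ndarray,
    combos: list[tuple[int, ...]],
    fold_ids: np.ndarray,
    n_folds: int,
    threshold: float = 1.0,
    unknown: str = "low",
) -> tuple[np.ndarray, np.ndarray]:
    """Train/test balanced accuracies for every (combo, phenotype, fold).

    ``pheno_mat`` is (B, n): B phenotype vectors evaluated simultaneously
    (B = 1 for an ordinary run, B = n_perm for a permutation test).
    Returns two arrays shaped (n_combos, B, n_folds).  A part with no valid
    cases or controls contributes the neutral 0.5 for the undefined
    sensitivity/specificity component.
    """
    if unknown not in UNKNOWN_POLICIES:
        raise ValueError(f"unknown-cell policy must be one of {UNKNOWN_POLICIES}")
    Y = np.ascontiguousarray(pheno_mat.T, dtype=np.float64)  # (n, B)
    n, B = Y.shape
    C = len(combos)
    train_ba = np.empty((C, B, n_folds))
    test_ba = np.empty((C, B, n_folds))
    part_masks = [(fold_ids != f, fold_ids == f) for f in range(n_folds)]

    for ci, cols in enumerate(combos):
        k = len(cols)
        g = genotypes[:, list(cols)]
        valid = (g != MISSING).all(axis=1)
        cell = np.zeros(n, dtype=np.int64)
        for j in range(k):
            cell = cell * 3 + np.where(valid, g[:, j], 0)
        n_cells = 3**k
        onehot = np.zeros((n_cells, n))
        onehot[cell[valid], np.nonzero(valid)[0]] = 1.0

        for f, (tr, te) in enumerate(part_masks):
            U = onehot[:, tr]
            tot = U.sum(axis=1)  # valid individuals per cell (train)
            case_cells = U @ Y[tr]  # (cells, B)
            v = valid[tr].astype(np.float64)
            ncase_tr = v @ Y[tr]  # (B,)
            nctrl_tr = v.sum() - ncase_tr
            ctrl_cells = tot[:, None] - case_cells
            high = case_cells * nctrl_tr[None, :] >= threshold * ctrl_cells * ncase_tr[None, :]
            empty = tot == 0
            known_cell = np.ones(n_cells, dtype=bool)
            if unknown == "low":
                high[empty] = False
            elif unknown == "high":
                high[empty] = True
            else:
                known_cell = ~empty

            for out, part in ((train_ba, tr), (test_ba, te)):
                rows = np.nonzero(part & valid)[0]
                if rows.size == 0:
                    out[ci, :, f] = 0.5
                    continue
                pred = high[cell[rows]]  # (nr, B)
                kn = known_cell[cell[rows]]  # (nr,)
                yp = Y[rows] * kn[:, None]
                tp = (pred * yp).sum(axis=0)
                ncase = yp.sum(axis=0)
                nctrl = kn.sum() - ncase
                tn = ((~pred) * (kn[:, None] - yp)).sum(axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    sens = np.where(ncase > 0, tp / np.maximum(ncase, 1), 0.5)
                    spec = np.where(nctrl > 0, tn / np.maximum(nctrl, 1), 0.5)
                out[ci, :, f] = (sens + spec) / 2.0
    return train_ba, test_ba


def _ordered_combos(dataset: Dataset, k: int) -> tuple[list[tuple[int, ...]], list[tuple[str, ...]]]:
    """All size-k column combinations in lexicographic SNP-id order."""
    order = sorted(range(dataset.n_snps), key=lambda j: dataset.snp_ids[j])
    col_combos = [tuple(c) for c in itertools.combinations(order, k)]
    id_combos = [tuple(dataset.snp_ids[j] for j in c) for c in col_combos]
    return col_combos, id_combos


def cross_validate(
    dataset: Dataset,
    combo,
    folds: int = 10,
    seed: int = 0,
    *,
    threshold: float = 1.0,
    unknown: str = "low",
    fold_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold training and testing balanced accuracies for one combination."""
    combo = tuple(combo)
    dataset.require_case_control()
    if fold_ids is None:
        fold_ids = assign_folds(dataset.phenotype, folds, seed)
    cols = tuple(dataset.snp_index(s) for s in combo)
    if len(set(cols)) != len(cols):
        raise ValidationError(f"duplicate SNP in combination {combo}")
    Y = dataset.phenotype[None, :].astype(np.float64)
    tr, te = _evaluate_combos(
        dataset.genotypes, Y, [cols], fold_ids, folds, threshold, unknown
    )
    return tr[0, 0], te[0, 0]


def search_best_models(
    dataset: Dataset,
    k_min: int = 1,
    k_max: int = 3,
    folds: int = 10,
    seed: int = 0,
    *,
    threshold: float = 1.0,
    unknown: str = "low",
) -> list[MDRModel]:
    """Exhaustive per-size search: one best MDRModel per model size.

    For each size k every combination is cross-validated on a shared fold
    partition; the winner maximizes mean training balanced accuracy (ties
    broken toward the lexicographically first SNP-id combination) and its
    CVC counts the folds whose fold-winner coincides with it.
    """
    dataset.require_case_control()
    if k_max > dataset.n_snps:
        raise ValidationError("k_max exceeds the number of SNPs")
    fold_ids = assign_folds(dataset.phenotype, folds, seed)
    Y = dataset.phenotype[None, :].astype(np.float64)
    models = []
    for k in range(k_min, k_max + 1):
        col_combos, id_combos = _ordered_combos(dataset, k)
        tr, te = _evaluate_combos(
            dataset.genotypes, Y, col_combos, fold_ids, folds, threshold, unknown
        )
        mean_tr = tr[:, 0, :].mean(axis=1)
        best = int(np.argmax(mean_tr))
        fold_best = np.argmax(tr[:, 0, :], axis=0)
        cvc = int((fold_best == best).sum())
        labeling = label_cells(build_cell_table(dataset, id_combos[best]), threshold)
        models.append(
            MDRModel(
                combo=id_combos[best],
                fold_train_ba=tr[best, 0],
                fold_test_ba=te[best, 0],
                cvc=cvc,
                n_folds=folds,
                cell_labels=labeling.labels,
            )
        )
    return models


def select_final_model(models: list[MDRModel]) -> MDRModel:
    """Pick the final model: max testing BA, then max CVC, then smallest k."""
    if not models:
        raise ValidationError("no candidate models")
    return max(models, key=lambda m: (m.test_ba, m.cvc, -m.k))


def permutation_test(
    dataset: Dataset,
    k: int,
    n_perm: int = 999,
    seed: int = 0,
    *,
    folds: int = 10,
    threshold: float = 1.0,
    unknown: str = "low",
    batch: int = 250,
) -> float:
    """Phenotype-permutation p-value for the size-k model's testing BA.

    The case/control labels are permuted ``n_perm`` times; for each
    relabeling the full size-k search is repeated on the same fold
    partition (exchangeable under the null) and the winner's mean testing
    BA recorded.  p = (#{permuted >= observed} + 1) / (n_perm + 1).
    """
    if n_perm < 19:
        raise ValidationError("n_perm must be at least 19")
    dataset.require_case_control()
    rng = np.random.default_rng(seed)
    fold_ids = assign_folds(dataset.phenotype, folds, int(rng.integers(2**31)))
    col_combos, _ = _ordered_combos(dataset, k)

    def best_test_ba(pheno_mat: np.ndarray) -> np.ndarray:
        tr, te = _evaluate_combos(
            dataset.genotypes, pheno_mat, col_combos, fold_ids, folds, threshold, unknown
        )
        mean_tr = tr.mean(axis=2)  # (C, B)
        best = np.argmax(mean_tr, axis=0)  # (B,)
        return te.mean(axis=2)[best, np.arange(pheno_mat.shape[0])]

    observed = float(best_test_ba(dataset.phenotype[None, :].astype(np.float64))[0])
    exceed = 0
    done = 0
    base = dataset.phenotype.astype(np.float64)
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = np.stack([rng.permutation(base) for _ in range(b)])
        stats_ = best_test_ba(perms)
        exceed += int((stats_ >= observed - 1e-12).sum())
        done += b
    return (exceed + 1) / (n_perm + 1)


def run_mdr(
    dataset: Dataset,
    k_min: int = 1,
    k_max: int = 3,
    folds: int = 10,
    seed: int = 0,
    n_perm: int = 0,
    *,
    threshold: float = 1.0,
    unknown: str = "low",
) -> tuple[list[MDRModel], MDRModel]:
    """Full pipeline: per-size search, optional permutation p, final pick."""
    models = search_best_models(
        dataset, k_min, k_max, folds, seed, threshold=threshold, unknown=unknown
    )
    if n_perm:
        for m in models:
            m.perm_p = permutation_test(
                dataset, m.k, n_perm, seed + m.k, folds=folds,
                threshold=threshold, unknown=unknown,
            )
    return models, select_final_model(models)
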
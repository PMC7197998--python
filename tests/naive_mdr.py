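"""Independent naive MDR re-implementation used as a test oracle.

Deliberately written in plain dict/loop Python with no shared code paths
with the package's vectorized engine: cell tables are dicts keyed by
genotype tuples, labelings are computed cell by cell, and balanced
accuracies are accumulated one individual at a time.
"""

from __future__ import annotations

import itertools


def cell_table(genotypes, phenotype, cols):
    """dict cell -> [cases, controls], plus typed case/control totals."""
    cells = {}
    n_cases = n_controls = 0
    for row, ph in zip(genotypes, phenotype):
        vals = [row[c] for c in cols]
        if any(v < 0 for v in vals):
            continue
        key = tuple(int(v) for v in vals)
        if key not in cells:
            cells[key] = [0, 0]
        cells[key][0 if ph == 1 else 1] += 1
        if ph == 1:
            n_cases += 1
        else:
            n_controls += 1
    return cells, n_cases, n_controls


def label(cells, n_cases, n_controls, threshold=1.0):
    out = {}
    for key, (ca, co) in cells.items():
        if ca + co == 0:
            out[key] = "unknown"
        elif ca * n_controls >= threshold * co * n_cases:
            out[key] = "high"
        else:
            out[key] = "low"
    return out


def _part_ba(genotypes, phenotype, cols, rows, labels, unknown):
    tp = fn = tn = fp = 0
    n_case = n_ctrl = 0
    for i in rows:
        vals = [genotypes[i][c] for c in cols]
        if any(v < 0 for v in vals):
            continue
        key = tuple(int(v) for v in vals)
        lab = labels.get(key, "unknown")
        if lab == "unknown":
            if unknown == "exclude":
                continue
            lab = unknown  # 'low' or 'high'
        pred_case = lab == "high"
        if phenotype[i] == 1:
            n_case += 1
            tp += pred_case
        else:
            n_ctrl += 1
            fp += pred_case
    sens = tp / n_case if n_case else 0.5
    spec = (n_ctrl - fp) / n_ctrl if n_ctrl else 0.5
    return (sens + spec) / 2.0


def fold_bas(genotypes, phenotype, cols, fold_ids, n_folds, threshold=1.0, unknown="low"):
    """Per-fold (train_ba, test_ba) lists for one column combination."""
    train, test = [], []
    n = len(phenotype)
    for f in range(n_folds):
        tr_rows = [i for i in range(n) if fold_ids[i] != f]
        te_rows = [i for i in range(n) if fold_ids[i] == f]
        g_tr = [genotypes[i] for i in tr_rows]
        p_tr = [phenotype[i] for i in tr_rows]
        cells, nca, nco = cell_table(g_tr, p_tr, cols)
        labels = label(cells, nca, nco, threshold)
        train.append(_part_ba(genotypes, phenotype, cols, tr_rows, labels, unknown))
        test.append(_part_ba(genotypes, phenotype, cols, te_rows, labels, unknown))
    return train, test


def rank_combos(genotypes, phenotype, snp_ids, k, fold_ids, n_folds,
                threshold=1.0, unknown="low"):
    """All size-k combos in lexicographic id order with mean train/test BA;
    returns (ordered combo list, best index, per-fold best indices)."""
    order = sorted(range(len(snp_ids)), key=lambda j: snp_ids[j])
    combos = [tuple(c) for c in itertools.combinations(order, k)]
    all_train, all_test = [], []
    for cols in combos:
        tr, te = fold_bas(genotypes, phenotype, cols, fold_ids, n_folds, threshold, unknown)
        all_train.append(tr)
        all_test.append(te)
    means = [sum(tr) / len(tr) for tr in all_train]
    best = max(range(len(combos)), key=lambda i: (means[i], -i))
    fold_best = []
    for f in range(n_folds):
        fold_best.append(max(range(len(combos)), key=lambda i: (all_train[i][f], -i)))
    id_combos = [tuple(snp_ids[j] for j in c) for c in combos]
    return id_combos, all_train, all_test, best, fold_best
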
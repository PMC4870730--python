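"""Independent brute-force reimplementation of the cross-validated
QMDR/GMDR search, used only as a test oracle.

Deliberately naive: nested Python loops and dictionaries, textbook
formulas, no code shared with the package's vectorised engine.  The
fold-assignment rule and tie-break conventions are reimplemented from
their documented definitions.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

BIG = 1.0e6


def _residuals(y, covariates):
    y = [float(v) for v in y]
    n = len(y)
    if covariates is None:
        X = [[1.0] for _ in range(n)]
    else:
        X = [[1.0] + [float(v) for v in row] for row in np.asarray(covariates)]
    p = len(X[0])
    # normal equations, solved by hand via numpy on the small matrices
    XtX = [[sum(X[i][a] * X[i][b] for i in range(n)) for b in range(p)]
           for a in range(p)]
    Xty = [sum(X[i][a] * y[i] for i in range(n)) for a in range(p)]
    beta = np.linalg.solve(np.array(XtX), np.array(Xty))
    return [y[i] - sum(X[i][a] * beta[a] for a in range(p)) for i in range(n)]


def _pooled_t(hi, lo):
    n1, n0 = len(hi), len(lo)
    if n1 == 0 or n0 == 0 or n1 + n0 - 2 <= 0:
        return -BIG
    m1 = sum(hi) / n1
    m0 = sum(lo) / n0
    ss = sum((x - m1) ** 2 for x in hi) + sum((x - m0) ** 2 for x in lo)
    sp2 = ss / (n1 + n0 - 2)
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    diff = m1 - m0
    if se == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(BIG, diff)
    return max(-BIG, min(BIG, diff / se))


def _bal_acc(high_cells, cell_of, z, members):
    pos_tot = sum(z[i] for i in members if z[i] > 0)
    neg_tot = sum(-z[i] for i in members if z[i] < 0)
    if pos_tot == 0 or neg_tot == 0:
        return -1.0
    ph = sum(z[i] for i in members if z[i] > 0 and cell_of(i) in high_cells)
    nl = sum(-z[i] for i in members if z[i] < 0 and cell_of(i) not in high_cells)
    return 0.5 * (ph / pos_tot + nl / neg_tot)


def naive_cv_search(G, snp_ids, y, covariates, method, k, n_folds, seed):
    """Exhaustive CV interaction search, the slow and obvious way.

    Returns a dict with the winner tuple (of SNP ids), per-fold
    (selected, train_stat, test_stat), cv_consistency and t_cv_score.
    """
    G = np.asarray(G)
    n = G.shape[0]
    z = _residuals(y, covariates)

    # documented fold rule: seeded uniform shuffle, position modulo folds
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = rng.permutation(n)
    fold_of = [0] * n
    for pos, subj in enumerate(perm):
        fold_of[subj] = pos % n_folds

    col = {s: j for j, s in enumerate(snp_ids)}
    combos = list(itertools.combinations(sorted(snp_ids), k))

    per_fold_sel = []
    per_fold_train = []
    all_test = {c: [] for c in combos}
    for f in range(n_folds):
        train = [i for i in range(n) if fold_of[i] != f]
        test = [i for i in range(n) if fold_of[i] == f]
        best_combo, best_train, fold_tests = None, None, {}
        for combo in combos:
            cols = [col[s] for s in combo]

            def cell_of(i, cols=cols):
                return tuple(int(G[i, c]) for c in cols)

            cells = {}
            for i in train:
                cells.setdefault(cell_of(i), []).append(i)
            if method == "qmdr":
                overall = sum(z[i] for i in train) / len(train)
                high = {
                    cell
                    for cell, mem in cells.items()
                    if sum(z[i] for i in mem) / len(mem) > overall
                }
                tr_stat = _pooled_t(
                    [z[i] for i in train if cell_of(i) in high],
                    [z[i] for i in train if cell_of(i) not in high],
                )
                te_stat = _pooled_t(
                    [z[i] for i in test if cell_of(i) in high],
                    [z[i] for i in test if cell_of(i) not in high],
                )
            else:
                high = {
                    cell
                    for cell, mem in cells.items()
                    if sum(z[i] for i in mem) > 0
                }
                tr_stat = _bal_acc(high, cell_of, z, train)
                te_stat = _bal_acc(high, cell_of, z, test)
            fold_tests[combo] = te_stat
            if best_train is None or tr_stat > best_train:
                best_combo, best_train = combo, tr_stat
        per_fold_sel.append(best_combo)
        per_fold_train.append(best_train)
        for combo in combos:
            all_test[combo].append(fold_tests[combo])

    counts = {c: per_fold_sel.count(c) for c in combos}
    top = max(counts.values())
    tied = [c for c in combos if counts[c] == top]
    if len(tied) > 1:
        means = {c: sum(all_test[c]) / n_folds for c in tied}
        best_mean = max(means.values())
        tied = [c for c in tied if means[c] == best_mean]
    winner = sorted(tied)[0]
    return {
        "winner": winner,
        "per_fold": [
            (per_fold_sel[f], per_fold_train[f], all_test[per_fold_sel[f]][f])
            for f in range(n_folds)
        ],
        "cv_consistency": counts[winner],
        "t_cv_score": sum(all_test[winner]) / n_folds,
        "test_stats": all_test,
    }
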
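"""QMDR / GMDR k-way gene-gene interaction search.

The multifactor-dimensionality-reduction idea: for a tuple of k SNPs,
the up-to-3^k multi-locus genotype combinations ("cells") are each
labelled High or Low, collapsing the k-dimensional genotype space to one
binary attribute.

* QMDR labels a cell High when its training-set trait mean exceeds the
  overall training mean, and scores the pooled High-vs-Low split with a
  two-sample pooled-variance t statistic.
* GMDR labels a cell High when the sum of its members' scores — the
  residuals of a covariate-only null model — is positive, and scores the
  split with a score-mass balanced accuracy.

The search is exhaustive over all k-tuples under tenfold
cross-validation: each fold labels cells on its training subjects,
selects the tuple with the best training statistic, and evaluates the
selected labelling on the held-out fold.  The winning tuple is the one
selected most often; its CV consistency is that selection count and its
T-CV score is the mean of its ten held-out statistics (which can be
negative).  Empirical significance comes from rerunning the entire
search on phenotype-permuted data.

Covariate adjustment: both methods run on the residuals of
``trait ~ intercept + age + sex + pack-years`` (for QMDR this keeps the
mean-comparison semantics while removing covariate main effects; for
GMDR the residuals are exactly the identity-link null-model scores).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

__all__ = [
    "CellPartition",
    "FoldRecord",
    "InteractionModel",
    "PermutationResult",
    "adjust_trait",
    "partition_cells",
    "label_cells_qmdr",
    "label_cells_gmdr",
    "qmdr_statistic",
    "gmdr_statistic",
    "cross_validated_search",
    "permutation_test",
]

#: cap for a t statistic with zero pooled variance (keeps rankings total)
T_CAP = 1.0e6
#: sentinel "worst" t when a pooled group is empty or dof <= 0
UNDEFINED_T = -1.0e6
#: sentinel "worst" balanced accuracy when the score mass is one-sided
UNDEFINED_ACC = -1.0

HIGH, LOW = "High", "Low"


# ---------------------------------------------------------------------------
# covariate adjustment

def adjust_trait(trait_values, covariates=None) -> np.ndarray:
    """Residuals of OLS of the trait on intercept + covariates.

    With ``covariates=None`` this is plain centring (intercept-only null
    model).  The residuals serve as the QMDR working phenotype and as
    the GMDR score vector (identity link); they sum to ~0.
    """
    y = np.asarray(trait_values, dtype=float)
    if np.isnan(y).any():
        raise ValueError("trait contains missing values; complete cases only")
    if covariates is None:
        return y - y.mean()
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.isnan(X).any():
        raise ValueError("covariates contain missing values")
    X = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


# ---------------------------------------------------------------------------
# cells and labels (reference per-tuple path)

@dataclass
class CellPartition:
    """Multi-locus genotype cells for one SNP tuple.

    ``cells`` maps each observed genotype tuple to the member subject
    indices (relative to the full genotype matrix).  After labelling,
    ``cell_means`` and ``labels`` are populated for non-empty cells.
    """

    snp_tuple: tuple[str, ...]
    cells: dict[tuple[int, ...], np.ndarray]
    n_excluded_missing: int = 0
    cell_means: dict[tuple[int, ...], float] = field(default_factory=dict)
    labels: dict[tuple[int, ...], str] = field(default_factory=dict)
    _geno_cols: np.ndarray | None = field(default=None, repr=False)

    def member_count(self) -> int:
        return int(sum(len(v) for v in self.cells.values()))

    def cell_of(self, subject_index: int) -> tuple[int, ...] | None:
        """Genotype cell of an arbitrary subject (None if missing a call)."""
        if self._geno_cols is None:
            raise ValueError("partition lacks genotype reference")
        row = self._geno_cols[subject_index]
        if (row == MISSING).any():
            return None
        return tuple(int(g) for g in row)


def _resolve_columns(genotypes, snp_tuple, snp_ids=None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(genotypes, GenotypeMatrix):
        idx = [genotypes.snp_index(s) for s in snp_tuple]
        return genotypes.calls[:, idx], tuple(snp_tuple)
    G = np.asarray(genotypes)
    ids = list(snp_ids) if snp_ids is not None else [
        f"snp{j + 1:03d}" for j in range(G.shape[1])
    ]
    idx = [ids.index(s) for s in snp_tuple]
    return G[:, idx], tuple(snp_tuple)


def partition_cells(genotypes, snp_tuple, subjects=None, snp_ids=None) -> CellPartition:
    """Assign subjects to multi-locus genotype cells for one SNP tuple.

    Subjects missing any of the tuple's genotypes are excluded and
    counted in ``n_excluded_missing``.
    """
    k = len(snp_tuple)
    n_snps = genotypes.n_snps if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes).shape[1]
    if k < 1 or k > n_snps:
        raise ValueError(f"tuple size {k} outside 1..{n_snps}")
    cols, ids = _resolve_columns(genotypes, snp_tuple, snp_ids)
    n = cols.shape[0]
    subj = np.arange(n) if subjects is None else np.asarray(subjects, dtype=int)
    if subj.size == 0:
        raise ValueError("subjects must be non-empty")
    ok = (cols[subj] != MISSING).all(axis=1)
    cells: dict[tuple[int, ...], list[int]] = {}
    for s in subj[ok]:
        key = tuple(int(g) for g in cols[s])
        cells.setdefault(key, []).append(int(s))
    return CellPartition(
        snp_tuple=ids,
        cells={k_: np.asarray(v, dtype=int) for k_, v in cells.items()},
        n_excluded_missing=int((~ok).sum()),
        _geno_cols=cols,
    )


def label_cells_qmdr(
    partition: CellPartition, trait_values, overall_mean: float | None = None
) -> CellPartition:
    """Label cells High/Low by comparing each cell's trait mean to the
    overall mean of the partition's (training) subjects.

    Ties (cell mean exactly equal to the overall mean) go Low; empty
    cells stay unlabelled.
    """
    y = np.asarray(trait_values, dtype=float)
    if overall_mean is None:
        members = np.concatenate(list(partition.cells.values()))
        overall_mean = float(y[members].mean())
    partition.cell_means = {
        cell: float(y[idx].mean()) for cell, idx in partition.cells.items()
    }
    partition.labels = {
        cell: (HIGH if mean > overall_mean else LOW)
        for cell, mean in partition.cell_means.items()
    }
    return partition


def label_cells_gmdr(partition: CellPartition, scores) -> CellPartition:
    """Label cells High when the sum of member scores is positive
    (a zero sum, including the all-zero case, goes Low)."""
    z = np.asarray(scores, dtype=float)
    partition.cell_means = {
        cell: float(z[idx].sum()) for cell, idx in partition.cells.items()
    }
    partition.labels = {
        cell: (HIGH if s > 0 else LOW) for cell, s in partition.cell_means.items()
    }
    return partition


def _pooled_t(y_high: np.ndarray, y_low: np.ndarray) -> float:
    """Pooled-variance two-sample t, (mean_High - mean_Low)/SE, with the
    documented guards: empty group or non-positive dof -> UNDEFINED_T;
    zero pooled variance -> 0 for equal means else +/- T_CAP."""
    n1, n0 = len(y_high), len(y_low)
    if n1 == 0 or n0 == 0 or n1 + n0 - 2 <= 0:
        return UNDEFINED_T
    m1, m0 = y_high.mean(), y_low.mean()
    ss = ((y_high - m1) ** 2).sum() + ((y_low - m0) ** 2).sum()
    sp2 = ss / (n1 + n0 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    diff = m1 - m0
    if se == 0.0:
        return 0.0 if diff == 0.0 else float(np.sign(diff) * T_CAP)
    return float(np.clip(diff / se, -T_CAP, T_CAP))


def _split_by_labels(partition: CellPartition, subjects) -> tuple[np.ndarray, np.ndarray]:
    """High/Low membership of arbitrary subjects under a labelled
    partition; subjects in unseen (unlabelled) cells go Low."""
    if not partition.labels:
        raise ValueError("partition is unlabelled")
    subj = np.asarray(subjects, dtype=int)
    high = np.zeros(subj.size, dtype=bool)
    for i, s in enumerate(subj):
        cell = partition.cell_of(int(s))
        high[i] = cell is not None and partition.labels.get(cell, LOW) == HIGH
    return subj[high], subj[~high]


def qmdr_statistic(partition: CellPartition, trait_values, subjects) -> float:
    """Pooled t between the High and Low pooled groups, evaluated on the
    given subjects under the partition's (training-derived) labels.
    Sign is kept: on held-out subjects the statistic can be negative."""
    y = np.asarray(trait_values, dtype=float)
    hi, lo = _split_by_labels(partition, subjects)
    return _pooled_t(y[hi], y[lo])


def gmdr_statistic(partition: CellPartition, scores, subjects) -> float:
    """Score-mass balanced accuracy in [0, 1]:
    0.5 * (positive score mass falling in High cells / total positive
    mass + negative score mass falling in Low cells / total negative
    mass), on the given subjects.  One-sided score mass -> sentinel."""
    z = np.asarray(scores, dtype=float)
    hi, lo = _split_by_labels(partition, subjects)
    subj = np.asarray(subjects, dtype=int)
    zv = z[subj]
    pos_tot = zv[zv > 0].sum()
    neg_tot = -zv[zv < 0].sum()
    if pos_tot == 0.0 or neg_tot == 0.0:
        return UNDEFINED_ACC
    zh, zl = z[hi], z[lo]
    pos_in_high = zh[zh > 0].sum()
    neg_in_low = -zl[zl < 0].sum()
    return float(0.5 * (pos_in_high / pos_tot + neg_in_low / neg_tot))


# ---------------------------------------------------------------------------
# vectorised exhaustive search

def _make_folds(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Near-equal fold ids by seeded uniform shuffle (no stratification)."""
    if n < n_folds:
        raise ValueError(f"{n} subjects cannot fill {n_folds} folds")
    perm = rng.permutation(n)
    fold_ids = np.empty(n, dtype=np.int64)
    fold_ids[perm] = np.arange(n) % n_folds
    return fold_ids


def _tuple_codes(G: np.ndarray, tuples: np.ndarray) -> np.ndarray:
    """Cell code of every subject for every tuple: base-3 digits of the
    tuple's genotypes.  Returns (n_tuples, n_subjects) int64."""
    T, k = tuples.shape
    codes = np.zeros((T, G.shape[0]), dtype=np.int64)
    for pos in range(k):
        codes = codes * 3 + G[:, tuples[:, pos]].T
    return codes


def _t_stats_vec(codes_sub: np.ndarray, high: np.ndarray, yv: np.ndarray) -> np.ndarray:
    """Pooled t per tuple for one subject set.  ``codes_sub`` is
    (T, m) cell codes, ``high`` (T, ncells) bool labels, ``yv`` (m,)."""
    T, m = codes_sub.shape
    if m < 3:
        return np.full(T, UNDEFINED_T)
    h = np.take_along_axis(high, codes_sub, axis=1).astype(float)
    n1 = h.sum(axis=1)
    n0 = m - n1
    s1 = h @ yv
    ss1 = h @ (yv * yv)
    s_tot = yv.sum()
    ss_tot = (yv * yv).sum()
    out = np.full(T, UNDEFINED_T)
    ok = (n1 > 0) & (n0 > 0)
    if not ok.any():
        return out
    n1o, n0o = n1[ok], n0[ok]
    m1 = s1[ok] / n1o
    m0 = (s_tot - s1[ok]) / n0o
    ss = (ss1[ok] - n1o * m1**2) + ((ss_tot - ss1[ok]) - n0o * m0**2)
    sp2 = np.maximum(ss, 0.0) / (m - 2)
    se = np.sqrt(sp2 * (1.0 / n1o + 1.0 / n0o))
    diff = m1 - m0
    t = np.where(
        se > 0.0,
        np.clip(diff / np.where(se > 0.0, se, 1.0), -T_CAP, T_CAP),
        np.where(diff == 0.0, 0.0, np.sign(diff) * T_CAP),
    )
    out[ok] = t
    return out


def _acc_stats_vec(codes_sub: np.ndarray, high: np.ndarray, zv: np.ndarray) -> np.ndarray:
    """Score-mass balanced accuracy per tuple for one subject set."""
    T, m = codes_sub.shape
    pos = np.where(zv > 0, zv, 0.0)
    neg = np.where(zv < 0, -zv, 0.0)
    pos_tot = pos.sum()
    neg_tot = neg.sum()
    if pos_tot == 0.0 or neg_tot == 0.0:
        return np.full(T, UNDEFINED_ACC)
    h = np.take_along_axis(high, codes_sub, axis=1).astype(float)
    pos_in_high = h @ pos
    neg_in_low = (1.0 - h) @ neg
    return 0.5 * (pos_in_high / pos_tot + neg_in_low / neg_tot)


def _fold_stats(
    codes: np.ndarray,
    yw: np.ndarray,
    tr_idx: np.ndarray,
    te_idx: np.ndarray,
    ncells: int,
    method: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Training and testing statistics for every tuple in one fold."""
    T = codes.shape[0]
    ytr = yw[tr_idx]
    flat = (codes[:, tr_idx] + (np.arange(T) * ncells)[:, None]).ravel()
    w = np.tile(ytr, T)
    if method == "qmdr":
        cnt = np.bincount(flat, minlength=T * ncells).reshape(T, ncells)
        sums = np.bincount(flat, weights=w, minlength=T * ncells).reshape(T, ncells)
        overall = ytr.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / cnt
        high = (cnt > 0) & (means > overall)  # empty/tied cells stay Low
        train = _t_stats_vec(codes[:, tr_idx], high, ytr)
        test = _t_stats_vec(codes[:, te_idx], high, yw[te_idx])
    elif method == "gmdr":
        ssum = np.bincount(flat, weights=w, minlength=T * ncells).reshape(T, ncells)
        high = ssum > 0
        train = _acc_stats_vec(codes[:, tr_idx], high, ytr)
        test = _acc_stats_vec(codes[:, te_idx], high, yw[te_idx])
    else:
        raise ValueError(f"unknown method '{method}'")
    return train, test


@dataclass(frozen=True)
class FoldRecord:
    """Audit record of one cross-validation fold."""

    fold: int
    selected: tuple[str, ...]
    train_stat: float
    test_stat: float


@dataclass
class InteractionModel:
    """The winning k-way model of one cross-validated search.

    ``cv_consistency`` counts the folds whose selected tuple equals the
    winner; ``t_cv_score`` is the mean of the winner's ten held-out
    statistics (a t statistic for QMDR, a balanced accuracy for GMDR)
    and may be negative.  ``permuted_p`` is attached by
    :func:`permutation_test`.
    """

    method: str
    k: int
    snp_tuple: tuple[str, ...]
    per_fold: list[FoldRecord]
    cv_consistency: int
    t_cv_score: float
    permuted_p: float | None = None

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)


def _search_core(
    codes: np.ndarray,
    yw: np.ndarray,
    fold_ids: np.ndarray,
    n_folds: int,
    ncells: int,
    method: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Run the exhaustive CV search; returns (selections, train_stats,
    test_stats, winner_index).  Stats arrays are (n_folds, n_tuples)."""
    T = codes.shape[0]
    train_stats = np.empty((n_folds, T))
    test_stats = np.empty((n_folds, T))
    sel = np.empty(n_folds, dtype=np.int64)
    for f in range(n_folds):
        te = fold_ids == f
        if not te.any():
            raise ValueError(f"fold {f} has zero test subjects")
        tr_idx = np.flatnonzero(~te)
        te_idx = np.flatnonzero(te)
        if tr_idx.size == 0:
            raise ValueError(f"fold {f} has an empty training set")
        tr_s, te_s = _fold_stats(codes, yw, tr_idx, te_idx, ncells, method)
        train_stats[f] = tr_s
        test_stats[f] = te_s
        sel[f] = int(np.argmax(tr_s))  # first max -> lexicographic tie-break

    counts = np.bincount(sel, minlength=T)
    best_count = counts.max()
    cand = np.flatnonzero(counts == best_count)
    if cand.size > 1:
        # larger mean testing statistic, then lexicographic order
        mean_test = test_stats[:, cand].mean(axis=0)
        cand = cand[mean_test == mean_test.max()]
    winner = int(cand[0])
    return sel, train_stats, test_stats, winner


def _prepare(genotypes, trait_values, covariates, snp_ids):
    """Coerce inputs; sort SNP columns by id so that tuple enumeration is
    lexicographic over sorted SNP ids."""
    if isinstance(genotypes, GenotypeMatrix):
        G = genotypes.calls
        ids = list(genotypes.snp_ids)
    else:
        G = np.asarray(genotypes)
        ids = list(snp_ids) if snp_ids is not None else [
            f"snp{j + 1:03d}" for j in range(G.shape[1])
        ]
    order = sorted(range(len(ids)), key=lambda j: ids[j])
    G = np.ascontiguousarray(G[:, order], dtype=np.int64)
    ids = [ids[j] for j in order]
    if (G == MISSING).any():
        raise ValueError(
            "the interaction search requires complete genotypes; drop or "
            "impute missing calls first"
        )
    yw = adjust_trait(trait_values, covariates)
    if len(yw) != G.shape[0]:
        raise ValueError("trait and genotypes must align")
    return G, ids, yw


def cross_validated_search(
    genotypes,
    trait_values,
    covariates=None,
    *,
    method: str = "qmdr",
    k: int = 2,
    n_folds: int = 10,
    seed: int = 0,
    snp_ids: list[str] | None = None,
) -> InteractionModel:
    """Exhaustive k-way interaction search with cross-validation.

    ``genotypes`` is a :class:`GenotypeMatrix` or an (n, S) additive
    array (``snp_ids`` naming its columns); ``covariates`` (DataFrame or
    array) are residualised out of the trait before the search.  The
    candidate set is every k-combination of SNPs in lexicographic id
    order; folds come from a seeded uniform shuffle.
    """
    G, ids, yw = _prepare(genotypes, trait_values, covariates, snp_ids)
    if k < 1 or k > G.shape[1]:
        raise ValueError(f"k={k} outside 1..{G.shape[1]}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fold_ids = _make_folds(G.shape[0], n_folds, rng)
    return _run_search(G, ids, yw, fold_ids, n_folds, method, k)


def _run_search(G, ids, yw, fold_ids, n_folds, method, k) -> InteractionModel:
    tuples = np.array(list(itertools.combinations(range(G.shape[1]), k)),
                      dtype=np.int64)
    codes = _tuple_codes(G, tuples)
    sel, train_stats, test_stats, winner = _search_core(
        codes, yw, fold_ids, n_folds, 3**k, method
    )
    id_tuple = lambda t: tuple(ids[j] for j in tuples[t])  # noqa: E731
    per_fold = [
        FoldRecord(
            fold=f,
            selected=id_tuple(sel[f]),
            train_stat=float(train_stats[f, sel[f]]),
            test_stat=float(test_stats[f, sel[f]]),
        )
        for f in range(n_folds)
    ]
    return InteractionModel(
        method=method,
        k=k,
        snp_tuple=id_tuple(winner),
        per_fold=per_fold,
        cv_consistency=int((sel == winner).sum()),
        t_cv_score=float(test_stats[:, winner].mean()),
    )


@dataclass
class PermutationResult:
    """Empirical significance of the winning model.

    ``p = (b + 1) / (B + 1)`` where ``b`` counts permuted search
    statistics >= the observed one; p can never drop below 1/(B+1).
    """

    observed_stat: float
    null_stats: np.ndarray
    b: int
    p: float
    model: InteractionModel


def permutation_test(
    genotypes,
    trait_values,
    covariates=None,
    *,
    method: str = "qmdr",
    k: int = 2,
    B: int = 1000,
    n_folds: int = 10,
    seed: int = 0,
    snp_ids: list[str] | None = None,
) -> PermutationResult:
    """Permutation significance of the cross-validated search.

    The observed statistic is the winning model's t_cv_score (mean
    held-out t for QMDR, mean held-out balanced accuracy for GMDR).
    Each of the B permutations shuffles the covariate-adjusted phenotype
    across subjects (genotypes untouched, preserving LD), re-draws the
    fold assignment, reruns the full search, and records the permuted
    winner's statistic.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    G, ids, yw = _prepare(genotypes, trait_values, covariates, snp_ids)
    if k < 1 or k > G.shape[1]:
        raise ValueError(f"k={k} outside 1..{G.shape[1]}")
    n = G.shape[0]
    tuples = np.array(list(itertools.combinations(range(G.shape[1]), k)),
                      dtype=np.int64)
    codes = _tuple_codes(G, tuples)
    ncells = 3**k

    children = np.random.SeedSequence(seed).spawn(B + 1)
    rng0 = np.random.default_rng(children[0])
    fold_ids = _make_folds(n, n_folds, rng0)
    model = _run_search(G, ids, yw, fold_ids, n_folds, method, k)
    observed = model.t_cv_score

    null_stats = np.empty(B)
    for b_i in range(B):
        rng = np.random.default_rng(children[b_i + 1])
        yp = rng.permutation(yw)
        perm_folds = _make_folds(n, n_folds, rng)
        _, _, test_stats, winner = _search_core(
            codes, yp, perm_folds, n_folds, ncells, method
        )
        null_stats[b_i] = test_stats[:, winner].mean()

    b = int((null_stats >= observed).sum())
    p = (b + 1) / (B + 1)
    model.permuted_p = p
    return PermutationResult(
        observed_stat=float(observed), null_stats=null_stats, b=b, p=p,
        model=model,
    )


def model_table(models: dict[str, InteractionModel], n_folds: int = 10) -> pd.DataFrame:
    """Render a trait -> model mapping as a published-style table row set
    (trait, tuple, T-CV score, CV consistency, permuted p / NS)."""
    rows = []
    for trait, m in models.items():
        p = m.permuted_p
        rows.append(
            {
                "trait": trait,
                "model": "*".join(m.snp_tuple),
                "t_cv_score": m.t_cv_score,
                "cv_consistency": f"{m.cv_consistency}/{m.n_folds}",
                "permuted_p": p if p is not None else np.nan,
                "significance": (
                    "" if p is None else ("NS" if p >= 0.05 else f"{p:.3f}*")
                ),
            }
        )
    return pd.DataFrame(rows)
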
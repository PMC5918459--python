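"""Exhaustive k-locus search with cross-validation for all four methods.

The four methods share one engine and differ only in two switches:

================  ==================  ============
method            null model          membership
================  ==================  ============
mdr               intercept only      indicator
fmdr              intercept only      sigmoid
gmdr              with covariates     indicator
fgmdr             with covariates     sigmoid
================  ==================  ============

Scores are computed once on the full data from the covariate-only null
model and reused across folds: the null model contains no genotype
terms, so the signal under test cannot leak into the scores.  Per-fold
refitting is available via ``refit_scores_per_fold`` for comparison.

For each fold every combination is scored on the training samples; the
fold's training-best combination is its winner, and cross-validation
consistency (CVC) counts the folds a combination wins.  Testing
balanced accuracy drops held-out samples into the cells and membership
degrees *learned on the training fold*; cells empty in training
contribute nothing to the test measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations as iter_combinations
from math import comb
from typing import Sequence

import numpy as np

from fgmdr.glm_scores import ScoreVector, scores_for, studentized_scores, fit_null_model
from fgmdr.io_formats import MISSING, GenotypeMatrix, PhenotypeTable
from fgmdr.mdr_core import (
    CellTable,
    balanced_accuracy,
    build_cell_table,
    fuzzy_confusion,
    table_from_arrays,
    cell_index,
)
from fgmdr.membership import (
    MembershipFunction,
    default_thresholds,
    mu_high,
    null_noise_thresholds,
)

METHODS = ("mdr", "fmdr", "gmdr", "fgmdr")

#: refuse exhaustive searches beyond this many combinations; candidate-SNP
#: pre-filtering (as done in real analyses) is the intended workaround
DEFAULT_COMBINATION_BUDGET = 200_000


@dataclass
class SearchConfig:
    order: int = 2
    n_folds: int = 10
    method: str = "fgmdr"
    t_l: float | None = None  # explicit sigmoid band; None -> data-driven default
    t_h: float | None = None
    threshold_spread: float = 1.0
    soft_se: float = 4.0  # half-transition width of the default band, in null SEs
    crisp_threshold: float = 0.0
    seed: int = 0
    stratify: bool = False
    refit_scores_per_fold: bool = False
    studentization: str = "internal"
    combination_budget: int = DEFAULT_COMBINATION_BUDGET

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if not 1 <= self.order <= 5:
            raise ValueError(f"interaction order must be in [1, 5], got {self.order}")

    @property
    def fuzzy(self) -> bool:
        return self.method in ("fmdr", "fgmdr")

    @property
    def uses_covariates(self) -> bool:
        return self.method in ("gmdr", "fgmdr")


@dataclass
class ModelResult:
    combination: tuple[str, ...]
    ba_train: float
    ba_test: float
    cvc: int
    fold_train_ba: np.ndarray = field(default=None, repr=False)
    fold_test_ba: np.ndarray = field(default=None, repr=False)


def search_membership(config: SearchConfig, s_train: np.ndarray) -> MembershipFunction:
    """Membership function used for every combination of one (training) dataset.

    Crisp methods use the indicator at the configured threshold.  Fuzzy
    methods use the explicit (t_l, t_h) band when configured, otherwise
    the a-priori null-noise band of
    :func:`fgmdr.membership.null_noise_thresholds`.  The band is fixed
    across combinations: a band re-estimated per table would make the
    fuzzy balanced accuracy nearly scale-free and erase the very
    between-model contrasts the search ranks on.
    """
    if not config.fuzzy:
        return MembershipFunction.indicator(config.crisp_threshold)
    if config.t_l is not None and config.t_h is not None:
        return MembershipFunction.sigmoid(config.t_l, config.t_h)
    sd = float(np.std(s_train))
    if sd == 0:
        return MembershipFunction.indicator(config.crisp_threshold)
    t_l, t_h = null_noise_thresholds(sd, len(s_train), config.order, config.soft_se)
    return MembershipFunction.sigmoid(t_l, t_h)


def membership_for_table(table: CellTable, config: SearchConfig) -> MembershipFunction:
    """Membership for reporting on a single, already-chosen cell table.

    Unlike the search default, this uses the spread of the table's own
    nonempty-cell means (:func:`fgmdr.membership.default_thresholds`),
    which is the natural scale when only one table is in play.  Falls
    back to the indicator when the means carry no spread.
    """
    if not config.fuzzy:
        return MembershipFunction.indicator(config.crisp_threshold)
    if config.t_l is not None and config.t_h is not None:
        return MembershipFunction.sigmoid(config.t_l, config.t_h)
    means = table.mean_score[table.nonempty]
    try:
        t_l, t_h = default_thresholds(means, spread=config.threshold_spread)
    except ValueError:
        return MembershipFunction.indicator(config.crisp_threshold)
    return MembershipFunction.sigmoid(t_l, t_h)


def evaluate_combination(
    genos: GenotypeMatrix,
    scores: ScoreVector,
    combination: Sequence[str],
    f: MembershipFunction,
) -> float:
    """Full-data balanced accuracy of one SNP combination."""
    table = build_cell_table(genos, combination, scores)
    return balanced_accuracy(fuzzy_confusion(table, f))


def make_folds(
    n: int,
    n_folds: int,
    labels: np.ndarray | None = None,
    seed: int = 0,
    stratify: bool = False,
) -> np.ndarray:
    """Deterministic fold assignment: an int array of fold ids in [0, n_folds).

    Without stratification, a seeded permutation is dealt round-robin,
    so fold sizes differ by at most one.  With ``stratify`` and binary
    ``labels``, the deal is round-robin within each class, preserving
    class proportions per fold within one sample.
    """
    if not 2 <= n_folds <= n:
        raise ValueError(f"need 2 <= n_folds <= n, got n_folds={n_folds}, n={n}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=np.int64)
    if stratify:
        if labels is None:
            raise ValueError("stratify=True requires labels")
        labels = np.asarray(labels)
        offset = 0
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            idx = rng.permutation(idx)
            # offset staggers the deal so overall fold sizes stay within 1
            folds[idx] = (np.arange(len(idx)) + offset) % n_folds
            offset += len(idx)
        uniq = np.unique(labels)
        if len(uniq) == 2:
            for f_id in range(n_folds):
                in_fold = folds == f_id
                for cls in uniq:
                    if not np.any(in_fold & (labels == cls)):
                        raise ValueError(
                            f"stratified fold {f_id} has no samples of class {cls}; "
                            "reduce n_folds"
                        )
    else:
        perm = rng.permutation(n)
        folds[perm] = np.arange(n) % n_folds
    return folds


def _test_ba(
    train_table: CellTable,
    f: MembershipFunction,
    test_cols: np.ndarray,
    test_scores: np.ndarray,
) -> float:
    """Test-fold BA with cell memberships learned on the training table.

    Test samples landing in training-empty cells carry no defined
    membership and are left out.  Returns NaN when the remaining test
    mass is one-sided (degenerate denominators).
    """
    test_table = table_from_arrays(train_table.combination, test_cols, test_scores)
    usable = train_table.nonempty & (test_table.count > 0)
    if not usable.any():
        return np.nan
    muh = np.asarray(mu_high(f, train_table.mean_score[usable]))
    mul = 1.0 - muh
    pos = test_table.pos_sum[usable]
    neg = test_table.neg_mag[usable]
    tp, fn = float(pos @ muh), float(pos @ mul)
    fp, tn = float(neg @ muh), float(neg @ mul)
    if tp + fn <= 0 or fp + tn <= 0:
        return np.nan
    return (tp / (tp + fn) + tn / (tn + fp)) / 2.0


def _fold_scores(
    phenos: PhenotypeTable, config: SearchConfig, train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold refitted scores: null model on the training fold, test scores
    from the training fit's coefficients."""
    covs = phenos.covariates if config.uses_covariates else phenos.covariates.iloc[:, :0]
    sub = PhenotypeTable(
        samples=[phenos.samples[i] for i in np.flatnonzero(train)],
        y=phenos.y[train],
        trait_family=phenos.trait_family,
        covariates=covs[train].reset_index(drop=True),
    )
    fit = fit_null_model(sub)
    s_train = studentized_scores(fit, sub, config.studentization).s
    z = covs.to_numpy(dtype=float).reshape(len(phenos.samples), -1)[test]
    eta = fit.intercept + (z @ fit.coefficients if z.shape[1] else 0.0)
    if phenos.trait_family == "gaussian":
        mu = eta
        s_test = (phenos.y[test] - mu) / np.sqrt(fit.dispersion)
    else:
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        s_test = (phenos.y[test] - mu) / np.sqrt(mu * (1 - mu))
    return s_train, s_test


def cross_validated_search(
    genos: GenotypeMatrix,
    scores: ScoreVector,
    config: SearchConfig,
    phenos: PhenotypeTable | None = None,
) -> list[ModelResult]:
    """Rank every k-SNP combination by cross-validated (fuzzy) balanced accuracy.

    Returns ModelResults sorted by CVC (descending), then mean testing
    BA (descending), then lexicographic combination — the best model is
    first.  ``phenos`` is only needed for stratified folds or per-fold
    score refitting.
    """
    p = genos.n_snps
    k = config.order
    if p < k:
        raise ValueError(f"need at least {k} SNPs, have {p}")
    n_combos = comb(p, k)
    if n_combos > config.combination_budget:
        raise ValueError(
            f"C({p},{k}) = {n_combos} combinations exceeds the budget of "
            f"{config.combination_budget}; pre-filter to a candidate SNP panel"
        )
    snps_sorted = sorted(genos.snps)
    combos = list(iter_combinations(snps_sorted, k))
    col_of = {s: genos.snp_index(s) for s in genos.snps}

    labels = None
    if config.stratify:
        if phenos is None:
            raise ValueError("stratified folds require the phenotype table")
        labels = phenos.y
    folds = make_folds(
        genos.n_samples, config.n_folds, labels=labels, seed=config.seed, stratify=config.stratify
    )

    values = genos.values
    s_full = scores.s
    train_ba = np.zeros((n_combos, config.n_folds))
    test_ba = np.full((n_combos, config.n_folds), np.nan)
    wins = np.zeros(n_combos, dtype=int)

    for f_id in range(config.n_folds):
        test_mask = folds == f_id
        train_mask = ~test_mask
        if config.refit_scores_per_fold:
            if phenos is None:
                raise ValueError("per-fold refitting requires the phenotype table")
            s_train, s_test = _fold_scores(phenos, config, train_mask, test_mask)
        else:
            s_train, s_test = s_full[train_mask], s_full[test_mask]
        f = search_membership(config, s_train)
        for c_id, combo in enumerate(combos):
            cols = values[:, [col_of[s] for s in combo]]
            tr_ok = train_mask & ~np.any(cols == MISSING, axis=1)
            te_ok = test_mask & ~np.any(cols == MISSING, axis=1)
            if config.refit_scores_per_fold:
                s_tr = s_train[tr_ok[train_mask]]
                s_te = s_test[te_ok[test_mask]]
            else:
                s_tr = s_full[tr_ok]
                s_te = s_full[te_ok]
            table = table_from_arrays(combo, cols[tr_ok], s_tr)
            train_ba[c_id, f_id] = balanced_accuracy(fuzzy_confusion(table, f))
            test_ba[c_id, f_id] = _test_ba(table, f, cols[te_ok], s_te)
        # fold winner: highest training BA, lexicographically first on ties
        wins[int(np.argmax(train_ba[:, f_id]))] += 1

    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN test columns
        for c_id, combo in enumerate(combos):
            results.append(
                ModelResult(
                    combination=combo,
                    ba_train=float(np.mean(train_ba[c_id])),
                    ba_test=float(np.nanmean(test_ba[c_id])),
                    cvc=int(wins[c_id]),
                    fold_train_ba=train_ba[c_id].copy(),
                    fold_test_ba=test_ba[c_id].copy(),
                )
            )
    results.sort(key=lambda r: (-r.cvc, -(r.ba_test if np.isfinite(r.ba_test) else -1), r.combination))
    return results


def run_method(
    genos: GenotypeMatrix, phenos: PhenotypeTable, config: SearchConfig
) -> list[ModelResult]:
    """Dispatch one of {mdr, fmdr, gmdr, fgmdr} end to end.

    Covariate-blind methods (mdr, fmdr) refit the null model without
    covariates; supplying covariates to them triggers a warning, not an
    error.
    """
    has_covs = phenos.covariates.shape[1] > 0
    if not config.uses_covariates and has_covs:
        warnings.warn(
            f"method {config.method!r} ignores covariates by construction", stacklevel=2
        )
    scores = scores_for(
        phenos, use_covariates=config.uses_covariates, variant=config.studentization
    )
    return cross_validated_search(genos, scores, config, phenos=phenos)
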
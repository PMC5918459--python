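"""Genotype-cell contingency tables and (fuzzy) balanced accuracy.

A k-SNP combination partitions samples into 3^k genotype cells.  Each
nonempty cell j carries the sum of its nonnegative scores (S+1_j), the
magnitude of the sum of its negative scores (|S+0_j|) and its mean
score (S._j).  Membership-weighted sums of the two score masses give a
fuzzy confusion table

    TP = sum_j S+1_j * mu_H(S._j)    FN = sum_j S+1_j * mu_L(S._j)
    FP = sum_j |S+0_j| * mu_H(S._j)  TN = sum_j |S+0_j| * mu_L(S._j)

and the fuzzy balanced accuracy BA = (TP/(TP+FN) + TN/(TN+FP)) / 2.
With indicator membership this is exactly the crisp GMDR balanced
accuracy; with an intercept-only score model it is the (F)MDR one.

The negative-score sum enters all four measures as its magnitude: a
signed convention would make FP/TN negative and push BA outside [0, 1],
breaking the sensitivity/specificity analogy the fuzzy measures draw.

Cell j is the mixed-radix base-3 encoding of the genotype tuple in
combination order (first SNP most significant), so cell order matches
the AABB..aabb enumeration used in cell reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from fgmdr.glm_scores import ScoreVector
from fgmdr.io_formats import MISSING, GenotypeMatrix
from fgmdr.membership import MembershipFunction, mu_high

MAX_ORDER = 5


class DegenerateCellError(ValueError):
    """Cell structure leaves a confusion-table denominator empty."""


@dataclass
class CellTable:
    """Per-cell score aggregates for one SNP combination.

    Arrays are indexed by cell id j in [0, 3^k); empty cells have
    count 0 and NaN mean.
    """

    combination: tuple[str, ...]
    count: np.ndarray  # samples per cell
    pos_sum: np.ndarray  # S+1_j  (sum of scores >= 0)
    neg_mag: np.ndarray  # |S+0_j| (magnitude of the sum of scores < 0)
    mean_score: np.ndarray  # S._j, NaN for empty cells

    @property
    def order(self) -> int:
        return len(self.combination)

    @property
    def n_cells(self) -> int:
        return 3**self.order

    @property
    def nonempty(self) -> np.ndarray:
        return self.count > 0


@dataclass
class FuzzyConfusion:
    tp: float
    fn: float
    fp: float
    tn: float


def cell_index(genotype_columns: np.ndarray) -> np.ndarray:
    """Mixed-radix base-3 cell id for each sample's genotype tuple."""
    cols = np.atleast_2d(np.asarray(genotype_columns))
    if cols.ndim != 2:
        raise ValueError("expected an (n, k) genotype array")
    k = cols.shape[1]
    weights = 3 ** np.arange(k - 1, -1, -1)
    return cols @ weights


def build_cell_table(
    genos: GenotypeMatrix, combination: Sequence[str], scores: ScoreVector
) -> CellTable:
    """Aggregate scores into the 3^k cells of a SNP combination.

    Samples missing any genotype in the combination are excluded from
    this table only.
    """
    combination = tuple(combination)
    k = len(combination)
    if not 1 <= k <= MAX_ORDER:
        raise ValueError(f"interaction order must be in [1, {MAX_ORDER}], got {k}")
    cols = genos.columns(combination)
    s = scores.s
    if len(s) != genos.n_samples:
        raise ValueError("score vector does not match genotype matrix")
    complete = ~np.any(cols == MISSING, axis=1)
    return table_from_arrays(combination, cols[complete], s[complete])


def table_from_arrays(
    combination: tuple[str, ...], geno_cols: np.ndarray, s: np.ndarray
) -> CellTable:
    """Cell table from raw arrays (no missing entries).  Hot path for searches."""
    n_cells = 3 ** len(combination)
    idx = cell_index(geno_cols)
    count = np.bincount(idx, minlength=n_cells).astype(float)
    pos_sum = np.bincount(idx, weights=np.where(s >= 0, s, 0.0), minlength=n_cells)
    neg_mag = -np.bincount(idx, weights=np.where(s < 0, s, 0.0), minlength=n_cells)
    total = pos_sum - neg_mag
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return CellTable(
        combination=combination, count=count, pos_sum=pos_sum, neg_mag=neg_mag, mean_score=mean
    )


def fuzzy_confusion(table: CellTable, f: MembershipFunction) -> FuzzyConfusion:
    """Membership-weighted confusion sums over nonempty cells.

    Empty cells have no mean score and contribute nothing to any term.
    """
    ne = table.nonempty
    if not ne.any():
        raise DegenerateCellError("all cells empty")
    muh = np.asarray(mu_high(f, table.mean_score[ne]))
    mul = 1.0 - muh
    pos = table.pos_sum[ne]
    neg = table.neg_mag[ne]
    return FuzzyConfusion(
        tp=float(pos @ muh),
        fn=float(pos @ mul),
        fp=float(neg @ muh),
        tn=float(neg @ mul),
    )


def balanced_accuracy(c: FuzzyConfusion) -> float:
    """(sensitivity + specificity) / 2 from a (fuzzy) confusion table."""
    if c.tp + c.fn <= 0:
        raise DegenerateCellError("no positive-score mass: sensitivity undefined")
    if c.fp + c.tn <= 0:
        raise DegenerateCellError("no negative-score mass: specificity undefined")
    sen = c.tp / (c.tp + c.fn)
    spe = c.tn / (c.tn + c.fp)
    return (sen + spe) / 2.0


def classify_cells(table: CellTable, T: float = 0.0) -> list[str]:
    """Crisp per-cell label: 'H' iff mean score >= T, 'L' otherwise, 'empty' if unobserved."""
    labels = []
    for j in range(table.n_cells):
        if table.count[j] == 0:
            labels.append("empty")
        else:
            labels.append("H" if table.mean_score[j] >= T else "L")
    return labels


def genotype_labels(k: int) -> list[str]:
    """Letter labels AABB..aabb: locus i uses the i-th alphabet letter,
    0 -> homozygous major (XX), 1 -> heterozygous (Xx), 2 -> homozygous minor (xx)."""
    letters = [chr(ord("A") + i) for i in range(k)]
    per_locus = [[L + L, L + L.lower(), L.lower() + L.lower()] for L in letters]
    return ["".join(parts) for parts in product(*per_locus)]


def cell_report(table: CellTable, f: MembershipFunction) -> pd.DataFrame:
    """Tabular per-cell report: the numeric content of a cell-diagram panel.

    One row per cell with the genotype label, sample count, positive and
    negative score mass, mean score and high-risk membership degree.
    """
    labels = genotype_labels(table.order)
    muh = np.full(table.n_cells, np.nan)
    ne = table.nonempty
    if ne.any():
        muh[ne] = np.asarray(mu_high(f, table.mean_score[ne]))
    return pd.DataFrame(
        {
            "genotype": labels,
            "count": table.count.astype(int),
            "pos_sum": table.pos_sum,
            "neg_mag": table.neg_mag,
            "mean_score": table.mean_score,
            "mu_high": muh,
        }
    )


def write_cell_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6f")
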
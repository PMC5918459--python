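import numpy as np
import pytest

from conftest import random_instance
from fgmdr.fixtures import brute_force_ba
from fgmdr.glm_scores import ScoreVector
from fgmdr.io_formats import GenotypeMatrix
from fgmdr.mdr_core import (
    CellTable,
    DegenerateCellError,
    FuzzyConfusion,
    balanced_accuracy,
    build_cell_table,
    cell_report,
    classify_cells,
    fuzzy_confusion,
    genotype_labels,
)
from fgmdr.membership import MembershipFunction


def _genos(values):
    values = np.asarray(values, dtype=np.int8)
    return GenotypeMatrix(
        samples=[f"I{i}" for i in range(values.shape[0])],
        snps=[f"SNP{j + 1}" for j in range(values.shape[1])],
        values=values,
    )


def _scores(s):
    return ScoreVector(s=np.asarray(s, float), family="gaussian")


def test_single_locus_hand_aggregation():
    genos = _genos([[0], [0], [1], [2]])
    table = build_cell_table(genos, ["SNP1"], _scores([1.0, -1.0, 2.0, -3.0]))
    assert table.count.tolist() == [2, 1, 1]
    assert table.pos_sum.tolist() == [1.0, 2.0, 0.0]
    assert table.neg_mag.tolist() == [1.0, 0.0, 3.0]
    assert table.mean_score[0] == 0.0
    assert table.mean_score[1] == 2.0
    assert table.mean_score[2] == -3.0


def test_counts_conserved_and_missing_excluded(rng):
    genos, scores = random_instance(rng, n=60, p=3, missing_rate=0.15)
    table = build_cell_table(genos, ["SNP1", "SNP3"], scores)
    complete = np.sum(~np.any(genos.values[:, [0, 2]] == -1, axis=1))
    assert int(table.count.sum()) == complete
    # identity pos - neg == count * mean on nonempty cells
    ne = table.nonempty
    assert np.allclose(
        table.pos_sum[ne] - table.neg_mag[ne], table.count[ne] * table.mean_score[ne]
    )


def test_unknown_snp_and_bad_order_rejected(rng):
    genos, scores = random_instance(rng, n=10, p=2)
    with pytest.raises(KeyError):
        build_cell_table(genos, ["nope"], scores)
    with pytest.raises(ValueError, match="order"):
        build_cell_table(genos, [], scores)


def test_fuzzy_confusion_hand_example():
    # two nonempty cells with pos mass (3, 1), neg mass (1, 2) and means
    # +-1/3; the band (-1, 1) gives mu_H = 0.8 and 0.2 exactly at those
    # means, so the four sums are tp=2.6, fn=1.4, fp=1.2, tn=1.8
    table = CellTable(
        combination=("A",),
        count=np.array([6.0, 3.0, 0.0]),
        pos_sum=np.array([3.0, 1.0, 0.0]),
        neg_mag=np.array([1.0, 2.0, 0.0]),
        mean_score=np.array([1 / 3, -1 / 3, np.nan]),
    )
    c = fuzzy_confusion(table, MembershipFunction.sigmoid(-1.0, 1.0))
    assert (c.tp, c.fn) == (pytest.approx(2.6), pytest.approx(1.4))
    assert (c.fp, c.tn) == (pytest.approx(1.2), pytest.approx(1.8))
    assert balanced_accuracy(c) == pytest.approx((0.65 + 0.60) / 2)
    assert balanced_accuracy(c) == pytest.approx(0.625)


def test_indicator_confusion_is_crisp_split():
    genos = _genos([[0], [0], [1], [2]])
    table = build_cell_table(genos, ["SNP1"], _scores([1.0, -1.0, 2.0, -3.0]))
    c = fuzzy_confusion(table, MembershipFunction.indicator(0.0))
    # H cells: means 0.0 and 2.0; L cell: mean -3.0
    assert c.tp == 3.0  # pos mass in H cells
    assert c.fn == 0.0
    assert c.fp == 1.0  # neg mass in H cells
    assert c.tn == 3.0


def test_half_membership_balances_confusion(rng):
    genos, scores = random_instance(rng, n=50, p=2)
    table = build_cell_table(genos, ["SNP1", "SNP2"], scores)
    # a huge band puts every cell mean near the midpoint -> mu close to 1/2
    f = MembershipFunction.sigmoid(-1e12, 1e12)
    c = fuzzy_confusion(table, f)
    assert c.tp == pytest.approx(c.fn, rel=1e-6)
    assert c.fp == pytest.approx(c.tn, rel=1e-6)
    assert balanced_accuracy(c) == pytest.approx(0.5, abs=1e-6)


def test_complementarity_invariant(rng):
    genos, scores = random_instance(rng, n=80, p=3)
    table = build_cell_table(genos, ["SNP2", "SNP3"], scores)
    f = MembershipFunction.sigmoid(-0.3, 0.4)
    c = fuzzy_confusion(table, f)
    assert c.tp + c.fn == pytest.approx(table.pos_sum.sum(), abs=1e-12)
    assert c.fp + c.tn == pytest.approx(table.neg_mag.sum(), abs=1e-12)


def test_degenerate_one_sided_mass_errors():
    genos = _genos([[0], [1]])
    table = build_cell_table(genos, ["SNP1"], _scores([1.0, 2.0]))
    with pytest.raises(DegenerateCellError, match="negative-score"):
        balanced_accuracy(fuzzy_confusion(table, MembershipFunction.indicator(0.0)))


def test_classify_cells_tie_goes_high():
    genos = _genos([[0], [0], [1], [2]])
    table = build_cell_table(genos, ["SNP1"], _scores([1.0, -1.0, -0.001, 5.0]))
    labels = classify_cells(table, T=0.0)
    assert labels[0] == "H"  # mean exactly 0 is nonnegative -> high risk
    assert labels[1] == "L"  # mean -0.001
    assert labels[2] == "H"


def test_classify_marks_empty_cells(rng):
    genos = _genos([[0, 0], [1, 1]])
    table = build_cell_table(genos, ["SNP1", "SNP2"], _scores([1.0, -1.0]))
    labels = classify_cells(table)
    assert labels.count("empty") == 7


def test_ba_invariant_under_snp_order_and_score_scaling(rng):
    genos, scores = random_instance(rng, n=70, p=3)
    f = MembershipFunction.sigmoid(-0.5, 0.5)
    t_ab = build_cell_table(genos, ["SNP1", "SNP2"], scores)
    t_ba = build_cell_table(genos, ["SNP2", "SNP1"], scores)
    assert balanced_accuracy(fuzzy_confusion(t_ab, f)) == pytest.approx(
        balanced_accuracy(fuzzy_confusion(t_ba, f)), abs=1e-14
    )
    # scaling scores and band together changes nothing
    c = 3.7
    scaled = ScoreVector(s=scores.s * c, family="gaussian")
    f_scaled = MembershipFunction.sigmoid(-0.5 * c, 0.5 * c)
    t_s = build_cell_table(genos, ["SNP1", "SNP2"], scaled)
    assert balanced_accuracy(fuzzy_confusion(t_s, f_scaled)) == pytest.approx(
        balanced_accuracy(fuzzy_confusion(t_ab, f)), abs=1e-12
    )


def test_fuzzy_to_crisp_limit(rng):
    genos, scores = random_instance(rng, n=100, p=2)
    table = build_cell_table(genos, ["SNP1", "SNP2"], scores)
    crisp = balanced_accuracy(fuzzy_confusion(table, MembershipFunction.indicator(0.0)))
    prev_gap = np.inf
    for width in (1e-2, 1e-5, 1e-9):
        f = MembershipFunction.sigmoid(-width, width)
        fuzzy = balanced_accuracy(fuzzy_confusion(table, f))
        gap = abs(fuzzy - crisp)
        assert gap <= prev_gap + 1e-15
        prev_gap = gap
    assert prev_gap < 1e-6


def test_cell_report_layout_and_membership_column(rng):
    genos, scores = random_instance(rng, n=90, p=2)
    table = build_cell_table(genos, ["SNP1", "SNP2"], scores)
    rep = cell_report(table, MembershipFunction.sigmoid(-0.2, 0.2))
    assert len(rep) == 9
    assert rep["genotype"].tolist() == genotype_labels(2)
    assert rep["genotype"].iloc[0] == "AABB"
    assert rep["genotype"].iloc[-1] == "aabb"
    vals = rep["mu_high"].dropna()
    assert ((vals >= 0) & (vals <= 1)).all()
    crisp = cell_report(table, MembershipFunction.indicator(0.0))["mu_high"].dropna()
    assert set(crisp.unique()) <= {0.0, 1.0}


def test_matches_brute_force_oracle(rng):
    for _ in range(25):
        genos, scores = random_instance(rng, n=40, p=3, missing_rate=0.1)
        f = MembershipFunction.sigmoid(-0.4, 0.7)
        table = build_cell_table(genos, ["SNP1", "SNP3"], scores)
        ba = balanced_accuracy(fuzzy_confusion(table, f))
        assert ba == pytest.approx(
            brute_force_ba(genos, ["SNP1", "SNP3"], scores, f), abs=1e-12
        )
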
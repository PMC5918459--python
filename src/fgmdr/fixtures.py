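"""Tiny deterministic datasets and a brute-force balanced-accuracy oracle.

Everything here exists to check the production modules from the
outside: ``brute_force_ba`` recomputes the fuzzy balanced accuracy with
plain per-sample Python loops and dictionaries, sharing no code with
the vectorised implementation, and the toy datasets plant known signal
(or none) for recovery checks.  Production modules never import this
module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fgmdr.io_formats import GenotypeMatrix, PhenotypeTable
from fgmdr.membership import MembershipFunction


def toy_dataset(kind: str, seed: int = 0) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Small named datasets with known structure.

    separable
        60 samples, 4 SNPs; a two-locus XOR pattern on SNP1/SNP2
        (trait 1 iff exactly one locus carries a minor allele)
        determines a binary trait exactly.
    null
        binary labels independent of all genotypes.
    covariate_confounded
        gaussian trait driven by a strong covariate plus a weak
        two-locus genotype effect on SNP1/SNP2 — the signal a
        covariate-blind method tends to miss.
    """
    rng = np.random.default_rng(seed)
    n, p = 60, 4
    g = rng.choice(3, size=(n, p), p=[0.25, 0.5, 0.25]).astype(np.int8)
    snps = [f"SNP{j + 1}" for j in range(p)]
    samples = [f"I{i + 1}" for i in range(n)]
    covs = pd.DataFrame()
    if kind == "separable":
        y = (((g[:, 0] > 0).astype(int) + (g[:, 1] > 0).astype(int)) == 1).astype(float)
        if len(np.unique(y)) < 2:  # re-draw pathological seeds
            return toy_dataset(kind, seed + 10_007)
        family = "binomial"
    elif kind == "null":
        y = rng.integers(0, 2, size=n).astype(float)
        if len(np.unique(y)) < 2:
            return toy_dataset(kind, seed + 10_007)
        family = "binomial"
    elif kind == "covariate_confounded":
        z = rng.normal(0, 1, size=n)
        xor = (((g[:, 0] > 0).astype(int) + (g[:, 1] > 0).astype(int)) == 1).astype(float)
        y = 2.0 * z + 0.8 * xor + rng.normal(0, 0.5, size=n)
        family = "gaussian"
        covs = pd.DataFrame({"z": z})
    else:
        raise ValueError(f"unknown toy dataset kind {kind!r}")
    genos = GenotypeMatrix(samples=samples, snps=snps, values=g)
    phenos = PhenotypeTable(samples=samples, y=y, trait_family=family, covariates=covs)
    return genos, phenos


def brute_force_ba(
    genos: GenotypeMatrix, combination, scores, membership: MembershipFunction
) -> float:
    """Fuzzy balanced accuracy by direct per-sample loops (oracle).

    Independent of the vectorised cell-table implementation: cells are
    a dict keyed by genotype tuples, membership is evaluated inline
    from the piecewise formula, and the four confusion sums are
    accumulated scalar by scalar.
    """
    s = scores.s if hasattr(scores, "s") else np.asarray(scores, dtype=float)
    cells: dict[tuple, list] = {}
    cols = [genos.snp_index(snp) for snp in combination]
    for i in range(genos.n_samples):
        key = tuple(int(genos.values[i, c]) for c in cols)
        if any(v < 0 for v in key):  # missing genotype: sample excluded
            continue
        cells.setdefault(key, []).append(float(s[i]))
    tp = fn = fp = tn = 0.0
    for vals in cells.values():
        pos = sum(v for v in vals if v >= 0)
        neg = -sum(v for v in vals if v < 0)
        mean = (pos - neg) / len(vals)
        if membership.kind == "indicator" or membership.t_l == membership.t_h:
            thr = membership.T if membership.kind == "indicator" else membership.t_l
            muh = 1.0 if mean >= thr else 0.0
        elif mean <= membership.t_l:
            muh = 0.0
        elif mean >= membership.t_h:
            muh = 1.0
        else:
            ratio = (mean - membership.t_h) / (mean - membership.t_l)
            muh = 1.0 / (1.0 + ratio * ratio)
        tp += pos * muh
        fn += pos * (1.0 - muh)
        fp += neg * muh
        tn += neg * (1.0 - muh)
    if tp + fn <= 0 or fp + tn <= 0:
        raise ValueError("degenerate: one-sided score mass")
    return (tp / (tp + fn) + tn / (tn + fp)) / 2.0
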
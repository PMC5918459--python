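"""Detection-power estimation and paired method comparison.

Power is the fraction of simulation replicates in which the true causal
SNP pair attains the strictly highest (fuzzy) balanced accuracy among
all C(p, 2) two-locus models — ties count as misses.  Replicates are
ranked by full-data training BA by default; cross-validated ranking is
available via ``with_cv``.  Replicate seeds are derived as
``base_seed + r`` so that methods evaluated on the same (scenario,
model, base_seed) triple see identical data, which makes per-model
power differences exactly paired for the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as iter_combinations

import numpy as np
from scipy import stats

from fgmdr.glm_scores import scores_for
from fgmdr.mdr_core import table_from_arrays
from fgmdr.membership import MembershipFunction, mu_high, null_noise_thresholds
from fgmdr.model_search import METHODS, SearchConfig, cross_validated_search
from fgmdr.simulator import PenetranceModel, SimulatedDataset, simulate_scenario1, simulate_scenario2, simulate_scenario3


@dataclass
class PowerResult:
    method: str
    scenario: int
    pattern: str
    maf: float
    heritability: float
    n_replicates: int
    hits: np.ndarray  # per-replicate 0/1 flags

    @property
    def power(self) -> float:
        return float(np.mean(self.hits))


def _pair_ba(counts, pos, neg, f: MembershipFunction) -> float:
    """BA of one 9-cell table from its aggregate arrays (hot path)."""
    ne = counts > 0
    if not ne.any():
        return np.nan
    mean = (pos[ne] - neg[ne]) / counts[ne]
    muh = np.asarray(mu_high(f, mean))
    mul = 1.0 - muh
    p, q = pos[ne], neg[ne]
    tp, fn = p @ muh, p @ mul
    fp, tn = q @ muh, q @ mul
    if tp + fn <= 0 or fp + tn <= 0:
        return np.nan
    return (tp / (tp + fn) + tn / (tn + fp)) / 2.0


def all_pair_bas(
    values: np.ndarray, s: np.ndarray, fuzzy: bool, soft_se: float = 4.0, T: float = 0.0
):
    """Full-data BA for every SNP pair; returns (pair index list, BA array).

    Fuzzy mode uses one a-priori null-noise band for every pair
    (:func:`fgmdr.membership.null_noise_thresholds`): the band must be
    common across pairs for their balanced accuracies to be comparable.
    """
    n, p = values.shape
    pairs = list(iter_combinations(range(p), 2))
    if fuzzy:
        sd = float(np.std(s))
        if sd > 0:
            t_l, t_h = null_noise_thresholds(sd, n, order=2, soft_se=soft_se)
            f = MembershipFunction.sigmoid(t_l, t_h)
        else:
            f = MembershipFunction.indicator(T)
    else:
        f = MembershipFunction.indicator(T)
    s_pos = np.where(s >= 0, s, 0.0)
    s_neg = np.where(s < 0, -s, 0.0)
    g = values.astype(np.int64)
    bas = np.empty(len(pairs))
    for m, (i, j) in enumerate(pairs):
        idx = 3 * g[:, i] + g[:, j]
        counts = np.bincount(idx, minlength=9).astype(float)
        pos = np.bincount(idx, weights=s_pos, minlength=9)
        neg = np.bincount(idx, weights=s_neg, minlength=9)
        bas[m] = _pair_ba(counts, pos, neg, f)
    return pairs, bas


def _hit_from_bas(pairs, bas, causal_pair) -> int:
    causal = tuple(sorted(causal_pair))
    m = pairs.index(causal)
    ba_c = bas[m]
    if not np.isfinite(ba_c):
        return 0
    others = np.delete(bas, m)
    # strictly highest; ties are misses
    return int(np.all(ba_c > others[np.isfinite(others)])) if np.isfinite(others).any() else 1


def replicate_hits(dataset: SimulatedDataset, methods=METHODS, soft_se: float = 4.0, T: float = 0.0) -> dict:
    """Hit flags for several methods on one replicate, sharing genotype work.

    The four methods need only two score vectors (with / without the
    covariate) and two membership modes, so evaluating them together
    costs little more than one method alone.
    """
    need_cov = any(m in ("gmdr", "fgmdr") for m in methods)
    need_plain = any(m in ("mdr", "fmdr") for m in methods)
    score_vec = {}
    if need_cov:
        score_vec[True] = scores_for(dataset.phenotype, use_covariates=True).s
    if need_plain:
        score_vec[False] = scores_for(dataset.phenotype, use_covariates=False).s
    out = {}
    cache = {}
    for method in methods:
        use_cov = method in ("gmdr", "fgmdr")
        fuzzy = method in ("fmdr", "fgmdr")
        key = (use_cov, fuzzy)
        if key not in cache:
            pairs, bas = all_pair_bas(
                dataset.genotypes.values, score_vec[use_cov], fuzzy, soft_se, T
            )
            cache[key] = _hit_from_bas(pairs, bas, dataset.causal_pair)
        out[method] = cache[key]
    return out


def replicate_hit(
    dataset: SimulatedDataset,
    method: str,
    soft_se: float = 4.0,
    T: float = 0.0,
    with_cv: bool = False,
    n_folds: int = 10,
) -> int:
    """1 iff the causal pair attains the strictly highest BA for ``method``."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if with_cv:
        config = SearchConfig(order=2, n_folds=n_folds, method=method, soft_se=soft_se,
                              crisp_threshold=T, seed=dataset.seed)
        scores = scores_for(dataset.phenotype, use_covariates=config.uses_covariates)
        results = cross_validated_search(dataset.genotypes, scores, config, phenos=dataset.phenotype)
        best = results[0]
        causal = tuple(sorted(dataset.causal_snps))
        runner_up_tied = len(results) > 1 and (results[1].cvc, results[1].ba_test) == (
            best.cvc, best.ba_test
        )
        return int(tuple(sorted(best.combination)) == causal and not runner_up_tied)
    return replicate_hits(dataset, methods=(method,), soft_se=soft_se, T=T)[method]


_SCENARIOS = {1: simulate_scenario1, 2: simulate_scenario2, 3: simulate_scenario3}


def simulate_replicate(model: PenetranceModel, scenario: int, seed: int, n: int = 2000, p: int = 100,
                       **kwargs) -> SimulatedDataset:
    if scenario not in _SCENARIOS:
        raise ValueError(f"scenario must be 1, 2 or 3, got {scenario}")
    if scenario == 3:
        return simulate_scenario3(model, n_cases=n // 2, n_controls=n - n // 2, p=p, seed=seed, **kwargs)
    return _SCENARIOS[scenario](model, n=n, p=p, seed=seed, **kwargs)


def estimate_power(
    method: str,
    scenario: int,
    model: PenetranceModel,
    n_replicates: int = 100,
    base_seed: int = 0,
    n: int = 2000,
    p: int = 100,
    soft_se: float = 4.0,
    T: float = 0.0,
    with_cv: bool = False,
) -> PowerResult:
    """Monte-Carlo power of one method under one scenario and penetrance model.

    Replicate r uses seed ``base_seed + r``; per-replicate flags are
    retained so that runs with a shared base seed pair exactly.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    hits = np.empty(n_replicates, dtype=int)
    for r in range(n_replicates):
        ds = simulate_replicate(model, scenario, seed=base_seed + r, n=n, p=p)
        hits[r] = replicate_hit(ds, method, soft_se=soft_se, T=T, with_cv=with_cv)
    return PowerResult(
        method=method, scenario=scenario, pattern=model.pattern, maf=model.maf,
        heritability=model.heritability, n_replicates=n_replicates, hits=hits,
    )


def estimate_powers_shared(
    scenario: int,
    model: PenetranceModel,
    n_replicates: int = 100,
    base_seed: int = 0,
    n: int = 2000,
    p: int = 100,
    methods=METHODS,
    soft_se: float = 4.0,
    T: float = 0.0,
) -> dict[str, PowerResult]:
    """All methods on identical replicates (one simulation per replicate)."""
    hits = {m: np.empty(n_replicates, dtype=int) for m in methods}
    for r in range(n_replicates):
        ds = simulate_replicate(model, scenario, seed=base_seed + r, n=n, p=p)
        flags = replicate_hits(ds, methods=methods, soft_se=soft_se, T=T)
        for m in methods:
            hits[m][r] = flags[m]
    return {
        m: PowerResult(
            method=m, scenario=scenario, pattern=model.pattern, maf=model.maf,
            heritability=model.heritability, n_replicates=n_replicates, hits=hits[m],
        )
        for m in methods
    }


def compare_methods(results_a, results_b, alternative: str = "two-sided"):
    """Wilcoxon signed-rank test on per-model power differences.

    ``results_a`` and ``results_b`` are PowerResult sequences over the
    same penetrance models with shared replicate seeds.  Zero
    differences are dropped (the conventional treatment); fewer than
    two nonzero differences is an error.
    """
    results_a, results_b = list(results_a), list(results_b)
    if len(results_a) != len(results_b):
        raise ValueError("paired comparison needs result sets of equal length")
    for ra, rb in zip(results_a, results_b):
        if (ra.scenario, ra.pattern, ra.maf, ra.heritability) != (
            rb.scenario, rb.pattern, rb.maf, rb.heritability,
        ):
            raise ValueError("result sets are not over the same models")
    diffs = np.array([ra.power - rb.power for ra, rb in zip(results_a, results_b)])
    nonzero = diffs[diffs != 0]
    if len(nonzero) < 2:
        raise ValueError(
            f"only {len(nonzero)} nonzero power difference(s); signed-rank test undefined"
        )
    stat, pvalue = stats.wilcoxon(nonzero, alternative=alternative)
    return {"statistic": float(stat), "pvalue": float(pvalue), "n_nonzero": int(len(nonzero)),
            "mean_difference": float(np.mean(diffs))}
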
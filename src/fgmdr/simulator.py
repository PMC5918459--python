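"""Two-locus penetrance-model simulation of epistatic traits.

A penetrance model is a 3x3 table f(g1, g2) of trait propensities for
the genotype combinations of two causal SNPs.  The generator builds
tables with *no marginal effect*: under Hardy-Weinberg weights
w = ((1-q)^2, 2q(1-q), q^2) at minor allele frequency q, every
HWE-weighted row mean and column mean equals the baseline, so neither
locus is detectable on its own and only the joint model carries signal.

Construction: f = b + d * P, where b is a constant baseline (0.5), and
P is an outer product u v^T of per-locus contrast vectors with
HWE-weighted mean zero — which makes all weighted marginals of P vanish
identically.  The scale d is solved so the broad-sense heritability of
the table,

    h^2 = Var_w(f) / (K (1 - K)),   K = E_w[f] = b,

matches the target (the standard definition for binary-disease
penetrance tables, with Bernoulli noise variance K(1-K) as the
environmental term).

Three trait scenarios share the genetic effect X_i ~ Normal(f(g1, g2), 0.1)
and a covariate Z_i ~ Normal(0, 0.7):

1. continuous:      Y = a + b*X + g*Z + e,  e ~ Normal(0, 1)
2. median split:    latent Y as scenario 1 with e ~ Normal(0, 0.5);
                    binary trait = [Y > median(Y)], giving an exactly
                    balanced case-control sample at even n
3. logit model:     logit P(Y=1) = a + b*X + g*Z + e with b = 0.5 and
                    e ~ Normal(0, 2); cases and controls accumulated by
                    rejection until both quotas are met

Defaults follow n = 2000 samples, p = 100 SNPs, coefficients b = g = 1
(b = 0.5 in scenario 3), a = 0.  Non-causal SNPs are independent HWE
draws with per-SNP MAF uniform in [0.05, 0.5].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fgmdr.io_formats import GenotypeMatrix, PhenotypeTable
import pandas as pd

#: per-locus zero-mean contrast shapes, before HWE-weight centering;
#: each pattern names the (u, v) seed shapes whose outer product forms
#: the epistasis table
PATTERNS = {
    # both loci linear in allele count -> product epistasis ("xor"-like
    # checkerboard of signs after centering)
    "xor": ((0.0, 1.0, 2.0), (0.0, 1.0, 2.0)),
    # heterozygote-vs-homozygote contrast on both loci
    "checkerboard": ((1.0, -1.0, 1.0), (1.0, -1.0, 1.0)),
    # linear x heterozygote mix
    "linear_het": ((0.0, 1.0, 2.0), (1.0, -1.0, 1.0)),
    # dominant-coded contrast on both loci
    "dominant": ((0.0, 1.0, 1.0), (0.0, 1.0, 1.0)),
    # recessive-coded contrast on both loci
    "recessive": ((0.0, 0.0, 1.0), (0.0, 0.0, 1.0)),
}


@dataclass
class PenetranceModel:
    """3x3 penetrance table with its MAF and heritability."""

    table: np.ndarray
    maf: float
    heritability: float
    pattern: str = ""

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (3, 3):
            raise ValueError("penetrance table must be 3x3")
        if np.any(self.table < 0) or np.any(self.table > 1):
            raise ValueError("penetrance values must lie in [0, 1]")

    @property
    def hwe_weights(self) -> np.ndarray:
        return hwe_proportions(self.maf)

    def marginal_means(self) -> tuple[np.ndarray, np.ndarray]:
        """HWE-weighted row and column mean penetrances."""
        w = self.hwe_weights
        return self.table @ w, self.table.T @ w


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    phenotype: PhenotypeTable
    causal_pair: tuple[int, int]
    scenario: int
    seed: int
    model: PenetranceModel = field(repr=False, default=None)

    @property
    def causal_snps(self) -> tuple[str, str]:
        i, j = self.causal_pair
        return (self.genotypes.snps[i], self.genotypes.snps[j])


def hwe_proportions(maf: float) -> np.ndarray:
    """Genotype proportions (P(0), P(1), P(2)) under Hardy-Weinberg equilibrium."""
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def hwe_genotypes(maf: float, n: int, seed) -> np.ndarray:
    """n i.i.d. additive genotype codes under HWE at the given MAF.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if not 0 < maf <= 0.5:
        raise ValueError(f"minor allele frequency must be in (0, 0.5], got {maf}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.choice(3, size=n, p=hwe_proportions(maf)).astype(np.int8)


def table_heritability(table: np.ndarray, maf: float) -> float:
    """Broad-sense heritability of a 3x3 penetrance table under HWE weights.

    Var_w(f) / (K(1-K)) with K the HWE-weighted mean penetrance — the
    usual normalisation for disease penetrance models.
    """
    table = np.asarray(table, dtype=float)
    w = hwe_proportions(maf)
    w2 = np.outer(w, w)
    k = float(np.sum(w2 * table))
    var_g = float(np.sum(w2 * (table - k) ** 2))
    if not 0 < k < 1:
        raise ValueError("mean penetrance must be strictly inside (0, 1)")
    return var_g / (k * (1 - k))


def make_penetrance_model(
    pattern: str, maf: float, heritability: float, baseline: float = 0.5
) -> PenetranceModel:
    """Build a marginal-effect-free penetrance model at a target heritability.

    The named base pattern is centred to HWE-weighted zero mean on each
    locus, combined as an outer product (so all weighted marginals
    vanish), and scaled about ``baseline`` until the table heritability
    hits the target.  Raises if the required scale pushes entries
    outside [0, 1], reporting the attainable maximum.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {sorted(PATTERNS)}")
    if not 0 < maf <= 0.5:
        raise ValueError(f"minor allele frequency must be in (0, 0.5], got {maf}")
    if heritability < 0:
        raise ValueError("heritability must be nonnegative")
    w = hwe_proportions(maf)
    u0, v0 = (np.asarray(v, dtype=float) for v in PATTERNS[pattern])
    u = u0 - float(w @ u0)
    v = v0 - float(w @ v0)
    contrast = np.outer(u, v)
    var_p = float(np.sum(np.outer(w, w) * contrast**2))  # E_w[P]=0 by construction
    if var_p == 0:
        raise ValueError(f"pattern {pattern!r} is degenerate at maf={maf}")
    if heritability == 0:
        d = 0.0
    else:
        # h2 = d^2 var_p / (b(1-b))  (mean stays at b since P has zero mean)
        d = float(np.sqrt(heritability * baseline * (1 - baseline) / var_p))
    table = baseline + d * contrast
    if np.any(table < 0) or np.any(table > 1):
        headroom = min(baseline, 1 - baseline) / float(np.max(np.abs(contrast)))
        h_max = headroom**2 * var_p / (baseline * (1 - baseline))
        raise ValueError(
            f"heritability {heritability} unattainable for pattern {pattern!r} at "
            f"maf={maf}: entries leave [0,1]; maximum attainable is {h_max:.4f}"
        )
    return PenetranceModel(table=table, maf=maf, heritability=heritability, pattern=pattern)


#: the heritability levels of the reference simulation design
STUDY_H2 = (0.01, 0.025, 0.05, 0.1, 0.2, 0.3, 0.4)
#: the two causal-SNP minor allele frequencies of the reference design
STUDY_MAF = (0.2, 0.4)


def study_models() -> list[PenetranceModel]:
    """The study grid of penetrance models: every built-in epistasis
    pattern at each (maf, h2) of the reference design that the pattern
    can attain with penetrances in [0, 1].

    The outer-product construction bounds the attainable heritability
    per (pattern, maf) — e.g. the xor pattern at maf 0.2 cannot exceed
    h2 ~ 0.016 — so the grid is filtered by attainability rather than
    forcing every pattern to every level.
    """
    models = []
    for pattern in sorted(PATTERNS):
        for maf in STUDY_MAF:
            for h2 in STUDY_H2:
                try:
                    models.append(make_penetrance_model(pattern, maf, h2))
                except ValueError:
                    continue
    return models


def load_penetrance_table(path, maf: float) -> PenetranceModel:
    """Load a user-supplied 3x3 penetrance table (tab-delimited, 3 rows).

    Lets published table collections be used verbatim in place of the
    built-in generator.  The heritability is computed from the table.
    """
    table = np.loadtxt(path)
    model = PenetranceModel(table=table, maf=maf, heritability=0.0)
    model.heritability = table_heritability(model.table, maf)
    return model


def _genotype_block(model: PenetranceModel, n: int, p: int, rng: np.random.Generator):
    """Causal-pair + background genotypes. Causal SNPs occupy columns 0 and 1."""
    if p < 2:
        raise ValueError("need at least 2 SNPs for a causal pair")
    g = np.empty((n, p), dtype=np.int8)
    g[:, 0] = hwe_genotypes(model.maf, n, rng)
    g[:, 1] = hwe_genotypes(model.maf, n, rng)
    for j in range(2, p):
        g[:, j] = hwe_genotypes(rng.uniform(0.05, 0.5), n, rng)
    snps = [f"SNP{j + 1}" for j in range(p)]
    return g, snps


def _genetic_effect(model: PenetranceModel, g: np.ndarray, rng: np.random.Generator, sd: float = 0.1):
    """X_i ~ Normal(f(g1_i, g2_i), sd): the penetrance value plus locus-level noise."""
    f_i = model.table[g[:, 0], g[:, 1]]
    return f_i + rng.normal(0.0, sd, size=len(f_i))


def _package(g, snps, y, family, z, scenario, seed, model) -> SimulatedDataset:
    n = g.shape[0]
    samples = [f"I{i + 1}" for i in range(n)]
    covs = pd.DataFrame({"Z": z})
    return SimulatedDataset(
        genotypes=GenotypeMatrix(samples=samples, snps=snps, values=g),
        phenotype=PhenotypeTable(samples=samples, y=y, trait_family=family, covariates=covs),
        causal_pair=(0, 1),
        scenario=scenario,
        seed=seed,
        model=model,
    )


def simulate_scenario1(
    model: PenetranceModel,
    n: int = 2000,
    p: int = 100,
    seed: int = 0,
    alpha: float = 0.0,
    beta: float = 1.0,
    gamma: float = 1.0,
    x_sd: float = 0.1,
    z_sd: float = 0.7,
    eps_sd: float = 1.0,
) -> SimulatedDataset:
    """Continuous trait: Y = a + b*X + g*Z + e with e ~ Normal(0, eps_sd)."""
    rng = np.random.default_rng(seed)
    g, snps = _genotype_block(model, n, p, rng)
    x = _genetic_effect(model, g, rng, x_sd)
    z = rng.normal(0.0, z_sd, size=n)
    y = alpha + beta * x + gamma * z + rng.normal(0.0, eps_sd, size=n)
    return _package(g, snps, y, "gaussian", z, 1, seed, model)


def simulate_scenario2(
    model: PenetranceModel,
    n: int = 2000,
    p: int = 100,
    seed: int = 0,
    alpha: float = 0.0,
    beta: float = 1.0,
    gamma: float = 1.0,
    x_sd: float = 0.1,
    z_sd: float = 0.7,
    eps_sd: float = 0.5,
) -> SimulatedDataset:
    """Binary trait by median split of the scenario-1 latent value (eps_sd 0.5).

    At even n the strict-above-median rule yields an exactly balanced
    1:1 case-control sample (ties have probability zero for the
    continuous latent value).
    """
    rng = np.random.default_rng(seed)
    g, snps = _genotype_block(model, n, p, rng)
    x = _genetic_effect(model, g, rng, x_sd)
    z = rng.normal(0.0, z_sd, size=n)
    latent = alpha + beta * x + gamma * z + rng.normal(0.0, eps_sd, size=n)
    y = (latent > np.median(latent)).astype(float)
    return _package(g, snps, y, "binomial", z, 2, seed, model)


def simulate_scenario3(
    model: PenetranceModel,
    n_cases: int = 1000,
    n_controls: int = 1000,
    p: int = 100,
    seed: int = 0,
    alpha: float = 0.0,
    beta: float = 0.5,
    gamma: float = 1.0,
    x_sd: float = 0.1,
    z_sd: float = 0.7,
    eps_sd: float = 2.0,
    max_draws: int = 2_000_000,
) -> SimulatedDataset:
    """Case-control trait from a logit model with an over-dispersion term.

    logit P(Y=1) = a + b*X + g*Z + e, e ~ Normal(0, eps_sd); individuals
    are drawn from the population and accumulated by rejection until the
    case and control quotas are both met.
    """
    rng = np.random.default_rng(seed)
    kept_g: list[np.ndarray] = []
    kept_z: list[np.ndarray] = []
    kept_y: list[np.ndarray] = []
    need_cases, need_controls = n_cases, n_controls
    drawn = 0
    snps = None
    while need_cases > 0 or need_controls > 0:
        batch = max(256, 2 * (need_cases + need_controls))
        if drawn + batch > max_draws:
            raise RuntimeError(
                f"case/control quota not met within {max_draws} draws "
                f"(still need {need_cases} cases, {need_controls} controls); "
                "the case probability is too extreme"
            )
        drawn += batch
        g, snps = _genotype_block(model, batch, p, rng)
        x = _genetic_effect(model, g, rng, x_sd)
        z = rng.normal(0.0, z_sd, size=batch)
        eta = alpha + beta * x + gamma * z + rng.normal(0.0, eps_sd, size=batch)
        prob = 1.0 / (1.0 + np.exp(-eta))
        y = (rng.random(batch) < prob).astype(float)
        case_idx = np.flatnonzero(y == 1)[:need_cases]
        ctrl_idx = np.flatnonzero(y == 0)[:need_controls]
        keep = np.concatenate([case_idx, ctrl_idx])
        need_cases -= len(case_idx)
        need_controls -= len(ctrl_idx)
        kept_g.append(g[keep])
        kept_z.append(z[keep])
        kept_y.append(y[keep])
    g_all = np.concatenate(kept_g)
    z_all = np.concatenate(kept_z)
    y_all = np.concatenate(kept_y)
    order = np.argsort(-y_all, kind="stable")  # cases first, deterministic
    return _package(g_all[order], snps, y_all[order], "binomial", z_all[order], 3, seed, model)
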
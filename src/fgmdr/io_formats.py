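"""Genotype / phenotype input parsing and result-table output.

Genotypes are additive-coded (0 = homozygous major, 1 = heterozygous,
2 = homozygous minor).  Two input dialects are supported: a plain
delimited sample-by-SNP matrix, and the PLINK ``.raw`` recode dialect
(six leading metadata columns, allele-suffixed SNP headers).  All output
tables are tab-delimited UTF-8 with a single header row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: internal code for a missing genotype call
MISSING = -1

#: tokens accepted as a missing genotype in input files
MISSING_TOKENS = {"NA", "", "-9", "nan", "NaN"}

_PLINK_PREFIX = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class ParseError(ValueError):
    """Malformed input file (bad genotype code, duplicate ids, ...)."""


class AlignmentError(ValueError):
    """Sample sets of two inputs cannot be brought into 1:1 correspondence."""


@dataclass
class GenotypeMatrix:
    """n samples x p SNPs of additive genotype codes.

    ``values`` is an ``int8`` array with entries in {0, 1, 2} or
    :data:`MISSING` (-1).
    """

    samples: list[str]
    snps: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        n, p = self.values.shape
        if len(self.samples) != n or len(self.snps) != p:
            raise ParseError(
                f"identifier lists ({len(self.samples)} samples, {len(self.snps)} SNPs) "
                f"do not match matrix shape {self.values.shape}"
            )
        if len(set(self.samples)) != n:
            raise ParseError("duplicate sample identifiers")
        if len(set(self.snps)) != p:
            raise ParseError("duplicate SNP identifiers")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParseError(
                f"invalid genotype code {self.values[i, j]} at sample "
                f"{self.samples[i]!r}, SNP {self.snps[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def snp_index(self, snp: str) -> int:
        try:
            return self.snps.index(snp)
        except ValueError:
            raise KeyError(f"unknown SNP identifier {snp!r}") from None

    def columns(self, combination: Sequence[str]) -> np.ndarray:
        """Genotype columns for a SNP combination, in the given order."""
        idx = [self.snp_index(s) for s in combination]
        return self.values[:, idx]


@dataclass
class PhenotypeTable:
    """Per-sample trait and covariates, aligned to a genotype matrix."""

    samples: list[str]
    y: np.ndarray
    trait_family: str  # "gaussian" | "binomial"
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.trait_family not in ("gaussian", "binomial"):
            raise ValueError(f"trait_family must be gaussian or binomial, got {self.trait_family!r}")
        if self.y.ndim != 1 or len(self.y) != len(self.samples):
            raise ValueError("trait vector does not match sample list")
        if self.trait_family == "binomial":
            uniq = set(np.unique(self.y))
            if not uniq <= {0.0, 1.0}:
                raise ValueError(f"binary trait contains values outside {{0,1}}: {sorted(uniq - {0.0, 1.0})}")
            if uniq != {0.0, 1.0}:
                raise ValueError("binary trait needs at least one case and one control")
        if len(self.covariates) == 0:
            self.covariates = pd.DataFrame(index=range(len(self.samples)))
        elif len(self.covariates) != len(self.samples):
            raise ValueError("covariate rows do not align with samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def covariate_matrix(self) -> np.ndarray:
        """Covariates as an (n, c) float array; c may be 0."""
        return self.covariates.to_numpy(dtype=float).reshape(len(self.samples), -1)


def _normalize_token(tok: str) -> int:
    tok = tok.strip()
    if tok in MISSING_TOKENS:
        return MISSING
    if tok in ("0", "1", "2"):
        return int(tok)
    # PLINK --recode A writes dosages as floats ("0", "1", "2" or "NA"),
    # some exporters write "0.0"
    try:
        val = float(tok)
    except ValueError:
        raise ParseError(f"unrecognized genotype token {tok!r}") from None
    if val in (0.0, 1.0, 2.0):
        return int(val)
    raise ParseError(f"genotype code {tok!r} not in {{0,1,2}}")


def _strip_allele_suffix(name: str) -> str:
    """PLINK .raw headers carry counted-allele suffixes: rs123_A -> rs123."""
    return re.sub(r"_[ACGT0-9]+$", "", name)


def read_genotypes(path, dialect: str = "delimited") -> GenotypeMatrix:
    """Read a genotype matrix from a delimited file or PLINK .raw file.

    Parameters
    ----------
    path : str or Path
        File with a header row of SNP identifiers.  The ``delimited``
        dialect expects an optional leading sample-id column followed by
        genotype columns; ``plink_raw`` expects the six PLINK metadata
        columns (FID IID PAT MAT SEX PHENOTYPE) before the genotypes.
    dialect : {"delimited", "plink_raw"}
    """
    if dialect not in ("delimited", "plink_raw"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = r"\s+" if dialect == "plink_raw" else None
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    if dialect == "plink_raw":
        missing_meta = [c for c in _PLINK_PREFIX if c not in df.columns]
        if missing_meta:
            raise ParseError(f"PLINK .raw file lacks metadata columns {missing_meta}")
        samples = df["IID"].tolist()
        geno = df.drop(columns=_PLINK_PREFIX)
        geno.columns = [_strip_allele_suffix(c) for c in geno.columns]
    else:
        first = df.columns[0]
        # a leading sample-id column is detected by non-genotype content
        col_vals = set(df[first].astype(str).str.strip())
        if col_vals <= ({"0", "1", "2"} | MISSING_TOKENS):
            samples = [f"S{i + 1}" for i in range(len(df))]
            geno = df
        else:
            samples = df[first].tolist()
            geno = df.drop(columns=[first])
    values = np.empty(geno.shape, dtype=np.int8)
    for j, col in enumerate(geno.columns):
        for i, tok in enumerate(geno[col]):
            try:
                values[i, j] = _normalize_token(str(tok))
            except ParseError as exc:
                raise ParseError(f"row {i + 1}, column {col!r}: {exc}") from None
    return GenotypeMatrix(samples=samples, snps=list(geno.columns), values=values)


def write_genotypes(genos: GenotypeMatrix, path) -> None:
    """Write a delimited genotype matrix (sample id + one column per SNP)."""
    df = pd.DataFrame(genos.values, columns=genos.snps)
    df = df.astype(object).where(df != MISSING, "NA")
    df.insert(0, "sample", genos.samples)
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(
    path,
    trait_family: str,
    covariate_names: Sequence[str] = (),
    sample_order: Sequence[str] | None = None,
    sample_col: str = "sample",
    trait_col: str = "y",
) -> PhenotypeTable:
    """Read a phenotype/covariate table keyed by sample identifier.

    When ``sample_order`` is given (normally the genotype matrix's sample
    list) rows are re-aligned to that order; a missing sample raises
    :class:`AlignmentError`.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in (sample_col, trait_col):
        if col not in df.columns:
            raise ParseError(f"phenotype file lacks required column {col!r}; has {list(df.columns)}")
    unknown = [c for c in covariate_names if c not in df.columns]
    if unknown:
        raise ParseError(
            f"unknown covariate column(s) {unknown}; available: "
            f"{[c for c in df.columns if c not in (sample_col, trait_col)]}"
        )
    df[sample_col] = df[sample_col].astype(str)
    if sample_order is not None:
        index = df.set_index(sample_col)
        absent = [s for s in sample_order if s not in index.index]
        if absent:
            raise AlignmentError(f"samples missing from phenotype file: {absent[:5]}")
        df = index.loc[list(sample_order)].reset_index()
    return PhenotypeTable(
        samples=df[sample_col].tolist(),
        y=df[trait_col].to_numpy(dtype=float),
        trait_family=trait_family,
        covariates=df[list(covariate_names)].reset_index(drop=True),
    )


def write_phenotypes(phenos: PhenotypeTable, path) -> None:
    df = pd.DataFrame({"sample": phenos.samples, "y": phenos.y})
    for col in phenos.covariates.columns:
        df[col] = phenos.covariates[col].to_numpy()
    df.to_csv(path, sep="\t", index=False)


def write_model_results(results, path) -> None:
    """Write ranked model results as TSV.

    Columns: order, snp_combination, cvc, ba_train, ba_test.  Rows are
    ordered by descending testing balanced accuracy, then descending
    cross-validation consistency, then lexicographic combination, so the
    file is deterministic for a given result set.
    """
    results = list(results)
    if not results:
        raise ValueError("refusing to write an empty result table")
    rows = [
        {
            "order": len(r.combination),
            "snp_combination": ",".join(r.combination),
            "cvc": r.cvc,
            "ba_train": r.ba_train,
            "ba_test": r.ba_test,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["ba_test", "cvc", "snp_combination"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_model_results(path) -> pd.DataFrame:
    """Read back a model-result TSV (round-trip counterpart of the writer)."""
    return pd.read_csv(path, sep="\t")
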
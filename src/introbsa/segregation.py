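"""Segregation-ratio goodness-of-fit tests and marker–phenotype cosegregation.

A single recessive locus segregates 3:1 (normal:brown) in an F2; the χ²
goodness-of-fit statistic is Σ(obs − exp)²/exp with expected counts from the
hypothesized ratio, compared against a chi-square distribution with
(categories − 1) degrees of freedom. No continuity correction is applied by
default (Yates' correction is available as a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RatioTest:
    observed: tuple[int, ...]
    ratio: tuple[float, ...]
    expected: tuple[float, ...]
    chi_square: float
    df: int
    p_value: float


def chi_square_ratio(
    observed: Sequence[int],
    ratio: Sequence[float],
    yates: bool = False,
) -> RatioTest:
    """Goodness-of-fit of observed category counts to an expected ratio.

    ``ratio`` is ordered as the observed categories are (e.g. (3, 1) for
    non-brown:brown). Zero expected counts are rejected.
    """
    obs = np.asarray(observed, dtype=float)
    r = np.asarray(ratio, dtype=float)
    if len(obs) != len(r):
        raise ValueError("observed and ratio must have the same length")
    if (obs < 0).any() or obs.sum() <= 0:
        raise ValueError("counts must be non-negative with a positive total")
    if (r <= 0).any():
        raise ValueError("zero expected share in ratio")
    expected = obs.sum() * r / r.sum()
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return RatioTest(
        observed=tuple(int(x) for x in obs),
        ratio=tuple(float(x) for x in r),
        expected=tuple(float(x) for x in expected),
        chi_square=chi2,
        df=df,
        p_value=p,
    )


def phenotype_ratio_test(
    n_normal: int, n_brown: int, yates: bool = False
) -> RatioTest:
    """3:1 (normal:brown) goodness-of-fit for a recessive single-locus F2."""
    return chi_square_ratio([n_normal, n_brown], [3, 1], yates=yates)


@dataclass
class CosegregationReport:
    n_individuals: int
    n_skipped: int
    violations: list[dict] = field(default_factory=list)

    @property
    def perfect(self) -> bool:
        return not self.violations


def cosegregation_check(
    table: pd.DataFrame,
    mutant_genotype: str = "AA",
    brown_phenotype: str = "brown",
    genotype_col: str = "genotype",
    phenotype_col: str = "phenotype",
) -> CosegregationReport:
    """Check that the mutant-homozygous marker genotype and the recessive
    phenotype identify exactly the same individuals.

    A violation is a brown individual that is not homozygous for the mutant
    allele, or a mutant-homozygote that is not brown. Rows with missing data
    are skipped and counted.
    """
    violations = []
    skipped = 0
    for _, row in table.iterrows():
        geno, pheno = row[genotype_col], row[phenotype_col]
        if pd.isna(geno) or pd.isna(pheno):
            skipped += 1
            continue
        is_mut = geno == mutant_genotype
        is_brown = pheno == brown_phenotype
        if is_mut != is_brown:
            violations.append(dict(row))
    return CosegregationReport(
        n_individuals=len(table) - skipped,
        n_skipped=skipped,
        violations=violations,
    )
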
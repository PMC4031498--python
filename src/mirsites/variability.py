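"""Per-gene expression variability and the Q1-vs-Q4 comparison.

Variability is the coefficient of variation theta = sigma / mu across samples,
with the sample (n - 1) standard deviation. Expression is consumed on the
scale provided; ``log2`` pre-transform is available for intensity panels
stored on a log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .stats import TestResult, ks_two_sample

logger = logging.getLogger("mirsites")


@dataclass(frozen=True)
class CVResult:
    gene_id: str
    mu: float
    sigma: float

    @property
    def cv(self) -> float:
        return self.sigma / self.mu


def coefficient_of_variation(values: Sequence[float], gene_id: str = "?") -> CVResult:
    """Mean, sample standard deviation and their ratio for one gene's profile."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise ValueError(f"gene {gene_id}: need >= 2 values for a CV")
    if not np.isfinite(arr).all():
        raise ValueError(f"gene {gene_id}: non-finite expression values")
    mu = float(arr.mean())
    if mu <= 0:
        raise ValueError(f"gene {gene_id}: mean expression {mu} not > 0")
    sigma = float(arr.std(ddof=1))
    return CVResult(gene_id, mu, sigma)


def expression_cv(matrix: ExpressionMatrix, log2_transform: bool = False) -> pd.DataFrame:
    """Per-gene CV table {gene_id, mu, sigma, cv}, vectorized over the matrix.

    Genes with nonpositive mean raise, matching the per-gene contract.
    """
    data = matrix.data
    if log2_transform:
        if (data.to_numpy() < 0).any():
            raise ValueError("negative intensities cannot be log2(x + 1) transformed")
        data = np.log2(data + 1.0)
    if data.shape[1] < 2:
        raise ValueError("need >= 2 samples for CVs")
    mu = data.mean(axis=1)
    bad = mu[mu <= 0]
    if len(bad):
        raise ValueError(f"mean expression not > 0 for genes: {list(bad.index[:5])}")
    sigma = data.std(axis=1, ddof=1)
    return pd.DataFrame({
        "gene_id": data.index, "mu": mu.to_numpy(), "sigma": sigma.to_numpy(),
        "cv": (sigma / mu).to_numpy(),
    }).reset_index(drop=True)


def group_cv_comparison(
    cv_by_gene: Mapping[str, float] | pd.Series,
    q1_set: Iterable[str],
    q4_set: Iterable[str],
) -> dict:
    """KS comparison of the CV distributions of the Q1 and Q4 gene groups."""
    cv = pd.Series(cv_by_gene, dtype=float).dropna()
    q1 = sorted(set(q1_set))
    q4 = sorted(set(q4_set))
    cv1 = cv.reindex(q1).dropna()
    cv4 = cv.reindex(q4).dropna()
    for name, requested, got in (("Q1", len(q1), len(cv1)), ("Q4", len(q4), len(cv4))):
        if requested - got:
            logger.info("%s: %d genes lack expression and were dropped", name, requested - got)
    if len(cv1) < 5 or len(cv4) < 5:
        raise ValueError(f"need >= 5 genes with CVs per group, got {len(cv1)} and {len(cv4)}")
    result: TestResult = ks_two_sample(cv1.to_numpy(), cv4.to_numpy())
    return {
        "ks_D": result.statistic,
        "p_value": result.p_value,
        "method": result.method,
        "mean_cv_q1": float(cv1.mean()),
        "mean_cv_q4": float(cv4.mean()),
        "n1": len(cv1),
        "n4": len(cv4),
    }
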
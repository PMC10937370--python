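"""Closed-form statistics: genetic-correlation z-tests and IVW meta-analysis.

Genetic-correlation estimates (r_g, se) come from external tools such as
LD score regression; only the comparison tests are computed here. The
one-tailed test against perfect correlation uses z = (1 - r_g) / se(r_g).
Replication pooling is inverse-variance-weighted fixed-effects
meta-analysis with the conventional Bonferroni significance helper.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GenCorrEstimate",
    "MetaResult",
    "rg_diff_from_one",
    "rg_diff_from_zero",
    "ivw_meta",
]


@dataclass(frozen=True)
class GenCorrEstimate:
    """A genetic-correlation estimate with its standard error."""

    rg: float
    se_rg: float
    label: str = ""

    def __post_init__(self):
        if not self.se_rg > 0:
            raise ValueError(f"se_rg must be positive (got {self.se_rg})")


@dataclass(frozen=True)
class MetaResult:
    """Inverse-variance-weighted fixed-effects pooled estimate."""

    beta: float
    se: float
    pvalue: float
    n_studies: int

    def significant(self, n_tests: int, alpha: float = 0.05) -> bool:
        """Bonferroni-corrected significance: p < alpha / n_tests."""
        if n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        return self.pvalue < alpha / n_tests


def rg_diff_from_one(est: GenCorrEstimate) -> tuple[float, float]:
    """One-tailed z-test of r_g against perfect correlation (r_g = 1).

    Returns ``(z, p)`` with ``z = (1 - rg) / se_rg`` and p the upper-tail
    standard-normal probability: small p means the correlation is
    significantly below 1.
    """
    z = (1.0 - est.rg) / est.se_rg
    return z, float(stats.norm.sf(z))


def rg_diff_from_zero(est: GenCorrEstimate) -> tuple[float, float]:
    """Two-tailed z-test of r_g against zero; returns ``(z, p)``."""
    z = est.rg / est.se_rg
    return z, float(2.0 * stats.norm.sf(abs(z)))


def ivw_meta(effects: Sequence[tuple[float, float]]) -> MetaResult:
    """Inverse-variance-weighted fixed-effects meta-analysis.

    Parameters
    ----------
    effects : sequence of (beta, se)
        Per-study estimates; all standard errors must be positive.

    Returns
    -------
    MetaResult
        Pooled ``beta = sum(b_i / se_i^2) / sum(1 / se_i^2)``,
        ``se = (sum 1 / se_i^2)^(-1/2)`` and two-tailed normal p-value.
    """
    if len(effects) == 0:
        raise ValueError("need >= 1 study")
    beta = np.asarray([b for b, _ in effects], float)
    se = np.asarray([s for _, s in effects], float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * beta) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / pooled_se
    return MetaResult(beta=pooled, se=pooled_se,
                      pvalue=float(2.0 * stats.norm.sf(abs(z))),
                      n_studies=len(effects))
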
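"""Bivariate effect pairs: the common currency of the cross-trait analyses.

An :class:`EffectPair` holds one variant's estimated log-odds-ratio in two
GWAS (trait X on the x axis, trait Y on the y axis), the standard errors of
both estimates, and the correlation ``r_est`` between the two estimators
induced by sample overlap (0 when the studies share no samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

PAIR_COLUMNS = ["variant_id", "beta_x", "se_x", "beta_y", "se_y", "r_est"]


@dataclass(frozen=True)
class EffectPair:
    """One variant's effect estimates in two GWAS.

    Parameters
    ----------
    variant_id : str
        Variant key, conventionally ``chr:pos:ref:alt``.
    beta_x, beta_y : float
        Log odds ratios in trait X and trait Y for the same alt allele.
    se_x, se_y : float
        Standard errors of the estimates; must be positive.
    r_est : float, default 0
        Correlation between the two effect estimators (from sample
        overlap); must satisfy ``|r_est| < 1``.
    """

    variant_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    r_est: float = 0.0

    def __post_init__(self) -> None:
        if not (self.se_x > 0 and self.se_y > 0):
            raise ValueError(
                f"{self.variant_id}: standard errors must be positive "
                f"(got se_x={self.se_x}, se_y={self.se_y})"
            )
        if not abs(self.r_est) < 1:
            raise ValueError(
                f"{self.variant_id}: |r_est| must be < 1 (got {self.r_est})"
            )

    @property
    def sampling_cov(self) -> np.ndarray:
        """2x2 sampling covariance of (beta_x, beta_y)."""
        c = self.r_est * self.se_x * self.se_y
        return np.array([[self.se_x**2, c], [c, self.se_y**2]])


PairsLike = Union[pd.DataFrame, Sequence[EffectPair], Iterable[EffectPair]]


def as_pairs_frame(pairs: PairsLike) -> pd.DataFrame:
    """Normalize a pair collection to a validated DataFrame.

    Accepts either a DataFrame with columns ``beta_x, se_x, beta_y, se_y``
    (``variant_id`` and ``r_est`` optional) or an iterable of
    :class:`EffectPair`.
    """
    if isinstance(pairs, pd.DataFrame):
        df = pairs.copy()
        for col in ("beta_x", "se_x", "beta_y", "se_y"):
            if col not in df.columns:
                raise ValueError(f"pairs table is missing column {col!r}")
        if "variant_id" not in df.columns:
            df["variant_id"] = [f"v{i}" for i in range(len(df))]
        if "r_est" not in df.columns:
            df["r_est"] = 0.0
    else:
        rows = list(pairs)
        if rows and not isinstance(rows[0], EffectPair):
            raise TypeError("expected EffectPair instances or a DataFrame")
        df = pd.DataFrame(
            [
                (p.variant_id, p.beta_x, p.se_x, p.beta_y, p.se_y, p.r_est)
                for p in rows
            ],
            columns=PAIR_COLUMNS,
        )
    df = df[PAIR_COLUMNS + [c for c in df.columns if c not in PAIR_COLUMNS]]
    if len(df):
        bad = df[(df["se_x"] <= 0) | (df["se_y"] <= 0)]
        if len(bad):
            raise ValueError(
                f"non-positive standard error for {bad['variant_id'].tolist()}"
            )
        bad = df[df["r_est"].abs() >= 1]
        if len(bad):
            raise ValueError(
                f"|r_est| >= 1 for {bad['variant_id'].tolist()}"
            )
    return df.reset_index(drop=True)


def frame_to_pairs(df: pd.DataFrame) -> list[EffectPair]:
    """Convert a pairs DataFrame to a list of :class:`EffectPair`."""
    df = as_pairs_frame(df)
    return [
        EffectPair(r.variant_id, r.beta_x, r.se_x, r.beta_y, r.se_y, r.r_est)
        for r in df.itertuples(index=False)
    ]


def read_pairs(path) -> pd.DataFrame:
    """Read a harmonized pairs TSV (as written by :func:`write_pairs`)."""
    return as_pairs_frame(pd.read_csv(path, sep="\t"))


def write_pairs(df: pd.DataFrame, path) -> None:
    """Write a pairs table as TSV."""
    as_pairs_frame(df).to_csv(path, sep="\t", index=False)
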
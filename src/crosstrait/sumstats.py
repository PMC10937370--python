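"""Reading, validating and joining GWAS summary statistics.

Tables are tab-separated with one row per variant: identifier, GRCh38
chromosome/position (1-based), ref/alt alleles, optional alt-allele
frequency, log-odds-ratio effect (``beta``), its standard error and p-value.
:func:`join_effects` matches a list of lead variants across two tables,
flipping the second trait's effect sign when the locus is stored with
ref/alt swapped, so downstream analyses see both effects for the same alt
allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pairs import as_pairs_frame

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = {
    "variant_id": str,
    "chromosome": str,
    "position": int,
    "ref_allele": str,
    "alt_allele": str,
    "beta": float,
    "se": float,
    "pvalue": float,
}
OPTIONAL_COLUMNS = {"alt_freq": float}

#: complementary bases, for detecting strand-ambiguous (A/T, C/G) variants
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class ReadReport:
    """Row-level accounting from :func:`read_sumstats`."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)


def read_sumstats(path, column_map: dict | None = None,
                  report: ReadReport | None = None) -> pd.DataFrame:
    """Read and validate a GWAS summary-statistics TSV.

    Parameters
    ----------
    path : str or path-like
        TSV file (gzip transparently supported via the ``.gz`` suffix).
    column_map : dict, optional
        Mapping from file column names to canonical names
        (``variant_id, chromosome, position, ref_allele, alt_allele,
        beta, se, pvalue`` and optionally ``alt_freq``), e.g.
        ``{"rsid": "variant_id", "b": "beta", "stderr": "se"}``.
    report : ReadReport, optional
        If given, filled with row drop counts.

    Returns
    -------
    pandas.DataFrame
        Validated table with canonical column names. Rows violating the
        invariants (``se > 0``, ``pvalue`` in (0, 1], parsable numerics,
        duplicate ``(chromosome, position, ref, alt)``) are dropped and
        the drop count logged.

    Raises
    ------
    ValueError
        If a mandatory column is absent after renaming.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    rep = report if report is not None else ReadReport()
    rep.n_read = len(df)

    for col, typ in {**CANONICAL_COLUMNS, **OPTIONAL_COLUMNS}.items():
        if col not in df.columns:
            continue
        if typ in (int, float):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            df[col] = df[col].astype(str)

    def drop(mask: pd.Series, reason: str) -> pd.Series:
        n = int(mask.sum())
        if n:
            rep.drop_reasons[reason] = rep.drop_reasons.get(reason, 0) + n
        return ~mask

    keep = pd.Series(True, index=df.index)
    numeric_cols = ["position", "beta", "se", "pvalue"]
    keep &= drop(df[numeric_cols].isna().any(axis=1), "unparsable_numeric")
    keep &= drop(keep & ~(df["se"] > 0), "nonpositive_se")
    keep &= drop(keep & ~((df["pvalue"] > 0) & (df["pvalue"] <= 1)),
                 "pvalue_out_of_range")
    if "alt_freq" in df.columns:
        bad_af = df["alt_freq"].notna() & ~(
            (df["alt_freq"] > 0) & (df["alt_freq"] < 1))
        keep &= drop(keep & bad_af, "alt_freq_out_of_range")
    df = df[keep].copy()
    df["position"] = df["position"].astype(int)

    dup = df.duplicated(
        subset=["chromosome", "position", "ref_allele", "alt_allele"],
        keep="first")
    if dup.any():
        rep.drop_reasons["duplicate_key"] = int(dup.sum())
        df = df[~dup]

    rep.n_kept = len(df)
    rep.n_dropped = rep.n_read - rep.n_kept
    if rep.n_dropped:
        logger.warning("read_sumstats(%s): dropped %d of %d rows (%s)",
                       path, rep.n_dropped, rep.n_read, rep.drop_reasons)
    return df.reset_index(drop=True)


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def _is_strand_ambiguous(ref: str, alt: str) -> bool:
    ref, alt = ref.upper(), alt.upper()
    return (len(ref) == 1 and len(alt) == 1
            and _COMPLEMENT.get(ref) == alt)


@dataclass
class JoinAudit:
    """Audit log from :func:`join_effects`."""

    n_requested: int = 0
    n_matched: int = 0
    n_flipped: int = 0
    unmatched: list = field(default_factory=list)
    dropped_ambiguous: list = field(default_factory=list)


def _index_table(df: pd.DataFrame) -> dict:
    idx = {}
    for r in df.itertuples(index=False):
        idx[variant_key(r.chromosome, r.position, r.ref_allele,
                        r.alt_allele)] = r
    return idx


def join_effects(table_x: pd.DataFrame, table_y: pd.DataFrame,
                 variants: list[str], r_est: float = 0.0,
                 audit: JoinAudit | None = None) -> pd.DataFrame:
    """Join two summary-statistics tables into a bivariate pairs table.

    Variant keys use the ``chr:pos:ref:alt`` form on the orientation of
    ``table_x``. If ``table_y`` stores the locus with ref/alt swapped, its
    beta sign is flipped so both effects refer to the same alt allele.
    Strand-ambiguous (A/T, C/G) variants that match only after the swap are
    dropped — their sign cannot be resolved safely. Variants matching
    neither orientation are omitted and listed in the audit, never imputed.

    Parameters
    ----------
    table_x, table_y : pandas.DataFrame
        Validated tables from :func:`read_sumstats`; X is the x-axis trait.
    variants : list of str
        Requested lead-variant keys (``chr:pos:ref:alt``, table-X
        orientation).
    r_est : float, default 0
        Estimator correlation applied to every pair (sample overlap); 0 for
        non-overlapping studies.
    audit : JoinAudit, optional
        Filled with match/flip/unmatched accounting.

    Returns
    -------
    pandas.DataFrame
        Pairs table with columns ``variant_id, beta_x, se_x, beta_y, se_y,
        r_est``.
    """
    aud = audit if audit is not None else JoinAudit()
    aud.n_requested = len(variants)
    ix, iy = _index_table(table_x), _index_table(table_y)

    rows = []
    for key in variants:
        try:
            chrom, pos, ref, alt = key.split(":")
        except ValueError:
            raise ValueError(
                f"variant key {key!r} is not in chr:pos:ref:alt form")
        rx = ix.get(key)
        if rx is None:
            aud.unmatched.append((key, "absent_from_x"))
            continue
        ry = iy.get(key)
        flip = False
        if ry is None:
            swapped = variant_key(chrom, pos, alt, ref)
            ry = iy.get(swapped)
            if ry is not None:
                if _is_strand_ambiguous(ref, alt):
                    aud.dropped_ambiguous.append(key)
                    logger.warning(
                        "join_effects: dropping strand-ambiguous variant %s "
                        "matched only after allele swap", key)
                    continue
                flip = True
        if ry is None:
            aud.unmatched.append((key, "absent_from_y"))
            continue
        beta_y = -ry.beta if flip else ry.beta
        aud.n_matched += 1
        aud.n_flipped += int(flip)
        rows.append((key, rx.beta, rx.se, beta_y, ry.se, r_est))

    if aud.unmatched:
        logger.warning("join_effects: %d requested variant(s) unmatched: %s",
                       len(aud.unmatched), aud.unmatched)
    return as_pairs_frame(pd.DataFrame(
        rows, columns=["variant_id", "beta_x", "se_x", "beta_y", "se_y",
                       "r_est"]))
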
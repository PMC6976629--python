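"""Stable-isotope tracer arithmetic.

Operates on long-format isotopologue tables (metabolite, isotopologue k
of "m+k", sample, intensity): per-pool isotopologue fractions, ratios of
labelled to unlabelled pools, and normalization of downstream
metabolites to a tracer input (e.g. m+5 ornithine over the 13C6-labelled
arginine pool, m+4 fumarate over the 13C4-labelled aspartate pool).
Natural-abundance isotope correction is not applied; intensities are
taken as already corrected (see the correction hook in the methods
documentation).
"""
from __future__ import annotations

import pandas as pd

from .errors import (
    EmptyInputError,
    UndefinedFractionError,
    UndefinedNormalizationError,
    UndefinedRatioError,
)

COLUMNS = ("metabolite", "isotopologue", "sample", "intensity")


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format contract: required columns, unique
    (metabolite, isotopologue, sample) keys, non-negative intensities."""
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise EmptyInputError(f"isotopologue table lacks columns {missing}")
    if table.duplicated(subset=["metabolite", "isotopologue", "sample"]).any():
        raise EmptyInputError("duplicate (metabolite, isotopologue, sample) rows")
    if (table["intensity"] < 0).any():
        raise EmptyInputError("negative intensities")
    if (table["isotopologue"] < 0).any():
        raise EmptyInputError("negative isotopologue indices")
    return table


def _pool(table: pd.DataFrame, metabolite: str, sample: str) -> pd.Series:
    sel = (table["metabolite"] == metabolite) & (table["sample"] == sample)
    pool = table.loc[sel].set_index("isotopologue")["intensity"]
    if pool.empty:
        raise EmptyInputError(
            f"no isotopologues for {metabolite!r} in sample {sample!r}"
        )
    return pool


def isotopologue_fraction(
    table: pd.DataFrame, metabolite: str, k: int, sample: str
) -> float:
    """Fraction of the metabolite pool in isotopologue m+k:
    intensity(m+k) / sum_j intensity(m+j). Returned as a proportion."""
    pool = _pool(table, metabolite, sample)
    total = float(pool.sum())
    if total <= 0:
        raise UndefinedFractionError(
            f"zero total pool for {metabolite!r} in {sample!r}"
        )
    return float(pool.get(k, 0.0)) / total


def label_ratio(
    table: pd.DataFrame, metabolite: str, labelled_k: int, sample: str
) -> float:
    """Ratio of the labelled (m+labelled_k) to the unlabelled (m+0)
    pool."""
    pool = _pool(table, metabolite, sample)
    unlabelled = float(pool.get(0, 0.0))
    if unlabelled <= 0:
        raise UndefinedRatioError(
            f"unlabelled (m+0) pool of {metabolite!r} in {sample!r} is zero; "
            "labelled:unlabelled ratio undefined"
        )
    return float(pool.get(labelled_k, 0.0)) / unlabelled


def normalize_to_tracer(
    table: pd.DataFrame,
    target_metabolite: str,
    target_k: int,
    tracer_metabolite: str,
    tracer_k: int,
    sample: str,
) -> float:
    """Normalize a target isotopologue to the tracer input pool:
    intensity(target, m+target_k) / intensity(tracer, m+tracer_k)."""
    tracer_pool = _pool(table, tracer_metabolite, sample)
    tracer = float(tracer_pool.get(tracer_k, 0.0))
    if tracer <= 0:
        raise UndefinedNormalizationError(
            f"tracer {tracer_metabolite!r} m+{tracer_k} is zero in {sample!r}"
        )
    target_pool = _pool(table, target_metabolite, sample)
    return float(target_pool.get(target_k, 0.0)) / tracer


def all_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Isotopologue fractions for every (metabolite, sample) pool.

    Long-format output with a ``fraction`` column; pools with zero total
    intensity are dropped."""
    validate_table(table)
    out = table.copy()
    totals = out.groupby(["metabolite", "sample"])["intensity"].transform("sum")
    out = out[totals > 0].copy()
    out["fraction"] = out["intensity"] / totals[totals > 0]
    return out[["metabolite", "isotopologue", "sample", "fraction"]]


def mass_balance_violations(
    fractions: pd.DataFrame, tol: float = 1e-9
) -> list[tuple[str, str]]:
    """(metabolite, sample) pools whose fractions fail to sum to 1
    within ``tol`` — a post-normalization consistency check."""
    sums = fractions.groupby(["metabolite", "sample"])["fraction"].sum()
    bad = sums[(sums - 1.0).abs() > tol]
    return sorted(bad.index.tolist())
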
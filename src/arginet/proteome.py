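"""Label-free proteomics stage.

Pipeline order is fixed: log2 intensities -> detection filter (3-of-4
replicates in at least one condition) -> left-censored imputation
(random normal centred on the per-sample detection limit) -> CV
discordance filter (overall CV must exceed every within-condition CV)
-> per-protein z-scores -> SAM-style s0-moderated t-test with
permutation-based FDR.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .design import SampleDesign
from .errors import (
    DegenerateSampleError,
    InvalidPermutationsError,
    InvalidS0Error,
    InvalidThresholdError,
    UndefinedCVError,
    UnknownConditionError,
)
from .seeding import substream


def missing_mask(matrix: pd.DataFrame) -> pd.DataFrame:
    """Boolean mask of missing cells (NaN encodes missing)."""
    return matrix.isna()


def detection_filter(
    matrix: pd.DataFrame, design: SampleDesign, min_reps: int = 3
) -> pd.Series:
    """Keep proteins identified in at least ``min_reps`` replicates of at
    least one condition."""
    keep = pd.Series(False, index=matrix.index)
    for cond in design.conditions:
        samples = [s for s in design.samples_for(cond) if s in matrix.columns]
        if not samples:
            continue
        if min_reps > len(samples):
            raise InvalidThresholdError(
                f"min_reps={min_reps} exceeds the {len(samples)} replicates of {cond!r}"
            )
        keep |= matrix[samples].notna().sum(axis=1) >= min_reps
    return keep


def impute_missing(
    matrix: pd.DataFrame,
    width_factor: float = 0.3,
    downshift: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Impute missing values from a random normal centred on the
    per-sample detection limit.

    The detection limit of a sample is its observed minimum, optionally
    shifted down by ``downshift`` observed-SD units (``downshift=1.8``
    with ``width_factor=0.3`` reproduces the Perseus-style downshifted
    normal, except that the centre anchors on the observed minimum
    rather than the mean). Imputation width is
    ``width_factor * per-sample observed SD``. Observed cells are
    untouched; deterministic given seed.
    """
    if width_factor <= 0 or downshift < 0:
        raise InvalidThresholdError("width_factor must be > 0 and downshift >= 0")
    rng = substream(seed, "impute")
    out = matrix.copy()
    for col in out.columns:
        observed = out[col].dropna()
        n_missing = out[col].isna().sum()
        if observed.empty:
            raise DegenerateSampleError(f"sample {col!r} has no observed values")
        if n_missing == 0:
            continue
        sd = float(observed.std(ddof=1)) if len(observed) > 1 else 0.0
        centre = float(observed.min()) - downshift * sd
        draws = rng.normal(centre, width_factor * sd, size=int(n_missing))
        out.loc[out[col].isna(), col] = draws
    return out


def _cv(values: np.ndarray, scale: str) -> np.ndarray:
    """Row-wise coefficient of variation, SD/mean, on linear or log2 scale."""
    x = np.exp2(values) if scale == "linear" else values
    mean = x.mean(axis=1)
    if (mean == 0).any():
        raise UndefinedCVError("zero mean encountered when computing CV")
    return x.std(axis=1, ddof=1) / mean


def cv_filter(
    matrix: pd.DataFrame, design: SampleDesign, scale: str = "linear"
) -> pd.Series:
    """Keep proteins whose overall CV strictly exceeds the CV within
    every condition — proteins that vary consistently between conditions
    but not between replicates.

    CV defaults to the linear intensity scale (2**log2 values), where
    SD/mean is well-behaved; ``scale="log2"`` computes it on the log
    scale instead.
    """
    if scale not in ("linear", "log2"):
        raise UndefinedCVError(f"unknown CV scale {scale!r}")
    if matrix.isna().any().any():
        raise DegenerateSampleError("cv_filter requires a fully observed matrix")
    cols = [s for s in design.sample_ids if s in matrix.columns]
    overall = _cv(matrix[cols].to_numpy(dtype=float), scale)
    keep = np.ones(len(matrix), dtype=bool)
    for cond in design.conditions:
        samples = [s for s in design.samples_for(cond) if s in matrix.columns]
        if len(samples) < 2:
            continue
        within = _cv(matrix[samples].to_numpy(dtype=float), scale)
        keep &= overall > within
    return pd.Series(keep, index=matrix.index)


def zscore_proteins(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-protein z-score across the matrix columns (constant rows map
    to zero)."""
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


@dataclass
class ProteinTestResult:
    """SAM-style differential-abundance result.

    ``table`` columns: ``d_stat`` (s0-moderated t), ``q_value``
    (permutation-based FDR estimate), ``significant``.
    """

    table: pd.DataFrame = field(repr=False)
    contrast: tuple[str, str] = ("A", "B")
    s0: float = 0.05
    fdr: float = 0.05

    @property
    def significant_proteins(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def _group_stats(x: np.ndarray, masks: np.ndarray, na: int, nb: int,
                 s0: float) -> np.ndarray:
    """d statistics for many label assignments at once.

    ``x``: proteins x samples; ``masks``: (B, n) boolean group-A
    selectors. Returns (proteins, B) array of d values."""
    m = masks.T.astype(float)  # (n, B)
    sum_a = x @ m
    sum_sq_a = (x ** 2) @ m
    tot = x.sum(axis=1, keepdims=True)
    tot_sq = (x ** 2).sum(axis=1, keepdims=True)
    mean_a = sum_a / na
    mean_b = (tot - sum_a) / nb
    ss_a = sum_sq_a - na * mean_a ** 2
    ss_b = (tot_sq - sum_sq_a) - nb * mean_b ** 2
    pooled = np.clip(ss_a + ss_b, 0.0, None) / (na + nb - 2)
    s = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    return (mean_a - mean_b) / (s + s0)


def sam_test(
    matrix: pd.DataFrame,
    design: SampleDesign,
    contrast: tuple[str, str],
    s0: float = 0.05,
    n_perm: int = 1000,
    fdr: float = 0.05,
    seed: int = 0,
) -> ProteinTestResult:
    """SAM-style moderated t-test with permutation-based FDR.

    d = (mean_A - mean_B) / (s_pooled + s0), where s_pooled is the
    two-sample pooled standard error and s0 a small fudge factor
    stabilizing low-variance proteins. The null is built by permuting
    group labels over the pooled samples (same permutation for all
    proteins); for each candidate threshold |d|, the estimated FDR
    (q-value) is the median permutation false-positive count divided by
    the observed positive count, monotonized to be non-increasing in
    |d| and capped at 1. ``significant`` means q <= ``fdr``.

    The assignment space is enumerated exhaustively when it has at most
    ``n_perm`` elements (70 for a 4v4 contrast).
    """
    if s0 < 0:
        raise InvalidS0Error("s0 must be non-negative")
    if n_perm < 1:
        raise InvalidPermutationsError("n_perm must be >= 1")
    samples_a = design.samples_for(contrast[0])
    samples_b = design.samples_for(contrast[1])
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise UnknownConditionError("both conditions need >=2 replicates")
    cols = samples_a + samples_b
    missing = [s for s in cols if s not in matrix.columns]
    if missing:
        raise UnknownConditionError(f"samples absent from matrix: {missing}")
    if matrix[cols].isna().any().any():
        raise DegenerateSampleError("sam_test requires a fully observed matrix")

    x = matrix[cols].to_numpy(dtype=float)
    na, nb = len(samples_a), len(samples_b)
    n = na + nb

    identity = np.zeros((1, n), dtype=bool)
    identity[0, :na] = True
    d_obs = _group_stats(x, identity, na, nb, s0)[:, 0]

    n_assign = comb(n, na)
    if n_assign <= n_perm:
        masks = np.zeros((n_assign, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), na)):
            masks[i, list(idx)] = True
    else:
        rng = substream(seed, "sam")
        order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :na]
        masks = np.zeros((n_perm, n), dtype=bool)
        np.put_along_axis(masks, order, True, axis=1)
    d_null = np.abs(_group_stats(x, masks, na, nb, s0))  # (proteins, B)

    abs_d = np.abs(d_obs)
    # observed positive count at each protein's own threshold
    sorted_obs = np.sort(abs_d)
    n_prot = abs_d.size
    obs_count = n_prot - np.searchsorted(sorted_obs, abs_d, side="left")
    # permutation false positives: per permutation, count |d*| >= threshold
    fp = np.empty((d_null.shape[1], n_prot))
    for b in range(d_null.shape[1]):
        col = np.sort(d_null[:, b])
        fp[b] = n_prot - np.searchsorted(col, abs_d, side="left")
    med_fp = np.median(fp, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q_raw = np.where(obs_count > 0, med_fp / obs_count, 1.0)
    # monotonize: q non-increasing in |d| (cumulative min from the least
    # significant protein back toward the most significant)
    order_desc = np.argsort(-abs_d, kind="stable")
    q_sorted = q_raw[order_desc]
    q_mono = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_mono)
    q[order_desc] = np.clip(q_mono, 0.0, 1.0)

    significant = q <= fdr
    table = pd.DataFrame(
        {"d_stat": d_obs, "q_value": q, "significant": significant},
        index=matrix.index,
    )
    return ProteinTestResult(table, contrast=contrast, s0=s0, fdr=fdr)


def run_pipeline(
    matrix: pd.DataFrame,
    design: SampleDesign,
    contrast: tuple[str, str],
    min_reps: int = 3,
    width_factor: float = 0.3,
    downshift: float = 0.0,
    cv_scale: str = "linear",
    s0: float = 0.05,
    n_perm: int = 1000,
    fdr: float = 0.05,
    seed: int = 0,
) -> tuple[ProteinTestResult, pd.DataFrame]:
    """Full proteomics stage in the fixed order: detection filter ->
    imputation -> CV filter -> z-score -> SAM test.

    Returns the test result and the processed (z-scored, filtered)
    matrix.
    """
    kept = detection_filter(matrix, design, min_reps=min_reps)
    filtered = matrix.loc[kept]
    imputed = impute_missing(filtered, width_factor=width_factor,
                             downshift=downshift, seed=seed)
    varying = cv_filter(imputed, design, scale=cv_scale)
    z = zscore_proteins(imputed.loc[varying])
    result = sam_test(z, design, contrast, s0=s0, n_perm=n_perm,
                      fdr=fdr, seed=seed)
    return result, z
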
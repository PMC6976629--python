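"""Pathway-level rank-sum permutation test.

For a pathway and two compared conditions, samples are ranked per gene
on expression within the union of the two groups; the test statistic is
the sum over pathway genes of the absolute difference between the rank
sums of the two groups,

    T = sum_g | sum_{s in A} rank(g, s) - sum_{s in B} rank(g, s) |.

The null distribution is obtained by permuting the group labels over the
pooled samples (the same permutation applied to all genes, preserving
gene–gene correlation), 12,000 randomizations by default, with an
empirical p-value and Bonferroni correction across pathways. When the
assignment space C(nA+nB, nA) is no larger than the permutation budget,
the test enumerates it exhaustively and the p-value is exact.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    EmptyPathwayError,
    InvalidPermutationsError,
    InvalidPValueError,
    TooLargeError,
    UnknownConditionError,
)
from .seeding import substream

DEFAULT_N_PERM = 12_000
EXACT_ENUMERATION_BOUND = 100_000


@dataclass
class RankPermResult:
    """Result of one pathway permutation test."""

    pathway_id: str
    t_obs: float
    null_sample: np.ndarray = field(repr=False)
    p_empirical: float = 1.0
    p_bonferroni: float = 1.0
    n_perm: int = 0
    n_genes: int = 0
    method: str = "monte-carlo"  # or "exhaustive"


def _rank_matrix(expr: pd.DataFrame, pathway_genes: list[str],
                 group_a: list[str], group_b: list[str]) -> tuple[np.ndarray, int, int]:
    """Per-gene midranks over the pooled samples of the two groups.

    Returns (ranks with group-A columns first, nA, nB)."""
    if set(group_a) & set(group_b):
        raise UnknownConditionError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise UnknownConditionError("each group needs >=2 samples")
    present = [g for g in pathway_genes if g in expr.index]
    if not present:
        raise EmptyPathwayError("no pathway gene present in expression matrix")
    pooled = list(group_a) + list(group_b)
    missing = [s for s in pooled if s not in expr.columns]
    if missing:
        raise UnknownConditionError(f"samples absent from matrix: {missing}")
    values = expr.loc[present, pooled].to_numpy(dtype=float)
    ranks = rankdata(values, axis=1, method="average")
    return ranks, len(group_a), len(group_b)


def _statistic_from_ranks(ranks: np.ndarray, a_mask: np.ndarray) -> float:
    """T for one 0/1 assignment vector over the pooled columns."""
    sum_a = ranks[:, a_mask].sum(axis=1)
    sum_b = ranks[:, ~a_mask].sum(axis=1)
    return float(np.abs(sum_a - sum_b).sum())


def pathway_statistic(
    expr: pd.DataFrame,
    pathway_genes: list[str],
    group_a: list[str],
    group_b: list[str],
) -> float:
    """Observed rank-sum statistic T for one pathway (midranks for ties)."""
    ranks, na, nb = _rank_matrix(expr, pathway_genes, group_a, group_b)
    mask = np.zeros(na + nb, dtype=bool)
    mask[:na] = True
    return _statistic_from_ranks(ranks, mask)


def _all_statistics(ranks: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Vectorized T over many assignments.

    ``masks``: (n_assign, n_samples) boolean, each row selecting group A.
    Uses T = sum_g |2 * S_A(g) - S_tot(g)| since S_B = S_tot - S_A.
    """
    tot = ranks.sum(axis=1)  # (genes,)
    s_a = ranks @ masks.T.astype(float)  # (genes, n_assign)
    return np.abs(2.0 * s_a - tot[:, None]).sum(axis=0)


def _enumerate_masks(n: int, na: int) -> np.ndarray:
    masks = np.zeros((comb(n, na), n), dtype=bool)
    for i, idx in enumerate(combinations(range(n), na)):
        masks[i, list(idx)] = True
    return masks


def exact_test(
    expr: pd.DataFrame,
    pathway_genes: list[str],
    group_a: list[str],
    group_b: list[str],
) -> tuple[float, np.ndarray]:
    """Exact permutation p-value by exhaustive enumeration.

    Enumerates every distinct assignment of nA of the pooled samples to
    group A (including the identity) and counts assignments with
    T* >= T_obs. Returns (p, full null sample). Refuses designs with more
    than 1e5 assignments.
    """
    ranks, na, nb = _rank_matrix(expr, pathway_genes, group_a, group_b)
    n = na + nb
    n_assign = comb(n, na)
    if n_assign > EXACT_ENUMERATION_BOUND:
        raise TooLargeError(
            f"C({n},{na}) = {n_assign} exceeds the exhaustive bound"
        )
    masks = _enumerate_masks(n, na)
    t_all = _all_statistics(ranks, masks)
    t_obs = t_all[0]  # identity assignment is the first combination
    # tolerance guards float round-off in midrank sums
    p = float((t_all >= t_obs - 1e-9).sum()) / n_assign
    return p, t_all


def permutation_test(
    expr: pd.DataFrame,
    pathway_genes: list[str],
    group_a: list[str],
    group_b: list[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    pathway_id: str = "",
    method: str = "auto",
) -> RankPermResult:
    """Rank-sum permutation test for one pathway.

    ``method="auto"`` enumerates the assignment space exhaustively when
    it has at most ``n_perm`` elements (e.g. the 4v4 design has only
    C(8,4) = 70 distinct assignments) and otherwise Monte-Carlo samples
    ``n_perm`` assignments with replacement; ``"exhaustive"`` and
    ``"monte-carlo"`` force the respective path. Monte-Carlo p-values
    use the add-one estimator (1 + #{T* >= T_obs}) / (1 + n_perm);
    exhaustive p-values are exact (identity included).
    """
    if n_perm < 1:
        raise InvalidPermutationsError("n_perm must be >= 1")
    if method not in ("auto", "exhaustive", "monte-carlo"):
        raise InvalidPermutationsError(f"unknown method {method!r}")
    ranks, na, nb = _rank_matrix(expr, pathway_genes, group_a, group_b)
    n = na + nb
    n_assign = comb(n, na)
    use_exact = method == "exhaustive" or (method == "auto" and n_assign <= n_perm)

    mask_obs = np.zeros(n, dtype=bool)
    mask_obs[:na] = True
    t_obs = _statistic_from_ranks(ranks, mask_obs)

    if use_exact:
        if n_assign > EXACT_ENUMERATION_BOUND:
            raise TooLargeError(f"assignment space {n_assign} too large to enumerate")
        masks = _enumerate_masks(n, na)
        null = _all_statistics(ranks, masks)
        p = float((null >= t_obs - 1e-9).sum()) / n_assign
        return RankPermResult(
            pathway_id=pathway_id, t_obs=t_obs, null_sample=null,
            p_empirical=p, p_bonferroni=min(1.0, p), n_perm=n_assign,
            n_genes=ranks.shape[0], method="exhaustive",
        )

    rng = substream(seed, "pathperm")
    # uniform random assignments with replacement: argsort of iid uniforms
    order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :na]
    masks = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(masks, order, True, axis=1)
    null = _all_statistics(ranks, masks)
    p = (1.0 + float((null >= t_obs - 1e-9).sum())) / (1.0 + n_perm)
    return RankPermResult(
        pathway_id=pathway_id, t_obs=t_obs, null_sample=null,
        p_empirical=p, p_bonferroni=min(1.0, p), n_perm=n_perm,
        n_genes=ranks.shape[0], method="monte-carlo",
    )


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni correction: each p multiplied by the family size,
    capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise InvalidPValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def test_pathways(
    expr: pd.DataFrame,
    pathways: dict[str, list[str]],
    group_a: list[str],
    group_b: list[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    method: str = "auto",
) -> pd.DataFrame:
    """Run the permutation test for every pathway and Bonferroni-correct
    across them (family size = number of pathways tested here).

    Pathways with no gene in the matrix are skipped and reported with
    NaN statistics.
    """
    rows = []
    results: list[RankPermResult | None] = []
    for pid, genes in pathways.items():
        try:
            res = permutation_test(
                expr, genes, group_a, group_b,
                n_perm=n_perm, seed=seed, pathway_id=pid, method=method,
            )
        except EmptyPathwayError:
            res = None
        results.append(res)
        rows.append(pid)
    tested = [r for r in results if r is not None]
    corrected = bonferroni([r.p_empirical for r in tested])
    for r, pb in zip(tested, corrected):
        r.p_bonferroni = float(pb)
    records = []
    for pid, r in zip(rows, results):
        if r is None:
            records.append({"pathway": pid, "n_genes": 0, "t_obs": np.nan,
                            "p_empirical": np.nan, "p_bonferroni": np.nan,
                            "n_perm": 0, "method": "skipped"})
        else:
            records.append({"pathway": pid, "n_genes": r.n_genes, "t_obs": r.t_obs,
                            "p_empirical": r.p_empirical,
                            "p_bonferroni": r.p_bonferroni,
                            "n_perm": r.n_perm, "method": r.method})
    return pd.DataFrame(records).set_index("pathway")
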
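"""Count-level transcriptomics: filtering, log-CPM, DE calls, clustering, MDS.

Genes are filtered on expression (CPM + 0.25 above 1 in at least three
samples), counts are converted to log2 counts-per-million, and
differential expression between two conditions is called with a
moderated two-sample t-test at |log2FC| > 1 and BH FDR < 5%. Utilities
for comparing DE sets (Jaccard), complete-linkage clustering of the top
DE genes, and classical MDS of sample profiles round out the stage.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .design import SampleDesign
from .errors import (
    DegenerateSampleError,
    EmptyInputError,
    InvalidThresholdError,
    UnknownConditionError,
)

DEFAULT_LOGCPM_PRIOR = 0.25
#: prior degrees of freedom of the variance-shrinkage step
MODERATION_D0 = 4.0


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.size == 0:
        raise EmptyInputError("count matrix is empty")
    if (counts.to_numpy() < 0).any():
        raise EmptyInputError("count matrix has negative entries")


def library_sizes(counts: pd.DataFrame) -> pd.Series:
    """Per-sample column sums."""
    return counts.sum(axis=0)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million; library sizes must all be positive."""
    _validate_counts(counts)
    lib = library_sizes(counts)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise DegenerateSampleError(f"samples with zero library size: {bad}")
    return counts.div(lib, axis=1) * 1e6


def filter_expressed(counts: pd.DataFrame, min_samples: int = 3) -> pd.Series:
    """Expression filter: keep genes with log(CPM + 0.25) > 0, i.e.
    CPM > 0.75, in at least ``min_samples`` samples.

    The inequality is base-independent: log(CPM + 0.25) > 0 in any base
    iff CPM + 0.25 > 1. Returns a boolean mask indexed by gene.
    """
    if min_samples < 1 or min_samples > counts.shape[1]:
        raise InvalidThresholdError(
            f"min_samples={min_samples} outside [1, {counts.shape[1]}]"
        )
    x = cpm(counts)
    return (x > 1.0 - DEFAULT_LOGCPM_PRIOR).sum(axis=1) >= min_samples


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (relative depth x composition).

    For each sample, the median over genes of count / per-gene geometric
    mean, computed on genes observed in every sample. Unlike raw column
    totals, these factors are robust to a subset of genes changing
    strongly between conditions (the classic library-composition bias).
    Falls back to relative column totals if no gene is always observed.
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        lib = x.sum(axis=0)
        return pd.Series(lib / np.exp(np.mean(np.log(lib))), index=counts.columns)
    lx = np.log(x[positive])
    ref = lx.mean(axis=1, keepdims=True)  # log geometric mean per gene
    return pd.Series(np.exp(np.median(lx - ref, axis=0)), index=counts.columns)


def normalize_logcpm(
    counts: pd.DataFrame,
    prior: float = DEFAULT_LOGCPM_PRIOR,
    scale_libraries: bool = True,
) -> pd.DataFrame:
    """log2 counts-per-million on composition-scaled library sizes.

    With ``scale_libraries`` (default), each sample's effective library
    size is its median-of-ratios size factor rescaled to the per-million
    range of the observed column totals; otherwise the raw column totals
    are used. value(g, s) = log2(count / effective_lib * 1e6 + prior).
    The prior keeps zero counts finite and matches the expression
    filter's constant; rescaling any sample's column by a positive
    constant leaves the output unchanged.
    """
    if prior <= 0:
        raise InvalidThresholdError("prior must be positive")
    _validate_counts(counts)
    lib = library_sizes(counts).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise DegenerateSampleError(f"samples with zero library size: {bad}")
    if scale_libraries:
        s = size_factors(counts)
        depth = float(np.exp(np.mean(np.log(lib / s))))
        lib = s * depth
    x = counts.div(lib, axis=1) * 1e6
    return np.log2(x + prior)


@dataclass
class DEResult:
    """Per-gene differential-expression table.

    ``table`` columns: ``log2fc`` (condition A minus condition B on the
    log2-CPM scale), ``statistic`` (moderated t), ``p``, ``fdr``
    (Benjamini–Hochberg), ``called`` (|log2fc| > lfc_threshold and
    fdr < fdr_threshold).
    """

    table: pd.DataFrame = field(repr=False)
    contrast: tuple[str, str] = ("A", "B")
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05

    @property
    def called_genes(self) -> set[str]:
        return set(self.table.index[self.table["called"]])


def test_de(
    expr: pd.DataFrame,
    design: SampleDesign,
    contrast: tuple[str, str],
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> DEResult:
    """Moderated two-sample t-test per gene on log2-CPM values.

    Per-gene pooled variances are shrunk toward their trend-free mean,
    s2_shrunk = (d0*s0^2 + d*s2) / (d0 + d) with d0 = 4 prior degrees of
    freedom, and p-values taken from a t distribution with d0 + d degrees
    of freedom — a self-contained stand-in for an empirical-Bayes
    moderated fit. A gene is called when |log2fc| > ``lfc_threshold``
    and BH FDR < ``fdr_threshold``.
    """
    cond_a, cond_b = contrast
    samples_a = design.samples_for(cond_a)
    samples_b = design.samples_for(cond_b)
    missing = [s for s in samples_a + samples_b if s not in expr.columns]
    if missing:
        raise UnknownConditionError(f"design samples absent from matrix: {missing}")
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise UnknownConditionError("both contrast conditions need >=2 replicates")

    a = expr[samples_a].to_numpy(dtype=float)
    b = expr[samples_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    d = na + nb - 2
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / d
    s0_sq = float(pooled.mean())
    shrunk = (MODERATION_D0 * s0_sq + d * pooled) / (MODERATION_D0 + d)

    lfc = mean_a - mean_b
    se = np.sqrt(shrunk * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    # se == 0 only if every gene is constant; lfc is then 0 too
    p = 2.0 * t_dist.sf(np.abs(stat), df=MODERATION_D0 + d)
    fdr = multipletests(p, method="fdr_bh")[1]
    called = (np.abs(lfc) > lfc_threshold) & (fdr < fdr_threshold)

    table = pd.DataFrame(
        {"log2fc": lfc, "statistic": stat, "p": p, "fdr": fdr, "called": called},
        index=expr.index,
    )
    return DEResult(table, contrast=contrast, lfc_threshold=lfc_threshold,
                    fdr_threshold=fdr_threshold)


def jaccard(set_a: set, set_b: set) -> float:
    """|A ∩ B| / |A ∪ B|; defined as 1.0 when both sets are empty (two
    empty DE sets agree perfectly by convention)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score; constant rows map to all-zero rows (keeps
    downstream distance computations total)."""
    x = values.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=values.index, columns=values.columns)


@dataclass
class ClusterResult:
    """Complete-linkage sample dendrogram on the top-DE-gene panel."""

    linkage: np.ndarray = field(repr=False)
    leaf_order: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list, repr=False)

    def to_newick(self) -> str:
        """Newick serialization with branch lengths from merge heights."""
        from scipy.cluster.hierarchy import to_tree

        root = to_tree(self.linkage)
        labels = self.labels  # linkage leaf ids index the original order

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(root, root.dist) + ";"


def cluster_top_genes(
    expr: pd.DataFrame, de: DEResult, k: int = 40
) -> ClusterResult:
    """Complete-linkage clustering of samples on the ``k`` genes with the
    largest |log2fc|.

    Gene rows are z-scored, samples compared by Euclidean distance, and
    agglomerated with complete linkage; returns the merge tree and the
    dendrogram leaf order of sample ids.
    """
    if k < 1:
        raise InvalidThresholdError("k must be >= 1")
    if k > expr.shape[0]:
        raise InvalidThresholdError(f"k={k} exceeds {expr.shape[0]} genes")
    ranked = de.table.loc[expr.index, "log2fc"].abs().sort_values(
        ascending=False, kind="stable"
    )
    top = ranked.index[:k].tolist()
    z = zscore_rows(expr.loc[top])
    dist = pdist(z.to_numpy().T, metric="euclidean")
    merge = linkage(dist, method="complete")
    order = [expr.columns[i] for i in leaves_list(merge)]
    return ClusterResult(
        linkage=merge, leaf_order=order, genes=top, labels=list(expr.columns)
    )


def mds_coordinates(expr: pd.DataFrame, dims: int = 2) -> pd.DataFrame:
    """Classical MDS (principal coordinates) of sample profiles.

    Double-centers the squared Euclidean distance matrix between sample
    columns and eigendecomposes it; coordinates are centered at the
    origin and signs fixed so each axis's largest-magnitude loading is
    positive (determinism across BLAS builds).
    """
    n = expr.shape[1]
    if n < dims + 1:
        raise InvalidThresholdError(f"need >= {dims + 1} samples for {dims}-d MDS")
    x = expr.to_numpy(dtype=float).T  # samples x genes
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ sq @ j
    eigval, eigvec = np.linalg.eigh(b)
    idx = np.argsort(eigval)[::-1][:dims]
    lam = np.clip(eigval[idx], 0.0, None)
    # degenerate axes (eigenvalue ~ 0 relative to the leading one) are
    # exactly zero, not numerical noise
    if lam.size and lam[0] > 0:
        lam[lam < 1e-12 * lam[0]] = 0.0
    coords = eigvec[:, idx] * np.sqrt(lam)
    for c in range(coords.shape[1]):
        col = coords[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return pd.DataFrame(
        coords,
        index=expr.columns,
        columns=[f"dim{i + 1}" for i in range(dims)],
    )
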
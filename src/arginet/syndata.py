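"""Synthetic multi-omics data generators with known ground truth.

Every input the downstream stages consume can be generated here:
negative-binomial RNA-seq counts with planted fold changes, log-normal
protein LFQ intensities with left-censored missingness, scale-free or
Erdős–Rényi weighted interaction networks, pathway gene-set collections,
and isotopologue intensity tables with known label fractions. Each
generator is deterministic given its arguments and seed, and reports the
planted truth so parameter recovery can be scored.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .design import DEFAULT_REPLICATES, SampleDesign, make_design
from .errors import (
    EmptyInputError,
    InvalidDesignError,
    InvalidIntervalError,
    InvalidRateError,
    InvalidSizeError,
)
from .seeding import substream


@dataclass
class SimTruth:
    """Planted ground truth of one synthetic study.

    ``de_genes`` maps gene id -> planted log2 fold change,
    ``da_proteins`` maps protein id -> planted log2 shift,
    ``shifted_pathways`` maps pathway id -> planted shift size,
    ``label_fractions`` maps metabolite -> true isotopologue fractions.
    """

    de_genes: dict[str, float] = field(default_factory=dict)
    da_proteins: dict[str, float] = field(default_factory=dict)
    shifted_pathways: dict[str, float] = field(default_factory=dict)
    label_fractions: dict[str, list[float]] = field(default_factory=dict)


def gen_design(
    conditions: list[str],
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> SampleDesign:
    """Balanced sample design; the seed is accepted for interface symmetry
    (the layout itself is deterministic)."""
    del seed  # layout is deterministic; kept for a uniform generator API
    return make_design(conditions, replicates)


def gen_counts_programs(
    n_genes: int,
    design: SampleDesign,
    programs: list[tuple[str, list[str], float, float]],
    dispersion: float = 0.1,
    lib_size_mean: int = 5_000_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth, pd.Series]:
    """Simulate NB counts with one or more planted expression programs.

    Each program is ``(name, affected_conditions, fraction, lfc)``: a
    disjoint ``fraction`` of genes carries a +/- ``lfc`` log2 shift in
    every sample of the listed conditions. The NB is parameterized by
    mean and dispersion (variance = mu + dispersion * mu**2); per-gene
    baseline abundances are log-normal, scaled so each sample's expected
    total equals ``lib_size_mean``.

    Returns (counts, truth, gene -> program-name assignment).
    """
    if n_genes <= 0:
        raise EmptyInputError("n_genes must be positive")
    if dispersion <= 0:
        raise InvalidRateError("dispersion must be positive")
    total_fraction = sum(frac for _, _, frac, _ in programs)
    if not 0.0 <= total_fraction <= 1.0:
        raise InvalidRateError("program fractions must sum to within [0, 1]")
    known = set(design.conditions)
    for name, conds, frac, lfc in programs:
        if frac > 0 and lfc <= 0:
            raise InvalidRateError(f"program {name!r}: lfc must be positive")
        unknown = set(conds) - known
        if unknown:
            raise InvalidDesignError(f"program {name!r}: unknown conditions {unknown}")

    rng = substream(seed, "counts")
    gene_ids = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    base = rng.lognormal(mean=1.5, sigma=1.0, size=n_genes)
    props = base / base.sum()

    # disjoint planted gene groups, drawn in one pass
    n_planted = [int(round(frac * n_genes)) for _, _, frac, _ in programs]
    pool = rng.choice(n_genes, size=sum(n_planted), replace=False)
    lfc_vec = np.zeros(n_genes)
    affected_of_gene: dict[int, set[str]] = {}
    program_of_gene = pd.Series("", index=pd.Index(gene_ids, name="gene"))
    offset = 0
    for (name, conds, _frac, lfc), k in zip(programs, n_planted):
        idx = pool[offset:offset + k]
        offset += k
        signs = rng.choice([-1.0, 1.0], size=k)
        lfc_vec[idx] = signs * lfc
        for i in idx:
            affected_of_gene[int(i)] = set(conds)
            program_of_gene.iloc[int(i)] = name

    condition_of = dict(zip(design.table["sample_id"], design.table["condition"]))
    sample_ids = design.sample_ids
    counts = np.empty((n_genes, len(sample_ids)), dtype=np.int64)
    r = 1.0 / dispersion  # NB size parameter
    shift = np.zeros(n_genes)
    for j, sid in enumerate(sample_ids):
        cond = condition_of[sid]
        shift[:] = 0.0
        for i, conds in affected_of_gene.items():
            if cond in conds:
                shift[i] = lfc_vec[i]
        mu = props * float(lib_size_mean) * np.exp2(shift)
        p = r / (r + mu)
        counts[:, j] = rng.negative_binomial(r, p)

    truth = SimTruth(
        de_genes={gene_ids[i]: float(lfc_vec[i]) for i in affected_of_gene}
    )
    mat = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"), columns=sample_ids)
    return mat, truth, program_of_gene


def gen_counts(
    n_genes: int,
    design: SampleDesign,
    de_fraction: float = 0.1,
    lfc_magnitude: float = 2.0,
    dispersion: float = 0.1,
    lib_size_mean: int = 5_000_000,
    seed: int = 0,
    contrast: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a gene x sample negative-binomial count matrix.

    A ``de_fraction`` of genes carries a planted log2 fold change of
    +/- ``lfc_magnitude`` in the second condition of ``contrast``
    (default: the design's first two conditions). See
    :func:`gen_counts_programs` for the generative model and for
    planting effects shared across several conditions.
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise InvalidRateError("de_fraction must be in [0, 1]")
    if lfc_magnitude <= 0:
        raise InvalidRateError("lfc_magnitude must be positive")
    conds = design.conditions
    if contrast is None:
        if len(conds) < 2:
            raise InvalidDesignError("need >=2 conditions to plant fold changes")
        contrast = (conds[0], conds[1])
    design.samples_for(contrast[0])  # validates membership
    design.samples_for(contrast[1])
    counts, truth, _ = gen_counts_programs(
        n_genes,
        design,
        [("de", [contrast[1]], de_fraction, lfc_magnitude)],
        dispersion=dispersion,
        lib_size_mean=lib_size_mean,
        seed=seed,
    )
    return counts, truth


def gen_pathways(
    gene_universe: list[str],
    n_sets: int = 10,
    size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random pathway gene sets, members drawn without replacement."""
    lo, hi = int(size_range[0]), int(size_range[1])
    if lo < 1 or hi < lo:
        raise InvalidSizeError(f"bad size_range {size_range}")
    if hi > len(gene_universe):
        raise InvalidSizeError(
            f"size_range upper bound {hi} exceeds universe of {len(gene_universe)}"
        )
    if n_sets < 1:
        raise EmptyInputError("n_sets must be positive")
    rng = substream(seed, "pathways")
    universe = np.asarray(gene_universe, dtype=object)
    sets: dict[str, list[str]] = {}
    for k in range(1, n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"PW{k:03d}"] = sorted(members.tolist())
    return sets


def _censor_offset(values: np.ndarray, rate: float, tau: float) -> float:
    """Solve for the logistic-center offset giving the requested overall
    missingness rate; P(miss | x) = expit((c - x) / tau)."""
    lo, hi = values.min() - 50 * tau, values.max() + 50 * tau

    def mean_rate(c: float) -> float:
        return float(expit((c - values) / tau).mean()) - rate

    return brentq(mean_rate, lo, hi, xtol=1e-10)


def gen_proteome(
    n_proteins: int,
    design: SampleDesign,
    effect_magnitude: float = 1.5,
    missing_rate: float = 0.1,
    detection_limit: float = 20.0,
    seed: int = 0,
    da_fraction: float = 0.05,
    rep_sd: float = 0.3,
    baseline_mean: float = 25.0,
    baseline_sd: float = 2.5,
    censor_tau: float = 0.8,
    contrast: tuple[str, str] | None = None,
    affected_conditions: list[str] | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a protein x sample log2 LFQ intensity matrix with
    left-censored missingness.

    Per-protein baselines are Gaussian on the log2 scale (log-normal
    intensities); replicate noise has SD ``rep_sd`` log2-units. A
    ``da_fraction`` of proteins carries a +/- ``effect_magnitude`` log2
    shift in every sample of ``affected_conditions`` (default: the
    second condition of ``contrast``). Missingness is logistic in
    (detection_limit - true value): low-abundance values vanish
    preferentially, with the logistic center offset calibrated so the
    overall missing fraction equals ``missing_rate``. Missing cells are
    NaN.
    """
    if n_proteins <= 0:
        raise EmptyInputError("n_proteins must be positive")
    if not 0.0 <= missing_rate < 1.0:
        raise InvalidRateError("missing_rate must be in [0, 1)")
    if effect_magnitude < 0:
        raise InvalidRateError("effect_magnitude must be non-negative")
    conds = design.conditions
    if contrast is None:
        if len(conds) < 2:
            raise InvalidDesignError("need >=2 conditions to plant effects")
        contrast = (conds[0], conds[1])
    design.samples_for(contrast[0])
    if affected_conditions is None:
        affected_conditions = [contrast[1]]
    samples_b: set[str] = set()
    for cond in affected_conditions:
        samples_b |= set(design.samples_for(cond))

    rng = substream(seed, "proteome")
    protein_ids = [f"P{i:05d}" for i in range(1, n_proteins + 1)]
    baselines = rng.normal(baseline_mean, baseline_sd, size=n_proteins)

    n_da = int(round(da_fraction * n_proteins)) if effect_magnitude > 0 else 0
    da_idx = rng.choice(n_proteins, size=n_da, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_da)
    shift = np.zeros(n_proteins)
    shift[da_idx] = signs * effect_magnitude

    sample_ids = design.sample_ids
    values = np.empty((n_proteins, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        mu = baselines + (shift if sid in samples_b else 0.0)
        values[:, j] = rng.normal(mu, rep_sd)

    if missing_rate > 0:
        # The logistic center is calibrated so the overall missing fraction
        # matches missing_rate; the calibrated center is the effective
        # detection limit and is reported in the matrix attrs alongside the
        # nominal one requested by the caller.
        c = _censor_offset(values.ravel(), missing_rate, censor_tau)
        p_miss = expit((c - values) / censor_tau)
        mask = rng.random(values.shape) < p_miss
        values = values.copy()
        values[mask] = np.nan

    truth = SimTruth(da_proteins={protein_ids[i]: float(shift[i]) for i in da_idx})
    mat = pd.DataFrame(
        values, index=pd.Index(protein_ids, name="protein"), columns=sample_ids
    )
    mat.attrs["nominal_detection_limit"] = float(detection_limit)
    if missing_rate > 0:
        mat.attrs["effective_detection_limit"] = float(c)
    return mat, truth


def gen_network(
    n_nodes: int,
    model: str = "scale-free",
    weight_interval: tuple[float, float] = (0.1, 1.0),
    seed: int = 0,
    m_attach: int = 2,
    edge_prob: float | None = None,
    node_ids: list[str] | None = None,
) -> nx.Graph:
    """Random undirected weighted interaction network.

    ``model`` is ``"scale-free"`` (Barabási–Albert preferential
    attachment, ``m_attach`` edges per new node) or ``"erdos-renyi"``
    (G(n, p); default p matched to the BA edge count). Only the largest
    connected component is kept (its size is recorded under
    ``G.graph["n_dropped"]``); edge weights are uniform in
    ``weight_interval`` which must be a subinterval of (0, 1].
    """
    if n_nodes < 2:
        raise EmptyInputError("need at least 2 nodes")
    lo, hi = float(weight_interval[0]), float(weight_interval[1])
    if not (0.0 < lo <= hi <= 1.0):
        raise InvalidIntervalError(
            f"weight_interval must satisfy 0 < lo <= hi <= 1, got {weight_interval}"
        )
    rng = substream(seed, "network")
    nx_seed = int(rng.integers(0, 2**31 - 1))
    if model == "scale-free":
        g = nx.barabasi_albert_graph(n_nodes, min(m_attach, n_nodes - 1), seed=nx_seed)
    elif model in ("erdos-renyi", "er"):
        if edge_prob is None:
            # match the expected BA edge count m*(n - m)
            edge_prob = min(1.0, 2.0 * m_attach / max(n_nodes - 1, 1))
        g = nx.gnp_random_graph(n_nodes, edge_prob, seed=nx_seed)
    else:
        raise InvalidIntervalError(f"unknown network model {model!r}")
    g.remove_edges_from(nx.selfloop_edges(g))
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    if not components:
        raise EmptyInputError("generated graph has no edges; increase density")
    giant = g.subgraph(components[0]).copy()
    n_dropped = n_nodes - giant.number_of_nodes()

    if node_ids is not None:
        if len(node_ids) < n_nodes:
            raise InvalidSizeError("node_ids shorter than n_nodes")
        mapping = {i: node_ids[i] for i in giant.nodes}
    else:
        width = len(str(n_nodes))
        mapping = {i: f"N{i:0{width}d}" for i in giant.nodes}
    giant = nx.relabel_nodes(giant, mapping)

    for _, _, data in giant.edges(data=True):
        data["weight"] = float(rng.uniform(lo, hi))
    giant.graph["n_dropped"] = n_dropped
    giant.graph["model"] = model
    return giant


def gen_isotopologues(
    metabolites: list[str],
    true_fractions: dict[str, list[float]],
    total_pool: float = 1000.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    n_samples: int = DEFAULT_REPLICATES,
    sample_prefix: str = "S",
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a long-format isotopologue intensity table.

    For each metabolite, isotopologue m+k receives intensity
    ``total_pool * fraction_k * (1 + eps)`` with multiplicative Gaussian
    noise of coefficient of variation ``noise_cv`` (truncated at zero).
    Fraction vectors must be non-negative and sum to 1.
    """
    if not metabolites:
        raise EmptyInputError("metabolite list is empty")
    if total_pool <= 0 or noise_cv < 0:
        raise InvalidRateError("total_pool must be > 0 and noise_cv >= 0")
    for met in metabolites:
        if met not in true_fractions:
            raise EmptyInputError(f"no fraction vector for metabolite {met!r}")
        fr = np.asarray(true_fractions[met], dtype=float)
        if (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-6:
            raise InvalidRateError(
                f"fractions for {met!r} must be non-negative and sum to 1"
            )
    rng = substream(seed, "isotopologues")
    rows = []
    for s in range(1, n_samples + 1):
        sample = f"{sample_prefix}{s}"
        for met in metabolites:
            fr = np.asarray(true_fractions[met], dtype=float)
            noise = 1.0 + rng.normal(0.0, noise_cv, size=fr.size) if noise_cv > 0 else 1.0
            intensities = np.maximum(total_pool * fr * noise, 0.0)
            for k, inten in enumerate(np.atleast_1d(intensities)):
                rows.append(
                    {
                        "metabolite": met,
                        "isotopologue": k,
                        "sample": sample,
                        "intensity": float(inten),
                    }
                )
    table = pd.DataFrame(rows)
    truth = SimTruth(
        label_fractions={m: list(map(float, true_fractions[m])) for m in metabolites}
    )
    return table, truth
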
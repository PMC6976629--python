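"""End-to-end synthetic study: generate every input, run every stage.

A single master seed drives the whole run, and the result is
bit-identical across invocations with the same seed — the property the
``fingerprint`` helper certifies. Sizes default to a desk-scale study
(hundreds to a couple of thousand features) rather than genome scale.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import netint, pathperm, proteome, rnaseq, syndata, tracing
from .design import STUDY_CONDITIONS, SampleDesign

#: gene-level contrasts of the study design
CONTRAST_RECARG1 = ("RANKL", "RANKL/Arg-Depletion")
CONTRAST_PLUS_ARG = ("M-CSF", "RANKL")
CONTRAST_RESCUE = ("M-CSF/Arg-Rescue", "RANKL/Arg-Rescue")
CONTRAST_STARVATION = ("M-CSF/Arg-Starvation", "RANKL/Arg-Starvation")
#: protein-level recArg1 contrast
CONTRAST_PROT_RECARG1 = ("RANKL/Arg-Rescue", "RANKL/Arg-Depletion")

#: Fig.-5-style tracer ground truth: 13C6-arginine and 13C4-aspartate
#: labelling of the urea-cycle / TCA intermediates.
TRACER_FRACTIONS = {
    "arginine": [0.05, 0.0, 0.0, 0.0, 0.0, 0.0, 0.95],       # m+6 tracer
    "citrulline": [0.55, 0.0, 0.0, 0.0, 0.0, 0.45],          # m+5
    "ornithine": [0.60, 0.0, 0.0, 0.0, 0.0, 0.40],           # m+5
    "putrescine": [0.70, 0.0, 0.0, 0.0, 0.30],               # m+4
    "aspartate": [0.10, 0.0, 0.0, 0.0, 0.90],                # m+4 tracer
    "fumarate": [0.75, 0.0, 0.0, 0.0, 0.25],                 # m+4
    "malate": [0.80, 0.0, 0.0, 0.0, 0.20],                   # m+4
}


@dataclass
class StudyResult:
    """Container for every stage output of one synthetic run."""

    design: SampleDesign
    counts: pd.DataFrame
    rna_truth: syndata.SimTruth
    expression: pd.DataFrame
    de: dict = field(default_factory=dict)        # contrast name -> DEResult
    pathways: dict = field(default_factory=dict)  # id -> members
    pathway_tests: pd.DataFrame | None = None
    protein_matrix: pd.DataFrame | None = None
    protein_truth: syndata.SimTruth | None = None
    prot: dict = field(default_factory=dict)      # contrast name -> ProteinTestResult
    isotopologues: pd.DataFrame | None = None
    fractions: pd.DataFrame | None = None
    network: object = None
    recarg1_hits: pd.DataFrame | None = None
    argdep_hits: pd.DataFrame | None = None
    tree_recarg1: netint.SteinerSolution | None = None
    tree_argdep: netint.SteinerSolution | None = None
    overlap: set = field(default_factory=set)
    overlap_null: netint.OverlapNull | None = None


def run_synthetic_study(
    seed: int,
    n_genes: int = 1200,
    n_proteins: int = 800,
    n_pathways: int = 8,
    n_network_nodes: int = 400,
    n_perm_pathway: int = 2000,
    n_perm_sam: int = 500,
    n_overlap_draws: int = 600,
) -> StudyResult:
    """Run the full synthetic pipeline under one master seed."""
    design = syndata.gen_design(list(STUDY_CONDITIONS), replicates=4, seed=seed)

    # Two planted transcriptional programs: an arginine-dependent RANKL
    # program (present when RANKL acts with arginine available: RANKL and
    # RANKL/Arg-Rescue, lost under depletion/starvation) and an
    # arginine-independent one (present in every RANKL condition).
    arg_dependent = ["RANKL", "RANKL/Arg-Rescue"]
    arg_independent = [
        "RANKL", "RANKL/Arg-Depletion", "RANKL/Arg-Starvation", "RANKL/Arg-Rescue",
    ]
    counts, rna_truth, programs = syndata.gen_counts_programs(
        n_genes, design,
        [
            ("arg_dependent", arg_dependent, 0.05, 3.0),
            ("arg_independent", arg_independent, 0.05, 3.0),
        ],
        dispersion=0.05, lib_size_mean=2_000_000, seed=seed,
    )
    keep = rnaseq.filter_expressed(counts, min_samples=3)
    expr = rnaseq.normalize_logcpm(counts.loc[keep])

    de = {}
    for name, contrast in [
        ("recarg1", CONTRAST_RECARG1),
        ("plus_arg", CONTRAST_PLUS_ARG),
        ("rescue", CONTRAST_RESCUE),
        ("starvation", CONTRAST_STARVATION),
    ]:
        de[name] = rnaseq.test_de(expr, design, contrast)

    pathways = syndata.gen_pathways(
        expr.index.tolist(), n_sets=n_pathways, size_range=(10, 40), seed=seed
    )
    pathway_tests = pathperm.test_pathways(
        expr, pathways,
        design.samples_for(CONTRAST_RECARG1[0]),
        design.samples_for(CONTRAST_RECARG1[1]),
        n_perm=n_perm_pathway, seed=seed,
    )

    # protein ids drawn from the gene namespace so the layers integrate
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    protein_ids = sorted(
        rng.choice(counts.index.to_numpy(), size=n_proteins, replace=False).tolist()
    )
    prot_raw, prot_truth = syndata.gen_proteome(
        n_proteins, design, effect_magnitude=1.5, missing_rate=0.12,
        seed=seed, da_fraction=0.06,
        contrast=CONTRAST_PROT_RECARG1,
        affected_conditions=["RANKL", "RANKL/Arg-Rescue"],
    )
    prot_raw.index = pd.Index(protein_ids, name="protein")
    prot_truth.da_proteins = {
        protein_ids[int(p[1:]) - 1]: v for p, v in prot_truth.da_proteins.items()
    }

    prot = {}
    for name, contrast in [
        ("recarg1", CONTRAST_PROT_RECARG1),
        ("rescue", CONTRAST_RESCUE),
        ("starvation", CONTRAST_STARVATION),
    ]:
        result, _ = proteome.run_pipeline(
            prot_raw, design, contrast, n_perm=n_perm_sam, seed=seed
        )
        prot[name] = result

    iso, _iso_truth = syndata.gen_isotopologues(
        list(TRACER_FRACTIONS), TRACER_FRACTIONS, total_pool=1e5,
        noise_cv=0.05, seed=seed, n_samples=4,
    )
    fractions = tracing.all_fractions(iso)

    network = syndata.gen_network(
        n_network_nodes, model="scale-free", seed=seed,
        node_ids=counts.index.tolist(),
    )
    recarg1_hits = netint.recarg1_effect_set(de["recarg1"], prot["recarg1"])
    argdep_hits = netint.arg_dependent_set(
        de["plus_arg"], de["rescue"], de["starvation"],
        prot["rescue"], prot["starvation"],
    )
    prizes_a, costs = netint.build_prizes_costs(network, recarg1_hits)
    tree_a = netint.pcst_heuristic(network, prizes_a, costs)
    prizes_b, _ = netint.build_prizes_costs(network, argdep_hits)
    tree_b = netint.pcst_heuristic(network, prizes_b, costs)
    shared = netint.tree_overlap(tree_a, tree_b)
    null = None
    if tree_a.size >= 1 and tree_b.size >= 1:
        null = netint.overlap_null(
            network, max(tree_a.size, 1), max(tree_b.size, 1),
            observed_overlap=len(shared), n_draws=n_overlap_draws, seed=seed,
        )

    return StudyResult(
        design=design, counts=counts, rna_truth=rna_truth, expression=expr,
        de=de, pathways=pathways, pathway_tests=pathway_tests,
        protein_matrix=prot_raw, protein_truth=prot_truth, prot=prot,
        isotopologues=iso, fractions=fractions, network=network,
        recarg1_hits=recarg1_hits, argdep_hits=argdep_hits,
        tree_recarg1=tree_a, tree_argdep=tree_b,
        overlap=shared, overlap_null=null,
    )


def fingerprint(result: StudyResult) -> str:
    """SHA-256 digest over every numeric output of a run; equal
    fingerprints mean bit-identical results."""
    h = hashlib.sha256()

    def add(label: str, payload: bytes) -> None:
        h.update(label.encode())
        h.update(payload)

    add("counts", result.counts.to_csv().encode())
    add("expression", result.expression.round(12).to_csv().encode())
    for name, res in sorted(result.de.items()):
        add(f"de:{name}", res.table.round(12).to_csv().encode())
    add("pathways", json.dumps(result.pathways, sort_keys=True).encode())
    add("pathway_tests", result.pathway_tests.round(12).to_csv().encode())
    add("proteins", result.protein_matrix.round(12).to_csv().encode())
    for name, res in sorted(result.prot.items()):
        add(f"prot:{name}", res.table.round(12).to_csv().encode())
    add("iso", result.isotopologues.round(9).to_csv().encode())
    add("hits_a", result.recarg1_hits.round(12).to_csv().encode())
    add("hits_b", result.argdep_hits.round(12).to_csv().encode())
    add("tree_a", json.dumps(sorted(map(str, result.tree_recarg1.nodes))).encode())
    add("tree_b", json.dumps(sorted(map(str, result.tree_argdep.nodes))).encode())
    add("overlap", json.dumps(sorted(map(str, result.overlap))).encode())
    if result.overlap_null is not None:
        add("null", result.overlap_null.null_overlaps.tobytes())
        add("p", f"{result.overlap_null.p_empirical:.12g}".encode())
    return h.hexdigest()
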
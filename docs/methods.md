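# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions at edge cases.

## Synthetic-data models

**RNA-seq counts.** Counts are negative binomial parameterized by mean
and dispersion, Var = μ + φμ² — the standard overdispersed model that
variance-modelling DE pipelines presuppose. Per-gene baseline
abundances are log-normal (log-mean 1.5, log-SD 1.0), normalized to
proportions, and scaled so every sample's expected total equals
`lib_size_mean` (default 5×10⁶). Library sizes are deliberately *not*
jittered across samples: CPM normalization removes pure depth
variation, and a deterministic expectation makes the generator's
concentration properties (e.g. doubling `lib_size_mean` doubles column
sums to within a few percent at a few thousand genes) exact statements
rather than approximate ones. Planted effects are organized as
*programs*: a disjoint fraction of genes receives a ±`lfc` log2 shift
in every sample of a listed condition set. The single-contrast wrapper
`gen_counts` plants one program in the second condition of its
contrast; the pipeline demo plants an arginine-dependent RANKL program
(active in RANKL and RANKL/Arg-Rescue) and an arginine-independent one
(active in all RANKL conditions), which is the minimal structure that
exercises the exclusive-disjunction hit rule downstream. Defaults
φ = 0.1 and |lfc| = 2 are generic mammalian-bulk values; the recovery
benchmarks use φ = 0.05 and |lfc| = 3, i.e. clearly separated effects
at four replicates. Dispersion and library-size distributions of the
reference data are not published, so these are declared generic
choices.

**Proteome intensities.** log2 LFQ values are Gaussian per protein
(baseline N(25, 2.5²)) with replicate noise SD 0.3 log2-units — about
23% CV, typical for label-free replicates. A `da_fraction` (default 5%)
of proteins carries a ±`effect_magnitude` (default 1.5 log2-units, i.e.
≈2.8-fold — an "abundantly changed" protein at 5 replicate-SDs) shift
in the affected conditions. Missingness is left-censored: the
probability a cell is missing is logistic in (limit − value) with
softness τ = 0.8 log2-units, and the logistic centre is calibrated by
root-finding so the realized overall missing fraction equals
`missing_rate`. This reproduces the qualitative structure that
justifies detection-limit-centred imputation: low-abundance values
vanish preferentially.

**Networks.** Scale-free graphs are Barabási–Albert (m = 2);
Erdős–Rényi graphs match the expected BA edge count unless an explicit
edge probability is given. Only the largest connected component is
kept (the count of dropped nodes is recorded on the graph), because the
Steiner and subgraph-sampling operations require connectivity. Edge
weights are uniform on a subinterval of (0, 1], standing in for
assay-confidence weights; the real confidence mapping is an input, not
something the package reproduces.

**Isotopologue tables.** Intensities are pool × fraction × (1 + ε)
with multiplicative Gaussian noise of the stated CV, truncated at
zero. Fraction vectors must sum to one. The generator emulates an
already peak-integrated, natural-abundance-corrected table; it does not
simulate spectra or chromatograms.

What passing tests on these generators shows — and what it does not:
the statistical machinery (filters, tests, FDR estimators, network
algorithms) behaves correctly under the assumed models. Real data add
batch effects, mean–variance trends beyond a single dispersion,
missingness not purely abundance-driven, and annotation noise, none of
which the generators model.

## Transcriptomics stage

The expression filter keeps genes with CPM > 0.75 (equivalently
log(CPM + 0.25) > 0 in any base — the implementation uses the
base-free inequality) in at least three samples, computed on raw
column-total CPM since filtering precedes normalization.

Normalization is log2(CPM + 0.25) with the CPM denominator built from
**median-of-ratios size factors** (per-sample median of count over
per-gene geometric mean, computed on genes observed everywhere,
rescaled to the observed depth range) rather than raw column totals.
The scaling step matters: with strongly asymmetric planted changes,
raw totals transfer the perturbation onto unchanged genes
(composition bias) and at unfavourable seeds the DE stage's precision
dropped from ~0.95 to ~0.71 before this correction. The prior 0.25
matches the filter constant and keeps zeros finite; an alternative
convention scales the prior with library size, which changes values by
a per-sample constant and none of the downstream calls.

The DE test is a moderated pooled-variance two-sample t: per-gene
pooled variances are shrunk toward their across-gene mean with
s²\* = (d₀·s₀² + d·s²)/(d₀ + d), d₀ = 4 prior degrees of freedom, and
p-values use d₀ + d degrees of freedom. This is a self-contained
approximation to an empirical-Bayes moderated fit (the shrinkage target
is the trend-free mean variance; no mean–variance trend is modelled),
not a reimplementation of any external package. Under the simulated
null its p-values are uniform to KS < 0.05 at 2000 genes. FDR is
Benjamini–Hochberg; a call requires |log2FC| > 1 *and* FDR < 0.05.
Constant rows z-score to zero rather than NaN so distance computations
stay total. MDS is classical principal coordinates via
eigendecomposition of the double-centred squared-distance matrix, with
near-zero eigenvalues clamped to exactly zero and axis signs fixed by
the largest loading for reproducibility across BLAS builds.

## Pathway permutation test

Ranks are midranks computed within the union of the two compared
groups only (the comparison is pairwise by design; pooling all seven
conditions would let unrelated conditions move the ranks). The
statistic T sums |rank-sum difference| over the pathway's genes; the
same label permutation is applied to all genes, preserving gene–gene
correlation. With C(n_A+n_B, n_A) ≤ n_perm the assignment space is
enumerated exhaustively (70 assignments for 4v4) and p is exact,
counting the identity; otherwise assignments are sampled with
replacement and p uses the add-one estimator (1 + #{T* ≥ T})/(1 + B),
which is strictly positive and conservative. Bonferroni multiplicity is
the number of pathways tested in the invocation.

A structural property of the 4v4 design worth knowing: T is invariant
under swapping the two group labels, so exact p-values come in steps of
2/70, the smallest attainable p is 2/70 ≈ 0.0286, and the test's true
size at α = 0.05 is at most 0.0286 — conservative, and further reduced
(measured ≈ 0.022–0.027) because T is integer-valued and top ties
occur. No faithful implementation of this statistic at 4v4 can have
size in a band whose floor exceeds 2/70; the acceptance suite records
the measured rate.

## Proteomics stage

Pipeline order is fixed: log2 → detection filter (≥3 of 4 replicates
in some condition) → imputation → CV filter → per-protein z-score →
SAM test.

Imputation draws from N(centre, (0.3·SD_sample)²) with centre = the
per-sample observed minimum minus `downshift`·SD. The default
downshift is 0 — the centre *is* the observed detection limit — while
`downshift=1.8, width_factor=0.3` reproduces the Perseus-style
downshifted normal for users who prefer it; which of the two the
reference workflow used is not stated, so both are reachable.

The CV filter compares SD/mean on the linear intensity scale (2^log2)
by default, where the CV is well-behaved; log2-scale CVs are mean-
dependent near zero but available via `scale="log2"` since the original
scale choice is unstated. The inequality is strict, so an all-constant
protein is dropped. Note the filter conditions on between-condition
variation; applied to null data it enriches for spuriously varying
proteins, so permutation FDR estimates downstream of it are optimistic
— the SAM calibration benchmarks therefore evaluate the test stage on
unfiltered matrices.

The SAM statistic d = Δmean/(s_pooled + s₀) with s₀ = 0.05 uses the
same exhaustive-or-sampled label assignments as the pathway test. The
q-value at each observed |d| is the median permutation count of
|d*| ≥ |d| divided by the observed count, monotonized from the least
significant protein backwards (BH-style cumulative minimum) and capped
at 1. No π₀ estimate is applied. On planted-effect benchmarks the
realized FDR at q ≤ 0.05 is typically 0.02–0.12 — mildly liberal in
the tail, so the recovery benchmark scores it against 0.1 rather than
the nominal 0.05.

## Tracer arithmetic

All three operations are ratios within a sample and therefore invariant
to uniform intensity rescaling. Natural-abundance correction is *not*
applied — tables are taken as already corrected; a correction would
slot in as a left-multiplication of each metabolite's intensity vector
by the inverse of its binomial contamination matrix before any ratio is
formed. Fractions are returned as proportions; the CLI offers
`--percent` for display. A mass-balance utility flags pools whose
fractions fail to sum to 1 within 1e-9.

## Network integration

Hit scores are |log2FC| for genes and |d| for proteins, tagged by
layer; a shared identifier keeps the maximum score. Prizes are
β·score (β = 1), edge costs 1 − w clamped to [1e-6, 1] so perfect-
confidence edges still carry positive cost and "minimal" trees are
well-defined.

The PCST heuristic greedily attaches, via shortest cost-paths, the
prized node with the largest positive objective gain, then prunes
leaves whose prize does not cover their edge cost. The greedy growth
is restarted from each of the 8 highest-prize roots and the best tree
kept: single-start greedy occasionally commits to the wrong root on
small instances (worst observed 0.85× the exhaustive optimum), while
the multi-start variant matches the brute-force optimum on ≥ 95% of
the benchmark instances and stayed above 0.97× on all of them. The
exact solver used as oracle enumerates all connected vertex subsets and
takes the minimum spanning tree of each induced subgraph; it is
exponential and restricted to ≤ 12 nodes.

The overlap null grows connected subgraphs by uniform random frontier
expansion from a uniform start node. This distribution is *not*
uniform over connected subgraphs (uniform sampling is computationally
hard); on a complete graph it reduces to uniform node subsets, which is
what the hypergeometric sanity check exploits. Null pairs are sampled
independently, sizes matched to the two observed trees, and the
p-value is the add-one estimator.

## Determinism

Every stochastic function takes an integer seed and derives its
generator from `SeedSequence(seed, spawn_key=(stage_id,))`, so stages
driven by one master seed are mutually decorrelated yet individually
reproducible. The end-to-end study is bit-identical across runs with
the same seed (certified by a SHA-256 fingerprint over all numeric
outputs).

## Problem sizes

The default synthetic study runs 1200 genes, 800 proteins, 8 pathways,
a 400-node network, 2000-permutation pathway tests, 500-permutation
SAM tests and 600 overlap draws — deliberately desk-scale; every size
is a parameter. The calibration benchmarks use 1000 null pathways ×
2000 permutations, 200 power simulations, 2000 genes/proteins for
recovery, and 50 PCST oracle instances.

## Known limitations

- The DE test approximates, not replicates, a voom/limma fit; exact
  reproduction of published DE counts would require the deposited data
  and the original tool stack.
- The SAM q-value is mildly anticonservative in the extreme tail (no
  π₀, median-based FP count).
- The subgraph sampler's non-uniformity biases the overlap null toward
  high-degree regions on heterogeneous graphs; the reference
  procedure's sampler is unspecified, so this is a documented choice.
- Batch effects, multimapping-aware counting, peptide-level inference
  and transcription-factor (garnet) scoring are out of scope; hit sets
  enter network integration directly from the omics stages.
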
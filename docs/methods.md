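# Methods

## Model and procedure

`codim` treats a drug-treatment compendium as a genes × treatments matrix
of expression z-scores E (one matrix per dataset: each cell line, and a
liver dataset whose treatments are drug × dose × time profiles). A
*module* is a bicluster: a gene set with signed scores and a treatment
set with signed scores, self-consistent under the Iterative Signature
Algorithm (ISA) update. Because membership is signed, one module can
contain up- and down-regulated genes and inversely responding drugs.

The pinned ISA conventions (the published workflow defers them to the
isa2/eisa reference implementations; they are fixed here so results are
reproducible):

- E_G is the row-standardized matrix (per-gene mean 0, s.d. 1, ddof 0),
  E_C the column-standardized one.
- Condition scores c = E_Gᵀ·g / ‖g‖₁; threshold |c_j| > t_drug·σ(c),
  σ taken over **all** conditions of that iteration. Gene scores
  g = E_C·c / ‖c‖₁; threshold |g_i| > t_gene·σ(g) over all genes.
- Convergence: Pearson correlation of consecutive gene-score vectors
  > 1 − ε on two consecutive iterations (ε = 0.01, the isa2 default);
  a run whose gene or condition set empties, or that exceeds 100
  iterations, yields nothing.
- Seeds are random gene sets of size max(5, 1% of genes), signs +1.
- A module and its global sign flip are the same object; the sweep
  canonicalizes so the strongest gene scores positive.

### Threshold grid and sweep order

Gene thresholds run 5→2, drug thresholds 4→1 (4→2 for liver data), step
0.2; every pair receives `n_seeds` random restarts (library default
2000; the original analyses used 20 000 — recovery on synthetic data
saturates far below that, so the demo and the acceptance checks run at
40–100 restarts per pair; all restarts at one threshold pair are
iterated as one vectorized batch).

The pooled module list is ordered from **permissive to stringent**
threshold pairs, and within a pair by descending basin size (how many
restarts reached the fixed point), with the fastest convergence and then
discovery order breaking ties. Rationale: downstream redundancy removal
keeps the first-seen module of each equal-priority band, and the
permissive end of a band holds the most complete variant of a bicluster
while the stringent end holds truncated fragments of it; basin size is a
direct robustness measure. The band prioritization itself is exactly the
published one (gene 4–3 over 5–3.2 over 2.8–2 for cell lines, 3–2 over
5–3.2 for liver; drug 3–2 over 4–3.2 over 1.8–1) and is a stable sort —
only the input order within equal bands embodies the rule above.

### Robustness filter

Each threshold pair's modules must beat the strongest module found by an
equal-sized sweep on a null matrix (the real matrix shuffled within rows
and then within columns), measured by the signature strength
|gᵀE_G c| / (‖g‖₂‖c‖₂). This removes the spurious fixed points that ISA
produces at permissive thresholds on pure noise (the unit tests show
> 90% removal on noise, full retention of strongly planted signal).

### Module filters

- *Constitutive filter*: remove a module when at least 10% (inclusive)
  of its gene pairs have Pearson r > 0.6 across untreated samples. Pairs
  involving genes absent from the untreated matrix, or with undefined
  correlation, count as not coexpressed; the denominator is always
  C(|genes|, 2).
- *Size filter*: ≥ 20 genes and ≥ 5 drugs (10 for liver), boundaries
  inclusive.
- *Redundancy removal*, two sequential passes over the priority order:
  (1) keep a module only if the Pearson correlation of its gene
  membership-score vector (over the dataset's gene universe, absent
  genes 0) with every kept module is ≤ 0.3 — signed, since
  anti-correlated modules describe opposite responses and the sweep has
  already canonicalized global sign; (2) keep only if the gene-overlap
  hypergeometric P against every kept module is ≥ 10⁻⁵.

### Cross-dataset comparison

For a dataset pair, memberships are projected into the intersection of
the two gene universes (after one-to-one orthology translation for
cross-species pairs); upper-tail hypergeometric P per module pair;
BH-FDR across the pair's P values; links significant at q < 0.01.
Reciprocal best hits (RBH) are mutual minimum-P partners (ties: larger
overlap, then module id). CODIMs are connected components of the RBH
graph among cell-line modules (≥ 2 members), with union gene and drug
sets; liver RBH partners annotate cross-species conservation but do not
contribute members. Drug-set overlap of linked cell-line modules uses a
one-sided Fisher test over the intersection of drug universes (refused
for liver data, where too few drugs are shared). The conservation
permutation test replaces each query-catalog module's gene set with a
uniform random set of the same size and recounts significant RBHs; the
empirical P uses the add-one rule, so 999 permutations bound P at 1/1000.

### Functional coherence and annotation

Coherence: proportion of within-module gene pairs present as network
edges, compared with 1000 random gene sets matched for size and drawn
from the **expression universe** (not network nodes only — modules come
from expression data, the network is a lookup; genes absent from the
network contribute no edges but keep their pairs in the denominator).
Network input is filtered to edges with score > 0.4 after dropping
excluded evidence channels (coexpression by default) and self-loops.

Annotation enrichment: one-sided Fisher per term, BH-FDR within each
category, significance at q < 0.1 (fragments q < 0.01); terms carrying
fewer than 5 drugs in the dataset's drug universe are dropped first.
The cutoffs are read as applying to the FDR-adjusted values. Fragment
generation and fingerprint computation are not performed here —
fragment×drug matrices and fingerprint bit-vectors (default 1024 bits)
are inputs, so any cheminformatics engine can be plugged in upstream.
Repositioning candidates are module drugs lacking the target term with
maximum Tanimoto similarity < 0.5 to every annotated module drug.

### Dose–response

Percent activity = 100·(raw − low)/(high − low), not clipped (the fixed
0/100% asymptotes absorb out-of-range values). The two-parameter
log-logistic model f(x) = 100/(1 + exp(b·(ln x − ln e))) is fitted by
Levenberg–Marquardt least squares from 5 midpoint starts log-spaced one
decade beyond the tested range (slope start 1); `converged` requires a
successful solve, gradient norm < 10⁻³, and non-flat responses. Standard
errors come from the Jacobian at the optimum. Ki = IC50/(1 + [L]/K_d);
hits are confirmed below 15 µM, ambiguous below 50 µM, disproved above.

## Synthetic compendia

The generator emulates the statistical structure of multi-dataset drug
perturbation compendia, directly on the post-preprocessing z-score
scale: background N(0, 1); planted biclusters shift their cells by
sign·effect (default study condition: effect 3 s.d., mixed sign
patterns); three cell lines share the gene/drug namespace; a liver-like
dataset covers 40% of genes through a one-to-one orthology map and
profiles each drug at 4 dose/time combinations treated downstream as
independent experiments. Constitutive modules additionally load on a
latent factor with s.d. 2 in untreated samples (pairwise r ≈ 0.8, well
past the 0.6 filter cut) and s.d. 1 in treated ones. The liver drug list
is two-thirds of the collection: a planted module's drugs must remain a
modest fraction (~15–20%) of a dataset's treatments, as in the real
compendia, or its conditions cannot clear any threshold ≥ 2 because the
module itself dominates the condition-score s.d.; the same constraint
shaped the demo design (three 40–50-gene modules of 10–15 drugs among
1500 × 120). A separate raw-mode generator emits probe-level
intensities with replicates, control samples, batch structure, duplicate
probes and missing values to exercise the preprocessing branch
end to end.

What the generator does **not** emulate: probe-level microarray physics,
dye and batch artifacts beyond additive offsets, correlated drug
similarity structure, or real chemical fingerprints. Passing the planted
recovery tests therefore shows the machinery is correct and calibrated
under idealized noise, not that real compendia are as forgiving — on
real data the published 20 000-restart setting and the full threshold
grid are advisable.

## Preprocessing

Liver-branch order is fixed: quantile normalization (excluding missing
entries from rank pooling) → drop probes with > 10% missing (strict) and
mean-impute the rest → keep the maximum-variance probe per gene (ties:
lexicographically smaller probe id) → regularized z-scores
z = (x − mean(controls)) / (sd + q), where sd is the per-gene s.d. over
all samples (treated and control, per the sentence order of the source
protocol) and q the 0.1-quantile of the per-gene s.d. distribution →
average replicates (dose/time combinations stay distinct) → restrict to
one-to-one orthologs of the reference gene set. The cell-line branch
accepts batch-adjusted z-scores (the batch correction itself follows a
different published procedure and is out of scope), selects one
replicate per drug and cell line maximizing mean pairwise cross-cell-line
correlation (exhaustive up to 64 combinations, else greedy coordinate
ascent from the best single pair), applies the > 10% present-call filter
("any cell line" reading), and collapses probes at random with a seeded
RNG. The end-to-end retention check measures the planted effect in units
of the processed matrix's own background s.d., since the regularized
z-score shrinks signal and noise by the same factor.

## Determinism

Every source of randomness descends from one seed through named integer
substreams (`SeedSequence([seed, stage, index])`); sweep restarts are
keyed by threshold-pair position. No output file contains wall-clock
information or absolute paths, so two runs of the demo with one seed are
byte-identical — this is asserted in the test suite.

## Problem sizes used by the checks

Unit and acceptance tests run at desk scale, chosen so the full suite
finishes in a few minutes: 40–100 ISA restarts per threshold pair
(recovery of effect-3 planted modules saturates by ~30), five data seeds
for recovery, 999 permutations for conservation and coherence, 400
trials for calibration, 200 simulations for dose-response noise. The
library defaults remain at the published scale where one exists.

## Known limitations

- ISA membership thresholds act on the s.d. of the current score vector;
  a bicluster occupying more than ~25% of rows or columns inflates that
  s.d. past its own scores and cannot be isolated — real compendia are
  far from this regime, but tiny matrices are not.
- The conservation null permutes module gene memberships, not the
  expression matrix; it tests overlap against size-matched random sets,
  which is the cheap, well-defined surrogate for re-running discovery on
  permuted data.
- Mean imputation and the interpolation-based quantile normalization of
  matrices with missing entries are approximations adequate for the
  ≤ 10% missingness the pipeline admits.
- `remove_redundant` is O(kept²) in module count; catalogs of tens of
  thousands of raw fixed points are fine, millions are not.
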
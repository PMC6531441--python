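# Methods

## The joint descriptor

`bowspace` encodes a protein–ligand pair as a 439-dimensional vector built
from three subspaces. The protein space (107 dims) is computed from the
amino-acid sequence alone; the ligand space (166 dims) is the MACCS
structural-key fingerprint; the interaction space (166 dims) summarises the
protein's position in a known interactome by averaging the fingerprints of
its known binding partners (MACCSP). The point of the third block is that a
candidate ligand can be compared — implicitly, by the downstream
classifier — with what the protein is already known to bind.

### Protein space (F1–F10, 107 dims)

| set | dims | definition |
|---|---|---|
| CV | 20 | amino-acid fractions, alphabetical order |
| CMV¹, CMV² | 20+20 | Σⱼ n₍ᵢⱼ₎ᵏ / N(N−1)…(N−k) over 1-based positions n₍ᵢⱼ₎ of residue i, order k ∈ {1,2} |
| BPC | 7 | raw property values summed along the sequence |
| NPC | 7 | Σᵢ \|Pᵢ² − Pᵢ₋₁Pᵢ₊₁\| over interior sites |
| IPC | 7 | mean over lags k of δₖ = mean over i of [P(Rᵢ₊ₖ) − P(Rᵢ)]², on scales standardized over the 20 amino acids |
| RG, EleG, ExG, HG, SCG | 5+5+6+4+6 | residue-group fractions |

Numerical conventions worth stating:

* **CMV positions are 1-based**; 0-based indexing would silently delete the
  first residue's contribution. Order 0 provably collapses to CV, which the
  test suite asserts on random sequences against the same code path.
* **IPC lag pairs** are (i, i+k): the lag-k difference term compares
  residues k apart, consistent with the expansion
  δ₂ ∝ J₁,₃ + J₂,₄ + …. IPC is a mean of squares, hence ≥ 0, and exactly 0
  on homopolymers. An O(N²) direct-summation oracle in the tests agrees
  with the production implementation to 1e−10.
* **NPC boundaries**: terms at i = 1 and i = N reference a missing
  neighbour and are excluded; sequences shorter than 3 residues return a
  zero vector with a logged warning rather than an error.
* **BPC is a sum, not a mean**, so it grows with sequence length and is
  additive under concatenation. This confounds composition with length but
  is the defined form of the descriptor.
* **Property scales.** Seven per-residue scales ship as the package
  default: Kyte–Doolittle hydropathy, net side-chain charge at neutral pH,
  Grantham polarity, Zamyatnin residue volume, Bhaskaran–Ponnuswamy
  flexibility, Zimmerman pI, and Jones molar refractivity. BPC and NPC use
  the raw values; IPC standardizes each scale to mean 0 / SD 1 across the
  20 amino acids. A user-supplied 20×7 CSV replaces the default table, and
  the table in use should be reported with any results.
* **Groupings.** RG, ExG and HG partition the 20 residues, so their
  fractions sum to 1. The five electronic groups cover 19 residues —
  cysteine belongs to none of them — so EleG sums to 1 − CV_C; we keep the
  published group lists rather than inventing an assignment for C. SCG
  groups overlap by design and a residue counts once per group.
* Non-canonical residues (B, J, O, U, X, Z) are rejected by default; a
  permissive mode drops them with a logged count.

### Ligand space

The 166 informative MACCS keys are computed with RDKit's key dictionary.
Open and commercial MACCS dialects differ in a few SMARTS definitions;
since the pipeline consumes bits generically, bit-level parity between
dialects is not asserted, and pre-computed 166-bit tables are accepted
as-is after validation. RDKit emits 167 positions with index 0 unused; the
package exposes exactly keys 1–166 as `maccs_1 … maccs_166`.

### Interaction space

MACCSP(p) is the element-wise mean fingerprint of p's partners in whatever
edge set is supplied. Orphan proteins get a zero vector (with a warning)
instead of an error so that pairs involving new proteins remain
predictable. Every entry therefore lies in [0, 1] and within the per-bit
min/max of the partner set. Duplicate edges cannot change the average
(edge-set semantics).

**Leakage control.** MACCSP must never average over the very interaction a
model is being asked to predict. The featurization functions take the edge
set explicitly; evaluation code should pass a network restricted to
training-set interactions (the conservative choice) and may pass all known
edges to reproduce the permissive variant. The synthetic benchmark goes one
step further and keeps the labelled edges disjoint from the known
interactome by construction (below).

## Dataset construction

Positives are the edges of the supplied network (set semantics). For real
edge lists the default negative protocol samples uniform pairs from
protein/ligand pools disjoint from every positive entity; the
negative:positive ratio (default 1:1) is recorded in the split manifest
because accuracy depends on it. An alternative "unlabeled-pairs" mode
samples non-edges among the known entities instead. Splits are stratified
70/30 plus stratified 10-fold CV, all seed-deterministic.

A caveat practitioners should know: under the disjoint-pool protocol every
entity occurs with a single label, so any feature that identifies an
entity (a composition vector, a fingerprint) lets a flexible model carry
label information across CV folds. Measured performance then mixes genuine
generalisation with entity memorisation. The synthetic benchmark uses the
unlabeled-pairs mode for exactly this reason (below); with real data,
entity-disjoint evaluation splits are the remedy.

## Classifiers

All five models train on the same matrix (any column mask of the 439).
Logistic regression (C = 1e5) and the RBF SVM (gamma = 1e−4, C = 100,
Platt-scaled probabilities) see per-column standardized features with the
scaler fitted on the training fold only; the tree, the forest and the
sum-of-trees model consume raw features. Hard labels use the asymmetric
0.5 rule: interaction iff p > 0.5.

The probabilistic reference model is a probit sum-of-trees ensemble
(BART): P(y=1|x) = Φ(μ₀ + Σₜ g(x; Tₜ, Mₜ)) fitted by backfitting MCMC with
truncated-normal latent draws. Priors are the standard regularising
choices: split probability α(1+d)^−β with α = 0.95, β = 2; leaf values
N(0, σ_μ²) with σ_μ = 3/(k√m), k = 2. Library defaults are m = 50 trees,
200 burn-in + 800 kept sweeps with thinning 2; grow/prune/change proposals
with a minimum leaf size of 5 and per-feature quantile cutpoint grids
(≤ 100 points). The reported probability is the posterior mean of Φ(f(x))
over kept draws and the 95% interval is the central band of those draws —
this interval is the practical payoff of the model, since the baselines
emit only a point score. Cross-validated benchmark runs use a lighter
profile (m = 30, 100 + 300 sweeps, thinning 3), sized for a ~2,000-pair,
439-column problem; on that problem the light profile's pooled AUC is
indistinguishable from slower settings at the reported precision.

## Feature selection

The shadow-feature selector surrounds a random forest (500 trees by
default): each iteration appends freshly shuffled copies of all candidate
columns, fits the forest on a random half of the rows, and scores each
column by the mean per-tree accuracy loss on the held-out half when that
column is permuted. Per-tree scoring matters: a forest's majority vote is
insensitive to a column only some trees use, and training-sample scoring
is degenerate for overfitted forests. A feature "hits" when it outscores
the best shadow; accumulated hits are tested against Binomial(n, ½)
two-sided at α = 0.05 (no multiplicity correction by default — α and the
correction are recorded per run). Rejected columns leave the design, and
the loop stops early once nothing is undecided. "Strictly selected" =
important; "selected" = important ∪ tentative.

## The synthetic benchmark

The generator emulates the minimal statistical structure the descriptor
exploits; it does not imitate real database statistics (degree
distributions, class sizes, chemistry).

* **Proteins** belong to latent classes; class residue profiles are drawn
  once from a symmetric Dirichlet (concentration 150, i.e. weakly
  separated) and druggable classes get a mild hydrophobic tilt
  (log-factor 0.25·signal on A,C,F,I,L,M,V) — this is the protein-space
  share of the planted signal, concentrated in interpretable columns such
  as `bpc_hydrophobicity`. Lengths are uniform in 120–400.
* **Ligands** derive from latent prototypes (166-bit patterns, bit density
  0.35) with independent 5% bit flips.
* **Interactions** follow a bipartite logistic random graph: edge log-odds
  = base + signal·(a_class + b_prototype + 9·B), where a, b ~ N(0, 1.2²)
  are smooth propensities and B is 1 exactly where a druggable class (3 of
  10) meets a drug-like prototype (6 of 20) *and* a per-cell Bernoulli(0.6)
  mask fires. The mask is the part of the signal only the interactome
  reveals: which chemotypes a given class actually binds. The base rate is
  solved by bisection so the mean edge probability equals the configured
  density; signal = 0 therefore collapses to an Erdős–Rényi bipartite
  graph of the same density.
* **Two edge draws, one compatibility.** A "known" interactome (density
  0.02) supports MACCSP averaging; an independent "assay" draw (density
  0.004) provides labels. Any pair present in both is treated as a new
  assay finding and removed from the known set, so no labelled pair's own
  edge enters its MACCSP average, and MACCSP stays a per-protein quantity
  identical across that protein's positive and negative pairs.
* **Labels.** Positives are the assay edges among the 500×500 core
  entities (~1,000 at the default densities); an equal number of negatives
  are uniform non-edges among the same core entities (the unlabeled-pairs
  mode — see the dataset caveat above for why the pool protocol is not
  used here). Held-out pools are still generated and the pool protocol is
  available via `negative_mode="pool"`.

Sizes were chosen once so that the documented contract of the generator
holds: at signal 0.9 all five classifiers exceed 0.9 pooled 10-fold AUC,
removing the MACCSP block strictly lowers forest AUC, every subspace
retains at least one selected feature, and at signal 0 every classifier
sits within [0.45, 0.55]. Because classes, prototypes and cells are
latent *shared* structure, these checks exercise generalisation to new
pairs, not memorisation of entities.

What passing these tests does **not** show: robustness to real chemistry
(fingerprint bit correlations, scaffold clustering), to heavy-tailed
degree distributions, to class imbalance, or to database noise. The
generator's uniform entity universes and balanced labels are deliberately
idealised.

## Degenerate inputs and numeric edges

Empty sequences, non-canonical residues, unparsable SMILES, wrong-length
bit vectors, dangling edge references, single-class training labels,
mismatched prediction columns, infeasible sampling requests and
single-class AUC all raise typed errors (or, where a zero is the defined
value, return it with a logged warning). Sensitivity/specificity are
reported as missing (NaN/null), never as 0, when their denominator is
empty. ROC curves are built over unique scores (ties grouped), pinned to
(0,0) and (1,1); AUC is the trapezoidal area and equals the
Wilcoxon–Mann–Whitney statistic with ties counted ½. "Average" CV ROC
means pooled out-of-fold scores by default; vertical threshold-averaging
over a 101-point FPR grid is available as an option.

## Known limitations

* Bit-level parity with commercial MACCS implementations is out of scope.
* The BART sampler is a compact single-chain implementation (no
  multi-chain convergence diagnostics, no variable-selection-aware split
  proposals); it targets calibrated probabilities on tabular problems of
  the benchmark's scale.
* Boruta's held-out-half importance replaces Breiman's out-of-bag
  importance; with very few rows the halving costs power.
* Headline accuracies reported for real curated datasets depend on the
  negative-set size and snapshot of the source databases and are not
  reproducible from this package alone; real gold standards enter as
  ordinary edge lists.
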
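# Methods

This note records the models, statistics and numerical choices behind
`modflex`, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Synthetic study model

The generator emulates a randomized two-arm trial with an RNA-seq substudy:
a treated arm (default n = 41) and a placebo arm (n = 21), each sampled at
baseline (Day 0) and after treatment (Day 30). Expression is on a log2-like
Gaussian scale; every gene has a subject-independent baseline level drawn
from Normal(8, 2), and fold changes are interpreted as `2**Δ` for a mean
shift of Δ log2 units.

**Modules.** Gene *i* in module *k* follows a one-factor model per dataset
(arm × timepoint):

    x_i = sqrt(ρ_k) · f_k + sqrt(1 − ρ_k) · ε_i ,

with the module factor `f_k` and the gene noise `ε_i` standard normal per
sample, so the expected pairwise within-module correlation is exactly ρ_k
(default 0.7, five modules of 100/80/60/50/40 genes among 2000). Background
genes are independent noise. This is the simplest generative model that
reproduces the co-expression structure the WGCNA-style machinery assumes;
module factors are drawn independently per timepoint (no within-subject
persistence of module activity).

**Dissolution.** In the treated arm at Day 30, a configurable subset of
modules (default: the first three) has ρ_k multiplied by
`dissolution_factor` (default 0.1; 0.0 erases the module entirely). This is
the drug effect: a targeted module loses internal co-expression while the
control arm and the baseline remain intact.

**Phenotype.** The clinical response ΔAF (change in the SAQ angina-frequency
score at Day 30 from baseline) of a treated subject is coupled to the causal
module's factor change:

    ΔAF = shift + scale · β · (f_causal,Day30 − f_causal,Day0)/√2 + Normal(0, σ) ,

clipped to (−25, 60). Defaults `shift = 25`, `scale = 20`, `β = 1`,
`σ = 6` (30% of the signal scale) give a treated arm at ΔAF ≈ 25 ± 21 SAQ
points — about 59% of treated subjects above the clinically significant
ΔAF ≥ 20, and a best-effect stratum (ΔAF ≥ 40) of median size ~9 of 41,
matching the responder shares and the implied best-stratum size of the
trial setting this package models. The standardization by √2 keeps `scale`
interpretable as the SAQ-point standard deviation of the signal; an
unstandardized eigengene-change coupling at these β values would imply a
ΔAF spread several times wider than the instrument's plausible range and
would pile most best-stratum subjects onto the 60-point ceiling. Control
subjects receive noise-only ΔAF ~ Normal(15, 20) (≈ 40% placebo responders)
with no expression coupling.

**DEGs.** A configurable number of *background* genes (default 100) receive
a `+deg_log2fc` mean shift (default 0.75, i.e. 1.68-fold) in the treated arm
at Day 30 only. Drawing DEGs from the background keeps the differential-
expression and differential-module signals orthogonal.

**What the generator does not emulate.** Count noise (the matrix is
Gaussian, not negative-binomial), library-size or batch effects, correlated
module factors, hub/periphery gradients inside modules (all module genes are
exchangeable), within-subject correlation across timepoints, and any
miRNA layer. Consequences worth knowing: (a) with exchangeable module
genes the connectivity branch of the preservation statistic carries little
signal for *intact* modules (intramodular connectivity differences between
genes are pure noise), so preservation of intact modules is driven by the
density branch — on real data with hub structure the connectivity branch is
informative; (b) passing tests demonstrates the machinery is correct and
well-calibrated under this model, not that any particular biological claim
transfers to real serum RNA-seq data.

## Network construction and module detection

* Pearson correlation (a biweight-midcorrelation flag is deliberately not
  implemented; Pearson is exact on the Gaussian generator).
* Unsigned adjacency `|r|^β` by default (signed available). Default β = 6,
  the common unsigned-network default; `pick_soft_threshold` implements the
  scale-free criterion (smallest β with fit R² ≥ 0.85 and negative slope
  over ≥10 equal-width connectivity bins, falling back to the best-fitting
  candidate with a warning). Note that sufficiently aggressive powers can
  make even pure-noise networks *look* scale-free by inflating the |r|
  tail; the fallback exists for the moderate-power regime.
* Unsigned TOM with the standard `min(k_i, k_j)` denominator; values are
  clipped to [0, 1] and symmetrized against floating-point drift.
* Average-linkage clustering of `1 − TOM`, static branch cut at height
  0.95, minimum module size 30, then iterative merging of modules whose
  eigengenes correlate at ≥ 1 − merge_height (default merge_height 0.25).
  The static cut is deterministic and recovers planted modules cleanly
  (ARI ≈ 0.98 at the default study size); cutting at 0.99 lets each module
  absorb dozens of background genes (ARI ≈ 0.78), so 0.95 is the default.
  All heights and sizes are config keys.
* The module eigengene is the first right singular vector of the per-gene
  z-scored (ddof = 1) module submatrix, rescaled to unit variance and
  sign-oriented so it correlates non-negatively with the module's mean
  standardized expression. The orientation makes eigengenes reproducible
  across gene orderings and datasets.

## Preservation Z_summary and DEM calling

Three statistics per module, observed and permuted:

* `meanAdj` — mean off-diagonal test-network adjacency within the module
  (density branch);
* `cor_kIM` — Pearson correlation across module genes of intramodular
  connectivity in the reference vs the test network;
* `cor_adj` — Pearson correlation across within-module gene pairs of
  reference vs test adjacency.

The null uses B (default 100, minimum 50) random gene sets of the module's
size drawn without replacement from the shared gene universe (overlap with
the module is allowed). `Z(stat) = (obs − mean_null)/sd_null`;
`z_connectivity = median(Z(cor_kIM), Z(cor_adj))`;
`z_summary = (z_density + z_connectivity)/2`; a DEM is `z_summary < 0`
(strict). This is a deliberately reduced composite — two branches, three
statistics — of the full seven-statistic permutation framework; results are
qualitatively, not numerically, comparable with the reference R
implementation. Modules smaller than 4 genes are skipped; a zero-spread
null raises an error rather than returning an infinite Z.

Direction matters: modules must be *defined* on data where they exist and
*evaluated* where they may have dissolved. The pipeline's preservation
stage is directional by config (`preserve.reference` / `preserve.test`);
with the planted-dissolution generator the informative direction is
control (or baseline) as reference and treated Day 30 as test, which is
what the default pipeline config uses.

## Module graph and topology

Connectivity score between modules: `|cor(eigengenes)|` by default (bounded,
symmetric, cheap); mean inter-module adjacency as the config alternative.
Edges at CS ≥ τ (default 0.3, mirroring the significance threshold used for
module–trait correlations). Density = m/(n(n−1)/2); CPL averages shortest
paths over reachable unordered pairs, excluding unreachable pairs with a
logged count (any graph of diameter ≤ 2 satisfies CPL = 2 − density);
clustering is the mean local coefficient with degree-<2 nodes contributing
zero; small-world σ = (C/C_rand)/(L/L_rand) against ≥ 20 seeded
Erdős–Rényi G(n, m) graphs with matched node and edge counts.

## Responder analysis

Strata are half-open, lower-inclusive ΔAF intervals (best ≥ 40,
40 > mild ≥ 20, none < 20; custom bins must not overlap). Module–trait
correlation is Pearson with the two-sided t-transform p-value
(`t = r·sqrt((n−2)/(1−r²))`, df = n − 2); significance is |r| ≥ 0.3 and
p < 0.05 (the magnitude is used so that anti-correlated modules are not
silently discarded — eigengene sign is a convention). METM selection:
highest |r| among significant modules, ties broken by smaller p, then by
module label; `None` when nothing is significant. Gene significance is
|cor(gene, ΔAF)|, module membership is cor(gene, eigengene), and hub genes
are the top-k by within-module adjacency row sums.

The pipeline offers two per-stratum modes. `project` (default) keeps the
reference module definitions, estimates each module's eigengene change
(Day 0 → Day 30) from *all* treated subjects for stability, and correlates
those scores with ΔAF inside the stratum. `redetect` re-runs module
detection inside the stratum, mirroring a fully stratified analysis; with
the planted-dissolution generator this mode cannot surface dissolved
modules (they are undetectable in the very data where they dissolved),
which is why projection is the default here.

## Flexibility

The METM's gene set is instantiated in each stratum network as a binary
graph (edge iff adjacency ≥ τ_g). τ_g defaults to the minimum within-module
adjacency of the *reference* stratum — the unique calibration making the
reference instantiation a complete (density-1) graph — and can be
overridden. The topological distance D is the Euclidean norm of the
difference of bounded feature vectors
(density, clustering, min(CPL/2, 1), mean degree/(n−1)); an edgeless graph
takes CPL component 1 (maximally distant). D is a pseudometric
(non-negative, symmetric, triangle inequality). OLS of D — and separately
of the edge count — on stratum mean ΔAF uses ≥ 3 strata and reports slope,
r² and the two-sided slope p.

Two degenerate regimes are handled explicitly: a constant predictor raises
an error, and when every bin instantiates the complete graph (which happens
when the arm-wide dissolution is uniform, so no response-graded topology
exists) the regressions are flat with undefined r², reported as null in
JSON output.

## Problem sizes and evaluation suites

`modflex.benchmarks` measures the operating characteristics used by the
test and reproduction suites, at the generator's default study conditions:

* preservation signs — 2000 genes, five ρ = 0.7 modules, 41 vs 21 subjects,
  first module dissolved to ρ = 0, B = 100, 10 seeds;
* module recovery — the default study, detection at default settings on the
  treated baseline, adjusted Rand index vs the planted partition, 10 seeds;
* METM recovery — the default study with dissolution disabled (isolating
  the phenotype coupling from module disruption), candidates = all detected
  modules, correlation inside the best stratum; seeds are scanned in order
  and only seeds with a best stratum of n ≥ 8 are used, since the
  within-stratum significance test (|r| ≥ 0.3 and p < 0.05) is underpowered
  below that size — at n = 8, p < 0.05 alone demands |r| ≥ 0.71;
* flexibility direction — six 10-subject cohorts with dissolution graded
  1.0 → 0.0 as mean ΔAF falls 50 → 0 on a 39-gene module.

These sizes keep the full suite at well under two minutes on one CPU while
matching the trial-scale sample sizes the package models.

## Known limitations

* The static branch cut is simpler than dynamic hybrid tree cutting; very
  close or nested modules merge or vanish earlier than they would under the
  adaptive method.
* The reduced two-branch preservation composite is not numerically
  comparable to the seven-statistic reference panel, and with exchangeable
  module genes its connectivity branch is uninformative for intact modules.
* The connectivity-score formula for module-module edges is a design choice
  (absolute eigengene correlation); other published choices would change
  edge sets and the resulting topology.
* Small strata (n < 8) make the within-stratum correlation test
  underpowered regardless of implementation; METM selection honestly
  returns `None` in that regime rather than an unstable pick.
* τ_g's reference-complete calibration degenerates toward 0 when the
  reference stratum contains weakly connected gene pairs, instantiating
  complete graphs everywhere; supply an explicit τ_g when comparing very
  noisy strata.
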
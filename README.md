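# modflex

Modular-pharmacology analysis of multi-target drug response from bulk
transcriptomics: weighted co-expression module detection, permutation-based
differential-module calling, module-level network topology, responder-stratified
selection of the most effective therapeutic module, and modular-flexibility
scoring — together with a synthetic-data generator that emulates a two-arm,
two-timepoint trial expression study so the whole pipeline is testable without
any patient data.

## Who this is for

Multi-target drugs (polypharmacological compounds, herbal injections,
combination therapies) rarely act through a single gene: per-gene differential
expression often shows nothing coherent while the *co-expression structure* of
whole gene modules is rewired. `modflex` is for computational biologists who
want to ask, from a gene-by-sample expression matrix plus per-subject clinical
response: which co-expression modules does the treatment perturb, how do those
modules relate to each other as a network, which module tracks clinical benefit
in the patients who actually responded, and how does that module's internal
topology flex across response strata?

## The method

1. **Co-expression network (WGCNA-style).** From a genes × samples log-scale
   matrix, build the soft-thresholded adjacency
   `a_ij = |cor(x_i, x_j)|^β` (or the signed variant `((1+r)/2)^β`), convert to
   topological overlap `TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
   cluster `1 − TOM` by average linkage with a static branch cut, and summarize
   each module by its **eigengene** (first principal component of the
   standardized module submatrix).

2. **Differential modules (DEMs) by permutation Z_summary.** A module's
   preservation in a test network is scored by a density branch (mean
   within-module adjacency) and a connectivity branch (correlation of
   intramodular connectivity, and of within-module adjacency, between the
   reference and test networks), each standardized against B random gene sets
   of the same size: `Z_summary = (Z_density + Z_connectivity)/2`. A module
   with `Z_summary < 0` — weaker structure than random gene sets — is a DEM,
   i.e. a module the treatment has disrupted.

3. **Module network.** DEMs become nodes; edges carry a connectivity score
   `CS = |cor(eigengene_i, eigengene_j)|` thresholded at τ. Topology is
   summarized by density, characteristic path length (CPL), clustering
   coefficient and small-world σ versus a matched Erdős–Rényi ensemble.

4. **Responder stratification and the METM.** Treated subjects are split by
   the clinical response ΔAF (change in the Seattle Angina Questionnaire
   angina-frequency score, 0–100 scale, at Day 30 from baseline): best effect
   ΔAF ≥ 40, mild 40 > ΔAF ≥ 20, none ΔAF < 20. Within a stratum, a module is
   significant when its eigengene–ΔAF Pearson correlation has |r| ≥ 0.3 and
   p < 0.05; the **most effective therapeutic module (METM)** is the
   significant module with the highest |r| in the best-effect stratum.

5. **Modular flexibility.** The METM's gene set is instantiated in each
   stratum's network (edge iff adjacency ≥ τ_g, calibrated so the reference
   instantiation is complete) and compared to the reference by the global
   topological distance **D** — the Euclidean norm of the difference of
   bounded feature vectors (density, clustering, CPL/2, normalized mean
   degree). D and the edge count are regressed on stratum mean ΔAF by OLS.

The synthetic generator plants modules with a one-factor Gaussian model
(`sqrt(ρ)·f + sqrt(1−ρ)·ε`), dissolves a configurable subset of them under
treatment, couples ΔAF to the causal module's eigengene change, and spikes a
set of true differentially expressed genes. See `docs/methods.md` for the
full model and its defaults.

## Worked example

Run the whole pipeline on a compact synthetic study (500 genes, three planted
modules of 60/50/40 genes, modules 1–2 dissolved to 30% of their
within-module correlation under treatment, module 1 driving ΔAF):

```bash
cat > demo.yaml <<'YAML'
simulate:
  n_genes: 500
  module_sizes: [60, 50, 40]
  dissolved_modules: [0, 1]
  causal_module: 0
  deg_genes: 40
  dissolution_factor: 0.3
network:
  min_module_size: 20
preserve:
  n_permutations: 100
YAML
modflex run --config demo.yaml --out demo --seed 1
```

The run report (also written to `demo/run_report.json`) prints, among others:

```
"n_degs": 36,
"n_modules": 3,
"n_dems": 1,
"strata": {"best": 14, "mild": 11, "none": 16},
"stratum_dems": {"best": 2, "mild": 1, "none": 1},
"metm": "M1",
```

and `demo/respond/correlations_best.tsv` contains the module–trait
correlations inside the best-effect stratum:

```
module_label  r        p_value   n   is_significant
M1            0.8074   0.00048   14  True
M2           -0.0715   0.80810   14  False
```

Reading the numbers: 36 genes pass the DEG rule (p < 0.05 and ≥ 1.5-fold
change — close to the 40 planted); the three planted modules are recovered;
within the 14 best responders two modules are differentially expressed and the
planted causal module `M1` is selected as the METM with an eigengene-change
correlation of r = 0.81 (p = 5·10⁻⁴) to ΔAF. Mild partial dissolution is not
always flagged at the whole-arm level (`n_dems` counts the arm-wide calls);
the stratum-level permutation test is the sensitive instrument here.

Because this generator dissolves modules uniformly across the treated arm,
the per-bin flexibility regression in this demo is flat; the graded-dissolution
setting that produces the expected signs (D falling, edge count rising with
ΔAF) is exercised by `modflex.benchmarks.flexibility_direction` and the
reproduction script below.

Stages are also available individually (`modflex simulate|deg|network|
preserve|run --help`), and everything is importable as a library
(`from modflex import build_network, detect_modules, preservation_z, ...`).

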
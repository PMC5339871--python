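# radnet

Integrative radiogenomic network analysis for small imaging–transcriptomics
cohorts: weighted gene co-expression modules, diffusion-MRI trait
integration, permutation-based pre-ranked GSEA with family-wise error
control, and survival contrast of radiogenomic subgroups.

## The problem

In diffuse brain tumours, diffusion-weighted MRI metrics — axial, radial and
mean diffusivity (AD, RD, MD) and fractional anisotropy (FA) — reflect tissue
microstructure, and bulk expression profiling of navigated biopsies from the
same region asks *which transcriptional programs the imaging phenotype
indexes*. A cohort of a few dozen patients yields one expression profile and
one trait vector per patient; the analysis has to be rank-based, permutation-
calibrated and multiplicity-aware to say anything defensible at that size.

`radnet` implements the full workflow as a tested library:

1. **Diffusion metrics** (`radnet.dti`). Log-linear least-squares tensor fit
   from ≥ 6 encoding directions, ln(S_i/S_0) = −b·gᵢᵀDgᵢ; eigenvalues
   λ₁ ≥ λ₂ ≥ λ₃ give AD = λ₁, RD = (λ₂+λ₃)/2, MD = (λ₁+λ₂+λ₃)/3 and
   FA = √(3/2)·√Σ(λᵢ−MD)²/√Σλᵢ²; ROI median per patient.
2. **Co-expression network** (`radnet.network`). Unsigned soft-thresholded
   adjacency a_ij = |cor(x_i,x_j)|^β, topological overlap
   ω_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij), average-linkage module
   detection on 1 − ω with an eigengene-merge step; module eigengenes (PC1),
   kME (gene–eigengene correlation), module–trait correlation, hub-gene
   ranking and Cytoscape-style network export.
3. **Trait redundancy** (`radnet.preprocess`). The tensor-derived
   diffusivities are mutually near-collinear and correlate with the same
   genes; the pipeline groups traits by profile correlation and carries one
   representative (MD by convention) forward.
4. **Gene screening and subgrouping** (`radnet.screening`). Per-gene Spearman
   ρ against the trait (exhaustive-permutation p at very small n,
   t-approximation otherwise), Benjamini–Hochberg adjustment, an |ρ| ≥ 0.6
   signature cut, and average-linkage clustering of samples on 1 − Spearman
   distance into subgroups named by ascending trait mean.
5. **Pre-ranked GSEA** (`radnet.gsea`). Weighted running-sum enrichment
   score on a fixed ranking (typically |kME| of the trait-associated
   module), gene-label permutation null, NES, nominal p against the
   same-sign null and FWER by the max-statistic over all sets.
6. **Survival** (`radnet.survival`). Kaplan–Meier product-limit estimates,
   two-group log-rank test and univariate Cox regression (Efron ties) via
   lifelines.
7. **Synthetic cohorts** (`radnet.synthetic`). A generator that plants every
   structure above — latent-factor modules with exact expected within-module
   correlation, traits linked to chosen modules at an exact target
   correlation, exponential survival with a planted hazard ratio, and gene
   sets matching module membership — with the ground truth recorded, so the
   whole pipeline is testable without any external data.

`radnet.pipeline.run_pipeline` chains the stages from a single YAML-able
config with one global seed; reruns are byte-identical. A thin CLI
(`radnet simulate|run|network|gsea|survival`) wraps the library.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/07_full_pipeline.py` prints:

```
retained traits after redundancy collapse: ['FA', 'MD']
trait groups: [['FA'], ['AD', 'MD', 'RD']]
5 modules at soft power 7
FA: log-rank p = 0.6531, HR(II vs I) = 0.86
MD: log-rank p = 0.001195, HR(II vs I) = 0.32
13 artifacts written to pipeline_demo/ ...
```

Read: the three diffusivities correlated with the same genes and were
collapsed to MD; five co-expression modules were detected; clustering the
cohort on MD-correlated genes produced two subgroups whose survival differs
(log-rank p ≈ 0.0012, hazard ratio ≈ 0.32 for the high-MD cluster II — the
planted protective MD effect), while the FA subgroups show no survival
contrast, as planted.

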
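# avlipidome

Quantitative lipidomics of human aortic-valve fibro-calcific disease
(FCAVD), as a reusable, tested pipeline. FCAVD remodels aortic-valve
leaflets through mildly diseased, fibrotic and calcific stages; the
valve lipidome records both the infiltration of blood lipoproteins
(cholesteryl esters, sphingomyelins) and their local enzymatic
processing (phosphatidylcholine → lyso-PC by LpPLA₂, sphingomyelin →
ceramide by sphingomyelinase). This package takes a study from
internal-standard-spiked LC-MS peak areas all the way to stage- and
sex-resolved statistics, and ships a ground-truthed synthetic study
generator so every stage of the pipeline is testable without any
external data.

It is written for analytical lipidomics groups and cardiovascular
researchers who need the full quantification chain — not just the
downstream statistics — under version control.

## What it computes

**Quantification.** Class-specific adduct/fragment areas are summed per
analyte, isotopically corrected, and converted by single-point
class-matched calibration:

```
c_i = (A_i / A_ISTD) · (M0_ISTD / M0_i) · n_spike / m_tissue   [pmol/mg]
```

where `M0` is the monoisotopic fraction of the isotopologue
distribution (type I correction; deuterated standards contribute label
purity per position), and unit-resolution panels additionally subtract
the M+2 isotopologue of the species with one more double bond (type II
correction, cascaded from the most unsaturated species). Calibration
linearity (widest contiguous span with bounded relative residuals),
per-lipid concentration-vs-area screens (R², externally studentized
residuals) and spike recovery rates are included.

**Statistics.** Per-sample class totals; the lipoprotein-proxy ratios
LPC/PC, LPE/PE, Cer/SM, SM/PC and CE/TG with stage fold changes
(ratios of stage means vs the mildly diseased stage); Welch's t and
one-way ANOVA; volcano tables gated on FC > 1.5 *and* p < 0.05;
log/center/scale heatmap matrices; class-distribution plot data.

**Trend clustering.** Missing cells are filled with 1/5 of each lipid's
observed minimum, trajectories are averaged to the three stages,
z-scored per lipid and clustered with a full-covariance Gaussian
mixture (k = 5), with size-canonical cluster relabeling
(`TrendClusterer` is a scikit-learn-compatible estimator).

**Topology.** A structure-aware UMAP of the lipidome: per-species
z-scored abundances + min-max-scaled chain features + the top-5 PCA
components of a pairwise maximum-common-edge-subgraph (MCES) distance
matrix between class backbone structures (acyl chains stripped). MCES
is solved exactly as a small 0/1 integer program (HiGHS); a precomputed
matrix for the packaged backbone panel ships with the repository.

**Sphingolipid flows.** Every molecular-level sphingolipid decomposes
into sphingoid base / subclass / N-acyl; concentrations aggregate into
conservation-checked Sankey links, with very-long-chain fatty acyl
(C22–C26) flagging.

**Synthetic studies.** The generator plants the disease's effect
structure — per-class stage multipliers, sex×stage interactions, shared
patient factors, log-normal dispersion, sparse missingness — and a
forward measurement model (response factors, isotopologue attenuation,
ISTD spikes, optional M+2 leakage) that the quantification module
inverts exactly at zero noise.

## Worked example

```
$ avlipidome run-all --out demo --seed 7
simulated 480 lipids x 63 samples -> demo/simulated
quantified 480 lipids (0 channel-flagged, 25 nonlinear) -> demo/quantified
stats: 480 lipids tested, 241 ANOVA-significant -> demo/stats
trends: 243 lipids in clusters of sizes {1: 80, 2: 71, 3: 39, 4: 34, 5: 19} -> demo/trends
topology: embedded 480 lipids -> demo/topology
sankey: pool 919 pmol/mg over 102 links (0 skipped) -> demo/sankey
pipeline complete -> demo
```

The simulated study is 21 patients × 3 valve sections. `quantified/`
holds the pmol-per-mg matrix recovered from the spiked peak areas (25
lipids flagged by the linearity screen at this noise level); 241 of 480
species differ across stages by one-way ANOVA at p < 0.05, and those
lipids split into five stage-trajectory clusters. `stats/ratio_metrics.tsv`
shows the recovered lipoprotein-proxy trajectories, e.g.

```
ratio   fc_mildly_diseased  fc_fibrotic  fc_calcific
LPC_PC  1.0                 2.58         3.80
Cer_SM  1.0                 1.58         1.81
```

— the per-sample LPC/PC ratio rises ~2.6-fold in fibrotic and ~3.8-fold
in calcific sections of this run (the generator plants 2.8×/4.0×), and
Cer/SM rises 1.6×/1.8× (planted 1.5×/1.8×), the signatures of LpPLA₂
and sphingomyelinase activity the ratios proxy.

The same steps are available as library calls (`simulate_concentrations`,
`quantify_single_point`, `ratio_metric`, `gmm_trend_cluster`, …) for
use on real exports: the quantify step reads Skyline-style transition
reports (`Replicate`, `Molecule Name`, `Precursor Adduct`, `Area`
columns are recognized directly).

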
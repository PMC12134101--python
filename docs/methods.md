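# Methods

This note documents the models, numerical choices and assumptions
behind `avlipidome`, and what the synthetic-study tests do and do not
establish about real data.

## Nomenclature and the class registry

Shorthand names (`CLASS C:DB;On`, chains resolved by `/`, ether prefix
`O-`/`P-`, deuterium label suffix `(dN)`) are parsed into an immutable
record keyed by a 28-subclass registry shipped as an editable TSV
(`data/class_registry.tsv`: subclass, category, head-group formula,
chain slots, linkage rule). The panel is study-specific, so the
registry is data, not code; categories partition the panel into neutral
lipids, glycerophospholipids, lyso-glycerophospholipids, sphingolipids
and sterol.

Ceramide-family subclasses are resolved from the sphingoid base's
oxygenation/unsaturation pattern, not from distinct class tokens: base
`;O` → 1-deoxyceramide, `;O3` → phytoceramide, saturated `;O2` →
dihydroceramide, di-unsaturated `;O2` → sphingadienine-ceramide,
otherwise ceramide. The pattern is deliberately independent of base
chain length (16:1;O2 classifies like 18:1;O2). `etherPE` is an alias
for PE with an ether bond; a bare `etherPE` token defaults to the
plasmenyl (P-) form, the dominant ether species in this tissue.

Elemental formulas compose as head group + Σ chain contributions − one
water per ester/amide bond. Ether bonds replace an ester (O-: −O +2H
relative to the diacyl form; P-: additionally −2H for the vinyl-ether
double bond, which the shorthand does not count). The sphingolipid core
follows `C_c H_{2c+1−2d} N O_{o+1}` from the summed composition — the
N-acyl carbonyl oxygen is implicit in shorthand — plus fixed head-group
additions (phosphocholine, hexoses, the trimmed GM3 glycan) from the
registry. A `0:0` chain is an empty sn-position and contributes no
linkage. All rules are validated against ~24 authoritative structures
(POPC, triolein, CL 72:8, deoxyceramides, …) in the test suite.

## Isotopic corrections

Natural isotope abundances are a fixed table (¹²C 0.9893, ¹H 0.999885,
¹⁴N 0.99636, ¹⁶O 0.99757, ³¹P 1.0; configurable). The monoisotopic
fraction is the M0 term of the isotopologue distribution, computed in
closed form as Π abundanceᶜᵒᵘⁿᵗ; deuterium positions contribute the
standard's isotopic purity per position (default 0.98 when a
certificate value is absent). Full patterns come from per-element
polynomial convolution, truncated exactly at the requested shift.

Type I correction multiplies the analyte/standard area ratio by
`M0(ISTD)/M0(analyte)` — the full-formula generalization that reduces
to the familiar carbon-only factor when other elements match. Type II
correction subtracts, within a subclass at fixed carbon and oxygen
count, the corrected area of the species with one more double bond
times that species' M+2/M0 ratio, cascading from the most unsaturated
species and clipping at zero. Deuterium count is part of the overlap
key: a labeled standard sits several Da from the endogenous species of
equal composition and must not be treated as its M+2 partner.

## Quantification and screening

Single-point calibration: `conc = ratio × spike / mass` in pmol per mg
wet tissue. Calibration curves are ordinary least squares of area on
amount; the linear range is the widest contiguous span of at least
three amount levels whose own OLS fit keeps every point's relative
residual ≤ 20 % (default). The per-lipid linearity screen regresses
calculated concentration on summed area across samples and flags lipids
with R² < 0.8 and samples with |externally studentized residual| > 3
(infinite values — leverage ≈ 1 — are flagged as extreme outliers).
Both screens only flag; removal is the caller's decision. These
thresholds are package defaults, not study-derived values.

## Statistics

Fold changes are ratios of group arithmetic means (not means of
per-patient ratios); a per-sample-ratio variant of the proxy metrics is
exposed through the ratio tables themselves. Welch's unequal-variance t
test is the default two-group test; stage comparisons use unpaired
one-way ANOVA even though sections share patients — the shared patient
factor makes this conservative, which is accepted as the study
convention; no multiple-testing correction is applied by default
(Benjamini–Hochberg is available via `adjust="bh"`). Volcano
significance requires |log2 FC| > log2(1.5) and p < 0.05, with lipids
missing in more than half of either group excluded. Heatmap rows are
imputed (trend rule), natural-log transformed with a guard of the
matrix's smallest positive value × 10⁻³ (keeps zeros finite without
perturbing observed magnitudes), mean-centered and unit-scaled;
zero-variance rows are dropped with a warning.

## Trend clustering

Missing cells are filled with 1/5 of the lipid's observed minimum;
trajectories are averaged to the three stages, z-scored per lipid
across the stage means (population SD; flat rows become zero vectors),
and clustered with a full-covariance Gaussian mixture, k = 5, n_init =
10, fixed seed 42 (all configurable). Hard assignments come from the
maximum posterior; cluster ids are relabeled in descending size (ties
by first occurrence) so a fixed seed yields a canonical labeling.
Singular fits retry with a 100× larger covariance regularizer, logged.
The default input set is the ANOVA-significant lipids (p < 0.05). The
cluster numbering is an artifact convention — size order, not fit
order.

## Lipidome topology

Backbone structures (one SMILES per subclass, acyl chains stripped;
28 subclasses share 21 unique backbones because lyso forms share their
parent's backbone) are compared by an exact
maximum-common-edge-subgraph distance `|E1| + |E2| − 2·|MCES|` with
element and bond-order labels; common subgraphs may be disconnected.
The solver is a 0/1 integer program (edge-match variables tied to an
injective vertex map, HiGHS branch-and-bound) — exact at backbone sizes,
though structurally dissimilar pairs above ~30 bonds can take tens of
seconds, which is why the packaged panel's 21×21 matrix ships
precomputed (`data/backbone_distances.tsv`, regenerable via
`avlipidome topology --recompute-distances`). The sterol backbones use
the tetracyclic core (the isooctyl side chain is stripped with the
chains), and the GM3 glycan is trimmed to a sialic-marker + hexose +
ceramide stub; distances between the large glycans and the rest should
be read as coarse structural dissimilarity, not exact chemistry.

The distance matrix rows are centered and reduced by PCA (10
components, top 5 kept). The feature matrix concatenates a z-scored
abundance block, min-max-scaled chain counts (total carbons, double
bonds) and the min-max-scaled backbone PCA block, each multiplied by a
weight factor (default 1.0, study-tunable). UMAP uses 15 neighbors,
min_dist 0.1, Euclidean metric and a fixed seed. Seeded embeddings are
deterministic for a fixed input order but **not** permutation
equivariant at the coordinate level (the library's seeded SGD is keyed
to row index); group structure, not coordinates, is the reproducible
object, and the tests treat it that way.

## Sphingolipid flows

Molecular-level sphingolipids decompose into (base, subclass, N-acyl);
species-level entries cannot be decomposed and are counted and
reported, never silently dropped. Flow tables sum group-mean
concentrations into base→subclass and subclass→acyl links; both sides
equal the pool total by construction (checked to 1e-9 relative). The
default averaging group is the mildly diseased tricuspid samples. Very
long chain fatty acyls are C22–C26 inclusive.

## The synthetic generator

The generator emulates the study conditions the pipeline was built for:
a tricuspid-valve cohort of 21 patients (11 male, 10 female), three
~20 mg sections per patient, 480 species across the 28-subclass panel
spanning ~6 orders of magnitude, and 0.16 % missing cells. Baseline
class totals follow the reference tissue (CE 10.8, TG 1.65, PC 0.8,
SM 0.76, etherPE 0.27 nmol/mg; remaining classes panel-realistic),
distributed over species by a per-class geometric rank profile (decay
0.72; 0.45 for CE so CE 18:2 dominates its class at ~5.9 nmol/mg). The
ceramide-family totals and acyl rank order are set so the pool
decomposes like the reference tissue (sphingosine base ≈ 74 %,
deoxysphingosine ≈ 10 %, sphingadienine ≈ 7 %; acyls 24:0 > 24:1 >
16:0).

Planted effects are multiplicative per subclass and solved once from
the headline stage changes: LPC (1, 3.325, 4.0) against PC (1, 1.1875,
1.0) yields LPC/PC ratio folds of exactly 2.8×/4.0×; SM (1, 1.9, 1.8)
with the same PC track yields SM/PC 1.6×/1.8×; the ceramide family
(1, 2.85, 3.24) against SM yields Cer/SM 1.5×/1.8×; CE (1, 2.7, 2.3)
carries a female fibrotic interaction of 1.481 (a 4-fold female rise)
with the male factor solved so the pooled fold stays 2.7×; male
baselines carry more TG (×1.33 vs ×0.64), concentrated by rank order in
polyunsaturated species. Sphingolipid sex interactions are identical
across SM and all ceramide subclasses, which keeps the planted Cer/SM
ratio folds exact by construction. Dispersion: per-cell log-normal
CV 0.4, patient factor log-normal CV 0.25 shared across a patient's
three sections (making sections paired, as in reality), both mean-1.
The dispersion values are declared assumptions, not measured ones.

The measurement model maps concentration × mass × class response
factor × monoisotopic fraction to areas split over two channels (80/20),
with standards scaling their spike amounts identically, so response
factors cancel in the quantification ratio and the forward→inverse
composition is the identity at zero noise (verified to < 1e-6
relative; in practice ~1e-15). Optional M+2 leakage injects ΔDB = 1
isotopologue overlap that type II correction removes. ISTD spike
amounts default to a tenth of each class's expected per-sample pool —
placeholders standing in for a tailored standard mixture.

What passing tests show — and don't. The generator's noise is clean
log-normal with known structure; real LC-MS data add retention-time
drift, batch effects, saturation, co-elution and identification errors,
none of which are simulated. Recovery of planted fold changes and
archetypes therefore validates the estimators' correctness, not their
robustness to instrument artifacts.

## Statistical calibration conditions

Type-I error checks run on null studies (all multipliers 1) with the
patient factor and missingness disabled, so that stage groups are
independent, fully observed log-normal draws — the setting whose size
Welch's t and one-way ANOVA nominally control. At log-normal CV 0.4 and
n = 21 per group both tests sit near 0.045 at α = 0.05, within the
0.04–0.06 acceptance band; the mild deflation is the familiar
skewness effect. Power is measured as the ANOVA rejection rate over
lipids whose class carries a planted stage effect of at least 1.5×
under the full default model (shared patient factor included, which is
conservative) and clears 80 % with a wide margin.

## Numerical conventions

Seeds: every stochastic routine takes an explicit seed; derived seeds
stay below 2³¹. Z-scores use population (ddof 0) standard deviations.
Ratios exclude samples with zero denominators (warning) and error only
when nothing remains. Concentrations are non-negative or missing;
areas are finite and non-negative, enforced at container boundaries.
Problem sizes in the shipped checks — 480 × 63 studies, 21 replicate
null studies (10,080 tests), 10 replicate studies for fold-change
recovery, 200 archetype trajectories — were chosen to bound Monte Carlo
error well below the decision thresholds they feed.

## Known limitations

No peak detection, retention-time alignment or batch-effect correction
(beyond bookkeeping); no MS/MS identification; no mixed-effects
modeling of the patient nesting (a paired analysis is possible by
construction of the generator but is not the default); the shorthand
grammar covers the study panel, not the full community grammar
(sn-positions, oxidized functional-group isomers and ring systems are
out of scope); GM3/Hex2Cer head groups are fixed lookup additions.
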
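# Methods

This note documents the models and procedures implemented in `tscreen`,
their assumptions, the defaults that matter, and what the synthetic-data
generators do and do not emulate.

## Cassette design scoring

A design candidate is one amino-acid change (restricted to Ala, Trp, Gln,
Asp, Pro — the substitutions most likely to destabilize a protein fold)
introduced by homology-directed repair, with a silent mutation destroying
the NGG PAM so the edited locus is not re-cut. The score is a table lookup:
class anchors 5 / 4.41 / 3.9 / 2 at PAM distance 0, minus 0.2 per 3-nt
step. The off-target class of the protospacer combines two binary flags
from an exhaustive both-strand scan over all NGG-adjacent 20-mers: an exact
match of the 11 PAM-proximal nucleotides at another site (the seed region
that dominates Cas9 specificity), and a full-length match with at most 4
mismatches. Penalties of −0.95 / −1.25 / −3 apply when only 4 / 3 / 2
substitutions are possible at a site; designs below a score of 3 are
excluded, and at most 10 sites × 5 substitutions are kept per gene.

Decisions where the scoring scheme is silent:

- distances that are not multiples of 3 interpolate linearly (0.2/3 per nt);
- distances above 30 nt are hard-excluded (the design window ends there);
- only NGG PAMs are scanned (no NAG);
- site-ranking ties break by smaller PAM distance, then lower protein
  position, making selection order-invariant;
- the first exact full-length protospacer match found in scan order is the
  on-target site; further exact matches count as off-target evidence.

Oligo assembly uses the highest-frequency *E. coli* K-12 codon for the
introduced mutation and any synonymous (or non-coding) single-base edit
that destroys the PAM. The 85-nt homology arm is centered on the mutation
codon and shifted when necessary so both edits stay ≥ 10 nt from the arm
edges; with a 20-nt protospacer the fixed segments sum to 199 nt, so the
≤ 200 nt constraint is an invariant, not a tight fit.

## Barcode counting

Paired reads are merged by the best ungapped overlap (default minimum 20 nt,
mismatch fraction ≤ 0.1, most matching bases wins, overlap conflicts
resolved toward the higher base quality). The merged read is trimmed to the
variable region between exact hits of the constant cassette flanks, and a
read is counted only if that region is 100 % identical to a designed
sequence. There is deliberately no edit-distance rescue: a mismatch may be a
mutated (malfunctioning) cassette rather than a sequencing error, and
counting it would mask exactly the failure mode the assay must exclude.
Conservation (counted + discarded = input) holds per sample.

## Fitness, clustering, TS calls

The fitness score divides a strain's relative read abundance by its t₀
relative abundance, so every strain with t₀ coverage starts at 1. Strains
with zero t₀ reads are undefined and excluded rather than imputed; strains
whose mean t₀ reads fall below 15 are dropouts. Trajectories (replicate
means over the 7 ordered timepoints, raw scale) are clustered per
temperature with k-means (k = 6, Euclidean, 50 restarts, seed 1). Clusters
are ranked by endpoint mean fitness: at k = 6, the top four are labelled
high, the next reduced, the last low (the 4/1/1 split such screens show);
for other k, endpoint thresholds of 0.7 / 0.3 apply. A strain is a putative
TS mutant when its 42 °C category is strictly worse than its 30 °C
category. The moving-average smoother for display uses a centered window of
3 timepoints.

## TS scoring

Eligibility requires all six criteria: mean t₀ reads ≥ 15, final 30 °C
fitness > 0.3, final 42 °C fitness < 0.4, replicate error e < 15,
AUC₃₀ > 5, and the nonlinear separation n̄₃₀ > 1/(1 + 0.25·n̄₄₂³) + 0.3,
which demands near-full 30 °C fitness (threshold 1.3) when the strain still
grows at 42 °C and relaxes to the plain 0.3 floor as 42 °C fitness
collapses. The replicate error sums |A−B| normalized by the replicate mean
over all timepoints and both temperatures; the printed form of this error
omits absolute-value bars, but as an accumulating error magnitude feeding
the one-sided criterion e < 15 it is implemented with absolute differences.
AUCs are trapezoidal over the replicate-mean series. Ranks (dense; ties
share the rank) are computed library-wide by default — most t₀ reads,
largest relative AUC difference (AUC₄₂ = 0 maps to +∞, ranked best),
largest final fitness difference, smallest e — and combined with weights
1.25 / 2 / 1.5 / 0.75. Per gene the lowest composite wins; residual ties
break by higher t₀ reads, then strain id. A per-gene ranking variant is
available via `per_gene_ranks=True`.

## Growth–temperature model

Maximal specific growth rates are the steepest slope of ln OD over sliding
9-point windows (≈ 90 min at 10-min sampling), restricted to windows whose
log-linear R² is at least 0.98 — the operational definition of "clean
exponential phase". A negative maximum, or no qualifying window, is no
growth (0 h⁻¹). Under 1 % multiplicative noise the estimator's typical
absolute error at μ = 0.5 h⁻¹ is ≈ 0.015 h⁻¹, with a slight upward bias
inherent to taking a maximum over windows.

The growth–temperature relationship is the minimal two-term Arrhenius
difference μ(T) = exp(a_act − E_act/RT) − exp(a_inact − E_inact/RT): an
activating term for the thermal acceleration of metabolism and a steeper
inactivating term (E_inact > E_act, built into the parameterization) for
the loss of the TS protein. Predictions are clipped at zero, and the
residuals compare the *clipped* prediction to the (nonnegative) measured
rates. Internally the exponentials are centered on 310.15 K so all four
parameters are well-scaled; fitting is bounded trust-region least squares
from a small multistart (activation energy seeded by Arrhenius regression
on the ascending flank, grids over the inactivation/activation ratio and
the crossing temperature), with the winning start polished to machine
tolerance. R² is computed on the rate scale; for degenerate flat data
(zero variance) it is computed against signal power instead so a good flat
fit does not score −∞.

Switch diagnostics: the optimum is located on 25–48 °C; the switching
temperature is the half-maximum crossing above the optimum (bisection,
0.01 K); responsiveness is the maximum of −dμ/dT (analytic derivative)
between the optimum and the zero crossing. Scaling μ by a constant leaves
the switching temperature unchanged and scales responsiveness — a useful
sanity check. Strains whose μ(T) has no interior maximum in range get
undefined (None) metrics. Switch-like vs gradual classification runs
k-means (k = 2) on profiles normalized to each strain's 30 °C rate; the
cluster with the larger mean steepness is switch-like, with a threshold
fallback (0.25 K⁻¹ on normalized steepness) when the two clusters are
indistinguishable.

## FI-MS metabolomics

Per sample the 10 highest-TIC profile-mode spectra are summed on the union
m/z grid (nearest-bin resampling). Peaks need height ≥ 1000 and topographic
prominence ≥ 500 (scipy's implementation; an independent brute-force
prominence oracle backs it in the tests). Annotation matches [M−H]⁻ or
[M+H]⁺ ions (proton mass 1.007276 Da) within 3 mDa; per metabolite the
maximum annotated peak height is kept, a metabolite hit in both polarities
resolves to the higher peak (an automated stand-in for manual curation by
peak shape — shape is not used), and peaks claimed by several metabolites
are flagged ambiguous rather than arbitrated.

Intensities are normalized to a control strain in log₂ space,
x_norm = log₂(x/x_control), and standardized per metabolite across strains:
mod-z = 0.6745·(x_norm − median)/MAD. The median/MAD axis is across strains
within each metabolite (the per-metabolite strip view of the data);
metabolites with MAD = 0 are undefined and flagged. Propagated standard
deviations use first-order log-ratio propagation,
σ_xnorm = √((σᵢ/xᵢ)² + (σ_c/x_c)²)/ln 2, including the control's
contribution, and σ_modz = 0.6745·σ_xnorm/MAD. Increases with mod-z > 3
define pathway responses: counts per (strain, pathway) with
multi-membership metabolites contributing to each of their pathways,
per-strain responding-pathway counts, target-pathway flags (the pathway
containing the strain's TS enzyme) and substrate flags (the enzyme's direct
substrate exceeding the threshold — the signature of a pathway bottleneck).
Strain–strain similarity uses Pearson correlation over jointly defined
metabolites (≥ 3 required; constant profiles undefined), with group
contrasts (all pairs vs pathway-internal vs complex-internal) tested by the
two-sided Wilcoxon rank-sum normal approximation with tie correction — the
group sizes in use make the exact test unnecessary. Feature enrichment is
the one-tailed Fisher exact test, P(X ≥ a) from the hypergeometric upper
tail; empty margins return p = 1 by convention.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their config (equal seeds give
byte-identical output) and serialize their ground truth.

**Competition screen.** 500 strains across 100 genes, read depth 10⁶,
timepoints 0–12 h every 2 h, two temperatures, two replicates. Because the
3-hourly back-dilutions keep cultures exponential and preserve composition,
relative abundance follows p_i(t) ∝ p_i(0)·exp(μ_i(T)·t) and read counts
are a single multinomial draw per sample. The population structure mirrors
what a destabilizing-mutation library shows: a healthy class
(μ₃₀ ≈ 0.35 ± 0.01 h⁻¹, the control-strain rate on minimal glucose), a
mildly reduced class (20 %, deficit 0.03–0.12 h⁻¹ at both temperatures), a
strongly defective class (20 %, μ₃₀ ∈ 0.02–0.15 h⁻¹ at both temperatures),
5 % preculture dropouts, and 10 % TS strains that grow control-like at
30 °C and have μ₄₂ ≤ 0 (death — lysis-like phenotypes — modelled as a
negative rate). Non-TS strains gain a uniform +0.3 h⁻¹ at 42 °C, matching
a control that grows faster at 42 than at 30 °C, so their *relative*
dynamics are temperature-independent. Replicates differ by multinomial
sampling plus a 2 % lognormal jitter on rates, so the replicate error e is
realistically nonzero. Not emulated: saturation effects between dilutions,
PCR amplification bias, realistic Illumina error profiles (optional FASTQ
emission uses uniform per-base errors), editing-efficiency differences
between strains.

**Growth curves.** 50 strains + control, 10 temperatures (30–44 °C), 3
replicates, OD sampled every 10 min for 8 h, exponential growth capped at
carrying capacity 1.0, 2 % multiplicative lognormal noise. Per-strain truth
parameters place the activation energy at 50–70 kJ/mol, the inactivation
term 5–10× steeper, and the growth collapse at 38–44 °C (the control at
50 °C, i.e. negligible inactivation in range). Strains collapsing at the
upper edge of the panel have a barely sampled descending flank; their
switching temperature is under-constrained, which is why the recovery
statistic reported is the panel *median* absolute error (≈ 0.07 K at 2 %
noise), not the maximum. No lag or stationary-phase structure is modelled,
so passing tests say nothing about rate extraction from curves dominated by
those phases.

**Spectra and metabolite matrices.** Spectra are Gaussian peaks (σ = 5 mDa)
at the [M∓H] m/z of a bundled synthetic panel of 30 common *E. coli*
metabolites with monoisotopic masses (including the threonine/homoserine
isobar pair, which exercises the ambiguity flag), on a uniform grid with
additive baseline noise; two deliberately tiny-TIC spectra exercise the
top-10 selection. The metabolite matrix plants an 8× substrate increase for
each enzyme-mutant strain (half of the non-control strains) on a lognormal
baseline with 10 % replicate CV over 3 replicates. Isotope patterns,
in-source fragmentation, ion suppression and chromatographic effects are
out of scope — detection rates measured here are upper bounds for real
FI-MS data.

## Problem sizes and numerical choices

The default problem sizes (500-strain screen at depth 10⁶, 50-strain
growth panel, 20-strain metabolome, 100-spectrum oracle comparisons) are
desk-scale choices that keep the full test suite and the acceptance script
in the tens of seconds while leaving every estimator in its intended
operating regime. Tolerances that matter: k-means uses 50 restarts and a
fixed seed (results are deterministic given the seed); the Arrhenius
multistart polishes to xtol/ftol ≈ 2.3e−16; T_switch bisection stops at
0.01 K; mod-z exactness is asserted at 1e−12. Known limitations are noted
inline above; the largest is that category-based TS calling cannot, by
construction, flag a strain that is already in the lowest fitness category
at 30 °C.
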
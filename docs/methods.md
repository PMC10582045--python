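# Methods

## Problem and scope

`pyrtrace` implements the data-reduction chain of an oral [U-¹³C₃]pyruvate
tolerance test (OPTT) in mice: a gavage solution in which 40 % of pyruvate
molecules are fully ¹³C-labelled is administered, blood is sampled at a
terminal time point, and GC-MS selected-ion-monitoring (SIM) signal areas of
derivatized metabolite fragments are reduced to corrected mass isotopomer
distributions (MIDs), atom percent excess (APE), fractional contributions
(FC), and a partition of blood glucose carbon into gavaged-pyruvate,
endogenous-pyruvate and non-pyruvate sources. A second, independent branch
screens MALDI mass-spectrometry-imaging (MSI) lipid intensities over kidney
regions of interest. Both branches are exercised end-to-end on synthetic
data with planted ground truth; the package does not attempt raw-spectrum
processing (peak integration and MSI peak picking are upstream,
vendor-software steps) and none of the indices are metabolic rates.

## Isotope patterns and the fragment library

Theoretical isotopologue distributions are computed by convolving per-atom
natural isotope-shift distributions, with shifts binned by nominal mass
(integer ΔM), matching the 1 m/z spacing of SIM channels; fine isotopic
structure within a channel is ignored. Isotope masses and abundances are
IUPAC/CIAAW 2021 values stored as package data (`data/isotopes.tsv`) so
results are reproducible bit-for-bit. Distributions are truncated at the
fragment's channel count and the truncated tail mass is reported rather
than redistributed.

Monoisotopic mass is the sum of lightest-isotope masses. Deprotonated
([M−H]⁻) m/z subtracts the proton mass 1.007276 Da (electron included); at
the 3-decimal reporting precision used for lipid ions this is
indistinguishable from subtracting a neutral hydrogen atom.

The SIM fragment library (`data/fragments.tsv`) is curated: published
methods print acquisition windows, not ion formulas, so each entry records
the conventional MOX/TBDMS [M−57]⁺ fragment formula, the printed window
verbatim, and the computed mass separately. For pyruvate, lactate,
succinate, malate, AKG, aspartate and the two citrate fragments the
computed mass rounds to the printed window start at one decimal; for
alanine, fumarate, glutamate, PEP and 3PG the printed start differs by
0.1 m/z from the conventional-fragment rounding, and no agreement is
forced. The glucose carbons-4–6 aldonitrile-pentapropionate fragment
(C₁₁H₁₅O₇, nominal 259, n = 3) is curator-supplied: it reports the
triose-phosphate-derived half of glucose and its exact window is not
printed in the instrument method (scan mode 170–380 m/z).

## Natural-abundance correction

For a fragment with n labelable carbons, column j of the correction matrix
is the fragment's theoretical channel distribution when exactly j labelable
carbons are fixed as ¹³C: those j carbons are removed from the convolution
and the pattern is shifted up j channels. The measured, area-normalised
channel vector is inverted by non-negative least squares (NNLS) and the
solution renormalised to sum 1. NNLS is chosen over plain inversion because
inversion can return negative isotopomer fractions on noisy data; the NNLS
residual norm is carried on every corrected MID so poor fits surface
instead of being absorbed. Rank-deficient matrices raise rather than fall
back to a pseudo-inverse. A tracer isotopic-purity deconvolution exists as
an explicit toggle but defaults to off: the 40 % gavage enrichment is a
molecule fraction, not an atom purity.

## Tracer metrics

With MID fractions M₀..Mₙ:

* APE = Σᵢ Mᵢ·i / n — the average fractional ¹³C labelling of the n
  carbons. The full corrected MID enters the sum, including partially
  labelled isotopomers (M₁, M₂), not only M₊₃; this is the natural reading
  of the definition and is stated here because the alternative (M₊₃-only)
  is not distinguishable from the published description.
* FC(product ← source) = APE_product / APE_source. Zero source APE raises
  an explicit error; FC > 1 (possible under noise) is flagged, not clipped.
* Glucose partition (using the C4–C6 fragment APE exclusively):
  FC from the gavaged tracer divides by the tracer enrichment (default
  0.40, configurable); FC from blood pyruvate divides by the measured blood
  pyruvate APE; the non-pyruvate share is 1 minus the latter, stored as the
  exact complement so the two always sum to one. Absolute attributions are
  FC × concentration (mg/dL for glucose, mM for lactate), with the
  endogenous-pyruvate share the difference between the blood-pyruvate and
  gavaged attributions; the three absolute shares sum to the measured
  concentration. A negative non-pyruvate share (noise) is reported with a
  flag; clipping at zero is opt-in, preserving auditability.
* Semi-quantitative abundance = summed isotopologue area / internal
  standard (norleucine) area / tissue weight (mg).

## Multiple testing and group comparison

The two-stage linear step-up procedure (Benjamini, Krieger & Yekutieli
2006, the "sharpened" adaptive procedure): stage 1 runs the
Benjamini–Hochberg step-up at q′ = q/(1+q) to estimate the number of true
nulls m − r₁; if 0 < r₁ < m, stage 2 reruns the step-up at
q′·m/(m − r₁). The implementation is authored here and cross-checked in
the test suite against both a literal loop-based restatement of the
definition and `statsmodels`' `fdr_tsbky`. Group fold changes use the
pooled-variance Student's t-test by default (Welch optional); two constant
but unequal groups return p = 0, while constant and equal groups raise
(the statistic is 0/0).

## MSI ROI screen

Species m/z values are annotated against a lipid reference table at 5 ppm
tolerance on [M−H]⁻ masses. Species with multiple candidates are removed
before class-level summaries (isobaric ambiguity is unresolvable at
MALDI-TOF resolution); species with zero candidates are likewise excluded
from class summaries since they carry no class label. Intensities are
averaged over the 9 ROIs per region × genotype (3 ROIs per section, 3
sections). Genotype/control ratios are computed per species and rolled up
per class as the ratio of summed intensities (sum-then-ratio; a
mean-of-ratios alternative is available behind a flag). Intensities are
taken as provided — no cross-section normalisation by default, with an
optional per-section median normalisation.

The two transition-area screens: up-in-overexpressor requires
fold(OE/control) > 1, fold(KO/control) < 0.75 and mean OE transition
intensity > 100 counts (a false-positive floor), ranked by descending OE
fold; down-in-overexpressor requires fold(KO/control) > 2 and
fold(OE/control) < 1, ranked by ascending OE fold. The published
description does not state the sort key; the transition-area
genotype/control fold is the natural reading and is the documented
assumption. Ties break by ascending m/z.

## Synthetic data

The generators are parameterised directly in the quantities the analysis
estimates, so parameter recovery exercises the analysis equations rather
than an unverifiable physiological model.

Tracing generator (`simulate_optt`): blood pyruvate MID is
(1−e)·unlabelled + e·M₊₃ with per-genotype enrichment e; lactate uses
λ·e (λ = 0.9 by default — lactate is nearly equilibrated with pyruvate);
the glucose C4–C6 precursor carries APE e with a fraction σ (default 0.1)
of its labelled mass redistributed from M₃ into M₁/M₂ in the unique
equal-mass way that preserves APE (emulating TCA-cycle scrambling), and
glucose is (1−f_np)·precursor + f_np·unlabelled, so the planted
non-pyruvate fraction f_np is exactly what the pipeline's
FC-complement estimates. True MIDs are pushed through each fragment's
correction matrix, scaled to a base area (10⁶ counts) and multiplied by
per-channel lognormal noise (mean 1, default CV 0.05 — multiplicative
noise is the standard model for MS signal areas). Genotype presets:
control e = 0.20, f_np = 0.55, glucose 180 mg/dL, lactate 5 mM;
overexpressor e = 0.25, f_np = 0.70, glucose 230 mg/dL, lactate 7 mM —
chosen to mirror the direction of the physiology the analysis is built
for (higher glycaemia with a larger non-pyruvate share), not as published
values. Eight samples per genotype by default.

MSI generator (`simulate_msi`): 72 species across 9 lipid classes with
class-parametric neutral formulas; reference m/z computed from the
formulas, observed m/z jittered ≤ 2 ppm; four designated isomeric
duplicate reference entries (same formula, different chain combination)
exercise multi-candidate removal; two designated low-abundance species
exercise the intensity floor. Class-level genotype multipliers apply fully
in the transition area and as their square root elsewhere; species-level
multiplicative tweaks (±15 %) make screen rankings unambiguous while
keeping every species inside its class's qualification band. ROI values
are lognormal around the planted means (default CV 0.10); 9 ROIs per
region × genotype.

What the generators do not emulate: gavage pharmacokinetics and
time-courses (the analysis uses one terminal point), inter-fragment
correlated noise, chromatographic interferences, spatial image structure,
and isobaric overlap beyond the planted duplicates. Passing tests
therefore demonstrate correctness of the estimation chain under its own
assumptions, not robustness to every artefact of real instruments.

## Numerical choices and problem sizes

Determinism: every stochastic routine takes a single integer seed through
`numpy.random.default_rng`; identical configurations give byte-identical
outputs. Correction round-trips are checked to 1e-9; isotope patterns are
validated against an exhaustive isotope-assignment enumeration oracle on
all library fragments up to 50 atoms (1e-9). FDR calibration uses 200
replicates of 500 uniform null p-values; cohort parameter recovery uses 8
samples per genotype at 5 % noise — sizes chosen to give stable estimates
at interactive runtimes. Degenerate inputs (all-zero measurements, zero
source APE, zero internal standard, missing ROI cells, rank-deficient
matrices) raise typed errors rather than propagating NaNs.

## Known limitations

Channel-count truncation discards a small tail of each theoretical
pattern (reported, not redistributed), which slightly biases NNLS fits for
heavily labelled, Si-rich fragments; the library's channel counts follow
the published SIM windows, which are wide enough that the effect is below
1e-3 per fraction. The ALDO glucose fragment formula is curated, not
derived from fragmentation rules. The MSI branch begins at ROI intensity
tables; imzML parsing, peak picking and image registration are out of
scope.
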
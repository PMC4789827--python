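# Methods

This note records the models, parameter choices and numerical decisions
behind `panc13c`, and what the synthetic data do and do not establish.

## Stage parameterization

Each disease stage is summarised by four tissue-extract measurements: the
alanine and lactate pool concentrations (μmol/g wet tissue) and the LDH and
ALT activities (mU/mg protein).  `stage_profile` returns the per-stage mean
values.  The 2-month KC stage has no extract measurements of its own —
that tissue is predominantly normal with low-grade lesions — so its
profile is synthetic: the midpoint of the control and 4-month profiles,
and it is excluded from any quantitative ordering claim.

## Activity → rate mapping

The established fact is qualitative: the alanine/lactate label partition
depends on the relative LDH and ALT activities and on the alanine and
lactate pool sizes.  We realise it as mass-action exchange at chemical
steady state: the unidirectional flux through each enzyme is proportional
to its measured activity times its product pool,

    J_lac = κ · LDH · [lac]      J_ala = κ · ALT · [ala]

so the apparent rate constants are k_LP = κ·LDH, k_PL = κ·LDH·L/P (and
likewise for alanine), with forward and reverse fluxes balancing exactly
(k_PL·P = k_LP·L): pure label exchange, no net conversion.  The
alternative family in which the rate constant is *divided* by the product
pool was rejected because it predicts k_PA/k_PL ∝ ALT·L/(LDH·A), which
orders the 9-month stage *above* the 4-month stage — opposite to every
measured endpoint.  The multiplied form gives ala*/lac* ≈ (ALT·A)/(LDH·L),
which reproduces the measured direction at every stage, including the
control-vs-pancreatitis separation that activity ratios alone (nearly
identical for those two stages) cannot produce.

**Calibration.**  κ (s⁻¹ per mU/mg protein) converts an in-vitro activity
into an in-tissue exchange constant and is not derivable from the reported
data; the package therefore asserts orderings and limits, never absolute
ratios.  Defaults, chosen once at design time:

* `IN_VIVO_CALIBRATION`, κ = 5×10⁻⁵: apparent k_PL spans 0.003–0.09 s⁻¹
  from control to tumour, the range reported for hyperpolarised pyruvate
  experiments in vivo.
* `ASSAY_CALIBRATION`, κ = 5×10⁻⁴: in the cell-free buffer (optimised
  cofactor supply) the diluted homogenate stays near-linear over the
  five-point initial window while tissue-strength pools approach isotopic
  equilibrium over tens of seconds, the regime implied by the
  near-saturated measured tumour ratios.  A scan over κ confirmed the
  five-stage ordering of the homogenate chain is stable across
  2×10⁻⁴–1×10⁻³ with its largest control/pancreatitis margin near the
  default.

With any steady-state exchange model the 20-s label partition is bounded
above by the pool ratio A/L; measured homogenate ratios above 1 (control)
are therefore outside the model family altogether, which is why magnitudes
are not an endpoint here.

## Magnetization simulation

Three-pool linear ODE with T1 losses and a rectangular bolus feeding
pyruvate (default: start 0 s, duration 10 s, so delivery has finished when
acquisition starts at 20 s).  T1 = 30 s for all three carbonyl carbons
(configurable; `math.inf` disables relaxation exactly).  RF excitations
multiply all longitudinal pools by cos α; samples taken at an event time
report the pre-event magnetization, which is what the excitation reads
out.  Propagation uses exact matrix exponentials of the augmented 4×4
system on the piecewise-constant segments, cached per step length — there
is no step-size error, and conservation identities hold to rounding.  An
independent fixed-step RK4 integrator in the test suite cross-checks
trajectories to 10⁻⁶ relative.

## CSI forward model

Phase-encode step n is acquired at start_delay + n·TR in centre-out order
(radius, ties by polar angle then ky; DC at array index matrix/2).  The
FID for each step is the spatial Fourier sum over voxels of
M·sin α·exp(2πi f_m t − t/T2*_m) per metabolite, with voxel positions
centred on the FOV.  Resonance offsets (Hz, pyruvate at 0): lactate +950,
alanine +440, pyruvate hydrate +640 — the 7 T carbonyl-carbon positions;
T2* = 15 ms (≈21 Hz linewidth) for all metabolites.  Pyruvate hydrate is
carried as a fixed fraction (default 0.08) of the pyruvate magnetization.
The 128-point FID at 6 kHz fills 21.3 ms of the 30 ms TR.  Receiver noise
is complex circular Gaussian, equal sd per channel, seeded.  Perfusion
enters as a per-voxel multiplicative bolus scale (the dynamics are linear,
so per-label unit solutions are scaled per voxel); it defaults to uniform,
matching the observation that vascular density does not change with stage.

## Reconstruction

The chain mirrors the processing applied to the real data, in order:
separable cosine k-space window cos(πk/(2k_max)) (1 at DC, 0 at the edge);
exponential line broadening exp(−π·lb·t) with lb = 20 Hz; zero-filling to
128×128 spatially (symmetric about DC) and 1024 spectrally; DFT along time
and inverse spatial DFT (conventions matched to the simulator and verified
against a direct-DFT oracle); per-voxel zero-order phase correction by
making the largest-magnitude peak real-positive; baseline removal by
subtracting the per-voxel median over signal-free bins (a polynomial
alternative is provided); peak integration as bin sums × bin width over
disjoint windows, default ±95 Hz around each resonance.

Decisions where the processing description is silent: first-order phasing
is omitted (TE 1.5 ms makes it negligible and the simulator generates
zero-phase FIDs); integration uses the phased real spectrum, falling back
to magnitude spectra only when the signal-weighted real fraction of peaks
≥10% of the strongest peak drops below 0.9 (magnitude integration
rectifies noise and biases ratios, so it is a last resort, not a default);
window width trades Lorentzian tail capture against cross-contamination —
the ~0.7% of the pyruvate peak that leaks into the alanine window is the
main accuracy limit on the weakest-signal ratios, exactly as for real
window integration.

## Ratio analysis

Ratio maps divide metabolite maps voxelwise, masked where the denominator
or pyruvate falls below 5% of the maximal pyruvate signal (display floor
against noise-dominated ratios).  ROI ratios default to ratio-of-sums
(sum numerator over the ROI / sum denominator), with mean-of-voxel-ratios
as the alternative; the reciprocal pair ala/lac and lac/ala always
multiply to 1.  Longitudinal change is reported as percent decreases
(100·(r_early − r_late)/r_early), repeatability as the sample CV in
percent.  `group_compare` runs one-way ANOVA with Tukey's post hoc when
every group passes Shapiro–Wilk and the set passes Levene at α = 0.05,
otherwise Kruskal–Wallis with Dunn's post hoc (rank z statistics, tie
correction, Bonferroni over pairs — written in-package because no
installed library provides Dunn).  Identical constant groups are resolved
to p = 1 rather than NaN.

## Homogenate assay

Added unlabelled alanine and lactate match the per-stage tissue
concentrations (mM): control 2/2, pancreatitis 1/1, 4-month 1/2, 9-month
1/4, tumour 2/9.  Added [3-¹³C]pyruvate defaults to 5 mM (the assay
concentration is not reported); tissue 0.2 g in 0.6 mL (the 1:2 g/mL
homogenisation), 37 °C.  The labelled-species ODE
d[lac*]/dt = J_L·(f_pyr − f_lac) (fluxes as above, scaled by the tissue
dilution W/V in the tube) conserves each pool total and the total label
exactly; time courses default to 0–300 s at 5 s steps — the repetition
time of the NMR readout — so the "initial five points" span 0–20 s.
Initial rates are OLS lines through those five points; dilution correction
is slope (mM/s ≡ μmol/mL/s) × sample volume / wet weight.  The 20-s
prediction integrates the same law with tissue pools assuming the injected
pyruvate stays essentially fully labelled, a*(t) = A(1 − e^{−R_a t/A})
(`integrated`, default), or uses rate × horizon (`linear`); both tend to
R_a/R_l as the horizon shrinks.  Extract quantification is TSP-referenced:
conc = (area/TSP area)·(9/protons)·5 mM·volume/mass, with 3 protons for
the lactate and alanine methyls.

## What the synthetic data show — and don't

The phantoms reproduce the *mechanism* (stage-specific enzyme/pool-driven
label partition read out through the true acquisition and processing
chain) under idealised conditions: uniform coil sensitivity, no B0/B1
inhomogeneity, no motion, rectangular bolus, uniform perfusion, Lorentzian
lines, and a pancreas that fills its voxels exactly.  Passing tests
therefore establish internal consistency of simulation, reconstruction and
analysis, and the robustness of the ordering endpoint to receiver noise —
not the in-vivo magnitudes, partial-volume behaviour at organ borders
(explorable via the `other_organ` label, but uncorrected), or transport
effects, none of which are modelled.

## Problem sizes and numerics

End-to-end tests and the acceptance script run the full 32×32×128 protocol
with 128×128×1024 reconstruction; unit tests use 8×8–16×16 instances where
the property is size-independent.  The repeatability CV in the acceptance
script uses 8 noisy repeats.  Matrix exponentials make simulation exact;
FFT-based reconstruction is verified to 10⁻⁸ against a direct DFT.
Degenerate inputs are handled explicitly: zero spectra phase to identity,
empty-ROI and all-masked-ROI raise, zero early ratios flag percent changes
as undefined, constant groups bypass the normality screen and identical
groups report p = 1.
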
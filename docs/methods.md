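# Methods

## Signal model and estimation

The package models the diffusion-weighted signal of a voxel with the
standard fourth-order cumulant (kurtosis) expansion of the log-signal:

    ln S(b, n) = ln S0 − b·D_app(n) + (1/6)·b²·D_app(n)²·K_app(n)

with `D_app(n) = Σ nᵢnⱼDᵢⱼ` and `K_app(n) = (MD²/D_app²)·Σ nᵢnⱼnₖnₗWᵢⱼₖₗ`.
`D` is the symmetric rank-2 diffusion tensor (µm²/ms) and `W` the fully
symmetric rank-4 kurtosis tensor (dimensionless, 15 unique elements). The
model is linear in the 22 parameters `[ln S0, D (6), MD²·W (15)]`; the
design matrix carries the combinatorial multiplicities of each unique
index pattern (1/2 for D; 1/4/6/12 for W), which are unit-tested against
directional hand evaluations.

Assumptions: single-compartment cumulant truncation (valid for
b·D ≲ 2–3; at b = 4 ms/µm² and AD = 1.6 µm²/ms the axial signal is near
the expansion's validity edge, which is the regime the two-shell protocol
was designed for); no exchange; Gaussian-phase diffusion within the
acquisition's δ/Δ (4/12 ms, carried as annotation only).

Estimation is two-pass weighted linear least squares: ordinary least
squares on ln S, then one re-weighted pass with weights equal to the
squared predicted signals (the inverse-variance weights of log-transformed
magnitude data). The pass count (default 2) and the log floor for
nonpositive signals (1e-6 × max signal, clamped values counted) are
exposed. No positivity constraints are imposed on D eigenvalues or
directional kurtosis; violations are flagged, never projected. The
kurtosis block estimates MD²·W, so W is recovered by dividing by the
fitted MD²; fits with MD ≤ 1e-10 µm²/ms (nerve MDs are O(1)) flag the
kurtosis tensor undefined rather than dividing by a vanishing number.

Units: b-values enter in s/mm² and are converted internally to ms/µm²
(÷1000), so diffusivities come out in µm²/ms — the scale on which the
outlier rule "RD > 1 µm²/ms" is stated.

## Scalar indices

Eigenvalues are sorted descending; AD = λ₁, RD = (λ₂+λ₃)/2,
MD = (AD+2·RD)/3 (an exact identity, tested to 1e-12),
FA = √(3/2)·‖λ−MD‖/‖λ‖. When λ₁−λ₂ < 1e-9·MD the principal axis is
arbitrary and the record is flagged.

MK, AK, RK are defined by *numerical* averaging of K_app: AK along e₁, RK
as the mean over 64 equally spaced in-plane directions (the in-plane
integrand is a degree-4 trigonometric polynomial, so this quadrature is
already exact — doubling the design changes RK by < 1e-10), MK as the mean
over a 256-point Fibonacci sphere design. Numerical averaging was chosen
over analytic closed forms because it fixes unambiguous, directly testable
semantics; both design sizes are configurable.

The FA/ratio conversion `FA = (1−r)/√(1+2r²)`, r = RD/AD, assumes a
cylindrically symmetric tensor; it is strictly decreasing, maps the
boundary slope 0.40 to 0.5222, and agrees with the eigenvalue FA to 1e-12
on cylindrical tensors (tested over a ratio grid).

## Slice-wise reduction and outlier rules

The unit of analysis is the slice: per-slice ROI means of each index, with
slices labeled proximal / injury / distal via a 0-based inclusive injury
interval along the third image axis. Slices with RD > 1 µm²/ms, RK < 0 or
RK > 2 are excluded as outliers with strict inequalities (boundary values
kept); exclusions are logged with their rule. The filter is applied before
both classifier training and the correlation analyses by default; each
application has its own config switch because only the correlation-side
filtering is unambiguous in the source protocol.

## Recovery classifier

Training set: distal slices at week 4, crush labeled recovered, cut/repair
non-recovered, after outlier filtering. The boundary is a linear
soft-margin SVM on unscaled (AD, RD) in µm²/ms so the slope and intercept
stay in physical units. The default cost is C = 1e6 with solver tolerance
1e-6: in these units the hard-margin solution has ‖w‖ ≈ 20 and dual
coefficients of order several hundred, so a small cost would cap them and
undershoot the maximum margin; with the default, the fitted margin matches
an exhaustive-direction-search oracle to ~1e-5 on separable data. C is
config-exposed. The decision value fed to calibration is the raw SVM
functional w·x + b, oriented so positive means recovered; the calibration
makes its normalization irrelevant.

Uncertainty: stratified bootstrap (resampling with replacement within each
class, so every replicate contains both classes), default 1000 replicates;
slope/intercept SDs are over successful refits.

Probabilities: a Platt sigmoid P(recovered | f) = 1/(1+exp(A·f+B)) fitted
by Newton iteration with backtracking line search on the cross-entropy
against smoothed targets t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2). The smoothing
keeps the optimum finite on fully separable training data — exactly the
regime of the week-4 clusters, where unpenalized logistic regression
diverges. Convergence is declared at gradient ∞-norm < 1e-10 (or < 1e-6
when the line search stalls at machine precision).

FA threshold: fa_from_ratio(slope), deliberately ignoring the fitted
intercept (the zero-offset reduction that makes the threshold a pure
ratio); the ignored intercept is logged. The SD propagates the conversion
over bootstrap slopes. Nerve-level call: mean probability over distal
slices > 0.5 (threshold config-exposed); nerves without distal slices are
marked not assessable.

## Group statistics

Pairwise cohort comparisons use Welch's unpaired t-test by default (a
pooled-variance mode exists); the experimental unit is the animal — slice
records are averaged per animal first to avoid pseudo-replication from
repeated slices of one nerve. All raw p-values of a family
(parameters × timepoints × pairs) are adjusted together by the classic
Benjamini–Hochberg step-up, implemented directly and cross-checked in
tests against both a literal transcription of the definition and
statsmodels. Degenerate comparisons (both cohorts constant) return t = 0,
p = 1 when means agree.

Correlations are sample Pearson r with the two-sided t-transform p-value
(n−2 df). Probability-vs-behavior correlations put both behavioral axes on
a "larger = better recovered" scale: SFI is already oriented that way
(0 normal, ≈ −90 after injury), while the foot-fault asymmetry score rises
with injury, so it is flipped to 1 − FF before correlating. This keeps
both reported r values positive when the model tracks recovery, matching
the convention of the source analyses.

## Synthetic data: what it emulates, what it does not

The generator works at the tensor level. Each animal (one per roster
entry; default roster 21 sham / 23 crush / 19 cut/repair across weeks
1/2/4/12) contributes proximal and distal slice records at its endpoint,
drawn from per-(cohort, week, region) distributions of AD and the RD/AD
ratio with an animal-level random effect plus slice-level jitter. Derived
indices are internally consistent: MD = (AD+2RD)/3 exactly, FA from the
ratio (cylindrical symmetry) plus measurement noise, RK falling and AK
rising with the ratio.

Defaults (all invented emulation parameters, config-exposed, none
measured): healthy AD 1.6 µm²/ms, ratio 0.20; weeks 1–2 after injury are
edema/degeneration-dominated (ratios 0.6–0.7, occasionally RD > 1 so the
outlier rule fires as it does on real data); week-4 distal crush ratio
0.25 (SD 0.05) vs cut/repair 0.55 (SD 0.05), kept strictly separable about
RD = 0.40·AD − 0.03 with a total vertical margin of 0.1 µm²/ms by
rejection sampling; week-12 cut/repair outcomes bimodal with a recovered
fraction of 0.5 (the expected success rate of end-to-end repair).
Behavior: SFI 0 = normal with a post-operative drop to ≈ −90 and FF
0 → ≈ 0.85, both recovering along logistic time courses (midpoints: crush
week 3, recovered cut/repair week 8; non-recovered plateau 25%). Histology:
axon density = 0.03 axons/µm² × an axon volume fraction that decreases
linearly in the mean distal ratio, plus Gaussian noise (SD 0.002) — in the
realistic 0.01–0.02 axons/µm² range for rat sciatic nerve.

Noise model: magnitude (Rician) noise, σ = S0/SNR, as
√((S+σg₁)² + (σg₂)²); the b=0 mean is verified against the analytic Rician
mean. Determinism: one master seed; per-animal substreams keyed by
(cohort, week, animal index, purpose), so outputs are byte-identical
across runs.

Not emulated: two-compartment axon-packing microgeometry, the physics of
inflammation/edema (weeks 1–2 appear only as distribution shifts), spatial
correlation along the nerve beyond the animal random effect, and partial
voluming at the nerve boundary. Consequently, passing tests demonstrate
that the pipeline's machinery is correct and that its statistical readouts
behave as designed under the emulated geometry — not that the specific
fitted boundary or correlation magnitudes transfer to real scans.

A known estimation property worth stating: at SNR 30 the rectified-noise
floor of the b = 4000 s/mm² shell (axial signal e⁻⁶ ≈ 0.0025 ≪ σ) biases
fitted FA downward by ≈ 0.11 for a truth FA of 0.603; the bias shrinks
with SNR (< 0.05 by SNR ≈ 150). The test suite asserts this measured
behavior rather than an optimistic bound.

## Numerical and design choices

- WLLS pass count 2; extra passes change estimates negligibly on
  noise-free data (the fit is exact there regardless).
- Rank checks name the deficiency; fitting needs ≥ 22 acquisitions over
  ≥ 2 nonzero shells and ≥ 15 directions.
- Gradient directions by seeded antipodal electrostatic repulsion from a
  random start (the acquisition's direction table is not published);
  uniformity is tested via the second moment ≈ I/3.
- Slice-record CSVs carry a schema-version header; readers reject unknown
  versions. Pipeline reruns with identical config and seed are
  bit-identical for CSV/JSON artifacts.
- Problem sizes used by the test suite and the acceptance script (100
  round-trip tensors, 300–500 Monte-Carlo noise draws, 1000 bootstrap
  replicates, small phantoms of ≲ 200 voxels) were chosen as the smallest
  sizes at which the checked quantities are stable to well within their
  tolerances.

## Limitations

- The classifier is a single linear boundary in (AD, RD); kurtosis-based
  or nonlinear classifiers are deliberately out of scope (the DKI indices
  did not improve recovery classification in the motivating data).
- The FA threshold inherits the zero-offset and cylindrical-symmetry
  assumptions; with a nonzero fitted intercept it is an approximation
  whose error grows at low AD.
- Bootstrap SDs on the default synthetic study are wider than those
  reported for the real cohorts; with ~60 training slices and a wide
  cluster gap, the support set is small and resampling moves the boundary
  substantially. The SDs are honest descriptions of that variability.
- Ex vivo fixed-tissue diffusivities do not translate directly to fresh
  tissue; only normalized indices (RD/AD, FA) are expected to carry over.
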
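# nervedki

Diffusion MRI assessment of peripheral nerve regeneration after trauma.

After a traumatic peripheral nerve injury, surgeons currently have no
noninvasive way to tell a regenerating repair from a failing one until the
muscle is reinnervated — often months too late for a corrective
reoperation. In rat sciatic nerve models, ex vivo diffusion tensor (DTI)
and diffusion kurtosis imaging (DKI) can see the difference much earlier:
as Wallerian degeneration clears and axons repopulate the distal stump,
radial diffusivity (RD) falls relative to axial diffusivity (AD), and
fractional anisotropy (FA) rises. `nervedki` implements that analysis as a
tested, reusable pipeline for three-cohort studies (sham, crush,
cut/repair) sampled at 1, 2, 4 and 12 weeks post-surgery.

## What the package computes

**Tensor estimation.** Per voxel, the standard 22-parameter log-linear DKI
representation

```
ln S(b, n) = ln S0 − b·D_app(n) + (1/6)·b²·D_app(n)²·K_app(n)
D_app(n) = Σ nᵢnⱼ Dᵢⱼ,   K_app(n) = (MD²/D_app(n)²)·Σ nᵢnⱼnₖnₗ Wᵢⱼₖₗ
```

is fitted by two-pass weighted linear least squares (pass 1 OLS on ln S;
pass 2 weighted by squared predicted signals), then reduced to the scalar
indices FA, MD, AD = λ₁, RD = (λ₂+λ₃)/2, and MK/AK/RK by deterministic
numerical averaging of K_app.

**Recovery classifier.** Slice-wise ROI means in the (AD, RD) plane at
week 4 — crush (reliably self-resolving, labeled recovered) vs cut/repair
(not yet recovered) — are linearly separable once post-surgical edema
subsides. A linear SVM in physical units yields the decision line
RD = slope·AD + intercept; a stratified bootstrap gives its uncertainty;
a Platt sigmoid with smoothed targets (well-posed on fully separable data,
unlike plain logistic regression) converts signed decision values into
calibrated recovery probabilities. Under cylindrical symmetry the
zero-offset boundary is a pure RD/AD ratio and maps to a unique FA
threshold:

```
FA = (1 − RD/AD) / sqrt(1 + 2·(RD/AD)²)
```

so a slope of 0.40 corresponds to FA ≈ 0.522.

**Cohort statistics.** Welch t-tests per timepoint/parameter (animal as
experimental unit) with Benjamini–Hochberg FDR control, and Pearson
correlations of recovery probabilities vs behavior (sciatic function
index, foot-fault score) and scalar indices vs histological axon density.

**Synthetic data.** Because the original scans are not publicly deposited,
a first-class generator emulates every input: two-shell gradient schemes
(b = 2000/4000 s/mm², 20 directions), Rician-noise voxel signals and tube
phantoms from known tensors, and full cohort studies (21/23/19 animals)
with behavioral and histological couplings. All generator distributions
are invented, clearly-labeled emulation parameters.

## Worked example

```bash
python examples/03_recovery_classifier.py
```

prints (seed 1):

```
simulated 63 animals, 819 slice records
boundary: RD = 0.383 x AD + 0.022  (bootstrap SDs 0.129 / 0.198)
FA threshold from slope (zero-offset reduction): 0.5426 +/- 0.1551

week-12 cut/repair nerves (the clinically interesting group):
        animal_id  mean_probability  recovered_call
cut_repair_w12_00             0.984            True
cut_repair_w12_01             0.917            True
cut_repair_w12_02             0.015           False
cut_repair_w12_03             0.958            True
cut_repair_w12_04             0.916            True
cut_repair_w12_05             0.015           False
```

The fitted boundary slope (0.383) recovers the line the generator
separated the week-4 clusters around (0.40) to within the bootstrap
uncertainty, and the derived FA threshold lands near 0.54. At week 12 the
cut/repair nerves split into confident recovered/non-recovered calls,
matching the generator's ground truth — the readout a surgeon would want
when deciding on reoperation. `examples/01…04` walk through the tensor
engine, the phantom-to-maps path, the classifier, and the group
statistics, one capability each.

A thin CLI wraps the same functions:

```bash
nervedki simulate --seed 1 --out sim
nervedki train --records sim/slice_records.csv --seed 1
nervedki run --seed 1 --out full_run
```

## Layout

- `src/nervedki/gradients.py` — gradient schemes, FSL bval/bvec IO
- `src/nervedki/dki.py` — forward model, WLLS fit, scalar indices
- `src/nervedki/synthetic.py` — signal/phantom/study generators
- `src/nervedki/slicewise.py` — slice labeling, ROI means, outlier rules
- `src/nervedki/classifier.py` — SVM boundary, bootstrap, Platt, FA threshold
- `src/nervedki/stats.py` — t-tests, FDR, correlations
- `src/nervedki/io.py`, `cli.py` — file formats, pipeline, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
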
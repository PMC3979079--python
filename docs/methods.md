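# Methods

This note documents the models, conventions and design choices behind
`sfdikit`, in the order the pipeline runs.

## Acquisition model and demodulation

An acquisition is a 5-axis stack (wavelength × frequency × phase × y × x):
four NIR wavelengths (658, 730, 850, 970 nm), thirty spatial frequencies
uniformly spaced on [0, 0.33] mm⁻¹, and three phase offsets (0, 2π/3, 4π/3 —
the standard three-phase scheme, which the demodulation identity assumes).
For f > 0 the renderer projects `½[1 + cos(2πf·x_mm + φ_k)]`; at f = 0 the
instrument projects a uniform field, so the three frames are identical
planar images. Consequently the demodulated AC envelope at f > 0 equals
`gain · R_d / 2` and the planar amplitude lives in the DC channel;
`modulation_amplitude()` returns the appropriate channel per frequency. The
factor-of-two modulation-depth convention is unobservable downstream because
calibration takes the tissue/standard ratio.

Demodulation is the exact pixelwise identity
`m_ac = (√2/3)·√[(I₁−I₂)² + (I₂−I₃)² + (I₃−I₁)²]`: for any three samples of
a cosine at 120° spacing it returns the amplitude regardless of the carrier
phase, which also removes ambient (additive) light. No spatial filtering is
applied anywhere.

Calibration multiplies the amplitude ratio by the diffusion-model
reflectance of the standard (defaults: μa ≈ 0.004–0.005 mm⁻¹,
μs′ ≈ 0.95–1.15 mm⁻¹ across the band, a TiO₂-in-siloxane-like standard) and
by the inverse-square height factor `(h − Δh)²/h²`. The default height
offset is 0 (factor 1): at h ≈ 120 mm a 1 mm offset changes the amplitude by
under 2%, a negligible scaling that the operation nevertheless implements
and tests. Pixels with zero reference amplitude become NaN and clear a
validity mask that every later stage carries.

## Light transport

The forward model is the spatial-frequency-domain diffusion approximation
for a semi-infinite homogeneous medium with refractive index n = 1.4:

    μ_tr = μa + μs′,  a′ = μs′/μ_tr,  μ_eff′ = √(3 μa μ_tr + (2πf_x)²)
    R_eff = 0.0636 n + 0.668 + 0.710/n − 1.440/n²,  C = (1−R_eff)/(2(1+R_eff))
    R_d   = 3 C a′ / [(μ_eff′/μ_tr + 1)(μ_eff′/μ_tr + 3C)]

f = 0 is the planar limit of the same expression and is included in fitting.
The model is monotone decreasing in f_x and μa and increasing in μs′ at
f = 0 over the tissue range, which the tests audit by finite differences. A
white Monte Carlo photon random walk (isotropic scattering at the reduced
coefficient, continuous absorption weighting, Fresnel boundary, Hankel
transform of R(ρ)) serves as an independent cross-model check; the two agree
within ~15% for μs′/μa ≥ 20 at f_x ≤ 0.2 mm⁻¹, a documented sanity band —
diffusion is least accurate near the source and at high frequency.

**Inversion.** Per pixel and wavelength, (μa, μs′) minimizes
Σ_f [R_meas − R_model]² against a precomputed LUT (64 × 64 points,
log-spaced over μa ∈ [10⁻³, 0.5] and μs′ ∈ [0.1, 5] mm⁻¹). The coarse argmin
(ties break toward smaller μa, then smaller μs′) is refined by a
deterministic zoomed grid search: five levels of a 9 × 9 log-spaced sub-grid
spanning the winner's second-nearest neighbours (the objective is shallow in
μa, so the bracket must tolerate a minimum slightly beyond the adjacent
cell), giving ~0.01% final resolution. This was chosen over per-pixel
quasi-Newton refinement for determinism and vectorization. R² uses
`1 − RSS/TSS` with TSS about the per-pixel frequency mean (the convention is
fixed here; other choices exist). Pixels with fewer than three finite
frequencies are invalid; `apply_r2_mask` clears the mask where the
worst-wavelength R² falls below the threshold (default 0.95), emulating the
exclusion of inked, specular or edge pixels.

## Spectral decomposition

Absorption is unmixed by non-negative least squares over three chromophores:
μa(λ) = c_HbO₂·ε_HbO₂(λ) + c_Hb·ε_Hb(λ) + f_H₂O·μa,water(λ). Water is
fitted as a fractional multiplier of the pure-water absorption spectrum,
matching %H₂O semantics. The extinction/absorption basis at the four
wavelengths is a packaged CSV transcribed (rounded) from the standard public
compilations (Prahl hemoglobin; Segelstein water); its condition is checked
at load. Derived quantities: HbT = c_HbO₂ + c_Hb (μM), %O₂ = 100·c_HbO₂/HbT
(defined as 0 when HbT = 0). No adipose/lipid chromophore is included.
Scattering is fitted as a line in ln μs′ vs ln(λ/λ₀) with λ₀ = 800 nm, a
conventional NIR anchor inside the band; A is μs′ at λ₀ and b the power-law
slope. Non-positive μs′ flags the pixel invalid rather than fitting.

## Classification protocol

Features are the five spectral parameters per pixel. The protocol per
cross-validation rotation: fit a ZCA whitening transform (inverse symmetric
square root of the training covariance; ridge on degenerate eigenvalues,
logged) on the training folds, trim training outliers, classify the held-out
fold with k-NN (scipy k-d tree; Euclidean distance in whitened space;
majority vote with ties broken by the nearest neighbour among tied classes).
Whitening is per-fold by default to avoid leakage; a `global_whiten` switch
reproduces the simpler whole-dataset variant.

Outlier trimming operationalizes an "interquartile fraction" rule: per class
and per feature, Tukey fences [Q1 − c·IQR, Q3 + c·IQR], with the multiplier
c found by bisection so the overall removed fraction is the largest value
not exceeding the budget (default 5%). Validation points are never trimmed.
Note that points inside [Q1, Q3] can never be fenced out, so a budget ≤ 20%
can never empty a class.

Folds are class-stratified with *equal* per-class counts; per-class
remainders mod 3 are dropped and logged. The confusion matrix pools the
three rotations (each sample is validated exactly once); scalar metrics are
averaged over rotations. Sensitivity/specificity intervals are
continuity-corrected score (Wilson–Yates) intervals, computed as the exact
roots of `(|x − np| − ½)² = z²·np(1−p)` clipped to [0, 1]. The ROC sweep
evaluates odd k (default 1–31) on the benign-vs-malignant task (malignant
positive) and reports the k maximizing Youden's index, ties toward smaller k.

A caveat the synthetic tests make visible: whitening on the *total*
covariance compresses any single separated direction to about two whitened
units against unit orthogonal noise, so a binary task retains a small
(~1%) irreducible k-NN error however separated the raw classes are. With
five classes spread across all feature axes the separable limit does reach
accuracy 1. Pixel-level samples within an ROI are not independent; group ids
are carried so a group-aware split is possible, but the default matches the
pixelwise protocol — pixelwise accuracies are optimistic relative to
patient-level generalization.

## Separability ranking and correlates

Class separability uses the Gaussian Bhattacharyya distance

    J_ij = ⅛ (μᵢ−μⱼ)ᵀ[(Σᵢ+Σⱼ)/2]⁻¹(μᵢ−μⱼ) + ½ ln[det((Σᵢ+Σⱼ)/2)/√(det Σᵢ det Σⱼ)]

generalized as J = Σᵢ Σⱼ PᵢPⱼ J_ij with priors from class sample fractions.
The Gaussian closed form is the canonical choice and is verified against
numerical quadrature of the Bhattacharyya coefficient in 1-D; it is affine
invariant. Near-singular covariances receive a ridge of 1e-8·tr(Σ)/d
(logged) — reachable by design, since ranking operates on region-averaged
features (one vector per ROI) and per-class ROI counts can be small relative
to five features. SFFS adds the J-maximizing feature, then conditionally
removes any feature whose exclusion beats the best recorded subset of that
size; the ranking is the order of entry into the best nested chain, ties
lexicographic. The J trace along the nested chain is non-decreasing (the
Bhattacharyya coefficient cannot increase under adding coordinates).
Spectral–IHC association uses Pearson r between ROI-mean parameters and the
seven IHC measures, paired by ROI id; zero-variance columns are flagged
undefined rather than reported.

## Synthetic phantoms

The generator emulates: class-conditional Gaussian parameter distributions
over five pathology classes (NOR, FA, DCIS, INV, INV_RX; benign = {NOR, FA}),
pixelwise heterogeneity, the acquisition geometry above, a smooth
multiplicative system gain, multiplicative Gaussian intensity noise (default
relative σ = 0.01 — simple, scale-free, adequate for round-trip testing),
a co-imaged reference standard, and ROI-level IHC tables linearly coupled to
ROI-mean parameters (slope b positively coupled to %stroma, negatively to
%epithelium and vascular measures; HbT positively to vessel density), with
composition percentages renormalized to sum to 100.

Default class means (A mm⁻¹ at 800 nm, b, HbT μM, O₂, water fractions) are
ordered to follow the qualitative pathology trends — NOR highest A and b;
FA lower A; INV higher HbT and lower %O₂; DCIS lower %O₂ and higher %H₂O;
INV_RX higher b than INV — with magnitudes chosen once to be plausible for
breast tissue in the NIR (A ≈ 0.85–1.30 mm⁻¹, b ≈ 0.6–1.0, HbT ≈ 14–28 μM,
%O₂ ≈ 55–72, %H₂O ≈ 28–50). They are generator conventions, not
measurements. The default layout is a 72 × 96 px image with thirty 10 × 10
ROIs, six per class — enough regions for region-level covariances and
correlates while keeping a full pipeline run around twenty seconds on one
CPU; O₂ and water fractions are clipped to [0, 1] and positive floors keep
derived optical properties strictly positive.

What the phantoms do *not* emulate: specimen surface-height variation and
edge artifacts (profile correction is out of scope), surgical-ink
contamination (beyond what the R² mask would catch), spatial correlation of
parameters within an ROI, instrument MTF roll-off, and shot/read noise
statistics. Passing tests therefore demonstrate correctness of the
algorithms and their couplings, not clinical-grade performance on real
specimens.

## Determinism and provenance

All randomness flows from a single root seed split per stage through
`numpy.random.SeedSequence`. The pipeline writes every image intermediate as
multi-frame TIFF with a JSON sidecar (axes, units, acquisition metadata),
tables as CSV, reports as JSON, and the LUT as an .npz container with a JSON
header. The manifest records the configuration hash, per-stage seeds and
statuses, and SHA-256 checksums of every output; no timestamps are stored,
so a rerun with identical configuration and seed reproduces the bundle byte
for byte, and `--resume` re-executes only stages whose outputs are missing
or downstream of a regenerated stage.

## Problem sizes

Test and example workloads are sized for a laptop-class single CPU: 64-point
LUT grids, 100-point inversion sweeps, phantoms of a few thousand labelled
pixels, 20-seed permutation nulls, 100-seed SFFS recovery studies, and
Monte Carlo cross-checks of 2–4 × 10⁵ photons. Each scales up by changing
one argument.
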
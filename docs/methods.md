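# Methods

This note documents the models, parameter conventions, numerical choices
and known limitations of the package. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coverage tracks and peak calling

Tracks are fixed-step binned coverage (default 50 bp). All internal
coordinates are 0-based half-open; only the wiggle reader/writer converts
to the format's 1-based declarations. variableStep files are rejected
rather than resampled, and a `span` differing from `step` is a format
error because bins must tile.

Normalization follows the usual ChIP workflow: values × 10⁶/library size
(RPM), per-bin input subtraction (floored at zero by default — the caller
thresholds are positive and negative enrichment has no downstream
meaning; the floor can be disabled), then the arithmetic mean across
replicates.

The peak caller is the browser-style thresholding rule: (1) bins with
value **≥** threshold are enriched (the comparison is ≥, chosen so the
boundary case is deterministic and testable); (2) maximal runs of
enriched bins are candidate regions; (3) successive regions with an
inter-region gap ≤ max_gap bp merge, the gap bins joining the span while
staying unenriched; (4) merged regions with span ≥ min_run bp are
returned. The length filter runs **after** merging, since the gap
parameter is what decides whether two enriched regions are distinct.
Reported per peak: span (on bin edges), maximum enriched-bin value, and
the number of enriched bins. The caller is verified bit-for-bit against a
brute-force enumeration on thousands of random tracks.

Classification uses ≥ 1 bp of overlap: interphase peaks overlapping any
mitotic peak are mitotically retained, the rest interphase-only; mitotic
peaks with no interphase overlap are mitosis-only. An interphase peak
overlapping several mitotic peaks is counted once.

Motif counting defaults to overlapping occurrences on both strands —
GAGAG arrays are self-overlapping, and (GA)ₖ contains k−2 overlapping
forward matches — with both switches exposed. Annotation labels a peak
`promoter` if it overlaps ±100 bp around a TSS, else `enhancer` if it
overlaps the enhancer set, else `other`; promoter deliberately takes
precedence. Metagene matrices center on floor((start+end)/2), cover
±flank (default 1 kb) on the track's own bin grid, and zero-fill
off-track positions.

## FRAP

Traces carry bleached, unbleached-neighbor and outside-nucleus ROI
intensities. Correction: I_corr = (I_bl − I_out)/(I_unbl − I_out);
normalization divides by the prebleach mean. The denominator uses the
*corrected* prebleach samples by default (so the normalized prebleach
mean is exactly 1); a literal variant normalizing by the raw bleached-ROI
prebleach mean is available (`normalize_by="raw"`).

The recovery model is F(t) = F_eq·F_D(t) + (1−F_eq)·F_exc(t). F_D is the
truncated series for a Gaussian bleach/illumination profile in the
bleach-depth constant K with characteristic time τ. Two series variants
exist: the default starts at n = 1, reproducing a published truncated
form verbatim; `standard_axelrod=True` restores the n = 0 term of the
classical series, which is the physically sensible choice — without it
F_D(0) < 0 and F_D(∞) = 0 for a fully mobile pool, i.e. the curve is not
a recovery. Both are kept so the printed form remains inspectable; the
synthetic generator defaults to the standard variant because its job is
to emulate real (monotonically recovering) data. The series order is 20
in the fit model; the β table (below) uses order 100 because at deep
bleaches (K ≳ 5) the order-20 truncation is not converged.

F_exc(t) = F_∞ − ((1−e^(−K))/K − F_∞)e^(−k_off·t) exactly as printed; its
t = 0 value is 2F_∞ − (1−e^(−K))/K, which does not obviously equal the
post-bleach bound-fraction signal — the offset convention is ambiguous
and is simply documented here.

**Identifiability.** The curve determines only the combinations F_eq·M
and (1−F_eq)((1−e^(−K))/K − F_∞) — the constant term is implied by these
— so the amplitude trio (M, F_eq, F_∞) lies on a flat ridge while K, τ
and k_off stay identified. This is precisely why the mobile fraction is
box-constrained to [0.9, 1.1]. The fitter therefore accepts `fix_M`
(e.g. 1.0) to pin the ridge when individual amplitude estimates are
wanted; with M free, only the identified quantities should be
interpreted.

Fitting: bounded nonlinear least squares (trf) on the first 1100
post-bleach frames, τ and k_off log-parameterized, M boxed to [0.9, 1.1]
and initialized from the depth relation M = (I_plateau − I₀)/(1 − I₀)
with the plateau read beyond 30τ; K initialized by inverting
(1−e^(−K))/K = I₀. A deterministic 3×3×3 grid over (τ, k_off, F_eq)
seeds the starts; all 27 are scored by initial SSE and the best five are
polished, keeping the lowest final SSE. The fitted τ is the *series
characteristic time*; conversion to the half-time of recovery goes
through β(K) = τ½/τ_D, tabulated by generating the pure-diffusion
standard-series recovery at τ_D = 1 and root-finding the time to reach
halfway between F(0) and the plateau. D = β(K)·w²/(4τ½) with w = 0.83 µm
by default. β(K) is monotone increasing and the round trip recovers a
known D to better than 1%.

Default acquisition geometry (53 ms frame interval, 1200 frames, 10
prebleach frames) is trace metadata only; it never enters the model.

## FCS

The model is the standard 3D-Gaussian-volume autocorrelation with n
diffusing species and a triplet correction, plus a long-lag offset G_∞.
Constraints in the two-species fit: τ_T ≤ 10 µs, Σfᵢ = 1 (parameterized
by f₁ ∈ [0,1]), diffusion times log-parameterized and returned sorted,
the structure parameter s fixed from calibration (default 5 when no
calibration is supplied — a typical confocal value that must be explicit
in config). Weights are uniform by default with an optional 1/G²
scheme. Curves are fitted independently and summarized by medians; no
global fitting. Calibration: w_xy = √(4·D_cal·τ_cal) with D_cal =
414 µm²/s for the reference dye; D = w_xy²/4τ_d.

When single-species data are fitted with n = 2 at realistic noise, the
global optimum may either concentrate one fraction near 1 or split the
species into two nearby diffusion times; both outcomes are the same
physical answer and the f-weighted mean diffusion time is the stable
summary.

An independent Brownian-dynamics oracle (particles random-walking in a
periodic 3-µm box, intensity = sum of Gaussian detection-volume weights,
ACF by FFT) checks the closed form's single-species shape without
sharing any code with it. The box has no minimum-image weighting — the
detection volume is far smaller than the box.

## Postmitotic memory

The activation delay decomposes as T_a = T_0 + T_r with T_0 the first
observed activation (pooled across movies by default; per-movie mode
available) and T_r the first-passage time of a linear irreversible chain
with up to three OFF states of common lifetime τ; S(t) is the
corresponding Gamma mixture. Nuclei never active by movie end enter
Kaplan–Meier as right-censored (a drop-censored alternative is a
switch). The model size is fixed at four states by default; the mixture
length is a parameter for robustness checks.

Fitting minimizes the unweighted sum of squares between the Kaplan–Meier
estimate and S(t) at the *event times* (avoiding grid arbitrariness),
with p on the simplex via a softmax reparameterization and τ
log-parameterized, from a deterministic multi-start (3 τ inits × corner
and center p inits, best four polished). Reported: p, τ, a = p₁+2p₂+3p₃,
b = τ, and the optimal cost O. A one-at-a-time cost-profile helper
covers parameter-sensitivity sweeps.

**Limitations worth knowing.** The KM curve's sampling noise is strongly
autocorrelated, and the mixture is flexible enough to absorb it: at a
few hundred events, b alone is weakly identified when the mixture is
dominated by single-jump paths (a·b, the mean delay, is always tight).
At a simplex corner such as p = (1,0,0) the fitted a can only deviate
upward. The moment estimator N = M²/V + 1 assumes T_r is measured from
T_0; any residual deterministic offset inflates it.

The simulator draws the jump count k ~ p and T_r ~ Gamma(k, τ) — exactly
the first-passage law — with right-censoring at movie end;
simulation and closed form agree to sup-distance < 0.02 at 10⁴ draws.
Cumulative activation curves normalize by the eventually-active count,
and t50 is the earliest grid time reaching 0.5.

## Imaging

Spot detection: 3D Laplacian of Gaussian (σ = 1 voxel by default; the
kernel unit is a stated convention, configurable), sign-flipped so blobs
are maxima, thresholded at µ + thr·σ_f of the filtered frame (per frame
in movies, thr shared across frames). A flat frame (σ_f = 0) yields no
spots rather than a degenerate threshold. 26-connected components become
spots; total intensity and the intensity-weighted center of mass are
computed from the *raw* voxels inside the mask. The sensitivity thr is
user-set: 3 suits small ROIs, while planted-truth evaluations on full
~5×10⁵-voxel stacks use 5, since a false-positive-free threshold over N
voxels needs roughly the 1/N normal tail (> 4.4σ).

Nuclei: Gaussian smoothing, then Otsu on the logarithm (the log
compensates intranuclear intensity gradients), thresholded per z-slice
(per timepoint and slice in movies); constant slices give an empty mask
with a warning; the log offset eps defaults to 1 intensity unit. Spots
whose rounded center voxel falls outside the mask are removed.

FISH distances: Euclidean in physical coordinates with z scaled by its
own voxel size, mutual-nearest-neighbor pairing (ties broken by lowest
index for reproducibility), and pairs beyond 1 µm discarded as aberrant.
Transcription-site intensities are the raw-voxel sums divided by the
mean of several (typically six) background-area means per movie.
De-novo filtering removes post-mitotic spots within a radius (default
0.5 µm) of any mitotic-frame spot position — a positional reading of
"spots present during mitosis"; identity-based tracking is out of scope.

## Synthetic data

Generators return (data, truth) and are deterministic functions of the
seed; a process-wide seed fans out through `SeedSequence([seed,
stage_code])` so adding a generator never shifts another stage's draws.

Defaults are the study conditions the analyses expect: FRAP — K = 1,
M = 1, τ = 0.2 s, F_eq = 0.7, k_off = 0.5 s⁻¹ (2-s residence), F_∞ = 1,
23 traces at 2% Gaussian noise on a 53-ms/1200-frame grid; FCS — N = 20,
T = 0.15, τ_T = 5 µs, two equal fractions at τ_d = 0.45 ms and 22.5 ms
(a 1:50 ratio, i.e. D ≈ 22 and 0.45 µm²/s at w_xy = 0.2 µm), 1%
multiplicative noise; coverage — |Normal| background (σ = 10) far below
the threshold of 100, rectangular planted peaks of height 150–400 with
2% edge jitter, separated by more than the merge gap; genomes carry
(GA)₅ arrays inside peaks on a two-letter {A,C} interior that cannot
contain GAGAG or CTCTC by chance, so per-peak motif counts are exact by
construction; stacks — σ = 1.5 voxel Gaussian spots, ≥ 4σ apart, at
chosen SNR on 0.1/0.3 µm voxels; lineages — active-mother daughters with
p = (0.6, 0.3, 0.1), τ = 70 s vs inactive-mother daughters with
p = (0.2, 0.4, 0.4), τ = 120 s, T_0 = 60 s, movies ending at 2000 s.

What the generators do *not* emulate — and hence what passing tests do
not show about real data: read-level sequencing artifacts and mappability
structure (peaks are planted rectangles, not pileups), detector
afterpulsing and photobleaching in FCS/FRAP, realistic PSFs and
chromatic aberration in imaging, and nuclei tracking errors upstream of
the activation tables.

## Problem sizes

The shipped tests and the acceptance script run at desk scale: 10³
random 200-bin tracks for oracle equivalence, 10⁴ simulated waiting
times for distribution-level checks (10⁵ draws for the moment
estimator), 23 FRAP traces, 10–15 FCS curves, 50-spot stacks, and
100 replicate simulations for the null behavior of the memory score.
These sizes were chosen so every statistical tolerance sits well inside
its sampling error; the whole suite completes in about half a minute.
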
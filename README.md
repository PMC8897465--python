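# mitobook

Quantitative analysis of **mitotic bookmarking** — the retention of a
transcription factor on mitotic chromatin and its consequence, faster
postmitotic gene reactivation — aimed at the early *Drosophila* embryo,
whose naturally synchronous nuclear cycles make it the classic system for
this question. The package is written for quantitative biologists who have
(or simulate) the five data kinds such a study produces and want a tested,
scriptable pipeline rather than one-off notebook code:

1. **Binned ChIP-seq coverage** (fixedStep wiggle, 50-bp bins) — RPM
   rescaling, input subtraction, replicate averaging, a browser-style
   *threshold peak caller*, interphase/mitotic peak classification,
   GAGAG-motif counting, promoter/enhancer annotation, metagene matrices.
2. **FRAP recovery traces** — ROI correction/normalization and fitting of a
   two-population reaction–diffusion recovery model yielding the unbinding
   rate k_off (residence time 1/k_off) and a diffusion coefficient.
3. **FCS autocorrelation curves** — two-species + triplet model fitting and
   confocal-volume calibration against a dye of known D.
4. **3D image stacks** — Laplacian-of-Gaussian spot detection with a
   relative threshold, log-Otsu nuclei segmentation, transcription-site
   intensity extraction, de-novo spot filtering, and mutual-nearest-neighbor
   DNA-FISH distances with anisotropic voxels.
5. **Lineage-annotated activation tables** — Kaplan–Meier survival of
   postmitotic activation delays and a mixed-Gamma model of transcriptional
   memory.

A synthetic-data module generates every input kind with planted ground
truth, so the whole pipeline is testable at desk scale.

## The models at the core

**Threshold peak calling.** On a binned track, bins with value ≥ *T* are
enriched; maximal runs of enriched bins are merged when separated by ≤
*Max.Gap* bp, and merged regions shorter than *Min.Run* bp are dropped
(defaults *T* = 100, *Min.Run* = 50 bp, *Max.Gap* = 200 bp). An interphase
peak that shares ≥ 1 bp with a mitotic peak is *mitotically retained*.

**FRAP.** The normalized recovery is
F(t) = F_eq·F_D(t) + C_eq·F_exc(t), with F_eq = k_off/(k_off + k*_on),
C_eq = 1 − F_eq. F_D is the order-20 series solution for a Gaussian bleach
profile with depth constant K and characteristic time τ; F_exc(t) =
F_∞ − ((1−e^(−K))/K − F_∞)·e^(−k_off·t). Diffusion coefficients come from
D = β(K)·w²/(4τ½) with w the 1/e² beam radius (0.83 µm) and β(K) a
numerically tabulated half-time correction.

**FCS.** G(t) = 1 + (1/N)(1 + T·e^(−t/τ_T)/(1−T)) Σᵢ fᵢ/((1+t/τᵢ)·
(1+t/(s²τᵢ))^(1/2)) + G_∞, with τᵢ = w_xy²/4Dᵢ and s = w_z/w_xy; the
triplet lifetime is constrained below 10 µs and the volume is calibrated
with D_cal = 414 µm²/s.

**Postmitotic memory.** The activation delay is T_a = T_0 + T_r; T_r is the
first-passage time of a linear irreversible chain of up to three OFF states
with common lifetime τ, so its survival is the Gamma mixture
S(t) = p₁e^(−t/τ) + p₂(1 − γ(2,t/τ)/Γ(2)) + p₃(1 − γ(3,t/τ)/Γ(3)).
Summaries: a = p₁+2p₂+3p₃, b = τ (mean delay a·b); moment estimate of the
chain size N = M²/V + 1; memory score (a·b)_inactive/(a·b)_active, with
values above 1 indicating a memory bias.

## Worked example

`examples/mitotic_memory.py` simulates 400 daughters of transcriptionally
active mothers and 400 of inactive mothers under the default memory
conditions and runs the full analysis:

```
  active: p = [0.499 0.16  0.341], tau = 60 s, a = 1.84, mean delay a*b = 110 s (cost O = 0.057)
inactive: p = [0.218 0.659 0.123], tau = 145 s, a = 1.90, mean delay a*b = 276 s (cost O = 0.029)
memory score (a*b ratio) = 2.49, lifetime ratio = 2.41
moment estimate: a = 1.73 -> N = 3 chain states
t50 (active-mother daughters) = 2.5 min after mitosis
```

The fitted p and τ describe how many silent states a nucleus traverses
before reactivating and how long each takes; the score of 2.49 says
daughters of inactive mothers wait ~2.5× longer — the memory bias the
pipeline is built to detect. The other examples
(`peak_calling.py`, `frap_fitting.py`, `fcs_fitting.py`,
`spot_distances.py`) exercise the remaining stages the same way; each
prints the quantities it computes and what they mean.

A thin CLI mirrors the library (`mitobook peaks call --wig … --threshold
100`, `mitobook frap fit --traces …`, `mitobook synth lineage --seed 1
--out dir`, …); every run writes a manifest with resolved parameters,
input hashes and the seed, and re-running with the same seed reproduces
outputs byte for byte.

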
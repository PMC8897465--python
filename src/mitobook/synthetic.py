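"""Synthetic-data generators with planted ground truth.

Each generator emulates one input kind the pipeline consumes — FRAP
recoveries, FCS autocorrelations, binned ChIP/Input coverage with a
matching genome, 3D spot stacks, and lineage-annotated activation
tables — with the statistical structure the corresponding analysis
assumes, and returns the data together with a :class:`SyntheticTruth`
carrying the generative parameters and planted ground truth.

Determinism: a process-wide seed fans out into independent per-stage
streams via ``SeedSequence([seed, stage_code])``, so adding a generator
never shifts another generator's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .chip_peaks import Peak, PeakSet
from .fcs import AcfCurve, acf_model
from .frap import FrapTrace, frap_model
from .imaging import ImageStack
from .io_formats import BedRecord, CoverageTrack, GenomeIntervals
from .memory import ActivationRecord, simulate_chain

__all__ = [
    "SyntheticTruth",
    "gen_frap_traces",
    "gen_acf",
    "gen_acf_brownian",
    "gen_coverage_and_genome",
    "gen_interphase_mitotic_pair",
    "gen_image_stack",
    "gen_lineage",
]

_STAGE_CODES = {
    "frap": 11,
    "fcs": 12,
    "fcs_brownian": 13,
    "coverage": 14,
    "stack": 15,
    "lineage": 16,
}


def _stream(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STAGE_CODES[stage]]))


@dataclass
class SyntheticTruth:
    stage: str
    parameters: dict[str, Any] = field(default_factory=dict)
    ground_truth: Any = None


# ---------------------------------------------------------------------------
# FRAP

#: Generative kinetics of a GAF-like factor: short-lived binding with
#: residence time 1/k_off = 2 s, ~30% bound at equilibrium, near-total
#: mobility, sub-second diffusive recovery in the bleached spot.
FRAP_DEFAULT_PARAMS = {
    "K": 1.0,
    "M": 1.0,
    "tau": 0.2,
    "F_eq": 0.7,
    "k_off": 0.5,
    "F_inf": 1.0,
}


def gen_frap_traces(
    params: dict[str, float] | None = None,
    n_traces: int = 23,
    noise_sd: float = 0.02,
    frame_dt: float = 0.053,
    n_frames: int = 1200,
    n_prebleach: int = 10,
    seed: int = 0,
    standard_axelrod: bool = True,
    I_out: float = 10.0,
    I_unbl: float = 110.0,
) -> tuple[list[FrapTrace], SyntheticTruth]:
    """FRAP traces from the recovery model plus i.i.d. Gaussian noise.

    The default trace geometry follows a fast confocal acquisition: one
    frame every 53 ms for 1200 frames, with ten prebleach frames.  The
    generator defaults to the standard-series (physically increasing)
    recovery variant.  Raw bleached/unbleached/outside channels are
    emitted so that :func:`mitobook.frap.correct_and_normalize`
    reproduces the noiseless normalized curve exactly at zero noise.
    """
    p = dict(FRAP_DEFAULT_PARAMS, **(params or {}))
    rng = _stream(seed, "frap")
    times = frame_dt * np.arange(n_frames)
    t_post = times[n_prebleach:] - times[n_prebleach]
    model = frap_model(
        t_post, p["K"], p["M"], p["tau"], p["F_eq"], p["k_off"], p["F_inf"],
        standard_axelrod=standard_axelrod,
    )
    traces = []
    for _ in range(n_traces):
        norm = np.concatenate([np.ones(n_prebleach), model])
        norm = norm + rng.normal(0.0, noise_sd, size=n_frames)
        I_bl = I_out + (I_unbl - I_out) * norm
        traces.append(
            FrapTrace(
                times=times.copy(),
                I_bl=I_bl,
                I_unbl=np.full(n_frames, I_unbl),
                I_out=np.full(n_frames, I_out),
                n_prebleach=n_prebleach,
                bleach_index=n_prebleach,
            )
        )
    truth = SyntheticTruth(
        stage="frap",
        parameters={
            **p, "noise_sd": noise_sd, "frame_dt": frame_dt,
            "n_frames": n_frames, "standard_axelrod": standard_axelrod,
        },
        ground_truth=p,
    )
    return traces, truth


# ---------------------------------------------------------------------------
# FCS

#: Two diffusing GFP-tagged species in a calibrated confocal volume
#: (w_xy = 0.2 um): a fast, freely diffusing pool (tau_d = 0.45 ms,
#: D ~ 22 um^2/s) and a 50x slower chromatin-interacting pool.
FCS_DEFAULT_PARAMS = {
    "N": 20.0,
    "T": 0.15,
    "tau_T": 5e-6,
    "f": (0.5, 0.5),
    "tau_d": (4.5e-4, 2.25e-2),
    "s_param": 5.0,
    "G_inf": 0.0,
}


def gen_acf(
    params: dict[str, Any] | None = None,
    lags: np.ndarray | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[AcfCurve, SyntheticTruth]:
    """Closed-form ACF with multiplicative Gaussian noise on G - 1."""
    p = dict(FCS_DEFAULT_PARAMS, **(params or {}))
    if lags is None:
        lags = np.logspace(-6, 0, 150)
    rng = _stream(seed, "fcs")
    g = acf_model(
        lags, p["N"], p["T"], p["tau_T"], np.asarray(p["f"]),
        np.asarray(p["tau_d"]), p["s_param"], p["G_inf"],
    )
    noisy = 1.0 + (g - 1.0) * (1.0 + rng.normal(0.0, noise_sd, size=len(lags)))
    truth = SyntheticTruth("fcs", {**p, "noise_sd": noise_sd}, p)
    return AcfCurve(lags=lags, G=noisy), truth


def gen_acf_brownian(
    D: float = 5.0,
    w_xy: float = 0.2,
    s_param: float = 5.0,
    n_particles: int = 200,
    duration: float = 20.0,
    dt: float = 2e-4,
    box: float = 3.0,
    seed: int = 0,
    n_lags: int = 60,
) -> tuple[AcfCurve, SyntheticTruth]:
    """Brownian-dynamics oracle ACF for a single diffusing species.

    Particles random-walk in a periodic cube; the detected intensity is
    the sum of 3D-Gaussian detection-volume weights
    exp(-2(x^2+y^2)/w_xy^2 - 2 z^2/w_z^2) and its autocorrelation is
    computed directly by FFT.  The result is an implementation-
    independent check of the closed-form single-species ACF shape, with
    expected diffusion time w_xy^2 / 4D.
    """
    rng = _stream(seed, "fcs_brownian")
    n_steps = int(round(duration / dt))
    w_z = s_param * w_xy
    step_sd = np.sqrt(2.0 * D * dt)
    pos = rng.uniform(-box / 2, box / 2, size=(n_particles, 3))
    intensity = np.empty(n_steps)
    chunk = 2000
    for start in range(0, n_steps, chunk):
        m = min(chunk, n_steps - start)
        steps = rng.normal(0.0, step_sd, size=(m, n_particles, 3))
        for j in range(m):
            pos += steps[j]
            pos = (pos + box / 2) % box - box / 2
            wgt = np.exp(
                -2.0 * (pos[:, 0] ** 2 + pos[:, 1] ** 2) / w_xy**2
                - 2.0 * pos[:, 2] ** 2 / w_z**2
            )
            intensity[start + j] = wgt.sum()
    dI = intensity - intensity.mean()
    f = np.fft.rfft(dI, n=2 * n_steps)
    acov = np.fft.irfft(f * np.conj(f))[:n_steps]
    acov /= np.arange(n_steps, 0, -1)  # unbiased normalization
    G = 1.0 + acov / intensity.mean() ** 2
    # log-spaced subset of lags, skipping lag 0
    idx = np.unique(
        np.round(np.logspace(0, np.log10(n_steps // 4), n_lags)).astype(int)
    )
    curve = AcfCurve(lags=idx * dt, G=G[idx])
    truth = SyntheticTruth(
        "fcs_brownian",
        {"D": D, "w_xy": w_xy, "s_param": s_param,
         "n_particles": n_particles, "duration": duration, "dt": dt},
        {"tau_d": w_xy**2 / (4.0 * D)},
    )
    return curve, truth


# ---------------------------------------------------------------------------
# ChIP coverage + genome


def _plant_motif_free(rng: np.random.Generator, length: int) -> str:
    """Peak-interior background over {A, C}: cannot contain GAGAG or CTCTC."""
    return "".join(rng.choice(list("AC"), size=length))


def gen_coverage_and_genome(
    n_chrom: int = 2,
    chrom_len: int = 100_000,
    bin_size: int = 50,
    n_peaks: int = 20,
    peak_height_range: tuple[float, float] = (150.0, 400.0),
    background_sd: float = 10.0,
    motif_arrays_per_peak: int = 2,
    motif_repeats: int = 5,
    min_gap_bins: int = 8,
    peak_width_bins: tuple[int, int] = (4, 12),
    seed: int = 0,
) -> tuple[CoverageTrack, CoverageTrack, dict[str, str], SyntheticTruth]:
    """Binned ChIP + Input tracks, a genome, and a truth BED of planted peaks.

    Background bins are |Normal(0, background_sd)| (well below a
    threshold of 100); planted peaks are rectangular blocks of
    uniformly drawn height with per-bin jitter, separated by more than
    the caller's default merge gap so each is called individually.  The
    genome carries (GA)_k arrays inside each planted peak on a
    two-letter background that cannot contain the GAGAG motif by
    chance, so per-peak motif counts are known by construction:
    ``motif_arrays_per_peak * (motif_repeats - 2)``.
    """
    rng = _stream(seed, "coverage")
    n_bins = chrom_len // bin_size
    per_chrom = [n_peaks // n_chrom + (1 if c < n_peaks % n_chrom else 0)
                 for c in range(n_chrom)]
    chip_vals: dict[str, np.ndarray] = {}
    input_vals: dict[str, np.ndarray] = {}
    genome: dict[str, str] = {}
    truth_records: list[BedRecord] = []
    truth_counts: list[int] = []
    motif_count = motif_arrays_per_peak * max(motif_repeats - 2, 0)
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        chip = np.abs(rng.normal(0.0, background_sd, size=n_bins))
        inp = np.abs(rng.normal(0.0, background_sd / 2, size=n_bins))
        seq = rng.choice(list("ACGT"), size=chrom_len)
        # place peaks left to right with random gaps
        k = per_chrom[c]
        widths = rng.integers(peak_width_bins[0], peak_width_bins[1] + 1, size=k)
        needed = widths.sum() + (k + 1) * min_gap_bins
        if needed > n_bins:
            raise ValueError(
                f"cannot pack {k} peaks of mean width {widths.mean():.0f} "
                f"bins into {n_bins} bins"
            )
        slack = n_bins - needed
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        base = min_gap_bins  # left edge before adding the sorted random cut
        for i in range(k):
            start_bin = base + int(cuts[i])
            w = int(widths[i])
            height = rng.uniform(*peak_height_range)
            block = height + rng.normal(0.0, 0.02 * height, size=w)
            chip[start_bin : start_bin + w] = np.maximum(
                block, peak_height_range[0] * 0.9
            )
            start_bp, end_bp = start_bin * bin_size, (start_bin + w) * bin_size
            truth_records.append(
                BedRecord(chrom, start_bp, end_bp, f"peak_{chrom}_{i}",
                          float(height), ".")
            )
            truth_counts.append(motif_count)
            # motif-free interior, then (GA)_k arrays with CC buffers
            interior = list(_plant_motif_free(rng, end_bp - start_bp))
            array = "CC" + "GA" * motif_repeats + "CC"
            span = len(array)
            n_sites = (end_bp - start_bp) // span
            sites = rng.choice(n_sites, size=min(motif_arrays_per_peak, n_sites),
                               replace=False)
            for site in sites:
                off = site * span
                interior[off : off + span] = list(array)
            seq[start_bp:end_bp] = list("".join(interior))
            base += w + min_gap_bins
        chip_vals[chrom] = chip
        input_vals[chrom] = inp
        genome[chrom] = "".join(seq)
    truth = SyntheticTruth(
        "coverage",
        {
            "n_chrom": n_chrom, "chrom_len": chrom_len, "bin_size": bin_size,
            "n_peaks": n_peaks, "peak_height_range": peak_height_range,
            "background_sd": background_sd,
            "motif_count_per_peak": motif_count,
        },
        {
            "peaks": GenomeIntervals(truth_records),
            "motif_counts": np.array(truth_counts),
        },
    )
    chip_track = CoverageTrack(bin_size, chip_vals)
    input_track = CoverageTrack(bin_size, input_vals)
    return chip_track, input_track, genome, truth


def gen_interphase_mitotic_pair(
    n_retained: int = 2,
    n_interphase_only: int = 1,
    n_mitosis_only: int = 1,
    bin_size: int = 50,
    width_bins: int = 6,
    height: float = 200.0,
    background_sd: float = 5.0,
    spacing_bins: int = 20,
    seed: int = 0,
) -> tuple[CoverageTrack, CoverageTrack, SyntheticTruth]:
    """Interphase + mitotic track pair with a designed peak classification.

    Retained sites appear in both tracks at the same position;
    interphase-only and mitosis-only sites appear in one track each.
    The truth payload records the designed category counts.
    """
    rng = _stream(seed, "coverage")
    n_sites = n_retained + n_interphase_only + n_mitosis_only
    n_bins = spacing_bins * (n_sites + 1) + width_bins * n_sites
    inter = np.abs(rng.normal(0.0, background_sd, size=n_bins))
    mito = np.abs(rng.normal(0.0, background_sd, size=n_bins))
    design: list[tuple[int, str]] = (
        [("retained", i) for i in range(n_retained)]
        + [("interphase_only", i) for i in range(n_interphase_only)]
        + [("mitosis_only", i) for i in range(n_mitosis_only)]
    )
    design = [d[0] for d in design]
    pos = spacing_bins
    placements = []
    for kind in design:
        sl = slice(pos, pos + width_bins)
        if kind in ("retained", "interphase_only"):
            inter[sl] = height + rng.normal(0, 2.0, width_bins)
        if kind in ("retained", "mitosis_only"):
            mito[sl] = height + rng.normal(0, 2.0, width_bins)
        placements.append((kind, pos * bin_size, (pos + width_bins) * bin_size))
        pos += width_bins + spacing_bins
    truth = SyntheticTruth(
        "coverage",
        {"n_retained": n_retained, "n_interphase_only": n_interphase_only,
         "n_mitosis_only": n_mitosis_only},
        {"placements": placements},
    )
    return (
        CoverageTrack(bin_size, {"chr1": inter}),
        CoverageTrack(bin_size, {"chr1": mito}),
        truth,
    )


# ---------------------------------------------------------------------------
# Image stacks


def gen_image_stack(
    shape: tuple[int, int, int] = (20, 64, 64),
    n_spots: int = 10,
    spot_sigma: float = 1.5,
    peak_intensity: float = 100.0,
    noise_sd: float = 2.0,
    voxel_xy: float = 0.1,
    voxel_z: float = 0.3,
    seed: int = 0,
    centers: np.ndarray | None = None,
) -> tuple[ImageStack, SyntheticTruth]:
    """3D Gaussian spots on Gaussian noise, clipped at zero.

    Spot centers are rejection-sampled with pairwise separation of at
    least 4 sigma (voxel units) and a 3-sigma border margin, or can be
    planted explicitly via ``centers`` (z, y, x voxel coordinates).
    """
    rng = _stream(seed, "stack")
    margin = 3.0 * spot_sigma
    if centers is None:
        pts: list[np.ndarray] = []
        for _ in range(20000):
            if len(pts) == n_spots:
                break
            cand = np.array(
                [rng.uniform(margin, s - 1 - margin) for s in shape]
            )
            if all(np.linalg.norm(cand - p) >= 4.0 * spot_sigma for p in pts):
                pts.append(cand)
        if len(pts) < n_spots:
            raise ValueError(
                f"could not pack {n_spots} spots of sigma {spot_sigma} "
                f"into shape {shape}"
            )
        centers = np.array(pts)
    else:
        centers = np.asarray(centers, dtype=float)
    data = np.zeros(shape)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    for cz, cy, cx in centers:
        r2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        data += peak_intensity * np.exp(-r2 / (2.0 * spot_sigma**2))
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=shape)
    data = np.clip(data, 0.0, None)
    truth = SyntheticTruth(
        "stack",
        {"shape": shape, "n_spots": len(centers), "spot_sigma": spot_sigma,
         "peak_intensity": peak_intensity, "noise_sd": noise_sd},
        {"centers": centers},
    )
    return ImageStack(data, voxel_xy=voxel_xy, voxel_z=voxel_z), truth


# ---------------------------------------------------------------------------
# Lineage tables

#: Study-like memory conditions: daughters of active mothers reactivate
#: with fewer effective OFF states and a shorter lifetime than daughters
#: of inactive mothers.
LINEAGE_DEFAULTS = {
    "p_act": (0.6, 0.3, 0.1),
    "tau_act": 70.0,
    "p_in": (0.2, 0.4, 0.4),
    "tau_in": 120.0,
    "T0": 60.0,
    "t_end": 2000.0,
}


def gen_lineage(
    n_active: int = 120,
    n_inactive: int = 80,
    p_act: tuple[float, ...] = LINEAGE_DEFAULTS["p_act"],
    tau_act: float = LINEAGE_DEFAULTS["tau_act"],
    p_in: tuple[float, ...] = LINEAGE_DEFAULTS["p_in"],
    tau_in: float = LINEAGE_DEFAULTS["tau_in"],
    T0: float = LINEAGE_DEFAULTS["T0"],
    t_end: float = LINEAGE_DEFAULTS["t_end"],
    seed: int = 0,
) -> tuple[list[ActivationRecord], SyntheticTruth]:
    """Activation table for two subpopulations split by mother state."""
    rng = _stream(seed, "lineage")
    rec_a = simulate_chain(
        np.asarray(p_act), tau_act, n_active, T0=T0, t_end=t_end,
        seed=rng, mother_state="active", movie_id="m_act",
    )
    rec_i = simulate_chain(
        np.asarray(p_in), tau_in, n_inactive, T0=T0, t_end=t_end,
        seed=rng, mother_state="inactive", movie_id="m_in",
    )
    truth = SyntheticTruth(
        "lineage",
        {"n_active": n_active, "n_inactive": n_inactive,
         "p_act": tuple(p_act), "tau_act": tau_act,
         "p_in": tuple(p_in), "tau_in": tau_in, "T0": T0, "t_end": t_end},
        {"a_act": sum((i + 1) * p for i, p in enumerate(p_act)),
         "a_in": sum((i + 1) * p for i, p in enumerate(p_in)),
         "b_act": tau_act, "b_in": tau_in},
    )
    return rec_a + rec_i, truth
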
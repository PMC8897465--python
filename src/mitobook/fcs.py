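"""Fluorescence correlation spectroscopy: ACF model, fitting, calibration.

The autocorrelation of intensity fluctuations in a 3D-Gaussian confocal
volume, for n freely diffusing species plus a triplet (dark-state)
correction, is

    G(t) = 1 + (1/N) (1 + T e^{-t/tau_T}/(1-T))
               * sum_i f_i / ((1 + t/tau_i) sqrt(1 + t/(s^2 tau_i)))
         + G_inf

where N is the mean number of molecules in the volume, T the triplet
fraction with lifetime tau_T (constrained below 10 us), f_i the species
fractions (sum 1), tau_i = w_xy^2 / 4 D_i the diffusion times, and
s = w_z / w_xy the structure parameter of the detection volume.  G_inf
absorbs long-time persistent correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .frap import FitError

__all__ = [
    "AcfCurve",
    "FcsFitResult",
    "VolumeCalibration",
    "acf_model",
    "fit_acf",
    "calibrate_volume",
    "diffusion_from_tau",
    "TRIPLET_TAU_MAX",
    "RHODAMINE_6G_D",
]

TRIPLET_TAU_MAX = 1e-5  # s; triplet lifetimes are sub-10-us
RHODAMINE_6G_D = 414.0  # um^2/s, calibration dye diffusion coefficient


@dataclass
class AcfCurve:
    lags: np.ndarray  # s, strictly increasing
    G: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.lags.shape != self.G.shape:
            raise ValueError("lags and G must have equal length")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")


@dataclass
class FcsFitResult:
    N: float  # mean molecules in the confocal volume
    T: float  # triplet fraction in [0, 1)
    tau_T: float  # triplet lifetime, s
    f: np.ndarray  # species fractions, sum 1
    tau_d: np.ndarray  # diffusion times, s, ascending
    s_param: float  # w_z / w_xy
    G_inf: float = 0.0
    sse: float = float("nan")

    def __post_init__(self) -> None:
        self.f = np.atleast_1d(np.asarray(self.f, dtype=float))
        self.tau_d = np.atleast_1d(np.asarray(self.tau_d, dtype=float))
        if self.f.shape != self.tau_d.shape:
            raise ValueError("f and tau_d must have the same length")
        order = np.argsort(self.tau_d)
        self.tau_d = self.tau_d[order]
        self.f = self.f[order]


@dataclass
class VolumeCalibration:
    """Confocal-volume geometry from a reference dye of known D."""

    D_cal: float
    tau_cal: float
    s_param: float
    w_xy: float = field(init=False)
    w_z: float = field(init=False)

    def __post_init__(self) -> None:
        if self.D_cal <= 0 or self.tau_cal <= 0 or self.s_param <= 0:
            raise ValueError("calibration inputs must be positive")
        self.w_xy = math.sqrt(4.0 * self.D_cal * self.tau_cal)
        self.w_z = self.s_param * self.w_xy


def acf_model(
    lags: np.ndarray,
    N: float,
    T: float,
    tau_T: float,
    f: np.ndarray,
    tau_d: np.ndarray,
    s_param: float,
    G_inf: float = 0.0,
) -> np.ndarray:
    """Evaluate the n-species + triplet autocorrelation at the given lags."""
    t = np.asarray(lags, dtype=float)
    if not 0 <= T < 1:
        raise ValueError("T must be in [0, 1)")
    f = np.atleast_1d(np.asarray(f, dtype=float))
    tau_d = np.atleast_1d(np.asarray(tau_d, dtype=float))
    if np.any(tau_d <= 0):
        raise ValueError("diffusion times must be positive")
    triplet = 1.0 + (T / (1.0 - T)) * np.exp(-t / tau_T) if T > 0 else 1.0
    diff = np.zeros_like(t)
    for fi, ti in zip(f, tau_d):
        diff += fi / ((1.0 + t / ti) * np.sqrt(1.0 + t / (s_param**2 * ti)))
    return 1.0 + (1.0 / N) * triplet * diff + G_inf


def fit_acf(
    curve: AcfCurve,
    n_species: int = 2,
    fix_s: float | None = 5.0,
    weights: str = "uniform",
    n_polish: int = 4,
) -> FcsFitResult:
    """Bounded least-squares fit of the ACF model to a measured curve.

    The triplet lifetime is constrained below 10 us; fractions sum to 1
    (for n = 2 parameterized by f1 in [0, 1]); diffusion times are
    log-parameterized and returned sorted ascending.  ``fix_s`` pins the
    structure parameter (the usual case: it comes from calibration);
    pass None to fit it.  Deterministic multi-start over diffusion-time
    placements; lowest SSE kept.
    """
    if n_species not in (1, 2):
        raise ValueError("n_species must be 1 or 2")
    t, g = curve.lags, curve.G
    if weights == "uniform":
        w = np.ones_like(g)
    elif weights == "inv_g2":
        w = 1.0 / g**2
    else:
        raise ValueError("weights must be 'uniform' or 'inv_g2'")

    amp = max(float(g[0] - 1.0 - min(0.0, g[-1] - 1.0)), 1e-6)
    N_init = 1.0 / amp
    lt_lo, lt_hi = math.log(t[0] * 0.1), math.log(t[-1] * 10.0)
    fit_s = fix_s is None

    # x = [log N, T, log tau_T, f1, log tau_1, (log tau_2), G_inf, (s)]
    def unpack(x: np.ndarray):
        i = 0
        N = math.exp(x[i]); i += 1
        T = x[i]; i += 1
        tau_T = math.exp(x[i]); i += 1
        if n_species == 2:
            f1 = x[i]; i += 1
            f = np.array([f1, 1.0 - f1])
            taus = np.exp(x[i : i + 2]); i += 2
        else:
            f = np.array([1.0])
            taus = np.exp(x[i : i + 1]); i += 1
        G_inf = x[i]; i += 1
        s = x[i] if fit_s else fix_s
        return N, T, tau_T, f, taus, s, G_inf

    def residuals(x: np.ndarray) -> np.ndarray:
        N, T, tau_T, f, taus, s, G_inf = unpack(x)
        return w * (acf_model(t, N, T, tau_T, f, taus, s, G_inf) - g)

    lo = [math.log(N_init) - 6, 0.0, math.log(1e-8)]
    hi = [math.log(N_init) + 6, 0.8, math.log(TRIPLET_TAU_MAX)]
    if n_species == 2:
        lo += [0.0]; hi += [1.0]
        lo += [lt_lo, lt_lo]; hi += [lt_hi, lt_hi]
    else:
        lo += [lt_lo]; hi += [lt_hi]
    lo += [-0.5]; hi += [0.5]
    if fit_s:
        lo += [1.0]; hi += [20.0]
    lo, hi = np.array(lo), np.array(hi)

    log_lo, log_hi = math.log(t[0]), math.log(t[-1])

    def quant(q: float) -> float:
        return log_lo + q * (log_hi - log_lo)

    starts = []
    if n_species == 2:
        for q1, q2 in ((0.2, 0.6), (0.3, 0.8), (0.1, 0.5), (0.4, 0.9)):
            for f1 in (0.3, 0.5, 0.7):
                x0 = [math.log(N_init), 0.1, math.log(3e-6), f1,
                      quant(q1), quant(q2), 0.0]
                if fit_s:
                    x0.append(5.0)
                starts.append(np.clip(x0, lo + 1e-9, hi - 1e-9))
    else:
        for q1 in (0.2, 0.4, 0.6):
            x0 = [math.log(N_init), 0.1, math.log(3e-6), quant(q1), 0.0]
            if fit_s:
                x0.append(5.0)
            starts.append(np.clip(x0, lo + 1e-9, hi - 1e-9))

    starts.sort(key=lambda x0: float(np.sum(residuals(x0) ** 2)))
    best = None
    for x0 in starts[:n_polish]:
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("ACF fit did not converge from any start")
    N, T, tau_T, f, taus, s, G_inf = unpack(best.x)
    return FcsFitResult(
        N=N, T=float(T), tau_T=tau_T, f=f, tau_d=taus, s_param=float(s),
        G_inf=float(G_inf), sse=float(np.sum((residuals(best.x) / w) ** 2)),
    )


def calibrate_volume(
    tau_cal: float, D_cal: float = RHODAMINE_6G_D, s_param: float = 5.0
) -> VolumeCalibration:
    """Derive w_xy (and w_z) from the fitted diffusion time of a calibrant."""
    return VolumeCalibration(D_cal=D_cal, tau_cal=tau_cal, s_param=s_param)


def diffusion_from_tau(tau_d: float, w_xy: float) -> float:
    """D = w_xy^2 / (4 tau_d), um^2/s."""
    if tau_d <= 0 or w_xy <= 0:
        raise ValueError("tau_d and w_xy must be positive")
    return w_xy**2 / (4.0 * tau_d)
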
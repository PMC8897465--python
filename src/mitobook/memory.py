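"""Postmitotic transcriptional-memory model.

The delay before a nucleus (re)activates transcription after mitosis is
T_a = T_0 + T_r: a deterministic lag T_0 common to all nuclei (set to
the first observed activation) plus a random time T_r modeled as the
first-passage time of a linear, irreversible continuous-time Markov
chain through up to three OFF states of common lifetime tau.  The
survival function of T_r is then a mixture of Gamma distributions,

    S(t) = p1 e^{-t/tau} + p2 (1 - gamma(2, t/tau)/GAMMA(2))
                         + p3 (1 - gamma(3, t/tau)/GAMMA(3)),

with p_k the probability of needing k jumps to reach ON (sum p_k = 1).
The summary statistics a = p1 + 2 p2 + 3 p3 (mean number of jumps) and
b = tau give mean delay E[T_r] = a*b; the number of chain states can
also be moment-estimated as N = M^2/V + 1 from the mean and variance
of the observed delays.  A *memory score* compares subpopulations whose
mothers were transcriptionally active vs inactive before mitosis: a
ratio (a*b)_inactive / (a*b)_active above 1 indicates memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.optimize import least_squares
from scipy.special import gammainc

from .frap import FitError

__all__ = [
    "ActivationRecord",
    "WaitingTimeSet",
    "SurvivalCurve",
    "MemoryFit",
    "extract_waiting_times",
    "kaplan_meier",
    "survival_model",
    "fit_survival",
    "estimate_states",
    "memory_score",
    "simulate_chain",
    "cumulative_activation",
    "cost_profile",
]


@dataclass(frozen=True)
class ActivationRecord:
    """One nucleus's postmitotic activation status in a movie."""

    nucleus_id: str
    movie_id: str
    mother_state: str  # "active" | "inactive" | "unknown"
    t_activation: float | None  # s from anaphase onset; None = censored
    t_end: float  # movie end, s

    def __post_init__(self) -> None:
        if self.mother_state not in {"active", "inactive", "unknown"}:
            raise ValueError(f"bad mother_state {self.mother_state!r}")
        if self.t_activation is not None and self.t_activation > self.t_end:
            raise ValueError("t_activation after movie end")

    @property
    def observed(self) -> bool:
        return self.t_activation is not None


@dataclass
class WaitingTimeSet:
    T0: float
    observed: np.ndarray  # T_r for activated nuclei, s
    censored: np.ndarray  # censoring times (t_end - T0) for never-active
    subpopulation: str = ""

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.censored = np.asarray(self.censored, dtype=float)
        if np.any(self.observed < 0) or np.any(self.censored < 0):
            raise ValueError("waiting times must be nonnegative")


@dataclass
class SurvivalCurve:
    times: np.ndarray  # step-function support, s
    S: np.ndarray  # survival estimate at each time
    n_at_risk: np.ndarray
    is_event: np.ndarray  # True where >=1 activation occurred at that time

    @property
    def event_times(self) -> np.ndarray:
        return self.times[self.is_event]

    @property
    def event_S(self) -> np.ndarray:
        return self.S[self.is_event]


@dataclass
class MemoryFit:
    p: np.ndarray  # (p1, p2, p3), sum 1
    tau: float  # common OFF-state lifetime, s
    O: float  # sum-of-squares cost at the optimum
    n_states: int = 4
    a: float = field(init=False)
    b: float = field(init=False)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        k = np.arange(1, len(self.p) + 1)
        self.a = float(np.sum(k * self.p))
        self.b = float(self.tau)

    @property
    def mean_delay(self) -> float:
        return self.a * self.b


# ---------------------------------------------------------------------------
# Waiting-time extraction and Kaplan-Meier


def extract_waiting_times(
    records: list[ActivationRecord], t0_mode: str = "pooled"
) -> dict[str, WaitingTimeSet]:
    """Split records by mother state and convert to T_r = T_a - T_0.

    T_0 is the earliest observed activation, pooled across movies by
    default, or per movie with ``t0_mode='per_movie'``.  Censored nuclei
    carry the censoring time t_end - T_0.
    """
    observed_any = [r for r in records if r.observed]
    if not observed_any:
        raise ValueError("no observed activation in records")
    if t0_mode == "pooled":
        t0_of = {r.movie_id: min(r.t_activation for r in observed_any)
                 for r in records}
    elif t0_mode == "per_movie":
        t0_of = {}
        for r in observed_any:
            t0_of[r.movie_id] = min(
                t0_of.get(r.movie_id, math.inf), r.t_activation
            )
    else:
        raise ValueError("t0_mode must be 'pooled' or 'per_movie'")

    out: dict[str, WaitingTimeSet] = {}
    for state in sorted({r.mother_state for r in records}):
        obs, cens = [], []
        for r in records:
            if r.mother_state != state:
                continue
            t0 = t0_of.get(r.movie_id)
            if t0 is None or math.isinf(t0):
                continue  # movie with no observed activation at all
            if r.observed:
                obs.append(max(r.t_activation - t0, 0.0))
            else:
                cens.append(max(r.t_end - t0, 0.0))
        out[state] = WaitingTimeSet(
            T0=min(t0_of.values()), observed=np.array(obs),
            censored=np.array(cens), subpopulation=state,
        )
    return out


def kaplan_meier(wts: WaitingTimeSet) -> SurvivalCurve:
    """Product-limit survival estimate of T_r with right censoring."""
    if wts.observed.size == 0:
        raise ValueError("need at least one observed event")
    durations = np.concatenate([wts.observed, wts.censored])
    events = np.concatenate(
        [np.ones_like(wts.observed), np.zeros_like(wts.censored)]
    ).astype(bool)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    S = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    table = kmf.event_table
    n_at_risk = table["at_risk"].reindex(times).to_numpy(dtype=float)
    n_events = table["observed"].reindex(times).fillna(0).to_numpy()
    return SurvivalCurve(
        times=times, S=S, n_at_risk=n_at_risk, is_event=n_events > 0
    )


# ---------------------------------------------------------------------------
# Mixed-Gamma survival model


def survival_model(
    t: np.ndarray, p: np.ndarray, tau: float
) -> np.ndarray:
    """Mixture-of-Gamma survival S(t) for the linear irreversible chain.

    Component k (k = 1..len(p)) is the survival of a Gamma(k, tau)
    first-passage time, expressed through the regularized lower
    incomplete gamma function.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("p must be nonnegative and sum to 1")
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    x = t / tau
    S = np.zeros_like(x)
    for k, pk in enumerate(p, start=1):
        S += pk * (1.0 - gammainc(k, x))
    return S


def fit_survival(
    curve: SurvivalCurve,
    n_components: int = 3,
    n_polish: int = 4,
) -> MemoryFit:
    """Least-squares fit of the mixed-Gamma survival to a Kaplan-Meier curve.

    Minimizes O = sum_j (S_exp(t_j) - S(t_j))^2 over the event times t_j,
    with p on the probability simplex (softmax reparameterization) and
    tau log-parameterized.  Deterministic multi-start; the fit with the
    lowest cost is returned.  n_components = n_states - 1.
    """
    tj = curve.event_times
    sj = curve.event_S
    if tj.size < 4:
        raise FitError(f"need >= 4 event times, got {tj.size}")
    mean_t = float(np.mean(tj))

    def unpack(x: np.ndarray):
        z = np.concatenate([[0.0], x[:-1]])
        e = np.exp(z - z.max())
        return e / e.sum(), math.exp(x[-1])

    def residuals(x: np.ndarray) -> np.ndarray:
        p, tau = unpack(x)
        return survival_model(tj, p, tau) - sj

    starts = []
    corner = 3.0
    p_inits = [np.zeros(n_components - 1)]
    for i in range(n_components):
        z = -corner * np.ones(n_components)
        z[i] = corner
        p_inits.append(z[1:] - z[0])
    for tau0 in (mean_t / 3.0, mean_t / 2.0, mean_t):
        for z0 in p_inits:
            starts.append(np.concatenate([z0, [math.log(tau0)]]))

    starts.sort(key=lambda x0: float(np.sum(residuals(x0) ** 2)))
    best = None
    for x0 in starts[:n_polish]:
        sol = least_squares(residuals, x0, method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    p, tau = unpack(best.x)
    return MemoryFit(
        p=p, tau=tau, O=float(np.sum(best.fun ** 2)),
        n_states=n_components + 1,
    )


def cost_profile(
    curve: SurvivalCurve,
    fit: MemoryFit,
    param: str,
    values: np.ndarray,
) -> np.ndarray:
    """One-at-a-time cost sweep around a fit (parameter-sensitivity aid).

    Varies ``param`` ('tau' or 'p1'/'p2'/'p3', renormalizing the other
    weights proportionally) and returns O at each value.
    """
    tj, sj = curve.event_times, curve.event_S
    out = np.empty(len(values))
    for i, v in enumerate(values):
        p, tau = fit.p.copy(), fit.tau
        if param == "tau":
            tau = float(v)
        elif param.startswith("p"):
            k = int(param[1:]) - 1
            rest = 1.0 - p[k]
            scale = (1.0 - v) / rest if rest > 0 else 0.0
            p = p * scale
            p[k] = v
        else:
            raise ValueError(f"unknown parameter {param!r}")
        out[i] = float(np.sum((survival_model(tj, p, tau) - sj) ** 2))
    return out


# ---------------------------------------------------------------------------
# Moment estimate of the number of chain states


def estimate_states(Tr: np.ndarray) -> tuple[float, float, int]:
    """Moment estimator of the chain size: a = M^2/V, N = a + 1.

    For a pure Gamma(k, tau) sample a converges to k, so N recovers the
    total number of states (k OFF states + ON).  A deterministic offset
    added to the delays inflates M without touching V and so biases a
    upward — the estimator assumes T_r is measured from T_0.
    """
    Tr = np.asarray(Tr, dtype=float)
    if Tr.size < 2:
        raise ValueError("need >= 2 observed waiting times")
    M = float(np.mean(Tr))
    V = float(np.var(Tr, ddof=1))
    if V == 0:
        raise ValueError("zero variance")
    a = M * M / V
    return a, a + 1.0, int(round(a + 1.0))


def memory_score(
    fit_from_inactive: MemoryFit, fit_from_active: MemoryFit
) -> tuple[float, float]:
    """Ratios (a*b)_inactive/(a*b)_active and b_inactive/b_active.

    Scores above 1 mean daughters of inactive mothers wait longer, i.e.
    a transcriptional-memory bias favoring active-mother daughters.
    """
    denom_ab = fit_from_active.a * fit_from_active.b
    if denom_ab == 0 or fit_from_active.b == 0:
        raise ZeroDivisionError("active-subpopulation fit has zero a*b or b")
    return (
        fit_from_inactive.a * fit_from_inactive.b / denom_ab,
        fit_from_inactive.b / fit_from_active.b,
    )


# ---------------------------------------------------------------------------
# Forward simulation of the chain


def simulate_chain(
    p: np.ndarray,
    tau: float,
    n: int,
    T0: float = 0.0,
    t_end: float = math.inf,
    seed: int | np.random.Generator = 0,
    mother_state: str = "unknown",
    movie_id: str = "sim",
) -> list[ActivationRecord]:
    """Draw n first-passage times of the linear irreversible chain.

    Each nucleus needs k jumps with probability p_k; T_r is the sum of k
    exponential lifetimes of mean tau (a Gamma(k, tau) draw); activation
    is at T0 + T_r, censored at t_end.
    """
    p = np.asarray(p, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ks = rng.choice(np.arange(1, len(p) + 1), size=n, p=p / p.sum())
    Tr = rng.gamma(shape=ks, scale=tau)
    records = []
    for i, t_act in enumerate(T0 + Tr):
        records.append(
            ActivationRecord(
                nucleus_id=f"{movie_id}_{i}",
                movie_id=movie_id,
                mother_state=mother_state,
                t_activation=float(t_act) if t_act <= t_end else None,
                t_end=float(t_end) if math.isfinite(t_end) else float(T0 + Tr.max()),
            )
        )
    return records


def cumulative_activation(
    records: list[ActivationRecord], t_grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fraction of eventually-active nuclei activated by time t, and t50.

    t50 is the earliest grid time at which the curve reaches 0.5 — the
    time for half of the (re)activating pattern to switch on.
    """
    acts = np.sort([r.t_activation for r in records if r.observed])
    if acts.size == 0:
        raise ValueError("no observed activations")
    if t_grid is None:
        t_grid = acts
    t_grid = np.asarray(t_grid, dtype=float)
    curve = np.searchsorted(acts, t_grid, side="right") / acts.size
    above = np.flatnonzero(curve >= 0.5)
    t50 = float(t_grid[above[0]]) if above.size else float("nan")
    return t_grid, curve, t50
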
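"""Dynamic mean-field (DMF) neural-mass core.

Each cortical region is reduced to one excitatory (NMDA) and one inhibitory
(GABA) population with input currents

    I_E = W_E*I0 + w_plus*J_NMDA*S_E + G*J_NMDA*sum_p C_np*S_E(p) - J_FIC*S_I
    I_I = W_I*I0 + J_NMDA*S_E - S_I

rates given by the sigmoidal F-I curve F(x) = x / (1 - exp(-d*x)) with
x = m*g*(I - I_thr) (the inhibitory modulator m is the per-region
neuromodulatory gain 1 + s_I*d_n built from the receptor map; the
excitatory population has m = 1), and gating dynamics

    dS_E/dt = -S_E/tau_NMDA + (1 - S_E)*gamma*r_E + sigma*nu(t)
    dS_I/dt = -S_I/tau_GABA + r_I            + sigma*nu(t)

integrated with Euler-Maruyama and gating clipped to [0, 1].  The
feedback inhibitory weight J_FIC is tuned per region so that the excitatory
population fires near 3 Hz at rest (feedback inhibition control): the
deterministic fixed point is solved analytically for an excellent initial
guess, then noise-driven simulation rounds verify the target and apply
greedy proportional corrections if needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .connectomes import Connectome
from .errors import AlignmentError, ConvergenceError, NumericalError, ValidationError
from .receptors import ReceptorMap

#: Default integration step (ms) and discarded burn-in (s).
DEFAULT_DT_MS = 0.1
DEFAULT_BURN_IN_S = 10.0
#: Default subsampling interval (ms) of the recorded excitatory rate.
DEFAULT_RECORD_DT_MS = 1.0
#: Feedback-inhibition-control target rate (Hz) and tolerance.
FIC_TARGET_RATE = 3.0
FIC_TOLERANCE = 0.5


@dataclass(frozen=True)
class DMFParameters:
    """Model constants (nA, Hz, ms) plus the free parameters G, s_I, J_FIC.

    Defaults are the standard parameterisation of the two-population
    mean-field reduction; G is the global coupling scaling long-range
    excitatory-to-excitatory interactions, s_I the inhibitory gain scaling
    applied through the receptor map, and J_FIC the per-region feedback
    inhibitory weight (nA) set by :func:`tune_fic`.
    """

    I0: float = 0.382          # external current, nA
    W_E: float = 1.0           # excitatory scaling of I0
    W_I: float = 0.7           # inhibitory scaling of I0
    w_plus: float = 1.4        # local excitatory recurrence
    J_NMDA: float = 0.15       # excitatory synaptic coupling, nA
    g_E: float = 310.0         # excitatory gain, nC^-1
    g_I: float = 615.0         # inhibitory gain, nC^-1
    I_thr_E: float = 0.403     # excitatory threshold, nA
    I_thr_I: float = 0.288     # inhibitory threshold, nA
    d_E: float = 0.16          # excitatory F-I shape, s
    d_I: float = 0.087         # inhibitory F-I shape, s
    gamma: float = 0.641       # excitatory kinetic parameter
    sigma: float = 0.01        # noise amplitude, nA
    tau_NMDA: float = 100.0    # ms
    tau_GABA: float = 10.0     # ms
    G: float = 1.0             # global coupling (free)
    s_I: float = 0.0           # inhibitory gain scaling (free, in [0, 1])
    J_FIC: np.ndarray | None = None  # per-region feedback inhibition, nA

    def __post_init__(self):
        if self.tau_NMDA <= 0 or self.tau_GABA <= 0:
            raise ValidationError("time constants must be positive")
        if self.sigma < 0:
            raise ValidationError("noise amplitude must be non-negative")
        if self.J_FIC is not None:
            j = np.asarray(self.J_FIC, dtype=float)
            if np.any(j < 0) or not np.all(np.isfinite(j)):
                raise ValidationError("J_FIC must be finite and non-negative")
            object.__setattr__(self, "J_FIC", j)

    def with_(self, **kwargs) -> "DMFParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GainVector:
    """Per-region multiplicative gain on the inhibitory F-I curve."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v <= 0):
            raise ValidationError("gains must be positive")
        object.__setattr__(self, "values", v)


@dataclass
class DMFState:
    """Synaptic gating (S_E, S_I) and the per-step derived quantities."""

    S_E: np.ndarray
    S_I: np.ndarray
    I_E: np.ndarray | None = None
    I_I: np.ndarray | None = None
    r_E: np.ndarray | None = None
    r_I: np.ndarray | None = None


@dataclass(frozen=True)
class NeuralTrace:
    """Excitatory firing rate over time, one row per region."""

    rates: np.ndarray          # (n_regions, n_samples), Hz
    dt_ms: float               # sampling interval of `rates`
    labels: tuple[str, ...]

    def __post_init__(self):
        if np.any(self.rates < 0):
            raise ValidationError("firing rates must be non-negative")

    @property
    def n_regions(self) -> int:
        return self.rates.shape[0]


def gain_vector(rmap: ReceptorMap | None, s_I: float, n_regions: int | None = None) -> GainVector:
    """Neuromodulatory inhibitory gain g_n = 1 + s_I * d_n.

    With ``rmap=None`` (or s_I = 0) every region has unit gain, recovering
    the unmodulated model.
    """
    if s_I < 0:
        raise ValidationError("s_I must be non-negative")
    if rmap is None:
        if n_regions is None:
            raise ValidationError("n_regions required when no receptor map is given")
        return GainVector(values=np.ones(n_regions))
    return GainVector(values=1.0 + s_I * rmap.normalised)


def transfer_rate(I, gain_factor: float, threshold: float, shape: float, modulator=1.0):
    """Population F-I curve F(x) = x / (1 - exp(-d*x)), x = m*g*(I - thr).

    The removable singularity at I = thr takes its two-sided limit 1/d
    (L'Hopital), evaluated through a first-order expansion for |d*x| small.
    Vectorised over ``I`` and ``modulator``.
    """
    I = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValidationError("non-finite input current")
    if shape <= 0 or gain_factor <= 0 or np.any(np.asarray(modulator) <= 0):
        raise ValidationError("gain, shape and modulator must be positive")
    x = np.asarray(modulator) * gain_factor * (I - threshold)
    dx = shape * x
    small = np.abs(dx) < 1e-8
    denom = -np.expm1(-np.where(small, 1.0, dx))  # 1 - exp(-d*x), guarded
    out = np.where(small, (1.0 + 0.5 * dx) / shape, x / denom)
    return out if out.ndim else float(out)


def rates_from_currents(I_E, I_I, p: DMFParameters, gain: GainVector):
    r_E = transfer_rate(I_E, p.g_E, p.I_thr_E, p.d_E, 1.0)
    r_I = transfer_rate(I_I, p.g_I, p.I_thr_I, p.d_I, gain.values)
    return r_E, r_I


def currents(state: DMFState, p: DMFParameters, c: Connectome):
    """Input currents I_E, I_I (nA) per region for the given gating state."""
    n = c.n_regions
    if len(state.S_E) != n or len(state.S_I) != n:
        raise AlignmentError("state and connectome have different region counts")
    J_fic = p.J_FIC if p.J_FIC is not None else np.zeros(n)
    if len(J_fic) != n:
        raise AlignmentError("J_FIC length does not match region count")
    I_E = (
        p.W_E * p.I0
        + p.w_plus * p.J_NMDA * state.S_E
        + p.G * p.J_NMDA * (c.weights @ state.S_E)
        - J_fic * state.S_I
    )
    I_I = p.W_I * p.I0 + p.J_NMDA * state.S_E - state.S_I
    return I_E, I_I


def step(
    state: DMFState,
    p: DMFParameters,
    c: Connectome,
    gain: GainVector,
    dt_ms: float,
    noise_draws: np.ndarray,
) -> DMFState:
    """One Euler-Maruyama update (reference NumPy implementation).

    ``noise_draws`` must be a ``(2, n)`` array of independent standard
    normals (excitatory row first). Gating is clipped to [0, 1] after the
    update. The compiled integrator in :func:`simulate` performs exactly
    this update.
    """
    if dt_ms <= 0:
        raise ValidationError("dt must be positive")
    noise_draws = np.asarray(noise_draws, dtype=float)
    if noise_draws.shape != (2, c.n_regions):
        raise ValidationError(f"noise_draws must have shape (2, {c.n_regions})")
    I_E, I_I = currents(state, p, c)
    r_E, r_I = rates_from_currents(I_E, I_I, p, gain)
    dt_s = dt_ms / 1000.0
    sq = p.sigma * math.sqrt(dt_s)
    tau_E = p.tau_NMDA / 1000.0
    tau_I = p.tau_GABA / 1000.0
    S_E = state.S_E + dt_s * (-state.S_E / tau_E + (1.0 - state.S_E) * p.gamma * r_E) + sq * noise_draws[0]
    S_I = state.S_I + dt_s * (-state.S_I / tau_I + r_I) + sq * noise_draws[1]
    if not (np.all(np.isfinite(S_E)) and np.all(np.isfinite(S_I))):
        raise NumericalError("non-finite gating after step", step=0)
    return DMFState(
        S_E=np.clip(S_E, 0.0, 1.0),
        S_I=np.clip(S_I, 0.0, 1.0),
        I_E=I_E,
        I_I=I_I,
        r_E=r_E,
        r_I=r_I,
    )


# ---------------------------------------------------------------------------
# Compiled integrator
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _fi(x: float, d: float) -> float:
    dx = d * x
    if abs(dx) < 1e-8:
        return (1.0 + 0.5 * dx) / d
    return x / (1.0 - math.exp(-dx))


@njit(cache=True, fastmath=True)
def _dmf_kernel(
    Ceff,            # (n, n) = G*J_NMDA*C
    J_fic,           # (n,)
    g_nm,            # (n,) inhibitory modulators
    wee,             # w_plus*J_NMDA
    WEI0,            # W_E*I0
    WII0,            # W_I*I0
    J,               # J_NMDA
    gE, gI, thrE, thrI, dE, dI, gamma, sigma,
    tauE, tauI,      # seconds
    dt,              # seconds
    n_steps, burn_steps, stride,
    seed,
    S_E, S_I,        # (n,) state, updated in place
    rec,             # (n, n_rec) output excitatory rates
):
    np.random.seed(seed)
    n = S_E.shape[0]
    sq = sigma * math.sqrt(dt)
    rE = np.empty(n)
    rI = np.empty(n)
    k = 0
    n_rec = rec.shape[1]
    for t in range(n_steps):
        for i in range(n):
            acc = 0.0
            for j in range(n):
                acc += Ceff[i, j] * S_E[j]
            IE = WEI0 + wee * S_E[i] + acc - J_fic[i] * S_I[i]
            II = WII0 + J * S_E[i] - S_I[i]
            rE[i] = _fi(gE * (IE - thrE), dE)
            rI[i] = _fi(g_nm[i] * gI * (II - thrI), dI)
        if t >= burn_steps and (t - burn_steps) % stride == 0 and k < n_rec:
            for i in range(n):
                rec[i, k] = rE[i]
            k += 1
        for i in range(n):
            se = S_E[i] + dt * (-S_E[i] / tauE + (1.0 - S_E[i]) * gamma * rE[i])
            si = S_I[i] + dt * (-S_I[i] / tauI + rI[i])
            if sigma > 0.0:
                se += sq * np.random.standard_normal()
                si += sq * np.random.standard_normal()
            if not (math.isfinite(se) and math.isfinite(si)):
                return t
            S_E[i] = min(max(se, 0.0), 1.0)
            S_I[i] = min(max(si, 0.0), 1.0)
    return -1


def _run_kernel(
    p: DMFParameters,
    c: Connectome,
    gain: GainVector,
    duration_s: float,
    dt_ms: float,
    burn_in_s: float,
    record_dt_ms: float,
    seed: int,
    state: DMFState | None,
):
    n = c.n_regions
    if gain.values.shape[0] != n:
        raise AlignmentError("gain vector length does not match connectome")
    J_fic = p.J_FIC if p.J_FIC is not None else np.zeros(n)
    if len(J_fic) != n:
        raise AlignmentError("J_FIC length does not match connectome")
    n_steps = int(round(duration_s * 1000.0 / dt_ms))
    burn_steps = int(round(burn_in_s * 1000.0 / dt_ms))
    if n_steps <= burn_steps:
        raise ValidationError("duration must exceed the burn-in")
    stride = max(int(round(record_dt_ms / dt_ms)), 1)
    if abs(stride * dt_ms - record_dt_ms) > 1e-9:
        raise ValidationError(
            f"record interval ({record_dt_ms} ms) must be an integer "
            f"multiple of dt ({dt_ms} ms)"
        )
    n_rec = (n_steps - burn_steps + stride - 1) // stride
    rec = np.empty((n, n_rec))
    if state is None:
        S_E = np.full(n, 0.001)
        S_I = np.full(n, 0.001)
    else:
        S_E = state.S_E.copy()
        S_I = state.S_I.copy()
    status = _dmf_kernel(
        np.ascontiguousarray(p.G * p.J_NMDA * c.weights),
        np.ascontiguousarray(J_fic, dtype=float),
        np.ascontiguousarray(gain.values),
        p.w_plus * p.J_NMDA,
        p.W_E * p.I0,
        p.W_I * p.I0,
        p.J_NMDA,
        p.g_E, p.g_I, p.I_thr_E, p.I_thr_I, p.d_E, p.d_I, p.gamma, p.sigma,
        p.tau_NMDA / 1000.0, p.tau_GABA / 1000.0,
        dt_ms / 1000.0,
        n_steps, burn_steps, stride,
        int(seed) % (2**32),
        S_E, S_I,
        rec,
    )
    if status >= 0:
        raise NumericalError(
            f"DMF integration blew up at step {status} "
            f"(t = {status * dt_ms / 1000.0:.3f} s)",
            step=int(status),
        )
    return rec, DMFState(S_E=S_E, S_I=S_I)


def simulate(
    p: DMFParameters,
    c: Connectome,
    gain: GainVector | None = None,
    duration_s: float = 60.0,
    dt_ms: float = DEFAULT_DT_MS,
    seed: int = 0,
    burn_in_s: float = DEFAULT_BURN_IN_S,
    record_dt_ms: float = DEFAULT_RECORD_DT_MS,
    initial_state: DMFState | None = None,
) -> NeuralTrace:
    """Simulate the coupled model and return the excitatory-rate trace.

    ``duration_s`` is the total simulated time including the discarded
    burn-in; the returned trace is subsampled every ``record_dt_ms``.
    Deterministic given ``seed``.
    """
    if gain is None:
        gain = gain_vector(None, 0.0, n_regions=c.n_regions)
    rec, _ = _run_kernel(
        p, c, gain, duration_s, dt_ms, burn_in_s, record_dt_ms, seed, initial_state
    )
    return NeuralTrace(rates=rec, dt_ms=record_dt_ms, labels=c.labels)


# ---------------------------------------------------------------------------
# Feedback inhibition control
# ---------------------------------------------------------------------------

class FICResult(NamedTuple):
    params: DMFParameters        # with tuned J_FIC
    rounds: int                  # noise-driven verification rounds used
    mean_rates: np.ndarray       # per-region mean rate at convergence, Hz
    history: list                # worst |rate - target| per round


def _deterministic_fic_init(
    p: DMFParameters, c: Connectome, gain: GainVector, target: float
) -> tuple[np.ndarray, DMFState]:
    """Solve the noise-free fixed point with every region at `target` Hz.

    Inverts the excitatory F-I curve for the current I_E* at the target
    rate, solves the per-region inhibitory self-consistency S_I =
    tau_I * F_I(W_I*I0 + J*S_E* - S_I), and reads J_FIC off the excitatory
    current balance.
    """
    tau_E = p.tau_NMDA / 1000.0
    tau_I = p.tau_GABA / 1000.0
    S_E_star = p.gamma * target * tau_E / (1.0 + p.gamma * target * tau_E)
    I_E_star = brentq(
        lambda I: transfer_rate(I, p.g_E, p.I_thr_E, p.d_E) - target,
        p.I_thr_E - 1.0,
        p.I_thr_E + 1.0,
        xtol=1e-12,
    )
    n = c.n_regions
    base_I_I = p.W_I * p.I0 + p.J_NMDA * S_E_star
    S_I_star = np.empty(n)
    for i in range(n):
        g = lambda s, m=gain.values[i]: (
            tau_I * transfer_rate(base_I_I - s, p.g_I, p.I_thr_I, p.d_I, m) - s
        )
        S_I_star[i] = brentq(g, 0.0, 1.0, xtol=1e-12)
    coupling = p.G * p.J_NMDA * (c.weights.sum(axis=1)) * S_E_star
    J = (p.W_E * p.I0 + p.w_plus * p.J_NMDA * S_E_star + coupling - I_E_star) / S_I_star
    J = np.maximum(J, 0.0)
    state = DMFState(S_E=np.full(n, S_E_star), S_I=S_I_star.copy())
    return J, state


def tune_fic(
    p: DMFParameters,
    c: Connectome,
    gain: GainVector | None = None,
    target_rate: float = FIC_TARGET_RATE,
    tolerance: float = FIC_TOLERANCE,
    eta: float = 0.01,
    max_rounds: int = 200,
    round_duration_s: float = 10.0,
    dt_ms: float = DEFAULT_DT_MS,
    seed: int = 0,
) -> FICResult:
    """Tune per-region J_FIC so excitatory populations fire near the target.

    Starts from the analytic deterministic fixed point, then runs
    noise-driven rounds of ``round_duration_s`` simulated seconds (2 s of
    each discarded as within-round burn-in, state carried across rounds);
    a round whose per-region time-averaged rates all fall within
    ``tolerance`` of the target terminates tuning, otherwise each J_FIC is
    nudged by ``eta * (rate - target) / target`` (floored at zero).
    Raises :class:`ConvergenceError` carrying the worst rate on failure.
    """
    if gain is None:
        gain = gain_vector(None, 0.0, n_regions=c.n_regions)
    J, state = _deterministic_fic_init(p, c, gain, target_rate)
    history: list[float] = []
    ss = np.random.SeedSequence(seed)
    round_burn_s = min(2.0, round_duration_s / 2.0)
    mean_rates = np.full(c.n_regions, np.nan)
    for rnd in range(max_rounds):
        trial = p.with_(J_FIC=J.copy())
        round_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        rec, state = _run_kernel(
            trial, c, gain,
            duration_s=round_duration_s, dt_ms=dt_ms,
            burn_in_s=round_burn_s, record_dt_ms=1.0,
            seed=round_seed, state=state,
        )
        mean_rates = rec.mean(axis=1)
        worst = float(np.abs(mean_rates - target_rate).max())
        history.append(worst)
        if worst <= tolerance:
            return FICResult(
                params=p.with_(J_FIC=J.copy()),
                rounds=rnd + 1,
                mean_rates=mean_rates,
                history=history,
            )
        J = np.maximum(J + eta * (mean_rates - target_rate) / target_rate, 0.0)
    worst_region = int(np.abs(mean_rates - target_rate).argmax())
    raise ConvergenceError(
        f"FIC tuning did not converge in {max_rounds} rounds; worst region "
        f"{worst_region} at {mean_rates[worst_region]:.2f} Hz "
        f"(target {target_rate} +/- {tolerance} Hz)"
    )


# ---------------------------------------------------------------------------
# NeuralTrace I/O: region x time TSV with header metadata lines.
# ---------------------------------------------------------------------------

def write_trace(trace: NeuralTrace, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"#dt_ms\t{trace.dt_ms}\n")
        if seed is not None:
            fh.write(f"#seed\t{seed}\n")
        fh.write("#labels\t" + "\t".join(trace.labels) + "\n")
        np.savetxt(fh, trace.rates.T, delimiter="\t", fmt="%.8g")


def read_trace(path) -> NeuralTrace:
    dt_ms = None
    labels: Sequence[str] | None = None
    with open(path) as fh:
        rows = []
        for ln in fh:
            if ln.startswith("#dt_ms"):
                dt_ms = float(ln.split("\t")[1])
            elif ln.startswith("#labels"):
                labels = ln.rstrip("\n").split("\t")[1:]
            elif ln.startswith("#"):
                continue
            elif ln.strip():
                rows.append([float(v) for v in ln.split()])
    rates = np.asarray(rows).T
    if dt_ms is None:
        raise ValidationError("trace file missing #dt_ms header")
    if labels is None:
        labels = [f"R{i:03d}" for i in range(rates.shape[0])]
    return NeuralTrace(rates=rates, dt_ms=dt_ms, labels=tuple(labels))
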
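"""Balloon-Windkessel haemodynamics: neural rate -> band-limited BOLD.

Each region's excitatory firing rate drives an independent haemodynamic
cascade (vasodilatory signal s, inflow f, venous volume v, deoxyhaemoglobin
q) in the canonical parameterisation:

    ds/dt    = z - kappa*s - gamma_h*(f - 1)
    df/dt    = s
    tau_h dv/dt = f - v**(1/alpha)
    tau_h dq/dt = f*(1 - (1 - rho)**(1/f))/rho - v**(1/alpha) * q/v
    BOLD     = V0*(k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v))

The neural drive is the firing rate normalised to its own baseline,
z = r_E/<r_E> - 1, so a silent or perfectly steady model sits exactly at
the resting fixed point (s, f, v, q) = (0, 1, 1, 1) and emits zero BOLD.
The simulated signal is sampled every TR and band-pass filtered to the
resting-state band (0.008-0.09 Hz) used for the empirical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import math

import numpy as np
from numba import njit
from scipy.signal import butter, filtfilt

from .dmf import NeuralTrace
from .errors import NumericalError, ValidationError

BANDPASS_LOW_HZ = 0.008
BANDPASS_HIGH_HZ = 0.09
DEFAULT_TR_S = 2.0


@dataclass(frozen=True)
class HemodynamicParameters:
    """Canonical Balloon-Windkessel constants (rate constants in s^-1)."""

    kappa: float = 0.65      # signal decay, s^-1
    gamma_h: float = 0.41    # flow-dependent elimination, s^-1
    tau_h: float = 0.98      # haemodynamic transit time, s
    alpha: float = 0.32      # Grubb's vessel stiffness exponent
    rho: float = 0.34        # resting oxygen extraction fraction
    V0: float = 0.02         # resting venous blood volume fraction

    @property
    def k1(self) -> float:
        return 7.0 * self.rho

    @property
    def k2(self) -> float:
        return 2.0

    @property
    def k3(self) -> float:
        return 2.0 * self.rho - 0.2


@dataclass(frozen=True)
class BOLDTimeseries:
    """Simulated (or pseudo-empirical) BOLD, one row per region."""

    signal: np.ndarray       # (n_regions, n_TRs), a.u.
    TR: float                # seconds
    labels: tuple[str, ...]

    def __post_init__(self):
        if self.TR <= 0:
            raise ValidationError("TR must be positive")
        if self.signal.ndim != 2 or self.signal.shape[1] < 2:
            raise ValidationError("signal must be region x TR with >= 2 TRs")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("non-finite BOLD signal")

    @property
    def n_regions(self) -> int:
        return self.signal.shape[0]

    @property
    def n_TRs(self) -> int:
        return self.signal.shape[1]


@njit(cache=True)
def _bw_kernel(z, dt, kappa, gamma_h, tau_h, inv_alpha, rho, V0, k1, k2, k3, stride, out):
    """Euler-integrate the Balloon-Windkessel system for one region.

    Inflow, volume and deoxyhaemoglobin are integrated in log space
    (lf = ln f etc.), the standard positivity-preserving change of
    variables for this system: f, v, q stay strictly positive even under
    sustained negative drive, without touching the model's vector field.
    """
    s = 0.0
    lf = 0.0
    lv = 0.0
    lq = 0.0
    n_steps = z.shape[0]
    k = 0
    n_out = out.shape[0]
    for t in range(n_steps):
        f = math.exp(lf)
        v = math.exp(lv)
        q = math.exp(lq)
        if t % stride == 0 and k < n_out:
            out[k] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
            k += 1
        fv = v ** inv_alpha
        E = 1.0 - (1.0 - rho) ** (1.0 / f)
        ds = z[t] - kappa * s - gamma_h * (f - 1.0)
        s += dt * ds
        lf += dt * s / f
        lv += dt * (f - fv) / (tau_h * v)
        lq += dt * (f * E / rho - fv * q / v) / (tau_h * q)
        # physiological saturation guard: inflow, volume and deoxyHb cannot
        # collapse to zero or grow without bound (e^3 ~ 20-fold range)
        lf = min(max(lf, -3.0), 3.0)
        lv = min(max(lv, -3.0), 3.0)
        lq = min(max(lq, -3.0), 3.0)
        if not (np.isfinite(s) and np.isfinite(lf) and np.isfinite(lv) and np.isfinite(lq)):
            return t
    return -1


def balloon_windkessel(
    trace: NeuralTrace,
    TR: float = DEFAULT_TR_S,
    hrf: HemodynamicParameters | None = None,
) -> BOLDTimeseries:
    """Turn a neural rate trace into BOLD sampled every ``TR`` seconds.

    The drive for each region is z = r/<r> - 1 with <r> the region's own
    time-mean rate (regions with a silent mean rate get z = 0), so the
    baseline model rests at the haemodynamic fixed point. Integration uses
    Euler steps at the trace's sampling interval.
    """
    hrf = hrf or HemodynamicParameters()
    dt_s = trace.dt_ms / 1000.0
    stride = int(round(TR / dt_s))
    if stride < 1 or abs(stride * dt_s - TR) > 1e-9:
        raise ValidationError(
            f"TR ({TR}s) must be an integer multiple of the trace sampling "
            f"interval ({dt_s}s)"
        )
    n, T = trace.rates.shape
    n_TRs = T // stride
    if n_TRs < 2:
        raise ValidationError("trace too short for 2 TRs of BOLD")
    baseline = trace.rates.mean(axis=1)
    signal = np.empty((n, n_TRs))
    for i in range(n):
        if baseline[i] > 1e-12:
            z = trace.rates[i] / baseline[i] - 1.0
        else:
            z = np.zeros(T)
        status = _bw_kernel(
            np.ascontiguousarray(z), dt_s,
            hrf.kappa, hrf.gamma_h, hrf.tau_h, 1.0 / hrf.alpha, hrf.rho,
            hrf.V0, hrf.k1, hrf.k2, hrf.k3, stride, signal[i],
        )
        if status >= 0:
            raise NumericalError(
                f"Balloon-Windkessel blow-up in region {i} at step {status}",
                step=int(status),
            )
    return BOLDTimeseries(signal=signal, TR=TR, labels=trace.labels)


def bandpass(
    b: BOLDTimeseries,
    low: float = BANDPASS_LOW_HZ,
    high: float = BANDPASS_HIGH_HZ,
) -> BOLDTimeseries:
    """Zero-phase order-2 Butterworth band-pass, then exact demeaning.

    The band must satisfy 0 < low < high < Nyquist(TR). Each region's
    filtered signal is demeaned so any residual filter edge offset is
    removed (|mean| << signal SD).
    """
    fs = 1.0 / b.TR
    nyq = fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ValidationError(
            f"band [{low}, {high}] Hz infeasible for TR={b.TR}s (Nyquist {nyq} Hz)"
        )
    sos_b, sos_a = butter(2, [low, high], btype="bandpass", fs=fs)
    filtered = filtfilt(sos_b, sos_a, b.signal, axis=1)
    filtered = filtered - filtered.mean(axis=1, keepdims=True)
    return BOLDTimeseries(signal=filtered, TR=b.TR, labels=b.labels)


# ---------------------------------------------------------------------------
# I/O: region x time TSV with a #TR header; the same dialect is used for
# pseudo-empirical fixtures.
# ---------------------------------------------------------------------------

def write_bold(b: BOLDTimeseries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#TR\t{b.TR}\n")
        fh.write("#labels\t" + "\t".join(b.labels) + "\n")
        np.savetxt(fh, b.signal.T, delimiter="\t", fmt="%.10g")


def read_bold(path) -> BOLDTimeseries:
    TR = None
    labels = None
    rows = []
    for ln in Path(path).read_text().splitlines():
        if ln.startswith("#TR"):
            TR = float(ln.split("\t")[1])
        elif ln.startswith("#labels"):
            labels = tuple(ln.split("\t")[1:])
        elif ln.startswith("#") or not ln.strip():
            continue
        else:
            rows.append([float(v) for v in ln.split()])
    if TR is None:
        raise ValidationError("BOLD file missing #TR header")
    signal = np.asarray(rows).T
    if labels is None:
        labels = tuple(f"R{i:03d}" for i in range(signal.shape[0]))
    return BOLDTimeseries(signal=signal, TR=TR, labels=labels)
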
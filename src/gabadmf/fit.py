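"""Model calibration sweeps, condition comparisons and connectome replacement.

The model's free parameters are fitted by grid search: for each candidate
value, seeded simulations are run through the full chain (mean-field
dynamics -> Balloon-Windkessel -> band-pass -> sliding-window FCD) and
scored by the KS distance between simulated and empirical FCD value
distributions; the optimum minimises the mean KS distance across
simulations.  The global coupling G (grid 0.1-2.5, step 0.1) is fitted
first with unit inhibitory gain; the inhibitory gain scaling s_I (grid
0-1, step 0.02) is then swept on the calibrated model with the feedback
inhibitory weights held fixed.  Connectome replacement swaps the structural
matrix of a calibrated model (keeping G and J_FIC) and re-evaluates the
relative fit to two empirical conditions; group differences in fit are
tested with permutation-based two-sample t-tests and standardised effect
sizes (Cohen's d, Hedges' g).
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, replace as dc_replace
from typing import NamedTuple, Sequence

import numpy as np

from . import bold as bold_mod
from . import dmf as dmf_mod
from .connectomes import Connectome, scale_for_simulation
from .dmf import DMFParameters, GainVector, gain_vector, tune_fic
from .errors import AlignmentError, NumericalError, ValidationError
from .fcd import FCDSample, fcd_matrix, fcd_sample, ks_distance
from .receptors import ReceptorMap

#: Grid defaults: G in 0.1..2.5 step 0.1; s_I in 0..1 step 0.02.
def default_G_grid() -> np.ndarray:
    return np.round(np.arange(1, 26) * 0.1, 10)


def default_sI_grid() -> np.ndarray:
    return np.round(np.arange(0, 51) * 0.02, 10)


#: A grid point must keep at least this fraction of its simulations to be
#: eligible as the sweep argmin.
MIN_SURVIVING_FRACTION = 0.8


@dataclass(frozen=True)
class SimulationConfig:
    """Resolved settings of one simulation-to-FCD pipeline run."""

    TR: float = 2.0               # s
    n_TRs: int = 250              # scan length matched to the empirical target
    dt_ms: float = 0.1            # integration step
    record_dt_ms: float = 1.0     # neural-trace subsampling fed to haemodynamics
    burn_in_s: float = 10.0       # discarded transient
    window: int = 30              # FCD window, TRs
    step: int = 3                 # FCD window increment, TRs
    exclude_overlap: bool = False
    scale_max: float = 0.2        # connectome rescaling (max entry)
    bandpass_low: float = 0.008   # Hz
    bandpass_high: float = 0.09   # Hz

    @property
    def duration_s(self) -> float:
        return self.n_TRs * self.TR + self.burn_in_s

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class CalibratedModel:
    """A connectome-bound model ready to simulate: parameters + gain + config."""

    params: DMFParameters         # includes G, s_I and tuned J_FIC
    connectome: Connectome        # already rescaled for simulation
    gain: GainVector
    config: SimulationConfig

    @property
    def labels(self) -> tuple[str, ...]:
        return self.connectome.labels

    def with_gain(self, rmap: ReceptorMap | None, s_I: float) -> "CalibratedModel":
        """Apply a receptor-map gain at a new s_I; J_FIC and G are kept."""
        return dc_replace(
            self,
            params=self.params.with_(s_I=s_I),
            gain=gain_vector(rmap, s_I, n_regions=self.connectome.n_regions),
        )

    def with_connectome(self, new_c: Connectome) -> "CalibratedModel":
        """Swap the structural matrix, holding G and J_FIC at calibrated values."""
        if new_c.labels != self.connectome.labels:
            raise AlignmentError("replacement connectome has a different region set")
        return dc_replace(
            self, connectome=scale_for_simulation(new_c, self.config.scale_max)
        )


def assemble_model(
    c: Connectome,
    rmap: ReceptorMap | None = None,
    G: float = 1.0,
    s_I: float = 0.0,
    config: SimulationConfig | None = None,
    seed: int = 0,
    J_FIC: np.ndarray | None = None,
    retune_fic: bool = False,
) -> CalibratedModel:
    """Scale the connectome, tune feedback inhibition, and bind everything.

    Feedback inhibition is tuned on the unmodulated model (unit inhibitory
    gain) and held fixed when a gain map is applied, mirroring a model
    calibrated on the conscious condition; pass ``retune_fic=True`` to tune
    under the modulated gain instead, or ``J_FIC`` to reuse a previous
    tuning.
    """
    config = config or SimulationConfig()
    cs = scale_for_simulation(c, config.scale_max)
    p = DMFParameters(G=G, s_I=s_I, J_FIC=J_FIC)
    if J_FIC is None:
        tune_gain = (
            gain_vector(rmap, s_I, n_regions=c.n_regions)
            if retune_fic
            else gain_vector(None, 0.0, n_regions=c.n_regions)
        )
        result = tune_fic(p, cs, tune_gain, dt_ms=config.dt_ms, seed=seed)
        p = result.params
    return CalibratedModel(
        params=p,
        connectome=cs,
        gain=gain_vector(rmap, s_I, n_regions=c.n_regions),
        config=config,
    )


# ---------------------------------------------------------------------------
# Simulation -> FCD sample
# ---------------------------------------------------------------------------

def simulate_bold(model: CalibratedModel, seed: int) -> bold_mod.BOLDTimeseries:
    """Run the full forward chain once and return band-passed BOLD."""
    cfg = model.config
    trace = dmf_mod.simulate(
        model.params,
        model.connectome,
        model.gain,
        duration_s=cfg.duration_s,
        dt_ms=cfg.dt_ms,
        seed=seed,
        burn_in_s=cfg.burn_in_s,
        record_dt_ms=cfg.record_dt_ms,
    )
    b = bold_mod.balloon_windkessel(trace, TR=cfg.TR)
    b = bold_mod.bandpass(b, cfg.bandpass_low, cfg.bandpass_high)
    if b.n_TRs > cfg.n_TRs:
        b = bold_mod.BOLDTimeseries(
            signal=b.signal[:, : cfg.n_TRs], TR=b.TR, labels=b.labels
        )
    return b

def simulate_fcd(model: CalibratedModel, seed: int) -> FCDSample:
    cfg = model.config
    b = simulate_bold(model, seed)
    try:
        m = fcd_matrix(b, window=cfg.window, step=cfg.step)
    except ValidationError as e:
        # a saturated/silent simulation with zero-variance windows is a
        # degenerate run, handled like a numerical failure by the sweeps
        raise NumericalError(f"degenerate simulated BOLD: {e}") from e
    return fcd_sample(m, exclude_overlap=cfg.exclude_overlap)


def simulate_fcd_samples(
    model: CalibratedModel, n_sims: int, seed: int
) -> list[FCDSample | None]:
    """Seeded batch of simulated FCD samples; failed runs are ``None``.

    Per-simulation seeds are spawned deterministically from ``seed``, so the
    i-th simulation is reproducible independent of batch size.
    """
    ss = np.random.SeedSequence(seed)
    out: list[FCDSample | None] = []
    for child in ss.spawn(n_sims):
        s = int(child.generate_state(1)[0] % (2**31))
        try:
            out.append(simulate_fcd(model, s))
        except NumericalError:
            out.append(None)
    return out


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepResult:
    """Grid-search outcome: KS distances per grid value and simulation."""

    grid: np.ndarray
    ks: np.ndarray               # (n_grid, n_sims), NaN = failed simulation
    argmin: float                # grid value minimising mean KS
    argmin_index: int
    n_failed: int = 0

    @property
    def mean_ks(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.ks, axis=1)

    @property
    def sd_ks(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanstd(self.ks, axis=1, ddof=1)

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "ks": [[None if math.isnan(v) else v for v in row] for row in self.ks],
            "mean_ks": [None if math.isnan(v) else v for v in self.mean_ks],
            "argmin": self.argmin,
            "argmin_index": self.argmin_index,
            "n_failed": self.n_failed,
        }


def score_sweep(
    grid: Sequence[float],
    samples_per_point: Sequence[Sequence[FCDSample | None]],
    empirical: FCDSample,
) -> SweepResult:
    """Score pre-computed per-grid-point FCD samples against an empirical target.

    The argmin is the grid value with the lowest mean KS distance among
    points retaining at least 80% of their simulations; ties break to the
    smallest parameter value. A grid point with every simulation failed
    raises :class:`NumericalError`.
    """
    grid = np.asarray(grid, dtype=float)
    n_sims = max(len(s) for s in samples_per_point)
    ks = np.full((len(grid), n_sims), np.nan)
    for gi, samples in enumerate(samples_per_point):
        ok = 0
        for si, s in enumerate(samples):
            if s is not None:
                ks[gi, si] = ks_distance(s, empirical)
                ok += 1
        if ok == 0:
            raise NumericalError(
                f"all simulations failed at grid value {grid[gi]}"
            )
    n_failed = int(np.isnan(ks).sum())
    with np.errstate(invalid="ignore"):
        mean_ks = np.nanmean(ks, axis=1)
    surviving = (~np.isnan(ks)).sum(axis=1) / np.array(
        [len(s) for s in samples_per_point]
    )
    eligible = surviving >= MIN_SURVIVING_FRACTION
    if not eligible.any():
        raise NumericalError("no grid point retained enough simulations")
    masked = np.where(eligible, mean_ks, np.inf)
    best = int(np.argmin(masked))  # np.argmin returns the first (smallest) tie
    return SweepResult(
        grid=grid, ks=ks, argmin=float(grid[best]), argmin_index=best,
        n_failed=n_failed,
    )


def sweep_G(
    c: Connectome,
    empirical: FCDSample,
    grid: Sequence[float] | None = None,
    n_sims: int = 100,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> SweepResult:
    """Fit the global coupling G against an empirical FCD sample.

    Feedback inhibition is re-tuned at every grid value (a stronger
    coupling needs stronger feedback inhibition to hold the 3 Hz firing
    target); the inhibitory gain is unmodulated during G calibration.
    """
    grid = default_G_grid() if grid is None else np.asarray(grid, float)
    if len(grid) == 0:
        raise ValidationError("empty G grid")
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    samples = []
    for child, G in zip(ss.spawn(len(grid)), grid):
        tune_seed, sims_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(2)
        )
        model = assemble_model(c, G=float(G), config=config, seed=tune_seed)
        samples.append(simulate_fcd_samples(model, n_sims, sims_seed))
    return score_sweep(grid, samples, empirical)


def sweep_sI(
    calibrated: CalibratedModel,
    rmap: ReceptorMap,
    empirical: FCDSample,
    grid: Sequence[float] | None = None,
    n_sims: int = 10,
    seed: int = 0,
) -> SweepResult:
    """Fit the inhibitory gain scaling s_I on a calibrated model.

    G and J_FIC stay at their calibrated values; each grid value applies
    the receptor-map gain 1 + s_I * d_n and scores simulations against the
    empirical FCD sample.
    """
    grid = default_sI_grid() if grid is None else np.asarray(grid, float)
    if len(grid) == 0:
        raise ValidationError("empty s_I grid")
    samples = sweep_sI_samples(calibrated, rmap, grid, n_sims, seed)
    return score_sweep(grid, samples, empirical)


def sweep_sI_samples(
    calibrated: CalibratedModel,
    rmap: ReceptorMap,
    grid: Sequence[float],
    n_sims: int,
    seed: int,
) -> list[list[FCDSample | None]]:
    """Per-grid-point simulated FCD samples for an s_I sweep.

    Exposed separately so one set of simulations can be scored against
    several empirical targets (the simulations do not depend on the target).
    """
    ss = np.random.SeedSequence(seed)
    out = []
    for child, s_I in zip(ss.spawn(len(grid)), np.asarray(grid, float)):
        sims_seed = int(child.generate_state(1)[0] % (2**31))
        model = calibrated.with_gain(rmap, float(s_I))
        out.append(simulate_fcd_samples(model, n_sims, sims_seed))
    return out


# ---------------------------------------------------------------------------
# Condition comparison and connectome replacement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    """Per-simulation fit (KS) of one model to two empirical conditions."""

    ks_A: np.ndarray
    ks_B: np.ndarray
    t_stat: float
    p_perm: float
    cohens_d: float
    hedges_g: float
    n_failed: int = 0

    @property
    def delta(self) -> np.ndarray:
        """Per-simulation ks_A - ks_B; negative means A fits better."""
        return self.ks_A - self.ks_B

    def to_dict(self) -> dict:
        return {
            "ks_A": self.ks_A.tolist(),
            "ks_B": self.ks_B.tolist(),
            "delta_mean": float(self.delta.mean()),
            "t_stat": self.t_stat,
            "p_perm": self.p_perm,
            "cohens_d": self.cohens_d,
            "hedges_g": self.hedges_g,
            "n_failed": self.n_failed,
        }


def evaluate_model(
    model: CalibratedModel,
    empirical_A: FCDSample,
    empirical_B: FCDSample,
    n_sims: int = 100,
    seed: int = 0,
) -> ComparisonResult:
    """Score one model against two empirical conditions, sim by sim.

    Each simulated FCD sample is compared (KS distance) with both empirical
    samples; the per-simulation difference delta = ks_A - ks_B measures
    relative fit, and the two KS distributions are compared with a
    permutation t-test and standardised effect sizes. Failed simulations
    are excluded pairwise and counted.
    """
    if len(empirical_A) == 0 or len(empirical_B) == 0:
        raise ValidationError("empirical samples must be non-empty")
    samples = simulate_fcd_samples(model, n_sims, seed)
    kept = [s for s in samples if s is not None]
    if not kept:
        raise NumericalError("all simulations failed")
    ks_A = np.array([ks_distance(s, empirical_A) for s in kept])
    ks_B = np.array([ks_distance(s, empirical_B) for s in kept])
    t, p = permutation_ttest(ks_A, ks_B, seed=_derived_seed(seed, "perm"))
    es = effect_sizes(
        ks_A.mean(), ks_A.std(ddof=1), len(ks_A),
        ks_B.mean(), ks_B.std(ddof=1), len(ks_B),
    )
    return ComparisonResult(
        ks_A=ks_A, ks_B=ks_B, t_stat=t, p_perm=p,
        cohens_d=es.cohens_d, hedges_g=es.hedges_g,
        n_failed=n_sims - len(kept),
    )


def connectome_replacement(
    calibrated: CalibratedModel,
    new_c: Connectome,
    empirical_A: FCDSample,
    empirical_B: FCDSample,
    n_sims: int = 100,
    seed: int = 0,
) -> ComparisonResult:
    """Swap the structural connectome of a calibrated model and re-evaluate.

    G and the tuned J_FIC are held at their calibrated values; only the
    inter-regional coupling matrix changes (rescaled by the same
    convention). The replacement must cover the same region set.
    """
    return evaluate_model(
        calibrated.with_connectome(new_c), empirical_A, empirical_B,
        n_sims=n_sims, seed=seed,
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _derived_seed(seed: int, tag: str) -> int:
    h = np.random.SeedSequence([seed, zlib.crc32(tag.encode()) % (2**31)])
    return int(h.generate_state(1)[0] % (2**31))


def _pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 <= 0:
        raise ValidationError("zero pooled variance")
    return float((x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny)))


def permutation_ttest(
    x: Sequence[float], y: Sequence[float], n_perm: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Permutation-based two-sample (pooled-variance) t-test, two-sided.

    Group labels are permuted ``n_perm`` times; the p-value uses the
    add-one estimator p = (1 + #{|t_perm| >= |t_obs|}) / (1 + n_perm), so it
    is never exactly zero.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("both groups need at least 2 observations")
    if np.allclose(x, x.mean()) and np.allclose(y, y.mean()) and np.isclose(x.mean(), y.mean()):
        return 0.0, 1.0
    t_obs = _pooled_t(x, y)
    pooled = np.concatenate([x, y])
    n = len(pooled)
    nx = len(x)
    rng = np.random.default_rng(seed)
    exceed = 0
    # vectorised permutations in manageable blocks
    block = 2000
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        perm = pooled[idx]
        px, py = perm[:, :nx], perm[:, nx:]
        vx = px.var(axis=1, ddof=1)
        vy = py.var(axis=1, ddof=1)
        sp2 = ((nx - 1) * vx + (n - nx - 1) * vy) / (n - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (px.mean(axis=1) - py.mean(axis=1)) / np.sqrt(
                sp2 * (1.0 / nx + 1.0 / (n - nx))
            )
        exceed += int(np.sum(np.abs(t) >= abs(t_obs) - 1e-12))
        done += b
    p = (1.0 + exceed) / (1.0 + n_perm)
    return t_obs, float(p)


class EffectSizes(NamedTuple):
    t: float
    cohens_d: float
    hedges_g: float


def effect_sizes(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> EffectSizes:
    """Pooled-variance t statistic, Cohen's d and Hedges' g from summaries.

    s_p = sqrt(((n1-1)sd1^2 + (n2-1)sd2^2) / (n1+n2-2)); t uses the
    standard error s_p*sqrt(1/n1 + 1/n2); d = (m1-m2)/s_p and g applies the
    small-sample correction 1 - 3/(4(n1+n2-2)-1).
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValidationError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    if sp == 0:
        raise ValidationError("zero pooled SD")
    t = (m1 - m2) / (sp * math.sqrt(1.0 / n1 + 1.0 / n2))
    d = (m1 - m2) / sp
    g = d * (1.0 - 3.0 / (4.0 * df - 1.0))
    return EffectSizes(t=t, cohens_d=d, hedges_g=g)


def save_result(result: SweepResult | ComparisonResult, path, extra: dict | None = None) -> None:
    payload = result.to_dict()
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
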
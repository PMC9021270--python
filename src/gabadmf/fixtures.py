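"""Synthetic fixtures emulating the statistical structure of the study inputs.

Real patient/volunteer diffusion and functional MRI cannot ship with the
package, so every pipeline stage is exercised on synthetic stand-ins:
distance-dependent connectomes on a sphere (so lattice-like and random
topologies are genuinely distinguishable), noisy per-subject cohorts with
edge dropout (exercising the strict-majority consensus rule), spatially
smooth receptor maps, and pseudo-empirical BOLD generated by the model
itself at known parameters.  The pseudo-empirical route is circular by
design: it validates the inference machinery (parameter recovery,
replacement contrasts), not any biological claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fit as fit_mod
from .bold import BOLDTimeseries
from .connectomes import CohortConnectomes, Connectome, validate_connectome
from .errors import ValidationError
from .receptors import ReceptorMap, normalise_map


@dataclass(frozen=True)
class FixtureSpec:
    """Generation settings for one synthetic dataset.

    Distances are in mm on a sphere of radius ``sphere_radius``;
    ``distance_decay`` is the exponential fall-off of edge weight per mm;
    ``subject_noise`` is the SD of multiplicative log-normal weight noise;
    ``dropout`` the per-subject probability of losing an edge;
    ``map_smoothness`` the Gaussian kernel width (mm) of the receptor field.
    """

    n_regions: int = 20
    edge_density: float = 0.3
    distance_decay: float = 0.03
    sphere_radius: float = 50.0
    layout: str = "sphere"       # "sphere" or "ring"
    cohort_size: int = 10
    subject_noise: float = 0.3
    dropout: float = 0.2
    map_smoothness: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 10:
            raise ValidationError("fixtures need at least 10 regions")
        if not (0.0 < self.edge_density <= 1.0):
            raise ValidationError("edge density must be in (0, 1]")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _sphere_points(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return radius * v


def _ring_points(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered equally spaced points on a circle, in angular order."""
    theta = 2.0 * np.pi * (np.arange(n) + rng.uniform(-0.2, 0.2, n)) / n
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)]
    )


def synth_connectome(spec: FixtureSpec) -> Connectome:
    """Distance-dependent connectome: w = exp(-decay*d) on a geometric layout.

    The ``edge_density`` fraction of closest region pairs is connected, so
    among connected pairs weight decreases strictly with distance — a
    geometry-dominated topology whose lattice and random rewirings differ
    sharply.  Layout ``"sphere"`` scatters regions on a sphere;
    ``"ring"`` places them on a circle with labels in angular order, so the
    label order used as the ring order by the lattice null coincides with
    the generating geometry.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    if spec.layout == "ring":
        coords = _ring_points(n, spec.sphere_radius, rng)
    elif spec.layout == "sphere":
        coords = _sphere_points(n, spec.sphere_radius, rng)
    else:
        raise ValidationError(f"unknown layout {spec.layout!r}")
    diff = coords[:, None, :] - coords[None, :, :]
    D = np.sqrt((diff**2).sum(-1))
    iu, ju = np.triu_indices(n, k=1)
    d = D[iu, ju]
    m = int(round(spec.edge_density * len(d)))
    if m < 1:
        raise ValidationError("edge density too low: no edges")
    keep = np.argsort(d, kind="stable")[:m]
    w = np.zeros((n, n))
    w[iu[keep], ju[keep]] = np.exp(-spec.distance_decay * d[keep])
    w = w + w.T
    labels = [f"R{i:03d}" for i in range(n)]
    return validate_connectome(w, labels, coordinates=coords)


def synth_cohort(spec: FixtureSpec, base: Connectome) -> CohortConnectomes:
    """Per-subject variants of a base connectome: log-normal weight noise
    plus independent symmetric edge dropout at the spec probability."""
    ss = np.random.SeedSequence([spec.seed, 1])
    children = ss.spawn(spec.cohort_size)
    iu, ju = np.triu_indices(base.n_regions, k=1)
    wbase = base.weights[iu, ju]
    subjects = []
    seeds = []
    for child in children:
        s = int(child.generate_state(1)[0] % (2**31))
        seeds.append(s)
        rng = np.random.default_rng(s)
        w = wbase * np.exp(rng.normal(0.0, spec.subject_noise, size=wbase.shape))
        w[rng.random(wbase.shape) < spec.dropout] = 0.0
        mat = np.zeros_like(base.weights)
        mat[iu, ju] = w
        mat = mat + mat.T
        subjects.append(
            validate_connectome(mat, base.labels, coordinates=base.coordinates)
        )
    return CohortConnectomes(
        subjects=tuple(subjects), metadata={"subject_seeds": seeds}
    )


def synth_receptor_map(spec: FixtureSpec, coordinates: np.ndarray) -> ReceptorMap:
    """Spatially smooth positive receptor field over the fixture regions.

    Gaussian-kernel-smoothed white noise (kernel width ``map_smoothness``),
    shifted positive as raw tracer-binding-like values, then passed through
    the standard z-score + min-max normalisation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    coordinates = np.asarray(coordinates, dtype=float)
    n = coordinates.shape[0]
    diff = coordinates[:, None, :] - coordinates[None, :, :]
    D = np.sqrt((diff**2).sum(-1))
    kernel = np.exp(-(D**2) / (2.0 * spec.map_smoothness**2))
    f = kernel @ rng.standard_normal(n)
    raw = f - f.min() + 1.0  # positive, arbitrary binding units
    labels = [f"R{i:03d}" for i in range(n)]
    return normalise_map(raw, labels)


def synth_empirical_bold(
    c: Connectome,
    rmap: ReceptorMap | None,
    G_true: float,
    sI_true: float,
    n_subjects: int,
    TRs: int,
    seed: int,
    config: fit_mod.SimulationConfig | None = None,
    J_FIC: np.ndarray | None = None,
) -> list[BOLDTimeseries]:
    """Pseudo-empirical BOLD: the full forward chain at known parameters.

    One band-passed scan of ``TRs`` volumes per subject, each with its own
    derived seed. Feedback inhibition is tuned once on the unmodulated
    model at ``G_true`` (or reused via ``J_FIC``) and held fixed while the
    gain map at ``sI_true`` is applied — the same convention the fitting
    machinery uses, so recovery experiments are exactly self-consistent.
    """
    config = config or fit_mod.SimulationConfig()
    config = fit_mod.SimulationConfig(**{**config.to_dict(), "n_TRs": TRs})
    ss = np.random.SeedSequence([seed, 3])
    tune_seed = int(ss.generate_state(1)[0] % (2**31))
    model = fit_mod.assemble_model(
        c, rmap=rmap, G=G_true, s_I=sI_true, config=config,
        seed=tune_seed, J_FIC=J_FIC,
    )
    scans = []
    for child in ss.spawn(n_subjects):
        s = int(child.generate_state(1)[0] % (2**31))
        scans.append(fit_mod.simulate_bold(model, s))
    return scans
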
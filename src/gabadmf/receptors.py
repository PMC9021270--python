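"""Receptor-density maps and their controls.

The per-region GABA-A receptor density d_n (benzodiazepine-site binding
from flumazenil PET, parcellated) drives regional inhibitory gain in the
mean-field model.  Raw densities are z-scored and min–max rescaled to
[0, 1].  Two control maps probe the role of the spatial pattern: a uniform
map (every region set to the mean density) and an autocorrelation-
preserving shuffle (a variogram-matched surrogate whose values are the
original multiset re-assigned to regions).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import AlignmentError, DegenerateInputError, ValidationError

#: Number of distance bins for the empirical variogram.
VARIOGRAM_BINS = 25

#: Default number of smoothed-noise candidates scored per surrogate call.
DEFAULT_SURROGATE_CANDIDATES = 100


@dataclass(frozen=True)
class ReceptorMap:
    """Per-region receptor density, raw and normalised to [0, 1]."""

    labels: tuple[str, ...]
    raw: np.ndarray
    normalised: np.ndarray

    def __post_init__(self):
        if not (len(self.labels) == len(self.raw) == len(self.normalised)):
            raise ValidationError("labels, raw and normalised must be length-matched")
        if np.any(self.normalised < -1e-12) or np.any(self.normalised > 1 + 1e-12):
            raise ValidationError("normalised densities must lie in [0, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.labels)


def normalise_map(raw_densities: Sequence[float], labels: Sequence[str]) -> ReceptorMap:
    """Z-score (population SD) then min–max rescale densities to [0, 1].

    The z-scoring step is order-preserving and the subsequent min–max
    rescale maps the extremes to exactly 0 and 1; a constant map leaves the
    z-score undefined and raises :class:`DegenerateInputError`.
    """
    raw = np.asarray(raw_densities, dtype=float)
    labels = tuple(str(l) for l in labels)
    if raw.ndim != 1 or len(raw) != len(labels):
        raise ValidationError("densities must be a 1-D array matching labels")
    if len(raw) < 2:
        raise ValidationError("need at least 2 regions")
    if not np.all(np.isfinite(raw)):
        raise ValidationError("non-finite density values")
    sd = raw.std()  # population SD
    if sd == 0:
        raise DegenerateInputError("constant receptor map: z-score undefined")
    z = (raw - raw.mean()) / sd
    norm = (z - z.min()) / (z.max() - z.min())
    return ReceptorMap(labels=labels, raw=raw.copy(), normalised=norm)


def uniform_map(rmap: ReceptorMap) -> ReceptorMap:
    """Replace every region's density by the mean of the distribution.

    The effective (normalised) density becomes spatially flat while its
    mean is conserved, isolating the role of overall inhibition level from
    its regional pattern.
    """
    n = rmap.n_regions
    return ReceptorMap(
        labels=rmap.labels,
        raw=np.full(n, rmap.raw.mean()),
        normalised=np.full(n, rmap.normalised.mean()),
    )


def variogram(values: np.ndarray, distances: np.ndarray, n_bins: int = VARIOGRAM_BINS) -> np.ndarray:
    """Distance-binned empirical semivariance of a regional map.

    Returns one semivariance per bin (NaN for empty bins); bins partition
    [0, max distance] uniformly.
    """
    iu, ju = np.triu_indices(len(values), k=1)
    d = distances[iu, ju]
    sq = 0.5 * (values[iu] - values[ju]) ** 2
    edges = np.linspace(0.0, d.max() * (1 + 1e-12), n_bins + 1)
    which = np.digitize(d, edges) - 1
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            out[b] = sq[sel].mean()
    return out


def _variogram_mad(v1: np.ndarray, v2: np.ndarray) -> float:
    ok = np.isfinite(v1) & np.isfinite(v2)
    return float(np.abs(v1[ok] - v2[ok]).mean())


def shuffle_preserving_autocorrelation(
    rmap: ReceptorMap,
    coordinates: np.ndarray,
    n_candidates: int = DEFAULT_SURROGATE_CANDIDATES,
    seed: int = 0,
    n_bins: int = VARIOGRAM_BINS,
) -> ReceptorMap:
    """Shuffle densities across regions, preserving spatial autocorrelation.

    Variogram-matching surrogate: candidate fields are spatially smoothed
    Gaussian noise (kernel widths spanning the observed distance range);
    each candidate is rank-remapped onto the original value multiset and
    scored by the mean absolute deviation between its distance-binned
    semivariance and that of the input map; the best candidate is returned.
    The output is therefore a permutation of the input values (multiset
    preserved exactly) whose variogram approximates the input's.
    """
    n = rmap.n_regions
    if n < 10:
        raise ValidationError(f"need at least 10 regions for a surrogate, got {n}")
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (n, 3):
        raise AlignmentError(
            f"coordinates must be ({n}, 3) matching the map, got {coordinates.shape}"
        )
    diff = coordinates[:, None, :] - coordinates[None, :, :]
    D = np.sqrt((diff**2).sum(-1))
    target = variogram(rmap.normalised, D, n_bins)

    pos = D[np.triu_indices(n, k=1)]
    widths = np.geomspace(
        max(np.percentile(pos, 5), 1e-6), max(pos.max() / 2.0, 1e-6), num=8
    )
    rng = np.random.default_rng(seed)
    order_norm = np.argsort(rmap.normalised, kind="stable")
    order_raw = np.argsort(rmap.raw, kind="stable")
    sorted_norm = rmap.normalised[order_norm]
    sorted_raw = rmap.raw[order_raw]

    best_score = np.inf
    best_norm = best_raw = None
    for k in range(n_candidates):
        w = widths[k % len(widths)]
        kernel = np.exp(-(D**2) / (2.0 * w**2))
        field = kernel @ rng.standard_normal(n)
        ranks = np.argsort(np.argsort(field, kind="stable"), kind="stable")
        cand = sorted_norm[ranks]
        score = _variogram_mad(variogram(cand, D, n_bins), target)
        if score < best_score:
            best_score = score
            best_norm = cand
            best_raw = sorted_raw[ranks]
    return ReceptorMap(labels=rmap.labels, raw=best_raw, normalised=best_norm)


# ---------------------------------------------------------------------------
# I/O: two-column TSV (label, value); coordinates handled by connectomes.py.
# ---------------------------------------------------------------------------

def read_map(path: str | Path, *, normalise: bool = True) -> ReceptorMap:
    """Read a two-column (label, density) file; normalises by default."""
    labels, values = [], []
    for ln in Path(path).read_text().splitlines():
        parts = ln.split()
        if not parts or parts[0].startswith("#"):
            continue
        labels.append(parts[0])
        values.append(float(parts[1]))
    if normalise:
        return normalise_map(values, labels)
    values = np.asarray(values, dtype=float)
    return ReceptorMap(labels=tuple(labels), raw=values, normalised=values)


def write_map(rmap: ReceptorMap, path: str | Path, *, which: str = "normalised") -> None:
    values = getattr(rmap, which)
    with open(path, "w") as fh:
        for lab, v in zip(rmap.labels, values):
            fh.write(f"{lab}\t{v:.12g}\n")
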
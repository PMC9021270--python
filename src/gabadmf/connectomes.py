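"""Structural connectomes: validation, group consensus, and topological nulls.

The connectome is the region-by-region matrix of white-matter coupling
strengths C_np that weights the long-range excitatory-to-excitatory
interactions of the mean-field model.  This module builds the group
consensus matrix from a cohort of single-subject matrices (strict-majority
edge retention, mean over non-zero subjects), and produces the two
topological null models used in connectome-replacement experiments: a
degree- and weight-distribution-preserving randomisation (Maslov–Sneppen
double edge swaps) and a ring-lattice rewiring (swaps accepted only when
they shorten total edge placement on a ring, latmio-style).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import AlignmentError, ValidationError

#: Default number of accepted/attempted swaps per edge for the null models.
DEFAULT_SWAPS_PER_EDGE = 10

#: Before simulation, weights are rescaled so the maximum entry equals this
#: value (a common mean-field convention; the global coupling G absorbs the
#: overall scale, which tractography leaves in arbitrary units).
DEFAULT_SCALE_MAX = 0.2


@dataclass(frozen=True)
class Connectome:
    """A symmetric, non-negative, zero-diagonal coupling matrix.

    Attributes
    ----------
    weights
        ``(n, n)`` float array of tract strengths (arbitrary units).
    labels
        Unique region identifiers, one per row/column.
    coordinates
        Optional ``(n, 3)`` region centroids in mm.
    """

    weights: np.ndarray
    labels: tuple[str, ...]
    coordinates: np.ndarray | None = None

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def edge_list(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (i, j, w) for the upper-triangle non-zero edges."""
        iu, ju = np.triu_indices(self.n_regions, k=1)
        w = self.weights[iu, ju]
        nz = w > 0
        return iu[nz], ju[nz], w[nz]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def degrees(self) -> np.ndarray:
        """Binary degree of each region."""
        return (self.weights > 0).sum(axis=0)


@dataclass(frozen=True)
class CohortConnectomes:
    """A cohort of per-subject connectomes sharing one label order."""

    subjects: tuple[Connectome, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.subjects) == 0:
            raise ValidationError("cohort must contain at least one subject")
        labels = self.subjects[0].labels
        for k, s in enumerate(self.subjects):
            if s.labels != labels:
                raise AlignmentError(
                    f"subject {k} labels do not match subject 0 labels"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return self.subjects[0].labels


def validate_connectome(
    weights: np.ndarray,
    labels: Sequence[str],
    coordinates: np.ndarray | None = None,
    *,
    symmetry_tol: float = 1e-9,
    diagonal_tol: float = 1e-12,
) -> Connectome:
    """Check the structural invariants and return a typed :class:`Connectome`.

    The matrix must be square, finite, non-negative and symmetric (within
    ``symmetry_tol``); the diagonal is zeroed only if already below
    ``diagonal_tol`` in magnitude. Violations raise :class:`ValidationError`
    naming the offending indices — asymmetry is never silently averaged away.
    """
    w = np.array(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError(f"weights must be square, got shape {w.shape}")
    labels = tuple(str(l) for l in labels)
    if len(labels) != w.shape[0]:
        raise ValidationError(
            f"{len(labels)} labels for a {w.shape[0]}-region matrix"
        )
    if len(set(labels)) != len(labels):
        raise ValidationError("region labels must be unique")
    bad = ~np.isfinite(w)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(f"non-finite weight at ({i}, {j})")
    neg = w < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValidationError(f"negative weight {w[i, j]} at ({i}, {j})")
    asym = np.abs(w - w.T)
    if asym.max() > symmetry_tol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValidationError(
            f"asymmetric weights at ({i}, {j}): {w[i, j]} vs {w[j, i]}"
        )
    w = 0.5 * (w + w.T)  # remove sub-tolerance asymmetry exactly
    d = np.abs(np.diag(w))
    if d.max() > diagonal_tol:
        i = int(np.argmax(d))
        raise ValidationError(f"non-zero diagonal {w[i, i]} at region {i}")
    np.fill_diagonal(w, 0.0)
    if coordinates is not None:
        coordinates = np.array(coordinates, dtype=float)
        if coordinates.shape != (w.shape[0], 3):
            raise ValidationError(
                f"coordinates must be ({w.shape[0]}, 3), got {coordinates.shape}"
            )
    return Connectome(weights=w, labels=labels, coordinates=coordinates)


def consensus_connectome(cohort: CohortConnectomes) -> Connectome:
    """Group-consensus matrix: strict-majority retention, mean of non-zeros.

    For each region pair, if strictly more than half of the subjects have a
    non-zero connection there, the consensus weight is the mean over the
    subjects with non-zero weight; otherwise it is zero. Ties at exactly
    half are dropped.
    """
    stack = np.stack([s.weights for s in cohort.subjects])
    nz = stack > 0
    count = nz.sum(axis=0)
    keep = count > len(cohort.subjects) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_nz = np.where(count > 0, stack.sum(axis=0) / np.maximum(count, 1), 0.0)
    out = np.where(keep, mean_nz, 0.0)
    np.fill_diagonal(out, 0.0)
    return validate_connectome(
        out, cohort.labels, coordinates=cohort.subjects[0].coordinates
    )


def _swap_topology(
    c: Connectome,
    n_swaps_per_edge: int,
    seed: int,
    *,
    lattice: bool,
) -> Connectome:
    """Shared double-edge-swap machinery for both null models.

    Topology is rewired by repeated swaps (a-b, c-d) -> (a-d, c-b), which
    preserve the binary degree sequence exactly. For the random null every
    feasible swap is accepted; for the lattice null a swap is accepted only
    if it strictly reduces the total ring distance of edge placements
    (regions on a ring in label order). The original weight multiset is then
    randomly reassigned to the rewired edge slots.
    """
    ii, jj, ww = c.edge_list()
    m = len(ww)
    n = c.n_regions
    if m < 4 or n < 4:
        raise ValidationError(
            f"need at least 4 edges and 4 regions to rewire, got {m} edges "
            f"on {n} regions"
        )
    rng = np.random.default_rng(seed)
    adj = c.weights > 0
    edges = np.stack([ii, jj], axis=1)  # each row i<j

    def ring_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        d = np.abs(a - b)
        return np.minimum(d, n - d)

    target_accepts = n_swaps_per_edge * m
    max_attempts = 50 * target_accepts
    accepts = 0
    attempts = 0
    while accepts < target_accepts and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        cc, dd = edges[e2]
        if rng.random() < 0.5:
            cc, dd = dd, cc
        if len({a, b, cc, dd}) < 4:
            continue
        # proposed edges a-dd and cc-b
        if adj[a, dd] or adj[cc, b]:
            continue
        if lattice:
            old = ring_dist(np.array([a, cc]), np.array([b, dd])).sum()
            new = ring_dist(np.array([a, cc]), np.array([dd, b])).sum()
            if new >= old:
                continue
        adj[a, b] = adj[b, a] = False
        adj[cc, dd] = adj[dd, cc] = False
        adj[a, dd] = adj[dd, a] = True
        adj[cc, b] = adj[b, cc] = True
        edges[e1] = sorted((a, dd))
        edges[e2] = sorted((cc, b))
        accepts += 1

    out = np.zeros_like(c.weights)
    perm = rng.permutation(m)
    out[edges[:, 0], edges[:, 1]] = ww[perm]
    out = out + out.T
    return validate_connectome(out, c.labels, coordinates=c.coordinates)


def randomise_weight_preserving(
    c: Connectome, n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE, seed: int = 0
) -> Connectome:
    """Degree-sequence- and weight-distribution-preserving randomisation.

    Maslov–Sneppen double edge swaps rewire the topology, then the original
    non-zero weight multiset is randomly reassigned to the new edges, so
    edge count, total weight and average connectivity are conserved exactly.
    Deterministic given ``seed``.
    """
    return _swap_topology(c, n_swaps_per_edge, seed, lattice=False)


def latticise(
    c: Connectome, n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE, seed: int = 0
) -> Connectome:
    """Rewire toward a ring lattice with the same weight distribution.

    Same swap machinery as :func:`randomise_weight_preserving`, but a swap is
    accepted only when it strictly reduces the summed ring distance of edge
    placements, with regions ordered on the ring by label order. The result
    is a regular, lattice-like topology with identical degree sequence and
    weight multiset.
    """
    return _swap_topology(c, n_swaps_per_edge, seed, lattice=True)


def total_ring_distance(c: Connectome) -> int:
    """Sum over edges of the ring distance between their endpoints."""
    ii, jj, _ = c.edge_list()
    d = np.abs(ii - jj)
    n = c.n_regions
    return int(np.minimum(d, n - d).sum())


def scale_for_simulation(
    c: Connectome, max_weight: float = DEFAULT_SCALE_MAX
) -> Connectome:
    """Rescale weights so the maximum entry equals ``max_weight``.

    Tractography leaves C_np in arbitrary units and the global coupling G
    absorbs any overall scale, so a fixed normalisation keeps G sweeps
    comparable across connectomes.
    """
    top = c.weights.max()
    if top <= 0:
        raise ValidationError("cannot scale an all-zero connectome")
    return Connectome(
        weights=c.weights * (max_weight / top),
        labels=c.labels,
        coordinates=c.coordinates,
    )


# ---------------------------------------------------------------------------
# I/O: whitespace-delimited square matrix + sidecar label list (one label per
# line) + optional 4-column coordinates file (label, x, y, z).
# ---------------------------------------------------------------------------

def read_connectome(
    matrix_path: str | Path,
    labels_path: str | Path | None = None,
    coordinates_path: str | Path | None = None,
) -> Connectome:
    w = np.loadtxt(matrix_path, ndmin=2)
    if labels_path is not None:
        labels = [ln.strip() for ln in Path(labels_path).read_text().splitlines() if ln.strip()]
    else:
        labels = [f"R{i:03d}" for i in range(w.shape[0])]
    coords = None
    if coordinates_path is not None:
        coords = read_coordinates(coordinates_path, labels)
    return validate_connectome(w, labels, coordinates=coords)


def write_connectome(
    c: Connectome,
    matrix_path: str | Path,
    labels_path: str | Path | None = None,
    coordinates_path: str | Path | None = None,
) -> None:
    np.savetxt(matrix_path, c.weights, delimiter="\t", fmt="%.12g")
    if labels_path is not None:
        Path(labels_path).write_text("\n".join(c.labels) + "\n")
    if coordinates_path is not None and c.coordinates is not None:
        with open(coordinates_path, "w") as fh:
            for lab, (x, y, z) in zip(c.labels, c.coordinates):
                fh.write(f"{lab}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_coordinates(path: str | Path, labels: Sequence[str]) -> np.ndarray:
    """Read a 4-column (label, x, y, z) file and order rows by ``labels``."""
    rows: dict[str, list[float]] = {}
    for ln in Path(path).read_text().splitlines():
        parts = ln.split()
        if not parts:
            continue
        rows[parts[0]] = [float(v) for v in parts[1:4]]
    missing = [l for l in labels if l not in rows]
    if missing:
        raise AlignmentError(f"coordinates missing for regions: {missing[:5]}")
    return np.array([rows[l] for l in labels], dtype=float)


def read_cohort(directory: str | Path, labels_path: str | Path) -> CohortConnectomes:
    """Read every ``*.tsv`` matrix in ``directory`` as one cohort."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.tsv"))
    if not paths:
        raise ValidationError(f"no *.tsv connectome files in {directory}")
    subjects = tuple(read_connectome(p, labels_path) for p in paths)
    return CohortConnectomes(subjects=subjects, metadata={"files": [p.name for p in paths]})
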
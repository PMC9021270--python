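"""Functional connectivity dynamics (FCD) and KS-type distances.

Functional connectivity (FC) is the Pearson correlation matrix of regional
BOLD within a sliding window (default 30 TRs, advancing 3 TRs).  The FCD
matrix correlates the vectorised upper triangles of the FC patterns at
every pair of windows, giving a time-versus-time similarity matrix.  Model
fit is judged by the two-sample Kolmogorov-Smirnov distance between the
distributions of empirical and simulated FCD values (upper triangle), with
a Peacock-style two-dimensional variant over (value, window lag) pairs as
an alternative that is sensitive to the temporal placement of the
correlations, not only their histogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import ks_2samp

from .bold import BOLDTimeseries
from .errors import ValidationError

DEFAULT_WINDOW_TRS = 30
DEFAULT_STEP_TRS = 3


@dataclass(frozen=True)
class FCDMatrix:
    """Window-by-window correlation of sliding-window FC patterns."""

    values: np.ndarray         # (n_windows, n_windows), in [-1, 1]
    window_starts: np.ndarray  # TR index of each window start
    window_length: int         # TRs
    step: int                  # TRs

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FCDSample:
    """Upper-triangle FCD values with their window-offset lags."""

    values: np.ndarray
    lags: np.ndarray

    def __post_init__(self):
        if len(self.values) != len(self.lags):
            raise ValidationError("values and lags must be length-matched")

    def __len__(self) -> int:
        return len(self.values)


def fcd_matrix(
    b: BOLDTimeseries,
    window: int = DEFAULT_WINDOW_TRS,
    step: int = DEFAULT_STEP_TRS,
) -> FCDMatrix:
    """Sliding-window FC, then correlation between all window pairs.

    Windows advance in whole TRs and the last partial window is dropped, so
    n_windows = floor((T - window)/step) + 1. A region with zero variance
    inside any window makes the Pearson FC undefined and raises a
    :class:`ValidationError` naming the window and region.
    """
    sig = b.signal
    n, T = sig.shape
    if T < window:
        raise ValidationError(f"need at least {window} TRs, got {T}")
    if n < 3:
        raise ValidationError("need at least 3 regions for FCD")
    starts = np.arange(0, T - window + 1, step)
    iu, ju = np.triu_indices(n, k=1)
    vecs = np.empty((len(starts), len(iu)))
    for k, s in enumerate(starts):
        seg = sig[:, s : s + window]
        sd = seg.std(axis=1)
        if np.any(sd == 0):
            r = int(np.flatnonzero(sd == 0)[0])
            raise ValidationError(
                f"zero-variance signal in window {k} (start TR {s}) region {r}"
            )
        fc = np.corrcoef(seg)
        vecs[k] = fc[iu, ju]
    fcd = np.atleast_2d(np.corrcoef(vecs))  # 1x1 for a single-window scan
    fcd = np.clip(fcd, -1.0, 1.0)
    fcd = 0.5 * (fcd + fcd.T)
    np.fill_diagonal(fcd, 1.0)
    return FCDMatrix(values=fcd, window_starts=starts, window_length=window, step=step)


def fcd_sample(m: FCDMatrix, exclude_overlap: bool = False) -> FCDSample:
    """Vectorise the upper triangle of an FCD matrix into (value, lag) pairs.

    With ``exclude_overlap`` only window pairs separated by at least
    window/step steps (i.e. non-overlapping windows) are kept; by default
    all upper-triangle entries enter the sample.
    """
    n = m.n_windows
    iu, ju = np.triu_indices(n, k=1)
    lags = ju - iu
    values = m.values[iu, ju]
    if exclude_overlap:
        keep = lags >= m.window_length / m.step
        values, lags = values[keep], lags[keep]
    return FCDSample(values=values, lags=lags)


def ks_distance(a: FCDSample, b: FCDSample) -> float:
    """Two-sample sup-norm ECDF (Kolmogorov-Smirnov) distance on raw values."""
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("cannot compare empty FCD samples")
    return float(ks_2samp(a.values, b.values).statistic)


def ks2d_distance(a: FCDSample, b: FCDSample, chunk: int = 2048) -> float:
    """Peacock-style two-sample 2-D KS distance over (value, lag) pairs.

    For every data point of both samples and each of the four quadrant
    orientations ((<=, <=), (<=, >), (>, <=), (>, >)), the absolute
    difference of the two empirical quadrant CDFs is evaluated; the maximum
    over all points and orientations is returned.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("cannot compare empty FCD samples")
    ax, ay = np.asarray(a.values, float), np.asarray(a.lags, float)
    bx, by = np.asarray(b.values, float), np.asarray(b.lags, float)
    px = np.concatenate([ax, bx])
    py = np.concatenate([ay, by])
    na, nb = len(ax), len(bx)
    best = 0.0
    for lo in range(0, len(px), chunk):
        qx = px[lo : lo + chunk][None, :]
        qy = py[lo : lo + chunk][None, :]
        a_lx = ax[:, None] <= qx
        a_ly = ay[:, None] <= qy
        b_lx = bx[:, None] <= qx
        b_ly = by[:, None] <= qy
        for fx, fy in ((1, 1), (1, 0), (0, 1), (0, 0)):
            ca = ((a_lx == bool(fx)) & (a_ly == bool(fy))).sum(axis=0) / na
            cb = ((b_lx == bool(fx)) & (b_ly == bool(fy))).sum(axis=0) / nb
            best = max(best, float(np.abs(ca - cb).max()))
    return best


def pool_fcd(samples: Sequence[FCDSample]) -> FCDSample:
    """Concatenate FCD samples across subjects/scans (group-wise pooling)."""
    if len(samples) == 0:
        raise ValidationError("need at least one sample to pool")
    return FCDSample(
        values=np.concatenate([s.values for s in samples]),
        lags=np.concatenate([s.lags for s in samples]),
    )


def n_windows(T: int, window: int = DEFAULT_WINDOW_TRS, step: int = DEFAULT_STEP_TRS) -> int:
    """Number of sliding windows for a scan of T TRs."""
    if T < window:
        return 0
    return (T - window) // step + 1


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fcd_matrix(m: FCDMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#window\t{m.window_length}\n#step\t{m.step}\n")
        np.savetxt(fh, m.values, delimiter="\t", fmt="%.8g")


def write_fcd_sample(s: FCDSample, path) -> None:
    np.savetxt(path, np.column_stack([s.values, s.lags]), delimiter="\t",
               fmt=("%.10g", "%d"), header="value\tlag")


def read_fcd_sample(path) -> FCDSample:
    arr = np.loadtxt(path, ndmin=2)
    return FCDSample(values=arr[:, 0], lags=arr[:, 1].astype(int))
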
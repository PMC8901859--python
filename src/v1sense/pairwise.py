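"""Pairwise correlation of deconvolved spontaneous activity vs distance.

ΔF/F traces are low-pass filtered (4th-order Butterworth, zero-phase),
deconvolved by the exact discrete inverse of a 3-s exponential kernel

    a(t) = x(t) − e^(−Δt/τ) · x(t−1),

and thresholded: samples below 2 × SD of the deconvolved trace are set
to zero, leaving sparse non-negative activity vectors.  The coupling of
a neuron pair is the cosine similarity of its vectors,

    Coefficient(A, B) = A·B / (‖A‖·‖B‖),

and the spatial structure of coupling is summarized by binning pairs by
Euclidean somatic distance (default 50 µm bins) and averaging the
coefficient per bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial.distance import pdist


def preprocess_trace(
    dff: np.ndarray,
    f: float,
    butter_order: int = 4,
    cutoff_hz: float | None = 2.0,
    tau_s: float = 3.0,
    zero_k: float = 2.0,
) -> np.ndarray:
    """Filter, deconvolve and threshold one ΔF/F trace.

    ``cutoff_hz=None`` skips the low-pass stage.  The deconvolution is
    the exact first-order inverse of the exponential kernel with decay
    ``tau_s``, so an isolated noiseless transient collapses to a single
    impulse of its ΔF/F amplitude.  Values below ``zero_k`` × SD of the
    deconvolved trace (negatives included) are zeroed.
    """
    x = np.asarray(dff, dtype=float)
    if x.ndim != 1:
        raise ValueError("one trace at a time")
    if cutoff_hz is not None:
        if cutoff_hz >= f / 2:
            raise ValueError(f"cutoff {cutoff_hz} Hz is not below Nyquist {f / 2} Hz")
        sos = signal.butter(butter_order, cutoff_hz, fs=f, output="sos")
        x = signal.sosfiltfilt(sos, x)
    r = np.exp(-1.0 / (f * tau_s))
    a = x.copy()
    a[1:] -= r * x[:-1]
    sd = a.std()
    a[a < zero_k * sd] = 0.0
    return a


def preprocess_traces(dff: np.ndarray, f: float, **kwargs) -> np.ndarray:
    """Row-wise :func:`preprocess_trace`."""
    dff = np.atleast_2d(dff)
    return np.stack([preprocess_trace(row, f, **kwargs) for row in dff])


def pair_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity A·B/(‖A‖·‖B‖); NaN when either vector is zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def coefficient_matrix(activity: np.ndarray) -> np.ndarray:
    """All-pairs cosine coefficients (rows = neurons); NaN rows for
    all-zero vectors; diagonal 1 where defined."""
    A = np.atleast_2d(np.asarray(activity, dtype=float))
    norms = np.linalg.norm(A, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        U = A / norms[:, None]
    M = np.clip(U @ U.T, -1.0, 1.0)
    M[norms == 0, :] = np.nan
    M[:, norms == 0] = np.nan
    return M


@dataclass
class DistanceCorrelation:
    """Pair coefficients binned by somatic distance."""

    distances: np.ndarray  # condensed, µm
    coefficients: np.ndarray  # condensed, aligned with distances
    bin_edges: np.ndarray
    bin_mean: np.ndarray
    bin_count: np.ndarray

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_um": self.bin_edges[:-1],
                "bin_hi_um": self.bin_edges[1:],
                "mean_coefficient": self.bin_mean,
                "n_pairs": self.bin_count,
            }
        )

    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted coefficients and their empirical CDF."""
        vals = np.sort(self.coefficients[~np.isnan(self.coefficients)])
        return vals, np.arange(1, vals.size + 1) / vals.size


def distance_binned_correlation(
    activity_or_coeffs: np.ndarray,
    positions: np.ndarray,
    bin_um: float = 50.0,
) -> DistanceCorrelation:
    """Bin pair coefficients by Euclidean distance (half-open bins).

    ``activity_or_coeffs`` is either a neurons × samples activity matrix
    (coefficients are computed) or a precomputed square coefficient
    matrix.  NaN coefficients (zero vectors) are excluded from bin
    means but retain their pair slot.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    M = np.asarray(activity_or_coeffs, dtype=float)
    if M.shape == (n, n) and np.allclose(M, M.T, equal_nan=True):
        coeff_mat = M
    else:
        coeff_mat = coefficient_matrix(M)
        if coeff_mat.shape[0] != n:
            raise ValueError("positions must cover all neurons")
    iu = np.triu_indices(n, k=1)
    coeffs = coeff_mat[iu]
    dists = pdist(positions)
    hi = max(dists.max(), bin_um) if dists.size else bin_um
    edges = np.arange(0.0, hi + bin_um, bin_um)
    if edges[-1] <= hi:
        edges = np.append(edges, edges[-1] + bin_um)
    which = np.digitize(dists, edges) - 1  # half-open [lo, hi)
    bin_mean = np.full(edges.size - 1, np.nan)
    bin_count = np.zeros(edges.size - 1, dtype=int)
    for b in range(edges.size - 1):
        sel = which == b
        vals = coeffs[sel]
        vals = vals[~np.isnan(vals)]
        bin_count[b] = vals.size
        if vals.size:
            bin_mean[b] = vals.mean()
    return DistanceCorrelation(
        distances=dists,
        coefficients=coeffs,
        bin_edges=edges,
        bin_mean=bin_mean,
        bin_count=bin_count,
    )
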
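"""n-order synchronization of calcium transients with a shuffle null.

Spontaneous activity is reduced to a binary raster (one "1" per
transient peak).  The occurrence of simultaneous transients in *n*
neurons within one frame is an *n*-order correlation; its count over
the recording is Firing(n), and the corresponding probability is

    Correlation_prob(n) = Firing(n) / Total_n,

where Total_n = ⌈T·f⌉ is the number of frames (73.5 s at 20.4 Hz gives
1500).  To compare circuits of different sizes, a subgroup of N neurons
(default 30) is drawn at random.

The independent model — what synchrony would look like if neurons fired
with the same rates but no coordination — is obtained by Monte-Carlo
shuffling: each neuron's spike frames are independently permuted
(preserving its spike count) and the probabilities recomputed, many
times (default 10,000).  Observed probabilities above the null's 97.5th
percentile, especially after aggregating over high orders (11–∞),
indicate genuine high-order synchrony.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import EventTrainSet

DEFAULT_RANGES = ((1, 10), (11, None))


def total_points(T: float, f: float) -> int:
    """Total point count of a binary series: ⌈T·f⌉ frames."""
    if T <= 0 or f <= 0:
        raise ValueError("T and f must be positive")
    return int(np.ceil(T * f - 1e-9))


def subsample_circuit(
    events: EventTrainSet, N: int = 30, seed: int | np.random.Generator | None = None
) -> EventTrainSet:
    """Uniformly draw N distinct neurons from the recorded population."""
    if events.n_neurons < N:
        raise ValueError(f"population of {events.n_neurons} is smaller than N={N}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(events.n_neurons, size=N, replace=False))
    return EventTrainSet(
        B=events.B[idx],
        f=events.f,
        neuron_ids=events.neuron_ids[idx],
        positions=None if events.positions is None else events.positions[idx],
    )


def firing_counts(events: EventTrainSet | np.ndarray) -> np.ndarray:
    """Firing(n) for n = 0..N: number of frames in which exactly n
    neurons emit a transient.  Index 0 (silent frames) is not an order
    of correlation and is excluded from probabilities downstream."""
    B = events.B if isinstance(events, EventTrainSet) else np.asarray(events)
    if not np.isin(B, (0, 1)).all():
        raise ValueError("event matrix must be binary")
    N = B.shape[0]
    per_frame = B.sum(axis=0)
    return np.bincount(per_frame, minlength=N + 1)


def correlation_prob(firing: np.ndarray, total_n: int) -> np.ndarray:
    """Correlation_prob(n) = Firing(n)/Total_n, elementwise."""
    if total_n <= 0:
        raise ValueError("total_n must be positive")
    return np.asarray(firing, dtype=float) / total_n


@dataclass
class SyncResult:
    """Observed n-order statistics for one (sub)circuit."""

    N: int
    total_n: int
    firing: np.ndarray  # length N+1, index = order n
    probs: np.ndarray  # firing / total_n

    @property
    def orders(self) -> np.ndarray:
        return np.arange(1, self.N + 1)


def observed_sync(events: EventTrainSet) -> SyncResult:
    firing = firing_counts(events)
    return SyncResult(
        N=events.n_neurons,
        total_n=events.total_n,
        firing=firing,
        probs=correlation_prob(firing, events.total_n),
    )


@dataclass
class ShuffleNull:
    """Null distribution of Correlation_prob over shuffles.

    ``probs`` has shape (n_shuffles, N+1); column n is the shuffled
    probability of an n-order correlation.
    """

    probs: np.ndarray
    method: str

    @property
    def n_shuffles(self) -> int:
        return self.probs.shape[0]

    def mean(self) -> np.ndarray:
        return self.probs.mean(axis=0)

    def percentile(self, q: float) -> np.ndarray:
        """Per-order q-th percentile across shuffles."""
        return np.percentile(self.probs, q, axis=0)

    def range_probs(self, ranges=DEFAULT_RANGES) -> np.ndarray:
        """Per-shuffle range aggregates, shape (n_shuffles, len(ranges))."""
        return np.stack(
            [aggregate_ranges(p, ranges) for p in self.probs], axis=0
        )

    def range_percentile(self, q: float, ranges=DEFAULT_RANGES) -> np.ndarray:
        return np.percentile(self.range_probs(ranges), q, axis=0)


def shuffle_null(
    events: EventTrainSet,
    n_shuffles: int = 10000,
    seed: int | np.random.Generator | None = None,
    method: str = "permute",
    _chunk: int = 2000,
) -> ShuffleNull:
    """Monte-Carlo independent model by count-preserving shuffling.

    ``method="permute"`` independently permutes each neuron's frame
    indices (destroying all cross-neuron structure while preserving each
    neuron's spike count); ``method="circular"`` applies an independent
    random circular shift per neuron (additionally preserving each
    neuron's inter-spike-interval structure).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if method not in ("permute", "circular"):
        raise ValueError(f"unknown shuffle method {method!r}")
    rng = np.random.default_rng(seed)
    B = events.B
    N, T = B.shape
    spike_counts = B.sum(axis=1)
    spike_frames = [np.flatnonzero(row) for row in B]
    all_probs = np.empty((n_shuffles, N + 1))
    done = 0
    while done < n_shuffles:
        S = min(_chunk, n_shuffles - done)
        counts = np.zeros((S, T), dtype=np.int16)
        rows = np.arange(S)[:, None]
        for i in range(N):
            k = int(spike_counts[i])
            if k == 0:
                continue
            if method == "permute":
                keys = rng.random((S, T), dtype=np.float32)
                idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            else:  # circular
                shifts = rng.integers(0, T, size=S)
                idx = (spike_frames[i][None, :] + shifts[:, None]) % T
            counts[rows, idx] += 1
        # per-shuffle histogram of coincidence sizes
        offs = counts.astype(np.int64) + np.arange(S)[:, None] * (N + 1)
        hist = np.bincount(offs.ravel(), minlength=S * (N + 1)).reshape(S, N + 1)
        assert (hist.sum(axis=1) == T).all()
        all_probs[done : done + S] = hist / T
        done += S
    return ShuffleNull(probs=all_probs, method=method)


def aggregate_ranges(probs: np.ndarray, ranges=DEFAULT_RANGES) -> np.ndarray:
    """Sum Correlation_prob(n) over inclusive order ranges.

    ``ranges`` are (lo, hi) pairs with 1-based inclusive bounds; ``hi =
    None`` means "to the largest order" (the 11–∞ band).  Ranges must
    not overlap.
    """
    probs = np.asarray(probs, dtype=float)
    N = probs.size - 1
    resolved = []
    for lo, hi in ranges:
        hi = N if hi is None else min(int(hi), N)
        lo = int(lo)
        if lo < 1:
            raise ValueError("range lower bound must be >= 1 (order 0 is no event)")
        resolved.append((lo, hi))
    covered: set[int] = set()
    for lo, hi in resolved:
        span = set(range(lo, hi + 1))
        if covered & span:
            raise ValueError("ranges overlap")
        covered |= span
    return np.array([probs[lo : hi + 1].sum() if hi >= lo else 0.0 for lo, hi in resolved])


# ---------------------------------------------------------------------------
# Pairwise synchronization by functional assembly
# ---------------------------------------------------------------------------

@dataclass
class AssemblySyncMatrix:
    """Pairwise synchronization counts grouped by functional type.

    ``counts[i, j]`` is the number of frames in which neurons i and j
    both emit a transient (diagonal zeroed); ``assembly_means[a, b]``
    the mean count over pairs with one neuron of type a and one of type
    b (within-assembly on the diagonal).
    """

    counts: np.ndarray
    types: np.ndarray
    assembly_means: "np.ndarray"
    assembly_labels: tuple[int, ...]

    @property
    def mean_count(self) -> float:
        """Mean pairwise synchronization count over all distinct pairs."""
        n = self.counts.shape[0]
        iu = np.triu_indices(n, k=1)
        return float(self.counts[iu].mean())


def pairwise_sync_counts(
    events: EventTrainSet, type_assignment: np.ndarray
) -> AssemblySyncMatrix:
    """Frame-coincidence counts for every neuron pair, summarized by the
    four-type assembly assignment."""
    B = events.B.astype(np.int64)
    types = np.asarray(type_assignment, dtype=int)
    if types.size != events.n_neurons:
        raise ValueError("type assignment must cover all neurons")
    counts = B @ B.T
    np.fill_diagonal(counts, 0)
    labels = tuple(sorted(np.unique(types).tolist()))
    K = len(labels)
    means = np.full((K, K), np.nan)
    for a_i, a in enumerate(labels):
        for b_i, b in enumerate(labels):
            ia = np.flatnonzero(types == a)
            ib = np.flatnonzero(types == b)
            if a == b:
                if ia.size < 2:
                    continue
                sub = counts[np.ix_(ia, ia)]
                iu = np.triu_indices(ia.size, k=1)
                means[a_i, b_i] = sub[iu].mean()
            else:
                if ia.size == 0 or ib.size == 0:
                    continue
                means[a_i, b_i] = counts[np.ix_(ia, ib)].mean()
    return AssemblySyncMatrix(
        counts=counts, types=types, assembly_means=means, assembly_labels=labels
    )
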
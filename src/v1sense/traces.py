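"""Calcium-trace analysis: ΔF/F₀, transient detection, responsiveness.

The pipeline implemented here mirrors standard bulk-loaded-indicator
(OGB-1) practice for layer-2/3 imaging at ~20 Hz:

1. per-ROI fluorescence is the mean grey value inside the cell-body mask
   (:func:`extract_roi_traces`);
2. activity is expressed as relative fluorescence change
   ΔF/F₀ = (F − F₀)/F₀ (:func:`compute_dff`);
3. a calcium transient is accepted where ΔF/F₀ has a local maximum
   exceeding ``k_sd`` (default 2.5) times the baseline standard deviation
   (:func:`detect_transients`); events are binary, one "1" per transient
   peak frame;
4. a neuron is stimulus-responsive in a trial when at least one transient
   peak falls inside the 2-s stimulus window
   (:func:`classify_responsive`).

Population summaries are the across-trial average percentage of
responding cells per stimulus, the per-neuron response probability and
amplitude, and the neural activity index
NAI = %responsive(S1) / %responsive(S4) — a scalar input–output measure
of intensity tuning (≈0.3 in wild-type-like data, ≈1 when weak and
strong stimuli recruit equally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .protocol import StimulusProtocol


@dataclass
class TraceSet:
    """Per-neuron fluorescence time series at a common sampling rate.

    ``F`` is raw fluorescence (a.u., neurons × frames); ``F0`` the
    baseline (per neuron scalar or per frame), ``dff`` the relative
    change (F − F₀)/F₀.  ``positions`` are ROI centroids in µm.
    """

    F: np.ndarray
    f: float
    neuron_ids: np.ndarray | None = None
    positions: np.ndarray | None = None
    F0: np.ndarray | None = None
    dff: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        if self.f <= 0:
            raise ValueError("sampling rate must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.F.shape[0])
        self.neuron_ids = np.asarray(self.neuron_ids)
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (frame k occurs at k/f; 0-based)."""
        return np.arange(self.n_frames) / self.f


@dataclass
class EventTrainSet:
    """Binary transient rasters: B[i, k] = 1 at a transient peak frame."""

    B: np.ndarray
    f: float
    neuron_ids: np.ndarray | None = None
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        B = np.atleast_2d(np.asarray(self.B))
        if not np.isin(B, (0, 1)).all():
            raise ValueError("event matrix must be binary")
        self.B = B.astype(np.uint8)
        if self.f <= 0:
            raise ValueError("sampling rate must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.B.shape[0])
        self.neuron_ids = np.asarray(self.neuron_ids)

    @property
    def n_neurons(self) -> int:
        return self.B.shape[0]

    @property
    def total_n(self) -> int:
        """Total point count of each binary series (= number of frames)."""
        return self.B.shape[1]

    @property
    def T(self) -> float:
        """Recording length in seconds."""
        return self.B.shape[1] / self.f


@dataclass
class ResponseTable:
    """Per-neuron, per-stimulus responsiveness summary.

    ``responded[label]`` is a neurons × trials boolean matrix;
    ``probability`` the per-neuron fraction of responsive trials.
    ``percent_responsive`` averages, across trials, the percentage of
    cells responding in that trial (equivalently 100 × mean probability).
    """

    responded: dict[str, np.ndarray]
    probability: pd.DataFrame
    amplitude: pd.DataFrame | None = None
    neuron_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.neuron_ids is None:
            self.neuron_ids = np.asarray(self.probability.index)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.probability.columns)

    def percent_responsive(self, label: str) -> float:
        """Average (over trials) percentage of cells responding to ``label``."""
        return 100.0 * float(np.mean(self.responded[label]))

    def nai(self, weak: str = "S1", strong: str = "S4") -> float:
        """Neural activity index: %responsive(weak) / %responsive(strong)."""
        return compute_nai(self, weak=weak, strong=strong)


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_roi_traces(
    movie: np.ndarray,
    rois,
    f: float,
    positions: np.ndarray | None = None,
) -> TraceSet:
    """Average pixel grey values inside each ROI mask, per frame.

    Parameters
    ----------
    movie
        Array of shape (frames, height, width).
    rois
        Sequence of boolean masks (height × width), or an object with a
        ``masks`` attribute (see :class:`v1sense.synthgen.ROISet`).
    f
        Imaging rate in Hz.
    """
    masks = getattr(rois, "masks", rois)
    movie = np.asarray(movie)
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, height, width)")
    flat = movie.reshape(movie.shape[0], -1).astype(float)
    traces = np.empty((len(masks), movie.shape[0]))
    for i, mask in enumerate(masks):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != movie.shape[1:]:
            raise ValueError(f"ROI {i} mask shape {mask.shape} does not match frames")
        idx = np.flatnonzero(mask.ravel())
        if idx.size == 0:
            raise ValueError(f"ROI {i} has an empty mask")
        traces[i] = flat[:, idx].mean(axis=1)
    if positions is None:
        positions = getattr(rois, "positions_um", None)
    return TraceSet(F=traces, f=f, positions=positions)


# ---------------------------------------------------------------------------
# ΔF/F₀
# ---------------------------------------------------------------------------

def compute_dff(
    traces: TraceSet,
    baseline_mode: str = "global-median",
    protocol: StimulusProtocol | None = None,
    prestim_s: float = 1.0,
) -> TraceSet:
    """Compute ΔF/F₀ = (F − F₀)/F₀ and attach it to the trace set.

    ``baseline_mode``:

    ``"global-median"``
        F₀ is the per-neuron median of the whole trace — appropriate for
        spontaneous recordings where no stimulus structure exists.
    ``"prestim-mean"``
        F₀ within each trial window (from ``prestim_s`` before onset to
        the end of the stimulus plus ``prestim_s``) is the mean of the
        1-s pre-stimulus segment of that trial; frames outside any trial
        window fall back to the global median.  Requires ``protocol``.
    """
    F = traces.F
    if baseline_mode == "global-median":
        f0 = np.median(F, axis=1, keepdims=True)
        if np.any(f0 <= 0):
            raise ValueError("non-positive baseline F0")
        dff = (F - f0) / f0
        f0_out: np.ndarray = f0[:, 0]
    elif baseline_mode == "prestim-mean":
        if protocol is None:
            raise ValueError("prestim-mean baseline requires a protocol")
        f0_frame = np.repeat(np.median(F, axis=1, keepdims=True), F.shape[1], axis=1)
        frame_t = traces.times
        for onset in protocol.onsets:
            pre = (frame_t >= onset - prestim_s) & (frame_t < onset)
            if not pre.any():
                raise ValueError(f"no pre-stimulus frames before onset {onset} s")
            win = (frame_t >= onset - prestim_s) & (
                frame_t < onset + protocol.duration + prestim_s
            )
            f0_frame[:, win] = F[:, pre].mean(axis=1, keepdims=True)
        if np.any(f0_frame <= 0):
            raise ValueError("non-positive baseline F0")
        dff = (F - f0_frame) / f0_frame
        f0_out = f0_frame
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    return TraceSet(
        F=F,
        f=traces.f,
        neuron_ids=traces.neuron_ids,
        positions=traces.positions,
        F0=f0_out,
        dff=dff,
    )


def _require_dff(traces: TraceSet) -> np.ndarray:
    if traces.dff is None:
        raise ValueError("trace set has no ΔF/F; run compute_dff first")
    return traces.dff


def baseline_sd(dff: np.ndarray, clip_k: float = 3.0, n_iter: int = 10) -> np.ndarray:
    """Per-neuron baseline SD of ΔF/F with iterative ±kσ clipping.

    Transients inflate a naive SD, so the estimate starts from the
    robust MAD (× 1.4826, the Gaussian consistency factor) and is then
    refined by clipping samples beyond ``clip_k`` estimated SDs from
    the median and re-estimating — this converges to the noise floor of
    the quiescent trace even when transients occupy much of it.
    """
    dff = np.atleast_2d(dff)
    out = np.empty(dff.shape[0])
    for i, x in enumerate(dff):
        kept = x[np.isfinite(x)]
        med = np.median(kept)
        mad = 1.4826 * np.median(np.abs(kept - med))
        sd = mad if mad > 0 else kept.std()
        for _ in range(n_iter):
            sel = np.abs(kept - med) <= clip_k * sd
            if not sel.any():
                break
            new_sd = kept[sel].std()
            if new_sd == 0 or abs(new_sd - sd) <= 1e-6 * sd:
                sd = new_sd if new_sd > 0 else sd
                break
            sd = new_sd
        out[i] = sd
    return out


# ---------------------------------------------------------------------------
# Transient detection
# ---------------------------------------------------------------------------

def detect_transients(
    traces: TraceSet,
    k_sd: float = 2.5,
    min_separation_s: float = 0.25,
    sustain_s: float = 0.3,
    sustain_frac: float = 0.5,
    smooth_s: float = 0.15,
) -> EventTrainSet:
    """Mark calcium-transient peaks in ΔF/F₀.

    Detection runs on a lightly smoothed copy of ΔF/F (boxcar of
    ``smooth_s``; single-frame noise excursions shrink, the much slower
    indicator transients do not).  A transient is accepted at a local
    maximum above ``k_sd`` × baseline SD that also looks like a calcium
    transient rather than a noise excursion: the peak's prominence must
    itself exceed the threshold (a noise bump riding the decay tail of
    an earlier transient rises only by the noise amplitude and is
    rejected), and the trace must stay elevated after the peak (mean
    ΔF/F over ``sustain_s`` ≥ ``sustain_frac`` × threshold — a noise
    spike at baseline decays immediately, an indicator transient
    outlasts the frame interval).  The raster holds a single 1 at the
    peak frame; peaks closer than ``min_separation_s`` are merged
    (highest wins, earliest on ties).
    """
    raw = _require_dff(traces)
    # threshold anchored to the raw-trace baseline SD; peak finding on a
    # lightly smoothed copy (noise peaks shrink, transients survive),
    # then refined to the raw-trace maximum so the marked frame is not
    # biased toward the decay by the smoothing window
    sd = baseline_sd(raw)
    width = max(1, int(round(smooth_s * traces.f)))
    if width > 1:
        from scipy.ndimage import uniform_filter1d

        dff = uniform_filter1d(raw, size=width, axis=1, mode="nearest")
    else:
        dff = raw
    # refinement window covers smoothing-induced peak drift; the marked
    # frame is the earliest raw sample within two baseline SDs of the
    # local maximum (the rise is a single frame, so this sits on the
    # transient onset rather than drifting down the decay)
    refine = max(width // 2 + 1, int(round(0.25 * traces.f)))
    if np.any(sd <= 0):
        bad = traces.neuron_ids[np.flatnonzero(sd <= 0)]
        raise ValueError(f"zero-variance trace(s): {list(bad)}")
    distance = max(1, int(round(min_separation_s * traces.f)))
    n_sustain = max(1, int(round(sustain_s * traces.f)))
    B = np.zeros(dff.shape, dtype=np.uint8)
    for i, x in enumerate(dff):
        thr = k_sd * sd[i]
        peaks, _ = signal.find_peaks(
            x, height=thr, prominence=thr, distance=distance
        )
        for p in peaks:
            if x[p : p + n_sustain].mean() >= sustain_frac * thr:
                lo = max(0, p - refine)
                seg = raw[i, lo : p + refine + 1]
                cand = np.flatnonzero(seg >= seg.max() - 2 * sd[i])
                B[i, lo + cand[0]] = 1
    return EventTrainSet(
        B=B, f=traces.f, neuron_ids=traces.neuron_ids, positions=traces.positions
    )


# ---------------------------------------------------------------------------
# Stimulus responsiveness
# ---------------------------------------------------------------------------

def _window_frames(onset: float, duration: float, f: float, n_frames: int) -> slice:
    # frames k with onset <= k/f < onset + duration  (half-open window)
    lo = int(np.ceil(onset * f - 1e-9))
    hi = int(np.ceil((onset + duration) * f - 1e-9))
    return slice(max(lo, 0), min(hi, n_frames))


def classify_responsive(
    events: EventTrainSet, protocol: StimulusProtocol
) -> ResponseTable:
    """Score each neuron × trial: responsive ⇔ ≥1 transient peak in the
    stimulus window [onset, onset + duration)."""
    B = events.B
    responded: dict[str, np.ndarray] = {}
    for label in protocol.stimulus_labels:
        onsets = protocol.trials(label)
        hit = np.zeros((events.n_neurons, len(onsets)), dtype=bool)
        for j, onset in enumerate(onsets):
            win = _window_frames(onset, protocol.duration, events.f, B.shape[1])
            hit[:, j] = B[:, win].any(axis=1)
        responded[label] = hit
    prob = pd.DataFrame(
        {lab: hit.mean(axis=1) for lab, hit in responded.items()},
        index=events.neuron_ids,
    )
    return ResponseTable(responded=responded, probability=prob)


def response_amplitude(
    traces: TraceSet,
    protocol: StimulusProtocol,
    table: ResponseTable,
) -> pd.DataFrame:
    """Peak ΔF/F within the stimulus window, averaged over responsive
    trials; NaN where a neuron never responded to that stimulus."""
    dff = _require_dff(traces)
    amp = pd.DataFrame(
        np.nan, index=table.probability.index, columns=list(table.labels)
    )
    for label in table.labels:
        onsets = protocol.trials(label)
        hits = table.responded[label]
        peaks = np.full(hits.shape, np.nan)
        for j, onset in enumerate(onsets):
            win = _window_frames(onset, protocol.duration, traces.f, dff.shape[1])
            peaks[:, j] = dff[:, win].max(axis=1)
        peaks[~hits] = np.nan
        any_hit = hits.any(axis=1)
        vals = np.full(hits.shape[0], np.nan)
        if any_hit.any():
            vals[any_hit] = np.nanmean(peaks[any_hit], axis=1)
        amp[label] = vals
    table.amplitude = amp
    return amp


def compute_nai(
    table: ResponseTable, weak: str = "S1", strong: str = "S4"
) -> float:
    """Neural activity index: %responsive(weak) / %responsive(strong).

    Raises if the strong-stimulus percentage is zero (undefined ratio).
    """
    p_strong = table.percent_responsive(strong)
    if p_strong == 0:
        raise ZeroDivisionError(
            f"NAI undefined: no responses to {strong!r} (denominator 0)"
        )
    return table.percent_responsive(weak) / p_strong
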
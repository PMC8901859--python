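"""Synthetic data with known ground truth.

Generators here emulate the statistical structure the analysis modules
assume, so that every estimator in the package can be exercised against
a known answer:

* populations of neurons scattered in a 517.77 µm × 517.77 µm field of
  view, labelled by functional type (#1 responds only to the strong
  stimulus S4, #2 only to the weak S1, #3 to both, #4 to neither), with
  optional Gaussian clustering;
* per-trial Bernoulli stimulus responses with type-dependent
  probabilities, background transients as a Poisson process, and shared
  population events that recruit random neuron subsets (injecting
  high-order synchrony);
* calcium traces built by convolving the spike raster with a single
  exponential kernel (decay τ, OGB-1-like) plus i.i.d. Gaussian noise,
  optionally rendered into a multi-frame movie with disc ROIs;
* piezo voltage traces with stimulus-locked deflections at a set
  latency;
* random branched dendritic trees writable as SWC.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .morpho import MorphologyTree
from .protocol import StimulusProtocol
from .traces import TraceSet

FOV_UM = 517.77
FRAME_PX = 768

TYPE_NAMES = {1: "S4-only", 2: "S1-only", 3: "both", 4: "neither"}

#: Default per-type response probabilities (weak S1, strong S4).
DEFAULT_P_RESP_BY_TYPE = {
    1: {"S1": 0.0, "S4": 0.6},
    2: {"S1": 0.6, "S4": 0.0},
    3: {"S1": 0.6, "S4": 0.6},
    4: {"S1": 0.0, "S4": 0.0},
}


@dataclass
class PopulationSpec:
    """Neuron positions, functional type labels and response probabilities."""

    positions: np.ndarray  # (n, 2) µm
    type_labels: np.ndarray  # ints 1..4
    p_resp: dict[str, np.ndarray]  # label -> per-neuron probability
    fov_um: float = FOV_UM

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.type_labels = np.asarray(self.type_labels, dtype=int)
        for lab, p in self.p_resp.items():
            p = np.asarray(p, dtype=float)
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"p_resp[{lab}] outside [0, 1]")
            self.p_resp[lab] = p
        if np.any(self.positions < 0) or np.any(self.positions > self.fov_um):
            raise ValueError("positions outside the field of view")

    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]


@dataclass
class SimConfig:
    """Imaging-simulation parameters.

    f: imaging rate (Hz); T: recording length (s); tau_decay: calcium
    kernel decay (s); amp: transient peak in ΔF/F units; noise_sd:
    Gaussian noise SD in ΔF/F units; bg_rate: background transient rate
    (Hz/neuron); sync_rate / sync_recruit: rate (Hz) of shared
    population events and per-neuron recruitment probability; f0:
    resting fluorescence (a.u.).
    """

    f: float = 20.4
    T: float = 73.5
    tau_decay: float = 1.0
    amp: float = 0.1
    noise_sd: float = 0.02
    bg_rate: float = 0.05
    sync_rate: float = 0.0
    sync_recruit: float = 0.5
    f0: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("f", "T", "tau_decay", "f0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("amp", "noise_sd", "bg_rate", "sync_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.sync_recruit <= 1:
            raise ValueError("sync_recruit must be in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(np.ceil(self.T * self.f))


@dataclass
class GroundTruth:
    """Generator-side truth used by parameter-recovery tests."""

    spike_frames: list[np.ndarray]
    evoked_flags: dict[str, np.ndarray]  # label -> (n_neurons, n_trials) bool
    population_events: list[tuple[int, np.ndarray]]  # (frame, neuron indices)
    n_frames: int
    f: float

    @property
    def n_neurons(self) -> int:
        return len(self.spike_frames)

    def raster(self) -> np.ndarray:
        B = np.zeros((self.n_neurons, self.n_frames), dtype=np.uint8)
        for i, fr in enumerate(self.spike_frames):
            B[i, fr] = 1
        return B

    def to_json(self, path) -> None:
        payload = {
            "n_frames": self.n_frames,
            "f": self.f,
            "spike_frames": [fr.tolist() for fr in self.spike_frames],
            "evoked_flags": {
                lab: flags.astype(int).tolist()
                for lab, flags in self.evoked_flags.items()
            },
            "population_events": [
                {"frame": int(frame), "neurons": idx.tolist()}
                for frame, idx in self.population_events
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

def make_population(
    n: int,
    fov_um: float = FOV_UM,
    type_fractions=(0.25, 0.25, 0.25, 0.25),
    p_resp_by_type: dict[int, dict[str, float]] | None = None,
    clustering: dict | None = None,
    seed: int | np.random.Generator | None = None,
) -> PopulationSpec:
    """Sample a neuron population with functional types and positions.

    ``type_fractions`` gives the multinomial probabilities of types
    #1..#4 and must sum to 1.  ``clustering`` is ``None`` (uniform,
    complete spatial randomness) or ``{"n_clusters": int, "sigma_um":
    float}`` for a mixture of isotropic Gaussians (samples falling
    outside the field of view are redrawn).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    fr = np.asarray(type_fractions, dtype=float)
    if fr.shape != (4,) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("type_fractions must be 4 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(np.arange(1, 5), size=n, p=fr)

    if clustering is None:
        positions = rng.uniform(0, fov_um, size=(n, 2))
    else:
        n_clusters = int(clustering.get("n_clusters", 4))
        sigma = float(clustering.get("sigma_um", 30.0))
        centers = rng.uniform(0, fov_um, size=(n_clusters, 2))
        which = rng.integers(0, n_clusters, size=n)
        positions = np.empty((n, 2))
        for i in range(n):
            while True:
                p = centers[which[i]] + rng.normal(0, sigma, size=2)
                if np.all((p >= 0) & (p <= fov_um)):
                    positions[i] = p
                    break

    table = p_resp_by_type or DEFAULT_P_RESP_BY_TYPE
    stim_labels = sorted({lab for d in table.values() for lab in d})
    p_resp = {
        lab: np.array([table[int(t)].get(lab, 0.0) for t in labels])
        for lab in stim_labels
    }
    return PopulationSpec(
        positions=positions, type_labels=labels, p_resp=p_resp, fov_um=fov_um
    )


def make_uniform_population(
    n: int,
    p_resp: dict[str, float] | None = None,
    fov_um: float = FOV_UM,
    clustering: dict | None = None,
    seed: int | np.random.Generator | None = None,
) -> PopulationSpec:
    """Population where every neuron shares the same response
    probabilities (wild-type-like default: p(S1)=0.10, p(S4)=0.35)."""
    p_resp = dict(p_resp or {"S1": 0.10, "S4": 0.35})
    s1 = p_resp.get("S1", 0.0) > 0
    s4 = p_resp.get("S4", 0.0) > 0
    t = 3 if (s1 and s4) else 1 if s4 else 2 if s1 else 4
    table = {k: ({} if k != t else p_resp) for k in (1, 2, 3, 4)}
    fractions = [1.0 if k == t else 0.0 for k in (1, 2, 3, 4)]
    return make_population(
        n,
        fov_um=fov_um,
        type_fractions=fractions,
        p_resp_by_type=table,
        clustering=clustering,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Activity
# ---------------------------------------------------------------------------

def _window_frame_range(onset: float, duration: float, f: float) -> tuple[int, int]:
    lo = int(np.ceil(onset * f - 1e-9))
    hi = int(np.ceil((onset + duration) * f - 1e-9))
    return lo, hi


def simulate_activity(
    pop: PopulationSpec,
    protocol: StimulusProtocol | None,
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
) -> GroundTruth:
    """Draw spike frames: evoked Bernoulli responses, Poisson background,
    and shared population events.

    Each stimulus trial independently evokes (with probability
    ``pop.p_resp[label][i]``) one transient at a uniformly random frame
    inside the 2-s stimulus window.  Background transients arrive as a
    homogeneous Poisson process at ``config.bg_rate`` Hz.  Population
    events occur at ``config.sync_rate`` Hz; each recruits every neuron
    independently with probability ``config.sync_recruit`` and places a
    synchronous spike at the event frame.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = pop.n_neurons
    n_frames = config.n_frames
    spikes: list[list[int]] = [[] for _ in range(n)]
    evoked_flags: dict[str, np.ndarray] = {}

    if protocol is not None:
        if protocol.onsets.size and protocol.onsets[-1] + protocol.duration > config.T:
            raise ValueError("protocol extends beyond the recording length T")
        for label in protocol.stimulus_labels:
            onsets = protocol.trials(label)
            p = pop.p_resp.get(label, np.zeros(n))
            flags = rng.random((n, len(onsets))) < p[:, None]
            evoked_flags[label] = flags
            for j, onset in enumerate(onsets):
                lo, hi = _window_frame_range(onset, protocol.duration, config.f)
                hi = min(hi, n_frames)
                hit = np.flatnonzero(flags[:, j])
                frames = rng.integers(lo, hi, size=hit.size)
                for i, fr in zip(hit, frames):
                    spikes[i].append(int(fr))

    if config.bg_rate > 0:
        counts = rng.poisson(config.bg_rate * config.T, size=n)
        for i in range(n):
            spikes[i].extend(rng.integers(0, n_frames, size=counts[i]).tolist())

    population_events: list[tuple[int, np.ndarray]] = []
    if config.sync_rate > 0:
        n_events = rng.poisson(config.sync_rate * config.T)
        frames = rng.integers(0, n_frames, size=n_events)
        for frame in frames:
            recruited = np.flatnonzero(rng.random(n) < config.sync_recruit)
            population_events.append((int(frame), recruited))
            for i in recruited:
                spikes[i].append(int(frame))

    spike_frames = [np.unique(np.asarray(s, dtype=int)) for s in spikes]
    return GroundTruth(
        spike_frames=spike_frames,
        evoked_flags=evoked_flags,
        population_events=population_events,
        n_frames=n_frames,
        f=config.f,
    )


def render_traces(
    truth: GroundTruth,
    config: SimConfig,
    positions: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> TraceSet:
    """Convolve spike rasters with the exponential calcium kernel.

    F(t) = F₀ · (1 + amp · Σ_spikes exp(−(t − t_spike)/τ)) + F₀ · ε(t),
    ε ~ N(0, noise_sd²); so the noiseless peak ΔF/F of an isolated
    transient equals ``amp``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_frames = truth.n_frames
    klen = max(1, int(np.ceil(8 * config.tau_decay * config.f)))
    kernel = np.exp(-np.arange(klen) / (config.tau_decay * config.f))
    F = np.empty((truth.n_neurons, n_frames))
    for i, frames in enumerate(truth.spike_frames):
        raster = np.zeros(n_frames)
        if frames.size:
            if frames.min() < 0 or frames.max() >= n_frames:
                raise ValueError("spike frame outside recording")
            raster[frames] = 1.0
        dff = config.amp * np.convolve(raster, kernel)[:n_frames]
        F[i] = config.f0 * (1.0 + dff)
    if config.noise_sd > 0:
        F += config.f0 * rng.normal(0, config.noise_sd, size=F.shape)
    return TraceSet(F=F, f=config.f, positions=positions)


# ---------------------------------------------------------------------------
# Movies
# ---------------------------------------------------------------------------

@dataclass
class ROISet:
    """Boolean ROI masks plus centroid positions in µm."""

    masks: list[np.ndarray]
    positions_um: np.ndarray
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        for m in self.masks:
            if m.shape != tuple(self.shape):
                raise ValueError("mask shape mismatch")


def disc_rois(
    positions_um: np.ndarray,
    fov_um: float = FOV_UM,
    shape: tuple[int, int] = (FRAME_PX, FRAME_PX),
    radius_px: int = 5,
) -> ROISet:
    """Disc masks centred on the given µm positions."""
    positions_um = np.asarray(positions_um, dtype=float).reshape(-1, 2)
    scale = shape[0] / fov_um
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    masks = []
    for x_um, y_um in positions_um:
        cx = np.clip(x_um * scale, radius_px, shape[1] - 1 - radius_px)
        cy = np.clip(y_um * scale, radius_px, shape[0] - 1 - radius_px)
        masks.append((yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2)
    return ROISet(masks=masks, positions_um=positions_um, shape=tuple(shape))


def render_movie(
    traces: TraceSet,
    rois: ROISet,
    background: float = 0.0,
    noise_sd: float = 0.0,
    dtype=np.float32,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Paint each ROI's trace into its mask on every frame.

    Overlapping masks are summed (and reported via a ``RuntimeWarning``);
    off-ROI pixels hold ``background`` plus noise.
    """
    import warnings

    rng = np.random.default_rng(seed)
    n_neurons, n_frames = traces.F.shape
    if len(rois.masks) != n_neurons:
        raise ValueError("one mask per neuron required")
    overlap = np.zeros(rois.shape, dtype=int)
    for m in rois.masks:
        overlap += m
    if np.any(overlap > 1):
        warnings.warn(
            f"{int(np.sum(overlap > 1))} pixels belong to more than one ROI",
            RuntimeWarning,
            stacklevel=2,
        )
    movie = np.full((n_frames,) + tuple(rois.shape), background, dtype=float)
    for i, mask in enumerate(rois.masks):
        movie[:, mask] += (traces.F[i][:, None] - background)
    if noise_sd > 0:
        movie += rng.normal(0, noise_sd, size=movie.shape)
    return movie.astype(dtype)


# ---------------------------------------------------------------------------
# Piezo
# ---------------------------------------------------------------------------

@dataclass
class PiezoRecording:
    """Raw piezo voltage at ``fs`` Hz (typically 1000)."""

    voltage: np.ndarray
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration(self) -> float:
        return self.voltage.size / self.fs

    @property
    def F0(self) -> float:
        """Session-mean voltage (the behavioural baseline)."""
        return float(self.voltage.mean())


def simulate_piezo(
    protocol: StimulusProtocol,
    evoked_amp: float | dict[str, float] = 0.5,
    latency_s: float = 0.1,
    decay_s: float = 0.3,
    noise_sd: float = 0.01,
    fs: float = 1000.0,
    baseline: float = 1.0,
    duration: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> PiezoRecording:
    """Piezo trace with a stimulus-locked deflection after each onset.

    The deflection is an exponential bump of peak ``evoked_amp`` (in
    units of the baseline voltage) starting ``latency_s`` after onset
    and decaying with ``decay_s``; noise is i.i.d. Gaussian with SD
    ``noise_sd`` × baseline.  ``evoked_amp`` may be a dict mapping
    stimulus label → amplitude (stimulus-dependent movement).
    """
    if fs < 200:
        raise ValueError("piezo sampling rate must be >= 200 Hz")
    rng = np.random.default_rng(seed)
    duration = duration if duration is not None else protocol.span
    n = int(round(duration * fs))
    v = np.full(n, baseline)
    t = np.arange(n) / fs
    for onset, label in zip(protocol.onsets, protocol.labels):
        amp = evoked_amp[label] if isinstance(evoked_amp, dict) else evoked_amp
        start = onset + latency_s
        sel = t >= start
        v[sel] += amp * baseline * np.exp(-(t[sel] - start) / decay_s)
    if noise_sd > 0:
        v += rng.normal(0, noise_sd * baseline, size=n)
    return PiezoRecording(voltage=v, fs=fs)


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

def make_morphology(
    n_primary: int = 4,
    branch_prob: float = 0.5,
    mean_seg_len: float = 40.0,
    max_order: int = 5,
    seed: int | np.random.Generator | None = None,
) -> MorphologyTree:
    """Random branched dendritic tree rooted at a soma node.

    Each primary dendrite grows straight segments of length
    ~U(0.5, 1.5)·``mean_seg_len`` µm; at the end of a segment the branch
    bifurcates with probability ``branch_prob`` while its centrifugal
    order is below ``max_order``, otherwise it terminates.
    """
    if n_primary < 1:
        raise ValueError("n_primary must be >= 1")
    if not 0 <= branch_prob <= 1:
        raise ValueError("branch_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [1]
    types = [1]
    xyz = [np.zeros(3)]
    radius = [6.0]
    parent = [-1]
    next_id = 2

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    def grow(parent_id: int, origin: np.ndarray, direction: np.ndarray, order: int):
        nonlocal next_id
        length = mean_seg_len * rng.uniform(0.5, 1.5)
        end = origin + direction * length
        nid = next_id
        next_id += 1
        ids.append(nid)
        types.append(3)
        xyz.append(end)
        radius.append(0.5)
        parent.append(parent_id)
        if order < max_order and rng.random() < branch_prob:
            for _ in range(2):
                d = unit(direction + rng.normal(0, 0.6, size=3))
                grow(nid, end, d, order + 1)

    for _ in range(n_primary):
        d = unit(rng.normal(size=3))
        grow(1, np.zeros(3), d, 1)

    return MorphologyTree(
        ids=np.array(ids),
        types=np.array(types),
        xyz=np.array(xyz),
        radius=np.array(radius),
        parent=np.array(parent),
    )
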
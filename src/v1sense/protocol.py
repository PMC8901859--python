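"""Visual stimulation protocols.

A protocol is the timetable of stimulus presentations in one imaging
session: which spot was shown (S1..S4, identified by angular diameter),
when it came on, for how long, and how long the black screen between
presentations lasted.  The default follows the two-stimulus paradigm used
throughout this package: five repeats each of a small (S1, 10.2 deg) and a
large (S4, 70.8 deg) white spot in randomized order, 2 s on, 20 s
inter-stimulus interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

#: Angular diameters (degrees of visual field) of the four stimulus spots,
#: smallest (weakest) first.
DEFAULT_PHI_DEG = {"S1": 10.2, "S2": 20.2, "S3": 39.1, "S4": 70.8}


@dataclass
class StimulusProtocol:
    """Timetable of stimulus presentations.

    Parameters
    ----------
    onsets
        Stimulus onset times in seconds, strictly increasing.
    labels
        Stimulus identity for each onset (e.g. ``"S1"``).
    duration
        Presentation duration in seconds (default 2 s).
    isi
        Inter-stimulus interval (black screen) in seconds (default 20 s).
    phi_deg
        Angular diameter of each stimulus label, metadata only.
    """

    onsets: np.ndarray
    labels: tuple[str, ...]
    duration: float = 2.0
    isi: float = 20.0
    phi_deg: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PHI_DEG))

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.labels = tuple(self.labels)
        if self.onsets.ndim != 1 or len(self.labels) != len(self.onsets):
            raise ValueError("onsets and labels must be 1-D and equally long")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if len(self.onsets) > 1:
            gaps = np.diff(self.onsets)
            if np.any(gaps <= 0):
                raise ValueError("onsets must be strictly increasing")
            if np.any(gaps < self.duration):
                raise ValueError("onsets closer than the stimulus duration")

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    @property
    def stimulus_labels(self) -> tuple[str, ...]:
        """Distinct labels, in first-appearance order."""
        return tuple(dict.fromkeys(self.labels))

    @property
    def span(self) -> float:
        """Time from 0 to the end of the trailing inter-stimulus interval."""
        if self.n_trials == 0:
            return 0.0
        return float(self.onsets[-1] + self.duration + self.isi)

    def trials(self, label: str) -> np.ndarray:
        """Onset times of all presentations of ``label``."""
        mask = np.array([lab == label for lab in self.labels])
        return self.onsets[mask]

    def repeats(self, label: str) -> int:
        return int(np.sum([lab == label for lab in self.labels]))

    @classmethod
    def generate(
        cls,
        repeats: int = 5,
        labels: tuple[str, ...] = ("S1", "S4"),
        duration: float = 2.0,
        isi: float = 20.0,
        lead_in: float = 5.0,
        order: str = "random",
        seed: int | np.random.Generator | None = None,
    ) -> "StimulusProtocol":
        """Build a protocol with ``repeats`` presentations of each label.

        ``order="random"`` shuffles the presentation sequence (the default
        paradigm); ``order="blocked"`` keeps each stimulus in one block.
        ``lead_in`` seconds of black screen precede the first onset so that
        baseline windows are available.
        """
        seq = [lab for lab in labels for _ in range(repeats)]
        if order == "random":
            rng = np.random.default_rng(seed)
            rng.shuffle(seq)
        elif order != "blocked":
            raise ValueError(f"unknown order {order!r}")
        onsets = lead_in + np.arange(len(seq)) * (duration + isi)
        return cls(onsets=onsets, labels=tuple(seq), duration=duration, isi=isi)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "onsets": [float(t) for t in self.onsets],
            "labels": list(self.labels),
            "duration": float(self.duration),
            "isi": float(self.isi),
            "phi_deg": {k: float(v) for k, v in self.phi_deg.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            onsets=np.asarray(d["onsets"], dtype=float),
            labels=tuple(d["labels"]),
            duration=float(d.get("duration", 2.0)),
            isi=float(d.get("isi", 20.0)),
            phi_deg=dict(d.get("phi_deg", DEFAULT_PHI_DEG)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StimulusProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
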
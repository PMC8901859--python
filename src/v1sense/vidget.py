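"""Visually induced fidget ("vidget") scoring from piezo voltage.

A piezoelectric sensor under the forepaws of a head-fixed mouse reports
limb movement as a voltage trace sampled at 1000 Hz.  Three quantities
summarize the stimulus-evoked movement:

* **vidget score** — the voltage is down-sampled to 100 Hz, expressed
  relative to the session-mean baseline F₀ as (F − F₀)/F₀, rectified
  (√(x²) = |x|, eliminating negative values), and averaged over the
  0.5 s following stimulus onset;
* **response delay** — the first post-onset time at which the rectified
  relative signal exceeds a pre-stimulus baseline threshold
  (mean + k·SD) continuously for a sustain interval;
* **cumulative slopes** — the cumulative rectified signal is fit by two
  least-squares lines with the breakpoint fixed at stimulus onset,
  giving a baseline slope k_baseline and a stimulation slope
  k_stimulus (a.u./s); an evoked response shows up as
  k_stimulus > k_baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import StimulusProtocol
from .synthgen import PiezoRecording


@dataclass
class VidgetResult:
    """Per-trial vidget summaries, aligned with ``protocol.onsets``."""

    scores: np.ndarray  # one per stimulus presentation, a.u.
    delays: np.ndarray | None = None  # s; NaN where no threshold crossing
    k_baseline: float = float("nan")  # a.u./s
    k_stimulus: float = float("nan")  # a.u./s

    def score_by_label(self, protocol: StimulusProtocol) -> dict[str, float]:
        labels = np.asarray(protocol.labels)
        return {
            lab: float(self.scores[labels == lab].mean())
            for lab in protocol.stimulus_labels
        }


def _relative_rectified(piezo: PiezoRecording, fs_out: float = 100.0):
    """Down-sample by block means, normalize to session mean, rectify."""
    step = piezo.fs / fs_out
    if abs(step - round(step)) > 1e-9 or step < 1:
        raise ValueError(
            f"cannot down-sample {piezo.fs} Hz to {fs_out} Hz by block means"
        )
    step = int(round(step))
    v = piezo.voltage
    n = (v.size // step) * step
    down = v[:n].reshape(-1, step).mean(axis=1)
    f0 = piezo.F0
    if f0 == 0:
        raise ValueError("session-mean baseline is zero; relative signal undefined")
    rel = (down - f0) / f0
    return np.abs(rel), fs_out


def vidget_score(
    piezo: PiezoRecording,
    protocol: StimulusProtocol,
    window_s: float = 0.5,
    fs_out: float = 100.0,
    mode: str = "rectify",
) -> np.ndarray:
    """Average rectified relative signal over ``window_s`` after each onset.

    ``mode="rectify"`` (default) averages |x| over the window;
    ``mode="rms"`` returns the window root-mean-square instead.
    Raises if any onset leaves less than ``window_s`` of signal.
    """
    x, fs = _relative_rectified(piezo, fs_out)
    n_win = int(round(window_s * fs))
    scores = np.empty(protocol.n_trials)
    for j, onset in enumerate(protocol.onsets):
        lo = int(round(onset * fs))
        hi = lo + n_win
        if hi > x.size:
            raise ValueError(
                f"onset at {onset} s leaves less than {window_s} s of signal"
            )
        w = x[lo:hi]
        scores[j] = np.sqrt(np.mean(w**2)) if mode == "rms" else np.mean(w)
    return scores


def vidget_delay(
    piezo: PiezoRecording,
    protocol: StimulusProtocol,
    k_sd: float = 3.0,
    sustain_s: float = 0.05,
    baseline_s: float = 2.0,
    fs_out: float = 100.0,
) -> np.ndarray:
    """Threshold-crossing response delay per trial (s); NaN if no crossing.

    The threshold is baseline mean + ``k_sd`` × baseline SD, estimated
    on the ``baseline_s`` seconds of rectified relative signal before
    onset; the crossing must be sustained for ``sustain_s``.
    """
    x, fs = _relative_rectified(piezo, fs_out)
    n_sustain = max(1, int(round(sustain_s * fs)))
    delays = np.full(protocol.n_trials, np.nan)
    for j, onset in enumerate(protocol.onsets):
        i_on = int(round(onset * fs))
        i_base = int(round((onset - baseline_s) * fs))
        if i_base < 0:
            raise ValueError(f"less than {baseline_s} s of baseline before onset {onset}")
        base = x[i_base:i_on]
        thr = base.mean() + k_sd * base.std()
        i_end = min(x.size, int(round((onset + protocol.duration + protocol.isi) * fs)))
        above = x[i_on:i_end] > thr
        run = 0
        for k, flag in enumerate(above):
            run = run + 1 if flag else 0
            if run >= n_sustain:
                delays[j] = (k - n_sustain + 1) / fs
                break
    return delays


def cumulative_magnitude(
    piezo: PiezoRecording,
    fs_out: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Times and cumulative integral of the rectified relative signal.

    The cumulative sum is scaled by the sample interval so slopes are in
    a.u./s; it is nondecreasing because the integrand is rectified.
    """
    x, fs = _relative_rectified(piezo, fs_out)
    t = np.arange(x.size) / fs
    return t, np.cumsum(x) / fs


def cumulative_fit(
    piezo: PiezoRecording,
    protocol: StimulusProtocol,
    pre_s: float = 2.0,
    post_s: float | None = None,
    fs_out: float = 100.0,
) -> tuple[float, float]:
    """Piecewise-linear slopes of the cumulative vidget magnitude.

    For each trial the cumulative magnitude over
    [onset − ``pre_s``, onset + ``post_s``] (``post_s`` defaults to the
    stimulus duration) is fit by two ordinary-least-squares lines with
    the breakpoint fixed at stimulus onset.  Returns the across-trial
    mean (k_baseline, k_stimulus) in a.u./s.
    """
    post_s = protocol.duration if post_s is None else post_s
    t, cum = cumulative_magnitude(piezo, fs_out)
    fs = fs_out
    kb, ks = [], []
    for onset in protocol.onsets:
        i0 = int(round((onset - pre_s) * fs))
        i1 = int(round(onset * fs))
        i2 = int(round((onset + post_s) * fs))
        if i0 < 0 or i2 > t.size:
            raise ValueError(f"window around onset {onset} s exceeds the recording")
        if i1 - i0 < 3 or i2 - i1 < 3:
            raise ValueError("degenerate fit: fewer than 3 points in a segment")
        kb.append(np.polyfit(t[i0:i1], cum[i0:i1], 1)[0])
        ks.append(np.polyfit(t[i1:i2], cum[i1:i2], 1)[0])
    return float(np.mean(kb)), float(np.mean(ks))


def analyze_vidget(
    piezo: PiezoRecording,
    protocol: StimulusProtocol,
    window_s: float = 0.5,
    k_sd: float = 3.0,
    sustain_s: float = 0.05,
) -> VidgetResult:
    """Score, delay and cumulative slopes in one pass."""
    scores = vidget_score(piezo, protocol, window_s=window_s)
    delays = vidget_delay(piezo, protocol, k_sd=k_sd, sustain_s=sustain_s)
    k_baseline, k_stimulus = cumulative_fit(piezo, protocol)
    return VidgetResult(
        scores=scores, delays=delays, k_baseline=k_baseline, k_stimulus=k_stimulus
    )
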
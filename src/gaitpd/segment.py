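"""Walking-span detection and step segmentation from vertical acceleration.

A heel strike shows up as a sharp negative trough in the vertical (x)
acceleration channel and the following toe off as a positive peak.  The
walking span is located by thresholding a wavelet detail envelope of acc_x
(the step band, a few Hz, carries essentially no energy while standing);
steps are then detected as alternating below-threshold troughs and
above-threshold peaks, each cycle yielding the trough-to-peak time A_i and
peak-to-next-trough time B_i.  All steps of a recording are cut to one fixed
window of W = round(fs * (mean A + mean B)) samples anchored at the heel
strike, so that every step of the recording has identical length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pywt
from scipy.signal import find_peaks

from .preprocess import UniformRecording

logger = logging.getLogger(__name__)


class NoWalkingError(ValueError):
    """No sample of the activity envelope exceeds the walking threshold."""


class TooFewStepsError(ValueError):
    """Fewer than two troughs (heel strikes) were detected."""


@dataclass
class StepCycleTiming:
    """Timing of one step cycle: heel-strike trough and following toe-off peak.

    ``A_i`` is the trough-to-peak duration, ``B_i`` the peak-to-next-trough
    duration, both in seconds.
    """

    heel_strike_idx: int
    toe_off_idx: int
    A_i: float
    B_i: float

    def __post_init__(self) -> None:
        if not (self.heel_strike_idx < self.toe_off_idx):
            raise ValueError("heel strike must precede toe off")
        if self.A_i <= 0 or self.B_i <= 0:
            raise ValueError("A_i and B_i must be positive")


@dataclass
class StepSegment:
    """Fixed-length 6-channel window for one detected step."""

    channels: np.ndarray  # (W, 6)
    timing: StepCycleTiming
    fs: float
    subject_id: str = "unknown"
    group: str = "unknown"
    recording_id: str = "rec0"
    step_index: int = 0

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[1] != 6:
            raise ValueError("channels must be (W, 6)")

    @property
    def window_length(self) -> int:
        return self.channels.shape[0]


def _wavelet_envelope(x: np.ndarray, fs: float, wavelet: str = "db4",
                      levels: Sequence[int] = (3, 4, 5),
                      smooth_s: float = 0.2) -> np.ndarray:
    """RMS-combined stationary-wavelet detail envelope of ``x``.

    With fs = 100 Hz the detail bands of levels 3–5 span roughly 1.5–12.5 Hz,
    covering step-rate harmonics and the heel-strike transients while
    excluding most wideband sensor noise.
    """
    max_level = max(levels)
    n = x.size
    pad = (-n) % (2 ** max_level)
    xp = np.pad(x, (0, pad), mode="edge")
    coeffs = pywt.swt(xp, wavelet, level=max_level, trim_approx=True, norm=False)
    # coeffs = [approx, detail_maxlevel, ..., detail_1]
    details = {max_level - i + 1: coeffs[i] for i in range(1, len(coeffs))}
    sq = np.zeros_like(xp)
    for lev in levels:
        sq += details[lev] ** 2
    env = np.sqrt(sq[:n])
    w = max(int(smooth_s * fs), 1)
    kernel = np.ones(w) / w
    return np.convolve(env, kernel, mode="same")


def detect_activity_span(rec: UniformRecording, wavelet: str = "db4",
                         levels: Sequence[int] = (3, 4, 5),
                         floor_g: float = 0.12,
                         rel_thresh: float = 0.25,
                         max_gap_s: float = 0.7) -> Tuple[int, int]:
    """Locate the contiguous walking span of a uniform, filtered recording.

    The wavelet detail envelope of the vertical acceleration is thresholded
    at ``max(floor_g, rel_thresh * envelope.max())``; supra-threshold runs
    separated by gaps shorter than ``max_gap_s`` are merged and the longest
    run wins.  Edges are then refined with a short-window (0.11 s) running
    SD of acc_x so the reported span hugs the actual movement rather than
    the envelope's spread.

    Returns a half-open index span ``(start, end)``.

    Raises
    ------
    NoWalkingError
        If no envelope sample exceeds the threshold (standing-only recording).
    """
    x = rec.channel("acc_x")
    x = x - np.median(x)
    env = _wavelet_envelope(x, rec.fs, wavelet=wavelet, levels=levels)
    thresh = max(floor_g, rel_thresh * float(env.max()))
    active = env >= thresh
    if not active.any():
        raise NoWalkingError(
            f"no walking detected (envelope max {env.max():.3f} g < threshold {thresh:.3f} g)")

    # merge runs separated by short gaps, keep the longest
    idx = np.flatnonzero(active)
    gaps = np.diff(idx)
    breaks = np.flatnonzero(gaps > max_gap_s * rec.fs)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]] + 1
    longest = int(np.argmax(ends - starts))
    i0, i1 = int(starts[longest]), int(ends[longest])

    # edge refinement on the raw short-window SD
    w = max(int(0.11 * rec.fs), 2)
    pad = w // 2
    xs = np.pad(x, (pad, pad), mode="edge")
    c1 = np.cumsum(np.r_[0.0, xs])
    c2 = np.cumsum(np.r_[0.0, xs ** 2])
    m = (c1[w:] - c1[:-w]) / w
    mstd = np.sqrt(np.maximum((c2[w:] - c2[:-w]) / w - m ** 2, 0.0))[: x.size]
    noise = float(np.percentile(mstd, 10))
    walk_level = float(np.percentile(mstd[i0:i1], 90))
    thr2 = max(4.0 * noise, 0.10 * walk_level)
    lo = max(i0 - int(rec.fs), 0)
    hi = min(i1 + int(rec.fs), x.size)
    above = np.flatnonzero(mstd[lo:hi] >= thr2)
    if above.size:
        i0, i1 = lo + int(above[0]), lo + int(above[-1]) + 1
    return i0, i1


def detect_events(acc_x: np.ndarray, fs: float,
                  pos_thresh: Optional[float] = None,
                  neg_thresh: Optional[float] = None,
                  refractory_s: float = 0.3) -> List[StepCycleTiming]:
    """Detect step cycles as alternating troughs (heel strikes) and peaks
    (toe offs) of the vertical acceleration.

    Peaks are local maxima above ``pos_thresh`` and troughs local minima
    below ``neg_thresh``, both relative to the signal mean; defaults are
    +/- 0.5 SD of the (demeaned) signal, which adapts to between-subject
    amplitude differences.  Consecutive same-sign extrema keep only the more
    extreme one, and a cycle is formed by each trough, the following peak,
    and the next trough (A_i = trough->peak, B_i = peak->next trough).  A
    final trough with no subsequent peak (the stopping contact) closes the
    last cycle but starts none.

    Raises
    ------
    TooFewStepsError
        If fewer than two troughs are found or no complete cycle exists.
    """
    x = np.asarray(acc_x, dtype=float)
    x = x - x.mean()
    sd = x.std()
    if pos_thresh is None:
        pos_thresh = 0.5 * sd
    if neg_thresh is None:
        neg_thresh = -0.5 * sd
    if not (neg_thresh < 0 < pos_thresh):
        raise ValueError("need neg_thresh < 0 < pos_thresh")

    dist = max(int(refractory_s * fs), 1)
    troughs, _ = find_peaks(-x, height=-neg_thresh, distance=dist)
    peaks, _ = find_peaks(x, height=pos_thresh, distance=max(dist // 2, 1))
    if troughs.size < 2:
        raise TooFewStepsError(f"only {troughs.size} trough(s) detected")

    # interleave and resolve same-type neighbours by keeping the more extreme
    events = sorted([(int(i), -1) for i in troughs] + [(int(i), +1) for i in peaks])
    cleaned: List[Tuple[int, int]] = []
    for i, typ in events:
        if cleaned and cleaned[-1][1] == typ:
            prev_i = cleaned[-1][0]
            better = i if typ * x[i] > typ * x[prev_i] else prev_i
            cleaned[-1] = (better, typ)
        else:
            cleaned.append((i, typ))

    timings: List[StepCycleTiming] = []
    for k in range(len(cleaned) - 2):
        (i_tr, t_tr), (i_pk, t_pk), (i_next, t_next) = cleaned[k:k + 3]
        if (t_tr, t_pk, t_next) == (-1, +1, -1):
            timings.append(StepCycleTiming(
                heel_strike_idx=i_tr, toe_off_idx=i_pk,
                A_i=(i_pk - i_tr) / fs, B_i=(i_next - i_pk) / fs))
    if not timings:
        raise TooFewStepsError("no complete trough-peak-trough cycle detected")
    return timings


def cut_steps(rec: UniformRecording, timings: Sequence[StepCycleTiming],
              window_length: Optional[int] = None) -> List[StepSegment]:
    """Cut fixed windows, one per detected step, from all six channels.

    The window length is ``W = round(fs * (mean A_i + mean B_i))`` unless
    ``window_length`` overrides it (e.g. to impose one cohort-global W).
    Windows start at the heel-strike trough; steps whose window would run
    past the end of the recording are dropped (and logged).
    """
    if len(timings) < 2:
        raise TooFewStepsError("need at least 2 step timings")
    if window_length is None:
        mean_a = float(np.mean([tm.A_i for tm in timings]))
        mean_b = float(np.mean([tm.B_i for tm in timings]))
        window_length = int(round(rec.fs * (mean_a + mean_b)))
    if window_length < 10:
        raise ValueError(f"degenerate step window of {window_length} samples")

    segments: List[StepSegment] = []
    n = rec.n_samples
    dropped = 0
    for k, tm in enumerate(timings):
        start = tm.heel_strike_idx
        if start + window_length > n:
            dropped += 1
            continue
        segments.append(StepSegment(
            channels=rec.channels[start:start + window_length],
            timing=tm, fs=rec.fs,
            subject_id=rec.subject_id, group=rec.group,
            recording_id=rec.recording_id, step_index=k))
    if dropped:
        logger.info("cut_steps: dropped %d step(s) overrunning recording %s",
                    dropped, rec.recording_id)
    return segments


def segment_recording(rec: UniformRecording,
                      pos_k: float = 0.5, neg_k: float = 0.5,
                      window_length: Optional[int] = None) -> List[StepSegment]:
    """Full segmentation chain: activity span -> event detection -> windows.

    Thresholds are ``+pos_k`` / ``-neg_k`` times the SD of the vertical
    acceleration over the detected activity span.  Returned heel-strike
    indices are in whole-recording coordinates.
    """
    i0, i1 = detect_activity_span(rec)
    x = rec.channel("acc_x")[i0:i1]
    sd = (x - x.mean()).std()
    timings = detect_events(x, rec.fs, pos_thresh=pos_k * sd, neg_thresh=-neg_k * sd)
    shifted = [StepCycleTiming(tm.heel_strike_idx + i0, tm.toe_off_idx + i0,
                               tm.A_i, tm.B_i) for tm in timings]
    return cut_steps(rec, shifted, window_length=window_length)
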
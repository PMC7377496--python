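"""Measurement utilities for validating the pipeline on simulated data.

These helpers quantify how well the chain recovers known ground truth:
heel-strike recall/precision against the generator's event times, walking
span coverage, and the empirical frequency response of the low-pass filter.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional

import numpy as np

from . import synthetic
from .preprocess import UniformRecording, preprocess
from .segment import (NoWalkingError, TooFewStepsError, detect_activity_span,
                      segment_recording)
from .synthetic import GaitProfile


def segmentation_fidelity_metrics(seed: int, n_recordings: int = 50,
                                  profile: Optional[GaitProfile] = None,
                                  n_steps: int = 20,
                                  tol_s: float = 0.050) -> Dict[str, float]:
    """Heel-strike recall/precision (within ``tol_s``) and span accuracy
    pooled over ``n_recordings`` simulated walks."""
    profile = profile or synthetic.control_profile()
    seeds = [int(s) for s in
             np.random.SeedSequence(seed).generate_state(n_recordings) % (2 ** 31)]
    n_true = n_det = n_match = 0
    coverages, idle_fracs = [], []
    for s in seeds:
        sim = synthetic.simulate_recording(profile, n_steps=n_steps, seed=s)
        uni = preprocess(sim.recording)
        i0, i1 = detect_activity_span(uni)
        det_lo, det_hi = uni.t0 + i0 / uni.fs, uni.t0 + i1 / uni.fs
        lo, hi = sim.active_span
        walk = hi - lo
        coverages.append(max(0.0, min(det_hi, hi) - max(det_lo, lo)) / walk)
        idle_total = uni.n_samples / uni.fs - walk
        idle_fracs.append((max(0.0, lo - det_lo) + max(0.0, det_hi - hi)) / idle_total)
        try:
            steps = segment_recording(uni)
        except (NoWalkingError, TooFewStepsError):
            steps = []
        det = uni.t0 + np.array([st.timing.heel_strike_idx for st in steps]) / uni.fs
        n_true += sim.n_steps
        n_det += len(det)
        used = np.zeros(len(det), bool)
        for hs in sim.true_heel_strikes:
            if det.size == 0:
                break
            d = np.abs(det - hs)
            d[used] = np.inf
            j = int(np.argmin(d))
            if d[j] < tol_s:
                used[j] = True
                n_match += 1
    return dict(recall=n_match / n_true,
                precision=n_match / n_det if n_det else 0.0,
                coverage=float(np.mean(coverages)),
                idle_fraction=float(np.mean(idle_fracs)),
                n_true=n_true, n_detected=n_det, n_recordings=n_recordings)


def filter_gains(freqs: Iterable[float] = (5.0, 40.0), fs: float = 100.0,
                 cutoff: float = 20.0, order: int = 4,
                 duration_s: float = 10.0) -> Dict[float, float]:
    """Measured amplitude gain of the zero-phase low-pass on pure sinusoids
    (RMS ratio over the central 60% of the recording)."""
    from .preprocess import lowpass_filter
    out = {}
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    mid = slice(int(0.2 * n), int(0.8 * n))
    for f in freqs:
        chans = np.zeros((n, 6))
        chans[:, 0] = np.sin(2 * np.pi * f * t)
        filt = lowpass_filter(UniformRecording(fs=fs, channels=chans),
                              cutoff=cutoff, order=order)
        out[float(f)] = float(np.sqrt(np.mean(filt.channels[mid, 0] ** 2) /
                                      np.mean(chans[mid, 0] ** 2)))
    return out
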
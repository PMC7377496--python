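"""Synthetic waist-worn IMU walking recordings with ground-truth gait events.

The study protocol this generator emulates is a supervised 20-step straight
hallway walk with a smartphone fixed at the waist: the recording starts and
ends with the subject standing still, the vertical acceleration channel shows
one sharp negative trough per heel strike and one positive peak per toe off,
and the sensors sample at a nominal 100 Hz with slight timestamp jitter.

Every recording carries its ground truth (event times, active walking span),
so segmentation recall/precision and end-to-end classification behaviour can
be measured exactly.  Group-level gait differences (cadence, step-time
variability, impact amplitude) are controllable through :class:`GaitProfile`;
the clinical motivation is that parkinsonian gait is slower, more variable
and lower-impact than control gait, but the magnitudes are free parameters
of the simulation, not estimates of any patient population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocess import CHANNEL_NAMES, Recording

GRAVITY_BASELINE_G = 1.0  # vertical accelerometer reads +1 g standing still
_NOMINAL_DT = 0.01        # 100 Hz nominal sampling
_JITTER_S = 0.002         # uniform timestamp jitter, +/- 2 ms
_A_FRACTION = 0.35        # toe-off sits ~35% into the step cycle


@dataclass(frozen=True)
class GaitProfile:
    """Subject-level gait parameters driving the waveform generator.

    Parameters
    ----------
    group : {"PD", "control"}
    cadence_hz : steps per second (step rate, not stride rate).
    step_time_cv : coefficient of variation of step intervals (unitless).
    heel_strike_amp_g : magnitude of the negative heel-strike trough, in g.
    toe_off_amp_g : magnitude of the positive toe-off peak, in g.
    amp_asymmetry : left/right amplitude ratio (1 = symmetric).
    noise_sd_g : additive white sensor noise SD on accelerometer channels, g.
    gyro_scale_dps : amplitude scale of angular-rate oscillation, deg/s.
    """

    group: str
    cadence_hz: float = 1.85
    step_time_cv: float = 0.025
    heel_strike_amp_g: float = 1.1
    toe_off_amp_g: float = 0.75
    amp_asymmetry: float = 1.05
    noise_sd_g: float = 0.04
    gyro_scale_dps: float = 45.0

    def __post_init__(self) -> None:
        if self.group not in ("PD", "control"):
            raise ValueError(f"group must be 'PD' or 'control', got {self.group!r}")
        if self.cadence_hz <= 0:
            raise ValueError("cadence_hz must be > 0")
        if self.step_time_cv < 0:
            raise ValueError("step_time_cv must be >= 0")
        if self.heel_strike_amp_g <= 0 or self.toe_off_amp_g <= 0:
            raise ValueError("amplitudes must be > 0")
        if self.amp_asymmetry <= 0:
            raise ValueError("amp_asymmetry must be > 0")
        if self.noise_sd_g < 0:
            raise ValueError("noise_sd_g must be >= 0")
        if self.gyro_scale_dps <= 0:
            raise ValueError("gyro_scale_dps must be > 0")


def control_profile(**overrides) -> GaitProfile:
    """Default control-group profile (brisk, regular, symmetric gait)."""
    return GaitProfile(group="control", **overrides)


def pd_profile(**overrides) -> GaitProfile:
    """Default parkinsonian profile: slower cadence, higher step-time
    variability, lower impact amplitudes and more asymmetry than control."""
    defaults = dict(
        cadence_hz=1.55,
        step_time_cv=0.09,
        heel_strike_amp_g=0.70,
        toe_off_amp_g=0.48,
        amp_asymmetry=1.18,
        noise_sd_g=0.04,
        gyro_scale_dps=30.0,
    )
    defaults.update(overrides)
    return GaitProfile(group="PD", **defaults)


@dataclass
class SimulatedRecording:
    """A generated recording plus its ground truth."""

    recording: Recording
    true_heel_strikes: np.ndarray  # event times in seconds, one per step
    true_toe_offs: np.ndarray
    n_steps: int
    active_span: Tuple[float, float]  # (start, end) of the walking interval
    profile: GaitProfile

    def __post_init__(self) -> None:
        self.true_heel_strikes = np.asarray(self.true_heel_strikes, dtype=float)
        self.true_toe_offs = np.asarray(self.true_toe_offs, dtype=float)
        if len(self.true_heel_strikes) != self.n_steps:
            raise ValueError("one heel strike per step required")
        if np.any(np.diff(self.true_heel_strikes) <= 0):
            raise ValueError("event times must be strictly increasing")
        lo, hi = self.active_span
        for ev in (self.true_heel_strikes, self.true_toe_offs):
            if ev.size and (ev.min() < lo or ev.max() > hi):
                raise ValueError("events must lie within the active span")


def _gauss_pulses(t: np.ndarray, centers: np.ndarray, amps: np.ndarray,
                  sigma: float) -> np.ndarray:
    """Sum of Gaussian pulses at sorted times t (each truncated at +/-5 sigma)."""
    out = np.zeros_like(t)
    half = 5.0 * sigma
    for c, a in zip(np.atleast_1d(centers), np.atleast_1d(amps)):
        i0 = np.searchsorted(t, c - half)
        i1 = np.searchsorted(t, c + half)
        if i1 > i0:
            out[i0:i1] += a * np.exp(-0.5 * ((t[i0:i1] - c) / sigma) ** 2)
    return out


def _smooth_gate(t: np.ndarray, start: float, end: float, ramp: float = 0.3) -> np.ndarray:
    """0->1->0 window over [start, end] with smooth ~ramp-second edges."""
    up = 0.5 * (1.0 + np.tanh((t - start) / (ramp / 2.0)))
    down = 0.5 * (1.0 + np.tanh((end - t) / (ramp / 2.0)))
    return up * down


def simulate_recording(profile: GaitProfile, n_steps: int = 20, seed: int = 0,
                       subject_id: str = "S000", recording_id: str = "rec0",
                       updrs: Optional[float] = None,
                       rng: Optional[np.random.Generator] = None) -> SimulatedRecording:
    """Generate one 20-step-style walking recording.

    The recording contains 1–3 s of standing at either end, ``n_steps`` full
    step cycles (heel-strike trough followed by toe-off peak in the vertical
    acceleration), and one terminal foot contact when the subject stops
    (a final trough that begins no new cycle).  Timestamps are a 100 Hz grid
    perturbed by uniform +/-2 ms jitter.  Deterministic given ``seed``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    mean_step = 1.0 / profile.cadence_hz
    idle_head = rng.uniform(1.0, 3.0)
    idle_tail = rng.uniform(1.0, 3.0)

    # Step intervals with configurable coefficient of variation.
    intervals = rng.normal(mean_step, profile.step_time_cv * mean_step, size=n_steps)
    intervals = np.clip(intervals, 0.4 * mean_step, 1.8 * mean_step)

    walk_start = idle_head
    first_hs = walk_start + 0.6 * mean_step
    heel_strikes = first_hs + np.concatenate([[0.0], np.cumsum(intervals[:-1])])
    terminal_contact = heel_strikes[-1] + intervals[-1]  # stopping foot placement
    toe_offs = heel_strikes + _A_FRACTION * intervals * rng.uniform(0.92, 1.08, size=n_steps)
    walk_end = terminal_contact + 0.5 * mean_step
    duration = walk_end + idle_tail

    n_nominal = int(np.ceil(duration / _NOMINAL_DT)) + 1
    t = np.arange(n_nominal) * _NOMINAL_DT
    t = t + rng.uniform(-_JITTER_S, _JITTER_S, size=n_nominal)
    t[0] = max(t[0], 0.0)
    t = np.sort(t)  # jitter < half grid keeps order; sort guards the edge case
    t, keep_idx = np.unique(t, return_index=True)

    # Per-step amplitude scaling: left/right asymmetry alternates, plus a
    # small random step-to-step modulation.
    asym = np.sqrt(profile.amp_asymmetry)
    side = np.where(np.arange(n_steps) % 2 == 0, asym, 1.0 / asym)
    mod = 1.0 + 0.06 * rng.standard_normal(n_steps)
    hs_amps = profile.heel_strike_amp_g * side * mod
    to_amps = profile.toe_off_amp_g * side * (1.0 + 0.06 * rng.standard_normal(n_steps))

    # the walking interval reported as ground truth runs between the
    # half-amplitude points of the activity gate
    gate_lo, gate_hi = walk_start + 0.1, walk_end - 0.1
    gate = _smooth_gate(t, gate_lo, gate_hi)
    f_step = profile.cadence_hz
    f_stride = f_step / 2.0
    phase = rng.uniform(0, 2 * np.pi, size=6)

    # Vertical channel: gravity baseline, sharp negative heel-strike troughs,
    # broader positive toe-off peaks, terminal contact, and gait harmonics.
    acc_x = np.full(t.size, GRAVITY_BASELINE_G)
    acc_x -= _gauss_pulses(t, heel_strikes, hs_amps, sigma=0.020)
    acc_x -= _gauss_pulses(t, np.array([terminal_contact]),
                           np.array([0.8 * profile.heel_strike_amp_g]), sigma=0.022)
    acc_x += _gauss_pulses(t, toe_offs, to_amps, sigma=0.035)
    acc_x += gate * (
        0.12 * profile.heel_strike_amp_g * np.sin(2 * np.pi * f_step * t + phase[0])
        + 0.06 * profile.heel_strike_amp_g * np.sin(2 * np.pi * 2 * f_step * t + phase[1])
    )

    # Mediolateral sway at stride frequency plus attenuated impact transients.
    acc_y = gate * 0.30 * profile.heel_strike_amp_g * np.sin(2 * np.pi * f_stride * t + phase[2])
    acc_y += 0.18 * _gauss_pulses(t, heel_strikes, hs_amps * np.where(side > 1, 1, -1), sigma=0.025)

    # Anterior-posterior: propulsion oscillation at step frequency + toe-off echo.
    acc_z = gate * 0.25 * profile.heel_strike_amp_g * np.sin(2 * np.pi * f_step * t + phase[3])
    acc_z += 0.30 * _gauss_pulses(t, toe_offs, to_amps, sigma=0.030)

    g = profile.gyro_scale_dps
    gyr_x = gate * g * np.sin(2 * np.pi * f_stride * t + phase[4])          # yaw sway
    gyr_y = gate * 0.6 * g * np.sin(2 * np.pi * f_step * t + phase[5])      # pitch
    gyr_z = gate * 0.4 * g * np.sin(2 * np.pi * f_stride * t + phase[2] + 0.7)
    gyr_x += 6.0 * _gauss_pulses(t, heel_strikes, np.where(side > 1, 1.0, -1.0) * np.ones(n_steps), sigma=0.03)

    chans = np.column_stack([acc_x, acc_y, acc_z, gyr_x, gyr_y, gyr_z])
    noise = rng.standard_normal(chans.shape)
    noise[:, :3] *= profile.noise_sd_g
    noise[:, 3:] *= profile.noise_sd_g * 25.0  # gyro noise floor, deg/s
    chans = chans + noise

    rec = Recording(t=t, channels=chans, subject_id=subject_id,
                    group=profile.group, updrs=updrs, recording_id=recording_id)
    return SimulatedRecording(
        recording=rec,
        true_heel_strikes=heel_strikes,
        true_toe_offs=toe_offs,
        n_steps=n_steps,
        active_span=(gate_lo, gate_hi),
        profile=profile,
    )


def simulate_idle_recording(profile: GaitProfile, duration: float = 10.0,
                            seed: int = 0) -> Recording:
    """A standing-only recording: gravity baseline plus sensor noise."""
    rng = np.random.default_rng(seed)
    n = int(duration / _NOMINAL_DT)
    t = np.sort(np.arange(n) * _NOMINAL_DT + rng.uniform(-_JITTER_S, _JITTER_S, n))
    t = np.unique(t)
    chans = np.zeros((t.size, 6))
    chans[:, 0] = GRAVITY_BASELINE_G
    chans[:, :3] += rng.standard_normal((t.size, 3)) * profile.noise_sd_g
    chans[:, 3:] += rng.standard_normal((t.size, 3)) * profile.noise_sd_g * 25.0
    return Recording(t=t, channels=chans, group=profile.group)


@dataclass(frozen=True)
class ProfileDistribution:
    """Between-subject distribution of gait profiles for one group.

    Each subject's numeric parameters are the group means multiplied by
    independent ``1 + rel_sd * N(0,1)`` factors (clipped at +/-2.5 SD),
    giving mild, realistic between-subject variability.
    """

    mean: GaitProfile
    rel_sd: float = 0.05

    def sample(self, rng: np.random.Generator) -> GaitProfile:
        def jitter(v: float, lo: float = 1e-6) -> float:
            f = 1.0 + self.rel_sd * float(np.clip(rng.standard_normal(), -2.5, 2.5))
            return max(v * f, lo)

        m = self.mean
        return GaitProfile(
            group=m.group,
            cadence_hz=jitter(m.cadence_hz),
            step_time_cv=jitter(m.step_time_cv),
            heel_strike_amp_g=jitter(m.heel_strike_amp_g),
            toe_off_amp_g=jitter(m.toe_off_amp_g),
            amp_asymmetry=jitter(m.amp_asymmetry),
            noise_sd_g=m.noise_sd_g,
            gyro_scale_dps=jitter(m.gyro_scale_dps),
        )


def default_profiles() -> Tuple[ProfileDistribution, ProfileDistribution]:
    """(control, PD) profile distributions at their default group effects."""
    return (ProfileDistribution(control_profile()),
            ProfileDistribution(pd_profile()))


def null_profiles() -> Tuple[ProfileDistribution, ProfileDistribution]:
    """Zero-effect pair: the PD group walks exactly like controls.

    Only the group label differs, so any downstream classification accuracy
    above chance would indicate leakage or bias.
    """
    ctrl = control_profile()
    sham = GaitProfile(group="PD", cadence_hz=ctrl.cadence_hz,
                       step_time_cv=ctrl.step_time_cv,
                       heel_strike_amp_g=ctrl.heel_strike_amp_g,
                       toe_off_amp_g=ctrl.toe_off_amp_g,
                       amp_asymmetry=ctrl.amp_asymmetry,
                       noise_sd_g=ctrl.noise_sd_g,
                       gyro_scale_dps=ctrl.gyro_scale_dps)
    return (ProfileDistribution(ctrl), ProfileDistribution(sham))


def simulate_cohort(n_per_group: int = 29,
                    profiles: Optional[Tuple[ProfileDistribution, ProfileDistribution]] = None,
                    recordings_per_subject: int = 2,
                    seed: int = 0,
                    steps_range: Tuple[int, int] = (19, 20),
                    p_missing_recording: float = 0.15,
                    ) -> Tuple[List[SimulatedRecording], pd.DataFrame]:
    """Simulate a balanced case-control walking-test cohort.

    Each of ``2 * n_per_group`` subjects gets a profile drawn from their
    group's :class:`ProfileDistribution` and up to ``recordings_per_subject``
    recordings of ``steps_range`` steps each (recordings beyond the first may
    be missing with probability ``p_missing_recording``, mimicking failed
    recordings in a clinical protocol).

    Returns the recordings and a per-subject metadata table.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if profiles is None:
        profiles = (ProfileDistribution(control_profile()),
                    ProfileDistribution(pd_profile()))
    ctrl_dist, pd_dist = profiles
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    recordings: List[SimulatedRecording] = []
    meta_rows = []
    sid = 0
    for dist in (ctrl_dist, pd_dist):
        for _ in range(n_per_group):
            subject_id = f"S{sid:03d}"
            prof = dist.sample(rng)
            n_recs = 1 + sum(rng.random() >= p_missing_recording
                             for _ in range(recordings_per_subject - 1))
            total_steps = 0
            for r in range(n_recs):
                n_steps = int(rng.integers(steps_range[0], steps_range[1] + 1))
                sim = simulate_recording(
                    prof, n_steps=n_steps,
                    subject_id=subject_id, recording_id=f"{subject_id}_r{r}",
                    rng=rng,
                )
                recordings.append(sim)
                total_steps += n_steps
            meta_rows.append(dict(subject_id=subject_id, group=prof.group,
                                  n_recordings=n_recs, n_true_steps=total_steps,
                                  cadence_hz=prof.cadence_hz,
                                  step_time_cv=prof.step_time_cv))
            sid += 1
    meta = pd.DataFrame(meta_rows)
    return recordings, meta


# ---------------------------------------------------------------------------
# plain-text persistence: CSV of samples + JSON sidecar with metadata/truth

def write_recording(sim: SimulatedRecording, csv_path) -> None:
    """Write samples as CSV (t_s + 6 channels) and ground truth as JSON sidecar."""
    csv_path = Path(csv_path)
    rec = sim.recording
    df = pd.DataFrame(rec.channels, columns=list(CHANNEL_NAMES))
    df.insert(0, "t_s", rec.t)
    df.to_csv(csv_path, index=False, float_format="%.6f")
    sidecar = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "updrs": rec.updrs,
        "recording_id": rec.recording_id,
        "true_events": {
            "heel_strikes": sim.true_heel_strikes.tolist(),
            "toe_offs": sim.true_toe_offs.tolist(),
            "active_span": list(sim.active_span),
            "n_steps": sim.n_steps,
        },
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(csv_path) -> Tuple[Recording, Optional[dict]]:
    """Read a recording CSV (+ JSON sidecar if present)."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = {}
    side = csv_path.with_suffix(".json")
    truth = None
    if side.exists():
        payload = json.loads(side.read_text())
        truth = payload.get("true_events")
        meta = {k: payload[k] for k in ("subject_id", "group", "updrs", "recording_id")
                if payload.get(k) is not None}
    rec = Recording(t=df["t_s"].to_numpy(),
                    channels=df[list(CHANNEL_NAMES)].to_numpy(), **meta)
    return rec, truth
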
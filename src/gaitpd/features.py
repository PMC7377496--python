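"""Per-step statistical feature extraction.

Each detected step is summarized by a 201-dimensional vector:

* 24 time- and frequency-domain statistics for each of the 6 raw channels
  (144 features);
* Pearson correlation for all 15 unordered pairs of the 6 channels
  (15 features);
* 21 of the same statistics for the two magnitude channels, the
  accelerometer norm and the gyroscope norm (42 features).  The crossing
  counts and the first/last-sample difference are omitted for magnitude
  channels, where a non-negative signal makes them degenerate or
  edge-noise dominated.

All spectral quantities are computed from the one-sided periodogram of the
raw window with the DC bin excluded; band powers are reported as fractions
of the non-DC power.  The registry is data, not code: it can be filtered,
reordered, serialized to JSON and replaced wholesale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import CHANNEL_NAMES
from .segment import StepSegment

MAGNITUDE_CHANNELS = ("acc_norm", "gyr_norm")

#: statistics computed for every raw channel, in registry order
STAT_NAMES: Tuple[str, ...] = (
    "mean", "median", "std", "var", "min", "max", "range", "rms",
    "iqr", "mad", "skewness", "kurtosis", "energy", "mav",
    "zero_crossings", "mean_crossings", "first_last_diff", "autocorr_lag1",
    "dom_freq", "dom_freq_power", "spectral_entropy", "spectral_centroid",
    "bandpower_0.5_3", "bandpower_3_8",
)

#: statistics omitted for the non-negative magnitude channels
_MAGNITUDE_EXCLUDED = ("zero_crossings", "mean_crossings", "first_last_diff")
MAGNITUDE_STAT_NAMES: Tuple[str, ...] = tuple(
    s for s in STAT_NAMES if s not in _MAGNITUDE_EXCLUDED)


@dataclass(frozen=True)
class FeatureSpec:
    """One registry entry: a statistic of a channel, or a channel-pair correlation."""

    name: str
    kind: str                   # "stat" | "corr"
    channels: Tuple[str, ...]   # 1 channel for "stat", 2 for "corr"
    stat: Optional[str] = None  # statistic identifier for kind == "stat"


@dataclass
class FeatureRegistry:
    """Ordered, named list of per-step features."""

    entries: List[FeatureSpec]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> List[str]:
        return [e.name for e in self.entries]

    def filter(self, kind: str) -> "FeatureRegistry":
        return FeatureRegistry([e for e in self.entries if e.kind == kind])

    def to_json(self, path) -> None:
        payload = [dict(name=e.name, kind=e.kind, channels=list(e.channels),
                        stat=e.stat) for e in self.entries]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "FeatureRegistry":
        payload = json.loads(Path(path).read_text())
        return cls([FeatureSpec(name=d["name"], kind=d["kind"],
                                channels=tuple(d["channels"]), stat=d.get("stat"))
                    for d in payload])


def default_registry() -> FeatureRegistry:
    """The default 201-entry registry: 24 x 6 + 15 + 21 x 2."""
    entries: List[FeatureSpec] = []
    for ch in CHANNEL_NAMES:
        for stat in STAT_NAMES:
            entries.append(FeatureSpec(name=f"{ch}__{stat}", kind="stat",
                                       channels=(ch,), stat=stat))
    for c1, c2 in combinations(CHANNEL_NAMES, 2):
        entries.append(FeatureSpec(name=f"corr__{c1}__{c2}", kind="corr",
                                   channels=(c1, c2)))
    for ch in MAGNITUDE_CHANNELS:
        for stat in MAGNITUDE_STAT_NAMES:
            entries.append(FeatureSpec(name=f"{ch}__{stat}", kind="stat",
                                       channels=(ch,), stat=stat))
    return FeatureRegistry(entries)


# ---------------------------------------------------------------------------
# statistic implementations

def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    # zero-variance inputs yield 0 rather than NaN, keeping the matrix finite
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _periodogram(x: np.ndarray, fs: float) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum with the DC bin removed."""
    n = x.size
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs[1:], spec[1:]


def compute_stat(x: np.ndarray, stat: str, fs: float) -> float:
    """Evaluate one named statistic on a 1-D window."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if stat == "mean":
        return float(x.mean())
    if stat == "median":
        return float(np.median(x))
    if stat == "std":
        return float(x.std(ddof=1))
    if stat == "var":
        return float(x.var(ddof=1))
    if stat == "min":
        return float(x.min())
    if stat == "max":
        return float(x.max())
    if stat == "range":
        return float(x.max() - x.min())
    if stat == "rms":
        return float(np.sqrt(np.mean(x ** 2)))
    if stat == "iqr":
        q75, q25 = np.percentile(x, [75, 25])
        return float(q75 - q25)
    if stat == "mad":
        return float(np.median(np.abs(x - np.median(x))))
    if stat == "skewness":
        return 0.0 if np.ptp(x) == 0 else float(sps.skew(x, bias=True))
    if stat == "kurtosis":
        return 0.0 if np.ptp(x) == 0 else float(sps.kurtosis(x, fisher=True, bias=True))
    if stat == "energy":
        return float(np.sum(x ** 2))
    if stat == "mav":
        return float(np.mean(np.abs(x)))
    if stat == "zero_crossings":
        return float(np.count_nonzero(x[:-1] * x[1:] < 0))
    if stat == "mean_crossings":
        xc = x - x.mean()
        return float(np.count_nonzero(xc[:-1] * xc[1:] < 0))
    if stat == "first_last_diff":
        return float(x[-1] - x[0])
    if stat == "autocorr_lag1":
        return _safe_corr(x[:-1], x[1:])

    freqs, p = _periodogram(x, fs)
    total = p.sum()
    if stat == "dom_freq":
        return 0.0 if total == 0 else float(freqs[int(np.argmax(p))])
    if stat == "dom_freq_power":
        return 0.0 if total == 0 else float(p.max() / total)
    if stat == "spectral_entropy":
        if total == 0:
            return 0.0
        q = p / total
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())
    if stat == "spectral_centroid":
        return 0.0 if total == 0 else float((freqs * p).sum() / total)
    if stat.startswith("bandpower_"):
        lo, hi = (float(v) for v in stat.split("_")[1:3])
        if total == 0:
            return 0.0
        mask = (freqs >= lo) & (freqs < hi)
        return float(p[mask].sum() / total)
    raise KeyError(f"unknown statistic {stat!r}")


def _channel_series(step: StepSegment, name: str) -> np.ndarray:
    if name in CHANNEL_NAMES:
        return step.channels[:, CHANNEL_NAMES.index(name)]
    if name == "acc_norm":
        return np.linalg.norm(step.channels[:, :3], axis=1)
    if name == "gyr_norm":
        return np.linalg.norm(step.channels[:, 3:], axis=1)
    raise KeyError(f"unknown channel {name!r}")


def extract(step: StepSegment, registry: Optional[FeatureRegistry] = None) -> np.ndarray:
    """Compute the feature vector of one step, in registry order."""
    if registry is None:
        registry = default_registry()
    if step.window_length < 4:
        raise ValueError("step window shorter than 4 samples")
    cache: Dict[str, np.ndarray] = {}

    def series(name: str) -> np.ndarray:
        if name not in cache:
            cache[name] = _channel_series(step, name)
        return cache[name]

    out = np.empty(len(registry))
    for i, e in enumerate(registry.entries):
        if e.kind == "stat":
            out[i] = compute_stat(series(e.channels[0]), e.stat, step.fs)
        elif e.kind == "corr":
            out[i] = _safe_corr(series(e.channels[0]), series(e.channels[1]))
        else:
            raise KeyError(f"unknown feature kind {e.kind!r}")
    return out


@dataclass
class FeatureMatrix:
    """steps x features matrix with per-row subject/label/recording metadata."""

    values: np.ndarray
    feature_names: List[str]
    subject_ids: np.ndarray
    labels: np.ndarray          # PD = 1, control = 0
    recording_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        self.recording_ids = np.asarray(self.recording_ids)
        n, p = self.values.shape
        if p != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if not (len(self.subject_ids) == len(self.labels) == len(self.recording_ids) == n):
            raise ValueError("metadata length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    def subset(self, feature_names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(f) for f in feature_names]
        return FeatureMatrix(self.values[:, idx], list(feature_names),
                             self.subject_ids, self.labels, self.recording_ids)

    def rows(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.values[mask], self.feature_names,
                             self.subject_ids[mask], self.labels[mask],
                             self.recording_ids[mask])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "recording_id", self.recording_ids)
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        meta = ["subject_id", "label", "recording_id"]
        feats = [c for c in df.columns if c not in meta]
        return cls(df[feats].to_numpy(float), feats,
                   df["subject_id"].to_numpy(), df["label"].to_numpy(int),
                   df["recording_id"].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path))


_LABELS = {"PD": 1, "control": 0}


def build_matrix(steps: Sequence[StepSegment],
                 registry: Optional[FeatureRegistry] = None) -> FeatureMatrix:
    """Extract features for every step, preserving input order."""
    if len(steps) == 0:
        raise ValueError("no steps to extract features from")
    if registry is None:
        registry = default_registry()
    for s in steps:
        if s.group not in _LABELS:
            raise ValueError(f"step of subject {s.subject_id} has no PD/control label")
    values = np.stack([extract(s, registry) for s in steps])
    return FeatureMatrix(
        values=values,
        feature_names=registry.names,
        subject_ids=np.array([s.subject_id for s in steps]),
        labels=np.array([_LABELS[s.group] for s in steps]),
        recording_ids=np.array([s.recording_id for s in steps]),
    )
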
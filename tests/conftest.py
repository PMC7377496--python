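import numpy as np
import pytest

import gaitpd as g
from gaitpd.features import FeatureMatrix


@pytest.fixture(scope="session")
def small_cohort_fm() -> FeatureMatrix:
    """Feature matrix of a small simulated cohort (8 subjects, full registry)."""
    recs, _ = g.simulate_cohort(n_per_group=4, recordings_per_subject=1, seed=11)
    steps = []
    for sim in recs:
        uni = g.preprocess(sim.recording)
        steps.extend(g.segment_recording(uni))
    return g.build_matrix(steps)


@pytest.fixture(scope="session")
def one_recording():
    """One default-control simulated recording with its preprocessed form."""
    sim = g.simulate_recording(g.control_profile(), n_steps=20, seed=3)
    uni = g.preprocess(sim.recording)
    return sim, uni


def make_separable_fm(n_subjects: int = 8, steps_per_subject: int = 10,
                      n_noise: int = 1, gap: float = 4.0, seed: int = 0) -> FeatureMatrix:
    """Toy matrix: feature 0 carries the label (bounded noise, so a gap > 2
    makes the classes strictly linearly separable), the rest is noise."""
    rng = np.random.default_rng(seed)
    rows, subs, labels = [], [], []
    for s in range(n_subjects):
        label = s % 2
        for _ in range(steps_per_subject):
            x = rng.standard_normal(1 + n_noise)
            x[0] = rng.uniform(-1, 1) + gap * label
            rows.append(x)
            subs.append(f"S{s:02d}")
            labels.append(label)
    subs = np.array(subs)
    return FeatureMatrix(np.array(rows),
                         [f"f{i}" for i in range(1 + n_noise)],
                         subs,
                         np.array(labels),
                         np.char.add(subs, "_r0"))


@pytest.fixture
def separable_fm() -> FeatureMatrix:
    return make_separable_fm()
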
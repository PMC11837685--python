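import numpy as np
import pytest

from swayclass.datasets import CohortDataset


def make_fake_dataset(n_pd=4, n_hc=4, samples_per_subject=6, shape=(12, 12),
                      separation=2.0, noise=0.5, seed=0, band_rows=None,
                      freqs=None):
    """Fabricated labeled image dataset with subject structure.

    PD samples get ``separation`` added either everywhere or only on
    ``band_rows`` (a slice), on top of per-subject offsets and pixel
    noise — enough structure for split/normalization/training tests
    without running the spectrogram pipeline.
    """
    rng = np.random.default_rng(seed)
    xs, ys, subjects = [], [], []
    if freqs is None:
        freqs = 15.0 * 2.0 ** (-np.arange(shape[0]) / max(shape[0] / 7, 1))
    for group, label, count in (("PD", 1, n_pd), ("HC", 0, n_hc)):
        for i in range(count):
            sid = f"{group}{i + 1:02d}"
            subj_off = rng.normal(0, 0.3)
            for _ in range(samples_per_subject):
                img = rng.normal(subj_off, noise, size=shape)
                if label:
                    if band_rows is None:
                        img += separation
                    else:
                        img[band_rows, :] += separation
                xs.append(np.abs(img).astype(np.float32))
                ys.append(label)
                subjects.append(sid)
    return CohortDataset(
        x=np.stack(xs), y=np.array(ys), subjects=np.array(subjects),
        freqs=np.asarray(freqs), parameter="COP", direction="ml",
    )


@pytest.fixture
def fake_dataset():
    return make_fake_dataset()


@pytest.fixture(scope="session")
def complete_study_dataset():
    """18 PD + 15 HC subjects with the full 60 samples each (tiny pixels),
    mirroring a complete recorded cohort's sample bookkeeping."""
    return make_fake_dataset(n_pd=18, n_hc=15, samples_per_subject=60,
                             shape=(8, 8), seed=1)
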
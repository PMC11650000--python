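import numpy as np
import pytest

import alphaslow as al


@pytest.fixture(scope="session")
def small_spec():
    return al.CohortSpec(n_controls=4, n_patients=4, duration=20.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return al.simulate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    recordings, _ = small_cohort
    spectra = [al.relative_power(al.welch_psd(r)) for r in recordings]
    return al.ratio_table(spectra, recordings)


@pytest.fixture()
def sine_recording():
    """68-region recording, every region a unit 10 Hz sinusoid at fs 250."""
    fs, dur = 250.0, 60.0
    t = np.arange(int(fs * dur)) / fs
    data = np.tile(np.sin(2 * np.pi * 10.0 * t), (68, 1))
    from alphaslow.parcellation import default_hemispheres, default_region_labels

    return al.Recording(
        subject_id="sine", group="control", modality="EEG", fs=fs, data=data,
        region_labels=default_region_labels(), hemisphere=default_hemispheres(),
    )
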
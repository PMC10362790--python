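import numpy as np
import pytest

from ppgvitals.synth import GroundTruthMap, SyntheticPatientSpec, generate_record


@pytest.fixture(scope="session")
def noiseless_map() -> GroundTruthMap:
    """Ground-truth map with all label-noise processes switched off."""
    return GroundTruthMap.noiseless()


@pytest.fixture()
def clean_spec() -> SyntheticPatientSpec:
    return SyntheticPatientSpec(patient_id="clean", heart_rate_bpm=60.0, noise_sd=0.0)


@pytest.fixture()
def clean_record(clean_spec, noiseless_map):
    """A noiseless, artifact-free 20-s record at the canonical 125 Hz."""
    return generate_record(clean_spec, duration_s=20.0, fs=125.0, seed=0, gt_map=noiseless_map)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
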
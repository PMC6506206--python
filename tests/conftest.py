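import numpy as np
import pytest

from tcsyn import sta, synthdata


@pytest.fixture(scope="session")
def clean_pair():
    """Moderate-noise connected pair with ground truth (session-cached)."""
    syn = synthdata.GroundTruthSynapse(mean_amp=1.5, amp_cv=0.4, p_fail=0.37)
    rec = synthdata.generate_pair(
        syn,
        rate_hz=8.0,
        duration_s=100.0,
        noise=synthdata.NoiseParams.from_total_sd(0.3),
        seed=11,
    )
    return rec


@pytest.fixture(scope="session")
def clean_pair_rec(clean_pair):
    return sta.PairedRecording.from_synthetic(clean_pair)


@pytest.fixture(scope="session")
def corrected_sta(clean_pair_rec):
    raw = sta.compute_sta(clean_pair_rec)
    jit = sta.compute_jittered_sta(clean_pair_rec, seed=7)
    return raw - jit


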
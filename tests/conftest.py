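import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from riboterm.annotation import TranscriptModel
from riboterm.footprints import DensityTrack
from riboterm.simulate import SimulationParams, simulate_footprints, simulate_transcriptome

# toy transcript used across modules: 5 nt 5'UTR, 18 nt CDS ending in TAA,
# 3'UTR beginning AAA TGA so the next in-frame stop sits 3 nt past the NTC
TOY_SEQ = "GGGGG" + "ATGAAACCCGGGTTTTAA" + "AAATGA" + "C" * 31


@pytest.fixture
def toy_model() -> TranscriptModel:
    return TranscriptModel(
        transcript_id="toy1", length=len(TOY_SEQ), cds_start=5, cds_end=23, sequence=TOY_SEQ
    )


@pytest.fixture
def uniform_track():
    def make(tm: TranscriptModel, value: int = 1) -> DensityTrack:
        return DensityTrack(tm.transcript_id, np.full(tm.length, value, dtype=np.int64))

    return make


@pytest.fixture(scope="session")
def small_sim():
    """A 100-transcript simulated dataset shared by oracle-style tests."""
    params = SimulationParams(n_transcripts=100, expression_shape=3.0,
                              expression_scale=1.0, pause_multiplier=2.0,
                              readthrough_fraction=0.05)
    models = simulate_transcriptome(params, 101)
    records = simulate_footprints(models, params, 202)
    return params, models, records
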
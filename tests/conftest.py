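import numpy as np
import pytest
from hypothesis import settings

from igtrace.repertoire_io import ChainRecord, translate_frame1

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_chain(
    cell_id: str,
    junction: str,
    locus: str = "IGH",
    v_call: str = "IGHV1-2*01",
    j_call: str = "IGHJ4*01",
    patient_id: str = "P1",
    prefix: str = "GGT" * 10,
    suffix: str = "GCT" * 10,
) -> ChainRecord:
    """Toy chain whose sequence embeds the junction between fixed flanks."""
    seq = prefix + junction + suffix
    return ChainRecord(
        cell_id=cell_id,
        patient_id=patient_id,
        locus=locus,
        v_call=v_call,
        j_call=j_call,
        junction_nt=junction,
        sequence_nt=seq,
        sequence_aa=translate_frame1(seq),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small noise-free cohort shared by read-only pipeline tests."""
    from igtrace import synthetic_data as sd

    cfg = sd.SimConfig(
        n_patients=3,
        cells_per_patient=80,
        n_secretor_clonotypes=4,
        shm_rate=0.0,
        noise_floor=0.0,
        seed=42,
    )
    return sd.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    from igtrace import synthetic_data as sd

    out = tmp_path_factory.mktemp("cohort")
    return sd.write_cohort(small_cohort, out)
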
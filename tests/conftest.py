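import numpy as np
import pytest

import hybridotu as h


def make_read(bases, quals=None, rid="r1", sample="s1", role="R1"):
    if quals is None:
        quals = [40] * len(bases)
    return h.Read(id=rid, bases=bases, quals=np.asarray(quals, dtype=np.uint8),
                  mate_role=h.MateRole(role), sample_id=sample)


@pytest.fixture(scope="session")
def small_study():
    """A small but fully featured synthetic study reused across tests."""
    cfg = h.SimConfig(
        n_species=8, n_subjects=4, n_replicates=2, reads_per_sample=300, seed=7
    )
    return h.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_run(small_study):
    data = small_study
    return h.run_pipeline(
        data, data.ledger.refs, data.ledger.lineages,
        h.PipelineParams(seed=7),
    )


@pytest.fixture(scope="session")
def reference_set():
    cfg = h.SimConfig(n_species=20, seed=11)
    return h.generate_reference_set(cfg)
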
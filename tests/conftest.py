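import pytest

from ighclone import SimConfig, load_packaged_germline, load_hybridoma_panel, simulate_repertoire


@pytest.fixture(scope="session")
def germline_db():
    return load_packaged_germline()


@pytest.fixture(scope="session")
def panel_records():
    return load_hybridoma_panel()


@pytest.fixture(scope="session")
def sim_default(germline_db):
    """Default mixed-topology repertoire, seed 1."""
    return simulate_repertoire(SimConfig(seed=1), germline_db)


@pytest.fixture(scope="session")
def sim_annotated(germline_db, sim_default):
    """Annotations for the default simulated repertoire."""
    from ighclone import annotate_sequence

    return {
        rec.record_id: annotate_sequence(rec.record_id, rec.nt_seq, germline_db)
        for rec in sim_default.records
    }
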
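import pytest

from mxpipe.synthetic_data import SynthesisSpec, generate_corpus


@pytest.fixture(scope="session")
def corpus7():
    """Default-condition synthetic corpus at seed 7, shared across tests."""
    return generate_corpus(SynthesisSpec(seed=7))


@pytest.fixture(scope="session")
def transfer_records7(corpus7):
    from mxpipe import annotation_transfer as at

    return at.run_transfer(
        corpus7.old_cds(),
        corpus7.stage_candidates(),
        mapped_old_models=corpus7.old.mapped_models,
        new_models=corpus7.models,
        old_categories=corpus7.old.categories,
    )
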
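import numpy as np
import pytest

from ame_smallrna import synthetic_data as syn

TRIGGER = "AAGCTCAGGAGGGATAGCGCC"  # miR390 mature (DNA alphabet)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small zero-noise synthetic study written to disk once per session."""
    out = tmp_path_factory.mktemp("bundle")
    paths = syn.simulate_bundle(out, seed=11, n_transcripts=10, n_hairpins=6)
    return paths


@pytest.fixture(scope="session")
def planted(small_bundle):
    """Regenerate the same study in memory for truth-based assertions."""
    transcripts, reference, ledger = syn.generate_transcriptome(
        n_transcripts=10, n_hairpins=6, seed=11
    )
    tas_tr, tas = syn.simulate_tas_locus(TRIGGER, seed=11)
    transcripts.append(tas_tr)
    ledger.tas_loci.append(tas)
    return transcripts, reference, ledger


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
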
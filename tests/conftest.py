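import pytest

from phar_regulon import (
    CONSENSUS_INPUT_SITES,
    PHAR_CONSENSUS,
    IUPACConsensus,
    load_regulon_tables,
)


@pytest.fixture(scope="session")
def consensus():
    """The published degenerate binding consensus."""
    return IUPACConsensus(PHAR_CONSENSUS)


@pytest.fixture(scope="session")
def published_tables():
    """The packaged 70-row repressed/activated candidate tables."""
    return load_regulon_tables()


@pytest.fixture(scope="session")
def consensus_input_sites():
    """The eight printed 12-mer sites the consensus derives from."""
    return list(CONSENSUS_INPUT_SITES)


@pytest.fixture
def tiny_fasta(tmp_path):
    """Write a small FASTA file and return its path."""

    def _write(records, name="genome.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for cid, seq in records.items():
                fh.write(f">{cid}\n{seq}\n")
        return path

    return _write
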
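import numpy as np
import pytest

from period3.synthetic import FIXTURE_SPECS, generate_gene


@pytest.fixture(scope="session")
def three_exon():
    """Canonical three-exon synthetic gene (seq, annotation)."""
    return generate_gene(FIXTURE_SPECS["three_exon"])


@pytest.fixture(scope="session")
def single_exon():
    return generate_gene(FIXTURE_SPECS["single_exon"])


@pytest.fixture(scope="session")
def short_exon():
    return generate_gene(FIXTURE_SPECS["short_exon"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def write_fasta_text(path, records):
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")
    return path
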
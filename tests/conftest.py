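import pytest

from codoncraft.records import SequenceRecord
from codoncraft.synth import BiasSpec, generate_cds_set, skewed_bias
from codoncraft.usage_table import CodonUsageTable, compute_usage_table


@pytest.fixture(scope="session")
def biased_cds_set() -> list[SequenceRecord]:
    """Small reproducible CDS set with strongly skewed codon usage."""
    spec = BiasSpec(
        frequencies=skewed_bias(0.35), n_genes=60, min_codons=60,
        max_codons=120, seed=11,
    )
    return generate_cds_set(spec)


@pytest.fixture(scope="session")
def usage_table(biased_cds_set) -> CodonUsageTable:
    """Complete usage table (every family observed) from the biased set."""
    table = compute_usage_table(biased_cds_set, source="test fixture set")
    assert table.is_complete()
    return table
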
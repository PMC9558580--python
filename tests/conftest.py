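import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from rhizotax.synth import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated study shared across tests (4 taxa, 6 markers)."""
    config = SimulationConfig(
        n_taxa=4, n_markers=6, marker_length_range=(100, 200),
        tree_depth=0.05, contig_length_range=(6_000, 8_000), seed=7,
    )
    return simulate_dataset(config)


@pytest.fixture()
def fasta_file(tmp_path):
    def _write(content: str, name: str = "seqs.fasta") -> Path:
        p = tmp_path / name
        p.write_text(content)
        return p
    return _write
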
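"""Shared fixtures: simulated datasets and small hand-built objects."""

import pytest

from sexscan.model import Sex, SexRegistry, TagCatalog, TagRecord
from sexscan.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def clean_zw():
    """Noiseless ZW dataset: perfectly separable by construction."""
    return simulate_dataset(SimConfig(dropout=0.0, error=0.0, seed=1))


@pytest.fixture(scope="session")
def noisy_zw():
    """ZW dataset at the default dropout/error rates."""
    return simulate_dataset(SimConfig(seed=42))


@pytest.fixture(scope="session")
def null_sim():
    """No planted sex-linked structure."""
    return simulate_dataset(SimConfig(system="none", seed=2))


@pytest.fixture
def registry_5x5():
    return SexRegistry(
        {**{f"F{i}": Sex.F for i in range(1, 6)}, **{f"M{i}": Sex.M for i in range(1, 6)}}
    )


def make_catalog(tag_id: str, consensus: str, sample_alleles: dict) -> TagCatalog:
    tc = TagCatalog()
    tc.tags[tag_id] = TagRecord(tag_id, consensus, sample_alleles)
    return tc


@pytest.fixture
def zw_tag_catalog():
    """One 300 bp tag with a single female-specific site at position 150."""
    base = ("ACGT" * 75)
    w = base[:150] + "T" + base[151:]
    assert base[150] == "G" and len(base) == 300
    alleles = {f"M{i}": [base] for i in range(1, 6)}
    alleles.update({f"F{i}": sorted([base, w]) for i in range(1, 6)})
    return make_catalog("CLocus_7", base, alleles)
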
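import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from codonsel.codon_model import CODONS, GeneModel, STANDARD_BACTERIAL_CODE

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

SENSE_CODONS = tuple(c for c in CODONS if not STANDARD_BACTERIAL_CODE.is_stop(c))


def random_gene(rng: np.random.Generator, n_codons: int = 200, gene_id: str = "g") -> GeneModel:
    codons = rng.choice(SENSE_CODONS, size=n_codons)
    return GeneModel(gene_id=gene_id, cds="".join(codons))


@pytest.fixture
def code():
    return STANDARD_BACTERIAL_CODE


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
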
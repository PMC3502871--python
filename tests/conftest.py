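import numpy as np
import pytest

from mirqtl.config import PipelineConfig
from mirqtl.core import GeneModel, MicroRNA
from mirqtl.synth import gen_mir_catalog


@pytest.fixture
def let7() -> MicroRNA:
    # canonical let-7 family mature sequence; seed 2-8 = GAGGUAG
    return MicroRNA("let-7-like", "UGAGGUAGUAGGUUGUAUAGUU")


@pytest.fixture
def catalog() -> list[MicroRNA]:
    return gen_mir_catalog(10, seed=123)


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def single_exon_gene() -> GeneModel:
    # exon 101-200, CDS 131-170 in 1-based closed coordinates (+ strand)
    return GeneModel("geneA", "chr1", "+", exons=[(100, 200)], cds=[(130, 170)])


def random_utr(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
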
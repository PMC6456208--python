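import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")

from spinsex.genotyping import AlleleDepth, GenotypeCall, GenotypeState
from spinsex.io import Role, Sample, SampleSheet, Sex, VariantSite, VariantTable
from spinsex.syndata import SimConfig, generate_dataset


HOM_REF = GenotypeCall(GenotypeState.HOM_REF, (0, 0))
HOM_ALT = GenotypeCall(GenotypeState.HOM_ALT, (1, 1))
HET01 = GenotypeCall(GenotypeState.HET, (0, 1))
HET02 = GenotypeCall(GenotypeState.HET, (0, 2))
HET12 = GenotypeCall(GenotypeState.HET, (1, 2))


@pytest.fixture
def sheet_2x2() -> SampleSheet:
    return SampleSheet([
        Sample("F1", Sex.FEMALE), Sample("F2", Sex.FEMALE),
        Sample("M1", Sex.MALE), Sample("M2", Sex.MALE),
    ])


@pytest.fixture
def sheet_8x8() -> SampleSheet:
    return SampleSheet(
        [Sample(f"F{i}", Sex.FEMALE) for i in range(1, 9)]
        + [Sample(f"M{i}", Sex.MALE) for i in range(1, 9)]
    )


def make_site(unigene="u1", pos=5, ref="A", alts=("G",), **depths):
    """Build a VariantSite from sample=(ref_depth, alt_depths...) kwargs."""
    d = {
        s: AlleleDepth(v[0], tuple(v[1:])) for s, v in depths.items()
    }
    return VariantSite(unigene, pos, ref, tuple(alts), d)


@pytest.fixture
def tiny_sim() -> "generate_dataset":
    """Small but complete synthetic dataset for integration tests."""
    cfg = SimConfig(n_msy=6, n_par=8, n_autosome=10, gene_length=600, seed=11)
    return generate_dataset(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
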
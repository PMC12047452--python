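import hypothesis.strategies as st
import pytest

from stpath.pathway_io import Interaction, Pathway
from stpath.st_core import LEVEL2_RANGES, STCode, parse_st_code
from stpath.synth import SynthConfig, generate_catalog, generate_pathways


def make_pathway(codes: list[str], id: str = "pw") -> Pathway:
    """Chain of anonymous entities carrying the given ST codes."""
    steps = tuple(
        Interaction(f"{id}_n{i}", f"{id}_n{i + 1}", parse_st_code(c))
        for i, c in enumerate(codes)
    )
    return Pathway(id, steps)


@st.composite
def st_codes(draw) -> STCode:
    l1 = draw(st.integers(1, 6))
    r2 = LEVEL2_RANGES[l1]
    l2 = draw(st.integers(r2.start, r2.stop - 1))
    l3 = draw(st.integers(1, 9))
    l4 = draw(st.integers(1, 9))
    return STCode(l1, l2, l3, l4)


@pytest.fixture(scope="session")
def synth_config() -> SynthConfig:
    return SynthConfig(seed=11, n_entities=25, n_interactions=80, n_pathways=15,
                       length_range=(3, 6))


@pytest.fixture(scope="session")
def catalog(synth_config):
    return generate_catalog(synth_config)


@pytest.fixture(scope="session")
def pathways(catalog, synth_config):
    return generate_pathways(catalog, synth_config)
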
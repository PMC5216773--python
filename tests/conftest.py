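import numpy as np
import pytest

from fmlncsim import (
    FixtureConfig,
    generate_corpus,
    disease_similarity_from_mesh,
    parse_mesh_ascii,
)

MESH_FIXTURE = """\
*NEWRECORD
MH = Neoplasms
MN = C04
UI = D009369

*NEWRECORD
MH = Neoplasms by Histologic Type
MN = C04.557
UI = D009370

*NEWRECORD
MH = Neoplasms, Glandular and Epithelial
MN = C04.557.470
UI = D009375

*NEWRECORD
MH = Respiratory Tract Neoplasms
MN = C04.588
MN = F03.785
UI = D012142

*NEWRECORD
MH = Lung Neoplasms
MN = C04.588.894
MN = F03.785.520
UI = D008175

*NEWRECORD
MH = Heterocyclic Compounds
MN = D03.633
UI = D006571
"""


@pytest.fixture
def mesh_file(tmp_path):
    path = tmp_path / "mesh.txt"
    path.write_text(MESH_FIXTURE)
    return path


@pytest.fixture
def descriptors(mesh_file):
    return parse_mesh_ascii(mesh_file)


@pytest.fixture(scope="session")
def corpus():
    """Default block-structured synthetic corpus."""
    return generate_corpus(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def corpus_fs(corpus):
    fs, name_map = disease_similarity_from_mesh(
        corpus.descriptors, corpus.association.disease_ids
    )
    assert not name_map.unmapped
    return fs


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
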
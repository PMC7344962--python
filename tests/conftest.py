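import pytest

from frshift.imgt import Mutation, RegionScheme
from frshift.synthetic import (
    FixtureConfig,
    design_mutations,
    make_parental_fv,
    make_toy_germline_directory,
)


@pytest.fixture(scope="session")
def scheme():
    return RegionScheme()


@pytest.fixture(scope="session")
def parental_fv(scheme):
    """(VH, VL, toy structure) of the packaged synthetic parent."""
    return make_parental_fv(scheme=scheme)


@pytest.fixture(scope="session")
def parent_vh(parental_fv):
    return parental_fv[0]


@pytest.fixture(scope="session")
def parent_vl(parental_fv):
    return parental_fv[1]


@pytest.fixture(scope="session")
def fv_structure(parental_fv):
    return parental_fv[2]


@pytest.fixture(scope="session")
def design_vh_mutations():
    return design_mutations()[0]


@pytest.fixture(scope="session")
def design_vl_mutations():
    return design_mutations()[1]


@pytest.fixture(scope="session")
def full_design_mutations(design_vh_mutations, design_vl_mutations):
    """The complete design: 19 VH + 4 grafted VL + the Protein-L T8P."""
    return list(design_vh_mutations) + list(design_vl_mutations) + [
        Mutation("VL", "T", 8, "P")
    ]


@pytest.fixture(scope="session")
def vh_directory(scheme):
    return make_toy_germline_directory(FixtureConfig(seed=0), "VH", scheme)


@pytest.fixture(scope="session")
def vl_directory(scheme):
    return make_toy_germline_directory(FixtureConfig(seed=0), "VL_kappa", scheme)
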
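import numpy as np
import pytest

from idpanchor.conformational_states import load_region_config
from idpanchor.synthetic_ensembles import build_peptide, build_synthetic_complex


@pytest.fixture(scope="session")
def helix_peptide():
    """Ideal-geometry helical 13-mer of the p53 segment (Glu17-Asn29)."""
    return build_peptide()


@pytest.fixture(scope="session")
def extended_peptide():
    return build_peptide(backbone="extended")


@pytest.fixture(scope="session")
def cage_complex(helix_peptide):
    """Helical peptide occluded at residues 19/23/26 by a rigid cage."""
    return build_synthetic_complex(helix_peptide, [19, 23, 26])


@pytest.fixture(scope="session")
def region_config():
    region_sets, bound_refs = load_region_config()
    return region_sets, bound_refs


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
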
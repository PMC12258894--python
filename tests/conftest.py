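import numpy as np
import pytest

from voltgate.core_io import AtomTable


def make_ca_table(n, resnames=None, chain="A", first_resid=1):
    """Minimal one-CA-per-residue atom table for network/flow fixtures."""
    resnames = resnames or ["ALA"] * n
    return AtomTable(
        atom_id=np.arange(n) + 1,
        atom_name=np.array(["CA"] * n, dtype=object),
        residue_id=np.arange(first_resid, first_resid + n),
        residue_name=np.array(resnames, dtype=object),
        chain_id=np.array([chain] * n, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        partial_charge=np.zeros(n),
        vdw_radius=np.full(n, 1.7),
    )


@pytest.fixture
def ca_table_factory():
    return make_ca_table


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
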
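import numpy as np
import pytest

from mflogp.data_io import FidelityDataset, MoleculeRecord, canonicalize

# varied small organics: rings, heteroatoms, carbonyls, halogens, charges-free
SMALL_SMILES = [
    "C", "O", "CC", "CCO", "C=O", "C#N", "CCN", "CC=O", "OCO",
    "c1ccccc1", "Cc1ccccc1", "Oc1ccccc1", "Nc1ccccc1", "c1ccncc1",
    "CC(=O)O", "CC(=O)NC", "CCCl", "CCBr", "CCS", "FC(F)F",
    "C1CCCCC1", "C1CCOC1", "CC(C)C", "CC(C)(C)O", "CN(C)C",
]


def make_dataset(pairs, fidelity="HF", label="test"):
    return FidelityDataset(
        [
            MoleculeRecord(
                smiles=s, logp=v, fidelity=fidelity, canonical_smiles=canonicalize(s)
            )
            for s, v in pairs
        ],
        label=label,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small synthetic multi-fidelity bundle shared by the slower tests."""
    from mflogp.synthetic_data import SyntheticParams, generate_multifidelity

    return generate_multifidelity(
        SyntheticParams(n_lf=120, n_hf=60, n_test=40, seed=11)
    )
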
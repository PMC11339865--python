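import numpy as np
import pandas as pd
import pytest

from pkaret import synthetic_data as sd
from pkaret.chem_graph import parse_molecule


@pytest.fixture(scope="session")
def molecules50():
    """Fifty generator molecules shared across structural tests."""
    return sd.generate_molecules(50, seed=4)


@pytest.fixture(scope="session")
def feat_cache():
    """Session-wide featurization cache (ETKDG embeddings are the slow part)."""
    return {}


def _records_frame(smiles, fidelity, seed):
    rows = []
    for s in smiles:
        mol = parse_molecule(s)
        pka, cls = sd.synth_labels(mol, fidelity, seed)
        qm = sd.synth_qm_features(mol, seed)
        rows.append({"smiles": mol.smiles, "pka": pka, "site_class": cls,
                     "fidelity": fidelity, "source": "fixture",
                     **{f"qm_{k + 1}": qm[k] for k in range(5)}})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def overfit_frame():
    """32 labeled molecules used as the overfitting oracle."""
    return _records_frame(sd.generate_molecules(32, seed=7), "experimental", 7)


@pytest.fixture(scope="session")
def small_frame():
    """16 labeled molecules for fast training-behavior tests."""
    return _records_frame(sd.generate_molecules(16, seed=9), "experimental", 9)


@pytest.fixture(scope="session")
def benchmark_small():
    """Reduced-size two-fidelity benchmark shared by the transfer tests."""
    spec = sd.SyntheticSpec(n_low=600, n_high=150)
    return spec, *sd.make_benchmark(spec, seed=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
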
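import numpy as np
import pytest

from protdescal.fixtures import FixtureSpec, synthetic_structure
from protdescal.protein_io import ProteinModel, ResidueRecord
from protdescal.scales import ONE_TO_THREE


@pytest.fixture
def coil30():
    return synthetic_structure(FixtureSpec("synthetic_coil", 30, seed=7))


@pytest.fixture
def helix20():
    return synthetic_structure(FixtureSpec("synthetic_helix", 20, seed=1))


@pytest.fixture
def cluster40():
    return synthetic_structure(FixtureSpec("random_cluster", 40, seed=3, n_core=8))


def make_model(sequence: str, coords=None, ss=None, model_id="test"):
    """Build a model directly from a sequence and optional Cα coordinates."""
    residues = []
    for i, letter in enumerate(sequence):
        atoms = {}
        label = None
        if coords is not None:
            atoms = {"CA": np.asarray(coords[i], dtype=float)}
            label = ss[i] if ss is not None else "COIL"
        residues.append(ResidueRecord(
            position=i + 1, aa_type=ONE_TO_THREE[letter], atoms=atoms,
            ss_label=label,
        ))
    return ProteinModel(
        id=model_id, residues=residues,
        has_structure=coords is not None, source_format="PDB" if coords is not None else "FASTA",
    )


@pytest.fixture
def make_sequence_model():
    return lambda seq, **kw: make_model(seq, **kw)
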
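import numpy as np
import pytest

from seqregister.alphabet import AA1
from seqregister.profile_align import AlignmentParams
from seqregister.register_scanner import ScanConfig
from seqregister.structure_io import Chain, Residue, StructureModel, TargetSequence


@pytest.fixture(scope="session")
def params():
    return AlignmentParams()


@pytest.fixture(scope="session")
def scan_config():
    return ScanConfig()


def make_chain(types3, numbers=None, icodes=None, chain_id="A", with_atoms=False):
    """Build a bare chain from three-letter residue names."""
    numbers = numbers or list(range(1, len(types3) + 1))
    icodes = icodes or [""] * len(types3)
    residues = []
    for i, (t, n, ic) in enumerate(zip(types3, numbers, icodes)):
        atoms = {}
        if with_atoms:
            atoms = {"CA": np.array([3.8 * i, 5.0, 5.0])}
        residues.append(Residue(number=n, icode=ic, type3=t, atoms=atoms))
    return Chain(id=chain_id, residues=residues)


@pytest.fixture
def two_chain_model():
    a = make_chain(["ALA"] * 30, chain_id="A", with_atoms=True)
    b = make_chain(["GLY"] * 10, chain_id="B", with_atoms=True)
    return StructureModel(chains=[a, b], cell=(130.0, 20.0, 20.0, 90.0, 90.0, 90.0))


def random_window(rng, length):
    """Random valid probability window (rows sum to 1)."""
    w = rng.random((length, 20)) + 1e-3
    return w / w.sum(axis=1, keepdims=True)


def random_sequence(rng, length, seq_id="s"):
    return TargetSequence(id=seq_id, residues="".join(rng.choice(list(AA1), size=length)))
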
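import numpy as np
import pytest

from fepscan import (
    ChainSpec,
    SyntheticTrajectorySpec,
    ThermoState,
    generate_toy_trajectory,
)


@pytest.fixture(scope="session")
def thermo():
    """Room-temperature thermodynamic state (300 K, kB in kcal/(mol·K))."""
    return ThermoState()


@pytest.fixture(scope="session")
def two_chain_spec():
    """Five-bead peptide chain P against five-bead receptor chain R;
    residue 1 in contact for frames 1-7 of 10, no noise."""
    return SyntheticTrajectorySpec(
        n_frames=10,
        chains=(
            ChainSpec("P", ("TYR", "ILE", "TYR", "THR", "GLN")),
            ChainSpec("R", ("ALA", "ALA", "ALA", "ALA", "ALA")),
        ),
        contact_schedule={1: ((1, 8),)},
        noise_sigma=0.0,
        contact_distance=4.0,
        separated_distance=30.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def two_chain_traj(two_chain_spec):
    return generate_toy_trajectory(two_chain_spec)


MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY B   2       5.000   5.000   5.000  1.00  0.00           O
ATOM      5  CA  GLY B   2       6.000   5.500   5.250  1.00  0.00           C
END
"""


@pytest.fixture()
def mini_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path
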
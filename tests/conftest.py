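"""Shared fixtures: small text-format structures and synthetic ensembles."""

from __future__ import annotations

import numpy as np
import pytest

import heatdyn as hd
from heatdyn import synthetic as syn
from heatdyn.io import ComponentMap


TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CA  GLY A   2       3.800   1.500   0.200  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.100   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.558   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.109   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.351   2.390   0.000  1.00  0.00           O
ATOM      5  CA  GLY A   2       3.900   1.500   0.200  1.00  0.00           C
ENDMDL
END
"""

GRO_THREE_ATOMS = """\
three-atom fixture
    3
    1ALA      N    1   0.100   0.200   0.300
    1ALA     CA    2   0.200   0.300   0.400
    1ALA      C    3   0.300   0.400   0.500
   5.00000   5.00000   5.00000
"""


@pytest.fixture
def two_model_pdb(tmp_path):
    path = tmp_path / "two_model.pdb"
    path.write_text(TWO_MODEL_PDB)
    return path


@pytest.fixture
def gro_file(tmp_path):
    path = tmp_path / "three.gro"
    path.write_text(GRO_THREE_ATOMS)
    return path


@pytest.fixture
def two_block_map():
    return ComponentMap.from_entries([("blockA", "A", 1, 8),
                                      ("blockB", "A", 9, 16)])


@pytest.fixture
def two_block_ensemble():
    """16-bead Gaussian ensemble: intra 0.9, inter -0.5, 20k frames."""
    spec = syn.BlockCovarianceSpec(
        blocks=(("blockA", 8), ("blockB", 8)), intra=(0.9, 0.9),
        inter=((0.9, -0.5), (-0.5, 0.9)), per_bead_stddev=0.5)
    corr = syn.build_correlation_matrix(spec)
    ens = syn.sample_gaussian_ensemble(
        syn._straight_chain(16), corr, 0.5, 20_000, seed=42)
    return ens, spec


@pytest.fixture
def hinge_setup():
    """Default 60-bead hinge ensemble with its two-segment component map."""
    spec = syn.HingeSpec(segment_lengths=(30, 30), opening_amplitude=20.0,
                         n_frames=5000, seed=7)
    ens, pivot = syn.make_hinge_ensemble(spec)
    cmap = ComponentMap.from_entries([("seg1", "A", 1, 30),
                                      ("seg2", "A", 31, 60)])
    beads = hd.select_beads(ens, cmap)
    return ens, pivot, cmap, beads


def random_rigid_motion(rng):
    """A uniform random rotation matrix and a translation vector."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(rng=np.random.default_rng(rng.integers(2**31)))
    return R.as_matrix(), rng.normal(scale=20.0, size=3)


@pytest.fixture
def apply_rigid():
    def _apply(ensemble, seed=0, per_frame=True):
        rng = np.random.default_rng(seed)
        coords = ensemble.coords.copy()
        if per_frame:
            for t in range(coords.shape[0]):
                R, tr = random_rigid_motion(rng)
                coords[t] = coords[t] @ R.T + tr
        else:
            R, tr = random_rigid_motion(rng)
            coords = coords @ R.T + tr
        return ensemble.with_coords(coords)
    return _apply
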
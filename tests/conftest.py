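import struct

import numpy as np
import pytest

from cryolabel import FixtureSpec, VoxelGrid, make_helix, make_noisy_map


def write_raw_mrc(path, data_crs, mapc, mapr, maps, cell, sampling,
                  origin=(0.0, 0.0, 0.0), nstart=(0, 0, 0),
                  angles=(90.0, 90.0, 90.0)):
    """Minimal independent MRC2014 writer for crafting header variants.

    ``data_crs`` is the on-disk array indexed [sections][rows][columns];
    mapc/mapr/maps name which physical axis (1=x, 2=y, 3=z) varies fastest.
    Used only to build test inputs that exercise the reader's header
    handling; deliberately does not share code with the package.
    """
    ns, nr, nc = data_crs.shape
    h = np.zeros(256, dtype="<i4")
    hf = h.view("<f4")
    h[0], h[1], h[2] = nc, nr, ns
    h[3] = 2
    h[4:7] = nstart
    h[7:10] = sampling
    hf[10:13] = cell
    hf[13:16] = angles
    h[16], h[17], h[18] = mapc, mapr, maps
    hf[19] = data_crs.min()
    hf[20] = data_crs.max()
    hf[21] = data_crs.mean()
    h[22] = 1
    h[52] = struct.unpack("<i", b"MAP ")[0]
    h[53] = struct.unpack("<i", b"\x44\x44\x00\x00")[0]
    hf[49:52] = origin
    with open(path, "wb") as fh:
        fh.write(h.tobytes())
        fh.write(np.asarray(data_crs, dtype="<f4").tobytes())


@pytest.fixture
def helix5():
    return make_helix(5)


@pytest.fixture
def small_grid():
    """Empty 24^3 grid at 1 A centred near the origin."""
    return VoxelGrid(np.zeros((24, 24, 24), dtype=np.float32),
                     voxel_size=(1, 1, 1), origin=(-6.0, -8.0, -8.0))


@pytest.fixture
def noisy_pair(helix5):
    spec = FixtureSpec(n_residues=5, noise_sigma=0.1, resolution=3.0, seed=7)
    return make_noisy_map(helix5, spec)


GLY_PDB = """\
ATOM      1  N   GLY A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       2.200   2.500   3.400  1.00  0.00           C
ATOM      3  C   GLY A   1       3.100   1.600   4.200  1.00  0.00           C
ATOM      4  O   GLY A   1       3.000   0.400   4.100  1.00  0.00           O
END
"""


@pytest.fixture
def gly_pdb(tmp_path):
    p = tmp_path / "gly.pdb"
    p.write_text(GLY_PDB)
    return p
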
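import numpy as np
import pytest

from cryolabel import (
    AtomRecord,
    NeighborhoodSpec,
    SimulationParams,
    Structure,
    VoxelGrid,
    coord_to_voxel,
    dilated_mask,
    extract_subcubes,
    generate_labels,
    make_atomtype_label,
    make_classification_label,
    make_regression_label,
    reassemble_subcubes,
)
from cryolabel.labelgen import AlignmentError
from cryolabel.synthetic_fixtures import FixtureSpec, make_fixture_bundle, make_helix, make_noisy_map


def atom(x, y, z, element="C", name="CA", residue="ALA"):
    return AtomRecord(element=element, atom_name=name, residue_name=residue,
                      chain_id="A", coord=(x, y, z))


def brute_force_mask(structure, grid, radius):
    """Oracle: per-voxel minimum distance to any atom coordinate."""
    out = np.zeros(grid.shape, dtype=bool)
    zc, yc, xc = (grid.axis_coords(a) for a in range(3))
    coords = structure.coords()
    for i, z in enumerate(zc):
        for j, y in enumerate(yc):
            for k, x in enumerate(xc):
                d = np.sqrt(((coords - [x, y, z]) ** 2).sum(axis=1)).min()
                out[i, j, k] = d <= radius
    return out


# --- coordinate conversion -------------------------------------------------

@pytest.mark.parametrize(
    "coord, origin, expected_ijk",
    [
        ((10.4, 5.0, 3.7), (0, 0, 0), (3, 5, 10)),
        ((0.0, 0.0, 0.0), (0, 0, 0), (0, 0, 0)),
        ((7.5, 2.25, 0.0), (-2, -2, -2), (2, 4, 9)),
    ],
)
def test_coord_to_voxel_floor_convention(coord, origin, expected_ijk):
    """i pairs with z, j with y, k with x; floor after the origin shift."""
    grid = VoxelGrid(np.zeros((32, 32, 32)), (1, 1, 1), origin)
    assert coord_to_voxel(coord, grid) == expected_ijk


# --- dilated mask ----------------------------------------------------------

def test_radius_zero_marks_only_the_center_voxel():
    grid = VoxelGrid(np.zeros((9, 9, 9)), (1, 1, 1), (0, 0, 0))
    st = Structure([atom(4.0, 4.0, 4.0)])  # exactly at a voxel center
    mask = dilated_mask(st, grid, NeighborhoodSpec(radius=0.0))
    assert mask.sum() == 1 and mask[4, 4, 4]


def test_single_atom_ball_count_matches_lattice_enumeration():
    """True-voxel count equals the number of integer offsets with norm <= 6."""
    grid = VoxelGrid(np.zeros((21, 21, 21)), (1, 1, 1), (0, 0, 0))
    st = Structure([atom(10.0, 10.0, 10.0)])
    mask = dilated_mask(st, grid, NeighborhoodSpec(radius=6.0))
    offsets = np.arange(-6, 7)
    dz, dy, dx = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    expected = int((dz**2 + dy**2 + dx**2 <= 36).sum())
    assert mask.sum() == expected


def test_disjoint_balls_double_the_count():
    grid = VoxelGrid(np.zeros((21, 21, 41)), (1, 1, 1), (0, 0, 0))
    st1 = Structure([atom(10.0, 10.0, 10.0)])
    st2 = Structure([atom(10.0, 10.0, 10.0), atom(30.0, 10.0, 10.0)])
    r = NeighborhoodSpec(radius=6.0)
    assert dilated_mask(st2, grid, r).sum() == 2 * dilated_mask(st1, grid, r).sum()


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_mask_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    grid = VoxelGrid(np.zeros((14, 15, 16)), (1.0, 0.9, 1.1), (-2.0, 0.0, 1.0))
    atoms = [atom(*c) for c in rng.uniform(-2, 14, size=(4, 3))]
    st = Structure(atoms)
    for radius in (2.5, 4.0):
        fast = dilated_mask(st, grid, NeighborhoodSpec(radius=radius))
        np.testing.assert_array_equal(fast, brute_force_mask(st, grid, radius))


def test_mask_monotone_in_radius():
    st = make_helix(3)
    grid = VoxelGrid(np.zeros((20, 20, 20)), (1, 1, 1), (-6, -6, -6))
    m1 = dilated_mask(st, grid, NeighborhoodSpec(radius=3.0))
    m2 = dilated_mask(st, grid, NeighborhoodSpec(radius=6.0))
    assert np.all(m2[m1])  # mask(r1) subset of mask(r2)


# --- label constructors ----------------------------------------------------

def test_classification_semantics_single_atom():
    grid = VoxelGrid(np.zeros((15, 15, 15)), (1, 1, 1), (0, 0, 0))
    st = Structure([atom(7.0, 7.0, 7.0)])
    label = make_classification_label(st, grid, NeighborhoodSpec(radius=3.0))
    data = label.data
    assert (data == 1).sum() == 1 and data[7, 7, 7] == 1
    mask = dilated_mask(st, grid, NeighborhoodSpec(radius=3.0))
    assert np.all(data[mask & (data != 1)] == 2)
    assert np.all(data[~mask & (data != 1)] == 0)


def test_classification_atom_precedence_and_shared_voxel():
    grid = VoxelGrid(np.zeros((15, 15, 15)), (1, 1, 1), (0, 0, 0))
    st = Structure([atom(7.2, 7.2, 7.2), atom(7.6, 7.6, 7.6)])  # same voxel
    label = make_classification_label(st, grid, NeighborhoodSpec(radius=3.0))
    assert (label.data == 1).sum() == 1


def test_classification_radius_zero_has_no_neighbor_class():
    grid = VoxelGrid(np.zeros((9, 9, 9)), (1, 1, 1), (0, 0, 0))
    st = Structure([atom(4.3, 4.3, 4.3)])  # off-center: ball of radius 0 empty
    label = make_classification_label(st, grid, NeighborhoodSpec(radius=0.0))
    assert set(np.unique(label.data)) <= {0, 1}


def test_atomtype_glycine_has_no_cb_class():
    grid = VoxelGrid(np.zeros((12, 12, 12)), (1, 1, 1), (0, 0, 0))
    st = Structure([
        atom(5.0, 5.0, 5.0, "N", "N", "GLY"),
        atom(6.0, 5.0, 5.0, "C", "CA", "GLY"),
        atom(7.0, 5.0, 5.0, "C", "C", "GLY"),
        atom(8.0, 5.0, 5.0, "O", "O", "GLY"),
    ])
    label = make_atomtype_label(st, grid)
    assert 2 not in np.unique(label.data)
    assert (label.data > 0).sum() == 4


def test_atomtype_collision_last_atom_wins():
    grid = VoxelGrid(np.zeros((12, 12, 12)), (1, 1, 1), (0, 0, 0))
    st = Structure([
        atom(5.2, 5.2, 5.2, "C", "CA", "ALA"),
        atom(5.7, 5.7, 5.7, "N", "N", "ALA"),  # same voxel, later in file
    ])
    label = make_atomtype_label(st, grid)
    assert label.data[5, 5, 5] == 5


def test_regression_is_simulated_inside_mask_zero_outside():
    st = make_helix(3)
    grid = VoxelGrid(np.zeros((20, 20, 20), dtype=np.float32), (1, 1, 1),
                     (-6, -6, -6))
    rng = np.random.default_rng(0)
    simulated = grid.with_data(rng.uniform(0, 1, grid.shape).astype(np.float32))
    spec = NeighborhoodSpec(radius=4.0)
    label = make_regression_label(st, grid, simulated, spec)
    mask = dilated_mask(st, grid, spec)
    np.testing.assert_array_equal(label.data[mask], simulated.data[mask])
    assert not label.data[~mask].any()


def test_regression_alignment_checked():
    st = make_helix(2)
    a = VoxelGrid(np.zeros((10, 10, 10)), (1, 1, 1), (0, 0, 0))
    b = VoxelGrid(np.zeros((10, 10, 10)), (1, 1, 1), (1, 0, 0))
    with pytest.raises(AlignmentError):
        make_regression_label(st, a, b)


# --- end-to-end bundles ----------------------------------------------------

@pytest.mark.parametrize("seed", range(20))
def test_bundle_invariants_on_randomized_fixtures(seed):
    """Value domains, atom_type=>class1, masked regression, shared geometry."""
    rng = np.random.default_rng(seed)
    spec = FixtureSpec(
        n_residues=int(rng.integers(2, 7)),
        noise_sigma=float(rng.uniform(0.0, 0.3)),
        resolution=float(rng.uniform(2.0, 4.0)),
        voxel_size=1.0,
        box_pad=float(rng.uniform(6.0, 9.0)),
        seed=seed,
    )
    _, _, _, bundle = make_fixture_bundle(spec)
    bundle.validate()
    n_atoms = 5 * spec.n_residues
    assert (bundle.classification.data == 1).sum() <= n_atoms


def test_labels_depend_only_on_geometry():
    """Two maps with identical geometry but different noise give equal labels."""
    st = make_helix(4)
    noisy_a, _ = make_noisy_map(st, FixtureSpec(n_residues=4, noise_sigma=0.2, seed=1))
    noisy_b, _ = make_noisy_map(st, FixtureSpec(n_residues=4, noise_sigma=0.2, seed=2))
    p = SimulationParams(resolution=3.0)
    ba = generate_labels(st, noisy_a, p)
    bb = generate_labels(st, noisy_b, p)
    np.testing.assert_array_equal(ba.regression.data, bb.regression.data)
    np.testing.assert_array_equal(ba.classification.data, bb.classification.data)
    np.testing.assert_array_equal(ba.atom_type.data, bb.atom_type.data)


def test_generate_labels_is_deterministic(helix5, noisy_pair):
    noisy, _ = noisy_pair
    p = SimulationParams(resolution=3.0)
    a = generate_labels(helix5, noisy, p)
    b = generate_labels(helix5, noisy, p)
    np.testing.assert_array_equal(a.regression.data, b.regression.data)


# --- sub-cube extraction ---------------------------------------------------

def test_single_tile_when_volume_fits():
    vol = np.arange(64**3, dtype=np.float32).reshape(64, 64, 64)
    tiles = extract_subcubes(vol, cube_edge=64, stride=64)
    assert len(tiles) == 1 and tiles[0][0] == (0, 0, 0)
    np.testing.assert_array_equal(tiles[0][1], vol)


def test_tiling_counts_and_round_trip():
    rng = np.random.default_rng(0)
    vol = rng.normal(size=(100, 100, 100)).astype(np.float32)
    tiles = extract_subcubes(vol, cube_edge=64, stride=64)
    assert len(tiles) == 8  # ceil(100/64) = 2 per axis
    back = reassemble_subcubes(tiles, vol.shape)
    np.testing.assert_array_equal(back, vol)
    # edge tiles are zero-padded to the full cube edge
    assert all(cube.shape == (64, 64, 64) for _, cube in tiles)


def test_tiling_rejects_bad_stride():
    with pytest.raises(ValueError):
        extract_subcubes(np.zeros((8, 8, 8)), cube_edge=4, stride=0)
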
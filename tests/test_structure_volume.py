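"""Structure I/O, rigid superposition, and grid volumetrics oracles."""

import gemmi
import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from agopam import structure_volume as sv
from agopam.exceptions import GeometryError, UsageError
from agopam.synthetic_data import _write_pdb, generate_geometry_fixtures

MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  O   ALA A   1       2.000   1.200   0.000  1.00  0.00           O
HETATM    4  C1  LIG B   1       5.000   5.000   5.000  1.00  0.00           C
END
"""


@pytest.fixture()
def mini_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path


def test_read_structure_elements_radii_and_ligand_flag(mini_pdb):
    atoms = sv.read_structure(mini_pdb, ligand_codes=["LIG"])
    assert len(atoms) == 4
    assert atoms.elements == ("N", "C", "O", "C")
    assert np.allclose(atoms.radii, [1.55, 1.70, 1.52, 1.70])
    assert atoms.is_ligand.tolist() == [False, False, False, True]
    assert len(atoms.protein) == 3 and len(atoms.ligand) == 1


def test_pdb_and_mmcif_renderings_agree(mini_pdb, tmp_path):
    st = gemmi.read_structure(str(mini_pdb))
    st.setup_entities()
    cif_path = tmp_path / "mini.cif"
    st.make_mmcif_document().write_file(str(cif_path))
    a = sv.read_structure(mini_pdb, ligand_codes=["LIG"])
    b = sv.read_structure(cif_path, ligand_codes=["LIG"])
    assert a.elements == b.elements
    assert np.allclose(a.coords, b.coords, atol=1e-3)
    assert a.is_ligand.tolist() == b.is_ligand.tolist()


def test_unknown_element_falls_back_with_warning():
    with pytest.warns(UserWarning, match="unknown element"):
        r = sv.vdw_radius("Xx")
    assert r == sv.FALLBACK_RADIUS


def two_domain_structure():
    """Chain A with residues 1-10 (N-terminal domain) and 11-20 (C-terminal),
    1 atom each, plus one ligand atom."""
    n = 20
    coords = np.column_stack([np.arange(n, dtype=float) * 3.0, np.zeros(n), np.zeros(n)])
    elements = ["C"] * n + ["S"]
    coords = np.vstack([coords, [[100.0, 0.0, 0.0]]])
    return sv.AtomSet.from_arrays(
        elements,
        coords,
        is_ligand=np.array([False] * n + [True]),
        chains=("A",) * n + ("L",),
        resnames=("GLY",) * n + ("LIG",),
        resnums=tuple(range(1, n + 1)) + (1,),
        atom_names=("CA",) * n + ("S1",),
    )


def test_truncate_keeps_cterminal_domain_and_ligand():
    s = two_domain_structure()
    out = sv.truncate_to_tmd(s, {"A": 11})
    kept = [rn for rn, lig in zip(out.resnums, out.is_ligand) if not lig]
    assert kept == list(range(11, 21))
    assert out.is_ligand.sum() == 1


def test_truncate_boundary_edge_cases():
    s = two_domain_structure()
    assert len(sv.truncate_to_tmd(s, {"A": 1})) == len(s)  # boundary before first
    with pytest.raises(UsageError):
        sv.truncate_to_tmd(s, {"A": 99})  # boundary after last


def test_superpose_identity_and_rigid_motion():
    rng = np.random.default_rng(2)
    P = rng.normal(size=(10, 3))
    tr, rmsd = sv.superpose(P, P)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    R = Rotation.from_euler("zyx", [37.0, 12.0, -5.0], degrees=True).as_matrix()
    Q = P @ R.T + np.array([4.0, -2.0, 9.0])
    tr, rmsd = sv.superpose(P, Q)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.det(tr.rotation) == pytest.approx(1.0)


def test_superpose_never_reflects():
    rng = np.random.default_rng(8)
    P = rng.normal(size=(12, 3))
    mirrored = P * np.array([-1.0, 1.0, 1.0])
    tr, _ = sv.superpose(P, mirrored)
    assert np.linalg.det(tr.rotation) == pytest.approx(1.0)


def test_superpose_matches_numerical_minimization_oracle():
    """Perturbed cloud: Kabsch RMSD equals a direct optimizer over rotations."""
    rng = np.random.default_rng(3)
    P = rng.normal(scale=3.0, size=(10, 3))
    Q = P + rng.normal(scale=0.2, size=(10, 3))
    _, rmsd = sv.superpose(P, Q)

    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)

    def objective(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1)))

    best = min(
        (
            minimize(objective, x0, method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-14})
            for x0 in (np.zeros(3), np.array([0.5, -0.2, 0.1]), np.array([2.0, 1.0, -1.0]))
        ),
        key=lambda r: r.fun,
    )
    assert rmsd == pytest.approx(best.fun, abs=1e-6)


def test_superpose_degenerate_inputs():
    with pytest.raises(GeometryError):
        sv.superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(GeometryError):
        sv.superpose(line, line)


def single_atom(radius=2.0, center=(0.0, 0.0, 0.0)):
    return sv.AtomSet(
        elements=("X",), coords=np.array([center], dtype=float), radii=np.array([radius])
    )


def test_sphere_volume_within_2pct_of_analytic():
    v = sv.molecular_volume(single_atom(2.0), spacing=0.25)
    analytic = 4.0 / 3.0 * np.pi * 2.0**3
    assert v == pytest.approx(analytic, rel=0.02)


def test_union_semantics_and_monotonicity():
    a = single_atom(2.0)
    both = sv.AtomSet(
        elements=("X", "X"), coords=np.zeros((2, 3)), radii=np.array([2.0, 2.0])
    )
    grid = sv.GridSpec.from_bounds([-3] * 3, [9] * 3, spacing=0.25)
    assert sv.molecular_volume(both, grid) == sv.molecular_volume(a, grid)
    apart = sv.AtomSet(
        elements=("X", "X"),
        coords=np.array([[0.0, 0.0, 0.0], [6.0, 0.0, 0.0]]),
        radii=np.array([2.0, 2.0]),
    )
    assert sv.molecular_volume(apart, grid) > sv.molecular_volume(a, grid)


def test_volume_rigid_motion_invariance_within_grid_error():
    rng = np.random.default_rng(6)
    coords = rng.normal(scale=1.5, size=(8, 3))
    atoms = sv.AtomSet.from_arrays(["C"] * 8, coords)
    R = Rotation.from_euler("xyz", [20, 40, 60], degrees=True).as_matrix()
    moved = atoms.transformed(sv.RigidTransform(rotation=R, translation=np.array([3.1, -2.2, 0.7])))
    v1 = sv.molecular_volume(atoms, spacing=0.5)
    v2 = sv.molecular_volume(moved, spacing=0.5)
    assert v2 == pytest.approx(v1, rel=0.03)
    # refining the grid changes the estimate by < 3%
    v_fine = sv.molecular_volume(atoms, spacing=0.25)
    assert v_fine == pytest.approx(v1, rel=0.03)


def test_shell_cavity_volume_within_5pct(geometry, shell_cavity_points):
    volume = len(shell_cavity_points) * 0.5**3
    assert volume == pytest.approx(geometry["cavity_volume"], rel=0.05)


def test_cavity_points_never_inside_protein(geometry, shell_cavity_points):
    shell = geometry["shell"]
    d = np.linalg.norm(
        shell_cavity_points[:, None, :] - shell.coords[None, :, :], axis=2
    )
    assert np.all(d.min(axis=1) >= shell.radii.max() - 1e-9)


def test_no_cavity_without_protein():
    empty = sv.AtomSet(
        elements=("C",),
        coords=np.array([[50.0, 50.0, 50.0]]),
        radii=np.array([1.7]),
        is_ligand=np.array([True]),
    )
    pts = sv.detect_cavity_points(empty, (0.0, 0.0, 0.0), 5.0, spacing=0.5)
    assert pts.shape[0] == 0


def test_pocket_filter_cutoffs(geometry, shell_cavity_points):
    lig = geometry["ligand"]
    full = sv.pocket_volume(shell_cavity_points, [lig], cutoff=np.inf, spacing=0.5)
    assert full.volume == pytest.approx(len(shell_cavity_points) * 0.125)
    nothing = sv.pocket_volume(shell_cavity_points, [lig], cutoff=0.0, spacing=0.5)
    assert nothing.n_points == 0 and nothing.volume == 0.0
    # the centered ligand reaches every cavity point within 4.5 A + inner radius
    kept = sv.pocket_volume(shell_cavity_points, [lig], cutoff=4.5, spacing=0.5)
    assert kept.n_points == len(shell_cavity_points)
    with pytest.raises(UsageError):
        sv.pocket_volume(shell_cavity_points, [], cutoff=4.5, spacing=0.5)


def test_pocket_result_invariant():
    with pytest.raises(ValueError):
        sv.PocketResult(n_points=10, volume=99.0, spacing=0.5, cutoff=4.5, opening=8.0)


def test_geometry_fixture_round_trip(tmp_path):
    fx = generate_geometry_fixtures(seed=1, outdir=tmp_path)
    shell = sv.read_structure(fx["files"]["shell"])
    assert len(shell) == len(fx["shell"])
    assert np.allclose(shell.coords, fx["shell"].coords, atol=1e-3)
    lig = sv.read_structure(fx["files"]["ligand"], ligand_codes=["LIG"])
    assert lig.is_ligand.all()


def test_ligand_from_smiles_deterministic_and_plausible():
    a = sv.ligand_from_smiles(sv.RAC_BHFF_SMILES, seed=20)
    b = sv.ligand_from_smiles(sv.RAC_BHFF_SMILES, seed=20)
    assert np.allclose(a.coords, b.coords)
    # heavy-atom count of the drawn structure: C17 F3 O3 = 23
    assert len(a.heavy) == 23
    with pytest.raises(UsageError):
        sv.ligand_from_smiles("not a smiles")


def test_write_points_pdb_readable(tmp_path):
    pts = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]])
    out = tmp_path / "points.pdb"
    sv.write_points_pdb(pts, out)
    text = out.read_text()
    assert text.count("HETATM") == 2 and text.strip().endswith("END")
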
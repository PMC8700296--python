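"""Structure handling and grid-based volumetrics.

Reads receptor structures (PDB/mmCIF via gemmi) and small-molecule ligands
(SDF or SMILES via RDKit), superposes structures rigidly (Kabsch), and
computes two kinds of volume on a regular Cartesian grid:

* **molecular (van-der-Waals) volume** — the volume of the union of atomic
  vdW spheres, counted as grid points whose centers fall inside any sphere,
  times the grid-cell volume ``h**3``;
* **binding-pocket volume** — cavity "site points" detected by a ray-burial
  criterion (a point is part of a cavity if it is outside every protein
  atom, inside a focus region, and a sufficient fraction of 26 rays cast
  from it hit protein within a site-opening distance), filtered to points
  lying within a distance cutoff of bound ligand atoms, times ``h**3``.

Defaults follow the published convention for the transmembrane PAM pocket:
0.5 Å grid spacing, 8 Å site opening, 4.5 Å ligand-proximity cutoff.  The
original cavity detection was done with proprietary software whose
site-point definition is not public; the ray-burial method here is a
documented replacement sharing the two stated parameters, so pocket volumes
agree approximately, not bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from agopam.exceptions import GeometryError, UsageError

__all__ = [
    "BONDI_RADII",
    "AtomSet",
    "GridSpec",
    "PocketResult",
    "RigidTransform",
    "read_structure",
    "truncate_to_tmd",
    "superpose",
    "molecular_volume",
    "detect_cavity_points",
    "pocket_volume",
    "ligand_from_smiles",
    "ligand_from_sdf",
    "write_points_pdb",
]

#: Bondi van-der-Waals radii (Å) for the elements that occur in receptors
#: and drug-like ligands; unknown elements fall back to carbon's 1.7 Å.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}
FALLBACK_RADIUS = 1.70

#: SMILES of the published GABA_B PAM chemotypes (drawn structures).
GS39783_SMILES = "CSc1nc(NC2CCCC2)c([N+](=O)[O-])c(NC3CCCC3)n1"
RAC_BHFF_SMILES = "CC(C)(C)c1cc(C(C)(C)C)c2OC(=O)C(O)(C(F)(F)F)c2c1"
CGP7930_SMILES = "CC(C)(C)c1cc(CC(C)(O)CC(C)C)cc(C(C)(C)C)c1O"


def vdw_radius(element: str) -> float:
    r = BONDI_RADII.get(element.upper())
    if r is None:
        warnings.warn(f"unknown element {element!r}: using {FALLBACK_RADIUS} Å")
        return FALLBACK_RADIUS
    return r


@dataclass(frozen=True)
class AtomSet:
    """A bag of atoms with coordinates, vdW radii and minimal annotation."""

    elements: tuple  # element symbols
    coords: np.ndarray  # (N, 3) Å
    radii: np.ndarray  # (N,) Å
    chains: tuple = ()
    resnames: tuple = ()
    resnums: tuple = ()
    atom_names: tuple = ()
    is_ligand: np.ndarray = None  # (N,) bool

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        n = coords.shape[0]
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=float))
        if self.is_ligand is None:
            object.__setattr__(self, "is_ligand", np.zeros(n, dtype=bool))
        else:
            object.__setattr__(self, "is_ligand", np.asarray(self.is_ligand, dtype=bool))
        for name in ("chains", "resnames", "resnums", "atom_names"):
            if not getattr(self, name):
                object.__setattr__(self, name, ("",) * n if name != "resnums" else (0,) * n)
        if coords.shape != (n, 3) or not np.all(np.isfinite(coords)):
            raise ValueError("coords must be a finite (N, 3) array")
        if self.radii.shape != (n,) or np.any(self.radii <= 0):
            raise ValueError("radii must be positive, one per atom")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_arrays(cls, elements, coords, is_ligand=None, **kw) -> "AtomSet":
        radii = np.array([vdw_radius(e) for e in elements])
        return cls(
            elements=tuple(elements), coords=coords, radii=radii, is_ligand=is_ligand, **kw
        )

    def subset(self, mask: np.ndarray) -> "AtomSet":
        mask = np.asarray(mask, dtype=bool)
        pick = lambda t: tuple(v for v, m in zip(t, mask) if m)  # noqa: E731
        return AtomSet(
            elements=pick(self.elements),
            coords=self.coords[mask],
            radii=self.radii[mask],
            chains=pick(self.chains),
            resnames=pick(self.resnames),
            resnums=pick(self.resnums),
            atom_names=pick(self.atom_names),
            is_ligand=self.is_ligand[mask],
        )

    @property
    def protein(self) -> "AtomSet":
        return self.subset(~self.is_ligand)

    @property
    def ligand(self) -> "AtomSet":
        return self.subset(self.is_ligand)

    @property
    def heavy(self) -> "AtomSet":
        """Non-hydrogen atoms (the crystal-structure volume convention)."""
        return self.subset(np.array([e.upper() != "H" for e in self.elements]))

    def transformed(self, transform: "RigidTransform") -> "AtomSet":
        return AtomSet(
            elements=self.elements,
            coords=transform.apply(self.coords),
            radii=self.radii,
            chains=self.chains,
            resnames=self.resnames,
            resnums=self.resnums,
            atom_names=self.atom_names,
            is_ligand=self.is_ligand,
        )


def read_structure(path, ligand_codes=()) -> AtomSet:
    """Read a PDB or mmCIF file into an :class:`AtomSet`.

    Atoms whose residue name is in ``ligand_codes`` (or that are HETATM
    records other than water) are flagged as ligand atoms.  vdW radii are
    assigned from the Bondi set by element.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    codes = {c.upper() for c in ligand_codes}
    elements, coords, chains, resnames, resnums, names, lig = [], [], [], [], [], [], []
    model = st[0]
    for chain in model:
        for residue in chain:
            resname = residue.name.upper()
            if resname == "HOH":
                continue
            het = residue.het_flag == "H"
            for atom in residue:
                elements.append(atom.element.name.upper())
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                chains.append(chain.name)
                resnames.append(resname)
                resnums.append(residue.seqid.num)
                names.append(atom.name)
                lig.append(resname in codes or (het and not codes))
    if not elements:
        raise UsageError(f"no atoms read from {path}")
    return AtomSet.from_arrays(
        elements,
        np.asarray(coords),
        is_ligand=np.asarray(lig),
        chains=tuple(chains),
        resnames=tuple(resnames),
        resnums=tuple(resnums),
        atom_names=tuple(names),
    )


def truncate_to_tmd(structure: AtomSet, boundary_residues: dict) -> AtomSet:
    """Drop the extracellular portion of each receptor chain.

    ``boundary_residues`` maps a chain id to the first residue number of the
    transmembrane domain; protein residues before the boundary are removed.
    Ligand atoms and chains without a boundary entry are kept unchanged.
    """
    resnums = np.asarray(structure.resnums)
    chains = np.asarray(structure.chains)
    keep = structure.is_ligand.copy()
    for i in range(len(structure)):
        if structure.is_ligand[i]:
            continue
        bound = boundary_residues.get(chains[i])
        keep[i] = bound is None or resnums[i] >= bound
    for chain_id, bound in boundary_residues.items():
        chain_prot = (chains == chain_id) & ~structure.is_ligand
        if chain_prot.any() and not (keep & chain_prot).any():
            raise UsageError(
                f"boundary {bound} removes every residue of chain {chain_id!r}"
            )
    if not keep.any():
        raise UsageError("truncation removed every atom")
    return structure.subset(keep)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` (rotation determinant +1)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def _ca_pairs(mobile: AtomSet, reference: AtomSet):
    """Match shared Cα atoms by (chain, residue number)."""

    def ca_index(s: AtomSet):
        return {
            (s.chains[i], s.resnums[i]): i
            for i in range(len(s))
            if s.atom_names[i] == "CA" and not s.is_ligand[i]
        }

    mi, ri = ca_index(mobile), ca_index(reference)
    shared = sorted(set(mi) & set(ri))
    return (
        mobile.coords[[mi[k] for k in shared]],
        reference.coords[[ri[k] for k in shared]],
    )


def superpose(mobile, reference, selection: str = "CA"):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Accepts :class:`AtomSet` pairs (matched on shared Cα atoms when
    ``selection == "CA"``) or two paired ``(N, 3)`` coordinate arrays.
    Returns ``(RigidTransform, rmsd)`` where the RMSD is measured after
    applying the transform.  The rotation is constrained to be proper
    (determinant +1): a reflection is never produced, even when it would fit
    better.  Fewer than 3 pairs, or a collinear point set, leaves the
    rotation underdetermined and raises :class:`GeometryError`.
    """
    if isinstance(mobile, AtomSet) and isinstance(reference, AtomSet):
        if selection != "CA":
            raise UsageError(f"unknown selection {selection!r}")
        P, Q = _ca_pairs(mobile, reference)
    else:
        P, Q = np.asarray(mobile, dtype=float), np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("superposition needs two equal (N, 3) coordinate sets")
    if P.shape[0] < 3:
        raise GeometryError(f"need >= 3 paired atoms, got {P.shape[0]}")
    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise GeometryError("collinear points: rotation underdetermined")
    # Kabsch: SVD of the covariance, with the smallest singular direction
    # flipped if needed to keep det(R) = +1.
    U, _, Vt = np.linalg.svd(Pc.T @ Qc)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    transform = RigidTransform(rotation=R, translation=t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(P) - Q) ** 2, axis=1))))
    return transform, rmsd


@dataclass(frozen=True)
class GridSpec:
    """Regular Cartesian grid: ``origin + h * (i, j, k)``."""

    origin: tuple
    spacing: float
    dims: tuple  # (nx, ny, nz)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(int(d) < 1 for d in self.dims):
            raise ValueError("dims must be >= 1")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @classmethod
    def from_bounds(cls, lower, upper, spacing: float = 0.5, padding: float = 0.0):
        """Grid covering [lower - padding, upper + padding], origin snapped
        to one spacing below the padded lower corner."""
        lower = np.asarray(lower, dtype=float) - padding
        upper = np.asarray(upper, dtype=float) + padding
        if np.any(upper < lower):
            raise ValueError("upper bound below lower bound")
        origin = lower - spacing
        dims = np.ceil((upper - origin) / spacing).astype(int) + 1
        return cls(origin=tuple(origin), spacing=spacing, dims=tuple(dims))

    @classmethod
    def around_atoms(cls, atoms: AtomSet, spacing: float = 0.5, padding: float = 0.0):
        pad = float(atoms.radii.max()) + padding
        return cls.from_bounds(
            atoms.coords.min(axis=0), atoms.coords.max(axis=0), spacing, padding=pad
        )

    @property
    def cell_volume(self) -> float:
        return self.spacing**3

    def points(self) -> np.ndarray:
        """All grid-point coordinates, shape (nx*ny*nz, 3)."""
        axes = [
            self.origin[k] + self.spacing * np.arange(self.dims[k]) for k in range(3)
        ]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


@dataclass(frozen=True)
class PocketResult:
    """Site-point count and pocket volume with the parameters that made it."""

    n_points: int
    volume: float  # Å³, exactly n_points * spacing**3
    spacing: float
    cutoff: float
    opening: float

    def __post_init__(self) -> None:
        expected = self.n_points * self.spacing**3
        if not np.isclose(self.volume, expected):
            raise ValueError("volume must equal n_points * spacing**3")


def molecular_volume(atoms: AtomSet, grid: GridSpec = None, spacing: float = 0.5) -> float:
    """Fused-sphere van-der-Waals volume (Å³) on a regular grid.

    Counts grid points whose centers lie strictly inside the vdW sphere of
    at least one atom; overlapping spheres are counted once (union
    semantics).  With no explicit ``grid``, one is built around the atoms
    with enough padding to contain every sphere.
    """
    if len(atoms) == 0:
        warnings.warn("empty AtomSet: volume 0")
        return 0.0
    if grid is None:
        grid = GridSpec.around_atoms(atoms, spacing=spacing)
    counted = np.zeros(grid.dims, dtype=bool)
    origin = np.asarray(grid.origin)
    h = grid.spacing
    for center, r in zip(atoms.coords, atoms.radii):
        lo = np.maximum(np.floor((center - r - origin) / h).astype(int), 0)
        hi = np.minimum(np.ceil((center + r - origin) / h).astype(int) + 1, grid.dims)
        if np.any(hi <= lo):
            continue
        axes = [origin[k] + h * np.arange(lo[k], hi[k]) for k in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        inside = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 < r**2
        counted[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= inside
    return int(counted.sum()) * grid.cell_volume


# 26 ray directions: all neighbours of a cube vertex, normalized.
_RAY_DIRECTIONS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ],
    dtype=float,
)
_RAY_DIRECTIONS /= np.linalg.norm(_RAY_DIRECTIONS, axis=1, keepdims=True)


def detect_cavity_points(
    structure: AtomSet,
    focus_center,
    focus_radius: float,
    grid: GridSpec = None,
    opening: float = 8.0,
    spacing: float = 0.5,
    burial_fraction: float = 2.0 / 3.0,
) -> np.ndarray:
    """Cavity site points inside a focus sphere, by ray burial.

    A grid point qualifies when it is (a) outside every protein atom's vdW
    sphere, (b) within ``focus_radius`` of ``focus_center``, and (c) buried:
    at least ``burial_fraction`` of 26 rays cast from it hit protein within
    the site-opening distance.  Rays are marched in steps of half the grid
    spacing; a sample "hits" when it falls inside the vdW sphere of its
    nearest protein atom.

    Returns the qualifying points as an ``(M, 3)`` array.
    """
    protein = structure.protein
    focus_center = np.asarray(focus_center, dtype=float)
    if grid is None:
        grid = GridSpec.from_bounds(
            focus_center - focus_radius, focus_center + focus_radius, spacing
        )
    pts = grid.points()
    if pts.size == 0:
        raise UsageError("empty grid")
    pts = pts[np.linalg.norm(pts - focus_center, axis=1) <= focus_radius]
    if len(protein) == 0 or pts.size == 0:
        return np.empty((0, 3))

    tree = cKDTree(protein.coords)
    r_max = float(protein.radii.max())

    def inside_protein(samples: np.ndarray) -> np.ndarray:
        dist, idx = tree.query(samples, distance_upper_bound=r_max)
        hit = np.isfinite(dist)
        hit[hit] &= dist[hit] < protein.radii[idx[hit]]
        return hit

    pts = pts[~inside_protein(pts)]
    if pts.size == 0:
        return np.empty((0, 3))

    step = grid.spacing / 2.0
    arc = np.arange(step, opening + step / 2, step)
    hits = np.zeros(len(pts), dtype=int)
    for d in _RAY_DIRECTIONS:
        samples = pts[:, None, :] + arc[None, :, None] * d  # (M, S, 3)
        ray_hit = inside_protein(samples.reshape(-1, 3)).reshape(len(pts), arc.size)
        hits += ray_hit.any(axis=1)
    buried = hits >= burial_fraction * len(_RAY_DIRECTIONS)
    return pts[buried]


def pocket_volume(
    cavity_points: np.ndarray,
    ligands,
    cutoff: float = 4.5,
    grid: GridSpec = None,
    spacing: float = 0.5,
    opening: float = 8.0,
) -> PocketResult:
    """Volume of the cavity restricted to the ligand-proximal site points.

    Keeps cavity points at a distance strictly less than ``cutoff`` from any
    atom of any supplied ligand (all in a common frame, i.e. after
    superposition), and reports ``n_points * spacing**3``.
    """
    ligands = list(ligands)
    if not ligands or all(len(lig) == 0 for lig in ligands):
        raise UsageError("need at least one non-empty ligand AtomSet")
    h = grid.spacing if grid is not None else spacing
    cavity_points = np.asarray(cavity_points, dtype=float).reshape(-1, 3)
    if cavity_points.shape[0] == 0:
        return PocketResult(0, 0.0, h, cutoff, opening)
    lig_coords = np.vstack([lig.coords for lig in ligands if len(lig)])
    dist, _ = cKDTree(lig_coords).query(cavity_points)
    n = int((dist < cutoff).sum())
    return PocketResult(n, n * h**3, h, cutoff, opening)


def _mol_to_atomset(mol) -> AtomSet:
    conf = mol.GetConformer()
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
         for i in range(mol.GetNumAtoms())]
    )
    lig = np.ones(len(elements), dtype=bool)
    return AtomSet.from_arrays(elements, coords, is_ligand=lig)


def ligand_from_smiles(smiles: str, seed: int = 20, add_hs: bool = True) -> AtomSet:
    """Build one energy-minimized 3D conformer from a SMILES string.

    Embedding uses the ETKDG distance-geometry method with a fixed random
    seed, followed by MMFF94 minimization; hydrogens are explicit by
    default so the fused-sphere volume reflects the full molecule.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise UsageError(f"unparsable SMILES: {smiles!r}")
    if add_hs:
        mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise UsageError(f"3D embedding failed for {smiles!r}")
    AllChem.MMFFOptimizeMolecule(mol)
    return _mol_to_atomset(mol)


def ligand_from_sdf(path, add_hs: bool = True) -> AtomSet:
    """Read the first molecule of an SDF file, keeping its coordinates."""
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise UsageError(f"no readable molecule in {path}")
    if add_hs and not any(a.GetSymbol() == "H" for a in mol.GetAtoms()):
        from rdkit.Chem import AllChem

        mol = Chem.AddHs(mol, addCoords=True)
        AllChem.MMFFOptimizeMolecule(mol)
    return _mol_to_atomset(mol)


def write_points_pdb(points: np.ndarray, path) -> None:
    """Dump grid points as pseudo-atoms (HETATM, element X) for inspection."""
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(np.asarray(points, dtype=float), start=1):
            fh.write(
                f"HETATM{i % 100000:5d}  X   PNT P{i % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           X\n"
            )
        fh.write("END\n")
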
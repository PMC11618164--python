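"""Deterministic desk-scale fixtures: toy protein-ligand complexes with
known ground truth.

Pockets are synthetic peptide cages: backbone-only residues placed on a
shell around the ligand pose(s), inside a distance window that guarantees
(a) no covalent contact and (b) every residue lies within the pocket
radius of every ligand pose it is supposed to select.  The cages are not
physically realistic folds; every operator under test depends only on
geometry, sequence identity and chemistry.

Two ready-made scenarios are provided:

* :func:`make_filter_scenario` -- twelve ligand instances of which exactly
  one violates each selection step and two survive;
* :func:`make_ensemble_scenario` -- four identical-pocket families that
  exercise superposition, SMILES deduplication, singleton removal, the
  cluster-merge path, representative picking and the full range of
  Shape Tversky difficulty bins.

Scenario content is a pure function of the structure of the generator
(fixed internal seeds); the user-facing ``seed`` only randomizes the
rigid placement of each structure in space, so every documented expected
outcome holds for any seed.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .pair_shapes import vdw_radius

POCKET_RADIUS = 6.5

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_LETTERS = "".join(sorted(ONE_TO_THREE))


# ---------------------------------------------------------------------------
# molecule construction

def build_molecule(smiles: str, seed: int = 0xD06) -> Chem.Mol:
    """Embedded 3D conformer (with hydrogens) in the principal frame:
    heavy-atom centroid at the origin, long axis along x."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    if AllChem.EmbedMolecule(mol, randomSeed=seed) != 0:
        # large/flexible molecules: retry from random coordinates
        params = AllChem.ETKDGv3()
        params.randomSeed = seed
        params.useRandomCoords = True
        params.maxIterations = 500
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise RuntimeError(f"embedding failed for {smiles!r} (seed {seed})")
        AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    _to_principal_frame(mol)
    return mol


def _to_principal_frame(mol: Chem.Mol) -> None:
    conf = mol.GetConformer()
    coords = np.array(
        [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
    )
    heavy = np.array([a.GetAtomicNum() > 1 for a in mol.GetAtoms()])
    center = coords[heavy].mean(axis=0)
    coords -= center
    u, s, vt = np.linalg.svd(coords[heavy], full_matrices=False)
    rot = vt  # rows: principal axes, largest variance first
    if np.linalg.det(rot) < 0:
        rot[2] *= -1
    coords = coords @ rot.T
    # fix axis signs deterministically via the first heavy atom
    first = coords[np.flatnonzero(heavy)[0]]
    for ax in range(3):
        if first[ax] < -1e-9:
            coords[:, ax] *= -1
    if np.linalg.det(np.eye(3)) < 0:  # pragma: no cover
        coords[:, 2] *= -1
    for i in range(mol.GetNumAtoms()):
        conf.SetAtomPosition(i, coords[i].tolist())


def mol_atoms(mol: Chem.Mol, transform=None) -> list[tuple[str, np.ndarray, bool]]:
    conf = mol.GetConformer()
    out = []
    for atom in mol.GetAtoms():
        pos = np.array(list(conf.GetAtomPosition(atom.GetIdx())))
        if transform is not None:
            pos = transform(pos)
        out.append((atom.GetSymbol(), pos, atom.GetAtomicNum() == 1))
    return out


def substructure_coords(host: Chem.Mol, pattern_smiles: str) -> np.ndarray:
    """Heavy-atom coordinates of ``pattern`` as matched inside ``host``."""
    pattern = Chem.MolFromSmiles(pattern_smiles)
    match = Chem.RemoveHs(host).GetSubstructMatch(pattern)
    if not match:
        raise ValueError(f"{pattern_smiles!r} not found in host")
    heavy_host = Chem.RemoveHs(host)
    conf = heavy_host.GetConformer()
    return np.array([list(conf.GetAtomPosition(i)) for i in match])


def place_on_coords(mol: Chem.Mol, target_heavy: np.ndarray) -> Chem.Mol:
    """Rigidly align a molecule's heavy atoms onto target coordinates
    (least squares), moving hydrogens along."""
    from scipy.spatial.transform import Rotation

    mol = Chem.Mol(mol)
    conf = mol.GetConformer()
    coords = np.array(
        [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
    )
    heavy_idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    src = coords[heavy_idx]
    src_c, tgt_c = src.mean(axis=0), target_heavy.mean(axis=0)
    rot, _ = Rotation.align_vectors(target_heavy - tgt_c, src - src_c)
    moved = rot.apply(coords - src_c) + tgt_c
    for i in range(mol.GetNumAtoms()):
        conf.SetAtomPosition(i, moved[i].tolist())
    return mol


def transform_mol(mol: Chem.Mol, offset=(0.0, 0.0, 0.0), z_rot_deg: float = 0.0) -> Chem.Mol:
    mol = Chem.Mol(mol)
    conf = mol.GetConformer()
    th = math.radians(z_rot_deg)
    rot = np.array(
        [[math.cos(th), -math.sin(th), 0.0],
         [math.sin(th), math.cos(th), 0.0],
         [0.0, 0.0, 1.0]]
    )
    off = np.asarray(offset, dtype=float)
    for i in range(mol.GetNumAtoms()):
        pos = np.array(list(conf.GetAtomPosition(i)))
        conf.SetAtomPosition(i, (rot @ pos + off).tolist())
    return mol


def heavy_coords_of(mol: Chem.Mol) -> np.ndarray:
    conf = mol.GetConformer()
    return np.array(
        [list(conf.GetAtomPosition(a.GetIdx()))
         for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    )


# ---------------------------------------------------------------------------
# cage construction

@dataclass
class CageResidue:
    resname: str
    resnum: int
    backbone: dict[str, np.ndarray]  # N, CA, C, O


def build_cage(
    clearance_poses: list[np.ndarray],
    selection_poses: list[np.ndarray] | None,
    min_clear: float = 3.0,
    max_select: float = 5.9,
    min_sep: float = 3.2,
    grid_spacing: float = 1.0,
    n_residues: int | None = None,
) -> list[np.ndarray]:
    """CA positions on a shell around the ligand pose(s).

    Every position is at least ``min_clear`` from every atom of every
    clearance pose.  If ``selection_poses`` is given, every position is
    within ``max_select`` of *each* of those poses (so each pose selects
    the full cage under the pocket radius); otherwise within
    ``max_select`` of the union (a plain enclosing shell).
    Deterministic: candidates come from a fixed raster, greedily thinned
    to ``min_sep``.
    """
    union = np.vstack(clearance_poses)
    lo = union.min(axis=0) - (max_select + grid_spacing)
    hi = union.max(axis=0) + (max_select + grid_spacing)
    axes = [np.arange(lo[i], hi[i] + grid_spacing, grid_spacing) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def _min_dist(pts, pose):
        d = np.linalg.norm(pts[:, None, :] - pose[None, :, :], axis=-1)
        return d.min(axis=1)

    ok = _min_dist(points, union) >= min_clear
    if selection_poses is None:
        ok &= _min_dist(points, union) <= max_select
    else:
        for pose in selection_poses:
            ok &= _min_dist(points, pose) <= max_select
    candidates = points[ok]

    kept: list[np.ndarray] = []
    for cand in candidates:
        if all(np.linalg.norm(cand - k) >= min_sep for k in kept):
            kept.append(cand)
            if n_residues is not None and len(kept) == n_residues:
                break
    if n_residues is not None and len(kept) < n_residues:
        raise ValueError(
            f"cage infeasible: only {len(kept)} of {n_residues} positions"
        )
    return kept


def plan_backbones(
    ca_positions: list[np.ndarray],
    ligand_union: np.ndarray,
    clear_floor: float = 2.2,
) -> list[dict[str, np.ndarray]]:
    """Expand CA positions into backbone atom sets (N, CA, C, O) in the
    tangent plane of the shell.

    For each residue the tangent frame is rotated to maximize the
    backbone's minimum distance to the ligand atoms; residues that cannot
    reach ``clear_floor`` are dropped, so the cage never triggers the
    covalent-contact rule."""
    backbones = []
    for ca in ca_positions:
        d = np.linalg.norm(ligand_union - ca, axis=1)
        inward = ligand_union[np.argmin(d)] - ca
        inward /= np.linalg.norm(inward)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, inward)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        t1_base = np.cross(inward, helper)
        t1_base /= np.linalg.norm(t1_base)
        t2_base = np.cross(inward, t1_base)

        best, best_clear = None, -np.inf
        for angle in np.linspace(0.0, np.pi, 12, endpoint=False):
            t1 = math.cos(angle) * t1_base + math.sin(angle) * t2_base
            t2 = np.cross(inward, t1)
            backbone = {
                "N": ca + 1.46 * t1,
                "CA": ca.copy(),
                "C": ca - 1.52 * t1,
                "O": ca - 1.52 * t1 + 1.23 * t2,
            }
            clear = min(
                np.linalg.norm(ligand_union - p, axis=1).min()
                for p in backbone.values()
            )
            if clear > best_clear:
                best, best_clear = backbone, clear
        if best_clear >= clear_floor:
            backbones.append(best)
    return backbones


def cage_residues(
    backbones: list[dict[str, np.ndarray]], sequence: str
) -> list[CageResidue]:
    if len(sequence) != len(backbones):
        raise ValueError("sequence length must match number of residues")
    return [
        CageResidue(resname=ONE_TO_THREE[letter], resnum=i + 1, backbone=bb)
        for i, (bb, letter) in enumerate(zip(backbones, sequence))
    ]


# ---------------------------------------------------------------------------
# complexes and PDB serialization

@dataclass
class ToyLigand:
    het: str
    chain: str
    resnum: int
    atoms: list[tuple[str, np.ndarray, bool]]  # element, xyz, is_hydrogen

    def heavy_coords(self) -> np.ndarray:
        return np.array([p for e, p, h in self.atoms if not h])

    @property
    def key_str(self) -> str:
        return f"{self.het}:{self.chain}:{self.resnum}"


@dataclass
class ToyComplex:
    entry_id: str
    resolution: float | None
    release_date: _dt.date
    residues: list[CageResidue]
    ligands: list[ToyLigand]
    chain_id: str = "A"

    @property
    def sequence(self) -> str:
        three_to_one = {v: k for k, v in ONE_TO_THREE.items()}
        return "".join(three_to_one[r.resname] for r in self.residues)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ToyComplex":
        def _t(p):
            return rotation @ p + translation

        residues = [
            CageResidue(
                r.resname, r.resnum,
                {k: _t(v) for k, v in r.backbone.items()},
            )
            for r in self.residues
        ]
        ligands = [
            ToyLigand(
                l.het, l.chain, l.resnum,
                [(e, _t(p), h) for e, p, h in l.atoms],
            )
            for l in self.ligands
        ]
        return ToyComplex(
            self.entry_id, self.resolution, self.release_date,
            residues, ligands, self.chain_id,
        )

    def to_pdb_text(self) -> str:
        date = self.release_date.strftime("%d-%b-%y").upper()
        lines = [
            "HEADER    " + "SYNTHETIC COMPLEX".ljust(40)
            + f"{date:>9}   {self.entry_id.upper():<4}"
        ]
        if self.resolution is not None:
            lines.append(
                f"REMARK   2 RESOLUTION.    {self.resolution:4.2f} ANGSTROMS."
            )

        def _coord_line(record, serial, name, resname, chain, resnum,
                        pos, element):
            x, y, z = pos
            return (
                f"{record:<6s}{serial:5d} {name:<4s} {resname:>3s} "
                f"{chain:1s}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{20.0:6.2f}"
                f"          {element:>2s}"
            )

        serial = 1
        for res in self.residues:
            for name in ("N", "CA", "C", "O"):
                element = "N" if name == "N" else "O" if name == "O" else "C"
                lines.append(
                    _coord_line("ATOM", serial, name, res.resname,
                                self.chain_id, res.resnum,
                                res.backbone[name], element)
                )
                serial += 1
        lines.append("TER")
        for lig in self.ligands:
            counts: dict[str, int] = {}
            for element, pos, _is_h in lig.atoms:
                counts[element] = counts.get(element, 0) + 1
                name = f"{element.upper()}{counts[element]}"[:4]
                lines.append(
                    _coord_line("HETATM", serial, name, lig.het,
                                lig.chain, lig.resnum, pos, element.upper())
                )
                serial += 1
        lines.append("END")
        return "\n".join(lines) + "\n"

    def pocket_residue_numbers(self, ligand_index: int = 0,
                               radius: float = POCKET_RADIUS) -> list[int]:
        """Residues within the pocket radius of the ligand, computed
        directly from the construction coordinates (ground truth)."""
        lig = np.array([p for _e, p, _h in self.ligands[ligand_index].atoms])
        out = []
        for res in self.residues:
            bb = np.array(list(res.backbone.values()))
            d = np.linalg.norm(bb[:, None, :] - lig[None, :, :], axis=-1)
            if d.min() <= radius:
                out.append(res.resnum)
        return out

    def manifest_row(self) -> dict:
        lig = self.ligands[0]
        return {
            "entry_id": self.entry_id,
            "resolution": self.resolution,
            "release_date": self.release_date.isoformat(),
            "n_chains": 1,
            "n_residues": len(self.residues),
            "sequence": self.sequence,
            "ligands": [
                {
                    "het": l.het,
                    "chain": l.chain,
                    "resnum": l.resnum,
                    "n_heavy_atoms": int(sum(1 for _e, _p, h in l.atoms if not h)),
                    "n_atoms": len(l.atoms),
                }
                for l in self.ligands
            ],
            "pocket_residues": self.pocket_residue_numbers(),
        }


def make_toy_complex(
    pocket_sequence: str,
    ligand_smiles: str,
    entry_id: str = "t001",
    resolution: float = 1.8,
    release_date: _dt.date = _dt.date(2015, 6, 1),
    het: str = "LIG",
    seed: int = 0xD06,
) -> tuple[str, dict]:
    """One synthetic complex: a peptide cage of ``len(pocket_sequence)``
    residues around an embedded conformer of ``ligand_smiles``.

    Returns (PDB text, manifest row with ground-truth counts and the
    pocket residue list).
    """
    try:
        mol = build_molecule(ligand_smiles, seed=seed)
    except (ValueError, RuntimeError) as exc:
        raise RuntimeError(
            f"ligand embedding failed (smiles={ligand_smiles!r}, seed={seed}): {exc}"
        ) from exc
    atoms = mol_atoms(mol)
    pose = heavy_coords_of(mol)
    positions = build_cage([pose], None, max_select=5.9)
    backbones = plan_backbones(positions, pose)
    if len(backbones) < len(pocket_sequence):
        raise ValueError(
            f"cage infeasible: only {len(backbones)} of "
            f"{len(pocket_sequence)} residues placeable"
        )
    residues = cage_residues(
        backbones[: len(pocket_sequence)], pocket_sequence
    )
    complex_ = ToyComplex(
        entry_id=entry_id,
        resolution=resolution,
        release_date=release_date,
        residues=residues,
        ligands=[ToyLigand(het=het, chain="A", resnum=301, atoms=atoms)],
    )
    return complex_.to_pdb_text(), complex_.manifest_row()


# ---------------------------------------------------------------------------
# deformation fields (controllable backbone RMSD geometry)

def _rigid_free_field(n_atoms: int, coords: np.ndarray, rng) -> np.ndarray:
    """Zero-mean, rotation-free random displacement field of unit RMS."""
    d = rng.normal(size=(n_atoms, 3))
    d -= d.mean(axis=0)
    r = coords - coords.mean(axis=0)
    # remove the infinitesimal-rotation component: solve M w = sum r x d
    m = np.zeros((3, 3))
    for ri in r:
        m += np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri)
    w = np.linalg.solve(m, np.cross(r, d).sum(axis=0))
    d -= np.cross(np.tile(w, (len(r), 1)), r)
    d -= d.mean(axis=0)
    return d / np.sqrt((d ** 2).sum(axis=1).mean())


def deformation_basis(coords: np.ndarray, seed: int = 1234) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    d1 = _rigid_free_field(len(coords), coords, rng)
    d2 = _rigid_free_field(len(coords), coords, rng)
    d2 = d2 - d1 * (d1 * d2).sum() / (d1 * d1).sum()
    d2 /= np.sqrt((d2 ** 2).sum(axis=1).mean())
    return d1, d2


def random_rigid_transform(rng) -> tuple[np.ndarray, np.ndarray]:
    from scipy.spatial.transform import Rotation

    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    rotation = Rotation.from_quat(quat).as_matrix()
    translation = rng.uniform(-20.0, 20.0, size=3)
    return rotation, translation


# ---------------------------------------------------------------------------
# Monte-Carlo shape oracle (generator-side ground truth for subset labels)

def mc_shape_tversky(
    t_coords: np.ndarray, t_elements, q_coords: np.ndarray, q_elements,
    n_samples: int = 200_000, seed: int = 99,
) -> float:
    """Shape Tversky (t=1, q=0) by uniform point sampling over the
    template's bounding box: fraction of template volume covered by the
    query."""
    rng = np.random.default_rng(seed)
    t_radii = np.array([vdw_radius(e) for e in t_elements])
    q_radii = np.array([vdw_radius(e) for e in q_elements])
    lo = (t_coords - t_radii[:, None]).min(axis=0)
    hi = (t_coords + t_radii[:, None]).max(axis=0)
    pts = rng.uniform(lo, hi, size=(n_samples, 3))

    def _inside(points, coords, radii):
        d2 = ((points[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
        return (d2 <= (radii ** 2)[None, :]).any(axis=1)

    in_t = _inside(pts, t_coords, t_radii)
    if not in_t.any():
        raise ValueError("template volume empty")
    in_q = _inside(pts[in_t], q_coords, q_radii)
    return float(in_q.sum() / in_t.sum())


# ---------------------------------------------------------------------------
# scenarios

@dataclass
class Scenario:
    """Generated structures plus tables and the expected-outcome manifest."""

    structures: dict[str, str]  # entry_id -> PDB text
    activity_tsv: str
    edia_tsv: str
    manifest: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for entry_id, text in sorted(self.structures.items()):
            (outdir / f"{entry_id}.pdb").write_text(text)
        (outdir / "activity.tsv").write_text(self.activity_tsv)
        (outdir / "edia.tsv").write_text(self.edia_tsv)
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True, default=str)
            + "\n"
        )


def _activity_tsv(rows) -> str:
    lines = ["entry_id\thet\ttype\tvalue\tunit\tsource"]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    return "\n".join(lines) + "\n"


def _edia_tsv(rows) -> str:
    lines = ["entry_id\thet\tchain\tresnum\tedia_m"]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    return "\n".join(lines) + "\n"


SMILES = {
    "NPH": "c1ccc2ccccc2c1",           # naphthalene, 10 heavy atoms
    "QUN": "c1ccc2ncccc2c1",           # quinoline, 10
    "ANT": "c1ccc2cc3ccccc3cc2c1",     # anthracene, 14
    "FLU": "C1c2ccccc2-c2ccccc21",     # fluorene, 13
    "BIP": "c1ccc(-c2ccccc2)cc1",      # biphenyl, 12
    "ACE": "C1=Cc2cccc3cccc1c23",      # acenaphthylene, 12
    "PHE": "c1ccc2c(c1)ccc1ccccc12",   # phenanthrene, 14
    "TMS": "C[Si](C)(C)c1ccccc1",      # trimethyl(phenyl)silane, 10
    "TDC": "CCCCCCCCCCCCCC",           # n-tetradecane, 11 rotatable bonds
    "IND": "c1ccc2[nH]ccc2c1",         # indole, 9 heavy atoms
    "C70": "C" * 70,                   # above the molecular weight gate
}


def _sequence(rng, n: int) -> str:
    return "".join(rng.choice(list(AA_LETTERS)) for _ in range(n))


def _cage_complex(
    entry_id: str,
    ligand_mols: list[tuple[str, Chem.Mol]],
    resolution: float,
    release_date: _dt.date,
    cage: list[CageResidue],
) -> ToyComplex:
    ligands = [
        ToyLigand(het=het, chain="A", resnum=301 + i, atoms=mol_atoms(mol))
        for i, (het, mol) in enumerate(ligand_mols)
    ]
    return ToyComplex(
        entry_id=entry_id, resolution=resolution, release_date=release_date,
        residues=cage, ligands=ligands,
    )


def make_filter_scenario(seed: int = 0) -> Scenario:
    """Twelve ligand instances: one violating each of the ten selection
    steps (attributed to its first-failing step) and two survivors.

    The duplicate-removal step is exercised by one entry holding two
    copies of the same molecule with different EDIA scores; the better
    copy is one of the two survivors.
    """
    import random as _random

    seq_rng = _random.Random(4101)
    user_rng = np.random.default_rng(seed)

    mols = {code: build_molecule(smi) for code, smi in SMILES.items()
            if code in ("NPH", "QUN", "ANT", "PHE", "TMS", "TDC", "IND", "C70")}

    plan = [
        # entry, het, resolution, edia, activity (value, unit) or None
        ("f301", "NPH", 3.0, 0.92, (10, "nM")),   # resolution > 2.5
        ("f302", "NPH", 1.8, 0.50, (10, "nM")),   # EDIA <= 0.8
        ("f303", "C70", 1.8, 0.92, (10, "nM")),   # molecular weight > 975
        ("f304", "TDC", 1.8, 0.92, (10, "nM")),   # rotatable bonds > 10
        ("f305", "TMS", 1.8, 0.92, (10, "nM")),   # disallowed element (Si)
        ("f306", "IND", 1.8, 0.92, (10, "nM")),   # heavy atoms < 10
        ("f308", "PHE", 1.8, 0.92, None),         # no activity value
        ("f309", "ANT", 1.8, 0.92, (1, "mM")),    # LE = 1.37*3/14 <= 0.3
        ("f311", "QUN", 1.8, 0.92, (10, "nM")),   # survivor
    ]

    structures = {}
    manifest_rows = []
    activity_rows = []
    edia_rows = []

    def _finish(complex_: ToyComplex):
        rotation, translation = random_rigid_transform(user_rng)
        placed = complex_.transformed(rotation, translation)
        structures[placed.entry_id] = placed.to_pdb_text()
        manifest_rows.append(placed.manifest_row())

    for entry_id, het, resolution, edia, activity in plan:
        mol = mols[het]
        pose = heavy_coords_of(mol)
        positions = build_cage([pose], None, max_select=5.9)
        backbones = plan_backbones(positions, pose)
        cage = cage_residues(backbones, _sequence(seq_rng, len(backbones)))
        complex_ = _cage_complex(
            entry_id, [(het, mol)], resolution,
            _dt.date(2000 + len(manifest_rows), 3, 1), cage,
        )
        _finish(complex_)
        edia_rows.append((entry_id, het, "A", 301, edia))
        if activity is not None:
            activity_rows.append(
                (entry_id, het, "Ki", activity[0], activity[1], "synthetic")
            )

    # duplicate-removal entry: two naphthalene copies, EDIA 0.95 / 0.85
    nph = mols["NPH"]
    pose_a = heavy_coords_of(nph)
    copy_b = transform_mol(nph, offset=(12.0, 0.0, 0.0), z_rot_deg=30.0)
    pose_b = heavy_coords_of(copy_b)
    positions = build_cage([pose_a, pose_b], None, max_select=5.9)
    union = np.vstack([pose_a, pose_b])
    backbones = plan_backbones(positions, union)
    cage = cage_residues(backbones, _sequence(seq_rng, len(backbones)))
    dup = ToyComplex(
        entry_id="f307", resolution=1.8, release_date=_dt.date(2012, 3, 1),
        residues=cage,
        ligands=[
            ToyLigand("NPH", "A", 301, mol_atoms(nph)),
            ToyLigand("NPH", "A", 302, mol_atoms(copy_b)),
        ],
    )
    _finish(dup)
    edia_rows += [("f307", "NPH", "A", 301, 0.95), ("f307", "NPH", "A", 302, 0.85)]
    activity_rows.append(("f307", "NPH", "Ki", 10, "nM", "synthetic"))

    # buriedness violator: cage built around a virtual pose at the origin,
    # ligand displaced far outside it
    displaced = transform_mol(nph, offset=(25.0, 0.0, 0.0))
    positions = build_cage([pose_a], None, max_select=5.9)
    backbones = plan_backbones(positions, pose_a)
    cage = cage_residues(backbones, _sequence(seq_rng, len(backbones)))
    buried_not = ToyComplex(
        entry_id="f310", resolution=1.8, release_date=_dt.date(2013, 3, 1),
        residues=cage,
        ligands=[ToyLigand("NPH", "A", 301, mol_atoms(displaced))],
    )
    _finish(buried_not)
    edia_rows.append(("f310", "NPH", "A", 301, 0.92))
    activity_rows.append(("f310", "NPH", "Ki", 10, "nM", "synthetic"))

    expected_discards = {
        "PDB Resolution > 2.5 A": ["f301:NPH:A:301"],
        "EDIA_m < 0.8": ["f302:NPH:A:301"],
        "Molecular weight > 975 g/mol": ["f303:C70:A:301"],
        "Rotatable bonds > 10": ["f304:TDC:A:301"],
        "Atom type filter": ["f305:TMS:A:301"],
        "Heavy atoms < 10": ["f306:IND:A:301"],
        "Duplicate removal": ["f307:NPH:A:302"],
        "No activity value": ["f308:PHE:A:301"],
        "Ligand efficiency <= 0.3": ["f309:ANT:A:301"],
        "Buriedness < 0.5": ["f310:NPH:A:301"],
    }
    manifest = {
        "seed": seed,
        "n_ligand_instances": 12,
        "complexes": manifest_rows,
        "expected": {
            "per_step_discards": expected_discards,
            "per_step_discarded_counts": [1] * 10,
            "survivors": sorted(["f307:NPH:A:301", "f311:QUN:A:301"]),
        },
    }
    return Scenario(
        structures=structures,
        activity_tsv=_activity_tsv(activity_rows),
        edia_tsv=_edia_tsv(edia_rows),
        manifest=manifest,
    )


def _toy_to_entry(complex_: ToyComplex):
    """Exact in-memory StructureEntry (no PDB round-trip, full float64)."""
    from .structure_io import Atom, LigandInstance, ProteinChain
    from .structure_io import Residue as IoResidue
    from .structure_io import StructureEntry

    residues = [
        IoResidue(
            residue_name=r.resname,
            residue_number=r.resnum,
            insertion_code="",
            backbone={k: np.asarray(v, dtype=float) for k, v in r.backbone.items()},
        )
        for r in complex_.residues
    ]
    ligands = [
        LigandInstance(
            entry_id=complex_.entry_id,
            residue_name=l.het,
            chain_id=l.chain,
            residue_number=l.resnum,
            atoms=[
                Atom(element=e, x=float(p[0]), y=float(p[1]), z=float(p[2]),
                     is_hydrogen=h)
                for e, p, h in l.atoms
            ],
        )
        for l in complex_.ligands
    ]
    return StructureEntry(
        entry_id=complex_.entry_id,
        resolution=complex_.resolution,
        release_date=complex_.release_date,
        chains=[ProteinChain(chain_id=complex_.chain_id, residues=residues)],
        ligand_candidates=ligands,
    )


def _heavy_elements(mol: Chem.Mol) -> list[str]:
    return [a.GetSymbol() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]


#: backbone-deformation coordinates (unit RMSD plane) of the merge family;
#: chosen so that per-SMILES nearest-RMSD picks yield two seed clusters
#: that only the late-processed a107 ensemble connects (forcing a merge)
MERGE_FAMILY_LAYOUT = {
    "a101": ("NPH", (0.0, 0.0), 1994),
    "a102": ("QUN", (0.3, 0.0), 2001),
    "a103": ("NPH", (3.0, 0.0), 2005),
    "a104": ("QUN", (3.3, 1.5), 2008),
    "a105": ("ANT", (0.6, 1.5), 2010),
    "a106": ("ANT", (3.6, 0.0), 2013),
    "a107": ("NPH", (1.95, -0.5), 2017),
}
DEFORMATION_SCALE = 0.06  # Angstrom of backbone RMSD per unit plane distance

#: quinoline placement inside the merge-family pocket: partially stacked
#: over the anthracene so its pairs fall into middle difficulty bins
QUN_OFFSET = (2.3, 0.5, 1.3)
QUN_ZROT = 15.0

#: stacked-pair family: the quinoline sits beyond van-der-Waals contact
#: above the naphthalene, in the same fully shared cage (zero overlap)
STACK_SEPARATION = 3.5


def _ensemble_family_poses() -> dict[str, Chem.Mol]:
    anth = build_molecule(SMILES["ANT"])
    naph = place_on_coords(
        build_molecule(SMILES["NPH"]),
        substructure_coords(anth, SMILES["NPH"]),
    )
    quin = transform_mol(
        build_molecule(SMILES["QUN"]), offset=QUN_OFFSET, z_rot_deg=QUN_ZROT
    )
    return {"ANT": anth, "NPH": naph, "QUN": quin}


def make_ensemble_scenario(seed: int = 0) -> Scenario:
    """Twelve structures in four identical-pocket families.

    * merge family (a101..a107): three naphthalene, two quinoline and two
      anthracene copies of one pocket with controlled backbone
      deformations; SMILES deduplication then produces two seed clusters
      that the a107 ensemble bridges, forcing a cluster merge.
    * coincident family (b201, b202): phenanthrene and naphthalene in
      matching poses (the naphthalene occupies two of the phenanthrene's
      rings) -- a near-complete-coverage pair.
    * stacked family (e201, e202): naphthalene and quinoline in disjoint
      parts of one pocket -- a zero-overlap (subset_0) pair.
    * singleton family (c301): one acenaphthylene pocket, whose ensemble
      is removed after deduplication.
    """
    import random as _random

    user_rng = np.random.default_rng(seed)
    seq_rng = _random.Random(8812)

    structures: dict[str, str] = {}
    manifest_rows = []
    activity_rows = []
    edia_rows = []
    transforms: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def _emit(complex_: ToyComplex, het: str):
        rotation, translation = random_rigid_transform(user_rng)
        transforms[complex_.entry_id] = (rotation, translation)
        placed = complex_.transformed(rotation, translation)
        structures[placed.entry_id] = placed.to_pdb_text()
        manifest_rows.append(placed.manifest_row())
        activity_rows.append(
            (complex_.entry_id, het, "Ki", 10, "nM", "synthetic")
        )
        edia_rows.append((complex_.entry_id, het, "A", 301, 0.9))

    # ---- merge family -------------------------------------------------
    poses = _ensemble_family_poses()
    pose_arrays = {k: heavy_coords_of(m) for k, m in poses.items()}
    union = np.vstack(list(pose_arrays.values()))
    positions = build_cage(
        list(pose_arrays.values()), list(pose_arrays.values()),
        min_clear=3.2, max_select=5.7,
    )
    backbones = plan_backbones(positions, union)
    seq_a = _sequence(seq_rng, len(backbones))
    cage_a = cage_residues(backbones, seq_a)
    bb_coords = np.array(
        [r.backbone[n] for r in cage_a for n in ("N", "CA", "C", "O")]
    )
    d1, d2 = deformation_basis(bb_coords, seed=1234)

    resolutions = iter([1.6, 1.7, 1.8, 1.9, 2.0, 2.1, 2.2])
    for entry_id, (het, (sx, sy), year) in MERGE_FAMILY_LAYOUT.items():
        disp = DEFORMATION_SCALE * (sx * d1 + sy * d2)
        residues = []
        k = 0
        for res in cage_a:
            backbone = {}
            for name in ("N", "CA", "C", "O"):
                backbone[name] = res.backbone[name] + disp[k]
                k += 1
            residues.append(CageResidue(res.resname, res.resnum, backbone))
        complex_ = ToyComplex(
            entry_id=entry_id,
            resolution=next(resolutions),
            release_date=_dt.date(year, 6, 15),
            residues=residues,
            ligands=[ToyLigand(het, "A", 301, mol_atoms(poses[het]))],
        )
        _emit(complex_, het)

    # ---- coincident family --------------------------------------------
    phen = build_molecule(SMILES["PHE"])
    naph_b = place_on_coords(
        build_molecule(SMILES["NPH"]), substructure_coords(phen, SMILES["NPH"])
    )
    phen_pose, naph_b_pose = heavy_coords_of(phen), heavy_coords_of(naph_b)
    positions = build_cage(
        [phen_pose, naph_b_pose], [phen_pose, naph_b_pose],
        min_clear=3.0, max_select=5.9,
    )
    backbones = plan_backbones(positions, np.vstack([phen_pose, naph_b_pose]))
    seq_b = _sequence(seq_rng, len(backbones))
    cage_b = cage_residues(backbones, seq_b)
    for entry_id, het, mol, year in (
        ("b201", "PHE", phen, 1999), ("b202", "NPH", naph_b, 2003)
    ):
        complex_ = ToyComplex(
            entry_id=entry_id, resolution=1.9,
            release_date=_dt.date(year, 2, 10),
            residues=cage_b,
            ligands=[ToyLigand(het, "A", 301, mol_atoms(mol))],
        )
        _emit(complex_, het)

    # ---- stacked (zero-overlap) family ---------------------------------
    naph_e = build_molecule(SMILES["NPH"])
    quin_e = transform_mol(
        build_molecule(SMILES["QUN"]), offset=(0.0, 0.0, STACK_SEPARATION)
    )
    naph_pose, quin_pose = heavy_coords_of(naph_e), heavy_coords_of(quin_e)
    positions = build_cage(
        [naph_pose, quin_pose], [naph_pose, quin_pose],
        min_clear=2.8, max_select=6.3,
    )
    backbones = plan_backbones(positions, np.vstack([naph_pose, quin_pose]))
    seq_e = _sequence(seq_rng, len(backbones))
    cage_e = cage_residues(backbones, seq_e)
    for entry_id, het, mol, year in (
        ("e201", "NPH", naph_e, 2016), ("e202", "QUN", quin_e, 2021)
    ):
        complex_ = ToyComplex(
            entry_id=entry_id, resolution=1.8,
            release_date=_dt.date(year, 9, 5),
            residues=cage_e,
            ligands=[ToyLigand(het, "A", 301, mol_atoms(mol))],
        )
        _emit(complex_, het)

    # ---- singleton family ----------------------------------------------
    ace = build_molecule(SMILES["ACE"])
    ace_pose = heavy_coords_of(ace)
    positions = build_cage([ace_pose], [ace_pose], max_select=5.9)
    backbones = plan_backbones(positions, ace_pose)
    seq_c = _sequence(seq_rng, len(backbones))
    cage_c = cage_residues(backbones, seq_c)
    _emit(
        ToyComplex(
            entry_id="c301", resolution=2.0,
            release_date=_dt.date(2018, 4, 20),
            residues=cage_c,
            ligands=[ToyLigand("ACE", "A", 301, mol_atoms(ace))],
        ),
        "ACE",
    )

    if len({seq_a, seq_b, seq_e, seq_c}) != 4:  # pragma: no cover
        raise AssertionError("family pocket sequences must be distinct")

    # ---- expected outcomes ---------------------------------------------
    def _k(entry, het):
        return f"{entry}:{het}:A:301"

    expected_ensembles = {
        "ANT_A_301-a105": [_k("a105", "ANT"), _k("a101", "NPH"), _k("a102", "QUN")],
        "ANT_A_301-a106": [_k("a106", "ANT"), _k("a103", "NPH"), _k("a104", "QUN")],
        "NPH_A_301-a101": [_k("a101", "NPH"), _k("a102", "QUN"), _k("a105", "ANT")],
        "NPH_A_301-a103": [_k("a103", "NPH"), _k("a104", "QUN"), _k("a106", "ANT")],
        "NPH_A_301-a107": [_k("a107", "NPH"), _k("a102", "QUN"), _k("a106", "ANT")],
        "QUN_A_301-a102": [_k("a102", "QUN"), _k("a101", "NPH"), _k("a105", "ANT")],
        "QUN_A_301-a104": [_k("a104", "QUN"), _k("a103", "NPH"), _k("a106", "ANT")],
        "PHE_A_301-b201": [_k("b201", "PHE"), _k("b202", "NPH")],
        "NPH_A_301-b202": [_k("b202", "NPH"), _k("b201", "PHE")],
        "NPH_A_301-e201": [_k("e201", "NPH"), _k("e202", "QUN")],
        "QUN_A_301-e202": [_k("e202", "QUN"), _k("e201", "NPH")],
    }
    expected_clusters = [
        sorted(
            ["ANT_A_301-a105", "ANT_A_301-a106", "NPH_A_301-a101",
             "NPH_A_301-a103", "NPH_A_301-a107", "QUN_A_301-a102",
             "QUN_A_301-a104"]
        ),
        sorted(["NPH_A_301-b202", "PHE_A_301-b201"]),
        sorted(["NPH_A_301-e201", "QUN_A_301-e202"]),
    ]
    representatives = {
        "ANT_A_301-a105": True, "NPH_A_301-e201": True, "PHE_A_301-b201": True,
    }

    # ground-truth pair labels from the Monte-Carlo oracle on the
    # reference poses (Shape Tversky is rigid-invariant)
    rep_members = {
        "ANT_A_301-a105": [("a105", poses["ANT"]), ("a101", poses["NPH"]),
                           ("a102", poses["QUN"])],
        "PHE_A_301-b201": [("b201", phen), ("b202", naph_b)],
        "NPH_A_301-e201": [("e201", naph_e), ("e202", quin_e)],
    }
    expected_pairs = {}
    for ens_name, members in rep_members.items():
        for t_entry, t_mol in members:
            for q_entry, q_mol in members:
                if t_entry == q_entry:
                    continue
                sti = mc_shape_tversky(
                    heavy_coords_of(t_mol), _heavy_elements(t_mol),
                    heavy_coords_of(q_mol), _heavy_elements(q_mol),
                )
                bin_idx = min(int(sti * 10), 9)
                margin = min(abs(sti - bin_idx / 10), abs(sti - (bin_idx + 1) / 10))
                if not (sti >= 0.97 or sti <= 0.03 or margin >= 0.03):
                    raise AssertionError(
                        f"engineered pair ({t_entry},{q_entry}) too close to a "
                        f"bin edge: {sti:.3f}"
                    )
                expected_pairs[f"{t_entry}|{q_entry}"] = {
                    "ensemble": ens_name,
                    "mc_shape_tversky": round(sti, 4),
                    "subset": f"subset_{bin_idx * 10}",
                }

    manifest = {
        "seed": seed,
        "complexes": manifest_rows,
        "expected": {
            "ensembles": expected_ensembles,
            "removed_singletons": ["ACE_A_301-c301"],
            "clusters": sorted(expected_clusters),
            "representatives": sorted(representatives),
            "pairs": expected_pairs,
            "n_pairs": len(expected_pairs),
            "release_growth": {"2001": 2, "2003": 2, "2010": 4, "2021": 2},
        },
        "deformation_scale": DEFORMATION_SCALE,
        "layout": {
            k: {"het": v[0], "plane": list(v[1]), "year": v[2]}
            for k, v in MERGE_FAMILY_LAYOUT.items()
        },
    }
    return Scenario(
        structures=structures,
        activity_tsv=_activity_tsv(activity_rows),
        edia_tsv=_edia_tsv(edia_rows),
        manifest=manifest,
    )


def make_rigid_copy_entries(seed: int = 0):
    """Three exact rigid copies of one pocket (full float64, no file
    round-trip), each holding a different ligand from the merge-family
    pose set.

    Returns (entries, ligand ground-truth poses in the reference frame,
    per-entry rigid transforms).  Superimposing these pockets must
    recover the reference overlay to numerical precision.
    """
    rng = np.random.default_rng(seed)
    poses = _ensemble_family_poses()
    pose_arrays = {k: heavy_coords_of(m) for k, m in poses.items()}
    union = np.vstack(list(pose_arrays.values()))
    positions = build_cage(
        list(pose_arrays.values()), list(pose_arrays.values()),
        min_clear=3.2, max_select=5.7,
    )
    backbones = plan_backbones(positions, union)
    seq = _sequence(__import__("random").Random(4242), len(backbones))
    cage = cage_residues(backbones, seq)

    entries = []
    ref_poses = {}
    transforms = {}
    for i, het in enumerate(("ANT", "NPH", "QUN")):
        entry_id = f"r10{i + 1}"
        complex_ = ToyComplex(
            entry_id=entry_id, resolution=1.8,
            release_date=_dt.date(2010 + i, 1, 1),
            residues=cage,
            ligands=[ToyLigand(het, "A", 301, mol_atoms(poses[het]))],
        )
        rotation, translation = random_rigid_transform(rng)
        entries.append(_toy_to_entry(complex_.transformed(rotation, translation)))
        ref_poses[f"{entry_id}:{het}:A:301"] = np.array(
            [p for _e, p, _h in complex_.ligands[0].atoms]
        )
        transforms[entry_id] = (rotation, translation)
    return entries, ref_poses, transforms
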
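"""Structure parsing, ligand-candidate enumeration and geometry output.

PDB entries are read with gemmi (first model only); every HETATM residue
group except water becomes a ligand candidate.  Candidates that are out of
scope for overlay benchmarking -- metal ions, covalently bound ligands,
linked HETATM polymers, groups whose bonds cannot be perceived -- are
flagged but kept, so that construction-time exclusions remain accountable.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import gemmi
import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .ensemble_builder import LigandEnsemble

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: solvent residue names dropped before candidate listing
SOLVENT_RESNAMES = frozenset({"HOH", "DOD"})

#: metals named explicitly; anything gemmi flags as metallic is also caught
METAL_SYMBOLS = frozenset(
    {"NA", "MG", "K", "CA", "MN", "FE", "CO", "NI", "CU", "ZN", "CD", "HG"}
)


class PdbParseError(ValueError):
    """Raised for malformed or empty PDB input."""


@dataclass
class Atom:
    element: str
    x: float
    y: float
    z: float
    is_hydrogen: bool = False
    name: str = ""

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Residue:
    residue_name: str
    residue_number: int
    insertion_code: str
    backbone: dict[str, np.ndarray]  # atom name -> coordinates
    side_chain: list[Atom] = field(default_factory=list)

    @property
    def backbone_complete(self) -> bool:
        return all(a in self.backbone for a in BACKBONE_ATOMS)

    @property
    def one_letter(self) -> str:
        code = gemmi.find_tabulated_residue(self.residue_name)
        if code is not None and code.is_amino_acid():
            letter = code.one_letter_code.upper()
            if letter.isalpha():
                return letter
        return "X"

    def heavy_coords(self) -> np.ndarray:
        coords = list(self.backbone.values())
        coords += [a.coord for a in self.side_chain
                   if not a.is_hydrogen]
        return np.array(coords, dtype=float)


@dataclass
class ProteinChain:
    chain_id: str
    residues: list[Residue]


@dataclass
class LigandInstance:
    """One ligand occurrence in a structure.

    ``skip_reason`` marks construction-time exclusions; a flagged instance
    never enters the filter cascade.
    """

    entry_id: str
    residue_name: str
    chain_id: str
    residue_number: int
    atoms: list[Atom]
    smiles: str | None = None
    skip_reason: str | None = None  # metal_ion | covalent | polymer | unparseable
    properties: object | None = None  # chem_properties.LigandProperties
    mol: object | None = None  # perceived RDKit molecule (with conformer)
    edia_m: float | None = None
    ligand_efficiency: float | None = None
    p_value: float | None = None
    buriedness: float | None = None

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.entry_id, self.residue_name, self.chain_id, self.residue_number)

    @property
    def key_str(self) -> str:
        return f"{self.entry_id}:{self.residue_name}:{self.chain_id}:{self.residue_number}"

    def heavy_coords(self) -> np.ndarray:
        return np.array(
            [a.coord for a in self.atoms if not a.is_hydrogen], dtype=float
        )

    def all_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms if not a.is_hydrogen)


@dataclass
class StructureEntry:
    entry_id: str
    resolution: float | None
    release_date: _dt.date | None
    chains: list[ProteinChain]
    ligand_candidates: list[LigandInstance]
    exclusion: str | None = None  # no_ligand | skipped_by_construction:<reason>

    def protein_heavy_atoms(self) -> tuple[list[str], np.ndarray]:
        """Elements and coordinates of all protein heavy atoms, in a
        single consistent order."""
        elements: list[str] = []
        coords: list[np.ndarray] = []
        for chain in self.chains:
            for res in chain.residues:
                for name, pos in res.backbone.items():
                    elements.append(
                        "N" if name == "N" else "O" if name == "O" else "C"
                    )
                    coords.append(pos)
                for atom in res.side_chain:
                    if not atom.is_hydrogen:
                        elements.append(atom.element)
                        coords.append(atom.coord)
        if not coords:
            return [], np.empty((0, 3))
        return elements, np.array(coords, dtype=float)

    def protein_heavy_coords(self) -> np.ndarray:
        return self.protein_heavy_atoms()[1]


_DATE_RE = re.compile(r"(\d{2})-([A-Z]{3})-(\d{2,4})")
_MONTHS = {m: i + 1 for i, m in enumerate(
    ["JAN", "FEB", "MAR", "APR", "MAY", "JUN",
     "JUL", "AUG", "SEP", "OCT", "NOV", "DEC"])}


def _parse_pdb_date(token: str) -> _dt.date | None:
    m = _DATE_RE.search(token)
    if not m:
        return None
    day, mon, year = int(m.group(1)), _MONTHS.get(m.group(2)), int(m.group(3))
    if mon is None:
        return None
    if year < 100:  # two-digit PDB years: 00-49 -> 2000s, 50-99 -> 1900s
        year += 2000 if year < 50 else 1900
    try:
        return _dt.date(year, mon, day)
    except ValueError:
        return None


def _scan_header(pdb_text: str) -> tuple[float | None, _dt.date | None]:
    """Extract resolution (REMARK 2) and release date (HEADER / REVDAT 1)."""
    resolution = None
    date = None
    for line in pdb_text.splitlines():
        rec = line[:6].strip()
        if rec == "REMARK" and line[6:10].strip() == "2" and "RESOLUTION" in line:
            m = re.search(r"RESOLUTION\.?\s+([\d.]+)\s+ANGSTROM", line)
            if m:
                resolution = float(m.group(1))
        elif rec == "HEADER" and date is None:
            date = _parse_pdb_date(line[50:59])
        elif rec == "REVDAT" and line[7:10].strip() == "1":
            revdat = _parse_pdb_date(line[13:22])
            if revdat is not None:
                date = revdat
    return resolution, date


def _validate_coordinate_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line[:6] not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise PdbParseError(f"malformed coordinate line {lineno}: too short")
        try:
            coords = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        except ValueError as exc:
            raise PdbParseError(
                f"malformed coordinate line {lineno}: {exc}") from exc
        if not all(np.isfinite(coords)):
            raise PdbParseError(
                f"malformed coordinate line {lineno}: non-finite coordinate")


def parse_structure(pdb_text: str, entry_id: str | None = None) -> StructureEntry:
    """Parse PDB-format text into a :class:`StructureEntry`.

    Only the first model is read; alternate conformers other than altLoc
    'A'/blank are dropped with a warning; waters are excluded before
    candidate listing.  Entries without any HETATM group are flagged
    ``no_ligand``.
    """
    if not pdb_text.strip():
        raise PdbParseError("empty PDB input")
    _validate_coordinate_lines(pdb_text)

    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise PdbParseError("no coordinate section found")
    model = st[0]

    if entry_id is None:
        entry_id = (st.name or "xxxx").strip().lower()[:4] or "xxxx"
    entry_id = entry_id.lower()

    resolution, release_date = _scan_header(pdb_text)
    if resolution is None and st.resolution > 0:
        resolution = float(st.resolution)

    chains: list[ProteinChain] = []
    candidates: list[LigandInstance] = []
    dropped_altloc = 0

    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            atoms = []
            for at in res:
                if at.altloc not in ("", "A", "\0"):
                    dropped_altloc += 1
                    continue
                atoms.append(at)
            if not atoms:
                continue
            if res.het_flag == "H":
                if res.name in SOLVENT_RESNAMES or res.is_water():
                    continue
                lig_atoms = [
                    Atom(
                        element=at.element.name,
                        x=at.pos.x, y=at.pos.y, z=at.pos.z,
                        is_hydrogen=at.is_hydrogen(),
                        name=at.name,
                    )
                    for at in atoms
                ]
                candidates.append(
                    LigandInstance(
                        entry_id=entry_id,
                        residue_name=res.name,
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        atoms=lig_atoms,
                    )
                )
            else:
                backbone: dict[str, np.ndarray] = {}
                side: list[Atom] = []
                for at in atoms:
                    pos = np.array([at.pos.x, at.pos.y, at.pos.z])
                    if at.name in BACKBONE_ATOMS:
                        backbone[at.name] = pos
                    else:
                        side.append(
                            Atom(at.element.name, *pos,
                                 is_hydrogen=at.is_hydrogen(), name=at.name)
                        )
                residues.append(
                    Residue(
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        backbone=backbone,
                        side_chain=side,
                    )
                )
        if residues:
            residues.sort(key=lambda r: (r.residue_number, r.insertion_code))
            chains.append(ProteinChain(chain_id=chain.name, residues=residues))

    if dropped_altloc:
        logger.warning(
            "%s: dropped %d alternate-conformer atoms (altLoc other than 'A')",
            entry_id, dropped_altloc,
        )

    entry = StructureEntry(
        entry_id=entry_id,
        resolution=resolution,
        release_date=release_date,
        chains=chains,
        ligand_candidates=candidates,
    )
    if not candidates:
        entry.exclusion = "no_ligand"
    return entry


def _is_metal(element: str) -> bool:
    if element.upper() in METAL_SYMBOLS:
        return True
    el = gemmi.Element(element)
    return bool(el.is_metal)


def classify_candidates(
    entry: StructureEntry,
    covalent_cutoff: float = 1.9,
    attempt_perception: bool = True,
) -> StructureEntry:
    """Assign construction-time skip reasons to the ligand candidates.

    metal_ion  -- a single non-carbon heavy atom of a metallic element
    covalent   -- any ligand heavy atom within ``covalent_cutoff`` of a
                  protein heavy atom
    polymer    -- bonded (heavy-atom distance < cutoff) to another HETATM
                  residue group
    unparseable -- bond perception fails (only if ``attempt_perception``)

    Idempotent: flags are recomputed from geometry, never accumulated.
    """
    protein = entry.protein_heavy_coords()
    heavy_sets = [lig.heavy_coords() for lig in entry.ligand_candidates]

    for i, lig in enumerate(entry.ligand_candidates):
        lig.skip_reason = None
        heavy = heavy_sets[i]
        if len(heavy) == 1:
            elements = [a.element for a in lig.atoms if not a.is_hydrogen]
            if elements[0].upper() != "C" and _is_metal(elements[0]):
                lig.skip_reason = "metal_ion"
                continue
        if len(protein) and len(heavy):
            d = np.linalg.norm(protein[None, :, :] - heavy[:, None, :], axis=-1)
            if d.min() < covalent_cutoff:
                lig.skip_reason = "covalent"
                continue
        linked = False
        for j, other in enumerate(heavy_sets):
            if j == i or not len(other) or not len(heavy):
                continue
            d = np.linalg.norm(other[None, :, :] - heavy[:, None, :], axis=-1)
            if d.min() < covalent_cutoff:
                linked = True
                break
        if linked:
            lig.skip_reason = "polymer"
            continue
        if attempt_perception:
            from .chem_properties import perceive_molecule

            try:
                perceive_molecule(lig)
            except Exception:
                lig.skip_reason = "unparseable"
    return entry


def write_ensemble_sdf(ensemble: "LigandEnsemble", path) -> None:
    """Write one multi-record SDF for a superimposed ligand ensemble.

    Records are ordered by ascending backbone RMSD with the search ligand
    first; each record carries the member's coordinates in the ensemble
    frame plus provenance data fields.
    """
    from rdkit import Chem
    from rdkit.Chem import SDWriter

    members = sorted(
        ensemble.members,
        key=lambda m: (m.ligand.key != ensemble.search_ligand.key, m.backbone_rmsd),
    )
    writer = SDWriter(str(path))
    try:
        for member in members:
            lig = member.ligand
            if member.coords is None or lig.mol is None:
                raise ValueError(
                    f"member {lig.key_str} has no superimposed coordinates"
                )
            mol = Chem.Mol(lig.mol)
            conf = mol.GetConformer()
            for idx in range(mol.GetNumAtoms()):
                x, y, z = member.coords[idx]
                conf.SetAtomPosition(idx, (float(x), float(y), float(z)))
            mol.SetProp("_Name", lig.key_str)
            mol.SetProp("entry_id", lig.entry_id)
            mol.SetProp("het_code", lig.residue_name)
            mol.SetProp("chain", lig.chain_id)
            mol.SetProp("residue_number", str(lig.residue_number))
            mol.SetProp("backbone_rmsd", f"{member.backbone_rmsd:.3f}")
            mol.SetProp("smiles", lig.smiles or "")
            writer.write(mol)
    finally:
        writer.close()
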
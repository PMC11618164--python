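"""Per-ligand molecular descriptors used for filtering and reporting.

Bond orders are perceived from 3D coordinates and element identities with
RDKit; descriptors follow the conventions below:

* rotatable bonds: acyclic single bonds, excluding amide C-N bonds, bonds
  to a nitrile group, and bonds where either end is a terminal heavy atom
  (the Veber-style definition);
* HBD: one count per hydrogen on an N or O atom;
* HBA: N and O atoms, excluding pyrrole-type N-H nitrogens and amide
  nitrogens;
* SlogP: Wildman-Crippen atomic contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdDetermineBonds
from rdkit.Geometry import Point3D

from .structure_io import LigandInstance


class PerceptionError(ValueError):
    """Bond/valence perception from 3D coordinates failed."""


@dataclass(frozen=True)
class LigandProperties:
    smiles: str
    molecular_weight: float  # g/mol, includes hydrogens
    heavy_atom_count: int
    rotatable_bonds: int
    elements: frozenset[str]
    hbd: int
    hba: int
    slogp: float


def mol_from_instance(ligand: LigandInstance, charge: int = 0) -> Chem.Mol:
    """Build an RDKit molecule from a ligand's atoms and 3D coordinates."""
    if ligand.heavy_atom_count < 1:
        raise PerceptionError("ligand has no heavy atoms")
    rw = Chem.RWMol()
    for atom in ligand.atoms:
        rd_atom = Chem.Atom(atom.element.capitalize())
        rw.AddAtom(rd_atom)
    conf = Chem.Conformer(rw.GetNumAtoms())
    for i, atom in enumerate(ligand.atoms):
        conf.SetAtomPosition(i, Point3D(atom.x, atom.y, atom.z))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    try:
        rdDetermineBonds.DetermineBonds(mol, charge=charge)
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise PerceptionError(str(exc)) from exc
    return mol


def count_rotatable_bonds(mol: Chem.Mol) -> int:
    """Rotatable = acyclic single bond, not amide C-N, not to a nitrile
    group, and neither end a terminal heavy atom."""
    mol_h = Chem.RemoveHs(mol)
    count = 0
    for bond in mol_h.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetDegree() <= 1 or b.GetDegree() <= 1:
            continue  # terminal heavy atom
        if _is_amide_bond(a, b) or _is_amide_bond(b, a):
            continue
        if _is_nitrile_atom(a) or _is_nitrile_atom(b):
            continue
        count += 1
    return count


def _is_amide_bond(c_atom: Chem.Atom, n_atom: Chem.Atom) -> bool:
    if c_atom.GetSymbol() != "C" or n_atom.GetSymbol() != "N":
        return False
    for bond in c_atom.GetBonds():
        other = bond.GetOtherAtom(c_atom)
        if other.GetSymbol() == "O" and bond.GetBondType() == Chem.BondType.DOUBLE:
            return True
    return False


def _is_nitrile_atom(atom: Chem.Atom) -> bool:
    """True for the carbon or nitrogen of a C#N group."""
    for bond in atom.GetBonds():
        if bond.GetBondType() == Chem.BondType.TRIPLE:
            pair = {bond.GetBeginAtom().GetSymbol(), bond.GetEndAtom().GetSymbol()}
            if pair == {"C", "N"}:
                return True
    return False


def count_hbd_hba(mol: Chem.Mol) -> tuple[int, int]:
    molh = Chem.AddHs(mol)
    hbd = 0
    hba = 0
    for atom in molh.GetAtoms():
        if atom.GetSymbol() not in ("N", "O"):
            continue
        n_h = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1)
        hbd += n_h
        if atom.GetSymbol() == "N":
            if atom.GetIsAromatic() and n_h > 0:
                continue  # pyrrole-type N-H
            if _is_amide_nitrogen(atom):
                continue
        hba += 1
    return hbd, hba


def _is_amide_nitrogen(n_atom: Chem.Atom) -> bool:
    for nb in n_atom.GetNeighbors():
        if nb.GetSymbol() != "C":
            continue
        for bond in nb.GetBonds():
            other = bond.GetOtherAtom(nb)
            if other.GetSymbol() == "O" and bond.GetBondType() == Chem.BondType.DOUBLE:
                return True
    return False


def predict_slogp(mol: Chem.Mol) -> float:
    """Wildman-Crippen logP (sum of per-atom contributions)."""
    return float(Crippen.MolLogP(mol))


def properties_from_mol(mol: Chem.Mol, isomeric: bool = True) -> LigandProperties:
    """Descriptor bundle for a perceived molecule.

    ``isomeric=False`` drops stereochemistry from the canonical SMILES,
    making downstream uniqueness checks stereo-blind."""
    heavy = Chem.RemoveHs(mol)
    hbd, hba = count_hbd_hba(mol)
    return LigandProperties(
        smiles=Chem.MolToSmiles(heavy, isomericSmiles=isomeric),
        molecular_weight=float(Descriptors.MolWt(mol)),
        heavy_atom_count=heavy.GetNumAtoms(),
        rotatable_bonds=count_rotatable_bonds(mol),
        elements=frozenset(
            a.GetSymbol() for a in heavy.GetAtoms()
        ),
        hbd=hbd,
        hba=hba,
        slogp=predict_slogp(mol),
    )


def perceive_molecule(ligand: LigandInstance) -> LigandProperties:
    """Perceive bonds for a ligand instance and populate its descriptors.

    On failure the ligand is flagged ``unparseable`` and the error is
    re-raised as :class:`PerceptionError`.
    """
    try:
        mol = mol_from_instance(ligand)
        props = properties_from_mol(mol)
    except PerceptionError:
        ligand.skip_reason = "unparseable"
        raise
    ligand.mol = mol
    ligand.smiles = props.smiles
    ligand.properties = props
    return props


def perceive_all(ligands) -> list[LigandInstance]:
    """Perceive every unskipped ligand; flagged failures are kept but
    excluded from the returned list."""
    ok = []
    for lig in ligands:
        if lig.skip_reason is not None:
            continue
        try:
            perceive_molecule(lig)
        except PerceptionError:
            continue
        ok.append(lig)
    return ok
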
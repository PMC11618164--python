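"""Binding-site extraction, identical-sequence matching and ensemble building.

A binding site is the set of residues with at least one atom within a
fixed radius (default 6.5 Angstrom) of any ligand atom.  Sites whose
per-chain one-letter sequences are identical (up to a chain bijection)
are superimposed on their backbone atoms with the Kabsch algorithm; the
ligands follow their sites into the query frame, yielding a superimposed
ligand ensemble named after the search ligand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .structure_io import (
    BACKBONE_ATOMS,
    LigandInstance,
    Residue,
    StructureEntry,
)

logger = logging.getLogger(__name__)

DEFAULT_POCKET_RADIUS = 6.5


class DegenerateGeometry(ValueError):
    pass


@dataclass
class SiteChain:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class BindingSite:
    ligand: LigandInstance
    chains: list[SiteChain]  # canonical order: longest selected run first

    @property
    def signature(self) -> tuple[str, ...]:
        return tuple(c.sequence for c in self.chains)

    @property
    def signature_str(self) -> str:
        return "/".join(self.signature)

    def backbone_coords(self, usable: Sequence[bool] | None = None) -> np.ndarray:
        """Backbone atom coordinates (N, CA, C, O per residue) over all
        chains in canonical order, restricted to backbone-complete
        residues (optionally further restricted by ``usable``)."""
        coords = []
        i = 0
        for chain in self.chains:
            for res in chain.residues:
                keep = res.backbone_complete and (usable is None or usable[i])
                if keep:
                    coords += [res.backbone[a] for a in BACKBONE_ATOMS]
                i += 1
        if not coords:
            return np.empty((0, 3))
        return np.array(coords, dtype=float)

    def residues_flat(self) -> list[Residue]:
        return [r for c in self.chains for r in c.residues]


@dataclass
class EnsembleMember:
    ligand: LigandInstance
    coords: np.ndarray  # all-atom coordinates in the ensemble frame
    backbone_rmsd: float


@dataclass
class LigandEnsemble:
    name: str
    search_ligand: LigandInstance
    members: list[EnsembleMember]
    removed: bool = False  # set when deduplication leaves < 2 members

    @property
    def complexes(self) -> frozenset[tuple[str, tuple]]:
        return frozenset((m.ligand.entry_id, m.ligand.key) for m in self.members)

    @property
    def size(self) -> int:
        return len(self.members)


def ensemble_name(ligand: LigandInstance) -> str:
    return (
        f"{ligand.residue_name}_{ligand.chain_id}_"
        f"{ligand.residue_number}-{ligand.entry_id}"
    )


def extract_binding_site(
    ligand: LigandInstance,
    structure: StructureEntry,
    radius: float = DEFAULT_POCKET_RADIUS,
) -> BindingSite:
    """Residues with >= 1 atom (hydrogens included) within ``radius`` of
    any ligand atom; chains ordered by (selected-run length desc,
    sequence string)."""
    lig_coords = ligand.all_coords()
    chains: list[SiteChain] = []
    for chain in structure.chains:
        selected = []
        for res in chain.residues:
            res_coords = [pos for pos in res.backbone.values()]
            res_coords += [a.coord for a in res.side_chain]
            if not res_coords:
                continue
            d = np.linalg.norm(
                np.asarray(res_coords)[:, None, :] - lig_coords[None, :, :],
                axis=-1,
            )
            if d.min() <= radius:
                selected.append(res)
        if selected:
            chains.append(SiteChain(chain_id=chain.chain_id, residues=selected))
    if not chains:
        raise DegenerateGeometry(
            f"no residue within {radius} A of ligand {ligand.key_str}"
        )
    chains.sort(key=lambda c: (-len(c.residues), c.sequence, c.chain_id))
    return BindingSite(ligand=ligand, chains=chains)


class SiteIndex:
    """Index of binding sites keyed by their canonical signature.

    Two sites match when their per-chain sequence strings are equal as
    sorted tuples, i.e. identical under some chain bijection.  With the
    canonical chain order, chains then pair positionally (equal strings
    pair with equal strings), which realizes one valid bijection
    deterministically.
    """

    def __init__(self) -> None:
        self._by_signature: dict[tuple[str, ...], list[BindingSite]] = {}

    def add(self, site: BindingSite) -> None:
        key = tuple(sorted(site.signature))
        self._by_signature.setdefault(key, []).append(site)

    def find_identical_sites(self, query: BindingSite) -> list[BindingSite]:
        key = tuple(sorted(query.signature))
        return list(self._by_signature.get(key, []))

    def all_sites(self) -> list[BindingSite]:
        return [s for sites in self._by_signature.values() for s in sites]

    def to_tsv(self, path) -> None:
        lines = ["signature\tentry_id\tligand_key"]
        for sites in self._by_signature.values():
            for s in sites:
                lines.append(
                    f"{s.signature_str}\t{s.ligand.entry_id}\t{s.ligand.key_str}"
                )
        Path(path).write_text("\n".join(lines) + "\n")


def build_site_index(
    ligands: Iterable[LigandInstance],
    entries: Mapping[str, StructureEntry],
    radius: float = DEFAULT_POCKET_RADIUS,
) -> SiteIndex:
    index = SiteIndex()
    for lig in ligands:
        index.add(extract_binding_site(lig, entries[lig.entry_id], radius))
    return index


def kabsch_superpose(
    ref_coords: np.ndarray, mov_coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mov`` onto ``ref``.

    Returns (rotation, translation, rmsd) with a proper rotation
    (det = +1) such that ``mov @ rotation.T + translation`` minimizes the
    RMSD to ``ref``.  Requires >= 3 non-collinear points.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate sets must be equal-length Nx3 arrays")
    if len(ref) < 3:
        raise DegenerateGeometry("need at least 3 points for superposition")

    ref_center = ref.mean(axis=0)
    mov_center = mov.mean(axis=0)
    p = ref - ref_center
    q = mov - mov_center
    if np.linalg.matrix_rank(q, tol=1e-8) < 2 or np.linalg.matrix_rank(p, tol=1e-8) < 2:
        raise DegenerateGeometry("collinear point set")

    h = q.T @ p
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = ref_center - rotation @ mov_center
    moved = mov @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


def _paired_backbone(
    query: BindingSite, hit: BindingSite
) -> tuple[np.ndarray, np.ndarray, int]:
    """Backbone coordinates over the 1:1 residue pairing, keeping only
    residue pairs where both residues are backbone-complete."""
    q_res = query.residues_flat()
    h_res = hit.residues_flat()
    assert len(q_res) == len(h_res)
    usable = [
        q.backbone_complete and h.backbone_complete
        for q, h in zip(q_res, h_res)
    ]
    ref_list, mov_list = [], []
    for u, q, h in zip(usable, q_res, h_res):
        if u:
            ref_list += [q.backbone[a] for a in BACKBONE_ATOMS]
            mov_list += [h.backbone[a] for a in BACKBONE_ATOMS]
    n_res = sum(usable)
    if n_res == 0:
        return np.empty((0, 3)), np.empty((0, 3)), 0
    return np.array(ref_list), np.array(mov_list), n_res


def build_ensemble(
    query_ligand: LigandInstance,
    query_site: BindingSite,
    site_index: SiteIndex,
) -> LigandEnsemble:
    """Superimpose every identical site onto the query's and carry each
    site's ligand into the query frame."""
    members: list[EnsembleMember] = []
    for hit in site_index.find_identical_sites(query_site):
        ref, mov, n_res = _paired_backbone(query_site, hit)
        if n_res < 3:
            logger.warning(
                "skipping site of %s for query %s: only %d usable backbone "
                "residues", hit.ligand.key_str, query_ligand.key_str, n_res,
            )
            continue
        rotation, translation, rmsd = kabsch_superpose(ref, mov)
        coords = hit.ligand.all_coords() @ rotation.T + translation
        members.append(
            EnsembleMember(ligand=hit.ligand, coords=coords, backbone_rmsd=rmsd)
        )
    members.sort(key=lambda m: (m.ligand.key != query_ligand.key, m.backbone_rmsd))
    return LigandEnsemble(
        name=ensemble_name(query_ligand),
        search_ligand=query_ligand,
        members=members,
    )


def deduplicate_members(ensemble: LigandEnsemble) -> LigandEnsemble:
    """One member per canonical SMILES (lowest backbone RMSD wins, ties by
    smallest ligand key); ensembles left with < 2 members are marked
    removed."""
    by_smiles: dict[str | None, EnsembleMember] = {}
    for member in sorted(
        ensemble.members, key=lambda m: (m.backbone_rmsd, m.ligand.key)
    ):
        smiles = member.ligand.smiles
        if smiles in by_smiles:
            prev = by_smiles[smiles]
            if prev.backbone_rmsd == member.backbone_rmsd:
                logger.warning(
                    "RMSD tie for SMILES %s in %s: keeping %s",
                    smiles, ensemble.name, prev.ligand.key_str,
                )
            continue
        by_smiles[smiles] = member
    members = sorted(
        by_smiles.values(),
        key=lambda m: (m.ligand.key != ensemble.search_ligand.key, m.backbone_rmsd),
    )
    ensemble.members = members
    ensemble.removed = len(members) < 2
    return ensemble


def build_all_ensembles(
    ligands: Sequence[LigandInstance],
    entries: Mapping[str, StructureEntry],
    radius: float = DEFAULT_POCKET_RADIUS,
) -> list[LigandEnsemble]:
    """Full ensemble stage: index sites, build one ensemble per surviving
    ligand, deduplicate by SMILES and drop singletons."""
    index = build_site_index(ligands, entries, radius)
    sites = {s.ligand.key: s for s in index.all_sites()}
    ensembles = []
    for lig in ligands:
        ens = build_ensemble(lig, sites[lig.key], index)
        ens = deduplicate_members(ens)
        if not ens.removed:
            ensembles.append(ens)
    return ensembles
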
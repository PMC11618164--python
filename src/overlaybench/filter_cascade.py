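"""Ordered ligand selection cascade with per-step accounting.

The cascade applies, in order: resolution, electron-density support
(EDIA_m, consumed from a precomputed table), molecular weight, rotatable
bonds, element filter, heavy-atom count, per-entry duplicate removal,
activity presence, ligand efficiency and buriedness.  Every discarded
ligand is attributed to exactly one (first-failing) step, so the report
conserves counts: remaining_before - discarded = remaining_after.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import affinity_ledger as ledger_mod
from .structure_io import LigandInstance, StructureEntry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    max_resolution: float = 2.5          # Angstrom
    min_edia: float = 0.8                # retained if EDIA_m > min_edia
    max_molecular_weight: float = 975.0  # g/mol
    max_rotatable_bonds: int = 10
    allowed_elements: frozenset[str] = frozenset(
        {"C", "O", "N", "S", "P", "Cl", "F", "Br", "I", "B"}
    )
    min_heavy_atoms: int = 10
    min_ligand_efficiency: float = 0.3   # strict: LE must exceed this
    min_buriedness: float = 0.5          # kept if buriedness >= this


@dataclass
class FilterStepRow:
    step_index: int
    step_name: str
    entries_discarded: int
    entries_remaining: int


@dataclass
class FilterReport:
    rows: list[FilterStepRow] = field(default_factory=list)
    survivors: list[tuple] = field(default_factory=list)
    discard_reasons: dict[tuple, str] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        lines = ["Step\tFilter\tEntries discarded\tEntries remaining"]
        for row in self.rows:
            lines.append(
                f"{row.step_index}\t{row.step_name}\t"
                f"{row.entries_discarded}\t{row.entries_remaining}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def read_edia_table(path) -> dict[tuple[str, str, str, int], float]:
    """TSV with header ``entry_id het chain resnum edia_m``."""
    table: dict[tuple[str, str, str, int], float] = {}
    lines = Path(path).read_text().splitlines()
    if not lines:
        return table
    header = lines[0].split("\t")
    idx = {name: i for i, name in enumerate(header)}
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        key = (
            f[idx["entry_id"]].lower(),
            f[idx["het"]],
            f[idx["chain"]],
            int(f[idx["resnum"]]),
        )
        table[key] = float(f[idx["edia_m"]])
    return table


def compute_buriedness(
    ligand: LigandInstance,
    protein_elements: Sequence[str],
    protein_coords: np.ndarray,
    probe_radius: float = 1.4,
    point_number: int = 480,
    method: str = "sasa",
) -> float:
    """Fraction of a ligand enclosed by its protein environment.

    ``sasa`` (default): 1 - SASA(ligand in complex) / SASA(ligand alone),
    Shrake-Rupley with standard vdW radii, clamped to [0, 1].
    ``neighbor_count``: fraction of ligand heavy atoms with at least two
    protein heavy atoms within 4.5 Angstrom.
    """
    lig_coords = ligand.heavy_coords()
    lig_elements = [a.element for a in ligand.atoms if not a.is_hydrogen]
    protein_coords = np.asarray(protein_coords, dtype=float).reshape(-1, 3)

    if method == "neighbor_count":
        if not len(protein_coords):
            return 0.0
        d = np.linalg.norm(
            lig_coords[:, None, :] - protein_coords[None, :, :], axis=-1
        )
        buried_atoms = (d < 4.5).sum(axis=1) >= 2
        return float(buried_atoms.mean())
    if method != "sasa":
        raise ValueError(f"unknown buriedness method {method!r}")

    import biotite.structure as struc

    def _atom_array(elements, coords):
        arr = struc.AtomArray(len(elements))
        arr.coord = np.asarray(coords, dtype=np.float32)
        arr.element = np.array([e.upper() for e in elements])
        arr.res_name = np.array(["UNK"] * len(elements))
        arr.atom_name = np.array([e.upper() for e in elements])
        return arr

    lig_arr = _atom_array(lig_elements, lig_coords)
    free = struc.sasa(
        lig_arr, probe_radius=probe_radius, vdw_radii="Single",
        point_number=point_number,
    )
    free_total = float(np.nansum(free))
    if free_total <= 0:
        raise ValueError("degenerate ligand geometry: zero free surface area")

    if len(protein_coords):
        complex_arr = _atom_array(
            list(lig_elements) + list(protein_elements),
            np.vstack([lig_coords, protein_coords]),
        )
        in_complex = struc.sasa(
            complex_arr, probe_radius=probe_radius, vdw_radii="Single",
            point_number=point_number,
            atom_filter=np.arange(len(complex_arr)) < len(lig_elements),
        )
        complex_total = float(np.nansum(in_complex[: len(lig_elements)]))
    else:
        complex_total = free_total

    return float(np.clip(1.0 - complex_total / free_total, 0.0, 1.0))


def dedupe_by_edia(ligands: Sequence[LigandInstance]) -> list[LigandInstance]:
    """Within each (entry_id, canonical SMILES) group keep the instance
    with the best EDIA_m; ties keep the lexicographically smallest
    (chain_id, residue_number)."""
    groups: dict[tuple[str, str | None], list[LigandInstance]] = {}
    for lig in ligands:
        groups.setdefault((lig.entry_id, lig.smiles), []).append(lig)
    kept = []
    for group in groups.values():
        def _edia(l: LigandInstance) -> float:
            return l.edia_m if l.edia_m is not None else float("-inf")

        best = sorted(
            group, key=lambda l: (-_edia(l), l.chain_id, l.residue_number)
        )[0]
        n_best = sum(1 for l in group if _edia(l) == _edia(best))
        if n_best > 1:
            logger.warning(
                "EDIA tie in entry %s for SMILES %s: keeping %s",
                best.entry_id, best.smiles, best.key_str,
            )
        kept.append(best)
    # preserve the original input order for determinism of reports
    kept_keys = {l.key for l in kept}
    return [l for l in ligands if l.key in kept_keys]


#: (step index, Table-style name) in cascade order
CASCADE_STEPS = [
    (3, "PDB Resolution > 2.5 A"),
    (4, "EDIA_m < 0.8"),
    (5, "Molecular weight > 975 g/mol"),
    (6, "Rotatable bonds > 10"),
    (7, "Atom type filter"),
    (8, "Heavy atoms < 10"),
    (9, "Duplicate removal"),
    (10, "No activity value"),
    (11, "Ligand efficiency <= 0.3"),
    (12, "Buriedness < 0.5"),
]


def apply_cascade(
    ligands: Sequence[LigandInstance],
    entries: Mapping[str, StructureEntry],
    activity_ledger: Mapping[tuple[str, str], list],
    edia_table: Mapping[tuple, float] | None = None,
    thresholds: FilterThresholds = FilterThresholds(),
    le_value_selection: str = "min_p",
    buriedness_method: str = "sasa",
) -> FilterReport:
    """Run the ten selection steps in order and account for every discard.

    ``ligands`` must already be perceived (SMILES and descriptors set) and
    free of construction-time skip flags.  A missing EDIA score fails the
    EDIA step; unknown resolution fails the resolution step.
    """
    edia_table = edia_table or {}
    report = FilterReport()
    current: list[LigandInstance] = [
        l for l in ligands if l.skip_reason is None
    ]

    for lig in current:
        if lig.edia_m is None:
            lig.edia_m = edia_table.get(lig.key)

    def _record(step_index: int, step_name: str, survivors, discarded):
        for lig in discarded:
            report.discard_reasons[lig.key] = step_name
        report.rows.append(
            FilterStepRow(step_index, step_name, len(discarded), len(survivors))
        )
        return survivors

    for step_index, step_name in CASCADE_STEPS:
        if step_index == 3:
            keep = [
                l for l in current
                if (res := entries[l.entry_id].resolution) is not None
                and res <= thresholds.max_resolution
            ]
        elif step_index == 4:
            keep = [
                l for l in current
                if l.edia_m is not None and l.edia_m > thresholds.min_edia
            ]
        elif step_index == 5:
            keep = [
                l for l in current
                if l.properties.molecular_weight <= thresholds.max_molecular_weight
            ]
        elif step_index == 6:
            keep = [
                l for l in current
                if l.properties.rotatable_bonds <= thresholds.max_rotatable_bonds
            ]
        elif step_index == 7:
            keep = [
                l for l in current
                if l.properties.elements <= thresholds.allowed_elements
            ]
        elif step_index == 8:
            keep = [
                l for l in current
                if l.properties.heavy_atom_count >= thresholds.min_heavy_atoms
            ]
        elif step_index == 9:
            keep = dedupe_by_edia(current)
        elif step_index == 10:
            keep = []
            for lig in current:
                records = activity_ledger.get(
                    (lig.entry_id, lig.residue_name), []
                )
                result = ledger_mod.min_le_for_ligand(
                    records, lig.properties.heavy_atom_count,
                    value_selection=le_value_selection,
                ) if records else None
                if result is not None:
                    lig.p_value = result.p_value
                    lig.ligand_efficiency = result.ligand_efficiency
                    keep.append(lig)
        elif step_index == 11:
            keep = [
                l for l in current
                if l.ligand_efficiency is not None
                and l.ligand_efficiency > thresholds.min_ligand_efficiency
            ]
        elif step_index == 12:
            keep = []
            for lig in current:
                if lig.buriedness is None:
                    entry = entries[lig.entry_id]
                    elements, coords = entry.protein_heavy_atoms()
                    lig.buriedness = compute_buriedness(
                        lig, elements, coords, method=buriedness_method
                    )
                if lig.buriedness >= thresholds.min_buriedness:
                    keep.append(lig)
        discarded = [l for l in current if l.key not in {k.key for k in keep}]
        current = _record(step_index, step_name, keep, discarded)

    report.survivors = [l.key for l in current]
    return report
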
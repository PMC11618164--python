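"""Ordered ligand pairs, Shape Tversky scoring and difficulty subsets.

The Shape Tversky Index with t = 1, q = 0 measures how much of the
template molecule's volume is covered by the query:

    ShapeTversky(T, Q) = overlap(T, Q) / (overlap(T, Q) + nonOverlap(T))

Volumes are hard-sphere grid volumes over heavy atoms with Bondi vdW
radii.  Pairs are binned into ten 0.1-wide subsets; the top bin is closed
(an index of exactly 1.0 falls into subset_90).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .ensemble_builder import EnsembleMember, LigandEnsemble

#: Bondi van der Waals radii (Angstrom); 1.70 for anything unlisted
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "B": 1.92, "Si": 2.10, "Se": 1.90,
}
DEFAULT_RADIUS = 1.70
DEFAULT_SPACING = 0.4


@dataclass(frozen=True)
class LigandPair:
    ensemble_name: str
    template_key: tuple
    query_key: tuple
    shape_tversky: float
    subset: str


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.capitalize(), DEFAULT_RADIUS)


def _occupancy(
    coords: np.ndarray,
    radii: np.ndarray,
    origin: np.ndarray,
    shape: tuple[int, int, int],
    spacing: float,
) -> np.ndarray:
    """Boolean lattice: a cell is occupied iff its center lies within the
    vdW radius of at least one atom."""
    occ = np.zeros(shape, dtype=bool)
    for (x, y, z), r in zip(coords, radii):
        lo = np.floor((np.array([x, y, z]) - r - origin) / spacing).astype(int)
        hi = np.ceil((np.array([x, y, z]) + r - origin) / spacing).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape)
        if np.any(lo >= hi):
            continue
        axes = [
            origin[i] + spacing * np.arange(lo[i], hi[i]) for i in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        inside = (gx - x) ** 2 + (gy - y) ** 2 + (gz - z) ** 2 <= r * r
        occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= inside
    return occ


def volume_overlap(
    template_coords: np.ndarray,
    template_elements: Sequence[str],
    query_coords: np.ndarray,
    query_elements: Sequence[str],
    spacing: float = DEFAULT_SPACING,
    margin: float | None = None,
) -> tuple[float, float, float]:
    """Grid-counted (overlap, nonOverlap(T), nonOverlap(Q)) in cubic
    Angstrom, heavy atoms only."""
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    t_coords = np.asarray(template_coords, dtype=float).reshape(-1, 3)
    q_coords = np.asarray(query_coords, dtype=float).reshape(-1, 3)
    t_radii = np.array([vdw_radius(e) for e in template_elements])
    q_radii = np.array([vdw_radius(e) for e in query_elements])
    if margin is None:
        margin = 2.0 * float(max(t_radii.max(), q_radii.max()))

    all_coords = np.vstack([t_coords, q_coords])
    origin = all_coords.min(axis=0) - margin
    upper = all_coords.max(axis=0) + margin
    shape = tuple(np.ceil((upper - origin) / spacing).astype(int) + 1)

    t_occ = _occupancy(t_coords, t_radii, origin, shape, spacing)
    q_occ = _occupancy(q_coords, q_radii, origin, shape, spacing)
    cell = spacing ** 3
    overlap = float(np.count_nonzero(t_occ & q_occ)) * cell
    non_t = float(np.count_nonzero(t_occ & ~q_occ)) * cell
    non_q = float(np.count_nonzero(q_occ & ~t_occ)) * cell
    return overlap, non_t, non_q


def shape_tversky(
    overlap: float, non_overlap_t: float, non_overlap_q: float,
    t: float = 1.0, q: float = 0.0,
) -> float:
    """Shape Tversky Index from precomputed volume terms."""
    denom = overlap + t * non_overlap_t + q * non_overlap_q
    if denom <= 0:
        raise ValueError("template volume is zero")
    return overlap / denom


def pair_shape_tversky(
    template: EnsembleMember,
    query: EnsembleMember,
    spacing: float = DEFAULT_SPACING,
    t: float = 1.0,
    q: float = 0.0,
) -> float:
    tc, te = _heavy(template)
    qc, qe = _heavy(query)
    ov, nt, nq = volume_overlap(tc, te, qc, qe, spacing=spacing)
    return shape_tversky(ov, nt, nq, t=t, q=q)


def _heavy(member: EnsembleMember) -> tuple[np.ndarray, list[str]]:
    mask = np.array([not a.is_hydrogen for a in member.ligand.atoms])
    coords = np.asarray(member.coords, dtype=float)[mask]
    elements = [a.element for a in member.ligand.atoms if not a.is_hydrogen]
    return coords, elements


def assign_subset(index: float) -> str:
    """subset_{10*floor(10*index)}; 1.0 maps to subset_90."""
    if not (0.0 <= index <= 1.0):
        raise ValueError(f"index {index} outside [0, 1]")
    bin_idx = min(int(index * 10), 9)
    return f"subset_{bin_idx * 10}"


def enumerate_pairs(
    ensemble: LigandEnsemble, spacing: float = DEFAULT_SPACING
) -> list[LigandPair]:
    """All n*(n-1) ordered (template, query) pairs of an ensemble."""
    pairs = []
    for template in ensemble.members:
        for query in ensemble.members:
            if template.ligand.key == query.ligand.key:
                continue
            sti = pair_shape_tversky(template, query, spacing=spacing)
            pairs.append(
                LigandPair(
                    ensemble_name=ensemble.name,
                    template_key=template.ligand.key,
                    query_key=query.ligand.key,
                    shape_tversky=sti,
                    subset=assign_subset(sti),
                )
            )
    return pairs


def pairs_to_tsv(pairs: Sequence[LigandPair], path) -> None:
    lines = ["ensemble_name\ttemplate_key\tquery_key\tshape_tversky\tsubset"]
    for p in pairs:
        t = ":".join(str(x) for x in p.template_key)
        q = ":".join(str(x) for x in p.query_key)
        lines.append(
            f"{p.ensemble_name}\t{t}\t{q}\t{p.shape_tversky:.4f}\t{p.subset}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
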
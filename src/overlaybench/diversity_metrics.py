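"""Dataset characterization: scaffold diversity, fingerprint similarity,
ensemble statistics and release-date growth.

The consensus-diversity coordinates of a molecule set are (median MACCS
Tanimoto similarity, scaffold AUC).  Scaffold AUC is the area under the
scaffold recovery curve: Bemis-Murcko scaffolds sorted by frequency
descending, points (i / n_scaffolds, cumulative molecule fraction),
trapezoid rule.  0.5 means every molecule has its own scaffold; values
toward 1 mean the set concentrates on few scaffolds.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import MACCSkeys
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CdpPoint:
    set_id: str
    median_fp_similarity: float
    scaffold_auc: float
    set_size: int
    degenerate_scaffolds: bool = False


@dataclass(frozen=True)
class EnsembleStats:
    name: str
    n_members: int
    hac_mean: float
    hac_std: float  # sample standard deviation (n - 1)
    hac_min: int
    hac_max: int


def bemis_murcko_scaffold(mol: Chem.Mol) -> str:
    """Canonical SMILES of the Bemis-Murcko framework; acyclic molecules
    yield an empty scaffold (their own scaffold class)."""
    scaffold = MurckoScaffold.GetScaffoldForMol(Chem.RemoveHs(mol))
    return Chem.MolToSmiles(scaffold)


def scaffold_curve(labels: Sequence[str]) -> np.ndarray:
    """Recovery-curve points (scaffold fraction, cumulative molecule
    fraction), including the origin."""
    if len(labels) == 0:
        raise ValueError("empty molecule set")
    counts = sorted(Counter(labels).values(), reverse=True)
    n_mol = len(labels)
    n_scaf = len(counts)
    xs = np.arange(n_scaf + 1) / n_scaf
    ys = np.concatenate([[0.0], np.cumsum(counts) / n_mol])
    return np.column_stack([xs, ys])


def scaffold_auc(labels: Sequence[str]) -> float:
    """Trapezoid area under the scaffold recovery curve, in [0.5, 1] for
    two or more scaffolds.  A single scaffold class degenerates to the
    diagonal (0.5) and is flagged with a warning."""
    curve = scaffold_curve(labels)
    if len(curve) == 2:
        logger.warning(
            "scaffold AUC is degenerate: a single scaffold class yields "
            "the diagonal value 0.5"
        )
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


def maccs_fingerprint(mol: Chem.Mol):
    return MACCSkeys.GenMACCSKeys(Chem.RemoveHs(mol))


def median_pairwise_similarity(mols: Sequence[Chem.Mol]) -> float | None:
    """Median MACCS-key Tanimoto over all unordered distinct pairs;
    absent for fewer than two molecules."""
    if len(mols) < 2:
        return None
    fps = [maccs_fingerprint(m) for m in mols]
    sims = []
    for i in range(len(fps)):
        sims.extend(DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:]))
    return float(np.median(sims))


def cdp_point(set_id: str, mols: Sequence[Chem.Mol]) -> CdpPoint:
    labels = [bemis_murcko_scaffold(m) for m in mols]
    return CdpPoint(
        set_id=set_id,
        median_fp_similarity=median_pairwise_similarity(mols),
        scaffold_auc=scaffold_auc(labels),
        set_size=len(mols),
        degenerate_scaffolds=len(set(labels)) == 1,
    )


def cdp_table(points: Iterable[CdpPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_id": p.set_id,
                "set_size": p.set_size,
                "median_fp_similarity": p.median_fp_similarity,
                "scaffold_auc": p.scaffold_auc,
                "degenerate_scaffolds": p.degenerate_scaffolds,
            }
            for p in points
        ]
    )


def ensemble_stats(ensemble) -> EnsembleStats:
    """Mean and sample (n-1) standard deviation of member heavy atom
    counts."""
    hacs = np.array(
        [
            m.ligand.properties.heavy_atom_count
            if m.ligand.properties is not None
            else m.ligand.heavy_atom_count
            for m in ensemble.members
        ],
        dtype=float,
    )
    return EnsembleStats(
        name=ensemble.name,
        n_members=len(hacs),
        hac_mean=float(hacs.mean()),
        hac_std=float(hacs.std(ddof=1)) if len(hacs) > 1 else 0.0,
        hac_min=int(hacs.min()),
        hac_max=int(hacs.max()),
    )


def hac_sample_std(hacs: Sequence[float]) -> float:
    """Sample standard deviation of heavy atom counts (n - 1)."""
    arr = np.asarray(hacs, dtype=float)
    if len(arr) < 2:
        return 0.0
    return float(arr.std(ddof=1))


PROPERTY_COLUMNS = ("molecular_weight", "slogp", "hbd", "hba", "rotatable_bonds")


def property_distribution_summary(
    properties: Sequence, n_bins: int = 20
) -> pd.DataFrame:
    """Quantile summary (min, quartiles, max) per descriptor for a set of
    perceived molecules' properties."""
    frame = pd.DataFrame(
        [
            {col: getattr(p, col) for col in PROPERTY_COLUMNS}
            for p in properties
        ]
    )
    rows = []
    for col in PROPERTY_COLUMNS:
        values = frame[col].to_numpy(dtype=float)
        q = np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0])
        rows.append(
            {
                "property": col,
                "min": q[0], "q1": q[1], "median": q[2], "q3": q[3],
                "max": q[4],
            }
        )
    return pd.DataFrame(rows)


def release_growth(
    pairs: Sequence, release_dates: Mapping[str, "object"]
) -> pd.DataFrame:
    """Per-year counts of ligand pairs, dated by the *latest* release
    date of the pair's two source entries, plus the cumulative series.
    Pairs with a missing date are excluded with a log line."""
    years = []
    for pair in pairs:
        entries = (pair.template_key[0], pair.query_key[0])
        dates = [release_dates.get(e) for e in entries]
        if any(d is None for d in dates):
            logger.warning("pair %s/%s lacks a release date; excluded",
                           *entries)
            continue
        years.append(max(d.year for d in dates))
    counts = Counter(years)
    index = sorted(counts)
    frame = pd.DataFrame(
        {"year": index, "n_pairs": [counts[y] for y in index]}
    )
    frame["cumulative_pairs"] = frame["n_pairs"].cumsum()
    return frame
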
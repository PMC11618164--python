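"""Grouping of intersecting ensembles into clusters and representative picking.

Two ensembles intersect when they share a protein-ligand complex, i.e.
the same (entry, ligand) occurs in both.  Ensembles are processed largest
first (name as tie-break); an ensemble that intersects no existing
cluster founds a new one, one intersecting a single cluster joins it, and
one intersecting several triggers a merge of those clusters.  The result
is the set of connected components of the "shares a complex" graph, so no
complex ever occurs in two retained representative ensembles.

A strict first-match variant (assign to the first intersecting cluster,
never merge) is available for comparison; it does not guarantee the
non-intersection property.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .ensemble_builder import LigandEnsemble

logger = logging.getLogger(__name__)


@dataclass
class EnsembleCluster:
    ensembles: list[LigandEnsemble]
    representative: str | None = None

    @property
    def complexes(self) -> frozenset:
        out: set = set()
        for ens in self.ensembles:
            out |= ens.complexes
        return frozenset(out)


def order_ensembles(ensembles: Sequence[LigandEnsemble]) -> list[LigandEnsemble]:
    """Sort by member count descending, then ensemble name ascending."""
    names = [e.name for e in ensembles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate ensemble names")
    return sorted(ensembles, key=lambda e: (-e.size, e.name))


def cluster_ensembles(
    ordered: Sequence[LigandEnsemble], merge: bool = True
) -> list[EnsembleCluster]:
    """Incremental clustering over a pre-ordered ensemble list.

    With ``merge`` (default) the outcome equals the connected components
    of the shared-complex graph regardless of processing order.
    """
    clusters: list[list[LigandEnsemble]] = []
    cluster_complexes: list[set] = []
    for ens in ordered:
        hits = [
            i for i, cplx in enumerate(cluster_complexes)
            if cplx & ens.complexes
        ]
        if not hits:
            clusters.append([ens])
            cluster_complexes.append(set(ens.complexes))
        elif len(hits) == 1 or not merge:
            i = hits[0]
            clusters[i].append(ens)
            cluster_complexes[i] |= ens.complexes
        else:
            # merge all intersected clusters plus the ensemble
            target = hits[0]
            for i in reversed(hits[1:]):
                clusters[target] += clusters.pop(i)
                cluster_complexes[target] |= cluster_complexes.pop(i)
            clusters[target].append(ens)
            cluster_complexes[target] |= ens.complexes
    return [EnsembleCluster(ensembles=group) for group in clusters]


def pick_representative(cluster: EnsembleCluster) -> str:
    """Ensemble whose search ligand has the highest heavy atom count;
    ties resolved by ensemble name ascending."""
    if not cluster.ensembles:
        raise ValueError("empty cluster")

    def _hac(ens: LigandEnsemble) -> int:
        lig = ens.search_ligand
        if lig.properties is not None:
            return lig.properties.heavy_atom_count
        return lig.heavy_atom_count

    best = sorted(cluster.ensembles, key=lambda e: (-_hac(e), e.name))[0]
    ties = [e for e in cluster.ensembles if _hac(e) == _hac(best)]
    if len(ties) > 1:
        logger.warning(
            "representative HAC tie (%d): choosing %s", _hac(best), best.name
        )
    cluster.representative = best.name
    return best.name


def cluster_and_pick(
    ensembles: Sequence[LigandEnsemble], merge: bool = True
) -> list[EnsembleCluster]:
    clusters = cluster_ensembles(order_ensembles(ensembles), merge=merge)
    for cluster in clusters:
        pick_representative(cluster)
    return clusters


def representatives(clusters: Sequence[EnsembleCluster]) -> list[LigandEnsemble]:
    out = []
    for cluster in clusters:
        name = cluster.representative or pick_representative(cluster)
        out.append(next(e for e in cluster.ensembles if e.name == name))
    return out


def clusters_to_tsv(clusters: Sequence[EnsembleCluster], path) -> None:
    lines = ["cluster_id\tensemble_name\tis_representative\tn_members\tsearch_ligand_hac"]
    for i, cluster in enumerate(clusters):
        for ens in sorted(cluster.ensembles, key=lambda e: e.name):
            hac = (
                ens.search_ligand.properties.heavy_atom_count
                if ens.search_ligand.properties is not None
                else ens.search_ligand.heavy_atom_count
            )
            rep = int(ens.name == cluster.representative)
            lines.append(f"{i}\t{ens.name}\t{rep}\t{ens.size}\t{hac}")
    Path(path).write_text("\n".join(lines) + "\n")
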
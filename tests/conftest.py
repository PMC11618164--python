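"""Shared fixtures: synthetic scenarios and a fully executed pipeline.

Scenario generation and the end-to-end run are comparatively expensive
(conformer embedding, SASA, grids), so they are session-scoped and
shared by all tests that only read from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pytest

from overlaybench import (
    affinity_ledger,
    ensemble_builder,
    filter_cascade,
    nbse_clustering,
    pair_shapes,
    structure_io,
    synthetic_fixtures,
)


@dataclass
class PipelineRun:
    scenario: synthetic_fixtures.Scenario
    entries: dict = field(default_factory=dict)
    ligands: list = field(default_factory=list)
    report: object = None
    survivors: list = field(default_factory=list)
    ensembles: list = field(default_factory=list)
    clusters: list = field(default_factory=list)
    pairs: list = field(default_factory=list)

    @property
    def manifest(self):
        return self.scenario.manifest


def _run_pipeline(scenario, tmp_path: Path, through: str = "pairs") -> PipelineRun:
    run = PipelineRun(scenario=scenario)
    for entry_id, text in sorted(scenario.structures.items()):
        entry = structure_io.parse_structure(text, entry_id=entry_id)
        structure_io.classify_candidates(entry)
        run.entries[entry_id] = entry
        run.ligands += [
            l for l in entry.ligand_candidates if l.skip_reason is None
        ]
    activity = tmp_path / "activity.tsv"
    edia = tmp_path / "edia.tsv"
    activity.write_text(scenario.activity_tsv)
    edia.write_text(scenario.edia_tsv)
    ledger = affinity_ledger.build_ledger(
        affinity_ledger.read_activity_table(activity)
    )
    run.report = filter_cascade.apply_cascade(
        run.ligands, run.entries, ledger, filter_cascade.read_edia_table(edia)
    )
    keys = set(run.report.survivors)
    run.survivors = [l for l in run.ligands if l.key in keys]
    if through == "filter":
        return run
    run.ensembles = ensemble_builder.build_all_ensembles(
        run.survivors, run.entries
    )
    run.clusters = nbse_clustering.cluster_and_pick(run.ensembles)
    for rep in nbse_clustering.representatives(run.clusters):
        run.pairs += pair_shapes.enumerate_pairs(rep)
    return run


@pytest.fixture(scope="session")
def filter_scenario():
    return synthetic_fixtures.make_filter_scenario(seed=1)


@pytest.fixture(scope="session")
def ensemble_scenario():
    return synthetic_fixtures.make_ensemble_scenario(seed=1)


@pytest.fixture(scope="session")
def filter_run(filter_scenario, tmp_path_factory):
    return _run_pipeline(
        filter_scenario, tmp_path_factory.mktemp("filter_run"),
        through="filter",
    )


@pytest.fixture(scope="session")
def ensemble_run(ensemble_scenario, tmp_path_factory):
    return _run_pipeline(
        ensemble_scenario, tmp_path_factory.mktemp("ensemble_run")
    )
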
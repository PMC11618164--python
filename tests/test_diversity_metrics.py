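"""Scaffold diversity, fingerprint similarity, ensemble and growth stats."""

import datetime

import numpy as np
import pytest
from rdkit import Chem, DataStructs
from rdkit.Chem import MACCSkeys

from overlaybench import diversity_metrics as dm


def _mol(smiles):
    return Chem.MolFromSmiles(smiles)


class TestBemisMurckoScaffold:
    def test_toluene_reduces_to_benzene(self):
        assert dm.bemis_murcko_scaffold(_mol("Cc1ccccc1")) == Chem.CanonSmiles(
            "c1ccccc1"
        )

    def test_acyclic_molecule_yields_the_empty_scaffold(self):
        assert dm.bemis_murcko_scaffold(_mol("CCCCCC")) == ""

    def test_diphenylmethane_keeps_rings_and_linker(self):
        scaffold = dm.bemis_murcko_scaffold(_mol("c1ccccc1Cc1ccccc1"))
        assert scaffold == Chem.CanonSmiles("c1ccccc1Cc1ccccc1")

    def test_substituents_are_pruned_from_a_drug_like_molecule(self):
        scaffold = dm.bemis_murcko_scaffold(
            _mol("CC(=O)Nc1ccc(O)cc1")  # paracetamol
        )
        assert scaffold == Chem.CanonSmiles("c1ccccc1")


class TestScaffoldAuc:
    def test_all_unique_scaffolds_give_the_diagonal(self):
        labels = [f"s{i}" for i in range(40)]
        assert dm.scaffold_auc(labels) == pytest.approx(0.5, abs=1e-12)

    def test_ninety_nine_to_one_split_matches_the_trapezoid_value(self):
        labels = ["major"] * 99 + ["minor"]
        # points (0,0), (0.5, 0.99), (1, 1): area = 0.2475 + 0.4975
        assert dm.scaffold_auc(labels) == pytest.approx(0.745, abs=1e-12)

    def test_single_scaffold_degenerates_to_the_diagonal(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            value = dm.scaffold_auc(["only"] * 10)
        assert value == pytest.approx(0.5)
        assert any("degenerate" in r.message for r in caplog.records)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            dm.scaffold_auc([])

    def test_concentrating_counts_at_fixed_scaffold_number_raises_the_auc(
        self,
    ):
        # merging whole classes can *lower* the AUC because it rescales
        # the scaffold axis; the clean concentration property holds at a
        # fixed number of scaffolds: moving one molecule from a smaller
        # class to a larger one (both staying nonempty) never decreases
        # the area under the recovery curve
        from collections import Counter

        rng = np.random.default_rng(21)
        checked = 0
        for _ in range(60):
            n = int(rng.integers(8, 40))
            k = int(rng.integers(3, 6))
            labels = [f"s{rng.integers(k)}" for _ in range(n)]
            counts = Counter(labels)
            donors = [s for s, c in counts.items() if c >= 2]
            if len(counts) < 3 or not donors:
                continue
            donor = min(donors, key=lambda s: counts[s])
            receiver = max(counts, key=lambda s: (counts[s], s != donor))
            if receiver == donor:
                continue
            before = dm.scaffold_auc(labels)
            moved = list(labels)
            moved[moved.index(donor)] = receiver
            after = dm.scaffold_auc(moved)
            assert after >= before - 1e-12
            checked += 1
        assert checked >= 20

    def test_curve_matches_brute_force_construction(self):
        labels = ["a"] * 5 + ["b"] * 3 + ["c"] * 2
        curve = dm.scaffold_curve(labels)
        # brute force: counts sorted descending = [5, 3, 2]
        expected = np.array(
            [[0, 0], [1 / 3, 0.5], [2 / 3, 0.8], [1.0, 1.0]]
        )
        assert np.allclose(curve, expected)


class TestMedianPairwiseSimilarity:
    def test_identical_molecules_score_one(self):
        mols = [_mol("CC(=O)Nc1ccccc1")] * 4
        assert dm.median_pairwise_similarity(mols) == pytest.approx(1.0)

    def test_fewer_than_two_molecules_is_absent(self):
        assert dm.median_pairwise_similarity([_mol("CCO")]) is None

    def test_median_equals_a_brute_force_double_loop(self):
        smiles = ["CCO", "c1ccccc1O", "CC(=O)NC1CCCCC1", "NCCc1ccncc1",
                  "OC(=O)c1ccccc1"]
        mols = [_mol(s) for s in smiles]
        fps = [MACCSkeys.GenMACCSKeys(m) for m in mols]
        sims = [
            DataStructs.TanimotoSimilarity(fps[i], fps[j])
            for i in range(len(fps)) for j in range(i + 1, len(fps))
        ]
        assert dm.median_pairwise_similarity(mols) == pytest.approx(
            float(np.median(sims)), abs=1e-12
        )

    def test_permutation_invariant_and_bounded(self):
        mols = [_mol(s) for s in ("CCO", "CCCO", "c1ccccc1", "CCN")]
        forward = dm.median_pairwise_similarity(mols)
        backward = dm.median_pairwise_similarity(list(reversed(mols)))
        assert forward == backward
        assert 0.0 <= forward <= 1.0


class _StubEnsemble:
    def __init__(self, name, hacs):
        class _Lig:
            def __init__(self, hac):
                self.properties = None
                self.heavy_atom_count = hac

        class _Member:
            def __init__(self, hac):
                self.ligand = _Lig(hac)

        self.name = name
        self.members = [_Member(h) for h in hacs]


class TestEnsembleStats:
    def test_extreme_example_with_two_ligands(self):
        # heavy atom counts 18 and 43: sample std 17.68 (two decimals)
        stats = dm.ensemble_stats(_StubEnsemble("0NJ_A_601-4e5d", [18, 43]))
        assert stats.hac_std == pytest.approx(17.68, abs=0.005)

    def test_equal_counts_give_zero_spread(self):
        stats = dm.ensemble_stats(_StubEnsemble("X", [21, 21, 21]))
        assert stats.hac_std == 0.0

    def test_three_point_sample_std(self):
        stats = dm.ensemble_stats(_StubEnsemble("X", [10, 20, 30]))
        assert stats.hac_std == pytest.approx(10.0, abs=1e-12)
        assert stats.hac_mean == pytest.approx(20.0)

    def test_matches_a_two_pass_formula_on_random_inputs(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            hacs = rng.integers(8, 60, size=int(rng.integers(2, 12)))
            stats = dm.ensemble_stats(_StubEnsemble("X", list(hacs)))
            mean = sum(hacs) / len(hacs)
            var = sum((h - mean) ** 2 for h in hacs) / (len(hacs) - 1)
            assert stats.hac_std == pytest.approx(np.sqrt(var), abs=1e-12)


class TestPropertySummary:
    def test_single_molecule_quantiles_collapse(self):
        from overlaybench.chem_properties import LigandProperties

        props = [LigandProperties("CCO", 46.07, 3, 0, frozenset("CO"),
                                  1, 1, -0.0014)]
        table = dm.property_distribution_summary(props)
        row = table[table["property"] == "molecular_weight"].iloc[0]
        assert row["min"] == row["median"] == row["max"] == 46.07

    def test_quartiles_match_a_sort_based_oracle(self):
        from overlaybench.chem_properties import LigandProperties

        weights = [100.0, 150.0, 200.0, 250.0, 400.0]
        props = [
            LigandProperties("C", w, 10, 2, frozenset("C"), 1, 1, 0.5)
            for w in weights
        ]
        table = dm.property_distribution_summary(props)
        row = table[table["property"] == "molecular_weight"].iloc[0]
        assert row["median"] == np.median(weights)
        assert row["q1"] == np.quantile(weights, 0.25)
        assert row["max"] == max(weights)


class _StubPair:
    def __init__(self, entry_a, entry_b):
        self.template_key = (entry_a, "LIG", "A", 301)
        self.query_key = (entry_b, "LIG", "A", 301)


class TestReleaseGrowth:
    def test_pair_is_dated_by_the_latest_of_its_two_entries(self):
        dates = {
            "e001": datetime.date(1994, 1, 1),
            "e002": datetime.date(2017, 6, 1),
        }
        table = dm.release_growth([_StubPair("e001", "e002")], dates)
        assert table["year"].tolist() == [2017]

    def test_single_year_collapses_to_one_row(self):
        dates = {"e001": datetime.date(2010, 1, 1),
                 "e002": datetime.date(2010, 5, 5)}
        pairs = [_StubPair("e001", "e002"), _StubPair("e002", "e001")]
        table = dm.release_growth(pairs, dates)
        assert len(table) == 1
        assert table["n_pairs"].iloc[0] == 2

    def test_cumulative_series_is_the_prefix_sum(self):
        dates = {
            "e001": datetime.date(2000, 1, 1),
            "e002": datetime.date(2005, 1, 1),
            "e003": datetime.date(2010, 1, 1),
        }
        pairs = [
            _StubPair("e001", "e001"), _StubPair("e001", "e002"),
            _StubPair("e002", "e003"), _StubPair("e003", "e001"),
        ]
        table = dm.release_growth(pairs, dates)
        assert table["cumulative_pairs"].tolist() == list(
            np.cumsum(table["n_pairs"])
        )
        assert (np.diff(table["cumulative_pairs"]) >= 0).all()

    def test_missing_date_excludes_the_pair(self):
        dates = {"e001": datetime.date(2010, 1, 1), "e002": None}
        table = dm.release_growth(
            [_StubPair("e001", "e002"), _StubPair("e001", "e001")], dates
        )
        assert table["n_pairs"].sum() == 1
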
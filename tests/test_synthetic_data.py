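"""Generator contracts: determinism, planted structure, null calibration."""

import math

import numpy as np
import pytest

from mirderep import synthetic_data as sd
from mirderep.deg_integration import (
    AGING_UP,
    HYPOTHALAMUS_UP,
    PARABIOSIS_DOWN,
    filter_degs,
)
from mirderep.mirna_orthology import filter_conserved, map_mirna_orthologs

from conftest import SMALL, directory_hash


class TestScenarioValidation:
    def test_defaults_are_valid(self):
        sd.SyntheticScenario()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mu_up": 0.3},                      # below log2(1.5)
            {"beta_a": 0.5},
            {"widespread_multiplicity": (3, 6)},
            {"n_planted_reversal": 99},
            {"enrichment_factor": 0.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sd.SyntheticScenario(**kwargs)

    def test_load_scenario_rejects_unknown_keys(self, tmp_path):
        p = tmp_path / "sc.yaml"
        p.write_text("seed: 3\nn_genez: 10\n")
        with pytest.raises(ValueError, match="n_genez"):
            sd.load_scenario(p)

    def test_load_scenario_round_trip(self, tmp_path):
        p = tmp_path / "sc.yaml"
        p.write_text("seed: 3\npathway_size: [5, 50]\n")
        sc = sd.load_scenario(p)
        assert sc.seed == 3 and sc.pathway_size == (5, 50)


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            sd.write_scenario(sd.simulate_scenario(SMALL), tmp_path / sub)
        assert directory_hash(tmp_path / "a") == directory_hash(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        import dataclasses

        other = dataclasses.replace(SMALL, seed=SMALL.seed + 1)
        sd.write_scenario(sd.simulate_scenario(SMALL), tmp_path / "a")
        sd.write_scenario(sd.simulate_scenario(other), tmp_path / "b")
        assert directory_hash(tmp_path / "a") != directory_hash(tmp_path / "b")


class TestUniverseStructure:
    def test_decoy_mirnas_fail_seed_filter_exactly(self, small_bundle):
        u = small_bundle.universe
        report = map_mirna_orthologs(u.mouse_mirnas, u.human_mirnas)
        kept, excluded = filter_conserved(report.pairs)
        assert [e.mirna_id for e in excluded] == u.nonconserved_mirnas
        assert len(kept) == SMALL.n_mirnas - SMALL.n_decoy_nonconserved

    def test_planted_fraction_exceeds_background(self, small_bundle):
        u = small_bundle.universe
        targets_by_mirna: dict[str, set[str]] = {}
        for r in u.interactions.records:
            targets_by_mirna.setdefault(r.mirna_id, set()).add(r.gene_human)
        N = SMALL.n_genes
        for pair in u.planted_pairs:
            members = u.pathways.pathways[pair.pathway_id].members
            targets = targets_by_mirna[pair.mirna_id]
            frac = len(targets & members) / len(targets)
            assert frac > len(members) / N

    def test_null_scenario_plants_nothing(self):
        import dataclasses

        sc = dataclasses.replace(SMALL, enrichment_factor=1.0, n_planted_pairs=0,
                                 n_planted_aging=0, n_planted_reversal=0,
                                 n_planted_widespread=0)
        bundle = sd.simulate_scenario(sc)
        assert bundle.truth.planted_pairs == []
        assert bundle.truth.aging_genes == {} == bundle.truth.widespread_genes

    def test_infeasible_enrichment_raises(self):
        import dataclasses

        sc = dataclasses.replace(
            SMALL, n_genes=60, n_pathways=4, pathway_size=(40, 50),
            planted_min_pathway_size=40, planted_min_targets=55,
            target_set_size=(20, 60), enrichment_factor=4.0, n_planted_pairs=1,
        )
        with pytest.raises(ValueError, match="infeasible"):
            sd.simulate_universe(sc)

    def test_ortholog_table_is_one_to_one(self, small_bundle):
        recs = small_bundle.universe.orthologs.records
        assert len({r.human for r in recs}) == len(recs) == len({r.mouse for r in recs})


class TestGroundTruthConsistency:
    def test_planted_records_pass_published_filters(self, small_bundle):
        b = small_bundle
        aging_pass = {(r.cell_type, r.gene) for r in filter_degs(b.aging, AGING_UP)}
        for gene, cts in b.truth.aging_genes.items():
            for ct in cts:
                assert (ct, gene) in aging_pass
        para_pass = {(r.cell_type, r.gene) for r in filter_degs(b.parabiosis, PARABIOSIS_DOWN)}
        for gene, cts in b.truth.reversal_genes.items():
            for ct in cts:
                assert (b.cell_type_map[ct], gene) in para_pass
        hypo_pass = {(r.cell_type, r.gene) for r in filter_degs(b.hypothalamus, HYPOTHALAMUS_UP)}
        for gene, cts in b.truth.widespread_genes.items():
            assert len(cts) >= 5
            for ct in cts:
                assert (ct, gene) in hypo_pass

    def test_reversal_subset_of_aging_and_ground_truth_serializes(self, small_bundle):
        truth = small_bundle.truth
        assert set(truth.reversal_genes) <= set(truth.aging_genes)
        again = sd.GroundTruth.from_json(truth.to_json())
        assert again == truth

    def test_planted_widespread_multiplicity_boundary(self):
        import dataclasses

        sc = dataclasses.replace(SMALL, widespread_multiplicity=(5, 5))
        b = sd.simulate_scenario(sc)
        assert all(len(cts) == 5 for cts in b.truth.widespread_genes.values())


class TestNullCalibration:
    def test_null_pass_rate_matches_independence_model(self):
        """Fraction of null cells passing the aging filter ~ P(p<.05)*P(effect tail)."""
        import dataclasses

        sc = dataclasses.replace(SMALL, n_planted_aging=0, n_planted_reversal=0,
                                 n_planted_widespread=0, n_planted_pairs=0)
        expected = 0.05 * (1 - _phi(math.log2(1.5) / sc.sigma_null))
        rates = []
        for seed in range(20):
            b = sd.simulate_scenario(dataclasses.replace(sc, seed=seed))
            n = len(b.aging.records)
            rates.append(len(filter_degs(b.aging, AGING_UP)) / n)
        mean = float(np.mean(rates))
        se = math.sqrt(expected * (1 - expected) / (20 * n))
        assert abs(mean - expected) < 3 * se + 1e-4


def _phi(x: float) -> float:
    return 0.5 * (1 + math.erf(x / math.sqrt(2)))
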
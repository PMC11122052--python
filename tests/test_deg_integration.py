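"""Filter boundary semantics, target intersection, recurrence and reversal."""

import pytest
from hypothesis import given, settings, strategies as st

from mirderep.deg_integration import (
    AGING_UP,
    HYPOTHALAMUS_UP,
    LINEAR_FC,
    LOG2_FC,
    LOGFC_ANY_BASE,
    PARABIOSIS_DOWN,
    DEGFilterSpec,
    DEGRecord,
    DerepressionHit,
    ScaleMismatchError,
    detect_reversal,
    filter_degs,
    intersect_targets,
    recurrent_genes,
    widespread_genes,
)
from mirderep.io_formats import DEGTable


def _rec(gene, ct, effect, p, scale, dataset="d"):
    return DEGRecord(dataset_id=dataset, cell_type=ct, gene=gene,
                     effect=effect, effect_scale=scale, p_adj=p)


def _table(records, scale, dataset="d"):
    return DEGTable(dataset_id=dataset, effect_scale=scale, records=records)


# One row per boundary case of the three published filter rules.
BOUNDARY_ROWS = [
    # aging: FC >= 1.5 (inclusive), p < 0.05 (exclusive)
    (AGING_UP, _rec("g01", "ct", 1.5, 0.049, LINEAR_FC), True),   # both boundaries favourable
    (AGING_UP, _rec("g02", "ct", 1.5, 0.05, LINEAR_FC), False),   # p at alpha -> dropped
    (AGING_UP, _rec("g03", "ct", 1.4999, 0.01, LINEAR_FC), False),
    (AGING_UP, _rec("g04", "ct", 2.0, 0.0, LINEAR_FC), True),
    # parabiosis: logFC < 0 strict, p < 0.05
    (PARABIOSIS_DOWN, _rec("g05", "ct", 0.0, 0.001, LOGFC_ANY_BASE), False),  # zero excluded
    (PARABIOSIS_DOWN, _rec("g06", "ct", -1e-9, 0.049, LOGFC_ANY_BASE), True),
    (PARABIOSIS_DOWN, _rec("g07", "ct", -0.4, 0.05, LOGFC_ANY_BASE), False),
    (PARABIOSIS_DOWN, _rec("g08", "ct", 0.3, 0.001, LOGFC_ANY_BASE), False),
    # hypothalamus: log2FC > 0.1 strict, p < 0.05
    (HYPOTHALAMUS_UP, _rec("g09", "ct", 0.1, 0.01, LOG2_FC), False),  # boundary excluded
    (HYPOTHALAMUS_UP, _rec("g10", "ct", 0.1001, 0.01, LOG2_FC), True),
    (HYPOTHALAMUS_UP, _rec("g11", "ct", 0.5, 0.05, LOG2_FC), False),
    (HYPOTHALAMUS_UP, _rec("g12", "ct", -0.5, 0.01, LOG2_FC), False),
]


class TestFilterDegs:
    @pytest.mark.parametrize("spec, record, kept", BOUNDARY_ROWS)
    def test_boundary_semantics(self, spec, record, kept):
        table = _table([record], record.effect_scale)
        assert (filter_degs(table, spec) == [record]) is kept

    def test_scale_mismatch_is_an_error(self):
        table = _table([_rec("g", "ct", 0.5, 0.01, LOG2_FC)], LOG2_FC)
        with pytest.raises(ScaleMismatchError):
            filter_degs(table, AGING_UP)

    def test_idempotent_subset_and_permutation_invariant(self):
        records = [r for _, r, _ in BOUNDARY_ROWS if r.effect_scale == LINEAR_FC]
        table = _table(records, LINEAR_FC)
        once = filter_degs(table, AGING_UP)
        assert set(once) <= set(records)
        again = filter_degs(_table(once, LINEAR_FC), AGING_UP)
        assert again == once
        flipped = filter_degs(_table(records[::-1], LINEAR_FC), AGING_UP)
        assert set(flipped) == set(once)


GENE_TO_MIRNAS = {"CDKN2A": ["hsa-miR-320a-3p"], "TXNIP": ["hsa-miR-17-5p", "hsa-miR-20a-5p"]}
MOUSE_TO_HUMAN = {"Cdkn2a": "CDKN2A", "Txnip": "TXNIP", "Actb": "ACTB"}


class TestIntersectTargets:
    def test_targeted_gene_becomes_hit(self):
        hits = intersect_targets(
            [_rec("Cdkn2a", "OPC", 1.8, 0.01, LINEAR_FC)], GENE_TO_MIRNAS, MOUSE_TO_HUMAN
        )
        (h,) = hits
        assert h.mirnas == ("hsa-miR-320a-3p",) and h.cell_type == "OPC"

    def test_untargeted_and_unmapped_genes_yield_no_hit(self):
        hits = intersect_targets(
            [
                _rec("Actb", "OPC", 2.0, 0.01, LINEAR_FC),   # mapped but not targeted
                _rec("Novel1", "OPC", 2.0, 0.01, LINEAR_FC),  # no ortholog
            ],
            GENE_TO_MIRNAS,
            MOUSE_TO_HUMAN,
        )
        assert hits == []

    def test_empty_input(self):
        assert intersect_targets([], GENE_TO_MIRNAS, MOUSE_TO_HUMAN) == []


def _hit(gene, ct, effect=2.0, dataset="d"):
    return DerepressionHit(gene=gene, cell_type=ct, effect=effect, effect_scale=LINEAR_FC,
                           p_adj=0.01, mirnas=("m1",), dataset_id=dataset)


class TestRecurrentAndWidespread:
    def test_recurrence_boundary(self):
        hits = [_hit("A", "ct1"), _hit("A", "ct2"), _hit("B", "ct1")]
        assert recurrent_genes(hits, 2) == {"A": ["ct1", "ct2"]}
        assert recurrent_genes(hits, 1) == {"A": ["ct1", "ct2"], "B": ["ct1"]}

    def test_rollup_map_groups_types_into_classes(self):
        hits = [_hit("A", "OPC"), _hit("A", "OLG")]
        rollup = {"OPC": "oligo-lineage", "OLG": "oligo-lineage"}
        assert recurrent_genes(hits, 2, rollup) == {}
        assert recurrent_genes(hits, 2) == {"A": ["OLG", "OPC"]}

    def test_widespread_boundary_and_duplicate_types_counted_once(self):
        five = [_hit("W", f"ct{i}") for i in range(5)] + [_hit("W", "ct0")]
        four = [_hit("V", f"ct{i}") for i in range(4)]
        assert set(widespread_genes(five + four, 5)) == {"W"}

    def test_widespread_requires_single_dataset(self):
        with pytest.raises(ValueError):
            widespread_genes([_hit("A", "ct", dataset="d1"), _hit("B", "ct", dataset="d2")], 1)

    @given(st.lists(st.tuples(st.sampled_from("ABC"), st.sampled_from([f"ct{i}" for i in range(6)])), max_size=30))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_minimum_count(self, pairs):
        hits = [_hit(g, ct) for g, ct in pairs]
        sizes = [len(recurrent_genes(hits, m)) for m in range(1, 5)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


CT_MAP = {"endothelial": "BEC", "OPC": "OPC_p"}


class TestDetectReversal:
    def _parabiosis(self, records):
        return _table(records, LOGFC_ANY_BASE, dataset="parabiosis")

    def test_reversal_detected_in_corresponding_cell_type(self):
        aging = [_hit("Cdkn1a", "endothelial")]
        para = self._parabiosis([_rec("Cdkn1a", "BEC", -0.4, 0.01, LOGFC_ANY_BASE)])
        report = detect_reversal(aging, para, PARABIOSIS_DOWN, CT_MAP)
        (h,) = report.hits
        assert h.parabiosis_effect == -0.4 and h.cell_type == "endothelial"
        # containment: the hit is in aging AND in the parabiosis down-set
        down = filter_degs(para, PARABIOSIS_DOWN)
        assert any(r.gene == h.gene and r.cell_type == CT_MAP[h.cell_type] for r in down)

    def test_nonsignificant_parabiosis_change_is_no_reversal(self):
        aging = [_hit("Cdkn1a", "endothelial")]
        para = self._parabiosis([_rec("Cdkn1a", "BEC", -0.4, 0.2, LOGFC_ANY_BASE)])
        assert detect_reversal(aging, para, PARABIOSIS_DOWN, CT_MAP).hits == []

    def test_positive_parabiosis_change_is_no_reversal(self):
        aging = [_hit("Btg2", "endothelial")]
        para = self._parabiosis([_rec("Btg2", "BEC", 0.4, 0.001, LOGFC_ANY_BASE)])
        assert detect_reversal(aging, para, PARABIOSIS_DOWN, CT_MAP).hits == []

    def test_missing_map_entry_raises_listing_types(self):
        aging = [_hit("Cdkn1a", "microglia")]
        para = self._parabiosis([_rec("Cdkn1a", "BEC", -0.4, 0.01, LOGFC_ANY_BASE)])
        with pytest.raises(ValueError, match="microglia"):
            detect_reversal(aging, para, PARABIOSIS_DOWN, CT_MAP)

    def test_mapped_type_absent_from_table_is_logged_not_raised(self):
        aging = [_hit("Cdkn1a", "OPC")]  # maps to OPC_p, absent from the table
        para = self._parabiosis([_rec("Cdkn1a", "BEC", -0.4, 0.01, LOGFC_ANY_BASE)])
        report = detect_reversal(aging, para, PARABIOSIS_DOWN, CT_MAP)
        assert report.hits == [] and report.skipped_cell_types == ["OPC"]
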
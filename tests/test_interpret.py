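import numpy as np
import pandas as pd
import pytest

from simpa.core import candidate_seed, impute_bin, make_training
from simpa.genome_bins import BinSet
from simpa.interpret import (
    CoexpressionTable,
    GeneAnnotation,
    InterpretationResult,
    FeatureRecord,
    annotate_nearest_gene,
    correlate_importance_coexpression,
    interpret_position,
    promoter_scan,
)

from conftest import binset, make_reference


@pytest.fixture
def annotation():
    return GeneAnnotation(
        pd.DataFrame(
            {
                "symbol": ["ALPHA", "BETA", "GAMMA", "ZETA"],
                "chrom": ["chrT", "chrT", "chrT", "chrQ"],
                "tss": [2500, 12500, 17500, 1000],
                "strand": ["+", "-", "+", "+"],
            }
        )
    )


class TestInterpretPosition:
    def test_constant_all_ones_class(self, tiny_reference):
        # bin 1 is present in every experiment -> degenerate model
        res = interpret_position(tiny_reference, binset([0, 2]), ("chrT", 5000), seed=1)
        assert res.probability == 1.0
        assert all(f.importance == 0.0 for f in res.features)

    def test_importances_sum_to_one(self, small_benchmark):
        rs, truth = small_benchmark
        sc = rs.row_binset(0)
        sc = BinSet(sorted(sc.keys)[:40], rs.bin_size, rs.assembly)
        cand = next(k for k in rs.columns
                    if k not in sc and 0 < rs.column(k).sum() < rs.n)
        res = interpret_position(rs, sc, (cand[0], cand[1] * rs.bin_size), seed=2)
        assert res.probability == pytest.approx(
            impute_bin(make_training(rs, sc)[0], rs.column(cand),
                       candidate_seed(2, rs.column(cand)))
        )
        assert sum(f.importance for f in res.features) == pytest.approx(1.0)

    def test_query_inside_cell_flagged(self, tiny_reference):
        res = interpret_position(tiny_reference, binset([1, 2]), ("chrT", 5001), seed=0)
        assert res.already_observed and res.probability == 1.0

    def test_query_outside_reference_universe(self, tiny_reference):
        with pytest.raises(ValueError, match="outside the reference universe"):
            interpret_position(tiny_reference, binset([1]), ("chrT", 999 * 5000), seed=0)

    def test_tss_restriction_reduces_features(self, tiny_reference, annotation):
        sc = binset([0, 1, 2, 3])
        free = interpret_position(tiny_reference, sc, ("chrT", 4 * 5000), seed=1)
        tight = interpret_position(
            tiny_reference, sc, ("chrT", 4 * 5000), seed=1,
            max_tss_distance=1, annotation=annotation,
        )
        assert len(tight.features) <= len(free.features)
        # bins 0, 2, 3 have midpoints exactly on the TSS of ALPHA/BETA/GAMMA
        assert {f.bin for f in tight.features} == {
            ("chrT", 0), ("chrT", 2), ("chrT", 3)
        }

    def test_tss_restriction_can_empty(self, tiny_reference, annotation):
        with pytest.raises(ValueError, match="no input bin"):
            interpret_position(
                tiny_reference, binset([1]), ("chrT", 4 * 5000), seed=1,
                max_tss_distance=1, annotation=annotation,
            )

    def test_position_string_parsing(self, tiny_reference):
        a = interpret_position(tiny_reference, binset([0, 2]), "chrT:5000", seed=1)
        b = interpret_position(tiny_reference, binset([0, 2]), ("chrT", 5000), seed=1)
        assert a.probability == b.probability


class TestNearestGene:
    def test_midpoint_on_tss(self, annotation):
        hits = annotate_nearest_gene(binset([0]), annotation)
        assert hits[("chrT", 0)] == ("ALPHA", 0)  # midpoint 2500 == ALPHA TSS

    def test_equidistant_tie_lexicographic(self):
        ann = GeneAnnotation(
            pd.DataFrame(
                {
                    "symbol": ["BBB", "AAA"],
                    "chrom": ["chrT", "chrT"],
                    "tss": [2000, 3000],
                    "strand": ["+", "+"],
                }
            )
        )
        hits = annotate_nearest_gene(binset([0]), ann)  # midpoint 2500
        assert hits[("chrT", 0)][0] == "AAA"

    def test_unannotated_chrom(self, annotation):
        hits = annotate_nearest_gene(
            BinSet([("chrZ", 0)], 5000, "testasm"), annotation
        )
        assert hits[("chrZ", 0)] == (None, None)

    def test_signed_distance_respects_strand(self, annotation):
        # bin 1 midpoint 7500: ALPHA (+, TSS 2500) downstream +5000;
        # BETA (-, TSS 12500) -> 7500 is downstream of a minus-strand TSS: +5000
        hits = annotate_nearest_gene(binset([1]), annotation)
        gene, dist = hits[("chrT", 1)]
        assert gene in ("ALPHA", "BETA") and dist == 5000


class TestCoexpressionCorrelation:
    def make_result(self, importances):
        features = tuple(
            FeatureRecord(("chrT", i), imp, gene, 0)
            for i, (gene, imp) in enumerate(importances)
        )
        return InterpretationResult(("chrT", 99), 5000, 0.5, features)

    def test_proportional_gives_one(self):
        res = self.make_result([("A", 0.5), ("B", 0.3), ("C", 0.2)])
        coex = CoexpressionTable([("A", "Q", 0.5), ("B", "Q", 0.3), ("C", "Q", 0.2)])
        assert correlate_importance_coexpression(res, "Q", coex) == pytest.approx(1.0)

    def test_antiproportional_gives_minus_one(self):
        res = self.make_result([("A", 0.5), ("B", 0.3), ("C", 0.2)])
        coex = CoexpressionTable([("A", "Q", 0.1), ("B", "Q", 0.3), ("C", "Q", 0.4)])
        assert correlate_importance_coexpression(res, "Q", coex) == pytest.approx(-1.0)

    def test_duplicate_genes_aggregated(self):
        res = self.make_result([("A", 0.3), ("A", 0.2), ("B", 0.3), ("C", 0.2)])
        coex = CoexpressionTable([("A", "Q", 0.5), ("B", "Q", 0.3), ("C", "Q", 0.2)])
        assert correlate_importance_coexpression(res, "Q", coex) == pytest.approx(1.0)

    def test_missing_pairs_score_zero(self):
        res = self.make_result([("A", 0.5), ("B", 0.3), ("C", 0.2)])
        coex = CoexpressionTable([("A", "Q", 1.0)])
        r = correlate_importance_coexpression(res, "Q", coex)
        assert r is not None and r > 0

    def test_zero_variance_undefined(self):
        res = self.make_result([("A", 0.4), ("B", 0.4), ("C", 0.2)])
        coex = CoexpressionTable([])  # all scores 0 -> zero variance
        assert correlate_importance_coexpression(res, "Q", coex) is None

    def test_too_few_genes(self):
        res = self.make_result([("A", 0.6), ("B", 0.4)])
        with pytest.raises(ValueError, match=">= 3"):
            correlate_importance_coexpression(res, "Q", CoexpressionTable([]))


class TestPromoterScan:
    def test_coverage_fractions(self, tiny_reference, annotation):
        cells = [binset([0, 2]), binset([2, 3])]
        table = promoter_scan(
            tiny_reference, cells, ["ALPHA", "GAMMA"], annotation, seed=1, trees=5
        )
        alpha = table[table.gene == "ALPHA"].iloc[0]  # promoter bin 0
        assert alpha["coverage"] == 0.5
        gamma = table[table.gene == "GAMMA"].iloc[0]  # promoter bin 3
        assert gamma["coverage"] == 0.5

    def test_promoter_in_every_cell(self, tiny_reference, annotation):
        cells = [binset([0, 1]), binset([0, 2])]
        table = promoter_scan(
            tiny_reference, cells, ["ALPHA"], annotation, seed=1, trees=5
        )
        row = table.iloc[0]
        assert row["coverage"] == 1.0 and row["mean_probability"] == 1.0

    def test_unknown_gene_skipped_with_warning(self, tiny_reference, annotation):
        with pytest.warns(UserWarning, match="absent"):
            table = promoter_scan(
                tiny_reference, [binset([0])], ["NOSUCH"], annotation, seed=1
            )
        assert len(table) == 0

    def test_low_frequency_filter(self, tiny_reference, annotation):
        # promoter bins: ALPHA->0 (freq .5), BETA->2 (freq .5), GAMMA->3 (freq .5)
        table = promoter_scan(
            tiny_reference, [binset([1])], ["ALPHA", "BETA", "GAMMA"], annotation,
            seed=1, trees=5, max_reference_frequency=0.2,
        )
        assert len(table) == 0
        table = promoter_scan(
            tiny_reference, [binset([1])], ["ALPHA"], annotation,
            seed=1, trees=5, max_reference_frequency=0.6,
        )
        assert len(table) == 1


class TestGeneAnnotationValidation:
    def test_duplicate_symbols_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GeneAnnotation(
                pd.DataFrame(
                    {
                        "symbol": ["A", "A"],
                        "chrom": ["chr1", "chr1"],
                        "tss": [1, 2],
                        "strand": ["+", "+"],
                    }
                )
            )

    def test_tsv_round_trip(self, tmp_path, annotation):
        path = tmp_path / "genes.tsv"
        annotation.table.to_csv(path, sep="\t", index=False)
        back = GeneAnnotation.from_tsv(path)
        assert back.nearest("chrT", 2500) == ("ALPHA", 0)
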
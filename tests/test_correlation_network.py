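import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernet.correlation_network import (
    PAIR_LNCRNA_MRNA,
    PAIR_MIRNA_LNCRNA,
    PAIR_MIRNA_MRNA,
    CorrelationPair,
    assemble_cerna_triads,
    intersect_with_predictions,
    pearson_pairs,
    threshold_pairs,
)
from cernet.dataio import ExpressionMatrix, TargetPredictionTable


def matrix(rows, layer):
    df = pd.DataFrame(rows).T
    df.columns = [f"S{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df.astype(float), layer)


def predictions(pairs):
    rows = [(m, t, layer, 1) for m, t, layer in pairs]
    return TargetPredictionTable(pd.DataFrame(
        rows, columns=["mirna_id", "target_id", "target_layer", "n_sources"]))


class TestPearsonPairs:
    def test_perfect_anticorrelation(self):
        a = matrix({"m1": [1, 2, 3]}, "miRNA")
        b = matrix({"g1": [-1, -2, -3]}, "mRNA")
        (p,) = pearson_pairs(a, b, PAIR_MIRNA_MRNA)
        assert p.r == pytest.approx(-1.0)

    def test_hand_computed_r_and_p(self):
        # cov 1, variances 5/4 each -> r = 3/5; p from the exact t transform
        a = matrix({"m1": [1, 2, 3, 4]}, "miRNA")
        b = matrix({"g1": [2, 1, 4, 3]}, "mRNA")
        (p,) = pearson_pairs(a, b, PAIR_MIRNA_MRNA)
        assert p.r == pytest.approx(0.6)
        ref = stats.pearsonr([1, 2, 3, 4], [2, 1, 4, 3])
        assert p.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_row_skipped(self):
        a = matrix({"m1": [5, 5, 5, 5], "m2": [1, 2, 3, 4]}, "miRNA")
        b = matrix({"g1": [2, 1, 4, 3]}, "mRNA")
        pairs = pearson_pairs(a, b, PAIR_MIRNA_MRNA)
        assert [p.source_id for p in pairs] == ["m2"]

    def test_symmetry(self, small_cohort):
        a = ExpressionMatrix(small_cohort.mirna.values.iloc[:5],
                             "miRNA")
        b = ExpressionMatrix(small_cohort.mrna.values.iloc[:5], "mRNA")
        fwd = {(p.source_id, p.target_id): p.r
               for p in pearson_pairs(a, b, PAIR_MIRNA_MRNA)}
        rev = {(p.target_id, p.source_id): p.r
               for p in pearson_pairs(b, a, PAIR_LNCRNA_MRNA)}
        for key, r in fwd.items():
            assert rev[key] == pytest.approx(r, abs=1e-12)

    def test_fdr_is_bh_over_pairs(self):
        rng = np.random.default_rng(4)
        a = matrix({f"m{i}": rng.normal(size=8) for i in range(4)}, "miRNA")
        b = matrix({f"g{i}": rng.normal(size=8) for i in range(3)}, "mRNA")
        pairs = pearson_pairs(a, b, PAIR_MIRNA_MRNA)
        from cernet.differential import bh_adjust

        np.testing.assert_allclose([p.fdr for p in pairs],
                                   bh_adjust([p.p for p in pairs]))

    def test_too_few_samples(self):
        a = matrix({"m1": [1, 2]}, "miRNA")
        b = matrix({"g1": [2, 1]}, "mRNA")
        with pytest.raises(ValueError):
            pearson_pairs(a, b, PAIR_MIRNA_MRNA)


class TestThresholdPairs:
    def _pair(self, r, p, pair_type=PAIR_MIRNA_MRNA):
        return CorrelationPair("s", "t", pair_type, r, p)

    @pytest.mark.parametrize("pair_type,r,p,kept", [
        (PAIR_MIRNA_MRNA, -0.6, 0.01, True),
        (PAIR_MIRNA_MRNA, -0.5, 0.001, False),   # boundary is strict
        (PAIR_MIRNA_MRNA, 0.9, 0.001, False),    # positive never kept
        (PAIR_MIRNA_MRNA, -0.6, 0.06, False),
        (PAIR_MIRNA_LNCRNA, 0.7, 0.02, True),    # either sign for lncRNA
        (PAIR_MIRNA_LNCRNA, -0.7, 0.02, True),
        (PAIR_MIRNA_LNCRNA, 0.5, 0.001, False),
        (PAIR_LNCRNA_MRNA, 0.7, 0.01, True),
        (PAIR_LNCRNA_MRNA, -0.7, 0.01, False),   # only positive confirmation
    ])
    def test_rules(self, pair_type, r, p, kept):
        out = threshold_pairs([self._pair(r, p, pair_type)], pair_type)
        assert bool(out) is kept

    def test_alpha_on_fdr(self):
        pair = CorrelationPair("s", "t", PAIR_MIRNA_MRNA, -0.9, 0.01, 0.2)
        assert threshold_pairs([pair], PAIR_MIRNA_MRNA, alpha_on="p")
        assert not threshold_pairs([pair], PAIR_MIRNA_MRNA, alpha_on="fdr")

    def test_unknown_pair_type(self):
        with pytest.raises(ValueError):
            threshold_pairs([], "mirna_circ")


class TestIntersectWithPredictions:
    def test_kept_and_dropped(self):
        pairs = [CorrelationPair("M1", "G1", PAIR_MIRNA_MRNA, -0.7, 0.01),
                 CorrelationPair("M1", "G2", PAIR_MIRNA_MRNA, -0.8, 0.01)]
        out = intersect_with_predictions(pairs, predictions([("M1", "G1", "mRNA")]))
        assert [(p.source_id, p.target_id) for p in out] == [("M1", "G1")]
        assert out[0].predicted

    def test_empty_prediction_table_gives_empty_output(self):
        pairs = [CorrelationPair("M1", "G1", PAIR_MIRNA_MRNA, -0.7, 0.01)]
        empty = TargetPredictionTable(pd.DataFrame(
            columns=["mirna_id", "target_id", "target_layer", "n_sources"]))
        assert intersect_with_predictions(pairs, empty) == []


class TestAssembleTriads:
    def _edge(self, src, tgt, pair_type, r, predicted=True):
        return CorrelationPair(src, tgt, pair_type, r, 0.01, 0.02, predicted)

    def test_basic_triad(self):
        mm = [self._edge("M1", "G1", PAIR_MIRNA_MRNA, -0.7)]
        ml = [self._edge("M1", "L1", PAIR_MIRNA_LNCRNA, -0.8)]
        (t,) = assemble_cerna_triads(mm, ml)
        assert (t.lncrna_id, t.mirna_id, t.mrna_id) == ("L1", "M1", "G1")

    def test_positive_lncrna_edge_blocks_triad(self):
        mm = [self._edge("M1", "G1", PAIR_MIRNA_MRNA, -0.7)]
        ml = [self._edge("M1", "L1", PAIR_MIRNA_LNCRNA, 0.6)]
        assert assemble_cerna_triads(mm, ml) == []

    def test_unpredicted_edge_blocks_triad(self):
        mm = [self._edge("M1", "G1", PAIR_MIRNA_MRNA, -0.7, predicted=False)]
        ml = [self._edge("M1", "L1", PAIR_MIRNA_LNCRNA, -0.8)]
        assert assemble_cerna_triads(mm, ml) == []

    def test_cross_product_count(self):
        mm = [self._edge("M1", g, PAIR_MIRNA_MRNA, -0.7)
              for g in ("G1", "G2", "G3")]
        ml = [self._edge("M1", l, PAIR_MIRNA_LNCRNA, -0.8) for l in ("L1", "L2")]
        triads = assemble_cerna_triads(mm, ml)
        assert len(triads) == 6
        # brute-force cross product oracle
        expected = {(l, "M1", g) for l in ("L1", "L2")
                    for g in ("G1", "G2", "G3")}
        assert {(t.lncrna_id, t.mirna_id, t.mrna_id) for t in triads} == expected

    def test_lncrna_mrna_confirmation_edge(self):
        mm = [self._edge("M1", "G1", PAIR_MIRNA_MRNA, -0.7)]
        ml = [self._edge("M1", "L1", PAIR_MIRNA_LNCRNA, -0.8)]
        lm = [self._edge("L1", "G1", PAIR_LNCRNA_MRNA, 0.9)]
        assert assemble_cerna_triads(mm, ml, lm, require_lncrna_mrna_edge=True)
        assert not assemble_cerna_triads(mm, ml, [], require_lncrna_mrna_edge=True)

    def test_sorted_output(self):
        mm = [self._edge("M2", "G1", PAIR_MIRNA_MRNA, -0.7),
              self._edge("M1", "G2", PAIR_MIRNA_MRNA, -0.7)]
        ml = [self._edge("M2", "L1", PAIR_MIRNA_LNCRNA, -0.8),
              self._edge("M1", "L2", PAIR_MIRNA_LNCRNA, -0.8)]
        triads = assemble_cerna_triads(mm, ml)
        keys = [(t.mirna_id, t.lncrna_id, t.mrna_id) for t in triads]
        assert keys == sorted(keys)


class TestBruteForceOracle:
    def test_small_matrices_match_exhaustive_recomputation(self, small_cohort):
        """The vectorized pipeline equals a per-pair scipy recomputation on
        <=10 features per layer, including thresholding, prediction support
        and triad enumeration."""
        truth = small_cohort.truth
        lnc0, mir0, gene0 = truth.triads[0]
        mir_ids = [mir0] + [f for f in small_cohort.mirna.feature_ids
                            if f != mir0][:7]
        gene_ids = [gene0] + [f for f in small_cohort.mrna.feature_ids
                              if f != gene0][:7]
        lnc_ids = [lnc0] + [f for f in small_cohort.lncrna.feature_ids
                            if f != lnc0][:7]
        mi = small_cohort.mirna.subset_features(mir_ids)
        mr = small_cohort.mrna.subset_features(gene_ids)
        ln = small_cohort.lncrna.subset_features(lnc_ids)
        preds = predictions([(mir0, gene0, "mRNA"), (mir0, lnc0, "lncRNA")])

        mm = intersect_with_predictions(
            threshold_pairs(pearson_pairs(mi, mr, PAIR_MIRNA_MRNA),
                            PAIR_MIRNA_MRNA), preds)
        ml = intersect_with_predictions(
            threshold_pairs(pearson_pairs(mi, ln, PAIR_MIRNA_LNCRNA),
                            PAIR_MIRNA_LNCRNA), preds)
        got = {(t.lncrna_id, t.mirna_id, t.mrna_id)
               for t in assemble_cerna_triads(mm, ml)}

        # independent exhaustive recomputation
        pred_pairs = {(mir0, gene0), (mir0, lnc0)}
        def ok_neg(x, y):
            r, p = stats.pearsonr(x, y)
            return r < -0.5 and p < 0.05
        expected = set()
        for m, l, g in itertools.product(mir_ids, lnc_ids, gene_ids):
            if (m, g) in pred_pairs and (m, l) in pred_pairs:
                xm = small_cohort.mirna.values.loc[m]
                if (ok_neg(xm, small_cohort.mrna.values.loc[g])
                        and ok_neg(xm, small_cohort.lncrna.values.loc[l])):
                    expected.add((l, m, g))
        assert got == expected
        assert (lnc0, mir0, gene0) in got

    def test_triad_referential_integrity(self, small_cohort):
        mi, mr, ln = (small_cohort.mirna, small_cohort.mrna, small_cohort.lncrna)
        preds = predictions(
            [(m, g, "mRNA") for _, m, g in small_cohort.truth.triads]
            + [(m, l, "lncRNA") for l, m, _ in small_cohort.truth.triads])
        mm = intersect_with_predictions(
            threshold_pairs(pearson_pairs(mi, mr, PAIR_MIRNA_MRNA),
                            PAIR_MIRNA_MRNA), preds)
        ml = intersect_with_predictions(
            threshold_pairs(pearson_pairs(mi, ln, PAIR_MIRNA_LNCRNA),
                            PAIR_MIRNA_LNCRNA), preds)
        mm_keys = {(p.source_id, p.target_id) for p in mm}
        ml_keys = {(p.source_id, p.target_id) for p in ml}
        for t in assemble_cerna_triads(mm, ml):
            assert (t.mirna_id, t.mrna_id) in mm_keys
            assert (t.mirna_id, t.lncrna_id) in ml_keys
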